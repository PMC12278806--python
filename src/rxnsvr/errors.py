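"""Exception hierarchy shared across the package."""


class RxnSvrError(Exception):
    """Base class for all package errors."""


class ParseError(RxnSvrError, ValueError):
    """A SMILES/SMARTS string could not be parsed."""


class ContractError(RxnSvrError, ValueError):
    """An operation was called with arguments violating its contract."""


class ConfigurationError(RxnSvrError, ValueError):
    """A run configuration is inconsistent or infeasible."""
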