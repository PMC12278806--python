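"""Epsilon-insensitive SVR over the composite kernels, with grid-search CV.

The solver is libsvm's epsilon-SVR on a precomputed kernel matrix; the
hyperparameters C and epsilon are chosen by 5-fold cross-validated R² over a
grid, with a fixed fold assignment shared across all grid cells (shuffled
once from ``cv_seed``) and ties broken toward smaller C, then smaller
epsilon. The refit dual solution — support-vector fingerprints, dual
coefficients (alpha_i − alpha_i*) and intercept b — is exposed directly
because the fast screening path consumes it: the prediction for a reactant
pair (x1, x2) is

    y_hat = sum_i coef_i * K_T(x1, sv1_i) * K_T(x2, sv2_i) + b

for the product kernel, and the analogous expansion for the other kinds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from . import chem
from .chem import BitFingerprint
from .errors import ConfigurationError, ContractError
from .kernels import FingerprintPair, KernelSpec, gram
from .templates import ReactionRecord

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0, 1000.0)
DEFAULT_EPSILON_GRID = (0.01, 0.05, 0.1, 0.5, 1.0)


@dataclass(frozen=True)
class SVRConfig:
    """Hyperparameter search settings for :func:`train`."""

    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    epsilon_grid: tuple[float, ...] = DEFAULT_EPSILON_GRID
    cv_folds: int = 5
    cv_seed: int = 0
    scoring: str = "r2"

    def __post_init__(self) -> None:
        if not self.c_grid or not self.epsilon_grid:
            raise ConfigurationError("hyperparameter grids must be non-empty")
        if any(c <= 0 for c in self.c_grid) or any(e <= 0 for e in self.epsilon_grid):
            raise ConfigurationError("C and epsilon values must be positive")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if self.scoring != "r2":
            raise ConfigurationError(f"unsupported scoring {self.scoring!r}")


@dataclass
class TrainedSVR:
    """Dual solution of a fitted SVR, sufficient for bit-exact prediction."""

    kernel: KernelSpec
    dual_coefs: np.ndarray  # (nSV,), alpha_i - alpha_i*
    intercept: float
    chosen_c: float
    chosen_epsilon: float
    sv_fp1: list[BitFingerprint] = field(default_factory=list)
    sv_fp2: list[BitFingerprint] = field(default_factory=list)
    sv_fp_product: list[BitFingerprint] = field(default_factory=list)
    cv_score: float = float("nan")

    @property
    def n_sv(self) -> int:
        return len(self.dual_coefs)

    def sv_pairs(self) -> list[FingerprintPair]:
        return list(zip(self.sv_fp1, self.sv_fp2))


def featurize_pairs(
    records: Sequence[ReactionRecord], n_bits: int
) -> list[FingerprintPair]:
    """Marked-reactant fingerprint pairs, one per record."""
    return [
        (chem.ecfp4(r.pair.r1, n_bits), chem.ecfp4(r.pair.r2, n_bits))
        for r in records
    ]


def featurize_products(
    records: Sequence[ReactionRecord], n_bits: int
) -> list[BitFingerprint]:
    """Unmarked product fingerprints, one per record (baseline model input)."""
    return [chem.ecfp4(r.product, n_bits) for r in records]


def _featurize(records: Sequence[ReactionRecord], spec: KernelSpec):
    if spec.is_pair:
        return featurize_pairs(records, spec.n_bits)
    return featurize_products(records, spec.n_bits)


def train(
    records: Sequence[ReactionRecord],
    spec: KernelSpec,
    config: SVRConfig = SVRConfig(),
) -> TrainedSVR:
    """Grid-search CV then refit on all records; returns the dual solution.

    The full training kernel matrix is computed once and sliced per fold, so
    every grid cell sees the identical fold assignment.
    """
    if len(records) < config.cv_folds:
        raise ConfigurationError(
            f"{len(records)} records but {config.cv_folds}-fold CV requested"
        )
    y = np.asarray([r.y for r in records], dtype=np.float64)
    X = _featurize(records, spec)
    K = gram(X, X, spec)

    folds = list(
        KFold(
            n_splits=config.cv_folds, shuffle=True, random_state=config.cv_seed
        ).split(K)
    )
    best: tuple[float, float, float] | None = None  # (score, C, eps)
    for c in sorted(config.c_grid):
        for eps in sorted(config.epsilon_grid):
            scores = []
            for tr, te in folds:
                est = SVR(kernel="precomputed", C=c, epsilon=eps)
                est.fit(K[np.ix_(tr, tr)], y[tr])
                pred = est.predict(K[np.ix_(te, tr)])
                if np.allclose(y[te], y[te][0]):
                    continue  # R^2 undefined on a constant fold
                scores.append(r2_score(y[te], pred))
            mean = float(np.mean(scores)) if scores else float("-inf")
            # strict improvement only: earlier (smaller C, then smaller
            # epsilon) wins ties
            if best is None or mean > best[0] + 1e-12:
                best = (mean, c, eps)
    assert best is not None
    cv_score, chosen_c, chosen_eps = best

    est = SVR(kernel="precomputed", C=chosen_c, epsilon=chosen_eps)
    est.fit(K, y)
    sv_idx = est.support_
    model = TrainedSVR(
        kernel=spec,
        dual_coefs=est.dual_coef_.ravel().astype(np.float64),
        intercept=float(est.intercept_[0]),
        chosen_c=chosen_c,
        chosen_epsilon=chosen_eps,
        cv_score=cv_score,
    )
    if spec.is_pair:
        model.sv_fp1 = [X[i][0] for i in sv_idx]
        model.sv_fp2 = [X[i][1] for i in sv_idx]
    else:
        model.sv_fp_product = [X[i] for i in sv_idx]
    return model


def predict(model: TrainedSVR, pairs: Sequence[FingerprintPair]) -> np.ndarray:
    """Dual-expansion prediction for reactant-pair inputs.

    A degenerate fit with no support vectors (constant target inside the
    epsilon tube) predicts the bare intercept.
    """
    if not model.kernel.is_pair:
        raise ContractError("pair input passed to a product-fingerprint model")
    if model.n_sv == 0:
        return np.full(len(pairs), model.intercept)
    K = gram(list(pairs), model.sv_pairs(), model.kernel)
    return K @ model.dual_coefs + model.intercept


def predict_products(
    model: TrainedSVR, products: Sequence[BitFingerprint]
) -> np.ndarray:
    """Dual-expansion prediction for product-fingerprint (baseline) inputs."""
    if model.kernel.is_pair:
        raise ContractError("product input passed to a pair-kernel model")
    if model.n_sv == 0:
        return np.full(len(products), model.intercept)
    K = gram(list(products), model.sv_fp_product, model.kernel)
    return K @ model.dual_coefs + model.intercept


def predict_product_averaged(
    model: TrainedSVR, groups: Mapping[str, Sequence[FingerprintPair]]
) -> dict[str, float]:
    """Mean per-pair prediction for each product.

    Different reactant pairs that assemble the same product are averaged to
    one value per product, so reactant- and product-based models can be
    compared on identical evaluation sets.
    """
    out: dict[str, float] = {}
    for product_id, pairs in groups.items():
        if len(pairs) == 0:
            raise ContractError(f"empty pair group for product {product_id!r}")
        out[product_id] = float(np.mean(predict(model, list(pairs))))
    return out


# --- serialization ----------------------------------------------------------

def _fp_to_json(fp: BitFingerprint) -> list[int]:
    return list(fp.on_bits)


def save_model(model: TrainedSVR, path: str | Path) -> None:
    """Write the model as JSON (on-bit lists, coefficients, intercept, kernel)."""
    payload = {
        "kernel_kind": model.kernel.kind,
        "n_bits": model.kernel.n_bits,
        "dual_coefs": [float(c) for c in model.dual_coefs],
        "intercept": model.intercept,
        "chosen_c": model.chosen_c,
        "chosen_epsilon": model.chosen_epsilon,
        "cv_score": model.cv_score,
        "sv_fp1": [_fp_to_json(f) for f in model.sv_fp1],
        "sv_fp2": [_fp_to_json(f) for f in model.sv_fp2],
        "sv_fp_product": [_fp_to_json(f) for f in model.sv_fp_product],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedSVR:
    payload = json.loads(Path(path).read_text())
    n_bits = int(payload["n_bits"])
    fp = lambda bits: BitFingerprint(on_bits=tuple(bits), n_bits=n_bits)  # noqa: E731
    return TrainedSVR(
        kernel=KernelSpec(kind=payload["kernel_kind"], n_bits=n_bits),
        dual_coefs=np.asarray(payload["dual_coefs"], dtype=np.float64),
        intercept=float(payload["intercept"]),
        chosen_c=float(payload["chosen_c"]),
        chosen_epsilon=float(payload["chosen_epsilon"]),
        cv_score=float(payload["cv_score"]),
        sv_fp1=[fp(b) for b in payload["sv_fp1"]],
        sv_fp2=[fp(b) for b in payload["sv_fp2"]],
        sv_fp_product=[fp(b) for b in payload["sv_fp_product"]],
    )
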