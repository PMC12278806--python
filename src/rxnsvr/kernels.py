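"""Tanimoto kernel and reactant-wise composite kernels.

The central object is the product kernel over a pair of reactants,

    K((x1_a, x2_a), (x1_b, x2_b)) = K_T(x1_a, x1_b) * K_T(x2_a, x2_b),

with K_T the Tanimoto (Jaccard) similarity on fingerprint on-bit sets. Two
comparison kernels are provided: the sum of the component Tanimoto kernels
(range [0, 2]) and the Tanimoto kernel of the concatenated component
fingerprints. All three are positive semidefinite (products and sums of PSD
kernels are PSD; concatenation is a Tanimoto kernel on a wider bit vector).

Empty-fingerprint convention: tanimoto(∅, ∅) = 1 and tanimoto(∅, x≠∅) = 0,
preserving k(x, x) = 1 and avoiding 0/0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .chem import DEFAULT_N_BITS, BitFingerprint
from .errors import ContractError

KernelKind = Literal["single_tanimoto", "product", "sum", "concat"]

#: Kernel kinds operating on reactant pairs (everything but the product-
#: fingerprint baseline).
PAIR_KINDS = ("product", "sum", "concat")


@dataclass(frozen=True)
class KernelSpec:
    """Which composite kernel a model uses, and the fingerprint width."""

    kind: KernelKind
    n_bits: int = DEFAULT_N_BITS

    def __post_init__(self) -> None:
        if self.kind not in ("single_tanimoto",) + PAIR_KINDS:
            raise ContractError(f"unknown kernel kind: {self.kind!r}")

    @property
    def is_pair(self) -> bool:
        return self.kind in PAIR_KINDS

    @property
    def upper_bound(self) -> float:
        return 2.0 if self.kind == "sum" else 1.0


FingerprintPair = tuple[BitFingerprint, BitFingerprint]


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| of two equal-width fingerprints."""
    if a.n_bits != b.n_bits:
        raise ContractError(f"fingerprint widths differ: {a.n_bits} vs {b.n_bits}")
    sa, sb = a.as_set(), b.as_set()
    union = len(sa | sb)
    if union == 0:
        return 1.0
    return len(sa & sb) / union


def pack(fps: Sequence[BitFingerprint]) -> np.ndarray:
    """Stack fingerprints into a dense (n, n_bits) float32 0/1 matrix."""
    if not fps:
        raise ContractError("cannot pack an empty fingerprint list")
    n_bits = fps[0].n_bits
    dense = np.zeros((len(fps), n_bits), dtype=np.float32)
    for row, fp in enumerate(fps):
        if fp.n_bits != n_bits:
            raise ContractError("mixed fingerprint widths in one batch")
        if fp.on_bits:
            dense[row, list(fp.on_bits)] = 1.0
    return dense


def tanimoto_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto matrix between rows of two dense 0/1 matrices.

    Empty-vs-empty rows score 1, empty-vs-nonempty 0.
    """
    # popcounts fit exactly in float32, so the matmul is exact; divide in
    # float64 to keep full precision
    inter = (A @ B.T).astype(np.float64)
    ca = A.sum(axis=1, dtype=np.float64)
    cb = B.sum(axis=1, dtype=np.float64)
    union = ca[:, None] + cb[None, :] - inter
    out = np.zeros_like(inter)
    both_empty = (ca[:, None] == 0) & (cb[None, :] == 0)
    np.divide(inter, union, out=out, where=union > 0)
    out[both_empty] = 1.0
    return out


def _concat(p: FingerprintPair) -> BitFingerprint:
    f1, f2 = p
    n = f1.n_bits
    return BitFingerprint(
        on_bits=tuple(f1.on_bits) + tuple(b + n for b in f2.on_bits),
        n_bits=2 * n,
    )


def pair_kernel(p: FingerprintPair, q: FingerprintPair, spec: KernelSpec) -> float:
    """Composite kernel value between two reactant pairs.

    product: K_T1 * K_T2 in [0, 1]; sum: K_T1 + K_T2 in [0, 2];
    concat: Tanimoto of the concatenated 2*n_bits vectors in [0, 1].
    """
    if not spec.is_pair:
        raise ContractError("pair_kernel requires a pair kernel kind")
    if spec.kind == "concat":
        return tanimoto(_concat(p), _concat(q))
    k1 = tanimoto(p[0], q[0])
    k2 = tanimoto(p[1], q[1])
    return k1 * k2 if spec.kind == "product" else k1 + k2


def gram(
    X: Sequence[FingerprintPair] | Sequence[BitFingerprint],
    Y: Sequence[FingerprintPair] | Sequence[BitFingerprint],
    spec: KernelSpec,
) -> np.ndarray:
    """Kernel matrix with entry (i, j) = k(X[i], Y[j]) under ``spec``.

    For ``single_tanimoto`` the inputs are plain product fingerprints; for
    the pair kinds they are (component-1, component-2) fingerprint tuples.
    """
    if len(X) == 0 or len(Y) == 0:
        raise ContractError("gram requires non-empty inputs")
    if spec.kind == "single_tanimoto":
        return tanimoto_matrix(pack(list(X)), pack(list(Y)))
    if spec.kind == "concat":
        return tanimoto_matrix(
            pack([_concat(p) for p in X]), pack([_concat(q) for q in Y])
        )
    K1 = tanimoto_matrix(pack([p[0] for p in X]), pack([q[0] for q in Y]))
    K2 = tanimoto_matrix(pack([p[1] for p in X]), pack([q[1] for q in Y]))
    return K1 * K2 if spec.kind == "product" else K1 + K2
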