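"""Fast exhaustive scoring of all reactant combinations from two pools.

The product kernel factorizes over reactant components, so screening
n1 x n2 combinations does not require assembling any molecule: one Tanimoto
table per component between the model's support vectors and the candidates
(nSV x n1 and nSV x n2) is precomputed, after which the prediction for a
combination (c1, c2) is a single weighted inner product

    y_hat(c1, c2) = sum_i coef_i * T1[i, c1] * T2[i, c2] + b,

i.e. 2*nSV multiplications, nSV-1 additions and one intercept addition per
combination. The scorer enumerates the full grid in column chunks and keeps
a bounded best-k set, so memory stays at O(nSV * chunk + top_k) regardless
of grid size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import chem, models
from .chem import BitFingerprint, MoleculeRef
from .datasets import passes_eligibility
from .errors import ContractError
from .kernels import pack, tanimoto_matrix
from .templates import (
    RetroTemplate,
    dissect_product,
    forward_products,
)

logger = logging.getLogger(__name__)


@dataclass
class ComponentKernelTable:
    """Tanimoto values between every support vector and every candidate."""

    component: int  # 1 or 2
    values: np.ndarray  # (nSV, nCandidates)
    candidate_ids: list[str]

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.candidate_ids):
            raise ContractError("kernel table column count != candidate count")


@dataclass(frozen=True)
class ScoredCombination:
    """One scored (component-1, component-2) candidate combination."""

    idx1: int
    idx2: int
    y_hat: float


def build_tables(
    model: models.TrainedSVR,
    cands1: Sequence[BitFingerprint],
    cands2: Sequence[BitFingerprint],
    candidate_ids1: Sequence[str] | None = None,
    candidate_ids2: Sequence[str] | None = None,
) -> tuple[ComponentKernelTable, ComponentKernelTable]:
    """Per-component support-vector x candidate Tanimoto tables.

    The factorized fast path is specific to the product kernel; any other
    kernel kind is rejected.
    """
    if model.kernel.kind != "product":
        raise ContractError(
            f"fast screening requires the product kernel, got {model.kernel.kind!r}"
        )
    if len(cands1) == 0 or len(cands2) == 0:
        raise ContractError("candidate lists must be non-empty")
    ids1 = list(candidate_ids1 or (str(i) for i in range(len(cands1))))
    ids2 = list(candidate_ids2 or (str(i) for i in range(len(cands2))))
    t1 = tanimoto_matrix(pack(model.sv_fp1), pack(list(cands1)))
    t2 = tanimoto_matrix(pack(model.sv_fp2), pack(list(cands2)))
    return (
        ComponentKernelTable(component=1, values=t1, candidate_ids=ids1),
        ComponentKernelTable(component=2, values=t2, candidate_ids=ids2),
    )


def score_all(
    model: models.TrainedSVR,
    tables: tuple[ComponentKernelTable, ComponentKernelTable],
    top_k: int = 10_000,
    chunk: int = 256,
) -> list[ScoredCombination]:
    """Global top-k combinations by predicted activity, exactly.

    All n1*n2 combinations are enumerated in chunks of at most ``chunk``
    component-1 columns; the result is the exact global top ``top_k`` in
    descending y_hat with ties broken by ascending (idx1, idx2). The output
    is identical for any chunk size >= 1.
    """
    if top_k < 1:
        raise ContractError("top_k must be >= 1")
    if chunk < 1:
        raise ContractError("chunk must be >= 1")
    t1, t2 = tables[0].values, tables[1].values
    if t1.shape[0] != model.n_sv or t2.shape[0] != model.n_sv:
        raise ContractError("tables do not match the model's support vectors")
    coefs = model.dual_coefs
    n1, n2 = t1.shape[1], t2.shape[1]
    top_k = min(top_k, n1 * n2)

    # running best-k buffers
    best_y = np.empty(0, dtype=np.float64)
    best_i1 = np.empty(0, dtype=np.int64)
    best_i2 = np.empty(0, dtype=np.int64)
    logger.info("scoring %d x %d = %d combinations", n1, n2, n1 * n2)
    for start in range(0, n1, chunk):
        stop = min(start + chunk, n1)
        # (chunk, n2) block of predictions
        block = (t1[:, start:stop] * coefs[:, None]).T @ t2 + model.intercept
        flat = block.ravel()
        i1 = np.repeat(np.arange(start, stop, dtype=np.int64), n2)
        i2 = np.tile(np.arange(n2, dtype=np.int64), stop - start)
        if flat.size > top_k:
            # cheap pre-selection; exact ordering is restored below
            keep = np.argpartition(-flat, top_k - 1)[:top_k]
            flat, i1, i2 = flat[keep], i1[keep], i2[keep]
        best_y = np.concatenate([best_y, flat])
        best_i1 = np.concatenate([best_i1, i1])
        best_i2 = np.concatenate([best_i2, i2])
        order = np.lexsort((best_i2, best_i1, -best_y))[:top_k]
        best_y, best_i1, best_i2 = best_y[order], best_i1[order], best_i2[order]
    return [
        ScoredCombination(idx1=int(a), idx2=int(b), y_hat=float(y))
        for a, b, y in zip(best_i1, best_i2, best_y)
    ]


def score_one_instrumented(
    model: models.TrainedSVR,
    tables: tuple[ComponentKernelTable, ComponentKernelTable],
    idx1: int,
    idx2: int,
) -> tuple[float, dict[str, int]]:
    """Scalar scorer that counts its arithmetic operations.

    Returns (y_hat, counts) where counts tallies multiplications and
    additions: 2*nSV multiplications, nSV-1 summation additions and one
    intercept addition per combination.
    """
    t1 = tables[0].values[:, idx1]
    t2 = tables[1].values[:, idx2]
    coefs = model.dual_coefs
    mults = adds = 0
    acc = 0.0
    for i in range(model.n_sv):
        term = coefs[i] * t1[i]
        mults += 1
        term = term * t2[i]
        mults += 1
        if i == 0:
            acc = term
        else:
            acc = acc + term
            adds += 1
    acc = acc + model.intercept
    adds += 1
    return float(acc), {"mult": mults, "add": adds, "total": mults + adds}


def ad_filter(
    model: models.TrainedSVR,
    candidates: Sequence[BitFingerprint],
    component: int,
    threshold: float,
) -> list[int]:
    """Applicability-domain pre-filter on one candidate pool.

    Keeps (returns the indices of) candidates whose maximum Tanimoto
    similarity to any support vector of the given component reaches
    ``threshold``; dissimilar candidates yield near-random predictions and
    can be dropped before combination.
    """
    if not 0 <= threshold <= 1:
        raise ContractError("threshold must be in [0, 1]")
    if component not in (1, 2):
        raise ContractError("component must be 1 or 2")
    svs = model.sv_fp1 if component == 1 else model.sv_fp2
    sims = tanimoto_matrix(pack(svs), pack(list(candidates)))
    keep = sims.max(axis=0) >= threshold
    return [i for i, k in enumerate(keep) if k]


def eligibility_filter(products: Sequence[MoleculeRef]) -> list[MoleculeRef]:
    """Keep products passing the element / MW / ring-size rules."""
    return [p for p in products if passes_eligibility(p)]


@dataclass
class FocusedLibraryEntry:
    """One ranked virtual product surviving the two-stage workflow."""

    rank: int
    idx1: int
    idx2: int
    y_hat_pk: float
    y_hat_baseline: float
    product: MoleculeRef
    passed_filters: bool


def focused_library(
    pk_model: models.TrainedSVR,
    baseline_model: models.TrainedSVR,
    cands1: Sequence[MoleculeRef],
    cands2: Sequence[MoleculeRef],
    template: RetroTemplate,
    stage1_k: int = 1_000_000,
    stage2_k: int = 10_000,
    chunk: int = 256,
) -> list[FocusedLibraryEntry]:
    """Two-stage focused-library workflow.

    Stage 1 ranks all reactant combinations with the product-kernel model
    and keeps the top ``stage1_k``; their products are assembled by forward
    template application and reranked by the product-based baseline model,
    keeping ``stage2_k``. Survivors are then checked against the structural
    eligibility rules and the template round-trip (dissection must
    regenerate the pair); entries failing either check are returned with
    ``passed_filters=False``. Pairs whose assembly fails are dropped and
    counted in a log summary.
    """
    fps1 = [chem.ecfp4(m, pk_model.kernel.n_bits) for m in cands1]
    fps2 = [chem.ecfp4(m, pk_model.kernel.n_bits) for m in cands2]
    tables = build_tables(pk_model, fps1, fps2)
    stage1 = score_all(pk_model, tables, top_k=stage1_k, chunk=chunk)

    assembled: list[tuple[ScoredCombination, MoleculeRef]] = []
    failures = 0
    for combo in stage1:
        prods = forward_products(
            template, cands1[combo.idx1].mol(), cands2[combo.idx2].mol()
        )
        if not prods:
            failures += 1
            continue
        assembled.append((combo, prods[0]))
    if failures:
        logger.warning("%d of %d pairs failed forward assembly", failures, len(stage1))

    base_preds = models.predict_products(
        baseline_model,
        [chem.ecfp4(p, baseline_model.kernel.n_bits) for _, p in assembled],
    )
    order = np.lexsort(
        (
            [c.idx2 for c, _ in assembled],
            [c.idx1 for c, _ in assembled],
            -base_preds,
        )
    )[:stage2_k]

    out: list[FocusedLibraryEntry] = []
    for rank, pos in enumerate(order, start=1):
        combo, product = assembled[pos]
        ok = passes_eligibility(product)
        if ok:
            pairs = dissect_product(product, template)
            ok = any(
                (p.unmarked()[0].smiles, p.unmarked()[1].smiles)
                == (cands1[combo.idx1].smiles, cands2[combo.idx2].smiles)
                for p in pairs
            )
        out.append(
            FocusedLibraryEntry(
                rank=rank,
                idx1=combo.idx1,
                idx2=combo.idx2,
                y_hat_pk=combo.y_hat,
                y_hat_baseline=float(base_preds[pos]),
                product=product,
                passed_filters=ok,
            )
        )
    return out
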