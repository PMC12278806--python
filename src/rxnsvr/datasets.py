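"""Reaction-dataset curation and train/test splitting strategies.

Curation applies, in order: an element whitelist (C, N, O, F, S, P, Cl, Br,
I, implicit H) per reactant, molecular weight <= 800 per reactant, all SSSR
ring sizes <= 7, a per-component heavy-atom-count outlier fence at 1.5x the
interquartile range, and a minimum dataset size (100 by default).

Two splitting strategies target different generalization questions:
product-based splitting (random 6:4 over unique products, then removal of
test products too similar to any training product) allows reactants to be
shared across the split; reactant-based splitting arranges the reactants of
each component on a frequency-ordered grid and cuts it into a lower-left
training block and an upper-right test block with no shared reactant on
either axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from . import chem
from .chem import MoleculeRef
from .errors import ConfigurationError
from .kernels import tanimoto
from .templates import ReactionRecord

ALLOWED_ELEMENTS = frozenset({"C", "N", "O", "F", "S", "P", "Cl", "Br", "I", "H"})
MAX_MOLECULAR_WEIGHT = 800.0
MAX_RING_SIZE = 7
MIN_DATASET_SIZE = 100


@dataclass
class SplitResult:
    """Partition of a reaction dataset into train / test / discarded."""

    train: list[ReactionRecord]
    test: list[ReactionRecord]
    discarded: list[ReactionRecord]
    strategy: str  # {"product_based", "reactant_based"}

    def assignments(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for name in ("train", "test", "discarded"):
            for rec in getattr(self, name):
                out[rec.record_id] = name
        return out


def _passes_structure_rules(mol: Chem.Mol) -> bool:
    if any(a.GetSymbol() not in ALLOWED_ELEMENTS for a in mol.GetAtoms()):
        return False
    if Descriptors.MolWt(mol) > MAX_MOLECULAR_WEIGHT:
        return False
    return all(
        len(ring) <= MAX_RING_SIZE for ring in mol.GetRingInfo().AtomRings()
    )


def passes_eligibility(mol: MoleculeRef) -> bool:
    """Element whitelist, MW <= 800 and all SSSR ring sizes <= 7.

    Reaction-site isotope marks are ignored: the rules judge the chemical
    structure, not the 1000/900 labels (which would dominate the weight).
    """
    if mol.marked:
        mol = chem.strip_site_marks(mol)
    return _passes_structure_rules(mol.mol())


def _heavy_atom_fence(counts: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.percentile(counts, [25, 75])
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def curate(
    records: Sequence[ReactionRecord], min_size: int = MIN_DATASET_SIZE
) -> list[ReactionRecord]:
    """Apply the structural and outlier rules; empty if too few survive.

    The heavy-atom interquartile fence is computed per reactant component on
    the records surviving the structural rules; a reaction is removed when
    any of its reactants falls outside its component's fence. Idempotent.
    """
    survivors = [
        r
        for r in records
        if passes_eligibility(r.pair.r1) and passes_eligibility(r.pair.r2)
    ]
    if not survivors:
        return []
    h1 = np.asarray([r.pair.r1.mol().GetNumHeavyAtoms() for r in survivors])
    h2 = np.asarray([r.pair.r2.mol().GetNumHeavyAtoms() for r in survivors])
    lo1, hi1 = _heavy_atom_fence(h1)
    lo2, hi2 = _heavy_atom_fence(h2)
    kept = [
        r
        for r, a, b in zip(survivors, h1, h2)
        if lo1 <= a <= hi1 and lo2 <= b <= hi2
    ]
    return kept if len(kept) >= min_size else []


def dataset_overlap_prune(
    datasets: Sequence[list[ReactionRecord]], threshold: float = 0.6
) -> list[list[ReactionRecord]]:
    """Drop smaller datasets sharing >= 60% of their products with a larger one.

    Overlap between two datasets is the number of shared product canonical
    SMILES divided by the size (unique products) of the smaller one; pruning
    proceeds largest-first and iterates until stable. Surviving datasets are
    returned in their input order.
    """
    if not datasets:
        raise ConfigurationError("dataset_overlap_prune requires >= 1 dataset")
    products = [frozenset(r.product.smiles for r in ds) for ds in datasets]
    alive = [True] * len(datasets)
    changed = True
    while changed:
        changed = False
        order = sorted(
            (i for i in range(len(datasets)) if alive[i]),
            key=lambda i: -len(products[i]),
        )
        for pos, i in enumerate(order):
            for j in order[pos + 1:]:
                if not (alive[i] and alive[j]):
                    continue
                small = min(len(products[i]), len(products[j]))
                if small == 0:
                    continue
                if len(products[i] & products[j]) / small >= threshold:
                    drop = j if len(products[j]) <= len(products[i]) else i
                    alive[drop] = False
                    changed = True
    return [list(ds) for ds, a in zip(datasets, alive) if a]


def product_split(
    records: Sequence[ReactionRecord],
    ratio: float = 0.6,
    sim_cutoff: float = 0.8,
    seed: int = 0,
) -> SplitResult:
    """Random 6:4 split over unique products, plus a similarity filter.

    All records of a product follow its assignment. Test records whose
    product has a maximum ECFP4 Tanimoto similarity >= ``sim_cutoff``
    against any training product are moved to ``discarded``, enforcing
    genuine train/test separation.
    """
    product_ids = sorted({r.product.smiles for r in records})
    if len(product_ids) < 2:
        raise ConfigurationError("product_split requires >= 2 distinct products")
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(product_ids))
    n_train = round(ratio * len(shuffled))
    train_products = set(shuffled[:n_train])

    train = [r for r in records if r.product.smiles in train_products]
    rest = [r for r in records if r.product.smiles not in train_products]

    train_fps = {
        s: chem.ecfp4(chem.canonicalize(s)) for s in train_products
    }
    test, discarded = [], []
    test_fp_cache: dict[str, float] = {}
    for rec in rest:
        s = rec.product.smiles
        if s not in test_fp_cache:
            fp = chem.ecfp4(rec.product)
            test_fp_cache[s] = max(
                (tanimoto(fp, tfp) for tfp in train_fps.values()), default=0.0
            )
        (discarded if test_fp_cache[s] >= sim_cutoff else test).append(rec)
    return SplitResult(train=train, test=test, discarded=discarded, strategy="product_based")


def alternating_order(freq_sorted: Sequence[str]) -> list[str]:
    """Most frequent, least frequent, second most, second least, ...

    Input is the descending-frequency reactant list; the interleaved order
    spreads heavily reused reactants across the grid axis so the cut does
    not isolate them in one region.
    """
    items = list(freq_sorted)
    out: list[str] = []
    lo, hi = 0, len(items) - 1
    while lo <= hi:
        out.append(items[lo])
        if lo != hi:
            out.append(items[hi])
        lo += 1
        hi -= 1
    return out


def _frequency_order(smiles_list: Sequence[str]) -> list[str]:
    """Unique reactants in descending frequency; ties broken lexicographically."""
    counts: dict[str, int] = {}
    for s in smiles_list:
        counts[s] = counts.get(s, 0) + 1
    return sorted(counts, key=lambda s: (-counts[s], s))


def reactant_split(
    records: Sequence[ReactionRecord],
    ratio: float = 0.6,
    count_mode: str = "area",
) -> SplitResult:
    """Grid split with zero reactant overlap between train and test.

    Component-1 reactants are laid on one axis in the alternating
    most/least-frequent order, component-2 reactants on the other axis in
    plain descending frequency. The cut (a, b) — first ``a`` rows and ``b``
    columns form the training block, the complementary rows and columns the
    test block — is chosen by exhaustive search to bring the
    training:test region ratio as close as possible to ``ratio``, counting
    either all grid cells (``count_mode="area"``) or only observed reactions
    (``count_mode="observed"``). Records in the off-diagonal blocks are
    discarded; by construction the two sets share no reactant on either
    axis.
    """
    if count_mode not in ("area", "observed"):
        raise ConfigurationError(f"unknown count_mode {count_mode!r}")
    r1_axis = alternating_order(_frequency_order([r.pair.r1.smiles for r in records]))
    r2_axis = _frequency_order([r.pair.r2.smiles for r in records])
    n1, n2 = len(r1_axis), len(r2_axis)
    if n1 < 2 or n2 < 2:
        raise ConfigurationError(
            "reactant_split requires >= 2 unique reactants per component"
        )
    row = {s: i for i, s in enumerate(r1_axis)}
    col = {s: j for j, s in enumerate(r2_axis)}

    if count_mode == "observed":
        occ = np.zeros((n1, n2), dtype=np.int64)
        for r in records:
            occ[row[r.pair.r1.smiles], col[r.pair.r2.smiles]] += 1
        cum = occ.cumsum(axis=0).cumsum(axis=1)
        total = cum[-1, -1]

    best: tuple[float, float, int, int] | None = None
    for a in range(1, n1):
        for b in range(1, n2):
            if count_mode == "area":
                lower = a * b
                upper = (n1 - a) * (n2 - b)
            else:
                lower = int(cum[a - 1, b - 1])
                upper = int(
                    total
                    - cum[a - 1, -1]
                    - cum[-1, b - 1]
                    + cum[a - 1, b - 1]
                )
            if lower + upper == 0:
                continue
            dist = abs(lower / (lower + upper) - ratio)
            key = (dist, abs(a / n1 - b / n2), a, b)
            if best is None or key < (best[0], best[1], best[2], best[3]):
                best = key
    assert best is not None
    _, _, a, b = best

    train, test, discarded = [], [], []
    for r in records:
        i, j = row[r.pair.r1.smiles], col[r.pair.r2.smiles]
        if i < a and j < b:
            train.append(r)
        elif i >= a and j >= b:
            test.append(r)
        else:
            discarded.append(r)
    return SplitResult(train=train, test=test, discarded=discarded, strategy="reactant_based")
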