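"""Accuracy metrics, paired target-wise testing, and library diversity profiles.

Metrics are the coefficient of determination R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²,
RMSE and MAE. Model variants are compared per target with the two-sided
Wilcoxon signed-rank test over their paired per-dataset R² values.

Generated libraries are profiled by Murcko scaffold diversity: the unique
scaffold count, and a network over the top-N most frequent scaffolds whose
edges connect scaffolds with fingerprint Tanimoto similarity above a
threshold; its simple-graph density 2E/(V(V−1)) summarizes how redundant
the library's chemotypes are.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy import stats

from . import chem
from .chem import MoleculeRef
from .errors import ContractError
from .kernels import tanimoto

logger = logging.getLogger(__name__)

try:  # SA score ships as an RDKit contrib module
    import os
    import sys

    from rdkit.Chem import RDConfig

    sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
    import sascorer  # type: ignore

    _HAVE_SASCORE = True
except Exception:  # noqa: BLE001
    _HAVE_SASCORE = False


@dataclass(frozen=True)
class MetricReport:
    """R², RMSE and MAE over one evaluation set. R² is NaN when undefined."""

    r2: float
    rmse: float
    mae: float
    n: int


def metrics(y_true: Sequence[float], y_pred: Sequence[float]) -> MetricReport:
    """Exact evaluation of R², RMSE and MAE.

    R² is reported as NaN with a warning when ``y_true`` is constant (its
    denominator vanishes).
    """
    yt = np.asarray(y_true, dtype=np.float64)
    yp = np.asarray(y_pred, dtype=np.float64)
    if yt.shape != yp.shape or yt.size == 0:
        raise ContractError("y_true and y_pred must be equal-length and non-empty")
    resid = yt - yp
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("R^2 undefined for constant y_true; reported as NaN")
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return MetricReport(r2=r2, rmse=rmse, mae=mae, n=int(yt.size))


def targetwise_test(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-dataset scores.

    Zero differences are discarded (standard convention); if every
    difference is zero the methods are indistinguishable and p = 1.0. The
    exact null distribution is used for n <= 25 pairs, the normal
    approximation above.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ContractError("paired score lists of equal length >= 2 required")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return 1.0
    method = "exact" if nonzero.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(
            a, b, zero_method="wilcox", alternative="two-sided", method=method
        )
    except ValueError:
        res = stats.wilcoxon(
            a, b, zero_method="wilcox", alternative="two-sided", method="approx"
        )
    return float(res.pvalue)


@dataclass
class ScaffoldNetwork:
    """Similarity network over the most frequent Murcko scaffolds."""

    graph: nx.Graph  # nodes: scaffold SMILES
    unique_scaffolds: int
    acyclic_count: int

    @property
    def density(self) -> float:
        v = self.graph.number_of_nodes()
        if v < 2:
            return 0.0
        return 2 * self.graph.number_of_edges() / (v * (v - 1))


def murcko_scaffold(product: MoleculeRef) -> str:
    """Canonical Murcko scaffold SMILES; empty string for acyclic molecules."""
    scaffold = MurckoScaffold.GetScaffoldForMol(product.mol())
    return Chem.MolToSmiles(scaffold) if scaffold.GetNumAtoms() else ""


def scaffold_profile(
    products: Sequence[MoleculeRef],
    top_n: int = 20,
    sim_threshold: float = 0.45,
) -> ScaffoldNetwork:
    """Unique-scaffold count plus the top-N scaffold similarity network.

    Scaffolds are compared by the ECFP4 Tanimoto similarity of the scaffold
    structures themselves; an edge joins two of the ``top_n`` most frequent
    scaffolds when similarity exceeds ``sim_threshold``. Acyclic molecules
    have an empty scaffold; they are counted separately and excluded from
    the network.
    """
    if not products:
        raise ContractError("scaffold_profile requires a non-empty product list")
    counts: dict[str, int] = {}
    acyclic = 0
    for p in products:
        s = murcko_scaffold(p)
        if not s:
            acyclic += 1
            continue
        counts[s] = counts.get(s, 0) + 1
    top = sorted(counts, key=lambda s: (-counts[s], s))[:top_n]
    graph = nx.Graph()
    graph.add_nodes_from(top)
    fps = {s: chem.ecfp4(chem.canonicalize(s)) for s in top}
    for i, s1 in enumerate(top):
        for s2 in top[i + 1:]:
            if tanimoto(fps[s1], fps[s2]) > sim_threshold:
                graph.add_edge(s1, s2)
    return ScaffoldNetwork(
        graph=graph, unique_scaffolds=len(counts), acyclic_count=acyclic
    )


PROPERTY_COLUMNS = [
    "MolWt",
    "HeavyAtomCount",
    "NumHDonors",
    "NumHAcceptors",
    "RingCount",
    "TPSA",
    "SAscore",
]


def property_profile(products: Sequence[MoleculeRef]) -> pd.DataFrame:
    """Descriptor table (one row per product) for generated-library profiling.

    SAscore is the synthetic-accessibility score on its 1 (easy) to 10
    (difficult) scale; NaN if the scorer's data are unavailable.
    """
    rows = []
    for p in products:
        mol = p.mol()
        rows.append(
            {
                "smiles": p.smiles,
                "MolWt": Descriptors.MolWt(mol),
                "HeavyAtomCount": mol.GetNumHeavyAtoms(),
                "NumHDonors": rdMolDescriptors.CalcNumHBD(mol),
                "NumHAcceptors": rdMolDescriptors.CalcNumHBA(mol),
                "RingCount": rdMolDescriptors.CalcNumRings(mol),
                "TPSA": rdMolDescriptors.CalcTPSA(mol),
                "SAscore": sascorer.calculateScore(mol) if _HAVE_SASCORE else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["smiles"] + PROPERTY_COLUMNS)
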