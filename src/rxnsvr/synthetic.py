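"""Deterministic synthetic combinatorial reaction libraries with known truth.

Emulates the structure of a curated single-reaction activity dataset: a grid
of (component-1, component-2) building blocks, a retro template that
dissects every product back into its reactants, additive reactant-level
activity on a pKi-like scale with optional interaction and noise terms,
Zipf-skewed reactant reuse (so grid-based splitting is exercised on a
realistic frequency profile), a controllable fraction of products whose
template dissection is ambiguous (two cut points), and candidate pools
containing decoys that fail the single-reaction-center rule.

The default reaction is a reductive-amination-style coupling
(aldehyde + primary amine -> secondary amine): products formed from linear
primary amines carry two CH2-NH cut points and therefore dissect two ways,
which is exactly the ambiguity the augmentation step exploits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import rdBase

from . import chem, templates
from .chem import MoleculeRef
from .errors import ConfigurationError
from .templates import ReactantPair, ReactionRecord, RetroTemplate

#: Retro template of the default fixture reaction: cleave an acyclic
#: CH2-NH bond into an aldehyde (component 1) and a primary amine
#: (component 2).
AMINE_ALKYLATION = RetroTemplate(
    template_id="amine_alkylation",
    retro_smarts="([CX4+0H2R0:1]-[NX3+0H1R0:2])>>[O]=[CX3+0H1R0:1].[NX3+0H2R0:2]",
    component_queries=("[CX3;H1;+0](=[OX1])", "[NX3;H2;+0]"),
)

#: Acid chloride (component 1) + primary amine (component 2) -> amide.
AMIDE_COUPLING = RetroTemplate(
    template_id="amide_coupling",
    retro_smarts=(
        "([CX3+0R0:1](=[OX1:3])-[NX3+0H1R0:2])>>"
        "[Cl]-[CX3+0R0:1]=[OX1:3].[NX3+0H2R0:2]"
    ),
    component_queries=("[CX3;+0](=[OX1])[Cl]", "[NX3;H2;+0]"),
)

TEMPLATES = {
    "amine_alkylation": AMINE_ALKYLATION,
    "amide_coupling": AMIDE_COUPLING,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Generation conditions for one synthetic combinatorial library.

    ``occupancy`` is the fraction of the n_r1 x n_r2 grid that is observed;
    ``freq_skew`` the Zipf exponent of reactant reuse; the ``*_sd`` fields
    the standard deviations of the additive reactant effects, the pairwise
    interaction and the measurement noise (all on the pKi scale);
    ``ambiguous_fraction`` the fraction of observed products whose template
    dissection has two cut points. With
    ``randomize_observed_dissection`` the recorded reactant pair of an
    ambiguous product is drawn uniformly among its dissections instead of
    being the generating pair, emulating not knowing which precursors were
    actually used.
    """

    template_kind: str = "amine_alkylation"
    n_r1: int = 40
    n_r2: int = 40
    occupancy: float = 0.5
    freq_skew: float = 1.0
    effect_sd1: float = 0.8
    effect_sd2: float = 0.8
    interaction_sd: float = 0.1
    noise_sd: float = 0.3
    ambiguous_fraction: float = 0.2
    randomize_observed_dissection: bool = False
    mu: float = 6.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.template_kind not in TEMPLATES:
            raise ConfigurationError(f"unknown template_kind {self.template_kind!r}")
        if self.n_r1 < 2 or self.n_r2 < 2:
            raise ConfigurationError("need at least 2 reactants per component")
        if not 0 < self.occupancy <= 1:
            raise ConfigurationError("occupancy must be in (0, 1]")
        if not 0 <= self.ambiguous_fraction <= 1:
            raise ConfigurationError("ambiguous_fraction must be in [0, 1]")
        if min(self.effect_sd1, self.effect_sd2, self.interaction_sd, self.noise_sd) < 0:
            raise ConfigurationError("standard deviations must be non-negative")
        if self.template_kind == "amide_coupling" and self.ambiguous_fraction > 0:
            raise ConfigurationError(
                "amide products dissect uniquely; ambiguous_fraction must be 0 "
                "for amide_coupling"
            )


@dataclass
class LibraryTruth:
    """Ground-truth additive activity model of a generated library."""

    mu: float
    effects1: dict[str, float]  # canonical (unmarked) SMILES -> effect
    effects2: dict[str, float]

    def additive(self, smiles1: str, smiles2: str) -> float:
        return self.mu + self.effects1[smiles1] + self.effects2[smiles2]

    def argmax(self) -> tuple[str, str]:
        best1 = max(self.effects1, key=lambda s: (self.effects1[s], s))
        best2 = max(self.effects2, key=lambda s: (self.effects2[s], s))
        return best1, best2


# --- substituent vocabulary -------------------------------------------------

_BODIES_CACHE: list[str] | None = None


def _bodies() -> list[str]:
    """Deterministic, effectively unbounded list of substituent SMILES bodies.

    A curated aromatic/aliphatic set first, then a systematic family of
    decorated pentyl chains (substituent pattern encoded base-4 along the
    chain) for overflow. All bodies start with an sp3 carbon and contain no
    aldehyde or primary-amine group, so reaction-center counts stay under
    the generator's control.
    """
    links = ["C" * k for k in range(1, 7)]
    links += [f"C({s})" + "C" * (k - 1) for k in range(2, 7) for s in ("C", "F")]
    links += [f"CC({s})" + "C" * (k - 2) for k in range(3, 7) for s in ("C", "F")]
    caps = [
        "", "O", "OC", "F", "Cl", "C(F)(F)F", "C#N",
        "c1ccccc1", "c1ccc(F)cc1", "c1ccc(Cl)cc1", "c1ccc(C)cc1",
        "c1ccc(OC)cc1", "c1ccco1", "c1ccsc1", "c1ccncc1",
        "C1CCC1", "C1CCCC1", "C1CCCCC1",
    ]
    global _BODIES_CACHE
    if _BODIES_CACHE is not None:
        return _BODIES_CACHE
    curated = [link + cap for link, cap in itertools.product(links, caps)]
    subs = ["", "(C)", "(F)", "(OC)"]
    systematic = []
    for code in range(4**5):
        digits = [(code // 4**p) % 4 for p in range(5)]
        systematic.append("".join("C" + subs[d] for d in digits))
    _BODIES_CACHE = curated + systematic
    return _BODIES_CACHE


def _head_variants(kind: str) -> tuple[str, str, str]:
    """(component-1 head, ambiguous component-2 head, branched component-2 head)."""
    if kind == "amine_alkylation":
        return "O=C", "NC", "NC(C)"
    return "ClC(=O)", "NC", "NC(C)"  # amide_coupling (ambiguous head unused)


def _enumerate_component(
    head: str,
    query_smarts: str,
    needed: int,
    parity: int | None = None,
    skip: frozenset[str] = frozenset(),
) -> list[MoleculeRef]:
    """First ``needed`` valid single-center molecules of the form head+body.

    ``parity`` restricts the body list to even (0) or odd (1) indices; the
    two reaction components draw from disjoint parities so that a symmetric
    product can never be formed by two different observed cells.
    """
    out: list[MoleculeRef] = []
    seen: set[str] = set()
    query = Chem.MolFromSmarts(query_smarts)
    bodies = _bodies()
    if parity is not None:
        bodies = bodies[parity::2]
    block = rdBase.BlockLogs()  # some head+body combinations are valence-invalid
    for body in bodies:
        smiles = head + body
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        ref = chem.from_mol(mol)
        if ref.smiles in seen or ref.smiles in skip:
            continue
        seen.add(ref.smiles)
        if templates.count_reaction_centers(ref, query) != 1:
            continue
        out.append(ref)
        if len(out) >= needed:
            return out
    raise ConfigurationError(
        f"substituent vocabulary exhausted: needed {needed} molecules for "
        f"head {head!r}, found {len(out)}"
    )


def _decoys(template: RetroTemplate, component: int, n: int) -> list[MoleculeRef]:
    """Pool decoys violating the single-reaction-center rule.

    Alternates molecules with zero centers (plain chains/ethers) and with two
    centers (dialdehydes / bis acid chlorides / diamines).
    """
    if component == 1:
        head = "O=C" if template.template_id == "amine_alkylation" else "ClC(=O)"
        tail = "C=O" if template.template_id == "amine_alkylation" else "C(=O)Cl"
    else:
        head, tail = "NC", "CN"
    out: list[MoleculeRef] = []
    seen: set[str] = set()
    block = rdBase.BlockLogs()
    for i, body in enumerate(_bodies()):
        smiles = ("C" + body) if len(out) % 2 == 0 else (head + body + tail)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        ref = chem.from_mol(mol)
        if ref.smiles in seen:
            continue
        seen.add(ref.smiles)
        out.append(ref)
        if len(out) >= n:
            return out
    return out


def _zipf_probs(n: int, skew: float) -> np.ndarray:
    w = (np.arange(1, n + 1, dtype=np.float64)) ** (-skew)
    return w / w.sum()


def _pick_ambiguous_columns(
    col_counts: np.ndarray, target: int
) -> list[int]:
    """Subset of columns whose observed-cell counts sum exactly to ``target``.

    Deterministic subset-sum DP; raises when no subset reaches the target
    (the requested ambiguous fraction is then unachievable at this
    occupancy pattern).
    """
    reach: dict[int, tuple[int, int] | None] = {0: None}  # sum -> (column, prev sum)
    for j in range(len(col_counts)):
        c = int(col_counts[j])
        if c == 0:
            continue
        for s in list(reach.keys()):
            t = s + c
            if t <= target and t not in reach:
                reach[t] = (j, s)
    if target not in reach:
        raise ConfigurationError(
            f"ambiguous_fraction unachievable: no column subset sums to {target}"
        )
    picked: list[int] = []
    s = target
    while reach[s] is not None:
        j, s = reach[s]
        picked.append(j)
    return sorted(picked)


def enumerate_candidates(
    template_kind: str, component: int, n: int
) -> list[MoleculeRef]:
    """Deterministic candidate pool of ``n`` single-center building blocks.

    Component 1 enumerates the electrophile family (even-parity bodies, the
    same order the library reactants are drawn from, so any library of up to
    ``n`` component-1 reactants is a subset); component 2 interleaves the
    linear and branched amine families.
    """
    if template_kind not in TEMPLATES:
        raise ConfigurationError(f"unknown template_kind {template_kind!r}")
    head1, head_amb, head_branch = _head_variants(template_kind)
    q1, q2 = TEMPLATES[template_kind].component_queries
    if component == 1:
        return _enumerate_component(head1, q1, n, parity=0)
    if component != 2:
        raise ConfigurationError("component must be 1 or 2")
    amb = _enumerate_component(head_amb, q2, (n + 1) // 2, parity=1)
    branch = _enumerate_component(head_branch, q2, n // 2)
    return amb + branch


def generate_library(
    spec: FixtureSpec,
) -> tuple[list[ReactionRecord], list[MoleculeRef], list[MoleculeRef], RetroTemplate, LibraryTruth]:
    """Build a synthetic reaction dataset plus candidate pools and truth.

    Returns ``(records, pool1, pool2, template, truth)``. Pools contain the
    library building blocks followed by decoys (zero or two reaction
    centers) amounting to ~20% of each pool. Generation is fully
    deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    template = TEMPLATES[spec.template_kind]
    head1, head_amb, head_branch = _head_variants(spec.template_kind)
    q1, q2 = template.component_queries

    r1 = _enumerate_component(head1, q1, spec.n_r1, parity=0)
    # Linear (ambiguous) amines draw bodies of the opposite parity from the
    # aldehydes: their products are symmetric around the N, and disjoint body
    # sets rule out two observed cells assembling the same product.
    amb_pool = _enumerate_component(head_amb, q2, spec.n_r2, parity=1)
    branch_pool = _enumerate_component(head_branch, q2, spec.n_r2)

    n1, n2 = spec.n_r1, spec.n_r2
    n_obs = max(1, round(spec.occupancy * n1 * n2))
    p1 = _zipf_probs(n1, spec.freq_skew)
    p2 = _zipf_probs(n2, spec.freq_skew)
    cell_p = np.outer(p1, p2).ravel()
    cell_p /= cell_p.sum()
    cells = rng.choice(n1 * n2, size=n_obs, replace=False, p=cell_p)
    cells.sort()
    rows, cols = np.divmod(cells, n2)

    col_counts = np.bincount(cols, minlength=n2)
    target = round(spec.ambiguous_fraction * n_obs)
    ambiguous_cols = set(_pick_ambiguous_columns(col_counts, target))

    amb_iter, branch_iter = iter(amb_pool), iter(branch_pool)
    r2 = [
        next(amb_iter) if j in ambiguous_cols else next(branch_iter)
        for j in range(n2)
    ]

    e1 = rng.normal(0.0, spec.effect_sd1, n1)
    e2 = rng.normal(0.0, spec.effect_sd2, n2)
    g = rng.normal(0.0, spec.interaction_sd, n_obs) if spec.interaction_sd > 0 else np.zeros(n_obs)
    eps = rng.normal(0.0, spec.noise_sd, n_obs) if spec.noise_sd > 0 else np.zeros(n_obs)

    records: list[ReactionRecord] = []
    seen_products: set[str] = set()
    for k, (i, j) in enumerate(zip(rows, cols)):
        prods = templates.forward_products(template, r1[i].mol(), r2[j].mol())
        if len(prods) != 1:
            raise ConfigurationError(
                f"fixture assembly did not give a unique product for "
                f"({r1[i].smiles}, {r2[j].smiles}): {[p.smiles for p in prods]}"
            )
        product = prods[0]
        if product.smiles in seen_products:
            raise ConfigurationError(f"product collision in fixture: {product.smiles}")
        seen_products.add(product.smiles)
        dissections = templates.dissect_product(product, template)
        generating = [
            p
            for p in dissections
            if (p.unmarked()[0].smiles, p.unmarked()[1].smiles)
            == (r1[i].smiles, r2[j].smiles)
        ]
        if not generating:
            raise ConfigurationError(
                f"round-trip failure: {product.smiles} does not dissect back to "
                f"({r1[i].smiles}, {r2[j].smiles})"
            )
        if spec.randomize_observed_dissection and len(dissections) > 1:
            pair = dissections[int(rng.integers(len(dissections)))]
        else:
            pair = generating[0]
        y = spec.mu + e1[i] + e2[j] + g[k] + eps[k]
        records.append(
            ReactionRecord(
                record_id=f"R{k:05d}",
                product=product,
                pair=pair,
                y=float(y),
                provenance="observed",
            )
        )

    truth = LibraryTruth(
        mu=spec.mu,
        effects1={r1[i].smiles: float(e1[i]) for i in range(n1)},
        effects2={r2[j].smiles: float(e2[j]) for j in range(n2)},
    )
    pool1 = r1 + _decoys(template, 1, max(2, n1 // 5))
    pool2 = r2 + _decoys(template, 2, max(2, n2 // 5))
    return records, pool1, pool2, template, truth


def plant_known_optimum(
    pool1: list[MoleculeRef],
    pool2: list[MoleculeRef],
    truth: LibraryTruth,
    template: RetroTemplate,
    margin: float = 1.0,
) -> tuple[list[MoleculeRef], list[MoleculeRef], tuple[str, str]]:
    """Insert one candidate per component whose true effect dominates all others.

    Returns extended pools and the (smiles1, smiles2) of the planted pair;
    ``truth`` is updated in place so its argmax is the planted pair. The
    planted candidates pass the single-reaction-center filter.
    """
    head1, head_amb, _ = _head_variants(template.template_id)
    q1, q2 = template.component_queries
    existing1 = frozenset(m.smiles for m in pool1) | frozenset(truth.effects1)
    existing2 = frozenset(m.smiles for m in pool2) | frozenset(truth.effects2)
    new1 = [
        m
        for m in _enumerate_component(head1, q1, len(existing1) + 1, parity=0)
        if m.smiles not in existing1
    ][0]
    new2 = [
        m
        for m in _enumerate_component(head_amb, q2, len(existing2) + 1, parity=1)
        if m.smiles not in existing2
    ][0]
    truth.effects1[new1.smiles] = max(truth.effects1.values()) + margin
    truth.effects2[new2.smiles] = max(truth.effects2.values()) + margin
    return pool1 + [new1], pool2 + [new2], (new1.smiles, new2.smiles)
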