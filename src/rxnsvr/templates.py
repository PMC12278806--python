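"""Retro reaction templates: product dissection, augmentation, candidate filtering.

A retro template is a reaction SMARTS mapping one product pattern to exactly
two reactant patterns (decomposition into more than two components is
rejected). Applying it to a product yields one reactant pair per distinct
match of the product pattern; a product with, e.g., a symmetric secondary
amine can dissect at two points and yields two distinct pairs. Those
alternative pairs are what the augmentation step adds to a training set.

Atom marking on dissection follows the template mechanics: product atoms
carrying a template atom map become reaction centers (isotope 1000), atoms
introduced by the retro transform (present on the reactant side only, e.g.
the Cl of an alkyl chloride) are leaving groups (isotope 900).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from typing import Sequence

from rdkit import Chem
from rdkit.Chem import AllChem

from . import chem
from .chem import CENTER_ISOTOPE, LEAVING_ISOTOPE, MoleculeRef
from .errors import ConfigurationError, ContractError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RetroTemplate:
    """Two-component retro reaction SMARTS plus per-component center queries.

    ``retro_smarts`` maps the product pattern to exactly two reactant
    patterns (``product >> r1 . r2``); ``component_queries`` are substructure
    SMARTS that identify the reaction center on purchasable candidates for
    component 1 and component 2 respectively.
    """

    template_id: str
    retro_smarts: str
    component_queries: tuple[str, str]

    def __post_init__(self) -> None:
        rxn = AllChem.ReactionFromSmarts(self.retro_smarts)
        if rxn is None:
            raise ConfigurationError(f"invalid reaction SMARTS: {self.retro_smarts!r}")
        if rxn.GetNumReactantTemplates() != 1 or rxn.GetNumProductTemplates() != 2:
            raise ConfigurationError(
                "retro template must map one product pattern to exactly two "
                f"reactant patterns; got {rxn.GetNumReactantTemplates()} >> "
                f"{rxn.GetNumProductTemplates()} in {self.retro_smarts!r}"
            )
        mapped = any(
            a.GetAtomMapNum() > 0
            for a in rxn.GetReactantTemplate(0).GetAtoms()
        )
        if not mapped:
            raise ConfigurationError(
                f"retro template has no atom maps on the product pattern: "
                f"{self.retro_smarts!r}"
            )
        for q in self.component_queries:
            if Chem.MolFromSmarts(q) is None:
                raise ConfigurationError(f"invalid component query SMARTS: {q!r}")

    @cached_property
    def retro_rxn(self) -> AllChem.ChemicalReaction:
        rxn = AllChem.ReactionFromSmarts(self.retro_smarts)
        rxn.Initialize()
        return rxn

    @cached_property
    def forward_smarts(self) -> str:
        left, right = self.retro_smarts.split(">>")
        return f"{right}>>{left}"

    @cached_property
    def forward_rxn(self) -> AllChem.ChemicalReaction:
        rxn = AllChem.ReactionFromSmarts(self.forward_smarts)
        rxn.Initialize()
        return rxn

    def query_mol(self, component: int) -> Chem.Mol:
        return Chem.MolFromSmarts(self.component_queries[component - 1])


@dataclass(frozen=True, order=True)
class ReactantPair:
    """An ordered, site-marked reactant pair; order fixed by the template."""

    r1: MoleculeRef
    r2: MoleculeRef

    def __post_init__(self) -> None:
        for ref in (self.r1, self.r2):
            if not any(
                a.GetIsotope() == CENTER_ISOTOPE for a in ref.mol().GetAtoms()
            ):
                raise ContractError(
                    f"reactant lacks an isotope-{CENTER_ISOTOPE} center: {ref.smiles}"
                )

    def key(self) -> tuple[str, str]:
        """Dedup key: ordered canonical SMILES tuple, isotopes included."""
        return (self.r1.smiles, self.r2.smiles)

    def unmarked(self) -> tuple[MoleculeRef, MoleculeRef]:
        return (chem.strip_site_marks(self.r1), chem.strip_site_marks(self.r2))


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction: product, ordered reactant pair, activity, provenance."""

    record_id: str
    product: MoleculeRef
    pair: ReactantPair
    y: float
    provenance: str = "observed"  # {"observed", "augmented"}

    def __post_init__(self) -> None:
        if not (self.y == self.y and abs(self.y) != float("inf")):
            raise ContractError(f"non-finite activity for record {self.record_id}")
        if self.provenance not in ("observed", "augmented"):
            raise ContractError(f"unknown provenance {self.provenance!r}")


def _marked_fragment(frag: Chem.Mol) -> MoleculeRef | None:
    """Sanitize a retro-transform fragment and apply site isotopes.

    Mapped template atoms -> isotope 1000; atoms without a source atom in the
    product (introduced by the transform) -> isotope 900. Returns None when
    the fragment fails sanitization.
    """
    for atom in frag.GetAtoms():
        if atom.HasProp("old_mapno"):
            atom.SetIsotope(CENTER_ISOTOPE)
        elif not atom.HasProp("react_atom_idx"):
            atom.SetIsotope(LEAVING_ISOTOPE)
    try:
        Chem.SanitizeMol(frag)
    except Exception:  # noqa: BLE001 - RDKit raises various sanitization errors
        return None
    return chem.from_mol(frag)


def dissect_product(product: MoleculeRef, template: RetroTemplate) -> list[ReactantPair]:
    """Apply the retro template, returning one marked pair per distinct match.

    Pairs are deduplicated by the ordered tuple of canonical SMILES; matches
    whose fragments fail chemistry sanitization are skipped with a logged
    warning. Returns an empty list when the product lacks the pattern.
    """
    mol = product.mol()
    results: list[ReactantPair] = []
    seen: set[tuple[str, str]] = set()
    for frags in template.retro_rxn.RunReactants((mol,)):
        if len(frags) != 2:
            continue
        r1 = _marked_fragment(frags[0])
        r2 = _marked_fragment(frags[1])
        if r1 is None or r2 is None:
            logger.warning(
                "template %s produced an invalid reactant for product %s; "
                "match skipped",
                template.template_id,
                product.smiles,
            )
            continue
        pair = ReactantPair(r1=r1, r2=r2)
        if pair.key() not in seen:
            seen.add(pair.key())
            results.append(pair)
    return results


def forward_products(
    template: RetroTemplate, mol1: Chem.Mol, mol2: Chem.Mol
) -> list[MoleculeRef]:
    """Forward-apply the template to two reactant molecules.

    Returns the distinct unmarked canonical products (usually one; symmetric
    or multi-site reactants can give several), in deterministic order.
    """
    out: list[MoleculeRef] = []
    seen: set[str] = set()
    for prods in template.forward_rxn.RunReactants((mol1, mol2)):
        for p in prods:
            try:
                Chem.SanitizeMol(p)
            except Exception:  # noqa: BLE001
                continue
            ref = chem.strip_site_marks(chem.from_mol(p))
            if ref.smiles not in seen:
                seen.add(ref.smiles)
                out.append(ref)
    out.sort()
    return out


def assemble_products(pair: ReactantPair, template: RetroTemplate) -> list[MoleculeRef]:
    """Forward-apply the template to a marked reactant pair."""
    return forward_products(template, pair.r1.mol(), pair.r2.mol())


def reassembly_check(
    pair: ReactantPair, template: RetroTemplate, product: MoleculeRef
) -> bool:
    """True iff the pair forward-assembles to the product and is among the
    product's own dissections (canonical-SMILES comparison on both sides)."""
    target = chem.strip_site_marks(product)
    if target.smiles not in {p.smiles for p in assemble_products(pair, template)}:
        return False
    return pair.key() in {p.key() for p in dissect_product(target, template)}


def augment_records(
    records: Sequence[ReactionRecord], template: RetroTemplate
) -> list[ReactionRecord]:
    """Add every alternative dissection of each product as an augmented record.

    For each distinct product, dissection pairs not already present among the
    product's records are appended with provenance ``"augmented"`` and the
    product's observed activity. Existing records are returned unchanged and
    first; the output is never smaller than the input.
    """
    out = list(records)
    by_product: dict[str, list[ReactionRecord]] = {}
    for rec in records:
        by_product.setdefault(rec.product.smiles, []).append(rec)
    for smiles, recs in by_product.items():
        present = {rec.pair.key() for rec in recs}
        counter = 0
        for pair in dissect_product(recs[0].product, template):
            if pair.key() in present:
                continue
            present.add(pair.key())
            counter += 1
            out.append(
                ReactionRecord(
                    record_id=f"{recs[0].record_id}-aug{counter}",
                    product=recs[0].product,
                    pair=pair,
                    y=recs[0].y,
                    provenance="augmented",
                )
            )
    return out


def count_reaction_centers(mol: MoleculeRef, query: Chem.Mol) -> int:
    """Number of distinct reaction centers (unique matched atom sets)."""
    matches = mol.mol().GetSubstructMatches(query, uniquify=False)
    return len({frozenset(m) for m in matches})


def find_candidates(
    pool: Sequence[MoleculeRef], query_smarts: str
) -> list[MoleculeRef]:
    """Candidates from a pool with exactly one reaction center under the query.

    Symmetry-equivalent substructure matches (same atom set in a different
    order) count once, so a single symmetric site is not rejected. Pool order
    is preserved. Molecules with zero or multiple centers are excluded to
    avoid regioselectivity ambiguity.
    """
    query = Chem.MolFromSmarts(query_smarts)
    if query is None:
        raise ConfigurationError(f"invalid query SMARTS: {query_smarts!r}")
    return [m for m in pool if count_reaction_centers(m, query) == 1]
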