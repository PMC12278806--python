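"""Molecular standardization, reaction-site marking and circular fingerprints.

Molecules are carried around as canonical SMILES (:class:`MoleculeRef`).
Reaction centers are tagged with isotope 1000 and leaving-group atoms with
isotope 900 so that the circular-fingerprint hashing distinguishes them from
chemically identical atoms elsewhere in the molecule: the ECFP atom
invariants include the isotope, so a marked variant of a molecule never
hashes to the same feature set as the unmarked one.

Fingerprints are extended-connectivity fingerprints of diameter 4 (radius 2)
hashed and folded into a fixed-width bit vector, 8192 bits by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .errors import ContractError, ParseError

#: Isotope label for atoms at the reaction center.
CENTER_ISOTOPE = 1000
#: Isotope label for leaving-group atoms introduced by a retro template.
LEAVING_ISOTOPE = 900

DEFAULT_N_BITS = 8192


@dataclass(frozen=True, order=True)
class MoleculeRef:
    """A molecule identified by its canonical (isotope-preserving) SMILES.

    ``marked`` records whether any atom carries a reaction-site isotope
    (1000 for centers, 900 for leaving groups).
    """

    smiles: str
    marked: bool = False

    def mol(self) -> Chem.Mol:
        """Return the RDKit molecule for this reference."""
        return _mol_from_smiles(self.smiles)


@dataclass(frozen=True)
class BitFingerprint:
    """Folded binary circular fingerprint as a sorted tuple of on-bit indices."""

    on_bits: tuple[int, ...]
    n_bits: int = DEFAULT_N_BITS

    def __post_init__(self) -> None:
        bits = tuple(sorted(set(int(b) for b in self.on_bits)))
        object.__setattr__(self, "on_bits", bits)
        if bits and (bits[0] < 0 or bits[-1] >= self.n_bits):
            raise ContractError(
                f"on-bit index out of range [0, {self.n_bits}): {bits[0]}..{bits[-1]}"
            )

    def as_set(self) -> frozenset[int]:
        return frozenset(self.on_bits)

    def __len__(self) -> int:
        return len(self.on_bits)


@lru_cache(maxsize=200_000)
def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def _is_marked(mol: Chem.Mol) -> bool:
    return any(
        a.GetIsotope() in (CENTER_ISOTOPE, LEAVING_ISOTOPE) for a in mol.GetAtoms()
    )


def canonicalize(smiles: str) -> MoleculeRef:
    """Parse a SMILES string and return its canonical :class:`MoleculeRef`.

    Isotope labels (including the 1000/900 site marks) survive
    canonicalization, and the operation is idempotent.
    """
    if not smiles:
        raise ParseError("empty SMILES string")
    mol = _mol_from_smiles(smiles)
    return from_mol(mol)


def from_mol(mol: Chem.Mol) -> MoleculeRef:
    """Build a :class:`MoleculeRef` from an RDKit molecule."""
    return MoleculeRef(smiles=Chem.MolToSmiles(mol), marked=_is_marked(mol))


def mark_reaction_sites(
    mol: MoleculeRef,
    center_atoms: list[int],
    leaving_atoms: list[int],
) -> MoleculeRef:
    """Label reaction-center atoms with isotope 1000 and leaving-group atoms with 900.

    ``center_atoms`` and ``leaving_atoms`` are atom indices into the canonical
    molecule; the two sets must be disjoint.
    """
    centers = set(center_atoms)
    leaving = set(leaving_atoms)
    if centers & leaving:
        raise ContractError(
            f"center and leaving atom sets overlap: {sorted(centers & leaving)}"
        )
    rw = Chem.RWMol(mol.mol())
    n = rw.GetNumAtoms()
    for idx in centers | leaving:
        if not 0 <= idx < n:
            raise IndexError(f"atom index {idx} out of range for {n}-atom molecule")
    for idx in centers:
        rw.GetAtomWithIdx(idx).SetIsotope(CENTER_ISOTOPE)
    for idx in leaving:
        rw.GetAtomWithIdx(idx).SetIsotope(LEAVING_ISOTOPE)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return from_mol(out)


def strip_site_marks(mol: MoleculeRef) -> MoleculeRef:
    """Remove any 1000/900 site isotopes, returning the unmarked molecule."""
    rw = Chem.RWMol(mol.mol())
    for atom in rw.GetAtoms():
        if atom.GetIsotope() in (CENTER_ISOTOPE, LEAVING_ISOTOPE):
            atom.SetIsotope(0)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return from_mol(out)


@lru_cache(maxsize=64)
def _morgan_generator(n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)


@lru_cache(maxsize=400_000)
def _ecfp4_cached(smiles: str, n_bits: int) -> BitFingerprint:
    gen = _morgan_generator(n_bits)
    fp = gen.GetFingerprint(_mol_from_smiles(smiles))
    return BitFingerprint(on_bits=tuple(fp.GetOnBits()), n_bits=n_bits)


def ecfp4(mol: MoleculeRef, n_bits: int = DEFAULT_N_BITS) -> BitFingerprint:
    """ECFP4 (diameter-4 circular) fingerprint folded to ``n_bits`` bits.

    Binary presence/absence bits; deterministic for a given canonical SMILES
    and width. Isotope marks change the atom invariants, so marked and
    unmarked variants of the same molecule give different fingerprints.
    """
    if n_bits < 1:
        raise ContractError(f"n_bits must be >= 1, got {n_bits}")
    return _ecfp4_cached(mol.smiles, n_bits)


def unfolded_feature_hashes(mol: MoleculeRef) -> frozenset[int]:
    """Raw (unfolded) circular-feature hash identifiers of the molecule.

    The folded fingerprint at width ``n`` is the image of this set modulo
    ``n``; exposed so the folding step can be verified independently.
    """
    gen = _morgan_generator(DEFAULT_N_BITS)
    sparse = gen.GetSparseFingerprint(mol.mol())
    return frozenset(sparse.GetOnBits())
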