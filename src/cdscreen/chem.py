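"""Structure parsing, canonicalization and counter-ion handling.

Guest structures arrive as SMILES or InChI strings.  Canonical identity is
the InChIKey computed after counter-ion stripping, so stereoisomers stay
distinct while salt forms collapse onto their parent molecule.
"""

from __future__ import annotations

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")


class StructureError(ValueError):
    """Raised when a structure string cannot be turned into a usable molecule."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


def parse_structure(text: str) -> Chem.Mol:
    """Parse a SMILES or InChI string into a sanitized RDKit molecule.

    InChI is recognised by its ``InChI=`` prefix; everything else is treated
    as SMILES.  Raises :class:`StructureError` with reason ``parse_failure``
    on malformed input.
    """
    if not isinstance(text, str) or not text.strip():
        raise StructureError("missing_structure")
    text = text.strip()
    if text.startswith("InChI="):
        mol = Chem.MolFromInchi(text)
    else:
        mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise StructureError("parse_failure", text)
    return mol


def strip_counter_ions(mol: Chem.Mol) -> Chem.Mol:
    """Remove single-atom components (counter-ions such as Na+, Cl-).

    Multi-atom components are retained.  If several multi-atom components
    remain (a true mixture) the largest by heavy-atom count is kept, which
    matches the usual "keep parent" salt-stripping convention.  Raises
    :class:`StructureError` (``no_multi_atom_component``) when nothing but
    single atoms is present.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    multi = [f for f in frags if f.GetNumAtoms() > 1]
    if not multi:
        raise StructureError("no_multi_atom_component")
    keep = max(multi, key=lambda f: f.GetNumAtoms())
    Chem.SanitizeMol(keep)
    return keep


def canonical_smiles(mol: Chem.Mol) -> str:
    """Canonical isomeric SMILES (stereochemistry preserved)."""
    return Chem.MolToSmiles(mol)


def inchikey(mol: Chem.Mol) -> str:
    """InChIKey of the molecule; the canonical record key for guests."""
    key = Chem.MolToInchiKey(mol)
    if not key:
        raise StructureError("inchikey_failure", Chem.MolToSmiles(mol))
    return key


def molecular_weight(mol: Chem.Mol) -> float:
    """Average molecular weight in daltons."""
    return Descriptors.MolWt(mol)


def standardize_structure(text: str) -> tuple[str, str, float]:
    """Parse, strip counter-ions and canonicalize one structure string.

    Returns ``(canonical_smiles, inchikey, molecular_weight)``.
    """
    mol = strip_counter_ions(parse_structure(text))
    return canonical_smiles(mol), inchikey(mol), molecular_weight(mol)
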