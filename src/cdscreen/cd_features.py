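"""Cyclodextrin decomposition descriptors and guest/system featurization.

A cyclodextrin is represented by two pieces of information: the size of the
macrocycle (number of alpha-1,4-linked glucopyranose units: 6, 7 or 8 for
the alpha/beta/gamma families) and the side-chain fragment attached to the
primary face, written as a stand-alone small molecule terminated by a
hydrogen atom.  The native hydroxymethyl group at C-6 therefore reads as
methanol; a 2-hydroxypropyl ether reads as 1-methoxy-2-propanol, and so on.
Separating a nearly invariant macrocycle from its variable side chains puts
the descriptor variance where the chemistry actually differs between CD
types.

The CD feature vector is ``[n_glucose] + descriptors(fragment) + [ds]``
where ``ds`` is the average degree of substitution per glucose unit — a
scalar that distinguishes, say, dimethyl- from trimethyl-beta-CD, which
share a methyl-ether fragment.

Descriptor providers are pluggable: anything mapping a structure to an
ordered dict of named finite floats works.  Two are built in — a fast
~14-descriptor provider used throughout the test pipeline and a full RDKit
2D+3D provider (several hundred descriptors) for production featurization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Protocol

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, Descriptors3D, rdMolDescriptors

from .chem import StructureError, parse_structure


class NotACyclodextrinError(ValueError):
    pass


@dataclass(frozen=True)
class CDDecomposition:
    """Macrocycle size plus canonical side-chain fragment of one CD."""

    n_glucose: int
    side_chain_fragment: str
    degree_of_substitution: float = 0.0
    substitution_note: str = ""

    def __post_init__(self):
        if parse_structure(self.side_chain_fragment) is None:  # pragma: no cover
            raise ValueError(f"unparseable fragment {self.side_chain_fragment!r}")


# ---------------------------------------------------------------------------
# registry


def _load_registry() -> dict:
    with resources.files("cdscreen.data").joinpath("cd_registry.json").open() as fh:
        return json.load(fh)


_REGISTRY_RAW = _load_registry()["entries"]


def _norm(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


_REGISTRY: dict[str, dict] = {}
for _e in _REGISTRY_RAW:
    for _alias in [_e["name"], *_e["aliases"]]:
        _REGISTRY[_norm(_alias)] = _e


def registry_names() -> list[str]:
    """Canonical names of all registered CD types."""
    return [e["name"] for e in _REGISTRY_RAW]


def lookup_cd(name: str) -> dict | None:
    """Registry entry for a CD name or alias, or None."""
    return _REGISTRY.get(_norm(name))


# ---------------------------------------------------------------------------
# decomposition


def decompose_cyclodextrin(cd_spec: str) -> CDDecomposition:
    """Decompose a CD given by registry name or structure.

    Names (and their aliases) resolve through the built-in registry.
    Structure strings are decomposed by detecting the macrocycle of
    alpha-1,4-linked pyranose rings and excising the primary-face side
    chain; raises :class:`NotACyclodextrinError` when no 6/7/8-unit
    macrocycle is present.
    """
    entry = lookup_cd(cd_spec)
    if entry is not None:
        return CDDecomposition(
            n_glucose=entry["n_glucose"],
            side_chain_fragment=entry["fragment"],
            degree_of_substitution=entry["degree_of_substitution"],
        )
    try:
        mol = parse_structure(cd_spec)
    except StructureError as err:
        raise NotACyclodextrinError(f"not a known CD name and not parseable: {err}")
    return decompose_structure(mol)


def decompose_structure(mol: Chem.Mol) -> CDDecomposition:
    """Detect the pyranose macrocycle of a CD structure and extract its side chain."""
    ring_info = mol.GetRingInfo()
    pyranoses = []
    for ring in ring_info.AtomRings():
        if len(ring) != 6:
            continue
        syms = [mol.GetAtomWithIdx(i).GetSymbol() for i in ring]
        if syms.count("O") == 1 and syms.count("C") == 5:
            pyranoses.append(frozenset(ring))
    # two pyranoses are glycosidically linked when a non-ring O bridges them
    links: dict[frozenset, set[frozenset]] = {p: set() for p in pyranoses}
    ring_atoms = set().union(*pyranoses) if pyranoses else set()
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "O" or atom.GetIdx() in ring_atoms:
            continue
        touched = [p for p in pyranoses if any(n.GetIdx() in p for n in atom.GetNeighbors())]
        if len(touched) == 2:
            links[touched[0]].add(touched[1])
            links[touched[1]].add(touched[0])
    cycle = [p for p in pyranoses if len(links[p]) == 2]
    n = len(cycle)
    if n not in (6, 7, 8) or n != len(pyranoses):
        raise NotACyclodextrinError(
            f"no 6/7/8-unit alpha-1,4 pyranose macrocycle found ({len(pyranoses)} pyranose rings)"
        )
    fragments = [_excise_side_chain(mol, ring) for ring in cycle]
    fragments = [f for f in fragments if f is not None]
    if not fragments:
        raise NotACyclodextrinError("macrocycle found but no C-5 side chain")
    counts = pd.Series(fragments).value_counts()
    note = "" if counts.size == 1 else f"heterogeneous side chains: {dict(counts)}"
    return CDDecomposition(
        n_glucose=n,
        side_chain_fragment=counts.index[0],
        degree_of_substitution=_estimate_ds(counts, n),
        substitution_note=note,
    )


def _estimate_ds(fragment_counts: pd.Series, n: int) -> float:
    native = fragment_counts.get("CO", 0)
    return round(float(n - native) / n, 3)


def _excise_side_chain(mol: Chem.Mol, ring: frozenset) -> str | None:
    """Fragment attached at C-5 (via the exocyclic C-6), H-terminated."""
    ring_o = next(i for i in ring if mol.GetAtomWithIdx(i).GetSymbol() == "O")
    for c5 in mol.GetAtomWithIdx(ring_o).GetNeighbors():
        if c5.GetIdx() not in ring:
            continue
        exo = [
            n for n in c5.GetNeighbors() if n.GetIdx() not in ring and n.GetSymbol() == "C"
        ]
        if not exo:
            continue
        bond = mol.GetBondBetweenAtoms(c5.GetIdx(), exo[0].GetIdx())
        pieces = Chem.FragmentOnBonds(mol, [bond.GetIdx()], addDummies=False)
        for frag in Chem.GetMolFrags(pieces, asMols=True, sanitizeFrags=True):
            # the piece not containing the macrocycle is the side chain
            if frag.GetNumAtoms() < mol.GetNumAtoms() / 2:
                return Chem.MolToSmiles(frag)
    return None


# ---------------------------------------------------------------------------
# descriptor providers


class DescriptorProvider(Protocol):
    name: str

    def __call__(self, mol: Chem.Mol, conformer_seed: int) -> dict[str, float]: ...


def _embed(mol: Chem.Mol, seed: int) -> Chem.Mol:
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(molh, params) != 0:
        raise StructureError("embedding_failure", Chem.MolToSmiles(mol))
    return molh


def _chiral_volume_sum(molh: Chem.Mol) -> float:
    """Sum of signed tetrahedral volumes over 4-coordinate atoms.

    Flips sign under reflection, so enantiomers get opposite values while
    achiral molecules land near a value shared by both mirror images.
    Neighbor order is fixed by atom index, making the sign well defined for
    a given input structure.
    """
    conf = molh.GetConformer()
    pos = conf.GetPositions()
    total = 0.0
    for atom in molh.GetAtoms():
        nbrs = sorted(n.GetIdx() for n in atom.GetNeighbors())
        if len(nbrs) != 4:
            continue
        p0 = pos[nbrs[0]]
        total += float(np.linalg.det(np.stack([pos[i] - p0 for i in nbrs[1:]])))
    return total


class MinimalDescriptorProvider:
    """Fast ~14-descriptor provider: constitutional/topological 2D terms plus
    two conformer-derived 3D terms (radius of gyration and a chirality-signed
    volume sum)."""

    name = "minimal-v1"

    def __call__(self, mol: Chem.Mol, conformer_seed: int = 17) -> dict[str, float]:
        d = {
            "mw": Descriptors.MolWt(mol),
            "heavy_atoms": float(mol.GetNumHeavyAtoms()),
            "rings": float(rdMolDescriptors.CalcNumRings(mol)),
            "aromatic_rings": float(rdMolDescriptors.CalcNumAromaticRings(mol)),
            "hbd": float(rdMolDescriptors.CalcNumHBD(mol)),
            "hba": float(rdMolDescriptors.CalcNumHBA(mol)),
            "tpsa": rdMolDescriptors.CalcTPSA(mol),
            "logp": Crippen.MolLogP(mol),
            "rotatable_bonds": float(rdMolDescriptors.CalcNumRotatableBonds(mol)),
            "fraction_csp3": rdMolDescriptors.CalcFractionCSP3(mol),
            "chi0v": rdMolDescriptors.CalcChi0v(mol),
            "hetero_fraction": (
                sum(a.GetAtomicNum() not in (1, 6) for a in mol.GetAtoms())
                / max(mol.GetNumAtoms(), 1)
            ),
        }
        molh = _embed(mol, conformer_seed)
        d["gyration_radius"] = Descriptors3D.RadiusOfGyration(molh)
        d["chiral_volume_sum"] = _chiral_volume_sum(molh)
        return d


class RDKitDescriptorProvider:
    """Full RDKit descriptor set: every 2D descriptor in ``Descriptors.descList``
    plus the standard 3D shape descriptors and the chirality-signed volume sum
    (several hundred raw features; non-finite values are left for
    :func:`clean_feature_matrix` to drop)."""

    name = "rdkit-full-v1"

    _3d = (
        "Asphericity",
        "Eccentricity",
        "InertialShapeFactor",
        "NPR1",
        "NPR2",
        "PMI1",
        "PMI2",
        "PMI3",
        "RadiusOfGyration",
        "SpherocityIndex",
    )

    def __call__(self, mol: Chem.Mol, conformer_seed: int = 17) -> dict[str, float]:
        d: dict[str, float] = {}
        for name, fn in Descriptors.descList:
            try:
                d[name] = float(fn(mol))
            except Exception:
                d[name] = float("nan")
        molh = _embed(mol, conformer_seed)
        for name in self._3d:
            d[name] = float(getattr(Descriptors3D, name)(molh))
        d["chiral_volume_sum"] = _chiral_volume_sum(molh)
        return d


def get_provider(name: str) -> DescriptorProvider:
    if name in ("minimal", "minimal-v1"):
        return MinimalDescriptorProvider()
    if name in ("rdkit", "rdkit-full", "rdkit-full-v1"):
        return RDKitDescriptorProvider()
    raise KeyError(f"unknown descriptor provider {name!r}")


# ---------------------------------------------------------------------------
# feature vectors


def guest_feature_vector(
    structure: str, provider: DescriptorProvider, conformer_seed: int = 17
) -> pd.Series:
    """Descriptor vector of a guest structure (deterministic for fixed seed)."""
    mol = parse_structure(structure)
    vec = provider(mol, conformer_seed)
    return pd.Series(vec, dtype=float).rename(structure)


def cd_feature_vector(
    decomposition: CDDecomposition, provider: DescriptorProvider, conformer_seed: int = 17
) -> pd.Series:
    """``[n_glucose] + fragment descriptors + [degree of substitution]``."""
    frag = provider(parse_structure(decomposition.side_chain_fragment), conformer_seed)
    out = {"n_glucose": float(decomposition.n_glucose)}
    out.update(frag)
    out["degree_of_substitution"] = decomposition.degree_of_substitution
    return pd.Series(out, dtype=float)


def system_feature_vector(guest_fv: pd.Series, cd_fv: pd.Series) -> pd.Series:
    """Concatenate guest and CD vectors under ``guest.``/``cd.`` namespaces."""
    if len(guest_fv) == 0 or len(cd_fv) == 0:
        raise ValueError("schema_mismatch: empty feature vector")
    g = guest_fv.rename(lambda c: f"guest.{c}")
    c = cd_fv.rename(lambda c: f"cd.{c}")
    return pd.concat([g, c])


def clean_feature_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop features missing/non-finite for any record or constant across all.

    Returns the cleaned matrix and the retained feature names, which must be
    reused verbatim at prediction time.
    """
    finite = matrix.replace([np.inf, -np.inf], np.nan)
    keep = finite.columns[finite.notna().all(axis=0)]
    cleaned = finite[keep]
    if len(cleaned) > 1:
        keep = cleaned.columns[cleaned.nunique(dropna=False) > 1]
        cleaned = cleaned[keep]
    if cleaned.shape[1] == 0:
        raise ValueError("all features dropped during cleaning")
    return cleaned, list(cleaned.columns)


# ---------------------------------------------------------------------------
# sklearn-style featurizer


from sklearn.base import BaseEstimator, TransformerMixin  # noqa: E402


class SystemFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer mapping (guest structure, CD spec) pairs to a feature matrix.

    ``fit`` computes raw guest+CD descriptors for the training pairs and
    records the retained (finite, non-constant) feature names;
    ``transform`` recomputes descriptors and reindexes onto exactly that
    schema, raising if a retained feature cannot be produced.

    Parameters
    ----------
    provider : str
        Descriptor provider id (``"minimal"`` or ``"rdkit-full"``).
    conformer_seed : int
        Random seed for 3D conformer embedding; part of the feature schema.
    """

    def __init__(self, provider: str = "minimal", conformer_seed: int = 17):
        self.provider = provider
        self.conformer_seed = conformer_seed

    def _raw_matrix(self, pairs) -> pd.DataFrame:
        prov = get_provider(self.provider)
        guest_cache: dict[str, pd.Series] = {}
        cd_cache: dict[str, pd.Series] = {}
        rows = []
        for guest, cd in pairs:
            if guest not in guest_cache:
                guest_cache[guest] = guest_feature_vector(guest, prov, self.conformer_seed)
            if cd not in cd_cache:
                cd_cache[cd] = cd_feature_vector(
                    decompose_cyclodextrin(cd), prov, self.conformer_seed
                )
            rows.append(system_feature_vector(guest_cache[guest], cd_cache[cd]))
        return pd.DataFrame(rows).reset_index(drop=True)

    def fit(self, X, y=None):
        """X: sequence of (guest structure, CD name-or-structure) pairs."""
        raw = self._raw_matrix(X)
        _, self.feature_names_ = clean_feature_matrix(raw)
        return self

    def transform(self, X) -> pd.DataFrame:
        raw = self._raw_matrix(X)
        missing = [c for c in self.feature_names_ if c not in raw.columns]
        if missing:
            raise ValueError(f"schema_mismatch: missing features {missing[:5]}")
        out = raw[self.feature_names_]
        if not np.isfinite(out.to_numpy()).all():
            raise ValueError("schema_mismatch: non-finite value in retained feature")
        return out

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        raw = self._raw_matrix(X)
        cleaned, self.feature_names_ = clean_feature_matrix(raw)
        return cleaned
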