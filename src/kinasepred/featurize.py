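"""Molecular fingerprints with bit -> atom-set provenance.

Three binary fingerprint kinds are supported:

``morgan``            hashed circular atom environments, radius 2, 2048 bits
``path_subgraph``     hashed bond-path subgraphs, 1-7 bonds, 2048 bits
``substructure_keys`` the 881-position substructure-key dictionary

Every fingerprint carries a ``bit_atoms`` map recording, for each set
bit, the heavy-atom index sets of all environments / subgraphs / pattern
matches that fired it. This provenance is what makes atom-level
retro-mapping of attribution scores possible downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from . import keys881
from .curation import LabeledDataset, MoleculeRecord

FINGERPRINT_KINDS = ("morgan", "path_subgraph", "substructure_keys")
FP_LENGTH = {"morgan": 2048, "path_subgraph": 2048, "substructure_keys": 881}

DEFAULT_MORGAN_RADIUS = 2
DEFAULT_NBITS = 2048
DEFAULT_MIN_PATH = 1
DEFAULT_MAX_PATH = 7


@dataclass
class Fingerprint:
    """Binary feature vector plus provenance for each set bit."""

    kind: str
    bits: np.ndarray  # uint8, length per kind
    bit_atoms: dict[int, list[frozenset[int]]]
    n_heavy_atoms: int

    def __post_init__(self) -> None:
        if self.kind not in FINGERPRINT_KINDS:
            raise ValueError(f"unknown fingerprint kind {self.kind!r}")
        expected = FP_LENGTH[self.kind]
        if len(self.bits) != expected:
            raise ValueError(
                f"{self.kind} fingerprint must have {expected} bits, "
                f"got {len(self.bits)}"
            )
        for bit, atom_sets in self.bit_atoms.items():
            if not self.bits[bit]:
                raise ValueError(f"provenance for unset bit {bit}")
            for atoms in atom_sets:
                for a in atoms:
                    if a >= self.n_heavy_atoms:
                        raise ValueError(
                            f"atom index {a} out of range for bit {bit}"
                        )

    @property
    def on_bits(self) -> list[int]:
        return np.flatnonzero(self.bits).tolist()


@dataclass
class FeatureMatrix:
    """Row-per-compound binary matrix in dataset order."""

    compound_ids: list[str]
    kind: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.compound_ids), FP_LENGTH[self.kind]):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.compound_ids)} ids and kind {self.kind}"
            )


def _as_mol(molecule: Chem.Mol | MoleculeRecord | str) -> Chem.Mol:
    if isinstance(molecule, Chem.Mol):
        return molecule
    if isinstance(molecule, MoleculeRecord):
        if not molecule.kept or molecule.smiles_std is None:
            raise ValueError(
                f"cannot featurize rejected record {molecule.compound_id!r}"
            )
        smiles = molecule.smiles_std
    else:
        smiles = molecule
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    return mol


def _check_nonempty(mol: Chem.Mol) -> None:
    if mol.GetNumHeavyAtoms() == 0:
        raise ValueError("cannot fingerprint an empty molecule")


def morgan_fp(
    molecule,
    radius: int = DEFAULT_MORGAN_RADIUS,
    nbits: int = DEFAULT_NBITS,
) -> Fingerprint:
    """Hashed circular fingerprint with per-bit environment provenance.

    Environment invariants are the default connectivity invariants
    (element, charge, degree, H count, ring membership); chirality is
    not used and bits are binary.
    """
    mol = _as_mol(molecule)
    _check_nonempty(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    bv = gen.GetFingerprint(mol, additionalOutput=ao)
    bits = np.zeros(nbits, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    bit_atoms: dict[int, list[frozenset[int]]] = {}
    for bit, envs in ao.GetBitInfoMap().items():
        sets = []
        for center, env_radius in envs:
            if env_radius == 0:
                sets.append(frozenset([center]))
                continue
            bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, env_radius, center)
            atoms = {center}
            for bid in bond_ids:
                bond = mol.GetBondWithIdx(bid)
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
            sets.append(frozenset(atoms))
        bit_atoms[bit] = sets
    return Fingerprint("morgan", bits, bit_atoms, mol.GetNumHeavyAtoms())


def path_subgraph_fp(
    molecule,
    nbits: int = DEFAULT_NBITS,
    min_size: int = DEFAULT_MIN_PATH,
    max_size: int = DEFAULT_MAX_PATH,
) -> Fingerprint:
    """Hashed bond-path/subgraph fingerprint with subgraph provenance."""
    mol = _as_mol(molecule)
    _check_nonempty(mol)
    bit_info: dict[int, list[list[int]]] = {}
    bv = Chem.RDKFingerprint(
        mol,
        minPath=min_size,
        maxPath=max_size,
        fpSize=nbits,
        bitInfo=bit_info,
    )
    bits = np.zeros(nbits, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    bit_atoms: dict[int, list[frozenset[int]]] = {}
    for bit, paths in bit_info.items():
        sets = []
        for bond_path in paths:
            atoms: set[int] = set()
            for bid in bond_path:
                bond = mol.GetBondWithIdx(bid)
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
            sets.append(frozenset(atoms))
        # distinct atom sets only: identical duplicated fragments hash to
        # the same bit and the same induced set-bit pattern
        bit_atoms[bit] = sets
    return Fingerprint("path_subgraph", bits, bit_atoms, mol.GetNumHeavyAtoms())


def substructure_keys_fp(molecule) -> Fingerprint:
    """881-position substructure-key fingerprint.

    Pattern-type keys carry match-atom provenance; count-type keys
    (element and ring counts) have empty provenance and are excluded
    from atom retro-mapping.
    """
    mol = _as_mol(molecule)
    _check_nonempty(mol)
    on_bits, provenance = keys881.evaluate(mol)
    bits = np.zeros(keys881.N_BITS, dtype=np.uint8)
    bits[on_bits] = 1
    bit_atoms = {
        bit: [frozenset(match) for match in matches]
        for bit, matches in provenance.items()
        if matches
    }
    return Fingerprint(
        "substructure_keys", bits, bit_atoms, mol.GetNumHeavyAtoms()
    )


_FP_FUNCS = {
    "morgan": morgan_fp,
    "path_subgraph": path_subgraph_fp,
    "substructure_keys": substructure_keys_fp,
}


def fingerprint(molecule, kind: str, **kwargs) -> Fingerprint:
    """Dispatch to the fingerprint function for ``kind``."""
    if kind not in _FP_FUNCS:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    return _FP_FUNCS[kind](molecule, **kwargs)


def featurize_dataset(dataset: LabeledDataset, kind: str) -> FeatureMatrix:
    """Fingerprint every record of a dataset, preserving row order."""
    rows = []
    ids = []
    for rec, _ in dataset.records:
        try:
            rows.append(fingerprint(rec, kind).bits)
        except ValueError as exc:
            raise ValueError(
                f"failed to featurize compound {rec.compound_id!r}: {exc}"
            ) from exc
        ids.append(rec.compound_id)
    matrix = (
        np.vstack(rows) if rows else np.zeros((0, FP_LENGTH[kind]), dtype=np.uint8)
    )
    return FeatureMatrix(compound_ids=ids, kind=kind, matrix=matrix)


def featurize_molecules(
    molecules: list[MoleculeRecord], kind: str
) -> FeatureMatrix:
    """Fingerprint a list of kept molecule records."""
    rows = []
    ids = []
    for rec in molecules:
        rows.append(fingerprint(rec, kind).bits)
        ids.append(rec.compound_id)
    matrix = (
        np.vstack(rows) if rows else np.zeros((0, FP_LENGTH[kind]), dtype=np.uint8)
    )
    return FeatureMatrix(compound_ids=ids, kind=kind, matrix=matrix)
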