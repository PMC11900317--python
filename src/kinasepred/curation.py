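"""Compound curation: standardization, filters, labeling, balancing, splits.

The pipeline mirrors a typical bioactivity-database preparation protocol:
parse SMILES, keep the largest organic fragment, neutralize and re-ionize
at physiological pH with a fixed rule table, reject molecules with
disallowed elements / extreme size, collapse duplicates on the canonical
standardized SMILES, balance actives with randomly drawn decoys, and split
80:20 (stratified) for model development.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Elements allowed in curated structures (plus implicit/explicit hydrogen).
ALLOWED_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"]
)

MAX_MOL_WEIGHT = 800.0  # Da, inclusive
MIN_HEAVY_ATOMS = 15  # inclusive

#: Activity value (nM) at or below which a compound counts as active (10 uM).
ACTIVITY_THRESHOLD_NM = 10_000.0
#: Minimum target-assignment confidence for a usable activity record.
MIN_CONFIDENCE = 9

ACTIVITY_TYPES = ("IC50", "Ki", "Kd", "EC50")


class RejectReason(str, Enum):
    PARSE_ERROR = "parse_error"
    VALENCE_ERROR = "valence_error"
    DISALLOWED_ELEMENT = "disallowed_element"
    MW_TOO_HIGH = "mw_too_high"
    TOO_FEW_HEAVY_ATOMS = "too_few_heavy_atoms"
    DUPLICATE = "duplicate"


@dataclass
class RawActivityRecord:
    """One activity measurement for a compound against a target."""

    compound_id: str
    smiles: str
    target_id: str
    activity_type: str
    value_nM: float
    confidence: int

    def __post_init__(self) -> None:
        if self.activity_type not in ACTIVITY_TYPES:
            raise ValueError(
                f"activity_type must be one of {ACTIVITY_TYPES}, "
                f"got {self.activity_type!r}"
            )
        if not self.value_nM > 0:
            raise ValueError(f"value_nM must be positive, got {self.value_nM}")
        if not 0 <= int(self.confidence) <= 9:
            raise ValueError(f"confidence must be in [0, 9], got {self.confidence}")


@dataclass
class MoleculeRecord:
    """A standardized compound with provenance and rejection status."""

    compound_id: str
    smiles_raw: str
    smiles_std: str | None = None
    heavy_atoms: int = 0
    mol_weight: float = 0.0
    status: str = "kept"
    reject_reason: RejectReason | None = None

    @property
    def kept(self) -> bool:
        return self.status == "kept"

    def rejected(self, reason: RejectReason) -> "MoleculeRecord":
        return replace(self, status="rejected", reject_reason=reason)


@dataclass
class LabeledDataset:
    """Curated records with binary labels; the unit models train on."""

    records: list[tuple[MoleculeRecord, str]]
    source_tag: str = ""

    def __post_init__(self) -> None:
        for rec, label in self.records:
            if not rec.kept:
                raise ValueError(f"record {rec.compound_id} is not kept")
            if label not in ("active", "inactive"):
                raise ValueError(f"bad label {label!r}")
        seen: set[str] = set()
        for rec, _ in self.records:
            if rec.smiles_std in seen:
                raise ValueError(f"duplicate smiles_std: {rec.smiles_std}")
            seen.add(rec.smiles_std)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def class_counts(self) -> tuple[int, int]:
        n_act = sum(1 for _, lab in self.records if lab == "active")
        return n_act, len(self.records) - n_act

    @property
    def labels(self) -> np.ndarray:
        return np.array([1 if lab == "active" else 0 for _, lab in self.records])

    @property
    def molecules(self) -> list[MoleculeRecord]:
        return [rec for rec, _ in self.records]


@dataclass
class SplitSpec:
    """A train/test partition of dataset indices."""

    train_indices: list[int]
    test_indices: list[int]
    train_fraction: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_indices) & set(self.test_indices)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

# Re-ionization rule table applied at pH 7.4, in order. Acidic groups that
# are essentially fully deprotonated at 7.4 become anions; basic aliphatic
# nitrogens become cations. Everything else is left neutral.
_REIONIZE_RULES: list[tuple[str, int]] = [
    # carboxylic acid -> carboxylate
    ("[CX3](=O)[OX2H1]", -1),
    # sulfonic acid -> sulfonate
    ("[SX4](=O)(=O)[OX2H1]", -1),
    # phosphonic/phosphoric acid OH -> anion (first proton only)
    ("[PX4](=O)[OX2H1]", -1),
    # amidine / guanidine carbon=N -> protonated on the sp2 N
    ("[NX2;H0,H1]=[CX3]([NX3])", +1),
    # aliphatic primary/secondary/tertiary amine -> ammonium
    (
        "[NX3;H2,H1,H0;+0;!$(N-C=[O,N,S]);!$(N-S=O);!$(N-a);!$(N=*);"
        "!$(N-[O,N]);!$(N#*)]",
        +1,
    ),
]
_REIONIZE_PATTERNS = [
    (Chem.MolFromSmarts(smarts), charge) for smarts, charge in _REIONIZE_RULES
]


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]

    def key(frag: Chem.Mol) -> tuple:
        return (
            frag.GetNumHeavyAtoms(),
            Descriptors.MolWt(frag),
            Chem.MolToSmiles(frag),
        )

    return max(frags, key=key)


def _reionize(mol: Chem.Mol) -> Chem.Mol:
    mol = Chem.RWMol(mol)
    claimed: set[int] = set()
    for pattern, charge in _REIONIZE_PATTERNS:
        if pattern is None:  # pragma: no cover - table is static
            continue
        for match in mol.GetSubstructMatches(pattern):
            if charge < 0:
                # the protonated O/acidic H carrier is the last SMARTS atom
                idx = match[-1]
                atom = mol.GetAtomWithIdx(idx)
                if idx in claimed or atom.GetFormalCharge() != 0:
                    continue
                if atom.GetTotalNumHs() < 1:
                    continue
                atom.SetFormalCharge(-1)
                atom.SetNumExplicitHs(max(atom.GetNumExplicitHs() - 1, 0))
                atom.SetNoImplicit(True)
                claimed.add(idx)
            else:
                idx = match[0]
                atom = mol.GetAtomWithIdx(idx)
                if idx in claimed or atom.GetFormalCharge() != 0:
                    continue
                atom.SetFormalCharge(+1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
                atom.SetNoImplicit(True)
                claimed.add(idx)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def standardize_structure(smiles: str, compound_id: str = "") -> MoleculeRecord:
    """Standardize one SMILES string into a :class:`MoleculeRecord`.

    Steps: parse; keep the largest fragment (heavy atoms, then MW, then
    canonical-SMILES tiebreak); neutralize all charges where valence
    allows; re-ionize with the fixed pH-7.4 rule table; emit canonical
    SMILES. Failures are reported through ``status``/``reject_reason``,
    never raised.
    """
    record = MoleculeRecord(compound_id=compound_id, smiles_raw=smiles)
    if not isinstance(smiles, str) or not smiles.strip():
        return record.rejected(RejectReason.PARSE_ERROR)

    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None or mol.GetNumAtoms() == 0:
        return record.rejected(RejectReason.PARSE_ERROR)
    try:
        Chem.SanitizeMol(mol)
    except Chem.AtomValenceException:
        return record.rejected(RejectReason.VALENCE_ERROR)
    except Exception:
        return record.rejected(RejectReason.PARSE_ERROR)

    try:
        mol = _largest_fragment(mol)
        Chem.SanitizeMol(mol)
        mol = rdMolStandardize.Uncharger().uncharge(mol)
        mol = _reionize(mol)
        smiles_std = Chem.MolToSmiles(mol)
    except Exception:
        return record.rejected(RejectReason.VALENCE_ERROR)

    return replace(
        record,
        smiles_std=smiles_std,
        heavy_atoms=mol.GetNumHeavyAtoms(),
        mol_weight=Descriptors.MolWt(mol),
    )


def apply_filters(record: MoleculeRecord) -> MoleculeRecord:
    """Classify a parsed record against element / MW / heavy-atom rules.

    Boundaries are inclusive on the keep side: MW <= 800 Da and
    heavy atoms >= 15 are kept. Idempotent.
    """
    if not record.kept:
        return record
    if record.smiles_std is None:
        raise ValueError("apply_filters requires a standardized record")
    mol = Chem.MolFromSmiles(record.smiles_std)
    if mol is None:  # pragma: no cover - smiles_std is canonical
        return record.rejected(RejectReason.PARSE_ERROR)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ALLOWED_ELEMENTS:
            return record.rejected(RejectReason.DISALLOWED_ELEMENT)
    if record.mol_weight > MAX_MOL_WEIGHT:
        return record.rejected(RejectReason.MW_TOO_HIGH)
    if record.heavy_atoms < MIN_HEAVY_ATOMS:
        return record.rejected(RejectReason.TOO_FEW_HEAVY_ATOMS)
    return record


def deduplicate(records: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """Mark later occurrences of the same ``smiles_std`` as duplicates.

    First occurrence wins; output order is the input order. Records that
    are already rejected pass through untouched.
    """
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    for rec in records:
        if rec.kept and rec.smiles_std is not None:
            if rec.smiles_std in seen:
                rec = rec.rejected(RejectReason.DUPLICATE)
            else:
                seen.add(rec.smiles_std)
        out.append(rec)
    return out


def curate_structures(
    smiles_and_ids: Iterable[tuple[str, str]],
) -> list[MoleculeRecord]:
    """Full structure pipeline: standardize -> filter -> deduplicate."""
    records = [standardize_structure(smi, cid) for smi, cid in smiles_and_ids]
    records = [apply_filters(r) if r.kept else r for r in records]
    return deduplicate(records)


def curation_report(records: Sequence[MoleculeRecord]) -> dict:
    """Count kept records and per-reason rejections; counts sum to input."""
    report = {"input": len(records), "kept": 0, "rejected": {}}
    for rec in records:
        if rec.kept:
            report["kept"] += 1
        else:
            reason = rec.reject_reason.value
            report["rejected"][reason] = report["rejected"].get(reason, 0) + 1
    return report


# ---------------------------------------------------------------------------
# labeling and dataset assembly
# ---------------------------------------------------------------------------


def label_family_active(records: Sequence[RawActivityRecord]) -> str:
    """Family-level label for one compound's activity records.

    ``"active"`` iff at least one record has value <= 10 uM (10,000 nM)
    with confidence >= 9; otherwise ``"excluded"`` (such compounds do not
    enter the family dataset at all).
    """
    if records:
        ids = {r.compound_id for r in records}
        if len(ids) > 1:
            raise ValueError(f"records span multiple compounds: {sorted(ids)}")
    for rec in records:
        if rec.value_nM <= ACTIVITY_THRESHOLD_NM and rec.confidence >= MIN_CONFIDENCE:
            return "active"
    return "excluded"


def build_family_dataset(
    actives: LabeledDataset,
    decoy_pool: Sequence[MoleculeRecord],
    seed: int,
    source_tag: str = "family",
) -> LabeledDataset:
    """Balance actives with an equal number of decoys sampled without
    replacement (uniformly, seeded)."""
    n_act = len(actives)
    pool = [m for m in decoy_pool if m.kept]
    active_smiles = {rec.smiles_std for rec, _ in actives.records}
    pool = [m for m in pool if m.smiles_std not in active_smiles]
    if len(pool) < n_act:
        raise ValueError(
            f"decoy pool too small: need {n_act}, have {len(pool)} "
            f"(shortfall {n_act - len(pool)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n_act, replace=False)
    records = list(actives.records)
    records.extend((pool[i], "inactive") for i in sorted(chosen))
    return LabeledDataset(records=records, source_tag=source_tag)


def split_sizes(n: int, train_fraction: float) -> tuple[int, int]:
    """Train/test sizes under the floor convention: |train| = floor(f*N)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(np.floor(train_fraction * n))
    return n_train, n - n_train


def make_split(
    dataset: LabeledDataset, train_fraction: float, seed: int
) -> SplitSpec:
    """Stratified train/test split with |train| = floor(f*N), seeded.

    Per-class train counts are the floors of the ideal allocations,
    topped up by largest fractional remainder until the total matches.
    """
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train, _ = split_sizes(n, train_fraction)
    labels = dataset.labels
    rng = np.random.default_rng(seed)

    classes = sorted(set(labels.tolist()))
    by_class = {c: np.flatnonzero(labels == c) for c in classes}
    ideal = {c: train_fraction * len(by_class[c]) for c in classes}
    take = {c: int(np.floor(ideal[c])) for c in classes}
    short = n_train - sum(take.values())
    for c in sorted(classes, key=lambda c: ideal[c] - take[c], reverse=True):
        if short <= 0:
            break
        take[c] += 1
        short -= 1

    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in classes:
        idx = by_class[c].copy()
        rng.shuffle(idx)
        train_idx.extend(idx[: take[c]].tolist())
        test_idx.extend(idx[take[c] :].tolist())
    return SplitSpec(
        train_indices=sorted(train_idx),
        test_indices=sorted(test_idx),
        train_fraction=train_fraction,
        seed=seed,
    )


def subtract_by_structure(
    library: Sequence[MoleculeRecord], reference: Sequence[MoleculeRecord]
) -> list[MoleculeRecord]:
    """Library members whose smiles_std does not occur in the reference."""
    ref = {m.smiles_std for m in reference if m.smiles_std is not None}
    return [m for m in library if m.smiles_std not in ref]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_activity_csv(path: str | Path) -> list[RawActivityRecord]:
    """Read an activity table (compound_id, smiles, target_id,
    activity_type, value_nM, confidence)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {
        "compound_id",
        "smiles",
        "target_id",
        "activity_type",
        "value_nM",
        "confidence",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"activity CSV missing columns: {sorted(missing)}")
    return [
        RawActivityRecord(
            compound_id=str(row.compound_id),
            smiles=str(row.smiles),
            target_id=str(row.target_id),
            activity_type=str(row.activity_type),
            value_nM=float(row.value_nM),
            confidence=int(row.confidence),
        )
        for row in df.itertuples(index=False)
    ]


def read_smi(path: str | Path) -> list[tuple[str, str]]:
    """Read a .smi file: ``SMILES whitespace id`` per line. Missing ids get
    sequential names."""
    out: list[tuple[str, str]] = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        smi = parts[0]
        cid = parts[1].strip() if len(parts) > 1 else f"mol_{i}"
        out.append((smi, cid))
    return out


def read_sdf(path: str | Path) -> list[tuple[str, str]]:
    """Read structures from an SDF file as (smiles, id) pairs."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=False)
    out: list[tuple[str, str]] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol_{i}"
        out.append((Chem.MolToSmiles(mol), cid or f"mol_{i}"))
    return out


def write_dataset_csv(dataset: LabeledDataset, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "compound_id": [rec.compound_id for rec, _ in dataset.records],
            "smiles_std": [rec.smiles_std for rec, _ in dataset.records],
            "label": [lab for _, lab in dataset.records],
            "source_tag": dataset.source_tag,
        }
    ).to_csv(path, index=False)


def read_dataset_csv(path: str | Path) -> LabeledDataset:
    import pandas as pd

    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        rec = MoleculeRecord(
            compound_id=str(row.compound_id),
            smiles_raw=str(row.smiles_std),
            smiles_std=str(row.smiles_std),
        )
        mol = Chem.MolFromSmiles(rec.smiles_std)
        if mol is not None:
            rec.heavy_atoms = mol.GetNumHeavyAtoms()
            rec.mol_weight = Descriptors.MolWt(mol)
        records.append((rec, str(row.label)))
    tag = str(df["source_tag"].iloc[0]) if "source_tag" in df and len(df) else ""
    return LabeledDataset(records=records, source_tag=tag)


def write_split_json(split: SplitSpec, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "seed": split.seed,
                "train_fraction": split.train_fraction,
                "train_indices": split.train_indices,
                "test_indices": split.test_indices,
            }
        )
    )
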