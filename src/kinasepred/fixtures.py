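"""Deterministic synthetic datasets with a planted activity motif.

Molecules are enumerated combinatorially from scaffold templates and
substituent fragments. "Active" molecules carry a planted fused-bicycle
motif (a 7-azaindole, echoing classic hinge-binding chemotypes);
"inactive" molecules never contain it. Every generated structure passes
the curation filters by construction, which makes these fixtures suitable
for end-to-end pipeline tests with no external data.

Templates contain ``{X}`` (a variable substituent) and ``{Y}`` (either the
motif or a benign group). Ring-closure digits are partitioned between
templates (1-2), Y fragments (3-4), and X fragments (5-6), so plain string
substitution always yields valid SMILES.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem

from .curation import (
    LabeledDataset,
    MoleculeRecord,
    RawActivityRecord,
    apply_filters,
    standardize_structure,
)

#: The planted motif (7-azaindole core) as a canonical SMILES.
DEFAULT_MOTIF = "c1cnc2[nH]ccc2c1"
#: The motif as an attachable fragment (methylene-linked, digits 3-4).
MOTIF_FRAGMENT = "Cc3cnc4[nH]ccc4c3"

DEFAULT_SCAFFOLDS: tuple[str, ...] = (
    "O=C(N{X})c1ccc({Y})cc1",
    "O=C(N{X})c1cccc({Y})c1",
    "O=S(=O)(N{X})c1ccc({Y})cc1",
    "O=C(O{X})c1ccc({Y})cc1",
    "CN({X})C(=O)c1ccc({Y})cc1",
    "O=C(N{X})c1ccc2cc({Y})ccc2c1",
    "O=C(N{X})c1ccc(O{Y})cc1",
    "O=C(N{X})c1ccc(S{Y})cc1",
    "O=C(N{X})Cc1ccc({Y})cc1",
    "O=C(N{X})CCc1ccc({Y})cc1",
    "O=C(N{X})c1ccc(C{Y})cc1",
    "O=C(N{X})c1ccc({Y})cn1",
    "O=C(N{X})c1ccc({Y})cc1F",
    "O=C(N{X})c1cc({Y})ccc1C",
    "CCN({X})C(=O)c1ccc({Y})cc1",
    "O=C(N{X})c1ccc(CO{Y})cc1",
)

DEFAULT_X_SUBSTITUENTS: tuple[str, ...] = (
    "CCCCC", "CCCCCC", "CC(C)CC", "CC(C)CCC", "CCOCC", "CCOCCC", "CCSCC",
    "CCCCF", "CCCCCl", "CC(F)CC", "CCCC#N", "CCc5ccccc5", "Cc5ccccc5",
    "CCc5ccncc5", "CCS(=O)(=O)C", "CCC(=O)OC", "CCOC(C)C",
    "CCc5ccc(F)cc5", "CCc5ccc(Cl)cc5", "CCc5ccc(C)cc5",
)

DEFAULT_Y_BENIGN: tuple[str, ...] = ("C", "CC", "CCC", "CCO", "COC", "CC(C)C")


@dataclass
class FixtureSpec:
    """Recipe for one planted-motif dataset."""

    n_active: int = 200
    n_inactive: int = 200
    motif: str = DEFAULT_MOTIF
    motif_fragment: str = MOTIF_FRAGMENT
    scaffolds: tuple[str, ...] = DEFAULT_SCAFFOLDS
    x_substituents: tuple[str, ...] = DEFAULT_X_SUBSTITUENTS
    y_benign: tuple[str, ...] = DEFAULT_Y_BENIGN
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.label_noise < 1:
            raise ValueError("label_noise must be in [0, 1)")


def _motif_query(motif: str) -> Chem.Mol:
    q = Chem.MolFromSmiles(motif)
    if q is None:
        q = Chem.MolFromSmarts(motif)
    if q is None:
        raise ValueError(f"unparsable motif {motif!r}")
    return q


def _build_record(smiles: str, compound_id: str, motif_q: Chem.Mol, want_motif: bool) -> MoleculeRecord:
    rec = apply_filters(standardize_structure(smiles, compound_id))
    if not rec.kept:
        raise AssertionError(
            f"fixture molecule failed curation ({rec.reject_reason}): {smiles}"
        )
    mol = Chem.MolFromSmiles(rec.smiles_std)
    has = mol.HasSubstructMatch(motif_q)
    if has != want_motif:
        raise AssertionError(
            f"motif constraint violated for {smiles} (want={want_motif})"
        )
    return rec


def generate_family_fixture(spec: FixtureSpec) -> LabeledDataset:
    """Enumerate a balanced-by-request planted-motif dataset.

    Actives are scaffold x X-substituent products carrying the motif at
    the Y position; inactives replace it with a benign group. Enumeration
    order is shuffled deterministically with the spec seed, and label
    noise (exact flip count ``round(noise * N)``) is applied last.
    """
    rng = np.random.default_rng(spec.seed)
    motif_q = _motif_query(spec.motif)

    active_combos = [
        scaf.replace("{X}", x).replace("{Y}", spec.motif_fragment)
        for scaf in spec.scaffolds
        for x in spec.x_substituents
    ]
    inactive_combos = [
        scaf.replace("{X}", x).replace("{Y}", y)
        for scaf in spec.scaffolds
        for x in spec.x_substituents
        for y in spec.y_benign
    ]
    if spec.n_active > len(active_combos):
        raise ValueError(
            f"cannot generate {spec.n_active} actives; "
            f"maximum is {len(active_combos)}"
        )
    if spec.n_inactive > len(inactive_combos):
        raise ValueError(
            f"cannot generate {spec.n_inactive} inactives; "
            f"maximum is {len(inactive_combos)}"
        )

    a_order = rng.permutation(len(active_combos))
    i_order = rng.permutation(len(inactive_combos))

    records: list[tuple[MoleculeRecord, str]] = []
    seen: set[str] = set()
    n = 0
    for idx in a_order:
        if n >= spec.n_active:
            break
        rec = _build_record(
            active_combos[idx], f"ACT_{n:04d}", motif_q, want_motif=True
        )
        if rec.smiles_std in seen:
            continue
        seen.add(rec.smiles_std)
        records.append((rec, "active"))
        n += 1
    if n < spec.n_active:
        raise ValueError(
            f"only {n} distinct actives available, requested {spec.n_active}"
        )
    n = 0
    for idx in i_order:
        if n >= spec.n_inactive:
            break
        rec = _build_record(
            inactive_combos[idx], f"DEC_{n:04d}", motif_q, want_motif=False
        )
        if rec.smiles_std in seen:
            continue
        seen.add(rec.smiles_std)
        records.append((rec, "inactive"))
        n += 1
    if n < spec.n_inactive:
        raise ValueError(
            f"only {n} distinct inactives available, requested {spec.n_inactive}"
        )

    order = rng.permutation(len(records))
    records = [records[i] for i in order]

    n_flip = int(round(spec.label_noise * len(records)))
    if n_flip:
        flip_idx = rng.choice(len(records), size=n_flip, replace=False)
        for i in flip_idx:
            rec, lab = records[i]
            records[i] = (rec, "inactive" if lab == "active" else "active")

    return LabeledDataset(records=records, source_tag=f"fixture_seed{spec.seed}")


def motif_atom_indices(smiles: str, motif: str = DEFAULT_MOTIF) -> frozenset[int]:
    """Atom indices of the first planted-motif match in a molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    match = mol.GetSubstructMatch(_motif_query(motif))
    return frozenset(match)


# ---------------------------------------------------------------------------
# per-target activity fixtures
# ---------------------------------------------------------------------------

_ACTIVITY_TYPES = ("IC50", "Ki", "Kd", "EC50")


def generate_target_fixture(
    n_targets: int,
    specs: list[FixtureSpec],
    shared_compound_fraction: float = 0.0,
) -> list[RawActivityRecord]:
    """Per-target activity records for the target-model pipeline.

    Motif-bearing compounds receive potencies drawn log-uniformly in
    [10, 10^4] nM (active side of the 10 uM rule); motif-free compounds
    fall in (10^4, 10^6] nM. ``label_noise`` in a spec flips the value
    across the 10 uM boundary for that fraction of compounds, degrading
    the separability of that target's dataset. Confidence is always 9.
    A fraction of each target's compounds can be shared with the next
    target to exercise multi-target bookkeeping.
    """
    if len(specs) != n_targets:
        raise ValueError(f"need {n_targets} specs, got {len(specs)}")
    if not 0 <= shared_compound_fraction < 1:
        raise ValueError("shared_compound_fraction must be in [0, 1)")

    records: list[RawActivityRecord] = []
    datasets = [generate_family_fixture(_noise_free(spec)) for spec in specs]
    for t, (spec, dataset) in enumerate(zip(specs, datasets)):
        rng = np.random.default_rng(spec.seed + 7919 * (t + 1))
        target_id = f"KIN{t:03d}"
        entries = list(dataset.records)
        if shared_compound_fraction and t > 0:
            prev = datasets[t - 1].records
            n_share = int(shared_compound_fraction * len(prev))
            entries = entries + list(prev[:n_share])
        n_flip = int(round(spec.label_noise * len(entries)))
        flip = set(
            rng.choice(len(entries), size=n_flip, replace=False).tolist()
            if n_flip
            else []
        )
        for i, (rec, label) in enumerate(entries):
            is_active = (label == "active") ^ (i in flip)
            if is_active:
                value = 10 ** rng.uniform(1, 4)
            else:
                value = 10 ** rng.uniform(4 + 1e-9, 6)
            records.append(
                RawActivityRecord(
                    compound_id=f"{target_id}_{rec.compound_id}",
                    smiles=rec.smiles_std,
                    target_id=target_id,
                    activity_type=_ACTIVITY_TYPES[i % 4],
                    value_nM=float(value),
                    confidence=9,
                )
            )
    return records


def _noise_free(spec: FixtureSpec) -> FixtureSpec:
    from dataclasses import replace

    return replace(spec, label_noise=0.0)


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_family_fixture(dataset: LabeledDataset, out_dir: str | Path) -> None:
    """Emit .smi + labels CSV in the curation module's input schema."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "molecules.smi", "w") as fh:
        for rec, _ in dataset.records:
            fh.write(f"{rec.smiles_std} {rec.compound_id}\n")
    pd.DataFrame(
        {
            "compound_id": [rec.compound_id for rec, _ in dataset.records],
            "smiles_std": [rec.smiles_std for rec, _ in dataset.records],
            "label": [lab for _, lab in dataset.records],
        }
    ).to_csv(out / "labels.csv", index=False)


def write_activity_fixture(
    records: list[RawActivityRecord], path: str | Path
) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "smiles": [r.smiles for r in records],
            "target_id": [r.target_id for r in records],
            "activity_type": [r.activity_type for r in records],
            "value_nM": [r.value_nM for r in records],
            "confidence": [r.confidence for r in records],
        }
    ).to_csv(path, index=False)
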