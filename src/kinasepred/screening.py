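"""Virtual screening with the family model, plus hit clustering.

Screening scores a curated compound library with a trained family model
and flags hits at a probability threshold. Hits are grouped by
sphere-exclusion (leader) clustering on Tanimoto distance of Morgan
fingerprints, processed in descending-probability order so leaders are
deterministic; the cluster representative is the member with maximal mean
similarity to its cluster (the centroid).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .curation import MoleculeRecord
from .family_model import TrainedModel, predict_proba
from .featurize import featurize_molecules

DEFAULT_CLUSTER_CUTOFF = 0.4  # Tanimoto distance


@dataclass
class ScreeningHit:
    compound_id: str
    smiles_std: str
    probability: float
    predicted: bool
    cluster_id: int | None = None
    is_representative: bool = False


def screen_library(
    model: TrainedModel,
    library: Sequence[MoleculeRecord],
    threshold: float = 0.5,
) -> list[ScreeningHit]:
    """Score a curated library; returns hits sorted by descending
    probability (ties broken by compound id for determinism).

    Refuses libraries that were not curated (any non-kept record) or that
    structurally overlap the model's training set.
    """
    bad = [m.compound_id for m in library if not m.kept or m.smiles_std is None]
    if bad:
        raise ValueError(f"library contains un-curated records: {bad[:10]}")
    if model.training_smiles:
        leaked = [
            m.compound_id for m in library if m.smiles_std in model.training_smiles
        ]
        if leaked:
            raise ValueError(
                f"library overlaps model training data: {leaked[:10]}"
                + ("..." if len(leaked) > 10 else "")
            )
    if not library:
        return []
    features = featurize_molecules(list(library), model.fingerprint_kind)
    probs = predict_proba(model, features)
    hits = [
        ScreeningHit(
            compound_id=m.compound_id,
            smiles_std=m.smiles_std,
            probability=float(p),
            predicted=bool(p >= threshold),
        )
        for m, p in zip(library, probs)
    ]
    hits.sort(key=lambda h: (-h.probability, h.compound_id))
    return hits


def _morgan_bitvects(smiles_list: Sequence[str]):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    out = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparsable SMILES {smi!r}")
        out.append(gen.GetFingerprint(mol))
    return out


def cluster_hits(
    hits: Sequence[ScreeningHit],
    distance_cutoff: float = DEFAULT_CLUSTER_CUTOFF,
) -> list[ScreeningHit]:
    """Sphere-exclusion clustering of hits on Morgan/Tanimoto distance.

    Hits are visited in descending-probability order (the order
    ``screen_library`` returns). A hit within ``distance_cutoff`` of an
    existing leader joins that leader's cluster (nearest leader wins);
    otherwise it founds a new cluster. Every hit is assigned to exactly
    one cluster; each cluster's representative is its centroid (max mean
    Tanimoto similarity to the cluster, leaders win ties).
    """
    if not hits:
        raise ValueError("no hits to cluster")
    if distance_cutoff < 0:
        raise ValueError("distance_cutoff must be >= 0")
    ordered = sorted(hits, key=lambda h: (-h.probability, h.compound_id))
    fps = _morgan_bitvects([h.smiles_std for h in ordered])

    leaders: list[int] = []
    assignment: list[int] = []
    for i in range(len(ordered)):
        if leaders:
            sims = DataStructs.BulkTanimotoSimilarity(fps[i], [fps[j] for j in leaders])
            best = int(np.argmax(sims))
            if 1.0 - sims[best] <= distance_cutoff:
                assignment.append(best)
                continue
        leaders.append(i)
        assignment.append(len(leaders) - 1)

    out = [replace(h, cluster_id=cid, is_representative=False)
           for h, cid in zip(ordered, assignment)]

    for cid in range(len(leaders)):
        members = [i for i, a in enumerate(assignment) if a == cid]
        if len(members) == 1:
            out[members[0]] = replace(out[members[0]], is_representative=True)
            continue
        member_fps = [fps[i] for i in members]
        mean_sims = []
        for i, fp in zip(members, member_fps):
            sims = DataStructs.BulkTanimotoSimilarity(fp, member_fps)
            mean_sims.append(sum(sims) / len(sims))
        rep = members[int(np.argmax(mean_sims))]
        out[rep] = replace(out[rep], is_representative=True)
    return out


def write_hits_csv(hits: Sequence[ScreeningHit], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "compound_id": [h.compound_id for h in hits],
            "smiles": [h.smiles_std for h in hits],
            "probability": [h.probability for h in hits],
            "predicted": [int(h.predicted) for h in hits],
            "cluster_id": [h.cluster_id for h in hits],
            "is_representative": [int(h.is_representative) for h in hits],
        }
    ).to_csv(path, index=False)
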