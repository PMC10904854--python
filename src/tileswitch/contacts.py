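"""Ligand-residue contact scoring and contact-fingerprint pose clustering.

The contact score of a residue is the mean number of ligand heavy atoms within
a cutoff (default 4.5 Å) of any of its heavy atoms, averaged over frames — so
a score above 1 means more than one ligand atom engaged on average, the
threshold used to call persistent interaction partners.  Bound poses are
grouped by average-linkage hierarchical clustering of per-frame binary contact
fingerprints under Jaccard distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import cdist, pdist

from .ensembles import ConformerEnsemble, Selection, select

DEFAULT_CONTACT_CUTOFF = 4.5  # Å, heavy-atom convention


@dataclass(frozen=True)
class ContactScores:
    """Residue id -> mean ligand heavy atoms in contact per frame."""

    scores: dict[int, float]
    cutoff: float
    n_frames: int


@dataclass(frozen=True)
class PoseClusters:
    """Cluster id -> member frame indices, plus a representative per cluster."""

    members: dict[int, list[int]]
    representatives: dict[int, int]
    linkage_threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.members)


def _heavy_split(ens: ConformerEnsemble, ligand_sel: Selection, residue_sel: Selection):
    lig_mask = ligand_sel.mask(ens.atoms)
    res_mask = residue_sel.mask(ens.atoms)
    if (lig_mask & res_mask).any():
        raise ValueError("ligand and residue selections overlap")
    if not lig_mask.any() or not res_mask.any():
        raise ValueError("ligand and residue selections must be non-empty")
    heavy = np.array([a.element.upper() != "H" for a in ens.atoms])
    return lig_mask & heavy, res_mask & heavy


def contact_score(
    ens: ConformerEnsemble,
    ligand_sel: Selection,
    residue_sel: Selection,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ContactScores:
    """Mean count of ligand heavy atoms within ``cutoff`` of each residue."""
    lig_mask, res_mask = _heavy_split(ens, ligand_sel, residue_sel)
    res_ids = np.array([a.residue_id for a in ens.atoms])[res_mask]
    unique_res = np.unique(res_ids)
    totals = {int(r): 0.0 for r in unique_res}
    for f in range(ens.n_frames):
        d = cdist(ens.frames[f][lig_mask], ens.frames[f][res_mask])
        within = d <= cutoff
        for r in unique_res:
            cols = res_ids == r
            # ligand atoms within cutoff of ANY heavy atom of residue r
            totals[int(r)] += int(within[:, cols].any(axis=1).sum())
    return ContactScores(
        {r: t / ens.n_frames for r, t in totals.items()}, cutoff, ens.n_frames
    )


def contact_fingerprint(
    ens: ConformerEnsemble,
    ligand_sel: Selection,
    residue_sel: Selection,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> tuple[np.ndarray, np.ndarray]:
    """(fingerprints, residue_ids): per-frame binary contact vectors.

    Bit i of frame f is set when residue i has at least one ligand heavy atom
    within ``cutoff`` in that frame.
    """
    lig_mask, res_mask = _heavy_split(ens, ligand_sel, residue_sel)
    res_ids = np.array([a.residue_id for a in ens.atoms])[res_mask]
    unique_res = np.unique(res_ids)
    fps = np.zeros((ens.n_frames, unique_res.size), dtype=bool)
    for f in range(ens.n_frames):
        d = cdist(ens.frames[f][lig_mask], ens.frames[f][res_mask])
        within = (d <= cutoff).any(axis=0)
        for j, r in enumerate(unique_res):
            fps[f, j] = within[res_ids == r].any()
    return fps, unique_res


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return 1.0 - np.logical_and(a, b).sum() / union


def cluster_poses(fingerprints: np.ndarray, distance_threshold: float = 0.5) -> PoseClusters:
    """Average-linkage Jaccard clustering of fingerprints, cut at a threshold.

    Deterministic given input order; the representative of a cluster is the
    member minimizing the summed Jaccard distance to its co-members, ties
    broken by lowest frame index.
    """
    fps = np.asarray(fingerprints, dtype=bool)
    n = fps.shape[0]
    if n < 1:
        raise ValueError("need at least one fingerprint")
    if n == 1:
        return PoseClusters({1: [0]}, {1: 0}, distance_threshold)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = _jaccard(fps[i], fps[j])
    condensed = dmat[np.triu_indices(n, 1)]
    labels = fcluster(average(condensed), t=distance_threshold, criterion="distance")
    members: dict[int, list[int]] = {}
    for frame, lab in enumerate(labels):
        members.setdefault(int(lab), []).append(frame)
    reps = {}
    for lab, idx in members.items():
        sums = dmat[np.ix_(idx, idx)].sum(axis=1)
        reps[lab] = idx[int(np.argmin(sums))]  # argmin takes lowest index on ties
    return PoseClusters(members, reps, distance_threshold)


def top_contact_residues(
    scores: ContactScores, min_score: float | None = 1.0, top_k: int | None = None
) -> list[int]:
    """Residues with score above a threshold (default >1), or the top k."""
    items = sorted(scores.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        return [r for r, _ in items[:top_k]]
    return sorted(r for r, s in scores.scores.items() if s > min_score)


def scores_to_tsv(scores: ContactScores, path) -> None:
    pd.DataFrame(
        {"residue_id": list(scores.scores), "contact_score": list(scores.scores.values())}
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def clusters_to_tsv(clusters: PoseClusters, path) -> None:
    rows = [
        {"cluster": lab, "frame": f, "representative": f == clusters.representatives[lab]}
        for lab, idx in sorted(clusters.members.items())
        for f in idx
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
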