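"""Ensemble descriptors: RMSD series, per-residue RMSF, and
conformational-family clustering with silhouette-based model selection.

Clustering follows the two-selection scheme used for chaperone
complexes: frames are first aligned on the ordered secondary-structure
backbone, then grouped by the RMSD of the remaining (disordered)
backbone, so the families differ maximally in exactly the regions free
to rearrange.  The cluster count is chosen by silhouette analysis over
a candidate range and each family is represented by its medoid frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .ensemble import Ensemble, Selection, Structure, kabsch, superpose


@dataclass
class RMSDSeries:
    """Per-frame RMSD [Å] against a reference structure."""

    values: np.ndarray
    times: np.ndarray
    replicas: np.ndarray
    fit_label: str
    measure_label: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"replica": self.replicas, "time_ns": self.times, "rmsd_A": self.values}
        )


@dataclass
class ClusterModel:
    """Conformational families of an ensemble.

    ``assignments`` are 1..K per frame; ``medoids`` holds the
    representative frame index of each cluster (the member minimising
    summed within-cluster RMSD); ``silhouettes`` maps every candidate K
    to its mean silhouette score.
    """

    n_clusters: int
    assignments: np.ndarray
    medoids: np.ndarray
    silhouettes: dict[int, float]

    def to_frame(self, ensemble: Ensemble) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(ensemble.n_frames),
                "replica": ensemble.replicas,
                "time_ns": ensemble.times,
                "cluster": self.assignments,
            }
        )


def rmsd_series(
    ensemble: Ensemble,
    fit: Selection,
    measure: Selection,
    reference: Structure | None = None,
) -> RMSDSeries:
    """RMSD of the measure selection after fitting each frame on the fit
    selection to the reference (default: the ensemble's topology)."""
    if len(fit) < 3:
        raise ValueError("fit selection needs >= 3 atoms")
    ref = reference if reference is not None else ensemble.reference
    if ref.n_atoms != ensemble.n_atoms:
        raise ValueError("reference atom count differs from ensemble")
    ref_fit = ref.coords[fit.indices]
    ref_meas = ref.coords[measure.indices]
    vals = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        r, t = kabsch(ensemble.frames[f][fit.indices], ref_fit)
        moved = ensemble.frames[f][measure.indices] @ r.T + t
        vals[f] = np.sqrt(np.mean(np.sum((moved - ref_meas) ** 2, axis=1)))
    return RMSDSeries(
        values=vals,
        times=ensemble.times.copy(),
        replicas=ensemble.replicas.copy(),
        fit_label=fit.label,
        measure_label=measure.label,
    )


def rmsf_profile(ensemble: Ensemble, selection: Selection) -> np.ndarray:
    """Per-site RMSF [Å] about the ensemble-average structure.

    Frames are superposed (on the selection) onto their average
    structure — obtained by a first pass fitted to the topology
    reference, so the result is invariant to frame order — and the
    fluctuation of each site about its mean position is reported:
    RMSF_r = sqrt(<|x_r − <x_r>|²>).
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    fitted = superpose(ensemble, selection, reference=ensemble.reference)
    avg = fitted.frames.mean(axis=0)
    avg_struct = ensemble.reference.with_coords(avg)
    fitted = superpose(ensemble, selection, reference=avg_struct)
    x = fitted.frames[:, selection.indices, :]
    mean = x.mean(axis=0)
    return np.sqrt(np.mean(np.sum((x - mean[None]) ** 2, axis=2), axis=0))


def pairwise_rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    """All-vs-all coordinate RMSD (no per-pair refitting), (F, F).

    Uses the Gram-matrix identity mean|x_f − x_g|² = m_f + m_g − 2·G_fg
    so the cost is one matrix product instead of F² passes.
    """
    f, m, _ = coords.shape
    flat = coords.reshape(f, -1)
    sq = np.einsum("ij,ij->i", flat, flat) / m
    gram = flat @ flat.T / m
    d2 = sq[:, None] + sq[None, :] - 2 * gram
    np.fill_diagonal(d2, 0.0)
    d2 = np.maximum(d2, 0.0)
    d2 = (d2 + d2.T) / 2.0
    return np.sqrt(d2)


def cluster_conformations(
    ensemble: Ensemble,
    align_selection: Selection,
    cluster_selection: Selection,
    k_candidates: range | list[int] = range(2, 11),
    linkage_method: str = "average",
) -> ClusterModel:
    """Hierarchical agglomerative clustering into conformational families.

    Frames are aligned on ``align_selection`` (ordered regions) to the
    first frame, distances are the RMSD of ``cluster_selection``
    (disordered regions), and K maximises the mean silhouette over the
    candidates (ties broken toward smaller K).  Deterministic given the
    frame order.
    """
    f = ensemble.n_frames
    k_candidates = [k for k in k_candidates if 2 <= k <= f - 1]
    if not k_candidates:
        raise ValueError("no valid candidate cluster count in [2, F-1]")
    fitted = superpose(ensemble, align_selection, reference="first")
    dist = pairwise_rmsd_matrix(fitted.frames[:, cluster_selection.indices, :])
    if dist.max() <= 1e-5:
        warnings.warn("all frames identical on the cluster selection; K = 1")
        return ClusterModel(
            n_clusters=1,
            assignments=np.ones(f, dtype=int),
            medoids=np.array([0]),
            silhouettes={},
        )
    z = linkage(squareform(dist, checks=False), method=linkage_method)
    sil: dict[int, float] = {}
    assignments: dict[int, np.ndarray] = {}
    for k in k_candidates:
        lab = fcluster(z, t=k, criterion="maxclust")
        assignments[k] = lab
        if len(np.unique(lab)) < 2:
            sil[k] = -1.0
        else:
            sil[k] = float(silhouette_score(dist, lab, metric="precomputed"))
    best = max(sorted(sil), key=lambda k: (sil[k], -k))
    lab = assignments[best]
    medoids = np.empty(len(np.unique(lab)), dtype=int)
    for ci, c in enumerate(np.unique(lab)):
        members = np.flatnonzero(lab == c)
        within = dist[np.ix_(members, members)].sum(axis=1)
        medoids[ci] = members[int(np.argmin(within))]
    return ClusterModel(
        n_clusters=int(best),
        assignments=lab,
        medoids=medoids,
        silhouettes=sil,
    )
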