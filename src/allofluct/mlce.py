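"""Matrix of Local Coupling Energies (MLCE).

A symmetric N×N residue-pair non-bonded interaction-energy matrix M
(kcal/mol, e.g. from an MM/GBSA per-residue decomposition) is
eigendecomposed, M = Σ_α λ_α v_α v_αᵀ.  The most negative eigenvalues
carry the dominant stabilising interactions, so a low-rank
reconstruction M̃ over the k most negative components isolates the
energetically defining couplings.  Masking M̃ element-wise with a Cα
contact matrix (Hadamard product) restricts the map to spatially
proximal pairs:

    MLCE_ij = M̃_ij · C_ij,   C_ij = 1 iff residues i, j are within the
                              contact cutoff (default 6 Å) and i ≠ j.

Residues whose strongest local coupling is among the most stabilising
form the folding core; contiguous stretches whose strongest coupling is
weakest are soft spots — candidate interface / unfolding-prone regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .ensemble import Selection, Structure

SYMMETRY_TOL = 1e-6


@dataclass
class EnergyMatrix:
    """Symmetric residue-pair interaction-energy matrix [kcal/mol]."""

    values: np.ndarray
    labels: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("energy matrix must be square")
        if len(self.labels) != n:
            raise ValueError("label count must match matrix size")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("energy matrix contains non-finite entries")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            warnings.warn(
                f"energy matrix asymmetric by {asym:.3g} kcal/mol; symmetrising"
            )
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        names = [f"{c}:{r}" for c, r in self.labels]
        pd.DataFrame(self.values, index=names, columns=names).to_csv(
            path, sep="\t", float_format="%.10g"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnergyMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = []
        for name in df.index:
            c, r = str(name).split(":")
            labels.append((c, int(r)))
        return cls(df.to_numpy(dtype=float), labels)


@dataclass
class ContactMatrix:
    """Binary Cα–Cα contact matrix at a distance cutoff."""

    values: np.ndarray
    cutoff: float
    labels: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("contact matrix must be symmetric")
        if np.any(np.diag(self.values)):
            raise ValueError("contact matrix diagonal must be zero")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("contact matrix entries must be 0/1")


@dataclass
class Segment:
    """A maximal sequence-contiguous residue run with its mean score."""

    chain: str
    start: int
    end: int
    indices: np.ndarray
    mean_score: float

    def __str__(self) -> str:
        return f"{self.chain}:{self.start}-{self.end} ({self.mean_score:.3f} kcal/mol)"


@dataclass
class MLCEResult:
    """Spectral reconstruction, coupling map and extracted residue sets."""

    eigenvalues: np.ndarray
    k: int
    reconstructed: np.ndarray
    coupling_map: np.ndarray
    soft_segments: list[Segment]
    core_segments: list[Segment]
    labels: list[tuple[str, int]]

    def segments_to_tsv(self, path: str | Path) -> None:
        rows = []
        for kind, segs in (("core", self.core_segments), ("soft", self.soft_segments)):
            for s in segs:
                rows.append((kind, s.chain, s.start, s.end, s.mean_score))
        pd.DataFrame(
            rows, columns=["kind", "chain", "start", "end", "mean_score"]
        ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def build_contact_matrix(
    structure: Structure,
    site_selection: Selection,
    cutoff: float = 6.0,
) -> ContactMatrix:
    """Cα contact matrix: C_ij = 1 iff i ≠ j and d(Cα_i, Cα_j) ≤ cutoff.

    The cutoff is inclusive — only pairs strictly farther than the
    cutoff are non-contacts.  ``site_selection`` must provide exactly
    one site per residue; residues lacking one are reported by name.
    """
    idx = site_selection.indices
    labels = [(str(structure.chain_ids[i]), int(structure.resids[i])) for i in idx]
    if len(set(labels)) != len(labels):
        raise ValueError("site selection maps several atoms to one residue")
    missing = [lab for lab in structure.residue_labels if lab not in set(labels)]
    if missing:
        raise ValueError(
            "no site (Cα) selected for residues: "
            + ", ".join(f"{c}:{r}" for c, r in missing)
        )
    d = squareform(pdist(structure.coords[idx]))
    c = ((d <= cutoff) & ~np.eye(len(idx), dtype=bool)).astype(int)
    return ContactMatrix(values=c, cutoff=cutoff, labels=labels)


def _select_k(eigenvalues: np.ndarray, fraction: float = 0.85) -> int:
    """Spectrum-adaptive eigenvector count.

    Include components in ascending-eigenvalue order while the running
    |λ| total over included *negative* eigenvalues stays below
    ``fraction`` of the total |λ| over all negative eigenvalues
    (minimum 1).  In a near-rank-1 spectrum this reduces to the single
    most negative eigenvector.
    """
    neg = eigenvalues[eigenvalues < 0]
    if neg.size == 0:
        return 1
    total = np.abs(neg).sum()
    cum = 0.0
    k = 0
    for lam in neg:  # ascending, most negative first
        if k >= 1 and cum >= fraction * total:
            break
        cum += abs(lam)
        k += 1
    return max(k, 1)


def spectral_reconstruct(
    energy: EnergyMatrix,
    k: int | str = "auto",
) -> tuple[np.ndarray, np.ndarray, int]:
    """Low-rank reconstruction over the most negative eigencomponents.

    Returns (eigenvalues ascending, M̃, k).  With ``k='auto'`` the
    component count follows the cumulative-|λ| rule of :func:`_select_k`;
    ``k = N`` reproduces the input exactly (completeness).
    """
    lam, vec = np.linalg.eigh(energy.values)  # ascending: most negative first
    n = lam.size
    if k == "auto":
        kk = _select_k(lam)
    else:
        kk = int(k)
        if not 1 <= kk <= n:
            raise ValueError(f"k must be in [1, {n}]")
    recon = (vec[:, :kk] * lam[:kk]) @ vec[:, :kk].T
    recon = (recon + recon.T) / 2.0
    return lam, recon, kk


def mlce_map(reconstructed: np.ndarray, contacts: ContactMatrix) -> np.ndarray:
    """Hadamard product of the reconstruction with the contact matrix."""
    r = np.asarray(reconstructed, dtype=float)
    if r.shape != contacts.values.shape:
        raise ValueError(
            f"dimension mismatch: map {r.shape} vs contacts {contacts.values.shape}"
        )
    return r * contacts.values


def residue_coupling_scores(
    coupling_map: np.ndarray, contacts: ContactMatrix
) -> np.ndarray:
    """Per-residue score: the most stabilising (minimum) coupling among
    the residue's contacts; NaN for residues with no contacts."""
    n = coupling_map.shape[0]
    scores = np.full(n, np.nan)
    for i in range(n):
        nbr = np.flatnonzero(contacts.values[i])
        if nbr.size:
            scores[i] = coupling_map[i, nbr].min()
    return scores


def extract_segments(
    coupling_map: np.ndarray,
    contacts: ContactMatrix,
    labels: list[tuple[str, int]],
    mode: str = "soft",
    fraction: float = 0.10,
    min_run_length: int = 3,
) -> list[Segment]:
    """Extract folding-core or soft-spot residue segments.

    Each residue is scored by its most stabilising contact coupling.
    Mode ``'core'`` keeps the tail ``fraction`` with the most negative
    scores (strongest couplings); mode ``'soft'`` keeps the tail whose
    strongest coupling is weakest, i.e. the scores closest to (or above)
    zero.  Values tied with the threshold are all included.  Maximal
    sequence-contiguous runs of length ≥ ``min_run_length`` within one
    chain are reported, sorted by how extreme their mean score is.
    Residues without any contact are excluded from both tails.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if mode not in ("soft", "core"):
        raise ValueError("mode must be 'soft' or 'core'")
    scores = residue_coupling_scores(coupling_map, contacts)
    valid = np.flatnonzero(np.isfinite(scores))
    if valid.size == 0:
        warnings.warn("no residue has contacts; empty result")
        return []
    sv = scores[valid]
    if np.ptp(sv) == 0:
        warnings.warn("all residue coupling scores tied; empty result")
        return []
    m = max(1, int(round(fraction * valid.size)))
    order = np.argsort(sv, kind="stable")
    if mode == "soft":
        order = order[::-1]
    threshold = sv[order[m - 1]]
    if mode == "core":
        picked = valid[sv <= threshold]
    else:
        picked = valid[sv >= threshold]
    if (mode == "core" and threshold >= sv.max()) or (
        mode == "soft" and threshold <= sv.min()
    ):
        warnings.warn("tail threshold spans all scores (ties); empty result")
        return []
    picked_set = set(picked.tolist())
    segments: list[Segment] = []
    run: list[int] = []

    def flush(run: list[int]) -> None:
        if len(run) >= min_run_length:
            idx = np.array(run)
            segments.append(
                Segment(
                    chain=labels[run[0]][0],
                    start=labels[run[0]][1],
                    end=labels[run[-1]][1],
                    indices=idx,
                    mean_score=float(scores[idx].mean()),
                )
            )

    for i in range(len(labels)):
        contiguous = (
            bool(run)
            and labels[i][0] == labels[run[-1]][0]
            and i == run[-1] + 1
        )
        if i in picked_set:
            if contiguous:
                run.append(i)
            else:
                flush(run)
                run = [i]
        else:
            flush(run)
            run = []
    flush(run)
    segments.sort(key=lambda s: s.mean_score, reverse=(mode == "soft"))
    if not segments:
        warnings.warn("no contiguous run met the minimum length; empty result")
    return segments


def run_mlce(
    energy: EnergyMatrix,
    contacts: ContactMatrix,
    k: int | str = "auto",
    fraction: float = 0.10,
    min_run_length: int = 3,
) -> MLCEResult:
    """Full MLCE pipeline: eigendecompose, reconstruct, mask, extract."""
    if contacts.values.shape[0] != energy.n_residues:
        raise ValueError("contact matrix size must match energy matrix")
    lam, recon, kk = spectral_reconstruct(energy, k=k)
    cmap = mlce_map(recon, contacts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        soft = extract_segments(cmap, contacts, energy.labels, "soft",
                                fraction, min_run_length)
        core = extract_segments(cmap, contacts, energy.labels, "core",
                                fraction, min_run_length)
    return MLCEResult(
        eigenvalues=lam,
        k=kk,
        reconstructed=recon,
        coupling_map=cmap,
        soft_segments=soft,
        core_segments=core,
        labels=list(energy.labels),
    )
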