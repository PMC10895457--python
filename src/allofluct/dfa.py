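"""Distance-fluctuation (DF) analysis of residue-pair coordination.

The DF statistic for a residue pair (i, j) is the variance of the
inter-site distance over all frames of a metatrajectory,

    DF_ij = <(d_ij - <d_ij>)^2>,

where d_ij is the Cα–Cα distance in one frame and <·> averages over
frames.  Low DF marks pairs moving quasi-rigidly (high allosteric
coordination); high DF marks uncoordinated pairs.  Being built from
internal distances the statistic is invariant to any per-frame
rigid-body motion, so superposition of the metatrajectory is optional.

The coarse views reproduce the standard presentation: block averaging
over consecutive residue stretches (default 40×40, i.e. 1600 pairs per
block) and quantisation into a small number of shades (default 5).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .ensemble import Ensemble, Selection


@dataclass
class DFMatrix:
    """Symmetric per-residue-pair distance-fluctuation matrix [Å²]."""

    values: np.ndarray
    labels: list[tuple[str, int]]
    n_frames: int
    convention: str = "variance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("DF matrix must be square")
        if len(self.labels) != n:
            raise ValueError("label count must equal matrix size")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    def as_std(self) -> "DFMatrix":
        """Square-root view (per-pair distance standard deviation, Å)."""
        return DFMatrix(np.sqrt(self.values), list(self.labels),
                        self.n_frames, convention="std")

    def to_tsv(self, path: str | Path) -> None:
        names = [f"{c}:{r}" for c, r in self.labels]
        df = pd.DataFrame(self.values, index=names, columns=names)
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, n_frames: int = 0) -> "DFMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = []
        for name in df.index:
            c, r = str(name).split(":")
            labels.append((c, int(r)))
        return cls(df.to_numpy(dtype=float), labels, n_frames)


@dataclass
class BlockDFMatrix:
    """Block-averaged DF matrix with an optional quantised view."""

    values: np.ndarray
    block_size: int
    block_labels: list[str]
    quantized: np.ndarray | None = None
    levels: int | None = None

    @property
    def n_blocks(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path, view: str = "values") -> None:
        mat = self.values if view == "values" else self.quantized
        if mat is None:
            raise ValueError("quantized view not filled")
        df = pd.DataFrame(mat, index=self.block_labels, columns=self.block_labels)
        df.to_csv(path, sep="\t", float_format="%.10g")


def _site_distances(frames: np.ndarray) -> np.ndarray:
    """Condensed per-frame pairwise distances, (F, N(N-1)/2)."""
    return np.array([pdist(f) for f in frames])


def compute_df(
    ensemble: Ensemble,
    selection: Selection,
    convention: str = "variance",
) -> DFMatrix:
    """Distance-fluctuation matrix over all frames of a metatrajectory.

    ``selection`` must map one site (typically the Cα) per residue; the
    variance is computed with an exact two-pass algorithm so results are
    bit-stable against a naive per-frame reference.
    """
    if ensemble.n_frames < 2:
        raise ValueError("DF requires at least 2 frames (variance undefined)")
    idx = selection.indices
    ref = ensemble.reference
    labels = [(str(ref.chain_ids[i]), int(ref.resids[i])) for i in idx]
    if len(set(labels)) != len(labels):
        raise ValueError("selection must map exactly one site per residue")
    coords = ensemble.frames[:, idx, :]
    f = coords.shape[0]
    # exact two-pass variance over frames, O(pairs) memory; the first
    # frame's distances serve as an offset so a rigid ensemble yields an
    # exact zero and cancellation error stays small
    d0 = pdist(coords[0])
    mean = np.zeros_like(d0)
    for frame in coords:
        mean += pdist(frame) - d0
    mean /= f
    ssq = np.zeros_like(d0)
    for frame in coords:
        dev = pdist(frame) - d0 - mean
        ssq += dev * dev
    var = ssq / f
    values = squareform(var)
    mat = DFMatrix(values, labels, n_frames=f, convention="variance")
    if convention == "std":
        return mat.as_std()
    if convention != "variance":
        raise ValueError("convention must be 'variance' or 'std'")
    return mat


def block_average(df: DFMatrix, block_size: int = 40) -> BlockDFMatrix:
    """Average DF scores over consecutive residue blocks.

    Each output entry is the arithmetic mean of its covered residue
    pairs; trailing partial blocks are averaged over their actual entry
    count rather than padded.
    """
    if block_size < 1:
        raise ValueError("block size must be >= 1")
    n = df.n_residues
    b = math.ceil(n / block_size)
    out = np.empty((b, b))
    bounds = [(k * block_size, min((k + 1) * block_size, n)) for k in range(b)]
    for p, (i0, i1) in enumerate(bounds):
        for q, (j0, j1) in enumerate(bounds):
            out[p, q] = np.sum(df.values[i0:i1, j0:j1]) / ((i1 - i0) * (j1 - j0))
    labels = []
    for i0, i1 in bounds:
        c0, r0 = df.labels[i0]
        c1, r1 = df.labels[i1 - 1]
        labels.append(f"{c0}:{r0}-{c1}:{r1}")
    return BlockDFMatrix(out, block_size=block_size, block_labels=labels)


def quantize(block: BlockDFMatrix, levels: int = 5) -> BlockDFMatrix:
    """Fill the quantised view: equal-width bins over [min, max].

    The maximum maps to the top level; a degenerate (constant) matrix
    maps entirely to level 0.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    v = block.values
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        q = np.zeros_like(v, dtype=int)
    else:
        width = (vmax - vmin) / levels
        q = np.minimum((v - vmin) // width, levels - 1).astype(int)
    return BlockDFMatrix(block.values, block.block_size, list(block.block_labels),
                         quantized=q, levels=levels)


def df_difference(a: DFMatrix, b: DFMatrix) -> np.ndarray:
    """Element-wise DF difference a − b between two ligand states [Å²]."""
    if a.labels != b.labels:
        for i, (la, lb) in enumerate(zip(a.labels, b.labels)):
            if la != lb:
                raise ValueError(
                    f"residue label mismatch at position {i}: {la} vs {lb}"
                )
        raise ValueError("residue label lists differ in length")
    return a.values - b.values


def per_residue_profile(
    df: DFMatrix,
    partners: list[int] | None = None,
) -> np.ndarray:
    """Average coordination of each residue [Å²].

    Default: row mean over all partners, excluding the diagonal.  With
    ``partners`` (0-based positional indices), averages only over that
    subset — e.g. each residue's coordination with a client protein —
    excluding the residue itself when it belongs to the subset.
    """
    v = df.values
    n = df.n_residues
    if partners is None:
        if n < 2:
            raise ValueError("profile needs at least 2 residues")
        return (v.sum(axis=1) - np.diag(v)) / (n - 1)
    partners = np.asarray(partners, dtype=int)
    if partners.size == 0:
        raise ValueError("partner subset is empty")
    out = np.empty(n)
    pset = set(partners.tolist())
    for i in range(n):
        cols = [j for j in partners if j != i]
        if not cols:
            out[i] = np.nan
            warnings.warn(f"residue {i} has no partners outside itself")
        else:
            out[i] = v[i, cols].mean()
    return out
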