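"""Structures, trajectory ensembles, atom selections and superposition.

File I/O (PDB, DCD, XTC, multi-model PDB) is delegated to MDAnalysis;
the in-memory containers here are thin typed arrays so that downstream
statistics stay independent of any trajectory library.

Conventions: lengths in Å, times in ns.  Residues keep PDB author
numbering; matrices downstream use 0-based positional indices with an
explicit (chain, resid) label map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

_BACKBONE_NAMES = ("N", "CA", "C", "O")


class FormatError(ValueError):
    """A structure or trajectory file violates its format contract."""


@dataclass
class Structure:
    """A single protein conformation with per-atom metadata.

    Attributes
    ----------
    chain_ids, resids, resnames, atom_names
        Per-atom arrays of length A.  ``resids`` carries author numbering.
    coords
        (A, 3) Cartesian coordinates in Å.
    """

    chain_ids: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    atom_names: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (A, 3)")
        if self.n_atoms < 1:
            raise FormatError("structure has zero atoms")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates")
        triples = list(zip(self.chain_ids, self.resids, self.atom_names))
        if len(set(triples)) != len(triples):
            seen: set = set()
            for t in triples:
                if t in seen:
                    raise FormatError(
                        f"duplicate atom record (chain={t[0]!r}, resid={t[1]}, "
                        f"name={t[2]!r})"
                    )
                seen.add(t)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def residue_labels(self) -> list[tuple[str, int]]:
        """Unique (chain, author resid) pairs in atom order."""
        out: list[tuple[str, int]] = []
        seen: set = set()
        for c, r in zip(self.chain_ids, self.resids):
            key = (str(c), int(r))
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    @property
    def n_residues(self) -> int:
        return len(self.residue_labels)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def to_universe(self):
        """Build an MDAnalysis Universe mirroring this structure."""
        import MDAnalysis as mda

        labels = self.residue_labels
        index_of = {lab: i for i, lab in enumerate(labels)}
        residx = np.array(
            [index_of[(str(c), int(r))] for c, r in zip(self.chain_ids, self.resids)]
        )
        res_chain = [lab[0] for lab in labels]
        res_resid = [lab[1] for lab in labels]
        res_name = [""] * len(labels)
        for i, c, r, rn in zip(residx, self.chain_ids, self.resids, self.resnames):
            res_name[i] = str(rn)
        # one segment per distinct chain id, in first-appearance order
        seg_ids = list(dict.fromkeys(res_chain))
        seg_index = {s: i for i, s in enumerate(seg_ids)}
        segidx = np.array([seg_index[c] for c in res_chain])
        u = mda.Universe.empty(
            self.n_atoms,
            n_residues=len(labels),
            n_segments=len(seg_ids),
            atom_resindex=residx,
            residue_segindex=segidx,
            trajectory=True,
        )
        u.add_TopologyAttr("names", [str(n) for n in self.atom_names])
        u.add_TopologyAttr("resnames", res_name)
        u.add_TopologyAttr("resids", res_resid)
        u.add_TopologyAttr("chainIDs", [str(c) for c in self.chain_ids])
        u.add_TopologyAttr("segids", seg_ids)
        u.add_TopologyAttr("elements", [""] * self.n_atoms)
        u.add_TopologyAttr("tempfactors", np.zeros(self.n_atoms))
        u.add_TopologyAttr("occupancies", np.ones(self.n_atoms))
        u.atoms.positions = self.coords.astype(np.float32)
        return u


@dataclass
class Selection:
    """An ordered atom-index subset of a parent Structure."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size == 0:
            raise ValueError(f"empty selection (rule: {self.label!r})")
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("selection indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class Ensemble:
    """An ordered frame set over a fixed atom set, with replica bookkeeping.

    ``frames`` is (F, A, 3) in Å; ``replicas`` and ``times`` label every
    frame.  A multi-replica concatenation (a *metatrajectory*) is simply
    an Ensemble whose replica labels change along the frame axis.
    """

    reference: Structure
    frames: np.ndarray
    replicas: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.replicas = np.asarray(self.replicas)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (F, A, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.frames.shape[1] != self.reference.n_atoms:
            raise FormatError(
                f"atom count mismatch: topology has {self.reference.n_atoms}, "
                f"frames have {self.frames.shape[1]}"
            )
        if len(self.replicas) != self.n_frames or len(self.times) != self.n_frames:
            raise ValueError("replica/time labels must match frame count")
        for rep in self.replica_names:
            t = self.times[self.replicas == rep]
            if np.any(np.diff(t) < 0):
                raise ValueError(f"time stamps decrease within replica {rep!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def replica_names(self) -> list[str]:
        return list(dict.fromkeys(str(r) for r in self.replicas))

    def replica_frames(self, name: str) -> np.ndarray:
        return self.frames[self.replicas == name]

    def concat(self, other: "Ensemble") -> "Ensemble":
        if other.n_atoms != self.n_atoms:
            raise FormatError("cannot concatenate ensembles with different atom counts")
        return Ensemble(
            self.reference,
            np.concatenate([self.frames, other.frames]),
            np.concatenate([self.replicas, other.replicas]),
            np.concatenate([self.times, other.times]),
        )


# ---------------------------------------------------------------------------
# readers / writers


def load_structure(path: str | Path) -> Structure:
    """Read a PDB file into a Structure (first MODEL of multi-model files).

    Author residue numbering and chain identifiers are preserved.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # noqa: BLE001 - surface as format error
            raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(u.atoms) == 0:
        raise FormatError(f"{path} contains zero atoms")
    u.trajectory[0]
    if hasattr(u.atoms, "chainIDs"):
        chains = np.array([str(c) for c in u.atoms.chainIDs])
    else:
        chains = np.array([str(s) for s in u.atoms.segids])
    return Structure(
        chain_ids=chains,
        resids=np.asarray(u.atoms.resids, dtype=int),
        resnames=np.array([str(r) for r in u.atoms.resnames]),
        atom_names=np.array([str(n) for n in u.atoms.names]),
        coords=u.atoms.positions.astype(float),
    )


def write_pdb(
    structure: Structure,
    path: str | Path,
    bfactors: np.ndarray | None = None,
) -> None:
    """Write a Structure as PDB, optionally annotating per-atom B-factors.

    ``bfactors`` may be per-atom (length A) or per-residue (length
    n_residues, broadcast to every atom of the residue).
    """
    u = structure.to_universe()
    if bfactors is not None:
        b = np.asarray(bfactors, dtype=float)
        if b.size == structure.n_residues and b.size != structure.n_atoms:
            labels = structure.residue_labels
            per_res = {lab: v for lab, v in zip(labels, b)}
            b = np.array(
                [per_res[(str(c), int(r))]
                 for c, r in zip(structure.chain_ids, structure.resids)]
            )
        if b.size != structure.n_atoms:
            raise ValueError("bfactors must be per-atom or per-residue")
        u.atoms.tempfactors = b
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_ensemble_pdb(ensemble: Ensemble, path: str | Path) -> None:
    """Write an Ensemble as a multi-model PDB (one MODEL per frame)."""
    import MDAnalysis as mda

    u = ensemble.reference.to_universe()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True, n_atoms=u.atoms.n_atoms) as w:
            for frame in ensemble.frames:
                u.atoms.positions = frame.astype(np.float32)
                w.write(u.atoms)


def write_ensemble_dcd(ensemble: Ensemble, path: str | Path) -> None:
    """Write an Ensemble's frames to a DCD trajectory."""
    import MDAnalysis as mda

    u = ensemble.reference.to_universe()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=u.atoms.n_atoms) as w:
            for frame in ensemble.frames:
                u.atoms.positions = frame.astype(np.float32)
                w.write(u.atoms)


def load_ensemble(
    topology: Structure,
    trajectory_paths: Sequence[str | Path],
    replica_labels: Sequence[str] | None = None,
    stride: int = 1,
    time_step: float = 1.0,
    t0: float | None = None,
) -> Ensemble:
    """Load one or more trajectories (DCD/XTC/multi-model PDB) as a
    metatrajectory.

    Frames are concatenated in the given replica order.  Within each
    replica, frame k (0-based, after striding) receives time stamp
    ``t0 + k * time_step`` (ns); ``t0`` defaults to ``time_step``, the
    usual convention for production trajectories whose first saved frame
    lies one output interval after the run start.
    """
    import MDAnalysis as mda

    if stride < 1:
        raise ValueError("stride must be >= 1")
    if replica_labels is None:
        replica_labels = [f"r{i + 1}" for i in range(len(trajectory_paths))]
    if len(replica_labels) != len(trajectory_paths):
        raise ValueError("one replica label per trajectory required")
    if t0 is None:
        t0 = time_step

    all_frames: list[np.ndarray] = []
    reps: list[str] = []
    times: list[float] = []
    for path, label in zip(trajectory_paths, replica_labels):
        path = Path(path)
        u = topology.to_universe()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                u.load_new(str(path))
            except Exception as exc:  # noqa: BLE001
                msg = str(exc)
                if "atom" in msg.lower():
                    raise FormatError(
                        f"{path}: atom count mismatch with topology "
                        f"(expected {topology.n_atoms}): {msg}"
                    ) from exc
                raise FormatError(f"cannot read trajectory {path}: {msg}") from exc
            if u.trajectory.n_atoms != topology.n_atoms:
                raise FormatError(
                    f"{path}: expected {topology.n_atoms} atoms, "
                    f"found {u.trajectory.n_atoms}"
                )
            k = 0
            for i, ts in enumerate(u.trajectory):
                if i % stride:
                    continue
                all_frames.append(ts.positions.astype(float).copy())
                reps.append(label)
                times.append(t0 + k * time_step)
                k += 1
    return Ensemble(
        reference=topology,
        frames=np.array(all_frames),
        replicas=np.array(reps),
        times=np.array(times),
    )


# ---------------------------------------------------------------------------
# selections


def _parse_ranges(text: str) -> list[tuple[int, int]]:
    out = []
    for part in text.replace(" ", "").split(","):
        if not part:
            continue
        if "-" in part[1:]:  # allow a leading minus sign on the first bound
            i = part.index("-", 1)
            out.append((int(part[:i]), int(part[i + 1:])))
        else:
            out.append((int(part), int(part)))
    return out


def select(
    structure: Structure,
    rule: str | Sequence[tuple[int, int]] | np.ndarray,
    chain: str | None = None,
    atom_names: Iterable[str] | None = None,
) -> Selection:
    """Build a deterministic atom Selection.

    ``rule`` is one of:

    * ``"calpha"`` — one Cα per residue;
    * ``"backbone"`` — N, CA, C, O heavy atoms;
    * ``"all"`` — every atom;
    * ``"resid 10-12,40"`` or a list of (lo, hi) author-resid ranges;
    * a boolean per-residue mask (ordered as ``structure.residue_labels``),
      e.g. a secondary-structure mask.

    ``chain`` restricts to one chain; ``atom_names`` further filters by
    atom name (e.g. backbone heavy atoms within residue ranges).
    """
    mask = np.ones(structure.n_atoms, dtype=bool)
    label = str(rule)
    if isinstance(rule, str):
        r = rule.strip().lower()
        if r in ("calpha", "ca"):
            mask &= structure.atom_names == "CA"
        elif r == "backbone":
            mask &= np.isin(structure.atom_names, _BACKBONE_NAMES)
        elif r in ("all", "protein"):
            pass
        elif r.startswith("resid"):
            ranges = _parse_ranges(rule.split(None, 1)[1])
            rmask = np.zeros(structure.n_atoms, dtype=bool)
            for lo, hi in ranges:
                rmask |= (structure.resids >= lo) & (structure.resids <= hi)
            mask &= rmask
        else:
            raise ValueError(f"unknown selection rule {rule!r}")
    elif isinstance(rule, np.ndarray) and rule.dtype == bool:
        labels = structure.residue_labels
        if rule.size != len(labels):
            raise ValueError("residue mask length must equal residue count")
        keep = {lab for lab, m in zip(labels, rule) if m}
        mask &= np.array(
            [(str(c), int(i)) in keep
             for c, i in zip(structure.chain_ids, structure.resids)]
        )
        label = "residue-mask"
    else:  # sequence of (lo, hi) ranges
        rmask = np.zeros(structure.n_atoms, dtype=bool)
        for lo, hi in rule:
            rmask |= (structure.resids >= lo) & (structure.resids <= hi)
        mask &= rmask
        label = f"ranges {list(rule)}"
    if chain is not None:
        mask &= structure.chain_ids == chain
    if atom_names is not None:
        mask &= np.isin(structure.atom_names, list(atom_names))
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"selection rule {label!r} matches no atoms")
    return Selection(indices=idx, label=label)


def secondary_structure_mask(structure: Structure) -> np.ndarray:
    """Cα-distance heuristic marking helix/strand residues (True) vs.
    disordered (False).

    A residue is helical when the i→i+3 and i→i+4 Cα distances sit in
    the canonical α-helix windows (≈5.1 Å and ≈6.2 Å), and strand-like
    when the local chain is extended (i→i+2 ≳ 6.3 Å).  This is a crude
    torsion-free stand-in for a DSSP assignment; explicit residue
    ranges are preferred when known.
    """
    ca = select(structure, "calpha")
    x = structure.coords[ca.indices]
    n = x.shape[0]
    helix = np.zeros(n, dtype=bool)
    strand = np.zeros(n, dtype=bool)
    d = lambda i, j: float(np.linalg.norm(x[i] - x[j]))  # noqa: E731
    for i in range(n - 4):
        if 4.5 <= d(i, i + 3) <= 5.8 and 5.5 <= d(i, i + 4) <= 6.8:
            helix[i : i + 5] = True
    for i in range(n - 2):
        if d(i, i + 2) >= 6.3 and not helix[i : i + 3].any():
            strand[i : i + 3] = True
    return helix | strand


# ---------------------------------------------------------------------------
# superposition


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid-body fit of ``mobile`` onto ``target``.

    Returns (R, t) such that ``mobile @ R.T + t`` minimises the RMSD to
    ``target``.  Proper rotation enforced via the SVD sign correction.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if np.array_equal(mobile, target):  # already aligned: exact identity
        return np.eye(3), np.zeros(3)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = tc - r @ mc
    return r, t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD between two (M, 3) arrays (no fitting)."""
    return float(np.sqrt(np.mean(np.sum((np.asarray(a) - np.asarray(b)) ** 2, axis=1))))


def superpose(
    ensemble: Ensemble,
    fit_selection: Selection,
    reference: Structure | str = "first",
) -> Ensemble:
    """Rigid-body superpose every frame onto a reference.

    Each frame is rotated/translated to minimise the least-squares
    deviation of the fit-selection atoms from the reference; the
    transform is applied to all atoms.  Returns a new Ensemble.
    """
    if len(fit_selection) < 3:
        raise ValueError("superposition needs >= 3 fit atoms (rotation under-determined)")
    idx = fit_selection.indices
    if isinstance(reference, str):
        if reference != "first":
            raise ValueError("reference must be 'first' or a Structure")
        ref_xyz = ensemble.frames[0][idx]
    else:
        if reference.n_atoms != ensemble.n_atoms:
            raise FormatError("reference atom count differs from ensemble")
        ref_xyz = reference.coords[idx]
    out = np.empty_like(ensemble.frames)
    for f in range(ensemble.n_frames):
        r, t = kabsch(ensemble.frames[f][idx], ref_xyz)
        out[f] = ensemble.frames[f] @ r.T + t
    return Ensemble(ensemble.reference, out, ensemble.replicas.copy(), ensemble.times.copy())
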