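"""Synthetic ensembles, paired perturbation runs and energy matrices.

A statistical emulator, not a physics simulator: equilibrium ensembles
are i.i.d. draws from the Gaussian distribution an elastic network of
harmonic springs would equilibrate to, paired perturbation runs share
their noise realisations (common random numbers, the stochastic analogue
of branching a run while keeping its velocities), and energy matrices
carry planted strongly coupled cores and weakly coupled patches.  Every
generator is seed-deterministic, and each generated set records its own
ground truth so downstream analyses can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components

from .ensemble import Ensemble, Structure


@dataclass
class HarmonicModel:
    """Elastic-network specification of an equilibrium ensemble.

    One Cα-like site per residue.  Displacements about ``coords`` are
    zero-mean Gaussian with per-axis covariance σ²·L⁺, where L is the
    graph Laplacian weighted by the spring stiffnesses k_ij
    [kcal/mol/Å²] and ⁺ the Moore–Penrose pseudo-inverse (the standard
    Gaussian-network convention, axes independent).  ``restraint`` adds
    a weak harmonic tether of every site to its reference position,
    which regularises disconnected coupling graphs.
    """

    coords: np.ndarray
    couplings: Sequence[tuple[int, int, float]]
    sigma: float
    seed: int
    restraint: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        for i, j, k in self.couplings:
            if k < 0:
                raise ValueError("stiffness must be >= 0")
            if not (0 <= i < self.n_sites and 0 <= j < self.n_sites) or i == j:
                raise ValueError(f"bad coupling ({i}, {j})")

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]

    def laplacian(self) -> np.ndarray:
        n = self.n_sites
        lap = np.zeros((n, n))
        for i, j, k in self.couplings:
            lap[i, j] -= k
            lap[j, i] -= k
            lap[i, i] += k
            lap[j, j] += k
        if self.restraint > 0:
            lap[np.diag_indices(n)] += self.restraint
        return lap

    def displacement_factor(self) -> np.ndarray:
        """Matrix S with S @ S.T = σ²·L⁺ (or σ²·L⁻¹ under a restraint)."""
        if self.restraint <= 0:
            adj = np.zeros((self.n_sites, self.n_sites))
            for i, j, k in self.couplings:
                if k > 0:
                    adj[i, j] = adj[j, i] = 1
            ncomp, _ = connected_components(adj, directed=False)
            if ncomp > 1:
                raise ValueError(
                    "coupling graph is disconnected: relative-motion covariance "
                    "is ill-defined; set restraint > 0 to regularise"
                )
        lam, vec = np.linalg.eigh(self.laplacian())
        tol = max(1e-10, 1e-12 * abs(lam[-1]))
        keep = lam > tol
        return self.sigma * vec[:, keep] / np.sqrt(lam[keep])

    def covariance(self) -> np.ndarray:
        """Per-axis site covariance σ²·L⁺ implied by the coupling graph."""
        s = self.displacement_factor()
        return s @ s.T


def make_ca_structure(
    coords: np.ndarray,
    chain: str = "A",
    first_resid: int = 1,
) -> Structure:
    """One-CA-per-residue Structure around the given site coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return Structure(
        chain_ids=np.array([chain] * n),
        resids=np.arange(first_resid, first_resid + n),
        resnames=np.array(["ALA"] * n),
        atom_names=np.array(["CA"] * n),
        coords=coords,
    )


def helical_coords(n: int, rise: float = 1.5, radius: float = 2.3,
                   turn: float = 100.0) -> np.ndarray:
    """Idealised α-helical Cα trace — a compact, self-avoiding backbone."""
    ang = np.deg2rad(turn) * np.arange(n)
    return np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), rise * np.arange(n)]
    )


def sample_harmonic_ensemble(
    model: HarmonicModel,
    frames: int,
    replicas: int = 1,
    time_step: float = 20.0,
    structure: Structure | None = None,
) -> Ensemble:
    """Draw an i.i.d. equilibrium ensemble from the harmonic model.

    ``frames`` is per replica; replica labels are r1..rK and frame k of
    a replica is stamped (k+1)·time_step ns.  Bit-identical for a given
    seed.
    """
    if frames < 1 or replicas < 1:
        raise ValueError("frames and replicas must be >= 1")
    s = model.displacement_factor()
    rng = np.random.default_rng(model.seed)
    total = frames * replicas
    # one (modes, 3) standard-normal block per frame
    z = rng.standard_normal((total, s.shape[1], 3))
    disp = np.einsum("nm,fmd->fnd", s, z)
    xyz = model.coords[None, :, :] + disp
    if structure is None:
        structure = make_ca_structure(model.coords)
    reps = np.repeat([f"r{i + 1}" for i in range(replicas)], frames)
    times = np.tile((np.arange(frames) + 1) * time_step, replicas)
    return Ensemble(structure, xyz, reps, times)


# ---------------------------------------------------------------------------
# paired perturbation (D-NEMD-like) sets


@dataclass
class PerturbationSpec:
    """An abstract structural perturbation with a known displacement.

    ``targets`` are 0-based site indices; the displacement of a target
    site at time t after ``onset`` is ``vector`` (mode "constant") or
    ``vector · min(t/ramp_time, 1)`` (mode "ramp").  At the onset instant
    itself the displacement is zero.
    """

    targets: Sequence[int]
    vector: np.ndarray
    mode: str = "constant"
    ramp_time: float = 1.0
    onset: float = 0.0

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (3,):
            raise ValueError("vector must be a 3-vector")
        if self.mode not in ("constant", "ramp"):
            raise ValueError("mode must be 'constant' or 'ramp'")

    def displacement(self, t: float) -> np.ndarray:
        dt = t - self.onset
        if dt <= 0:
            return np.zeros(3)
        if self.mode == "constant":
            return self.vector
        return self.vector * min(dt / self.ramp_time, 1.0)


def make_paired_dnemd_set(
    base: HarmonicModel,
    spec: PerturbationSpec,
    branch_times: Sequence[float],
    run_length: float,
    sampling_interval: float,
    seed: int | None = None,
):
    """Build paired unperturbed/perturbed runs sharing noise realisations.

    For each branch time, both members of the pair are the same sequence
    of equilibrium draws (common random numbers emulate restarting from
    identical positions and velocities); the perturbed member
    additionally displaces the target sites by the spec's displacement
    at each relative time.  The exact planted response is stored as
    ground truth.

    Returns a :class:`~allofluct.dnemd.PairedRunSet`.
    """
    from .dnemd import PairedRunSet, RunPair

    branch_times = list(branch_times)
    if not branch_times:
        raise ValueError("branch-time list is empty")
    if run_length < sampling_interval:
        raise ValueError("run length must cover at least one sampling interval")
    n_t = int(round(run_length / sampling_interval))
    grid = sampling_interval * np.arange(1, n_t + 1)
    s = base.displacement_factor()
    rng = np.random.default_rng(base.seed if seed is None else seed)
    n = base.n_sites
    targets = np.asarray(list(spec.targets), dtype=int)

    pairs = []
    for b in branch_times:
        z = rng.standard_normal((n_t, s.shape[1], 3))
        noise = np.einsum("nm,fmd->fnd", s, z)
        unp = base.coords[None, :, :] + noise
        per = unp.copy()
        for k, t in enumerate(grid):
            per[k, targets, :] += spec.displacement(t)[None, :]
        pairs.append(RunPair(unperturbed=unp, perturbed=per, branch_time=float(b)))

    truth = np.zeros((n, n_t))
    for k, t in enumerate(grid):
        truth[targets, k] = np.linalg.norm(spec.displacement(t))
    structure = make_ca_structure(base.coords)
    return PairedRunSet(
        pairs=pairs,
        time_grid=grid,
        structure=structure,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# planted energy matrices


def make_energy_matrix(
    n_residues: int,
    core: Sequence[int],
    core_strength: float,
    soft_patch: Sequence[int] = (),
    background_scale: float = 0.0,
    seed: int = 0,
    soft_attenuation: float = 0.05,
):
    """Symmetric residue-pair energy matrix with planted structure.

    Core×core couplings are strongly stabilising (mean −core_strength
    kcal/mol); rows of the soft patch are attenuated towards zero; all
    remaining off-diagonal entries are weakly stabilising half-normal
    couplings of scale ``background_scale`` — non-bonded pair energies
    are predominantly negative, which is also what gives the matrix the
    strongly negative leading spectrum the low-rank reconstruction
    relies on.  Diagonal is zero (self-couplings are not pairwise
    couplings).  Returns an :class:`~allofluct.mlce.EnergyMatrix` whose
    labels are chain A, resids 1..N.
    """
    from .mlce import EnergyMatrix

    core = np.asarray(list(core), dtype=int)
    soft = np.asarray(list(soft_patch), dtype=int)
    if core_strength <= 0:
        raise ValueError("core strength must be > 0")
    if np.intersect1d(core, soft).size:
        raise ValueError("core and soft patch must be disjoint")
    rng = np.random.default_rng(seed)
    m = np.zeros((n_residues, n_residues))
    if background_scale > 0:
        iu = np.triu_indices(n_residues, k=1)
        noise = -np.abs(rng.normal(0.0, background_scale, size=iu[0].size))
        m[iu] = noise
        m.T[iu] = noise
    # attenuate the soft patch before planting the core so a (disallowed)
    # overlap could never weaken the core block
    m[soft, :] *= soft_attenuation
    m[:, soft] *= soft_attenuation
    cc = np.ix_(core, core)
    block = np.full((core.size, core.size), -core_strength)
    if background_scale > 0:
        jit = rng.normal(0.0, background_scale, size=(core.size, core.size))
        block = block + (jit + jit.T) / 2.0
    m[cc] = block
    m[np.diag_indices(n_residues)] = 0.0
    labels = [("A", i + 1) for i in range(n_residues)]
    return EnergyMatrix(values=m, labels=labels)
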