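# Methods

This note documents the models and procedures implemented in
`allofluct`, their assumptions, the parameters that matter, and the
numerical choices made where the underlying conventions were genuinely
open.

## Distance-fluctuation analysis

For each residue pair the statistic is the population variance of the
inter-site (Cα–Cα) distance over all frames of the metatrajectory,
DF_ij = ⟨(d_ij − ⟨d_ij⟩)²⟩, in Å².  The literature around this
statistic is inconsistent about whether the reported quantity is the
variance or its square root; this package computes the variance as the
primary statistic (the convention of the method's originating work) and
exposes the standard-deviation view via `DFMatrix.as_std()`.  The
convention used is recorded in the matrix metadata.

Numerics: an exact two-pass variance with the first frame's distances
as an offset, so a rigid ensemble yields an exact zero and the
computation is bit-stable against a naive per-frame reference.  DF is
computed from internal distances and is therefore invariant to any
per-frame rigid-body motion; prior superposition of the metatrajectory
is permitted but mathematically immaterial.  The pooled (metatrajectory)
variance equals the frame-count-weighted combination of per-replica
variances and means, which the tests verify from sufficient statistics.

Coarse views: block averaging uses the arithmetic mean over the covered
entries, with trailing partial blocks averaged over their actual entry
count (no padding, so edge blocks are unbiased).  The default block
size is 40 residues — 1600 pairs per block.  Quantisation uses
`levels` (default 5) equal-width bins spanning the observed [min, max]
of the block matrix, with the maximum mapped to the top level; a
constant matrix maps entirely to level 0.  No universal numeric
threshold separates "high" from "low" coordination; reports therefore
describe terciles of the observed DF distribution rather than absolute
cut-offs.

## D-NEMD response

Branch points are taken from the equilibrated part of each replica at
times `discard + k·interval` (defaults 100 ns and 20 ns).  A branch
point is kept only if at least `continuation` ns of trajectory remain
after it — the unperturbed continuation the subtraction pairs against —
with `continuation` defaulting to the interval (a non-equilibrium run
as long as the extraction spacing).  Under this rule four 1000-ns
replicas sampled every 20 ns yield 44 branch points per replica, 176 in
total.  Setting `continuation=0` allows branches up to the final frame.
Pair counts are always data-driven, never assumed.

The response is the mean over pairs of the per-residue Euclidean
deviation |x_pert − x_unpert| at equivalent relative times (mean of
norms).  The alternative — norm of the mean displacement vector, which
cancels sign-alternating responses — is exposed as
`metric="norm_mean"` for sensitivity checks.  By default each perturbed
frame is rigid-body fitted onto its paired unperturbed frame over all
sites before subtraction, removing trivial drift; the fit redistributes
roughly 1/N of a localised displacement onto the remaining residues, so
exact-recovery checks disable it (`superpose_first=False`).  Whether to
fit is a genuine protocol choice with no established convention, hence
the flag.

Uncertainty is the across-pair standard error (sample SD over pairs /
√pairs) with no autocorrelation correction: branch points are distinct
equilibrium configurations by construction.  Reductions over pairs are
performed in sorted order so the profile is bit-identical under any
pair enumeration order.

## MLCE

The energy matrix is symmetrised on load (warning above 1e-6 kcal/mol
asymmetry).  Eigendecomposition uses LAPACK `eigh`; the reconstruction
sums the k most-negative-eigenvalue components.  The eigenvector-count
rule — the main open convention in this method — defaults to: include
components in ascending-eigenvalue order while the cumulative |λ| over
included negative eigenvalues is below 85% of the total |λ| over all
negative eigenvalues, minimum one.  The rule is deterministic,
spectrum-adaptive, reduces to the single most negative eigenvector for
near-rank-1 spectra, and the realised k is always recorded; an explicit
integer k may be supplied instead.

Contacts: C_ij = 1 iff i ≠ j and the Cα–Cα distance is ≤ the cutoff
(default 6 Å, boundary inclusive).  The coupling map is the Hadamard
product M̃ ∘ C, so masking is idempotent.

Segment extraction scores each residue by its most stabilising contact
coupling (row minimum over contacting partners); residues with no
contacts are excluded.  Mode `core` keeps the `fraction` (default 0.10)
of residues with the most negative scores; mode `soft` keeps the tail
whose strongest coupling is weakest (scores closest to, or above,
zero).  Values tied with the threshold are all included.  Maximal
sequence-contiguous runs of at least `min_run_length` (default 3)
residues within one chain are reported with mean scores; an optional
spatial merge of runs is deliberately not the default, since reported
soft spots are conventionally sequence ranges.  A fully tied score
vector yields an empty result with a warning, not an error.  Outputs
are labelled low-coupling segments — candidate interface /
unfolding-prone regions — not claims about in-vivo unfolding.  The
upstream MM/GBSA computation that produces the energy matrix is out of
scope; the matrix is an input (residue-labelled TSV).

## Descriptors and clustering

RMSD: each frame is fitted (Kabsch, proper rotation enforced) on the
fit selection to the reference, and the RMSD taken over the measure
selection.  RMSF: frames are superposed on the site selection onto the
topology reference, the average structure is formed, frames are
re-superposed onto that average, and RMSF_r = √⟨|x_r − ⟨x_r⟩|²⟩.
Using the topology (not the first frame) for the initial pass makes the
profile invariant to frame order.

Clustering aligns frames on the ordered (secondary-structure) backbone
to the first frame, computes all-vs-all RMSD over the disordered
selection without per-pair refitting (a Gram-matrix identity keeps this
O(F²) with one matrix product), and applies hierarchical agglomerative
clustering.  Linkage defaults to average (stable against chaining on
RMSD matrices; single/complete are available).  The cluster count
maximises the mean silhouette over the candidate range (default 2–10),
with ties broken toward smaller K; every candidate's silhouette is
reported.  Representatives are medoids — the member minimising summed
within-cluster RMSD.  The procedure is deterministic given frame order.
Ensembles whose frames are identical on the cluster selection (pairwise
RMSD ≤ 1e-5 Å, the resolution of the Gram-based distances) return K = 1
with a warning.

Secondary-structure masks may be given explicitly as residue ranges
(preferred) or derived from a crude Cα-distance heuristic (i→i+3 and
i→i+4 distances in the canonical helix windows; extended i→i+2 spacing
for strands); the heuristic is torsion-free and intentionally simple.

## Synthetic ensembles (ground truth)

The generator is a statistical emulator, not a physics simulator: no
integrator, thermostat or force field.

*Equilibrium ensembles.*  One Cα-like site per residue.  Displacements
about the reference are zero-mean Gaussian with per-axis covariance
σ²·L⁺, where L is the graph Laplacian weighted by the spring
stiffnesses k_ij (kcal/mol/Å²) and ⁺ the Moore–Penrose pseudo-inverse —
the standard Gaussian-network convention, axes independent.  Frames are
i.i.d. draws; time stamps are bookkeeping (frame k of a replica is
stamped (k+1)·Δt, the convention of production trajectories whose first
saved frame falls one output interval after the start).  Disconnected
coupling graphs are rejected — relative motion between components has
no stationary distribution — unless a weak per-site restraint
regularises L.  Every generator is bit-deterministic given its seed.
For an isolated pair with mutual stiffness k the separation variance is
σ²/k per axis, so coordination strengthens monotonically with k — the
property the DF tests exploit.

*Paired perturbation runs.*  Each branch point yields an unperturbed
and a perturbed member built from identical noise draws (common random
numbers — the stochastic analogue of restarting a branched run with the
same positions and velocities); the perturbed member additionally
displaces the target residues by a known constant or time-ramped
vector, zero at the onset instant.  The exact planted response is
stored as ground truth.  Under shared noise the Kubo–Onsager recovery
is exact; stochastic calibration is instead tested on null pairs built
from independent equilibrium segments, whose per-residue deviation has
the analytic Maxwell mean 2√(2/π)·√(2v_r).

*Energy matrices.*  Off-diagonal background couplings are half-normal
negative (scale `background_scale`) — non-bonded pair energies are
predominantly stabilising, which also gives the matrix the strongly
negative leading spectrum the reconstruction relies on.  The core block
is planted at mean −`core_strength`; soft-patch rows are attenuated by
a factor 0.05 toward zero.  With zero background the core block is
exactly −`core_strength` and everything else exactly zero.

*What the emulator does not capture.*  Time correlation and barrier
crossing (frames are i.i.d., so no relaxation kinetics), anharmonicity
and conformational substates within a state, side-chain packing, and
solvent-mediated couplings.  Passing tests therefore demonstrate that
the statistics are computed correctly and recover planted signals of
realistic geometry and magnitude — not that any particular biological
system behaves harmonically.

## Problem sizes and defaults

Synthetic checks use 8–100-residue systems: DF oracle comparisons at
8 residues × 300 frames; covariance convergence at 50,000 frames;
DF-difference recovery on a 40-residue two-domain system with a planted
6×6-pair decoupled block (1000 frames per state); D-NEMD with 10–20
pairs on 5–10-point grids; MLCE recovery on 100 residues with
10-residue planted core and soft patch over 20 seeds; clustering with
2–3 planted families of 40–100 frames.  These sizes give every
stochastic check a comfortable margin while keeping the full suite
fast on a single CPU.

Parameter defaults: block size 40 residues; 5 quantisation levels;
contact cutoff 6.0 Å (inclusive); MLCE tail fraction 0.10 and minimum
run length 3; branch-point discard 100 ns and interval 20 ns; silhouette
candidates K = 2..10; harmonic σ of order 0.5 Å and stiffnesses of
order 1–4 kcal/mol/Å², giving site fluctuations comparable to folded
proteins' sub-Å to Å-scale RMSF.

## Known limitations

- PDB-format coordinates carry 1e-3 Å precision; round-trips through
  text trajectories are tested to that tolerance (XTC to its 1e-3 Å
  lossy compression, DCD to 1e-5 Å single precision).
- The pipeline's multi-model-PDB trajectory dialect keeps fixtures
  text-only but is verbose; DCD/XTC are preferred for real data.
- Segment extraction reports sequence-contiguous runs only; spatially
  contiguous but sequence-discontinuous soft spots appear as separate
  runs.
- The silhouette criterion, like any global index, can prefer merging
  genuinely distinct but overlapping families; the per-candidate scores
  are reported so such calls can be reviewed.
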