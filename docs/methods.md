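# Methods

This note documents the models, conventions and numerical choices behind
hingemd, in the order an analysis runs: superposition, stability metrics,
domain geometry, the closed/open progress variable, the protein structure
network, the synthetic generator that validates all of it, and the pipeline.

## Superposition and deviation metrics

All deviation metrics are computed after optimal rigid-body least-squares
superposition (Kabsch, via SVD of the 3×3 covariance of the centred fit
selections). The sign of the smallest singular vector is corrected so that
det(R) = +1: reflections are never admitted, since a mirror image of a
chiral backbone is not a physical superposition. The transform fitted on the
fit selection is applied to *all* atoms.

By default both the fit and the measurement use Cα atoms; a backbone
(N, CA, C, O) fit is available via selections, since conventions differ on
whether one fits on backbone and measures on Cα. The fit is unweighted (no
masses), matching the unweighted RMSD definition

    RMSD(t) = sqrt( (1/N) Σᵢ |rᵢ(t) − rᵢ_ref|² ).

Degenerate fit selections (fewer than three points, or collinear) are
rejected by default because the minimising *transform* is not unique there.
The minimum RMSD *value* is still well defined, and `strict=False`
(the default inside `rmsd_series`) accepts such selections — this is what
makes the two-atom worked example (reference atoms 2 Å apart, frame atoms
4 Å apart, post-fit RMSD exactly 1 Å) computable. Per-domain RMSD always
requires at least three atoms per domain.

Per-domain RMSD uses an independent superposition per domain (fit =
measure = that domain's Cα). This deliberately removes rigid-body motion of
the whole domain, so the series tracks internal domain deformation only; a
globally fitted per-domain RMSD would conflate hinge motion with domain
instability.

RMSF is computed about the trajectory-average structure: frames are aligned
to the first frame, averaged, re-aligned once to that average, and the
per-atom RMS deviation about the final average is reported:

    RMSF(i) = sqrt( (1/T) Σₜ |rᵢ(t) − ⟨rᵢ⟩|² ).

One re-alignment pass (not a fixed-point iteration) is the standard,
deterministic choice; further iterations change the result below the noise
floor. An optional separate fit selection lets callers align on a rigid
scaffold and measure elsewhere. A single-frame trajectory yields an all-zero
profile with a warning (or an error, by flag). For isotropic i.i.d.
per-coordinate noise of width σ the expected per-atom RMSF is √3·σ, minus a
small deficit because the 6 rigid-body degrees of freedom absorbed by the
alignment are shared across 3N coordinates (≈1% for ~100 atoms); the
validation threshold of 5% accommodates this.

## Equilibration detection

Equilibration points are estimated from a metric series (whole-protein Cα
RMSD by default) with a sliding-window flatness test. Candidate start frames
are scanned from the beginning; a start qualifies when, splitting the
remaining frames into consecutive windows of `window` frames (default 10%
of the series, minimum 4), every window's least-squares linear slope
satisfies |slope| ≤ `slope_tol` (default 0.02 Å/ns) and the spread of window
means does not exceed twice the pooled within-window standard deviation.
The reported equilibration point is the **end of the first window** of the
earliest qualifying start — one full stable window must be observed before a
run counts as equilibrated, so a stationary series equilibrates at the first
window boundary, not at time zero. A series that never qualifies (monotone
drift) returns a "not equilibrated" sentinel (`None`); the pipeline then
uses the whole run and records the flag. All production statistics
(RMSF, PSN persistence, state calls, comparison tables) use frames after
the equilibration point.

## Domain geometry

The radius of gyration is mass-weighted and needs no superposition (it is
rigid-invariant). Atom masses come from element symbols; coarse Cα-only
bead models use plain carbon (12.011 amu). Whole-protein Rg uses all atoms
present; the selection is recorded in the series metadata.

Inter-domain distances use the **mass-weighted centre of mass** of each
domain's Cα atoms; hinge angles use the **unweighted centre of geometry**.
The two flavors nearly coincide for Cα-only selections (all masses equal
makes them identical), but both are kept because conventions for the two
observables differ. The hinge angle at vertex domain B is
θ = arccos(BA·BC/|BA||BC|) in degrees, range [0°, 180°]; coincident centres
raise a degenerate-geometry error rather than returning NaN.

## The ΔRMSD progress variable

For each frame, σ_closed and σ_open are post-fit Cα RMSDs to a closed and
an open reference structure, **each with its own independent
superposition** — a shared fit would bias Δσ = σ_closed − σ_open toward
whichever reference supplied the fit. References are caller-supplied
structures (typically first production frames of reference runs, but any
two conformers work).

Since post-fit RMSD satisfies the triangle inequality, |Δσ| ≤ D with
D the inter-reference post-fit RMSD; D is therefore the natural scale for
classification. A frame is *closed* when Δσ < −f·D, *open* when Δσ > +f·D,
else *intermediate*, with `threshold_frac` f = 0.2 by default — "close to
zero" is not standardised, and 20% of the reference separation is a
conservative, documented operationalisation. The per-system call is the
majority frame label over the production run (ties break toward closed,
then intermediate, deterministically).

Transition detection is a baseline-departure test: the mean and SD of Δσ
over the first `baseline_frames` frames define a band of ±n_sigma·SD
(default 6); the transition is the first frame outside the band for
`sustain` (3) consecutive frames. This locates a programmed switch to
within a frame or two at realistic noise levels.

## Protein structure network

Residues are nodes; edges are non-covalent interactions of three classes
with per-frame geometric criteria:

| class | all-atom criterion (defaults) | residue-centre criterion |
|---|---|---|
| SB | min distance between charged-group atoms of oppositely charged residues (Asp/Glu vs Lys/Arg/His⁺) ≤ 4.5 Å | opposite-charge pair, representative-point distance ≤ 4.5 Å |
| HB | donor–acceptor heavy-atom distance ≤ 3.5 Å; D–H···A angle ≥ 120° enforced only when explicit hydrogens exist | both polar-capable, distance ≤ 3.5 Å |
| HC | side-chain heavy-atom-centre distance ≤ 5.0 Å, both residues in {Ala, Val, Leu, Ile, Met, Phe, Trp, Pro} | both hydrophobic, distance ≤ 5.0 Å |

The cutoffs follow the conventional defaults of published
interaction-network tools and are fully config-overridable; His counts as
protonatable-positive by default (configurable). Pairs closer than 2
positions in sequence are excluded in all classes (covalently adjacent
contacts are trivial). The residue-centre mode exists for coarse bead
models whose representative point is the Cα.

Persistence is the fraction of production-run frames in which a pair
satisfies its criterion, computed as an exact integer count divided once at
the end. The threshold p_crit is chosen by the largest-hydrophobic-cluster
criterion: scan p over [0, 1] in 0.02 steps plus one virtual step above 1.0
at which every edge has vanished (so a final collapse is observable), record
the size of the largest connected component of the HC-only graph at each p,
and place p_crit at the grid value just above the largest single-step drop;
ties resolve to the smallest such threshold (determinism). The merged PSN
keeps edges with persistence ≥ p_crit of their class; the cross-domain
interaction table uses strictly > p_crit, matching the convention that
tables report persistences *exceeding* the threshold. One p_crit (from the
HC graph) is applied to all three classes in the pipeline, with per-class
overrides available.

Node degree counts **distinct residue pairs** — a pair linked by both a
salt bridge and a hydrogen bond contributes 1 — because pairwise counting
makes degrees comparable across classes; per-class counting is available by
flag. Hubs are residues with degree strictly greater than k_min in at least
one analysed system (both k > 4 and k > 6 conventions are produced by the
pipeline), and ΔDegreeᵢ = kᵢ_open − kᵢ_closed is an exact integer
difference with absent residues counting as degree 0, so
Σᵢ ΔDegreeᵢ = 2(E_open − E_closed) on a shared node set.

## Synthetic hinge model

The generator emulates the geometry of a three-domain hinge protein, not
its physics. Domains are rigid shells of pseudo-Cα beads (antipodally
symmetrised golden-spiral points, so each shell's centroid is *exactly* its
programmed centre); the terminal domains sit at fixed arm length from the
central domain with the programmed hinge angle between the arms; linkers
are straight bead chains re-anchored between domain centres every frame.
The hinge path is closed until an optional transition frame, ramps over 10%
of the run to θ_closed + park_fraction·(θ_open − θ_closed), and stays
parked. Designed domain I–III contacts (an Asp bead in domain I, a Lys bead
in domain III, placed 3.5 Å apart) exist only while θ ≤ θ_contact
(default: closed phase only); the displaced bead's shift is compensated
across the remaining beads of its domain, so programmed centres, hinge
angles and centre distances remain exact ground truth. i.i.d. Gaussian
noise of `noise_sigma` per coordinate is added last; all randomness flows
from one integer seed.

Defaults: 30 beads/domain of radius 7 Å, 6-bead linkers, arm length 22 Å,
θ_closed = 60°, θ_open = 110°, σ = 0.3 Å, 400 frames at 0.1 ns/frame.
These give desk-scale runs whose observables sit in protein-like ranges
(reference separation D ≈ 6.5 Å, Rg ≈ 14 Å) and whose designed-contact
persistence, phase angles and state labels are recoverable to the
tolerances the test suite asserts.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: correlated thermal motion (noise is i.i.d., so
RMSF has a closed form but no physical correlation structure), side-chain
chemistry (the PSN runs in residue-centre mode on beads), solvent,
force-field energetics, and spontaneous (rather than programmed)
transitions. Tests against it validate the *analysis machinery*, not any
biophysical claim.

## Pipeline

Stage order is fixed: whole-protein RMSD and equilibration first; every
subsequent statistic uses production frames only. Each stage runs inside an
error boundary — a failing stage is recorded in the report with its name
and message, and independent stages continue. The pipeline is a pure
function of (config, input files): no stage is stochastic, CSV floats are
written with a fixed 10-significant-digit format, and JSON keys are sorted,
so repeated runs are byte-identical (asserted in the test suite). Outputs
carry units in their column names (`rmsd_A`, `angle_deg`, `time_ns`).

## Known limitations

- Only multi-model PDB trajectories are supported in core; binary formats
  (DCD/XTC) would be thin adapters behind the same `Trajectory` contract.
- The equilibration detector is a flatness heuristic, not an
  autocorrelation/statistical-inefficiency analysis; block averaging and
  free-energy or Markov-state analyses of the open/closed transition are
  out of scope.
- The all-atom hydrogen-bond test falls back to a pure distance criterion
  when explicit hydrogens are absent, which overcounts marginal geometries.
- Whole-protein metrics include linker residues; per-domain metrics exclude
  them (linkers belong to no domain by construction).
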