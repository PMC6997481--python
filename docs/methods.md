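# Methods

This note documents the models behind `hingeflex`, the parameters that
matter, the numerical choices, and what the synthetic benchmarks do and do
not demonstrate about real peptide data.

Units are fixed throughout: nm, ps, kJ/mol, kelvin;
kB = 0.0083144621 kJ/(mol·K). PDB files are the only ångström surface.
Angles are radians internally; the opening angle is reported in degrees and
dihedrals in radians.

## Coarse hinge models

Each preset builds a two-chain topology of Cα beads plus one Sγ bead per
cysteine:

| preset | sequence/chain | disulfides | orientation |
|---|---|---|---|
| `hinge_peptide` | CHWECRGCRLVC | A1–B12, B1–A12, A5–A8, B5–B8 | antiparallel |
| `ser_hinge` | CHWESRGSRLVC | A1–B12, B1–A12 | antiparallel |
| `tyr_hinge` | YCHWECRGCRLVC | as native, indices shifted | antiparallel |
| `pro_igg` | TCPPCPAP | A2–B2, A5–B5 | parallel |
| `ala_igg` | TCAACPAP | as pro_igg | parallel |
| `gly_igg` | TCGGCPAP | as pro_igg | parallel |

The reference geometry is an idealization: straight Cα traces at 0.35 nm
spacing, 0.5 nm between chains, antiparallel chains running in opposite
directions, and Sγ beads placed symmetrically on each disulfide axis so
every declared S–S pair sits at exactly 0.205 nm (lifted out of the
backbone plane, one height per disulfide, so sulfur clusters stay
distinct). Only descriptor and PCA *correctness* is tested on these
structures, not structural realism — there is no force field, no hydrogen
bonding, no β-sheet geometry.

Two deliberate conventions: positions 5/8 of the designed hinge are "apex
residues" for the opening angle regardless of whether they are cysteine or
the serine replacement; and the Tyr elongation attaches at the N-terminus
by default (`build_topology(..., tyr_terminus=...)` switches it — the
attachment point is genuinely open, so it is a parameter, not a guess).

## Descriptors

* **Opening angle** — the vertex is the centroid of the four terminal-
  cysteine Sγ atoms (the physical hinge pin); the arms point to the
  per-chain centroids of the apex-residue Cα atoms. Computed with
  `atan2(|u×v|, u·v)`, stable near 0° and 180°. The vertex choice is
  configurable through `DescriptorSpec`.
* **Core dihedral** — signed torsion over four cysteine Cα atoms resolved
  symbolically from the topology (antiparallel family: first Cys of chain
  A, last of B, first of B, last of A; parallel family: first A, first B,
  second B, second A). IUPAC convention: cis = 0, sign right-handed about
  the 2→3 axis, range (−π, π]. Note the classic identity that this torsion
  is *invariant* under full order reversal of the quadruple; mirror
  reflection negates it. Both are regression-tested.
* **Trp–Trp distance** — Cα of the first tryptophan of each chain (the
  coarse model has no side chains); skipped for Trp-free presets.
* **RMSD** — Kabsch superposition via SVD with proper-rotation correction,
  mass-unweighted, Cα-only by default. Degenerate (collinear) selections
  and atom-count mismatches are hard errors.

## Essential dynamics

Frames are superposed onto a self-consistent mean: align to frame 1,
recompute the mean, re-align all frames to it, and iterate until the mean
stops moving (tolerance 1e-12, capped at 50 passes; it converges in a
handful). At the fixed point the alignment of a trajectory whose
displacements carry no net translation or torque is exactly the identity,
which is why the synthetic generator orthogonalizes its mode vectors
against the six-dimensional rigid-body subspace of the reference
(`internal_mode_vectors`): ground-truth variance fractions then survive
superposition to machine precision rather than only to first order.

The covariance is the full 3N×3N positional covariance of the aligned,
mean-centered coordinates with population (1/n) normalization — chosen so
noise-free sinusoidal trajectories reproduce their analytic eigenvalues
A²/2 exactly; variance *fractions*, the reported quantity, are independent
of that choice. Eigenvector signs are fixed (largest-magnitude component
positive) for determinism. Fractions use all 3N modes in the denominator.
Mode labels (twist vs open/close) are assigned by correlating PC
projections with descriptor series at |Pearson r| > 0.7, since visual
assignment is not reproducible.

The sinusoidal generator uses integer cycle counts over the frame window,
making sample variances exactly A²/2 and cross-mode covariances exactly
zero — this is what turns fraction recovery into a sharp (1e-6) test
rather than a statistical one. The noisy benchmark adds isotropic
per-coordinate Gaussian noise at 10 % of the smallest mode's
per-coordinate RMS displacement (A_min/√3N); at that scale the isotropic
noise floor perturbs fractions by well under 0.02 at 5,000 frames.

## Langevin dynamics and well-tempered metadynamics

Dynamics runs directly in collective-variable space — a desk-scale
surrogate for thermostatted all-atom MD, not a physical model of the
peptide. The integrator is BAOAB splitting with defaults dt = 0.01 ps,
friction 1 ps⁻¹, unit mass per CV (all configurable; the 2-D hinge-surface
runs use lighter masses, 5e-4 and 0.5, purely to decorrelate sampling
faster). Forces during long runs come from a fine-grid linear interpolant
of the potential (801–4001 nodes), with exact callable evaluation as the
fallback outside the grid; the interpolation error is orders of magnitude
below the thermal force scale and is regression-tested.

Deposition follows the well-tempered rule: a Gaussian of height
h = w₀·exp(−V(s)/kBΔT), ΔT = (γ−1)T, every `stride` ps. Defaults are the
standard hinge-peptide protocol: w₀ = 0.175 kJ/mol, γ = 8, stride 1 ps,
σ = 0.05 for the twist-like CV (0.35 for distance-like CVs; which width
belongs to which CV is a config field, as the pairing is ambiguous in the
protocol's source). Periodic CVs (dihedrals) wrap hill displacements into
[−π, π], making the bias exactly 2π-periodic. The hill log is exact and
append-only; `bias_value`/`bias_gradient` are straight sums over all hills
(vectorized), and the deposited height always uses this exact sum. Only
the integrator's per-step bias *force* reads from an incrementally updated
grid accumulator — at ~2×10⁶ steps and ~2×10⁴ hills an exact O(hills) sum
per step would be prohibitive, and the interpolation error is negligible
against kBT. The engine biases whatever CV it is given — a geometric
descriptor or a PC projection; both are supported.

Free energy from a converged bias: F(s) = −(γ/(γ−1))·V(s), shifted so
min F = 0. On the 15 kJ/mol double well (whose potential *is* the exact
free energy for 1-D CV dynamics) the default protocol reaches ~0.5–0.9
kJ/mol pointwise error after 20 ns (2×10⁶ steps, 20,000 hills) — the
residual is the usual hill-granularity ripple of order the late-stage hill
height times γ/(γ−1).

## Free-energy surfaces from reweighted histograms

Frames enter the histogram with weight exp(+V_bias/kBT) where V_bias is
the *final* bias at the frame's CV position (static last-bias reweighting,
the simplest estimator appropriate for converged well-tempered runs;
time-dependent-offset estimators are future work). F = −kBT·ln(w/w_max),
min-shifted; bins that never received weight are masked, never imputed or
extrapolated. The default grid is 425 bins per axis over (opening angle,
Trp–Trp distance) — read as bins *per axis*, the common convention; it is
a plain parameter.

At 425 bins a single bin is ~0.3° wide and the raw argmin bin of a sampled
FES is statistically meaningless (tens of counts per bin). `locate_minima`
therefore (i) smooths the Boltzmann weights (Gaussian filter, default
σ = 4 bins) for the 8-neighborhood local-minimum search, (ii) rejects
candidates whose level-set region within `level` (default kBT) connects to
any deeper bin — noise dips on a larger basin's shoulder fail this
prominence test — and (iii) refines each surviving minimum by the
Boltzmann-weighted centroid of the *unsmoothed* weights over the
contiguous level-set region. For a locally symmetric basin the centroid is
an unbiased sub-bin estimator of the basin center; on the default
two-basin surface it localizes both basins to a fraction of a bin across
seeds.

## The two-basin hinge surface

`make_hinge_potential_2d` models the hinge peptide's conformational
landscape over (θ in degrees, d in nm): Gaussian wells at (110°, 2.5 nm)
(open/twisted, depth 8 kJ/mol, widths 18°/0.5 nm) and (43°, 0.3 nm)
(compact, depth 5 kJ/mol, widths 6°/0.08 nm), a 3 kJ/mol Gaussian saddle
bump at the midpoint (width = separation/6, narrow enough not to shift the
basin minima), and steep quartic walls outside θ ∈ [30°, 150°] and
d ∈ [0.05, 3.5] nm. Effective well depths are obtained from a 2×2 linear
solve so that U at each declared basin center equals −depth *exactly*
(raw Gaussian tails would otherwise offset the basins by ~1e-7 and shift
the minima off their declared coordinates). Depths and widths were chosen
so that 300 K sampling visits opening angles from roughly 40° to 140°,
keeps both basins populated (the compact basin holds a few per cent of the
weight, ~3 kJ/mol above the open one), and crosses between them many times
in a 20 ns run.

## Problem sizes

The shipped benchmarks use: 600 frames (noise-free PCA) and 5,000 frames
(noisy PCA) on the 32-bead hinge dimer; 2×10⁶ Langevin steps (20 ns) for
the double-well metadynamics reconstruction; 4×10⁶ steps (20 ns at
dt = 0.005 ps) for the 2-D basin-location run; 10⁵ samples for the
Gaussian Boltzmann-inversion check; 10⁶ steps for the harmonic
equipartition check. These sizes give each estimate a comfortable margin
against its tolerance while keeping the whole suite in the minutes range
on one CPU.

## What the synthetic benchmarks do not show

The generators emulate the *statistical structure* the analysis stages
must handle — prescribed covariance spectra, metastable two-basin
densities, decaying hill heights — not peptide physics. Passing tests
demonstrates that descriptors, PCA, the metadynamics engine and the FES
estimators are mathematically correct and internally consistent; they say
nothing about force-field accuracy, solvent effects, convergence of real
microsecond simulations, or the actual mode percentages of any laboratory
peptide. Known limitations: no multiple-walker or parallel-bias
metadynamics, no MBAR/WHAM multi-window combination, no FES error bars, no
kernel PCA or time-lagged components, and binary trajectory formats are
out of scope (multi-frame XYZ text is the native format).
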