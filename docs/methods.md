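# Methods

This note records the models implemented in `slimbind`, the numerical
choices behind them, and what the synthetic-data generators do and do
not emulate.

## Two-state titration thermodynamics (`slimbind.binding`)

A peptide ligand L binds a protein P in a single two-state equilibrium
P + L <-> PL with dissociation constant Kd.  For residues in fast
exchange the observed amide peak sits at the population-weighted
average position, so the combined chemical-shift perturbation

    dd = sqrt(dH^2 + (0.2 dN)^2)        [ppm]

grows with the bound protein fraction.  The 0.2 weight maps the wider
15N shift range onto the 1H scale and is fixed, not configurable, so
outputs remain comparable across datasets.  The exact mass-balance
solution gives the bound fraction at total concentrations Lt, Pt:

    pB(Lt) = (Kd + Lt + Pt - sqrt((Kd + Lt + Pt)^2 - 4 Lt Pt)) / (2 Pt)

and the fitted model is dd_r(Lt) = ddmax_r * pB(Lt) with one shared Kd
and one saturating amplitude ddmax_r per residue (per-residue
amplitudes are standard practice; a shared amplitude would force all
sites to report identically).  Because ddmax enters linearly it is
profiled analytically, leaving a one-parameter trust-region search
over Kd started at the median nonzero ligand concentration.  Samples
are prepared fresh per titration point, so no dilution correction is
applied.

*Uncertainty.* Kd +/- sd comes from a residue-level bootstrap (200
draws by default, seeded): whole residues are resampled with
replacement, preserving the within-residue correlation of points.

*Rectification bias.* The magnitude of a noisy 2D shift difference is
Rice-distributed; its mean exceeds the true perturbation, which
inflates the weak CSPs of early titration points and biases Kd low
(about -1 sd at the weak-affinity end of the conditions we simulate).
When the per-axis shift noise sigma is known (duplicate spectra, or
the generator's planted value), `fit_global_kd(..., noise_sd=sigma)`
fits the noise-floored expectation sqrt(dd^2 + 1.04 sigma^2), which
removes the bias; the plain model is the default.

*Residue selection.* `select_fast_exchange` keeps residues whose
intensity never falls below 30% of the apo value and whose per-step
CSP never exceeds 0.15 ppm.  Both thresholds are heuristics for "the
peak remains traceable"; an explicit residue list overrides them, since
published analyses typically curate the set by hand.

Free-energy differences use ddG = R T ln(Kd_b / Kd_a), positive for
the weaker binder b.

## CPMG relaxation dispersion (`slimbind.cpmg`)

Two-site chemical exchange A <-> B (populations pA, pB; rate
kex = kAB + kBA; 15N shift separation |dw|) modulates the effective
transverse relaxation rate measured in a constant-time CPMG
experiment, R2,eff(nu) = -ln(I(nu)/I0) / T_cpmg, with T_cpmg = 39 ms
and refocusing rate nu = n_echo / (2 T_cpmg).

*Forward model.* In-phase magnetization (mA, mB) starts at the
equilibrium populations and evolves under the 2x2 complex
Bloch-McConnell matrix

    A = [[-R2A - kAB,        kBA          ],
         [ kAB,       -R2B - kBA - i dw   ]]

during each free-precession delay tau = 1/(4 nu); ideal 180-degree
pulses act as instantaneous complex conjugations.  The echo train is
propagated exactly (batched eigendecomposition of the echo-pair
operator), and R2,eff is taken from the magnitude of the total
transverse magnetization at T_cpmg.  Off-resonance effects, pulse
imperfections, scalar coupling and 1H decoupling artefacts are outside
the model.  |dw| converts ppm to rad/s through the 1H field and the
15N/1H gyromagnetic ratio (0.10137); the sign of dw is not observable
in CPMG and is stored as a magnitude.

*Closed-form oracle.* `carver_richard_oracle` evaluates the same
two-site problem in closed form: the Carver-Richards echo-pair
eigenvalues completed with the exact amplitude term, written out as
scalar Cayley-Hamilton algebra.  It matches the propagator to ~1e-13
and validates it independently.  The textbook approximate rate
(`carver_richard_rate`, the D+/eta acosh expression) is also provided;
it neglects the echo amplitude factor and deviates from a fixed-delay
R2,eff by up to ~10% in slow exchange (kex ~ 200 /s, |dw| ~ 4 ppm),
which is why it is not used as the primary oracle.

*Error model.* Each acquisition includes one duplicated nu value.
Spectrometer noise is additive and uniform on the intensity scale, so
the duplicate pairs of all curves in a dataset are pooled into one
intensity-noise sd, which is then propagated per point through the
log-ratio: sigma(R2,eff) = sigma_I / (I T_cpmg).  (A per-curve sigma
from a single pair is a 1-degree-of-freedom estimate whose scatter
distorts the fit weights and inflates the estimator variance well
above the reported curvature sd; pooling restores agreement between
reported and replicate-to-replicate uncertainties.)  Datasets without
duplicates fall back to a flat 0.3 /s floor.  The per-curve estimator
`sigma_from_duplicates` is retained as a diagnostic.

*Global fits.*  Two modes, both requiring curves at >= 2 static
fields:

* **naive** -- shared (pB, kex), per-residue |dw| and R2,0, with
  R2,B = R2,A (dR2 = 0);
* **constrained** -- pB fixed from the independently measured Kd and
  the known concentrations, shared kex, per-residue |dw|, R2,A and a
  free R2,B.  A large fitted dR2 = R2,B - R2,A absorbs unresolved
  micro-to-millisecond exchange within the bound state; per-residue
  R2,B is weakly determined (the very degeneracy that motivates fixing
  pB), but |dw| values are stable across modes.

The objective is sum(((obs - sim)/sigma)^2), minimized by trust-region
reflective least squares exploiting the block-sparse Jacobian (shared
columns dense, per-residue columns local).  kex is fitted as log10;
five starts log-spaced over kex = 100-10000 /s (jittered by the seed)
guard against the multimodal exchange surface, and the best start is
refined to tight tolerances.  Parameter sds come from the
reduced-chi2-scaled inverse Gauss-Newton Hessian.  A three-state model
is deliberately not implemented; the constrained two-state fit is the
surrogate.

*Kinetics.*  With L_free = Lt - pB*Pt:

    k_off = (1 - pB) kex,   k_on = pB kex / L_free,   Kd = k_off / k_on

and first-order error propagation treating pB and kex as independent.

## Motif census (`slimbind.census`)

Tripeptide motifs of the four families IxI, IxV, VxI, VxV are counted
with the central position x iterated over the 20 amino acids, in three
databases: the whole proteome, its disordered regions (intervals of
>= 20 residues), and the structured remainder obtained by exact
subtraction (M_structured = M_proteome - M_disordered per cell).
Conventions:

* overlapping windows each count -- windows are the natural unit of the
  expectation formula below;
* a motif is *disordered* only when all three residues lie inside one
  disorder region; straddling windows therefore count as structured
  (a motif must be fully accessible to act as a binding element);
* coordinates are 0-based, half-open, including the mask file dialect;
* ambiguous letters (B, J, O, U, X, Z) never match and are excluded
  from frequency denominators.

Expected counts assume positional independence:
N = M_r * prod_q p_r(AA_q), with p_r the amino-acid frequencies of
database r and M_r its total window count.  Enrichment is tested with

    chi2_tot = sum_{4 families} sum_{20 centres} (obs - exp)^2 / exp

on nu = 80 - 4 = 76 degrees of freedom (one totals constraint per
family), upper-tail p-value from the chi-square survival function.  No
multiple-testing correction is applied: it is a single global test.
On unplanted i.i.d. proteomes the statistic's mean over seeds sits at
nu within sampling error, which calibrates the null.  The per-centre
enrichment profile is the percentage-share difference of disordered
vs structured motif centres; it sums to zero by construction.

## Trajectory analysis (`slimbind.traj`)

Backbone phi (C'-N-CA-C) and psi (N-CA-C-N') dihedrals use the
standard two-plane-normal signed angle, wrapped to (-180, 180];
degenerate (collinear) geometry raises.  The Ramachandran free-energy
surface is a Boltzmann inversion of the binned angle density,
dG = -kB T ln(n / n_max), on a 36x36 grid (10-degree bins; the
binning is a package default, chosen to resolve basin structure at a
few hundred frames) at 310.15 K (37 C) by default.  Empty bins are
masked, never infinite, and the global minimum defines dG = 0.
The occupied-bin count is the headline contrast statistic: a
proline-like centre (tight phi band) occupies far fewer bins than a
leucine-like one.

Superposition is the Kabsch SVD solution with a determinant correction
against improper rotations; collinear point sets are rejected.  The
combined-ensemble PCA concatenates two trajectories, superposes every
frame onto a user-supplied reference conformation (bound-state Calpha
coordinates; the generators emit one, so no external structure is
required), excludes terminal residues by default, and
eigendecomposes the covariance of the flattened Calpha coordinates.
Projections carry per-frame source labels so ensemble spreads can be
compared; explained-variance fractions sum to one over the full
spectrum.

## Synthetic data (`slimbind.synth`)

Generators are pure functions of their arguments including the seed
(byte-identical reruns) and return ground-truth ledgers.

* **Titrations** -- 16 fast-exchange residues named after the amide
  resonances tracked in this system, with fixed per-residue ddmax
  (0.02-0.6 ppm per axis), 200 µM protein, a geometric ladder to the
  10:1 point at 2 mM (the exact intermediate concentrations of the
  original titration are unpublished, so a geometric ladder stands
  in), and Gaussian shift noise of 0.002 ppm per axis.  Optional
  slow-exchange residues keep their apo position and lose intensity
  proportionally to the bound fraction, emulating peaks that broaden
  away.
* **CPMG** -- 10 residues, |dw| spread over 1-3 ppm, R2,0 = 12 /s,
  fields 500/600 MHz (1H), T_cpmg 39 ms, 19 nu values with even echo
  counts plus one duplicate, additive intensity noise of sd 0.005
  (about 0.3 /s in R2,eff at typical attenuation).  Exchange states
  use the measured populations/off-rates of the wild-type-like
  (pB 2.4%, koff 515 /s) and mutant-like (pB 2.0%, koff 610 /s)
  scenarios.
* **Proteomes** -- i.i.d. residues from human-like frequencies, one
  disorder interval per protein covering ~30% of its length (>= 20
  residues), and motif plantings that are rejection-checked (up to
  1000 attempts) so each write adds exactly one recorded match of the
  planted query in the target database; residual background matches
  are reported in the ledger.
* **Peptide trajectories** -- per-residue phi/psi sampled from von
  Mises mixtures (narrow proline-like: phi ~ vM(-65, kappa 60);
  broad leucine-like: multi-basin mixture), converted to Cartesian
  N/CA/C backbones with ideal bond geometry via natural-extension
  placement.  The sampled angles invert exactly through the dihedral
  analysis.

What the generators do *not* emulate: spectral artefacts (solvent
lines, phase errors, peak overlap), scalar relaxation pathways,
realistic proteome phylogenetic correlation or compositional clustering,
side-chain atoms and solvent in trajectories, and any three-state
exchange.  Passing recovery tests therefore demonstrate estimator
correctness under the stated noise models, not robustness to every
artefact of real data.

## Problem sizes used by the test suite and acceptance script

Recovery studies use 50 seeded replicates per scenario (16-residue
titrations; 10-residue, two-field CPMG datasets), the null chi-square
calibration uses 200 seeds of 60-protein proteomes (400-900 residues),
and trajectory contrasts use 300-500 frames.  These sizes give stable
percentile statistics while keeping a full run in the minutes range on
one CPU.

## Known limitations

* The CPMG model is in-phase 15N two-site exchange with ideal pulses;
  no CEST/R1rho, no multiple-quantum or 1H variants.
* pB and kex sds assume a locally quadratic likelihood; strongly
  under-determined datasets (single field, tiny dispersions) are
  flagged rather than rescued.
* The census's independence null ignores residue-neighbour
  correlation; on real proteomes the chi-square statistic is expected
  to reject it for biological as well as statistical reasons.
* Disorder masks are consumed, never predicted.
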