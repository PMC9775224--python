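# Methods

## The linkage model

For a homodimerization reaction 2M → D of a protein with titratable
sites, linkage theory gives the pH derivative of the standard free-energy
change as

    dΔG°/dpH = RT ln10 · (n̄^D − 2 n̄^M),

where n̄^M and n̄^D are the mean numbers of protons bound by the monomer
and the dimer at that pH. The sign convention is fixed by the semi-grand
partition-function identity d(−RT lnΞ)/dpH = RT ln10 · n̄ (Ξ the binding
polynomial); the test suite pins it by differentiating the enumerated
−RT[lnΞ_D − 2 lnΞ_M] and comparing against the integrand. Integrating
from a reference pH yields the *shape* ΔΔG°(pH); the absolute offset is
unknowable from titration data alone and is recovered, when experimental
ΔG° points exist, as a single vertical least-squares shift (upper-bound
points are excluded from the fit but reported with residuals).

`pH_ref` defaults to the lowest sampled pH. Changing it rigidly shifts
the curve; differences ΔΔG(pH₂) − ΔΔG(pH₁) are invariant (tested).

## Thermodynamically anchored Hermite splines

CpHMD studies sample few, widely spaced pH values (here six, spacing 1),
so the integrand must be interpolated. The key structural fact is that
each sampled titration point carries its own exact derivative through the
fluctuation relations

    dn̄/dpH   = −ln10 · var(n),
    dn̄_i/dpH = −ln10 · cov(n_i, n),

with var/cov computed over the same frames as the means. Each titration
curve therefore becomes a cubic Hermite spline through (pH, n̄) with
prescribed slopes, and the linkage integral is evaluated in closed form
(the antiderivative of a piecewise cubic; implemented via
`scipy.interpolate.CubicHermiteSpline.antiderivative`, which is exact
polynomial algebra, and cross-checked against composite Simpson at 1e-9).
Slopes are **never** taken from finite differences of the sampled means.
No monotonicity repair is applied: the slopes are physical, and any
overshoot between knots is reported, not clipped.

Because Hermite interpolation is linear in its (value, slope) data and
protonation is a sum over sites, the per-site splines sum identically to
the total spline, and the per-site free-energy decomposition

    ΔΔG_i°(pH) = RT ln10 ∫ ( n̄_i^{A,D} + n̄_i^{B,D} − 2 n̄_i^{M} ) dpH′

sums to the total to machine precision at every grid pH. Homologous-site
pairing between dimer chains A/B and the monomer is by chain-stripped
label.

A comparison route integrates fitted Hill curves instead, using the
closed-form antiderivative

    ∫ dpH / (1 + 10^{h(pH−pKa)}) = pH − ln(1 + 10^{h(pH−pKa)}) / (h ln10),

evaluated with `logaddexp` for stability. On exactly Hill-shaped sites
the two routes agree to < 0.1 kJ/mol; on coupled sites they differ, which
is precisely the argument for the spline route.

## Moment conventions

Variances and covariances use population (1/N) normalisation: the
fluctuation relations are ensemble identities, and 1/(N−1) would break
the exact additivity n̄ = Σ n̄_i, var(n) = Σ cov(n_i, n) that the
decomposition relies on. Statistics pool retained frames across
replicates; per-replicate statistics remain available for per-replicate
summaries (e.g. interface torsion means). Frames are masked, never
deleted — the time axis must stay intact for autocorrelation analysis,
which operates on the longest contiguous retained stretch per replicate.

RT ln10 comes from a single constants module (R = 8.3145×10⁻³ kJ/mol/K,
default T = 300 K); energies are kJ/mol internally with a kcal/mol
display conversion (4.184 kJ/kcal).

## Bootstrap

Errors of protonation-derived quantities use a two-level scheme chosen
because occupancy series are strongly autocorrelated: replicates are
resampled with replacement, then circular moving blocks of retained
frames (default block 1 ns, configurable) within each chosen replicate;
the statistic — up to and including the entire moments → slopes →
splines → integral pipeline — is recomputed per resample. Free-energy
envelopes are pointwise 2.5/97.5 percentile bands (clipped to bracket the
central estimate). With a single replicate the scheme degrades to
block-only resampling with a warning; between-run variability is then
underrepresented, so multi-replicate input is recommended.

## The synthetic oracle

The coupled-site titration model assigns microstate s ∈ {0,1}^M the
log-weight

    ln w(s) = Σ_i s_i ln10 (pKa_i − pH) − β Σ_{i<j} W_ij s_i s_j,

with W (kJ/mol, symmetric) paid when *both* members of a pair are
protonated — one standard convention of the pairwise titration
Hamiltonian; under the hole transform s → 1−s it is equivalent to a
deprotonated-pair convention with shifted intrinsic pKas, so nothing in
the oracle role depends on the choice. Exact moments come from microstate
enumeration with log-sum-exp stabilisation (guarded at 20 sites); dimers
are two chain copies plus an interchain coupling block, and the exact
relative dimerization free energy is −RT[lnΞ_D − 2 lnΞ_M] differenced
against the reference pH. A single-site-flip Metropolis sampler (seeded,
with configurable per-site flip-attempt rates to create designed
slow-exchanging sites) produces occupancy trajectories with the exact
stationary distribution.

What the generator emulates: coupled titration, replicate structure,
autocorrelated exchange kinetics, association-induced protonation shifts.
What it does not: conformation–protonation coupling, tautomer identity
(occupancy is the collapsed binding count; the analyses use only counts),
solvent or ionic-strength effects on pKas, and real forcefield noise.
Passing tests therefore demonstrate the correctness of the estimators
and integrals, not the accuracy of any particular simulation engine.

Benchmark conditions: oracle model pairs of 4–10 sites with mixed
attractive/repulsive couplings, sampled at pH {3…8}; Monte-Carlo checks
use 10⁶ steps per pH (recorded every 10 steps, split into two replicates)
— sizes at which enumeration is exact and sampling noise is well inside
the test tolerances.

## Stage-specific conventions

* **Hill fits** — `scipy.optimize.least_squares` on
  n̄(pH) = 1/(1+10^{h(pH−pKa)}), initialised at the interpolated
  half-protonation pH with h₀ = 1, h bounded to [0.05, 10]. A fit is
  flagged not-converged when the solver fails or the fitted pKa falls
  more than 2 units outside the sampled window (extrapolated midpoints
  are indicative only).
* **Isoionic point** — root of the Hermite-interpolated charge curve
  (charge spline = protonation spline minus the acid count, so the charge
  and protonation interpolants cross zero together); reported at 0.1
  resolution by default.
* **Correlations** — Pearson ρ over pooled retained frames;
  zero-variance sites are flagged invalid rather than zero so networks
  cannot contain spurious null edges. Correlation time is the *first*
  lag with ACF below threshold (default 0.1), not a sustained crossing;
  the ACF curve is reported alongside to expose noise sensitivity. The
  ACF estimator normalises each lag by its pair count, so a strictly
  alternating series gives ACF(1) = −1 exactly.
* **Ion grids** — number density per Å³ from isotropic Gaussians
  (default bandwidth 2 Å) on a 1 Å mesh, truncated at 4σ (mass loss well
  under the 1% conservation check run on every build), converted to mM
  via 10³⁰/N_A. Ions are first minimum-imaged relative to the protein
  centroid, then carried through the protein's least-squares rigid fit
  onto the reference structure. The Boltzmann map applies
  c = c_bulk·exp(−zFφ/RT) voxelwise to a user-supplied potential grid;
  no Poisson–Boltzmann equation is solved here — that is an external
  solver's job, and re-implementing one is out of scope.
* **SASA** — Shrake–Rupley with a deterministic golden-spiral point set
  (default 960 points, probe 0.14 nm), neighbour search via a k-d tree.
  Contact area is SASA(A) + SASA(B) − SASA(A∪B); the default reported
  value is half of that (the area lost per partner), configurable to the
  full buried area, and the convention is recorded in output metadata.
* **Superposition** — Kabsch least squares with proper-rotation
  enforcement (no reflections), via
  `scipy.spatial.transform.Rotation.align_vectors`. Central structure =
  frame minimising the mean squared pairwise superposed RMSD, ties broken
  by lowest index.
* **Decoupled PCA** — frames are superposed using only the fit
  selection; PCA (scikit-learn, full SVD) then decomposes the transform
  selection's Cartesian coordinates. Fit and transform selections must be
  disjoint, which removes whole-system rigid motion from the projections
  (tested to 1e-8). An all-rigid ensemble reports variance fractions of
  exactly zero. The loop-motion analysis is the same operation with fit =
  backbone minus the loop and transform = loop backbone; no special code
  path.
* **Landscapes** — 2-D Gaussian KDE with per-axis bandwidth
  σ·(4N/3)^(−1/5) (σ the axis standard deviation). A printed form of
  this rule of thumb that *grows* with N circulates in the literature;
  the negative exponent is the only choice consistent with a
  kernel-bandwidth rule, and it is what is implemented. Mesh spacing is
  configurable (2 PC-units for dimer-configuration maps, 0.5 for loop
  maps by convention). F = −k_B T ln(P/P_max), so F = 0 exactly at the
  density maximum. 1-D histograms use the same bandwidth rule with 1/N
  normalisation.

## Degenerate inputs and numerical choices

Zero retained frames raise; equilibration cut-offs beyond the last frame
mask everything with a warning. Flat titration data yield a
not-converged Hill fit rather than an exception. Charge curves without a
sign change refuse to report an isoionic point, naming the bracketing
failure. Spline integration refuses extrapolation outside the knot
range. All stochastic components require explicit seeds; every CLI stage
is pure given (inputs, config, seed) and bit-reproducible.

## Known limitations

* The bootstrap block length is a fixed default (1 ns), not adaptively
  estimated from the measured correlation times.
* The dissociation filter recomputes pairwise RMSD per frame in Python;
  it is adequate for the ensemble sizes used here, not for
  millions-of-frames production trajectories.
* Engine-specific protonation logs are not parsed; conversion to the
  occupancy-table dialect is the caller's one-line responsibility.
* Mediated (positive) correlations are reported, not mechanistically
  explained; the package offers no path-finding for mediators.
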