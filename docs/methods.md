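# Methods

This note records the models, estimators and numerical conventions behind
`idpchain`, and what its synthetic validation does and does not establish.

## Scope and units

All analyses operate on Cα traces: ordered per-frame sequences of Cα
positions for a single chain. Internal units are nm for lengths and nm⁻¹
for momentum transfer; conversions (PDB Å × 0.1; SAXS Å⁻¹ × 10) happen only
at file boundaries. XYZ trajectories are read and written in nm natively.
Residue indices are 1-based in files and in shift tables, 0-based in
arrays. Frame order is preserved exactly by all I/O because time order
matters for block errors and autocorrelation.

## Chain observables

**Radius of gyration.** Per frame, the root-mean-square distance of the Cα
beads from their unweighted centroid. This is a Cα-trace proxy: it ignores
side-chain mass and so differs slightly from the mass-weighted all-atom
R_g an MD analysis would report. The histogrammed density integrates to 1;
the reported mean is the plain series mean, not the binned approximation.

**Orientational correlation.** C(s) = ⟨n_i · n_{i+s}⟩ with n_i the unit
vector between consecutive Cα positions. All (i, frame) pairs are pooled;
averaging over frames first and then over i is identical in expectation,
and pooling is simpler and has the same estimator variance here because
every frame contributes the same number of pairs. A zero-length bond is an
error (the unit vector is undefined) and the message names the frame and
residue.

**Persistence length.** C(s) = e^{−s/k} is fitted by linear least squares
of ln C(s) on s over s ∈ {1..4} (free intercept; k = −1/slope). The short
range is deliberate: for real and synthetic disordered chains the
exponential regime holds only at small separations, beyond which C(s)
either vanishes or crosses over to a power law. l_p = k × 0.38 nm uses the
consecutive-Cα spacing. Exact exponential input recovers k to machine
precision; a non-decaying profile raises rather than returning a divergent
k. The power-law tail fit is the analogous regression of ln C on ln s, with
the slope reported signed.

**Internal distances and Flory fits.** R_s is the mean (not RMS) Cα–Cα
distance over all pairs at separation s and all frames. R_s = R_0 s^ν is
fitted as a straight line in log–log space, the convention matching how
such data are plotted and judged; fits are unweighted by default (per-s
inverse-variance weighting is a flag) because the per-s uncertainties of a
well-sampled ensemble are nearly uniform on the log scale and the
unweighted fit is reproducible without an error model. The two-regime fit
places the boundary point s = 10 in the short-range regime (s ≤ 10 and
s > 10). With fewer than three points beyond the split only the first
regime is fitted and the result is flagged, not an error. For the freely
jointed chain the mean *squared* distance is s·b² exactly, and the mean
distance approaches √(8s/3π)·b in the Gaussian limit; the test suite checks
both closed forms separately since conflating mean and RMS distance is an
easy factor-√(3π/8) mistake.

**Contacts.** A contact is a pair with |i−j| ≥ 3 within 0.8 nm by default.
No universal Cα contact definition exists; both constants are exposed and
logged in reports. The contact map is the per-pair contact frequency over
frames (symmetric, unit diagonal).

## Synthetic ensembles (what the generators emulate)

The generators produce coarse-grained homopolymer ensembles whose
statistics are known exactly, standing in for MD trajectories as the
package's validation substrate.

- **Freely jointed chain** — fixed bond length b = 0.38 nm, independent
  uniform bond directions. Ideal coil: ⟨R_ee²⟩ = (N−1)b², ν = 0.5.
- **Freely rotating chain** — each bond lies on the cone at angle arccos g
  about its predecessor, azimuth uniform. Cone sampling fixes the
  successive cosine *exactly*, making C(s) = g^s an identity rather than an
  expectation — a deliberately clean oracle for the persistence-length
  pipeline. g = 0.535 gives k = −1/ln g ≈ 1.60, l_p ≈ 0.61 nm.
- **Self-avoiding walk** — hard-sphere diameter d (default d = b =
  0.38 nm) enforced for all |i−j| ≥ 2, sampled by the pivot algorithm:
  rotate the chain tail about a uniformly chosen interior bead by a
  uniform random rotation, accept iff the hard core holds (only head–tail
  pairs need re-checking). Chosen over chain-growth methods for its simple
  correctness argument and speed at N ≤ 200. Frames are emitted every 2N
  accepted pivots after a 10N-pivot burn-in from a straight chain; the
  sampler raises after a bounded run of consecutive rejections, which
  signals an infeasible diameter (d ≥ 2b is rejected up front — even a
  straight chain violates the s = 2 constraint there). At N = 100 the
  fitted tail exponent is ≈ 0.59–0.60, consistent with the asymptotic
  good-solvent value 0.588 once finite-size error is allowed for.

Two paired-data generators close the loop for the agreement metrics: a
SAXS pair (experiment = a·Debye curve + background + relative Gaussian
noise, with σ set to the true noise sd so χ² ≈ 1 when correctly specified;
σ = 1 in the noise-free branch so χ² = 0 remains computable) and a shift
pair (calc = expt − offset + noise, random-coil table per residue type
from fixed plausible backbone ranges, plus a smooth sinusoidal "structure"
term so ΔCS is not trivially zero).

All generators are pure functions of (spec, seed): the same inputs
reproduce ensembles bit for bit.

What passing these tests does **not** show: real IDP ensembles are
heteropolymers with charge patterning, proline stiffness and transient
secondary structure; real SAXS requires atomic form factors and the
hydration shell; real calculated shifts come from a structure-based
predictor with its own error floor. The synthetic models validate the
estimators, not force fields or predictors.

## Scattering agreement

χ² = (k−1)⁻¹ Σ[(I_expt − (c·I_sim + bgd))/σ]². The nuisance parameters
(c, bgd) are the weighted-least-squares solution of the 2×2 normal
equations — deterministic and testable against brute-force grid search. A
constant simulated curve is rejected as collinear with the background. The
1/(k−1) normalisation is kept as the field's reporting convention even
though two parameters are fitted; `dof="k-3"` gives the strict convention,
and under the correctly specified synthetic generator the (k−1) statistic
has mean (k−3)/(k−1) ≈ 0.96 at k = 50 — the calibration tests use a wide
band accordingly. Grid mismatch is handled by linear interpolation of the
(smooth) simulated curve onto the experimental q grid, flagged in the
result; extrapolation is refused. No default q-range truncation is
applied; `q_min`/`q_max` are exposed because published comparisons often
truncate and the choice materially changes χ².

The intensity calculators are explicit simplifications: the Debye
Gaussian-chain form factor I(x) = 2(e^{−x} + x − 1)/x², x = q²R_g²
(series-expanded below x = 10⁻⁸ for stability), and the orientation-averaged
point-scatterer sum I(q) = ⟨Σ_{ij} sinc(q d_{ij})⟩ with unit form factors
(I(0) = N²). The convergence diagnostic scores growing trajectory prefixes
(first 1/n, 2/n, … of frames) against a fixed experimental curve;
a plateau indicates the ensemble average has converged.

## Chemical shifts

Secondary shifts ΔCS = CS − CS^RC are formed by matching each record's
(residue type, atom) against the random-coil table; records without a
reference entry are dropped and counted, mirroring per-residue bar plots
with gaps. The random-coil table is an input file, not embedded data — the
package ships no third-party reference values.

"Linear regression" offset: the correction actually applied is a pure
constant CS^calc → CS^calc + O, so the regression is run with slope fixed
to 1, for which the least-squares O is mean(expt − calc) over shared
residues. A free-slope diagnostic (slope, intercept) is reported on request
but never applied, since a multiplicative correction is not part of the
pipeline. Because the random-coil term cancels in a pure offset, fitting on
raw CS or on ΔCS is identical; raw CS is used. Offsets are fitted per atom
type independently.

RMSE(x) = √(n⁻¹ Σ_i (ΔCS^expt − ΔCS^calc)²) over the n residues shared by
both tables for atom x. Its uncertainty comes from five contiguous
residue blocks: the block-mean standard-error formula applied to per-block
RMSE values (√ of the block MSE), keeping the error bar in p.p.m. on the
same scale as the RMSE. With fewer than two usable blocks the error is
NaN. Published per-atom RMS floors of a widely used shift predictor
(1.12/0.44/0.52/0.17/0.12 p.p.m. for N/CA/CB/H/HA) are carried in reports
as interpretation context only.

## Replica ladders, block errors, autocorrelation

The ladder λ_i = exp(−i/(n−1)·ln(Tmax/T0)) is geometric in T_i = T0/λ_i;
endpoints are pinned exactly (λ_0 = 1, λ_{n−1} = T0/Tmax) against rounding.
Choosing Tmax outside 450–500 K warns rather than errors: below, the
hottest replica may decorrelate too slowly; above, scaled replicas start
sampling collapsed states and replicas are wasted. Exchange probabilities
are acceptance fractions per neighbour pair; a pair with zero attempts is
NaN (missing), never 0, and the 0–1 pair is reported as the lowest-rank
headline value (a convention — the alternative, averaging the lowest
replica's two neighbour pairs, can be read off the per-pair vector).

Block standard error: five contiguous equal blocks in time order;
stderr = √(Σ(m_i − m̄)²/(n(n−1))). A non-divisible length drops trailing
frames (equal blocks are required) and reports the count.

Autocorrelation: C_t(τ) = cov(x_t, x_{t+τ})/var(x), biased estimator
(lag sums divided by the full length L) by default — it is non-negative
definite and stable at large lags, the right convention for decay-rate
diagnostics; the unbiased variant (divide by L−τ) is a flag and is the one
that reproduces textbook identities exactly on short series (e.g. an
alternating ±1 series has C_t(1) = −1 unbiased but −(L−1)/L biased).

## Problem sizes and tolerances

Reference computations use 2000 freely jointed chains (ν), 500
pivot-decorrelated self-avoiding chains (ν), and 5000 freely rotating
chains (l_p), each at N = 100–101 residues — sizes at which the
Monte-Carlo error of each fitted quantity is well below the tolerance it
is checked against (±0.03 on ν ideal, ±0.04 on ν self-avoiding to absorb
finite-size crossover, ±0.03 nm on l_p). Stochastic assertions elsewhere
in the suite use 3-standard-error bands computed from the data, with exact
(machine-precision) assertions reserved for identities that hold by
construction. Degenerate inputs fail loudly and early: rod-like profiles
(no decay), non-positive values under a log, zero variance, zero-length
bonds, infeasible hard-core diameters.

## Known limitations

- Cα-trace only; no side chains, no mass weighting, no secondary-structure
  assignment.
- The scattering calculators omit atomic form factors and hydration-shell
  contrast; computed χ² values against *measured* protein curves are not
  comparable to published ones obtained with explicit-solvent calculators.
- Homopolymer generators cannot emulate sequence-specific effects (charge
  patterning, proline content) that differentiate real IDPs.
- The pivot sampler targets desk-scale chains (N ≲ 200); its O(N²)
  acceptance check is the binding cost at larger N.
- The replica-exchange engine itself (Metropolis coordinate swaps) is not
  implemented; only schedule planning and post-hoc log analysis are.
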