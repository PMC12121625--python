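# Methods

## The stopping rule

Each λ-window of a TI transformation produces a dV/dλ gradient time
series sampled at a uniform interval. The controller runs an initial
production block, then alternates assessment and fixed-length
extension until one of three exits fires. The assessment pipeline is:

1. **Equilibration.** The equilibration start t₀ is the candidate that
   maximizes the effective sample count (N − t₀)/g(t₀). The
   statistical inefficiency g = 1 + 2 Σ_τ (1 − τ/N) ρ̂(τ) uses the
   empirical autocorrelation ρ̂ truncated at its first non-positive
   value (the initial-positive-sequence heuristic); g is clipped to
   ≥ 1. Candidates cover every index when the series has ≤ 2000
   samples — the chosen cut is then exactly optimal with respect to
   the estimator — and otherwise ~1000 evenly spaced indices over
   [0, 0.9 N], which bounds the cost of an assessment while keeping
   the grid resolution below the extension block length at the
   cadences used here. Autocorrelations are computed by FFT, so one
   assessment costs O(candidates × N log N).
2. **Decorrelation.** The equilibrated region is subsampled with
   stride ⌈g⌉, rounding the inefficiency up to the nearest integer so
   retained samples are at least one correlation time apart.
3. **Jensen–Shannon test.** The decorrelated series is split in half
   chronologically (the second half keeps the extra sample of an odd
   count). Both halves are binned into `n_bins` (default 7) equally
   spaced bins spanning the **pooled** min/max of the two halves —
   per-half ranges would make the probability vectors incomparable —
   with the rightmost bin closed. The JS distance is the square root
   of the symmetrized KL divergence against the mixture M = ½(P+Q),
   computed with base-2 logarithms. The base matters: it bounds the
   distance in [0, 1] and therefore fixes the scale on which the
   convergence threshold operates; a natural-log convention would
   shrink every distance by √(ln 2) and effectively loosen the
   threshold.
4. **Decision.** In order of precedence: *converged* when
   JS ≤ threshold (a tie counts) with at least `min_decorrelated`
   samples; *soft cap* when the total window time has reached
   `soft_cap` with strictly more than `min_decorrelated` samples;
   *hard cap* when the total time has reached `hard_cap`; otherwise
   *extend*. The one-sample asymmetry between "at least" (convergence)
   and "strictly more" (soft cap) is intentional and kept as a literal
   reading of the rule. When fewer than two decorrelated samples
   exist, the JS distance is undefined (reported as NaN, serialized as
   null); it fails the convergence predicate, so such a window can
   only stop at the hard cap.

Assessment is recomputed on the full accumulated series after every
extension rather than incrementally; at the series lengths the caps
allow this is cheap and avoids any path dependence on the extension
history. Cap checks happen only at assessment points, so a window
whose block straddles a cap stops at the next check; total time never
exceeds `hard_cap` by more than one extension block. Windows are fully
independent — no information crosses λ.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| initial_length | preset (0.5–3.5) | ns | first production block; longer values buy more chance to observe slow behavior before the first verdict |
| additional_length | preset (0.25–0.5) | ns | extension block; sets convergence-check frequency (more checks → more false-positive convergence risk) |
| js_threshold | 0.1 | — | convergence strictness on the base-2 JS scale |
| min_decorrelated | 50 | samples | floor on the effective sample count behind a converged verdict |
| soft_cap / hard_cap | 6.5 / 10.5 | ns | budget limits; soft cap requires > min_decorrelated samples |
| n_bins | 7 | — | histogram resolution; more bins sharpen distribution differences and slow acceptance |

The six presets A (2.5/0.5 ns, 9 windows), B (1.5/0.5, 9),
C (1.0/0.25, 9), D (0.5/0.25, 9), E (3.5/0.5, 9) and C12 (1.0/0.25,
12) differ only in block lengths and window count; the caps and test
parameters are shared, including for C12, whose finer time step does
not change the rule itself.

## Estimation stack

Window means come from the decorrelated series with a bootstrap
standard error (default 1000 resamples, seeded; the count is a package
choice). ΔG is the weighted sum Σ wᵢ⟨dV/dλ⟩ᵢ with Gauss–Legendre
weights mapped to [0, 1] (exact to polynomial degree 2n − 1) or
composite trapezoid weights on an explicit node list. Window errors
propagate in quadrature, which assumes independent windows — valid for
the single-replica scheme; replicate-level spread is handled in the
evaluation module instead. A trapezoid schedule whose nodes do not
span [0, 1] (e.g. the nine equal windows 0.1…0.9) is flagged
`truncated_domain`: it integrates only the covered range and leaves
endpoint treatment to the caller, since softcore endpoint behavior is
outside this package.

The absolute-binding cycle is assembled as
ΔG_bind = ΔG_int^solv − ΔG_+VB^prot − ΔG_int^prot − ΔG_−VB^prot°.
The sign convention was validated by back-computing the analytic
restraint term from six published result rows, which agree on a single
value within 0.03 kcal/mol. The analytic term itself is the standard
stiff-spring closed form for releasing one distance, two angle and
three dihedral harmonic restraints (U = ½k(x − x₀)²) into the 1 M
standard-state volume:

ΔG = −RT ln[ 8π² V° √(k_r k_θA k_θB k_φA k_φB k_φC) /
(r₀² sin θ_A sin θ_B (2πRT)³) ],

with R = 1.98720425864083×10⁻³ kcal/(mol K), T = 300 K and
V° = 1660.5392 Å³ by default. No symmetry-number terms are included.
The unit tests check this form against a numerical configurational
integral of the restrained system (separable 1-D quadratures with the
exact r² sin θ Jacobian); in the stiff regimes used in practice the
two agree within 0.05 kcal/mol, the discrepancy being the Jacobian
curvature and finite angular domain the stiff limit neglects.

## Synthetic gradient streams

The generator module emulates the statistical behaviors a gradient
series can exhibit, not the physics that produces them:

- `iid_gaussian` — a well-behaved window (white noise);
- `ar1` — slow configurational sampling (true g = 1 + 2φ/(1 − φ));
- `transient` — an unequilibrated start (exponential mean decay);
- `heteroscedastic` — persistent non-convergence (σ doubling over a
  fixed time);
- `two_state` — conformational switching (mean alternating ±Δ; the
  `transient_height` field doubles as Δ).

Streams are counter-based: the value at sample index i is a pure
function of (seed, i) (per-index uniforms from a counter-mode
generator, mapped through the normal quantile function), so the
concatenation of `extend()` calls depends only on the seed and total
duration, never on how calls were partitioned. The AR(1) recursion
carries one state value across calls and inherits the same property.
Default cadence is 1 ps (1000 samples/ns), a plausible gradient output
frequency; it is always explicit in the spec object.

What passing tests on these streams do **not** show: real gradient
distributions are generally non-Gaussian (softcore endpoints produce
heavy tails), their autocorrelation is not single-exponential, and
transients are not cleanly exponential. The synthetic suite validates
the *decision logic and estimators* under controlled truth, not the
field performance of the thresholds on MD data.

## Numerical choices and degenerate inputs

- Zero-variance (constant) series: g := 1 with an explicit flag rather
  than an error, so the controller can still count samples; the
  histogram pair of a zero-width pooled range puts all mass of both
  halves in one bin (P = Q, JS = 0) and flags the report.
- Equilibration-cut ties favor the earliest t₀.
- 0·log 0 := 0 in the JS sum; the mixture M is positive wherever P or
  Q is, so no division by zero arises.
- Probability normalization is validated to 1e−9; bin probabilities
  are exact ratios of counts.
- Records serialize to canonical JSON (sorted keys, NaN → null), so
  identical seeds give byte-identical audit files.
- Evaluation: R² is the squared Pearson correlation of predictions vs
  references (an alternative — the coefficient of determination about
  the identity line — can be negative and is *not* what is computed
  here). Batch resampling draws replicates without replacement within
  a transformation and independently across transformations, and
  enumerates combinations exhaustively whenever their total count does
  not exceed the requested sample count. Truncation times beyond a
  series' length clamp to its full length.

## Known limitations

- The MD-engine side (job submission, mdout polling) is expressed only
  through the sampler contract; only synthetic streams and stored
  series are first-class inputs.
- No BAR/MBAR estimators, no λ-schedule optimization, no replica
  exchange, no finite-size or softcore endpoint corrections.
- The AMBER reader extracts instantaneous DV/DL records only; it does
  not parse the full energy decomposition, and the sampling cadence
  must be supplied by the user.
- Energies are kcal/mol only; no kJ support.
- The 50-sample minimum counts the full decorrelated series, not the
  per-half counts; whether to count before or after halving is a
  genuine design freedom and this package fixes it this way.
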