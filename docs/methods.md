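# Methods

## The generative model

`telosim` simulates the full qPCR measurement chain for relative telomere
length, per individual *i* in a cohort of *n*:

1. **True biology.** `tl_i ~ Normal(1, σ_t)`, the individual's telomere
   abundance relative to a typical genome.  The mean is fixed at 1 because
   the TS ratio is a purely relative measure.
2. **DNA sample.** `DNA_s,i ~ Normal(μ_s, σ_s)` (arbitrary units) is the
   amount of single-copy-gene sequence in the sample; the telomeric amount
   is exactly `DNA_t,i = a · tl_i · DNA_s,i`, with `a >> 1` the abundance
   fold of the telomeric repeat over the single-copy gene.
3. **Ideal Cqs.** Assuming 100% amplification efficiency,
   `iCq = f − log2(DNA)` for each assay, with `f` the fluorescence-threshold
   constant.
4. **Measurement error.** `mCq = iCq + ε`, with `(ε_t, ε_s)` bivariate
   normal, SDs `(σ_εt, σ_εs)`, correlation `ρ`, independently per technical
   replicate; the `k` replicate Cqs are averaged, so the effective error SD
   is `σ/√k`.
5. **TS ratios.** `mTS = 2^−(mCq_t − rCq_t − mCq_s + rCq_s)` with the
   cohort-mean measured Cqs as references `rCq` (making mean mTS ≈ 1); the
   ideal `iTS` uses the cohort-mean *ideal* Cqs, so it is error-free by
   construction.  Reference choice only rescales the ratios by a common
   constant and cannot affect correlations or repeatability; both objects
   carry their references so this is checkable.

Key structural consequences, each verified by tests against the closed
forms in `analytic_oracle`:

* `DNA_s` cancels exactly in the TS ratio; only `tl` and the error
  difference `D = ε_t − ε_s` survive: `mTS ∝ tl · 2^−D`.
* `L = 2^−D` is lognormal with log-SD `σ_L = ln(2)·σ_D`,
  `σ_D² = σ_εt² + σ_εs² − 2ρσ_εt σ_εs`.  The TS error `iTS·(L−1)` is a
  normal–log-normal mixture: positively skewed, leptokurtic, and with
  conditional mean magnitude `E|mTS − iTS| = E|L−1| · tl`, exactly
  proportional to true telomere length.
* Perfectly correlated equal-SD errors cancel (`σ_D = 0`): the TS ratio is
  then error-free even though each Cq is noisy.

## Default parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n` | 10 000 | cohort size; large enough that pattern estimates are limited by the model, not sampling noise |
| `μ_s`, `σ_s` | 10, 1 | sample-to-sample DNA variation small relative to its mean |
| `a` | 1000 | telomeric sequence many-fold more abundant; puts telomere Cq ≈ 14.7 and single-copy Cq ≈ 24.7, the empirically typical range for `f = 28` |
| `σ_t` | 0.1 | between-individual SD of relative telomere length ~10% of the mean, as in terminal-restriction-fragment data |
| `f` | 28 | fluorescence threshold constant (cycles) |
| `σ_εt`, `σ_εs` | 0 (varied 0–0.3) | error sigmas, in cycles; ~0.05 is typical of careful replicate data, 0.3 is far beyond plausible practice |
| `ρ` | 0 | Cq errors independent between the two reactions unless stated |
| `k_reps` | 1 | error sigmas are interpreted as *effective* (post replicate-averaging) values; `k_reps > 1` exists for the averaging demonstrations |

Draw order is fixed (tl, then DNA_s, then errors) and a single generator is
threaded through every draw, so any run is bit-reproducible from its seed.
The CLI derives per-subcommand streams from one global seed via a CRC32
spawn key, so adding an experiment never perturbs another's stream.

## Experiments

* **Repeated-sampling designs** (repeatability, crossover, longitudinal
  null) hold `tl` fixed and redraw DNA amounts and errors; each sampling is
  normalised by its own cohort means, as separate assay runs would be.  The
  consistency ICC — `(MS_rows − MS_error)/(MS_rows + (k−1)·MS_error)` from
  the two-way decomposition, with the occasion effect removed from the
  error — is deliberately invariant to such per-occasion rescaling.
* **Sweeps** default to 10 Monte-Carlo replicates per grid point with the
  between-replicate SE reported; grid points for the error sigmas are
  restricted to the examined range [0, 0.3].
* **Crossover** between ICC(mTS) and ICC(mCq_t) is reported as the first
  grid point where the TS curve falls to or below the raw-Cq curve, refined
  by linear interpolation of the difference between the bracketing points.
* The **distribution study** reports each error SD scaled by the SD of the
  corresponding ideal quantity, plus sample skewness (g1) and excess
  kurtosis (g2) with the D'Agostino and Anscombe–Glynn z-tests.  The
  bias-uncorrected moment definitions are used; at n ≥ 10³ the correction
  is negligible and the values are exactly reproducible.

## Closed-form companions

`analytic_oracle` derives everything from the factorisation `mTS = iTS · L`:
lognormal moments of `L`; the population consistency ICC
`v_b/(v_b + v_w)` with `v_b = σ_t²·m1²` and `v_w = (1 + σ_t²)(m2 − m1²)`
(`m1`, `m2` the first two raw moments of `L`, and `E[iTS²] = 1 + σ_t²` the
exact normal second moment of unit-mean tl); the folded moment
`E|L − 1| = e^{σ_L²/2}(Φ(σ_L) − Φ(−σ_L))` for the error-vs-tl slope; the
Blomquist change-vs-baseline correlation
`(r·sd2 − sd1)/√(sd1² + sd2² − 2r·sd1·sd2)`; and the `σ/√k` replicate rule.
These closed forms treat `iTS ≈ tl` (the geometric-mean normalising
constant `e^{−σ_t²/2} ≈ 0.995` is neglected, a ≲0.5% effect); the test
suite checks simulation against oracle across a 5×5 sigma grid within
Monte-Carlo error.  At error σ 0.05/0.10/0.15 the expected duplicate-run
ICC is 0.80/0.51/0.31.

## QC estimators

From a long-format technical-replicate table (sample, plate, well, target,
Cq), the per-assay error σ is estimated as the pooled within-sample SD
(variances pooled with replicates−1 weights) and, equivalently for balanced
data, as the RMS of within-sample pairwise Cq differences divided by √2.
Per-plate estimates restrict to each plate.  Replicate-group mean SDs are
computed by grouping wells in input order within each plate; the implied
reduction factor equals √(group size) only if replicates are independent —
per-plate mean shifts pull it below that, which the fixture generator can
emulate.  Duplicate-run TS ICCs are flagged below the conventional 0.75
benchmark.  CV output exists but is de-emphasised and carries a warning:
with Cq means of ~15–25 cycles, a raw-Cq CV of 0.004 corresponds to an
error σ of ~0.1 cycles, i.e. poor repeatability.

## The fixture generator and what passing tests show

`qc_empirical.generate_fixture` emulates a large replicate study: one
biological sample, two targets, 576 wells per target over two plates, Cq =
plate mean + Normal(0, σ_assay), with per-assay sigmas defaulting to 0.053
(telomere) and 0.095 (single-copy).  It reproduces the *statistical*
structure needed by the estimators (replication, plates, optional plate
shifts); it does not model well-position effects, amplification-efficiency
variation, pipetting gradients or between-sample biology.  Parameter
recovery on these fixtures therefore demonstrates estimator correctness,
not robustness to every real-world artefact.

## Numerical choices and degenerate inputs

* Normal draws for `tl` and `DNA_s` are rejection-resampled at ≤ 0 so the
  subsequent log2 is always defined; at the defaults the rejection
  probability is ≪ 1e−15, so the distributions are unaffected.
* Zero-variance inputs raise explicit errors (undefined ICC, undefined
  moments, zero-mean CVs); the zero-error longitudinal null is reported
  with a `degenerate` flag (change identically zero up to floating-point
  cancellation of the DNA term) rather than a meaningless correlation.
* ICC mean squares clip a (numerically) negative error sum of squares at 0.
* All file outputs are written atomically (temp file + rename); CSVs use
  full float precision ("%.17g").

## Problem sizes

Simulation-based checks use the default cohort (n = 10 000) with 10–20
seeded replicates for stochastic summaries, 10⁵ draws for SD-scaling
checks, and up to 10⁶ individuals for the binned error-vs-tl comparison —
sizes at which every check runs in seconds while Monte-Carlo error is well
below the assertion tolerances.

## Known limitations

* No plate/well systematic-effect modelling and no correction for
  amplification efficiency (efficiency is exactly 2); the model addresses
  the residual error that remains after such corrections.
* Each individual has a unitary `tl`; within-individual telomere length
  distributions are not modelled.
* The closed-form ICC is a population quantity; finite-sample distributions
  of ICC estimates are out of scope.
* The published single-run repeatability at error σ 0.15 (0.28) sits ~0.03
  below both the closed form and this simulator's multi-seed mean (~0.31);
  the discrepancy is documented rather than calibrated away, and both
  values are reported by the experiments.
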