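# Methods

## Design model

The pipeline analyses a two-factor design: stage (two levels, role A =
earlier, role B = later, taken from order of appearance in the sample sheet)
× fraction (`input`, `monosome`, `polysome`), with ≥ 2 biological replicates
per cell (the emulated design uses 3). Abundances are FPKM-like non-negative
values; the pipeline is agnostic to the upstream quantifier and performs no
within-sample renormalisation.

## Differential abundance per fraction

For each isoform and fraction, replicates are transformed to
log₂(x + c) and compared between stages with Welch's unequal-variance *t*
(two-sided, Welch–Satterthwaite df). p-values are corrected by
Benjamini–Hochberg step-up **within the fraction** (the three fraction
contrasts are separate families, matching how they are interpreted
downstream); an opt-in `global_correction` mode pools the three families
into one. Direction is `up`/`down` at q ≤ α by the sign of the log fold
change.

Parameters:

| parameter | default | units | why |
|---|---|---|---|
| pseudocount c | 1.0 | abundance | stabilises log₂ near zero; 1 FPKM-like unit is the conventional floor |
| α | 0.05 | FDR | the 5% FDR criterion of the emulated analysis |
| detection threshold | 1.0 | mean abundance | an isoform is "detected" in a stage when its replicate mean reaches this; the value is a configurable stand-in, since no canonical threshold exists for FPKM-like units — report it with any results |

Degenerate rows (zero variance in both stages with equal means, e.g. all-zero
abundances) get t = 0, p = 1 and a `degenerate` flag rather than NaN, so they
count as unambiguous non-calls in the BH family.

## State classification

States are assigned by strict precedence: (1) any input change ⇒
`transcription_up`/`transcription_down`; (2–3) else polysome down/up ⇒
`repressed`/`derepressed`; (4) else any monosome change ⇒ `monosome_shift`;
(5) else `steady`. Transcriptional change disqualifies the translational
labels because "translationally altered" is defined within steady-state
transcripts; the monosome direction never vetoes a polysome call and is kept
for reporting only. Detection in input does not gate eligibility — polysome
profiling sees low-abundance transcripts that total RNA-seq misses — but the
`detected_in_input` flag travels with each call so the below-detection subset
of derepressed isoforms can be counted. `monosome_shift` is this package's
explicit rendering of the residual class of steady-state isoforms that change
in the monosome pool only; it is an interpretation, not a claim that such
isoforms form a mechanistically coherent group.

## Fraction compositions

Per-replicate raw F/M/LP/HP abundances are closed (divided by their total) so
profiles are comparable across gradients; closure is idempotent and
scale-invariant, and all downstream differences live in [−1, 1]. A fraction
difference (default HP − F) is computed per replicate on closed profiles and
compared between the two conditions with Welch's *t*. Computing per replicate
and then testing across replicates is the only order compatible with a
t-test; testing differences of condition means would discard the replicate
variance. No correction is applied across the six possible fraction pairs by
default (comparisons are reported at nominal significance, matching how such
gradient comparisons are usually presented); a BH option exists for users who
test many pairs.

## ΔΔCt

ΔCt = Ct_target − Ct_reference per sample (reference = housekeeping control,
e.g. Gapdh); ΔΔCt = mean ΔCt(condition) − mean ΔCt(control);
fold = 2^(−ΔΔCt), so the control condition is 1 by construction and swapping
the roles of two conditions inverts the fold exactly. Replicates are
aggregated by the arithmetic mean of ΔCt (the standard Livak formulation);
spread is reported as the SD of ΔCt, on the Ct scale, because fold-change SDs
are asymmetric and misleading.

## Permutation set enrichment

For one (input, target) pair over a background universe B: draw |input| genes
from B without replacement n_perm times (default 10,000) and report
p = #{draws with overlap ≥ observed}/n_perm — the literal empirical rule,
which can return 0. Results therefore always carry the raw exceedance count;
−log₁₀ p for a zero count is rendered at the resolution floor
−log₁₀(1/n_perm) and marked as a lower bound, and an optional
(count + 1)/(n_perm + 1) pseudocount variant is available for users who need
strictly positive p. Members outside the universe are an error by default
(silent clipping changes the null); `clip_to_universe` downgrades this to an
intersection. The exact hypergeometric tail is provided as the analytic
counterpart and is used in the test suite to verify the sampler; grids derive
a per-pair sub-seed from the master seed and the pair's set names (CRC32), so
results are independent of traversal order.

## Synthetic data generator

The generator emulates the two-stage × three-fraction × three-replicate
design with planted states. Noise is negative binomial around the planted
mean (var = μ + φμ²), the standard overdispersed model for RNA-seq-derived
abundances; the original FPKM estimates come with no stated noise model, so
NB is a stand-in, not a claim about the real data, and a mean-matched
log-normal alternative (`noise_model="lognormal"`) is exposed for sensitivity
checks. Defaults: baseline mean 50 (a mid-range FPKM-like value), dispersion
0.1 (typical for bulk biological replicates), fold 4 for planted effects,
3 replicates.

Planted effects: transcriptional states scale all stage-B fractions;
repression/derepression scales stage-B polysome only, leaving the monosome
untouched (the default, since the magnitude of any monosome↔polysome
exchange is unquantified); an optional mass-conserving mode moves the same
mass between monosome and polysome, clamped so a pool cannot donate more
than its own mean. Fraction pooling is simulated directly at the three
pooled fractions rather than as twelve raw gradient fractions. A configurable
fraction of derepressed isoforms is planted with input means below the
detection threshold at both stages (default 0.1 × threshold), exercising the
below-detection reporting path.

What the generator does **not** emulate: library-size and length biases,
correlated isoforms of one gene, batch effects, heavy-tailed outliers, or
abundance-dependent dispersion. Passing recovery tests therefore demonstrates
the pipeline's correctness under a clean NB world, not its performance on
real libraries.

## Statistical power at the emulated design — a known limitation

With three replicates per group, Welch's *t* has ≈ 4 degrees of freedom. At
NB dispersion 0.1 the within-group log₂ sd is ≈ √(1/μ + 0.1)/ln 2 ≥ 0.46, so
a fold-4 effect (Δlog₂ = 2) yields a noncentrality of ≈ 5 — large, but the
heavy t₄ tail means such isoforms still rarely reach the p ≈ 0.002–0.008
range that BH demands over a 2,000-isoform family. The per-isoform
sensitivity of the repressed/derepressed calls under these conditions is
therefore low (the acceptance script measures it, typically a few percent at
baseline 50), while the false-discovery proportion stays controlled at or
below the nominal level. This is a property of the n = 3 Welch-per-isoform
design itself, not of the implementation: recovery becomes essentially
perfect once replicate noise is small (see the low-dispersion recovery test),
and variance-moderated count models would be the remedy on real data but are
outside this package's defined statistic.

## Numerical and problem-size choices

- BH is computed by statsmodels' step-up implementation and verified against
  a brute-force `min_{j≥i} p₍ⱼ₎·m/j` in the tests to 1e-12.
- Welch p-values use `scipy.stats.t`; the degenerate zero-variance cases are
  handled by convention (equal means → p = 1; unequal → p = 0) before the
  t lookup.
- The hypergeometric tail is evaluated through `scipy.stats.hypergeom.sf`
  (log-space stable) and checked against direct binomial-coefficient sums.
- Permutation sampling vectorises draws as arg-partitioned random keys in
  chunks capped at ~4 × 10⁶ floats, keeping memory flat for large universes.
- Monte-Carlo suite sizes: null calibration uses 200 matrices of 500
  isoforms; recovery uses 20 matrices of 2,000; the fraction-shift power
  estimate uses 500 seeded runs; chosen to keep Monte-Carlo error well below
  the margins being tested.
- Determinism: one master seed; per-pair/per-stage sub-seeds derived via
  `SeedSequence`, so outputs are byte-identical across reruns and invariant
  to computation order.
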