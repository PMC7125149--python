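# polystate

Classification of mRNA isoforms into translational-regulation states from
polysome-profiling RNA-seq, with compositional statistics for sucrose-gradient
fractions, permutation gene-set enrichment, and ΔΔCt qPCR quantification.

## The problem

Polysome profiling separates a tissue lysate on a sucrose gradient into
translationally distinct pools: free mRNPs (F), the 40S–60S–80S monosome pool
(M), and light/heavy polysomes (LP/HP). Sequencing the **input** (total RNA),
**monosome** and **polysome** pools at two developmental stages (e.g. mouse
neocortex at E13 and E16, three biological replicates each — 18 libraries)
reveals which transcripts change their ribosome engagement rather than their
abundance:

- **transcriptional regulation** — total (input) abundance changes between
  stages;
- **translational repression** — total abundance is steady, but polysome
  association *decreases* from stage A to stage B;
- **translational derepression** — steady total abundance, polysome
  association *increases*;
- **monosome shift** — only the monosome pool changes;
- **steady** — nothing changes.

`polystate` implements this partition as a reproducible pipeline. Because
polysome RNA-seq is more sensitive than total RNA-seq at low expression,
isoforms undetected in input remain eligible for the translational classes
and are flagged, so the below-detection subset can be reported separately.

## Methods at a glance

- **Per-fraction contrast** (stage B vs A): Welch's *t* on
  log₂(x + pseudocount) across replicates, two-sided, with Benjamini–Hochberg
  FDR within each fraction; direction called at q ≤ α (default α = 0.05).
- **State classifier**: precedence rules — input change ⇒ transcriptional;
  else polysome down/up ⇒ repressed/derepressed; else monosome change ⇒
  monosome shift; else steady.
- **Fraction compositions**: closure operator x_i / Σx, then per-replicate
  differences (e.g. HP − F) compared between conditions with Welch's *t*
  (Welch–Satterthwaite df).
- **Set enrichment**: draw |input| genes from the background universe without
  replacement *n* times (default 10,000); p = fraction of draws whose overlap
  with the target set ≥ the observed overlap. The exact hypergeometric tail
  P(K ≥ k) = Σ_j C(T, j)·C(B−T, n−j)/C(B, n) serves as an analytic
  cross-check.
- **ΔΔCt**: ΔCt = Ct_target − Ct_reference per sample, ΔΔCt relative to the
  control condition's mean ΔCt, fold = 2^(−ΔΔCt).
- **Synthetic data**: negative-binomial abundances
  (var = μ + φμ²) around planted per-state means, so sensitivity, false
  discovery and calibration are measurable against known truth.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate an experiment with 20% of 2,000 isoforms planted as translationally
regulated, then classify:

```sh
polystate simulate --n-isoforms 2000 --seed 7 --out demo
# writes demo/abundance.tsv, demo/samples.tsv, demo/truth.tsv
cat > demo.yaml <<EOF
out_dir: demo_run
seed: 7
simulate:
  n_isoforms: 2000
  baseline_mean: 500.0
  dispersion: 0.001
  state_proportions: {steady: 0.8, repressed: 0.1, derepressed: 0.1}
EOF
polystate run --config demo.yaml
```

which prints `wrote 8 files to demo_run`, and `demo_run/state_summary.tsv`
then holds one row of category counts:

```
transcription_up  transcription_down  repressed  derepressed  monosome_shift  steady  translationally_altered  below_detection_derepressed  n_total
0                 0                   203        201          0               1596    404                      0                            2000
```

At this low noise the 200 planted repressed and 200 planted derepressed
isoforms are all recovered (`translationally_altered = 404` includes 4
borderline false calls, consistent with BH at α = 0.05), and
`state_table.tsv` gives the per-isoform direction calls behind them. With
realistic replicate noise the same pipeline recovers far fewer of the
planted isoforms — three replicates give Welch's *t* only ~4 degrees of
freedom — which is exactly what the summary quantifies against `truth.tsv`.

Enrichment of an id list against disease gene sets:

```sh
polystate enrich --input-gmt inputs.gmt --target-gmt targets.gmt \
  --universe universe.txt --n-perm 10000 --seed 7 --out grid.tsv
```

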