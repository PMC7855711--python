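# Methods

## Pipeline model and assumptions

`cernax` operates on collections of feature × sample expression
matrices assumed to be on a log scale (a `log2_transform` switch —
log2(x+1) — is available for linear-scale inputs; nothing is
transformed by default, because Pearson screens are scale-sensitive and
silent transformation would be worse than an explicit contract).
Missing values use the token `NA` and are handled by pairwise deletion
inside every correlation; a feature absent from a dataset simply
contributes no evidence from that dataset.

The screening funnel makes the following assumptions explicit:

* **Severity contrasts are binary.**  Multi-level clinical features are
  collapsed into a severe-level set vs. a mild-level set
  (`ContrastSpec`); the test is a one-way ANOVA between the two groups
  (identical to a pooled-variance t-test, F = t²), and the direction of
  a call is the sign of the severe-minus-mild mean difference.
* **Significance is assessed on FDR-adjusted values.**  The q ≤ α rule
  (α = 0.01 by default) is applied to Benjamini–Hochberg step-up
  q-values computed within each (dataset × contrast) family.  The
  alternative reading — raw p ≤ α with FDR merely reported — is
  selectable (`adjust=False` / `--raw-pvalues`) because descriptions of
  this style of screen are often ambiguous on the point.
* **Cross-dataset agreement is vote counting, not meta-analysis.**  A
  gene (or a signed lncRNA–bait association) is retained when supported
  in ≥ `min_fraction` (default ½) of consulted datasets, compared with
  exact rational arithmetic so that 5-of-10 passes a 50 % threshold
  without floating-point accidents.  No effect-size pooling is done;
  the procedure implemented is the vote-counting one.  The denominator
  counts **all** consulted datasets, including those not measuring the
  feature (configurable to measured-only), for the bait and
  lncRNA-selection stages.
* **A dataset supports a direction if any of its contrasts calls it.**
  Per-contrast provenance is kept in `de_calls.tsv`, but the vote is
  per dataset.
* **Conflicts are surfaced, not resolved.**  A gene reaching consensus
  in both directions, or a lncRNA landing in both A∩D and B∩C, is
  excluded from the clean lists and reported as conflicting.  The
  packaged published four-list fixture illustrates why: one lncRNA
  (LINC00312) sits in the full oncogene-side intersection yet was not
  taken forward in the original screen; the classifier reports the full
  intersection and flags the discrepancy rather than guessing an
  editorial rule.

## Axis reconstruction

For a candidate lncRNA the axis stage consumes three evidence tables
(lncRNA–miRNA binding predictions, experimentally validated miRNA→mRNA
targets, miRNA–disease dysregulation annotations) plus expression data:

1. miRNAs negatively correlated with the lncRNA at p ≤ 0.001 in a
   designated **reference dataset** (default: first in the manifest).
   Using one reference matrix mirrors the common situation where only a
   single large cohort carries joint miRNA and mRNA quantification.
2. Union with binding-predicted miRNAs ("completing" the correlation
   output; union, not intersection, because reported axes can retain
   miRNAs whose correlation support alone is weak).  Each miRNA keeps
   per-channel evidence flags.
3. miRNAs with no validated target rows are dropped and logged.
4. miRNAs are restricted to those annotated for the study disease;
   conflicting dysregulation directions from different sources are all
   reported, never resolved.
5. An axis is emitted per (miRNA, validated target mRNA) pair whose
   mRNA passes the lncRNA–mRNA **positive-correlation consensus**:
   positively correlated at p ≤ 0.01 in at least half of the datasets
   measuring the pair.  This vote uses a measured-pairs denominator —
   unlike the upstream screens — because a dataset without both
   features carries no evidence either way, and the axis stage would
   otherwise punish platform gaps twice (once in the numerator, once in
   the denominator).  The reported coefficient comes from the reference
   dataset when it passes there, else from the passing dataset with the
   smallest p (deterministic tie-break by dataset id).

The **negative miRNA–mRNA constraint is soft by default**: every axis
records its miRNA–mRNA correlation and a `strict_pass` flag (miRNA
significantly negative with the lncRNA *and* negatively correlated with
the mRNA); `strict=True` / `--strict-negative` emits only those.
Reported axis tables in this literature include pairs with positive or
non-significant miRNA–mRNA correlations, so the intended filter
severity is genuinely ambiguous — hence a switch instead of a guessed
cutoff.  "Highest-R" filtering is exposed as `top_k_mrnas` /
`min_r_lnc_mrna` with keep-all defaults, because no numeric cutoff is
stated for it anywhere; the output is ranked by descending lncRNA–mRNA
r either way.

Identifiers are compared case-insensitively after trimming; no alias
or namespace resolution (miRBase versions, gene symbol synonyms) is
attempted.

## qPCR quantification

ΔCt = mean(Ct_target replicates) − mean(Ct_reference replicates) per
sample; ΔΔCt = mean ΔCt(case) − mean ΔCt(control); fold change
2^-ΔΔCt.  Technical replicates are aggregated by arithmetic mean with
no automatic outlier removal (a convention; the source protocols rarely
state one).  Group comparison uses Student's t on the ΔCts — paired on
within-pair differences when a matched design (`pair_id`) is declared,
pooled-variance unpaired otherwise; Welch's variant is available by
flag but is not the default because plain "unpaired t-test" is the
stated method.  Significance is flagged at p ≤ 0.05.  No
amplification-efficiency correction (Pfaffl), melt-curve QC or
standard-curve fitting is performed.  When all ΔCts are exactly
replicate-free (noise-free simulated plates), the fold change is still
reported and the t-statistic is NaN rather than an error.

## Synthetic cohort generator

The generator's job is to produce cohorts in which every screening
stage has recoverable planted structure, under an additive Gaussian
latent-factor model on the log scale:

x(feature, sample) = b_{d,f} + s_f · e_d · sd_w · 1[severe]
                     + load_f · g_sample + σ · ε

* `b_{d,f}`: per-dataset, per-feature baseline ~ N(8, 1) — platform
  heterogeneity;
* `e_d`: the bait effect size (default 1.5, in within-group SD units
  sd_w = √(λ²+σ²)) with ±20 % per-dataset jitter;
* `g`: one standard-normal latent factor per sample; the sponge lncRNA
  and its axis mRNAs load +λ (λ = `sponge_coupling`, default 0.8), the
  axis miRNAs −λ, down-baits +λ, up-baits −λ;
* the whole planted ceRNA module is itself severity-associated — the
  sponge and axis mRNAs carry the down-in-severe shift, the axis miRNAs
  the up-in-severe shift (sign s_f) — because that is the premise of
  the screen: a sponge whose expression did *not* track the
  severity-dysregulated genes would be undiscoverable by marginal
  correlation, and the discovered candidates in this literature are
  themselves severity-associated;
* decoy mRNAs/lncRNAs/miRNAs are independent noise; each feature is
  dropped from each dataset with probability
  `missing_feature_fraction` (default 0.1), except that planted
  features always remain in the reference dataset and every feature is
  measured somewhere.

Closed forms used by the tests: two features sharing only the factor
with loadings λ₁, λ₂ have corr = λ₁λ₂ / √((λ₁²+σ²)(λ₂²+σ²)); with a
shared shift h = e·sd_w at an equal group split the shared-variance
term h²/4 is added to both numerator and the marginal variances.  At
the defaults the sponge–mRNA correlation is ≈ 0.67, the factor-only
bait coupling ≈ 0.39.

Interaction tables mix true rows (every sponge–axis-miRNA binding row,
every axis miRNA→mRNA target row, oncomiR disease annotations) with
configurable decoy rows drawn from the decoy pools, plus
binding-predicted miRNAs deliberately lacking target rows to exercise
the exclusion rule.  The qPCR plate simulator draws reference Cts
around cycle 20 and offsets target Cts so the case group's true
ΔΔCt = −log2(fold change), with independent Gaussian cycle noise.

All randomness flows from a single master seed through named substreams
(`SeedSequence([seed, crc32(stage), index])`), so adding a stage never
perturbs another stage's draws and identical seeds give byte-identical
output files (numeric TSV cells are written with 6 significant digits,
which also makes write→read→write round-trips bit-identical).

**What the generator does not emulate** — and therefore what passing
recovery tests do *not* establish about real data: probe-level
microarray artifacts, RNA-seq count distributions and mean–variance
coupling, batch structure within a dataset, correlated decoys
(co-expression modules unrelated to the planted axis), annotation
errors beyond random decoy rows, and identifier-namespace mismatches.
Recovery on these cohorts demonstrates that the implementation applies
its stated rules correctly at realistic effect sizes, not that the
thresholds are well-calibrated for any particular real repository.

## Numerical choices and degenerate inputs

* Pearson p-values come from the t-transform with n−2 df (two-sided),
  not permutation; records need ≥ 3 jointly non-missing samples, and
  constant vectors raise a distinct degenerate-input error.
* BH q-values are the standard step-up min-forward-cumulative formula;
  q ≥ p element-wise and q ≤ 1 always.
* A feature constant across both groups of a contrast is excluded from
  testing (F = 0 would be uninformative and pollute the FDR family).
* Vote fractions are exact `Fraction`s; candidate output is sorted
  lexicographically; axis output is sorted by (−r_lnc_mrna, miRNA,
  mRNA) — all ties deterministic.
* Pipeline stage failures abort with the stage name, a non-zero exit
  status, and partial TSVs moved to `out/quarantine/`.

## Problem sizes in the shipped checks

The recovery checks run the full pipeline on the default cohort
(8 datasets × 120 samples, ≈ 95 features) over 20 seeded replicates;
null error control uses 2 null datasets × 430 mRNAs for the DE rate and
1,000 simulations (n = 10 per group) for the t-test type-I rate; oracle
equivalence uses 100 random small instances per primitive at 1e−9
agreement.  These sizes give every stochastic assertion a comfortable
margin (binomial SEs well below the asserted bounds) while keeping the
whole suite around twenty seconds.

## Known limitations

* No partial correlation or covariate adjustment: the screen is
  marginal Pearson by design, and confounding (e.g. tumor purity) will
  propagate into the lists exactly as it does in the procedure the
  package implements.
* Vote counting ignores dataset size and quality; a 22-sample dataset
  counts as much as a 566-sample one.
* The miRNA stage depends on a single reference dataset; if it is
  unrepresentative, axis correlations inherit its biases.
* No de-novo binding-site prediction; binding evidence is consumed as
  tables and is only as good as its sources.
* The CLI's `run-all` is deterministic given inputs and config, but the
  discovery thresholds themselves (0.01 / 0.001 / 50 %) are conventions
  of the emulated procedure, not optimized quantities.
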