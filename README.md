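# cernax

Consensus differential-expression screening and ceRNA
(lncRNA–miRNA–mRNA) axis reconstruction for collections of
heterogeneous expression datasets, with a planted-truth synthetic
cohort generator and 2^-ΔΔCt qPCR statistics.

## The problem

Competing-endogenous-RNA (ceRNA) analysis asks whether a long
non-coding RNA acts as a **miRNA sponge**: lncRNA and mRNAs sharing
miRNA response elements compete for the same miRNAs, so their
abundances should be **positively** correlated with each other and
**negatively** correlated with the shared miRNAs.  `cernax` implements
the in-silico funnel that discovers such candidates from multi-study
expression collections (for example colorectal-cancer cohorts) and
reconstructs their molecular axes:

1. **Bait-gene screen** — per dataset, every protein-coding gene is
   tested with a one-way ANOVA between samples with *severe* vs. *mild*
   levels of a clinical feature (metastasis, MSI, stage, mutation
   status, …), with Benjamini–Hochberg FDR control at q ≤ 0.01; genes
   dysregulated in the same direction in ≥ 50 % of the consulted
   datasets become the up-/down-regulated **bait genes** (BGs).
2. **lncRNA selection** — every lncRNA is correlated (Pearson,
   p < 0.01) with every BG per dataset, votes are counted per
   (lncRNA, BG, sign) triple across datasets at the same 50 % rule, and
   four lists are built: positive-with-down-BGs (A),
   positive-with-up-BGs (B), negative-with-down-BGs (C),
   negative-with-up-BGs (D).  A ∩ D yields tumor-suppressor candidates,
   B ∩ C oncogene candidates; membership in both is surfaced as a
   conflict, never silently resolved.
3. **Axis reconstruction** — for a candidate lncRNA: miRNAs negatively
   correlated with it (p ≤ 0.001) are unioned with miRNAs carrying
   predicted binding sites; miRNAs without experimentally validated
   mRNA targets are excluded; the rest are restricted to annotated
   disease-involved oncomiRs; one axis is emitted per
   (miRNA, validated target mRNA) pair whose mRNA passes the
   positive-correlation consensus with the lncRNA, ranked by the
   lncRNA–mRNA coefficient and flagged `strict_pass` when the full
   negative sign pattern of the sponge model holds.
4. **qPCR stage** — ΔCt = Ct(target) − Ct(reference), fold change
   2^-ΔΔCt, group comparison by paired or unpaired Student t-test at
   p ≤ 0.05, mirroring bench validation of the candidates.

The statistics underneath are the classical ones: Pearson r with the
two-sided t-transform p-value (t = r·√((n−2)/(1−r²)), df = n−2),
BH step-up q-values, one-way ANOVA (≡ pooled t² for two groups).

## Worked example

Generate a synthetic eight-dataset cohort with a planted sponge lncRNA
and run the full pipeline:

```bash
cernax simulate --out-dir cohort --seed 7
cat > config.yaml <<EOF
manifest: cohort/manifest.yaml
contrasts: cohort/contrasts.yaml
binding_table: cohort/lncrna_mirna_binding.tsv
targets_table: cohort/mirna_mrna_targets.tsv
cancer_table: cohort/mirna_cancer.tsv
disease: CRC
seed: 7
EOF
cernax run-all --config config.yaml --out-dir out
```

The run report's funnel counts (seed 7):

```
{'axes_emitted': 24, 'bait_down': 25, 'bait_up': 5,
 'candidates_tumor_suppressor': 1, 'candidates_oncogene': 0,
 'candidates_conflict': 0, 'datasets_read': 8, 'de_calls': 219,
 'list_A': 1, 'list_B': 0, 'list_C': 0, 'list_D': 1,
 'mirnas_merged': 7, 'mirnas_with_targets': 5, 'mirnas_oncomir': 5}
```

The single tumor-suppressor candidate is the planted sponge
(`LNC-SPONGE1`, found in lists A and D); the 24 emitted axes are
exactly the planted (4 miRNA × 6 mRNA) triplets.  `out/axes.tsv` holds
one row per axis with all six correlation numbers, e.g.

```
lncrna_id    mirna_id  mrna_id  r_lnc_mirna  r_mirna_mrna  r_lnc_mrna  strict_pass
LNC-SPONGE1  miR-AX01  AXM005   -0.681       -0.698        0.691       True
```

— the sponge sign pattern (lncRNA–mRNA positive, miRNA negative with
both).  The qPCR stage on the simulated plate (true fold change 0.5,
i.e. a halved transcript level in cases):

```bash
cernax qpcr --ct-table cohort/qpcr.csv --reference PPIA \
       --case case --control control --out qpcr_report.tsv
# target       ddct     fold_change  t       p            significant
# LNC-SPONGE1  1.04618  0.484248     5.6202  0.000221399  True
```

`cernax curated-fixture` classifies the packaged, published
colorectal-cancer four-list fixture: the A∩D tumor-suppressor set is
{DLEU1, LINC00261, LINC00483, LINC01207, MCF2L-AS1}, the full B∩C
intersection is {LINC00312, MEG3, RUNX1-IT1, TP73-AS1} with LINC00312
flagged as absent from the curated oncogene trio.

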