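# epidriver

A causal screen for transcription factors (TFs) that **drive** histone-mark
changes in cancer cell lines, rather than merely correlating with them.

Across a panel of cell lines, TF and histone-mark (HM) binding activities
are quantified from ChIP-seq peak files as normalized signal enrichment. A
pan-cancer OLS screen

&nbsp;&nbsp;&nbsp;&nbsp;`HM_ik ~ β·(TF_ij·C_k) + α₁·E_ij + T_i + ε` (BH FDR < 0.1)

proposes candidate TF–mark pairs, and a two-stage least-squares (2SLS)
instrumental-variable stage, using the TF's binary somatic mutation status
as the instrument,

&nbsp;&nbsp;&nbsp;&nbsp;`HM_ik ~ β₀ + β₁·TF_ij + E_ij + T_i | Mut_ij + E_ij + T_i + ε`

estimates the causal effect β₁ with weak-instrument (Kleibergen–Paap-style
robust first-stage F) and Wu–Hausman endogeneity diagnostics. Pairs passing
the dual gate (FDR < 0.1 **and** FDRweak < 0.1) are *driver pairs*. Their
target genes — genes whose TSS windows meet the pair's co-bound loci — are
then characterized by CERES dependency-bin and gene-set enrichment,
per-cancer Pearson correlation of co-bound signals, drug-response (IC50)
association, Kaplan–Meier/log-rank survival, and a score-thresholded
protein-interaction network.

The package is written for methodologists and computational biologists who
want the full inference chain testable end to end: a synthetic-cohort
generator plants a known mutation → TF activity → mark activity causal
chain behind a latent confounder, so ordinary regression is provably biased
while the IV stage recovers the planted effects. See `docs/methods.md` for
the model, all conventions, and known limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (60 cell lines, 3 cancer types, 12 TFs × 3 marks, two
planted causal pairs with effect 1.5) and write tables under
`results/analysis/`:

```bash
for s in analysis/0*.py; do python "$s"; done
```

The screen tests 36 pairs and keeps 4 candidates at FDR < 0.1 — the two
planted pairs with vanishing p-values plus two borderline chance
correlations (an FDR of 0.1 admits them by design):

```
tested 36 TF–mark pairs; 4 candidates at FDR < 0.1:
  tf      hm      beta            p          fdr
TF00 H3K4me3  0.963653 5.424549e-30 9.764188e-29
TF01 H3K4me1  1.002981 1.991054e-39 7.167796e-38
TF10 H3K27ac -0.323715 7.192648e-03 8.297453e-02
TF11 H3K4me1  0.347583 9.219393e-03 8.297453e-02
```

The IV stage then reports, per candidate, β₁ on the standardized activity
scale, exp(β₁) (labeled `or_exp_beta1`), and the three diagnostics:

```
  tf      hm     beta1  or_exp_beta1       wald_p  weak_instruments_p  wu_hausman_p
TF00 H3K4me3  0.594001      1.811221 2.452852e-03        2.025065e-03      0.000632
TF01 H3K4me1  0.872034      2.391772 4.226703e-16        2.483366e-05      0.023706
TF10 H3K27ac -0.347126      0.706716 7.151207e-02        1.049388e-07      0.876859
TF11 H3K4me1  0.531334      1.701201 3.918325e-03        1.597278e-11      0.113562
```

Both planted pairs are confidently flagged (small Wald *and* Wu–Hausman
p-values: a real effect whose OLS estimate was endogenous). The two
spurious candidates illustrate the known failure mode of a lenient dual
gate — note their non-significant Wu–Hausman columns. Downstream, the
planted gene set tops the enrichment table (fold 4.3, p = 1.3e-12), the
planted drug class shows median exp(β₁) = 1.57 with Fisher-combined
p = 1.3e-69, and mutation carriers of the planted TF have markedly worse
survival:

```
mutation_group: log-rank p = 1.71e-08
   mutated: n=92, 60-month OS 27.5% (95% CI 17.2–38.9)
      wild: n=208, 60-month OS 63.4% (95% CI 55.5–70.3)
```

The simulation study (`analysis/09_recovery_simulation.py`) quantifies the
bias the IV stage exists to remove — with confounding calibrated to an
analytic OLS bias of 0.49 at true effect 1.5:

```
mean OLS estimate:  1.9926
mean 2SLS estimate: 1.4947
95% CI coverage:    93.0%
```

The same pipeline is scriptable from a shell (`epidriver run-all --seed 1
--out results/pipeline`) or from Python (`epidriver.pipeline.run_pipeline`),
and consumes user-supplied narrowPeak/broadPeak files, mutation/expression
matrices and metadata in `--mode files`.

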