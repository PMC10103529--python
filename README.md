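# sigbridge

Rank-based single-sample immune-signature scoring across expression
platforms: a targeted NanoString-style panel (~770 probes) and whole
transcriptome sequencing of the same tumours.

## The problem

Immuno-oncology groups score curated gene signatures — such as the 18-gene
Tumour Inflammation Signature (TIS) or the PD-1 checkpoint axis
(PDCD1/PDCD1LG2/CD274) — to characterise the tumour microenvironment and
predict response to anti-PD-1 therapy.  Targeted panels and RNA-seq measure
the same biology on different scales, and panel genes are deliberately
chosen from the well-expressed part of the transcriptome, so their
within-sample ranks are compressed into the upper region of a
whole-transcriptome ranking.  Any analysis that scores signatures on one
platform and applies them on the other must handle that rank skew.

`sigbridge` implements the undirected rank-based single-sample score
(*singscore*-style) together with three cross-platform ranking
calibrations, the diagnostics to decide between them, and the downstream
response analysis:

- **scoring** — per-sample gene ranks from 0 with competition ties; the
  undirected score of a gene set is the mean absolute deviation of its
  ranks from the sample's median rank, normalised to [0, 1] by the extreme
  placements on the tie-free rank grid.  Calibrations: plain ranks
  (`no_stable` / `all` / `part`), stable-gene-stratified ranks
  (`hk_genes`), and a linear rank remap fitted between uniform quantiles
  and the overlap genes' whole-transcriptome median ranks (`skewed`).
- **nanostring** — an emulation of the documented nCounter normalisation
  chain (background floor 20, geometric-mean positive-control and
  housekeeping content factors, %CV housekeeping screen, flag at content
  ratio >= 10, per-gene panel-standard cartridge calibration).  Because the
  score is rank-based, these per-sample rescalings provably cannot change
  it.
- **consistency** — cross-platform gene-rank consistency (average pairwise
  order preservation against the transcriptome's median-rank reference) and
  the MAD-based stable-gene candidate screen.
- **cohort** — responder/non-responder differential testing (two-sided
  Mann-Whitney, Benjamini-Hochberg FDR), RECIST-derived response labels,
  and the reference cohort's clinical contingency tables.
- **agreement** — per-sample and per-signature score agreement for the four
  comparison pairs bridging panel and transcriptome scoring.
- **model** — stability feature selection by 1000x ten-fold CV-LASSO
  selection frequencies, an unpenalised logistic response model, and
  cross-platform evaluation (AUC, sensitivity, specificity, MCC) at the
  default 0.5 and Youden-optimal thresholds.
- **synthetic** — a paired-platform cohort generator with known ground
  truth (rank-biased panel membership, transcriptional-program signatures,
  response effects, batch/platform/housekeeping corruption), so every stage
  is testable without the access-restricted patient data.

## Worked example

```python
import sigbridge as sb

cohort = sb.simulate_cohort(sb.CohortConfig(seed=7))
scores = sb.score_table(cohort.panel_counts, cohort.signatures, "no_stable")
diff = sb.mannwhitney_bh(scores, cohort.metadata["response"],
                         positive_group="R")
print(diff[["delta_median", "p_adj", "tier"]].round(4))
```

prints (seed 7, default world):

```
                 delta_median   p_adj   tier
signature
inflammation_18       -0.0829  0.0000  fdr05
checkpoint_3          -0.1125  0.0012  fdr05
stromal_10             0.1550  0.0000    top
null_10               -0.0443  0.4895     ns
```

The three response-linked signatures separate the groups at FDR <= 0.05;
the null signature does not.  Note the signs: an undirected score measures
a set's *displacement* from the sample's rank centre, so its direction
depends on which side of the centre the set occupies.  The injected sets
sit below the panel's centre, so responder-up expression moves them toward
the centre (lower score) and the responder-down set away from it (higher
score) — direction is interpreted per signature, exactly as with volcano
plots of undirected scores in practice.  The `examples/` directory has
one short script per capability: simulation, normalisation, scoring under
all calibrations, consistency screening, response testing, and
cross-platform prediction.

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch — cohort
simulation, panel normalisation, rank-consistency screening, the four
cross-platform agreement pairs, response differential testing, and the
stability-selected logistic model evaluated on the other platform — and
writes its results as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
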