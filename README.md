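# qmpflow

Quantitative microbiome profiling (QMP) of longitudinal, multi-segment
gut communities, with time-course serum-metabolome integration.

Relative microbiome profiling (RMP) — sequencing proportions summing to
1 per sample — is blind to changes in total microbial load, and load
changes of several orders of magnitude are exactly what happens in a
developing gut. `qmpflow` implements the full analysis chain for a
developmental cohort design (here: broiler chickens, 10 birds × 4 gut
segments × 8 days posthatch, bacteria and fungi): qPCR-calibrated
absolute abundances, community typing, source tracking along the gut,
ecological assembly-process inference, longitudinal occurrence
patterns, co-occurrence networks, metabolome trajectory analysis, and
microbe–metabolite co-occurrence modelling. A synthetic-data module
generates the whole study design with planted ground truth, so every
stage is testable without access to sequencing data.

It is written for microbial ecologists who want the statistics of such
a study as tested, reusable, scriptable functions.

## The core models

* **QMP transform** — a qPCR standard curve `Ct = a·log10(copies) + b`
  (10³–10⁸ copies; efficiency `(10^(−1/a) − 1)·100 %`) converts Ct
  values to copies per gram; each sample's proportions are multiplied
  by its load, so row sums equal loads exactly.
* **Community types** — a Dirichlet multinomial mixture (DMM) over
  samples binned as `round(log10(1 + copies/g))`; K chosen by a
  MAP-Laplace approximation to the model evidence (BIC reported).
* **Source tracking** — the sink community is multinomial with
  probabilities `Σ_k α_k γ_k` over source profiles `γ_k` plus an
  unknown source; `α` estimated by EM (monotone likelihood), reported
  as the adjacent-anterior contribution per bird × day.
* **Assembly processes** — βMNTD between communities, z-scored against
  a tip-shuffling null (βNTI), then Raup–Crick on Bray–Curtis
  (RC_Bray ∈ [−1, 1]) for pairs with |βNTI| < 2; pairs map to
  heterogeneous/homogeneous selection, dispersal limitation,
  homogenizing dispersal, or undominated.
* **Occurrence patterns** — a genus is *present* at a day when detected
  in ≥ 9 of 10 birds, *absent* at ≤ 1; ordered state sequences classify
  into colonization, disappearance, core, or irregular.
* **Co-occurrence networks** — partial Spearman correlation (ranks
  residualised on day posthatch) over genus pairs passing a 30%
  prevalence filter, Benjamini–Hochberg FDR ≤ 0.05, with topology,
  keystone (top-degree) taxa, generalist/specialist edges, and a 3×3
  Pos/Neg/NS consistency cross-tab between QMP and RMP networks.
* **Metabolome** — OPLS-DA with VIP (mean squared VIP = 1; cutoff 1.5),
  per-metabolite GLM of log-intensity on day (categorical, BH-FDR),
  and six-cluster hierarchical clustering (Euclidean, complete linkage)
  of z-scored mean trajectories.
* **Integration** — `P(metabolite | microbe) = softmax(U_i·V_j + b_j)`,
  a low-rank model trained on paired samples; the top 1% of pairs by
  conditional probability form the interaction network.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (`python analysis/01_simulate_study.py --seed 7`, then 02 … 10 in
order; outputs land under `results/`). Highlights of that run:

```
standard curve: slope -3.3219, efficiency 100.0%, r^2 1.0000
bacteria: mean log10 load by segment -> {'cecum': 9.77, 'duodenum': 7.78,
                                         'ileum': 8.78, 'jejunum': 8.27}
bacteria: QMP-RMP protest m12 = 0.617 (p = 0.005)
variance partition (marginal R^2):   bird 0.018, dph 0.127, segment 0.287
bacteria: Laplace selects K = 3
bacteria: mean adjacent-anterior contribution ->
    {'cecum': 0.246, 'ileum': 0.308, 'jejunum': 0.324}   # planted: 0.3 each
bacteria: planted occurrence-category agreement 100.0%
time-associated metabolites: 503 of 862 (FDR < 0.05)
QMP-vs-RMP correlation consistency (%): duodenum 66.7 ... cecum 64.5
```

Reading these: the perfect-efficiency curve reproduces its defining
slope; loads rise toward the cecal carrying capacity; the ordinations
of absolute and relative profiles agree only partially (m12 = 0.617),
and more than a third of genus-pair correlations change category
between the two modes — the compositional distortion this package
exists to expose. Segment explains the largest share of community
variance, the EM source tracker recovers the planted 0.3
adjacent-segment transmission, and the planted colonization /
disappearance / core labels are recovered essentially perfectly.

## Layout

```
src/qmpflow/      library: synthio, quantify, structure, commtypes,
                  sourcetrack, assembly, occurrence, conetwork,
                  metabolome, integrate, tables, pipeline
analysis/         numbered drivers reproducing the study stage by stage
tests/            pytest suite (unit, property, end-to-end)
scripts/          acceptance.py
docs/methods.md   modelling and design notes
```
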