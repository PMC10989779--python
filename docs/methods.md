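# Methods and design notes

This note records the models implemented in `qmpflow`, the parameter
choices that matter, what the synthetic-data generator does and does
not emulate, and the decisions taken where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Quantification (qPCR → copies per gram)

The standard curve is ordinary least squares of Ct on log10 copies over
a dilution series (defaults span 10³–10⁸ copies, the range of the
lowest to highest calibration standards). Amplification efficiency is
`(10^(−1/slope) − 1) × 100 %`; a perfectly doubling reaction has slope
−1/log10 2 ≈ −3.3219. Back-calculation inverts the line and scales by
`dilution_factor / sample_weight`. The dilution factor bundles
extraction, elution and reaction volumes and is a required user input —
there is no defensible default. Ct values outside the calibrated range
are extrapolations and warn.

Loads are marker-gene **copies** per gram, not cells: no 16S/ITS
copy-number correction is applied by default (a per-taxon hook exists
but is off, because per-genus copy numbers are rarely known and the
uncorrected scale is the directly measured one). The QMP transform is
`proportions × load` with no prior rarefaction; a sample missing its
load is an error (optional geometric-mean imputation within segment ×
day exists behind a flag, default exclusion).

## Community structure

Shannon diversity uses the natural log by default (base configurable).
Bray–Curtis is the dissimilarity throughout; it is a semimetric, so
PCoA (classical scaling, via scikit-bio) can produce negative
eigenvalues, which are reported rather than hidden. PERMANOVA is
implemented in-package because the variance partition needs R² =
SS_among/SS_total alongside the pseudo-F; permutation p is
`(1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`. The per-factor partition runs
**marginal** one-factor models (bird, segment, day each in its own
run): a sequential decomposition would depend on an ordering the study
design does not privilege. Marginal R² values of correlated factors
need not sum to 1.

Procrustes/protest: both configurations are centred and scaled to unit
sum of squares; the optimal rotation allows reflection; m12 =
√(1 − m²); the permutation null shuffles rows of the second
configuration. Per-sample residuals are distances between matched
points after superimposition.

## Community types (DMM)

Absolute abundances are binned as `round(log10(1 + x))` — base 10 and a
pseudocount of 1, both exposed in configuration — producing the small
integer matrix the Dirichlet multinomial mixture is fitted to. EM uses
exact component log-likelihoods (E-step) and Minka's fixed-point update
for each α_k (M-step, 10 inner iterations); the observed-data
log-likelihood is non-decreasing and convergence is declared at
ΔLL < 1e-4. Five random restarts per K, best likelihood kept.

K is selected by a MAP-Laplace approximation to the negative log model
evidence, computed per component in log-α coordinates with a weak
Gaussian prior N(0, 10) on each coordinate:

    −ll + ‖log α‖²/(2σ²) + (d/2)·log σ² + ½·log det(−H + I/σ²)
        + ((K−1)/2)·log n

The per-component Hessian has rank-one-plus-diagonal structure. The
prior normalisation term is essential: without it, a duplicated
component's flat posterior directions masquerade as extra evidence and
the criterion over-selects K. BIC is reported alongside for
transparency. DMM is fitted jointly across segments per domain (the
community types are shared labels whose frequencies then vary by
segment × day); a per-segment fit is a caller-side subset.

## Source tracking

The sink is multinomial with taxon probabilities `Σ_k α_k γ_kj`. The
default keeps the known-source profiles fixed at their observed
proportions with a 1e-8 pseudocount, which makes the fit deterministic;
full joint re-estimation of source profiles from their own counts is
available behind `refit_sources`. The unknown source is initialised
from the non-negative least-squares residual of the sink composition on
the source profiles — i.e. from exactly the sink mass the sources
cannot explain — re-estimated for a short burn-in (25 iterations), then
frozen. A freely re-estimated unknown is degenerate (its global ML
solution copies the sink and takes all the mass); the NNLS
initialisation plus freeze keeps the model identifiable while the EM
remains monotone (each sweep is a partial M-step).

Sinks are matched to same-bird, same-day sources — the strictest
pairing consistent with the design — and only the adjacent-anterior
proportion is reported. The first segment has no anterior source and
yields no row. In the zero-transmission control the *median*
contribution is the calibrated summary: adjacent segments occasionally
draw the same community type, and those pairs are genuinely similar, so
the mean carries a small heavy tail that does not reflect transmission.

## Assembly processes

βMNTD is abundance-weighted by default (unweighted available):
`0.5·[Σ_i f_i·min_j d(i,j) + Σ_j f_j·min_i d(j,i)]` with patristic
distances; a taxon shared by both communities has nearest-taxon
distance zero. The null shuffles taxon labels across tree tips with
abundances fixed; βNTI is the z-score over n_null draws (default 999;
desk-scale runs use 199 or 99). When the null is permutation-invariant
(e.g. a star tree) the variance is zero and the observed value equals
the null mean; βNTI is then defined as 0. Pairs whose null is
degenerate for other reasons are flagged `undefined` and excluded from
process fractions (their count is reported).

RC_Bray nulls preserve each community's richness and total abundance:
taxa are drawn without replacement with probability proportional to
their pool occurrence frequency, then filled multinomially by pool mean
relative abundance; `RC = 2·[P(null < obs) + ½·P(null = obs)] − 1`. The
species pool is per segment (the communities being compared), not the
whole data set.

The process mapping follows the threshold table with βNTI < −2 as
heterogeneous selection — the reverse of the more common sign
convention in this literature. Both conventions are implemented
(`convention="negative-selection"` default, `"stegen"` swaps) and the choice is part
of every result's provenance. Boundary values are closed deliberately:
|βNTI| = 2 joins the adjacent selection class, |RC| = 0.95 is
undominated. Pairs are compared within segment across all days;
cross-segment pairs are excluded.

## Occurrence patterns

Detection is abundance > 0 copies/g after the QMP transform — the
generator's absolute detection limit (below) makes this an
absolute-abundance property end-to-end. Presence needs ≥ 9 of 10
detecting birds; absence allows ≤ 1 (the symmetric complement of the
presence rule; the absence threshold is a free choice and is exposed).
Any sequence containing a transition state is irregular by default;
`transitions_as="absent"|"present"` recodes instead. Colonization
requires an absent prefix then an unbroken present suffix;
disappearance the mirror; core is present everywhere. The rules are
total and depend only on state order, not on the calendar days.

## Co-occurrence networks

Partial Spearman = Pearson correlation of rank vectors residualised on
the (ranked) covariates plus intercept — algebraically identical to the
recursive partial-correlation formula; p from t with n − 2 − k df. The
conditioning set is the most consequential unstated choice in this
analysis: the default conditions on day posthatch (rank-coded) to
suppress shared developmental trends; `none` and custom covariates are
supported and the choice is recorded in each network's provenance.
Prevalence filter: nonzero in ≥ 30% of samples, boundary inclusive.
BH-FDR is applied across all pairs within one network; edges retained
at adjusted p ≤ 0.05, signed by ρ. Bacteria and fungi are pooled into
one network per segment (per-domain networks are a caller-side subset).
Networks are built on QMP by default; RMP networks exist for the
consistency comparison, whose 3×3 cross-tab is total-normalised
(row-normalisation available). Edge identity across segments ignores
sign. Topology: average local clustering, unnormalised betweenness
averaged over vertices, mean shortest-path length over connected pairs
only. Keystone ties break by summed |ρ| then lexical name. The sign
ratio uses a 0.5 pseudocount on both counts.

## Metabolome

All modelling uses log10(1 + intensity). Feature filtering keeps
features present in **more than** 30% of samples (strict, unlike the
network filter's inclusive boundary — both follow their respective
stated rules) and annotated. The time GLM treats day as a categorical
factor with normal errors — the observed cluster shapes are
non-monotone, which a linear-in-time model would miss — and is an
omnibus F per metabolite with BH-FDR across metabolites.

OPLS-DA dummy-codes the groups, removes `n_orth` Y-orthogonal
components (Trygg-style filtering: predictive weight from the SVD of
XᵀY, orthogonalised loading), then fits a PLS2 with groups − 1
predictive components. VIP uses the standard weighted-loading formula;
mean squared VIP = 1 by construction; 1.5 is the selection cutoff.
Trajectory clustering z-scores each associated metabolite's per-day
mean profile and cuts a complete-linkage Euclidean tree at k = 6;
per-day means (not per-sample profiles) are clustered, matching the
trajectory-heatmap convention; both the linkage and k are exposed.

## Microbe–metabolite integration

The conditional co-occurrence model is an explicit low-rank softmax
factorisation `P(j|i) = softmax_j(U_i·V_j + b_j)` (latent dim 3,
default 300–500 epochs), trained by full-batch gradient descent on the
expected multinomial log-likelihood in which microbe tokens occur in
proportion to within-sample microbe counts and predict the sample's
relative metabolite intensities. Metabolite intensities are not counts;
the per-sample relative-intensity normalisation is part of the training
contract and makes the fit invariant to per-sample scaling of either
table. The step size backtracks (halved when the loss would rise), so
the loss is non-increasing and training is deterministic under a seed.
`latent_dim=0` degenerates to a bias-only model whose every row is the
global metabolite frequency vector. Models are fitted per segment ×
domain and merged at the selection stage; selection takes the global
top 1% of pairs (ceil, stable tie-break), and retention percentages are
stratified by (segment × domain) × metabolite cluster.

## The synthetic study generator

`synthio` emulates the design and the phenomena the pipeline is built
to detect, with one seeded generator stream (same seed ⇒ byte-identical
output):

* **Design**: 10 birds × {duodenum, jejunum, ileum, cecum} × days
  {1, 4, 7, 14, 21, 28, 35, 42}, bacteria (100 taxa, 5 community
  types) and fungi (50 taxa, 4 types), 1000 metabolites, sequencing
  depth 20 000.
* **Loads**: per-segment logistic curves in copies/g (bacteria 10⁸ →
  10¹⁰ duodenum → cecum; fungi 10⁶ → 10⁷; growth 2/day, inflection day
  3 — a plateau by day 7) times lognormal noise (0.25 log10). qPCR
  plumbing (Ct from a perfect-efficiency curve, sample weights ~0.2 g,
  dilution factor 100) is generated so the quantification stage runs
  end-to-end.
* **Communities**: sparse community-type centroids (each type occupies
  ~60% of the taxon pool, as real genus tables do), Dirichlet
  overdispersion (concentration 200), segment-preferential type draws.
  Transmission mixes each segment's **realized** community with its
  anterior neighbour's at the configured proportion — the organisms
  that seed a downstream segment are the ones actually present
  upstream, which is also what makes the transmission recoverable by
  source tracking.
* **Detection limit**: organisms whose absolute abundance would fall
  below 10³ copies/g (the lowest standard-curve point; the limit is an
  assumption, no quantitative statement exists to anchor it) are absent
  before counts are drawn, so early low-biomass communities are
  genuinely sparse in an absolute sense. Occurrence-pattern taxa
  (defaults: 15 colonization, 10 disappearance, 18 core per domain)
  are shaped at the proportion level (absent phases zeroed, present
  phases floored at 5 expected counts) with single-copy detection
  enforcement and a 0.5% per-cell detection-noise rate at the margin.
* **Metabolome**: six trajectory templates (monotone-up/-down,
  step-up/-down after day 1, up-then-down, gradual-down) on the log10
  scale, amplitude 0.5 log10, noise 0.15; 42% of metabolites are flat
  (time-null); 10% unannotated and 5% rare features exercise the
  filter. A designated block of 8 cecal bacterial core taxa and 20
  metabolites shares a latent per-(bird, day) activity: the block
  microbes' proportions swing 10^(±activity) and the coupled
  metabolites' log-intensities add 0.9 × activity — a planted
  microbe–metabolite signal that is not a time trend in disguise.
* **Trees**: random coalescent-style joins with exponential heights
  (ultrametric); no claim about real gut phylogenies is intended.

What the generator does **not** emulate: read-level artefacts (chimeras,
primer bias, taxonomy mis-assignment), archaea (excluded from scope),
batch effects, inter-bird covariance structure beyond the shared block
activity, and realistic phylogenetic signal in community membership.
Passing tests therefore demonstrate the statistics recover *planted*
structure under this noise model — they do not certify performance on
real sequencing data, where taxonomic resolution and compositional
sparsity are harsher.

## Problem sizes and numerical choices

Null-model and permutation sizes in the analysis drivers and the
acceptance script are desk-scale choices made once: PERMANOVA/protest
permutations 199, βNTI nulls 199 (499+ for publication-grade z-scores),
RC_Bray nulls 99 with assembly restricted to a seeded subsample of ≤ 60
pairs per segment; the library defaults remain 999. EM tolerances:
DMM ΔLL < 1e-4, source tracking relative ΔLL < 1e-9. Degenerate inputs
are first-class: all-zero diversity vectors and double-zero
dissimilarities raise; constant variables in correlation are
non-significant with a warning; empty networks, empty selections and
zero-metabolite tables return typed empty results.
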