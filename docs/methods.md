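# Methods

`mergetraj` implements an analysis chain from resting-state-like
multivariate time series to molecular-evolution inference: functional
graphs, merging-trajectory coarsening with segregator/integrator
classification, spatial transcriptome screening against the resulting
phenotype map with spatial-autocorrelation-preserving nulls,
surrogate-calibrated gene-set overrepresentation, and dN/dS-versus-
divergence-time regression with a gene-list permutation null. This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic data generator does and does not emulate.

## Functional connectivity graphs

Per subject, node-by-node Pearson correlations are computed over time with
two-sided p-values from the exact t transform (`t = r sqrt((n-2)/(1-r^2))`,
n−2 degrees of freedom). The Benjamini–Hochberg procedure is applied to the
upper-triangle p-values of each subject's matrix at level `q_fdr`
(default 0.001; presets 0.05 / 0.001 / 0.0001 cover the usual robustness
tiers), negative correlations are removed, and surviving coefficients are
Fisher z-transformed (`atanh`). BH rather than BY is used because edge
tests here are the standard positively dependent case; the transform is
monotone, so the descending-strength merge schedule is unaffected by it.

## Merging-trajectory coarsening

For an adjacent pair of super-nodes (u, v), the rule compares the weighted
degree of *shared* links — links to common neighbors, counted from both
endpoints, `sum_{w in N(u)∩N(v)} [w(u,w) + w(v,w)]` — against the weighted
degree of *distinct* links (the single link to every neighbor of exactly
one endpoint). The (u, v) edge itself enters neither sum, so two nodes
with identical neighborhoods and no private links always merge. On a
merge, the super-node's connectivity to any neighbor is the mean strength
over all original member pairs with absent links counted as zero; this
average-linkage convention is associative, so incremental updates equal
recomputation from the original matrix (the property the brute-force test
oracle exploits).

Edges are visited in descending current weight, ties broken by
(min node index, max node index). After every merge the sweep restarts
from the strongest live edge, so a growing super-node whose mean-strength
links remain strongest keeps absorbing neighbors sequentially. The
alternative — batching all merges of a pass before re-sorting — produces
synchronized pairwise doubling in which every node's growth curve is
convex regardless of its role, destroying the early/late distinction; the
per-merge restart is therefore the package's reading of the
descending-order iteration. The process stops when a full sweep yields no
merge; each merge removes one node, so termination is guaranteed.

### Trajectory classification

Each original node v has a cluster-size growth curve c_v: the size of its
super-node after each merge event, normalized by the node count. The time
axis is the *merging time* of each event: the normalized position of the
merged link in the descending-strength schedule,
`t_k = (w_max − w_k)/(w_max − w_min)` over the merged link weights. This
is the variable the iteration actually descends; nodes absorbed through
strong links act early in strength-time even if many weaker events
precede them in wall-clock event order. (With event-index time the
log/exp comparison below cannot separate early from late mergers at all —
a node's event rank is dominated by how much of the whole graph happens
to be processed before its module, not by its own connectivity.)

Two models are fit per node: logarithmic, `y = a + b ln(t + ε)` with
`ε = 1/K` (K = number of events) by ordinary least squares, and
exponential, `y = a e^{bt}` by log-linear OLS, with both R² evaluated on
the original y scale. The score `s_v = R²_log − R²_exp` labels a node
*segregator* (early merger) when positive and *integrator* (late merger)
when negative; nodes that never merge have undefined fits and stay
unclassified. Group-level labels average s_v across subjects before
taking the sign, which absorbs subject-level noise in the merge schedule;
group S and I maps are means of per-subject min–max normalized R² maps,
and the phenotype map is their difference S − I.

## Transcriptome screening

Every gene's regional expression profile is Pearson-correlated with the
phenotype map across regions. Candidate genes are those beyond
mean ± 1.96 SD of the correlation distribution (the multiplier is
configurable; raising it never adds genes).

Because a spatially smooth map correlates strongly with smooth expression
patterns by chance, significance is calibrated with surrogate maps that
preserve the map's value multiset exactly and its variogram approximately:
a random permutation of the values is smoothed with a Gaussian kernel over
the inter-region distance matrix and the original values are re-assigned
by rank of the smoothed field. The smoothing scale is selected from a grid
(zero = plain permutation, plus ten distance quantiles) by minimizing the
mean squared misfit between surrogate and target variograms, estimated on
a 40-surrogate trial ensemble per scale; the trial size matters because a
noisy scale estimate propagates into miscalibrated surrogate gene lists
downstream. Variograms use equal-count distance bins
(γ(h) = mean of ½(x_i − x_j)² per bin, 10 bins by default). Pooling all
surrogate × gene correlations gives the two-sided 0.05 significance
bounds (2.5th/97.5th percentiles) and per-gene add-one empirical
p-values. Both the ±SD selection cutoffs and the surrogate bounds are
reported; a selection cutoff falling inside the surrogate bound is logged
as a warning rather than silently accepted.

## Enrichment

Overrepresentation of a selected gene list in an annotation term is the
one-sided Fisher exact (hypergeometric upper-tail) test, with fold
enrichment = (overlap/selection size)/(term size/universe size). Terms
with fewer than 5 or more than 2000 genes are removed before testing;
terms with overlap < 3 or Fisher p ≥ 0.01 are flagged and excluded from
calibration.

Calibration compares each term's Fisher p against the Fisher p's obtained
from gene lists selected on each surrogate map *using the original
cutoffs* (re-deriving cutoffs per surrogate would re-admit the spatial
autocorrelation the null is meant to retain). The empirical p is the
add-one rank of the original among the surrogate p's. Fisher p-values are
discrete (a zero-overlap term has p = 1 exactly), so exact ties are split
by a seeded random rank draw — the standard construction under which the
null empirical p is exactly discrete-uniform; the deterministic
ties-against-the-original variant is available by passing no rng.
Surviving terms are BH-corrected at q = 0.05.

Surviving terms are grouped by Cohen's kappa of their binary gene-
membership vectors (undefined kappas set to 0 and logged), using
average-linkage hierarchical clustering on distance 1 − κ cut at
κ > 0.3; each cluster is summarized by its most significant member
(ties → lexicographically smaller term id). Singleton terms are reported
as singleton clusters.

## Evolutionary regression

For an annotation, each gene–species pair contributes ω = dN/dS; pairs
with dS = 0 or missing values are excluded (logged), not clamped. The
per-species arithmetic mean ω over the annotation's genes is regressed on
divergence time (million years; default panel: chimpanzee 6.6, gorilla
8.8, orangutan 15.8, macaque/olive baboon/vervet 29.4, marmoset 43.2)
under four families: linear, logarithmic (b0 + b1 ln t), quadratic, and
exponential (b0 e^{b1 t}). All are least squares on the original ω scale;
the exponential uses Gauss–Newton refinement (scipy `curve_fit`) started
from the log-linear fit, because comparing a ln-space fit's original-scale
R² against directly optimized rivals systematically handicaps the
exponential family in model selection. F and p follow the overall-F
identity `F = (R²/k)/((1−R²)/(n−k−1))`.

Best-family selection is highest R² moderated by two indistinguishability
windows: families within `min(0.07, 2(1−R²_top))` of the top R² compete
on parameter count, and equally parsimonious families within
`min(0.016, 0.5(1−R²_best))` of each other fall back to the listed family
order. The residual-scaled windows mean noiseless data always returns the
generating family (a nested rival tying at R² = 1 loses on parsimony),
while at realistic noise a more flexible family must beat a simpler one
by a margin exceeding the R² fluctuation scale of the n = 7 design. The
window caps were chosen from the observed spread of R² across families at
10%-of-range noise on this design.

Robustness uses a gene-list permutation null: `n_permutations` (default
100) random lists of the annotation's size, drawn from the universe
excluding the annotation's own genes, are refit under the chosen family;
the original R² is z-scored against the null R² distribution and the
corrected p is the upper normal tail 1 − Φ(z). Under a true null this
corrected p averages ≈ 0.5 (verified in the acceptance suite).

## Synthetic data generator

The generator supplies every input with planted ground truth:

* **Time series** — a latent-factor model: module m has an i.i.d. standard
  normal latent z_m(t); members are `coupling·z_m + noise_sd·e`
  (defaults: coupling 0.8, noise_sd 0.5, T = 300); integrator hubs couple
  weakly-but-broadly, `0.4·Σ_m z_m/√M + noise_sd·e`; background nodes are
  pure noise. Only second-order structure matters downstream, so
  hemodynamics, motion, and nonstationarity are deliberately absent:
  passing recovery tests shows the chain recovers planted covariance
  structure, not that it is robust to fMRI artifacts.
* **Geometry** — uniform random centroids in a 140 mm cube; duplicate
  draws are rejected.
* **Expression** — planted genes are constructed with sample correlation
  exactly ±0.8 against the target map (noise enters through the
  orthogonal component); background genes are white noise smoothed to a
  30 mm autocorrelation length so the surrogate null has real work to do.
  Probe-level noise, donor effects and hemispheric structure are not
  modeled.
* **Gene sets** — uniform random terms (default 100 terms, sizes 10–200)
  plus one planted term built from the planted-positive genes (25) padded
  with 15 background genes.
* **dN/dS** — per gene and species, ω = family(t) + Gaussian noise
  (floored at 10⁻⁴), dS uniform on [0.05, 0.5] so ratios are always
  defined, dN = ω·dS. Default family coefficients
  (linear (0.15, 0.004); logarithmic (0, 0.12); quadratic
  (0.4, −0.02, 0.0004); exponential (0.04, 0.06)) were chosen so each
  family's curve departs from its best rival-family approximation by a
  clear margin relative to the default noise over the primate time
  window, within a purifying-selection ω range (~0.05–0.55). An
  exponential *decay* default is deliberately avoided: on five distinct
  design points it is statistically indistinguishable from a
  negative-coefficient logarithm.

Every generator is a pure function of its spec including the seed. The
pipeline derives per-stage sub-seeds from the master seed by hashing the
stage name, so stages are reproducible and independently perturbable.

## Pipeline scales and determinism

The default synthetic study is 200 nodes (8 modules × 20 members, 8
integrators, 32 background), 10 subjects, 68 regions, 2000 genes
(25 + 25 planted at |r| = 0.8), 100 terms, 1000 surrogate maps and 100
permutations; the test and acceptance runs use 200 surrogates and 50–100
permutations, which keeps the full chain under ~10 s while leaving all
calibration properties measurable. Node-level maps are aggregated to
regions by contiguous-block assignment (region value = mean over member
nodes). Two runs with the same master seed produce byte-identical outputs
and manifests; the manifest records config, per-stage seeds and SHA-256
checksums of every written file.

## Known limitations

* The trajectory construct (growth curves over strength-time, log/exp R²
  comparison) is a formalization of a qualitative idea; other readings of
  the iteration order and trajectory variable exist, and per-subject
  labels are noisier (~89% recovery) than group labels (100% on planted
  panels).
* The surrogate generator matches variograms approximately through a
  single global smoothing scale; maps with anisotropic or multi-scale
  autocorrelation will be matched imperfectly.
* Empirical p-values are bounded below by 1/(S+1); with the default
  prefilter (Fisher p < 0.01) and small surrogate ensembles, BH across
  the conditioned set controls FDR within that set, not unconditionally.
* Curve-family selection on 7 species (5 distinct times) is
  fundamentally low-powered; the reported recovery rates (~80–100% per
  family at 10% noise) are specific to the default coefficient scales.
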