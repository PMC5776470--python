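# Methods

`turbicom` reimplements, as a reusable and tested pipeline, the statistical
workflow used to characterize bacterioplankton communities across a set of
glacial lakes spanning a turbidity gradient: alpha diversity under
rarefaction, Raup-Crick beta diversity with a constructed permutation null,
a rarity-inclusion decomposition of beta diversity, ensemble co-occurrence
network inference, phylogenetic community structure, and two optical
indices of dissolved organic matter (DOM). Because the original sequence
data are not bundled, every stage is exercised against a synthetic
generator that emulates the study design; this note records the models,
the defaults, and what the synthetic experiments do and do not show.

## The synthetic study design

`synthetic.GradientDesign` encodes one survey: `n_lakes` lakes (default 6)
sampled in `n_replicates` composite replicates (default 3) and profiled in
two nucleic-acid fractions, rDNA (bulk community) and rRNA (putatively
active community), sequenced to fixed depths of 1863 and 1052 reads — the
rarefaction depths of the emulated survey. Default lake turbidities
(0.8–64.1 NTU) follow the survey's span.

The community model, per OTU `i` and lake `L`:

```
w_iL = baseline_i · exp(−(env_L − opt_i)² / (2·nb_i²))
```

* `baseline_i ~ Lognormal(0, abundance_sigma)`, optionally multiplied by a
  per-OTU `baseline_scale` — the long rare tail. At `abundance_sigma ≥ 2`
  a lake's rank-abundance curve spans over two orders of magnitude.
* `opt_i` is the OTU's environmental optimum: a convex mixture
  `√s·BM + √(1−s)·ε` of a Brownian-motion trait on a unit-depth Yule tree
  and white noise, min–max rescaled to the gradient span. `s = phylo_signal`
  controls how strongly niche occupancy is phylogenetically conserved.
* `nb_i` (`niche_breadth`, NTU) is the Gaussian niche width, scalar or
  per-OTU. 15 NTU is the moderate default; the "narrow" setting used by
  the gradient-recovery experiments is 4 NTU, chosen so that a clear-lake
  niche window covers only the low tail of the optimum distribution.
* Each replicate multiplies `w` by per-OTU `Lognormal(0, replicate_sigma)`
  noise (default 0.2): composite water samples are not identical, and
  without this term within-lake Raup-Crick dissimilarity degenerates to
  exactly 0, which no real replicate set shows.
* Planted associations `(a, b, sign, strength)` draw one latent factor
  `g ~ Lognormal(0, strength)` per sample; a co-presence pair multiplies
  both members by `g`, a mutual-exclusion pair multiplies one by `g` and
  the other by `1/g`.
* Counts are multinomial at the configured depth. The rRNA fraction
  re-weights the same per-sample expectations by per-clade activity
  multipliers (clades are labelled by subtree membership) and renormalizes
  before sampling — the "activity-scaled bulk community" model. Note the
  renormalization: boosting a clade of relative abundance share `f` by a
  factor `a` yields an observable ratio `a/(1 + f(a−1))`, so activity
  recovery experiments use small clades (a few percent share).

What the generator does **not** emulate: sequencing error and chimeras,
PCR bias, copy-number variation between taxa, temporal ("conditionally
rare") dynamics, and spatial metacommunity processes. Passing tests
therefore demonstrate the statistical machinery recovers planted structure
under multinomial sampling noise — not robustness to those artefacts.

## Rarefaction and alpha diversity

Rarefaction is an exact multivariate-hypergeometric subsample (no
replacement). Multivariate stages use one fixed draw per sample; alpha
estimates average over `n_draws` (default 100) independent draws.
Estimators: bias-corrected Chao-1 (`S_obs + F1(F1−1)/(2(F2+1))`, finite
when doubletons are absent), inverse Simpson `1/Σp²`, bootstrap richness
`S_obs + Σ(1−p_i)^N`, and rooted Faith's PD (branch length of the minimal
subtree spanning the present tips and the root — documented because the
unrooted variant differs).

## Raup-Crick beta diversity

For a sample pair with richness `n₁, n₂` sharing `s_obs` OTUs, null
assemblages of the same richness are drawn from the whole OTU pool without
replacement with inclusion probability proportional to each OTU's total
abundance across the table (Gumbel-top-k sampling; an `occurrence`
weighting is available as a switch). The dissimilarity is

```
RC = [#(s_null > s_obs) + ½·#(s_null = s_obs)] / n_reps
```

the probability-scaled evidence that the pair shares *fewer* taxa than
the null expects. The half-weighted ties centre the metric at exactly 0.5
under its own null (two identical maximal-richness samples tie every
replicate and score 0.5; disjoint species-rich samples approach 1). Null
assemblages are drawn once per replicate per sample and compared across
all pairs — each pair's marginal null is identical to drawing per-pair,
at a fraction of the cost. `n_reps` defaults to 999.

## Ordination, ANOSIM, environmental fitting

NMDS minimizes Kruskal stress-1 by SMACOF with isotonic regression on the
dissimilarity ranks (20 random restarts, 500 iterations, tolerance 1e-7;
deterministic per seed). Because a rank-based configuration is scale-free,
the centred coordinates are rescaled so configuration distances are
least-squares matched to the input dissimilarities (the analogue of
half-change scaling); convex-hull areas then track dissimilarity
magnitude, which the rarity profile relies on. ANOSIM uses the standard
rank statistic `R = (r̄_between − r̄_within)/(M/2)` with label-permutation
p-values; envfit reports the squared multiple correlation of a variable
with the ordination axes and a permutation p-value. Replicates enter
ordination and ANOSIM as individual samples; pooling by lake happens only
in the rare/abundant partition, group ratios and per-lake phylogenetic
statistics.

## Rarity-inclusion profile

OTUs are ranked by total abundance (ties broken lexicographically); for
each prefix of size 100, 150, … the subset table gets its own Raup-Crick
matrix, 2-D NMDS and convex-hull area. The bimodal ("U"-shaped) profile
arises when the most abundant and the rare OTUs are lake-specific while
intermediate OTUs are shared: `synthetic.bimodal_rarity_design` builds
exactly that condition with three deterministic baseline strata (100
abundant lake specialists ×60, 100 gradient-indifferent intermediates,
400 sparse specialists ×0.3) on a linearly spaced 5–55 NTU gradient, so
every lake has a distinct dominant flora and rare specialists remain
countable at the default depths.

## Ensemble co-occurrence inference

Computed on the rDNA fraction only. OTUs present in fewer than 5 samples
are removed; five association measures are computed on sample-wise
relative abundances: Pearson, Spearman, mutual information (4
equal-frequency bins, nats), Bray-Curtis `Σ|x−y|/Σ(x+y)`, and symmetrized
Kullback-Leibler divergence of the OTUs' across-sample profiles
(pseudocount 1e-6). Per measure, the `n_top` (default 1000) strongest
co-presence and mutual-exclusion candidates are retained with boundary
ties kept; dissimilarities map smallest→co-presence, largest→exclusion;
MI is unsigned and inherits the pair's Spearman sign (Spearman exactly 0
is sign-inconclusive).

Candidate p-values come from a permutation null: every OTU's counts are
shuffled across samples independently and, with the default
`renormalize=True`, sample relative abundances are recomputed afterwards
so the null retains compositional closure. One permutation per replicate
is shared across candidates (identical marginal null; a per-edge
reference implementation, `permutation_pvalue`, is kept and
cross-checked).

Pairs with sign-discordant support or support from fewer than 2 of the 5
measures are dropped. Per-pair p-values are then combined by **Brown's
method**: the statistic `−2Σln p` is referred to a scaled chi-square whose
scale and degrees of freedom are matched to the statistic's empirical
mean and variance over the shared permutation null. This is the package's
deliberate design choice over plain Fisher combination: the five measures
are strongly mutually dependent (Pearson/Spearman/MI especially), and on
structureless tables Fisher-merged p-values inflated the q ≤ 0.05 edge
count to roughly a quarter of tested pairs, while the Brown adjustment
holds the false-discovery fraction at the nominal level. Fisher remains
available as a switch. Benjamini-Hochberg FDR is applied over all
surviving pairs; edges with q ≤ 0.05 form the network. Edge inference is
invariant to the input column order (columns are canonicalized before
scoring).

Edges are attributed to a lake iff both OTUs are detected in that lake's
pooled replicates — one defensible choice for the per-lake positive-edge
fraction; the original analysis does not state its rule.

## Phylogenetic structure

Cophenetic distances are tip-to-tip path lengths. MNTD is the mean
distance of each community member to its nearest co-occurring relative;
the SES (z-score) compares the observed MNTD with a tip-shuffle null
(equivalently uniform random tip sets of equal richness, vectorized that
way; 999 draws by default). Negative z = clustering, positive =
overdispersion; a community equal to the whole pool has a degenerate null
and is flagged rather than scored. The rank p is `(1 + #(null ≤ obs)) /
(n_null + 1)`, exactly uniform for continuous distances. Per-lake
community-vs-network-subset comparisons share one null seed per lake so
the two columns are paired. Cophenetic distances of co-presence versus
mutual-exclusion edges are compared with Welch's unequal-variance t-test
implemented from the closed form (Welch–Satterthwaite degrees of freedom)
and cross-checked against scipy.

## DOM optics

The spectral slope is minus the least-squares slope of ln(absorption)
versus wavelength; `S_R = S(275–295)/S(350–400)`, inversely related to
dominant DOM molecular weight. Coble fluorescence windows use the
classical definitions (b Ex270–280/Em300–310; t 270–280/330–350; a
250–260/380–460; m 305–320/380–420; c 330–350/420–480; all overridable),
with the window maximum as peak statistic and percentages normalized to
the five-peak sum. Inputs are assumed instrument-corrected. The synthetic
EEM uses truncated Gaussian bumps (2.5σ) so single-window fixtures place
exactly 100% in their window.

## Numerical and experimental choices

* One global seed derives independent per-stage substreams via
  `SeedSequence`; every output is bit-reproducible for a fixed config.
* Experiment sizes used by the acceptance tests: Raup-Crick calibration on
  150 null samples (11k pairs, 199 replicates); SES-MNTD type-I on 1000
  random communities of a 128-tip tree (199 nulls each); network null
  calibration on 50 structureless surveys of 150 OTUs at 199
  permutations; planted-edge recovery on 20 surveys at 999 permutations
  with `abundance_sigma=1.5` and latent strength 2.0 over the 40
  highest-baseline OTUs — the flattened tail keeps every planted OTU
  countable at the survey's depths, so the measured sensitivity reflects
  the inference rather than count starvation; gradient recovery on 100
  surveys with `niche_breadth=4`, `phylo_signal=1`.
* Degenerate inputs: all-zero OTU columns are dropped at table
  construction; zero-richness samples are an error for Raup-Crick;
  zero-variance OTUs are excluded from correlation-based candidate sets;
  collinear point sets have hull area 0.

## Known limitations

* Brown's moment-matching extrapolates the chi-square tail beyond the
  permutation resolution; with few permutations, very small merged
  p-values are approximate.
* The rarity profile's hull area depends on the ordination rescaling
  convention; profiles from software with a different scaling are
  comparable in shape, not in absolute area.
* rRNA:rDNA group ratios are undefined (reported as missing, not
  infinite) for groups absent from the rDNA fraction of a lake.
* ANOSIM and envfit p-values are permutation-floor-limited at
  `1/(n_perm+1)`.
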