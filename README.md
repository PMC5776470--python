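# turbicom

Statistical analysis of bacterioplankton community structure along
glacial-lake turbidity gradients.

Glacier-fed lakes span huge gradients in turbidity, temperature and
dissolved organic matter (DOM), and their bacterial communities — profiled
by 16S rDNA (bulk) and 16S rRNA (putatively active) amplicons — reorganize
along them. `turbicom` packages the complete statistical workflow such a
survey needs, for microbial ecologists who have OTU tables, sample
metadata, a phylogenetic tree and (optionally) DOM optical spectra:

* **Alpha diversity under rarefaction** — bootstrap richness, bias-corrected
  Chao-1, inverse Simpson, rooted Faith's PD, rarefaction curves.
* **Null-model beta diversity** — the Raup-Crick metric
  `RC = P(s_null > s_obs) + ½·P(s_null = s_obs)`, evaluated against
  permutation nulls in which taxa are selected proportionally to their
  abundance; NMDS (Kruskal stress-1), ANOSIM, environmental vector fitting.
* **Rarity-inclusion profiles** — beta diversity (convex-hull area of the
  ordination) as rare taxa are stepwise included from the 100 most
  abundant OTUs to the full community, quantifying how the rare biosphere
  contributes to between-lake dissimilarity.
* **Ensemble co-occurrence networks** — Pearson, Spearman, mutual
  information, Bray-Curtis and Kullback-Leibler support; edge-count
  thresholding, per-edge permutation p-values with compositional
  renormalization, dependence-adjusted (Brown) p-value merging,
  Benjamini-Hochberg FDR, signed co-presence/mutual-exclusion edges.
* **Phylogenetic structure** — cophenetic distances, SES-MNTD (z-score of
  the mean nearest taxon distance against a tip-shuffle null; z < 0 means
  clustering), and Welch's t comparison of the phylogenetic distances
  spanned by positive versus negative network edges.
* **DOM optics** — absorbance slope ratio `S_R = S(275–295)/S(350–400)` and
  the relative distribution of the Coble fluorescence peaks (b, t
  protein-like; a, m, c humic-like).
* **A synthetic study-design generator** — Yule trees, Brownian-motion
  niche optima with tunable phylogenetic signal, lognormal abundance
  structure with a long rare tail, paired rDNA/rRNA fractions linked by
  per-clade activity multipliers, and planted pairwise associations — so
  the whole pipeline is testable end to end without external data.

## Worked example

Run the whole pipeline on a simulated six-lake survey (3 replicates per
lake, rDNA rarefied to 1863 and rRNA to 1052 reads):

```yaml
# survey.yaml
seed: 11
simulate: {n_otus: 120, niche_breadth: 4.0, phylo_signal: 1.0}
alpha: {n_draws: 20}
beta: {rc_reps: 199, nmds_restarts: 8, n_perm: 199}
rarity: {initial_top: 40, step: 30, rc_reps: 99}
subsample: {n_draws: 4, rc_reps: 99}
network: {n_perm: 199}
phylo: {n_null: 199}
dom: {s_short: 0.03, s_long: 0.015, peak_weights: {b: 2, t: 1, a: 0.5, m: 0.3, c: 0.2}}
```

```bash
turbicom run --config survey.yaml --out results/
```

writes rarefied tables, alpha-diversity TSVs, Raup-Crick matrices, NMDS
coordinates, the rarity profile, the edge list (TSV + GraphML), SES-MNTD
per lake, DOM indices, and a manifest. `results/beta_stats.json` for the
rDNA fraction of this run contains

```json
{"anosim_R": 0.793004, "anosim_p": 0.005, "nmds_stress": 0.000524,
 "envfit": {"turbidity": {"r2": 0.986424, "p": 0.005},
            "temperature": {"r2": 0.789615, "p": 0.005}}}
```

— the lakes are strongly separated (ANOSIM R = 0.79 at the permutation
floor p = 0.005), the ordination is essentially stress-free, and turbidity
explains the community structure (envfit R² = 0.99) better than any other
covariate, as expected for a narrow-niche gradient simulation. The
`dom.json` output reports `"s_r": 2.0` for the configured 2:1 spectral
slopes. Rerunning the same config and seed reproduces every numeric output
bit for bit.

The same stages are available as library functions
(`turbicom.beta.raup_crick`, `turbicom.cooccurrence.infer_network`,
`turbicom.phylostructure.ses_mntd`, ...) and as individual subcommands
(`turbicom simulate | alpha | beta | rarity-profile |
subsample-ordination | network | phylo | dom`).

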