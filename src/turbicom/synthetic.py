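"""Synthetic study-design generator.

Emulates a survey of six glacial lakes spanning a turbidity gradient, each
sampled in three replicates and profiled in two nucleic-acid fractions
(rDNA = bulk community, rRNA = active community). The generative model:

* a pure-birth (Yule) phylogeny over the OTU pool, scaled ultrametric with
  root-to-tip depth 1;
* per-OTU environmental optima as a mixture of a Brownian-motion trait on
  that tree and independent noise, the mixing fraction being the
  phylogenetic signal;
* lognormal baseline abundances (long rare tail) shaded by a Gaussian
  niche response around each OTU's optimum along the gradient;
* optional planted pairwise associations through shared (co-presence) or
  opposed (mutual-exclusion) per-sample lognormal latent factors;
* multinomial sequencing at fixed depths; the rRNA fraction re-weights the
  rDNA expectations by per-clade activity multipliers before sampling.

Defaults mirror the emulated survey: 6 lakes x 3 replicates, turbidities
0.8-64.1 NTU, sequencing depths 1863 (rDNA) and 1052 (rRNA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .datamodel import OtuTable, Taxonomy, ValidationError

#: Default lake turbidities (NTU), sorted ascending; the span matches the
#: emulated gradient (clear proglacial lakes to lakes fed directly by
#: glacial meltwater).
DEFAULT_TURBIDITY = (0.8, 5.5, 6.9, 11.1, 60.1, 64.1)


@dataclass
class GradientDesign:
    """Parameters of one synthetic survey.

    ``niche_breadth`` is in gradient (NTU) units and may be a scalar or a
    per-OTU sequence; ``phylo_signal`` is the fraction of optimum variance
    attributable to Brownian motion on the tree; ``activity_model`` maps
    clade labels to rRNA:rDNA activity multipliers (missing clades get 1);
    ``planted_edges`` holds (otu_a, otu_b, sign, strength) tuples where
    sign is +1/-1 and strength is the log-scale s.d. of the latent factor.
    """

    n_lakes: int = 6
    n_replicates: int = 3
    env_values: Sequence[float] = DEFAULT_TURBIDITY
    depth_dna: int = 1863
    depth_rna: int = 1052
    n_otus: int = 300
    abundance_sigma: float = 2.0
    baseline_scale: float | Sequence[float] = 1.0
    niche_breadth: float | Sequence[float] = 15.0
    replicate_sigma: float = 0.2
    phylo_signal: float = 0.8
    n_clades: int = 12
    activity_model: Mapping[str, float] = field(default_factory=dict)
    planted_edges: Sequence[tuple[str, str, int, float]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lakes < 2:
            raise ValidationError("need at least 2 lakes")
        env = np.asarray(self.env_values, dtype=float)
        if len(env) != self.n_lakes:
            raise ValidationError("env_values must have one value per lake")
        if not np.all(np.diff(env) > 0):
            raise ValidationError("env_values must be strictly monotone over lakes")
        if self.depth_dna <= 0 or self.depth_rna <= 0:
            raise ValidationError("sequencing depths must be > 0")
        if not (0.0 <= self.phylo_signal <= 1.0):
            raise ValidationError("phylo_signal must be in [0, 1]")
        nb = np.asarray(self.niche_breadth, dtype=float)
        if np.any(nb <= 0):
            raise ValidationError("niche_breadth must be > 0")
        if np.any(np.asarray(self.baseline_scale, dtype=float) <= 0):
            raise ValidationError("baseline_scale must be > 0")


# -- phylogeny -------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int) -> TreeNode:
    """Pure-birth tree with exponential waiting times, scaled ultrametric.

    Root-to-tip depth is exactly 1 for every tip. Tips are labelled
    ``OTU0001`` ... in tree traversal order; deterministic given the seed.
    """
    if n_tips < 2:
        raise ValidationError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)

    root = TreeNode()
    birth: dict[int, float] = {}
    t = 0.0
    # first split: the root bifurcates at time 0 (the stem is dropped)
    active: list[TreeNode] = []
    for _ in range(2):
        child = TreeNode()
        root.append(child)
        birth[id(child)] = 0.0
        active.append(child)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(rng.integers(len(active)))
        node.length = t - birth[id(node)]
        for _ in range(2):
            child = TreeNode()
            node.append(child)
            birth[id(child)] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / len(active))
    for node in active:
        node.length = t_end - birth[id(node)]
    # scale to unit depth
    for node in root.traverse(include_self=False):
        node.length = node.length / t_end
    for i, tip in enumerate(root.tips()):
        tip.name = f"OTU{i + 1:04d}"
    return root


def _brownian_trait(tree: TreeNode, rng: np.random.Generator) -> pd.Series:
    """One Brownian-motion realization over the tips (root value 0)."""
    values: dict[int, float] = {id(tree): 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, np.sqrt(node.length)) if node.length else 0.0
        values[id(node)] = values[id(node.parent)] + step
        if node.is_tip():
            out[node.name] = values[id(node)]
    return pd.Series(out)


def simulate_optima(
    tree: TreeNode,
    phylo_signal: float,
    seed: int,
    env_range: tuple[float, float] = (DEFAULT_TURBIDITY[0], DEFAULT_TURBIDITY[-1]),
) -> pd.Series:
    """Per-OTU environmental optima with tunable phylogenetic signal.

    optimum_i = sqrt(s) * BM_i + sqrt(1-s) * eps_i with both components
    standardized to unit variance across tips, then min-max rescaled to
    ``env_range``.
    """
    if not (0.0 <= phylo_signal <= 1.0):
        raise ValidationError("phylo_signal must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bm = _brownian_trait(tree, rng)
    eps = pd.Series(rng.normal(size=len(bm)), index=bm.index)

    def _std(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=0)
        return (x - x.mean()) / sd if sd > 0 else x * 0.0

    trait = np.sqrt(phylo_signal) * _std(bm) + np.sqrt(1.0 - phylo_signal) * _std(eps)
    lo, hi = env_range
    span = trait.max() - trait.min()
    if span == 0:
        return pd.Series((lo + hi) / 2.0, index=trait.index)
    return lo + (trait - trait.min()) / span * (hi - lo)


# -- taxonomy from subtree membership --------------------------------------

def assign_clades(tree: TreeNode, n_clades: int) -> pd.Series:
    """Partition tips into clades by repeatedly splitting the largest one."""
    clades: list[TreeNode] = [c for c in tree.children]
    while len(clades) < n_clades:
        sizes = [c.count(tips=True) for c in clades]
        idx = int(np.argmax(sizes))
        node = clades.pop(idx)
        kids = list(node.children)
        if not kids:  # a tip cannot be split further
            clades.append(node)
            break
        clades.extend(kids)
    labels: dict[str, str] = {}
    for i, clade in enumerate(clades):
        name = f"Clade{i + 1:02d}"
        if clade.is_tip():
            labels[clade.name] = name
        else:
            for tip in clade.tips():
                labels[tip.name] = name
    return pd.Series(labels)


# -- community simulation ---------------------------------------------------

def _sample_expectations(design: GradientDesign, tree: TreeNode, rng_base: np.random.Generator):
    """Shared deterministic ingredients: tips, baselines, optima, clades."""
    tips = [t.name for t in tree.tips()]
    if len(tips) < design.n_otus:
        raise ValidationError(
            f"tree has {len(tips)} tips, fewer than n_otus={design.n_otus}"
        )
    otus = tips[: design.n_otus]
    return otus


def bimodal_rarity_design(seed: int, n_otus: int = 600) -> GradientDesign:
    """Study design with lake-specific abundant and rare OTUs but shared
    intermediates — the condition under which beta diversity is bimodal
    along accumulating rarity (hull-area profile dips at intermediate
    inclusion and rises again).

    Three deterministic baseline strata: 100 abundant lake-specialists
    (60x baseline, narrow 3-NTU niches), 100 gradient-indifferent
    intermediates, and 400 sparse lake-specialists (0.3x baseline). The
    gradient is linearly spaced so every lake has a distinct dominant
    flora.
    """
    scale = np.ones(n_otus)
    nb = np.full(n_otus, 3.0)
    scale[:100] = 60.0
    nb[100:200] = 1e6
    scale[200:] = 0.3
    return GradientDesign(
        n_otus=n_otus,
        abundance_sigma=0.0,
        env_values=(5.0, 15.0, 25.0, 35.0, 45.0, 55.0),
        baseline_scale=scale,
        niche_breadth=nb,
        replicate_sigma=0.4,
        phylo_signal=0.5,
        seed=seed,
    )


def baseline_abundances(design: GradientDesign, tree: TreeNode) -> pd.Series:
    """The lognormal baseline abundances :func:`simulate_community` will use.

    Deterministic given ``design.seed``; lets an experiment plant
    associations among taxa known to be common enough to detect.
    """
    ss = np.random.SeedSequence(design.seed)
    rng_base = np.random.default_rng(ss.spawn(5)[0])
    otus = _sample_expectations(design, tree, rng_base)
    base = rng_base.lognormal(0.0, design.abundance_sigma, size=len(otus))
    base = base * np.broadcast_to(
        np.asarray(design.baseline_scale, dtype=float), (len(otus),)
    )
    return pd.Series(base, index=otus)


def simulate_community(
    design: GradientDesign, tree: TreeNode
) -> tuple[OtuTable, OtuTable, pd.DataFrame, Taxonomy]:
    """Simulate paired rDNA/rRNA tables, metadata and taxonomy.

    Deterministic given ``design.seed``; replicate-level counts are
    independent multinomial draws at the configured depths.
    """
    ss = np.random.SeedSequence(design.seed)
    rng_base, rng_opt, rng_edge, rng_count, rng_meta = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    otus = _sample_expectations(design, tree, rng_base)
    n = len(otus)
    env = np.asarray(design.env_values, dtype=float)

    baseline = rng_base.lognormal(0.0, design.abundance_sigma, size=n)
    baseline = baseline * np.broadcast_to(
        np.asarray(design.baseline_scale, dtype=float), (n,)
    )
    optima = simulate_optima(
        tree, design.phylo_signal, seed=int(rng_opt.integers(2**31)),
        env_range=(env.min(), env.max()),
    ).loc[otus].to_numpy()
    nb = np.broadcast_to(np.asarray(design.niche_breadth, dtype=float), (n,))
    if np.any(nb <= 0):
        raise ValidationError("niche_breadth must be > 0")

    clades = assign_clades(tree, design.n_clades).loc[otus]
    activity = clades.map(lambda c: design.activity_model.get(c, 1.0)).to_numpy(float)

    otu_pos = {o: i for i, o in enumerate(otus)}
    planted = []
    for a, b, sign, strength in design.planted_edges:
        if a not in otu_pos or b not in otu_pos:
            raise ValidationError(f"planted edge ({a},{b}) names unknown OTUs")
        if sign not in (+1, -1):
            raise ValidationError("planted edge sign must be +1 or -1")
        planted.append((otu_pos[a], otu_pos[b], sign, float(strength)))

    sample_ids, lake_ids, reps = [], [], []
    rows_dna, rows_rna = [], []
    for li in range(design.n_lakes):
        lake = f"L{li + 1}"
        niche = np.exp(-((env[li] - optima) ** 2) / (2.0 * nb**2))
        base_w = baseline * niche
        for r in range(design.n_replicates):
            w = base_w.copy()
            if design.replicate_sigma > 0:
                # per-replicate compositional overdispersion (composite
                # water samples are not identical)
                w = w * rng_count.lognormal(0.0, design.replicate_sigma, size=n)
            for ia, ib, sign, strength in planted:
                g = rng_edge.lognormal(0.0, strength)
                w[ia] *= g
                w[ib] *= g if sign > 0 else 1.0 / g
            p_dna = w / w.sum()
            rows_dna.append(rng_count.multinomial(design.depth_dna, p_dna))
            w_rna = w * activity
            rows_rna.append(rng_count.multinomial(design.depth_rna, w_rna / w_rna.sum()))
            sample_ids.append(f"{lake}-{r + 1}")
            lake_ids.append(lake)
            reps.append(r + 1)

    metadata = _simulate_metadata(design, sample_ids, lake_ids, reps, rng_meta)
    counts_dna = pd.DataFrame(rows_dna, index=sample_ids, columns=otus)
    counts_rna = pd.DataFrame(rows_rna, index=sample_ids, columns=otus)
    table_dna = OtuTable(counts_dna, fraction="rDNA", metadata=metadata)
    table_rna = OtuTable(counts_rna, fraction="rRNA", metadata=metadata)

    lineage = pd.DataFrame(
        {"phylum": clades.values, "genus": [f"g_{o}" for o in otus], "group": clades.values},
        index=pd.Index(otus, name="otu"),
    )
    return table_dna, table_rna, metadata, Taxonomy(lineage)


def _simulate_metadata(
    design: GradientDesign,
    sample_ids: list[str],
    lake_ids: list[str],
    reps: list[int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Environmental covariates loosely co-varying with turbidity.

    Temperature and the absorbance slope ratio decline with turbidity,
    total phosphorus rises with it; TN and DOC are gradient-independent.
    Ranges bracket the emulated survey (temp 0.7-12.1 degC, TP 6-64 ug/l,
    S_R 1.37-2.33).
    """
    env = np.asarray(design.env_values, dtype=float)
    logt = np.log10(env + 1.0)
    rel = (logt - logt.min()) / (logt.max() - logt.min())
    per_lake = {
        f"L{i + 1}": dict(
            turbidity=env[i],
            temperature=12.0 - 11.0 * rel[i] + rng.normal(0, 0.3),
            tp=6.0 + 58.0 * rel[i] + rng.normal(0, 1.0),
            tn=float(np.round(rng.uniform(0.04, 0.45), 3)),
            doc=float(np.round(rng.uniform(1.0, 5.6), 2)),
            s_r=2.3 - 0.9 * rel[i] + rng.normal(0, 0.03),
        )
        for i in range(design.n_lakes)
    }
    rows = []
    for sid, lake, rep in zip(sample_ids, lake_ids, reps):
        rec = {"lake": lake, "replicate": rep}
        rec.update(per_lake[lake])
        rows.append(rec)
    meta = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample"))
    meta["tp"] = meta["tp"].clip(lower=1.0)
    meta["s_r"] = meta["s_r"].clip(lower=0.5)
    return meta


# -- DOM optics fixtures -----------------------------------------------------

#: Coble excitation/emission windows (nm): b, t protein-like; a, m, c
#: humic-like. Classical definitions; the DOM module shares them.
COBLE_WINDOWS = {
    "b": ((270.0, 280.0), (300.0, 310.0)),
    "t": ((270.0, 280.0), (330.0, 350.0)),
    "a": ((250.0, 260.0), (380.0, 460.0)),
    "m": ((305.0, 320.0), (380.0, 420.0)),
    "c": ((330.0, 350.0), (420.0, 480.0)),
}


def simulate_spectra(
    s_short: float,
    s_long: float,
    peak_weights: Mapping[str, float],
    seed: int = 0,
    noise: float = 0.0,
    a0: float = 10.0,
):
    """Absorbance spectrum + EEM with known slope ratio and peak weights.

    The absorbance curve is a continuous piecewise exponential whose
    log-slope is exactly ``s_short`` below 300 nm and ``s_long`` above, so
    the downstream slope ratio is s_short/s_long by construction. The EEM
    is a weighted sum of truncated Gaussian bumps centred in the five Coble
    windows (truncation at 2.5 sigma keeps non-target windows exactly
    zero at zero noise) plus optional white noise.

    Returns ``(spectrum, eem)`` where spectrum is a DataFrame
    (wavelength_nm, absorption) and eem a DataFrame indexed by excitation
    with emission columns.
    """
    if s_short <= 0 or s_long <= 0:
        raise ValidationError("spectral slopes must be > 0")
    weights = {k: float(peak_weights.get(k, 0.0)) for k in COBLE_WINDOWS}
    if any(w < 0 for w in weights.values()):
        raise ValidationError("peak weights must be >= 0")
    if sum(weights.values()) == 0:
        raise ValidationError("peak weights must not all be zero")
    rng = np.random.default_rng(seed)

    wl = np.arange(250.0, 450.5, 1.0)
    a = np.where(
        wl <= 300.0,
        a0 * np.exp(-s_short * (wl - 275.0)),
        a0 * np.exp(-s_short * 25.0) * np.exp(-s_long * (wl - 300.0)),
    )
    spectrum = pd.DataFrame({"wavelength_nm": wl, "absorption": a})

    ex = np.arange(245.0, 362.5, 2.5)
    em = np.arange(280.0, 502.5, 2.5)
    EX, EM = np.meshgrid(ex, em, indexing="ij")
    intensity = np.zeros_like(EX)
    sig_ex, sig_em = 4.0, 8.0
    for peak, ((ex_lo, ex_hi), (em_lo, em_hi)) in COBLE_WINDOWS.items():
        cx, cm = (ex_lo + ex_hi) / 2.0, (em_lo + em_hi) / 2.0
        dx, dm = (EX - cx) / sig_ex, (EM - cm) / sig_em
        bump = np.exp(-0.5 * (dx**2 + dm**2))
        bump[(np.abs(dx) > 2.5) | (np.abs(dm) > 2.5)] = 0.0
        intensity += weights[peak] * bump
    if noise > 0:
        intensity = np.clip(intensity + rng.normal(0.0, noise, intensity.shape), 0.0, None)
    eem = pd.DataFrame(intensity, index=pd.Index(ex, name="excitation_nm"), columns=em)
    return spectrum, eem
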