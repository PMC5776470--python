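"""End-to-end pipeline orchestration with a single structured config.

One global seed deterministically derives independent per-stage
substreams (via ``numpy.random.SeedSequence``), so every stage is
reproducible in isolation and a rerun with the same config and seed
produces bit-identical numeric outputs. Stages communicate only through
the files they write; a manifest records outputs, the config hash and
per-stage runtimes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beta, cooccurrence, diversity, dom, io, phylostructure, synthetic
from .datamodel import ValidationError

logger = logging.getLogger(__name__)

_ALLOWED = {
    "": {"seed", "output_dir", "simulate", "inputs", "alpha", "beta", "rarity",
         "subsample", "network", "phylo", "dom"},
    "simulate": {"n_lakes", "n_replicates", "env_values", "depth_dna", "depth_rna",
                 "n_otus", "abundance_sigma", "niche_breadth", "phylo_signal",
                 "n_clades", "activity_model", "planted_edges", "n_tree_tips"},
    "inputs": {"otu_table_dna", "otu_table_rna", "metadata", "tree", "taxonomy",
               "spectrum", "eem"},
    "alpha": {"depth_dna", "depth_rna", "n_draws"},
    "beta": {"rc_reps", "nmds_restarts", "n_perm"},
    "rarity": {"initial_top", "step", "rc_reps", "nmds_restarts"},
    "subsample": {"n_individuals", "n_draws", "rc_reps"},
    "network": {"min_occ", "n_top", "n_perm", "min_support", "q_threshold",
                "renormalize", "n_bins"},
    "phylo": {"n_null"},
    "dom": {"s_short", "s_long", "peak_weights", "noise"},
}

#: fixed spawn order of per-stage random substreams
_STAGES = ("simulate", "rarefy", "alpha", "beta", "rarity", "subsample",
           "network", "phylo", "dom")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    unknown = set(cfg) - _ALLOWED[""]
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    for section, allowed in _ALLOWED.items():
        if section and section in cfg and cfg[section] is not None:
            extra = set(cfg[section]) - allowed
            if extra:
                raise ValidationError(
                    f"unknown keys in config section {section!r}: {sorted(extra)}"
                )
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ValidationError("config needs either a 'simulate' or an 'inputs' block")
    return cfg


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(_STAGES, ss.spawn(len(_STAGES)))
    }


def _write_dm(dm, path: Path) -> None:
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, sep="\t", index_label="sample"
    )


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_all(cfg: dict, output_dir: str | Path | None = None) -> dict:
    """Execute every configured stage; returns the manifest dict."""
    cfg = validate_config(cfg)
    seed = int(cfg.get("seed", 0))
    seeds = _stage_seeds(seed)
    out = Path(output_dir or cfg.get("output_dir", "turbicom_out"))
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": seed,
        "config_hash": config_hash(cfg),
        "files": [],
        "runtimes_s": {},
    }

    def record(path: Path) -> Path:
        manifest["files"].append(str(path.relative_to(out)))
        return path

    current = "setup"
    try:
        # ---- inputs or simulation -----------------------------------------
        current = "simulate"
        t0 = time.perf_counter()
        if "simulate" in cfg:
            sim = dict(cfg["simulate"] or {})
            n_tips = sim.pop("n_tree_tips", None)
            design = synthetic.GradientDesign(seed=seeds["simulate"], **{
                k: (tuple(map(tuple, v)) if k == "planted_edges" else v)
                for k, v in sim.items()
            })
            tree = synthetic.simulate_tree(n_tips or design.n_otus, seeds["simulate"])
            tab_dna, tab_rna, metadata, taxonomy = synthetic.simulate_community(design, tree)
            fx = out / "fixtures"
            fx.mkdir(exist_ok=True)
            io.write_otu_table(tab_dna, record(fx / "otu_dna.tsv"))
            io.write_otu_table(tab_rna, record(fx / "otu_rna.tsv"))
            io.write_metadata(metadata, record(fx / "metadata.tsv"))
            io.write_newick(tree, record(fx / "tree.nwk"))
            io.write_taxonomy(taxonomy, record(fx / "taxonomy.tsv"))
            depth_dna, depth_rna = design.depth_dna, design.depth_rna
        else:
            inputs = cfg["inputs"]
            metadata = io.read_metadata(inputs["metadata"])
            tab_dna = io.read_otu_table(inputs["otu_table_dna"], "rDNA", metadata)
            tab_rna = io.read_otu_table(inputs["otu_table_rna"], "rRNA", metadata)
            tree = io.read_newick(inputs["tree"])
            taxonomy = io.read_taxonomy(inputs["taxonomy"])
            depth_dna = int(cfg.get("alpha", {}).get("depth_dna", 1863))
            depth_rna = int(cfg.get("alpha", {}).get("depth_rna", 1052))
        manifest["runtimes_s"]["simulate"] = round(time.perf_counter() - t0, 3)

        # ---- rarefaction (one fixed draw for multivariate stages) ---------
        current = "rarefy"
        t0 = time.perf_counter()
        depth_dna = min(depth_dna, int(tab_dna.sample_totals().min()))
        depth_rna = min(depth_rna, int(tab_rna.sample_totals().min()))
        raref_dna = diversity.rarefy_table(tab_dna, depth_dna, seeds["rarefy"])
        raref_rna = diversity.rarefy_table(tab_rna, depth_rna, seeds["rarefy"] + 1)
        io.write_otu_table(raref_dna, record(out / "rarefied_dna.tsv"))
        io.write_otu_table(raref_rna, record(out / "rarefied_rna.tsv"))
        manifest["runtimes_s"]["rarefy"] = round(time.perf_counter() - t0, 3)

        tables = {"rDNA": raref_dna, "rRNA": raref_rna}
        depths = {"rDNA": depth_dna, "rRNA": depth_rna}

        # ---- alpha diversity ----------------------------------------------
        current = "alpha"
        t0 = time.perf_counter()
        acfg = cfg.get("alpha") or {}
        n_draws = int(acfg.get("n_draws", 100))
        for frac, tab in tables.items():
            alpha = diversity.alpha_diversity_table(
                tab, tree, depths[frac], n_draws=n_draws, seed=seeds["alpha"]
            )
            alpha.to_csv(record(out / f"alpha_{frac.lower()}.tsv"), sep="\t")
        manifest["runtimes_s"]["alpha"] = round(time.perf_counter() - t0, 3)

        # ---- beta: Raup-Crick, NMDS, ANOSIM, envfit ------------------------
        current = "beta"
        t0 = time.perf_counter()
        bcfg = cfg.get("beta") or {}
        rc_reps = int(bcfg.get("rc_reps", 999))
        restarts = int(bcfg.get("nmds_restarts", 20))
        n_perm = int(bcfg.get("n_perm", 999))
        beta_stats: dict = {}
        ordinations = {}
        for i, (frac, tab) in enumerate(tables.items()):
            dist = beta.raup_crick(tab, n_reps=rc_reps, seed=seeds["beta"] + i)
            _write_dm(dist, record(out / f"raup_crick_{frac.lower()}.tsv"))
            ordn = beta.nmds(dist, k=2, n_restarts=restarts, seed=seeds["beta"] + 10 + i)
            ordn.coordinates.to_csv(
                record(out / f"nmds_{frac.lower()}.tsv"), sep="\t", index_label="sample"
            )
            ordinations[frac] = ordn
            r, p = beta.anosim(dist, tab.lakes(), n_perm=n_perm, seed=seeds["beta"] + 20 + i)
            fits = {}
            for j, col in enumerate(
                c for c in ("turbidity", "temperature", "tp", "tn", "doc", "s_r")
                if tab.metadata is not None and c in tab.metadata
            ):
                env = tab.metadata[col].to_numpy(float)
                if np.ptp(env) == 0:
                    continue
                r2, pf = beta.envfit(ordn, env, n_perm=n_perm, seed=seeds["beta"] + 30 + j)
                fits[col] = {"r2": round(r2, 6), "p": pf}
            beta_stats[frac] = {
                "anosim_R": round(r, 6),
                "anosim_p": p,
                "nmds_stress": round(ordn.stress, 6),
                "envfit": fits,
            }
        _dump_json(beta_stats, record(out / "beta_stats.json"))
        manifest["runtimes_s"]["beta"] = round(time.perf_counter() - t0, 3)

        # ---- rarity-inclusion profile --------------------------------------
        current = "rarity"
        t0 = time.perf_counter()
        rcfg = cfg.get("rarity") or {}
        for frac, tab in tables.items():
            initial = int(rcfg.get("initial_top", 100))
            if tab.n_otus > initial:
                prof = beta.rarity_inclusion_profile(
                    tab,
                    initial_top=initial,
                    step=int(rcfg.get("step", 50)),
                    n_reps=int(rcfg.get("rc_reps", rc_reps)),
                    seed=seeds["rarity"],
                    nmds_restarts=int(rcfg.get("nmds_restarts", restarts)),
                )
                prof.profile.to_csv(
                    record(out / f"rarity_profile_{frac.lower()}.tsv"),
                    sep="\t", index=False,
                )
        manifest["runtimes_s"]["rarity"] = round(time.perf_counter() - t0, 3)

        # ---- random-subsample separation -----------------------------------
        current = "subsample"
        t0 = time.perf_counter()
        scfg = cfg.get("subsample") or {}
        n_ind = scfg.get("n_individuals") or min(depth_dna, depth_rna) // 2
        sub = beta.random_subsample_ordination(
            raref_dna, raref_rna,
            n_individuals=int(n_ind),
            n_draws=int(scfg.get("n_draws", 20)),
            seed=seeds["subsample"],
            rc_reps=int(scfg.get("rc_reps", 199)),
        )
        sub.to_csv(record(out / "subsample_separation.tsv"), sep="\t")
        manifest["runtimes_s"]["subsample"] = round(time.perf_counter() - t0, 3)

        # ---- rRNA:rDNA group ratios ---------------------------------------
        ratios = beta.rna_dna_group_ratio(raref_dna, raref_rna, taxonomy)
        ratios.to_csv(record(out / "rna_dna_group_ratios.tsv"), sep="\t")

        # ---- co-occurrence network (rDNA only) -----------------------------
        current = "network"
        t0 = time.perf_counter()
        ncfg = cfg.get("network") or {}
        network = cooccurrence.infer_network(
            raref_dna,
            min_occ=int(ncfg.get("min_occ", 5)),
            n_top=int(ncfg.get("n_top", 1000)),
            n_perm=int(ncfg.get("n_perm", 999)),
            min_support=int(ncfg.get("min_support", 2)),
            q_threshold=float(ncfg.get("q_threshold", 0.05)),
            renormalize=bool(ncfg.get("renormalize", True)),
            n_bins=int(ncfg.get("n_bins", 4)),
            seed=seeds["network"],
        )
        network.provenance["config_hash"] = manifest["config_hash"]
        io.write_edge_list(network, record(out / "network_edges.tsv"), "tsv")
        io.write_edge_list(network, record(out / "network_edges.graphml"), "graphml")
        summary = cooccurrence.network_summaries(network, taxonomy, raref_dna)
        _dump_json(summary, record(out / "network_summary.json"))
        manifest["runtimes_s"]["network"] = round(time.perf_counter() - t0, 3)

        # ---- phylogenetic structure ----------------------------------------
        current = "phylo"
        t0 = time.perf_counter()
        pcfg = cfg.get("phylo") or {}
        n_null = int(pcfg.get("n_null", 999))
        dist = phylostructure.cophenetic_distances(tree)
        ses = phylostructure.community_vs_edge_ses(
            raref_dna, network, dist, n_null=n_null, seed=seeds["phylo"]
        )
        ses.to_csv(record(out / "ses_mntd.tsv"), sep="\t")
        phylo_stats: dict = {}
        n_pos = int((network.edges["sign"] == "co-presence").sum()) if network.n_edges else 0
        n_neg = network.n_edges - n_pos
        if n_pos >= 2 and n_neg >= 2:
            cmp_res = phylostructure.edge_set_phylo_comparison(network, dist)
            phylo_stats["edge_comparison"] = asdict(cmp_res)
        _dump_json(phylo_stats, record(out / "edge_phylo.json"))
        manifest["runtimes_s"]["phylo"] = round(time.perf_counter() - t0, 3)

        # ---- DOM optics ----------------------------------------------------
        current = "dom"
        t0 = time.perf_counter()
        dom_out = None
        if "dom" in cfg and cfg["dom"]:
            dcfg = cfg["dom"]
            spectrum, eem = synthetic.simulate_spectra(
                s_short=float(dcfg["s_short"]),
                s_long=float(dcfg["s_long"]),
                peak_weights=dcfg.get("peak_weights", {"b": 1.0}),
                seed=seeds["dom"],
                noise=float(dcfg.get("noise", 0.0)),
            )
            dom_out = {
                "s_r": dom.slope_ratio(spectrum),
                "coble_peaks_percent": dom.coble_peak_distribution(eem),
            }
        elif "inputs" in cfg and cfg["inputs"].get("spectrum"):
            spectrum = dom.read_spectrum(cfg["inputs"]["spectrum"])
            dom_out = {"s_r": dom.slope_ratio(spectrum)}
            if cfg["inputs"].get("eem"):
                eem = dom.read_eem(cfg["inputs"]["eem"])
                dom_out["coble_peaks_percent"] = dom.coble_peak_distribution(eem)
        if dom_out is not None:
            _dump_json(dom_out, record(out / "dom.json"))
        manifest["runtimes_s"]["dom"] = round(time.perf_counter() - t0, 3)

    except Exception as exc:
        manifest["failed_stage"] = current
        _dump_json(manifest, out / "manifest.json")
        (out / "FAILED").write_text(f"stage {current}: {exc}\n")
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    _dump_json(manifest, out / "manifest.json")
    return manifest
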