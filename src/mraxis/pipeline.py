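"""End-to-end pipeline driver.

Runs the analysis stages in dependency order — simulate → score →
regulators → gsea/ssgsea → variants → tssprofile — from a single YAML
configuration, with deterministic seeding and a manifest recording the
SHA-256 checksum and record counts of every output. Re-running with the
same configuration and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import de, enrichment, io, network, synthetic, tss, variants

__all__ = ["ConfigError", "load_config", "validate_config", "run_pipeline"]

log = logging.getLogger("mraxis")

STAGES = ("simulate", "score", "regulators", "gsea", "ssgsea", "variants", "tssprofile")

DEFAULTS: dict = {
    "outdir": "mraxis_out",
    "seed": 0,
    "stages": {s: True for s in STAGES},
    "simulate": {
        "network": {},
        "plant": {"planted_tf": "TF001"},
        "expression": {"n_samples_per_group": 4, "shift": 3.0},
        "variants": {},
        "coverage": {"depletion_factor": 0.2, "flank": 1000, "n_depleted": 10},
    },
    "thresholds": {"fc_threshold": 1.0, "q_threshold": 0.05},
    "gsea": {"n_perm": 1000, "weight": 1.0},
    "ssgsea": {"alpha": 0.25},
    "tss": {"flank": 15000, "bin_size": 300},
}


class ConfigError(ValueError):
    """Raised when the pipeline configuration does not validate."""


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML config over the shipped defaults."""
    config = DEFAULTS
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config must be a YAML mapping")
        config = _deep_merge(config, user)
    if overrides:
        config = _deep_merge(config, overrides)
    return config


def validate_config(config: dict) -> dict:
    """Report-only validation: lists of errors and warnings."""
    errors, warnings_ = [], []
    for key in config:
        if key not in DEFAULTS:
            warnings_.append(f"unknown key {key!r}")
    if not isinstance(config.get("seed"), int):
        errors.append("seed: must be an integer")
    for name, value in (
        ("tss.flank", config.get("tss", {}).get("flank")),
        ("tss.bin_size", config.get("tss", {}).get("bin_size")),
        ("gsea.n_perm", config.get("gsea", {}).get("n_perm")),
    ):
        if value is not None and (not isinstance(value, int) or value <= 0):
            errors.append(f"{name}: must be a positive integer")
    th = config.get("thresholds", {})
    for name in ("fc_threshold", "q_threshold"):
        if name in th and not (isinstance(th[name], (int, float)) and th[name] > 0):
            errors.append(f"thresholds.{name}: must be positive")
    stages = config.get("stages", {})
    for s in stages:
        if s not in STAGES:
            warnings_.append(f"stages: unknown stage {s!r}")
    if not stages.get("simulate", False):
        for s in STAGES[1:]:
            if stages.get(s):
                # downstream stages read simulate outputs from outdir
                outdir = Path(config.get("outdir", "."))
                if not outdir.exists():
                    errors.append(
                        f"stage {s!r} enabled without 'simulate' but outdir "
                        f"{outdir} does not exist"
                    )
                break
    return {"errors": errors, "warnings": warnings_}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict) -> dict:
    """Execute the enabled stages; return the run manifest.

    The manifest records, per stage, the record counts in and out of
    every filter, and a checksum for every file written. A stage failure
    aborts with a stage-tagged error.
    """
    report = validate_config(config)
    if report["errors"]:
        raise ConfigError("; ".join(report["errors"]))
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    stages = config["stages"]
    manifest: dict = {"seed": seed, "stages": {}, "checksums": {}}
    written: list[Path] = []

    def emit(path: Path) -> None:
        written.append(path)

    current = "config"
    try:
        for stage in STAGES:
            if not stages.get(stage, False):
                continue
            current = stage
            log.info("stage %s: starting", stage)
            info = _STAGE_FUNCS[stage](config, outdir, seed, emit)
            manifest["stages"][stage] = info
            log.info("stage %s: %s", stage, info)
    except ConfigError:
        raise
    except Exception as exc:  # tag the failing stage for the operator
        raise RuntimeError(f"stage {current!r} failed: {exc}") from exc
    for path in written:
        manifest["checksums"][path.name] = _sha256(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# --------------------------------------------------------------------------
# stages


def _stage_simulate(config, outdir, seed, emit):
    sim = config["simulate"]
    net_cfg = synthetic.NetworkSimConfig(**{**sim["network"], "seed": seed})
    edges = synthetic.simulate_network(net_cfg)
    edges_df = pd.DataFrame(
        [(e.source, e.target, e.kind, e.confidence) for e in edges],
        columns=["source", "target", "kind", "confidence"],
    )
    edges_path = outdir / "edges.tsv"
    edges_df.to_csv(edges_path, sep="\t", index=False)
    emit(edges_path)

    plant_cfg = synthetic.PlantConfig(**{**sim["plant"], "seed": seed})
    table, truth = synthetic.plant_regulator(edges, plant_cfg)
    de_path = outdir / "de_table.tsv"
    table.to_csv(de_path, sep="\t", index=False)
    emit(de_path)
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    emit(truth_path)

    # gene sets for pre-ranked GSEA: planted direct targets + a decoy
    depth1 = sorted(g for g, d in truth["member_depths"].items() if d == 1)
    all_genes = sorted(table["gene"])
    decoy = all_genes[:: max(1, len(all_genes) // max(len(depth1), 1))][: len(depth1)]
    sets = {"planted_direct_targets": set(depth1), "decoy_set": set(decoy) or {all_genes[0]}}
    gmt_path = outdir / "gene_sets.gmt"
    io.write_gmt(sets, gmt_path)
    emit(gmt_path)

    expr_cfg = dict(sim["expression"])
    n_per = expr_cfg.pop("n_samples_per_group")
    shift = expr_cfg.pop("shift")
    expr_sets = {
        "shifted_set": {f"S{i:03d}" for i in range(1, 31)},
        "control_set": {f"C{i:03d}" for i in range(1, 31)},
    }
    mat = synthetic.simulate_expression_matrix(
        n_per, expr_sets, "shifted_set", shift, seed=seed, **expr_cfg
    )
    expr_path = outdir / "expression.tsv"
    io.write_expression(mat, expr_path)
    emit(expr_path)
    expr_gmt = outdir / "expression_sets.gmt"
    io.write_gmt(expr_sets, expr_gmt)
    emit(expr_gmt)

    var_cfg = synthetic.VariantSimConfig(**{**sim["variants"], "seed": seed})
    calls, blacklist, truth_keys = synthetic.simulate_variant_calls(var_cfg)
    for (caller, normal), recs in calls.items():
        vcf_path = outdir / f"calls_{caller}_{normal}.vcf"
        variants.write_vcf(recs, vcf_path)
        emit(vcf_path)
    bl_path = outdir / "blacklist.tsv"
    io.write_blacklist(blacklist, bl_path)
    emit(bl_path)
    vt_path = outdir / "variant_truth.tsv"
    io.write_blacklist(truth_keys, vt_path)  # same 4-column key format
    emit(vt_path)

    cov_cfg = dict(sim["coverage"])
    n_depleted = cov_cfg.pop("n_depleted")
    annotation = synthetic.random_gene_annotation(seed=seed)
    depleted = list(annotation["name"][:n_depleted])
    track = synthetic.simulate_coverage(annotation, depleted, seed=seed, **cov_cfg)
    ann_path = outdir / "annotation.bed"
    io.write_bed6(annotation, ann_path)
    emit(ann_path)
    cov_path = outdir / "coverage.bedgraph"
    io.write_bedgraph(track, cov_path)
    emit(cov_path)
    dep_path = outdir / "depleted_genes.txt"
    dep_path.write_text("\n".join(depleted) + "\n")
    emit(dep_path)
    return {
        "n_edges": len(edges),
        "n_genes": len(table),
        "planted_tf": truth["planted_tf"],
        "n_call_sets": len(calls),
        "n_truth_variants": len(truth_keys),
    }


def _stage_score(config, outdir, seed, emit):
    table = de.read_de_table(outdir / "de_table.tsv")
    scores = de.score_table(table)
    ranked = de.rank_genes(scores)
    ranked_path = outdir / "ranked_scores.tsv"
    ranked.to_csv(ranked_path, sep="\t", index=False)
    emit(ranked_path)
    th = config["thresholds"]
    calls = de.call_differential(table, th["fc_threshold"], th["q_threshold"])
    for direction in ("up", "down"):
        path = outdir / f"de_{direction}.txt"
        path.write_text("\n".join(sorted(calls[direction])) + "\n")
        emit(path)
    return {
        "n_genes": len(table),
        "n_up": len(calls["up"]),
        "n_down": len(calls["down"]),
    }


def _stage_regulators(config, outdir, seed, emit):
    edges = network.read_edges(outdir / "edges.tsv")
    ranked = pd.read_csv(outdir / "ranked_scores.tsv", sep="\t")
    up = set((outdir / "de_up.txt").read_text().split())
    down = set((outdir / "de_down.txt").read_text().split())
    result = network.score_regulators(edges, ranked, up | down)
    path = outdir / "regulators.tsv"
    result.to_csv(path, sep="\t", index=False)
    emit(path)
    return {"n_tfs": len(result), "top_tf": result["tf"].iloc[0]}


def _stage_gsea(config, outdir, seed, emit):
    ranked = pd.read_csv(outdir / "ranked_scores.tsv", sep="\t")
    sets = io.read_gmt(outdir / "gene_sets.gmt")
    gene_sets = [
        enrichment.GeneSet(name, frozenset(genes)) for name, genes in sets.items()
    ]
    result = enrichment.preranked_gsea_collection(
        ranked,
        gene_sets,
        n_perm=config["gsea"]["n_perm"],
        weight=config["gsea"]["weight"],
        seed=seed,
    )
    path = outdir / "gsea.tsv"
    result.to_csv(path, sep="\t", index=False)
    emit(path)
    return {"n_sets": len(result)}


def _stage_ssgsea(config, outdir, seed, emit):
    mat = io.read_expression(outdir / "expression.tsv")
    sets = io.read_gmt(outdir / "expression_sets.gmt")
    prepped = enrichment.prep_expression(mat)
    result = enrichment.ssgsea(prepped, sets, alpha=config["ssgsea"]["alpha"])
    path = outdir / "ssgsea.tsv"
    result.to_csv(path, sep="\t", index=False)
    emit(path)
    return {"n_genes_kept": len(prepped), "n_scores": len(result)}


def _stage_variants(config, outdir, seed, emit):
    call_paths = sorted(outdir.glob("calls_*_*.vcf"))
    calls = {}
    for path in call_paths:
        _, caller, normal = path.stem.split("_", 2)
        calls[(caller, normal)] = variants.read_vcf(path, caller=caller)
    blacklist = io.read_blacklist(outdir / "blacklist.tsv")
    consensus = variants.unmatched_consensus(calls, blacklist)
    filtered = variants.somatic_filter(consensus)
    out_path = outdir / "somatic_filtered.vcf"
    variants.write_vcf(filtered, out_path)
    emit(out_path)
    n_in = sum(len(v) for v in calls.values())
    return {
        "n_input_calls": n_in,
        "n_consensus": len(consensus),
        "n_filtered": len(filtered),
    }


def _stage_tssprofile(config, outdir, seed, emit):
    track = io.read_bedgraph(outdir / "coverage.bedgraph")
    annotation = io.read_bed6(outdir / "annotation.bed")
    depleted = (outdir / "depleted_genes.txt").read_text().split()
    cfg = config["tss"]
    windows = tss.tss_windows(annotation, depleted, flank=cfg["flank"])
    profile = tss.profile_density(
        track,
        windows,
        bin_size=cfg["bin_size"],
        flank=cfg["flank"],
        gene_set_name="depleted",
    )
    path = outdir / "tss_profile.tsv"
    profile.to_frame().to_csv(path, sep="\t", index=False)
    emit(path)
    return {"n_genes": profile.n_genes, "n_bins": int(profile.mean_density.size)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "score": _stage_score,
    "regulators": _stage_regulators,
    "gsea": _stage_gsea,
    "ssgsea": _stage_ssgsea,
    "variants": _stage_variants,
    "tssprofile": _stage_tssprofile,
}
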