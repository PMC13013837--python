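"""Configured, seeded orchestration of the full synthetic pipeline.

Stages run in dependency order: simulate -> quantify -> profile ->
behavior -> de -> regulon -> integrate. All tabular interchange is
headered TSV; manifests and truth are JSON; sequence artifacts are
FASTA/BED/JASPAR text. A run manifest records parameters, seeds and
SHA-256 checksums of every output, so identical config + seed yields
identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from tfap import behavior as beh
from tfap import integration as integ
from tfap import quantify as quant
from tfap import regulon as reg
from tfap import synthetic as syn
from tfap import transcriptome as tx
from tfap._errors import ConfigError
from tfap.activity import normalize_to_controls, summarize_groups

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "quantify",
    "profile",
    "behavior",
    "de",
    "regulon",
    "integrate",
)

STAGE_DEPENDENCIES = {
    "quantify": ("simulate",),
    "profile": ("quantify",),
    "behavior": ("simulate",),
    "de": ("simulate",),
    "regulon": ("simulate",),
    "integrate": ("profile", "de", "regulon"),
}

_KNOWN_STAGE_KEYS = {
    "simulate": set(syn.SimulationConfig.__dataclass_fields__) | {"noise_sd_cq"},
    "quantify": set(),
    "profile": {"reference_group"},
    "behavior": {"direction"},
    "de": {"pseudocount", "p_thresh", "fc_up", "fc_down", "use_q"},
    "regulon": {
        "upstream",
        "downstream",
        "threshold_kind",
        "threshold_value",
        "motif_pseudocount",
    },
    "integrate": {"discordant_multiplier"},
}

_KNOWN_TOP_KEYS = {"seed", "stages", *STAGES}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGES),
    "simulate": {},
    "quantify": {},
    "profile": {"reference_group": "control"},
    "behavior": {"direction": "with_over_without"},
    "de": {
        "pseudocount": 1.0,
        "p_thresh": 0.05,
        "fc_up": 2.0,
        "fc_down": 0.5,
        "use_q": False,
    },
    "regulon": {
        "threshold_kind": "relative",
        "threshold_value": 0.8,
        "motif_pseudocount": 0.01,
    },
    "integrate": {"discordant_multiplier": 0.25},
}


def load_config(path) -> dict:
    with open(path) as handle:
        loaded = yaml.safe_load(handle) or {}
    return merge_config(loaded)


def merge_config(overrides: Mapping) -> dict:
    config = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in overrides.items():
        if isinstance(value, Mapping) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def validate_config(config: Mapping) -> list[str]:
    """Every unknown key, missing requirement and out-of-range value."""
    issues: list[str] = []
    for key in config:
        if key not in _KNOWN_TOP_KEYS:
            issues.append(f"unknown top-level key {key!r}")
    stages = config.get("stages", list(STAGES))
    for stage in stages:
        if stage not in STAGES:
            issues.append(f"unknown stage {stage!r}")
    enabled = set(stages)
    for stage, deps in STAGE_DEPENDENCIES.items():
        if stage in enabled:
            for dep in deps:
                if dep not in enabled:
                    issues.append(
                        f"stage {stage!r} enabled but its dependency "
                        f"{dep!r} is not"
                    )
    if "seed" not in config and enabled & {"simulate"}:
        issues.append("stochastic stages enabled but no seed given")
    for stage, keys in _KNOWN_STAGE_KEYS.items():
        block = config.get(stage, {})
        if not isinstance(block, Mapping):
            issues.append(f"stage block {stage!r} must be a mapping")
            continue
        for key in block:
            if key not in keys:
                issues.append(f"unknown key {key!r} in stage {stage!r}")
    sim_block = {
        k: v
        for k, v in config.get("simulate", {}).items()
        if k in syn.SimulationConfig.__dataclass_fields__
    }
    if "seed" in config:
        sim_block.setdefault("seed", config["seed"])
    try:
        syn.config_from_dict(sim_block)
    except (ConfigError, TypeError, ValueError) as exc:
        issues.append(f"simulate: {exc}")
    de_block = config.get("de", {})
    if isinstance(de_block, Mapping):
        if de_block.get("pseudocount", 1.0) < 0:
            issues.append("de: pseudocount must be >= 0")
        if not 0 < de_block.get("p_thresh", 0.05) <= 1:
            issues.append("de: p_thresh must be in (0, 1]")
    regulon_block = config.get("regulon", {})
    if isinstance(regulon_block, Mapping):
        kind = regulon_block.get("threshold_kind", "relative")
        value = regulon_block.get("threshold_value", 0.8)
        if kind not in ("relative", "bits"):
            issues.append(f"regulon: unknown threshold kind {kind!r}")
        elif kind == "relative" and not 0 < value <= 1:
            issues.append("regulon: relative threshold must be in (0, 1]")
    return issues


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(
    config: Mapping, out_dir, seed: int | None = None
) -> dict:
    """Execute the enabled stages and return the run manifest."""
    config = merge_config(config)
    if seed is not None:
        config["seed"] = seed
    issues = validate_config(config)
    if issues:
        raise ConfigError("invalid config: " + "; ".join(issues))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = list(config["stages"])
    outputs: dict[str, list[str]] = {}
    applied: dict[str, dict] = {}

    def record(stage: str, *paths: Path) -> None:
        outputs.setdefault(stage, []).extend(p.name for p in paths)

    sim_params = {
        k: v
        for k, v in config["simulate"].items()
        if k in syn.SimulationConfig.__dataclass_fields__
    }
    sim_params["seed"] = config["seed"]
    sim_config = syn.config_from_dict(sim_params)

    try:
        if "simulate" in enabled:
            _stage_simulate(sim_config, config, out, record, applied)
        if "quantify" in enabled:
            _stage_quantify(out, record)
        if "profile" in enabled:
            _stage_profile(config, out, record, applied)
        if "behavior" in enabled:
            _stage_behavior(config, out, record, applied)
        if "de" in enabled:
            _stage_de(config, out, record, applied)
        if "regulon" in enabled:
            _stage_regulon(config, sim_config, out, record, applied)
        if "integrate" in enabled:
            _stage_integrate(config, out, record, applied)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    manifest = {
        "config": _jsonable(config),
        "seed": config["seed"],
        "parameters_applied": applied,
        "outputs": {
            stage: {name: _sha256(out / name) for name in names}
            for stage, names in outputs.items()
        },
    }
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
    return manifest


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _stage_simulate(sim_config, config, out: Path, record, applied) -> None:
    logger.info("simulate: %d TFs, %d genes", sim_config.n_tfs, sim_config.n_genes)
    truth = syn.make_truth(sim_config)
    motifs = syn.make_motifs(sim_config)
    reporter_counts = syn.simulate_reporter_counts(truth, sim_config)
    curves, standards = syn.make_standard_curves(sim_config)
    qpcr = syn.simulate_qpcr(
        reporter_counts,
        curves,
        noise_sd_cq=config["simulate"].get("noise_sd_cq", 0.0),
        rng=sim_config.child_rng("qpcr"),
    )
    expr, lengths, sample_groups = syn.simulate_expression(truth, sim_config)
    trials = syn.simulate_behavior(truth, sim_config)
    promoters = syn.simulate_promoters(truth, motifs, sim_config)

    syn.truth_to_json(truth, out / "truth.json")
    _write_tsv(syn.standards_to_frame(standards), out / "standards.tsv")
    _write_tsv(qpcr, out / "qpcr.tsv")
    groups = pd.DataFrame(
        sorted(
            {r.animal_id: r.group for r in reporter_counts.itertuples()}.items()
        ),
        columns=["animal_id", "group"],
    )
    _write_tsv(groups, out / "groups.tsv")
    _write_tsv(expr.rename_axis("gene"), out / "counts.tsv", index=True)
    _write_tsv(
        lengths.rename_axis("gene").reset_index(), out / "lengths.tsv"
    )
    _write_tsv(
        pd.DataFrame(
            sorted(sample_groups.items()), columns=["sample", "group"]
        ),
        out / "sample_groups.tsv",
    )
    _write_tsv(trials, out / "behavior.tsv")
    syn.write_fasta(promoters.genome, out / "genome.fasta")
    syn.write_bed(promoters.tss_bed, out / "tss.bed")
    syn.write_fasta(
        {g: rec.sequence for g, rec in promoters.promoters.items()},
        out / "promoters.fasta",
    )
    reg.write_jaspar(motifs, out / "motifs.jaspar")
    record(
        "simulate",
        *(
            out / name
            for name in (
                "truth.json",
                "standards.tsv",
                "qpcr.tsv",
                "groups.tsv",
                "counts.tsv",
                "lengths.tsv",
                "sample_groups.tsv",
                "behavior.tsv",
                "genome.fasta",
                "tss.bed",
                "promoters.fasta",
                "motifs.jaspar",
            )
        ),
    )
    applied["simulate"] = {
        "battery_size": sim_config.battery_size,
        "noise_sd_reporter": sim_config.noise_sd_reporter,
        "noise_sd_expr": sim_config.noise_sd_expr,
        "noise_sd_behavior": sim_config.noise_sd_behavior,
    }


def _stage_quantify(out: Path, record) -> None:
    standards = quant.read_standards_tsv(out / "standards.tsv")
    curves = quant.fit_all_curves(standards)
    qpcr = pd.read_csv(out / "qpcr.tsv", sep="\t")
    measurements = quant.quantify_qpcr_table(qpcr, curves)
    quant.write_measurements_tsv(measurements, out / "measurements.tsv")
    record("quantify", out / "measurements.tsv")


def _stage_profile(config, out: Path, record, applied) -> None:
    measurements = pd.read_csv(out / "measurements.tsv", sep="\t")
    groups = pd.read_csv(out / "groups.tsv", sep="\t")
    labels = dict(zip(groups["animal_id"], groups["group"]))
    reference = config["profile"].get("reference_group", "control")
    tfap = normalize_to_controls(measurements, labels, reference)
    summary = summarize_groups(tfap, reference)
    _write_tsv(tfap, out / "tfap.tsv")
    _write_tsv(summary, out / "group_summary.tsv")
    record("profile", out / "tfap.tsv", out / "group_summary.tsv")
    applied["profile"] = {"reference_group": reference}


def _stage_behavior(config, out: Path, record, applied) -> None:
    trials = pd.read_csv(out / "behavior.tsv", sep="\t")
    direction = config["behavior"].get("direction", "with_over_without")
    rated = beh.apply_outlier_rule(beh.compute_si_rates(trials, direction))
    stressed = [g for g in rated["group"].unique() if g != "control"]
    phenotypes = beh.classify_phenotypes(rated, stressed)
    normalized = beh.normalize_si_by_day(rated)
    _write_tsv(phenotypes, out / "phenotypes.tsv")
    _write_tsv(normalized, out / "si_normalized.tsv")
    record("behavior", out / "phenotypes.tsv", out / "si_normalized.tsv")
    applied["behavior"] = {
        "direction": direction,
        "outlier_threshold": beh.OUTLIER_SI_THRESHOLD,
        "susceptible_cutoff": beh.SUSCEPTIBLE_SI_CUTOFF,
    }


def _stage_de(config, out: Path, record, applied) -> None:
    counts = pd.read_csv(out / "counts.tsv", sep="\t", index_col="gene")
    lengths = pd.read_csv(out / "lengths.tsv", sep="\t").set_index("gene")[
        "length_bp"
    ]
    sample_groups = dict(
        pd.read_csv(out / "sample_groups.tsv", sep="\t").itertuples(
            index=False, name=None
        )
    )
    block = config["de"]
    tpm = tx.counts_to_tpm(counts, lengths)
    groups_present = sorted(set(sample_groups.values()))
    contrast = [g for g in groups_present if g != "control"][0]
    de = tx.differential_expression(
        tpm, sample_groups, contrast, "control", block["pseudocount"]
    )
    degs = tx.call_degs(
        de,
        p_thresh=block["p_thresh"],
        fc_up=block["fc_up"],
        fc_down=block["fc_down"],
        use_q=block["use_q"],
    )
    de_out = de.copy()
    de_out["deg_class"] = degs
    _write_tsv(de_out.reset_index(), out / "de_results.tsv")
    _write_tsv(
        de_out[de_out["deg_class"] != "none"].reset_index(), out / "degs.tsv"
    )
    deg_genes = degs.index[degs != "none"]
    if len(deg_genes) > 0:
        scaled = tx.scale_rows(tpm, deg_genes)
    else:
        scaled = pd.DataFrame(columns=tpm.columns)
    _write_tsv(scaled.rename_axis("gene"), out / "scaled_matrix.tsv", index=True)
    record(
        "de", out / "de_results.tsv", out / "degs.tsv", out / "scaled_matrix.tsv"
    )
    applied["de"] = dict(block)
    logger.info(
        "de: contrast %s vs control; DEG rule p<%s FC>%s or FC<%s (use_q=%s)",
        contrast,
        block["p_thresh"],
        block["fc_up"],
        block["fc_down"],
        block["use_q"],
    )


def _stage_regulon(config, sim_config, out: Path, record, applied) -> None:
    block = config["regulon"]
    upstream = block.get("upstream", sim_config.promoter_upstream)
    downstream = block.get("downstream", sim_config.promoter_downstream)
    promoters = reg.extract_promoters(
        out / "tss.bed", out / "genome.fasta", upstream, downstream
    )
    motifs = reg.read_jaspar(
        out / "motifs.jaspar", block.get("motif_pseudocount", 0.01)
    )
    policy = (block["threshold_kind"], block["threshold_value"])
    regmap = reg.build_regulon_map(promoters, motifs, policy)
    reg.write_regulons_tsv(regmap, out / "regulons.tsv")
    reg.write_regulons_gmt(regmap, out / "regulons.gmt")
    record("regulon", out / "regulons.tsv", out / "regulons.gmt")
    applied["regulon"] = {
        "upstream": upstream,
        "downstream": downstream,
        "threshold": list(policy),
    }


def _stage_integrate(config, out: Path, record, applied) -> None:
    summary = pd.read_csv(out / "group_summary.tsv", sep="\t")
    de = pd.read_csv(out / "de_results.tsv", sep="\t").set_index("gene")
    regmap = reg.RegulonMap.from_frame(
        pd.read_csv(out / "regulons.tsv", sep="\t")
    )
    contrast_groups = sorted(summary["group"].unique())
    summary_one = (
        summary[summary["group"] == contrast_groups[0]]
        if contrast_groups
        else summary
    )
    table = integ.integrate(
        summary_one,
        de,
        regmap,
        deg_classes=de["deg_class"],
        discordant_multiplier=config["integrate"]["discordant_multiplier"],
    )
    _write_tsv(table, out / "integration.tsv")
    _write_tsv(
        table[["tf_id", "activity_log2fc", "mean_target_log2fc"]],
        out / "activity_vs_targets.tsv",
    )
    _write_tsv(
        table[["rank", "tf_id", "driver_score", "enrichment_p", "shift_p"]],
        out / "drivers.tsv",
    )
    record(
        "integrate",
        out / "integration.tsv",
        out / "activity_vs_targets.tsv",
        out / "drivers.tsv",
    )
    applied["integrate"] = dict(config["integrate"])
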