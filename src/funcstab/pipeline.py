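"""End-to-end orchestration of the biodiversity-loss analysis.

One :class:`RunConfig` drives the whole sequence: ingest or simulate a
joint profile, build the nested extinction series, compute beta-diversity
statistics for taxonomy and function, the function-specific response
panel, and per-level co-occurrence networks, then write a deterministic
report bundle (every table carries a comment header naming its stage and
parameters; a manifest records the config hash, seed and file checksums).
Two runs with the same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, betadiv, extinction, function_response, network
from .errors import ContractError
from .io_profiles import (
    AbundanceTable,
    LinkedProfile,
    project,
    read_linked_profile,
    to_relative_abundance,
)
from .synthetic_data import SyntheticConfig, generate_community

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str
    input_path: str | None = None  # long-format TSV; mutually exclusive with synthetic
    synthetic: SyntheticConfig | None = None
    level_sizes: list[int] | None = None  # default: all/8/5/2/1 clipped
    permutations: int = 999
    seed: int = 0
    dominance_cutoff_trend: float = 0.01  # "dominant" categories for trends/heatmap
    dominance_cutoff_stats: float = 0.005  # wider set for the statistics panel
    network: network.NetworkConfig = field(default_factory=network.NetworkConfig)
    taxonomy_network_level: str = "genus"
    function_network_level: str = "level3"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_path or synthetic must be set")


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file mirroring the dataclass fields."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "synthetic" in raw and raw["synthetic"] is not None:
        raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
    if "network" in raw and raw["network"] is not None:
        net = dict(raw["network"])
        if "scan_range" in net:
            net["scan_range"] = tuple(net["scan_range"])
        raw["network"] = network.NetworkConfig(**net)
    return RunConfig(**raw)


def _config_fingerprint(config: RunConfig) -> str:
    def encode(obj):
        if dataclasses.is_dataclass(obj):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    fields = encode(config)
    fields.pop("out_dir", None)  # output location does not determine the analysis
    blob = json.dumps(fields, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_table(df: pd.DataFrame, path: Path, stage: str, params: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# stage: {stage}; params: {params}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g", lineterminator="\n")


def _load_profile(config: RunConfig) -> LinkedProfile:
    if config.synthetic is not None:
        logger.info("generating synthetic community (seed=%d)", config.synthetic.seed)
        return generate_community(config.synthetic)
    return read_linked_profile(config.input_path)


def _stack_levels(
    tables: dict[str, dict[str, AbundanceTable]], kind: str
) -> tuple[AbundanceTable, list[str]]:
    """Concatenate per-level relative tables; loss level becomes the factor."""
    blocks, labels = [], []
    feature_union: list[str] = []
    rel = {}
    for name, per_kind in tables.items():
        t = to_relative_abundance(per_kind[kind])
        rel[name] = t
        for f in t.features:
            if f not in feature_union:
                feature_union.append(f)
    for name, t in rel.items():
        vals = t.values.reindex(columns=feature_union, fill_value=0.0)
        vals.index = [f"{name}:{s}" for s in vals.index]
        blocks.append(vals)
        labels.extend([name] * len(vals))
    first = next(iter(tables.values()))[kind]
    stacked = AbundanceTable(
        values=pd.concat(blocks), kind=kind, level=first.level, relative=True
    )
    return stacked, labels


def run(config: RunConfig, dry_run: bool = False) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out_dir = Path(config.out_dir)
    if dry_run:
        if config.input_path is not None and not Path(config.input_path).exists():
            raise FileNotFoundError(config.input_path)
        logger.info("dry run: config valid")
        return {"config_hash": _config_fingerprint(config), "dry_run": True}
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_hash": _config_fingerprint(config), "seed": config.seed}

    profile = _load_profile(config)
    ranking = extinction.rank_phyla(profile)
    levels = extinction.default_levels(ranking, config.level_sizes)
    level_names = [lv.name for lv in levels]
    logger.info("loss levels: %s", {lv.name: len(lv.retained_phyla) for lv in levels})

    # -- extinction series ----------------------------------------------------
    report, tables = extinction.loss_series(profile, levels)
    trend_rows = [
        {"kind": kind, "quantity": q, "r": res.r, "r2": res.r2, "p": res.p}
        for q, store in (("S", report.s_trend), ("N", report.n_trend))
        for kind, res in store.items()
    ]
    _write_table(report.table, out_dir / "loss_report.tsv", "extinction.loss_series",
                 f"levels={level_names}")
    if trend_rows:
        _write_table(pd.DataFrame(trend_rows), out_dir / "loss_trends.tsv",
                     "extinction.loss_series", "pearson S,N vs level index")
    results["loss_report"] = "loss_report.tsv"

    # -- beta-diversity: taxonomy vs function ---------------------------------
    enough_groups = len(levels) >= 2 and all(
        len(per_kind["taxonomy"].samples) >= 2 for per_kind in tables.values()
    )
    sim_rows = []
    for kind in ("taxonomy", "function"):
        stacked, labels = _stack_levels(tables, kind)
        dist = betadiv.bray_curtis(stacked, relative=False)
        for name in level_names:
            idx = np.flatnonzero(np.asarray(labels) == name)
            if len(idx) >= 2:
                sim_rows.append({
                    "kind": kind, "level": name,
                    "mean_bray_curtis_similarity_pct":
                        dist.submatrix(idx).mean_offdiag_similarity_pct(),
                })
        if not enough_groups:
            logger.info("beta-diversity stage skipped for %s: fewer than two "
                        "loss levels or too few samples", kind)
            continue
        ord_res = betadiv.pcoa(dist, n_axes=2)
        coords = ord_res.coordinates.reset_index()
        coords["level"] = labels
        _write_table(coords, out_dir / f"pcoa_{kind}.tsv", "betadiv.pcoa",
                     f"axes=2; pct_variation={ord_res.percent_variation[:2].round(4).tolist()}")
        try:
            main = betadiv.permanova(dist, labels, config.permutations, seed=config.seed)
        except ContractError as exc:
            logger.warning("PERMANOVA skipped for %s: %s", kind, exc)
            continue
        pairs = betadiv.permanova_pairwise(dist, labels, config.permutations,
                                           seed=config.seed)
        main_df = pd.DataFrame([{
            "test": "main", "group_a": "", "group_b": "",
            "statistic": main.pseudo_F, "statistic_name": "pseudo_F",
            "df_between": main.df_between, "df_within": main.df_within,
            "R2": main.R2, "p": main.p,
        }])
        pair_df = pd.DataFrame([{
            "test": "pairwise", "group_a": r.group_a, "group_b": r.group_b,
            "statistic": r.pseudo_t, "statistic_name": "pseudo_t",
            "df_between": 1, "df_within": "", "R2": "", "p": r.p,
        } for r in pairs])
        _write_table(pd.concat([main_df, pair_df], ignore_index=True),
                     out_dir / f"permanova_{kind}.tsv", "betadiv.permanova",
                     f"permutations={config.permutations}; seed={config.seed}")
        results[f"permanova_{kind}"] = {"pseudo_F": main.pseudo_F, "R2": main.R2,
                                        "p": main.p}
    _write_table(pd.DataFrame(sim_rows), out_dir / "similarity_summary.tsv",
                 "betadiv.bray_curtis", "within-level mean pairwise similarity")

    # -- function-specific responses ------------------------------------------
    l1_tables = {
        lv.name: to_relative_abundance(
            project(extinction.apply_loss_level(profile, lv), "function", "level1")
        )
        for lv in levels
    }
    trend, dominant = function_response.category_trends(
        l1_tables, config.dominance_cutoff_trend
    )
    _, stats_set = function_response.category_trends(
        l1_tables, config.dominance_cutoff_stats
    )
    if enough_groups and len(levels) >= 2:
        anova = function_response.anova_per_category(l1_tables, categories=stats_set)
        fn_tables = {
            name: to_relative_abundance(per_kind["function"])
            for name, per_kind in tables.items()
        }
        category_of = {fn: lin[2] for fn, lin in profile.function_map.items()}
        within = function_response.within_category_permanova(
            fn_tables, category_of, config.permutations, seed=config.seed,
            categories=stats_set,
        )
        overall = trend.mean(axis=1)
        resp = pd.DataFrame({
            "category": stats_set,
            "mean_relative_abundance": [overall[c] for c in stats_set],
            "anova_F": [anova.loc[c, "F"] for c in stats_set],
            "anova_p": [anova.loc[c, "p"] for c in stats_set],
            "within_pseudo_F": [within[c].pseudo_F if c in within else np.nan
                                for c in stats_set],
            "within_p": [within[c].p if c in within else np.nan for c in stats_set],
        })
        _write_table(resp, out_dir / "category_response.tsv",
                     "function_response", f"cutoff={config.dominance_cutoff_stats}")
        try:
            corr = function_response.abundance_response_correlation(
                overall[stats_set], resp.set_index("category")["within_pseudo_F"]
            )
            results["abundance_response_correlation"] = {
                "r": corr.r, "p": corr.p, "n": corr.n
            }
        except ContractError as exc:
            logger.info("abundance-response correlation skipped: %s", exc)
    else:
        logger.info("function-response statistics skipped: fewer than two loss levels")
    if len(dominant) >= 2 and len(levels) >= 2:
        heat = function_response.heatmap_cluster(trend.loc[dominant])
        _write_table(heat.matrix.reset_index(), out_dir / "heatmap_matrix.tsv",
                     "function_response.heatmap_cluster",
                     f"cutoff={config.dominance_cutoff_trend}; row_order={heat.row_order}")
        link_df = pd.DataFrame(heat.linkage,
                               columns=["child_a", "child_b", "distance", "size"])
        _write_table(link_df, out_dir / "linkage.tsv",
                     "function_response.heatmap_cluster", "average linkage, Spearman distance")

    # -- co-occurrence networks per level --------------------------------------
    net_rows = []
    genus_phylum = profile.taxonomy_map
    l3_category = {}
    for fn, (l3, l2, l1) in profile.function_map.items():
        l3_category[l3] = l1
    for lv in levels:
        sub = extinction.apply_loss_level(profile, lv)
        specs = [
            ("taxonomy", config.taxonomy_network_level, genus_phylum),
            ("function", config.function_network_level, l3_category),
        ]
        for kind, net_level, classif in specs:
            table = to_relative_abundance(project(sub, kind, net_level))
            try:
                prepared = network.prepare_matrix(table, config.network)
                corr_m = network.correlation_matrix(prepared)
                s_t = network.select_threshold(corr_m, config.network)
                net_res = network.build_network(corr_m, s_t, classif)
            except ContractError as exc:
                logger.warning("network skipped (%s, level %s): %s", kind, lv.name, exc)
                continue
            network.export_cytoscape(net_res, out_dir / "networks",
                                     prefix=f"{kind}_{lv.name}")
            net_rows.append({"kind": kind, "level": lv.name, "S_t": s_t,
                             **net_res.indexes})
    if net_rows:
        _write_table(pd.DataFrame(net_rows), out_dir / "network_indexes.tsv",
                     "network.build_network",
                     f"method={config.network.threshold_method}")
        results["network_indexes"] = "network_indexes.tsv"

    # -- manifest --------------------------------------------------------------
    manifest = {
        "config_hash": results["config_hash"],
        "seed": config.seed,
        "version": __version__,
        "files": {
            str(p.relative_to(out_dir)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out_dir.rglob("*.tsv"))
        },
        "summary": {k: v for k, v in results.items()
                    if k not in ("config_hash", "seed")},
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
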