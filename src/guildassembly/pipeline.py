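"""End-to-end orchestration: simulate or ingest -> partition -> preprocess ->
distances -> beta-deviation -> attribution, from one validated config.

Each depth layer x guild stratum is analysed independently in a fixed order;
all outputs land under a run directory with a deterministic manifest
(package version, settings, seeds, input hashes) so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from contextlib import contextmanager
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .distances import (bray_curtis_frame, geographic_distance,
                        standardized_euclidean_1d)
from .errors import GuildAssemblyError, ValidationError
from .guild_partition import partition_table
from .matrix_stats import (category_contrast, forward_select_mrm, mantel,
                           nmds, partial_mantel, permanova,
                           variation_partitioning)
from .null_model import beta_deviation, mean_deviation_test
from .preprocess import (TransformScheme, apply_transforms,
                         community_weighted_mean, rarefy)
from .synthetic_data import AssemblyScenario, assemble_communities, simulate_pool
from .tabular_io import (DistanceMatrix, OtuTable, read_annotation,
                         read_metadata, read_otu_table, read_plant_community,
                         read_trait_table, write_distance_matrix,
                         write_otu_table)

__all__ = ["run_pipeline"]

logger = logging.getLogger("guildassembly")

_CWM_TRAITS = ("SRL", "SLA", "RCC")
_EDAPHIC_PREDICTORS = ("SM", "SEC", "MGWD")


@contextmanager
def _stage(name: str, detail: str = ""):
    logger.info("stage %s%s", name, f" [{detail}]" if detail else "")
    try:
        yield
    except GuildAssemblyError as exc:
        raise GuildAssemblyError(
            f"stage {name!r} failed"
            + (f" on {detail}" if detail else "") + f": {exc}") from exc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_dataset(config: dict):
    """Return (otu_table, annotation, metadata, plant_community, traits,
    scenario-or-None, input hash map)."""
    hashes: dict[str, str] = {}
    if config.get("simulate") is not None:
        sim = dict(config["simulate"])
        n_otus = sim.pop("n_otus", 300)
        sigma = sim.pop("lognormal_sigma", 1.5)
        sim.setdefault("seed", config["seed"])
        scenario = AssemblyScenario.from_dict(sim)
        ss = np.random.SeedSequence(scenario.seed)
        pool = simulate_pool(n_otus, sigma,
                             seed=int(ss.spawn(1)[0].generate_state(1)[0]),
                             env_range=scenario.env_gradient_range)
        ds = assemble_communities(pool, scenario)
        return (ds.otu_table, ds.annotation, ds.metadata, ds.plant_community,
                ds.trait_table, scenario, hashes)
    paths = {k: Path(v) for k, v in config["inputs"].items()}
    for key, path in paths.items():
        hashes[key] = _sha256(path)
    table = read_otu_table(paths["otu_table"])
    annotation = read_annotation(paths["annotation"])
    metadata = read_metadata(paths["metadata"])
    community = read_plant_community(paths["plant_community"])
    traits = read_trait_table(paths["trait_table"])
    return table, annotation, metadata, community, traits, None, hashes


def _expand_quadrat_matrix(dq: DistanceMatrix, metadata: pd.DataFrame
                           ) -> DistanceMatrix:
    """Lift a quadrat-level distance matrix to the sample level."""
    qidx = {lab: k for k, lab in enumerate(dq.labels)}
    missing = sorted(set(metadata["quadrat_id"]) - set(qidx))
    if missing:
        raise ValidationError(f"quadrats without plant data: {missing[:5]}")
    rows = [qidx[q] for q in metadata["quadrat_id"]]
    vals = dq.values[np.ix_(rows, rows)]
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(tuple(metadata["sample_id"]), vals,
                          signed=dq.signed)


def _build_predictors(metadata: pd.DataFrame, community: pd.DataFrame,
                      traits: pd.DataFrame, scheme: TransformScheme
                      ) -> tuple[dict[str, DistanceMatrix], DistanceMatrix,
                                 pd.DataFrame]:
    """Sample-level predictor distance matrices plus per-sample attributes."""
    meta_t = apply_transforms(metadata, scheme)
    traits_t = apply_transforms(traits, scheme)
    attributes = pd.DataFrame(index=metadata.index)
    predictors: dict[str, DistanceMatrix] = {}
    pcd_q = bray_curtis_frame(community)
    predictors["PCD"] = _expand_quadrat_matrix(pcd_q, metadata)
    for trait in _CWM_TRAITS:
        if trait not in traits_t.columns:
            continue
        cwm = community_weighted_mean(community, traits_t, trait)
        per_sample = metadata["quadrat_id"].map(cwm)
        attributes[trait] = per_sample
        predictors[trait] = standardized_euclidean_1d(
            pd.Series(per_sample.to_numpy(), index=metadata["sample_id"]))
    if "FRB" in metadata.columns:
        attributes["FRB"] = metadata["FRB"]
        predictors["FRB"] = standardized_euclidean_1d(
            pd.Series(metadata["FRB"].to_numpy(), index=metadata["sample_id"]))
    for var in _EDAPHIC_PREDICTORS:
        if var in meta_t.columns:
            predictors[var] = standardized_euclidean_1d(
                pd.Series(meta_t[var].to_numpy(), index=metadata["sample_id"]))
    space = geographic_distance(metadata)
    return predictors, space, attributes


def _analyse_stratum(name: str, table: OtuTable, metadata: pd.DataFrame,
                     predictors: Mapping[str, DistanceMatrix],
                     space: DistanceMatrix, attributes: pd.DataFrame,
                     config: dict, seed: int, out_dir: Path) -> dict:
    """Full per-stratum analysis; returns the JSON-ready summary."""
    warnings_log: list[str] = []
    totals = table.row_sums()
    keep = [s for s, t in zip(table.sample_ids, totals) if t > 0]
    if len(keep) < len(table.sample_ids):
        dropped = sorted(set(table.sample_ids) - set(keep))
        warnings_log.append(f"dropped {len(dropped)} zero-count sample(s): "
                            f"{dropped[:5]}")
        table = table.select_samples(keep)
    if table.n_samples < 4 or table.n_otus < 2:
        return {"skipped": True,
                "reason": f"too small ({table.n_samples} samples x "
                          f"{table.n_otus} OTUs)",
                "warnings": warnings_log}
    labels = table.sample_ids
    preds = {k: v.reorder(labels) for k, v in predictors.items()}
    geo = space.reorder(labels)
    meta = metadata.loc[list(labels)]
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(6)]

    with _stage("beta_deviation", name):
        bd = beta_deviation(table, n_null=config["n_null"],
                            mode=config["deviation_mode"], seed=seeds[0])
        if bd.flagged:
            warnings_log.append(f"{len(bd.flagged)} pair(s) with undefined "
                                "ses deviation")
        test = mean_deviation_test(bd)
    with _stage("mantel", name):
        mantel_table = {
            pname: vars(mantel(bd.deviation, pm, n_perm=config["n_perm"],
                               seed=seeds[1]))
            for pname, pm in preds.items()}
        mantel_table["space"] = vars(mantel(bd.deviation, geo,
                                            n_perm=config["n_perm"],
                                            seed=seeds[1]))
        partial_table = {
            pname: vars(partial_mantel(bd.deviation, pm, geo,
                                       n_perm=config["n_perm"], seed=seeds[2],
                                       controlled_label="space"))
            for pname, pm in preds.items()}
    with _stage("mrm", name):
        candidates = dict(preds)
        candidates["space"] = geo
        fsm = forward_select_mrm(bd.deviation, candidates,
                                 alpha=config["alpha"],
                                 n_perm=config["n_perm"], seed=seeds[3])
    with _stage("vpa", name):
        vpa = variation_partitioning(bd.deviation, env=preds,
                                     space={"space": geo})
    with _stage("ordination", name):
        nm = nmds(bd.observed_beta, k=2, n_starts=10, seed=seeds[4])
        groups = meta["vegetation_type"].tolist()
        counts = pd.Series(groups).value_counts()
        if len(counts) >= 2 and counts.min() >= 2:
            pmv = vars(permanova(bd.observed_beta, groups,
                                 n_perm=config["n_perm"], seed=seeds[5]))
        else:
            pmv = None
            warnings_log.append("PERMANOVA skipped: vegetation groups too small")
    with _stage("contrasts", name):
        contrasts = {}
        for attr, bins in (("SRL", 3), ("FRB", 2)):
            if attr not in attributes.columns:
                continue
            series = pd.Series(attributes.loc[list(labels), attr].to_numpy(),
                               index=list(labels))
            c = category_contrast(bd.deviation, series, n_bins=bins,
                                  alpha=config["alpha"])
            if c.excluded:
                warnings_log.append(
                    f"contrast {attr}: bins excluded {list(c.excluded)}")
            contrasts[attr] = {
                "bins": list(c.bin_labels),
                "stats": c.bin_stats,
                "pairwise_p": {f"{a}|{b}": p
                               for (a, b), p in c.pairwise_p.items()},
                "letters": c.letters,
                "excluded": list(c.excluded),
            }

    out_dir.mkdir(parents=True, exist_ok=True)
    write_distance_matrix(bd.deviation, out_dir / "deviation.tsv")
    write_distance_matrix(bd.observed_beta, out_dir / "observed_beta.tsv")
    nm.coords.to_csv(out_dir / "nmds_coords.tsv", sep="\t",
                     float_format="%.10g")
    summary = {
        "stratum": name,
        "n_samples": table.n_samples,
        "n_otus": table.n_otus,
        "deviation_mode": bd.mode,
        "n_null": bd.n_null,
        "mean_deviation_test": test,
        "mantel": mantel_table,
        "partial_mantel": partial_table,
        "mrm_forward": {
            "selected": list(fsm.selected),
            "coefficients": fsm.coefficients,
            "r_squared": fsm.r_squared,
            "p_per_predictor": fsm.p_per_predictor,
            "p_model": fsm.p_model,
            "selection_path": list(fsm.selection_path),
        },
        "vpa": {**vpa.fractions(), "r2_full": vpa.r2_full,
                "r2_env": vpa.r2_env, "r2_space": vpa.r2_space},
        "nmds_stress": nm.stress,
        "permanova": pmv,
        "contrasts": contrasts,
        "warnings": warnings_log,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    return summary


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Run the full analysis described by ``config``; returns the report."""
    out = Path(out_dir if out_dir is not None else config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config["seed"])
    rarefy_seed = int(master.spawn(1)[0].generate_state(1)[0])

    with _stage("load"):
        (table, annotation, metadata, community, traits, scenario,
         hashes) = _load_dataset(config)
    if scenario is not None:
        from .synthetic_data import SyntheticDataset
        sim_dir = out / "simulated_inputs"
        ds = SyntheticDataset(table, annotation, metadata, community, traits,
                              scenario)
        for key, path in ds.write(sim_dir).items():
            hashes[key] = _sha256(path)

    depths = ([config["depth_layer"]] if config["depth_layer"] != "both"
              else sorted(set(metadata["depth_layer"])))
    scheme = TransformScheme(
        sqrt_vars=frozenset(config["transforms"]["sqrt"]),
        log10_vars=frozenset(config["transforms"]["log10"]))
    report: dict = {"strata": {}, "warnings": []}

    for depth in depths:
        meta_d = metadata[metadata["depth_layer"] == depth]
        if meta_d.empty:
            report["warnings"].append(f"no samples at depth {depth!r}")
            continue
        with _stage("subset", depth):
            table_d = table.select_samples(list(meta_d["sample_id"]))
        with _stage("rarefy", depth):
            depth_cfg = config["rarefy_depth"]
            rare_to = (int(table_d.row_sums().min()) if depth_cfg == "auto"
                       else int(depth_cfg))
            table_d = rarefy(table_d, rare_to, seed=rarefy_seed)
        with _stage("partition", depth):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                parts = partition_table(table_d, annotation)
        with _stage("predictors", depth):
            preds, space, attributes = _build_predictors(
                meta_d, community.loc[sorted(set(meta_d["quadrat_id"]))],
                traits, scheme)
        for guild in config["guilds"]:
            if guild not in parts:
                raise ValidationError(f"unknown guild {guild!r} in config")
            stratum = f"{depth}/{guild}"
            stratum_hash = int.from_bytes(
                hashlib.sha256(stratum.encode()).digest()[:4], "little")
            stratum_seed = int(np.random.SeedSequence(
                (config["seed"], stratum_hash)).generate_state(1)[0])
            summary = _analyse_stratum(
                stratum, parts[guild], meta_d, preds, space, attributes,
                config, stratum_seed, out / depth / guild)
            report["strata"][stratum] = summary

    manifest = {
        "package": "guildassembly",
        "version": __version__,
        "config": _jsonable({k: v for k, v in config.items()}),
        "input_hashes": hashes,
        "rarefy_seed": rarefy_seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
    _write_report_md(report, out / "report.md")
    report["out_dir"] = str(out)
    return report


def _write_report_md(report: dict, path: Path) -> None:
    lines = ["# Run report", ""]
    for stratum, summary in report["strata"].items():
        lines.append(f"## {stratum}")
        if summary.get("skipped"):
            lines.append(f"Skipped: {summary['reason']}")
            lines.append("")
            continue
        t = summary["mean_deviation_test"]
        lines.append(f"- samples: {summary['n_samples']}, "
                     f"OTUs: {summary['n_otus']}")
        lines.append(f"- mean deviation ({summary['deviation_mode']}, "
                     f"{summary['n_null']} nulls): {t['mean']:.3f} "
                     f"(t={t['t']:.2f}, p={t['p']:.3g})")
        sel = summary["mrm_forward"]["selected"]
        lines.append(f"- MRM forward selection: "
                     f"{', '.join(sel) if sel else '(none)'} "
                     f"(R2={summary['mrm_forward']['r_squared']:.3f})")
        vpa = summary["vpa"]
        lines.append(f"- VPA: pure env {vpa['pure_env']:.3f}, "
                     f"pure space {vpa['pure_space']:.3f}, "
                     f"shared {vpa['shared']:.3f}, "
                     f"unexplained {vpa['unexplained']:.3f}")
        for w in summary["warnings"]:
            lines.append(f"- warning: {w}")
        lines.append("")
    if report["warnings"]:
        lines.append("## Warnings")
        lines.extend(f"- {w}" for w in report["warnings"])
        lines.append("")
    path.write_text("\n".join(lines))
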