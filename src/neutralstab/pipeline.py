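"""End-to-end orchestration: simulate or ingest, transform, fit, report.

A run is fully determined by its :class:`PipelineConfig` plus the global
seed; every stochastic stage derives its own seed from the root seed, the
effective configuration is persisted next to the outputs, and re-running
into the same output directory recomputes only stages whose inputs changed
(stage inputs are hashed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import avd as avd_mod
from . import multivariate as mv
from . import ncm as ncm_mod
from .datamodel import (
    ValidationError,
    filter_taxa,
    nutrient_change,
    rarefy,
    read_count_table,
    read_sample_frame,
    read_taxonomy_table,
    to_relative,
    write_count_table,
    write_sample_frame,
    write_taxonomy_table,
)
from .simulate import StudyDesignConfig, simulate_study

SCHEMA_VERSION = 1
log = logging.getLogger("neutralstab")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    simulate: bool = False
    simulate_kwargs: dict = field(default_factory=dict)
    filter_min_total: int = 2
    filter_min_prevalence: float = 0.0
    rarefy_depth: str | int | None = "auto"
    ncm_split_by: tuple = ("group",)
    ncm_detection_limit: int = 1
    ncm_ci: float = 0.95
    avd_strata: tuple = ("group", "lifestyle")
    avd_sd_ddof: int = 1
    avd_zero_variance: str = "exclude"
    permanova_terms: tuple = (
        "group", "time", "lifestyle", "group:time", "group:lifestyle",
        "time:lifestyle", "group:time:lifestyle",
    )
    n_perm: int = 999
    nutrient_sign: str = "final-initial"
    stages: tuple = ("data", "ncm", "avd", "multivariate")
    seed: int = 0
    out_dir: str = "results"

    def validate(self) -> None:
        if not self.simulate and (self.counts_path is None
                                  or self.metadata_path is None):
            raise ValidationError(
                "config needs either simulate=True or counts_path + metadata_path"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("ncm_split_by", "avd_strata", "permanova_terms", "stages"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True,
                               default=_json_default) + "\n")


def _config_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = []
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(out_dir / "run.log")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def _load_inputs(cfg: PipelineConfig, out_dir: Path):
    if cfg.simulate:
        sim_cfg = StudyDesignConfig(
            **{**cfg.simulate_kwargs, "seed": stage_seed(cfg.seed, "simulate")}
        )
        table, frame, truth = simulate_study(sim_cfg)
        write_count_table(table, out_dir / "counts.tsv")
        write_sample_frame(frame, out_dir / "metadata.tsv")
        write_taxonomy_table(truth["taxonomy"], out_dir / "taxonomy.tsv")
        taxonomy = truth["taxonomy"]
        truth_out = {
            "group_nm": truth["group_nm"],
            "labels": truth["labels"].to_dict(),
        }
        _dump_json(truth_out, out_dir / "truth.json")
        return table, frame, taxonomy, truth
    table = read_count_table(cfg.counts_path)
    frame = read_sample_frame(cfg.metadata_path)
    taxonomy = (read_taxonomy_table(cfg.taxonomy_path)
                if cfg.taxonomy_path else None)
    return table, frame, taxonomy, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write a report bundle.

    Returns the report dictionary; writes report.json, per-stage TSVs and
    the effective config into ``config.out_dir``. Deterministic for a fixed
    config (byte-identical report.json on re-run).
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _config_logging(out_dir)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=_json_default)
    (out_dir / "config.yaml").write_text(
        yaml.safe_dump(json.loads(cfg_json), sort_keys=True))

    hash_path = out_dir / ".stage_hashes.json"
    old_hashes = (json.loads(hash_path.read_text())
                  if hash_path.exists() else {})
    new_hashes = {}

    def stage_key(name: str, upstream: str = "") -> str:
        return hashlib.sha256(
            (cfg_json + "|" + name + "|" + upstream).encode()).hexdigest()

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s)
                        for s in ("simulate", "rarefy", "multivariate")},
    }

    # ---- data stage ------------------------------------------------------
    log.info("stage data: loading inputs")
    table, frame, taxonomy, truth = _load_inputs(config, out_dir)
    frame = frame.aligned_to(table)
    if any(c in frame.data.columns for c in ("NH4N", "NO2N", "NO3N", "PO4P")):
        frame = nutrient_change(frame, sign=config.nutrient_sign)
    table = filter_taxa(table, config.filter_min_total,
                        config.filter_min_prevalence)
    if config.rarefy_depth is not None:
        depth = (int(table.sample_totals().min())
                 if config.rarefy_depth == "auto" else int(config.rarefy_depth))
        rare = rarefy(table, depth, stage_seed(config.seed, "rarefy"))
    else:
        depth = None
        rare = table
    data_hash = stage_key("data")
    new_hashes["data"] = data_hash
    report["data"] = {
        "n_zotus": table.n_zotus,
        "n_samples": table.n_samples,
        "rarefy_depth": depth,
    }

    # ---- NCM stage -------------------------------------------------------
    if "ncm" in config.stages:
        key = stage_key("ncm", data_hash)
        out_file = out_dir / "ncm.json"
        if old_hashes.get("ncm") == key and out_file.exists():
            log.info("stage ncm: inputs unchanged, reusing %s", out_file)
            report["ncm"] = json.loads(out_file.read_text())
        else:
            log.info("stage ncm: fitting per %s", "/".join(config.ncm_split_by))
            ncm_report = {}
            for split_key, sub in frame.data.groupby(
                    list(config.ncm_split_by), observed=True, sort=False):
                label = (split_key if isinstance(split_key, str)
                         else "_".join(str(v) for v in split_key))
                sub_table = table.subset_samples(sub.index)
                fit = ncm_mod.fit_ncm(sub_table, d=config.ncm_detection_limit,
                                      ci_level=config.ncm_ci)
                summary = ncm_mod.partition_abundance(fit)
                entry = {
                    "Nm": fit.nm, "m": fit.m, "N": fit.n_reads,
                    "r_squared": fit.r_squared,
                    "partition_counts": fit.partition_counts(),
                    "cumulative_abundance": {
                        part: summary.cumulative_abundance(part)
                        for part in ncm_mod.PARTITIONS},
                }
                if taxonomy is not None:
                    fam = ncm_mod.partition_by_family(fit, taxonomy)
                    top = fam.table.reset_index().head(30)
                    entry["family_partitions"] = top.to_dict("records")
                ncm_report[label] = entry
                fit.per_zotu.to_csv(out_dir / f"ncm_per_zotu_{label}.tsv",
                                    sep="\t", lineterminator="\n")
            report["ncm"] = ncm_report
            _dump_json(ncm_report, out_file)
        new_hashes["ncm"] = key

    # ---- AVD stage -------------------------------------------------------
    if "avd" in config.stages:
        key = stage_key("avd", data_hash)
        out_file = out_dir / "avd.json"
        if old_hashes.get("avd") == key and out_file.exists():
            log.info("stage avd: inputs unchanged, reusing %s", out_file)
            report["avd"] = json.loads(out_file.read_text())
        else:
            log.info("stage avd: strata %s", "/".join(config.avd_strata))
            results, rep_avds = avd_mod.avd_by_stratum(
                rare, frame, strata=config.avd_strata,
                ddof=config.avd_sd_ddof,
                zero_variance=config.avd_zero_variance)
            avd_report = {
                "strata": [{"stratum": r.group, "k": r.k, "n": r.n,
                            "n_excluded": r.n_excluded, "avd": r.avd}
                           for r in results],
            }
            if len(rep_avds) and rep_avds["stratum"].nunique() >= 2:
                cmp_res = avd_mod.compare_avd(rep_avds)
                avd_report["anova_F"] = cmp_res.f_statistic
                avd_report["anova_p"] = cmp_res.p_value
                avd_report["letters"] = cmp_res.letters
            report["avd"] = avd_report
            _dump_json(avd_report, out_file)
            rep_avds.to_csv(out_dir / "avd_replicates.tsv", sep="\t",
                            index=False, lineterminator="\n")
        new_hashes["avd"] = key

    # ---- multivariate stage ---------------------------------------------
    if "multivariate" in config.stages:
        key = stage_key("multivariate", data_hash)
        out_file = out_dir / "multivariate.json"
        if old_hashes.get("multivariate") == key and out_file.exists():
            log.info("stage multivariate: inputs unchanged, reusing %s", out_file)
            report["multivariate"] = json.loads(out_file.read_text())
        else:
            mv_seed = stage_seed(config.seed, "multivariate")
            log.info("stage multivariate: %d permutations", config.n_perm)
            rel = to_relative(table)
            dm = mv.bray_curtis(rel)
            alpha = mv.alpha_diversity(table)
            alpha.to_csv(out_dir / "alpha.tsv", sep="\t", lineterminator="\n")
            perm = mv.permanova(dm, frame.data,
                                list(config.permanova_terms),
                                n_perm=config.n_perm, seed=mv_seed)
            anosim_res = mv.anosim(dm, frame.data["group"],
                                   n_perm=config.n_perm, seed=mv_seed)
            mrpp_res = mv.mrpp(dm, frame.data["group"],
                               n_perm=config.n_perm, seed=mv_seed)
            ord_res = mv.pcoa(dm)
            mantel_rows = []
            nutrient_cols = [c for c in frame.data.columns
                             if c.endswith("_change")
                             or c in ("NH4N", "NO2N", "NO3N", "PO4P",
                                      "n_oculata", "t_weissflogii")]
            for col in nutrient_cols:
                vals = frame.data[col].to_numpy(dtype=float)
                if np.isnan(vals).any() or np.ptp(vals) == 0:
                    continue
                env_d = np.abs(vals[:, None] - vals[None, :])
                env_dm = mv.DistanceMatrix(env_d, dm.sample_ids)
                row = {"factor": col}
                res = mv.mantel(dm, env_dm, n_perm=config.n_perm, seed=mv_seed)
                row["rho"] = res.statistic
                row["p"] = res.p_value
                for ls in ("PA", "FL"):
                    mask = (frame.data["lifestyle"] == ls).to_numpy()
                    if mask.sum() < 3:
                        continue
                    idx = np.flatnonzero(mask)
                    sub_dm = mv.DistanceMatrix(
                        dm.data[np.ix_(idx, idx)],
                        [dm.sample_ids[i] for i in idx])
                    sub_env = mv.DistanceMatrix(
                        env_d[np.ix_(idx, idx)],
                        [dm.sample_ids[i] for i in idx])
                    res_ls = mv.mantel(sub_dm, sub_env,
                                       n_perm=config.n_perm, seed=mv_seed)
                    row[f"rho_{ls}"] = res_ls.statistic
                    row[f"p_{ls}"] = res_ls.p_value
                mantel_rows.append(row)
            rda_report = None
            constraint_cols = [c for c in nutrient_cols
                               if not np.isnan(
                                   frame.data[c].to_numpy(dtype=float)).any()
                               and np.ptp(frame.data[c].to_numpy(dtype=float)) > 0]
            if constraint_cols:
                constraints = frame.data[constraint_cols].astype(float)
                # Hellinger-transformed abundances: the standard response
                # scale for RDA on community data
                hellinger = pd.DataFrame(
                    np.sqrt(rel.data.to_numpy().T), index=rel.sample_ids,
                    columns=rel.zotu_ids)
                try:
                    rda_ord, rda_test = mv.rda(hellinger, constraints,
                                               n_perm=config.n_perm,
                                               seed=mv_seed)
                    db_ord, db_test = mv.dbrda(dm, constraints,
                                               n_perm=config.n_perm,
                                               seed=mv_seed)
                    rda_ord.biplot_scores.to_csv(
                        out_dir / "rda.tsv", sep="\t", lineterminator="\n")
                    rda_report = {
                        "rda_constrained_proportion":
                            rda_ord.constrained_proportion,
                        "rda_F": rda_test.statistic,
                        "rda_p": rda_test.p_value,
                        "dbrda_constrained_proportion":
                            db_ord.constrained_proportion,
                        "dbrda_F": db_test.statistic,
                        "dbrda_p": db_test.p_value,
                        "constraints": constraint_cols,
                    }
                except ValidationError as exc:
                    log.warning("constrained ordination skipped: %s", exc)
            mantel_df = pd.DataFrame(mantel_rows)
            mantel_df.to_csv(out_dir / "mantel.tsv", sep="\t", index=False,
                             lineterminator="\n")
            perm.table.to_csv(out_dir / "permanova.tsv", sep="\t",
                              lineterminator="\n")
            pd.DataFrame(dm.data, index=dm.sample_ids,
                         columns=dm.sample_ids).to_csv(
                out_dir / "bray_curtis.tsv", sep="\t", lineterminator="\n")
            ord_res.coordinates.iloc[:, :4].to_csv(
                out_dir / "pcoa.tsv", sep="\t", lineterminator="\n")
            newick = mv.hclust_average(dm)
            (out_dir / "tree.nwk").write_text(newick + "\n")
            perm_records = [
                {k: (None if isinstance(v, float) and np.isnan(v) else v)
                 for k, v in rec.items()}
                for rec in perm.table.reset_index().to_dict("records")
            ]
            mv_report = {
                "permanova": perm_records,
                "anosim": {"R": anosim_res.statistic,
                           "p": anosim_res.p_value},
                "mrpp": {"delta": mrpp_res.statistic,
                         "A": mrpp_res.extras["A"],
                         "p": mrpp_res.p_value},
                "mantel": mantel_rows,
                "constrained_ordination": rda_report,
                "pcoa": {
                    "proportion_explained":
                        ord_res.proportion_explained[:4].tolist(),
                    "coordinates": {
                        sid: ord_res.coordinates.iloc[i, :2].tolist()
                        for i, sid in enumerate(dm.sample_ids)},
                },
            }
            report["multivariate"] = mv_report
            _dump_json(mv_report, out_file)
        new_hashes["multivariate"] = key

    _dump_json(new_hashes, hash_path)
    _dump_json(report, out_dir / "report.json")
    log.info("pipeline complete: %s", out_dir / "report.json")
    return report
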