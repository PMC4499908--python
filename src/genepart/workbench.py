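"""Pipeline orchestration: configuration, the pathway scan, and the
null-calibration run.

``run_pathway_scan`` wires the stages end to end: load -> MAF filter ->
marker/gene mapping -> GRMs -> one simple-model fit per trait ->
per-pathway partitioned fits -> random-gene-group null -> monotone
threshold curves -> dual criteria -> chi-square reference selection ->
Benjamini-Hochberg FDR -> TSV/JSON outputs.  Every random draw derives from
the master seed, and re-running a config reproduces the outputs
bit for bit.
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

from . import __version__
from .data import (
    DataError,
    filter_maf,
    read_gene_annotation,
    read_genotypes,
    read_pathway_map,
    read_phenotypes,
)
from .grm import build_full_grm, center_scale, partition_grms
from .mapping import focal_region_genes, map_markers_to_genes, pathway_marker_set
from .nulldist import (
    build_null_distribution,
    default_max_target,
    evaluate_criteria,
    fit_threshold_curve,
    pathway_pvalues,
    select_chi2_df,
)
from .reml import (
    FAILURE_FLAGS,
    fit_partitioned,
    fit_simple,
    h2_set,
    likelihood_ratio,
    qc_fit,
    residual_weights,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "run_pathway_scan", "run_null_calibration"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Flat, typed configuration for a scan or calibration run."""

    genotypes: str = ""
    genotype_format: str = "dosage_tsv"
    genes: str = ""
    genes_format: str = "tsv"
    pathways: str = ""
    pathways_format: str = "tsv"
    phenotypes: str = ""
    trait: str = ""
    maf: float = 0.01
    flank: int = 0
    focal_gene: str | None = None
    focal_window: int = 500_000
    n_null_groups: int = 1000
    max_target: int | None = None
    taus: tuple[float, ...] = (0.5, 0.95)
    lam: float | None = None
    df_policy: str = "auto"  # auto | chi2_df1 | chi2_df2 | mixture
    fdr_level: float = 0.10
    min_reliability: float = 0.01
    missing: str = "reject"
    seed: int | None = None
    out_dir: str | None = None

    def validate(self, need_pathways: bool = True) -> None:
        if self.seed is None:
            raise ConfigError("a master seed is mandatory for any sampling step")
        if not (0 <= self.maf < 0.5):
            raise ConfigError("maf must lie in [0, 0.5)")
        if self.flank < 0:
            raise ConfigError("flank must be non-negative")
        if self.n_null_groups < 1:
            raise ConfigError("n_null_groups must be positive")
        if self.df_policy not in ("auto", "chi2_df1", "chi2_df2", "mixture"):
            raise ConfigError(f"unknown df_policy {self.df_policy!r}")
        if not (0 < self.fdr_level < 1):
            raise ConfigError("fdr_level must lie in (0, 1)")
        paths = [("genotypes", self.genotypes), ("genes", self.genes), ("phenotypes", self.phenotypes)]
        if need_pathways:
            paths.append(("pathways", self.pathways))
        for name, p in paths:
            if not p:
                raise ConfigError(f"missing required input path: {name}")
            probe = Path(p + ".bed") if name == "genotypes" and self.genotype_format == "plink" else Path(p)
            if not probe.exists():
                raise ConfigError(f"{name} file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "taus" in raw:
            raw["taus"] = tuple(raw["taus"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["taus"] = list(self.taus)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _load_stage(cfg: RunConfig, need_pathways: bool = True):
    """Load and align all inputs; returns the per-trait working set."""
    geno = read_genotypes(cfg.genotypes, cfg.genotype_format, missing=cfg.missing)
    geno = filter_maf(geno, cfg.maf)
    genes = read_gene_annotation(cfg.genes, cfg.genes_format)
    pmap = read_pathway_map(cfg.pathways, cfg.pathways_format) if need_pathways else None
    pheno = read_phenotypes(cfg.phenotypes)
    trait = cfg.trait or pheno.traits()[0]
    records = pheno.trait_frame(trait)
    keep = [i for i in geno.individual_ids if i in set(records["individual_id"])]
    if len(keep) < 3:
        raise DataError("fewer than 3 individuals with both genotype and phenotype")
    if len(keep) < geno.n_individuals:
        geno = geno.subset_individuals(keep)
    records = records.set_index("individual_id").loc[keep].reset_index()
    y = records["value"].to_numpy()
    rel = records["reliability"].to_numpy()
    weights = None if np.isnan(rel).all() else residual_weights(np.nan_to_num(rel, nan=cfg.min_reliability),
                                                                cfg.min_reliability)
    if np.isnan(rel).any() and not np.isnan(rel).all():
        log.warning("mixed missing/present reliabilities; missing set to the floor")
    index = map_markers_to_genes(geno, genes, cfg.flank)
    focal_genes = None
    if cfg.focal_gene:
        focal_genes = focal_region_genes(cfg.focal_gene, genes, cfg.focal_window)
    return geno, genes, pmap, trait, y, weights, index, focal_genes


def _fit_curves(null_df: pd.DataFrame, cfg: RunConfig, stratified: bool) -> dict:
    """Threshold curves per (statistic, tau, stratum)."""
    curves = {}
    strata = ["all"]
    if stratified:
        ok = null_df.loc[~null_df["excluded"], "contains_focal"]
        if ok.sum() >= 50 and (~ok).sum() >= 50:
            strata = ["focal", "non_focal"]
        else:
            log.warning("too few focal/non-focal null groups for stratified curves; using 'all'")
    for stat in ("lr", "h2_set"):
        for tau in cfg.taus:
            for stratum in strata:
                curves[(stat, tau, stratum)] = fit_threshold_curve(
                    null_df, statistic=stat, tau=tau, stratum=stratum, lam=cfg.lam
                )
    return curves


def _curve_for(curves: dict, stat: str, tau: float, contains_focal: bool):
    stratum = "all"
    if (stat, tau, "focal") in curves:
        stratum = "focal" if contains_focal else "non_focal"
    return curves[(stat, tau, stratum)]


def _metadata(cfg: RunConfig, trait: str, geno, index, extra: dict) -> dict:
    meta = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.seed,
        "trait": trait,
        "n_individuals": geno.n_individuals,
        "n_markers": geno.n_markers,
        "n_mapped_markers": index.n_mapped_markers,
    }
    meta.update(extra)
    return meta


def run_null_calibration(cfg: RunConfig):
    """Null table, threshold curves and chi-square reference for one trait.

    Returns (null_df, curves, selection, metadata) and, when ``out_dir`` is
    set, writes null_samples.tsv, curves.tsv and calibration_meta.json.
    """
    cfg.validate(need_pathways=False)
    geno, genes, _, trait, y, weights, index, focal_genes = _load_stage(cfg, need_pathways=False)
    w = center_scale(geno)
    max_target = cfg.max_target or default_max_target(index)
    null_df, simple = build_null_distribution(
        y, w, index, cfg.n_null_groups, cfg.seed, weights=weights,
        max_target=max_target, focal_genes=focal_genes,
    )
    curves = _fit_curves(null_df, cfg, stratified=focal_genes is not None)
    lrs = null_df.loc[~null_df["excluded"], "lr"].to_numpy()
    selection = select_chi2_df(lrs) if cfg.df_policy == "auto" else None
    meta = _metadata(cfg, trait, geno, index, {
        "max_target": max_target,
        "n_null_groups": cfg.n_null_groups,
        "n_excluded": int(null_df["excluded"].sum()),
        "simple_fit": {"sigma2_g": simple.sigma2_g, "sigma2_e": simple.sigma2_e, "loglik": simple.loglik},
        "df_selection": dataclasses.asdict(selection) if selection else cfg.df_policy,
    })
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        null_df.to_csv(out / "null_samples.tsv", sep="\t", index=False, float_format="%.10g")
        _write_curves(curves, out / "curves.tsv")
        (out / "calibration_meta.json").write_text(json.dumps(meta, indent=2, default=str))
    return null_df, curves, selection, meta


def run_pathway_scan(cfg: RunConfig):
    """Full competitive pathway scan for one trait.

    Returns (results_df, metadata); with ``out_dir`` set, also writes
    results.tsv, null_samples.tsv, curves.tsv and scan_meta.json.
    """
    cfg.validate(need_pathways=True)
    geno, genes, pmap, trait, y, weights, index, focal_genes = _load_stage(cfg, need_pathways=True)
    w = center_scale(geno)
    g_all = build_full_grm(w)
    simple = fit_simple(y, g_all, weights)
    max_target = cfg.max_target or default_max_target(index)

    rows = []
    for pid in sorted(pmap.pathways):
        row = {
            "pathway": pid, "trait": trait, "m_S": 0, "h2_set": np.nan, "lr": np.nan,
            "expected_h2": np.nan, "flags": "", "usable": False,
        }
        try:
            fs = pathway_marker_set(pid, pmap, index, focal_genes)
            if fs.m_S >= w.m:
                raise DataError("pathway covers every marker")
            gs, gn = partition_grms(w, fs, g_all)
            fit = fit_partitioned(y, gs, gn, weights)
            lrt = likelihood_ratio(fit, simple)
            fit.qc_flags |= lrt.qc_flags
            qc_fit(fit)
            row.update(
                m_S=fs.m_S,
                contains_focal=fs.contains_focal,
                h2_set=h2_set(fit),
                lr=lrt.lr,
                expected_h2=fs.m_S / w.m,
                sigma2_S=fit.sigma2_S,
                sigma2_notS=fit.sigma2_notS,
                sigma2_e=fit.sigma2_e,
                loglik=fit.loglik,
                flags=",".join(sorted(fit.qc_flags)),
                usable=not (fit.qc_flags & FAILURE_FLAGS),
            )
        except (DataError, KeyError) as exc:
            row["flags"] = f"error:{exc}"
            log.warning("pathway %s skipped: %s", pid, exc)
        rows.append(row)
    results = pd.DataFrame(rows)

    null_df, _ = build_null_distribution(
        y, w, index, cfg.n_null_groups, cfg.seed, weights=weights,
        max_target=max_target, focal_genes=focal_genes, simple_fit=simple, g_all=g_all,
    )
    curves = _fit_curves(null_df, cfg, stratified=focal_genes is not None)
    for i, row in results.iterrows():
        if not row["usable"]:
            results.loc[i, ["passes_lr95", "passes_h95"]] = pd.NA
            continue
        lr_c = _curve_for(curves, "lr", 0.95, bool(row.get("contains_focal", False)))
        h2_c = _curve_for(curves, "h2_set", 0.95, bool(row.get("contains_focal", False)))
        p_lr, p_h2 = evaluate_criteria(row["lr"], row["h2_set"], int(row["m_S"]), lr_c, h2_c)
        results.loc[i, "passes_lr95"] = p_lr
        results.loc[i, "passes_h95"] = p_h2

    null_lrs = null_df.loc[~null_df["excluded"], "lr"].to_numpy()
    if cfg.df_policy == "auto":
        selection = select_chi2_df(null_lrs)
    else:
        selection = select_chi2_df(null_lrs)
        selection.selected = cfg.df_policy
    usable = results.loc[results["usable"]]
    pv = pathway_pvalues(pd.Series(usable["lr"].to_numpy(), index=usable["pathway"]), selection, cfg.fdr_level)
    results = results.merge(pv[["pathway_id", "p_value", "q_value", "significant"]],
                            left_on="pathway", right_on="pathway_id", how="left").drop(columns=["pathway_id"])
    results = results.sort_values("pathway").reset_index(drop=True)

    meta = _metadata(cfg, trait, geno, index, {
        "max_target": max_target,
        "n_pathways": len(pmap.pathways),
        "n_usable_pathways": int(results["usable"].sum()),
        "n_null_groups": cfg.n_null_groups,
        "n_null_excluded": int(null_df["excluded"].sum()),
        "df_selection": dataclasses.asdict(selection),
        "simple_fit": {"sigma2_g": simple.sigma2_g, "sigma2_e": simple.sigma2_e, "loglik": simple.loglik},
    })
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.tsv", sep="\t", index=False, float_format="%.10g")
        null_df.to_csv(out / "null_samples.tsv", sep="\t", index=False, float_format="%.10g")
        _write_curves(curves, out / "curves.tsv")
        (out / "scan_meta.json").write_text(json.dumps(meta, indent=2, default=str))
    return results, meta


def _write_curves(curves: dict, path: Path) -> None:
    rows = []
    for (stat, tau, stratum), curve in sorted(curves.items(), key=str):
        grid = np.unique(np.round(np.linspace(curve.knots[0], curve.knots[-1], 50)))
        for s, v in zip(grid, curve(grid)):
            rows.append((stat, tau, stratum, curve.lam, int(s), v))
    pd.DataFrame(rows, columns=["statistic", "tau", "stratum", "lambda", "group_size", "threshold"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
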