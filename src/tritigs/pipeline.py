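"""End-to-end pipeline: simulate|load → qc → {ld, structure} → pheno → gs.

A single YAML config drives every stage; a master seed deterministically
spawns per-stage seeds so stages never share RNG state and reruns are
bit-identical.  Every artifact lands in the output directory and is listed
in a JSON manifest with its SHA-256 content hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from . import ld as tld
from . import qc as tqc
from . import structure as tstruct
from . import pheno as tpheno
from .cv import CVConfig, run_cv, summarize_cv
from .simulate import SimulationConfig, simulate_panel

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "demo_config_path"]

log = logging.getLogger("tritigs")

STAGES = ("simulate", "qc", "ld", "structure", "pheno", "gs")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with per-stage parameter blocks."""

    stages: tuple = STAGES
    outdir: str = "tritigs_out"
    seed: int = 0
    genotype_path: str | None = None
    marker_map_path: str | None = None
    trials_path: str | None = None
    pebv_path: str | None = None  # genotype->PEBV TSV, used if pheno is skipped
    sim: dict = field(default_factory=dict)
    qc: dict = field(default_factory=lambda: {
        "min_call_rate": 0.7, "min_maf": 0.05, "max_sample_missing": 0.3})
    ld: dict = field(default_factory=lambda: {
        "window_bp": 50_000, "bin_bp": 500, "cutoff": 0.1, "alpha": 0.05})
    structure: dict = field(default_factory=lambda: {
        "k_min": 1, "k_max": 10, "variance_target": 0.95, "n_starts": 20})
    pheno: dict = field(default_factory=lambda: {"model": "both"})
    gs: dict = field(default_factory=lambda: {
        "models": ["rrblup", "gblup", "gauss"],
        "train_sizes": [50, 100, 150, 200],
        "marker_counts": [200, 500, 1000],
        "n_iterations": 10, "fixed_train_size": 200})


def validate_config(raw) -> tuple:
    """Parse and validate raw YAML text / dict.

    Returns ``(PipelineConfig or None, list_of_violations)``; an empty raw
    config yields the defaults (simulate mode).  Violations are collected,
    not thrown, so a config can be fully linted in one pass.
    """
    if raw is None:
        data = {}
    elif isinstance(raw, dict):
        data = dict(raw)
    else:
        data = yaml.safe_load(raw) or {}
        if not isinstance(data, dict):
            return None, ["config must be a YAML mapping"]
    errors = []
    known = {f.name for f in dc_fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
        for k in unknown:
            data.pop(k)
    cfg = PipelineConfig(**{k: v for k, v in data.items()})
    cfg.stages = tuple(cfg.stages)
    bad = set(cfg.stages) - set(STAGES)
    if bad:
        errors.append(f"unknown stages: {sorted(bad)}")
    if not isinstance(cfg.seed, int) or cfg.seed < 0:
        errors.append("seed must be a non-negative integer")
    if not 0 <= cfg.qc.get("min_maf", 0.05) <= 0.5:
        errors.append("min_maf must lie in [0, 0.5] (MAF cannot exceed 0.5)")
    for key in ("min_call_rate", "max_sample_missing"):
        v = cfg.qc.get(key, 0.5)
        if not 0 <= v <= 1:
            errors.append(f"{key} must lie in [0, 1]")
    if cfg.ld.get("window_bp", 1) <= 0:
        errors.append("window_bp must be positive")
    if cfg.structure.get("k_min", 1) < 1:
        errors.append("k_min must be >= 1")
    if cfg.structure.get("k_max", 1) < cfg.structure.get("k_min", 1):
        errors.append("k_max must be >= k_min")
    if cfg.gs.get("n_iterations", 1) < 1:
        errors.append("n_iterations must be >= 1")
    if "simulate" not in cfg.stages:
        if any(s in cfg.stages for s in ("qc", "ld", "structure", "gs")) and not cfg.genotype_path:
            errors.append("genotype_path required when qc/ld/structure/gs run without simulate")
        if "pheno" in cfg.stages and not cfg.trials_path:
            errors.append("trials_path required when pheno runs without simulate")
        if cfg.genotype_path and not Path(cfg.genotype_path).exists():
            errors.append(f"genotype_path does not exist: {cfg.genotype_path}")
        if cfg.trials_path and not Path(cfg.trials_path).exists():
            errors.append(f"trials_path does not exist: {cfg.trials_path}")
    if "gs" in cfg.stages and "pheno" not in cfg.stages and not cfg.pebv_path:
        errors.append("gs requires the pheno stage or a pebv_path")
    if cfg.sim:
        try:
            SimulationConfig(**cfg.sim)
        except (TypeError, ValueError) as exc:
            errors.append(f"sim block invalid: {exc}")
    return (None, errors) if errors else (cfg, [])


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the manifest dict (also written to ``manifest.json``): every
    artifact with its SHA-256 hash, plus the seed and parameters.  A stage
    failure raises after the partial manifest is flushed.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    manifest = {"seed": cfg.seed, "stages": list(cfg.stages), "artifacts": {}}

    def save(path: Path):
        artifacts.append(path)

    def flush_manifest():
        manifest["artifacts"] = {str(p.relative_to(out)): _sha256(p) for p in artifacts}
        _write_json(manifest, out / "manifest.json")

    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s %(message)s")
    from . import __version__

    log.info("version %s seed %s stages %s", __version__, cfg.seed, cfg.stages)

    geno = marker_map = trials = truth = None
    pebv = None
    try:
        if "simulate" in cfg.stages:
            seed = _stage_seed(cfg.seed, "simulate")
            sim_cfg = SimulationConfig(**{"seed": seed, **cfg.sim})
            log.info("[simulate] seed %d, %d accessions x %d markers",
                     seed, sim_cfg.n_accessions, sim_cfg.n_markers)
            geno, marker_map, truth, trials = simulate_panel(sim_cfg)
            tio.write_vcf(geno, marker_map, out / "panel.vcf")
            tio.write_marker_map(marker_map, out / "marker_map.tsv")
            tio.write_trials(trials, out / "trials.csv")
            pd.DataFrame({
                "accession": geno.accession_ids,
                "subpop": truth.subpop_labels + 1,
                "winter_type": truth.winter_type.astype(int),
                "breeding_value": truth.breeding_values,
            }).to_csv(out / "truth_accessions.tsv", sep="\t", index=False)
            for p in ("panel.vcf", "marker_map.tsv", "trials.csv", "truth_accessions.tsv"):
                save(out / p)
        else:
            log.info("[load] %s", cfg.genotype_path)
            if cfg.genotype_path:
                geno, mm_from_file = tio.read_genotypes(cfg.genotype_path)
                marker_map = (tio.read_marker_map(cfg.marker_map_path)
                              if cfg.marker_map_path else mm_from_file)
            if cfg.trials_path:
                trials = tio.read_trials(cfg.trials_path)

        if "qc" in cfg.stages:
            log.info("[qc] %d accessions x %d markers in", geno.n_accessions, geno.n_markers)
            geno, report = tqc.run_qc(geno, **cfg.qc)
            log.info("[qc] %d x %d retained", geno.n_accessions, geno.n_markers)
            tio.write_dosage_table(geno, out / "genotypes_qc.tsv")
            _write_json(report.to_dict(), out / "qc_report.json")
            if marker_map is not None:
                keep = marker_map["marker_id"].isin(set(geno.marker_ids))
                marker_map = marker_map[keep].reset_index(drop=True)
                tally = tqc.genome_tally(marker_map)
                tally.to_csv(out / "genome_tally.tsv", sep="\t", index=False)
                save(out / "genome_tally.tsv")
            save(out / "genotypes_qc.tsv")
            save(out / "qc_report.json")

        if "ld" in cfg.stages:
            log.info("[ld] windowed pairwise r2")
            pairs = tld.pairwise_ld(geno, marker_map, window_bp=cfg.ld["window_bp"])
            pairs.pairs.to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
            curve = tld.bin_decay(pairs, bin_bp=cfg.ld["bin_bp"], cutoff=cfg.ld["cutoff"])
            curve.to_frame().to_csv(out / "ld_decay.tsv", sep="\t", index=False)
            summary = tld.ld_summary(pairs, marker_map, alpha=cfg.ld["alpha"],
                                     bin_bp=cfg.ld["bin_bp"], cutoff=cfg.ld["cutoff"])
            _write_json(summary, out / "ld_summary.json")
            log.info("[ld] %d pairs, decay %.0f bp", len(pairs), curve.decay_distance)
            for p in ("ld_pairs.tsv", "ld_decay.tsv", "ld_summary.json"):
                save(out / p)

        if "structure" in cfg.stages:
            seed = _stage_seed(cfg.seed, "structure")
            sc = cfg.structure
            log.info("[structure] PCA / k-means BIC / Ward / DAPC (seed %d)", seed)
            pca = tstruct.run_pca(geno)
            km = tstruct.kmeans_bic(pca, range(sc["k_min"], sc["k_max"] + 1),
                                    n_starts=sc["n_starts"], seed=seed,
                                    variance_target=sc["variance_target"])
            hc_labels = (tstruct.hierarchical_clusters(geno, km.k).labels
                         if km.k >= 2 else np.ones(geno.n_accessions, dtype=int))
            dapc = (tstruct.run_dapc(pca, km.labels,
                                     variance_target=sc["variance_target"])
                    if km.k >= 2 else None)
            pd.DataFrame(pca.scores[:, :10],
                         index=geno.accession_ids,
                         columns=[f"PC{i+1}" for i in range(min(10, pca.n_components))]
                         ).to_csv(out / "pca_scores.tsv", sep="\t")
            pd.DataFrame({"k": list(km.bic), "wss": list(km.wss.values()),
                          "bic": list(km.bic.values())}).to_csv(
                out / "bic_curve.tsv", sep="\t", index=False)
            pd.DataFrame({"accession": geno.accession_ids, "kmeans": km.labels,
                          "hierarchical": hc_labels}).to_csv(
                out / "cluster_labels.tsv", sep="\t", index=False)
            if dapc is not None:
                pd.DataFrame(dapc.coordinates, index=geno.accession_ids,
                             columns=[f"DA{i+1}" for i in range(dapc.n_da)]).to_csv(
                    out / "dapc_coords.tsv", sep="\t")
                pd.DataFrame(dapc.loadings, index=geno.marker_ids,
                             columns=[f"DA{i+1}" for i in range(dapc.n_da)]).to_csv(
                    out / "dapc_loadings.tsv", sep="\t")
            log.info("[structure] BIC-selected k = %d", km.k)
            if truth is not None:
                comp = tstruct.composition_table(km.labels, truth.winter_type)
                comp.to_csv(out / "cluster_composition.tsv", sep="\t", index=False)
                save(out / "cluster_composition.tsv")
            artifacts_struct = ["pca_scores.tsv", "bic_curve.tsv", "cluster_labels.tsv"]
            if dapc is not None:
                artifacts_struct += ["dapc_coords.tsv", "dapc_loadings.tsv"]
            for p in artifacts_struct:
                save(out / p)

        if "pheno" in cfg.stages:
            log.info("[pheno] %d environments", len(trials))
            fits, report = [], {}
            for t in trials:
                lat = tpheno.fit_lattice(t)
                sp = tpheno.fit_spatial(t)
                eff = tpheno.efficiency(sp, lat)
                report[t.environment] = {
                    "lattice": lat.varcomps, "spatial": sp.varcomps,
                    "efficiency_pct": eff,
                    "H2_lattice": tpheno.heritability(lat),
                    "H2_spatial": tpheno.heritability(sp),
                }
                log.info("[pheno] %s efficiency %.1f%% H2 %.2f/%.2f", t.environment,
                         eff, report[t.environment]["H2_lattice"],
                         report[t.environment]["H2_spatial"])
                fits.append(sp if cfg.pheno.get("model", "both") != "lattice" else lat)
            blue = tpheno.combine_environments(fits)
            pebv = blue
            blue.pebv.rename("pebv_g_m2").to_csv(out / "pebv.tsv", sep="\t")
            report["combined"] = blue.varcomps
            _write_json(report, out / "pheno_report.json")
            save(out / "pebv.tsv")
            save(out / "pheno_report.json")

        if "gs" in cfg.stages:
            seed = _stage_seed(cfg.seed, "gs")
            if pebv is None:
                s = pd.read_csv(cfg.pebv_path, sep="\t", index_col=0).iloc[:, 0]
                pebv = s.reindex(list(geno.accession_ids)).to_numpy(float)
            gsc = dict(cfg.gs)
            cvcfg = CVConfig(
                models=tuple(gsc.get("models", ["rrblup", "gblup", "gauss"])),
                train_sizes=tuple(gsc.get("train_sizes", (50, 100, 150, 200))),
                marker_counts=tuple(
                    min(m, geno.n_markers) for m in gsc.get("marker_counts", (500,))
                ),
                n_iterations=gsc.get("n_iterations", 10),
                fixed_train_size=min(
                    gsc.get("fixed_train_size", 200),
                    max(gsc.get("train_sizes", (50, 100, 150, 200))),
                ),
                seed=seed,
            )
            log.info("[gs] CV grid %s, %d iterations (seed %d)",
                     cvcfg.grid(), cvcfg.n_iterations, seed)
            result = run_cv(geno, pebv, cvcfg)
            table, size_curve, density_curve = summarize_cv(result)
            table.to_csv(out / "cv_results.tsv", sep="\t", index=False)
            _write_json(
                {"mean_accuracy": float(table["mean"].mean()),
                 "by_model": table.groupby("model")["mean"].mean().to_dict()},
                out / "cv_summary.json")
            log.info("[gs] mean accuracy %.3f", table["mean"].mean())
            save(out / "cv_results.tsv")
            save(out / "cv_summary.json")
    except Exception:
        flush_manifest()
        raise
    flush_manifest()
    return manifest


def demo_config_path() -> Path:
    """Path of the bundled desk-scale demo configuration."""
    return Path(__file__).parent / "demo.config"
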