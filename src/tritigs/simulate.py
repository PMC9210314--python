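"""Synthetic GBS panel and field-trial generator with known ground truth.

Emulates a diversity panel of hexaploid triticale: ~289 accessions drawn
from 5 subpopulations, biallelic SNPs assigned to the A/B/R sub-genomes
with bp positions, allele-frequency differentiation following the
Balding–Nichols model, and linkage disequilibrium that decays smoothly
with physical distance.  Phenotypes are multi-environment field trials on
a row x column grid with incomplete blocks, a smooth 2-D spatial trend,
random row/column effects, genotype-by-environment interaction and
additive QTL genetics.

The LD engine is a founder-haplotype copying chain: each subpopulation
carries a small pool of founder haplotypes, themselves generated with a
latent AR(1) Gaussian process along each chromosome so that founder
alleles at nearby sites are correlated; each gamete copies along the
founder pool, switching founders with a per-bp probability.  Both layers
decay exponentially with distance, giving a tunable, monotone r² decline
without an external coalescent simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import GenotypeMatrix, make_marker_map

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "FieldTrial",
    "simulate_genotypes",
    "simulate_trials",
    "simulate_panel",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic panel and trials.

    Defaults mirror the study panel: 289 accessions in 5 subpopulations,
    markers split across the A, B and R sub-genomes in the proportions of
    the mapped SNP set, MAF spectrum bounded below near 0.05, LD decaying
    below r² = 0.1 within ~10 kb, up to 30% missing calls before QC, a
    quantitative yield trait with plot-level heritability ≈ 0.45, and
    3 environments laid out as lattices with spatial heterogeneity.
    """

    n_accessions: int = 289
    n_subpops: int = 5
    n_markers: int = 2000
    #: markers per sub-genome label; None = A/B/R split 19/25/56% (the
    #: mapped-marker proportions of the panel), remainder to R.
    sub_genome_sizes: dict | None = None
    #: chromosomes per sub-genome (wheat/rye homoeologous groups 1-7)
    n_chrom_per_genome: int = 7
    chrom_length: int = 1_000_000
    #: per-bp founder-switch probability; controls the LD decay scale.
    #: The default places the r²=0.1 crossing near 10 kb.
    recomb_rate: float = 2e-5
    #: Balding–Nichols differentiation of subpop allele frequencies.
    fst: float = 0.1
    n_founders: int = 100
    maf_min: float = 0.05
    missing_rate: float = 0.1
    n_qtl: int = 50
    h2_plot: float = 0.45
    n_envs: int = 3
    field_rows: int = 34
    field_cols: int = 17
    n_reps: int = 2
    #: sd (g·m⁻²) of the smooth spatial surface
    spatial_amplitude: float = 40.0
    #: var(GxE) / var(G)
    ge_variance_ratio: float = 0.5
    mu_yield: float = 900.0
    genetic_sd: float = 80.0
    env_sd: float = 50.0
    row_col_sd: float = 15.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_accessions", "n_subpops", "n_markers", "n_chrom_per_genome",
                     "chrom_length", "n_founders", "n_qtl", "n_envs", "field_rows",
                     "field_cols", "n_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.h2_plot < 1:
            raise ValueError("h2_plot must lie in (0, 1)")
        for name in ("missing_rate",):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be non-negative")
        if self.sub_genome_sizes is None:
            a = int(round(0.19 * self.n_markers))
            b = int(round(0.25 * self.n_markers))
            self.sub_genome_sizes = {"A": a, "B": b, "R": self.n_markers - a - b}
        if sum(self.sub_genome_sizes.values()) != self.n_markers:
            raise ValueError("sub_genome_sizes must sum to n_markers")
        if any(v < 0 for v in self.sub_genome_sizes.values()):
            raise ValueError("sub_genome_sizes must be non-negative")


@dataclass
class GroundTruth:
    """Generating quantities recorded for downstream validation."""

    subpop_labels: np.ndarray  # per accession, in 0..n_subpops-1
    winter_type: np.ndarray  # per accession, bool; enriched in the last subpop
    ancestral_freq: np.ndarray  # per marker
    subpop_freq: np.ndarray  # n_subpops x n_markers
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    breeding_values: np.ndarray  # per accession, yield units
    env_effects: np.ndarray | None = None  # per environment
    ge_effects: np.ndarray | None = None  # n_envs x n_accessions
    spatial_surfaces: list = field(default_factory=list)  # per env, rows x cols
    variance_components: list = field(default_factory=list)  # per env dicts

    def entry_mean_h2(self, env: int, n_reps: int) -> float:
        """Entry-mean heritability of the env-specific genetic value."""
        vc = self.variance_components[env]
        vg = vc["sigma2_g"] + vc["sigma2_ge"]
        return vg / (vg + vc["sigma2_e"] / n_reps)


@dataclass
class FieldTrial:
    """One environment's plot table.

    ``plots`` columns: env, row, col, rep, block, genotype, yield_g_m2.
    (row, col) pairs are unique within the environment.
    """

    environment: str
    plots: pd.DataFrame

    def __post_init__(self):
        required = {"env", "row", "col", "rep", "block", "genotype", "yield_g_m2"}
        missing = required - set(self.plots.columns)
        if missing:
            raise ValueError(f"plot table missing columns: {sorted(missing)}")
        if self.plots.duplicated(["row", "col"]).any():
            raise ValueError("duplicate (row, col) plot coordinates")
        if not np.isfinite(self.plots["yield_g_m2"]).all():
            raise ValueError("non-finite yields")


def _ar1_haplotypes(rng, n_hap, freqs, positions, rate):
    """Founder haplotypes with distance-decaying allelic correlation.

    A latent standard-normal AR(1) process along the chromosome, with
    lag-correlation exp(-rate * distance), is thresholded at the allele
    frequency of each site.
    """
    m = len(positions)
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        a = np.exp(-rate * np.diff(positions))
        eps = rng.standard_normal((n_hap, m - 1))
        for k in range(1, m):
            z[:, k] = a[k - 1] * z[:, k - 1] + math.sqrt(1 - a[k - 1] ** 2) * eps[:, k - 1]
    return (norm.cdf(z) < freqs[None, :]).astype(np.int8)


def _copy_gametes(rng, founders, positions, rate, n_gametes):
    """Gametes copied along the founder pool with per-bp switch probability."""
    n_f, m = founders.shape
    idx = np.empty((n_gametes, m), dtype=np.int32)
    idx[:, 0] = rng.integers(n_f, size=n_gametes)
    if m > 1:
        p_switch = 1.0 - np.exp(-rate * np.diff(positions))
        switch = rng.random((n_gametes, m - 1)) < p_switch[None, :]
        new = rng.integers(n_f, size=(n_gametes, m - 1)).astype(np.int32)
        for k in range(1, m):
            idx[:, k] = np.where(switch[:, k - 1], new[:, k - 1], idx[:, k - 1])
    return founders[idx, np.arange(m)[None, :]]


def simulate_genotypes(cfg: SimulationConfig):
    """Simulate the genotype panel.

    Returns ``(geno, marker_map, truth)``: a :class:`GenotypeMatrix` with
    dosages in {0, 1, 2, NaN}, the marker map table (markers sorted by
    chromosome then position), and the :class:`GroundTruth`.
    """
    if cfg.n_qtl > cfg.n_markers:
        raise ValueError("n_qtl cannot exceed n_markers")
    rng = np.random.default_rng(cfg.seed)

    # --- marker placement: chromosomes 1A..7A, 1B..7B, 1R..7R -------------
    chrom_names, chrom_marker_counts = [], []
    for genome in ("A", "B", "R"):
        total = cfg.sub_genome_sizes[genome]
        base = total // cfg.n_chrom_per_genome
        rem = total - base * cfg.n_chrom_per_genome
        for c in range(cfg.n_chrom_per_genome):
            cnt = base + (1 if c < rem else 0)
            if cnt == 0:
                continue
            if cnt > cfg.chrom_length:
                raise ValueError("chromosome too short to place markers")
            chrom_names.append(f"{c + 1}{genome}")
            chrom_marker_counts.append(cnt)

    marker_ids, chroms, positions, sub_genomes, raw_classes = [], [], [], [], []
    per_chrom = []  # (positions array, slice into global marker index)
    offset = 0
    for name, cnt in zip(chrom_names, chrom_marker_counts):
        pos = np.sort(rng.choice(cfg.chrom_length, size=cnt, replace=False)) + 1
        genome = name[-1]
        per_chrom.append((pos, slice(offset, offset + cnt)))
        for j, p in enumerate(pos):
            marker_ids.append(f"S{name}_{p}")
        chroms.extend([name] * cnt)
        positions.extend(pos.tolist())
        sub_genomes.extend([genome] * cnt)
        # R markers mimic the mapping provenance mix: about a third arrived
        # via wheat-D alignment, the rest are rye-specific.
        if genome == "R":
            raw_classes.extend(
                rng.choice(["wheat_D", "rye_specific"], size=cnt, p=[0.33, 0.67]).tolist()
            )
        else:
            raw_classes.extend([f"wheat_{genome}"] * cnt)
        offset += cnt

    marker_map = make_marker_map(marker_ids, chroms, positions, raw_class=raw_classes)
    # raw_class wheat_D maps to R automatically; A/B direct.

    # --- allele frequencies: Balding–Nichols around ancestral U(0.05,0.5) --
    m = cfg.n_markers
    p_anc = rng.uniform(cfg.maf_min, 0.5, size=m)
    F = cfg.fst
    shape = (1.0 - F) / F
    p_sub = np.empty((cfg.n_subpops, m))
    for s in range(cfg.n_subpops):
        p_sub[s] = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
    p_sub = np.clip(p_sub, 1e-3, 1 - 1e-3)

    # --- subpopulation assignment ----------------------------------------
    labels = np.repeat(np.arange(cfg.n_subpops), math.ceil(cfg.n_accessions / cfg.n_subpops))
    labels = labels[: cfg.n_accessions]

    # --- gametes via founder copying per subpop, per chromosome -----------
    dosage = np.empty((cfg.n_accessions, m), dtype=float)
    for s in range(cfg.n_subpops):
        acc_idx = np.where(labels == s)[0]
        n_gam = 2 * len(acc_idx)
        for pos, sl in per_chrom:
            founders = _ar1_haplotypes(rng, cfg.n_founders, p_sub[s, sl], pos, cfg.recomb_rate)
            gametes = _copy_gametes(rng, founders, pos, cfg.recomb_rate, n_gam)
            dosage[acc_idx, sl] = (gametes[::2] + gametes[1::2]).astype(float)

    # --- QTL genetics ------------------------------------------------------
    qtl_idx = np.sort(rng.choice(m, size=cfg.n_qtl, replace=False))
    effects = rng.standard_normal(cfg.n_qtl)
    g_raw = dosage[:, qtl_idx] @ effects
    g_raw = g_raw - g_raw.mean()
    sd = g_raw.std()
    if sd > 0:
        scale = cfg.genetic_sd / sd
        g = g_raw * scale
        effects_scaled = effects * scale
    else:  # degenerate: no genetic variance in the draw
        g = g_raw
        effects_scaled = effects
    # winter/spring covariate: enriched (82%) in the last subpopulation
    p_winter = np.where(labels == cfg.n_subpops - 1, 0.82, 0.5)
    winter = rng.random(cfg.n_accessions) < p_winter

    truth = GroundTruth(
        subpop_labels=labels.copy(),
        winter_type=winter,
        ancestral_freq=p_anc,
        subpop_freq=p_sub,
        qtl_indices=qtl_idx,
        qtl_effects=effects_scaled,
        breeding_values=g,
    )

    # --- missingness -------------------------------------------------------
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = np.nan

    acc_ids = np.array([f"TCL{i + 1:03d}" for i in range(cfg.n_accessions)], dtype=object)
    geno = GenotypeMatrix(acc_ids, np.array(marker_ids, dtype=object), dosage)
    return geno, marker_map, truth


def _smooth_surface(rng, rows, cols, amplitude):
    """Random smooth 2-D trend: low-frequency cosine mixture, sd=amplitude."""
    r = np.arange(rows)[:, None] / max(rows - 1, 1)
    c = np.arange(cols)[None, :] / max(cols - 1, 1)
    surf = np.zeros((rows, cols))
    for _ in range(4):
        fr, fc = rng.uniform(0.5, 2.0, size=2)
        ph_r, ph_c = rng.uniform(0, 2 * np.pi, size=2)
        surf += rng.standard_normal() * np.cos(2 * np.pi * fr * r + ph_r) * np.cos(
            2 * np.pi * fc * c + ph_c
        )
    sd = surf.std()
    if sd > 0 and amplitude > 0:
        surf = surf * (amplitude / sd)
    elif amplitude == 0:
        surf = np.zeros((rows, cols))
    return surf - surf.mean()


def simulate_trials(geno: GenotypeMatrix, truth: GroundTruth, cfg: SimulationConfig):
    """Simulate per-environment field trials on a lattice layout.

    Plot yield = μ + g_i + E_e + GE_ie + f(row, col) + row effect +
    col effect + residual.  The residual variance is set from
    ``cfg.h2_plot``: h² = σ²_g / (σ²_g + σ²_ge + σ²_e) at the plot level,
    after removal of the spatial and row/column terms the analysis models
    explicitly.  Incomplete blocks are the field rows within each
    replicate band (a √n x √n lattice for the 289-line default).
    """
    n = geno.n_accessions
    n_plots = n * cfg.n_reps
    if n_plots > cfg.field_rows * cfg.field_cols:
        raise ValueError(
            f"grid {cfg.field_rows}x{cfg.field_cols} too small for "
            f"{n} accessions x {cfg.n_reps} reps"
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7_341]))

    s2_g = cfg.genetic_sd**2
    s2_ge = cfg.ge_variance_ratio * s2_g
    s2_e = s2_g / cfg.h2_plot - s2_g - s2_ge
    if s2_e < 0:
        raise ValueError("h2_plot unattainable: ge_variance_ratio too large")

    g = truth.breeding_values
    env_eff = rng.normal(0.0, cfg.env_sd, size=cfg.n_envs)
    ge = rng.normal(0.0, math.sqrt(s2_ge), size=(cfg.n_envs, n)) if s2_ge > 0 else np.zeros(
        (cfg.n_envs, n)
    )
    truth.env_effects = env_eff
    truth.ge_effects = ge
    truth.spatial_surfaces = []
    truth.variance_components = []

    trials = []
    for e in range(cfg.n_envs):
        surf = _smooth_surface(rng, cfg.field_rows, cfg.field_cols, cfg.spatial_amplitude)
        row_eff = rng.normal(0.0, cfg.row_col_sd, size=cfg.field_rows)
        col_eff = rng.normal(0.0, cfg.row_col_sd, size=cfg.field_cols)
        truth.spatial_surfaces.append(surf)
        truth.variance_components.append(
            {"sigma2_g": s2_g, "sigma2_ge": s2_ge, "sigma2_e": s2_e,
             "sigma2_row": cfg.row_col_sd**2, "sigma2_col": cfg.row_col_sd**2}
        )

        records = []
        plot = 0
        for rep in range(cfg.n_reps):
            order = rng.permutation(n)
            for k, gi in enumerate(order):
                r, c = divmod(plot, cfg.field_cols)
                eps = rng.normal(0.0, math.sqrt(s2_e))
                y = (
                    cfg.mu_yield
                    + g[gi]
                    + env_eff[e]
                    + ge[e, gi]
                    + surf[r, c]
                    + row_eff[r]
                    + col_eff[c]
                    + eps
                )
                records.append(
                    {
                        "env": f"ENV{e + 1}",
                        "row": r,
                        "col": c,
                        "rep": rep + 1,
                        "block": f"R{rep + 1}B{r + 1}",
                        "genotype": geno.accession_ids[gi],
                        "yield_g_m2": y,
                    }
                )
                plot += 1
        trials.append(FieldTrial(f"ENV{e + 1}", pd.DataFrame.from_records(records)))
    return trials


def simulate_panel(cfg: SimulationConfig | None = None, **overrides):
    """Convenience: genotypes + trials in one call.

    Returns ``(geno, marker_map, truth, trials)``.
    """
    if cfg is None:
        cfg = SimulationConfig(**overrides)
    elif overrides:
        cfg = replace(cfg, **overrides)
    geno, marker_map, truth = simulate_genotypes(cfg)
    trials = simulate_trials(geno, truth, cfg)
    return geno, marker_map, truth, trials
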