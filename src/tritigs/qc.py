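"""Genotype quality control: marker/sample filters, imputation, sub-genome tally.

Filters reproduce a GBS diversity-panel workflow: keep biallelic SNPs with
call rate ≥ 0.7 and MAF strictly > 0.05, drop accessions with more than 30%
missing calls, then impute remaining gaps with the marker mean.  Marker MAF
is recomputed after sample removal so the frequency filter reflects the
retained panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, RAW_CLASSES, assign_sub_genome

__all__ = [
    "FilterReport",
    "filter_markers",
    "filter_samples",
    "impute_mean",
    "genome_tally",
    "run_qc",
]


@dataclass
class FilterReport:
    """Counts of markers/samples removed per rule."""

    n_markers_in: int = 0
    n_samples_in: int = 0
    removed_multiallelic: int = 0
    removed_call_rate: int = 0
    removed_maf: int = 0
    removed_samples: int = 0
    n_markers_out: int = 0
    n_samples_out: int = 0

    def to_dict(self):
        return dict(self.__dict__)


def filter_markers(
    g: GenotypeMatrix,
    min_call_rate: float = 0.7,
    min_maf: float = 0.05,
    biallelic_only: bool = True,
    report: FilterReport | None = None,
) -> GenotypeMatrix:
    """Keep biallelic markers with call rate ≥ min_call_rate and MAF > min_maf.

    The MAF rule is strict (> min_maf): a marker at exactly the threshold
    frequency is removed, and monomorphic markers (MAF 0) always fail.
    """
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    bi = g.biallelic if biallelic_only else np.ones(g.n_markers, bool)
    cr = g.call_rate >= min_call_rate
    with np.errstate(invalid="ignore"):
        maf_arr = np.nan_to_num(g.maf, nan=0.0)
    mf = maf_arr > min_maf
    keep = bi & cr & mf
    if report is not None:
        report.removed_multiallelic += int((~bi).sum())
        report.removed_call_rate += int((bi & ~cr).sum())
        report.removed_maf += int((bi & cr & ~mf).sum())
    if not keep.any():
        warnings.warn("all markers removed by filters", stacklevel=2)
    return g.subset(marker_idx=np.where(keep)[0])


def filter_samples(g: GenotypeMatrix, max_missing: float = 0.3,
                   report: FilterReport | None = None) -> GenotypeMatrix:
    """Drop accessions with missing fraction strictly greater than max_missing.

    An accession at exactly the threshold is retained.  Order of retained
    accessions is preserved.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must lie in [0, 1]")
    keep = g.sample_missing <= max_missing
    if not keep.any():
        raise ValueError("all accessions removed by the missingness filter")
    if report is not None:
        report.removed_samples += int((~keep).sum())
    return g.subset(accession_idx=np.where(keep)[0])


def impute_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call by the marker's mean observed dosage.

    Mean imputation preserves marker means (hence allele frequencies) and
    leaves observed entries untouched.
    """
    d = g.dosages.copy()
    n_obs = (~np.isnan(d)).sum(axis=0)
    if (n_obs == 0).any():
        bad = g.marker_ids[n_obs == 0][:5]
        raise ValueError(f"markers with zero observed calls (filter first): {list(bad)}")
    miss = np.isnan(d)
    if miss.any():
        col_means = np.nanmean(d, axis=0)
        d[miss] = np.broadcast_to(col_means, d.shape)[miss]
    out = GenotypeMatrix(g.accession_ids, g.marker_ids, d, g.biallelic.copy())
    return out


def genome_tally(marker_map: pd.DataFrame) -> pd.DataFrame:
    """Tally markers by raw mapping class and assigned sub-genome.

    Wheat-D and rye-specific markers pool into the R sub-genome (triticale
    carries no D genome).  Returns a table with columns
    ``(level, label, count, percent)`` where level is ``raw_class`` or
    ``sub_genome``; percentages are within level and sum to 100.
    """
    unknown = set(marker_map["raw_class"]) - set(RAW_CLASSES)
    if unknown:
        raise ValueError(f"unknown raw mapping classes: {sorted(unknown)}")
    rows = []
    n = len(marker_map)
    for cls in RAW_CLASSES:
        cnt = int((marker_map["raw_class"] == cls).sum())
        rows.append(("raw_class", cls, cnt, 100.0 * cnt / n if n else 0.0))
    assigned = marker_map["raw_class"].map(assign_sub_genome)
    for sg in ("A", "B", "R", "unmapped"):
        cnt = int((assigned == sg).sum())
        rows.append(("sub_genome", sg, cnt, 100.0 * cnt / n if n else 0.0))
    return pd.DataFrame(rows, columns=["level", "label", "count", "percent"])


def run_qc(
    g: GenotypeMatrix,
    min_call_rate: float = 0.7,
    min_maf: float = 0.05,
    max_sample_missing: float = 0.3,
    impute: bool = True,
):
    """Full QC pipeline: biallelic+call-rate → sample missingness → MAF → impute.

    MAF is applied last, recomputed on the retained samples, so the
    frequency filter is not distorted by accessions that were dropped.
    Returns ``(geno, FilterReport)``.
    """
    report = FilterReport(n_markers_in=g.n_markers, n_samples_in=g.n_accessions)
    g = filter_markers(g, min_call_rate=min_call_rate, min_maf=0.0,
                       biallelic_only=True, report=report)
    g = filter_samples(g, max_missing=max_sample_missing, report=report)
    g = filter_markers(g, min_call_rate=0.0, min_maf=min_maf,
                       biallelic_only=False, report=report)
    g = g.polarize_minor()
    if impute:
        g = impute_mean(g)
    report.n_markers_out = g.n_markers
    report.n_samples_out = g.n_accessions
    return g, report
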