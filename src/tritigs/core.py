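"""Core containers shared by every pipeline stage.

The panel is held as a :class:`GenotypeMatrix` — accessions x markers
minor-allele dosages in {0, 1, 2} with ``NaN`` for missing calls — plus a
marker map table assigning each SNP a chromosome, a bp position and a
sub-genome label. Hexaploid triticale lines genotyped by GBS yield diploid
genotype calls at each biallelic locus, so dosages are treated as diploid
(heterozygote = 1) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Raw mapping classes a marker may carry after alignment to the wheat and
#: rye reference genomes.
RAW_CLASSES = ("wheat_A", "wheat_B", "wheat_D", "rye_specific", "both", "unmapped")

#: Sub-genomes of hexaploid triticale.  Triticale carries no D genome, so
#: wheat-D-mapped markers are reassigned to the rye-derived R sub-genome.
SUB_GENOMES = ("A", "B", "R", "unmapped")

MARKER_MAP_COLUMNS = ["marker_id", "raw_class", "sub_genome", "chromosome", "position"]


def assign_sub_genome(raw_class: str) -> str:
    """Map a raw alignment class to a triticale sub-genome.

    Markers aligning to the wheat D genome are reclassified as R: cultivated
    triticale substitutes the D genome with rye chromatin, so a D-genome hit
    indicates rye-derived sequence.  ``both`` (wheat + rye hits) cannot be
    placed and is reported as unmapped at the sub-genome level.
    """
    if raw_class not in RAW_CLASSES:
        raise ValueError(f"unknown raw mapping class: {raw_class!r}")
    return {
        "wheat_A": "A",
        "wheat_B": "B",
        "wheat_D": "R",
        "rye_specific": "R",
        "both": "unmapped",
        "unmapped": "unmapped",
    }[raw_class]


def make_marker_map(
    marker_ids,
    chromosome,
    position,
    raw_class=None,
    sub_genome=None,
) -> pd.DataFrame:
    """Build a marker map table with columns ``MARKER_MAP_COLUMNS``.

    Either ``raw_class`` (sub-genome derived via :func:`assign_sub_genome`)
    or ``sub_genome`` directly may be given; omitting both marks every
    marker unmapped.  Positions are 1-based bp (VCF convention).
    """
    n = len(marker_ids)
    if raw_class is None:
        raw_class = ["unmapped"] * n
    raw_class = list(raw_class)
    if sub_genome is None:
        sub_genome = [assign_sub_genome(c) for c in raw_class]
    pos = np.asarray(position, dtype=np.int64)
    if (pos < 0).any():
        raise ValueError("marker positions must be non-negative")
    df = pd.DataFrame(
        {
            "marker_id": list(marker_ids),
            "raw_class": raw_class,
            "sub_genome": list(sub_genome),
            "chromosome": list(chromosome),
            "position": pos,
        }
    )
    return df


@dataclass
class GenotypeMatrix:
    """Accessions x markers minor-allele dosage matrix.

    Parameters
    ----------
    accession_ids : sequence of str
    marker_ids : sequence of str
    dosages : ndarray, shape (n_accessions, n_markers)
        Minor-allele counts in {0, 1, 2}; ``NaN`` marks a missing call.
    """

    accession_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray
    biallelic: np.ndarray = field(default=None)  # bool per marker

    def __post_init__(self):
        self.accession_ids = np.asarray(self.accession_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.accession_ids), len(self.marker_ids)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} inconsistent with "
                f"{len(self.accession_ids)} accessions x {len(self.marker_ids)} markers"
            )
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and (np.nanmin(obs) < 0 or np.nanmax(obs) > 2):
            raise ValueError("dosages must lie in {0, 1, 2} or be NaN")
        if self.biallelic is None:
            self.biallelic = np.ones(len(self.marker_ids), dtype=bool)
        else:
            self.biallelic = np.asarray(self.biallelic, dtype=bool)
        if len(np.unique(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    @property
    def sample_missing(self) -> np.ndarray:
        """Per-accession fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=1)

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-marker frequency of the counted allele among observed calls.

        NaN for markers with no observed calls.
        """
        import warnings as _w

        with np.errstate(invalid="ignore"), _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency in [0, 0.5]."""
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def polarize_minor(self) -> "GenotypeMatrix":
        """Flip markers so the counted allele is the minor one."""
        p = self.allele_freq
        flip = p > 0.5
        d = self.dosages.copy()
        d[:, flip] = 2.0 - d[:, flip]
        return GenotypeMatrix(self.accession_ids, self.marker_ids, d, self.biallelic.copy())

    def subset(self, accession_idx=None, marker_idx=None) -> "GenotypeMatrix":
        """Row/column subset preserving order of the given indices."""
        ai = np.arange(self.n_accessions) if accession_idx is None else np.asarray(accession_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            self.accession_ids[ai],
            self.marker_ids[mi],
            self.dosages[np.ix_(ai, mi)],
            self.biallelic[mi],
        )

    def to_frame(self) -> pd.DataFrame:
        """Dosages as a DataFrame (accessions as rows)."""
        return pd.DataFrame(self.dosages, index=self.accession_ids, columns=self.marker_ids)
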