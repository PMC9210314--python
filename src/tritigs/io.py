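"""Reading and writing panel data: VCF, dosage tables, marker maps, trials.

VCF handling is intentionally minimal: genotypes are taken from the GT
subfield of diploid calls (GBS pipelines emit diploid calls for these
hexaploid lines), written back as a v4.2 file with placeholder REF/ALT
alleles.  Tab-delimited dosage tables (accessions x markers, ``NA`` for
missing) are the round-trip-exact alternative.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, make_marker_map, MARKER_MAP_COLUMNS

__all__ = [
    "read_genotypes",
    "read_vcf",
    "write_vcf",
    "read_dosage_table",
    "write_dosage_table",
    "read_marker_map",
    "write_marker_map",
    "read_trials",
    "write_trials",
]

_GT_DOSAGE = {0: 0.0, 1: 1.0, 3: 2.0, 2: np.nan}  # cyvcf2 gt_types codes


def read_vcf(path):
    """Read a VCF into a GenotypeMatrix plus a chromosome/position map.

    Dosages are polarized to the minor allele per marker.  Multi-allelic
    records are kept but flagged non-biallelic for downstream removal.
    Missing GT (./.) becomes NaN.  Returns ``(geno, marker_map)``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, positions, rows, bi = [], [], [], [], []
    line_no = 0
    try:
        for v in vcf:
            line_no += 1
            mid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
            ids.append(mid)
            chroms.append(v.CHROM)
            positions.append(v.POS)
            bi.append(len(v.ALT) == 1)
            gt = v.gt_types
            rows.append([_GT_DOSAGE[int(t)] for t in gt])
    except Exception as exc:  # pragma: no cover - malformed input path
        raise ValueError(f"malformed VCF record at variant #{line_no + 1}: {exc}") from exc
    if len(ids) != len(set(ids)):
        dupes = pd.Series(ids).value_counts()
        raise ValueError(f"duplicate marker ids in VCF: {dupes[dupes > 1].index.tolist()[:5]}")
    dos = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    geno = GenotypeMatrix(samples, ids, dos, biallelic=np.array(bi, dtype=bool))
    geno = geno.polarize_minor()
    mmap = make_marker_map(ids, chroms, positions)
    return geno, mmap


def write_vcf(geno: GenotypeMatrix, marker_map: pd.DataFrame, path):
    """Write a minimal VCF v4.2 (placeholder REF=A, ALT=T; GT only)."""
    mm = marker_map.set_index("marker_id").loc[list(geno.marker_ids)]
    order = np.lexsort((mm["position"].to_numpy(), mm["chromosome"].to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tritigs\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for ch in pd.unique(mm["chromosome"].to_numpy()[order]):
            fh.write(f"##contig=<ID={ch}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in geno.accession_ids) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in order:
            mid = geno.marker_ids[j]
            col = geno.dosages[:, j]
            gts = "\t".join("./." if np.isnan(d) else gt_map[d] for d in col)
            fh.write(
                f"{mm['chromosome'].iloc[j]}\t{mm['position'].iloc[j]}\t{mid}"
                f"\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_dosage_table(geno: GenotypeMatrix, path):
    geno.to_frame().to_csv(path, sep="\t", na_rep="NA", index_label="accession")


def read_dosage_table(path):
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return GenotypeMatrix(df.index.to_numpy(object), df.columns.to_numpy(object), df.to_numpy(float))


def read_genotypes(path):
    """Read genotypes from a VCF (.vcf) or a tab-delimited dosage table.

    Returns ``(geno, marker_map_or_None)``; dosage tables carry no
    positional metadata, so their map is None.
    """
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return read_vcf(path)
    return read_dosage_table(path), None


def write_marker_map(marker_map: pd.DataFrame, path):
    marker_map[MARKER_MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_marker_map(path):
    df = pd.read_csv(path, sep="\t")
    missing = {"marker_id", "sub_genome", "chromosome", "position"} - set(df.columns)
    if missing:
        raise ValueError(f"marker map missing columns: {sorted(missing)}")
    if "raw_class" not in df.columns:
        df["raw_class"] = "unmapped"
    return df[MARKER_MAP_COLUMNS]


def write_trials(trials, path):
    """Write field trials to one CSV (env column distinguishes them)."""
    pd.concat([t.plots for t in trials], ignore_index=True).to_csv(path, index=False)


def read_trials(path):
    from .simulate import FieldTrial

    df = pd.read_csv(path)
    return [FieldTrial(env, sub.reset_index(drop=True)) for env, sub in df.groupby("env", sort=True)]
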