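"""Readers and writers for genotypes, phenotypes and run provenance.

Genotypes travel either as VCF (unphased diploid GT, biallelic SNPs) or as
a delimited -1/0/1 matrix (rows = genotypes, header row of marker ids).
Phenotypes are a comma-separated plot table with the columns genotype,
site, year, rep, block and one column per trait.  Every randomized command
records a provenance object (config hash, seed, package versions) so runs
are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import MarkerMatrix
from .mixedlm import REQUIRED_COLUMNS, validate_phenotypes

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes_vcf",
    "write_genotype_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "outlier_filter",
    "provenance_record",
]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, fmt: str | None = None) -> MarkerMatrix:
    """Read a marker matrix from VCF or a delimited -1/0/1 matrix.

    ``fmt`` is ``"vcf"`` or ``"matrix"``; inferred from the extension when
    omitted.  VCF: unphased or phased diploid GT mapped hom-ref/-het/
    hom-alt to -1/0/1, missing preserved as NaN; records that are not
    biallelic SNPs are skipped (count logged).
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() in (".vcf", ".gz", ".bcf") else "matrix"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path) -> MarkerMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, marker_ids, chroms, positions = [], [], [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        codes = np.full(len(samples), np.nan)
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                continue
            codes[i] = a + b - 1.0
        rows.append(codes)
        marker_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
    vcf.close()
    if skipped:
        logger.info("skipped %d non-biallelic/non-SNP records", skipped)
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    values = np.vstack(rows).T  # samples x markers
    pos = pd.DataFrame({"chrom": chroms, "pos": positions})
    mm = MarkerMatrix(values, samples, marker_ids, positions=pos)
    mm.n_skipped_records = skipped
    return mm


def _read_matrix(path: Path) -> MarkerMatrix:
    df = pd.read_csv(path, index_col=0)
    return MarkerMatrix(
        df.to_numpy(dtype=float),
        [str(g) for g in df.index],
        [str(m) for m in df.columns],
    )


_GT = {-1: "0/0", 0: "0/1", 1: "1/1"}


def write_genotypes_vcf(markers: MarkerMatrix, path) -> None:
    """Write integer-coded genotypes as a minimal VCF (GT field, unphased).

    Fractional (imputed) codes cannot be represented; positions default to
    a single synthetic chromosome when absent.
    """
    path = Path(path)
    vals = markers.values
    finite = vals[np.isfinite(vals)]
    if finite.size and not np.all(np.isin(finite, (-1.0, 0.0, 1.0))):
        raise ValueError("VCF output requires integer -1/0/1 codes (not imputed)")
    if markers.positions is not None:
        chroms = markers.positions["chrom"].tolist()
        poss = markers.positions["pos"].tolist()
    else:
        chroms = ["1"] * markers.n_markers
        poss = list(range(1, markers.n_markers + 1))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(str(c) for c in chroms):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(markers.genotype_ids) + "\n"
        )
        for j in range(markers.n_markers):
            col = vals[:, j]
            gts = "\t".join(
                "./." if not math.isfinite(v) else _GT[int(v)] for v in col
            )
            fh.write(
                f"{chroms[j]}\t{poss[j]}\t{markers.marker_ids[j]}\tA\tT\t.\t.\t.\tGT\t"
                + gts + "\n"
            )


def write_genotype_matrix(markers: MarkerMatrix, path) -> None:
    """Delimited matrix: genotype ids in the first column, marker ids as header."""
    markers.to_dataframe().to_csv(path)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path, traits: list[str] | None = None) -> pd.DataFrame:
    """Read the plot-level phenotype table (CSV, header row).

    Validates the schema, coerces factor columns to strings, reports
    per-trait missingness, and rejects duplicate (genotype, site, year,
    rep) records.
    """
    df = pd.read_csv(path)
    trait_cols = validate_phenotypes(df, traits)
    for c in ("genotype", "site", "block", "rep"):
        df[c] = df[c].astype(str)
    for t in trait_cols:
        df[t] = pd.to_numeric(df[t], errors="coerce")
        n_missing = int(df[t].isna().sum())
        if n_missing:
            logger.info("trait %s: %d missing plot values", t, n_missing)
    return df


def write_phenotypes(data: pd.DataFrame, path) -> None:
    validate_phenotypes(data)
    cols = list(REQUIRED_COLUMNS) + [
        c for c in data.columns if c not in REQUIRED_COLUMNS
    ]
    data[cols].to_csv(path, index=False)


def outlier_filter(
    data: pd.DataFrame,
    k: float = 3.0,
    traits: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rule-based outlier masking, replacing visual screening.

    Per trait x site x year cell, plot values outside ``median +- k * IQR``
    are set missing.  Returns the filtered copy and a report of removal
    counts per cell.  ``k = inf`` leaves the data untouched.
    """
    trait_cols = traits or validate_phenotypes(data)
    out = data.copy()
    report_rows = []
    for t in trait_cols:
        for (site, year), idx in data.groupby(["site", "year"]).groups.items():
            v = out.loc[idx, t]
            vv = v.dropna()
            if vv.empty or not np.isfinite(k):
                removed = 0
            else:
                med = float(vv.median())
                iqr = float(vv.quantile(0.75) - vv.quantile(0.25))
                lo, hi = med - k * iqr, med + k * iqr
                bad = v.notna() & ((v < lo) | (v > hi))
                removed = int(bad.sum())
                out.loc[v.index[bad], t] = np.nan
            report_rows.append(
                {"trait": t, "site": site, "year": year, "n_removed": removed,
                 "n_plots": int(v.notna().sum())}
            )
    return out, pd.DataFrame(report_rows)


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def provenance_record(config: dict, seed: int | None = None) -> dict:
    """Machine-readable run record: config hash, seed, versions."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
        "seed": seed,
        "versions": {
            "shuttlegp": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
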