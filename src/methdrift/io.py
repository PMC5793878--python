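"""Readers and writers for the flat-file dialects the pipeline touches.

Coordinates are 0-based half-open everywhere in memory.  Coverage files
default to 0-based starts; pass ``one_based=True`` for the 1-based
dialect some callers emit.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_coverage_file",
    "write_coverage_file",
    "read_gene_models",
    "read_gene_sets",
    "read_de_table",
    "read_clinical_table",
    "write_dmr_bed",
]

_COVERAGE_COLS = ["chrom", "start", "end", "meth_pct", "count_meth", "count_unmeth"]


def read_coverage_file(
    path: str | Path, sample_id: str | None = None, one_based: bool = False
) -> pd.DataFrame:
    """Read a Bismark-style coverage file into per-CpG counts.

    Columns expected: chrom, start, end, methylation %, methylated count,
    unmethylated count (tab-separated, no header).  Returns a frame with
    columns ``chrom, pos, meth, total`` sorted by (chrom, pos);
    ``pos`` is the 0-based CpG start.  Records with total coverage 0 are
    dropped; their number is kept in ``attrs['n_zero_coverage_dropped']``
    and reported as a warning.

    Raises
    ------
    ValueError
        On a malformed line (wrong field count, non-numeric counts, or a
        negative count), naming the offending line number.
    """
    rows = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 tab-separated fields, got {len(fields)}")
            try:
                chrom = fields[0]
                start = int(fields[1])
                m = int(fields[4])
                u = int(fields[5])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate or count") from exc
            if start < 0 or m < 0 or u < 0:
                raise ValueError(f"{path}: line {lineno}: negative coordinate or count")
            total = m + u
            if total == 0:
                n_dropped += 1
                continue
            rows.append((chrom, start - (1 if one_based else 0), m, total))
    out = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])
    out = out.sort_values(["chrom", "pos"]).reset_index(drop=True)
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} records with zero coverage", stacklevel=2)
    out.attrs["n_zero_coverage_dropped"] = n_dropped
    out.attrs["sample_id"] = sample_id
    return out


def write_coverage_file(counts: pd.DataFrame, path: str | Path) -> None:
    """Write per-CpG counts back to the 6-column coverage dialect (0-based)."""
    meth_pct = 100.0 * counts["meth"] / counts["total"]
    frame = pd.DataFrame(
        {
            "chrom": counts["chrom"],
            "start": counts["pos"],
            "end": counts["pos"] + 1,
            "meth_pct": meth_pct,
            "count_meth": counts["meth"],
            "count_unmeth": counts["total"] - counts["meth"],
        }
    )
    frame.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read BED6 gene intervals and derive the TSS from the strand.

    TSS = start for '+' genes and end - 1 for '-' genes (0-based 5' end).
    """
    genes = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    if genes["strand"].isna().any():
        raise ValueError(f"{path}: gene models need a strand column (BED6)")
    bad = ~genes["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{path}: invalid strand value {genes.loc[bad, 'strand'].iloc[0]!r}")
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    return genes[["gene_id", "chrom", "start", "end", "strand", "tss"]]


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets (name, description, members...); members deduplicated.

    A set with fewer than 2 distinct genes is rejected by name.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                if line.strip():
                    raise ValueError(f"{path}: malformed GMT line: {line[:60]!r}")
                continue
            name, members = fields[0], set(g for g in fields[2:] if g)
            if len(members) < 2:
                raise ValueError(f"{path}: gene set {name!r} has fewer than 2 genes")
            sets[name] = members
    return sets


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression TSV (gene_id, log2fc, pvalue, padj)."""
    de = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "pvalue", "padj"}
    missing = required - set(de.columns)
    if missing:
        raise ValueError(f"{path}: missing DE columns {sorted(missing)}")
    return de


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV (sample_id, group, survival_time, event)."""
    clin = pd.read_csv(path, sep="\t")
    required = {"sample_id", "survival_time", "event"}
    missing = required - set(clin.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical columns {sorted(missing)}")
    if (clin["survival_time"] < 0).any():
        raise ValueError(f"{path}: negative survival time")
    return clin


def write_dmr_bed(dmrs: pd.DataFrame, path: str | Path) -> None:
    """Write DMRs as BED6 (0-based half-open).

    name = DMR id, score = -10*log10(adjusted p) capped at 1000 (1000 when
    the adjusted p underflows to 0), strand = '.'.
    """
    with open(path, "w") as fh:
        for i, rec in enumerate(dmrs.itertuples(index=False), start=1):
            padj = getattr(rec, "p_adj", None)
            if padj is None or (isinstance(padj, float) and math.isnan(padj)):
                score = 0
            elif padj <= 0:
                score = 1000
            else:
                score = min(1000, int(round(-10.0 * math.log10(padj))))
            name = getattr(rec, "dmr_id", None) or f"dmr_{i}"
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{name}\t{score}\t.\n")


def read_dmr_bed(path: str | Path) -> pd.DataFrame:
    """Read a DMR BED6 back (inverse of :func:`write_dmr_bed` for coordinates)."""
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "dmr_id", "score", "strand"],
        dtype={"chrom": str, "dmr_id": str},
    )


def write_dmr_table(dmrs: pd.DataFrame, path: str | Path) -> None:
    """Write the full DMR table as TSV; member CpG positions comma-joined."""
    out = dmrs.copy()
    if "members" in out.columns:
        out["members"] = out["members"].map(lambda ms: ",".join(str(m) for m in ms))
    out.to_csv(path, sep="\t", index=False)


def read_dmr_table(path: str | Path) -> pd.DataFrame:
    """Read a DMR TSV written by :func:`write_dmr_table`."""
    dmrs = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "members" in dmrs.columns:
        dmrs["members"] = dmrs["members"].map(
            lambda s: [int(x) for x in str(s).split(",")] if pd.notna(s) else []
        )
    return dmrs
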