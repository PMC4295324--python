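"""Per-CpG methylation call I/O, strand combining, depth filtering and QC.

A call table is a pandas DataFrame with columns
``chrom, pos, strand, n_meth, n_total`` where ``pos`` is the 0-based
coordinate of the cytosine (after strand combining, the plus-strand C of
the CpG) and counts satisfy ``0 <= n_meth <= n_total``.

Two on-disk dialects are supported. The Bismark coverage dialect is
1-based inclusive (chrom, start, end, methylation %, count methylated,
count unmethylated); the bedGraph-with-counts dialect carries the same six
columns but 0-based half-open coordinates. The dialect converters are the
only place coordinates shift.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CALL_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_total"]

DIALECTS = ("bismark_cov", "bedgraph_counts")


class CallFormatError(ValueError):
    """Raised for unparsable or invalid methylation-call input."""


def empty_calls() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "n_meth": pd.Series(dtype=np.int64),
            "n_total": pd.Series(dtype=np.int64),
        }
    )


def read_calls(path: str, dialect: str = "bismark_cov") -> pd.DataFrame:
    """Read a methylation call file, normalizing to internal 0-based coordinates.

    Malformed lines raise :class:`CallFormatError` with 1-based line numbers.
    The strand of file-backed calls is unknown and recorded as ``'.'``;
    :func:`combine_strands` resolves it against the genome.
    """
    if dialect not in DIALECTS:
        raise CallFormatError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    chroms, poss, meths, totals = [], [], [], []
    bad: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                bad.append(f"line {lineno}: expected 6 tab-separated fields")
                continue
            try:
                start = int(f[1])
                n_meth = int(f[4])
                n_unmeth = int(f[5])
            except ValueError:
                bad.append(f"line {lineno}: non-numeric coordinate or count")
                continue
            if n_meth < 0 or n_unmeth < 0:
                bad.append(f"line {lineno}: negative count")
                continue
            pos = start - 1 if dialect == "bismark_cov" else start
            chroms.append(f[0])
            poss.append(pos)
            meths.append(n_meth)
            totals.append(n_meth + n_unmeth)
    if bad:
        raise CallFormatError("; ".join(bad[:20]))
    if not chroms:
        return empty_calls()
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(poss, dtype=np.int64),
            "strand": ".",
            "n_meth": np.asarray(meths, dtype=np.int64),
            "n_total": np.asarray(totals, dtype=np.int64),
        }
    )


def write_calls(calls: pd.DataFrame, path: str, dialect: str = "bismark_cov") -> None:
    if dialect not in DIALECTS:
        raise CallFormatError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    df = calls.sort_values(["chrom", "pos"], kind="mergesort")
    pos = df["pos"].to_numpy()
    if dialect == "bismark_cov":
        start, end = pos + 1, pos + 1
    else:
        start, end = pos, pos + 1
    n_meth = df["n_meth"].to_numpy()
    n_total = df["n_total"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_total > 0, 100.0 * n_meth / np.maximum(n_total, 1), 0.0)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "start": start,
            "end": end,
            "pct": [f"{p:.6g}" for p in pct],
            "n_meth": n_meth,
            "n_unmeth": n_total - n_meth,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class StrandQC:
    """Bookkeeping from strand combining."""

    n_input: int
    n_merged_sites: int
    n_non_cpg_dropped: int


def combine_strands(calls: pd.DataFrame, genome: dict[str, str]) -> tuple[pd.DataFrame, StrandQC]:
    """Pool plus- and minus-strand calls of each CpG onto the plus-strand C.

    The genomic context decides the strand of every call: a C followed by G
    is the plus-strand cytosine; a G preceded by C is the minus-strand
    cytosine and is shifted one base left. Calls at positions that are not
    part of a CpG (SNPs, errors, non-CpG context) are dropped and counted
    in the QC record, not fatal. Total counts over valid sites are conserved.
    """
    parts = []
    n_dropped = 0
    for chrom, grp in calls.groupby("chrom", sort=True):
        seq = genome.get(chrom)
        if seq is None:
            n_dropped += len(grp)
            continue
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
        pos = grp["pos"].to_numpy()
        in_bounds = (pos >= 0) & (pos < len(arr))
        base = np.full(len(pos), b"?", dtype="S1")
        base[in_bounds] = arr[pos[in_bounds]]
        nxt = np.full(len(pos), b"?", dtype="S1")
        ok_next = in_bounds & (pos + 1 < len(arr))
        nxt[ok_next] = arr[np.minimum(pos + 1, len(arr) - 1)[ok_next]]
        prv = np.full(len(pos), b"?", dtype="S1")
        ok_prev = in_bounds & (pos - 1 >= 0)
        prv[ok_prev] = arr[np.maximum(pos - 1, 0)[ok_prev]]
        plus = (base == b"C") & (nxt == b"G")
        minus = (base == b"G") & (prv == b"C")
        canon = np.where(plus, pos, np.where(minus, pos - 1, -1))
        valid = plus | minus
        n_dropped += int((~valid).sum())
        sub = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": canon[valid],
                "n_meth": grp["n_meth"].to_numpy()[valid],
                "n_total": grp["n_total"].to_numpy()[valid],
            }
        )
        parts.append(sub)
    if parts:
        merged = (
            pd.concat(parts, ignore_index=True)
            .groupby(["chrom", "pos"], as_index=False, sort=True)[["n_meth", "n_total"]]
            .sum()
        )
    else:
        merged = empty_calls().drop(columns=["strand"])
    merged.insert(2, "strand", "merged")
    qc = StrandQC(
        n_input=len(calls), n_merged_sites=len(merged), n_non_cpg_dropped=n_dropped
    )
    return merged.reset_index(drop=True), qc


def filter_depth(calls: pd.DataFrame, min_depth: int = 8) -> pd.DataFrame:
    """Keep calls sequenced at least ``min_depth`` times (inclusive bound)."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    return calls[calls["n_total"] >= min_depth].reset_index(drop=True)


def conversion_efficiency(non_cpg_calls: pd.DataFrame) -> float | None:
    """Bisulfite conversion efficiency from non-CpG cytosine calls.

    Efficiency is the fraction of covered non-CpG cytosines read as T
    (converted). Returns None when there is no coverage — the quantity is
    undefined, not zero.
    """
    total = int(non_cpg_calls["n_total"].sum()) if len(non_cpg_calls) else 0
    if total == 0:
        return None
    unconverted = int(non_cpg_calls["n_meth"].sum())
    return (total - unconverted) / total
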