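"""Sliding-window CpG-island caller and CGI genomic categorization.

Islands are called by scanning each chromosome with fixed 150 bp windows on
a 25 bp grid anchored at position 0, keeping windows with GC fraction
> 0.55 and CpG observed/expected ratio > 0.65, taking the union of passing
windows, joining resulting blocks separated by less than 50 bp, and keeping
merged intervals longer than 250 bp. A promoter-focused variant lowers the
size cutoff to 225 bp and keeps only islands whose midpoint lies within
800 bp of a TSS.

The CpG ratio uses the Gardiner-Garden observed/expected form
``(#CpG * L) / (#C * #G)``. N bases are excluded from composition counts
and any window containing an N fails.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genemodels import exon_intervals, intron_intervals, tss_positions


@dataclass(frozen=True)
class CGIParams:
    window: int = 150
    offset: int = 25
    min_gc: float = 0.55
    min_cpg_ratio: float = 0.65
    merge_gap: int = 50
    min_size: int = 250

    def __post_init__(self) -> None:
        if self.window <= 0 or self.offset <= 0:
            raise ValueError("window and offset must be positive")
        if self.min_size < self.window:
            raise ValueError("min_size must be >= window")


#: Promoter-variant parameters (smaller islands, TSS-restricted).
PROMOTER_PARAMS = CGIParams(min_size=225)
PROMOTER_TSS_MAX_DIST = 800

#: Category rule: TSS if midpoint < 1000 bp from the closest TSS.
TSS_MAX_DIST = 1000


def composition(seq: str) -> tuple[float, float, int]:
    """GC fraction, CpG observed/expected ratio and CpG count of a sequence.

    N bases are excluded from all counts and from the effective length.
    An all-N (or empty-after-exclusion) sequence has undefined composition,
    returned as NaN.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    s = seq.upper()
    n_n = s.count("N")
    length = len(s) - n_n
    if length == 0:
        return math.nan, math.nan, 0
    n_c = s.count("C")
    n_g = s.count("G")
    n_cpg = s.count("CG")
    gc = (n_c + n_g) / length
    ratio = (n_cpg * length) / (n_c * n_g) if n_c * n_g > 0 else 0.0
    return gc, ratio, n_cpg


def _passing_windows(seq: str, params: CGIParams) -> np.ndarray:
    """Start positions of grid windows passing both composition thresholds.

    Vectorized over the chromosome with cumulative counts; windows
    containing any N fail.
    """
    L = len(seq)
    w = params.window
    if L < w:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
    is_c = (arr == b"C").astype(np.int64)
    is_g = (arr == b"G").astype(np.int64)
    is_n = (arr == b"N").astype(np.int64)
    is_cg = np.zeros(L, dtype=np.int64)
    is_cg[:-1] = (arr[:-1] == b"C") & (arr[1:] == b"G")
    cum = lambda x: np.concatenate(([0], np.cumsum(x)))
    cc, cg_, cn, ccg = cum(is_c), cum(is_g), cum(is_n), cum(is_cg)
    starts = np.arange(0, L - w + 1, params.offset, dtype=np.int64)
    ends = starts + w
    n_c = cc[ends] - cc[starts]
    n_g = cg_[ends] - cg_[starts]
    n_n = cn[ends] - cn[starts]
    # CpG dinucleotide must start within the window and its G stay inside
    n_cpg = ccg[ends - 1] - ccg[starts]
    gc = (n_c + n_g) / w
    denom = n_c * n_g
    ratio = np.where(denom > 0, n_cpg * w / np.maximum(denom, 1), 0.0)
    ok = (n_n == 0) & (gc > params.min_gc) & (ratio > params.min_cpg_ratio)
    return starts[ok]


def _merge_windows(starts: np.ndarray, window: int, merge_gap: int) -> list[tuple[int, int]]:
    """Union overlapping/adjacent windows, then join blocks with gap < merge_gap."""
    blocks: list[list[int]] = []
    for s in starts:
        e = int(s) + window
        if blocks and s <= blocks[-1][1]:
            blocks[-1][1] = max(blocks[-1][1], e)
        else:
            blocks.append([int(s), e])
    joined: list[list[int]] = []
    for s, e in blocks:
        if joined and s - joined[-1][1] < merge_gap:
            joined[-1][1] = e
        else:
            joined.append([s, e])
    return [(s, e) for s, e in joined]


def call_cgis(genome: dict[str, str], params: CGIParams = CGIParams()) -> pd.DataFrame:
    """Call CpG islands on every chromosome.

    Returns a BED-like DataFrame ``chrom, start, end, gc_fraction,
    cpg_ratio, n_cpg`` with 0-based half-open intervals, sorted. Chromosomes
    shorter than one window are skipped.
    """
    rows = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        starts = _passing_windows(seq, params)
        for s, e in _merge_windows(starts, params.window, params.merge_gap):
            if e - s > params.min_size:
                gc, ratio, n_cpg = composition(seq[s:e])
                rows.append((chrom, s, e, gc, ratio, n_cpg))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gc_fraction", "cpg_ratio", "n_cpg"]
    )


def nearest_tss_distance(cgis: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Distance from each CGI midpoint to the closest TSS (NaN if none on chrom).

    Ties between equidistant TSSs are irrelevant for the distance itself;
    midpoints use (start + end) / 2.
    """
    cgis = cgis.reset_index(drop=True)
    tss = tss_positions(genes)
    out = np.full(len(cgis), np.nan)
    for chrom, grp in cgis.groupby("chrom"):
        t = tss.loc[tss["chrom"] == chrom, "pos"].to_numpy()
        if len(t) == 0:
            continue
        t = np.sort(t)
        mid = (grp["start"].to_numpy() + grp["end"].to_numpy()) / 2.0
        idx = np.searchsorted(t, mid)
        left = np.abs(mid - t[np.clip(idx - 1, 0, len(t) - 1)])
        right = np.abs(t[np.clip(idx, 0, len(t) - 1)] - mid)
        out[grp.index.to_numpy()] = np.minimum(left, right)
    return pd.Series(out, index=cgis.index, name="tss_distance")


def call_promoter_cgis(
    genome: dict[str, str],
    genes: pd.DataFrame,
    params: CGIParams = PROMOTER_PARAMS,
    tss_max_dist: int = PROMOTER_TSS_MAX_DIST,
) -> pd.DataFrame:
    """Promoter-focused CGI calls: smaller min size, midpoint < tss_max_dist of a TSS."""
    cgis = call_cgis(genome, params)
    if len(genes) == 0 or len(cgis) == 0:
        return cgis.iloc[0:0]
    dist = nearest_tss_distance(cgis, genes)
    keep = dist < tss_max_dist  # strict: exactly at the cutoff is excluded
    return cgis[keep.fillna(False)].reset_index(drop=True)


def _trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in df.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(grp["start"], grp["end"]) if e > s
        )
    return trees


def categorize(cgis: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Assign each CGI exactly one genomic category.

    Priority: TSS (midpoint < 1 kb from the closest TSS) > exon (>= 1 bp
    exon overlap) > intron (entirely inside an intron) > intergenic.
    """
    if len(cgis) == 0:
        return pd.Series(dtype=str, name="category")
    dist = nearest_tss_distance(cgis, genes)
    exons = _trees(exon_intervals(genes)) if len(genes) else {}
    introns = _trees(intron_intervals(genes)) if len(genes) else {}
    cats = []
    for i, cgi in enumerate(cgis.itertuples()):
        if not np.isnan(dist.iloc[i]) and dist.iloc[i] < TSS_MAX_DIST:
            cats.append("TSS")
            continue
        ex = exons.get(cgi.chrom)
        if ex is not None and ex.overlap(cgi.start, cgi.end):
            cats.append("exon")
            continue
        intr = introns.get(cgi.chrom)
        if intr is not None and any(
            iv.begin <= cgi.start and iv.end >= cgi.end
            for iv in intr.overlap(cgi.start, cgi.end)
        ):
            cats.append("intron")
            continue
        cats.append("intergenic")
    return pd.Series(cats, index=cgis.index, name="category")


def classify_promoter_cpg_content(seq: str) -> str:
    """HCP/ICP/LCP promoter classes from the -700..+200 promoter sequence.

    Follows the common convention: HCP if CpG ratio > 0.75 and GC > 0.55
    in the promoter window, LCP if CpG ratio < 0.48, otherwise ICP.
    """
    gc, ratio, _ = composition(seq)
    if math.isnan(gc):
        return "unassigned"
    if ratio > 0.75 and gc > 0.55:
        return "HCP"
    if ratio < 0.48:
        return "LCP"
    return "ICP"


def write_cgi_bed(cgis: pd.DataFrame, path: str, extra_cols: list[str] | None = None) -> None:
    """Write CGIs as BED with score = round(1000 * cpg_ratio / 2)."""
    df = cgis.sort_values(["chrom", "start"]).reset_index(drop=True)
    name = df["feature_id"] if "feature_id" in df else pd.Series(
        [f"CGI_{i:04d}" for i in range(len(df))]
    )
    score = (1000 * df["cpg_ratio"] / 2).round().astype(int) if "cpg_ratio" in df else 0
    out = pd.DataFrame(
        {"chrom": df["chrom"], "start": df["start"], "end": df["end"], "name": name, "score": score}
    )
    if extra_cols:
        for c in extra_cols:
            out[c] = df[c].to_numpy()
    out.to_csv(path, sep="\t", header=False, index=False)
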