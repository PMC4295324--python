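"""CGI methylation classes, pmCGI calling, and single-allele read analysis.

Aggregate methylation hides whether a 40%-methylated CGI carries one fully
methylated and one unmethylated allele (imprinted) or sparse methylation on
every molecule. Single sequenced molecules resolve this: each read covering
several CpGs of a CGI yields a read-level methylation score (fraction of
its CpGs methylated), and the shape of the score distribution — bimodal
versus unimodal-sparse — separates allele-specific from partial
methylation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

# u/pm/m aggregate methylation bands (strict inequalities; values falling
# in the definitional gaps [0.10, 0.15] and exactly 0.60 stay unassigned)
U_MAX = 0.10
PM_BAND = (0.15, 0.60)
M_MIN = 0.60


def classify_methylation(level: float | None) -> str:
    """u (< 10%), pm (> 15% and < 60%), m (> 60%) or unassigned."""
    if level is None or (isinstance(level, float) and np.isnan(level)):
        return "unassigned"
    if level < U_MAX:
        return "u"
    if PM_BAND[0] < level < PM_BAND[1]:
        return "pm"
    if level > M_MIN:
        return "m"
    return "unassigned"


def call_pmcgis(
    cgi_meth: pd.DataFrame,
    imprinted_dmrs: pd.DataFrame | None = None,
    x_chroms: tuple = ("chrX",),
    band: tuple[float, float] = PM_BAND,
) -> pd.DataFrame:
    """Partially methylated CGIs at the final stage.

    Keeps CGIs with methylation strictly inside ``band``, then removes any
    CGI overlapping a known imprinted DMR interval and any CGI on a flagged
    sex chromosome. ``cgi_meth`` needs chrom, start, end, feature_id,
    methylation columns.
    """
    m = cgi_meth["methylation"]
    keep = (m > band[0]) & (m < band[1])
    out = cgi_meth[keep.fillna(False)]
    out = out[~out["chrom"].isin(x_chroms)]
    if imprinted_dmrs is not None and len(imprinted_dmrs):
        trees: dict[str, IntervalTree] = {}
        for chrom, grp in imprinted_dmrs.groupby("chrom"):
            trees[chrom] = IntervalTree.from_tuples(
                (int(s), int(e)) for s, e in zip(grp["start"], grp["end"]) if e > s
            )
        hits = [
            bool(trees.get(r.chrom) and trees[r.chrom].overlap(r.start, r.end))
            for r in out.itertuples()
        ]
        out = out[~np.asarray(hits, dtype=bool)] if len(out) else out
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# read patterns

PATTERN_COLUMNS = ["read_id", "cgi_id", "chrom", "positions", "states"]


def write_patterns(patterns: pd.DataFrame, path: str) -> None:
    df = patterns.copy()
    if len(df):
        df["positions"] = df["positions"].map(lambda p: ",".join(map(str, p)))
        df["states"] = df["states"].map(lambda s: "".join(map(str, s)))
    df.to_csv(path, sep="\t", index=False)


def read_patterns(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"states": str})
    df["positions"] = df["positions"].map(lambda p: tuple(int(x) for x in str(p).split(",")))
    df["states"] = df["states"].map(lambda s: tuple(int(c) for c in str(s)))
    return df


def read_scores(patterns: pd.DataFrame, min_cpg_per_read: int = 3) -> tuple[np.ndarray, int]:
    """Per-molecule methylation scores; reads covering too few CpGs are
    excluded and counted."""
    scores, n_excluded = [], 0
    for states in patterns["states"]:
        if len(states) < min_cpg_per_read:
            n_excluded += 1
            continue
        scores.append(sum(states) / len(states))
    return np.asarray(scores, dtype=float), n_excluded


@dataclass
class ScoreHistogram:
    """Normalized distribution of single-molecule methylation scores."""

    edges: np.ndarray
    masses: np.ndarray
    n_reads: int
    n_excluded: int
    mean_score: float
    mass_low: float  # fraction of reads with score <= 0.2
    mass_high: float  # fraction of reads with score >= 0.8


def read_score_distribution(
    patterns: pd.DataFrame, min_cpg_per_read: int = 3, n_bins: int = 10
) -> ScoreHistogram:
    """Histogram of read scores for one feature over [0, 1]."""
    scores, n_excluded = read_scores(patterns, min_cpg_per_read)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    if len(scores) == 0:
        return ScoreHistogram(edges, np.zeros(n_bins), 0, n_excluded, np.nan, 0.0, 0.0)
    counts, _ = np.histogram(scores, bins=edges)
    return ScoreHistogram(
        edges=edges,
        masses=counts / len(scores),
        n_reads=len(scores),
        n_excluded=n_excluded,
        mean_score=float(scores.mean()),
        mass_low=float((scores <= 0.2).mean()),
        mass_high=float((scores >= 0.8).mean()),
    )


def allele_mode_test(
    hist: ScoreHistogram,
    extreme_threshold: float = 0.8,
    tail_min: float = 0.2,
    min_reads: int = 10,
) -> str:
    """Decide whether partial methylation is allele-specific or sparse.

    allele_specific: combined mass at the score extremes (<= 0.2 and >= 0.8)
    exceeds ``extreme_threshold`` with at least ``tail_min`` in each extreme
    (bimodal, imprinted-like). sparse_uniform: almost no fully methylated
    molecules (mass >= 0.8 below 0.1) and mean score in (0.1, 0.6). Anything
    else, or fewer than ``min_reads`` molecules, is indeterminate.

    These thresholds are this package's operational rule for a contrast the
    source analyses establish visually; they are configurable.
    """
    if hist.n_reads < min_reads:
        return "indeterminate"
    extreme = hist.mass_low + hist.mass_high
    if extreme > extreme_threshold and hist.mass_low >= tail_min and hist.mass_high >= tail_min:
        return "allele_specific"
    if hist.mass_high < 0.1 and 0.1 < hist.mean_score < 0.6:
        return "sparse_uniform"
    return "indeterminate"


def assign_cgi_class(
    wt_series: dict[str, float],
    e85_by_genotype: dict[str, float],
    hist: ScoreHistogram | None = None,
    early_stage: str = "E3.5",
    mid_stage: str = "E5.5",
    late_stage: str = "E8.5",
) -> str:
    """Composite kinetic classification of one CGI against all evidence.

    Combines the imprinted-DMR templates (stable ~50% -> germline;
    DNMT3B-dependent post-implantation gain -> somatic), the slow/fast
    speed rule, the pm band and the protected (persistently unmethylated)
    state. Aggregate counts cannot separate a somatic DMR from a pmCGI —
    both sit at intermediate methylation with a DNMT3B-dependent gain — so
    the single-molecule score distribution arbitrates when available.
    """
    from .knockout import classify_dmr
    from .tiles import classify_speed

    label, _ = classify_dmr(wt_series, e85_by_genotype, early_stage=early_stage, late_stage=late_stage)
    if label == "gDMR":
        return "gdmr"
    speed = classify_speed(
        wt_series.get(early_stage, np.nan),
        wt_series.get(mid_stage, np.nan),
        wt_series.get(late_stage, np.nan),
    )
    if speed in ("slow", "fast"):
        return speed
    if label == "sDMR":
        if hist is not None and allele_mode_test(hist) == "sparse_uniform":
            return "pm"
        return "sdmr"
    late = wt_series.get(late_stage, np.nan)
    if not np.isnan(late):
        if PM_BAND[0] < late < PM_BAND[1]:
            if hist is not None and allele_mode_test(hist) == "allele_specific":
                return "sdmr"
            return "pm"
        if late < U_MAX:
            return "protected"
    return "other"
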