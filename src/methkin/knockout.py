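"""Knockout-versus-wild-type comparisons and imprinted DMR classification.

Tile deltas (WT minus knockout) quantify genotype-dependent methylation
loss; tiles losing more than 60% in the Dnmt3b knockout, merged into
contiguous blocks, define the DNMT3B-dependent targets. Imprinted DMRs are
classified as germline (stable aggregate methylation through development,
unaffected in either single knockout) or somatic (low in blastocysts,
gained after implantation in a DNMT3B-dependent manner).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def delta_tiles(m_wt: pd.Series, m_ko: pd.Series) -> pd.Series:
    """WT minus KO tile methylation on the tiles valid in both samples.

    Both series must come from the same tile grid (same (chrom, start)
    index convention); a disjoint index is treated as a grid mismatch.
    """
    common = m_wt.index.intersection(m_ko.index)
    if len(m_wt) and len(m_ko) and len(common) == 0:
        raise ValueError("tile grids do not match (no shared tiles)")
    diff = (m_wt.loc[common] - m_ko.loc[common]).dropna()
    diff.name = "delta"
    return diff


def changed_tiles(deltas: pd.Series, threshold: float = 0.10) -> tuple[int, int]:
    """(n_loss, n_gain): tiles changing by strictly more than ``threshold``.

    Loss means the knockout is lower than WT (delta > threshold), gain the
    opposite.
    """
    return int((deltas > threshold).sum()), int((deltas < -threshold).sum())


def call_dnmt3b_targets(deltas: pd.Series, threshold: float = 0.60, tile_size: int = 400) -> pd.DataFrame:
    """Merged intervals of tiles losing more than ``threshold`` methylation.

    On a fixed grid passing tiles can only abut; merging joins abutting and
    overlapping tiles into maximal non-overlapping target intervals.
    """
    passing = deltas[deltas > threshold]
    rows = []
    for chrom, grp in passing.groupby(level=0):
        starts = np.sort(np.asarray([s for _, s in grp.index]))
        for s in starts:
            e = int(s) + tile_size
            if rows and rows[-1][0] == chrom and s <= rows[-1][2]:
                rows[-1][2] = max(rows[-1][2], e)
                rows[-1][3] += 1
            else:
                rows.append([chrom, int(s), e, 1])
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_tiles"])


@dataclass(frozen=True)
class DMRClassParams:
    """Bands for the germline-vs-somatic DMR decision.

    The stability band reflects the ~40-50% aggregate methylation of a
    one-allele-methylated locus; tolerances are this package's calibrated
    defaults (the distinguishing criteria are qualitative in origin).
    """

    band_low: float = 0.40
    band_high: float = 0.50
    band_tol: float = 0.15
    ko_tol: float = 0.15
    sdmr_e35_max: float = 0.25
    sdmr_gain_min: float = 0.20
    sdmr_3bko_drop_min: float = 0.30


def classify_dmr(
    wt_series: dict[str, float],
    e85_by_genotype: dict[str, float],
    params: DMRClassParams = DMRClassParams(),
    early_stage: str = "E3.5",
    late_stage: str = "E8.5",
) -> tuple[str, str]:
    """Classify one imprinted DMR as gDMR, sDMR or indeterminate.

    gDMR: every WT stage value lies within the stability band (band +/-
    tolerance) and the late-stage methylation is unaffected (within
    ``ko_tol``) in both single knockouts. sDMR: hypomethylated at the early
    stage, gains methylation in WT development, and that gain depends on
    DNMT3B. Returns (label, reason).
    """

    def _missing(v) -> bool:
        return v is None or (isinstance(v, float) and np.isnan(v))

    for st in (early_stage, late_stage):
        if st not in wt_series or _missing(wt_series[st]):
            return "indeterminate", f"missing WT value at {st}"
    for gt in ("Dnmt3aKO", "Dnmt3bKO"):
        if gt not in e85_by_genotype or _missing(e85_by_genotype[gt]):
            return "indeterminate", f"missing {gt} value at {late_stage}"

    wt_late = wt_series[late_stage]
    lo = params.band_low - params.band_tol
    hi = params.band_high + params.band_tol
    stable = all(lo <= v <= hi for v in wt_series.values() if not _missing(v))
    ko_flat = all(
        abs(wt_late - e85_by_genotype[gt]) < params.ko_tol
        for gt in ("Dnmt3aKO", "Dnmt3bKO")
    )
    if stable and ko_flat:
        return "gDMR", "stable in development and in both knockouts"

    wt_early = wt_series[early_stage]
    if (
        wt_early < params.sdmr_e35_max
        and wt_late - wt_early > params.sdmr_gain_min
        and wt_late - e85_by_genotype["Dnmt3bKO"] > params.sdmr_3bko_drop_min
    ):
        return "sDMR", "post-implantation DNMT3B-dependent gain"
    return "indeterminate", "matches neither the germline nor the somatic template"


def genotype_distribution_stats(
    matrix: pd.DataFrame, wt_column: str, min_wt: float = 0.50
) -> pd.DataFrame:
    """Median and quartiles of tile methylation per genotype column,
    restricted to tiles with WT methylation above ``min_wt``."""
    sel = matrix[matrix[wt_column] > min_wt]
    rows = []
    for col in matrix.columns:
        v = sel[col].dropna().to_numpy()
        if len(v):
            q25, med, q75 = np.percentile(v, [25, 50, 75])
        else:
            q25 = med = q75 = np.nan
        rows.append((col, med, q25, q75, len(v)))
    return pd.DataFrame(rows, columns=["sample", "median", "q25", "q75", "n"])
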