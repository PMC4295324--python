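"""Fixed-grid tiling, methylation trajectories and gene metaprofiles.

The unit of genome-wide comparison is a 400 bp tile on a fixed grid
anchored at coordinate 0. A tile has a methylation value in a sample only
when at least three distinct CpGs are covered there; the value is the
pooled-count (coverage-weighted) mean ``sum(n_meth) / sum(n_total)`` over
those CpGs. Feature-level (CGI, DMR) methylation uses the same pooled rule
over the CpGs inside the feature interval.
"""
from __future__ import annotations

import numpy as np
import pandas as pd


def make_tiles(
    calls: pd.DataFrame, tile_size: int = 400, min_cpg: int = 3
) -> pd.DataFrame:
    """Aggregate depth-filtered merged calls into fixed tiles.

    Returns ``chrom, start, end, n_cpg, n_meth, n_total, methylation``;
    tiles with fewer than ``min_cpg`` covered CpGs keep their counts but
    have missing (NaN) methylation.
    """
    if len(calls) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_cpg", "n_meth", "n_total", "methylation"]
        )
    df = calls.assign(start=(calls["pos"] // tile_size) * tile_size)
    g = df.groupby(["chrom", "start"], as_index=False, sort=True).agg(
        n_cpg=("pos", "nunique"), n_meth=("n_meth", "sum"), n_total=("n_total", "sum")
    )
    g["end"] = g["start"] + tile_size
    meth = g["n_meth"] / g["n_total"]
    g["methylation"] = meth.where(g["n_cpg"] >= min_cpg)
    return g[["chrom", "start", "end", "n_cpg", "n_meth", "n_total", "methylation"]]


def tile_matrix(samples: dict[str, pd.DataFrame], tile_size: int = 400, min_cpg: int = 3) -> pd.DataFrame:
    """Per-sample tile methylation, one column per sample, indexed (chrom, start)."""
    cols = {}
    for name, calls in samples.items():
        t = make_tiles(calls, tile_size=tile_size, min_cpg=min_cpg)
        cols[name] = t.set_index(["chrom", "start"])["methylation"]
    return pd.DataFrame(cols).sort_index()


def transition_changes(
    m_before: pd.Series, m_after: pd.Series, delta: float = 0.20
) -> tuple[int, int, pd.Index]:
    """Tiles gaining or losing more than ``delta`` methylation across a transition.

    Only tiles with values in both samples are considered; the inequality is
    strict on both sides (a change of exactly ``delta`` is neither).
    Returns (n_gain, n_loss, index of changed tiles).
    """
    both = m_before.notna() & m_after.notna()
    diff = (m_after - m_before)[both]
    gain = diff > delta
    loss = diff < -delta
    return int(gain.sum()), int(loss.sum()), diff.index[gain | loss]


def de_novo_set(
    m_early: pd.Series, m_late: pd.Series, low: float = 0.20, high: float = 0.50
) -> pd.Index:
    """Tiles de novo methylated in development: < ``low`` at the early stage
    and > ``high`` at the late stage (both strict)."""
    both = m_early.notna() & m_late.notna()
    member = (m_early < low) & (m_late > high) & both
    return m_early.index[member]


def kinetics_summary(values: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of feature methylation per stage.

    ``values`` has one row per feature and one column per stage; missing
    features are excluded stage by stage. Raises on an empty feature set.
    """
    if len(values) == 0:
        raise ValueError("empty feature set")
    rows = []
    for stage in values.columns:
        v = values[stage].dropna().to_numpy()
        if len(v) == 0:
            rows.append((stage, np.nan, np.nan, np.nan, 0))
        else:
            q25, med, q75 = np.percentile(v, [25, 50, 75])
            rows.append((stage, med, q25, q75, len(v)))
    return pd.DataFrame(rows, columns=["stage", "median", "q25", "q75", "n"])


def classify_speed(
    e35: float, e55: float, e85: float, low: float = 0.20, mid: float = 0.50
) -> str:
    """Classify a CGI trajectory as slow or fast de novo methylation.

    slow: < 20% at E3.5, < 50% at E5.5 and > 50% at E8.5;
    fast: < 20% at E3.5, > 50% at E5.5 and > 50% at E8.5;
    anything else (including boundary values) is 'neither'; a missing
    required stage makes the series 'unclassifiable'.
    """
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in (e35, e55, e85)):
        return "unclassifiable"
    if e35 < low and e85 > mid:
        if e55 < mid:
            return "slow"
        if e55 > mid:
            return "fast"
    return "neither"


def feature_methylation(
    calls: pd.DataFrame, features: pd.DataFrame, min_cpg: int = 3
) -> pd.Series:
    """Pooled-count methylation of non-overlapping features (CGIs, DMRs).

    ``features`` needs ``chrom, start, end`` and a ``feature_id`` column;
    returns methylation per feature_id, NaN when fewer than ``min_cpg``
    covered CpGs fall inside the feature.
    """
    out = pd.Series(np.nan, index=features["feature_id"], name="methylation", dtype=float)
    for chrom, feats in features.groupby("chrom"):
        sub = calls[calls["chrom"] == chrom]
        if len(sub) == 0:
            continue
        feats = feats.sort_values("start")
        starts = feats["start"].to_numpy()
        ends = feats["end"].to_numpy()
        pos = sub["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        if not inside.any():
            continue
        grp = pd.DataFrame(
            {
                "fid": feats["feature_id"].to_numpy()[idx[inside]],
                "n_meth": sub["n_meth"].to_numpy()[inside],
                "n_total": sub["n_total"].to_numpy()[inside],
            }
        ).groupby("fid").agg(n=("n_meth", "size"), m=("n_meth", "sum"), t=("n_total", "sum"))
        ok = grp[grp["n"] >= min_cpg]
        out.loc[ok.index] = ok["m"] / ok["t"]
    return out


def stage_series(
    samples: dict[str, pd.DataFrame],
    sample_meta: pd.DataFrame,
    features: pd.DataFrame,
    genotype: str = "WT",
    min_cpg: int = 3,
) -> pd.DataFrame:
    """Feature x stage methylation table for one genotype.

    ``sample_meta`` has columns ``sample_id, stage, genotype``; replicate
    samples of the same stage are pooled at the count level by concatenating
    their calls (pooled-count averaging).
    """
    meta = sample_meta[sample_meta["genotype"] == genotype]
    cols = {}
    for stage, grp in meta.groupby("stage", sort=False):
        pooled = pd.concat([samples[s] for s in grp["sample_id"]], ignore_index=True)
        pooled = pooled.groupby(["chrom", "pos"], as_index=False)[["n_meth", "n_total"]].sum()
        cols[stage] = feature_methylation(pooled, features, min_cpg=min_cpg)
    return pd.DataFrame(cols)


def gene_metaprofile(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    n_gene_bins: int = 20,
    n_flank_bins: int = 10,
    flank_bin_size: int = 1000,
    exclude_chroms: tuple = ("chrX", "chrY"),
    min_gene_length: int = 20,
) -> pd.DataFrame:
    """Average methylation profile over scaled gene bodies and fixed flanks.

    Per gene: ``n_flank_bins`` 1-kb windows upstream, ``n_gene_bins``
    equal-sized windows within the gene, ``n_flank_bins`` 1-kb windows
    downstream, oriented 5'->3' (minus-strand genes are flipped). The
    aggregate is the mean over genes of the per-gene pooled-count bin
    methylation. Sex chromosomes are excluded; genes shorter than
    ``min_gene_length`` are skipped.
    """
    n_bins = 2 * n_flank_bins + n_gene_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    by_chrom = {c: g.sort_values("pos") for c, g in calls.groupby("chrom")}
    for gene in genes.itertuples():
        if gene.chrom in exclude_chroms:
            continue
        glen = gene.end - gene.start
        if glen < min_gene_length:
            continue
        sub = by_chrom.get(gene.chrom)
        if sub is None:
            continue
        lo = gene.start - n_flank_bins * flank_bin_size
        hi = gene.end + n_flank_bins * flank_bin_size
        pos = sub["pos"].to_numpy()
        i0, i1 = np.searchsorted(pos, [lo, hi])
        if i1 <= i0:
            continue
        p = pos[i0:i1]
        m = sub["n_meth"].to_numpy()[i0:i1]
        t = sub["n_total"].to_numpy()[i0:i1]
        bins = np.empty(len(p), dtype=int)
        up = p < gene.start
        down = p >= gene.end
        body = ~(up | down)
        bins[up] = (p[up] - lo) // flank_bin_size
        bins[body] = n_flank_bins + (p[body] - gene.start) * n_gene_bins // glen
        bins[down] = n_flank_bins + n_gene_bins + (p[down] - gene.end) // flank_bin_size
        bm = np.bincount(bins, weights=m, minlength=n_bins)
        bt = np.bincount(bins, weights=t, minlength=n_bins)
        if gene.strand == "-":
            bm, bt = bm[::-1], bt[::-1]
        has = bt > 0
        sums[has] += bm[has] / bt[has]
        counts[has] += 1
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"bin": np.arange(n_bins), "methylation": profile, "n_genes": counts})
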