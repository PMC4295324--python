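"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written against the definitions directly (character
counting, explicit window enumeration, per-site pooling, exact binomial
tails) and deliberately shares no code with the package.
"""
from __future__ import annotations

import math
from collections import Counter, defaultdict

import numpy as np
from scipy.stats import binom, poisson  # noqa: F401  (binom used below)


def oracle_composition(seq: str):
    """GC fraction / CpG O-E ratio / CpG count by direct character counting."""
    s = seq.upper()
    counts = Counter(s)
    length = len(s) - counts["N"]
    if length == 0:
        return math.nan, math.nan, 0
    n_cpg = sum(1 for i in range(len(s) - 1) if s[i] == "C" and s[i + 1] == "G")
    n_c, n_g = counts["C"], counts["G"]
    gc = (n_c + n_g) / length
    ratio = n_cpg * length / (n_c * n_g) if n_c * n_g > 0 else 0.0
    return gc, ratio, n_cpg


def oracle_call_cgis(
    genome: dict,
    window: int = 150,
    offset: int = 25,
    min_gc: float = 0.55,
    min_ratio: float = 0.65,
    merge_gap: int = 50,
    min_size: int = 250,
):
    """Enumerate every grid window, filter, union positions, join, filter size."""
    out = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        passing = []
        for s in range(0, len(seq) - window + 1, offset):
            if seq.count("N", s, s + window) > 0:
                continue
            n_c = seq.count("C", s, s + window)
            n_g = seq.count("G", s, s + window)
            n_cpg = seq.count("CG", s, s + window)
            gc = (n_c + n_g) / window
            ratio = n_cpg * window / (n_c * n_g) if n_c * n_g > 0 else 0.0
            if gc > min_gc and ratio > min_ratio:
                passing.append(s)
        # union of passing windows as an explicit position set
        covered = set()
        for s in passing:
            covered.update(range(s, s + window))
        blocks = []
        for p in sorted(covered):
            if blocks and p == blocks[-1][1]:
                blocks[-1][1] = p + 1
            else:
                blocks.append([p, p + 1])
        joined = []
        for s, e in blocks:
            if joined and s - joined[-1][1] < merge_gap:
                joined[-1][1] = e
            else:
                joined.append([s, e])
        for s, e in joined:
            if e - s > min_size:
                out.append((chrom, s, e))
    return sorted(out)


def oracle_pool_by_site(rows):
    """Per-site pooled methylation from (chrom, pos, n_meth, n_total) rows."""
    acc = defaultdict(lambda: [0, 0])
    for chrom, pos, m, t in rows:
        acc[(chrom, pos)][0] += m
        acc[(chrom, pos)][1] += t
    return {k: (v[0], v[1]) for k, v in acc.items()}


def oracle_tile_means(rows, tile_size=400, min_cpg=3):
    """Per-tile pooled methylation from merged (chrom, pos, n_meth, n_total)."""
    acc = defaultdict(lambda: [0, 0, 0])
    for chrom, pos, m, t in rows:
        key = (chrom, (pos // tile_size) * tile_size)
        acc[key][0] += m
        acc[key][1] += t
        acc[key][2] += 1
    return {
        k: v[0] / v[1] for k, v in acc.items() if v[2] >= min_cpg and v[1] > 0
    }


def expected_changed_count(n1: np.ndarray, n2: np.ndarray, p: float, delta: float = 0.2):
    """Exact expectation and variance of the changed-tile count under the null.

    Both replicates of a tile draw Binomial(n_i, p); the tile is counted
    when |X1/n1 - X2/n2| > delta under the same floating-point comparison
    the pipeline uses. Returns (expected_count, variance).
    """
    exp = 0.0
    var = 0.0
    for a, b in zip(n1, n2):
        i = np.arange(a + 1)
        j = np.arange(b + 1)
        w = np.outer(binom.pmf(i, a, p), binom.pmf(j, b, p))
        diff = np.abs(i[:, None] / a - j[None, :] / b)
        pt = float(w[diff > delta].sum())
        exp += pt
        var += pt * (1 - pt)
    return exp, var


def oracle_gene_bins(calls_rows, gene, n_gene_bins=20, n_flank_bins=10, flank=1000):
    """Per-gene bin methylation by explicit per-call assignment.

    ``gene`` is (chrom, start, end, strand); returns a list of 40 values
    (NaN where a bin has no coverage), oriented 5'->3'.
    """
    chrom, start, end, strand = gene
    n_bins = 2 * n_flank_bins + n_gene_bins
    m = [0.0] * n_bins
    t = [0.0] * n_bins
    for c, pos, nm, nt in calls_rows:
        if c != chrom:
            continue
        if start - n_flank_bins * flank <= pos < start:
            b = (pos - (start - n_flank_bins * flank)) // flank
        elif start <= pos < end:
            b = n_flank_bins + (pos - start) * n_gene_bins // (end - start)
        elif end <= pos < end + n_flank_bins * flank:
            b = n_flank_bins + n_gene_bins + (pos - end) // flank
        else:
            continue
        m[int(b)] += nm
        t[int(b)] += nt
    vals = [mi / ti if ti > 0 else math.nan for mi, ti in zip(m, t)]
    if strand == "-":
        vals = vals[::-1]
    return vals
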