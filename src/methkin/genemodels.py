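"""Minimal gene models: BED12 reading/writing and TSS/exon/intron accessors.

A gene model table has one row per gene with columns
``gene_id, chrom, start, end, strand, exon_starts, exon_ends`` where exon
coordinates are absolute, 0-based half-open, and sorted. This is the subset
of a RefSeq-style annotation the CGI categorizer and metaprofile need.
"""
from __future__ import annotations

import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "exon_starts", "exon_ends"]


def tss_positions(genes: pd.DataFrame) -> pd.DataFrame:
    """One row per gene: chrom, pos (0-based base of the TSS), gene_id.

    For a plus-strand gene the TSS is the first base; for a minus-strand
    gene it is the last base of the interval.
    """
    pos = genes.apply(
        lambda g: g["start"] if g["strand"] == "+" else g["end"] - 1, axis=1
    )
    out = pd.DataFrame(
        {"chrom": genes["chrom"], "pos": pos.astype(int), "gene_id": genes["gene_id"]}
    )
    # deterministic tie-breaking downstream: sort by chrom, pos, gene start
    return out.sort_values(["chrom", "pos", "gene_id"]).reset_index(drop=True)


def exon_intervals(genes: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for g in genes.itertuples():
        for s, e in zip(g.exon_starts, g.exon_ends):
            rows.append((g.chrom, int(s), int(e), g.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def intron_intervals(genes: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for g in genes.itertuples():
        for e_prev, s_next in zip(g.exon_ends[:-1], g.exon_starts[1:]):
            if s_next > e_prev:
                rows.append((g.chrom, int(e_prev), int(s_next), g.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def write_bed12(genes: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for g in genes.sort_values(["chrom", "start", "gene_id"]).itertuples():
            sizes = [e - s for s, e in zip(g.exon_starts, g.exon_ends)]
            rel = [s - g.start for s in g.exon_starts]
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g.chrom,
                        g.start,
                        g.end,
                        g.gene_id,
                        0,
                        g.strand,
                        g.start,
                        g.end,
                        "0,0,0",
                        len(sizes),
                        ",".join(map(str, sizes)) + ",",
                        ",".join(map(str, rel)) + ",",
                    )
                )
                + "\n"
            )


def read_bed12(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            rel = [int(x) for x in f[11].rstrip(",").split(",")]
            ex_s = tuple(start + r for r in rel)
            ex_e = tuple(s + sz for s, sz in zip(ex_s, sizes))
            rows.append((name, chrom, start, end, strand, ex_s, ex_e))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)
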