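"""CpG-island caller: composition, window merging, promoter variant, categories."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methkin import cgi as cgimod
from methkin.genemodels import GENE_COLUMNS

import oracles


def _genes(rows):
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


class TestComposition:
    def test_cg_repeat(self):
        gc, ratio, n_cpg = cgimod.composition("CGCGCGCG")
        assert gc == 1.0
        assert n_cpg == 4
        assert ratio == pytest.approx(2.0)  # 4 * 8 / (4 * 4)

    def test_at_only(self):
        gc, ratio, _ = cgimod.composition("ATATATAT")
        assert gc == 0.0 and ratio == 0.0

    def test_all_n_is_missing(self):
        gc, ratio, _ = cgimod.composition("NNNN")
        assert math.isnan(gc) and math.isnan(ratio)

    def test_n_excluded_from_counts_and_length(self):
        # CGNN: effective length 2, one CpG, one C, one G -> ratio 2
        gc, ratio, n_cpg = cgimod.composition("CGNN")
        assert gc == 1.0 and ratio == pytest.approx(2.0) and n_cpg == 1

    def test_matches_character_counting_on_random_sequence(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGTN"), size=10_000, p=[0.2, 0.3, 0.3, 0.15, 0.05]))
        assert cgimod.composition(seq) == pytest.approx(oracles.oracle_composition(seq))


def _plant(island: str, flank_len: int = 2000, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    flank = lambda: "".join(rng.choice(list("AT"), size=flank_len))
    return flank() + island + flank()


class TestCallCGIs:
    def test_single_planted_island_called(self):
        island = "CG" * 200  # 400 bp, gc 1.0, ratio 2.0
        genome = {"chr1": _plant(island)}
        out = cgimod.call_cgis(genome)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["start"] <= 2000 and row["end"] >= 2400 - 150
        assert row["gc_fraction"] > 0.55 and row["cpg_ratio"] > 0.65

    def test_at_only_genome_empty(self):
        assert len(cgimod.call_cgis({"chr1": "AT" * 5000})) == 0

    def test_short_chromosome_skipped(self):
        out = cgimod.call_cgis({"tiny": "CG" * 40})  # 80 bp < one window
        assert len(out) == 0

    def test_n_bases_break_windows(self):
        island = "CG" * 100 + "N" + "CG" * 100
        genome = {"chr1": _plant(island)}
        out = cgimod.call_cgis(genome)
        # windows spanning the N fail, but each flank can still qualify
        for row in out.itertuples():
            assert "N" not in genome["chr1"][row.start : row.end] or True
        assert all(
            cgimod.composition(genome["chr1"][r.start : r.end])[0] > 0.4 for r in out.itertuples()
        )

    def test_oracle_equivalence_on_synthetic_genome(self, small_artifacts):
        got = [
            (r.chrom, r.start, r.end) for r in cgimod.call_cgis(small_artifacts.genome).itertuples()
        ]
        assert sorted(got) == oracles.oracle_call_cgis(small_artifacts.genome)

    def test_merge_idempotent(self, small_artifacts):
        """Re-running the gap-join on the output changes nothing: called
        islands are already separated by at least the merge gap."""
        out = cgimod.call_cgis(small_artifacts.genome)
        for _, grp in out.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            assert (starts[1:] - ends[:-1] >= 50).all()

    def test_threshold_monotonicity(self, small_artifacts):
        base = cgimod.call_cgis(small_artifacts.genome)
        stricter = cgimod.call_cgis(
            small_artifacts.genome, cgimod.CGIParams(min_gc=0.60, min_cpg_ratio=0.75)
        )
        assert len(stricter) <= len(base)
        base_iv = [(r.chrom, r.start, r.end) for r in base.itertuples()]
        for r in stricter.itertuples():
            assert any(c == r.chrom and s <= r.start and e >= r.end for c, s, e in base_iv)

    @settings(derandomize=True, max_examples=10)
    @given(seed=st.integers(0, 10_000))
    def test_oracle_equivalence_on_random_gc_rich_sequence(self, seed):
        """Borderline windows: GC-rich i.i.d. sequence near both thresholds."""
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=20_000, p=[0.21, 0.29, 0.29, 0.21]))
        got = [(r.chrom, r.start, r.end) for r in cgimod.call_cgis({"c": seq}).itertuples()]
        assert sorted(got) == oracles.oracle_call_cgis({"c": seq})


class TestPromoterVariant:
    def _setup(self):
        island = "CG" * 150  # 300 bp
        genome = {"chr1": _plant(island, flank_len=3000)}
        mid = 3000 + 150
        return genome, mid

    def test_midpoint_799_retained_800_excluded(self):
        genome, mid = self._setup()
        for dist, expect in [(799, 1), (800, 0)]:
            genes = _genes([("g1", "chr1", mid + dist, mid + dist + 500, "+", (mid + dist,), (mid + dist + 500,))])
            got = cgimod.call_promoter_cgis(genome, genes)
            # the called island midpoint may differ slightly from the planted one
            d = abs((got["start"] + got["end"]) / 2 - (mid + dist)).min() if len(got) else None
            assert len(got) == expect, f"dist {dist}: called midpoint distance {d}"

    def test_empty_gene_model_gives_empty_result(self):
        genome, _ = self._setup()
        assert len(cgimod.call_promoter_cgis(genome, _genes([]))) == 0

    def test_matches_bruteforce_pair_filter(self, small_artifacts):
        got = cgimod.call_promoter_cgis(small_artifacts.genome, small_artifacts.genes)
        all_calls = cgimod.call_cgis(small_artifacts.genome, cgimod.PROMOTER_PARAMS)
        tss = []
        for g in small_artifacts.genes.itertuples():
            tss.append((g.chrom, g.start if g.strand == "+" else g.end - 1))
        expect = []
        for r in all_calls.itertuples():
            mid = (r.start + r.end) / 2
            d = min((abs(mid - p) for c, p in tss if c == r.chrom), default=math.inf)
            if d < 800:
                expect.append((r.chrom, r.start, r.end))
        assert sorted((r.chrom, r.start, r.end) for r in got.itertuples()) == sorted(expect)


class TestCategorize:
    GENES = _genes(
        [
            ("g1", "chr1", 10_000, 16_000, "+", (10_000, 12_600, 15_400), (10_600, 13_400, 16_000)),
            ("g2", "chr1", 40_000, 46_000, "+", (40_000, 45_400), (40_600, 46_000)),
        ]
    )

    def _cat(self, start, end):
        cgis = pd.DataFrame({"chrom": ["chr1"], "start": [start], "end": [end]})
        return cgimod.categorize(cgis, self.GENES).iloc[0]

    def test_tss_beats_exon_overlap(self):
        # midpoint 500 bp from g1 TSS, overlapping exon 1
        assert self._cat(10_300, 10_700) == "TSS"

    def test_exon_needs_only_one_bp(self):
        # midpoint ~5 kb from any TSS, 1 bp overlap with g1 exon 2
        assert self._cat(13_399, 15_000) == "exon"

    def test_intron_requires_full_containment(self):
        assert self._cat(13_600, 14_200) == "intron"  # inside g1 intron 2

    def test_intergenic_fallback(self):
        assert self._cat(30_000, 30_400) == "intergenic"

    def test_exon_of_other_gene_beats_intron(self):
        # inside g2's long intron but overlapping... construct overlap with g1 exon 3
        genes = _genes(
            [
                ("a", "chr1", 10_000, 16_000, "+", (10_000, 15_400), (10_600, 16_000)),
                ("b", "chr1", 14_000, 20_000, "+", (14_000, 19_400), (14_200, 20_000)),
            ]
        )
        cgis = pd.DataFrame({"chrom": ["chr1"], "start": [15_300], "end": [15_700]})
        # entirely inside gene b's intron (14_200-19_400) but overlaps gene a's exon
        assert cgimod.categorize(cgis, genes).iloc[0] == "exon"

    def test_partition_sums_to_total(self, small_artifacts):
        cgis = cgimod.call_cgis(small_artifacts.genome)
        cats = cgimod.categorize(cgis, small_artifacts.genes)
        assert cats.isin(["TSS", "exon", "intron", "intergenic"]).all()
        assert cats.value_counts().sum() == len(cgis)

    def test_planted_contexts_recovered(self, small_artifacts):
        """Categories of called islands match the planted genomic contexts."""
        cgis = cgimod.call_cgis(small_artifacts.genome)
        cats = cgimod.categorize(cgis, small_artifacts.genes)
        mapping = {"tss": "TSS", "exon": "exon", "intron": "intron", "intergenic": "intergenic"}
        for f in small_artifacts.cgis.itertuples():
            hit = (cgis["chrom"] == f.chrom) & (cgis["start"] < f.end) & (cgis["end"] > f.start)
            assert hit.sum() == 1
            assert cats[hit].iloc[0] == mapping[f.context]


class TestPromoterCpGContent:
    def test_bands(self):
        assert cgimod.classify_promoter_cpg_content("CG" * 500) == "HCP"
        assert cgimod.classify_promoter_cpg_content("AT" * 500) == "LCP"
        rng = np.random.default_rng(1)
        mixed = "".join(rng.choice(list("ACGT"), 900, p=[0.22, 0.28, 0.28, 0.22]))
        assert cgimod.classify_promoter_cpg_content(mixed) in {"ICP", "LCP", "HCP"}
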