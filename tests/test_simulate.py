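"""Synthetic-data generator: genome composition, truth table, count model."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from methkin import calls as callsmod
from methkin import simulate, tiles
from methkin.config import SimulationConfig

import oracles

NO_CGIS = {k: 0 for k in ("protected", "fast", "slow", "pm", "gdmr", "sdmr", "xlinked")}


class TestConfigValidation:
    def test_unordered_stages_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            SimulationConfig(stage_list=("E5.5", "E3.5"), bulk_kinetics=(0.1, 0.2),
                             fast_cgi_kinetics=(0.1, 0.2), slow_cgi_kinetics=(0.1, 0.2),
                             sdmr_mat_kinetics=(0.1, 0.2), pm_shape=(0.5, 1.0))

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(conversion_error=1.5)

    def test_min_sizes(self):
        with pytest.raises(ValueError):
            SimulationConfig(chrom_length=5000)
        with pytest.raises(ValueError):
            SimulationConfig(mean_depth=0.5)


class TestGenerateGenome:
    def test_no_planted_cgis_no_qualifying_intervals(self):
        cfg = SimulationConfig(seed=3, n_chromosomes=2, chrom_length=60_000,
                               n_cgis_per_class=NO_CGIS, n_genes=4, n_te=4)
        art = simulate.generate_genome(cfg)
        assert len(art.cgis) == 0
        assert oracles.oracle_call_cgis(art.genome) == []

    def test_planted_islands_satisfy_composition(self, small_artifacts):
        from methkin.cgi import composition

        for f in small_artifacts.cgis.itertuples():
            seq = small_artifacts.genome[f.chrom][f.start : f.end]
            gc, ratio, _ = composition(seq)
            assert gc > 0.55 and ratio > 0.65 and len(seq) > 250

    def test_background_cpg_depleted(self, small_artifacts):
        from methkin.cgi import composition

        chrom = "chr1"
        mask = np.ones(len(small_artifacts.genome[chrom]), dtype=bool)
        for f in small_artifacts.cgis.query("chrom == @chrom").itertuples():
            mask[f.start : f.end] = False
        bg = "".join(c for c, m in zip(small_artifacts.genome[chrom], mask) if m)
        _, ratio, _ = composition(bg)
        assert ratio < 0.4

    def test_genes_have_multiple_exons(self, small_artifacts):
        assert (small_artifacts.genes["exon_starts"].map(len) >= 2).all()

    def test_capacity_error(self):
        cfg = SimulationConfig(seed=0, n_chromosomes=2, chrom_length=10_000, n_genes=40)
        with pytest.raises(simulate.CapacityError):
            simulate.generate_genome(cfg)

    def test_truth_table_gdmr_alleles(self):
        counts = dict(NO_CGIS, gdmr=2)
        cfg = SimulationConfig(seed=5, n_chromosomes=2, chrom_length=80_000,
                               n_cgis_per_class=counts, n_genes=4, n_te=2)
        art = simulate.generate_genome(cfg)
        gd = art.truth.query("cgi_class == 'gdmr'")
        assert gd["feature_id"].nunique() == 2
        assert (gd.query("allele == 'mat'")["p"] > 0.9).all()
        assert (gd.query("allele == 'pat'")["p"] < 0.1).all()

    def test_every_feature_once_in_truth(self, small_artifacts, small_config):
        truth = small_artifacts.truth
        per_combo = truth.groupby(["feature_id", "stage", "genotype", "allele"]).size()
        assert (per_combo == 1).all()
        n_feat = len(small_artifacts.cgis) + 1  # + background
        assert truth["feature_id"].nunique() == n_feat

    def test_deterministic(self, small_config, small_artifacts):
        again = simulate.generate_genome(small_config)
        assert again.genome == small_artifacts.genome
        pd.testing.assert_frame_equal(again.truth, small_artifacts.truth)


class TestSimulateMethylomes:
    def test_counts_bounded(self, small_data):
        for df in small_data.samples.values():
            assert (df["n_meth"] <= df["n_total"]).all()
            assert (df["n_meth"] >= 0).all()

    def test_deterministic(self, small_config, small_artifacts, small_data):
        again = simulate.simulate_methylomes(small_artifacts, small_config)
        for sid, df in small_data.samples.items():
            pd.testing.assert_frame_equal(df, again.samples[sid])
        pd.testing.assert_frame_equal(small_data.patterns, again.patterns)

    def test_pm_level_zero_gives_zero_meth(self):
        counts = dict(NO_CGIS, pm=2)
        cfg = SimulationConfig(seed=9, n_chromosomes=2, chrom_length=80_000,
                               n_cgis_per_class=counts, n_genes=4, n_te=2,
                               pm_level=0.0, conversion_error=0.0)
        art = simulate.generate_genome(cfg)
        rng = np.random.default_rng(1)
        sample, _ = simulate.simulate_sample(art, cfg, "E8.5", "WT", rng)
        merged, _ = callsmod.combine_strands(sample, art.genome)
        meth = tiles.feature_methylation(
            merged, art.cgis[["feature_id", "chrom", "start", "end"]], min_cpg=1
        )
        assert (meth == 0).all()

    def test_gdmr_aggregate_near_half_at_high_depth(self):
        counts = dict(NO_CGIS, gdmr=2)
        cfg = SimulationConfig(seed=13, n_chromosomes=2, chrom_length=80_000,
                               n_cgis_per_class=counts, n_genes=4, n_te=2,
                               mean_depth=1000, conversion_error=0.0,
                               gdmr_allele_meth=1.0, gdmr_allele_unmeth=0.0)
        art = simulate.generate_genome(cfg)
        sample, _ = simulate.simulate_sample(art, cfg, "E8.5", "WT", np.random.default_rng(2))
        merged, _ = callsmod.combine_strands(sample, art.genome)
        feats = art.cgis[["feature_id", "chrom", "start", "end"]]
        meth = tiles.feature_methylation(merged, feats)
        for f in feats.itertuples():
            cov = merged.query("chrom == @f.chrom and @f.start <= pos < @f.end")["n_total"].sum()
            assert abs(meth[f.feature_id] - 0.5) < 3 * np.sqrt(0.25 / cov)

    def test_parameter_recovery_within_binomial_noise(self, small_config, small_artifacts, small_qc_samples):
        """Pooled feature estimates track their truth probabilities."""
        lookup = simulate.truth_lookup(small_artifacts.truth)
        feats = small_artifacts.cgis[["feature_id", "chrom", "start", "end"]]
        calls = small_qc_samples["WT_E8.5"]
        meth = tiles.feature_methylation(calls, feats)
        for f in small_artifacts.cgis.itertuples():
            p_true = 0.5 * (
                lookup[(f.feature_id, "E8.5", "WT", "mat")]
                + lookup[(f.feature_id, "E8.5", "WT", "pat")]
            )
            e = small_config.conversion_error
            p_true = p_true * (1 - e) + (1 - p_true) * e
            cov = calls.query("chrom == @f.chrom and @f.start <= pos < @f.end")["n_total"].sum()
            if cov < 200:
                continue
            sd = np.sqrt(max(p_true * (1 - p_true), 0.25 / cov) / cov)
            assert abs(meth[f.feature_id] - p_true) < 3 * max(sd, 0.01), f.feature_id

    def test_bulk_median_recovers_configured_kinetics(self, small_config, small_artifacts, small_qc_samples):
        cgi_mask = small_artifacts.cgis
        for stage, p in zip(("E4.5", "E5.5"), (0.12, 0.62)):
            t = tiles.make_tiles(small_qc_samples[f"WT_{stage}"])
            # restrict to tiles not touching any planted island
            keep = []
            for r in t.itertuples():
                hit = cgi_mask[(cgi_mask["chrom"] == r.chrom) & (cgi_mask["start"] < r.end) & (cgi_mask["end"] > r.start)]
                keep.append(len(hit) == 0)
            vals = t[np.array(keep)]["methylation"].dropna()
            n_med = t[np.array(keep)]["n_total"].median()
            sd = np.sqrt(p * (1 - p) / n_med)
            assert abs(vals.median() - p) < 3 * sd

    def test_missing_truth_record_is_hard_error(self, small_config, small_artifacts):
        broken = dataclasses.replace(small_config)
        art = simulate.GenomeArtifacts(
            genome=small_artifacts.genome,
            genes=small_artifacts.genes,
            tes=small_artifacts.tes,
            cgis=small_artifacts.cgis,
            truth=small_artifacts.truth.query("cgi_class != 'slow'"),
            x_chroms=small_artifacts.x_chroms,
            noncpg_sites=small_artifacts.noncpg_sites,
        )
        with pytest.raises(KeyError, match="missing truth record"):
            simulate.simulate_sample(art, broken, "E8.5", "WT", np.random.default_rng(0))

    def test_xlinked_gain_is_dnmt3b_dependent(self, small_artifacts, small_qc_samples):
        feats = small_artifacts.cgis.query("cgi_class == 'xlinked'")[
            ["feature_id", "chrom", "start", "end"]
        ]
        wt = tiles.feature_methylation(small_qc_samples["WT_E8.5"], feats)
        ko = tiles.feature_methylation(small_qc_samples["Dnmt3bKO_E8.5"], feats)
        assert (wt > 0.2).all()  # female WT gains pm-like methylation on X
        assert (ko < 0.1).all()  # absent in the Dnmt3b knockout


class TestWriteDataset:
    def test_files_round_trip(self, tmp_path, small_config, small_artifacts, small_data):
        out = tmp_path / "ds"
        simulate.write_dataset(small_artifacts, small_data, str(out))
        from methkin.genome import load_fasta
        from methkin.genemodels import read_bed12

        genome = load_fasta(str(out / "genome.fa"))
        assert genome == small_artifacts.genome
        genes = read_bed12(str(out / "genes.bed"))
        assert len(genes) == len(small_artifacts.genes)
        back = callsmod.read_calls(str(out / "calls" / "WT_E8.5.cov"), "bismark_cov")
        orig = small_data.samples["WT_E8.5"]
        assert back["n_total"].sum() == orig["n_total"].sum()
        truth = pd.read_csv(out / "truth.tsv", sep="\t")
        assert len(truth) == len(small_artifacts.truth)
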