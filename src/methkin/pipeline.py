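"""End-to-end pipeline: QC -> CGI calls -> tiles -> kinetics -> knockouts -> summary.

Every output TSV is stamped with a hash of the full run configuration, rows
are sorted and floats written with a fixed format, so a rerun with the same
config and inputs is byte-identical.
"""
from __future__ import annotations

import logging
import os
import time

import numpy as np
import pandas as pd
import yaml

from . import calls as callsmod
from . import cgi as cgimod
from . import cgiclasses, knockout, simulate, tiles
from .config import RunConfig, _stage_time
from .genemodels import read_bed12
from .genome import load_fasta

log = logging.getLogger("methkin")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its inputs."""


def _write_tsv(df: pd.DataFrame, path: str, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_output(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _stage_order(stages) -> list[str]:
    return sorted(set(stages), key=_stage_time)


def _pool_counts(frames: list[pd.DataFrame]) -> pd.DataFrame:
    df = pd.concat(frames, ignore_index=True)
    out = df.groupby(["chrom", "pos"], as_index=False, sort=True)[["n_meth", "n_total"]].sum()
    out.insert(2, "strand", "merged")
    return out


def run_pipeline(config: RunConfig) -> str:
    """Run all stages into ``config.out_dir`` and return that directory."""
    t0 = time.time()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    cfg_hash = config.config_hash()
    handler = logging.FileHandler(os.path.join(out, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out, cfg_hash, t0)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: str, cfg_hash: str, t0: float) -> str:
    snapshot = config.to_dict()
    snapshot.pop("out_dir", None)  # the directory itself records the location
    with open(os.path.join(out, "config.yaml"), "w") as fh:
        yaml.safe_dump(snapshot, fh, sort_keys=True)

    # ---- stage 0: inputs -------------------------------------------------
    if config.simulation is not None:
        sim_cfg = config.simulation
        inputs = os.path.join(out, "inputs")
        artifacts = simulate.generate_genome(sim_cfg)
        data = simulate.simulate_methylomes(artifacts, sim_cfg)
        simulate.write_dataset(artifacts, data, inputs)
        genome = artifacts.genome
        genes = artifacts.genes
        dmr_annot = artifacts.cgis[artifacts.cgis["cgi_class"].isin(["gdmr", "sdmr"])][
            ["feature_id", "chrom", "start", "end", "cgi_class"]
        ].rename(columns={"cgi_class": "claimed"})
        dmr_annot["claimed"] = dmr_annot["claimed"].map({"gdmr": "gDMR", "sdmr": "sDMR"})
        sheet = data.sample_sheet.copy()
        sheet["path"] = [os.path.join(inputs, "calls", f"{s}.cov") for s in sheet["sample_id"]]
        sheet["noncpg_path"] = [
            os.path.join(inputs, "noncpg", f"{s}.cov") for s in sheet["sample_id"]
        ]
        x_chroms = tuple(artifacts.x_chroms)
        dialect = "bismark_cov"
    else:
        if not (config.sample_sheet and config.genome_fasta):
            raise PipelineError("inputs: need a sample sheet and a genome FASTA (or a simulation block)")
        sheet = pd.read_csv(config.sample_sheet, sep="\t")
        if len(sheet) == 0:
            raise PipelineError("inputs: empty sample sheet")
        genome = load_fasta(config.genome_fasta)
        genes = read_bed12(config.genes_bed) if config.genes_bed else pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "strand", "exon_starts", "exon_ends"]
        )
        if config.dmr_bed:
            dmr_annot = pd.read_csv(
                config.dmr_bed, sep="\t", header=None,
                names=["chrom", "start", "end", "feature_id", "claimed"],
            )
        else:
            dmr_annot = pd.DataFrame(columns=["feature_id", "chrom", "start", "end", "claimed"])
        x_chroms = tuple(config.x_chroms)
        dialect = sheet["dialect"].iloc[0] if "dialect" in sheet else "bismark_cov"
    log.info("inputs ready (%.1fs)", time.time() - t0)

    # ---- stage 1: QC -----------------------------------------------------
    qc_rows = []
    filtered: dict[str, pd.DataFrame] = {}
    for row in sheet.itertuples():
        raw = callsmod.read_calls(row.path, dialect)
        merged, sqc = callsmod.combine_strands(raw, genome)
        kept = callsmod.filter_depth(merged, config.min_depth)
        filtered[row.sample_id] = kept
        eff = None
        nc_path = getattr(row, "noncpg_path", None)
        if nc_path and os.path.exists(nc_path):
            eff = callsmod.conversion_efficiency(callsmod.read_calls(nc_path, dialect))
        qc_rows.append(
            (
                row.sample_id, row.stage, row.genotype, sqc.n_input, sqc.n_merged_sites,
                sqc.n_non_cpg_dropped, len(kept),
                f"{eff:.6g}" if eff is not None else "NA",
            )
        )
    qc = pd.DataFrame(
        qc_rows,
        columns=[
            "sample_id", "stage", "genotype", "n_calls_in", "n_sites_merged",
            "n_non_cpg_dropped", "n_sites_depth_filtered", "conversion_efficiency",
        ],
    )
    _write_tsv(qc, os.path.join(out, "qc_report.tsv"), cfg_hash)
    log.info("qc done (%.1fs)", time.time() - t0)

    # pooled calls per (genotype, stage)
    pooled: dict[tuple[str, str], pd.DataFrame] = {}
    for (gt, stage), grp in sheet.groupby(["genotype", "stage"]):
        pooled[(gt, stage)] = _pool_counts([filtered[s] for s in grp["sample_id"]])

    wt_stages = _stage_order(sheet.loc[sheet["genotype"] == "WT", "stage"])
    if not wt_stages:
        raise PipelineError("qc: no WT samples in the sample sheet")
    first_stage, last_stage = wt_stages[0], wt_stages[-1]
    ko_genotypes = [g for g in sheet["genotype"].unique() if g != "WT"]

    # ---- stage 2: CGI calls ----------------------------------------------
    cgis = cgimod.call_cgis(genome)
    cgis.insert(0, "feature_id", [f"CGI_{i:04d}" for i in range(len(cgis))])
    cgis["category"] = (
        cgimod.categorize(cgis, genes) if len(genes) else "intergenic"
    )
    _write_tsv(cgis, os.path.join(out, "cgi_calls.tsv"), cfg_hash)
    cgimod.write_cgi_bed(cgis, os.path.join(out, "cgi_calls.bed"), extra_cols=["category"])
    log.info("cgi calls done: %d islands (%.1fs)", len(cgis), time.time() - t0)

    # ---- stage 3: tiles --------------------------------------------------
    pooled_named = {f"{gt}:{st}": df for (gt, st), df in pooled.items()}
    matrix = tiles.tile_matrix(
        pooled_named, tile_size=config.tile_size, min_cpg=config.min_cpg_per_tile
    )
    _write_tsv(matrix.reset_index(), os.path.join(out, "tiles.tsv"), cfg_hash)
    log.info("tiling done: %d tiles (%.1fs)", len(matrix), time.time() - t0)

    # ---- stage 4: kinetics and CGI classes --------------------------------
    trans_rows = []
    for s_a, s_b in zip(wt_stages, wt_stages[1:]):
        n_gain, n_loss, _ = tiles.transition_changes(
            matrix[f"WT:{s_a}"], matrix[f"WT:{s_b}"], delta=config.transition_delta
        )
        trans_rows.append((s_a, s_b, n_gain, n_loss))
    transitions = pd.DataFrame(trans_rows, columns=["from", "to", "n_gain", "n_loss"])
    _write_tsv(transitions, os.path.join(out, "transitions.tsv"), cfg_hash)

    dn = tiles.de_novo_set(
        matrix[f"WT:{first_stage}"], matrix[f"WT:{last_stage}"],
        low=config.de_novo_low, high=config.de_novo_high,
    )
    wt_cols = [f"WT:{s}" for s in wt_stages]
    dn_summary = tiles.kinetics_summary(
        matrix.loc[dn, wt_cols].rename(columns=dict(zip(wt_cols, wt_stages)))
    ) if len(dn) else pd.DataFrame(columns=["stage", "median", "q25", "q75", "n"])
    _write_tsv(dn_summary, os.path.join(out, "denovo_kinetics.tsv"), cfg_hash)

    cgi_feats = cgis[["feature_id", "chrom", "start", "end"]]
    series = pd.DataFrame(
        {
            st: tiles.feature_methylation(pooled[("WT", st)], cgi_feats, config.min_cpg_per_tile)
            for st in wt_stages
        }
    )
    ko_e85 = {
        gt: tiles.feature_methylation(pooled[(gt, last_stage)], cgi_feats, config.min_cpg_per_tile)
        for gt in ko_genotypes
        if (gt, last_stage) in pooled
    }
    series_out = series.copy()
    for gt, vals in ko_e85.items():
        series_out[f"{gt}:{last_stage}"] = vals
    _write_tsv(
        series_out.rename_axis("feature_id").reset_index(),
        os.path.join(out, "cgi_series.tsv"), cfg_hash,
    )

    speed = pd.Series(
        [
            tiles.classify_speed(
                row.get("E3.5", np.nan), row.get("E5.5", np.nan), row.get("E8.5", np.nan)
            )
            for _, row in series.iterrows()
        ],
        index=series.index,
        name="speed",
    )
    meth_class = series[last_stage].map(cgiclasses.classify_methylation)
    cgi_table = cgis.assign(
        methylation_last=series[last_stage].to_numpy(),
        speed=speed.to_numpy(),
        meth_class=meth_class.to_numpy(),
    )
    class_matrix = (
        cgi_table.pivot_table(
            index="category", columns="meth_class", values="feature_id", aggfunc="count", fill_value=0
        )
        .rename_axis(None, axis=1)
        .reset_index()
    )
    _write_tsv(class_matrix, os.path.join(out, "cgi_class_matrix.tsv"), cfg_hash)

    pm = cgiclasses.call_pmcgis(
        cgi_table.rename(columns={"methylation_last": "methylation"}),
        imprinted_dmrs=dmr_annot if len(dmr_annot) else None,
        x_chroms=x_chroms,
        band=tuple(config.pm_band),
    )
    _write_tsv(
        pm[["feature_id", "chrom", "start", "end", "methylation", "category"]],
        os.path.join(out, "pmcgi.tsv"), cfg_hash,
    )
    log.info("kinetics/classes done (%.1fs)", time.time() - t0)

    # ---- stage 5: knockouts ----------------------------------------------
    ko_rows = []
    targets = pd.DataFrame(columns=["chrom", "start", "end", "n_tiles"])
    if ko_genotypes:
        wt_col = f"WT:{last_stage}"
        for gt in ko_genotypes:
            col = f"{gt}:{last_stage}"
            if col not in matrix:
                continue
            deltas = knockout.delta_tiles(matrix[wt_col], matrix[col])
            n_loss, n_gain = knockout.changed_tiles(deltas, config.ko_delta)
            ko_rows.append((gt, n_loss, n_gain, len(deltas)))
            if gt == "Dnmt3bKO":
                targets = knockout.call_dnmt3b_targets(
                    deltas, config.dnmt3b_target_delta, config.tile_size
                )
        box = knockout.genotype_distribution_stats(
            matrix[[wt_col] + [f"{g}:{last_stage}" for g in ko_genotypes if f"{g}:{last_stage}" in matrix]],
            wt_column=wt_col,
        )
        _write_tsv(box, os.path.join(out, "ko_boxstats.tsv"), cfg_hash)
    ko_changed = pd.DataFrame(ko_rows, columns=["genotype", "n_loss", "n_gain", "n_tiles_compared"])
    _write_tsv(ko_changed, os.path.join(out, "ko_changed_tiles.tsv"), cfg_hash)
    _write_tsv(targets, os.path.join(out, "dnmt3b_targets.tsv"), cfg_hash)
    targets.to_csv(os.path.join(out, "dnmt3b_targets.bed"), sep="\t", header=False, index=False)

    # ---- stage 6: DMR classification --------------------------------------
    dmr_rows = []
    if len(dmr_annot):
        feats = dmr_annot.rename(columns={"claimed": "type_claimed"})[
            ["feature_id", "chrom", "start", "end", "type_claimed"]
        ]
        dmr_series = pd.DataFrame(
            {
                st: tiles.feature_methylation(pooled[("WT", st)], feats, config.min_cpg_per_tile)
                for st in wt_stages
            }
        )
        dmr_ko = {
            gt: tiles.feature_methylation(pooled[(gt, last_stage)], feats, config.min_cpg_per_tile)
            for gt in ko_genotypes
            if (gt, last_stage) in pooled
        }
        for fid in feats["feature_id"]:
            wt_vals = {st: dmr_series.loc[fid, st] for st in wt_stages}
            ko_vals = {gt: dmr_ko[gt].loc[fid] for gt in dmr_ko}
            label, reason = knockout.classify_dmr(wt_vals, ko_vals)
            claimed = feats.set_index("feature_id").loc[fid, "type_claimed"]
            dmr_rows.append(
                (fid, claimed, label, reason,
                 f"{wt_vals.get('E3.5', np.nan):.4g}", f"{wt_vals.get(last_stage, np.nan):.4g}")
            )
    dmr_calls = pd.DataFrame(
        dmr_rows,
        columns=["feature_id", "type_claimed", "type_called", "reason", "wt_early", "wt_late"],
    )
    _write_tsv(dmr_calls, os.path.join(out, "dmr_calls.tsv"), cfg_hash)
    log.info("knockout/DMR done (%.1fs)", time.time() - t0)

    # ---- stage 7: summary -------------------------------------------------
    summary_rows = [
        ("n_samples", len(sheet)),
        ("n_cgis_called", len(cgis)),
        ("n_tiles", len(matrix)),
        ("n_de_novo_tiles", len(dn)),
        ("n_slow_cgis", int((speed == "slow").sum())),
        ("n_fast_cgis", int((speed == "fast").sum())),
        ("n_pmcgis", len(pm)),
        ("n_dnmt3b_targets", len(targets)),
        ("n_gdmr_called", int((dmr_calls["type_called"] == "gDMR").sum()) if len(dmr_calls) else 0),
        ("n_sdmr_called", int((dmr_calls["type_called"] == "sDMR").sum()) if len(dmr_calls) else 0),
    ]
    summary = pd.DataFrame(summary_rows, columns=["statistic", "value"])
    _write_tsv(summary, os.path.join(out, "summary.tsv"), cfg_hash)
    log.info("pipeline complete (%.1fs)", time.time() - t0)
    return out


# ---------------------------------------------------------------------------
# report

OUTPUT_FILES = {
    "qc": "qc_report.tsv",
    "transitions": "transitions.tsv",
    "cgi_matrix": "cgi_class_matrix.tsv",
    "denovo": "denovo_kinetics.tsv",
    "ko": "ko_changed_tiles.tsv",
    "boxstats": "ko_boxstats.tsv",
    "dmr": "dmr_calls.tsv",
    "summary": "summary.tsv",
}


def summarize(run_dir: str) -> str:
    """Human-readable report over a completed run directory.

    Missing sections (e.g. no knockout samples) are flagged, not fatal.
    """
    lines: list[str] = ["# methkin run report", f"run directory: {run_dir}", ""]

    def section(title: str, key: str, fmt=None) -> None:
        lines.append(f"## {title}")
        path = os.path.join(run_dir, OUTPUT_FILES[key])
        if not os.path.exists(path):
            lines.append("[absent]")
        else:
            df = read_output(path)
            if len(df) == 0:
                lines.append("[no rows]")
            else:
                lines.append(df.to_string(index=False))
        lines.append("")

    section("Sample QC and conversion efficiency", "qc")
    section("Tiles changed per developmental transition", "transitions")
    section("De novo methylation kinetics (median / quartiles)", "denovo")
    section("CGI category x methylation class", "cgi_matrix")
    section("Knockout changed tiles", "ko")
    section("Knockout methylation distributions", "boxstats")
    section("Imprinted DMR classification", "dmr")
    section("Headline statistics", "summary")
    return "\n".join(lines)
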