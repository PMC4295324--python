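"""Synthetic genome and staged RRBS-like methylome generator with known truth.

The generator plants CpG islands of known kinetic classes into a
CpG-depleted background genome, then draws per-CpG methylated/total read
counts per sample as binomial samples around class-, stage-, genotype- and
allele-specific truth probabilities:

* ``protected`` — CGIs that stay unmethylated throughout development;
* ``fast``/``slow`` — CGIs gaining methylation with bulk-like or delayed
  kinetics (slow and pm CGIs lose their gain in the Dnmt3b knockout);
* ``pm`` — partially methylated CGIs: the same sparse per-CpG probability
  on both alleles (no allele asymmetry);
* ``gdmr`` — imprinted germline DMRs: one allele fully methylated at every
  stage and in every genotype, the other unmethylated (~50% aggregate);
* ``sdmr`` — somatic DMRs: one allele gains methylation after implantation
  in a DNMT3B-dependent manner;
* ``xlinked`` — X-chromosome CGIs gaining pm-like methylation in female
  embryos, DNMT3B-dependently.

Two haplotypes are simulated explicitly and collapsed for count output, so
allele labels never leak into the emitted data; read patterns (binary
per-CpG states of single molecules) retain only the aggregate signal a
sequencer would see. All kinetic shapes are generative stand-ins for
empirical trajectories, anchored at a bulk gain from 12% (E4.5) to 62%
(E5.5).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calls as callsmod
from .cgiclasses import write_patterns
from .config import SimulationConfig
from .genemodels import GENE_COLUMNS, write_bed12
from .genome import write_fasta

BASES = np.frombuffer(b"ACGT", dtype="S1")

CGI_CONTEXTS = ("tss", "exon", "intron", "intergenic")

# gene element internal layout (relative, 0-based half-open)
GENE_LEN = 6000
EXONS_REL = ((0, 600), (2600, 3400), (5400, 6000))
CGI_REL_START = {"tss": -200, "exon": 2700, "intron": 3800}


class CapacityError(ValueError):
    """Requested features do not fit into the configured genome."""


@dataclass
class GenomeArtifacts:
    genome: dict[str, str]
    genes: pd.DataFrame
    tes: pd.DataFrame
    cgis: pd.DataFrame  # feature_id, cgi_class, context, chrom, start, end
    truth: pd.DataFrame  # long: feature_id, cgi_class, stage, genotype, allele, p
    x_chroms: tuple
    noncpg_sites: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# truth kinetics


def truth_probability(
    cgi_class: str, stage_idx: int, genotype: str, allele: str, config: SimulationConfig,
    sex: str = "F",
) -> float:
    """True per-CpG methylation probability for one class/stage/genotype/allele."""
    if cgi_class == "background":
        p = config.bulk_kinetics[stage_idx]
        if genotype in ("Dnmt3aKO", "Dnmt3bKO"):
            p = max(p - config.ko_bulk_offset, 0.01)
    elif cgi_class == "protected":
        p = config.protected_level
    elif cgi_class == "fast":
        kin = config.fast_cgi_kinetics
        p = kin[stage_idx]
        if genotype == "Dnmt3bKO":
            p = max(p - config.fast_3bko_offset, kin[0])
        elif genotype == "Dnmt3aKO":
            p = max(p - config.fast_3ako_offset, kin[0])
    elif cgi_class == "slow":
        kin = config.slow_cgi_kinetics
        p = kin[0] if genotype == "Dnmt3bKO" else kin[stage_idx]
    elif cgi_class == "pm":
        kin = config.pm_kinetics
        p = kin[0] if genotype == "Dnmt3bKO" else kin[stage_idx]
    elif cgi_class == "gdmr":
        p = config.gdmr_allele_meth if allele == "mat" else config.gdmr_allele_unmeth
    elif cgi_class == "sdmr":
        if allele == "pat":
            p = config.sdmr_pat_level
        else:
            kin = config.sdmr_mat_kinetics
            p = kin[0] if genotype == "Dnmt3bKO" else kin[stage_idx]
    elif cgi_class == "xlinked":
        kin = config.pm_kinetics
        if sex == "M" or genotype == "Dnmt3bKO":
            p = kin[0]
        else:
            p = kin[stage_idx]
    else:
        raise KeyError(f"unknown truth class {cgi_class!r}")
    return float(p)


def build_truth_table(cgis: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Long-format truth: one row per feature, stage, genotype and allele.

    A pseudo-feature ``background`` carries the bulk (non-CGI) kinetics.
    """
    rows = []
    feats = [("background", "background", "*", -1, -1)] + [
        (r.feature_id, r.cgi_class, r.chrom, r.start, r.end) for r in cgis.itertuples()
    ]
    for fid, cls, chrom, start, end in feats:
        for si, stage in enumerate(config.stage_list):
            for gt in config.genotypes:
                for allele in ("mat", "pat"):
                    rows.append(
                        (
                            fid,
                            cls,
                            chrom,
                            start,
                            end,
                            stage,
                            gt,
                            allele,
                            truth_probability(cls, si, gt, allele, config, config.sex),
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "cgi_class", "chrom", "start", "end",
            "stage", "genotype", "allele", "p",
        ],
    )


def truth_lookup(truth: pd.DataFrame) -> dict:
    """(feature_id, stage, genotype, allele) -> probability."""
    return {
        (r.feature_id, r.stage, r.genotype, r.allele): r.p for r in truth.itertuples()
    }


# ---------------------------------------------------------------------------
# sequence generation


def _background_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    """CpG-depleted background: ~40% GC i.i.d. draws, then 80% of CpG
    dinucleotides broken by mutating the G. Residual CpG O/E is ~0.2."""
    codes = rng.choice(4, size=length, p=[0.30, 0.20, 0.20, 0.30])
    cg = np.flatnonzero((codes[:-1] == 1) & (codes[1:] == 2))
    broken = cg[rng.random(len(cg)) < 0.8] + 1
    codes[broken] = rng.choice([0, 3], size=len(broken))
    return codes


def _island_seq(rng: np.random.Generator, length: int, max_tries: int = 50) -> np.ndarray:
    """A CpG-island sequence: every 150 bp window has GC > 0.57 and CpG
    O/E > 0.72 (margin over the caller thresholds so grid placement cannot
    break recovery)."""
    for _ in range(max_tries):
        out = []
        while len(out) < length:
            if rng.random() < 0.17:
                out.extend((1, 2))  # CpG dinucleotide
            else:
                out.append(rng.choice(4, p=[0.175, 0.325, 0.325, 0.175]))
        codes = np.asarray(out[:length], dtype=np.int64)
        if _island_ok(codes):
            return codes
    raise RuntimeError("could not generate a qualifying CGI sequence")


def _island_ok(codes: np.ndarray, window: int = 150, min_gc: float = 0.57, min_ratio: float = 0.72) -> bool:
    L = len(codes)
    is_c = (codes == 1).astype(np.int64)
    is_g = (codes == 2).astype(np.int64)
    is_cg = np.zeros(L, dtype=np.int64)
    is_cg[:-1] = (codes[:-1] == 1) & (codes[1:] == 2)
    cum = lambda x: np.concatenate(([0], np.cumsum(x)))
    cc, cg_, ccg = cum(is_c), cum(is_g), cum(is_cg)
    starts = np.arange(0, L - window + 1)
    if len(starts) == 0:
        starts = np.array([0])
        window = L
    ends = starts + window
    n_c = cc[ends] - cc[starts]
    n_g = cg_[ends] - cg_[starts]
    n_cpg = ccg[ends - 1] - ccg[starts]
    gc = (n_c + n_g) / window
    ratio = np.where(n_c * n_g > 0, n_cpg * window / np.maximum(n_c * n_g, 1), 0.0)
    # also require the full-length composition to clear the caller thresholds
    tc, tg, tcg = int(is_c.sum()), int(is_g.sum()), int(is_cg.sum())
    full_gc = (tc + tg) / L
    full_ratio = tcg * L / (tc * tg) if tc * tg else 0.0
    return bool(
        (gc > min_gc).all() and (ratio > min_ratio).all()
        and full_gc > 0.55 and full_ratio > 0.65
    )


# ---------------------------------------------------------------------------
# genome layout


def generate_genome(config: SimulationConfig) -> GenomeArtifacts:
    """Build the toy genome, annotations and truth table.

    Features (genes, TEs and planted CGIs in their four genomic contexts)
    are laid out sequentially per chromosome with 2.5-3.5 kb background
    gaps; a genome too small for the requested features raises
    :class:`CapacityError`.
    """
    rng = np.random.default_rng([int(config.seed), 11])
    n_chrom = config.n_chromosomes
    if config.x_chrom:
        if n_chrom < 2:
            raise CapacityError("x_chrom requires at least 2 chromosomes")
        chrom_names = [f"chr{i + 1}" for i in range(n_chrom - 1)] + ["chrX"]
        autosomes = chrom_names[:-1]
        x_chroms = ("chrX",)
    else:
        chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
        autosomes = list(chrom_names)
        x_chroms = ()

    # CGI specs: class x context, round-robin over the target chromosome pool
    cgi_specs = []
    for cls in sorted(config.n_cgis_per_class):
        for i in range(config.n_cgis_per_class[cls]):
            cgi_specs.append(
                {
                    "feature_id": f"{cls}_{i:03d}",
                    "cgi_class": cls,
                    "context": CGI_CONTEXTS[i % len(CGI_CONTEXTS)],
                    "length": int(rng.integers(config.min_cgi_len, config.max_cgi_len + 1)),
                }
            )
    n_hosted = sum(1 for s in cgi_specs if s["context"] != "intergenic")
    if n_hosted > config.n_genes:
        raise CapacityError(
            f"{n_hosted} CGI-hosting genes required but n_genes={config.n_genes}"
        )

    # distribute elements to chromosomes
    elements: dict[str, list] = {c: [] for c in chrom_names}
    gene_counter = 0
    for k, spec in enumerate(cgi_specs):
        pool = ["chrX"] if (spec["cgi_class"] == "xlinked" and config.x_chrom) else autosomes
        chrom = pool[k % len(pool)]
        if spec["context"] == "intergenic":
            elements[chrom].append({"kind": "cgi", "spec": spec})
        else:
            elements[chrom].append(
                {"kind": "gene", "gene_id": f"gene{gene_counter:03d}", "spec": spec}
            )
            gene_counter += 1
    for j in range(config.n_genes - gene_counter):
        chrom = chrom_names[j % len(chrom_names)]
        elements[chrom].append(
            {"kind": "gene", "gene_id": f"gene{gene_counter + j:03d}", "spec": None}
        )
    for j in range(config.n_te):
        chrom = autosomes[j % len(autosomes)]
        elements[chrom].append(
            {"kind": "te", "te_id": f"te{j:03d}", "length": int(rng.integers(300, 801))}
        )

    genome: dict[str, str] = {}
    gene_rows, te_rows, cgi_rows = [], [], []
    for chrom in chrom_names:
        codes = _background_seq(rng, config.chrom_length)
        order = rng.permutation(len(elements[chrom]))
        cursor = int(rng.integers(2500, 3501))
        for oi in order:
            el = elements[chrom][oi]
            el_len = (
                el["length"] if el["kind"] == "te"
                else el["spec"]["length"] if el["kind"] == "cgi"
                else GENE_LEN
            )
            if cursor + el_len > config.chrom_length - 1000:
                raise CapacityError(
                    f"features exceed available space on {chrom} "
                    f"(need > {cursor + el_len} bp, have {config.chrom_length})"
                )
            if el["kind"] == "te":
                te_rows.append((chrom, cursor, cursor + el["length"], el["te_id"]))
                cursor += el["length"]
            elif el["kind"] == "cgi":
                spec = el["spec"]
                L = spec["length"]
                codes[cursor : cursor + L] = _island_seq(rng, L)
                cgi_rows.append(
                    (spec["feature_id"], spec["cgi_class"], spec["context"], chrom, cursor, cursor + L)
                )
                cursor += L
            else:  # gene
                strand = "+" if rng.random() < 0.5 else "-"
                g_start = cursor
                exons = [(g_start + s, g_start + e) for s, e in EXONS_REL]
                gene_rows.append(
                    (
                        el["gene_id"], chrom, g_start, g_start + GENE_LEN, strand,
                        tuple(s for s, _ in exons), tuple(e for _, e in exons),
                    )
                )
                spec = el["spec"]
                if spec is not None:
                    L = spec["length"]
                    rel = CGI_REL_START[spec["context"]]
                    if strand == "-":
                        rel = GENE_LEN - (rel + L)
                    c_start = g_start + rel
                    codes[c_start : c_start + L] = _island_seq(rng, L)
                    cgi_rows.append(
                        (spec["feature_id"], spec["cgi_class"], spec["context"], chrom, c_start, c_start + L)
                    )
                cursor += GENE_LEN
            cursor += int(rng.integers(2500, 3501))
        genome[chrom] = b"".join(BASES[codes]).decode("ascii")

    genes = pd.DataFrame(gene_rows, columns=GENE_COLUMNS)
    tes = pd.DataFrame(te_rows, columns=["chrom", "start", "end", "te_id"])
    cgis = (
        pd.DataFrame(
            cgi_rows,
            columns=["feature_id", "cgi_class", "context", "chrom", "start", "end"],
        )
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )
    truth = build_truth_table(cgis, config)

    # fixed panel of non-CpG cytosines for conversion-efficiency QC
    noncpg: dict[str, np.ndarray] = {}
    per_chrom = max(config.n_noncpg_sites // len(chrom_names), 1)
    for chrom in chrom_names:
        arr = np.frombuffer(genome[chrom].encode("ascii"), dtype="S1")
        cand = np.flatnonzero((arr[:-1] == b"C") & (arr[1:] != b"G"))
        noncpg[chrom] = np.sort(rng.choice(cand, size=min(per_chrom, len(cand)), replace=False))

    return GenomeArtifacts(
        genome=genome, genes=genes, tes=tes, cgis=cgis, truth=truth,
        x_chroms=x_chroms, noncpg_sites=noncpg,
    )


# ---------------------------------------------------------------------------
# methylome simulation


@dataclass
class SimulatedData:
    sample_sheet: pd.DataFrame  # sample_id, stage, genotype, sex
    samples: dict[str, pd.DataFrame]  # strand-resolved CpG calls + non-CpG calls
    noncpg: dict[str, pd.DataFrame]  # non-CpG cytosine calls only
    patterns: pd.DataFrame  # single-molecule read patterns (final stage)


def _cpg_positions(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    return np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))


def _feature_index(pos: np.ndarray, feats: pd.DataFrame) -> np.ndarray:
    """Index into feats for each position (-1 = background). Features must
    be non-overlapping and sorted by start."""
    if len(feats) == 0:
        return np.full(len(pos), -1)
    starts = feats["start"].to_numpy()
    ends = feats["end"].to_numpy()
    idx = np.searchsorted(starts, pos, side="right") - 1
    inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
    return np.where(inside, idx, -1)


def simulate_sample(
    artifacts: GenomeArtifacts,
    config: SimulationConfig,
    stage: str,
    genotype: str,
    rng: np.random.Generator,
    sex: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one sample's strand-resolved CpG calls and non-CpG QC calls."""
    sex = sex or config.sex
    si = config.stage_index[stage]
    lookup = truth_lookup(artifacts.truth)
    e = config.conversion_error
    half = config.mean_depth / 2.0
    parts, nc_parts = [], []
    for chrom in sorted(artifacts.genome):
        pos = _cpg_positions(artifacts.genome[chrom])
        feats = artifacts.cgis[artifacts.cgis["chrom"] == chrom].sort_values("start").reset_index(drop=True)
        fidx = _feature_index(pos, feats)
        fids = np.array(["background"] + list(feats["feature_id"]), dtype=object)
        fid_per_pos = fids[fidx + 1]
        p_mat = np.empty(len(pos))
        p_pat = np.empty(len(pos))
        for fid in np.unique(fid_per_pos):
            try:
                pm = lookup[(fid, stage, genotype, "mat")]
                pp = lookup[(fid, stage, genotype, "pat")]
            except KeyError as exc:
                raise KeyError(f"missing truth record for feature {fid!r}") from exc
            sel = fid_per_pos == fid
            p_mat[sel], p_pat[sel] = pm, pp
        # symmetric read-level conversion error
        p_mat = p_mat * (1 - e) + (1 - p_mat) * e
        p_pat = p_pat * (1 - e) + (1 - p_pat) * e
        d_mat = rng.poisson(half, len(pos))
        d_pat = rng.poisson(half, len(pos))
        m_mat = rng.binomial(d_mat, p_mat)
        m_pat = rng.binomial(d_pat, p_pat)
        total = d_mat + d_pat
        meth = m_mat + m_pat
        keep = total > 0
        pos, total, meth = pos[keep], total[keep], meth[keep]
        # collapse haplotypes, then split counts over the two strands
        t_plus = rng.binomial(total, 0.5)
        m_plus = rng.hypergeometric(
            np.maximum(meth, 0), np.maximum(total - meth, 0), t_plus
        )
        for strand, p_, m_, t_ in (
            ("+", pos, m_plus, t_plus),
            ("-", pos + 1, meth - m_plus, total - t_plus),
        ):
            ok = t_ > 0
            parts.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos": p_[ok], "strand": strand,
                     "n_meth": m_[ok], "n_total": t_[ok]}
                )
            )
        # non-CpG cytosines: unconverted at the conversion-error rate
        ncpos = artifacts.noncpg_sites.get(chrom, np.empty(0, dtype=int))
        if len(ncpos):
            d = rng.poisson(config.mean_depth, len(ncpos))
            m = rng.binomial(d, e)
            ok = d > 0
            nc_parts.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos": ncpos[ok], "strand": "+",
                     "n_meth": m[ok], "n_total": d[ok]}
                )
            )
    calls = pd.concat(parts, ignore_index=True) if parts else callsmod.empty_calls()
    noncpg = pd.concat(nc_parts, ignore_index=True) if nc_parts else callsmod.empty_calls()
    full = pd.concat([calls, noncpg], ignore_index=True).sort_values(
        ["chrom", "pos", "strand"], kind="mergesort"
    ).reset_index(drop=True)
    return full, noncpg


def simulate_read_patterns(
    artifacts: GenomeArtifacts,
    config: SimulationConfig,
    stage: str,
    genotype: str,
    rng: np.random.Generator,
    sex: str | None = None,
) -> pd.DataFrame:
    """Single-molecule read patterns over every planted CGI for one sample.

    Each read picks one haplotype, covers a run of 3-6 consecutive CpGs and
    reports i.i.d. per-CpG states at the allele's truth probability (plus
    conversion error), so pmCGIs yield sparse unimodal and gDMRs bimodal
    read-score distributions by construction.
    """
    sex = sex or config.sex
    lookup = truth_lookup(artifacts.truth)
    e = config.conversion_error
    rows = []
    for feat in artifacts.cgis.itertuples():
        cpgs = _cpg_positions(artifacts.genome[feat.chrom][feat.start : feat.end]) + feat.start
        if len(cpgs) < config.read_cpgs_min:
            continue
        p_allele = {
            a: lookup[(feat.feature_id, stage, genotype, a)] * (1 - e)
            + (1 - lookup[(feat.feature_id, stage, genotype, a)]) * e
            for a in ("mat", "pat")
        }
        for r in range(config.reads_per_cgi):
            allele = "mat" if rng.random() < 0.5 else "pat"
            k = int(rng.integers(config.read_cpgs_min, config.read_cpgs_max + 1))
            k = min(k, len(cpgs))
            start = int(rng.integers(0, len(cpgs) - k + 1))
            states = (rng.random(k) < p_allele[allele]).astype(int)
            rows.append(
                (
                    f"{feat.feature_id}_r{r:04d}",
                    feat.feature_id,
                    feat.chrom,
                    tuple(int(x) for x in cpgs[start : start + k]),
                    tuple(states),
                )
            )
    return pd.DataFrame(rows, columns=["read_id", "cgi_id", "chrom", "positions", "states"])


def simulate_methylomes(
    artifacts: GenomeArtifacts, config: SimulationConfig
) -> SimulatedData:
    """Simulate the full staged/genotyped sample panel.

    WT is profiled at every stage; each knockout genotype at the configured
    knockout stages (final stage by default). Read patterns are generated
    for final-stage samples. Each sample draws from its own deterministic
    seed stream, so the panel composition never changes a sample's data.
    """
    sheet_rows = []
    for stage in config.stage_list:
        sheet_rows.append((f"WT_{stage}", stage, "WT", config.sex))
    for gt in config.genotypes:
        if gt == "WT":
            continue
        for stage in config.ko_stages:
            sheet_rows.append((f"{gt}_{stage}", stage, gt, config.sex))
    sheet = pd.DataFrame(sheet_rows, columns=["sample_id", "stage", "genotype", "sex"])

    samples: dict[str, pd.DataFrame] = {}
    noncpg: dict[str, pd.DataFrame] = {}
    pattern_parts = []
    last_stage = config.stage_list[-1]
    for row in sheet.itertuples():
        gi = list(config.genotypes).index(row.genotype)
        si = config.stage_index[row.stage]
        rng = np.random.default_rng([int(config.seed), 101, gi, si])
        full, nc = simulate_sample(artifacts, config, row.stage, row.genotype, rng, row.sex)
        samples[row.sample_id] = full
        noncpg[row.sample_id] = nc
        if row.stage == last_stage:
            prng = np.random.default_rng([int(config.seed), 202, gi, si])
            pats = simulate_read_patterns(artifacts, config, row.stage, row.genotype, prng, row.sex)
            pats.insert(0, "sample_id", row.sample_id)
            pattern_parts.append(pats)
    patterns = (
        pd.concat(pattern_parts, ignore_index=True)
        if pattern_parts
        else pd.DataFrame(columns=["sample_id", "read_id", "cgi_id", "chrom", "positions", "states"])
    )
    return SimulatedData(sample_sheet=sheet, samples=samples, noncpg=noncpg, patterns=patterns)


# ---------------------------------------------------------------------------
# on-disk dataset


def write_dataset(
    artifacts: GenomeArtifacts,
    data: SimulatedData,
    out_dir: str,
    dialect: str = "bismark_cov",
) -> None:
    """Write the synthetic dataset as plain-text files.

    genome.fa, genes.bed (BED12), te.bed, cgis_truth.bed, dmrs.bed (planted
    imprinted DMRs with claimed type), truth.tsv, sample_sheet.tsv,
    calls/<sample>.cov, noncpg/<sample>.cov, patterns.tsv.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    write_fasta(artifacts.genome, os.path.join(out_dir, "genome.fa"))
    write_bed12(artifacts.genes, os.path.join(out_dir, "genes.bed"))
    artifacts.tes.to_csv(os.path.join(out_dir, "te.bed"), sep="\t", header=False, index=False)
    artifacts.cgis[["chrom", "start", "end", "feature_id", "cgi_class", "context"]].to_csv(
        os.path.join(out_dir, "cgis_truth.bed"), sep="\t", header=False, index=False
    )
    dmrs = artifacts.cgis[artifacts.cgis["cgi_class"].isin(["gdmr", "sdmr"])]
    dmrs.assign(claimed=dmrs["cgi_class"].map({"gdmr": "gDMR", "sdmr": "sDMR"}))[
        ["chrom", "start", "end", "feature_id", "claimed"]
    ].to_csv(os.path.join(out_dir, "dmrs.bed"), sep="\t", header=False, index=False)
    artifacts.truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    data.sample_sheet.to_csv(os.path.join(out_dir, "sample_sheet.tsv"), sep="\t", index=False)
    os.makedirs(os.path.join(out_dir, "calls"), exist_ok=True)
    os.makedirs(os.path.join(out_dir, "noncpg"), exist_ok=True)
    for sid, df in data.samples.items():
        callsmod.write_calls(df, os.path.join(out_dir, "calls", f"{sid}.cov"), dialect)
    for sid, df in data.noncpg.items():
        callsmod.write_calls(df, os.path.join(out_dir, "noncpg", f"{sid}.cov"), dialect)
    write_patterns(data.patterns, os.path.join(out_dir, "patterns.tsv"))
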