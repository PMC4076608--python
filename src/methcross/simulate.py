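"""Ground-truthed RRBS-like data for an eight-sample reciprocal mouse cross.

The generator emulates the study design the package targets: two inbred
strains (B6, DBA) whose haplotypes differ at planted SNPs, reciprocal F1
hybrids (BXD: B6 mother; DXB: DBA mother), and read-level CpG methylation
drawn from per-haplotype levels.  Planted effects — strain-specific sites,
sex-specific sites, imprinted regions (maternal/paternal levels, independent
of genotype), and rare intergenerational epimutations — are recorded in truth
tables that downstream recovery tests score against.

Defaults follow the study conditions: ~60× coverage, <1% combined
error/non-conversion rate, CG methylation averaging 48.39% (drawn from a
low/high two-component mixture reflecting unmethylated CpG islands versus
high methylation elsewhere), CHG/CHH near zero (0.71%/0.75%).

Reads are modelled as fixed-width windows of consecutive CpGs; fragment
size selection is not simulated — coverage is modelled directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    CytosineSite,
    EpiRead,
    GenomicInterval,
    SampleMeta,
    aggregate_epireads,
    export_bed,
    standard_cross_samples,
)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TruthConfig:
    """Tunable knobs of the generator; defaults are the study conditions."""

    n_regions: int = 12
    region_length: int = 2000
    # haplotype divergence
    snp_rate: float = 0.008           # SNPs per bp among eligible bases
    ct_snp_fraction: float = 0.10     # fraction of SNPs that are C/T (unrecoverable)
    # context baselines (fractional methylation)
    cg_mean: float = 0.4839
    chg_mean: float = 0.0071
    chh_mean: float = 0.0075
    noncg_keep_fraction: float = 0.2  # subsample of non-CpG cytosines carried in site tables
    # planted effects
    n_strain_sites: int = 60
    strain_delta: float = 0.8
    n_sex_sites: int = 40
    sex_delta: float = 0.7
    n_imprinted_regions: int = 3
    imprinted_region_cpgs: int = 12
    imprinted_maternal_level: float = 0.95
    imprinted_paternal_level: float = 0.05
    n_epimutation_sites: int = 6
    epimutation_parent_level: float = 0.05
    epimutation_f1_level: float = 0.90
    # sequencing model
    coverage_mean: float = 60.0
    error_rate: float = 0.01
    read_width_cpgs: int = 6
    # biological replicate dispersion (s.d. of a logit-scale per-sample shift)
    sample_jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        for name in ("cg_mean", "chg_mean", "chh_mean", "error_rate",
                     "snp_rate", "ct_snp_fraction", "sample_jitter_sd"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in ("strain_delta", "sex_delta"):
            if not 0 < getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in (0, 1]")
        if self.imprinted_region_cpgs < 10:
            raise ConfigError("imprinted regions must span at least 10 CpGs")


F1_SAMPLES = ("BXD_F", "BXD_M", "DXB_F", "DXB_M")
PARENT_SAMPLES = ("B6_F", "B6_M", "DBA_F", "DBA_M")


# ---------------------------------------------------------------------------
# truth model
# ---------------------------------------------------------------------------

@dataclass
class TruthModel:
    """Everything the generator planted, the acceptance surface for recovery."""

    config: TruthConfig
    seed: int
    chroms: list[str]
    chrom_lengths: dict[str, int]
    sequences_b6: dict[str, str]
    sequences_dba: dict[str, str]
    cpg_positions: dict[str, np.ndarray]      # 1-based C of each + strand CpG
    baseline_levels: dict[str, np.ndarray]    # per-CpG baseline level
    noncg_sites: pd.DataFrame                 # chrom,pos,strand,context,level
    snps: pd.DataFrame                        # chrom,pos,b6,dba,recoverable
    strain_sites: pd.DataFrame                # chrom,pos,cpg_idx,b6_level,dba_level,delta
    sex_sites: pd.DataFrame                   # chrom,pos,cpg_idx,female_level,male_level,delta
    imprinted_regions: pd.DataFrame           # chrom,start,end,first_idx,n_cpgs,maternal,paternal
    epimutation_sites: pd.DataFrame           # chrom,pos,cpg_idx,strain,affected,parent_level,f1_level

    @property
    def parent_genotypes(self) -> dict[tuple[str, int], tuple[str, str]]:
        """SNP → (B6 allele, DBA allele) map, the phasing reference."""
        return {(r.chrom, int(r.pos)): (r.b6, r.dba)
                for r in self.snps.itertuples(index=False)}

    def n_cpgs(self) -> int:
        return int(sum(len(v) for v in self.cpg_positions.values()))


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)  # indices into _BASES


def _find_cpgs(seq_idx: np.ndarray) -> np.ndarray:
    """1-based positions of the C of every + strand CpG."""
    c, g = _BASE_INDEX["C"], _BASE_INDEX["G"]
    hits = np.flatnonzero((seq_idx[:-1] == c) & (seq_idx[1:] == g))
    return hits + 1


def _beta_params_for_mean(mean: float, a: float = 0.5) -> tuple[float, float]:
    return a, a * (1.0 - mean) / mean


def build_truth_model(config: TruthConfig | None = None,
                      seed: int = 0) -> TruthModel:
    """Deterministically build haplotypes, baselines and planted effects."""
    cfg = config or TruthConfig()
    rng = np.random.default_rng(seed)

    chroms = [f"chr{i + 1}" for i in range(cfg.n_regions)]
    sequences_b6: dict[str, str] = {}
    sequences_dba: dict[str, str] = {}
    cpg_positions: dict[str, np.ndarray] = {}
    baseline_levels: dict[str, np.ndarray] = {}
    snp_rows: list[tuple] = []
    noncg_rows: list[tuple] = []

    # CG baseline mixture: a mostly-unmethylated island component and a
    # highly methylated component, weighted to reach the configured mean.
    lo_a, lo_b = 0.5, 10.0
    hi_a, hi_b = 10.0, 2.5
    lo_mean = lo_a / (lo_a + lo_b)
    hi_mean = hi_a / (hi_a + hi_b)
    if not lo_mean < cfg.cg_mean < hi_mean:
        raise ConfigError(f"cg_mean {cfg.cg_mean} outside mixture range "
                          f"({lo_mean:.3f}, {hi_mean:.3f})")
    w_low = (hi_mean - cfg.cg_mean) / (hi_mean - lo_mean)

    for chrom in chroms:
        seq_idx = _random_sequence(rng, cfg.region_length)
        cpgs = _find_cpgs(seq_idx)
        cpg_positions[chrom] = cpgs

        low = rng.random(len(cpgs)) < w_low
        levels = np.where(low, rng.beta(lo_a, lo_b, len(cpgs)),
                          rng.beta(hi_a, hi_b, len(cpgs)))
        baseline_levels[chrom] = levels

        # SNP placement.  Clean SNPs are A/T substitutions (never part of a
        # CpG, never bisulfite-confounded); C/T SNPs are planted at non-CpG
        # cytosines to exercise the caller's exclusion rule.
        a_i, t_i, c_i, g_i = (_BASE_INDEX[b] for b in "ATCG")
        at_positions = np.flatnonzero((seq_idx == a_i) | (seq_idx == t_i)) + 1
        c_nonCpG = np.flatnonzero(
            (seq_idx[:-1] == c_i) & (seq_idx[1:] != g_i)) + 1
        n_snps = rng.poisson(cfg.snp_rate * cfg.region_length)
        n_ct = int(round(n_snps * cfg.ct_snp_fraction))
        n_clean = min(n_snps - n_ct, len(at_positions))
        n_ct = min(n_ct, len(c_nonCpG))
        dba_idx = seq_idx.copy()
        if n_clean > 0:
            chosen = rng.choice(at_positions, size=n_clean, replace=False)
            for pos in sorted(int(p) for p in chosen):
                ref = _BASES[seq_idx[pos - 1]]
                alt = "T" if ref == "A" else "A"
                dba_idx[pos - 1] = _BASE_INDEX[alt]
                snp_rows.append((chrom, pos, ref, alt, True))
        if n_ct > 0:
            chosen = rng.choice(c_nonCpG, size=n_ct, replace=False)
            for pos in sorted(int(p) for p in chosen):
                dba_idx[pos - 1] = t_i
                snp_rows.append((chrom, pos, "C", "T", False))

        sequences_b6[chrom] = "".join(_BASES[i] for i in seq_idx)
        sequences_dba[chrom] = "".join(_BASES[i] for i in dba_idx)

        # non-CpG cytosines carried site-wise in the methylation tables
        cpg_set = set(cpgs.tolist())
        ct_set = {r[1] for r in snp_rows if r[0] == chrom and not r[4]}
        for pos0 in np.flatnonzero(seq_idx == c_i):
            pos = int(pos0) + 1
            if pos in cpg_set or pos in ct_set:
                continue
            if rng.random() > cfg.noncg_keep_fraction:
                continue
            nxt2_is_g = pos + 1 < cfg.region_length and seq_idx[pos + 1] == g_i
            ctx = "CHG" if nxt2_is_g else "CHH"
            mean = cfg.chg_mean if ctx == "CHG" else cfg.chh_mean
            a, b = _beta_params_for_mean(mean)
            noncg_rows.append((chrom, pos, "+", ctx, float(rng.beta(a, b))))

    snps = pd.DataFrame(snp_rows,
                        columns=["chrom", "pos", "b6", "dba", "recoverable"])
    noncg = pd.DataFrame(noncg_rows,
                         columns=["chrom", "pos", "strand", "context", "level"])

    # ---- planted effects: sample disjoint CpG indices genome-wide ----------
    flat: list[tuple[str, int]] = []  # (chrom, cpg index)
    for chrom in chroms:
        flat.extend((chrom, i) for i in range(len(cpg_positions[chrom])))

    n_region_cpgs = cfg.n_imprinted_regions * cfg.imprinted_region_cpgs
    n_needed = (cfg.n_strain_sites + cfg.n_sex_sites
                + cfg.n_epimutation_sites + n_region_cpgs)
    if n_needed > len(flat):
        raise ConfigError(
            f"config plants {n_needed} effect CpGs but only {len(flat)} exist")

    # imprinted regions first: contiguous runs, one per chromosome where room
    used: set[tuple[str, int]] = set()
    imprint_rows = []
    region_chroms = rng.permutation(chroms)
    placed = 0
    for chrom in region_chroms:
        if placed == cfg.n_imprinted_regions:
            break
        cpgs = cpg_positions[chrom]
        if len(cpgs) < cfg.imprinted_region_cpgs:
            continue
        first = int(rng.integers(0, len(cpgs) - cfg.imprinted_region_cpgs + 1))
        idx = range(first, first + cfg.imprinted_region_cpgs)
        imprint_rows.append((chrom, int(cpgs[first]),
                             int(cpgs[idx[-1]]), first,
                             cfg.imprinted_region_cpgs,
                             cfg.imprinted_maternal_level,
                             cfg.imprinted_paternal_level))
        used.update((chrom, i) for i in idx)
        placed += 1
    if placed < cfg.n_imprinted_regions:
        raise ConfigError("not enough chromosomes with room for imprinted regions")
    imprinted = pd.DataFrame(imprint_rows, columns=[
        "chrom", "start", "end", "first_idx", "n_cpgs",
        "maternal_level", "paternal_level"])

    free = [x for x in flat if x not in used]
    order = rng.permutation(len(free))
    picks = [free[i] for i in order]

    def take(n: int) -> list[tuple[str, int]]:
        nonlocal picks
        got, picks = picks[:n], picks[n:]
        return got

    def _rows(sites, hi, lo):
        rows = []
        for chrom, i in sites:
            pos = int(cpg_positions[chrom][i])
            flip = rng.random() < 0.5
            a, b = (lo, hi) if flip else (hi, lo)
            rows.append((chrom, pos, i, a, b, abs(a - b)))
        return rows

    d = cfg.strain_delta / 2
    strain = pd.DataFrame(
        _rows(take(cfg.n_strain_sites), 0.5 + d, 0.5 - d),
        columns=["chrom", "pos", "cpg_idx", "b6_level", "dba_level", "delta"])
    d = cfg.sex_delta / 2
    sex = pd.DataFrame(
        _rows(take(cfg.n_sex_sites), 0.5 + d, 0.5 - d),
        columns=["chrom", "pos", "cpg_idx", "female_level", "male_level", "delta"])

    epi_rows = []
    for k, (chrom, i) in enumerate(take(cfg.n_epimutation_sites)):
        strain_k = "B6" if k % 2 == 0 else "DBA"
        n_affected = 1 if k % 2 == 0 else 2
        affected = ",".join(
            rng.choice(F1_SAMPLES, size=n_affected, replace=False))
        epi_rows.append((chrom, int(cpg_positions[chrom][i]), i, strain_k,
                         affected, cfg.epimutation_parent_level,
                         cfg.epimutation_f1_level))
    epimutations = pd.DataFrame(epi_rows, columns=[
        "chrom", "pos", "cpg_idx", "strain", "affected_f1",
        "parent_level", "f1_level"])

    return TruthModel(
        config=cfg, seed=seed, chroms=chroms,
        chrom_lengths={c: cfg.region_length for c in chroms},
        sequences_b6=sequences_b6, sequences_dba=sequences_dba,
        cpg_positions=cpg_positions, baseline_levels=baseline_levels,
        noncg_sites=noncg, snps=snps, strain_sites=strain, sex_sites=sex,
        imprinted_regions=imprinted, epimutation_sites=epimutations)


# ---------------------------------------------------------------------------
# per-sample simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedSample:
    """One animal's simulated output: site table, epireads, base counts."""

    meta: SampleMeta
    sites: list[CytosineSite]
    epireads: list[EpiRead]
    base_counts: dict[tuple[str, int], np.ndarray]  # (chrom,pos) → ACGT counts


def _copy_identity(meta: SampleMeta, copy: int) -> tuple[str, str]:
    """(strain, parental origin) of chromosome copy 0/1 for this animal."""
    origin = "maternal" if copy == 0 else "paternal"
    strain = meta.maternal_strain if copy == 0 else meta.paternal_strain
    return strain, origin


def _haplotype_levels(truth: TruthModel, meta: SampleMeta, copy: int,
                      jittered: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-CpG methylation level of one chromosome copy of one animal."""
    strain, origin = _copy_identity(meta, copy)
    levels = {c: jittered[c].copy() for c in truth.chroms}

    for r in truth.strain_sites.itertuples(index=False):
        levels[r.chrom][r.cpg_idx] = r.b6_level if strain == "B6" else r.dba_level
    for r in truth.sex_sites.itertuples(index=False):
        levels[r.chrom][r.cpg_idx] = (r.female_level if meta.sex == "F"
                                      else r.male_level)
    for r in truth.imprinted_regions.itertuples(index=False):
        lvl = r.maternal_level if origin == "maternal" else r.paternal_level
        levels[r.chrom][r.first_idx:r.first_idx + r.n_cpgs] = lvl
    for r in truth.epimutation_sites.itertuples(index=False):
        affected = (meta.generation == "F1" and strain == r.strain
                    and meta.sample_id in r.affected_f1.split(","))
        levels[r.chrom][r.cpg_idx] = r.f1_level if affected else r.parent_level
    return levels


def simulate_sample(truth: TruthModel, meta: SampleMeta,
                    seed: int = 0) -> SimulatedSample:
    """Draw one animal's reads and count tables from the truth model.

    Reads are fixed-width CpG windows drawn from the animal's two chromosome
    copies; per-CpG states are Bernoulli at the level implied by the copy's
    strain, the animal's sex, the copy's parental origin, and any planted
    epimutation, then flipped with probability ``error_rate``.  Reads record
    the haplotype base at every overlapped SNP (with the same error rate),
    which is the raw material of SNP calling and read phasing, and carry the
    true copy strain in a hidden truth channel.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    w = cfg.read_width_cpgs

    # biological-replicate dispersion: smooth per-sample logit shift
    jittered: dict[str, np.ndarray] = {}
    for chrom in truth.chroms:
        base = np.clip(truth.baseline_levels[chrom], 1e-4, 1 - 1e-4)
        shift = rng.normal(0.0, cfg.sample_jitter_sd, size=len(base))
        logit = np.log(base / (1 - base)) + shift
        jittered[chrom] = 1.0 / (1.0 + np.exp(-logit))

    levels_by_copy = [
        _haplotype_levels(truth, meta, c, jittered) for c in (0, 1)]

    epireads: list[EpiRead] = []
    base_counts: dict[tuple[str, int], np.ndarray] = {}
    snp_by_chrom: dict[str, tuple[np.ndarray, list[str], list[str]]] = {}
    for chrom, grp in truth.snps.groupby("chrom"):
        grp = grp.sort_values("pos")
        snp_by_chrom[chrom] = (grp["pos"].to_numpy(),
                               grp["b6"].tolist(), grp["dba"].tolist())

    read_serial = 0
    for chrom in truth.chroms:
        cpgs = truth.cpg_positions[chrom]
        n_cpg = len(cpgs)
        if n_cpg == 0:
            continue
        n_reads = rng.poisson(cfg.coverage_mean * (n_cpg + w - 1) / w)
        if n_reads == 0:
            continue
        starts = rng.integers(-(w - 1), n_cpg, size=n_reads)
        copies = rng.integers(0, 2, size=n_reads)

        snp_pos, snp_b6, snp_dba = snp_by_chrom.get(
            chrom, (np.empty(0, dtype=np.int64), [], []))

        for s, copy in zip(starts, copies):
            lo, hi = max(0, int(s)), min(n_cpg, int(s) + w)
            if hi <= lo:
                continue
            idx = np.arange(lo, hi)
            lv = levels_by_copy[copy][chrom][idx]
            meth = rng.random(len(idx)) < lv
            flip = rng.random(len(idx)) < cfg.error_rate
            meth ^= flip
            states = "".join("M" if m else "U" for m in meth)

            strain, _ = _copy_identity(meta, copy)
            span_lo, span_hi = int(cpgs[lo]), int(cpgs[hi - 1]) + 1
            obs: list[tuple[int, str]] = []
            if len(snp_pos):
                j0, j1 = np.searchsorted(snp_pos, (span_lo, span_hi + 1))
                for j in range(j0, j1):
                    pos = int(snp_pos[j])
                    true_base = snp_b6[j] if strain == "B6" else snp_dba[j]
                    if true_base == "C":
                        # bisulfite: the read shows C only if the cytosine is
                        # methylated; planted C/T SNP cytosines are half-methylated
                        true_base = "C" if rng.random() < 0.5 else "T"
                    if rng.random() < cfg.error_rate:
                        others = [b for b in _BASES if b != true_base]
                        true_base = others[rng.integers(0, 3)]
                    obs.append((pos, true_base))
                    key = (chrom, pos)
                    if key not in base_counts:
                        base_counts[key] = np.zeros(4, dtype=np.int64)
                    base_counts[key][_BASE_INDEX[true_base]] += 1

            read_serial += 1
            epireads.append(EpiRead(
                read_id=f"{meta.sample_id}.{read_serial}",
                chrom=chrom, sample_id=meta.sample_id,
                cpg_positions=tuple(int(p) for p in cpgs[idx]),
                states=states, allele_tag="uninformative",
                snp_obs=tuple(obs), true_allele=strain))

    sites = aggregate_epireads(epireads)
    for r in truth.noncg_sites.itertuples(index=False):
        n = int(rng.poisson(cfg.coverage_mean))
        if n == 0:
            continue
        k = int(rng.binomial(n, r.level))
        sites.append(CytosineSite(r.chrom, int(r.pos), r.strand, r.context, k, n))
    sites.sort(key=lambda s: (s.chrom, s.pos, s.strand))

    return SimulatedSample(meta=meta, sites=sites, epireads=epireads,
                           base_counts=base_counts)


def simulate_dataset(truth: TruthModel,
                     seed: int = 0) -> dict[str, SimulatedSample]:
    """Simulate all eight animals of the reciprocal cross design."""
    seqs = np.random.SeedSequence(seed).spawn(8)
    out: dict[str, SimulatedSample] = {}
    for meta, ss in zip(standard_cross_samples(), seqs):
        sample_seed = int(ss.generate_state(1)[0] % (2**31))
        out[meta.sample_id] = simulate_sample(truth, meta, sample_seed)
    return out


# ---------------------------------------------------------------------------
# synthetic expression data (validation-screen inputs)
# ---------------------------------------------------------------------------

def simulate_allelic_expression(truth: TruthModel, seed: int = 0,
                                n_null_genes: int = 40,
                                depth: int = 60,
                                imprint_bias: float = 0.9) -> pd.DataFrame:
    """Allelic RNA-seq count tables for imprinting validation.

    One gene per planted imprinted region is maternally expressed, so its
    allelic skew flips with cross direction (B6-skewed in BXD, DBA-skewed in
    DXB); null genes are allele-balanced in both directions.  Columns are the
    2×2 Fisher layout: cross direction × allele genotype.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(len(truth.imprinted_regions)):
        n_bxd, n_dxb = rng.poisson(depth), rng.poisson(depth)
        bxd_b6 = int(rng.binomial(n_bxd, imprint_bias))      # maternal = B6
        dxb_b6 = int(rng.binomial(n_dxb, 1 - imprint_bias))  # maternal = DBA
        rows.append({"gene": f"imprinted_{i + 1}",
                     "bxd_b6": bxd_b6, "bxd_dba": n_bxd - bxd_b6,
                     "dxb_b6": dxb_b6, "dxb_dba": n_dxb - dxb_b6,
                     "imprinted_truth": True})
    for j in range(n_null_genes):
        n_bxd, n_dxb = rng.poisson(depth), rng.poisson(depth)
        bxd_b6 = int(rng.binomial(n_bxd, 0.5))
        dxb_b6 = int(rng.binomial(n_dxb, 0.5))
        rows.append({"gene": f"null_{j + 1}",
                     "bxd_b6": bxd_b6, "bxd_dba": n_bxd - bxd_b6,
                     "dxb_b6": dxb_b6, "dxb_dba": n_dxb - dxb_b6,
                     "imprinted_truth": False})
    return pd.DataFrame(rows)


def simulate_expression_matrix(seed: int = 0, n_genes: int = 300,
                               n_de: int = 20, n_female: int = 10,
                               n_male: int = 6, fold: float = 2.0,
                               cv: float = 0.2) -> tuple[pd.DataFrame, list[str], set[str]]:
    """Genes × samples expression matrix with planted sex-biased genes."""
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i + 1}" for i in range(n_genes)]
    sexes = ["F"] * n_female + ["M"] * n_male
    base = rng.lognormal(mean=3.0, sigma=1.0, size=n_genes)
    de_genes = set(rng.choice(genes, size=n_de, replace=False).tolist())
    data = np.empty((n_genes, len(sexes)))
    for gi, gene in enumerate(genes):
        for si, sex in enumerate(sexes):
            mu = base[gi]
            if gene in de_genes and sex == "F":
                mu *= fold
            data[gi, si] = mu * rng.lognormal(0.0, cv)
    df = pd.DataFrame(data, index=genes,
                      columns=[f"s{si + 1}_{sex}" for si, sex in enumerate(sexes)])
    return df, sexes, de_genes


# ---------------------------------------------------------------------------
# truth table serialization
# ---------------------------------------------------------------------------

_TRUTH_TABLES = ("strain_sites", "sex_sites", "epimutation_sites",
                 "imprinted_regions", "snps", "noncg_sites")


def write_truth_tables(truth: TruthModel, outdir: str | Path) -> None:
    """One TSV per planted effect class, plus a BED of imprinted regions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in _TRUTH_TABLES:
        getattr(truth, name).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    export_bed(
        [GenomicInterval(r.chrom, int(r.start), int(r.end), f"imprinted_{i + 1}")
         for i, r in enumerate(truth.imprinted_regions.itertuples(index=False))],
        outdir / "imprinted_regions.bed")


def load_truth_tables(outdir: str | Path) -> dict[str, pd.DataFrame]:
    outdir = Path(outdir)
    return {name: pd.read_csv(outdir / f"{name}.tsv", sep="\t")
            for name in _TRUTH_TABLES}
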