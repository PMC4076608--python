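"""End-to-end orchestration of the reciprocal-cross methylation analysis.

The full run simulates the eight-animal dataset, calls SNPs from pooled base
counts, phases F1 reads to their parental haplotypes, runs the four site
screens (strain, allele, sex, imprinting) with simulation-based FDR
calibration, detects intergenerational epimutations, scans every sample for
allelically methylated regions and intersects them into imprinted-region
candidates, and finishes with the expression validation screens.  All stage
outputs are plain TSV/BED/JSON files under one output directory, and every
stage is a pure function of the configuration seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import amr as amr_mod
from . import diffmeth, expression, fdr, io, simulate, snps

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run-wide configuration; YAML keys mirror the field names."""

    outdir: str = "methcross_out"
    seed: int = 0
    truth: simulate.TruthConfig = field(default_factory=simulate.TruthConfig)
    n_sims: int = 1000          # null replicates per FDR estimate
    min_coverage: int = 10
    amr_window: int = 10
    amr_p_threshold: float = 0.01
    amr_delta_threshold: float = 0.5
    amr_min_samples: int = 6
    bin_size: int = 100_000
    run_amr: bool = True
    run_expression: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        truth_kwargs = raw.pop("truth", {})
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in {f.name for f in dataclasses.fields(cls)}})
        cfg.truth = simulate.TruthConfig(**truth_kwargs)
        return cfg


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def _screen_closure(spec: diffmeth.ComparisonSpec, n_a: int):
    """Wrap a t-test screen as a count function over (K, N) matrices."""

    def count(K: np.ndarray, N: np.ndarray) -> int:
        with np.errstate(invalid="ignore"):
            frac = np.where(N >= spec.min_coverage, K / N, np.nan)
        t, p = diffmeth.ttest_matrix(frac[:, :n_a], frac[:, n_a:],
                                     spec.min_group_size)
        delta = np.abs(diffmeth.masked_mean(frac[:, :n_a])
                       - diffmeth.masked_mean(frac[:, n_a:]))
        ok = ~np.isnan(p)
        return int(np.sum(ok & (p < spec.p_threshold)
                          & (delta > spec.delta_threshold)))

    return count


def _pairwise_closure(spec: diffmeth.ComparisonSpec):
    def count(K: np.ndarray, N: np.ndarray) -> int:
        flags = diffmeth.pairwise_binomial_flags(
            K[:, 0], N[:, 0], K[:, 1], N[:, 1],
            spec.min_coverage, spec.delta_threshold, spec.alpha)
        return int(np.sum(flags))

    return count


def _pairwise_matrices(table_a: pd.DataFrame, table_b: pd.DataFrame):
    merged = table_a.merge(table_b, on=["chrom", "pos", "strand"],
                           suffixes=("_a", "_b"))
    K = merged[["meth_count_a", "meth_count_b"]].to_numpy(dtype=float)
    N = merged[["total_count_a", "total_count_b"]].to_numpy(dtype=float)
    return K, N


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and return the summary dict (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(config.seed, 6)
    summary: dict[str, Any] = {"seed": config.seed, "stages": {}}

    # ---- simulate ---------------------------------------------------------
    truth = simulate.build_truth_model(config.truth, seed=seeds[0])
    dataset = simulate.simulate_dataset(truth, seed=seeds[1])
    simulate.write_truth_tables(truth, outdir / "truth")
    site_tables: dict[str, pd.DataFrame] = {}
    for sample_id, sim in dataset.items():
        io.write_site_table(sim.sites, outdir / f"sites_{sample_id}.tsv")
        io.write_epireads(sim.epireads, outdir / f"epireads_{sample_id}.tsv")
        site_tables[sample_id] = io.sites_to_frame(sim.sites)
    metas = {m.sample_id: m for m in io.standard_cross_samples()}
    rates = io.global_summary(dataset["B6_F"].sites)
    summary["stages"]["simulate"] = {
        "n_cpgs": truth.n_cpgs(),
        "n_snps_planted": int(len(truth.snps)),
        "global_methylation": rates,
    }

    # ---- SNP calling and read phasing ------------------------------------
    pool_samples = ["B6_F", "B6_M", "DBA_F", "DBA_M", "BXD_F", "BXD_M"]
    pooled = snps.pool_base_counts(
        [dataset[s].base_counts for s in pool_samples])
    calls = snps.call_snps(pooled)
    snps.write_snp_calls(calls, outdir / "snp_calls.tsv")
    genotypes = truth.parent_genotypes
    tagged: dict[str, list[io.EpiRead]] = {}
    n_polymorphic = n_reads_total = n_concordant = n_assigned = 0
    for sample_id in simulate.F1_SAMPLES:
        reads = snps.tag_reads(dataset[sample_id].epireads, calls, genotypes)
        tagged[sample_id] = reads
        n_reads_total += len(reads)
        for r in reads:
            if r.allele_tag in ("B6", "DBA"):
                n_polymorphic += 1
                n_assigned += 1
                if r.allele_tag == r.true_allele:
                    n_concordant += 1
    summary["stages"]["snp_allele"] = {
        "n_snps_called": len(calls),
        "polymorphic_read_fraction": n_polymorphic / max(n_reads_total, 1),
        "assignment_concordance":
            n_concordant / n_assigned if n_assigned else None,
    }

    # ---- allele-split site tables for F1s ---------------------------------
    f1_allele_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for sample_id in simulate.F1_SAMPLES:
        for allele in ("B6", "DBA"):
            sites = io.aggregate_epireads(tagged[sample_id], allele=allele)
            f1_allele_tables[(sample_id, allele)] = io.sites_to_frame(sites)

    # ---- screens ----------------------------------------------------------
    screens: dict[str, pd.DataFrame] = {}
    fdr_reports: dict[str, dict] = {}
    rng_seeds = _spawn_seeds(seeds[2], 8)

    # strain: pairwise binomial, females and males separately
    strain_spec = diffmeth.PRESETS["strain"]
    for i, (a, b) in enumerate((("B6_F", "DBA_F"), ("B6_M", "DBA_M"))):
        res = diffmeth.pairwise_screen(site_tables[a], site_tables[b],
                                       strain_spec)
        screens[f"strain_{a}_vs_{b}"] = res
        K, N = _pairwise_matrices(site_tables[a], site_tables[b])
        y = int(res["significant"].sum())
        if y > 0:
            est = fdr.estimate_fdr(_pairwise_closure(strain_spec), K, N,
                                   n_sims=min(config.n_sims, 100),
                                   seed=rng_seeds[i])
            fdr_reports[f"strain_{a}_vs_{b}"] = dataclasses.asdict(est)

    # allele: B6 vs DBA haplotypes across the four F1s
    allele_spec = diffmeth.PRESETS["allele"]
    allele_tables = {f"{s}:{al}": f1_allele_tables[(s, al)]
                     for s in simulate.F1_SAMPLES for al in ("B6", "DBA")}
    allele_groups = {u: ("A" if u.endswith("B6") else "B")
                     for u in allele_tables}
    screens["allele"] = diffmeth.screen_sites(allele_tables, allele_groups,
                                              allele_spec)

    # sex: all eight animals grouped by sex
    sex_spec = diffmeth.PRESETS["sex"]
    sex_groups = {s: ("A" if metas[s].sex == "F" else "B")
                  for s in site_tables}
    screens["sex"] = diffmeth.screen_sites(site_tables, sex_groups, sex_spec)

    # imprinting: maternal vs paternal haplotypes in the F1s
    imprint_spec = diffmeth.PRESETS["imprinting"]
    imprint_groups = {}
    for (sample_id, allele) in f1_allele_tables:
        origin = snps.parent_of_origin(allele, metas[sample_id].group)
        imprint_groups[f"{sample_id}:{allele}"] = (
            "A" if origin == "maternal" else "B")
    imprint_tables = {f"{s}:{al}": t
                      for (s, al), t in f1_allele_tables.items()}
    screens["imprinting"] = diffmeth.screen_sites(
        imprint_tables, imprint_groups, imprint_spec)

    # FDR for the three t-test screens
    for name, tables, groups, spec, sd in (
        ("allele", allele_tables, allele_groups, allele_spec, rng_seeds[2]),
        ("sex", site_tables, sex_groups, sex_spec, rng_seeds[3]),
        ("imprinting", imprint_tables, imprint_groups, imprint_spec,
         rng_seeds[4]),
    ):
        _, fa, fb, K, N = diffmeth.build_group_matrices(
            tables, groups, spec.min_coverage)
        y = int(screens[name]["significant"].sum())
        if y > 0:
            est = fdr.estimate_fdr(_screen_closure(spec, fa.shape[1]), K, N,
                                   n_sims=config.n_sims, seed=sd)
            fdr_reports[name] = dataclasses.asdict(est)
        else:
            log.info("FDR for %s skipped: no significant sites", name)

    for name, res in screens.items():
        res.to_csv(outdir / f"screen_{name}.tsv", sep="\t", index=False)
    with open(outdir / "fdr_reports.json", "w") as fh:
        json.dump(fdr_reports, fh, indent=2)
    summary["stages"]["screens"] = {
        name: {"n_tested": int(len(res)),
               "n_significant": int(res["significant"].sum())}
        for name, res in screens.items()}
    summary["stages"]["fdr"] = fdr_reports

    # ---- epimutations -----------------------------------------------------
    parent_tables = {s: site_tables[s] for s in simulate.PARENT_SAMPLES}
    parent_strain_of = {s: metas[s].group for s in simulate.PARENT_SAMPLES}
    known_imprinted = [
        io.GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in truth.imprinted_regions.itertuples(index=False)]
    sex_of = {s: m.sex for s, m in metas.items()}
    epi_calls, epi_summary = diffmeth.detect_epimutations(
        parent_tables, f1_allele_tables, parent_strain_of, known_imprinted,
        sex_of=sex_of)
    epi_calls.to_csv(outdir / "epimutation_calls.tsv", sep="\t", index=False)
    epi_summary.to_csv(outdir / "epimutation_sites.tsv", sep="\t", index=False)
    summary["stages"]["epimutations"] = {
        "n_pairwise_calls": int(len(epi_calls)),
        "n_sites_ge1": int(epi_summary["class_ge1"].sum()) if len(epi_summary) else 0,
        "n_sites_ge2": int(epi_summary["class_ge2"].sum()) if len(epi_summary) else 0,
    }

    # ---- AMR scan and imprinted candidates --------------------------------
    if config.run_amr:
        per_sample_regions = {}
        for i, sample_id in enumerate(dataset):
            reads = tagged.get(sample_id, dataset[sample_id].epireads)
            per_sample_regions[sample_id] = amr_mod.amr_scan(
                reads, w=config.amr_window,
                p_threshold=config.amr_p_threshold,
                delta_threshold=config.amr_delta_threshold,
                seed=seeds[3] + i)
        candidates = amr_mod.candidate_imprinted_regions(
            per_sample_regions, metas, min_samples=config.amr_min_samples)
        amr_rows = [
            {"sample": s, "chrom": r.chrom, "start": r.start, "end": r.end,
             "n_cpgs": r.n_cpgs, "best_p": r.best_p, "max_delta": r.max_delta}
            for s, regions in per_sample_regions.items() for r in regions]
        pd.DataFrame(amr_rows, columns=["sample", "chrom", "start", "end",
                                        "n_cpgs", "best_p", "max_delta"]
                     ).to_csv(outdir / "amr_regions.tsv", sep="\t", index=False)
        cand_rows = [
            {"chrom": c.chrom, "start": c.start, "end": c.end,
             "n_samples": c.n_samples,
             "samples": ",".join(c.samples_present),
             "best_p": c.best_p, "max_delta": c.max_delta}
            for c in candidates]
        pd.DataFrame(cand_rows, columns=["chrom", "start", "end", "n_samples",
                                         "samples", "best_p", "max_delta"]
                     ).to_csv(outdir / "amr_candidates.tsv", sep="\t",
                              index=False)
        io.export_bed([c.interval if hasattr(c, "interval") else
                       io.GenomicInterval(c.chrom, c.start, c.end)
                       for c in candidates], outdir / "amr_candidates.bed")
        summary["stages"]["amr"] = {
            "n_regions_total": len(amr_rows),
            "n_candidates": len(candidates),
        }
    else:
        candidates = []
        summary["stages"]["amr"] = {"skipped": True}

    # ---- expression screens ----------------------------------------------
    if config.run_expression:
        allelic = simulate.simulate_allelic_expression(truth, seed=seeds[4])
        imp_expr = expression.imprinting_expression_screen(
            allelic.drop(columns=["imprinted_truth"]))
        imp_expr.to_csv(outdir / "expression_imprinting.tsv", sep="\t",
                        index=False)
        expr, sexes, de_truth = simulate.simulate_expression_matrix(
            seed=seeds[5])
        sex_de = expression.sex_de_screen(expr, sexes)
        sex_de.to_csv(outdir / "expression_sex_de.tsv", sep="\t", index=False)
        summary["stages"]["expression"] = {
            "imprinting_significant":
                int((imp_expr["significant"] & imp_expr["parental_origin"]).sum()),
            "sex_de_significant": int(sex_de["significant"].sum()),
            "sex_de_truth_recovered":
                int(sex_de[sex_de["significant"]]["gene"].isin(de_truth).sum()),
        }
    else:
        summary["stages"]["expression"] = {"skipped": True}

    # ---- bin track for strain-significant sites ---------------------------
    strain_sig = screens["strain_B6_F_vs_DBA_F"]
    sig_sites = strain_sig[strain_sig["significant"]]
    bins, threshold = diffmeth.bin_counts(sig_sites, truth.chrom_lengths,
                                          bin_size=config.bin_size)
    bins.to_csv(outdir / "bins_strain_female.tsv", sep="\t", index=False)
    summary["stages"]["bins"] = {"threshold": threshold,
                                 "n_bins": int(len(bins))}

    # ---- recall against planted truth -------------------------------------
    summary["recall"] = _recall_table(truth, screens, epi_summary, candidates)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def _recall_table(truth, screens: Mapping[str, pd.DataFrame],
                  epi_summary: pd.DataFrame, candidates) -> dict[str, Any]:
    """Fraction of planted effects recovered by the matching screen."""
    out: dict[str, Any] = {}

    strain_keys = {(r.chrom, r.pos)
                   for r in truth.strain_sites.itertuples(index=False)}
    hit = set()
    for name in ("strain_B6_F_vs_DBA_F", "strain_B6_M_vs_DBA_M"):
        res = screens[name]
        sig = res[res["significant"]]
        hit |= {(r.chrom, r.pos) for r in sig.itertuples(index=False)}
    out["strain_recall"] = (len(strain_keys & hit) / len(strain_keys)
                            if strain_keys else None)

    sex_keys = {(r.chrom, r.pos)
                for r in truth.sex_sites.itertuples(index=False)}
    sig = screens["sex"][screens["sex"]["significant"]]
    sex_hit = {(r.chrom, r.pos) for r in sig.itertuples(index=False)}
    out["sex_recall"] = (len(sex_keys & sex_hit) / len(sex_keys)
                         if sex_keys else None)

    regions = [io.GenomicInterval(r.chrom, int(r.start), int(r.end))
               for r in truth.imprinted_regions.itertuples(index=False)]
    n_found = sum(
        any(c.chrom == reg.chrom and c.start <= reg.end and reg.start <= c.end
            for c in candidates)
        for reg in regions)
    out["imprinted_region_recall"] = (n_found / len(regions)
                                      if regions else None)

    epi_keys = {(r.chrom, r.pos)
                for r in truth.epimutation_sites.itertuples(index=False)}
    if len(epi_summary):
        epi_hit = {(r.chrom, r.pos)
                   for r in epi_summary.itertuples(index=False)}
    else:
        epi_hit = set()
    out["epimutation_recall"] = (len(epi_keys & epi_hit) / len(epi_keys)
                                 if epi_keys else None)
    return out
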