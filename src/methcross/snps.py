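"""SNP calling from pooled bisulfite base counts and read phasing.

Bisulfite conversion turns unmethylated C into T on the sequenced strand, so
an apparent C/T polymorphism in plus-strand read counts (or G/A in
minus-strand counts) is indistinguishable from methylation state and is never
called.  Calls require a minimum pooled coverage and minor allele frequency;
reads are then assigned to the B6 or DBA haplotype by majority vote over the
informative SNPs they cover, and the reciprocal cross maps alleles to
parental origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import EpiRead, MethDataError

log = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: allele pairs mimicked by bisulfite conversion, per read-count strand
BISULFITE_CONFOUNDS = {"+": frozenset({"C", "T"}), "-": frozenset({"G", "A"})}


@dataclass(frozen=True)
class BaseCounts:
    """Read base counts (A, C, G, T) at one position on one strand."""

    chrom: str
    pos: int
    counts: tuple[int, int, int, int]
    strand: str = "+"

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise MethDataError("negative base count")

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class SnpCall:
    """A biallelic call with minor allele frequency and pooled coverage."""

    chrom: str
    pos: int
    major_allele: str
    minor_allele: str
    maf: float
    total: int


def pool_base_counts(
    samples: Sequence[Mapping[tuple[str, int], np.ndarray]],
) -> dict[tuple[str, int], np.ndarray]:
    """Element-wise sum of per-sample ACGT count maps.

    Positions observed in any sample pass through; the pooling is what gives
    the caller enough depth at moderate per-sample coverage.
    """
    if not samples:
        raise MethDataError("pool_base_counts needs at least one sample")
    pooled: dict[tuple[str, int], np.ndarray] = {}
    for sample in samples:
        for key, counts in sample.items():
            if key in pooled:
                pooled[key] = pooled[key] + np.asarray(counts)
            else:
                pooled[key] = np.asarray(counts).copy()
    return pooled


def call_snps(
    pooled: Mapping[tuple[str, int], np.ndarray] | Iterable[BaseCounts],
    min_total: int = 6,
    maf_min: float = 0.10,
    max_third_allele_fraction: float = 0.05,
    strand: str = "+",
) -> list[SnpCall]:
    """Call biallelic SNPs from pooled base counts.

    A position is called when pooled coverage is at least ``min_total``, the
    minor allele frequency is at least ``maf_min``, the major/minor pair is
    not the strand's bisulfite confound (C/T for plus-strand counts, G/A for
    minus), and any third allele stays below a noise fraction.
    """
    confound = BISULFITE_CONFOUNDS[strand]
    if isinstance(pooled, Mapping):
        items = [(chrom, pos, np.asarray(counts), strand)
                 for (chrom, pos), counts in pooled.items()]
    else:
        items = [(bc.chrom, bc.pos, np.asarray(bc.counts), bc.strand)
                 for bc in pooled]

    calls: list[SnpCall] = []
    n_filtered = 0
    for chrom, pos, counts, pos_strand in sorted(items, key=lambda x: (x[0], x[1])):
        confound_here = BISULFITE_CONFOUNDS[pos_strand]
        total = int(counts.sum())
        if total < min_total:
            n_filtered += 1
            continue
        order = np.argsort(counts)[::-1]
        major, minor = _BASES[order[0]], _BASES[order[1]]
        minor_count = int(counts[order[1]])
        third_count = int(counts[order[2]])
        maf = minor_count / total
        if maf < maf_min:
            n_filtered += 1
            continue
        if {major, minor} == confound_here:
            n_filtered += 1
            continue
        if third_count > max_third_allele_fraction * total:
            n_filtered += 1
            continue
        calls.append(SnpCall(chrom, int(pos), major, minor, maf, total))
    if n_filtered:
        log.info("call_snps: %d positions filtered, %d called",
                 n_filtered, len(calls))
    return calls


def assign_read_allele(
    read: EpiRead,
    snp_calls: Iterable[SnpCall] | None,
    parent_genotypes: Mapping[tuple[str, int], tuple[str, str]],
    conflict_fraction: float = 0.25,
) -> str:
    """Assign a read to B6 or DBA by majority vote over its SNP observations.

    Only SNPs present in ``parent_genotypes`` (and, when ``snp_calls`` is
    given, also among the calls) vote.  Bisulfite-confounded allele pairs
    (C/T for these plus-strand read counts) never vote even when present in
    the genotype map: conversion state, not genotype, decides the observed
    base there.  A read with no informative SNP is ``uninformative``; a tie,
    or a minority vote above ``conflict_fraction``, is ``ambiguous``.  A base
    matching neither parental allele is counted as a sequencing-error
    mismatch and does not vote.
    """
    callable_pos = (None if snp_calls is None
                    else {(c.chrom, c.pos) for c in snp_calls})
    confound = BISULFITE_CONFOUNDS["+"]
    votes = {"B6": 0, "DBA": 0}
    n_mismatch = 0
    for pos, base in read.snp_obs:
        key = (read.chrom, pos)
        if key not in parent_genotypes:
            continue
        if callable_pos is not None and key not in callable_pos:
            continue
        b6, dba = parent_genotypes[key]
        if {b6, dba} == confound:
            continue
        if base == b6:
            votes["B6"] += 1
        elif base == dba:
            votes["DBA"] += 1
        else:
            n_mismatch += 1
    n_votes = votes["B6"] + votes["DBA"]
    if n_votes == 0:
        return "uninformative"
    if votes["B6"] == votes["DBA"]:
        return "ambiguous"
    minority = min(votes.values())
    if minority / n_votes > conflict_fraction:
        return "ambiguous"
    return "B6" if votes["B6"] > votes["DBA"] else "DBA"


def tag_reads(
    reads: Iterable[EpiRead],
    snp_calls: Iterable[SnpCall] | None,
    parent_genotypes: Mapping[tuple[str, int], tuple[str, str]],
    conflict_fraction: float = 0.25,
) -> list[EpiRead]:
    """Return reads with ``allele_tag`` filled in by :func:`assign_read_allele`."""
    snp_calls = list(snp_calls) if snp_calls is not None else None
    out = []
    for r in reads:
        tag = assign_read_allele(r, snp_calls, parent_genotypes,
                                 conflict_fraction)
        out.append(EpiRead(r.read_id, r.chrom, r.sample_id, r.cpg_positions,
                           r.states, tag, r.snp_obs, r.true_allele))
    return out


def parent_of_origin(allele: str, cross: str) -> str:
    """Map an allele strain to maternal/paternal for a reciprocal F1 cross.

    BXD animals have a B6 mother, DXB a DBA mother; parental (inbred) samples
    cannot be phased this way and raise.
    """
    if cross not in ("BXD", "DXB"):
        raise MethDataError(
            f"parent_of_origin undefined for non-F1 group {cross!r}")
    if allele not in ("B6", "DBA"):
        raise MethDataError(
            f"parent_of_origin needs a strain allele, got {allele!r}")
    maternal = "B6" if cross == "BXD" else "DBA"
    return "maternal" if allele == maternal else "paternal"


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_base_counts(counts: Mapping[tuple[str, int], np.ndarray],
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tA\tC\tG\tT\n")
        for (chrom, pos), c in sorted(counts.items()):
            fh.write(f"{chrom}\t{pos}\t{c[0]}\t{c[1]}\t{c[2]}\t{c[3]}\n")


def load_base_counts(path: str | Path) -> dict[tuple[str, int], np.ndarray]:
    out: dict[tuple[str, int], np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, pos, a, c, g, t = line.rstrip("\n").split("\t")
            out[(chrom, int(pos))] = np.array([int(a), int(c), int(g), int(t)],
                                              dtype=np.int64)
    return out


def write_snp_calls(calls: Sequence[SnpCall], path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "pos": [c.pos for c in calls],
            "major_allele": [c.major_allele for c in calls],
            "minor_allele": [c.minor_allele for c in calls],
            "maf": [c.maf for c in calls],
            "total": [c.total for c in calls],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_snp_calls(path: str | Path) -> list[SnpCall]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [SnpCall(r.chrom, int(r.pos), r.major_allele, r.minor_allele,
                    float(r.maf), int(r.total))
            for r in df.itertuples(index=False)]


def load_known_genotypes(path: str | Path) -> dict[tuple[str, int], tuple[str, str]]:
    """Read a chrom/pos/b6/dba TSV as a parent-genotype map."""
    df = pd.read_csv(path, sep="\t")
    return {(r.chrom, int(r.pos)): (r.b6, r.dba)
            for r in df.itertuples(index=False)}
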