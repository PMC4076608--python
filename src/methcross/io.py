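"""Core data model and I/O for allele-resolved bisulfite methylation data.

The unit of site-level analysis is a :class:`CytosineSite` — one cytosine on
one strand with methylated/total read counts.  The unit of read-level analysis
is an :class:`EpiRead` — the ordered CpG methylation states observed on a
single sequencing read, optionally tagged with the allele (strain haplotype)
the read derives from.

Coordinates are 1-based inclusive everywhere inside the package; the single
exception is BED output, which follows the 0-based half-open convention.
Plus- and minus-strand cytosines are always distinct sites and are never
pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
STATE_ALPHABET = frozenset("MUN")
ALLELE_TAGS = ("B6", "DBA", "ambiguous", "uninformative")
GROUPS = ("B6", "DBA", "BXD", "DXB")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MethDataError(ValueError):
    """Malformed methylation data (bad counts, alphabet, coordinates...)."""


class ContextError(MethDataError):
    """The queried reference base is not a cytosine on the requested strand."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CytosineSite:
    """A single cytosine with strand, trinucleotide context and read counts."""

    chrom: str
    pos: int  # 1-based position of the C on its strand
    strand: str
    context: str
    meth_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise MethDataError(f"bad strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise MethDataError(f"bad context {self.context!r}")
        if self.total_count <= 0:
            raise MethDataError(
                f"total_count must be positive, got {self.total_count}")
        if not 0 <= self.meth_count <= self.total_count:
            raise MethDataError(
                f"meth_count {self.meth_count} outside [0, {self.total_count}]")

    @property
    def level(self) -> float:
        """Fractional methylation k/n in [0, 1]."""
        return self.meth_count / self.total_count

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


@dataclass(frozen=True)
class EpiRead:
    """Per-read CpG methylation states (M/U/N) with an optional allele tag.

    ``snp_obs`` records the base observed by this read at SNP positions it
    overlaps; it is what makes a read genotype-informative.  ``true_allele``
    is a simulator-only truth channel and is never serialized.
    """

    read_id: str
    chrom: str
    sample_id: str
    cpg_positions: tuple[int, ...]
    states: str
    allele_tag: str = "uninformative"
    snp_obs: tuple[tuple[int, str], ...] = ()
    true_allele: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.states) != len(self.cpg_positions):
            raise MethDataError(
                f"read {self.read_id}: {len(self.states)} states for "
                f"{len(self.cpg_positions)} positions")
        if not set(self.states) <= STATE_ALPHABET:
            bad = set(self.states) - STATE_ALPHABET
            raise MethDataError(
                f"read {self.read_id}: states outside M/U/N alphabet: {bad}")
        if any(b > a for a, b in zip(self.cpg_positions[1:], self.cpg_positions)):
            raise MethDataError(
                f"read {self.read_id}: CpG positions not strictly increasing")
        if self.allele_tag not in ALLELE_TAGS:
            raise MethDataError(f"bad allele tag {self.allele_tag!r}")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint (first CpG, last CpG) of the read, 1-based."""
        return (self.cpg_positions[0], self.cpg_positions[-1])


@dataclass(frozen=True)
class SampleMeta:
    """One mouse of the reciprocal cross: strain group, sex and parentage.

    BXD F1 animals have a B6 mother and DBA father; DXB the reverse.  Parental
    animals are inbred, so maternal and paternal strains equal the group.
    """

    sample_id: str
    group: str
    sex: str
    generation: str
    maternal_strain: str
    paternal_strain: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise MethDataError(f"bad group {self.group!r}")
        if self.sex not in ("F", "M"):
            raise MethDataError(f"bad sex {self.sex!r}")
        expected = {
            "B6": ("parent", "B6", "B6"),
            "DBA": ("parent", "DBA", "DBA"),
            "BXD": ("F1", "B6", "DBA"),
            "DXB": ("F1", "DBA", "B6"),
        }[self.group]
        if (self.generation, self.maternal_strain, self.paternal_strain) != expected:
            raise MethDataError(
                f"{self.sample_id}: group {self.group} requires "
                f"(generation, maternal, paternal) == {expected}")

    @classmethod
    def from_group(cls, sample_id: str, group: str, sex: str) -> "SampleMeta":
        gen = "parent" if group in ("B6", "DBA") else "F1"
        mat, pat = {
            "B6": ("B6", "B6"), "DBA": ("DBA", "DBA"),
            "BXD": ("B6", "DBA"), "DXB": ("DBA", "B6"),
        }[group]
        return cls(sample_id, group, sex, gen, mat, pat)


def standard_cross_samples() -> list[SampleMeta]:
    """The eight-animal reciprocal-cross design: each group in both sexes."""
    out = []
    for group in GROUPS:
        for sex in ("F", "M"):
            out.append(SampleMeta.from_group(f"{group}_{sex}", group, sex))
    return out


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise MethDataError(
                f"interval start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def distance(self, chrom: str, pos: int) -> float:
        """Distance from a point to the interval; 0 inside, inf off-chromosome."""
        if chrom != self.chrom:
            return float("inf")
        if pos < self.start:
            return self.start - pos
        if pos > self.end:
            return pos - self.end
        return 0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.end and other.start <= self.end)


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------

def classify_context(ref_sequence: str, pos: int, strand: str = "+") -> str:
    """Classify the cytosine at 1-based ``pos`` as CG, CHG or CHH.

    On the plus strand the base at ``pos`` must be C and the context is read
    5'→3' to the right; on the minus strand the reference base must be G (a C
    on the minus strand) and the context is read leftwards, complemented.
    Sequence ends are padded with non-G bases, so a terminal C is CHH.
    """
    seq = str(ref_sequence).upper()

    def base(i: int) -> str:
        return seq[i - 1] if 1 <= i <= len(seq) else "N"

    if strand == "+":
        if base(pos) != "C":
            raise ContextError(
                f"base at +{pos} is {base(pos)!r}, not C")
        nxt, nxt2 = base(pos + 1), base(pos + 2)
    elif strand == "-":
        if base(pos) != "G":
            raise ContextError(
                f"base at -{pos} is {base(pos)!r}, not C on the minus strand")
        nxt = base(pos - 1).translate(_COMPLEMENT)
        nxt2 = base(pos - 2).translate(_COMPLEMENT)
    else:
        raise MethDataError(f"bad strand {strand!r}")

    if nxt == "G":
        return "CG"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def load_reference(path: str | Path) -> dict[str, str]:
    """Read a FASTA reference into a plain chrom → sequence dict."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# site table I/O
# ---------------------------------------------------------------------------

SITE_HEADER = "#chrom\tpos\tstrand\tcontext\tmeth_count\ttotal_count"


def write_site_table(sites: Iterable[CytosineSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(SITE_HEADER + "\n")
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.strand}\t{s.context}\t"
                     f"{s.meth_count}\t{s.total_count}\n")


def load_site_table(path: str | Path) -> list[CytosineSite]:
    sites: list[CytosineSite] = []
    seen: set[tuple[str, int, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise MethDataError(
                    f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            try:
                site = CytosineSite(parts[0], int(parts[1]), parts[2],
                                    parts[3], int(parts[4]), int(parts[5]))
            except (ValueError, MethDataError) as exc:
                raise MethDataError(f"{path}:{lineno}: {exc}") from exc
            if site.key in seen:
                raise MethDataError(
                    f"{path}:{lineno}: duplicate site {site.key}")
            seen.add(site.key)
            sites.append(site)
    return sites


def sites_to_frame(sites: Sequence[CytosineSite]) -> pd.DataFrame:
    """Tabular view of a site list (one row per cytosine)."""
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": np.array([s.pos for s in sites], dtype=np.int64),
            "strand": [s.strand for s in sites],
            "context": [s.context for s in sites],
            "meth_count": np.array([s.meth_count for s in sites], dtype=np.int64),
            "total_count": np.array([s.total_count for s in sites], dtype=np.int64),
        }
    ).assign(level=lambda d: d.meth_count / d.total_count)


def frame_to_sites(frame: pd.DataFrame) -> list[CytosineSite]:
    return [
        CytosineSite(r.chrom, int(r.pos), r.strand, r.context,
                     int(r.meth_count), int(r.total_count))
        for r in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# epiread I/O
# ---------------------------------------------------------------------------

EPIREAD_HEADER = "#chrom\tread_id\tsample_id\tcpg_positions\tstates\tallele_tag\tsnp_obs"


def _format_snp_obs(obs: tuple[tuple[int, str], ...]) -> str:
    if not obs:
        return "."
    return ";".join(f"{pos}:{base}" for pos, base in obs)


def _parse_snp_obs(text: str) -> tuple[tuple[int, str], ...]:
    if text == "." or not text:
        return ()
    out = []
    for item in text.split(";"):
        pos, base = item.split(":")
        out.append((int(pos), base))
    return tuple(out)


def write_epireads(reads: Iterable[EpiRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(EPIREAD_HEADER + "\n")
        for r in reads:
            fh.write(
                f"{r.chrom}\t{r.read_id}\t{r.sample_id}\t"
                f"{','.join(map(str, r.cpg_positions))}\t{r.states}\t"
                f"{r.allele_tag}\t{_format_snp_obs(r.snp_obs)}\n")


def load_epireads(path: str | Path) -> list[EpiRead]:
    reads: list[EpiRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (6, 7):
                raise MethDataError(
                    f"{path}:{lineno}: expected 6-7 columns, got {len(parts)}")
            try:
                positions = tuple(int(p) for p in parts[3].split(","))
                obs = _parse_snp_obs(parts[6]) if len(parts) == 7 else ()
                reads.append(EpiRead(parts[1], parts[0], parts[2],
                                     positions, parts[4], parts[5], obs))
            except (ValueError, MethDataError) as exc:
                raise MethDataError(f"{path}:{lineno}: {exc}") from exc
    return reads


def aggregate_epireads(
    reads: Iterable[EpiRead],
    allele: str | None = None,
    context: str = "CG",
    strand: str = "+",
    use_true_allele: bool = False,
) -> list[CytosineSite]:
    """Collapse epireads into a per-CpG count table.

    With ``allele`` set, only reads whose tag (or simulator truth channel,
    if ``use_true_allele``) matches contribute — this is how per-haplotype
    methylation tables are built for the allele and imprinting screens.
    """
    meth: dict[tuple[str, int], int] = {}
    total: dict[tuple[str, int], int] = {}
    for r in reads:
        if allele is not None:
            tag = r.true_allele if use_true_allele else r.allele_tag
            if tag != allele:
                continue
        for pos, state in zip(r.cpg_positions, r.states):
            if state == "N":
                continue
            key = (r.chrom, pos)
            total[key] = total.get(key, 0) + 1
            if state == "M":
                meth[key] = meth.get(key, 0) + 1
    return [
        CytosineSite(chrom, pos, strand, context, meth.get((chrom, pos), 0), n)
        for (chrom, pos), n in sorted(total.items())
    ]


# ---------------------------------------------------------------------------
# BED / annotation I/O
# ---------------------------------------------------------------------------

def export_bed(records: Iterable[CytosineSite | GenomicInterval],
               path: str | Path) -> None:
    """Write sites/intervals as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, CytosineSite):
                name = f"{rec.chrom}:{rec.pos}"
                fh.write(f"{rec.chrom}\t{rec.pos - 1}\t{rec.pos}\t{name}\t"
                         f"{rec.meth_count}\t{rec.strand}\n")
            else:
                name = rec.name or f"{rec.chrom}:{rec.start}-{rec.end}"
                fh.write(f"{rec.chrom}\t{rec.start - 1}\t{rec.end}\t{name}\t0\t+\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ into 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MethDataError(f"{path}:{lineno}: BED needs ≥3 columns")
            name = parts[3] if len(parts) > 3 else ""
            out.append(GenomicInterval(parts[0], int(parts[1]) + 1,
                                       int(parts[2]), name))
    return out


def read_gtf_genes(path: str | Path) -> list[GenomicInterval]:
    """Extract gene spans from a GTF (feature == 'gene'; 1-based inclusive)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = parts[8]
            name = ""
            for key in ("gene_name", "gene_id"):
                tag = key + ' "'
                if tag in attrs:
                    name = attrs.split(tag, 1)[1].split('"', 1)[0]
                    break
            out.append(GenomicInterval(parts[0], int(parts[3]),
                                       int(parts[4]), name))
    return out


def read_annotation(path: str | Path) -> list[GenomicInterval]:
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff", ".gff3"):
        return read_gtf_genes(path)
    return read_bed(path)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def global_summary(sites: Sequence[CytosineSite]) -> dict:
    """Mean fractional methylation overall and stratified by context.

    Contexts with no sites are simply absent from ``by_context`` rather than
    reported as zero.
    """
    if not sites:
        raise MethDataError("global_summary on empty site list")
    levels = np.array([s.level for s in sites])
    contexts = np.array([s.context for s in sites])
    by_context = {}
    for ctx in CONTEXTS:
        mask = contexts == ctx
        if mask.any():
            by_context[ctx] = {
                "mean_level": float(levels[mask].mean()),
                "n_sites": int(mask.sum()),
            }
    return {
        "overall_mean_level": float(levels.mean()),
        "n_sites": len(sites),
        "by_context": by_context,
    }
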