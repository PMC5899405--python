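"""Per-cytosine methylation extraction, sub-genome attribution and testing.

Extraction follows the bisulphite logic: on a top-strand (genome conversion
``CT``) fragment, a reference C read as C is methylated and read as T is
unmethylated; bottom-strand (``GA``) fragments report reference Gs read as
G (methylated) or A (unmethylated).  Context (CpG / CHG / CHH) is classified
from the reference.  Records are kept per strand: symmetric CpG positions
are NOT merged across strands, matching single-strand methylome profiling.

Sub-genome attribution uses diagnostic homoeologous SNP alleles carried by
high-confidence reads (mapping quality strictly over 20); differential
methylation between two samples is a per-position two-sided Fisher's exact
test on (methylated, unmethylated) counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.stats import fisher_exact

from .contexts import classify_context
from .simulate import XG_TOP
from .variants import AlignedRead


class CytosineCall(NamedTuple):
    """One per-read methylation observation."""

    contig: str
    pos: int  # 1-based
    strand: str
    context: str
    methylated: bool


@dataclass
class CytosineRecord:
    """Aggregated methylation evidence at one cytosine site (one strand)."""

    contig: str
    pos: int
    strand: str
    context: str
    meth_count: int = 0
    unmeth_count: int = 0
    per_subgenome: dict = field(default_factory=dict)  # genome -> [meth, unmeth]

    @property
    def depth(self) -> int:
        return self.meth_count + self.unmeth_count

    @property
    def level(self) -> float:
        """Fraction of reads methylated (NaN-free: requires depth > 0)."""
        return self.meth_count / self.depth

    @property
    def key(self):
        return (self.contig, self.pos, self.strand)


@dataclass
class ExtractionResult:
    per_read_calls: dict   # read name -> list[CytosineCall]
    records: dict          # (contig, pos, strand) -> CytosineRecord
    n_ignored_bases: int = 0   # non-informative bases at cytosine sites


def _conversion_strand(read: AlignedRead) -> str:
    xg = read.tags.get("XG")
    if xg is None:
        raise ValueError(
            f"read {read.name} lacks a bisulphite strand tag (XG)")
    return "+" if xg == XG_TOP else "-"


def extract_methylation(
    reads: list[AlignedRead],
    reference: dict,
) -> ExtractionResult:
    """Call methylation per read and aggregate per cytosine site.

    Reads must carry a genome-conversion-strand tag (``XG``: ``CT`` for
    top-strand, ``GA`` for bottom-strand fragments).  Bases other than C/T
    (top) or G/A (bottom) at a cytosine site are sequencing errors or
    unrecognised variants and are ignored but tallied.  Sites too close to
    a contig end to classify are labelled "truncated" and excluded from
    context-specific summaries by downstream consumers.
    """
    per_read: dict[str, list[CytosineCall]] = {}
    records: dict[tuple, CytosineRecord] = {}
    n_ignored = 0

    for r in reads:
        if not r.mapped:
            continue
        strand = _conversion_strand(r)
        if r.contig not in reference:
            raise ValueError(f"read {r.name}: unknown contig {r.contig!r}")
        ref = reference[r.contig]
        if r.end > len(ref):
            raise ValueError(f"read {r.name} overhangs contig {r.contig}")
        target, meth_base, unmeth_base = (
            ("C", "C", "T") if strand == "+" else ("G", "G", "A"))
        calls = per_read.setdefault(r.name, [])
        for i, base in enumerate(r.sequence):
            p0 = r.pos - 1 + i
            if ref[p0] != target:
                continue
            if base == meth_base:
                methylated = True
            elif base == unmeth_base:
                methylated = False
            else:
                n_ignored += 1
                continue
            context = classify_context(ref, p0, strand)
            call = CytosineCall(r.contig, p0 + 1, strand, context, methylated)
            calls.append(call)
            key = (r.contig, p0 + 1, strand)
            rec = records.get(key)
            if rec is None:
                rec = records[key] = CytosineRecord(
                    contig=r.contig, pos=p0 + 1, strand=strand, context=context)
            if methylated:
                rec.meth_count += 1
            else:
                rec.unmeth_count += 1
    return ExtractionResult(per_read, records, n_ignored)


@dataclass
class SubgenomeAssignment:
    records: dict            # (contig, pos, strand) -> CytosineRecord
    read_genome: dict        # read name -> genome label
    n_assigned: int = 0
    n_no_diagnostic: int = 0
    n_conflicting: int = 0
    n_low_mapq: int = 0


def _compatible_alleles(observed: str, read: AlignedRead) -> set:
    """Alleles a read base could represent, given bisulphite chemistry.

    On converted reads an observed T may be a converted (unmethylated) C on
    top-strand fragments, and an observed A may be a converted G on
    bottom-strand fragments; untreated reads match exactly.
    """
    alleles = {observed}
    xg = read.tags.get("XG")
    if xg is not None:
        if xg == XG_TOP and observed == "T":
            alleles.add("C")
        if xg != XG_TOP and observed == "A":
            alleles.add("G")
    return alleles


def assign_subgenome_methylation(
    extraction: ExtractionResult,
    reads: list[AlignedRead],
    homoeolog_list: list,
    min_mapq: int = 20,
    singleton_only: bool = True,
) -> SubgenomeAssignment:
    """Credit per-read methylation calls to sub-genomes via diagnostic alleles.

    A read participates iff its mapping quality is strictly over
    ``min_mapq`` and it overlaps at least one homoeologous SNP whose
    observed allele resolves to exactly one sub-genome (allele->genome sets
    that are not singletons are ignored by default).  All of a
    participating read's cytosine calls are credited to that genome; reads
    whose diagnostic alleles disagree are discarded and tallied.
    Bisulphite C->T (top) and G->A (bottom) ambiguity is respected: an
    observed base compatible with alleles of more than one genome is not
    diagnostic.
    """
    by_pos = {}
    for snp in homoeolog_list:
        by_pos.setdefault(snp.contig, {})[snp.pos] = snp

    records: dict[tuple, CytosineRecord] = {}
    for key, rec in extraction.records.items():
        records[key] = CytosineRecord(
            contig=rec.contig, pos=rec.pos, strand=rec.strand,
            context=rec.context, meth_count=rec.meth_count,
            unmeth_count=rec.unmeth_count)

    read_genome: dict[str, str] = {}
    n_no_diag = n_conflict = n_low = 0
    for r in reads:
        if not r.mapped or r.name not in extraction.per_read_calls:
            continue
        if not r.mapq > min_mapq:
            n_low += 1
            continue
        snps = by_pos.get(r.contig, {})
        genomes: set[str] = set()
        conflict = False
        for pos in range(r.pos, r.end + 1):
            snp = snps.get(pos)
            if snp is None:
                continue
            observed = r.base_at(pos)
            compat = _compatible_alleles(observed, r)
            groups = {snp.allele_map[a] for a in compat if a in snp.allele_map}
            if len(groups) != 1:
                continue  # observed base does not identify one allele group
            (group,) = groups
            if singleton_only and len(group) != 1:
                continue  # multi-genome groups are not attributed by default
            if genomes and group != frozenset(genomes):
                conflict = True
                break
            genomes = set(group)
        if conflict:
            n_conflict += 1
            continue
        if len(genomes) != 1:
            n_no_diag += 1
            continue
        (genome,) = genomes
        read_genome[r.name] = genome
        for call in extraction.per_read_calls[r.name]:
            rec = records[(call.contig, call.pos, call.strand)]
            pair = rec.per_subgenome.setdefault(genome, [0, 0])
            pair[0 if call.methylated else 1] += 1
    return SubgenomeAssignment(
        records=records, read_genome=read_genome,
        n_assigned=len(read_genome), n_no_diagnostic=n_no_diag,
        n_conflicting=n_conflict, n_low_mapq=n_low)


def per_subgenome_records(records: dict, genome: str) -> dict:
    """Project sub-genome counts for ``genome`` into plain records.

    Positions with no reads attributed to ``genome`` are dropped.  The
    result feeds :func:`differential_methylation` for the pairwise A-A /
    B-B / D-D comparisons between two samples.
    """
    out = {}
    for key, rec in records.items():
        if genome in rec.per_subgenome:
            m, u = rec.per_subgenome[genome]
            out[key] = CytosineRecord(
                contig=rec.contig, pos=rec.pos, strand=rec.strand,
                context=rec.context, meth_count=m, unmeth_count=u)
    return out


@dataclass
class ConversionEfficiencyResult:
    """Bisulphite conversion efficiency from an unmethylated control genome."""

    efficiency_pct: float | None  # 100 * T-like / (C-like + T-like)
    n_converted: int
    n_unconverted: int
    mean_depth: float
    pct_covered: float

    @property
    def n_observations(self) -> int:
        return self.n_converted + self.n_unconverted


def conversion_efficiency(
    reads: list[AlignedRead],
    control_name: str,
    control_seq: str,
) -> ConversionEfficiencyResult:
    """Estimate conversion efficiency on a genome assumed unmethylated.

    Every read base at a control-genome cytosine site (reference C for
    top-strand reads, reference G for bottom-strand reads) is a Bernoulli
    observation of the conversion process: T/A means converted, C/G means
    unconverted.  Also reports mean depth over, and percent coverage of,
    the control genome.  With zero observations the efficiency is undefined
    and reported as None.
    """
    L = len(control_seq)
    depth = np.zeros(L, dtype=np.int64)
    n_conv = n_unconv = 0
    for r in reads:
        if r.contig != control_name:
            continue
        strand = _conversion_strand(r)
        target, unconv, conv = ("C", "C", "T") if strand == "+" else ("G", "G", "A")
        if r.end > L:
            raise ValueError(f"read {r.name} overhangs control genome")
        depth[r.pos - 1:r.end] += 1
        for i, base in enumerate(r.sequence):
            if control_seq[r.pos - 1 + i] != target:
                continue
            if base == conv:
                n_conv += 1
            elif base == unconv:
                n_unconv += 1
    total = n_conv + n_unconv
    eff = 100.0 * n_conv / total if total else None
    return ConversionEfficiencyResult(
        efficiency_pct=eff, n_converted=n_conv, n_unconverted=n_unconv,
        mean_depth=float(depth.mean()) if L else 0.0,
        pct_covered=100.0 * float((depth > 0).mean()) if L else 0.0,
    )


@dataclass
class DmResult:
    contig: str
    pos: int
    strand: str
    group_a_counts: tuple  # (meth, unmeth)
    group_b_counts: tuple
    p_value: float
    meth_difference: float  # percentage points, a minus b
    significant: bool


@dataclass
class DmSummary:
    results: list
    n_tested: int
    n_significant: int

    @property
    def significant_fraction(self) -> float:
        return self.n_significant / self.n_tested if self.n_tested else 0.0


def differential_methylation(
    records_a: dict,
    records_b: dict,
    min_depth: int = 5,
    alpha: float = 0.01,
    min_diff: float = 25.0,
) -> DmSummary:
    """Pairwise per-position differential methylation by Fisher's exact test.

    Positions covered to at least ``min_depth`` in BOTH samples are tested
    with a two-sided Fisher's exact test on the 2x2 table
    [(meth_a, unmeth_a), (meth_b, unmeth_b)]; a position is significant iff
    p < ``alpha`` and the absolute methylation difference (percentage
    points) is at least ``min_diff``.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    results: list[DmResult] = []
    n_sig = 0
    for key in sorted(set(records_a) & set(records_b)):
        a, b = records_a[key], records_b[key]
        if a.depth < min_depth or b.depth < min_depth:
            continue
        table = [[a.meth_count, a.unmeth_count], [b.meth_count, b.unmeth_count]]
        _, p = fisher_exact(table, alternative="two-sided")
        diff = 100.0 * a.level - 100.0 * b.level
        sig = bool(p < alpha and abs(diff) >= min_diff)
        n_sig += sig
        results.append(DmResult(
            contig=a.contig, pos=a.pos, strand=a.strand,
            group_a_counts=(a.meth_count, a.unmeth_count),
            group_b_counts=(b.meth_count, b.unmeth_count),
            p_value=float(p), meth_difference=diff, significant=sig))
    return DmSummary(results=results, n_tested=len(results), n_significant=n_sig)
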