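"""Alignment filtering, pileup, polyploid SNP calling and sub-genome routing.

The polyploid caller reimplements the mpileup/VarScan-style thresholds used
for hexaploid capture data: a position is reported when it has at least 5x
coverage, a mean mapping quality above 15 and a non-reference allele at a
frequency greater than 0.1.  Alignments first pass the standard filters
(mapping quality >= 10, no duplicates, unique hits only).

Two independent routes build the homoeologous SNP list — the diagnostic
positions used to attribute reads and methylation calls to sub-genomes:
directly from coordinate-matched sub-genome haplotypes, or from reads that
have been assigned a genome of origin by exact full-length matching.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .contexts import revcomp
from .simulate import HomoeologousSnp

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class AlignedRead:
    """One SAM-style alignment record (sequence in reference orientation)."""

    name: str
    contig: str | None
    pos: int  # 1-based leftmost; ignored when unmapped
    strand: str
    mapq: int
    sequence: str
    cigar: str | None = None  # None means full-length match
    duplicate: bool = False
    unique: bool = True
    tags: dict = field(default_factory=dict)

    @property
    def mapped(self) -> bool:
        return self.contig is not None

    @property
    def end(self) -> int:
        return self.pos + len(self.sequence) - 1

    def base_at(self, pos: int) -> str:
        """Read base aligned to 1-based reference position ``pos``."""
        return self.sequence[pos - self.pos]

    def check_cigar(self) -> None:
        """Reject CIGARs containing anything but aligned-match operations."""
        if self.cigar is None:
            return
        ops = _CIGAR_RE.findall(self.cigar)
        if not ops or any(op not in "M=X" for _, op in ops):
            raise ValueError(
                f"read {self.name}: unsupported CIGAR {self.cigar!r} "
                "(only match operations are handled)")
        if sum(int(n) for n, _ in ops) != len(self.sequence):
            raise ValueError(f"read {self.name}: CIGAR/sequence length mismatch")


def filter_alignments(
    reads: list[AlignedRead],
    min_mapq: int = 10,
    drop_duplicates: bool = True,
    unique_only: bool = True,
) -> list[AlignedRead]:
    """Standard alignment filters; order is preserved.

    Removes unmapped reads, reads below the mapping-quality threshold
    (default: quality < 10 removed, 10 kept), duplicate-flagged reads and
    non-unique hits.
    """
    out = []
    for r in reads:
        if not r.mapped:
            continue
        if r.mapq < min_mapq:
            continue
        if drop_duplicates and r.duplicate:
            continue
        if unique_only and not r.unique:
            continue
        out.append(r)
    return out


@dataclass
class PileupColumn:
    contig: str
    pos: int  # 1-based
    ref_base: str
    base_counts: dict  # base -> count
    depth: int
    mean_mapq: float


def pileup(reads: list[AlignedRead], reference: dict) -> list[PileupColumn]:
    """Column-wise base counts over every covered reference position.

    Read sequences are stored in reference orientation, so base counts are
    recorded in reference orientation regardless of alignment strand.
    Zero-depth positions are omitted; columns are emitted sorted by
    (contig, position).
    """
    base_idx = {b: i for i, b in enumerate("ACGT")}
    counts: dict[str, np.ndarray] = {}
    mapq_sum: dict[str, np.ndarray] = {}
    for name, seq in reference.items():
        counts[name] = np.zeros((5, len(seq)), dtype=np.int64)
        mapq_sum[name] = np.zeros(len(seq), dtype=np.float64)

    for r in reads:
        if not r.mapped:
            continue
        r.check_cigar()
        if r.contig not in counts:
            raise ValueError(f"read {r.name}: unknown contig {r.contig!r}")
        L = len(reference[r.contig])
        if r.pos < 1 or r.end > L:
            raise ValueError(
                f"read {r.name} overhangs contig {r.contig} "
                f"({r.pos}-{r.end} vs length {L})")
        start0 = r.pos - 1
        for i, base in enumerate(r.sequence):
            counts[r.contig][base_idx.get(base, 4), start0 + i] += 1
        mapq_sum[r.contig][start0:start0 + len(r.sequence)] += r.mapq

    columns: list[PileupColumn] = []
    for name in sorted(counts):
        mat = counts[name]
        depth = mat.sum(axis=0)
        for j in np.flatnonzero(depth):
            bc = {b: int(mat[i, j]) for b, i in base_idx.items() if mat[i, j]}
            if mat[4, j]:
                bc["N"] = int(mat[4, j])
            d = int(depth[j])
            columns.append(PileupColumn(
                contig=name, pos=int(j) + 1,
                ref_base=reference[name][j],
                base_counts=bc, depth=d,
                mean_mapq=float(mapq_sum[name][j]) / d,
            ))
    return columns


@dataclass
class SnpCall:
    contig: str
    pos: int
    ref_allele: str
    alt_alleles: dict  # base -> frequency (count / depth), every observed alt
    depth: int
    mean_mapq: float

    @property
    def primary_alt(self) -> str:
        """Highest-frequency alternate allele; ties broken alphabetically."""
        return min(self.alt_alleles, key=lambda b: (-self.alt_alleles[b], b))


@dataclass
class CallerResult:
    calls: list
    n_skipped_unknown_ref: int = 0

    def __iter__(self):
        return iter(self.calls)

    def __len__(self):
        return len(self.calls)


def call_polyploid_snps(
    columns: list[PileupColumn],
    min_cov: int = 5,
    min_mean_mapq: float = 15.0,
    min_maf: float = 0.1,
) -> CallerResult:
    """Report positions containing an alternate allele, polyploid-style.

    A call is emitted iff depth >= ``min_cov``, the column's mean mapping
    quality is strictly above ``min_mean_mapq`` and some non-reference base
    has frequency strictly greater than ``min_maf`` (frequency = count /
    column depth).  Positions with an unknown reference base are skipped and
    tallied.
    """
    calls: list[SnpCall] = []
    skipped = 0
    for col in columns:
        if col.ref_base not in "ACGT":
            skipped += 1
            continue
        if col.depth < min_cov:
            continue
        if not col.mean_mapq > min_mean_mapq:
            continue
        alts = {b: c / col.depth for b, c in col.base_counts.items()
                if b != col.ref_base and b in "ACGT"}
        if not alts or max(alts.values()) <= min_maf:
            continue
        calls.append(SnpCall(
            contig=col.contig, pos=col.pos, ref_allele=col.ref_base,
            alt_alleles=alts, depth=col.depth, mean_mapq=col.mean_mapq,
        ))
    return CallerResult(calls=calls, n_skipped_unknown_ref=skipped)


@dataclass
class AssignmentResult:
    """Read -> genome-set assignments from exact full-length matching."""

    assignments: dict  # read name -> frozenset of sub-genome labels (size 1-2)
    n_unmatched: int = 0
    n_all_genomes: int = 0


def assign_reads_to_genomes(
    reads: list[AlignedRead],
    haplotypes: dict,
) -> AssignmentResult:
    """Assign reads to sub-genomes by perfect full-length sequence hits.

    A read is given the set of sub-genomes whose haplotype sequence contains
    it exactly (either orientation).  Only assignments to one or two genomes
    are informative and retained; reads matching none (sequencing error or
    off-target) or all three (no diagnostic difference in their span) are
    discarded and tallied.
    """
    joined = {lab: "#".join(contigs.values())
              for lab, contigs in haplotypes.items()}
    assignments: dict[str, frozenset] = {}
    n_unmatched = 0
    n_all = 0
    for r in reads:
        rc = revcomp(r.sequence)
        hit = frozenset(
            lab for lab, blob in joined.items()
            if r.sequence in blob or rc in blob
        )
        if len(hit) == 0:
            n_unmatched += 1
        elif len(hit) == len(joined):
            n_all += 1
        else:
            assignments[r.name] = hit
    return AssignmentResult(assignments, n_unmatched, n_all)


def build_homoeolog_list_from_haplotypes(
    reference: dict,
    haplotypes: dict,
) -> list[HomoeologousSnp]:
    """Diagnostic positions from coordinate-matched sub-genome sequences.

    Every position at which the haplotype bases are not all identical
    yields one record mapping each observed base to the sub-genomes
    carrying it.  Deterministic; on simulated data this reproduces the
    generator's truth table exactly.
    """
    labels = sorted(haplotypes)
    out: list[HomoeologousSnp] = []
    for name in sorted(reference):
        L = len(reference[name])
        seqs = {}
        for lab in labels:
            if name not in haplotypes[lab]:
                raise ValueError(f"haplotype {lab} missing contig {name}")
            if len(haplotypes[lab][name]) != L:
                raise ValueError(
                    f"haplotype {lab}/{name} length differs from reference")
            seqs[lab] = haplotypes[lab][name]
        for i in range(L):
            bases = {lab: seqs[lab][i] for lab in labels}
            if len(set(bases.values())) == 1:
                continue
            allele_map: dict[str, set] = {}
            for lab, b in bases.items():
                allele_map.setdefault(b, set()).add(lab)
            out.append(HomoeologousSnp(
                contig=name, pos=i + 1,
                allele_map={b: frozenset(g) for b, g in allele_map.items()},
            ))
    return out


def build_homoeolog_list_from_reads(
    reads: list[AlignedRead],
    assignments: dict,
    reference: dict,
    **caller_params,
) -> list[HomoeologousSnp]:
    """Diagnostic positions from genome-assigned reads.

    Runs the polyploid caller on reads that carry a genome-of-origin
    assignment, then attributes each allele at a called position to the
    union of the genome sets of the reads carrying it.  Positions whose
    alleles resolve to at least two distinct genome groups become
    homoeologous SNP records.
    """
    assigned = [r for r in reads if r.name in assignments]
    result = call_polyploid_snps(pileup(assigned, reference), **caller_params)

    by_contig: dict[str, list[AlignedRead]] = {}
    for r in assigned:
        by_contig.setdefault(r.contig, []).append(r)
    for rs in by_contig.values():
        rs.sort(key=lambda r: r.pos)
    starts = {c: [r.pos for r in rs] for c, rs in by_contig.items()}

    out: list[HomoeologousSnp] = []
    for call in result:
        rs = by_contig.get(call.contig, [])
        hi = bisect_right(starts.get(call.contig, []), call.pos)
        groups: dict[str, set] = {}
        for r in rs[:hi]:
            if r.end < call.pos:
                continue
            base = r.base_at(call.pos)
            if base in "ACGT":
                groups.setdefault(base, set()).update(assignments[r.name])
        distinct = {frozenset(g) for g in groups.values()}
        if len(groups) >= 2 and len(distinct) >= 2:
            out.append(HomoeologousSnp(
                contig=call.contig, pos=call.pos,
                allele_map={b: frozenset(g) for b, g in groups.items()},
            ))
    return out
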