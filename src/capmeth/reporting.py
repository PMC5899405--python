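"""Capture-efficiency summaries: per-contig coverage, bait depth, windows.

Mirrors the standard enrichment report: percent of reads aligned, percent
of each reference contig covered and its mean depth, how many contigs
captured anything at all, total base-space mapped, the fraction of baits
running hot (above twice the mean depth) or cold (below 5x), and min-max
normalised per-window feature frequencies along pseudomolecules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ContigCoverage:
    contig: str
    length: int
    covered_bases: int          # positions with depth >= 1
    pct_covered: float
    mean_depth_covered: float   # mean depth over covered positions
    mapped: bool


@dataclass
class CoverageSummary:
    pct_reads_aligned: float | None
    mean_pct_covered: float      # over mapped contigs
    mean_depth: float            # over mapped contigs
    n_contigs: int
    n_contigs_mapped: int
    pct_contigs_mapped: float
    total_base_space: int        # sum of covered bases


def _depth_arrays(alignments, reference) -> dict:
    depth = {name: np.zeros(len(seq), dtype=np.int64)
             for name, seq in reference.items()}
    for r in alignments:
        if not r.mapped:
            continue
        if r.contig not in depth:
            raise ValueError(f"read {r.name}: unknown contig {r.contig!r}")
        if r.pos < 1 or r.end > len(reference[r.contig]):
            raise ValueError(f"read {r.name} overhangs contig {r.contig}")
        depth[r.contig][r.pos - 1:r.end] += 1
    return depth


def coverage_stats(
    alignments: list,
    reference: dict,
    n_reads_total: int | None = None,
) -> tuple[list[ContigCoverage], CoverageSummary]:
    """Per-contig coverage rows plus the aggregate summary row.

    ``n_reads_total`` is the pre-filter sequenced-read count used as the
    denominator of the percent-aligned figure (individual records, not
    pairs); omit it and that figure is None.  Contig means are taken over
    mapped contigs (those with any covered base).
    """
    if not reference:
        raise ValueError("empty reference")
    depth = _depth_arrays(alignments, reference)
    rows: list[ContigCoverage] = []
    for name in sorted(reference):
        d = depth[name]
        covered = int((d > 0).sum())
        rows.append(ContigCoverage(
            contig=name, length=len(d), covered_bases=covered,
            pct_covered=100.0 * covered / len(d),
            mean_depth_covered=float(d[d > 0].mean()) if covered else 0.0,
            mapped=covered > 0))
    mapped = [r for r in rows if r.mapped]
    n_aligned = sum(1 for r in alignments if r.mapped)
    summary = CoverageSummary(
        pct_reads_aligned=(100.0 * n_aligned / n_reads_total
                           if n_reads_total else None),
        mean_pct_covered=(float(np.mean([r.pct_covered for r in mapped]))
                          if mapped else 0.0),
        mean_depth=(float(np.mean([r.mean_depth_covered for r in mapped]))
                    if mapped else 0.0),
        n_contigs=len(rows),
        n_contigs_mapped=len(mapped),
        pct_contigs_mapped=100.0 * len(mapped) / len(rows),
        total_base_space=sum(r.covered_bases for r in rows))
    return rows, summary


@dataclass
class BaitDepthProfile:
    n_baits: int
    mean_depth: float | None
    frac_above_2x_mean: float | None  # baits running hot
    frac_below_5x: float | None       # baits with low coverage (< 5x)
    undefined: bool = False


def bait_depth_profile(bait_mean_depths) -> BaitDepthProfile:
    """Fractions of baits above twice the overall mean depth and below 5x."""
    depths = np.asarray(list(bait_mean_depths), dtype=float)
    if depths.size == 0:
        return BaitDepthProfile(0, None, None, None, undefined=True)
    mean = float(depths.mean())
    return BaitDepthProfile(
        n_baits=int(depths.size),
        mean_depth=mean,
        frac_above_2x_mean=float((depths > 2.0 * mean).mean()),
        frac_below_5x=float((depths < 5.0).mean()),
    )


def bait_mean_depths(alignments, reference, baits) -> list[float]:
    """Mean depth over each bait interval (contig, start, end; 0-based)."""
    depth = _depth_arrays(alignments, reference)
    out = []
    for contig, start, end in baits:
        if contig not in depth:
            raise ValueError(f"bait on unknown contig {contig!r}")
        out.append(float(depth[contig][start:end].mean()) if end > start else 0.0)
    return out


@dataclass
class WindowTrack:
    chromosome: str
    window_size: int
    raw_counts: np.ndarray
    normalized: np.ndarray


def window_frequencies(
    positions,
    chromosome_lengths: dict,
    window_size: int = 1_000_000,
) -> dict:
    """Per-window feature counts, min-max normalised to [0, 1].

    ``positions`` is an iterable of (chromosome, pos) with 1-based
    coordinates; windows are half-open [k*w, (k+1)*w) in 0-based space.
    Normalisation is computed over all windows of the whole track (one
    genome-wide minimum and maximum), so it is idempotent and invariant to
    scaling the raw counts; a flat track (max == min) normalises to zeros.
    Positions beyond their chromosome raise, naming the feature.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    raw = {chrom: np.zeros(-(-length // window_size), dtype=np.int64)
           for chrom, length in chromosome_lengths.items()}
    for chrom, pos in positions:
        if chrom not in raw:
            raise ValueError(f"feature on unknown chromosome: ({chrom}, {pos})")
        if not 1 <= pos <= chromosome_lengths[chrom]:
            raise ValueError(
                f"feature beyond chromosome length: ({chrom}, {pos})")
        raw[chrom][(pos - 1) // window_size] += 1
    allv = np.concatenate(list(raw.values())) if raw else np.array([])
    lo = float(allv.min()) if allv.size else 0.0
    hi = float(allv.max()) if allv.size else 0.0
    out = {}
    for chrom, counts in raw.items():
        if hi > lo:
            norm = (counts - lo) / (hi - lo)
        else:
            norm = np.zeros_like(counts, dtype=float)
        out[chrom] = WindowTrack(chromosome=chrom, window_size=window_size,
                                 raw_counts=counts, normalized=norm)
    return out
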