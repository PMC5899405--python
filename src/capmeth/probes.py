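"""Capture probe-set design: tiling, annotation, ranking, boosting.

The design procedure tiles fixed-length (default 120 bp) candidate probes
across the genic design space at a regular step (default 40 bp), annotates
each candidate with alignment identity, overlapping homoeologous / varietal
SNP counts and prior capture depth, selects a target number of "best"
probes — optionally forcing one probe per contig before any contig gets a
second, and force-tiling priority genes end-to-end — and finally "boosts"
(duplicates) selected probes of above-average GC content to even out
capture efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import numpy as np


@dataclass
class ProbeCandidate:
    contig: str
    offset: int      # 0-based start
    length: int
    sequence: str
    alignment_identity: float | None = None
    homoeo_snp_count: int | None = None
    varietal_snp_count: int | None = None
    prior_mean_depth: float | None = None  # None = unknown, neutral in ranking
    gc_content: float = 0.0
    rank_score: float | None = None

    @property
    def interval(self) -> tuple:
        """0-based half-open interval on the contig."""
        return (self.offset, self.offset + self.length)


@dataclass
class ProbeSet:
    selected: list
    boosted: list = field(default_factory=list)  # repeated candidates
    target_count: int = 0

    def bed_records(self):
        """0-based half-open BED rows; boosted probes appear repeatedly."""
        for p in list(self.selected) + list(self.boosted):
            yield (p.contig, p.offset, p.offset + p.length)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return sum(1 for b in seq if b in "GC") / len(seq)


def tile_candidates(
    contigs: dict,
    probe_len: int = 120,
    step: int = 40,
) -> list[ProbeCandidate]:
    """Tile candidates at offsets 0, step, 2*step, ... per contig.

    A contig of length L >= probe_len yields floor((L - probe_len)/step) + 1
    candidates; shorter contigs yield none.
    """
    if probe_len < 1 or step < 1:
        raise ValueError("probe_len and step must be >= 1")
    out: list[ProbeCandidate] = []
    for name in sorted(contigs):
        seq = contigs[name]
        for off in range(0, len(seq) - probe_len + 1, step):
            sub = seq[off:off + probe_len]
            out.append(ProbeCandidate(
                contig=name, offset=off, length=probe_len, sequence=sub,
                gc_content=gc_fraction(sub)))
    return out


def annotate_candidates(
    candidates: list,
    alignments: dict | None = None,
    homoeo_snps: list | None = None,
    varietal_snps: list | None = None,
    depth_track: dict | None = None,
) -> list[ProbeCandidate]:
    """Fill per-candidate annotations in place (and return the list).

    ``alignments`` maps (contig, offset) -> alignment identity fraction
    (candidates without a record get 0).  SNP inputs are iterables with
    ``contig``/``pos`` attributes or (contig, pos, ...) tuples, 1-based;
    counts are SNPs overlapping [offset, offset + length).  ``depth_track``
    maps contig -> per-base depth array; when absent, prior depth stays
    None (unknown) and is treated as neutral by the ranking.
    """
    def _positions(snps):
        pos: dict[str, list] = {}
        for s in snps or ():
            contig, p = (s.contig, s.pos) if hasattr(s, "contig") else (s[0], s[1])
            pos.setdefault(contig, []).append(p)
        for v in pos.values():
            v.sort()
        return pos

    homoeo_pos = _positions(homoeo_snps)
    varietal_pos = _positions(varietal_snps)

    def _count(pos_map, cand):
        lo, hi = cand.interval  # 0-based half-open -> 1-based [lo+1, hi]
        arr = pos_map.get(cand.contig, [])
        return int(np.searchsorted(arr, hi, side="right")
                   - np.searchsorted(arr, lo + 1, side="left"))

    for cand in candidates:
        cand.alignment_identity = float(
            (alignments or {}).get((cand.contig, cand.offset), 0.0))
        cand.homoeo_snp_count = _count(homoeo_pos, cand)
        cand.varietal_snp_count = _count(varietal_pos, cand)
        if depth_track is not None and cand.contig in depth_track:
            lo, hi = cand.interval
            cand.prior_mean_depth = float(
                np.asarray(depth_track[cand.contig][lo:hi], float).mean())
        else:
            cand.prior_mean_depth = None
        cand.gc_content = gc_fraction(cand.sequence)
    return candidates


def score_candidates(candidates: list, weights=(1.0, 1.0, 1.0, 1.0)) -> None:
    """Rank score: a weighted sum of the design annotations.

    Components, each scaled to [0, 1] over the candidate set: alignment
    identity; homoeologous SNP count (normalised by the maximum); varietal
    SNP count (same); closeness of prior depth to the median prior depth
    (1 at the median, falling linearly to 0 at the farthest candidate).
    Unknown prior depth scores a neutral 0.5.  Transparent and monotone in
    each design criterion; weights are configurable.
    """
    w_id, w_h, w_v, w_d = weights
    max_h = max((c.homoeo_snp_count or 0) for c in candidates) if candidates else 0
    max_v = max((c.varietal_snp_count or 0) for c in candidates) if candidates else 0
    depths = [c.prior_mean_depth for c in candidates
              if c.prior_mean_depth is not None]
    med = median(depths) if depths else None
    max_dev = max((abs(d - med) for d in depths), default=0.0) if depths else 0.0
    for c in candidates:
        s = w_id * (c.alignment_identity or 0.0)
        s += w_h * ((c.homoeo_snp_count or 0) / max_h if max_h else 0.0)
        s += w_v * ((c.varietal_snp_count or 0) / max_v if max_v else 0.0)
        if c.prior_mean_depth is None or med is None:
            closeness = 0.5
        elif max_dev == 0.0:
            closeness = 1.0
        else:
            closeness = 1.0 - abs(c.prior_mean_depth - med) / max_dev
        s += w_d * closeness
        c.rank_score = float(s)


def tile_priority_intervals(
    contigs: dict,
    priority_intervals: list,
    probe_len: int = 120,
) -> list[ProbeCandidate]:
    """End-to-end (step = probe length) tiling of priority regions.

    Intervals are (contig, start, end), 0-based half-open.  Probes sit at
    start, start + probe_len, ...; when the interval length is not a
    multiple of the probe length a final probe flush with the interval end
    is added so the whole region is enriched.
    """
    out: list[ProbeCandidate] = []
    seen: set = set()
    for contig, start, end in priority_intervals:
        if contig not in contigs:
            raise ValueError(f"priority interval on unknown contig {contig!r}")
        seq = contigs[contig]
        if start < 0 or end > len(seq):
            raise ValueError(f"priority interval {contig}:{start}-{end} "
                             "outside contig")
        span = end - start
        if span < probe_len:
            continue
        offsets = list(range(start, end - probe_len + 1, probe_len))
        if offsets and offsets[-1] + probe_len < end:
            offsets.append(end - probe_len)
        for off in offsets:
            if (contig, off) in seen:
                continue
            seen.add((contig, off))
            sub = seq[off:off + probe_len]
            out.append(ProbeCandidate(
                contig=contig, offset=off, length=probe_len, sequence=sub,
                gc_content=gc_fraction(sub)))
    return out


def rank_and_select(
    candidates: list,
    target_count: int,
    weights=(1.0, 1.0, 1.0, 1.0),
    one_per_contig_bias: bool = True,
    priority_intervals: list | None = None,
    contigs: dict | None = None,
    probe_len: int = 120,
) -> ProbeSet:
    """Select the best ``target_count`` probes.

    Priority intervals are tiled end-to-end and force-included first (this
    needs ``contigs`` sequences).  With the one-per-contig bias, the best
    candidate of every contig is taken before any contig receives a second
    probe.  Remaining slots fill in descending rank score with a
    deterministic (contig, offset) tie-break, making the selection a
    permutation-invariant function of the candidate set.
    """
    forced: list[ProbeCandidate] = []
    if priority_intervals:
        if contigs is None:
            raise ValueError("priority_intervals require contig sequences")
        forced = tile_priority_intervals(contigs, priority_intervals, probe_len)
    if len(forced) > target_count:
        raise ValueError(
            f"target_count {target_count} is {len(forced) - target_count} "
            f"probes short of the {len(forced)} forced by priority intervals")

    score_candidates(candidates, weights)
    taken = {(p.contig, p.offset) for p in forced}
    selected = list(forced)
    per_contig_count: dict[str, int] = {}
    for p in forced:
        per_contig_count[p.contig] = per_contig_count.get(p.contig, 0) + 1

    order = sorted(candidates,
                   key=lambda c: (-c.rank_score, c.contig, c.offset))
    order = [c for c in order if (c.contig, c.offset) not in taken]

    if one_per_contig_bias:
        for c in order:
            if len(selected) >= target_count:
                break
            if per_contig_count.get(c.contig, 0):
                continue
            selected.append(c)
            taken.add((c.contig, c.offset))
            per_contig_count[c.contig] = 1
        order = [c for c in order if (c.contig, c.offset) not in taken]

    for c in order:
        if len(selected) >= target_count:
            break
        selected.append(c)
        taken.add((c.contig, c.offset))

    selected.sort(key=lambda c: (c.contig, c.offset))
    return ProbeSet(selected=selected, boosted=[], target_count=target_count)


def boost(
    probe_set: ProbeSet,
    capacity: int,
    gc_threshold: float | None = None,
) -> ProbeSet:
    """Duplicate high-GC probes round-robin until ``capacity`` is used.

    Probes strictly above the selected set's mean GC (or an explicit
    threshold) are eligible, taken highest GC first; with capacity left
    over after one pass, duplication wraps around.  Capacity 0, or no probe
    above average, leaves the set unchanged.
    """
    if capacity < 0:
        raise ValueError("capacity must be >= 0")
    boosted: list[ProbeCandidate] = []
    if capacity and probe_set.selected:
        thr = (gc_threshold if gc_threshold is not None
               else float(np.mean([p.gc_content for p in probe_set.selected])))
        eligible = sorted(
            (p for p in probe_set.selected if p.gc_content > thr),
            key=lambda p: (-p.gc_content, p.contig, p.offset))
        i = 0
        while eligible and len(boosted) < capacity:
            boosted.append(eligible[i % len(eligible)])
            i += 1
    return ProbeSet(selected=list(probe_set.selected), boosted=boosted,
                    target_count=probe_set.target_count)
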