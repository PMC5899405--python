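"""Synthetic polyploid genome and captured-read simulator.

Emulates the data shape of a dual-purpose (genotype + methylation) targeted
capture experiment on an allohexaploid: a collapsed capture reference whose
genes are single representatives of three homoeologous copies, three
coordinate-matched sub-genome haplotypes (A/B/D) that differ from the
reference at diagnostic homoeologous SNPs, accession-specific varietal SNPs,
per-context cytosine methylation states, an unmethylated control genome (the
chloroplast stand-in), and uniform-error captured reads — untreated or
bisulphite-converted — with exact truth alignments.

Every stochastic choice flows from one top-level seed through named
substreams, so identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .contexts import classify_context

BASES = np.array(list("ACGT"))
HAPLOTYPE_LABELS = ("A", "B", "D")
CONTROL = "control"
OFF_TARGET = "off-target"

#: genome-conversion-strand labels (value of the SAM ``XG`` tag)
XG_TOP = "CT"
XG_BOTTOM = "GA"

#: bisulphite strand types emitted in non-directional mode
BS_STRANDS = ("OT", "OB", "CTOT", "CTOB")


def _stream(seed: int, label: str) -> np.random.Generator:
    """Deterministic named substream of the top-level seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Genome-level simulation parameters.

    Rates are per-base probabilities; methylation rates are per-context
    probabilities that a cytosine site is methylated on a given chromosome
    copy (values typical of plant genic sequence).
    """

    n_contigs: int = 8
    contig_length: int = 3000
    homoeo_snp_rate: float = 0.01
    varietal_snp_rate: float = 0.002
    meth_cpg: float = 0.80
    meth_chg: float = 0.50
    meth_chh: float = 0.05
    control_length: int = 5000
    read_length: int = 125
    seed: int = 0

    def validate(self) -> None:
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if self.contig_length < self.read_length:
            raise ValueError(
                f"contig_length {self.contig_length} shorter than read_length "
                f"{self.read_length}"
            )
        if self.control_length < self.read_length:
            raise ValueError("control genome shorter than read length")
        for name in ("homoeo_snp_rate", "varietal_snp_rate", "meth_cpg",
                     "meth_chg", "meth_chh"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class HomoeologousSnp:
    """A diagnostic position: observed base -> set of sub-genomes carrying it."""

    contig: str
    pos: int  # 1-based
    allele_map: dict  # base -> frozenset of sub-genome labels

    def genome_allele(self, genome: str) -> str:
        for base, genomes in self.allele_map.items():
            if genome in genomes:
                return base
        raise KeyError(genome)


@dataclass
class GenomeModel:
    """Reference, haplotypes and truth tables for one simulated accession."""

    contigs: dict                 # name -> collapsed reference sequence
    haplotypes: dict              # label -> {contig name -> sequence}
    homoeo_truth: list            # list[HomoeologousSnp]
    varietal_truth: list          # list[(contig, pos, ref_allele, alt_allele)]
    methylation_truth: dict       # (hap, contig, pos, strand) -> probability
    control_genome: tuple         # (name, sequence); unmethylated everywhere
    config: SimulationConfig = None

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def contig_lengths(self) -> dict:
        return {name: len(seq) for name, seq in self.contigs.items()}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _methylation_probability(cfg: SimulationConfig, context: str) -> float:
    if context == "CpG":
        return cfg.meth_cpg
    if context == "CHG":
        return cfg.meth_chg
    # CHH and truncated edge sites share the lowest (asymmetric) rate
    return cfg.meth_chh


def build_genome(config: SimulationConfig) -> GenomeModel:
    """Build a collapsed reference, three haplotypes and truth tables.

    Homoeologous SNPs are introduced into the haplotypes relative to the
    reference (mostly one sub-genome deviating, occasionally all three
    distinct); varietal SNPs model accession-vs-reference differences and
    are applied to all three haplotypes, so inter-haplotype differences are
    exactly the homoeologous truth table.  Deterministic for a fixed seed.
    """
    config.validate()
    rng = _stream(config.seed, "genome")

    contigs = {}
    for k in range(config.n_contigs):
        contigs[f"contig_{k + 1:03d}"] = _random_seq(rng, config.contig_length)

    haplotypes = {lab: {} for lab in HAPLOTYPE_LABELS}
    homoeo_truth: list[HomoeologousSnp] = []
    varietal_truth: list[tuple] = []

    for name, ref in contigs.items():
        L = len(ref)
        hap_cols = {lab: list(ref) for lab in HAPLOTYPE_LABELS}
        is_homoeo = rng.random(L) < config.homoeo_snp_rate
        is_varietal = (rng.random(L) < config.varietal_snp_rate) & ~is_homoeo

        for i in np.flatnonzero(is_homoeo):
            refbase = ref[i]
            others = [b for b in "ACGT" if b != refbase]
            if rng.random() < 0.9:
                # one sub-genome deviates from the collapsed representative
                hap = HAPLOTYPE_LABELS[rng.integers(0, 3)]
                hap_cols[hap][i] = others[rng.integers(0, 3)]
            else:
                # all three sub-genomes carry distinct bases
                triple = rng.permutation(list("ACGT"))[:3]
                for lab, b in zip(HAPLOTYPE_LABELS, triple):
                    hap_cols[lab][i] = str(b)
            allele_map: dict[str, set] = {}
            for lab in HAPLOTYPE_LABELS:
                allele_map.setdefault(hap_cols[lab][i], set()).add(lab)
            homoeo_truth.append(HomoeologousSnp(
                contig=name, pos=int(i) + 1,
                allele_map={b: frozenset(g) for b, g in allele_map.items()},
            ))

        for i in np.flatnonzero(is_varietal):
            refbase = ref[i]
            others = [b for b in "ACGT" if b != refbase]
            alt = others[rng.integers(0, 3)]
            for lab in HAPLOTYPE_LABELS:
                hap_cols[lab][i] = alt
            varietal_truth.append((name, int(i) + 1, refbase, alt))

        for lab in HAPLOTYPE_LABELS:
            haplotypes[lab][name] = "".join(hap_cols[lab])

    # Methylation states are bimodal, as in real plant methylomes: each
    # cytosine site of each haplotype is methylated (probability 1 per read)
    # with its context rate, or unmethylated (probability 0).  The pooled
    # per-context methylation level therefore recovers the context rate.
    meth_rng = _stream(config.seed, "methylation")
    methylation_truth: dict = {}
    for lab in HAPLOTYPE_LABELS:
        for name, seq in haplotypes[lab].items():
            for i, base in enumerate(seq):
                if base == "C":
                    strand = "+"
                elif base == "G":
                    strand = "-"
                else:
                    continue
                ctx = classify_context(seq, i, strand)
                rate = _methylation_probability(config, ctx)
                methylation_truth[(lab, name, i + 1, strand)] = float(
                    meth_rng.random() < rate)

    control_seq = _random_seq(_stream(config.seed, "control"),
                              config.control_length)
    return GenomeModel(
        contigs=contigs,
        haplotypes=haplotypes,
        homoeo_truth=homoeo_truth,
        varietal_truth=varietal_truth,
        methylation_truth=methylation_truth,
        control_genome=("control", control_seq),
        config=config,
    )


@dataclass(frozen=True)
class ReadSimParams:
    """Read-level simulation parameters.

    ``depth`` is the requested mean on-target coverage; off-target reads are
    split between the unmethylated control genome (capture carryover) and
    unmappable random background.  ``mapq_distribution`` is a tuple of
    ``(mapq, weight)`` pairs so mapping-quality filters are exercisable.
    """

    depth: float = 30.0
    read_length: int = 125
    on_target_fraction: float = 0.5
    control_fraction: float = 0.5
    error_rate: float = 0.001
    duplicate_rate: float = 0.05
    mapq_distribution: tuple = ((60, 0.90), (20, 0.06), (5, 0.04))
    seed: int = 0

    def validate(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        for name in ("on_target_fraction", "control_fraction", "error_rate",
                     "duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        w = sum(p for _, p in self.mapq_distribution)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("mapq_distribution weights must sum to 1")


@dataclass
class SimulatedRead:
    """One simulated fragment, stored in reference orientation (SAM SEQ)."""

    name: str
    haplotype_of_origin: str  # A/B/D, "control" or "off-target"
    contig: str | None        # None for unmappable background reads
    start: int                # 1-based leftmost reference coordinate
    strand: str               # strand the fragment derives from
    sequence: str
    mapq: int
    duplicate: bool = False
    bs_strand: str | None = None  # OT/OB/CTOT/CTOB after conversion

    @property
    def end(self) -> int:
        """1-based inclusive rightmost coordinate."""
        return self.start + len(self.sequence) - 1

    @property
    def converted(self) -> bool:
        return self.bs_strand is not None

    @property
    def xg(self) -> str | None:
        """Genome conversion strand tag value (CT = top, GA = bottom)."""
        if self.bs_strand is None:
            return None
        return XG_TOP if self.bs_strand in ("OT", "CTOT") else XG_BOTTOM


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hit:
        cur = arr[i].decode()
        alts = [b for b in "ACGT" if b != cur]
        arr[i] = alts[rng.integers(0, 3)].encode()
    return arr.tobytes().decode()


def simulate_reads(model: GenomeModel, params: ReadSimParams) -> list[SimulatedRead]:
    """Simulate captured fragments with exact truth coordinates.

    On-target reads are drawn uniformly from the three haplotypes across the
    capture space (contigs weighted by length); off-target reads come from
    the control genome or from random, unmappable background sequence.  The
    number of on-target reads is chosen so that the realised mean on-target
    depth matches ``params.depth``.
    """
    params.validate()
    rng = _stream(params.seed, "reads")

    names = list(model.contigs)
    lengths = np.array([len(model.contigs[n]) for n in names], dtype=float)
    total_len = lengths.sum()
    rl = params.read_length
    if any(lengths < rl):
        raise ValueError("a reference contig is shorter than the read length")

    n_on = int(round(params.depth * total_len / rl))
    if params.on_target_fraction > 0:
        n_total = int(round(n_on / params.on_target_fraction))
    else:
        n_total = n_on  # degenerate: no on-target requested
        n_on = 0
    n_off = n_total - n_on
    n_control = int(round(n_off * params.control_fraction))
    n_background = n_off - n_control

    mq_values = np.array([m for m, _ in params.mapq_distribution])
    mq_weights = np.array([w for _, w in params.mapq_distribution])
    contig_p = lengths / total_len
    control_name, control_seq = model.control_genome

    reads: list[SimulatedRead] = []

    def _emit(origin, contig, seq_source, idx):
        L = len(seq_source)
        start0 = int(rng.integers(0, L - rl + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = _apply_errors(rng, seq_source[start0:start0 + rl],
                            params.error_rate)
        reads.append(SimulatedRead(
            name=f"r{idx:07d}",
            haplotype_of_origin=origin,
            contig=contig,
            start=start0 + 1,
            strand=strand,
            sequence=seq,
            mapq=int(mq_values[rng.choice(len(mq_values), p=mq_weights)]),
            duplicate=bool(rng.random() < params.duplicate_rate),
        ))

    idx = 0
    for _ in range(n_on):
        hap = HAPLOTYPE_LABELS[rng.integers(0, 3)]
        contig = names[rng.choice(len(names), p=contig_p)]
        _emit(hap, contig, model.haplotypes[hap][contig], idx)
        idx += 1
    for _ in range(n_control):
        _emit(CONTROL, control_name, control_seq, idx)
        idx += 1
    for _ in range(n_background):
        seq = _random_seq(rng, rl)
        reads.append(SimulatedRead(
            name=f"r{idx:07d}", haplotype_of_origin=OFF_TARGET,
            contig=None, start=0,
            strand="+" if rng.random() < 0.5 else "-",
            sequence=seq, mapq=0,
            duplicate=bool(rng.random() < params.duplicate_rate),
        ))
        idx += 1
    return reads


def bisulphite_convert(
    reads: list[SimulatedRead],
    model: GenomeModel,
    conversion_efficiency: float,
    directional: bool = False,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Apply in-silico bisulphite conversion to simulated fragments.

    Bisulphite deaminates unmethylated cytosines to uracil, read as T.  The
    chemistry acts on the strand the fragment derives from: in reference
    orientation a top-strand fragment shows C->T at unmethylated cytosines,
    a bottom-strand fragment shows G->A.  Each cytosine site is methylated
    per read with its truth-table probability (control and background reads
    are unmethylated everywhere); an unmethylated cytosine converts with
    probability ``conversion_efficiency``.  Non-directional libraries also
    contain the PCR complements of both converted strands, so half the
    output is labelled CTOT/CTOB; the reference-orientation substitution
    pattern, and hence the genome conversion strand, is unchanged.
    """
    if not 0.0 <= conversion_efficiency <= 1.0:
        raise ValueError("conversion_efficiency must be in [0, 1]")
    if any(r.converted for r in reads):
        raise ValueError("reads are already bisulphite converted")

    rng = _stream(seed, "bisulphite")
    truth = model.methylation_truth
    out: list[SimulatedRead] = []
    for read in reads:
        top = read.strand == "+"
        target, product, strand_key = ("C", "T", "+") if top else ("G", "A", "-")
        on_truth = read.haplotype_of_origin in HAPLOTYPE_LABELS
        seq = list(read.sequence)
        for i, base in enumerate(seq):
            if base != target:
                continue
            p_meth = 0.0
            if on_truth:
                p_meth = truth.get(
                    (read.haplotype_of_origin, read.contig,
                     read.start + i, strand_key), 0.0)
            if rng.random() < p_meth:
                continue  # methylated: protected from conversion
            if rng.random() < conversion_efficiency:
                seq[i] = product
        bs = "OT" if top else "OB"
        if not directional and rng.random() < 0.5:
            bs = "CTOT" if top else "CTOB"
        out.append(replace(read, sequence="".join(seq), bs_strand=bs))
    return out
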