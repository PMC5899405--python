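"""File I/O: SAM (pysam), FASTA/FASTQ (Biopython), truth/result tables.

The SAM dialect: sequences are stored in reference orientation; FLAG uses
the standard bits (0x4 unmapped, 0x10 reverse strand, 0x100 secondary,
0x400 duplicate).  Optional tags: ``XG`` genome conversion strand (``CT``
top / ``GA`` bottom) on bisulphite reads, ``XB`` the bisulphite strand type
(OT/OB/CTOT/CTOB), ``ZH`` the true haplotype of origin on simulated reads.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import HomoeologousSnp, SimulatedRead
from .variants import AlignedRead

# ---------------------------------------------------------------- FASTA/FASTQ

def write_fasta(path, sequences: dict) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path, reads) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


# ----------------------------------------------------------------------- SAM

def _sam_header(reference_lengths: dict) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length}
               for name, length in reference_lengths.items()],
    })


def write_sam(path, reads, reference_lengths: dict) -> None:
    """Write simulated reads as a truth SAM (text, uncompressed)."""
    header = _sam_header(reference_lengths)
    names = list(reference_lengths)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = r.name
            a.query_sequence = r.sequence
            a.query_qualities = pysam.qualitystring_to_array(
                "I" * len(r.sequence))
            is_sim = isinstance(r, SimulatedRead)
            start = r.start if is_sim else r.pos
            flag = 0
            if r.contig is None:
                flag |= 0x4
            else:
                a.reference_id = names.index(r.contig)
                a.reference_start = start - 1
                a.cigarstring = f"{len(r.sequence)}M"
                if r.strand == "-":
                    flag |= 0x10
            if r.duplicate:
                flag |= 0x400
            if not is_sim and not r.unique:
                flag |= 0x100
            a.flag = flag
            a.mapping_quality = r.mapq
            if is_sim:
                tags = [("ZH", r.haplotype_of_origin)]
                if r.converted:
                    tags += [("XG", r.xg), ("XB", r.bs_strand)]
            else:
                tags = list(r.tags.items())
            a.set_tags(tags)
            out.write(a)


def read_sam(path) -> list[AlignedRead]:
    """Load a SAM file into in-memory alignment records."""
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            tags = dict(rec.get_tags())
            out.append(AlignedRead(
                name=rec.query_name,
                contig=None if rec.is_unmapped else rec.reference_name,
                pos=0 if rec.is_unmapped else rec.reference_start + 1,
                strand="-" if rec.is_reverse else "+",
                mapq=rec.mapping_quality,
                sequence=rec.query_sequence or "",
                cigar=None if rec.is_unmapped else rec.cigarstring,
                duplicate=rec.is_duplicate,
                unique=not rec.is_secondary,
                tags=tags,
            ))
    return out


def simulated_to_aligned(reads) -> list[AlignedRead]:
    """In-memory view of simulated reads as alignment records."""
    out = []
    for r in reads:
        tags = {"ZH": r.haplotype_of_origin}
        if r.converted:
            tags["XG"] = r.xg
            tags["XB"] = r.bs_strand
        out.append(AlignedRead(
            name=r.name, contig=r.contig,
            pos=r.start if r.contig else 0,
            strand=r.strand, mapq=r.mapq, sequence=r.sequence,
            duplicate=r.duplicate, tags=tags))
    return out


# -------------------------------------------------------------------- tables

GENOME_LABELS = ("A", "B", "D")


def write_homoeolog_tsv(path, snps) -> None:
    """Homoeologous SNP table: per-genome allele columns, 1-based positions."""
    rows = []
    for s in snps:
        row = {"contig": s.contig, "pos": s.pos}
        for g in GENOME_LABELS:
            try:
                row[f"allele_{g}"] = s.genome_allele(g)
            except KeyError:
                row[f"allele_{g}"] = "."
        rows.append(row)
    pd.DataFrame(rows, columns=["contig", "pos"]
                 + [f"allele_{g}" for g in GENOME_LABELS]
                 ).to_csv(path, sep="\t", index=False)


def read_homoeolog_tsv(path) -> list[HomoeologousSnp]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    out = []
    for row in df.itertuples(index=False):
        allele_map: dict[str, set] = {}
        for g in GENOME_LABELS:
            base = getattr(row, f"allele_{g}")
            if base != ".":
                allele_map.setdefault(base, set()).add(g)
        out.append(HomoeologousSnp(
            contig=row.contig, pos=int(row.pos),
            allele_map={b: frozenset(g) for b, g in allele_map.items()}))
    return out


def write_varietal_tsv(path, varietal_truth) -> None:
    pd.DataFrame(varietal_truth,
                 columns=["contig", "pos", "ref_allele", "alt_allele"]
                 ).to_csv(path, sep="\t", index=False)


def write_methylation_truth_tsv(path, model) -> None:
    from .contexts import classify_context
    rows = []
    for (hap, contig, pos, strand), p in sorted(model.methylation_truth.items()):
        seq = model.haplotypes[hap][contig]
        rows.append({"haplotype": hap, "contig": contig, "pos": pos,
                     "strand": strand,
                     "context": classify_context(seq, pos - 1, strand),
                     "probability": p})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_snp_tsv(path, calls) -> None:
    rows = [{"contig": c.contig, "pos": c.pos, "ref": c.ref_allele,
             "alt": c.primary_alt,
             "alt_freq": round(c.alt_alleles[c.primary_alt], 6),
             "depth": c.depth, "mean_mapq": round(c.mean_mapq, 3)}
            for c in calls]
    pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "alt_freq",
                                "depth", "mean_mapq"]
                 ).to_csv(path, sep="\t", index=False)


def read_snp_tsv(path):
    from .variants import SnpCall
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    return [SnpCall(contig=r.contig, pos=int(r.pos), ref_allele=r.ref,
                    alt_alleles={r.alt: float(r.alt_freq)},
                    depth=int(r.depth), mean_mapq=float(r.mean_mapq))
            for r in df.itertuples(index=False)]


def write_cytosine_tsv(path, records, genomes=GENOME_LABELS) -> None:
    """methylKit-style per-base table: coverage / numCs / numTs semantics.

    Columns: contig, pos (1-based), strand, context, coverage, numCs,
    numTs, then per-genome coverage/numCs/numTs triples when any record
    carries sub-genome counts.
    """
    recs = sorted(records.values() if isinstance(records, dict) else records,
                  key=lambda r: (r.contig, r.pos, r.strand))
    with_genomes = any(r.per_subgenome for r in recs)
    rows = []
    for r in recs:
        row = {"contig": r.contig, "pos": r.pos, "strand": r.strand,
               "context": r.context, "coverage": r.depth,
               "numCs": r.meth_count, "numTs": r.unmeth_count}
        if with_genomes:
            for g in genomes:
                m, u = r.per_subgenome.get(g, (0, 0))
                row[f"coverage_{g}"] = m + u
                row[f"numCs_{g}"] = m
                row[f"numTs_{g}"] = u
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cytosine_tsv(path) -> dict:
    from .methylation import CytosineRecord
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    genome_cols = [c for c in df.columns if c.startswith("numCs_")]
    genomes = [c.split("_", 1)[1] for c in genome_cols]
    out = {}
    for r in df.itertuples(index=False):
        rec = CytosineRecord(
            contig=r.contig, pos=int(r.pos), strand=r.strand,
            context=r.context, meth_count=int(r.numCs),
            unmeth_count=int(r.numTs))
        for g in genomes:
            m = int(getattr(r, f"numCs_{g}"))
            u = int(getattr(r, f"numTs_{g}"))
            if m or u:
                rec.per_subgenome[g] = [m, u]
        out[rec.key] = rec
    return out


def write_bed(path, intervals) -> None:
    """0-based half-open BED rows: (contig, start, end[, name])."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> list[tuple]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        out.append((parts[0], int(parts[1]), int(parts[2])))
    return out
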