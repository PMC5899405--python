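"""Genotype-aware correction of the methylation analysis reference.

Two SNP classes matter for bisulphite analysis.  A sample C->T (or G->A)
variant looks exactly like a fully unmethylated cytosine and, left
unidentified, floods the methylome with false unmethylated calls: these
positions are masked.  Conversely an A/T->C/G variant creates a cytosine
the reference does not know about — a missed analysis opportunity — and is
substituted into the reference, adding a new analysable site.  C<->G swaps
move a cytosine from one strand to the other and are handled as a mask on
the lost strand plus an addition on the gained strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .contexts import cytosine_sites
from .variants import SnpCall


class SnpCategory(str, Enum):
    CT_GA = "CT_GA"      # reference C->T or G->A: cytosine lost, must be masked
    AT_CG = "AT_CG"      # reference A/T -> sample C/G: cytosine gained
    CG_SWAP = "CG_SWAP"  # C->G or G->C: cytosine switches strand
    OTHER = "OTHER"


@dataclass
class SnpClass:
    snp: SnpCall
    category: SnpCategory

    @property
    def alt(self) -> str:
        return self.snp.primary_alt


def _categorise(ref: str, alt: str) -> SnpCategory:
    if ref == alt:
        raise ValueError(f"reference and alternate allele are both {ref!r}")
    if (ref, alt) in (("C", "T"), ("G", "A")):
        return SnpCategory.CT_GA
    if ref in "AT" and alt in "CG":
        return SnpCategory.AT_CG
    if (ref, alt) in (("C", "G"), ("G", "C")):
        return SnpCategory.CG_SWAP
    return SnpCategory.OTHER


def classify_snps(snps: list) -> list[SnpClass]:
    """Classify calls by their effect on the cytosine analysis set.

    Each call's primary alternate allele (highest frequency, alphabetical
    tie-break) determines the category.
    """
    return [SnpClass(snp=s, category=_categorise(s.ref_allele, s.primary_alt))
            for s in snps]


@dataclass
class CorrectedReference:
    sequences: dict   # contig -> corrected sequence (same lengths)
    masked: set       # (contig, pos, strand) cytosine sites removed
    added: set        # (contig, pos, strand) cytosine sites gained
    n_edits: int

    def cytosine_site_set(self) -> set:
        """Analysable cytosine sites of the corrected reference.

        Sites of the corrected sequence minus the masked C->T / G->A
        positions (those are sample variants, not informative cytosines).
        Note masked sites are no longer cytosines in the corrected sequence,
        so the subtraction is a no-op kept for clarity.
        """
        sites = {(name, pos, strand)
                 for name, seq in self.sequences.items()
                 for pos, strand in cytosine_sites(seq)}
        return sites - self.masked


def correct_reference(
    reference: dict,
    snp_classes: list,
    hom_freq: float = 0.9,
) -> CorrectedReference:
    """Apply homozygous sample alleles to the reference and track the sites.

    Only calls whose primary alternate allele reaches frequency
    ``hom_freq`` (default 0.9) are applied — reference correction must not
    encode heterozygous states.  Corrected sequences keep their length.
    Overlapping contradictory edits raise.
    """
    seqs = {name: list(seq) for name, seq in reference.items()}
    applied: dict[tuple, str] = {}
    masked: set = set()
    added: set = set()
    for sc in snp_classes:
        s = sc.snp
        if s.alt_alleles[s.primary_alt] < hom_freq:
            continue
        if s.contig not in seqs:
            raise ValueError(f"SNP on unknown contig {s.contig!r}")
        key = (s.contig, s.pos)
        alt = s.primary_alt
        if key in applied:
            if applied[key] != alt:
                raise ValueError(
                    f"contradictory edits at {s.contig}:{s.pos} "
                    f"({applied[key]} vs {alt})")
            continue
        ref = seqs[s.contig][s.pos - 1]
        if ref != s.ref_allele:
            raise ValueError(
                f"SNP at {s.contig}:{s.pos} expects reference "
                f"{s.ref_allele}, found {ref}")
        applied[key] = alt
        seqs[s.contig][s.pos - 1] = alt
        # cytosine-site bookkeeping follows the base change itself, so the
        # set algebra (corrected = original - masked + added) is exact for
        # every category, including C->A / G->T losses outside CT_GA
        if ref == "C" and alt != "C":
            masked.add((s.contig, s.pos, "+"))
        if ref == "G" and alt != "G":
            masked.add((s.contig, s.pos, "-"))
        if alt == "C" and ref != "C":
            added.add((s.contig, s.pos, "+"))
        if alt == "G" and ref != "G":
            added.add((s.contig, s.pos, "-"))
    return CorrectedReference(
        sequences={name: "".join(chars) for name, chars in seqs.items()},
        masked=masked, added=added, n_edits=len(applied))


@dataclass
class CorrectionReport:
    """Accounting of what genotype correction does to the methylome."""

    n_snps_total: int
    n_ct_ga: int
    n_at_cg: int
    n_analyzable_cytosines: int
    pct_calls_eliminated: float | None
    n_cytosines_added: int
    pct_cytosines_added: float | None
    undefined: bool = False

    @classmethod
    def from_counts(
        cls,
        n_ct_ga: int,
        n_at_cg: int,
        n_analyzable_cytosines: int,
        n_snps_total: int | None = None,
    ) -> "CorrectionReport":
        """Build the report directly from SNP-class and cytosine counts.

        Percentages are the SNP-class counts over the analysable cytosine
        set, to one decimal; with zero analysable cytosines they are
        undefined and flagged.
        """
        if n_snps_total is None:
            n_snps_total = n_ct_ga + n_at_cg
        if n_analyzable_cytosines > 0:
            pct_elim = round(100.0 * n_ct_ga / n_analyzable_cytosines, 1)
            pct_add = round(100.0 * n_at_cg / n_analyzable_cytosines, 1)
            undefined = False
        else:
            pct_elim = pct_add = None
            undefined = True
        return cls(
            n_snps_total=n_snps_total, n_ct_ga=n_ct_ga, n_at_cg=n_at_cg,
            n_analyzable_cytosines=n_analyzable_cytosines,
            pct_calls_eliminated=pct_elim,
            n_cytosines_added=n_at_cg, pct_cytosines_added=pct_add,
            undefined=undefined)

    def to_dict(self) -> dict:
        return {
            "n_snps_total": self.n_snps_total,
            "n_ct_ga": self.n_ct_ga,
            "n_at_cg": self.n_at_cg,
            "n_analyzable_cytosines": self.n_analyzable_cytosines,
            "pct_calls_eliminated": self.pct_calls_eliminated,
            "n_cytosines_added": self.n_cytosines_added,
            "pct_cytosines_added": self.pct_cytosines_added,
        }


def correction_report(
    snp_classes: list,
    cytosine_records,
    min_depth: int = 10,
) -> CorrectionReport:
    """Summarise the correction's impact against observed cytosine coverage.

    ``pct_calls_eliminated`` is the C/G->T/A SNP count over the number of
    cytosine records covered to at least ``min_depth`` — the fraction of
    apparently analysable methylation calls that are actually genotype
    artefacts ("up to": not every such SNP necessarily reaches the depth
    cutoff itself).  ``pct_cytosines_added`` is the analogous ratio for
    A/T->C/G SNPs, the relative growth of the analysable set after
    correction.
    """
    records = (cytosine_records.values()
               if isinstance(cytosine_records, dict) else cytosine_records)
    n_analyzable = sum(1 for rec in records if rec.depth >= min_depth)
    n_ct_ga = sum(1 for sc in snp_classes if sc.category is SnpCategory.CT_GA)
    n_at_cg = sum(1 for sc in snp_classes if sc.category is SnpCategory.AT_CG)
    report = CorrectionReport.from_counts(
        n_ct_ga=n_ct_ga, n_at_cg=n_at_cg,
        n_analyzable_cytosines=n_analyzable,
        n_snps_total=len(snp_classes))
    return report
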