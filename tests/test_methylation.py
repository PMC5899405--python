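"""Methylation extraction, sub-genome attribution, conversion, DM testing."""

import math

import pytest

from capmeth import (
    AlignedRead,
    SimulationConfig,
    assign_subgenome_methylation,
    bisulphite_convert,
    build_genome,
    classify_context,
    conversion_efficiency,
    differential_methylation,
    extract_methylation,
    per_subgenome_records,
    simulate_reads,
)
from capmeth.methylation import CytosineRecord
from capmeth.simulate import HomoeologousSnp
from capmeth.io import simulated_to_aligned
from conftest import clean_params
from oracles import fisher_two_sided


def _bsread(name="r1", contig="c", pos=1, seq="ACGT", mapq=40, xg="CT"):
    return AlignedRead(name=name, contig=contig, pos=pos, strand="+",
                       mapq=mapq, sequence=seq, tags={"XG": xg})


class TestContextClassification:
    @pytest.mark.parametrize("seq,i,strand,expected", [
        ("TACGT", 2, "+", "CpG"),
        ("TACAG", 2, "+", "CHG"),
        ("TACAA", 2, "+", "CHH"),
        ("TACCG", 2, "+", "CHG"),   # H may be C
        ("TACCA", 2, "+", "CHH"),
        ("TACGT", 3, "-", "CpG"),
        ("TAGAG", 2, "-", "CHH"),
        ("TCAGT", 3, "-", "CHG"),
        ("TAAGT", 3, "-", "CHH"),
        ("AC", 1, "+", "truncated"),
        ("CA", 0, "+", "truncated"),
        ("GA", 0, "-", "truncated"),
    ])
    def test_examples(self, seq, i, strand, expected):
        assert classify_context(seq, i, strand) == expected

    def test_wrong_base_raises(self):
        with pytest.raises(ValueError):
            classify_context("AAAA", 0, "+")


class TestExtraction:
    def test_top_strand_converted_read_is_unmethylated_cpg(self):
        res = extract_methylation([_bsread(seq="TATGT")], {"c": "TACGT"})
        rec = res.records[("c", 3, "+")]
        assert (rec.meth_count, rec.unmeth_count) == (0, 1)
        assert rec.context == "CpG"

    def test_top_strand_retained_c_is_methylated(self):
        res = extract_methylation([_bsread(seq="TACGT")], {"c": "TACGT"})
        rec = res.records[("c", 3, "+")]
        assert (rec.meth_count, rec.unmeth_count) == (1, 0)

    def test_bottom_strand_reports_reference_gs(self):
        # ref G at pos 4; bottom-strand read shows A -> unmethylated
        res = extract_methylation([_bsread(seq="TACAT", xg="GA")],
                                  {"c": "TACGT"})
        assert ("c", 3, "+") not in res.records  # C is top-strand business
        rec = res.records[("c", 4, "-")]
        assert (rec.meth_count, rec.unmeth_count) == (0, 1)
        assert rec.context == "CpG"

    def test_other_bases_ignored_and_tallied(self):
        res = extract_methylation([_bsread(seq="TAGGT")], {"c": "TACGT"})
        assert ("c", 3, "+") not in res.records
        assert res.n_ignored_bases == 1

    def test_read_without_strand_tag_raises(self):
        read = AlignedRead(name="tagless", contig="c", pos=1, strand="+",
                           mapq=40, sequence="ACGT")
        with pytest.raises(ValueError, match="tagless"):
            extract_methylation([read], {"c": "ACGT"})

    def test_fully_methylated_fully_converted_has_no_unmeth(self):
        model = build_genome(SimulationConfig(
            n_contigs=2, contig_length=500, homoeo_snp_rate=0.0,
            varietal_snp_rate=0.0, meth_cpg=1.0, meth_chg=1.0, meth_chh=1.0,
            seed=41))
        reads = bisulphite_convert(
            simulate_reads(model, clean_params(depth=10.0, seed=42)),
            model, 1.0, seed=43)
        res = extract_methylation(simulated_to_aligned(reads), model.contigs)
        assert res.records
        assert all(r.unmeth_count == 0 for r in res.records.values())

    def test_pooled_cpg_level_recovers_simulated_rate(self):
        # SNP-free genome so reference context matches haplotype context
        model = build_genome(SimulationConfig(
            n_contigs=4, contig_length=2000, homoeo_snp_rate=0.0,
            varietal_snp_rate=0.0, seed=44))
        reads = bisulphite_convert(
            simulate_reads(model, clean_params(depth=30.0, seed=45)),
            model, 1.0, seed=46)
        res = extract_methylation(simulated_to_aligned(reads), model.contigs)
        cpg = [r for r in res.records.values() if r.context == "CpG"]
        m = sum(r.meth_count for r in cpg)
        n = m + sum(r.unmeth_count for r in cpg)
        sd = math.sqrt(0.8 * 0.2 / n)
        assert abs(m / n - 0.8) <= 3 * sd


class TestSubgenomeAssignment:
    SNP = HomoeologousSnp(contig="c", pos=6,
                          allele_map={"G": frozenset("D"),
                                      "C": frozenset("AB")})
    REF = {"c": "TACGTAGT"}

    def test_diagnostic_allele_credits_genome(self):
        read = _bsread(seq="TACGTGGT", mapq=30)
        res = extract_methylation([read], self.REF)
        out = assign_subgenome_methylation(res, [read], [self.SNP])
        assert out.read_genome == {"r1": "D"}
        assert out.records[("c", 3, "+")].per_subgenome == {"D": [1, 0]}

    def test_mapq_twenty_excluded_strictly(self):
        read = _bsread(seq="TACGTGGT", mapq=20)
        res = extract_methylation([read], self.REF)
        out = assign_subgenome_methylation(res, [read], [self.SNP])
        assert out.read_genome == {}
        assert out.n_low_mapq == 1

    def test_multi_genome_alleles_not_attributed_by_default(self):
        # observed C resolves to the {A,B} group: no singleton, no credit
        read = _bsread(seq="TACGTCGT", mapq=30)
        res = extract_methylation([read], self.REF)
        out = assign_subgenome_methylation(res, [read], [self.SNP])
        assert out.read_genome == {}
        assert out.n_no_diagnostic == 1

    def test_converted_diagnostic_base_is_ambiguous_not_wrong(self):
        # top-strand T could be a converted C ({A,B}) or a true T ({A}):
        # the read must not be assigned
        snp = HomoeologousSnp(contig="c", pos=6,
                              allele_map={"T": frozenset("A"),
                                          "C": frozenset("BD")})
        read = _bsread(seq="TACGTTGT", mapq=30)
        res = extract_methylation([read], self.REF)
        out = assign_subgenome_methylation(res, [read], [snp])
        assert out.read_genome == {}

    def test_conflicting_diagnostics_discarded(self):
        snps = [
            HomoeologousSnp(contig="c", pos=1,
                            allele_map={"T": frozenset("A"),
                                        "G": frozenset("B")}),
            HomoeologousSnp(contig="c", pos=6,
                            allele_map={"G": frozenset("D"),
                                        "C": frozenset("AB")}),
        ]
        read = _bsread(seq="TACGTGGT", mapq=30)  # T@1 -> A, G@6 -> D
        res = extract_methylation([read], self.REF)
        out = assign_subgenome_methylation(res, [read], snps)
        assert out.read_genome == {}
        assert out.n_conflicting == 1

    def test_error_free_simulation_assigns_perfectly(self, model,
                                                     bisulphite_alignments):
        res = extract_methylation(bisulphite_alignments, model.contigs)
        out = assign_subgenome_methylation(res, bisulphite_alignments,
                                           model.homoeo_truth)
        assert out.n_assigned > 300
        assert all(r.tags["ZH"] == out.read_genome[r.name]
                   for r in bisulphite_alignments
                   if r.name in out.read_genome)

    def test_subgenome_counts_bounded_by_totals(self, model,
                                                bisulphite_alignments):
        res = extract_methylation(bisulphite_alignments, model.contigs)
        out = assign_subgenome_methylation(res, bisulphite_alignments,
                                           model.homoeo_truth)
        for rec in out.records.values():
            m = sum(v[0] for v in rec.per_subgenome.values())
            u = sum(v[1] for v in rec.per_subgenome.values())
            assert m <= rec.meth_count and u <= rec.unmeth_count


class TestConversionEfficiency:
    def test_ninety_nine_percent_arithmetic(self):
        control = "C" * 100
        reads = ([_bsread(f"t{i}", contig="ctrl", seq="T" * 100)
                  for i in range(99)]
                 + [_bsread("u", contig="ctrl", seq="C" * 100)])
        res = conversion_efficiency(reads, "ctrl", control)
        assert res.efficiency_pct == pytest.approx(99.0)
        assert res.n_observations == 10_000
        assert res.pct_covered == 100.0

    def test_all_converted_is_hundred_percent(self):
        res = conversion_efficiency([_bsread(contig="ctrl", seq="TTTT")],
                                    "ctrl", "CCCC")
        assert res.efficiency_pct == 100.0

    def test_no_observations_undefined(self):
        res = conversion_efficiency([], "ctrl", "CCCC")
        assert res.efficiency_pct is None

    def test_bottom_strand_uses_g_positions(self):
        res = conversion_efficiency([_bsread(contig="ctrl", seq="AAAA",
                                             xg="GA")], "ctrl", "GGGG")
        assert res.efficiency_pct == 100.0
        assert res.n_observations == 4


class TestDifferentialMethylation:
    def _recs(self, counts):
        return {("c", i + 1, "+"): CytosineRecord(
            contig="c", pos=i + 1, strand="+", context="CpG",
            meth_count=m, unmeth_count=u) for i, (m, u) in enumerate(counts)}

    def test_fully_discordant_position_significant(self):
        dm = differential_methylation(self._recs([(5, 0)]),
                                      self._recs([(0, 5)]))
        (r,) = dm.results
        assert r.p_value == pytest.approx(2 / 252)
        assert r.meth_difference == pytest.approx(100.0)
        assert r.significant
        dm50 = differential_methylation(self._recs([(5, 0)]),
                                        self._recs([(0, 5)]), min_diff=50.0)
        assert dm50.results[0].significant

    def test_identical_counts_not_significant(self):
        dm = differential_methylation(self._recs([(3, 3)]),
                                      self._recs([(3, 3)]))
        (r,) = dm.results
        assert r.p_value == pytest.approx(1.0)
        assert not r.significant

    def test_depth_below_five_in_either_group_excluded(self):
        dm = differential_methylation(self._recs([(4, 0)]),
                                      self._recs([(0, 5)]))
        assert dm.n_tested == 0

    def test_min_depth_must_be_positive(self):
        with pytest.raises(ValueError):
            differential_methylation({}, {}, min_depth=0)

    def test_fisher_matches_enumeration_on_small_margins(self):
        for a in range(0, 7):
            for b in range(0, 7 - a):
                for c in range(0, 7):
                    for d in range(0, 7 - c):
                        if a + b == 0 or c + d == 0:
                            continue
                        dm = differential_methylation(
                            self._recs([(a, b)]), self._recs([(c, d)]),
                            min_depth=1)
                        (r,) = dm.results
                        expected = fisher_two_sided(a, b, c, d)
                        assert r.p_value == pytest.approx(expected,
                                                          rel=1e-7, abs=1e-12)

    def test_split_design_per_subgenome_concordance(self, model):
        def sample(seed):
            reads = bisulphite_convert(
                simulate_reads(model, clean_params(seed=seed)),
                model, 0.99, seed=seed + 100)
            al = simulated_to_aligned(reads)
            ex = extract_methylation(al, model.contigs)
            return assign_subgenome_methylation(
                ex, al, model.homoeo_truth).records

        ra, rb = sample(51), sample(52)
        tested = sig = 0
        for g in "ABD":
            dm = differential_methylation(per_subgenome_records(ra, g),
                                          per_subgenome_records(rb, g))
            tested += dm.n_tested
            sig += dm.n_significant
        assert tested > 100
        assert sig / tested <= 0.001
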