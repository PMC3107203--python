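import dataclasses

import numpy as np
import pytest

from corescan import (
    BipartiteMotifModel,
    GeneAnnotation,
    GenomeRecord,
    IUPACConsensus,
    MotifHit,
    assign_downstream_gene,
    check_minus10,
    filter_candidates,
    reverse_complement,
    scan_genome,
)
from corescan.errors import ContractError
from corescan.genome_scan import read_hits_tsv, write_hits_tsv

from _oracles import brute_force_scan


def _random_genome(seed, length, contig="chr1"):
    rng = np.random.default_rng(seed)
    return GenomeRecord(id=contig, seq="".join(rng.choice(list("ACGT"), size=length)))


def _hit_keys(hits):
    return {(h.minus35_start, h.strand, h.mismatches) for h in hits}


class TestScanGenome:
    def test_single_exact_planted_element(self, toy_model):
        model = dataclasses.replace(toy_model, max_mismatches=0)
        genome = GenomeRecord(id="g", seq="T" * 40 + "GTAACCCG" + "T" * 40)
        hits = scan_genome(genome, model, strands="+")
        assert [(h.minus35_start, h.strand, h.mismatches) for h in hits] == [
            (40, "+", 0)
        ]
        assert hits[0].window_seq == "GTAACCCG"

    def test_reverse_complement_planted_element(self, toy_model):
        model = dataclasses.replace(toy_model, max_mismatches=0)
        element = "GTAACCCG"
        genome = GenomeRecord(
            id="g", seq="T" * 40 + reverse_complement(element) + "T" * 40
        )
        hits = scan_genome(genome, model, strands="-")
        # the element's first base (scan orientation) sits at forward coord 47
        assert [(h.minus35_start, h.strand, h.mismatches) for h in hits] == [
            (47, "-", 0)
        ]
        assert hits[0].window_seq == element

    @pytest.mark.parametrize("budget", [0, 1, 2])
    def test_matches_brute_force_oracle_on_random_genome(self, budget):
        # DERIVED: exhaustive window enumeration on both strands
        genome = _random_genome(11, 10_000)
        consensus = IUPACConsensus("GTAACSV")
        model = BipartiteMotifModel(minus35=consensus, max_mismatches=budget)
        hits = scan_genome(genome, model, strands="both")
        assert _hit_keys(hits) == brute_force_scan(genome.seq, "GTAACSV", budget)

    def test_sorted_and_overlapping_hits_reported(self):
        model = BipartiteMotifModel(minus35=IUPACConsensus("AA"), max_mismatches=0)
        genome = GenomeRecord(id="g", seq="AAAA")
        hits = scan_genome(genome, model, strands="+")
        assert [h.minus35_start for h in hits] == [0, 1, 2]

    def test_strand_symmetry(self, toy_model):
        genome = _random_genome(5, 3000)
        mirrored = GenomeRecord(id="chr1", seq=reverse_complement(genome.seq))
        hits = scan_genome(genome, toy_model, strands="both")
        mirrored_hits = scan_genome(mirrored, toy_model, strands="both")
        N = genome.length
        expected = {
            (N - 1 - pos, {"+": "-", "-": "+"}[strand], m)
            for pos, strand, m in _hit_keys(hits)
        }
        assert _hit_keys(mirrored_hits) == expected

    def test_budget_monotonicity(self, toy_model):
        genome = _random_genome(6, 5000)
        keys = {}
        for budget in (0, 1, 2):
            model = dataclasses.replace(toy_model, max_mismatches=budget)
            keys[budget] = {
                (h.minus35_start, h.strand) for h in scan_genome(genome, model)
            }
        assert keys[0] <= keys[1] <= keys[2]

    def test_empty_result_is_valid(self):
        model = BipartiteMotifModel(minus35=IUPACConsensus("GGGGGGGG"), max_mismatches=0)
        genome = GenomeRecord(id="g", seq="A" * 100)
        assert scan_genome(genome, model) == []

    def test_genome_shorter_than_consensus_raises(self, toy_model):
        with pytest.raises(ContractError):
            scan_genome(GenomeRecord(id="g", seq="ACG"), toy_model)

    def test_bad_strand_arg(self, toy_model):
        genome = _random_genome(0, 100)
        with pytest.raises(ContractError):
            scan_genome(genome, toy_model, strands="*")


def _hit(pos, strand, window, contig="g"):
    return MotifHit(
        contig_id=contig,
        minus35_start=pos,
        strand=strand,
        mismatches=0,
        window_seq=window,
    )


class TestCheckMinus10:
    def test_spacer_17(self, toy_model):
        seq = "GTAACCCG" + "A" * 17 + "G" + "A" * 30
        genome = GenomeRecord(id="g", seq=seq)
        hit = check_minus10(_hit(0, "+", "GTAACCCG"), genome, toy_model)
        assert hit.spacer_len == 17
        assert hit.minus10_pos == 7 + 17 + 1

    def test_anchor_beyond_range_is_absent(self, toy_model):
        seq = "GTAACCCG" + "A" * 19 + "G" + "A" * 30
        genome = GenomeRecord(id="g", seq=seq)
        hit = check_minus10(_hit(0, "+", "GTAACCCG"), genome, toy_model)
        assert hit.spacer_len is None and hit.minus10_pos is None

    def test_smallest_qualifying_spacer_wins(self, toy_model):
        # DERIVED: anchors at spacer 16 and 18 -> 16 selected
        seq = "GTAACCCG" + "A" * 16 + "G" + "A" + "G" + "A" * 30
        genome = GenomeRecord(id="g", seq=seq)
        hit = check_minus10(_hit(0, "+", "GTAACCCG"), genome, toy_model)
        assert hit.spacer_len == 16

    def test_minus_strand_anchor(self, toy_model):
        cassette = "GTAACCCG" + "A" * 17 + "G"
        seq = "T" * 20 + reverse_complement(cassette) + "T" * 20
        genome = GenomeRecord(id="g", seq=seq)
        (raw,) = [
            h for h in scan_genome(genome, toy_model, "-") if h.mismatches == 0
        ]
        hit = check_minus10(raw, genome, toy_model)
        assert hit.spacer_len == 17
        assert genome.seq[hit.minus10_pos] == "C"  # G on the - strand

    def test_off_end_linear_vs_circular(self, toy_model):
        seq = "GTAACCCG" + "A" * 10  # anchor region runs past the contig end
        hit = _hit(0, "+", "GTAACCCG")
        linear = GenomeRecord(id="g", seq=seq)
        assert check_minus10(hit, linear, toy_model).spacer_len is None
        # circular wrap: anchor at (7 + 17 + 1) % 18 = 7 is 'G' at position 7
        circular = GenomeRecord(id="g", seq=seq, circular=True)
        wrapped = check_minus10(hit, circular, toy_model)
        assert wrapped.spacer_len == 17
        assert wrapped.minus10_pos == 7


class TestAssignDownstreamGene:
    def test_same_strand_gene_assigned(self):
        gene = GeneAnnotation("g", 100, 250, "+", "gene1")
        hit = _hit(42, "+", "GTAACCCG")  # last base at 49, distance 51
        cand = assign_downstream_gene(hit, [gene], max_distance=300)
        assert cand.downstream_gene == "gene1"
        assert cand.distance_to_start == 51
        assert cand.strand_ok

    def test_no_start_in_range_is_unassigned(self):
        gene = GeneAnnotation("g", 0, 500, "+", "gene1")
        hit = _hit(100, "+", "GTAACCCG")  # inside the gene; start is behind
        cand = assign_downstream_gene(hit, [gene], max_distance=300)
        assert cand.downstream_gene is None
        assert not cand.final

    def test_equidistant_tie_breaks_to_smaller_coordinate(self):
        # DERIVED: both starts are 100 nt downstream; the - strand gene's
        # translational start (99+... ) and + start coincide at coordinate 150
        genes = [
            GeneAnnotation("g", 150, 300, "+", "right"),
            GeneAnnotation("g", 20, 151, "-", "left"),
        ]
        hit = _hit(43, "+", "GTAACCCG")  # last base 50
        cand = assign_downstream_gene(hit, genes, max_distance=300)
        # '-' gene translational start = 150 == '+' gene start; smaller
        # coordinate ties, then annotation order decides
        assert cand.downstream_gene == "right"
        assert cand.distance_to_start == 100

    def test_minus_hit_looks_leftwards(self):
        gene = GeneAnnotation("g", 100, 200, "-", "gene1")
        hit = _hit(260, "-", "GTAACCCG")  # element last base at 253
        cand = assign_downstream_gene(hit, [gene], max_distance=300)
        assert cand.downstream_gene == "gene1"
        assert cand.distance_to_start == 253 - 199
        assert cand.strand_ok

    def test_opposite_strand_gene_flagged(self):
        gene = GeneAnnotation("g", 100, 200, "-", "gene1")
        hit = _hit(42, "+", "GTAACCCG")
        cand = assign_downstream_gene(hit, [gene], max_distance=300)
        assert cand.downstream_gene == "gene1"
        assert not cand.strand_ok
        assert not cand.final


class TestFilterCandidates:
    def _setup(self, toy_model):
        cassette = "GTAACCCG" + "C" * 17 + "G" + "A" * 20
        seq = "T" * 50 + cassette + "T" * 30
        genome = GenomeRecord(id="g", seq=seq)
        gene = GeneAnnotation("g", 50 + len(cassette), 50 + len(cassette) + 30, "+", "target")
        return genome, gene

    def test_passing_candidate_is_final(self, toy_model):
        genome, gene = self._setup(toy_model)
        hits = [h for h in scan_genome(genome, toy_model, "+") if h.mismatches == 0]
        report = filter_candidates(hits, toy_model, [gene], 300, genome=genome)
        final = report.final_candidates()
        assert len(final) == 1
        assert final[0].downstream_gene == "target"

    def test_opposite_strand_fails(self, toy_model):
        genome, gene = self._setup(toy_model)
        gene = GeneAnnotation(gene.contig_id, gene.start, gene.end, "-", "target")
        hits = [h for h in scan_genome(genome, toy_model, "+") if h.mismatches == 0]
        report = filter_candidates(hits, toy_model, [gene], 300, genome=genome)
        (cand,) = [c for c in report.candidates if c.downstream_gene == "target"]
        assert not cand.strand_ok and not cand.final

    def test_invariant_violation_fails(self, toy_model):
        genome, gene = self._setup(toy_model)
        # mutate invariant position 1 (T) of the planted element
        seq = genome.seq[:51] + "A" + genome.seq[52:]
        genome = GenomeRecord(id="g", seq=seq)
        hits = [h for h in scan_genome(genome, toy_model, "+") if h.minus35_start == 50]
        assert hits and hits[0].mismatches == 1
        report = filter_candidates(hits, toy_model, [gene], 300, genome=genome)
        cand = report.candidates[0]
        assert not cand.invariants_ok and not cand.final
        assert cand.strand_ok  # flags computed regardless of failure order

    def test_cascade_counts_monotonic(self, toy_model):
        rng = np.random.default_rng(9)
        genome = GenomeRecord(
            id="g", seq="".join(rng.choice(list("ACGT"), size=8000))
        )
        genes = [
            GeneAnnotation("g", s, s + 200, "+-"[i % 2], f"g{i}")
            for i, s in enumerate(range(500, 7500, 1000))
        ]
        hits = scan_genome(genome, toy_model)
        report = filter_candidates(hits, toy_model, genes, 300, genome=genome)
        c = report.counts
        assert c["raw"] >= c["oriented"] >= c["invariants"] >= c["final"]
        assert c["raw"] == len(hits)
        assert c["final"] == len(report.final_candidates())


def test_hits_tsv_round_trip(tmp_path, toy_model):
    genome = _random_genome(3, 2000)
    hits = [
        check_minus10(h, genome, toy_model) for h in scan_genome(genome, toy_model)
    ]
    path = tmp_path / "hits.tsv"
    write_hits_tsv(hits, path)
    assert read_hits_tsv(path) == hits
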