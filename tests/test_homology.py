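import random

import pytest
from hypothesis import given, settings, strategies as st

from phyletic.homology import (FilterPolicy, HomologyError, HomologyHit,
                               MockAlignmentBackend, QueryGene, TableBackend,
                               filter_hits, presence_matrix, read_hit_table,
                               write_hit_table)
from phyletic.taxonomy import GenomeRecord, Lineage

LIN = Lineage("s", "g", "f")


def record(acc):
    return GenomeRecord(acc, LIN)


def hit(gene="q1", genome="A", ident=50.0, cov=80.0, e=1e-10, bits=100.0):
    return HomologyHit(gene, genome, f"{genome}|p", ident, cov, e, bits)


class TestMockBackend:
    def test_identical_sequence_scores_full_identity_and_coverage(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        backend = MockAlignmentBackend(proteomes={"A": {"p1": seq}})
        hits = backend.search([QueryGene("q1", seq)], [record("A")])
        assert len(hits) == 1
        assert hits[0].percent_identity == pytest.approx(100.0)
        assert hits[0].query_coverage == pytest.approx(100.0)

    def test_unrelated_sequence_below_floor_yields_no_hit(self):
        backend = MockAlignmentBackend(
            proteomes={"A": {"p1": "WWWWWWWWHHHHHHHHCCCCCCCC" * 3}},
            min_report_identity=50.0,
        )
        hits = backend.search([QueryGene("q1", "MKTAYIAKQRGISLVK" * 4)],
                              [record("A")])
        assert hits == []

    def test_half_length_subject_halves_coverage(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQV"
        backend = MockAlignmentBackend(proteomes={"A": {"frag": seq[: len(seq) // 2]}})
        hits = backend.search([QueryGene("q1", seq)], [record("A")])
        assert len(hits) == 1
        assert hits[0].query_coverage == pytest.approx(50.0, abs=5.0)

    def test_mutated_copy_identity_tracks_substitution_load(self):
        rng = random.Random(0)
        seq = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(100))
        mutated = list(seq)
        for pos in rng.sample(range(100), 20):
            mutated[pos] = "W" if seq[pos] != "W" else "Y"
        backend = MockAlignmentBackend(proteomes={"A": {"m": "".join(mutated)}})
        hits = backend.search([QueryGene("q1", seq)], [record("A")])
        assert hits[0].percent_identity == pytest.approx(80.0, abs=1.0)


class TestTableBackend:
    def test_fixture_rows_pass_through_in_order(self, tmp_path):
        genes = [QueryGene("q1", "MKT" * 10), QueryGene("q2", "MAV" * 10)]
        hits = [hit("q1", "A", 90), hit("q1", "B", 70), hit("q2", "A", 40)]
        path = tmp_path / "hits.tsv"
        write_hit_table(hits, genes, path)
        backend = TableBackend(path)
        out = backend.search(genes, [record("A"), record("B")])
        assert [(h.gene_id, h.subject_genome) for h in out] == \
               [("q1", "A"), ("q1", "B"), ("q2", "A")]
        assert out[0].percent_identity == pytest.approx(90.0)

    def test_restricts_to_requested_genes_and_genomes(self, tmp_path):
        genes = [QueryGene("q1", "MKT" * 10)]
        path = tmp_path / "hits.tsv"
        write_hit_table([hit("q1", "A"), hit("q1", "C"), hit("q9", "A")],
                        genes + [QueryGene("q9", "MML" * 5)], path)
        out = TableBackend(path).search(genes, [record("A")])
        assert len(out) == 1 and out[0].subject_genome == "A"

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("q1\tA|p\t90\n")
        with pytest.raises(HomologyError, match="line 1"):
            read_hit_table(path)


class TestFilterHits:
    policy = FilterPolicy()

    def test_species_rank_keeps_qualifying_hit(self):
        assert filter_hits([hit(ident=65, cov=80)], "species", self.policy)

    def test_low_coverage_dropped_regardless_of_identity(self):
        assert filter_hits([hit(ident=65, cov=60)], "species", self.policy) == []

    def test_identity_cutoff_relaxes_with_rank(self):
        h = [hit(ident=30, cov=90)]
        assert filter_hits(h, "genus", self.policy) == []
        assert filter_hits(h, "family", self.policy) == h

    def test_cutoffs_are_inclusive(self):
        h = [hit(ident=60.0, cov=70.0)]
        assert filter_hits(h, "species", self.policy) == h

    def test_unknown_rank_rejected(self):
        with pytest.raises(HomologyError, match="order"):
            filter_hits([], "order", self.policy)

    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)), max_size=30))
    @settings(deadline=None)
    def test_filter_is_idempotent_and_monotone_in_thresholds(self, stats):
        hits = [hit(ident=i, cov=c) for i, c in stats]
        kept = filter_hits(hits, "genus", self.policy)
        assert filter_hits(kept, "genus", self.policy) == kept
        stricter = FilterPolicy(min_query_coverage=85.0,
                                identity_cutoff_by_rank={"species": 70.0,
                                                         "genus": 60.0,
                                                         "family": 35.0})
        assert set(map(id, filter_hits(hits, "genus", stricter))) <= set(map(id, kept))


class TestPresenceMatrix:
    genes = [QueryGene(f"q{i}", "MKT" * 10) for i in range(3)]
    genomes = [record(a) for a in "ABCD"]

    def test_multiple_hits_to_one_genome_collapse_to_one_cell(self):
        hits = [HomologyHit("q0", "A", "A|p1", 90, 90, 0, 1),
                HomologyHit("q0", "A", "A|p2", 80, 90, 0, 1)]
        pm = presence_matrix(hits, self.genes, self.genomes)
        assert pm.data.loc["q0"].sum() == 1
        assert bool(pm.data.loc["q0", "A"])

    def test_no_hits_gives_all_false_of_correct_shape(self):
        pm = presence_matrix([], self.genes, self.genomes)
        assert pm.data.shape == (3, 4)
        assert not pm.data.to_numpy().any()

    def test_constructed_pattern_is_reproduced(self):
        hits = [hit("q0", "A"), hit("q0", "C"), hit("q1", "D"), hit("q2", "B")]
        pm = presence_matrix(hits, self.genes, self.genomes)
        assert pm.data.loc["q0"].tolist() == [True, False, True, False]
        assert pm.data.loc["q1"].tolist() == [False, False, False, True]
        assert pm.data.loc["q2"].tolist() == [False, True, False, False]

    def test_hit_outside_set_signals_mismatch(self):
        with pytest.raises(HomologyError, match="outside"):
            presence_matrix([hit("q0", "Z")], self.genes, self.genomes)

    def test_raising_cutoffs_never_adds_presence(self):
        rng = random.Random(1)
        hits = [hit(f"q{rng.randrange(3)}", rng.choice("ABCD"),
                    rng.uniform(0, 100), rng.uniform(0, 100))
                for _ in range(60)]
        base = FilterPolicy()
        loose = presence_matrix(filter_hits(hits, "family", base),
                                self.genes, self.genomes).data
        strict_policy = FilterPolicy(min_query_coverage=90.0,
                                     identity_cutoff_by_rank={"species": 80.0,
                                                              "genus": 60.0,
                                                              "family": 40.0})
        strict = presence_matrix(filter_hits(hits, "family", strict_policy),
                                 self.genes, self.genomes).data
        assert ((~loose) & strict).sum().sum() == 0


class TestBlastBackend:
    def test_verbatim_copy_recovered_by_real_blastp(self, tmp_path):
        """Any backend must find a query copied verbatim into a subject
        proteome at >= 99.9 % identity and >= 99 % coverage."""
        from phyletic.homology import BlastBackend

        seq = ("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKAL"
               "PDAQFEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKALRPDEDRLSPLHSVYVDQWDWERVM")
        fasta = tmp_path / "A.faa"
        fasta.write_text(f">p1\n{seq}\n>p2\nMSTNPKPQRKTKRNTNRRPQDVKFPGG\n")
        rec = GenomeRecord("A", LIN, proteome_ref=str(fasta))
        hits = BlastBackend().search([QueryGene("q1", seq)], [rec])
        best = max(hits, key=lambda h: h.bit_score)
        assert best.subject_genome == "A"
        assert best.percent_identity >= 99.9
        assert best.query_coverage >= 99.0
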