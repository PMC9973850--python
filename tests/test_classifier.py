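import itertools

import pytest
from hypothesis import given, settings, strategies as st

from phyletic.classifier import (ClassificationThresholds, ClassifierError,
                                 PdtProfile, classify_gene, classify_genome,
                                 classifications_to_frame, compute_pdt)
from phyletic.homology import QueryGene, presence_matrix
from phyletic.taxonomy import compile_genome_sets, load_taxonomy_index

from _oracles import literal_rule_classifier
from conftest import taxonomy_frame


def profile(s=None, g1=None, g2=None, f1=None, f2=None):
    return PdtProfile(gene_id="g", pdt_species=s, pdt_genus_t1=g1,
                      pdt_genus_t2=g2, pdt_family_t1=f1, pdt_family_t2=f2)


class TestComputePdt:
    @pytest.mark.parametrize("present,size,expected", [
        (3, 10, 30.0), (0, 7, 0.0), (7, 7, 100.0), (1, 3, 100.0 / 3.0),
    ])
    def test_percentage_of_harbouring_genomes(self, present, size, expected):
        row = [True] * present + [False] * (size - present)
        assert compute_pdt(row, size) == pytest.approx(expected)

    def test_empty_set_is_undefined_not_zero(self):
        assert compute_pdt([], 0) is None


class TestClassifyGene:
    @pytest.mark.parametrize("prof,label,decided_at", [
        # sporadic in the species: recent transfer, other ranks irrelevant
        (profile(s=10, g1=100, g2=100, f1=100, f2=100), "alien_recent", "species"),
        # saturated species, sporadic in genus-minus-species: ancestral to species
        (profile(s=90, g1=50, g2=5, f1=50, f2=50), "alien_ancestral_species", "genus/T2"),
        # saturated species+genus, sporadic in family-minus-genus
        (profile(s=90, g2=60, f2=10), "alien_ancestral_genus", "family/T2"),
        # broad in the family exclusion set: native
        (profile(s=90, g2=60, f2=60), "native", "family/T2"),
        # intermediate species band, broad genus: native
        (profile(s=50, g1=80, f1=10), "native", "genus/T1"),
        # middle band at every rank: ambiguous
        (profile(s=50, g1=50, f1=35), "ambiguous", "family/T1"),
        # boundary: 30.0 is not < 30, falls to the genus T1 test
        (profile(s=30.0, g1=20, f1=100), "alien_recent", "genus/T1"),
        # boundary: exactly 80 stays in the intermediate band
        (profile(s=80.0, g1=70.0, f1=40.0), "ambiguous", "family/T1"),
    ])
    def test_decision_tree_cases(self, prof, label, decided_at):
        result = classify_gene(prof)
        assert result.label == label
        assert result.decided_at == decided_at

    def test_undefined_species_starts_at_genus_and_is_flagged(self):
        result = classify_gene(profile(s=None, g1=10, f1=10))
        assert result.label == "alien_recent"
        assert result.decided_at == "genus/T1"
        assert result.species_skipped is True

    def test_no_defined_pdt_anywhere_raises(self):
        with pytest.raises(ClassifierError, match="empty universe"):
            classify_gene(profile())

    def test_exhaustive_grid_matches_literal_rule_transcription(self):
        grid = [0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0]
        for s, g1, g2, f1, f2 in itertools.product(grid, repeat=5):
            got = classify_gene(profile(s, g1, g2, f1, f2)).label
            want = literal_rule_classifier(s, g1, g2, f1, f2)
            assert got == want, (s, g1, g2, f1, f2)

    pdt = st.floats(min_value=0, max_value=100, allow_nan=False)

    @given(pdt, pdt, pdt, pdt, pdt)
    @settings(deadline=None, max_examples=300)
    def test_total_and_dominated_by_sporadic_species(self, s, g1, g2, f1, f2):
        result = classify_gene(profile(s, g1, g2, f1, f2))
        assert result.label in {"alien_recent", "alien_ancestral_species",
                                "alien_ancestral_genus", "native", "ambiguous"}
        if s < 30.0:
            assert result.label == "alien_recent"

    @given(pdt, pdt, pdt, pdt, pdt, st.floats(-5, 5))
    @settings(deadline=None, max_examples=300)
    def test_labels_stable_when_pdts_clear_the_shifted_bands(self, s, g1, g2,
                                                             f1, f2, delta):
        """Shifting every threshold by |delta| <= 5 can only relabel profiles
        whose deciding PDT sits within 5 points of a cutoff."""
        base = ClassificationThresholds()
        cuts = (base.alien_pdt, base.species_well_distributed,
                base.genus_native, base.family_native)
        pdts = (s, g1, g2, f1, f2)
        if any(abs(p - c) <= 5.0 for p in pdts for c in cuts):
            return
        shifted = ClassificationThresholds(
            alien_pdt=base.alien_pdt + delta,
            species_well_distributed=base.species_well_distributed + delta,
            genus_native=base.genus_native + delta,
            family_native=base.family_native + delta,
        )
        assert classify_gene(profile(*pdts)).label == \
            classify_gene(profile(*pdts), shifted).label


class TestClassifyGenome:
    def setup_method(self):
        self.index = load_taxonomy_index(taxonomy_frame(3, 4, 6))
        self.sets = compile_genome_sets("QRY", self.index, min_t2_size=2)
        self.genes = [QueryGene(f"q{i}", "MKTAY" * 6) for i in range(3)]

    def matrices(self, hits_by_rank):
        out = {}
        for rank in ("species", "genus", "family"):
            rank_set = getattr(self.sets, f"{rank}_t1")
            out[rank] = presence_matrix(hits_by_rank.get(rank, []),
                                        self.genes, rank_set, rank)
        return out

    def test_all_present_everywhere_is_native(self):
        from phyletic.homology import HomologyHit
        hits = {
            rank: [HomologyHit(g.gene_id, acc, f"{acc}|p", 99, 99, 0, 1)
                   for g in self.genes
                   for acc in self.sets.accessions(f"{rank}_t1")]
            for rank in ("species", "genus", "family")
        }
        results = classify_genome(self.genes, self.sets, self.matrices(hits))
        assert [r.label for r in results] == ["native"] * 3

    def test_all_absent_everywhere_is_recent_alien(self):
        results = classify_genome(self.genes, self.sets, self.matrices({}))
        assert [r.label for r in results] == ["alien_recent"] * 3
        assert [r.gene_id for r in results] == ["q0", "q1", "q2"]

    def test_missing_gene_in_matrix_is_named(self):
        matrices = self.matrices({})
        for m in matrices.values():
            m.data.drop(index="q1", inplace=True)
        with pytest.raises(ClassifierError, match="q1"):
            classify_genome(self.genes, self.sets, matrices)

    def test_report_frame_carries_evidence_trail(self):
        results = classify_genome(self.genes, self.sets, self.matrices({}))
        frame = classifications_to_frame(results)
        assert len(frame) == 3
        assert frame.loc[0, "pdt_species"] == 0.0
        assert {"label", "decided_at", "pdt_family_t2",
                "genus_fallback"} <= set(frame.columns)


class TestThresholdValidation:
    def test_defaults_are_the_published_cutoffs(self):
        t = ClassificationThresholds()
        assert (t.alien_pdt, t.species_well_distributed,
                t.genus_native, t.family_native) == (30.0, 80.0, 70.0, 40.0)

    def test_inverted_ordering_rejected(self):
        with pytest.raises(ClassifierError):
            ClassificationThresholds(alien_pdt=90.0)
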