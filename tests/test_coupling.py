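"""Intra/near-motif classification, the disorder-matched sampler, and the
permutation test."""

import numpy as np
import pytest
from scipy.stats import fisher_exact

from motifswitch.core import DisorderProfile, ProteinRecord
from motifswitch.coupling import (
    UnsampleableMotif,
    candidate_intervals,
    classify_phospho_position,
    flank_residue_enrichment,
    near_site_cross_reference,
    permutation_test,
    sample_random_motif,
)

from .conftest import make_motif, make_site
from .oracles import fisher_two_sided


class TestClassify:
    @pytest.mark.parametrize(
        "position,expected",
        [
            (105, "intra"),
            (100, "intra"),
            (110, "intra"),
            (130, "near"),   # distance 20, boundary inclusive
            (80, "near"),
            (131, "outside"),
            (79, "outside"),
        ],
    )
    def test_window_boundaries(self, position, expected):
        motif = make_motif("P1", 100, 110)
        site = make_site("P1", position, "S")
        assert classify_phospho_position(motif, site, window=20) == expected

    def test_mismatched_accessions_raise(self):
        with pytest.raises(ValueError):
            classify_phospho_position(
                make_motif("P1", 1, 5), make_site("P2", 3, "S")
            )


class TestSampler:
    def test_single_sty_forces_interval(self):
        # poly-A with one S at position 50 outside the motif: any random
        # interval must cover that S
        seq = "A" * 49 + "S" + "A" * 50
        protein = ProteinRecord("P", seq)
        prof = DisorderProfile("P", tuple([0.5] * 100))
        motif = make_motif("P", 1, 5)
        rng = np.random.default_rng(0)
        for _ in range(10):
            s, e = sample_random_motif(protein, motif, prof, 1.0, rng)
            assert s <= 50 <= e

    def test_disorder_matching_tolerance(self):
        scores = tuple([0.9] * 50 + [0.3] * 50)
        protein = ProteinRecord("P", "ASYTA" * 20)
        prof = DisorderProfile("P", scores)
        motif = make_motif("P", 10, 19)  # mean disorder 0.9
        rng = np.random.default_rng(1)
        for _ in range(20):
            s, e = sample_random_motif(protein, motif, prof, 0.1, rng)
            assert 0.8 <= np.mean(scores[s - 1 : e]) <= 1.0

    def test_fixed_seed_is_deterministic(self):
        protein = ProteinRecord("P", "ASYTA" * 20)
        prof = DisorderProfile("P", tuple([0.5] * 100))
        motif = make_motif("P", 10, 19)
        a = sample_random_motif(protein, motif, prof, 0.1, np.random.default_rng(7))
        b = sample_random_motif(protein, motif, prof, 0.1, np.random.default_rng(7))
        assert a == b

    def test_unsampleable_motif_signalled(self):
        protein = ProteinRecord("P", "A" * 30)  # no S/T/Y anywhere
        prof = DisorderProfile("P", tuple([0.5] * 30))
        with pytest.raises(UnsampleableMotif):
            sample_random_motif(protein, make_motif("P", 1, 5), prof, 1.0,
                                np.random.default_rng(0))

    def test_candidates_never_overlap_motif(self):
        protein = ProteinRecord("P", "ASYTA" * 20)
        prof = DisorderProfile("P", tuple([0.5] * 100))
        motif = make_motif("P", 40, 49)
        starts = candidate_intervals(protein, motif, prof, 1.0)
        for s in starts:
            assert s + 9 < 40 or s > 49


class TestPermutationTest:
    def _setup(self):
        rng = np.random.default_rng(3)
        proteome, disorder, motifs = {}, {}, []
        for i in range(8):
            acc = f"P{i}"
            seq = "".join(rng.choice(list("ASTYLGV"), size=200))
            proteome[acc] = ProteinRecord(acc, seq)
            disorder[acc] = DisorderProfile(acc, tuple([0.5] * 200))
            motifs.append(make_motif(acc, 50, 61))
        return proteome, disorder, motifs

    def test_observed_zero_gives_p_one(self):
        proteome, disorder, motifs = self._setup()
        res = permutation_test(motifs, [], proteome, disorder, n_rand=50, seed=1)
        assert res.p_intra == 1.0 and res.p_near == 1.0

    def test_add_one_smoothing_floor(self):
        # sites on every S/T/Y inside the motifs only: observed count is
        # maximal, most replicates fall below, p approaches 1/(n+1)
        proteome, disorder, motifs = self._setup()
        sites = []
        for m in motifs:
            seq = proteome[m.accession].sequence
            for pos in range(m.start, m.end + 1):
                if seq[pos - 1] in "STY":
                    sites.append(make_site(m.accession, pos, seq[pos - 1]))
        res = permutation_test(motifs, sites, proteome, disorder, n_rand=200, seed=1)
        assert res.n_intra == len(motifs)
        assert res.p_intra >= 1 / 201
        assert res.p_intra > 0

    def test_empty_motif_set_raises(self):
        proteome, disorder, _ = self._setup()
        with pytest.raises(ValueError, match="empty test"):
            permutation_test([], [], proteome, disorder)

    def test_order_invariance_with_fixed_seed(self):
        proteome, disorder, motifs = self._setup()
        sites = [make_site(m.accession, m.start + 2, proteome[m.accession].sequence[m.start + 1])
                 for m in motifs
                 if proteome[m.accession].sequence[m.start + 1] in "STY"]
        a = permutation_test(motifs, sites, proteome, disorder, n_rand=300, seed=9)
        b = permutation_test(motifs[::-1], sites, proteome, disorder, n_rand=300, seed=9)
        assert (a.p_intra, a.p_near) == (b.p_intra, b.p_near)

    def test_strict_exceed_mode_is_less_conservative(self):
        proteome, disorder, motifs = self._setup()
        sites = [make_site("P0", 55, proteome["P0"].sequence[54])] if proteome[
            "P0"
        ].sequence[54] in "STY" else []
        res_inc = permutation_test(motifs, sites, proteome, disorder,
                                   n_rand=100, seed=2, inclusive=True)
        res_exc = permutation_test(motifs, sites, proteome, disorder,
                                   n_rand=100, seed=2, inclusive=False)
        assert res_exc.p_intra <= res_inc.p_intra
        assert res_exc.p_near <= res_inc.p_near

    def test_bonferroni_correction(self):
        proteome, disorder, motifs = self._setup()
        res = permutation_test(motifs, [], proteome, disorder, n_rand=20,
                               seed=0, n_tests=8)
        assert res.p_intra_corrected == 1.0
        assert res.p_intra_corrected == min(1.0, res.p_intra * 8)


class TestFlankEnrichment:
    def _inputs(self):
        rng = np.random.default_rng(5)
        proteome = {}
        motifs = []
        for i in range(6):
            acc = f"P{i}"
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=150))
            proteome[acc] = ProteinRecord(acc, seq)
            motifs.append(make_motif(acc, 60, 70))
        return proteome, motifs

    def test_symmetric_table_gives_p_one(self):
        assert fisher_two_sided([[1, 1], [1, 1]]) == 1.0

    def test_fisher_matches_tail_sum_oracle(self):
        table = [[3, 97], [27, 973]]
        p_scipy = fisher_exact(table)[1]
        assert p_scipy == pytest.approx(fisher_two_sided(table), abs=1e-12)

    def test_report_fields_consistent(self):
        proteome, motifs = self._inputs()
        rep = flank_residue_enrichment(motifs, proteome, [], residue="Y", window=20)
        assert 0 <= rep["flank_fraction"] <= 1
        assert 0 <= rep["proteome_fraction"] <= 1
        assert 0 < rep["p"] <= 1
        assert rep["table"][0][0] + rep["table"][0][1] == rep["flank_residues"]

    def test_bad_residue_raises(self):
        proteome, motifs = self._inputs()
        with pytest.raises(ValueError):
            flank_residue_enrichment(motifs, proteome, [], residue="B")

    def test_zero_flank_raises(self):
        proteome = {"P0": ProteinRecord("P0", "AAAA")}
        motifs = [make_motif("P0", 1, 4)]
        with pytest.raises(ValueError, match="zero residues"):
            flank_residue_enrichment(motifs, proteome, [], residue="Y", window=1)


class TestNearSiteCrossReference:
    def test_annotations(self):
        motifs = [
            make_motif("P1", 100, 110, domain="D_plain"),
            make_motif("P1", 125, 135, domain="D_kinase"),
        ]
        sites = [make_site("P1", 130, "S"), make_site("P1", 90, "S")]
        out = near_site_cross_reference(motifs, sites, kinase_proteins={"D_kinase"})
        by_pos = {(r["position"], r["near_motif"][0]): r for r in out}
        # site 130 is near motif 100-110 and inside motif 125-135
        rec = by_pos[(130, 100)]
        assert rec["inside_other_motif"] and rec["partner_is_kinase"]
        # site 90 is near motif 100-110 but inside nothing
        rec = by_pos[(90, 100)]
        assert not rec["inside_other_motif"] and not rec["partner_is_kinase"]
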