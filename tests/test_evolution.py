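"""Pairwise alignment mapping, origin assignment and trace
classification."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from scipy.stats import chi2

from motifswitch.core import ProteinRecord
from motifswitch.evolution import (
    DEFAULT_LINEAGE,
    EvoTrace,
    SpeciesLineage,
    TraceUnit,
    align_pair,
    build_alignments,
    classify_trace,
    classify_traces,
    expected_trace_fractions,
    motif_origin,
    phospho_origin,
    trace_null_test,
)
from motifswitch.patterns import load_pattern_library

from .oracles import chi2_statistic, gotoh_global_score

LINEAGE = SpeciesLineage()
PATTERNS = load_pattern_library()


class TestAlignPair:
    def test_identical_sequences_identity_mapping(self):
        rec = ProteinRecord("H", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
        aln = align_pair(rec, ProteinRecord("O", rec.sequence, "MOUSE"))
        assert aln.mapping == {i: i for i in range(1, len(rec) + 1)}

    def test_internal_deletion_shifts_mapping(self):
        human = ProteinRecord("H", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
        deleted = human.sequence[:10] + human.sequence[15:]  # drop 11..15
        aln = align_pair(human, ProteinRecord("O", deleted, "MOUSE"))
        for pos in range(1, 11):
            assert aln.mapping[pos] == pos
        for pos in range(16, len(human) + 1):
            assert aln.mapping[pos] == pos - 5
        for pos in range(11, 16):
            assert pos not in aln.mapping

    def test_score_matches_dp_oracle_on_random_pairs(self):
        blosum = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(12)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(50):
            n1, n2 = rng.integers(3, 13, size=2)
            s1 = "".join(rng.choice(letters, size=n1))
            s2 = "".join(rng.choice(letters, size=n2))
            aln = align_pair(ProteinRecord("A", s1), ProteinRecord("B", s2, "MOUSE"))
            oracle = gotoh_global_score(s1, s2, blosum, 11.0, 1.0)
            assert aln.score == pytest.approx(oracle)

    def test_mapping_strictly_increasing(self):
        rng = np.random.default_rng(3)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        s1 = "".join(rng.choice(letters, size=40))
        s2 = "".join(rng.choice(letters, size=35))
        aln = align_pair(ProteinRecord("A", s1), ProteinRecord("B", s2, "MOUSE"))
        items = sorted(aln.mapping.items())
        for (h1, o1), (h2, o2) in zip(items, items[1:]):
            assert h1 < h2 and o1 < o2


def _unit(motif_seq="RPAK", phospho_res="Y", present_motif=(), present_phospho=()):
    """Unit on a fixed scaffold; orthologs listed in present_* carry the
    element, all other taxa carry a scrambled/neutral replacement."""
    flank1 = "MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLV"
    flank2 = "GAHQNIVDCLESWMTAGFNQHDLVACISEWGTMNQAHDLV"
    gap = "GSAHQL"

    def build(taxon, has_motif, has_phos):
        mot = motif_seq if has_motif else "GAGA"[: len(motif_seq)].ljust(len(motif_seq), "G")
        ph = phospho_res if has_phos else "A"
        return ProteinRecord(f"U_{taxon}", flank1 + mot + gap + ph + flank2, taxon)

    human = build("HUMAN", True, True)
    orthologs = {
        t: build(t, t in present_motif, t in present_phospho)
        for t in DEFAULT_LINEAGE
        if t != "HUMAN"
    }
    return TraceUnit("u1", human, 41, 44, "SH3", 51, orthologs)


class TestOrigins:
    def test_phospho_origin_most_distant_sty(self):
        # tyrosine conserved only chimp..rat -> RATUS
        unit = _unit(present_motif=DEFAULT_LINEAGE,
                     present_phospho=("CHIMP", "MOUSE", "RATUS"))
        alns = build_alignments(unit)
        assert phospho_origin(unit, alns, LINEAGE) == "RATUS"

    def test_phospho_potential_counts_any_sty(self):
        # serine instead of the human tyrosine still counts through fly
        unit = _unit(present_motif=DEFAULT_LINEAGE, present_phospho=())
        drome = unit.orthologs["DROME"]
        seq = drome.sequence[:50] + "S" + drome.sequence[51:]
        unit.orthologs["DROME"] = ProteinRecord(drome.accession, seq, "DROME")
        alns = build_alignments(unit)
        assert phospho_origin(unit, alns, LINEAGE) == "DROME"

    def test_phospho_origin_defaults_to_human(self):
        unit = _unit(present_motif=DEFAULT_LINEAGE, present_phospho=())
        alns = build_alignments(unit)
        assert phospho_origin(unit, alns, LINEAGE) == "HUMAN"

    def test_motif_origin_through_worm(self):
        keep = [t for t in DEFAULT_LINEAGE if LINEAGE.rank(t) <= LINEAGE.rank("CAEEL")]
        unit = _unit(present_motif=keep, present_phospho=("CHIMP",))
        alns = build_alignments(unit)
        assert motif_origin(unit, alns, LINEAGE, PATTERNS) == "CAEEL"

    @pytest.mark.parametrize("displacement,expected", [(20, "MOUSE"), (21, "HUMAN")])
    def test_slack_boundary(self, displacement, expected):
        # motif displaced in the ortholog by exactly the slack is counted,
        # one residue further is not
        unit = _unit(present_motif=(), present_phospho=())
        mouse = unit.orthologs["MOUSE"]
        seq = list(mouse.sequence)
        start0 = 40 + displacement  # human motif start (0-based) + shift
        seq[start0 : start0 + 4] = "RPAK"
        unit.orthologs["MOUSE"] = ProteinRecord(mouse.accession, "".join(seq), "MOUSE")
        alns = build_alignments(unit)
        assert motif_origin(unit, alns, LINEAGE, PATTERNS) == expected

    def test_unit_without_pattern_hit_rejected(self):
        unit = _unit(motif_seq="GAGA")
        alns = build_alignments(unit)
        with pytest.raises(ValueError, match="matches no"):
            motif_origin(unit, alns, LINEAGE, PATTERNS)

    def test_origin_monotone_under_ortholog_deletion(self):
        keep = [t for t in DEFAULT_LINEAGE if LINEAGE.rank(t) <= LINEAGE.rank("DROME")]
        unit = _unit(present_motif=keep, present_phospho=keep)
        alns = build_alignments(unit)
        full_m = LINEAGE.rank(motif_origin(unit, alns, LINEAGE, PATTERNS))
        full_p = LINEAGE.rank(phospho_origin(unit, alns, LINEAGE))
        reduced = {t: a for t, a in alns.items() if t != "DROME"}
        assert LINEAGE.rank(motif_origin(unit, reduced, LINEAGE, PATTERNS)) <= full_m
        assert LINEAGE.rank(phospho_origin(unit, reduced, LINEAGE)) <= full_p


class TestClassification:
    @pytest.mark.parametrize(
        "motif_taxon,phospho_taxon,expected",
        [
            ("CAEEL", "RATUS", "motif-first"),
            ("XENTR", "DROME", "phospho-first"),
            ("XENTR", "XENTR", "co-appearance"),
        ],
    )
    def test_rank_comparison(self, motif_taxon, phospho_taxon, expected):
        assert classify_trace(motif_taxon, phospho_taxon, LINEAGE) == expected

    def test_classify_traces_builds_origin_matrix(self):
        keep_m = [t for t in DEFAULT_LINEAGE if LINEAGE.rank(t) <= LINEAGE.rank("CAEEL")]
        keep_p = [t for t in DEFAULT_LINEAGE if LINEAGE.rank(t) <= LINEAGE.rank("RATUS")]
        unit = _unit(present_motif=keep_m, present_phospho=keep_p)
        traces, counts, matrix = classify_traces([unit])
        assert counts["motif-first"] == 1
        assert matrix.at["CAEEL", "RATUS"] == 1
        assert matrix.to_numpy().sum() == 1


class TestNullModel:
    def _traces(self, spec):
        return [
            EvoTrace(f"u{i}", m, p, classify_trace(m, p, LINEAGE))
            for i, (m, p) in enumerate(spec)
        ]

    def test_single_taxon_concentration(self):
        traces = self._traces([("XENTR", "XENTR")] * 5)
        frac = expected_trace_fractions(traces, LINEAGE)
        assert frac["co-appearance"] == pytest.approx(1.0)
        assert frac["motif-first"] == frac["phospho-first"] == 0.0

    def test_uniform_two_taxa_product(self):
        traces = self._traces(
            [("HUMAN", "HUMAN"), ("HUMAN", "MOUSE"), ("MOUSE", "HUMAN"), ("MOUSE", "MOUSE")]
        )
        frac = expected_trace_fractions(traces, LINEAGE)
        assert frac["co-appearance"] == pytest.approx(0.5)
        assert frac["motif-first"] == pytest.approx(0.25)
        assert frac["phospho-first"] == pytest.approx(0.25)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        taxa = list(DEFAULT_LINEAGE)
        traces = self._traces(
            [(taxa[rng.integers(16)], taxa[rng.integers(16)]) for _ in range(30)]
        )
        frac = expected_trace_fractions(traces, LINEAGE)
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-12)

    def test_chi2_matches_oracle_on_toy(self):
        rng = np.random.default_rng(4)
        taxa = ["HUMAN", "MOUSE", "XENTR", "DROME"]
        traces = self._traces(
            [(taxa[rng.integers(4)], taxa[rng.integers(4)]) for _ in range(20)]
        )
        rep = trace_null_test(traces, LINEAGE)
        observed = [rep["observed"][c] for c in ("co-appearance", "motif-first", "phospho-first")]
        expected = [rep["expected"][c] for c in ("co-appearance", "motif-first", "phospho-first")]
        stat = chi2_statistic(observed, expected)
        assert rep["chi2"] == pytest.approx(stat)
        assert rep["p"] == pytest.approx(float(chi2.sf(stat, 2)))

    def test_bonferroni_and_low_count_warning(self):
        traces = self._traces([("HUMAN", "MOUSE")] * 3)
        rep = trace_null_test(traces, LINEAGE, n_tests=4)
        assert rep["p_corrected"] == min(1.0, rep["p"] * 4)
        assert rep["low_expected_warning"]
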