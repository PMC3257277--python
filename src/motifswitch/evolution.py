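"""Evolutionary tracing of interaction-regulation units.

An interaction-regulation unit couples a domain-binding motif with a
phosphorylatable residue inside or within 20 residues of it. For each
unit, the human protein is globally aligned to each ortholog along a fixed
ordered eukaryotic lineage, and an origin taxon is assigned to each
component:

* phospho origin — the taxon most distant from human whose aligned
  position carries Ser, Thr or Tyr (phospho-potential, not necessarily the
  identical residue);
* motif origin — the taxon most distant from human in which any pattern of
  the motif's family (subtypes unified) matches within +/-20 residues of
  the position aligned with the human motif start.

Comparing origin ranks classifies the unit's evolutionary trace as
co-appearance, motif-first or phospho-first. A marginal-product null
(expected class fractions from the product of the per-taxon motif- and
phospho-origin frequencies) provides a chi-square test of deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import chi2

from .core import ProteinRecord
from .patterns import SequencePattern, find_matches, patterns_for_family

#: ordered lineage from human outward; index = distance class from human.
DEFAULT_LINEAGE = (
    "HUMAN", "CHIMP", "MOUSE", "RATUS", "BOVIN", "CHICK", "XENTR", "DANRE",
    "CIONA", "DROME", "ANOGA", "CAEEL", "YEAST", "DICDI", "ARATH", "PLAFA",
)

DEFAULT_SLACK = 20

TRACE_CLASSES = ("co-appearance", "motif-first", "phospho-first")


class SpeciesLineage:
    """Ordered species list; rank 0 is human, higher rank = more distant."""

    def __init__(self, taxa: Sequence[str] = DEFAULT_LINEAGE):
        if taxa[0] != "HUMAN":
            raise ValueError("lineage must start at HUMAN")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxa in lineage")
        self.taxa = tuple(taxa)
        self._rank = {t: i for i, t in enumerate(taxa)}

    def rank(self, taxon: str) -> int:
        return self._rank[taxon]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._rank

    def __iter__(self):
        return iter(self.taxa)


@dataclass
class OrthologAlignment:
    """Pairwise global alignment between a human protein and an ortholog,
    reduced to a strictly increasing partial position mapping (1-based;
    gapped human positions are undefined)."""

    human: ProteinRecord
    ortholog: ProteinRecord
    taxon: str
    mapping: dict  # human position -> ortholog position
    score: float


def make_aligner(
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_pair(
    human: ProteinRecord,
    ortholog: ProteinRecord,
    aligner: Align.PairwiseAligner | None = None,
) -> OrthologAlignment:
    """Global affine-gap alignment; the position mapping comes from the
    aligned columns of the optimal alignment."""
    if not human.sequence or not ortholog.sequence:
        raise ValueError("empty sequence")
    if aligner is None:
        aligner = make_aligner()
    alignment = aligner.align(human.sequence, ortholog.sequence)[0]
    mapping = {}
    for (hs, he), (os_, oe) in zip(*alignment.aligned):
        for k in range(he - hs):
            mapping[hs + k + 1] = os_ + k + 1
    return OrthologAlignment(
        human, ortholog, ortholog.organism, mapping, float(alignment.score)
    )


@dataclass
class TraceUnit:
    """One interaction-regulation unit to be traced."""

    unit_id: str
    human: ProteinRecord
    motif_start: int
    motif_end: int
    family: str
    phospho_position: int
    orthologs: dict = field(default_factory=dict)  # taxon -> ProteinRecord


@dataclass(frozen=True)
class EvoTrace:
    unit_id: str
    motif_origin: str
    phospho_origin: str
    trace_class: str


def build_alignments(
    unit: TraceUnit, aligner: Align.PairwiseAligner | None = None
) -> dict[str, OrthologAlignment]:
    if aligner is None:
        aligner = make_aligner()
    return {
        taxon: align_pair(unit.human, rec, aligner)
        for taxon, rec in unit.orthologs.items()
    }


def phospho_origin(
    unit: TraceUnit,
    alignments: Mapping[str, OrthologAlignment],
    lineage: SpeciesLineage,
) -> str:
    """Most distant taxon whose aligned position keeps phospho-potential
    (S/T/Y at the position aligned with the human phosphosite); human if
    no ortholog qualifies."""
    pos = unit.phospho_position
    best = "HUMAN"
    for taxon, aln in alignments.items():
        if taxon not in lineage:
            continue
        opos = aln.mapping.get(pos)
        if opos is None:
            continue
        if aln.ortholog.sequence[opos - 1] in "STY":
            if lineage.rank(taxon) > lineage.rank(best):
                best = taxon
    return best


def motif_origin(
    unit: TraceUnit,
    alignments: Mapping[str, OrthologAlignment],
    lineage: SpeciesLineage,
    patterns: Sequence[SequencePattern],
    slack: int = DEFAULT_SLACK,
) -> str:
    """Most distant taxon in which any pattern of the motif's family
    matches within ``slack`` residues of the aligned human motif start.

    The human motif must itself match at least one library pattern
    (units failing this are excluded upstream). Motif location in
    orthologs is known to drift, hence the slack window.
    """
    fam_patterns = patterns_for_family(patterns, unit.family)
    human_hit = any(
        any(
            unit.motif_start - 1 <= s and s + len(p) - 1 <= unit.motif_end - 1
            for s in find_matches(unit.human.sequence, p.positions)
        )
        for p in fam_patterns
    )
    if not human_hit:
        raise ValueError(
            f"{unit.unit_id}: human motif matches no {unit.family} pattern"
        )
    best = "HUMAN"
    for taxon, aln in alignments.items():
        if taxon not in lineage:
            continue
        # anchor: aligned position of the motif start (fall back to the
        # first aligned position within the motif)
        anchor = None
        for hp in range(unit.motif_start, unit.motif_end + 1):
            anchor = aln.mapping.get(hp)
            if anchor is not None:
                break
        if anchor is None:
            continue
        oseq = aln.ortholog.sequence
        lo0 = anchor - 1 - slack  # 0-based window of allowed match starts
        hi0 = anchor - 1 + slack
        found = False
        for p in fam_patterns:
            for s in find_matches(oseq, p.positions):
                if lo0 <= s <= hi0:
                    found = True
                    break
            if found:
                break
        if found and lineage.rank(taxon) > lineage.rank(best):
            best = taxon
    return best


def classify_trace(motif_taxon: str, phospho_taxon: str, lineage: SpeciesLineage) -> str:
    rm, rp = lineage.rank(motif_taxon), lineage.rank(phospho_taxon)
    if rm == rp:
        return "co-appearance"
    return "motif-first" if rm > rp else "phospho-first"


def classify_traces(
    units: Iterable[TraceUnit],
    lineage: SpeciesLineage | None = None,
    patterns: Sequence[SequencePattern] | None = None,
    slack: int = DEFAULT_SLACK,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[list[EvoTrace], dict, pd.DataFrame]:
    """Assign origins and trace classes to every unit.

    Returns the per-unit traces, the 3-class counts, and the origin
    matrix (motif-origin rows x phospho-origin columns over the lineage).
    """
    if lineage is None:
        lineage = SpeciesLineage()
    if patterns is None:
        from .patterns import load_pattern_library

        patterns = load_pattern_library()
    if aligner is None:
        aligner = make_aligner()
    traces = []
    matrix = pd.DataFrame(
        0, index=list(lineage.taxa), columns=list(lineage.taxa), dtype=int
    )
    for unit in units:
        alignments = build_alignments(unit, aligner)
        m_org = motif_origin(unit, alignments, lineage, patterns, slack)
        p_org = phospho_origin(unit, alignments, lineage)
        traces.append(
            EvoTrace(unit.unit_id, m_org, p_org, classify_trace(m_org, p_org, lineage))
        )
        matrix.at[m_org, p_org] += 1
    counts = {c: sum(t.trace_class == c for t in traces) for c in TRACE_CLASSES}
    return traces, counts, matrix


def expected_trace_fractions(
    traces: Iterable[EvoTrace], lineage: SpeciesLineage
) -> dict:
    """Marginal-product null: expected fractions of the three trace
    classes from the product of the per-taxon motif- and phospho-origin
    frequencies. The three fractions sum to 1."""
    traces = list(traces)
    n = len(traces)
    if n == 0:
        raise ValueError("no traces")
    f_m = np.zeros(len(lineage.taxa))
    f_p = np.zeros(len(lineage.taxa))
    for t in traces:
        f_m[lineage.rank(t.motif_origin)] += 1
        f_p[lineage.rank(t.phospho_origin)] += 1
    f_m /= n
    f_p /= n
    joint = np.outer(f_m, f_p)  # joint[rm, rp]
    co = float(np.trace(joint))
    motif_first = float(np.tril(joint, -1).sum())  # rm > rp
    phospho_first = float(np.triu(joint, 1).sum())
    return {
        "co-appearance": co,
        "motif-first": motif_first,
        "phospho-first": phospho_first,
    }


def trace_null_test(
    traces: Iterable[EvoTrace],
    lineage: SpeciesLineage | None = None,
    n_tests: int = 1,
) -> dict:
    """Chi-square (2 df) test of the observed 3-class counts against the
    marginal-product expectation, Bonferroni-corrected over families."""
    if lineage is None:
        lineage = SpeciesLineage()
    traces = list(traces)
    expected_frac = expected_trace_fractions(traces, lineage)
    n = len(traces)
    observed = np.array(
        [sum(t.trace_class == c for t in traces) for c in TRACE_CLASSES], dtype=float
    )
    expected = np.array([expected_frac[c] * n for c in TRACE_CLASSES])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            expected > 0,
            (observed - expected) ** 2 / np.where(expected > 0, expected, 1.0),
            np.where(observed > 0, np.inf, 0.0),
        )
    stat = float(terms.sum())
    p = float(chi2.sf(stat, df=2))
    return {
        "observed": dict(zip(TRACE_CLASSES, observed.astype(int))),
        "expected": dict(zip(TRACE_CLASSES, expected)),
        "expected_fractions": expected_frac,
        "chi2": stat,
        "p": p,
        "p_corrected": min(1.0, p * n_tests),
        "low_expected_warning": bool((expected < 5).any()),
        "n": n,
    }
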