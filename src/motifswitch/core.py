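"""Domain types and database unification rules.

Coordinates are 1-based inclusive throughout the package, matching the
convention of the curated phosphosite and domain-motif interaction
databases this package consumes.

Evidence tiers: ``LTP`` (low-throughput, e.g. phospho-specific antibodies
or mutagenesis; highly reliable) and ``HTP`` (high-throughput surveys,
mostly mass spectrometry or arrays). On conflict LTP wins.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
PHOSPHO_RESIDUES = ("S", "T", "Y")
TIERS = ("LTP", "HTP")
DOMAIN_FAMILIES = ("SH2", "SH3", "PDZ", "WW")

#: default cap on motif length: longer stretches are judged not to have been
#: narrowed down to the binding element and are discarded.
MAX_MOTIF_LENGTH = 30

#: default overlap fraction (of the shorter motif) above which two records
#: of the same domain-motif pair are treated as duplicates.
DEDUP_OVERLAP_FRACTION = 0.8


def stronger_tier(a: str, b: str) -> str:
    """LTP (low-throughput, targeted evidence) beats HTP."""
    return "LTP" if "LTP" in (a, b) else "HTP"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence; positions are 1-based."""

    accession: str
    sequence: str
    organism: str = "HUMAN"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET - {"X"}
        if bad:
            raise ValueError(
                f"{self.accession}: non-amino-acid letters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"{self.accession}: position {position} out of range")
        return self.sequence[position - 1]


@dataclass(frozen=True)
class PhosphoSite:
    """One experimentally supported phosphorylated residue."""

    accession: str
    position: int
    residue: str
    tier: str
    sources: frozenset = frozenset()

    def __post_init__(self):
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(f"phospho residue must be S/T/Y, got {self.residue!r}")
        if self.tier not in TIERS:
            raise ValueError(f"tier must be LTP or HTP, got {self.tier!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1")


@dataclass(frozen=True)
class MotifInstance:
    """A documented domain-binding motif interval on a protein.

    ``accession`` is the motif-carrying protein; ``domain_protein`` is the
    interacting partner carrying the domain of family ``family``.
    """

    accession: str
    start: int
    end: int
    family: str
    tier: str
    domain_protein: str
    pattern_hit: str | None = None

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad interval {self.start}-{self.end}")
        if self.tier not in TIERS:
            raise ValueError(f"tier must be LTP or HTP, got {self.tier!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "MotifInstance") -> int:
        """Number of shared residues with another interval."""
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue predicted intrinsic-disorder scores in [0, 1]."""

    accession: str
    scores: tuple

    def __post_init__(self):
        arr = np.asarray(self.scores, dtype=float)
        if arr.size == 0:
            raise ValueError(f"{self.accession}: empty disorder profile")
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError(f"{self.accession}: disorder scores outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.scores, dtype=float)


@dataclass(frozen=True)
class Rejection:
    """A dropped input row, with the reason; collected rather than raised
    so that large merges survive dirty input."""

    reason: str
    row: tuple


def unify_phosphosites(
    records: Iterable[Mapping],
    proteome: Mapping[str, ProteinRecord],
) -> tuple[set[PhosphoSite], list[Rejection]]:
    """Merge raw phosphosite rows into one site per (accession, position).

    Rows whose residue letter disagrees with the proteome sequence, whose
    accession is unknown, or whose position is out of range are dropped and
    reported in the rejects list. Duplicate reports of the same event union
    their sources and take the stronger evidence tier (LTP over HTP).
    The result is independent of input row order.
    """
    merged: dict[tuple[str, int], PhosphoSite] = {}
    rejects: list[Rejection] = []
    for row in records:
        acc = row["accession"]
        pos = int(row["position"])
        res = row["residue"]
        key_row = (acc, pos, res, row["tier"], row.get("source", ""))
        protein = proteome.get(acc)
        if protein is None:
            rejects.append(Rejection("unknown accession", key_row))
            continue
        if not 1 <= pos <= len(protein):
            rejects.append(Rejection("position out of range", key_row))
            continue
        if protein.residue(pos) != res:
            rejects.append(
                Rejection(
                    f"sequence has {protein.residue(pos)} at {pos}, row says {res}",
                    key_row,
                )
            )
            continue
        sources = frozenset(
            s for s in str(row.get("source", "")).split(",") if s
        )
        site = PhosphoSite(acc, pos, res, row["tier"], sources)
        prev = merged.get((acc, pos))
        if prev is not None:
            site = PhosphoSite(
                acc,
                pos,
                res,
                stronger_tier(prev.tier, site.tier),
                prev.sources | site.sources,
            )
        merged[(acc, pos)] = site
    return set(merged.values()), rejects


def _overlap_groups(
    motifs: list[MotifInstance], overlap_fraction: float
) -> list[list[MotifInstance]]:
    """Connected components of the 'overlap > fraction of the shorter
    motif' relation (transitive closure over chained partial overlaps)."""
    n = len(motifs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            shorter = min(motifs[i].length, motifs[j].length)
            if motifs[i].overlap(motifs[j]) > overlap_fraction * shorter:
                parent[find(i)] = find(j)
    groups: dict[int, list[MotifInstance]] = {}
    for i, m in enumerate(motifs):
        groups.setdefault(find(i), []).append(m)
    return list(groups.values())


def filter_and_dedup_motifs(
    records: Iterable[Mapping],
    proteome: Mapping[str, ProteinRecord],
    max_length: int = MAX_MOTIF_LENGTH,
    overlap_fraction: float = DEDUP_OVERLAP_FRACTION,
) -> tuple[set[MotifInstance], list[Rejection]]:
    """Filter raw motif rows and collapse redundant records.

    Motifs longer than ``max_length`` residues are removed. For the same
    (domain protein, motif protein, family) pair, records whose intervals
    overlap in more than ``overlap_fraction`` of the shorter motif's
    residues are collapsed to a single instance: the shorter one (on equal
    length, the one with the smaller start). Chained partial overlaps are
    resolved by transitive closure. Non-overlapping duplicate reports are
    both kept. The kept instance carries the strongest tier in its group.
    """
    rejects: list[Rejection] = []
    candidates: list[MotifInstance] = []
    for row in records:
        acc = row["accession"]
        start, end = int(row["start"]), int(row["end"])
        key_row = (acc, start, end, row["family"], row["tier"], row["domain_protein"])
        protein = proteome.get(acc)
        if protein is None:
            rejects.append(Rejection("unknown accession", key_row))
            continue
        if not 1 <= start <= end <= len(protein):
            rejects.append(Rejection("interval outside protein", key_row))
            continue
        motif = MotifInstance(
            acc, start, end, row["family"], row["tier"], row["domain_protein"],
            row.get("pattern_hit") or None,
        )
        if motif.length > max_length:
            rejects.append(Rejection(f"motif longer than {max_length}", key_row))
            continue
        candidates.append(motif)

    kept: set[MotifInstance] = set()
    by_pair: dict[tuple, list[MotifInstance]] = {}
    for m in candidates:
        by_pair.setdefault((m.domain_protein, m.accession, m.family), []).append(m)
    for group in by_pair.values():
        for component in _overlap_groups(group, overlap_fraction):
            best = min(component, key=lambda m: (m.length, m.start, m.end))
            tier = "LTP" if any(m.tier == "LTP" for m in component) else "HTP"
            if tier != best.tier:
                best = replace(best, tier=tier)
            kept.add(best)
    return kept, rejects
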