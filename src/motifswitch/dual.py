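"""Dual-motif ("double switch") discovery for domains of different families.

A dual motif is a protein segment that simultaneously matches an
SH2-binding pattern and an SH3- or class I WW-binding pattern, overlapped
so that a single phosphorylatable residue switches binding from one domain
family to the other: phosphorylation of the shared tyrosine enables SH2
binding while blocking the partner domain, and dephosphorylation does the
opposite.

Two enumeration schemes are provided. The *strict* scheme only fuses the
SH2 phospho-tyrosine with a partner-pattern position that itself demands a
tyrosine, so the phosphorylated residue is vital to both interactions. The
*permissive* scheme accepts any class-compatible overlap of an SH2 pattern
with a partner pattern, as long as the SH2 phospho-tyrosine lies inside
the merged span.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
from scipy.stats import hypergeom

from .core import PhosphoSite, ProteinRecord
from .patterns import ANY, SequencePattern, matches_at, positions_to_regex


@dataclass(frozen=True)
class DualPattern:
    """Two component patterns fused at a compatible offset.

    ``offset`` is the shift of ``right`` relative to ``left`` (right
    position j sits on merged-sequence position ``offset + j``).
    ``switch_index`` is the 0-based index, in merged coordinates, of the
    phospho-residue that performs the switch (the SH2 tyrosine).
    """

    merged: SequencePattern
    left: SequencePattern
    right: SequencePattern
    offset: int
    switch_index: int
    scheme: str = "strict"

    def __len__(self) -> int:
        return len(self.merged)


@dataclass(frozen=True)
class DualHit:
    """A proteome match of a merged dual pattern whose switch position
    carries a documented phosphosite."""

    accession: str
    start: int  # 1-based
    dual: DualPattern
    switch_position: int  # 1-based absolute residue index
    phospho_tier: str


def merge_patterns(
    left: SequencePattern, right: SequencePattern, offset: int
) -> DualPattern | None:
    """Fuse two patterns at a given offset by per-position class
    intersection.

    Returns ``None`` when the patterns are incompatible (some overlapping
    intersection is empty). Raises if the offset gives no overlapping
    position at all. Positions covered by only one component keep that
    component's class.
    """
    n_overlap = min(len(left), offset + len(right)) - max(0, offset)
    if n_overlap < 1:
        raise ValueError(f"offset {offset} gives no overlap")
    start = min(0, offset)
    end = max(len(left), offset + len(right))
    merged = []
    for m in range(start, end):
        l_cls = left.positions[m] if 0 <= m < len(left) else None
        in_left = 0 <= m < len(left)
        j = m - offset
        in_right = 0 <= j < len(right)
        r_cls = right.positions[j] if in_right else None
        if in_left and in_right:
            if l_cls is ANY:
                cls = r_cls
            elif r_cls is ANY:
                cls = l_cls
            else:
                cls = l_cls & r_cls
                if not cls:
                    return None
        elif in_left:
            cls = l_cls
        else:
            cls = r_cls
        merged.append(cls)

    # the switching residue: the SH2 component's phospho-tyrosine when an
    # SH2 pattern is present, otherwise whichever component declares one.
    switch = None
    components = ((left, 0), (right, offset))
    for pat, shift in components:
        if pat.family.startswith("SH2") and pat.phospho_index is not None:
            switch = shift + pat.phospho_index - start
            break
    else:
        for pat, shift in components:
            if pat.phospho_index is not None:
                switch = shift + pat.phospho_index - start
                break
    merged_pattern = SequencePattern(
        tuple(merged),
        family=f"{left.family}+{right.family}",
        name=f"{left.name}+{right.name}@{offset}",
        phospho_index=switch,
    )
    return DualPattern(merged_pattern, left, right, offset, switch if switch is not None else -1)


def enumerate_dual_patterns(
    sh2_patterns: Iterable[SequencePattern],
    partner_patterns: Iterable[SequencePattern],
    scheme: str = "strict",
) -> list[DualPattern]:
    """All dual patterns from an SH2 library and a partner (SH3 / class I
    WW) library, duplicates (identical merged class lists) collapsed.

    strict: only offsets where the SH2 phospho-tyrosine coincides with a
    partner position whose class is exactly {Y}.
    permissive: all offsets with a non-empty, all-compatible overlap in
    which the SH2 phospho-tyrosine falls inside the merged span.
    """
    sh2_patterns = list(sh2_patterns)
    partner_patterns = list(partner_patterns)
    if not sh2_patterns or not partner_patterns:
        raise ValueError("empty pattern library")
    if scheme not in ("strict", "permissive"):
        raise ValueError(f"unknown scheme {scheme!r}")
    seen: dict[tuple, DualPattern] = {}
    for partner in partner_patterns:
        for sh2 in sh2_patterns:
            if sh2.phospho_index is None:
                continue
            # offset of the SH2 pattern relative to the partner pattern
            for offset in range(-len(sh2) + 1, len(partner)):
                dual = None
                try:
                    dual = merge_patterns(partner, sh2, offset)
                except ValueError:
                    continue
                if dual is None:
                    continue
                y_pos = offset + sh2.phospho_index  # in partner coordinates
                if scheme == "strict":
                    if not (
                        0 <= y_pos < len(partner)
                        and partner.positions[y_pos] == frozenset("Y")
                    ):
                        continue
                else:
                    # SH2 phospho-Y inside the merged span
                    if not 0 <= dual.merged.phospho_index < len(dual.merged):
                        continue
                dual = DualPattern(
                    dual.merged, dual.left, dual.right, dual.offset,
                    dual.switch_index, scheme,
                )
                key = dual.merged.positions
                if key not in seen:
                    seen[key] = dual
    return sorted(seen.values(), key=lambda d: (len(d), d.merged.name))


def scan_dual(
    proteome: Mapping[str, ProteinRecord],
    sites: Iterable[PhosphoSite],
    duals: Iterable[DualPattern],
) -> list[DualHit]:
    """Scan a proteome for dual-pattern matches with a documented
    phosphosite at the switch position.

    Overlapping matches are all reported; results are sorted and identical
    across runs and input orderings.
    """
    site_by_pos = {(s.accession, s.position): s for s in sites}
    hits: list[DualHit] = []
    for dual in duals:
        rx = re.compile("(?=(" + positions_to_regex(dual.merged.positions) + "))")
        for acc in proteome:
            seq = proteome[acc].sequence
            for m in rx.finditer(seq):
                start0 = m.start()
                switch_pos = start0 + dual.switch_index + 1  # 1-based
                site = site_by_pos.get((acc, switch_pos))
                if site is None:
                    continue
                hits.append(
                    DualHit(acc, start0 + 1, dual, switch_pos, site.tier)
                )
    return sorted(
        hits, key=lambda h: (h.accession, h.start, h.switch_position, h.dual.merged.name)
    )


def verify_hit(hit: DualHit, proteome: Mapping[str, ProteinRecord]) -> bool:
    """Cross-check that a hit's segment matches BOTH component patterns at
    their respective offsets (not just the merged pattern)."""
    seq = proteome[hit.accession].sequence
    base = hit.start - 1 + (-min(0, hit.dual.offset))  # merged start -> left start
    left_ok = matches_at(seq, base, hit.dual.left.positions)
    right_ok = matches_at(seq, base + hit.dual.offset, hit.dual.right.positions)
    return left_ok and right_ok


def network_overlap_test(
    ppi_edges: Iterable[tuple[str, str]],
    domain_families: Mapping[str, set],
    dual_hit_proteins: Iterable[str],
    partner_family: str = "SH3",
) -> dict:
    """Over-representation of dual-motif proteins among network proteins
    adjacent to both an SH2-carrier and a partner-domain carrier.

    A = proteins with at least one SH2-carrying neighbour and at least one
    distinct neighbour carrying the partner family; B = dual-hit proteins
    present in the network. The tail probability of |A ∩ B| is
    hypergeometric over the network's protein universe.
    """
    graph = nx.Graph()
    graph.add_edges_from(ppi_edges)
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    partner_root = partner_family.split("-")[0]

    def carries(node: str, family_root: str) -> bool:
        return any(
            f.split("-")[0] == family_root for f in domain_families.get(node, ())
        )

    bridge = set()
    for node in graph.nodes:
        neighbours = list(graph.neighbors(node))
        sh2_n = {n for n in neighbours if carries(n, "SH2")}
        part_n = {n for n in neighbours if carries(n, partner_root)}
        # require two distinct partners (one may carry both families as
        # long as another neighbour supplies the second role)
        if any(s != p for s in sh2_n for p in part_n):
            bridge.add(node)
    hit_set = set(dual_hit_proteins) & set(graph.nodes)
    overlap = len(bridge & hit_set)
    universe = graph.number_of_nodes()
    p = float(hypergeom.sf(overlap - 1, universe, len(bridge), len(hit_set)))
    return {
        "universe": universe,
        "n_bridge": len(bridge),
        "n_dual": len(hit_set),
        "overlap": overlap,
        "p": p,
    }
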