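"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the statistical structure of the real curated
inputs — motifs placed in intrinsically disordered regions, phosphosite
density per S/T/Y residue with an LTP/HTP evidence-tier mix, a tunable
coupling enrichment of phosphosites inside motifs and their flanking
windows, PDZ binding matrices with planted inverse-binding domain couples,
and ortholog families with staged appearance of motif and phosphosite
along the eukaryotic lineage. Every generator is deterministic given
(config, seed), and every output round-trips through the package readers.

Truth files record all planted structure so detector precision/recall can
be scored without re-reading configs.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import io as msio
from .core import DisorderProfile, MotifInstance, PhosphoSite, ProteinRecord
from .evolution import DEFAULT_LINEAGE

#: UniProt-like average amino-acid background frequencies (percent),
#: shipped as a static fixture of typical proteome composition.
AA_BACKGROUND = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38, "Q": 3.93,
    "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96, "L": 9.66, "K": 5.84,
    "M": 2.42, "F": 3.86, "P": 4.70, "S": 6.56, "T": 5.34, "W": 1.08,
    "Y": 2.92, "V": 6.87,
}

FAMILY_WEIGHTS = {"SH3": 0.4, "PDZ": 0.25, "WW": 0.2, "SH2": 0.15}


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators."""

    # proteome
    n_proteins: int = 200
    mean_length: float = 400.0
    min_length: int = 120
    # disorder model: alternating ordered/disordered blocks
    disorder_block_mean: float = 50.0
    disorder_high: float = 0.8
    disorder_low: float = 0.2
    disorder_sd: float = 0.05
    # motifs
    motif_rate: float = 0.4  # expected motifs per protein (Poisson)
    motif_length_mean: float = 12.0
    motif_length_sd: float = 4.0
    motif_length_range: tuple = (5, 25)
    motif_ltp_fraction: float = 0.45
    # phosphosites
    phospho_density: float = 0.03  # per S/T/Y residue
    site_ltp_fraction: float = 0.15
    coupling_enrichment: float = 1.0  # density multiplier in motif + flanks
    window: int = 20
    # dual-motif planting (segment, 0-based phospho offset within segment)
    n_dual_plants: int = 0
    dual_segment: str = "PNPDYEPI"
    dual_phospho_offset: int = 4
    # PDZ matrix
    pdz_n_domains: int = 20
    pdz_n_pairs: int = 12
    pdz_peptide_length: int = 6
    pdz_call_density: float = 0.3  # background probability of a 'B' call
    pdz_n_planted: int = 5
    # ortholog families
    evo_n_units: int = 20
    evo_mutation_rate: float = 0.02
    evo_flank: int = 60
    evo_gap: int = 6  # residues between motif end and phosphosite
    lineage: tuple = DEFAULT_LINEAGE
    # PPI network
    ppi_n_domain_proteins: int = 40
    ppi_edge_density: float = 0.02

    def __post_init__(self):
        for name in (
            "motif_rate", "phospho_density", "site_ltp_fraction",
            "motif_ltp_fraction", "pdz_call_density", "evo_mutation_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.coupling_enrichment < 0:
            raise ValueError("coupling_enrichment must be >= 0")
        if self.pdz_n_planted > self.pdz_n_domains // 2 * self.pdz_n_pairs:
            raise ValueError("planted switch count infeasible for dimensions")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys {sorted(bad)}")
        for key in ("motif_length_range", "lineage"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ProteomeBundle:
    proteome: dict
    motifs: list
    sites: list
    disorder: dict
    dual_truth: list = field(default_factory=list)

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        msio.write_fasta(self.proteome, os.path.join(outdir, "proteome.fasta"))
        msio.write_motif_table(self.motifs, os.path.join(outdir, "motifs.tsv"))
        msio.write_phosphosite_table(self.sites, os.path.join(outdir, "sites.tsv"))
        msio.write_disorder_table(self.disorder, os.path.join(outdir, "disorder.tsv"))
        with open(os.path.join(outdir, "dual_truth.tsv"), "w") as fh:
            fh.write("accession\tstart\tswitch_position\n")
            for acc, start, sw in sorted(self.dual_truth):
                fh.write(f"{acc}\t{start}\t{sw}\n")


def _draw_disorder(rng, length: int, cfg: SimConfig) -> np.ndarray:
    """Alternating ordered/disordered blocks with per-residue noise."""
    scores = np.empty(length)
    pos = 0
    high = bool(rng.integers(2))
    while pos < length:
        block = 1 + rng.geometric(1.0 / cfg.disorder_block_mean)
        level = cfg.disorder_high if high else cfg.disorder_low
        end = min(length, pos + block)
        scores[pos:end] = np.clip(
            rng.normal(level, cfg.disorder_sd, end - pos), 0.0, 1.0
        )
        pos = end
        high = not high
    return scores


def _high_blocks(scores: np.ndarray, threshold: float = 0.5) -> list[tuple[int, int]]:
    """Maximal runs of disorder >= threshold, as 1-based inclusive spans."""
    mask = scores >= threshold
    blocks = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            blocks.append((start + 1, i))
            start = None
    if start is not None:
        blocks.append((start + 1, len(scores)))
    return blocks


def gen_proteome_with_sites(
    cfg: SimConfig, seed: int = 0
) -> ProteomeBundle:
    """Generate a proteome with motifs in disordered blocks and
    phosphosites at ``phospho_density`` per S/T/Y residue, multiplied by
    ``coupling_enrichment`` inside motifs and their flanking windows.

    Raises when motif placement is infeasible (no disordered block
    anywhere can host a motif).
    """
    rng = np.random.default_rng(np.random.SeedSequence(int(seed) % (2**31)))
    letters = np.array(list(AA_BACKGROUND))
    freqs = np.array(list(AA_BACKGROUND.values()))
    freqs = freqs / freqs.sum()

    proteome: dict[str, ProteinRecord] = {}
    disorder: dict[str, DisorderProfile] = {}
    motifs: list[MotifInstance] = []
    dual_truth: list[tuple] = []
    requested_motifs = 0

    lmin, lmax = cfg.motif_length_range
    domain_pool = {
        fam: [f"D_{fam}_{k}" for k in range(1, 6)] for fam in FAMILY_WEIGHTS
    }
    families = list(FAMILY_WEIGHTS)
    fam_p = np.array([FAMILY_WEIGHTS[f] for f in families])
    fam_p = fam_p / fam_p.sum()

    dual_remaining = cfg.n_dual_plants

    for i in range(cfg.n_proteins):
        acc = f"P{i:04d}"
        length = max(cfg.min_length, int(rng.gamma(6.0, cfg.mean_length / 6.0)))
        seq = rng.choice(letters, size=length, p=freqs)
        scores = _draw_disorder(rng, length, cfg)

        # plant a dual-motif segment inside a disordered block
        planted_dual_positions: list[int] = []
        if dual_remaining > 0:
            seg = cfg.dual_segment
            blocks = [
                b for b in _high_blocks(scores) if b[1] - b[0] + 1 >= len(seg)
            ]
            if blocks:
                bs, be = blocks[int(rng.integers(len(blocks)))]
                start = int(rng.integers(bs, be - len(seg) + 2))
                seq[start - 1 : start - 1 + len(seg)] = list(seg)
                sw = start + cfg.dual_phospho_offset
                dual_truth.append((acc, start, sw))
                planted_dual_positions.append(sw)
                dual_remaining -= 1

        sequence = "".join(seq)
        protein = ProteinRecord(acc, sequence)
        proteome[acc] = protein
        disorder[acc] = DisorderProfile(acc, tuple(np.round(scores, 4)))

        # motif placement: uniform over intervals inside disordered blocks
        # that contain at least one S/T/Y
        n_mot = int(rng.poisson(cfg.motif_rate))
        requested_motifs += n_mot
        placed: list[tuple[int, int]] = []
        for _ in range(n_mot):
            mlen = int(np.clip(round(rng.normal(cfg.motif_length_mean, cfg.motif_length_sd)), lmin, lmax))
            blocks = _high_blocks(scores)
            options = []
            for bs, be in blocks:
                for s in range(bs, be - mlen + 2):
                    e = s + mlen - 1
                    if any(not (e < ps or s > pe) for ps, pe in placed):
                        continue
                    if any(c in "STY" for c in sequence[s - 1 : e]):
                        options.append(s)
            if not options:
                continue
            s = int(options[int(rng.integers(len(options)))])
            e = s + mlen - 1
            placed.append((s, e))
            fam = families[int(rng.choice(len(families), p=fam_p))]
            motifs.append(
                MotifInstance(
                    acc, s, e, fam,
                    "LTP" if rng.random() < cfg.motif_ltp_fraction else "HTP",
                    domain_pool[fam][int(rng.integers(len(domain_pool[fam])))],
                )
            )

    if requested_motifs > 0 and not motifs:
        raise RuntimeError(
            "infeasible placement: no disordered block can host a motif"
        )

    # phosphosites: per-S/T/Y Bernoulli, enriched in motifs and flanks
    sites: list[PhosphoSite] = []
    motif_spans: dict[str, list[tuple[int, int]]] = {}
    for m in motifs:
        motif_spans.setdefault(m.accession, []).append((m.start, m.end))
    for acc, protein in proteome.items():
        seq = protein.sequence
        spans = motif_spans.get(acc, [])
        enriched = np.zeros(len(seq), dtype=bool)
        inside = np.zeros(len(seq), dtype=bool)
        for s, e in spans:
            lo = max(1, s - cfg.window)
            hi = min(len(seq), e + cfg.window)
            enriched[lo - 1 : hi] = True
            inside[s - 1 : e] = True
        planted = {
            sw for a, st, sw in dual_truth if a == acc
        }
        for pos0, ch in enumerate(seq):
            pos = pos0 + 1
            if pos in planted:
                sites.append(PhosphoSite(acc, pos, ch, "LTP", frozenset({"planted"})))
                continue
            if ch not in "STY":
                continue
            p = cfg.phospho_density
            if enriched[pos0]:
                p = min(0.95, p * cfg.coupling_enrichment)
            if rng.random() < p:
                tier = "LTP" if rng.random() < cfg.site_ltp_fraction else "HTP"
                sites.append(PhosphoSite(acc, pos, ch, tier, frozenset({"sim"})))

    return ProteomeBundle(proteome, motifs, sites, disorder, dual_truth)


# --------------------------------------------------------------- PDZ

@dataclass
class PDZBundle:
    matrix: "object"  # PDZBindingMatrix
    pairs: list
    planted: list  # (plain, mimic, domain_a, domain_b)

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.matrix.to_tsv(os.path.join(outdir, "pdz_matrix.tsv"))
        with open(os.path.join(outdir, "pdz_truth.tsv"), "w") as fh:
            fh.write("plain\tmimic\tdomain_a\tdomain_b\n")
            for plain, mimic, da, db in self.planted:
                fh.write(f"{plain}\t{mimic}\t{da}\t{db}\n")


def gen_pdz_matrix(cfg: SimConfig, seed: int = 0) -> PDZBundle:
    """PDZ binding matrix with planted inverse-binding domain couples.

    Peptide pairs differ by a single S/T/Y <-> D/E swap in one of the last
    three positions (the other last-three positions are identical, so
    every generated pair satisfies the detector's pairing defaults).
    Planted couples get the double-switch call pattern; all remaining
    calls are 'B' with probability ``pdz_call_density``, else 'N'.
    """
    import pandas as pd

    from .pdz import PDZBindingMatrix, PeptidePair

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 7]))
    if cfg.pdz_n_planted > (cfg.pdz_n_domains // 2) * cfg.pdz_n_pairs:
        raise ValueError("infeasible planting")
    letters = np.array(list("ACFGHILMNQVW"))  # neutral context residues
    swaps = {"S": "D", "T": "E", "Y": "E"}
    pairs: list[PeptidePair] = []
    peptides: list[str] = []
    seen = set()
    while len(pairs) < cfg.pdz_n_pairs:
        core = "".join(rng.choice(letters, size=cfg.pdz_peptide_length))
        swap_pos = int(rng.choice([-1, -2, -3]))
        sty = str(rng.choice(list("STY")))
        k = cfg.pdz_peptide_length + swap_pos
        plain = core[:k] + sty + core[k + 1 :]
        mimic = core[:k] + swaps[sty] + core[k + 1 :]
        if plain in seen or mimic in seen:
            continue
        seen.update((plain, mimic))
        pairs.append(PeptidePair(plain, mimic, swap_pos))
        peptides.extend([plain, mimic])

    domains = [f"PDZ{d:02d}" for d in range(1, cfg.pdz_n_domains + 1)]
    calls = pd.DataFrame("N", index=domains, columns=peptides, dtype=object)
    background = rng.random((len(domains), len(peptides))) < cfg.pdz_call_density
    calls.iloc[:, :] = np.where(background, "B", "N")

    # plant inverse-binding couples on distinct domain couples
    couple_slots = [
        (pairs[k % len(pairs)], 2 * (k // len(pairs)), 2 * (k // len(pairs)) + 1)
        for k in range(cfg.pdz_n_planted)
    ]
    planted = []
    for pair, ia, ib in couple_slots:
        da, db = domains[ia], domains[ib]
        calls.at[da, pair.plain] = "B"
        calls.at[da, pair.mimic] = "N"
        calls.at[db, pair.plain] = "N"
        calls.at[db, pair.mimic] = "B"
        planted.append((pair.plain, pair.mimic, da, db))

    matrix = PDZBindingMatrix(domains, peptides, calls)
    return PDZBundle(matrix, pairs, planted)


# ---------------------------------------------------------- orthologs

#: local alphabet for flanks and scrambled segments: excludes P/R/K/Y so
#: no spurious SH3/WW/SH2 pattern hit can arise outside the planted motif.
SAFE_ALPHABET = "ACDEFGHILMNQSTVW"

#: concrete planted motifs per family (each matches a default library
#: pattern of its family).
PLANT_MOTIFS = {
    "SH3": "RPAK",      # RxxK
    "SH3b": "PAGP",     # PxxP
    "WW": "PPGY",       # class I PPxY
    "SH2": "YANA",      # Grb2 YxNx
}


@dataclass
class OrthologBundle:
    units: list  # TraceUnit
    truth: list  # dicts with unit_id, staged origins, class

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        rows = []
        for unit, info in zip(self.units, self.truth):
            msio.write_ortholog_fasta(
                {"HUMAN": unit.human, **unit.orthologs},
                os.path.join(outdir, f"{unit.unit_id}.fasta"),
            )
            rows.append(info)
        with open(os.path.join(outdir, "units.tsv"), "w") as fh:
            cols = [
                "unit_id", "family", "motif_start", "motif_end",
                "phospho_position", "motif_origin", "phospho_origin",
                "trace_class",
            ]
            fh.write("\t".join(cols) + "\n")
            for info in rows:
                fh.write("\t".join(str(info[c]) for c in cols) + "\n")


def _mutate(rng, seq: list, protected: set, rate: float) -> None:
    if rate <= 0:
        return
    alphabet = SAFE_ALPHABET
    for i in range(len(seq)):
        if i in protected:
            continue
        if rng.random() < rate:
            choices = [c for c in alphabet if c != seq[i]]
            seq[i] = choices[int(rng.integers(len(choices)))]


def gen_ortholog_families(
    cfg: SimConfig,
    seed: int = 0,
    stagings: list[tuple[str, str]] | None = None,
) -> OrthologBundle:
    """Ortholog families with staged appearance of motif and phosphosite.

    Each unit's human sequence carries a concrete family motif and a
    nearby phospho-residue; orthologs at taxa at or nearer than the staged
    origin carry the element, more distant taxa carry a scrambled segment
    (or lose the phospho-potential). Point substitutions outside the unit
    at ``evo_mutation_rate``; no indels, so noise-free stagings are
    recovered exactly.
    """
    from .evolution import SpeciesLineage, TraceUnit, classify_trace

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 11]))
    lineage = SpeciesLineage(cfg.lineage)
    if stagings is None:
        stagings = [
            (
                str(rng.choice(lineage.taxa)),
                str(rng.choice(lineage.taxa)),
            )
            for _ in range(cfg.evo_n_units)
        ]
    for m_org, p_org in stagings:
        if m_org not in lineage or p_org not in lineage:
            raise ValueError(f"staging taxon {m_org}/{p_org} absent from lineage")

    fam_keys = list(PLANT_MOTIFS)
    letters = np.array(list(SAFE_ALPHABET))
    units = []
    truth = []
    for u, (m_org, p_org) in enumerate(stagings):
        fam_key = fam_keys[u % len(fam_keys)]
        family = "WW-classI" if fam_key == "WW" else fam_key.rstrip("b")
        motif = PLANT_MOTIFS[fam_key]
        phospho_res = str(rng.choice(list("STY"))) if fam_key != "SH2" else "Y"
        flank1 = "".join(rng.choice(letters, size=cfg.evo_flank))
        gap = "".join(rng.choice(letters, size=cfg.evo_gap))
        flank2 = "".join(rng.choice(letters, size=cfg.evo_flank))
        if phospho_res == "Y":
            # neutralize the residues after the planted tyrosine so it can
            # never complete an SH2 pattern on its own
            flank2 = "AAA" + flank2[3:]
        motif_start = cfg.evo_flank + 1
        motif_end = motif_start + len(motif) - 1
        phospho_pos = motif_end + cfg.evo_gap + 1

        def build(taxon: str) -> ProteinRecord:
            rank = lineage.rank(taxon)
            has_motif = rank <= lineage.rank(m_org)
            has_phos = rank <= lineage.rank(p_org)
            mot = motif if has_motif else "".join(
                rng.choice(letters, size=len(motif))
            )
            phos = phospho_res if has_phos else "A"
            seq = list(flank1 + mot + gap + phos + flank2)
            protected = set(range(motif_start - 1, motif_end)) | {
                phospho_pos - 1, phospho_pos, phospho_pos + 1, phospho_pos + 2,
            }
            _mutate(rng, seq, protected, cfg.evo_mutation_rate if taxon != "HUMAN" else 0.0)
            return ProteinRecord(f"U{u:03d}_{taxon}", "".join(seq), taxon)

        human = build("HUMAN")
        orthologs = {t: build(t) for t in lineage.taxa if t != "HUMAN"}
        unit = TraceUnit(
            f"unit{u:03d}", human, motif_start, motif_end, family,
            phospho_pos, orthologs,
        )
        units.append(unit)
        truth.append(
            {
                "unit_id": unit.unit_id,
                "family": family,
                "motif_start": motif_start,
                "motif_end": motif_end,
                "phospho_position": phospho_pos,
                "motif_origin": m_org,
                "phospho_origin": p_org,
                "trace_class": classify_trace(m_org, p_org, lineage),
            }
        )
    return OrthologBundle(units, truth)


# ----------------------------------------------------------------- PPI

@dataclass
class PPIBundle:
    edges: list
    families: dict
    kinases: set

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        msio.write_ppi_table(self.edges, os.path.join(outdir, "ppi.tsv"))
        msio.write_domain_flags(
            self.families, self.kinases, os.path.join(outdir, "domains.tsv")
        )


def gen_ppi_network(
    cfg: SimConfig,
    seed: int,
    proteome_accessions: list,
    dual_hit_accessions: list,
    partner_family: str = "SH3",
) -> PPIBundle:
    """Random PPI network over the proteome plus domain-carrier proteins;
    every dual-hit protein is wired to one SH2 carrier and one partner
    carrier so the planted association is recoverable."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 13]))
    carriers = [f"C{k:03d}" for k in range(cfg.ppi_n_domain_proteins)]
    families: dict[str, set] = {acc: set() for acc in proteome_accessions}
    fams = ["SH2", partner_family, "PDZ", "WW"]
    for k, acc in enumerate(carriers):
        families[acc] = {fams[k % len(fams)]}
    kinases = {acc for acc in carriers if rng.random() < 0.2}
    nodes = list(proteome_accessions) + carriers
    edges = set()
    n_edges = int(cfg.ppi_edge_density * len(nodes) * (len(nodes) - 1) / 2)
    while len(edges) < n_edges:
        a, b = rng.choice(len(nodes), size=2, replace=False)
        edges.add(tuple(sorted((nodes[a], nodes[b]))))
    sh2_carriers = [c for c in carriers if "SH2" in families[c]]
    partner_carriers = [c for c in carriers if partner_family in families[c]]
    for acc in dual_hit_accessions:
        edges.add(tuple(sorted((acc, sh2_carriers[int(rng.integers(len(sh2_carriers)))]))))
        edges.add(tuple(sorted((acc, partner_carriers[int(rng.integers(len(partner_carriers)))]))))
    return PPIBundle(sorted(edges), families, kinases)
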