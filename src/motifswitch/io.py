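"""Readers and writers for the package's plain-text formats.

All tables are tab-separated with explicit headers; coordinates are
1-based inclusive. Writers emit deterministic, sorted output so that runs
can be compared by diff.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import DisorderProfile, MotifInstance, PhosphoSite, ProteinRecord

PHOSPHO_COLUMNS = ["accession", "position", "residue", "tier", "source"]
MOTIF_COLUMNS = ["motif_accession", "start", "end", "family", "tier", "domain_accession"]
DISORDER_COLUMNS = ["accession", "position", "score"]


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, ProteinRecord]:
    """Read a proteome FASTA. The record id is the accession; an optional
    description token is taken as the organism label."""
    proteome: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split(maxsplit=1)
        organism = parts[1].strip() if len(parts) > 1 else "HUMAN"
        if rec.id in proteome:
            raise ValueError(f"duplicate accession {rec.id} in {path}")
        proteome[rec.id] = ProteinRecord(rec.id, str(rec.seq).upper(), organism)
    return proteome


def write_fasta(proteome: Mapping[str, ProteinRecord], path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.accession, description=p.organism)
        for _, p in sorted(proteome.items())
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_ortholog_fasta(path) -> dict[str, ProteinRecord]:
    """Read a per-family ortholog FASTA with ``>TAXON|accession`` headers."""
    out: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        taxon, _, acc = rec.id.partition("|")
        out[taxon] = ProteinRecord(acc or rec.id, str(rec.seq).upper(), taxon)
    return out


def write_ortholog_fasta(orthologs: Mapping[str, ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for taxon, rec in orthologs.items():
            fh.write(f">{taxon}|{rec.accession}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ----------------------------------------------------------------- TSVs

def read_phosphosite_table(path) -> list[dict]:
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "source": str})
    missing = set(PHOSPHO_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = ""
    return df.fillna({"source": ""}).to_dict("records")


def write_phosphosite_table(sites: Iterable[PhosphoSite], path) -> None:
    rows = [
        {
            "accession": s.accession,
            "position": s.position,
            "residue": s.residue,
            "tier": s.tier,
            "source": ",".join(sorted(s.sources)),
        }
        for s in sites
    ]
    df = pd.DataFrame(rows, columns=PHOSPHO_COLUMNS)
    df = df.sort_values(["accession", "position"]).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)


def read_motif_table(path) -> list[dict]:
    df = pd.read_csv(path, sep="\t", dtype={"motif_accession": str, "domain_accession": str})
    missing = set(MOTIF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        {
            "accession": r["motif_accession"],
            "start": r["start"],
            "end": r["end"],
            "family": r["family"],
            "tier": r["tier"],
            "domain_protein": r["domain_accession"],
            "pattern_hit": r.get("pattern_hit"),
        }
        for r in df.to_dict("records")
    ]


def write_motif_table(motifs: Iterable[MotifInstance], path) -> None:
    rows = [
        {
            "motif_accession": m.accession,
            "start": m.start,
            "end": m.end,
            "family": m.family,
            "tier": m.tier,
            "domain_accession": m.domain_protein,
        }
        for m in motifs
    ]
    df = pd.DataFrame(rows, columns=MOTIF_COLUMNS)
    df = df.sort_values(MOTIF_COLUMNS).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)


def read_disorder_table(path) -> dict[str, DisorderProfile]:
    """Read a long-format per-residue disorder table (one row per residue,
    positions 1..L contiguous per accession)."""
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    missing = set(DISORDER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    profiles = {}
    for acc, sub in df.groupby("accession"):
        sub = sub.sort_values("position")
        positions = sub["position"].to_numpy()
        if positions[0] != 1 or not (positions[1:] - positions[:-1] == 1).all():
            raise ValueError(f"{path}: non-contiguous positions for {acc}")
        profiles[acc] = DisorderProfile(acc, tuple(sub["score"].astype(float)))
    return profiles


def write_disorder_table(profiles: Mapping[str, DisorderProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(DISORDER_COLUMNS) + "\n")
        for acc in sorted(profiles):
            for i, score in enumerate(profiles[acc].scores, start=1):
                fh.write(f"{acc}\t{i}\t{score:.4f}\n")


def read_ppi_table(path) -> list[tuple[str, str]]:
    """Undirected protein-protein interaction edges (columns a, b)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"a", "b"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns a, b")
    return [tuple(r) for r in df[["a", "b"]].itertuples(index=False)]


def write_ppi_table(edges: Iterable[tuple[str, str]], path) -> None:
    df = pd.DataFrame(sorted(tuple(sorted(e)) for e in edges), columns=["a", "b"])
    df.to_csv(path, sep="\t", index=False)


def read_domain_flags(path) -> tuple[dict[str, set], set]:
    """Per-protein domain-family annotation and kinase flags.

    Columns: accession, families (comma-separated, may be empty),
    is_kinase (0/1). Returns (families-by-accession, kinase accessions).
    """
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "families": str})
    families = {}
    kinases = set()
    for r in df.to_dict("records"):
        fams = str(r.get("families") or "")
        families[r["accession"]] = {f for f in fams.split(",") if f and f != "nan"}
        if int(r.get("is_kinase", 0)):
            kinases.add(r["accession"])
    return families, kinases


def write_domain_flags(families: Mapping[str, set], kinases: set, path) -> None:
    rows = [
        {
            "accession": acc,
            "families": ",".join(sorted(fams)),
            "is_kinase": int(acc in kinases),
        }
        for acc, fams in sorted(families.items())
    ]
    pd.DataFrame(rows, columns=["accession", "families", "is_kinase"]).to_csv(
        path, sep="\t", index=False
    )


def write_rejects(rejects, path) -> None:
    """Structured log of dropped rows; one line per rejection."""
    os.makedirs(os.path.dirname(str(path)) or ".", exist_ok=True)
    with open(path, "w") as fh:
        fh.write("reason\trow\n")
        for rej in rejects:
            fh.write(f"{rej.reason}\t{rej.row}\n")
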