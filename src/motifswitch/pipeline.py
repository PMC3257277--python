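"""End-to-end orchestration: unify -> coupling -> double-switch ->
pdz-switch -> evolution, with manifests, reject logs and a combined
multiple-testing ledger."""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass

import pandas as pd

from . import __version__
from . import io as msio
from .core import DOMAIN_FAMILIES, filter_and_dedup_motifs, unify_phosphosites
from .coupling import permutation_test
from .dual import enumerate_dual_patterns, network_overlap_test, scan_dual
from .evolution import TraceUnit, classify_traces, trace_null_test
from .patterns import load_pattern_library
from .pdz import PDZBindingMatrix, call_switches, find_peptide_pairs, switch_enrichment


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, subcommand: str, inputs: dict, seed: int, config=None) -> None:
    """One manifest per output directory: subcommand, config hash, input
    digests, seed, version, timestamp."""
    os.makedirs(outdir, exist_ok=True)
    cfg_text = json.dumps(config, sort_keys=True, default=str) if config else ""
    manifest = {
        "subcommand": subcommand,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "inputs": {
            name: _digest(path) for name, path in inputs.items() if os.path.exists(str(path))
        },
        "seed": seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def bonferroni_ledger(entries: list[dict], mode: str = "grouped") -> pd.DataFrame:
    """Combined multiple-testing ledger.

    Each entry: {analysis, group, test, p}. grouped: corrected =
    min(1, p * m) with m the number of tests in the entry's group;
    global: m is the total ledger size.
    """
    df = pd.DataFrame(entries, columns=["analysis", "group", "test", "p"])
    if df.empty:
        return df.assign(m=[], p_corrected=[])
    if mode == "global":
        df["m"] = len(df)
    elif mode == "grouped":
        df["m"] = df.groupby(["analysis", "group"])["p"].transform("size")
    else:
        raise ValueError(f"unknown ledger mode {mode!r}")
    df["p_corrected"] = (df["p"] * df["m"]).clip(upper=1.0)
    return df


@dataclass
class FullRunResult:
    outdir: str
    coupling: list
    dual_hits: list
    network: dict | None
    switches: list
    census: dict
    traces: list
    ledger: pd.DataFrame


def run_full_analysis(
    indir: str,
    outdir: str,
    seed: int = 0,
    window: int = 20,
    n_rand: int = 1000,
    scheme: str = "strict",
    ledger_mode: str = "grouped",
    patterns_path=None,
) -> FullRunResult:
    """Run the full analysis on a simulate-generated (or hand-assembled)
    input bundle directory."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        name: os.path.join(indir, fname)
        for name, fname in {
            "proteome": "proteome.fasta",
            "motifs": "motifs.tsv",
            "sites": "sites.tsv",
            "disorder": "disorder.tsv",
            "ppi": "ppi.tsv",
            "domains": "domains.tsv",
            "pdz_matrix": "pdz_matrix.tsv",
        }.items()
    }
    ledger_entries: list[dict] = []

    # ------------------------------------------------ stage: unify
    try:
        proteome = msio.read_fasta(paths["proteome"])
        sites, site_rejects = unify_phosphosites(
            msio.read_phosphosite_table(paths["sites"]), proteome
        )
        motifs, motif_rejects = filter_and_dedup_motifs(
            msio.read_motif_table(paths["motifs"]), proteome
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("core_data", str(exc)) from exc
    msio.write_phosphosite_table(sites, os.path.join(outdir, "sites_unified.tsv"))
    msio.write_motif_table(motifs, os.path.join(outdir, "motifs_unified.tsv"))
    msio.write_rejects(
        site_rejects + motif_rejects, os.path.join(outdir, "rejects.tsv")
    )

    # ---------------------------------------------- stage: coupling
    try:
        disorder = msio.read_disorder_table(paths["disorder"])
    except Exception as exc:  # noqa: BLE001
        raise StageError("coupling_stats", f"disorder input: {exc}") from exc
    coupling_results = []
    try:
        fam_groups = {
            fam: [m for m in motifs if m.family == fam] for fam in DOMAIN_FAMILIES
        }
        testable = {f: ms for f, ms in fam_groups.items() if ms}
        n_tests = 2 * len(testable)  # intra + near per family
        for fam, ms in sorted(testable.items()):
            res = permutation_test(
                ms, sites, proteome, disorder,
                window=window, n_rand=n_rand, seed=seed,
                family=fam, n_tests=n_tests,
            )
            coupling_results.append(res)
            ledger_entries.append(
                {"analysis": "coupling", "group": "permutation",
                 "test": f"{fam}:intra", "p": res.p_intra}
            )
            ledger_entries.append(
                {"analysis": "coupling", "group": "permutation",
                 "test": f"{fam}:near", "p": res.p_near}
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError("coupling_stats", str(exc)) from exc
    pd.DataFrame(
        [
            {
                "family": r.family, "tier": r.phospho_tier,
                "n_motifs": r.n_motifs, "n_intra": r.n_intra,
                "n_near": r.n_near, "window": r.window,
                "p_intra": r.p_intra, "p_near": r.p_near,
                "p_intra_corrected": r.p_intra_corrected,
                "p_near_corrected": r.p_near_corrected,
                "n_randomizations": r.n_randomizations,
                "n_excluded": r.n_excluded,
            }
            for r in coupling_results
        ]
    ).to_csv(os.path.join(outdir, "coupling.tsv"), sep="\t", index=False)

    # ------------------------------------------ stage: double-switch
    try:
        patterns = load_pattern_library(patterns_path)
        sh2 = [p for p in patterns if p.family == "SH2"]
        partners = [
            p for p in patterns if p.family in ("SH3", "WW-classI")
        ]
        duals = enumerate_dual_patterns(sh2, partners, scheme)
        hits = scan_dual(proteome, sites, duals)
        network = None
        if os.path.exists(paths["ppi"]) and os.path.exists(paths["domains"]):
            edges = msio.read_ppi_table(paths["ppi"])
            fam_flags, _kinases = msio.read_domain_flags(paths["domains"])
            network = network_overlap_test(
                edges, fam_flags, sorted({h.accession for h in hits})
            )
            ledger_entries.append(
                {"analysis": "double_switch", "group": "network",
                 "test": "SH2+partner overlap", "p": network["p"]}
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError("double_switch", str(exc)) from exc
    pd.DataFrame(
        [
            {
                "accession": h.accession, "start": h.start,
                "pattern": h.dual.merged.to_text(),
                "switch_position": h.switch_position,
                "phospho_tier": h.phospho_tier,
            }
            for h in hits
        ],
        columns=["accession", "start", "pattern", "switch_position", "phospho_tier"],
    ).to_csv(os.path.join(outdir, "dual_hits.tsv"), sep="\t", index=False)

    # --------------------------------------------- stage: pdz-switch
    switches, census = [], {}
    try:
        if os.path.exists(paths["pdz_matrix"]):
            matrix = PDZBindingMatrix.from_tsv(paths["pdz_matrix"])
            pairs = find_peptide_pairs(matrix.peptides)
            switches, census_counter, _skipped = call_switches(pairs, matrix)
            census = dict(census_counter)
            if census:
                enr = switch_enrichment(census_counter)
                ledger_entries.append(
                    {"analysis": "pdz_switch", "group": "enrichment",
                     "test": "double-switch", "p": enr["p"]}
                )
    except Exception as exc:  # noqa: BLE001
        raise StageError("pdz_switch", str(exc)) from exc
    pd.DataFrame(
        [
            {
                "plain": s.pair.plain, "mimic": s.pair.mimic,
                "swap_position": s.pair.swap_position,
                "pdz_a": s.pdz_a, "pdz_b": s.pdz_b,
            }
            for s in switches
        ],
        columns=["plain", "mimic", "swap_position", "pdz_a", "pdz_b"],
    ).to_csv(os.path.join(outdir, "pdz_switches.tsv"), sep="\t", index=False)

    # ---------------------------------------------- stage: evolution
    traces = []
    try:
        units_path = os.path.join(indir, "orthologs", "units.tsv")
        if os.path.exists(units_path):
            units = load_trace_units(os.path.join(indir, "orthologs"))
            traces, counts, matrix_df = classify_traces(units, patterns=patterns)
            null = trace_null_test(traces, n_tests=1)
            ledger_entries.append(
                {"analysis": "evolution", "group": "trace_null",
                 "test": "3-class chi2", "p": null["p"]}
            )
            matrix_df.to_csv(os.path.join(outdir, "origin_matrix.tsv"), sep="\t")
            pd.DataFrame(
                [
                    {"unit_id": t.unit_id, "motif_origin": t.motif_origin,
                     "phospho_origin": t.phospho_origin, "trace_class": t.trace_class}
                    for t in traces
                ]
            ).to_csv(os.path.join(outdir, "traces.tsv"), sep="\t", index=False)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("evolution_trace", str(exc)) from exc

    ledger = bonferroni_ledger(ledger_entries, ledger_mode)
    ledger.to_csv(os.path.join(outdir, "bonferroni_ledger.tsv"), sep="\t", index=False)

    with open(os.path.join(outdir, "summary.txt"), "w") as fh:
        fh.write("motifswitch full analysis summary\n")
        fh.write("=================================\n")
        fh.write(f"proteins: {len(proteome)}; motifs kept: {len(motifs)}; "
                 f"phosphosites: {len(sites)}\n")
        for r in coupling_results:
            fh.write(
                f"coupling {r.family}: {r.n_intra}/{r.n_motifs} intra "
                f"(p={r.p_intra:.4g}), {r.n_near}/{r.n_motifs} near "
                f"(p={r.p_near:.4g})\n"
            )
        fh.write(f"dual-motif hits ({scheme}): {len(hits)}\n")
        if network:
            fh.write(
                f"network overlap: {network['overlap']}/{network['n_dual']} "
                f"(p={network['p']:.4g})\n"
            )
        fh.write(f"PDZ double switches: {len(switches)} of "
                 f"{sum(census.values())} scenario calls\n")
        if traces:
            for cls in ("co-appearance", "motif-first", "phospho-first"):
                n = sum(t.trace_class == cls for t in traces)
                fh.write(f"evolution {cls}: {n}/{len(traces)}\n")

    write_manifest(outdir, "full", paths, seed,
                   {"window": window, "n_rand": n_rand, "scheme": scheme})
    return FullRunResult(
        outdir, coupling_results, hits, network, switches, census, traces, ledger
    )


def load_trace_units(ortholog_dir: str) -> list[TraceUnit]:
    """Load per-unit ortholog FASTA sets plus the units table."""
    units_df = pd.read_csv(os.path.join(ortholog_dir, "units.tsv"), sep="\t")
    units = []
    for row in units_df.to_dict("records"):
        orthologs = msio.read_ortholog_fasta(
            os.path.join(ortholog_dir, f"{row['unit_id']}.fasta")
        )
        human = orthologs.pop("HUMAN")
        units.append(
            TraceUnit(
                row["unit_id"], human,
                int(row["motif_start"]), int(row["motif_end"]),
                str(row["family"]), int(row["phospho_position"]), orthologs,
            )
        )
    return units
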