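"""Same-family (PDZ) specificity switches from a binding matrix.

PDZ domains bind the extreme C-terminus of their partners, with the last
three residues (positions -1, -2, -3) dominating specificity. Direct
binding data for phosphorylated peptides are rare, so the analysis relies
on the phosphomimetic convention: substituting Asp/Glu for Ser/Thr/Tyr
mimics the phosphorylated state. A *peptide pair* is a couple of highly
similar C-terminal peptides in which exactly one of the last three aligned
positions pairs S/T/Y with D/E ('plain' vs 'pseudo-phosphorylated'); of
the remaining last-three positions one must be identical and one highly
similar under both a PAM30 log-odds threshold and a biophysical
(composition/polarity/volume) distance threshold.

For a pair and two PDZ domains a/b, the four binding calls define one of
10 canonical binding scenarios (16 labeled configurations collapsed under
domain exchange). The *double switch* scenario is the one where domain a
binds only the plain peptide and domain b only the mimic.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy.stats import fisher_exact

PLAIN_RESIDUES = frozenset("STY")
MIMIC_RESIDUES = frozenset("DE")

#: default position weights from the C-terminus (-1, -2, -3); positions
#: further in get DEFAULT_FAR_WEIGHT. The C-terminal residues dominate
#: PDZ-binding specificity.
DEFAULT_WEIGHTS = (4.0, 2.0, 1.0)
DEFAULT_FAR_WEIGHT = 0.5

#: 'highly similar' thresholds: PAM30 log-odds score and biophysical
#: distance on the Grantham-style composition/polarity/volume scale.
DEFAULT_PAM30_MIN = 0.0
DEFAULT_BIOPHYS_MAX = 60.0

# Amino-acid composition (atomic weight ratio of non-C atoms in side
# chain), polarity and volume used by the classic biophysical difference
# formula D = rho * sqrt(alpha*dc^2 + beta*dp^2 + gamma*dv^2).
_PROPERTIES = {
    "S": (1.42, 9.2, 32), "R": (0.65, 10.5, 124), "L": (0.0, 4.9, 111),
    "P": (0.39, 8.0, 32.5), "T": (0.71, 8.6, 61), "A": (0.0, 8.1, 31),
    "V": (0.0, 5.9, 84), "G": (0.74, 9.0, 3), "I": (0.0, 5.2, 111),
    "F": (0.0, 5.2, 132), "Y": (0.20, 6.2, 136), "C": (2.75, 5.5, 55),
    "H": (0.58, 10.4, 96), "Q": (0.89, 10.5, 85), "N": (1.33, 11.6, 56),
    "K": (0.33, 11.3, 119), "D": (1.38, 13.0, 54), "E": (0.92, 12.3, 83),
    "M": (0.0, 5.7, 105), "W": (0.13, 5.4, 170),
}
_ALPHA, _BETA, _GAMMA, _RHO = 1.833, 0.1018, 0.000399, 50.723


def biophysical_distance_matrix() -> dict[tuple[str, str], float]:
    """Pairwise amino-acid distances from composition, polarity and
    volume (identical residues have distance 0)."""
    dist = {}
    for a, (ca, pa, va) in _PROPERTIES.items():
        for b, (cb, pb, vb) in _PROPERTIES.items():
            d = _RHO * np.sqrt(
                _ALPHA * (ca - cb) ** 2
                + _BETA * (pa - pb) ** 2
                + _GAMMA * (va - vb) ** 2
            )
            dist[(a, b)] = float(d)
    return dist

_BIOPHYS = biophysical_distance_matrix()
_PAM30 = substitution_matrices.load("PAM30")


def pam30_score(a: str, b: str) -> float:
    return float(_PAM30[a, b])


def biophysical_distance(a: str, b: str) -> float:
    return _BIOPHYS[(a, b)]


def is_highly_similar(
    a: str,
    b: str,
    pam30_min: float = DEFAULT_PAM30_MIN,
    biophys_max: float = DEFAULT_BIOPHYS_MAX,
) -> bool:
    """Similar under BOTH matrices' thresholds (identity qualifies)."""
    if a == b:
        return True
    return pam30_score(a, b) >= pam30_min and biophysical_distance(a, b) <= biophys_max


def weighted_similarity(
    p1: str,
    p2: str,
    matrix=pam30_score,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    far_weight: float = DEFAULT_FAR_WEIGHT,
) -> float:
    """Position-weighted similarity of two C-terminally aligned peptides.

    ``weights[k]`` applies to position -(k+1) from the C-terminus; all
    positions further in receive ``far_weight``. Score = sum over aligned
    positions of weight * matrix(a, b).
    """
    if len(p1) != len(p2):
        raise ValueError("peptides must have equal length")
    if any(w <= 0 for w in weights) or far_weight <= 0:
        raise ValueError("weights must be positive")
    score = 0.0
    for k, (a, b) in enumerate(zip(reversed(p1), reversed(p2))):
        w = weights[k] if k < len(weights) else far_weight
        score += w * matrix(a, b)
    return score


@dataclass(frozen=True)
class PeptidePair:
    """A plain / pseudo-phosphorylated C-terminal peptide couple."""

    plain: str
    mimic: str
    swap_position: int  # -1, -2 or -3
    similarity: tuple = ()  # (pam30 weighted score, biophys weighted score)

    def __post_init__(self):
        if len(self.plain) != len(self.mimic):
            raise ValueError("peptides must have equal length")
        k = len(self.plain) + self.swap_position
        if not (
            self.plain[k] in PLAIN_RESIDUES and self.mimic[k] in MIMIC_RESIDUES
        ):
            raise ValueError("swap position must pair S/T/Y with D/E")


def find_peptide_pairs(
    peptides: Iterable[str],
    swap_positions: Iterable[int] = (-1, -2, -3),
    pam30_min: float = DEFAULT_PAM30_MIN,
    biophys_max: float = DEFAULT_BIOPHYS_MAX,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
) -> list[PeptidePair]:
    """All unordered peptide couples qualifying as phosphomimetic pairs.

    A couple qualifies when exactly one of the last three aligned
    positions pairs S/T/Y with D/E, and of the other two last-three
    positions at least one is identical and the remaining one is at least
    highly similar under both matrices.
    """
    peptides = sorted(set(peptides))
    if len(peptides) < 2:
        return []
    swap_positions = set(swap_positions)
    out = []
    for pa, pb in itertools.combinations(peptides, 2):
        if len(pa) != len(pb):
            continue
        L = len(pa)
        last3 = [-1, -2, -3]
        swap = None
        plain, mimic = None, None
        ok = True
        for pos in last3:
            a, b = pa[L + pos], pb[L + pos]
            sw_ab = a in PLAIN_RESIDUES and b in MIMIC_RESIDUES
            sw_ba = b in PLAIN_RESIDUES and a in MIMIC_RESIDUES
            if sw_ab or sw_ba:
                if swap is not None:  # more than one swap position
                    ok = False
                    break
                swap = pos
                plain, mimic = (pa, pb) if sw_ab else (pb, pa)
        if not ok or swap is None or swap not in swap_positions:
            continue
        others = [pos for pos in last3 if pos != swap]
        res = [(pa[L + pos], pb[L + pos]) for pos in others]
        identical = [a == b for a, b in res]
        similar = [
            is_highly_similar(a, b, pam30_min, biophys_max) for a, b in res
        ]
        if not (any(identical) and all(similar)):
            continue
        sim = (
            weighted_similarity(pa, pb, pam30_score, weights),
            weighted_similarity(pa, pb, biophysical_distance, weights),
        )
        out.append(PeptidePair(plain, mimic, swap, sim))
    return out


# ------------------------------------------------------------- matrices

@dataclass
class PDZBindingMatrix:
    """Binding/non-binding calls for PDZ domains x C-terminal peptides.

    Calls are 'B' (binds), 'N' (no binding) or '-' (missing). Peptide
    positions are indexed from the C-terminus (-1 is the last residue).
    """

    domains: list[str]
    peptides: list[str]
    calls: pd.DataFrame  # index=domains, columns=peptides, values B/N/-

    def __post_init__(self):
        if list(self.calls.index) != list(self.domains) or list(
            self.calls.columns
        ) != list(self.peptides):
            raise ValueError("calls frame inconsistent with domain/peptide lists")
        bad = set(np.unique(self.calls.to_numpy())) - {"B", "N", "-"}
        if bad:
            raise ValueError(f"unexpected call values {sorted(bad)}")

    def call(self, domain: str, peptide: str) -> str:
        return str(self.calls.at[domain, peptide])

    @classmethod
    def from_tsv(cls, path, affinity_cutoff: float | None = None):
        """Read a matrix TSV: header row of peptides, one row per domain,
        cells in {B, N, -} or numeric affinities (dissociation constants;
        value <= cutoff means binding)."""
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        values = df.to_numpy()
        if affinity_cutoff is not None:
            converted = np.full(values.shape, "-", dtype=object)
            for i, j in np.ndindex(values.shape):
                cell = values[i, j]
                if cell in ("-", "", None) or pd.isna(cell):
                    continue
                converted[i, j] = "B" if float(cell) <= affinity_cutoff else "N"
            df = pd.DataFrame(converted, index=df.index, columns=df.columns)
        return cls(list(df.index), list(df.columns), df)

    def to_tsv(self, path) -> None:
        self.calls.to_csv(path, sep="\t")


# ------------------------------------------------------------ scenarios

DOUBLE_SWITCH = "double-switch"


def scenario_id(a_plain: str, a_mimic: str, b_plain: str, b_mimic: str) -> str:
    """Canonical label of a binding configuration, invariant under
    exchanging the two domains."""
    for c in (a_plain, a_mimic, b_plain, b_mimic):
        if c not in ("B", "N"):
            raise ValueError(f"call must be B or N, got {c!r}")
    a = (a_plain, a_mimic)
    b = (b_plain, b_mimic)
    if {a, b} == {("B", "N"), ("N", "B")}:
        return DOUBLE_SWITCH
    lo, hi = sorted([a, b])
    return f"{lo[0]}{lo[1]}/{hi[0]}{hi[1]}"


def n_scenarios() -> int:
    """Number of canonical binding scenarios for one peptide pair and two
    exchangeable domains (enumerated, not assumed)."""
    labels = {
        scenario_id(*cfg)
        for cfg in itertools.product("BN", repeat=4)
    }
    return len(labels)


@dataclass(frozen=True)
class SwitchCall:
    pair: PeptidePair
    pdz_a: str
    pdz_b: str
    scenario: str


def call_switches(
    pairs: Iterable[PeptidePair],
    matrix: PDZBindingMatrix,
) -> tuple[list[SwitchCall], Counter, list]:
    """Classify every (peptide pair, domain couple) into its canonical
    binding scenario.

    Returns the double-switch calls, the per-scenario census over all
    complete configurations, and a log of skipped (missing-call)
    configurations. A missing call always means skip-and-log, never
    no-binding.
    """
    switches: list[SwitchCall] = []
    census: Counter = Counter()
    skipped: list = []
    for pair in pairs:
        if pair.plain not in matrix.peptides or pair.mimic not in matrix.peptides:
            skipped.append((pair, None, None, "peptide absent from matrix"))
            continue
        for da, db in itertools.combinations(matrix.domains, 2):
            calls = (
                matrix.call(da, pair.plain),
                matrix.call(da, pair.mimic),
                matrix.call(db, pair.plain),
                matrix.call(db, pair.mimic),
            )
            if "-" in calls:
                skipped.append((pair, da, db, "missing call"))
                continue
            scenario = scenario_id(*calls)
            census[scenario] += 1
            if scenario == DOUBLE_SWITCH:
                # orient so pdz_a binds the plain peptide
                if calls[0] == "B":
                    switches.append(SwitchCall(pair, da, db, scenario))
                else:
                    switches.append(SwitchCall(pair, db, da, scenario))
    return switches, census, skipped


def switch_enrichment(census: Mapping[str, int], switch_probability: float = 2 / 16) -> dict:
    """Over-representation of the double-switch scenario against a
    configuration-uniform random expectation.

    Of the 16 labeled call configurations, two are double switches, so the
    random expectation is ``switch_probability`` of the census total. The
    observed (switch, other) counts are compared to the expected integer
    counts by a two-sided Fisher exact test.
    """
    total = sum(census.values())
    if total == 0:
        raise ValueError("empty census")
    observed_switch = census.get(DOUBLE_SWITCH, 0)
    expected_switch = int(round(total * switch_probability))
    table = [
        [observed_switch, total - observed_switch],
        [expected_switch, total - expected_switch],
    ]
    p = float(fisher_exact(table, alternative="two-sided")[1])
    return {
        "observed_switch": observed_switch,
        "expected_switch": expected_switch,
        "total": total,
        "table": table,
        "p": p,
    }
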