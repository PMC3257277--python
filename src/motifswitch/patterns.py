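"""Short-linear-motif sequence patterns.

Pattern syntax follows the usual SLiM shorthand: ``x`` or ``.`` is a
wildcard, an upper-case letter is a literal residue, and ``[ABC]`` is a
residue class. Internally a pattern is an ordered tuple of residue
classes, where ``None`` denotes the wildcard.

A pattern may carry a ``phospho_index``: the 0-based position whose
phosphorylation the domain family requires for binding (SH2, class IV WW)
or whose phosphorylation blocks binding (e.g. the tyrosine of the class I
WW PPxY pattern).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

from .core import AA_ALPHABET

ANY = None  # wildcard residue class


@dataclass(frozen=True)
class SequencePattern:
    positions: tuple  # tuple of frozenset (residue class) or None (any)
    family: str
    name: str = ""
    phospho_index: int | None = None

    def __post_init__(self):
        if len(self.positions) < 2:
            raise ValueError("pattern must span at least 2 positions")
        if self.phospho_index is not None:
            if not 0 <= self.phospho_index < len(self.positions):
                raise ValueError("phospho_index outside pattern")
            cls = self.positions[self.phospho_index]
            if cls is ANY or not cls <= {"S", "T", "Y"}:
                raise ValueError(
                    "phospho_index must point at a class of phospho-capable "
                    f"residues, got {cls!r}"
                )

    def __len__(self) -> int:
        return len(self.positions)

    def to_text(self) -> str:
        out = []
        for cls in self.positions:
            if cls is ANY:
                out.append(".")
            elif len(cls) == 1:
                out.append(next(iter(cls)))
            else:
                out.append("[" + "".join(sorted(cls)) + "]")
        return "".join(out)


def parse_pattern(text: str) -> tuple:
    """Parse SLiM shorthand into a tuple of residue classes."""
    positions = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in ".x":
            positions.append(ANY)
            i += 1
        elif ch == "[":
            j = text.index("]", i)
            cls = frozenset(text[i + 1 : j])
            if not cls or not cls <= AA_ALPHABET:
                raise ValueError(f"bad residue class in {text!r}")
            positions.append(cls)
            i = j + 1
        elif ch in AA_ALPHABET:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise ValueError(f"bad pattern character {ch!r} in {text!r}")
    return tuple(positions)


def positions_to_regex(positions: tuple) -> str:
    out = []
    for cls in positions:
        if cls is ANY:
            out.append(".")
        elif len(cls) == 1:
            out.append(next(iter(cls)))
        else:
            out.append("[" + "".join(sorted(cls)) + "]")
    return "".join(out)


def matches_at(sequence: str, start0: int, positions: tuple) -> bool:
    """Does the pattern match at a 0-based offset of the sequence?"""
    if start0 < 0 or start0 + len(positions) > len(sequence):
        return False
    for cls, ch in zip(positions, sequence[start0 : start0 + len(positions)]):
        if cls is not ANY and ch not in cls:
            return False
    return True


def find_matches(sequence: str, positions: tuple) -> list[int]:
    """All (overlapping) 0-based match starts of a pattern in a sequence."""
    rx = re.compile("(?=(" + positions_to_regex(positions) + "))")
    return [m.start() for m in rx.finditer(sequence)]


def load_pattern_library(path=None) -> list[SequencePattern]:
    """Load a plain-text pattern library.

    Format: one pattern per line, tab-separated ``family  name  pattern
    phospho_index`` (phospho_index is a 0-based integer or ``-``); ``#``
    starts a comment. With no path, the packaged default library is used.
    """
    if path is None:
        text = (
            resources.files("motifswitch.data").joinpath("patterns.txt").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    out = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"bad pattern line: {line!r}")
        family, name, pattern, pidx = fields
        out.append(
            SequencePattern(
                parse_pattern(pattern),
                family,
                name,
                None if pidx.strip() == "-" else int(pidx),
            )
        )
    if not out:
        raise ValueError("empty pattern library")
    return out


def patterns_for_family(patterns, family: str) -> list[SequencePattern]:
    """Patterns of one family with subtypes unified (family label match on
    the part before any ``-`` qualifier, so ``WW-classI`` belongs to WW)."""
    fam = family.split("-")[0]
    return [p for p in patterns if p.family.split("-")[0] == fam]
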