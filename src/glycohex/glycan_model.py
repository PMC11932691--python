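"""N-glycan composition model: parsing, structural classification, pathway mapping.

N-glycans are represented by generic monosaccharide compositions over four
residues: Hex (hexose: mannose + galactose), HexNAc (N-acetylhexosamine),
dHex (deoxyhexose, i.e. core fucose) and NeuAc (N-acetylneuraminic acid).
Composition alone cannot resolve isomeric structures, so classification is a
rule table over residue counts that partitions every valid composition into
exactly one structural class:

========  ================================================  ================
order     predicate                                         class
========  ================================================  ================
1         hexnac <= 2 and hex == 0                          chitobiose_core
2         hexnac == 2 and 1 <= hex <= 3 and neuac == 0      paucimannose
3         hexnac == 2 and hex >= 4 and dhex == 0
          and neuac == 0                                    oligomannose
4         hexnac == 3 and hex >= 5                          hybrid
5         hexnac >= 3                                       complex
6         (anything else)                                   other
========  ================================================  ================

Conventions encoded in the default table (composition-level calls, not
structure elucidation):

* Hex4HexNAc2 is classed oligomannose — paucimannose is restricted to the
  truncated Man1-3GlcNAc2(Fuc0-1) species ("M1"-"M3F").
* Fucosylated Hex>=4/HexNAc2 compositions (e.g. Hex5HexNAc2dHex1) cannot be
  canonical oligomannose and fall through to ``other``.
* hybrid vs complex from HexNAc count is a heuristic; ambiguous compositions
  resolve in table order.

The table can be exported/loaded as TSV so alternative conventions can be
swapped in without code changes.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "MonosaccharideComposition",
    "GlycanClass",
    "PathwayLabel",
    "GlycanParseError",
    "InvalidCompositionError",
    "UnsupportedLabelError",
    "ClassificationRule",
    "DEFAULT_RULES",
    "parse_composition",
    "classify_glycan",
    "short_label",
    "pathway_of",
    "rules_to_tsv",
    "rules_from_tsv",
]


class GlycanParseError(ValueError):
    """Raised when a composition string contains an unknown residue token."""


class InvalidCompositionError(ValueError):
    """Raised for compositions violating basic validity (negative or empty)."""


class UnsupportedLabelError(ValueError):
    """Raised when a short truncation label is requested for a non-truncated glycan."""


@dataclass(frozen=True, order=True)
class MonosaccharideComposition:
    """Integer residue counts defining one glycan species.

    Residues follow the generic glycomics search-space convention:
    ``hex`` (Man+Gal), ``hexnac`` (GlcNAc+GalNAc), ``dhex`` (fucose),
    ``neuac`` (sialic acid).
    """

    hex: int = 0
    hexnac: int = 0
    dhex: int = 0
    neuac: int = 0

    def __post_init__(self) -> None:
        for field in ("hex", "hexnac", "dhex", "neuac"):
            v = getattr(self, field)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise InvalidCompositionError(f"{field} count must be an integer, got {v!r}")
            if v < 0:
                raise InvalidCompositionError(f"{field} count must be non-negative, got {v}")
        if self.hex + self.hexnac < 1:
            raise InvalidCompositionError(
                "empty composition: hex + hexnac must be at least 1"
            )

    def __str__(self) -> str:
        parts = []
        for token, count in (
            ("Hex", self.hex),
            ("HexNAc", self.hexnac),
            ("dHex", self.dhex),
            ("NeuAc", self.neuac),
        ):
            if count:
                parts.append(f"{token}{count}")
        return "".join(parts)


class GlycanClass(str, enum.Enum):
    """Structural N-glycan classes (a total partition of valid compositions)."""

    PAUCIMANNOSE = "paucimannose"
    CHITOBIOSE_CORE = "chitobiose_core"
    OLIGOMANNOSE = "oligomannose"
    HYBRID = "hybrid"
    COMPLEX = "complex"
    OTHER = "other"


class PathwayLabel(str, enum.Enum):
    """Biosynthetic route implied by the structural class.

    Paucimannosidic and chitobiose-core glycans are products of the
    noncanonical truncation pathway (Hex-driven trimming); hybrid and
    complex glycans are products of canonical elongation; oligomannose
    species are the shared biosynthetic precursors.
    """

    TRUNCATION = "truncation"
    ELONGATION = "elongation"
    PRECURSOR = "precursor"


_TOKEN_ALIASES = {
    "hex": "hex",
    "hexnac": "hexnac",
    "dhex": "dhex",
    "fuc": "dhex",
    "neuac": "neuac",
    "neu5ac": "neuac",
}

# longest alternatives first so HexNAc/Neu5Ac win over their prefixes
_TOKEN_RE = re.compile(r"(hexnac|hex|dhex|fuc|neu5ac|neuac)\s*(\d+)", re.IGNORECASE)


def parse_composition(text: str) -> MonosaccharideComposition:
    """Parse a composition string such as ``"Hex3HexNAc2dHex1"``.

    Token matching is case-insensitive. ``Fuc`` is accepted as an alias for
    ``dHex`` and ``Neu5Ac`` for ``NeuAc``. Absent residues default to zero.

    Raises
    ------
    GlycanParseError
        If the string contains an unknown residue token or trailing junk.
    InvalidCompositionError
        If the parsed composition is empty (hex + hexnac == 0).
    """
    if not isinstance(text, str) or not text.strip():
        raise GlycanParseError(f"cannot parse composition from {text!r}")
    counts = {"hex": 0, "hexnac": 0, "dhex": 0, "neuac": 0}
    pos = 0
    s = text.strip()
    for m in _TOKEN_RE.finditer(s):
        if s[pos : m.start()].strip():
            raise GlycanParseError(f"unknown token {s[pos:m.start()].strip()!r} in {text!r}")
        token = m.group(1).lower()
        if token not in _TOKEN_ALIASES:
            raise GlycanParseError(f"unknown residue token {m.group(1)!r} in {text!r}")
        counts[_TOKEN_ALIASES[token]] += int(m.group(2))
        pos = m.end()
    if s[pos:].strip():
        raise GlycanParseError(f"unknown token {s[pos:].strip()!r} in {text!r}")
    return MonosaccharideComposition(**counts)


@dataclass(frozen=True)
class ClassificationRule:
    """One row of the ordered rule table: inclusive residue-count bounds.

    ``None`` bounds are unbounded. The first rule whose bounds all hold wins.
    """

    glycan_class: GlycanClass
    hexnac_min: Optional[int] = None
    hexnac_max: Optional[int] = None
    hex_min: Optional[int] = None
    hex_max: Optional[int] = None
    dhex_min: Optional[int] = None
    dhex_max: Optional[int] = None
    neuac_min: Optional[int] = None
    neuac_max: Optional[int] = None

    def matches(self, c: MonosaccharideComposition) -> bool:
        for value, lo, hi in (
            (c.hexnac, self.hexnac_min, self.hexnac_max),
            (c.hex, self.hex_min, self.hex_max),
            (c.dhex, self.dhex_min, self.dhex_max),
            (c.neuac, self.neuac_min, self.neuac_max),
        ):
            if lo is not None and value < lo:
                return False
            if hi is not None and value > hi:
                return False
        return True


DEFAULT_RULES: tuple[ClassificationRule, ...] = (
    ClassificationRule(GlycanClass.CHITOBIOSE_CORE, hexnac_max=2, hex_max=0),
    ClassificationRule(
        GlycanClass.PAUCIMANNOSE, hexnac_min=2, hexnac_max=2, hex_min=1, hex_max=3, neuac_max=0
    ),
    ClassificationRule(
        GlycanClass.OLIGOMANNOSE, hexnac_min=2, hexnac_max=2, hex_min=4, dhex_max=0, neuac_max=0
    ),
    ClassificationRule(GlycanClass.HYBRID, hexnac_min=3, hexnac_max=3, hex_min=5),
    ClassificationRule(GlycanClass.COMPLEX, hexnac_min=3),
    ClassificationRule(GlycanClass.OTHER),
)


def classify_glycan(
    c: MonosaccharideComposition,
    rules: Sequence[ClassificationRule] = DEFAULT_RULES,
) -> GlycanClass:
    """Assign a composition to exactly one structural class via the rule table."""
    if not isinstance(c, MonosaccharideComposition):
        raise InvalidCompositionError(f"expected MonosaccharideComposition, got {type(c)}")
    for rule in rules:
        if rule.matches(c):
            return rule.glycan_class
    # unreachable with the default table (final rule is catch-all)
    return GlycanClass.OTHER


def short_label(c: MonosaccharideComposition) -> str:
    """Short truncation-pathway label, e.g. ``M3F`` for Hex3HexNAc2dHex1.

    Paucimannosidic species are ``M{hex}`` with an ``F`` suffix for a single
    core fucose. Chitobiose-core species map to ``M0``/``M0F`` (HexNAc2 ±
    Fuc) and ``GlcNAc1``/``GlcNAc1F`` (the single-residue remnant).

    Raises :class:`UnsupportedLabelError` for any other class or for
    multiply-fucosylated truncated species (no conventional short name).
    """
    cls = classify_glycan(c)
    if cls not in (GlycanClass.PAUCIMANNOSE, GlycanClass.CHITOBIOSE_CORE):
        raise UnsupportedLabelError(
            f"{c} is {cls.value}; short labels exist only for truncated glycans"
        )
    if c.dhex > 1:
        raise UnsupportedLabelError(f"{c}: no short label for dhex > 1")
    suffix = "F" if c.dhex == 1 else ""
    if cls is GlycanClass.PAUCIMANNOSE:
        return f"M{c.hex}{suffix}"
    if c.hexnac == 2:
        return f"M0{suffix}"
    return f"GlcNAc{c.hexnac}{suffix}"


_PATHWAY_MAP = {
    GlycanClass.PAUCIMANNOSE: PathwayLabel.TRUNCATION,
    GlycanClass.CHITOBIOSE_CORE: PathwayLabel.TRUNCATION,
    GlycanClass.HYBRID: PathwayLabel.ELONGATION,
    GlycanClass.COMPLEX: PathwayLabel.ELONGATION,
    GlycanClass.OLIGOMANNOSE: PathwayLabel.PRECURSOR,
    GlycanClass.OTHER: PathwayLabel.PRECURSOR,
}


def pathway_of(g: GlycanClass) -> PathwayLabel:
    """Map a structural class to its biosynthetic pathway (total, deterministic)."""
    return _PATHWAY_MAP[GlycanClass(g)]


_TSV_COLUMNS = (
    "glycan_class",
    "hexnac_min",
    "hexnac_max",
    "hex_min",
    "hex_max",
    "dhex_min",
    "dhex_max",
    "neuac_min",
    "neuac_max",
)


def rules_to_tsv(path: str | Path, rules: Iterable[ClassificationRule] = DEFAULT_RULES) -> None:
    """Serialize an ordered rule table to TSV (blank cell = unbounded)."""
    lines = ["\t".join(_TSV_COLUMNS)]
    for r in rules:
        row = [r.glycan_class.value]
        for col in _TSV_COLUMNS[1:]:
            v = getattr(r, col)
            row.append("" if v is None else str(v))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def rules_from_tsv(path: str | Path) -> tuple[ClassificationRule, ...]:
    """Load an ordered rule table previously written by :func:`rules_to_tsv`."""
    lines = [
        ln for ln in Path(path).read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    header = lines[0].split("\t")
    if header != list(_TSV_COLUMNS):
        raise ValueError(f"rule table header mismatch: expected {_TSV_COLUMNS}, got {header}")
    rules = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        kwargs = {}
        for col, cell in zip(_TSV_COLUMNS[1:], cells[1:]):
            kwargs[col] = int(cell) if cell.strip() else None
        rules.append(ClassificationRule(GlycanClass(cells[0]), **kwargs))
    return tuple(rules)
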