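"""Bipartite -35/-10 promoter model: degenerate consensus, invariant columns,
and per-column information content (sequence-logo data).

The -35 element is a full IUPAC consensus built from an alignment of promoter
sequences; the -10 side is reduced to a single required anchor base at a
bounded spacer distance. The spacer convention used everywhere in this
package is: number of nucleotides *strictly between* the last base of the
-35 element and the anchor base.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import AlignmentError, ContractError

#: IUPAC nucleotide code -> set of concrete bases denoted.
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

SPACER_CONVENTION = "nucleotides strictly between the last -35 base and the -10 anchor"


@dataclass(frozen=True)
class IUPACConsensus:
    """A degenerate consensus: one IUPAC code per position."""

    code: str
    allowed: tuple[frozenset[str], ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.code:
            raise ContractError("consensus must be nonempty")
        try:
            sets = tuple(IUPAC_TO_BASES[c] for c in self.code)
        except KeyError as exc:
            raise ContractError(f"illegal IUPAC code {exc.args[0]!r}") from None
        object.__setattr__(self, "allowed", sets)

    def __len__(self) -> int:
        return len(self.code)

    @classmethod
    def from_allowed(cls, allowed: Iterable[Iterable[str]]) -> "IUPACConsensus":
        code = []
        for bases in allowed:
            key = frozenset(bases)
            if key not in BASES_TO_IUPAC:
                raise ContractError(f"no IUPAC code for base set {sorted(key)}")
            code.append(BASES_TO_IUPAC[key])
        return cls("".join(code))


@dataclass(frozen=True)
class PromoterAlignment:
    """Equal-length aligned promoter sequences with a designated -35 span.

    ``element_span`` is a half-open column interval; it defaults to the full
    row width.
    """

    labels: tuple[str, ...]
    rows: tuple[str, ...]
    element_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise AlignmentError("alignment needs at least 2 rows")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise AlignmentError("alignment rows must have equal length")
        if len(self.labels) != len(self.rows):
            raise AlignmentError("one label per row required")
        span = self.element_span or (0, width)
        if not (0 <= span[0] < span[1] <= width):
            raise AlignmentError(f"element_span {span} outside alignment width {width}")
        object.__setattr__(self, "element_span", span)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def element_rows(self) -> list[str]:
        a, b = self.element_span
        return [r[a:b] for r in self.rows]


@dataclass(frozen=True)
class BipartiteMotifModel:
    """The full promoter model used for genome scanning."""

    minus35: IUPACConsensus
    invariant_positions: frozenset[int] = frozenset()
    minus10_anchor: str = "G"
    spacer_min: int = 16
    spacer_max: int = 18
    spacer_convention: str = SPACER_CONVENTION
    max_mismatches: int = 2

    def __post_init__(self) -> None:
        if self.spacer_min > self.spacer_max:
            raise ContractError("spacer_min must be <= spacer_max")
        if self.max_mismatches < 0:
            raise ContractError("max_mismatches must be >= 0")
        if self.minus10_anchor not in "ACGT":
            raise ContractError("minus10 anchor must be a concrete base")
        if not set(self.invariant_positions) <= set(range(len(self.minus35))):
            raise ContractError("invariant positions outside the -35 consensus")

    def to_dict(self) -> dict:
        return {
            "minus35": self.minus35.code,
            "invariant_positions": sorted(self.invariant_positions),
            "minus10_anchor": self.minus10_anchor,
            "spacer_min": self.spacer_min,
            "spacer_max": self.spacer_max,
            "spacer_convention": self.spacer_convention,
            "max_mismatches": self.max_mismatches,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BipartiteMotifModel":
        return cls(
            minus35=IUPACConsensus(d["minus35"]),
            invariant_positions=frozenset(d.get("invariant_positions", ())),
            minus10_anchor=d.get("minus10_anchor", "G"),
            spacer_min=d.get("spacer_min", 16),
            spacer_max=d.get("spacer_max", 18),
            spacer_convention=d.get("spacer_convention", SPACER_CONVENTION),
            max_mismatches=d.get("max_mismatches", 2),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "BipartiteMotifModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ColumnStats:
    """Per-column composition and information content of an alignment."""

    column_index: int
    counts: dict[str, int]
    gap_count: int
    information_content: float
    conservation_class: str | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.gap_count


def build_consensus(alignment: PromoterAlignment) -> IUPACConsensus:
    """Per-column IUPAC union over the element span.

    Every input row matches the returned consensus with zero mismatches.
    """
    allowed = []
    a, _ = alignment.element_span
    for offset, column in enumerate(zip(*alignment.element_rows())):
        bases = set(column)
        if "-" in bases:
            raise AlignmentError(f"gap in element column {a + offset}")
        if not bases <= set("ACGT"):
            raise AlignmentError(f"non-ACGT base in element column {a + offset}")
        allowed.append(bases)
    return IUPACConsensus.from_allowed(allowed)


def invariant_positions(alignment: PromoterAlignment) -> set[int]:
    """Columns (relative to the element span) where all rows share one base."""
    out = set()
    for idx, column in enumerate(zip(*alignment.element_rows())):
        bases = set(column)
        if "-" in bases:
            raise AlignmentError(f"gap in element column {idx}")
        if len(bases) == 1:
            out.add(idx)
    return out


def iupac_mismatch_count(window: str, consensus: IUPACConsensus) -> int:
    """Number of window positions whose base falls outside the consensus set.

    ``N`` in the window mismatches every column except all-base (``N``)
    columns.
    """
    if len(window) != len(consensus):
        raise ContractError(
            f"window length {len(window)} != consensus length {len(consensus)}"
        )
    mismatches = 0
    for base, allowed in zip(window, consensus.allowed):
        if base == "N":
            if len(allowed) < 4:
                mismatches += 1
        elif base not in allowed:
            mismatches += 1
    return mismatches


def column_information(counts: dict[str, int], alphabet_size: int = 4) -> float:
    """log2(alphabet) minus Shannon entropy of the observed frequencies.

    No small-sample correction is applied.
    """
    total = sum(counts.values())
    if total == 0:
        raise ContractError("empty column")
    entropy = 0.0
    for count in counts.values():
        if count:
            p = count / total
            entropy -= p * math.log2(p)
    return math.log2(alphabet_size) - entropy


def information_content(column: ColumnStats, alphabet_size: int = 4) -> float:
    """Information content (bits) of a :class:`ColumnStats`."""
    return column_information(column.counts, alphabet_size)


def logo_table(alignment: PromoterAlignment) -> list[ColumnStats]:
    """One :class:`ColumnStats` per alignment column (gaps counted aside)."""
    table = []
    for idx, column in enumerate(zip(*alignment.rows)):
        counts: dict[str, int] = {}
        gaps = 0
        for base in column:
            if base == "-":
                gaps += 1
            else:
                counts[base] = counts.get(base, 0) + 1
        table.append(
            ColumnStats(
                column_index=idx,
                counts=counts,
                gap_count=gaps,
                information_content=column_information(counts) if counts else 0.0,
            )
        )
    return table


def find_seed(seq: str, seed: str = "AAC") -> list[int]:
    """Offsets of every occurrence of ``seed`` in ``seq`` (overlaps included).

    Helper for locating well-conserved -35 seed triplets in upstream regions
    before building an alignment.
    """
    hits, start = [], seq.find(seed)
    while start != -1:
        hits.append(start)
        start = seq.find(seed, start + 1)
    return hits


def model_from_alignment(
    alignment: PromoterAlignment,
    minus10_anchor: str = "G",
    spacer_min: int = 16,
    spacer_max: int = 18,
    max_mismatches: int = 2,
) -> BipartiteMotifModel:
    """Convenience: consensus + invariant columns -> full bipartite model."""
    return BipartiteMotifModel(
        minus35=build_consensus(alignment),
        invariant_positions=frozenset(invariant_positions(alignment)),
        minus10_anchor=minus10_anchor,
        spacer_min=spacer_min,
        spacer_max=spacer_max,
        max_mismatches=max_mismatches,
    )
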