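"""Detection and census of Cys-rich C-terminal domains (CRDs) on ECF sigma
factors, progressive alignment of CRDs, and column-conservation classes.

Sigma-domain coordinates are supplied externally (TSV) or replaced by a
last-k-residues fallback; no profile-HMM search is performed here. The census
homology pre-filter uses the Smith-Waterman/E-value engine from
:mod:`corescan.synteny`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .errors import AlignmentError, ContractError, DomainCoordinatesError
from .motif_model import ColumnStats, column_information
from .synteny import pairwise_similarity

#: Functional similarity groups used for the "similar" conservation class.
DEFAULT_SIMILARITY_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("ILVM"),
    frozenset("FWY"),
    frozenset("KRH"),
    frozenset("DE"),
    frozenset("ST"),
    frozenset("NQ"),
    frozenset("AG"),
    frozenset("C"),
    frozenset("P"),
)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

#: Linear gap penalty used by the progressive aligner (documented scoring:
#: BLOSUM62 substitution scores, -8 per gapped position, gap-vs-gap = 0).
GAP_PENALTY = 8.0


@dataclass(frozen=True)
class SigmaFactorRecord:
    """A sigma-factor protein with optional 1-based inclusive domain spans."""

    protein_id: str
    seq: str
    sigma2_span: tuple[int, int] | None = None
    sigma4_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        n = len(self.seq)
        for name, span in (("sigma2", self.sigma2_span), ("sigma4", self.sigma4_span)):
            if span is not None and not (1 <= span[0] <= span[1] <= n):
                raise ContractError(f"{self.protein_id}: {name} span {span} outside sequence")
        if (
            self.sigma2_span is not None
            and self.sigma4_span is not None
            and self.sigma2_span[1] > self.sigma4_span[0]
        ):
            raise ContractError(f"{self.protein_id}: sigma2 must precede sigma4")


@dataclass(frozen=True)
class CRDCriteria:
    min_cys: int = 4
    tail_policy: str = "after_sigma4"  # or "last_k_residues"
    tail_k: int = 45
    homology_evalue_max: float = 2e-10
    require_sigma_domains: bool = False
    allow_tail_fallback: bool = True

    def __post_init__(self) -> None:
        if self.min_cys < 1 or self.tail_k < 1:
            raise ContractError("min_cys and tail_k must be >= 1")
        if self.tail_policy not in ("after_sigma4", "last_k_residues"):
            raise ContractError(f"unknown tail policy {self.tail_policy!r}")


@dataclass(frozen=True)
class CRDAnnotation:
    """Cys census of a protein's C-terminal tail (1-based residue indices)."""

    protein_id: str
    tail_start: int
    tail_len: int
    cys_count: int
    cys_positions: tuple[int, ...]
    is_crd: bool


@dataclass(frozen=True)
class CensusEntry:
    protein_id: str
    similarity_bits: float
    evalue: float
    annotation: CRDAnnotation | None
    passed: bool
    reason: str | None  # None when passed; else "evalue" | "domains" | "tail"


@dataclass(frozen=True)
class ConservationParams:
    conserved_min_count: int | None = None  # default: ceil(11/21 * n_rows)
    conserved_fraction: float = 11.0 / 21.0
    similarity_groups: tuple[frozenset[str], ...] = DEFAULT_SIMILARITY_GROUPS

    def min_count(self, n_rows: int) -> int:
        if self.conserved_min_count is not None:
            if self.conserved_min_count > n_rows:
                raise ContractError("conserved_min_count exceeds row count")
            return self.conserved_min_count
        return max(1, math.ceil(self.conserved_fraction * n_rows))


def find_crd(protein: SigmaFactorRecord, criteria: CRDCriteria = CRDCriteria()) -> CRDAnnotation:
    """Cys census of the C-terminal tail.

    Tail = residues after the sigma4 span end (policy ``after_sigma4``) or
    the last ``tail_k`` residues. When the span is missing, the fallback
    applies only if ``allow_tail_fallback``; otherwise a
    :class:`DomainCoordinatesError` is raised.
    """
    if not protein.seq:
        raise ContractError("empty protein sequence")
    n = len(protein.seq)
    if criteria.tail_policy == "after_sigma4":
        if protein.sigma4_span is None:
            if not criteria.allow_tail_fallback:
                raise DomainCoordinatesError(
                    f"{protein.protein_id}: sigma4 span required by tail policy"
                )
            tail_start = max(1, n - criteria.tail_k + 1)
        else:
            tail_start = protein.sigma4_span[1] + 1
    else:
        tail_start = max(1, n - criteria.tail_k + 1)
    tail = protein.seq[tail_start - 1 :]
    cys_positions = tuple(
        tail_start + i for i, aa in enumerate(tail) if aa == "C"
    )
    return CRDAnnotation(
        protein_id=protein.protein_id,
        tail_start=tail_start,
        tail_len=len(tail),
        cys_count=len(cys_positions),
        cys_positions=cys_positions,
        is_crd=len(cys_positions) >= criteria.min_cys,
    )


def census(
    proteins: Sequence[SigmaFactorRecord],
    query: SigmaFactorRecord,
    criteria: CRDCriteria = CRDCriteria(),
) -> list[CensusEntry]:
    """Screen a proteome for CRD-bearing sigma-factor homologs of ``query``.

    A protein passes when (1) its local-alignment E-value against the query
    is within ``homology_evalue_max``, (2) sigma2/sigma4 spans are present if
    ``require_sigma_domains``, and (3) its tail passes :func:`find_crd`.
    Output is sorted by similarity (bit score, descending); every input
    protein appears with its failure reason if excluded.
    """
    if not find_crd(query, criteria).is_crd:
        raise ContractError("census query must itself carry a CRD")
    entries = []
    for protein in proteins:
        bits, evalue = pairwise_similarity(protein.seq, query.seq)
        if evalue > criteria.homology_evalue_max:
            entries.append(
                CensusEntry(protein.protein_id, bits, evalue, None, False, "evalue")
            )
            continue
        if criteria.require_sigma_domains and (
            protein.sigma2_span is None or protein.sigma4_span is None
        ):
            entries.append(
                CensusEntry(protein.protein_id, bits, evalue, None, False, "domains")
            )
            continue
        annotation = find_crd(protein, criteria)
        if not annotation.is_crd:
            entries.append(
                CensusEntry(protein.protein_id, bits, evalue, annotation, False, "tail")
            )
            continue
        entries.append(CensusEntry(protein.protein_id, bits, evalue, annotation, True, None))
    entries.sort(key=lambda e: (-e.similarity_bits, e.protein_id))
    return entries


def census_hits(entries: Iterable[CensusEntry]) -> list[CRDAnnotation]:
    """The passing annotations of a census, in census order."""
    return [e.annotation for e in entries if e.passed and e.annotation is not None]


def _profile_column_score(column: Sequence[str], residue: str) -> float:
    total = 0.0
    for aa in column:
        if aa == "-":
            total += -GAP_PENALTY
        else:
            total += float(_BLOSUM62[aa, residue])
    return total / len(column)


def _align_to_profile(profile: list[str], seq: str) -> list[str]:
    """Needleman-Wunsch of a sequence against an alignment profile.

    Columns score as the mean BLOSUM62 score of the new residue against the
    column's residues (gaps contributing -GAP_PENALTY); opening a gap on
    either side costs GAP_PENALTY per position (linear). Traceback prefers
    diagonal, then a gap in the new sequence, then a gap column.
    """
    cols = list(zip(*profile))
    n_cols, n_res = len(cols), len(seq)
    score = np.zeros((n_cols + 1, n_res + 1))
    move = np.zeros((n_cols + 1, n_res + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, n_cols + 1):
        score[i, 0] = -GAP_PENALTY * i
        move[i, 0] = 1
    for j in range(1, n_res + 1):
        score[0, j] = -GAP_PENALTY * j
        move[0, j] = 2
    for i in range(1, n_cols + 1):
        col = cols[i - 1]
        for j in range(1, n_res + 1):
            diag = score[i - 1, j - 1] + _profile_column_score(col, seq[j - 1])
            up = score[i - 1, j] - GAP_PENALTY
            left = score[i, j - 1] - GAP_PENALTY
            best = max(diag, up, left)
            score[i, j] = best
            move[i, j] = 0 if best == diag else (1 if best == up else 2)
    # traceback
    new_rows = ["" for _ in profile]
    new_seq_row = ""
    i, j = n_cols, n_res
    while i > 0 or j > 0:
        m = move[i, j]
        if m == 0:
            for r in range(len(profile)):
                new_rows[r] = profile[r][i - 1] + new_rows[r]
            new_seq_row = seq[j - 1] + new_seq_row
            i, j = i - 1, j - 1
        elif m == 1:
            for r in range(len(profile)):
                new_rows[r] = profile[r][i - 1] + new_rows[r]
            new_seq_row = "-" + new_seq_row
            i -= 1
        else:
            for r in range(len(profile)):
                new_rows[r] = "-" + new_rows[r]
            new_seq_row = seq[j - 1] + new_seq_row
            j -= 1
    return new_rows + [new_seq_row]


def align_crds(sequences: Sequence[str]) -> list[str]:
    """Progressive global multiple alignment, joining in input order.

    Deterministic given input order; row order is preserved. Scoring is
    documented on :func:`_align_to_profile`. This is not ClustalX: guide-tree
    construction is replaced by sequential joining.
    """
    if len(sequences) < 2:
        raise ContractError("alignment requires at least 2 sequences")
    for seq in sequences:
        if not seq:
            raise ContractError("empty sequence in alignment input")
    profile = [sequences[0]]
    for seq in sequences[1:]:
        profile = _align_to_profile(profile, seq)
    return profile


def conservation_classes(
    rows: Sequence[str],
    params: ConservationParams = ConservationParams(),
) -> list[ColumnStats]:
    """Classify every alignment column as invariant/conserved/similar/none.

    invariant: all rows share one residue, no gaps; conserved: the modal
    residue occurs in at least ``min_count`` rows; similar: some similarity
    group covers at least ``min_count`` residues; else none. Row order never
    affects the result.
    """
    if len(set(map(len, rows))) != 1:
        raise AlignmentError("rows must have equal length")
    n_rows = len(rows)
    min_count = params.min_count(n_rows)
    table = []
    for idx, column in enumerate(zip(*rows)):
        counts: dict[str, int] = {}
        gaps = 0
        for aa in column:
            if aa == "-":
                gaps += 1
            else:
                counts[aa] = counts.get(aa, 0) + 1
        if gaps == 0 and len(counts) == 1:
            cls = "invariant"
        elif counts and max(counts.values()) >= min_count:
            cls = "conserved"
        else:
            cls = "none"
            for group in params.similarity_groups:
                if sum(c for aa, c in counts.items() if aa in group) >= min_count:
                    cls = "similar"
                    break
        table.append(
            ColumnStats(
                column_index=idx,
                counts=counts,
                gap_count=gaps,
                information_content=(
                    column_information(counts, alphabet_size=20) if counts else 0.0
                ),
                conservation_class=cls,
            )
        )
    return table


def invariant_cys_columns(rows: Sequence[str]) -> list[int]:
    """Columns that are Cys in every row (no gaps)."""
    return [
        i
        for i, column in enumerate(zip(*rows))
        if set(column) == {"C"}
    ]


def read_domain_table(path: str | Path) -> dict[str, dict[str, tuple[int, int]]]:
    """TSV: protein_id, sigma2_start, sigma2_end, sigma4_start, sigma4_end.

    Empty fields mean the span is unknown.
    """
    table: dict[str, dict[str, tuple[int, int]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            spans = {}
            if row.get("sigma2_start") and row.get("sigma2_end"):
                spans["sigma2"] = (int(row["sigma2_start"]), int(row["sigma2_end"]))
            if row.get("sigma4_start") and row.get("sigma4_end"):
                spans["sigma4"] = (int(row["sigma4_start"]), int(row["sigma4_end"]))
            table[row["protein_id"]] = spans
    return table


def load_sigma_records(
    fasta_records: Iterable[tuple[str, str]],
    domain_table: Mapping[str, Mapping[str, tuple[int, int]]] | None = None,
) -> list[SigmaFactorRecord]:
    """Combine protein FASTA records with an optional domain-span table."""
    records = []
    for protein_id, seq in fasta_records:
        spans = (domain_table or {}).get(protein_id, {})
        records.append(
            SigmaFactorRecord(
                protein_id=protein_id,
                seq=seq,
                sigma2_span=spans.get("sigma2"),
                sigma4_span=spans.get("sigma4"),
            )
        )
    return records


def write_census_tsv(entries: Sequence[CensusEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(
            "protein_id\ttail_start\ttail_len\tcys_count\tcys_positions\t"
            "is_crd\tsimilarity_bits\tevalue\tpassed\treason\n"
        )
        for e in entries:
            a = e.annotation
            fh.write(
                "\t".join(
                    [
                        e.protein_id,
                        str(a.tail_start) if a else "",
                        str(a.tail_len) if a else "",
                        str(a.cys_count) if a else "",
                        ",".join(map(str, a.cys_positions)) if a else "",
                        str(a.is_crd) if a else "",
                        f"{e.similarity_bits:.2f}",
                        f"{e.evalue:.3g}",
                        str(e.passed),
                        e.reason or "",
                    ]
                )
                + "\n"
            )


def write_conservation_tsv(table: Sequence[ColumnStats], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("column\tclass\tgaps\tinformation_bits\tcounts\n")
        for col in table:
            counts = ",".join(f"{aa}:{n}" for aa, n in sorted(col.counts.items()))
            fh.write(
                f"{col.column_index}\t{col.conservation_class}\t{col.gap_count}\t"
                f"{col.information_content:.4f}\t{counts}\n"
            )
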