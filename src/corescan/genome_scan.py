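"""Genome-wide scan for the bipartite promoter motif and the three-stage
filter cascade (orientation, invariant -35 residues, -10 anchor spacing)
that turns raw matches into predicted regulon members.

Coordinate conventions for hits:

* ``+`` strand: ``minus35_start`` is the forward-genome coordinate of the
  element's first base; the element occupies
  ``[minus35_start, minus35_start + L)``.
* ``-`` strand: the scan runs over the reverse complement and coordinates
  are mapped back, so ``minus35_start`` is the forward coordinate of the
  base aligned with consensus position 0; the element occupies
  ``[minus35_start - L + 1, minus35_start + 1]``.

In both cases the promoter "reads" downstream in the hit's orientation:
increasing coordinates for ``+``, decreasing for ``-``.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ContractError
from .genome_io import GeneAnnotation, GenomeRecord, reverse_complement
from .motif_model import BipartiteMotifModel, IUPACConsensus

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class MotifHit:
    contig_id: str
    minus35_start: int
    strand: str
    mismatches: int
    window_seq: str
    spacer_len: int | None = None
    minus10_pos: int | None = None

    def element_last_base(self) -> int:
        """Forward coordinate of the element's last base in scan orientation."""
        L = len(self.window_seq)
        return self.minus35_start + L - 1 if self.strand == "+" else self.minus35_start - L + 1


@dataclass(frozen=True)
class PromoterCandidate:
    hit: MotifHit
    downstream_gene: str | None
    distance_to_start: int | None
    strand_ok: bool
    invariants_ok: bool
    minus10_ok: bool

    @property
    def final(self) -> bool:
        return (
            self.downstream_gene is not None
            and self.strand_ok
            and self.invariants_ok
            and self.minus10_ok
        )


@dataclass
class RegulonReport:
    model: BipartiteMotifModel
    candidates: list[PromoterCandidate]
    counts: dict[str, int]

    def final_candidates(self) -> list[PromoterCandidate]:
        return [c for c in self.candidates if c.final]

    def to_dict(self) -> dict:
        return {"model": self.model.to_dict(), "counts": dict(self.counts)}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _CODE_LUT[ord(_b)] = _i


def _mismatch_profile(seq: str, consensus: IUPACConsensus) -> np.ndarray:
    """Mismatch count of every window of ``seq`` against ``consensus``."""
    L = len(consensus)
    codes = _CODE_LUT[_encode(seq)]
    n_windows = len(seq) - L + 1
    if n_windows <= 0:
        return np.zeros(0, dtype=np.int32)
    allowed = np.zeros((L, 5), dtype=bool)
    for j, bases in enumerate(consensus.allowed):
        for b in bases:
            allowed[j, _BASE_INDEX[b]] = True
        # N in the genome only matches all-base columns
        allowed[j, 4] = len(bases) == 4
    mismatches = np.zeros(n_windows, dtype=np.int32)
    for j in range(L):
        mismatches += ~allowed[j, codes[j : j + n_windows]]
    return mismatches


def scan_genome(
    genome: GenomeRecord,
    model: BipartiteMotifModel,
    strands: str = "both",
) -> list[MotifHit]:
    """All windows (both strands by default) within the mismatch budget.

    Overlapping hits are all reported; output is sorted by
    (contig, coordinate, strand). ``-`` strand hits are found on the reverse
    complement and reported in forward genomic coordinates.
    """
    if strands not in ("+", "-", "both"):
        raise ContractError(f"strands must be '+', '-' or 'both', got {strands!r}")
    L = len(model.minus35)
    if genome.length < L:
        raise ContractError("genome shorter than the consensus")
    hits = []
    if strands in ("+", "both"):
        profile = _mismatch_profile(genome.seq, model.minus35)
        for pos in np.nonzero(profile <= model.max_mismatches)[0]:
            pos = int(pos)
            hits.append(
                MotifHit(
                    contig_id=genome.id,
                    minus35_start=pos,
                    strand="+",
                    mismatches=int(profile[pos]),
                    window_seq=genome.seq[pos : pos + L],
                )
            )
    if strands in ("-", "both"):
        rc = reverse_complement(genome.seq)
        profile = _mismatch_profile(rc, model.minus35)
        N = genome.length
        for pos in np.nonzero(profile <= model.max_mismatches)[0]:
            pos = int(pos)
            hits.append(
                MotifHit(
                    contig_id=genome.id,
                    minus35_start=N - 1 - pos,
                    strand="-",
                    mismatches=int(profile[pos]),
                    window_seq=rc[pos : pos + L],
                )
            )
    hits.sort(key=lambda h: (h.contig_id, h.minus35_start, h.strand))
    return hits


def check_minus10(
    hit: MotifHit, genome: GenomeRecord, model: BipartiteMotifModel
) -> MotifHit:
    """Locate the -10 anchor downstream of the element, smallest spacer first.

    The spacer is the number of nucleotides strictly between the element's
    last base and the anchor. Windows running past the contig end find no
    anchor unless the genome is circular, in which case coordinates wrap.
    """
    last = hit.element_last_base()
    N = genome.length
    for spacer in range(model.spacer_min, model.spacer_max + 1):
        if hit.strand == "+":
            pos = last + spacer + 1
            if pos >= N:
                if not genome.circular:
                    continue
                pos %= N
            base = genome.seq[pos]
        else:
            pos = last - spacer - 1
            if pos < 0:
                if not genome.circular:
                    continue
                pos %= N
            base = reverse_complement(genome.seq[pos])
        if base == model.minus10_anchor:
            return dataclasses.replace(hit, spacer_len=spacer, minus10_pos=pos)
    return dataclasses.replace(hit, spacer_len=None, minus10_pos=None)


def assign_downstream_gene(
    hit: MotifHit,
    annotations: Sequence[GeneAnnotation],
    max_distance: int = 300,
    model: BipartiteMotifModel | None = None,
) -> PromoterCandidate:
    """Assign the nearest downstream translational start within range.

    Distance runs from the element's last base to the gene's translational
    start (strictly positive). Genes on either strand are considered;
    ``strand_ok`` records whether the gene strand matches the hit strand.
    Ties are broken by the smaller genomic coordinate of the start, then
    annotation order.
    """
    last = hit.element_last_base()
    best: tuple[int, int, int] | None = None
    best_gene: GeneAnnotation | None = None
    for order, gene in enumerate(annotations):
        if gene.contig_id != hit.contig_id:
            continue
        tstart = gene.translational_start
        distance = tstart - last if hit.strand == "+" else last - tstart
        if distance <= 0 or distance > max_distance:
            continue
        key = (distance, tstart, order)
        if best is None or key < best:
            best, best_gene = key, gene
    invariants_ok = _invariants_ok(hit, model) if model is not None else False
    minus10_ok = hit.spacer_len is not None
    if best_gene is None:
        return PromoterCandidate(
            hit=hit,
            downstream_gene=None,
            distance_to_start=None,
            strand_ok=False,
            invariants_ok=invariants_ok,
            minus10_ok=minus10_ok,
        )
    return PromoterCandidate(
        hit=hit,
        downstream_gene=best_gene.gene_id,
        distance_to_start=best[0],
        strand_ok=best_gene.strand == hit.strand,
        invariants_ok=invariants_ok,
        minus10_ok=minus10_ok,
    )


def _invariants_ok(hit: MotifHit, model: BipartiteMotifModel) -> bool:
    for pos in model.invariant_positions:
        if hit.window_seq[pos] not in model.minus35.allowed[pos]:
            return False
    return True


def filter_candidates(
    hits: Iterable[MotifHit],
    model: BipartiteMotifModel,
    annotations: Sequence[GeneAnnotation],
    max_distance: int = 300,
    genome: GenomeRecord | None = None,
) -> RegulonReport:
    """Apply the three-stage cascade and report per-stage counts.

    Stages, in order: (1) downstream-gene assignment with matching strand,
    (2) exact match at the invariant -35 positions, (3) -10 anchor within the
    spacer range. All three flags are computed for every hit regardless of
    where it fails, so reports show why each candidate dropped out.

    When ``genome`` is given, hits lacking -10 information are completed
    with :func:`check_minus10` first.
    """
    candidates = []
    for hit in hits:
        if genome is not None and hit.minus10_pos is None and hit.spacer_len is None:
            hit = check_minus10(hit, genome, model)
        candidates.append(
            assign_downstream_gene(hit, annotations, max_distance, model=model)
        )
    n_raw = len(candidates)
    n_oriented = sum(
        1 for c in candidates if c.downstream_gene is not None and c.strand_ok
    )
    n_invariant = sum(
        1
        for c in candidates
        if c.downstream_gene is not None and c.strand_ok and c.invariants_ok
    )
    n_final = sum(1 for c in candidates if c.final)
    return RegulonReport(
        model=model,
        candidates=candidates,
        counts={
            "raw": n_raw,
            "oriented": n_oriented,
            "invariants": n_invariant,
            "final": n_final,
        },
    )


_HIT_COLUMNS = [
    "contig",
    "start",
    "strand",
    "mismatches",
    "spacer",
    "minus10_pos",
    "window",
]

_CANDIDATE_COLUMNS = _HIT_COLUMNS + [
    "gene",
    "distance",
    "strand_ok",
    "invariants_ok",
    "minus10_ok",
    "final",
]


def write_hits_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HIT_COLUMNS)
        for h in hits:
            writer.writerow(
                [
                    h.contig_id,
                    h.minus35_start,
                    h.strand,
                    h.mismatches,
                    "" if h.spacer_len is None else h.spacer_len,
                    "" if h.minus10_pos is None else h.minus10_pos,
                    h.window_seq,
                ]
            )


def read_hits_tsv(path: str | Path) -> list[MotifHit]:
    hits = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            hits.append(
                MotifHit(
                    contig_id=row["contig"],
                    minus35_start=int(row["start"]),
                    strand=row["strand"],
                    mismatches=int(row["mismatches"]),
                    window_seq=row["window"],
                    spacer_len=int(row["spacer"]) if row["spacer"] else None,
                    minus10_pos=int(row["minus10_pos"]) if row["minus10_pos"] else None,
                )
            )
    return hits


def write_candidates_tsv(
    candidates: Iterable[PromoterCandidate], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CANDIDATE_COLUMNS)
        for c in candidates:
            h = c.hit
            writer.writerow(
                [
                    h.contig_id,
                    h.minus35_start,
                    h.strand,
                    h.mismatches,
                    "" if h.spacer_len is None else h.spacer_len,
                    "" if h.minus10_pos is None else h.minus10_pos,
                    h.window_seq,
                    c.downstream_gene or "",
                    "" if c.distance_to_start is None else c.distance_to_start,
                    c.strand_ok,
                    c.invariants_ok,
                    c.minus10_ok,
                    c.final,
                ]
            )
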