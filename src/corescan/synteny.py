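"""Gene-neighborhood (synteny) comparison around anchor sigma-factor genes,
plus the pairwise protein-similarity engine shared with the CRD census.

Similarity is an in-package Smith-Waterman (BLOSUM62, gap open 11 / extend 1,
via Bio.Align) with a Karlin-Altschul style E-value estimate
``E = K * m * n * exp(-lambda * S)`` using the standard gapped BLOSUM62
parameters lambda = 0.267, K = 0.041. This approximates, but is not, BLASTP:
thresholds are configurable and the search space defaults to the product of
the two sequence lengths.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ContractError, UnknownGeneError
from .genome_io import GeneAnnotation

_LAMBDA = 0.267
_K = 0.041

_AMINO = set("ACDEFGHIKLMNPQRSTVWYXBZ*")


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _aligner()


def pairwise_similarity(
    a: str,
    b: str,
    search_space: float | None = None,
) -> tuple[float, float]:
    """(bit score, E-value estimate) of the best local alignment of a and b.

    Symmetric in its arguments. ``search_space`` defaults to ``len(a)*len(b)``.
    """
    if not a or not b:
        raise ContractError("sequences must be nonempty")
    for seq in (a, b):
        bad = set(seq) - _AMINO
        if bad:
            raise ContractError(f"illegal residue(s) {sorted(bad)}")
    raw = float(_ALIGNER.score(a, b))
    bits = (_LAMBDA * raw - math.log(_K)) / math.log(2.0)
    mn = search_space if search_space is not None else len(a) * len(b)
    evalue = _K * mn * math.exp(-_LAMBDA * raw)
    return bits, evalue


@dataclass(frozen=True)
class SyntenyParams:
    flank_genes: int = 2
    similarity_evalue_max: float = 1e-4
    extend_on_match: bool = False
    max_extension: int = 5  # cap on flank widening, genes per side

    def __post_init__(self) -> None:
        if self.flank_genes < 1:
            raise ContractError("flank_genes must be >= 1")


@dataclass(frozen=True)
class FlankProtein:
    protein_id: str
    seq: str
    strand: str
    offset: int  # genes from the anchor: -flank..-1, +1..+flank


@dataclass(frozen=True)
class Neighborhood:
    anchor_id: str
    flanks: tuple[FlankProtein, ...]
    truncated: bool = False

    def __post_init__(self) -> None:
        if any(f.offset == 0 for f in self.flanks):
            raise ContractError("flank offset 0 is reserved for the anchor")


@dataclass(frozen=True)
class MatchedPair:
    offset_a: int
    offset_b: int
    protein_a: str
    protein_b: str
    score_bits: float
    evalue: float
    passes_threshold: bool


@dataclass(frozen=True)
class SyntenyBlock:
    anchor_a: str
    anchor_b: str
    pairs: tuple[MatchedPair, ...]

    @property
    def conserved(self) -> bool:
        return any(p.passes_threshold for p in self.pairs)

    def passing_pairs(self) -> list[MatchedPair]:
        return [p for p in self.pairs if p.passes_threshold]


def extract_neighborhood(
    annotations: Sequence[GeneAnnotation],
    proteins: Mapping[str, str],
    anchor_gene_id: str,
    params: SyntenyParams = SyntenyParams(),
) -> Neighborhood:
    """The ``flank_genes`` genes on each side of the anchor, in genomic order.

    Order is restored by coordinates regardless of input order; strand does
    not affect which genes qualify. Anchors near a contig edge yield a
    truncated neighborhood with a warning.
    """
    anchor = next((a for a in annotations if a.gene_id == anchor_gene_id), None)
    if anchor is None:
        raise UnknownGeneError(anchor_gene_id)
    contig = sorted(
        (a for a in annotations if a.contig_id == anchor.contig_id),
        key=lambda a: (a.start, a.end, a.gene_id),
    )
    idx = next(i for i, a in enumerate(contig) if a.gene_id == anchor_gene_id)
    flanks = []
    for offset in range(-params.flank_genes, params.flank_genes + 1):
        if offset == 0:
            continue
        j = idx + offset
        if not (0 <= j < len(contig)):
            continue
        gene = contig[j]
        if gene.gene_id not in proteins:
            continue
        flanks.append(
            FlankProtein(
                protein_id=gene.gene_id,
                seq=proteins[gene.gene_id],
                strand=gene.strand,
                offset=offset,
            )
        )
    truncated = len(flanks) < 2 * params.flank_genes
    if truncated:
        warnings.warn(
            f"neighborhood of {anchor_gene_id} truncated to {len(flanks)} flank genes",
            stacklevel=2,
        )
    return Neighborhood(anchor_id=anchor_gene_id, flanks=tuple(flanks), truncated=truncated)


def _greedy_match(na: Neighborhood, nb: Neighborhood, evalue_max: float) -> list[MatchedPair]:
    scored = []
    for ia, fa in enumerate(na.flanks):
        for ib, fb in enumerate(nb.flanks):
            bits, evalue = pairwise_similarity(fa.seq, fb.seq)
            scored.append((-bits, abs(fa.offset), abs(fb.offset), ia, ib, evalue))
    scored.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for neg_bits, _, _, ia, ib, evalue in scored:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        fa, fb = na.flanks[ia], nb.flanks[ib]
        pairs.append(
            MatchedPair(
                offset_a=fa.offset,
                offset_b=fb.offset,
                protein_a=fa.protein_id,
                protein_b=fb.protein_id,
                score_bits=-neg_bits,
                evalue=evalue,
                passes_threshold=evalue <= evalue_max,
            )
        )
    pairs.sort(key=lambda p: (p.offset_a, p.offset_b))
    return pairs


def compare_neighborhoods(
    na: Neighborhood,
    nb: Neighborhood,
    params: SyntenyParams = SyntenyParams(),
    widen_a: Callable[[int], Neighborhood] | None = None,
    widen_b: Callable[[int], Neighborhood] | None = None,
) -> SyntenyBlock:
    """Greedy best-score matching between flank proteins, each used once.

    Ties break by smaller absolute offset, then input order. With
    ``extend_on_match`` and widening callbacks (flank count -> wider
    neighborhood), the window grows one gene per side while new passing
    pairs keep appearing, up to ``params.max_extension``.
    """
    pairs = _greedy_match(na, nb, params.similarity_evalue_max)
    if params.extend_on_match and widen_a is not None and widen_b is not None:
        flank = params.flank_genes
        n_passing = sum(p.passes_threshold for p in pairs)
        while n_passing > 0 and flank < params.max_extension:
            flank += 1
            wider = _greedy_match(
                widen_a(flank), widen_b(flank), params.similarity_evalue_max
            )
            new_passing = sum(p.passes_threshold for p in wider)
            if new_passing <= n_passing:
                break
            pairs, n_passing = wider, new_passing
            na, nb = widen_a(flank), widen_b(flank)
    return SyntenyBlock(anchor_a=na.anchor_id, anchor_b=nb.anchor_id, pairs=tuple(pairs))


def write_synteny_tsv(
    blocks: Sequence[tuple[str, str, SyntenyBlock]], path
) -> None:
    """Rows: genomeA, genomeB, offsets, score, evalue, pass, conserved."""
    with open(path, "w", newline="") as fh:
        fh.write(
            "genome_a\tgenome_b\toffset_a\toffset_b\tprotein_a\tprotein_b"
            "\tscore_bits\tevalue\tpass\tconserved\n"
        )
        for ga, gb, block in blocks:
            for p in block.pairs:
                fh.write(
                    f"{ga}\t{gb}\t{p.offset_a}\t{p.offset_b}\t{p.protein_a}\t"
                    f"{p.protein_b}\t{p.score_bits:.2f}\t{p.evalue:.3g}\t"
                    f"{p.passes_threshold}\t{block.conserved}\n"
                )
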