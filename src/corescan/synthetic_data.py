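"""Seeded generators for genomes, annotations and proteomes with planted
ground truth: promoter motifs at controlled mismatch/strand/spacer, regulon
genes, CRD-bearing sigma-factor-like proteins, and syntenic neighborhood
pairs.

All randomness flows from one integer seed; per-feature substreams are
derived from (seed, stable-name-hash) so adding features never shifts
earlier draws.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError
from .genome_io import GeneAnnotation, GenomeRecord, reverse_complement
from .motif_model import BipartiteMotifModel
from .synteny import FlankProtein, Neighborhood

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-feature random substream."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class PlantedPromoter:
    minus35_start: int
    strand: str
    mismatches: int
    spacer: int
    gene_id: str
    kind: str  # "true" | "near_miss" | "wrong_strand"


@dataclass(frozen=True)
class PlantedProtein:
    protein_id: str
    tail_len: int
    cys_count: int
    has_domains: bool


@dataclass
class SyntheticTruth:
    seed: int
    promoters: list[PlantedPromoter] = field(default_factory=list)
    crd_proteins: list[PlantedProtein] = field(default_factory=list)
    homolog_pairs: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "promoters": [dataclasses.asdict(p) for p in self.promoters],
            "crd_proteins": [dataclasses.asdict(p) for p in self.crd_proteins],
            "homolog_pairs": [list(p) for p in self.homolog_pairs],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_len: int = 20_000
    gc_fraction: float = 0.5
    contig_id: str = "synthetic_1"
    # regulon planting
    n_planted_promoters: int = 5
    planted_mismatches: Sequence[int] | None = None  # per site; default cycles 0,1,2
    planted_strands: Sequence[str] | None = None  # default alternates +,-
    planted_spacers: Sequence[int] | None = None  # default cycles 16,17,18
    n_near_miss: int = 2
    n_wrong_strand: int = 2
    n_decoy_genes: int = 3
    gene_len: tuple[int, int] = (150, 280)
    wrong_strand_gene_len: int = 120
    promoter_gene_gap: int = 20
    max_distance: int = 300
    # proteome planting
    n_decoy_proteins: int = 50
    protein_len: tuple[int, int] = (120, 240)
    core_len: int = 170
    homolog_identity: float = 0.7
    crd_plants: Sequence[Mapping] = field(
        default_factory=lambda: [{"tail_len": 38, "cys_count": 6}]
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if isinstance(cfg.gene_len, list):
            cfg.gene_len = tuple(cfg.gene_len)
        if isinstance(cfg.protein_len, list):
            cfg.protein_len = tuple(cfg.protein_len)
        return cfg


def random_dna(rng: np.random.Generator, length: int, gc_fraction: float = 0.5) -> str:
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    bases = rng.choice(list("ACGT"), size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(bases)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def simulate_genome(config: SimulationConfig) -> tuple[GenomeRecord, SyntheticTruth]:
    """Background genome drawn per ``gc_fraction``; bit-reproducible by seed."""
    if config.genome_len < 1:
        raise ConfigurationError("genome_len must be positive")
    rng = substream(config.seed, "background")
    seq = random_dna(rng, config.genome_len, config.gc_fraction)
    return GenomeRecord(id=config.contig_id, seq=seq), SyntheticTruth(seed=config.seed)


def _mutated_element(
    model: BipartiteMotifModel,
    mismatches: int,
    rng: np.random.Generator,
    avoid_invariant: bool,
) -> str:
    consensus = model.minus35
    bases = [rng.choice(sorted(allowed)) for allowed in consensus.allowed]
    mutable = [
        j
        for j in range(len(consensus))
        if len(consensus.allowed[j]) < 4
        and not (avoid_invariant and j in model.invariant_positions)
    ]
    if mismatches > len(mutable):
        raise ConfigurationError(
            f"cannot place {mismatches} mismatches in {len(mutable)} mutable columns"
        )
    for j in rng.choice(mutable, size=mismatches, replace=False):
        bases[int(j)] = rng.choice(sorted(set("ACGT") - consensus.allowed[int(j)]))
    return "".join(bases)


def _cassette(
    model: BipartiteMotifModel,
    mismatches: int,
    spacer: int,
    gene_len: int,
    gap: int,
    rng: np.random.Generator,
    avoid_invariant: bool,
) -> tuple[str, int, int]:
    """Promoter-orientation cassette; returns (seq, gene_start, gene_end)."""
    element = _mutated_element(model, mismatches, rng, avoid_invariant)
    non_anchor = sorted(set("ACGT") - {model.minus10_anchor})
    spacer_seq = "".join(rng.choice(non_anchor, size=spacer))
    gene_seq = random_dna(rng, gene_len)
    prefix = element + spacer_seq + model.minus10_anchor + random_dna(rng, gap)
    return prefix + gene_seq, len(prefix), len(prefix) + gene_len


def plant_regulon(
    genome: GenomeRecord,
    model: BipartiteMotifModel,
    config: SimulationConfig,
) -> tuple[GenomeRecord, list[GeneAnnotation], SyntheticTruth]:
    """Plant true promoters, near-miss and wrong-strand decoys, decoy genes.

    True sites get the requested mismatch count (placed outside invariant
    columns), strand and spacer, with their regulon gene within
    ``max_distance`` downstream on the matching strand. Near-miss decoys
    carry ``max_mismatches + 1`` mismatches; wrong-strand decoys put the
    downstream gene on the opposite strand. Sites are isolated so no planted
    promoter can be assigned to another site's gene.
    """
    n_true = config.n_planted_promoters
    mismatch_plan = list(config.planted_mismatches or [i % 3 for i in range(n_true)])
    strand_plan = list(config.planted_strands or ["+-"[i % 2] for i in range(n_true)])
    spacer_plan = list(config.planted_spacers or [16 + i % 3 for i in range(n_true)])
    if not (len(mismatch_plan) == len(strand_plan) == len(spacer_plan) == n_true):
        raise ConfigurationError("per-site plans must match n_planted_promoters")
    for m in mismatch_plan:
        if m > model.max_mismatches:
            raise ConfigurationError(
                "planted mismatches exceed the model budget; recovery cannot hold"
            )

    L = len(model.minus35)
    cassette_max = L + model.spacer_max + 1 + config.promoter_gene_gap + config.gene_len[1]
    slot = cassette_max + config.max_distance + 60
    n_slots = n_true + config.n_near_miss + config.n_wrong_strand + config.n_decoy_genes
    margin = 50
    if margin + n_slots * slot > genome.length:
        raise ConfigurationError(
            f"genome of {genome.length} nt cannot hold {n_slots} sites "
            f"({margin + n_slots * slot} nt needed)"
        )

    seq = list(genome.seq)
    annotations: list[GeneAnnotation] = []
    truth = SyntheticTruth(seed=config.seed)
    gene_counter = 0

    def place(
        site_idx: int,
        mismatches: int,
        strand: str,
        spacer: int,
        kind: str,
        gene_strand_flip: bool,
        gene_len: int,
    ) -> None:
        nonlocal gene_counter
        rng = substream(config.seed, f"site{site_idx}")
        cassette, gs, ge = _cassette(
            model,
            mismatches,
            spacer,
            gene_len,
            config.promoter_gene_gap,
            rng,
            avoid_invariant=(kind != "near_miss"),
        )
        offset = margin + site_idx * slot
        T = len(cassette)
        gene_counter += 1
        gene_id = f"SYNGENE_{gene_counter:04d}"
        if strand == "+":
            seq[offset : offset + T] = cassette
            minus35_start = offset
            gene_start, gene_end = offset + gs, offset + ge
            gene_strand = "+"
        else:
            seq[offset : offset + T] = reverse_complement(cassette)
            minus35_start = offset + T - 1
            gene_start, gene_end = offset + T - ge, offset + T - gs
            gene_strand = "-"
        if gene_strand_flip:
            gene_strand = "-" if gene_strand == "+" else "+"
        annotations.append(
            GeneAnnotation(
                contig_id=genome.id,
                start=gene_start,
                end=gene_end,
                strand=gene_strand,
                gene_id=gene_id,
                product=kind,
            )
        )
        truth.promoters.append(
            PlantedPromoter(
                minus35_start=minus35_start,
                strand=strand,
                mismatches=mismatches,
                spacer=spacer,
                gene_id=gene_id,
                kind=kind,
            )
        )

    site = 0
    for i in range(n_true):
        rng = substream(config.seed, f"genelen{site}")
        glen = int(rng.integers(config.gene_len[0], config.gene_len[1] + 1))
        place(site, mismatch_plan[i], strand_plan[i], spacer_plan[i], "true", False, glen)
        site += 1
    for i in range(config.n_near_miss):
        rng = substream(config.seed, f"genelen{site}")
        glen = int(rng.integers(config.gene_len[0], config.gene_len[1] + 1))
        place(
            site,
            model.max_mismatches + 1,
            "+-"[i % 2],
            16 + i % 3,
            "near_miss",
            False,
            glen,
        )
        site += 1
    for i in range(config.n_wrong_strand):
        place(
            site,
            0,
            "+-"[i % 2],
            16 + i % 3,
            "wrong_strand",
            True,
            config.wrong_strand_gene_len,
        )
        site += 1
    for i in range(config.n_decoy_genes):
        rng = substream(config.seed, f"decoygene{i}")
        glen = int(rng.integers(config.gene_len[0], config.gene_len[1] + 1))
        offset = margin + site * slot
        gene_counter += 1
        annotations.append(
            GeneAnnotation(
                contig_id=genome.id,
                start=offset,
                end=offset + glen,
                strand="+-"[i % 2],
                gene_id=f"SYNGENE_{gene_counter:04d}",
                product="decoy",
            )
        )
        site += 1

    annotations.sort(key=lambda a: (a.contig_id, a.start))
    planted = GenomeRecord(id=genome.id, seq="".join(seq), circular=genome.circular)
    return planted, annotations, truth


def _mutate_protein(
    template: str, identity: float, rng: np.random.Generator
) -> str:
    n_mut = round((1.0 - identity) * len(template))
    positions = rng.choice(len(template), size=n_mut, replace=False)
    seq = list(template)
    for pos in positions:
        pos = int(pos)
        seq[pos] = rng.choice(sorted(set(AMINO_ACIDS) - {seq[pos]}))
    return "".join(seq)


def _tail(rng: np.random.Generator, tail_len: int, cys_count: int) -> str:
    if cys_count > tail_len:
        raise ConfigurationError("cys_count exceeds tail_len")
    non_cys = sorted(set(AMINO_ACIDS) - {"C"})
    tail = list(rng.choice(non_cys, size=tail_len))
    for pos in rng.choice(tail_len, size=cys_count, replace=False):
        tail[int(pos)] = "C"
    return "".join(tail)


def simulate_proteomes(
    config: SimulationConfig,
) -> tuple[
    list[tuple[str, str]],
    dict[str, dict[str, tuple[int, int]]],
    SyntheticTruth,
]:
    """Decoy proteome plus planted sigma-factor-like proteins with tails.

    Planted proteins are mutated copies of a per-seed template core (length
    ``core_len``, identity ``homolog_identity`` to the template) with a tail
    of exactly the requested Cys count appended. Sigma2/sigma4 spans cover
    fixed core intervals and are recorded in the domain table unless the
    plant spec sets ``has_domains: false``.
    """
    truth = SyntheticTruth(seed=config.seed)
    proteins: list[tuple[str, str]] = []
    domains: dict[str, dict[str, tuple[int, int]]] = {}

    rng = substream(config.seed, "decoy_proteins")
    for i in range(config.n_decoy_proteins):
        length = int(rng.integers(config.protein_len[0], config.protein_len[1] + 1))
        proteins.append((f"DECOY_{i:04d}", random_protein(rng, length)))

    template = random_protein(substream(config.seed, "template"), config.core_len)
    for i, spec in enumerate(config.crd_plants):
        rng = substream(config.seed, f"plant{i}")
        tail_len = int(spec.get("tail_len", 38))
        cys_count = int(spec.get("cys_count", 6))
        identity = float(spec.get("identity", config.homolog_identity))
        has_domains = bool(spec.get("has_domains", True))
        core = template if i == 0 else _mutate_protein(template, identity, rng)
        seq = core + _tail(rng, tail_len, cys_count)
        protein_id = f"SIGMA_{i:04d}"
        proteins.append((protein_id, seq))
        if has_domains:
            domains[protein_id] = {
                "sigma2": (5, 60),
                "sigma4": (config.core_len - 59, config.core_len),
            }
        truth.crd_proteins.append(
            PlantedProtein(
                protein_id=protein_id,
                tail_len=tail_len,
                cys_count=cys_count,
                has_domains=has_domains,
            )
        )
    return proteins, domains, truth


def simulate_synteny_pair(
    seed: int,
    n_shared: int = 2,
    flank: int = 2,
    protein_len: int = 150,
    identity: float = 0.6,
) -> tuple[Neighborhood, Neighborhood, list[tuple[int, int]]]:
    """Two anchor neighborhoods sharing ``n_shared`` homologous flank proteins.

    Returns the neighborhoods and the planted (offset_a, offset_b) homolog
    pairs; all remaining flank proteins are independent decoys.
    """
    offsets = [o for o in range(-flank, flank + 1) if o != 0]
    if n_shared > len(offsets):
        raise ConfigurationError("n_shared exceeds available flank slots")
    rng = substream(seed, "synteny")
    shared_offsets = sorted(
        int(o) for o in rng.choice(offsets, size=n_shared, replace=False)
    )
    flanks_a, flanks_b = [], []
    pairs = []
    for o in offsets:
        seq_a = random_protein(rng, protein_len)
        strand = "+-"[int(rng.integers(0, 2))]
        flanks_a.append(FlankProtein(f"A_{o:+d}", seq_a, strand, o))
        if o in shared_offsets:
            seq_b = _mutate_protein(seq_a, identity, rng)
            pairs.append((o, o))
        else:
            seq_b = random_protein(rng, protein_len)
        flanks_b.append(FlankProtein(f"B_{o:+d}", seq_b, strand, o))
    na = Neighborhood(anchor_id="anchorA", flanks=tuple(flanks_a))
    nb = Neighborhood(anchor_id="anchorB", flanks=tuple(flanks_b))
    return na, nb, pairs


def write_domain_tsv(
    domains: Mapping[str, Mapping[str, tuple[int, int]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tsigma2_start\tsigma2_end\tsigma4_start\tsigma4_end\n")
        for pid, spans in domains.items():
            s2 = spans.get("sigma2", ("", ""))
            s4 = spans.get("sigma4", ("", ""))
            fh.write(f"{pid}\t{s2[0]}\t{s2[1]}\t{s4[0]}\t{s4[1]}\n")
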