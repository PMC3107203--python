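# corescan

Tools for predicting the regulon of an ECF sigma factor from a bipartite
promoter motif, and for characterizing the Cys-rich C-terminal domain (CRD)
that defines a group of metal-sensing ECF sigma factors:

* **genome_io** — FASTA/GFF3/GenBank reading, strand-aware upstream-region
  extraction (internal coordinates are 0-based half-open).
* **motif_model** — degenerate IUPAC consensus built from a promoter
  alignment, invariant columns, mismatch counting, per-column information
  content (sequence-logo data), and the bipartite −35/−10 model
  (consensus + spacer range + required −10 anchor base).
* **genome_scan** — exhaustive both-strand genome scanning within a mismatch
  budget, downstream-gene assignment, and a three-stage filter cascade
  (strand orientation → invariant −35 residues → −10 anchor at 16–18 nt
  spacer) producing a regulon report with per-stage counts.
* **crd_detector** — Cys census of C-terminal tails (after the σ4 domain, or
  a last-k fallback), proteome-wide census gated by a pairwise-similarity
  E-value, progressive CRD alignment, and column-conservation classes
  (invariant / conserved / functionally similar).
* **synteny** — gene-neighborhood extraction around anchor genes and greedy
  flank-protein matching between genomes, backed by an in-package
  Smith–Waterman similarity engine with a Karlin–Altschul-style E-value.
* **synthetic_data** — seeded generators that plant promoters (controlled
  mismatches/strand/spacer), decoy sites, CRD proteins and syntenic
  neighborhoods with full ground-truth bookkeeping, so every stage is
  testable end to end without downloads.

## Command line

```sh
corescan simulate --seed 5 --out-dir sim/            # synthetic dataset + truth
corescan build-motif --alignment promoters.fasta --out motif.json
corescan scan --genome genome.fasta --motif motif.json --out hits.tsv
corescan filter --hits hits.tsv --annotation genes.gff3 --motif motif.json \
    --max-distance 300 --out regulon.tsv --report report.json
corescan extract-upstream --genome genome.fasta --annotation genes.gff3 \
    --genes ids.txt --max-len 300 --out upstream.fasta
corescan crd --proteins proteome.fasta --domains domains.tsv \
    --query SIGMA_0000 --min-cys 4 --evalue 2e-10 --out crd.tsv
corescan align --proteins crds.fasta --out aligned.fasta
corescan conserve --alignment aligned.fasta --out columns.tsv
corescan synteny --annotation-a a.gff3 --proteins-a a.fasta --anchor-a geneA \
    --annotation-b b.gff3 --proteins-b b.fasta --anchor-b geneB --out synteny.tsv
```

`corescan filter` prints the per-stage counts as JSON; a candidate is final
only if it has a same-strand downstream gene within range, matches every
invariant −35 position, and has the −10 anchor within the spacer range.

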