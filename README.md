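# aatcensus

Census and comparison pipeline for amino-acid-transporter (AAT) gene
families in sap-feeding insects.  The package classifies candidate APC and
AAAP transporter transcripts from domain- and homology-hit tables, collapses
redundant transcripts (isoforms, fragments, allelic variants) into putative
representative loci, counts loci per taxon and family, and tests whether
galling versus free-living life history predicts the counts with
generalized least squares under a Brownian-motion tree covariance.

Everything runs offline: a synthetic-data module generates transcriptomes
with controlled isoform/paralog/contaminant structure (plus truth tables),
and a published per-taxon count table ships as a packaged fixture.

## What is implemented

- **`seqio`** — FASTA I/O with `id key=value` headers, six-frame longest-ORF
  finding (ATG-initiated, stop- or sequence-end-terminated), standard-code
  translation, affine-gap pairwise protein alignment (BLOSUM62, free end
  gaps) and codon back-translation.
- **`ks`** — Nei–Gojobori (1986) synonymous-rate calculator: per-codon site
  fractions, pathway-averaged difference counts, Jukes–Cantor correction
  `ks = -(3/4)·ln(1 - (4/3)·pS)`, with explicit `saturated` /
  `insufficient_overlap` statuses.
- **`classify`** — candidate selection: family domain hit (default Pfam
  accessions PF03024/PF01490, e-value < 1e-3), best-homology-hit
  verification (must be an APC/AAAP member from the required taxon group,
  default `hemiptera`), and a minimum-length ORF.
- **`coalesce`** — de novo locus collapsing (shared assembler component;
  pairwise Ks < 0.25; aligned overlap < 50 bp; transitive closure via
  union-find) and genome-guided collapsing (best mapping intervals sharing
  scaffold/strand within a 5 kb merge gap).  Every merge is logged with its
  reason.
- **`phylo`** — counts tables, integer-truncated group summaries, Newick
  parsing (dendropy), Brownian covariance from shared root-to-MRCA path
  lengths, and a whitening-based GLS fit with a nested-model F test.
- **`simulate`** — pure-birth trees, Brownian latent counts with a
  life-history shift, synthetic transcriptomes whose paralogs are diverged
  to measured Ks targets, mock hit tables consistent with truth, and
  reproducible on-disk bundles with manifests.
- **`cli`** — `aatcensus` command with `simulate`, `classify`, `coalesce`,
  `count`, `summarize`, `pgls`, and `run-all` subcommands.

## Command-line usage

```bash
# generate a synthetic input bundle (FASTA, hit tables, tree, labels, truth)
aatcensus simulate --out bundle/ --seed 1 --n-taxa 8

# run the whole analysis
aatcensus run-all \
    --fasta bundle/transcripts.fasta \
    --domains bundle/domain_hits.tsv \
    --blast bundle/blast_hits.tsv \
    --tree bundle/tree.nwk \
    --life-history bundle/life_history.tsv \
    --outdir results/

# stages can also be run individually:
aatcensus classify --fasta ... --domains ... --blast ... --out candidates.tsv
aatcensus coalesce --candidates candidates.tsv --out loci.tsv
aatcensus count --loci loci.tsv --life-history ... --out counts.tsv
aatcensus summarize --counts counts.tsv --out summary.tsv
aatcensus pgls --counts counts.tsv --tree tree.nwk --response total
```

Genome-guided collapsing: add `--mode genome --mapping mapping_hits.tsv`
(BLAST tabular; strand is derived from subject coordinates).

## Notes

- The fixture `aat_counts_published.tsv` stores per-family counts whose
  row totals are `apc + aaap`; group summaries truncate means toward zero
  and sum the truncated per-family means.
- The packaged `species_topology.nwk` carries unit branch lengths; it
  supports a direction-of-effect check, not magnitude reproduction, since
  real branch lengths are not distributed with the counts.
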