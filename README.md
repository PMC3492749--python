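# rmlstkit

Gene-by-gene ribosomal-protein MLST: a self-contained toolkit for
discovering, curating and indexing alleles of the 53 ribosomal-protein
loci in bacterial genome assemblies, building typing profiles, and
analysing them with standard phylogenetic and diversity statistics.

The core pieces:

- **`rmlstkit.scheme`** — locus catalogue plus a curated allele database
  (in-frame, internal-stop-free sequences only; stable sequential allele
  ids; per-locus FASTA persistence). Ships a default 53-locus catalogue.
- **`rmlstkit.search`** — seeded local-alignment search of contigs against
  allele collections. Nucleotide mode uses exact DNA word seeds (default
  word size 15) and an affine-gap local aligner (+1/−2, gap −5/−2);
  translated mode runs both sides in six reading frames with amino-acid
  word seeds and BLOSUM62 scoring.
- **`rmlstkit.tagger`** — the iterative, stringency-relaxing scanner: tag
  loci as complete / partial / missing / pseudogene, define new alleles
  from complete extractions, rescan to a fixpoint, relax identity from
  70% down to 50% in 5% steps, then repeat the loop in translated mode.
- **`rmlstkit.profiles`** — allelic profiles, rST assignment, profile
  comparison and corpus-level tagging summaries.
- **`rmlstkit.msa`** — codon-aware per-locus multiple alignment (protein
  level, back-translated so gaps are codon-sized), XMFA export/import,
  concatenation with per-column provenance.
- **`rmlstkit.phylo`** — p-distance with pairwise deletion,
  neighbour-joining, Newick output.
- **`rmlstkit.diversity`** — Hunter–Gaston discriminatory index, per-locus
  mean p-distance, Nei–Gojobori synonymous/nonsynonymous analysis with a
  codon-bootstrap Z-test of dN > dS.
- **`rmlstkit.synthgen`** — deterministic, seeded generator of schemes,
  evolved allele variants and fragmented genome assemblies with a
  ground-truth manifest; the test substrate for everything else.

## CLI

The `rmlst` entry point wires the modules into the genome → profile →
analysis workflow:

```sh
# make a synthetic corpus + seeded allele database
rmlst simulate --out sim --n-isolates 10 --n-loci 53 --divergence 20 --seed 1

# iterative allele discovery and tagging (augments the database)
rmlst discover --db sim/db --out run sim/*.fasta

# single-pass tagging against a fixed database
rmlst scan --db run/db --out tags.tsv sim/*.fasta

# profiles + rSTs, and a corpus tagging summary
rmlst profile --tags run/tags.tsv --scheme sim/scheme.tsv --out profiles.tsv
rmlst summary --tags run/tags.tsv --scheme sim/scheme.tsv --out summary.tsv

# per-locus codon alignments, concatenated NJ tree, diversity statistics
rmlst export-xmfa --db run/db --tags run/tags.tsv --out loci.xmfa
rmlst tree --xmfa loci.xmfa --out tree.nwk
rmlst stats --xmfa loci.xmfa --out stats.tsv --seed 1
```

Hit tables are tab-separated with a BLAST outfmt-6-like column order:
`locus, allele_id, contig, identity, aln_length, contig_start, contig_end,
allele_start, allele_end, strand, coverage, score, mode`. Coordinates are
0-based half-open on the contig forward strand; strand `-` means the
contig's reverse complement matches the allele. Tag tables carry
`isolate, locus, status, allele_id, contig, start, end, strand, flags,
phase, level`.

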