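# holoplast

Analysis toolkit for plastid genome degradation in holoparasitic plants.

Holoparasites have abandoned photosynthesis, and their chloroplast (plastid)
genomes decay accordingly: the genome shrinks, photosynthesis genes are
deleted or disabled, the quadripartite architecture (LSC / IRb / SSC / IRa)
rearranges, and fragments of the lost genes turn up — non-functionally — in
the mitochondrial and nuclear genomes. `holoplast` implements the
computational analyses needed to characterise such a genome end to end,
for researchers working on organellar genome evolution in parasitic
lineages:

- **Quadripartite structure** (`plastome_structure`): locates the maximal
  inverted-repeat pair and the two single-copy regions, summarises AT/GC
  composition, reports genes whose region assignment shifted against an
  autotrophic reference (IR expansion), and detects gene-order inversions
  as maximal reversed runs of a signed gene permutation.
- **Gene inventory** (`gene_inventory`): classifies each reference gene in
  a query genome as intact, pseudogene or lost. A pseudogene call carries
  its mechanism and 1-based codon index: a premature in-frame stop codon, a
  frameshifting indel (length ≢ 0 mod 3), or a 3′ truncation with no
  downstream similarity. Also builds cross-species gene-content matrices,
  audits pathway retention (e.g. the 63-gene photosynthesis pathway), and
  cross-checks transcriptome ratios against qPCR 2^−ΔΔCt fold changes.
- **Lost-gene localisation** (`igt_locator`): from genome-skimming paired
  reads, extracts plastid-like pairs by canonical k-mer matching against a
  bait panel of plastomes, assembles them with a de Bruijn graph, discards
  plastome-resident contigs (identity > 90% over the full contig length),
  annotates the rest by six-frame translated search against the reference
  plastid proteome (BLOSUM62, Karlin–Altschul E-values), and assigns each
  fragment to a compartment by sequencing depth — organellar copy-number
  ordering (plastid ≫ mitochondrial ≫ nuclear) makes mean read depth a
  genomic address. Depth over plastome-matching parts of a contig is
  masked, and fragments are screened against assembled transcripts for
  expression.
- **Selection relaxation** (`selection_relaxation`): Goldman–Yang (GY94)
  codon substitution model over the 61 sense codons with transition /
  transversion ratio κ, F3x4 codon frequencies and dN/dS ratio ω, fitted by
  maximum likelihood (Felsenstein pruning). Branch models M0 (one ω), M2
  (parasitic vs autotrophic ω) and M3 (holoparasitic / hemiparasitic /
  autotrophic ω) are compared with χ² likelihood-ratio tests,
  2Δℓ ~ χ²(df = Δ parameters).
- **Synthetic data** (`synthetic_data`): seeded generators for every input
  — a quadripartite plastome template with engineered deletions, premature
  stops, frameshifts, truncations and inversions; mito/nuclear backbones
  with inserted diverged gene fragments; error-bearing paired reads at
  configured copy numbers; transcripts; and codon alignments evolved under
  branch-specific ω — each with machine-readable ground truth.

## Worked example

Generate a degraded-plastome scenario and analyse its structure:

```bash
holoplast simulate --out-dir sim --seed 4 --n-fragments 4 \
    --mito-len 30000 --nuclear-len 50000
holoplast structure --genbank sim/plastome.gb --reference sim/reference.gb \
    --out struct.tsv
```

which prints

```
AT content: 49.74%
2 inversion segment(s): contains accD; contains rps15
```

and writes the region table (`struct.tsv`):

```
region  start   end     length  genome_length   at_percent
LSC     0       8758    8758    21683   49.74
IRb     8758    14760   6002    21683   49.74
```

The degraded genome keeps its quadripartite architecture (here a 21,683 bp
circle with 6,002 bp inverted repeats) and shows exactly the two engineered
inversions — one containing the intact `accD`, mirroring the rearrangement
pattern reported for real holoparasite plastomes. `holoplast inventory`
on the same pair prints `34 intact, 3 pseudogene, 27 lost`: the lost set is
the deleted photosynthesis genes, and the three pseudogenes carry their
engineered defects (ψatpI stop at codon 32, ψndhB stop at codon 53, ψatpA
truncated at codon 88). `holoplast igt` then recovers the planted
mitochondrial/nuclear fragments from the simulated reads, and
`holoplast selection` runs the M0/M2/M3 relaxation scan over a gene panel.

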