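# Methods

This note documents the models and procedures implemented in `holoplast`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open.

## Quadripartite structure detection

A plastome's inverted repeats are found by exact seeding: every k-mer
(default k = 25) of the circular sequence is matched against its reverse
complement, seed pairs are grouped by their anti-diagonal (constant for one
IR pair), and each group is extended ungapped in both directions. The
default mismatch tolerance is 0 (exact repeats); a `max_mismatch_frac` knob
admits greedy extension through mismatches with trailing mismatches
trimmed. The reported boundaries are maximal — extending either repeat end
by one base breaks the repeat — and the longest disjoint pair wins, ties
broken by leftmost start after canonical rotation (LSC start at index 0).
The two single-copy gaps become LSC (longer) and SSC (shorter); IRb is the
repeat following the LSC. Detection is rotation-invariant because
candidates are enumerated on the doubled sequence. Genomes shorter than two
minimum-length repeats, or lacking a qualifying pair, raise
`NoQuadripartite` so callers can treat the genome as IR-lacking.

AT/GC composition is computed over unambiguous A/C/G/T only; ambiguity
codes are counted and excluded.

### Region shifts and inversions

Genes are assigned to regions by majority span (circular-aware), with a
`boundary` flag when a gene straddles a region edge and a `duplicated` flag
when the query carries more copies than the reference (IR inclusion).

Gene order is compared as a signed permutation after collapsing IR
duplicates to the IRb copy (one occurrence per gene, stable rotation
starting at the LSC). An inversion segment is a maximal run of genes that
appear consecutively in reverse order and opposite strand relative to the
reference. The query is canonically rotated (and flipped if needed) to the
orientation that decomposes into the fewest reversal strips whose reversal
reproduces the reference order; if no rotation decomposes consistently
(complex rearrangements), the reversed runs of the unrotated query are
reported. Whole-genome alignment blocks (LCBs) are deliberately not
recomputed; the annotation-based analysis answers the same question —
how many reversed segments, and what they contain — without a genome
aligner.

## Gene-status classification

Each reference CDS (validated: in frame, start codon, terminal stop, no
internal stop; translation table 11 throughout, as appropriate for plastid
genes) is locally aligned to both strands of the query with the classic
nucleotide weights +2/−3, affine gaps −5/−2. Long targets are first scanned
for exact 13-mer anchors and the dynamic programming restricted to a window
around the densest anchor cluster; anchor-free queries fall back to a
score-only scan of both strands, and a best score under 50 is reported as
`lost` without traceback (no biologically meaningful hit can score that
low at the lost thresholds).

Terminal alignment blocks reachable only through an indel are kept only if
they score ≥ 15 on their own; this suppresses the chance "gap bridge" a
local aligner builds into downstream sequence when a few bases match by
accident, which otherwise misreports truncations as frameshifts and
inflates alignment ends.

Decision sequence:

1. no alignment with identity ≥ 60% covering ≥ 30% of the reference →
   **lost**;
2. first defect in alignment-column order:
   an indel run of length ≢ 0 mod 3 → **frameshift** at the codon holding
   the first reference base at/after the run; an in-frame stop codon in the
   aligned query before the reference's terminal stop → **premature stop**
   at that 1-based codon (the start codon is codon 1). Stops within the
   final 5% of codons are treated as terminal-stop drift and ignored
   (knob `terminal_stop_drift`);
3. alignment ending before 90% of the reference codons, with no rescue —
   the missing 3′ part must reappear within 2 kb downstream at ≥ 70%
   identity covering ≥ 40% of the missing part to rescue — → **truncation**
   at the last aligned codon + 1;
4. otherwise **intact**.

tRNA/rRNA genes use only identity and coverage (no frame logic). The
engineered-defect round-trip accuracy measured by the test suite is ≥ 95%
with exact codon indices; residual failures are chance-match overshoot of
a truncation junction by a full codon, and deletions engineered inside
reference homopolymer runs, where the gap position (hence the codon index)
is genuinely undefined — the generator therefore pins frameshifts to the
nearest unambiguous codon and records the pinned codon as truth.

Pathway audits are set arithmetic over a (pathway, gene, compartment) map;
qPCR fold changes are 2^−ΔΔCt with replicate Cts averaged first, and the
cross-check statistic is the squared Pearson correlation between log2 fold
changes and log2 transcriptome ratios over non-calibrator samples.

## Lost-gene localisation pipeline

Stages, each exposed as a function and chained by `run_igt_pipeline`:

1. **Extraction** — a read pair is retained when either mate shares ≥ 3
   canonical 31-mers with the bait plastome panel. This replaces an
   alignment-based read classifier with a self-contained k-mer test; its
   recall is validated against simulator truth (≥ 0.99 for plastid-derived
   and fragment-derived reads at the default divergence).
2. **Assembly** — de Bruijn graph on the 31-mers of both strands of the
   extracted reads. At each branching node, edges to children far below the
   best sibling's coverage (`edge_drop_frac`, default 0.15 of the best
   sibling, floor 1) are dropped; this clips error tips and pops
   single-mismatch bubbles in one pass, and residual same-length
   near-identical unitig twins are deduplicated by coverage. Unitigs below
   150 bp (the configured minimum contig length) are discarded. Tie-breaks
   are array-order deterministic, so assemblies are bit-reproducible.
3. **Depth re-mapping** — contig depths are recomputed from the *full*
   read set (not just extracted reads) by exact k-mer counting against
   contig k-mers, rescaled to read units by L/(L−k+1). Assembly-internal
   depths undercount fragment flanks, whose coverage comes mostly from
   mates of extracted pairs; compartment inference needs true backbone
   depth.
4. **Plastome filter** — best local alignment of each contig to the
   resident plastome; a contig is kept as a transfer candidate iff it has
   no hit, or identity ≤ 90% (inclusive), or the alignment is shorter than
   the contig. Contigs whose k-mers are ≥ 98% contained in the plastome
   are reported as full-length near-perfect hits without quadratic
   alignment (they can be tens of kilobases).
5. **Translated annotation** — six-frame translation, local BLOSUM62
   alignment (affine 11/1) against every reference plastid protein, scored
   with Karlin–Altschul E = K·m·n·e^(−λS) using the gapped BLOSUM62
   constants (λ = 0.267, K = 0.041) and the whole proteome as database
   size; best hit per contig at E ≤ 1e−5.
6. **Compartment assignment** — the plastid baseline is the
   length-weighted mean depth of plastome-resident contigs; the
   mitochondrial and nuclear baselines come from a deterministic 1-D
   k-means split of the remaining contigs' log10 depths (assembly debris
   below depth 2 ignored). A fragment's masked mean depth (plastome-hit
   intervals excluded when its gene is still plastome-resident) is
   assigned to the nearest baseline in log10 space; when the two nearest
   baselines are both within a factor of 3 the call is `ambiguous` rather
   than forced. Fragments at plastid-level depth are plastome remnants,
   not transfers, and are dropped from the call set. Explicit baselines or
   marker sequences override estimation.
7. **Expression** — a fragment is expressed iff some transcript carries a
   local alignment of ≥ 100 bp at ≥ 98% identity; expressed fragments are
   never counted as non-functional in the summary.

The per-gene summary assigns `both` when a gene has fragments in each
organellar compartment and marks genes still present in the resident
plastome. Paired-end insert parameters (350 ± 100) are carried in the
configuration for parity with the read simulator but deliberately unused
by assembly: unitig-level contigs suffice for fragment calls, and
scaffolding would add repeat-collapse failure modes without changing any
downstream decision.

## GY94 branch models

The codon substitution rate from codon *i* to *j* (single-nucleotide
changes only) is π_j, times κ for transitions, times ω for nonsynonymous
changes; each class's matrix is normalised to mean rate 1 so branch
lengths are expected substitutions per codon. Codon frequencies are F3x4
computed from the data (positional nucleotide frequencies, stops zeroed
and renormalised). The model is reversible, so P(t) comes from a symmetric
eigendecomposition, and the likelihood from Felsenstein pruning over
site-pattern-compressed columns with per-node rescaling; gap/ambiguous
codons are marginalised as missing data (all-ones partials).

Branch classes: M0 — one ω; M2 — parasitic (hemi + holo) foreground vs
autotrophic background; M3 — three classes. Tip classes come from a
sidecar mapping; an internal branch takes a class only when all its
descendant tips agree, else the autotrophic background. Branch lengths are
re-estimated under every model, together with the shared κ and per-class
ω, by L-BFGS-B on log parameters (ω ∈ [1e−4, 50], κ ∈ [0.1, 99], branch
lengths ∈ [1e−6, 20]), with 3 jittered restarts by default. A class whose
synonymous tree length (class branch length × synonymous rate fraction)
falls below 1e−4 has its ω flagged unavailable rather than reported.

`relaxation_scan` chains warm starts M0 → M2 → M3 with one restart per
model: initialising each alternative at the null's optimum guarantees the
nesting inequality lnL(M0) ≤ lnL(M2) ≤ lnL(M3) up to optimiser tolerance
and roughly halves the cost of a panel scan. LRTs use 2Δℓ against χ² with
df = the parameter-count difference (1 for both comparisons); a 2Δℓ below
−1e−4 is an optimiser failure, not evidence. Significance defaults to
α = 0.05 per comparison without multiple-testing correction;
Benjamini–Hochberg adjustment is available behind a flag but off by
default, matching common practice for these two planned comparisons.

## Synthetic data: what it emulates, and what it does not

The plastome template is a scaled-down quadripartite genome (≈ 34 kb; LSC
≈ 18 kb, IR ≈ 6 kb, SSC ≈ 4 kb) carrying a realistic plastid gene panel
(64 genes: rpl/rps, trn, rrn, ndh, psa, psb, pet, atp, rpo, accD, matK,
infA-like others) as random in-frame CDSs with random spacers; IRa is the
exact mirror of IRb, so edits to IR genes propagate to both copies. Region
junction bases are pinned so planted IR boundaries are maximal by
construction. Degradation edits (deletions, premature stops, frameshifts,
truncations, inversions) are applied at the element level and re-rendered,
and every edit is recorded as truth.

Transfer fragments are cut from the reference copies of lost genes in
disjoint within-gene windows (independently diverged copies of one gene
would otherwise share assembly k-mers and tangle the graph), mutated by
uniform substitutions to a drawn divergence (default 1–3%, consistent
with recent transfer and with the k-mer extraction sensitivity; lengths
log-normal, median ≈ 245 bp, floor 150 bp), and inserted at backbone
positions at least 2.5 kb apart so independent insertions cannot merge
into one chimeric contig. Defaults: mitochondrial backbone 300 kb, nuclear
2 Mb, copy numbers 500/50/5 (plastid/mito/nuclear — one order of magnitude
between compartments), 150 bp paired reads, insert 350 ± 100, 1%
substitution error, constant quality. The test suite runs the same
conditions on smaller backbones (tens of kilobases) to keep runtimes in
minutes; depth ratios, read geometry and error rate are unchanged.

Codon alignments are evolved by drawing the root from the F3x4 stationary
distribution (AT-rich positional frequencies by default) and sampling each
child from the exact transition matrix P(t) of its branch's class —
distributionally identical to simulating the jump process, and faster.

Not emulated: indel divergence in transfers (substitution-only keeps
identity oracles exact; a frameshift knob exists at the edit level),
empirical quality profiles, transcript abundance, heteroplasmy, and
repeat-rich backbone structure. Passing tests therefore show the pipeline
recovers transfers under clean copy-number separation and modest
divergence; they do not show robustness to repeat-mediated misassembly or
to compartments whose depths overlap (the pipeline reports `ambiguous`
there, by design).

## Numerical choices and degenerate inputs

- All internal coordinates are 0-based half-open; an interval with
  end ≤ start wraps the origin of a circular genome. GenBank's 1-based
  inclusive coordinates are converted on read and restored on write.
- IUPAC ambiguity codes are preserved on read and score as mismatches in
  every aligner.
- Baseline estimation refuses unimodal depth distributions and demands
  explicit baselines; compartment assignment refuses non-positive depths;
  an entirely masked contig raises `AmbiguousDepth` and the call becomes
  `ambiguous`.
- Assembly requires odd k (default 31); empty read sets yield empty
  contig lists, not errors.
- Optimiser non-convergence is flagged on the fit (`converged=False`)
  rather than raised; saturated ω classes are flagged unavailable.
- Every generator is a pure function of (config, seed); derived seeds stay
  below 2^31.

## Known limitations

- The inversion decomposition targets disjoint reversal segments (the
  relevant regime for plastomes); overlapping-reversal histories fall back
  to reporting reversed runs without reconstructing the event order.
- Karlin–Altschul parameters are the standard gapped BLOSUM62 constants,
  not re-estimated per scoring system.
- The k-mer extraction stage is calibrated for transfers ≲ 5% diverged
  from some bait; anciently transferred, highly diverged fragments would
  need a smaller k or an alignment-based extractor.
- Compartment assignment assumes the copy-number ordering holds; tissues
  or taxa where mitochondrial and nuclear depths overlap within a doubling
  will yield mostly `ambiguous` calls.
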