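"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the study system: a circular quadripartite plastome
with engineered gene deletions, pseudogenising edits and inversions;
mitochondrial and nuclear backbones carrying inserted fragments of the lost
plastid genes at distinct copy numbers (plastid >> mitochondrial >>
nuclear); error-bearing paired short reads; transcript sets; and codon
alignments evolved under branch-specific omega. Every generator is a pure
function of (config, seed) and records machine-readable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import AnnotatedGenome, GeneFeature, ReadPair, revcomp
from . import selection_relaxation as sel

_NUCS = np.frombuffer(b"ACGT", dtype=np.uint8)
_SENSE = [c for c in sel.SENSE_CODONS]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return bytes(_NUCS[rng.integers(0, 4, size=length)]).decode()


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """In-frame CDS: ATG + random sense codons + TAA, ``length`` nt total."""
    if length % 3 or length < 9:
        raise ValueError(f"CDS length {length} must be a multiple of 3, >= 9")
    n_mid = length // 3 - 2
    mid = "".join(_SENSE[i] for i in rng.integers(0, len(_SENSE), size=n_mid))
    return "ATG" + mid + "TAA"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PanelGene:
    name: str
    kind: str        # CDS | tRNA | rRNA
    length: int      # nt (CDS includes start and stop codons)
    region: str      # LSC | IR | SSC


def default_gene_panel() -> list[PanelGene]:
    """A scaled-down but structurally faithful plastid gene panel."""
    lsc_cds = [("psbA", 450), ("matK", 600), ("rps16", 300), ("atpA", 600),
               ("atpF", 300), ("atpH", 246), ("atpI", 450), ("rps2", 450),
               ("rpoC1", 600), ("rpoB", 600), ("petB", 300), ("psbD", 450),
               ("psbC", 600), ("psaA", 600), ("psaB", 600), ("ycf3", 300),
               ("rps4", 450), ("ndhJ", 300), ("ndhC", 300), ("atpE", 300),
               ("atpB", 600), ("rbcL", 600), ("accD", 450), ("petA", 450),
               ("psbE", 252), ("psbJ", 150), ("rps18", 300), ("rpl20", 300),
               ("clpP", 450), ("psbB", 600), ("rpl16", 360), ("rps3", 450),
               ("rpl22", 300), ("rps19", 279), ("rps8", 300), ("rpl14", 300)]
    ir = [("rpl2", "CDS", 600), ("rpl23", "CDS", 282), ("ndhB", "CDS", 600),
          ("rps7", "CDS", 450), ("rps12", "CDS", 372), ("ycf2", "CDS", 600),
          ("ycf1", "CDS", 600), ("rrn16", "rRNA", 500), ("rrn23", "rRNA", 800),
          ("rrn4.5", "rRNA", 120), ("rrn5", "rRNA", 120),
          ("trnL-CAA", "tRNA", 75), ("trnN-GUU", "tRNA", 72)]
    ssc = [("ndhF", "CDS", 600), ("ccsA", "CDS", 450), ("ndhD", "CDS", 450),
           ("psaC", "CDS", 246), ("ndhE", "CDS", 306), ("ndhA", "CDS", 600),
           ("ndhH", "CDS", 600), ("rps15", "CDS", 273),
           ("trnL-UAG", "tRNA", 75)]
    trn_lsc = [("trnH-GUG", 75), ("trnK-UUU", 75), ("trnQ-UUG", 72),
               ("trnC-GCA", 72), ("trnD-GUC", 74), ("trnE-UUC", 73)]
    panel = [PanelGene(n, "CDS", l, "LSC") for n, l in lsc_cds]
    panel += [PanelGene(n, "tRNA", l, "LSC") for n, l in trn_lsc]
    panel += [PanelGene(n, k, l, "IR") for n, k, l in ir]
    panel += [PanelGene(n, k, l, "SSC") for n, k, l in ssc]
    return panel


@dataclass
class Edit:
    """One engineered degradation event."""

    kind: str                    # delete | premature_stop | frameshift | truncation | inversion
    gene: str | None = None
    codon: int | None = None     # 1-based, counting the start codon as 1
    genes: list[str] | None = None  # consecutive run for an inversion


@dataclass
class FragmentSpec:
    gene: str
    compartment: str                  # mitochondrial | nuclear
    length: int | None = None         # drawn if None
    divergence: float | None = None   # drawn if None
    source_offset: int | None = None  # within-gene start; placed if None


@dataclass
class TransferSpec:
    fragments: list[FragmentSpec] = field(default_factory=list)
    n_fragments: int = 0              # used when fragments is empty
    length_log_mu: float = 5.5        # log bp (median ~245 bp)
    length_log_sigma: float = 0.6
    min_length: int = 150
    divergence_range: tuple[float, float] = (0.01, 0.03)
    compartment_weights: tuple[float, float] = (0.5, 0.5)  # mito, nuclear
    min_insertion_spacing: int = 2500  # bp between inserts in one backbone


@dataclass
class ReadSpec:
    read_len: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 100.0
    error_rate: float = 0.01
    quality_char: str = "I"


@dataclass
class CodonSimSpec:
    kappa: float = 2.0
    omega_by_class: dict = field(default_factory=lambda: {
        "autotrophic": 0.2, "hemiparasitic": 0.2, "holoparasitic": 0.2})
    n_codons: int = 500
    # AT-rich positional nucleotide frequencies (plastid-like)
    positional_freqs: tuple = ((0.30, 0.18, 0.20, 0.32),) * 3


@dataclass
class SimConfig:
    seed: int = 0
    panel: list[PanelGene] = field(default_factory=default_gene_panel)
    spacer_range: tuple[int, int] = (30, 80)
    edits: list[Edit] = field(default_factory=list)
    transfer: TransferSpec = field(default_factory=TransferSpec)
    copy_numbers: tuple[float, float, float] = (500.0, 50.0, 5.0)  # plastid, mito, nuclear
    reads: ReadSpec = field(default_factory=ReadSpec)
    mito_len: int = 300_000
    nuclear_len: int = 2_000_000
    codon: CodonSimSpec = field(default_factory=CodonSimSpec)

    def __post_init__(self) -> None:
        p, m, n = self.copy_numbers
        if not (p >= m >= n > 0):
            raise ValueError("copy numbers must satisfy plastid >= mito >= nuclear > 0")
        if not 0.0 <= self.reads.error_rate <= 1.0:
            raise ValueError("error rate outside [0,1]")


@dataclass
class TruthFragment:
    fragment_id: str
    gene: str
    compartment: str
    length: int
    divergence: float
    n_substitutions: int
    source_offset: int            # within the source gene CDS
    insertion_pos: int            # in the final backbone coordinates
    sequence: str


@dataclass
class SimulationTruth:
    """Ground truth of every engineered event, for scoring downstream stages."""

    gene_status: dict[str, tuple[str, str, int]] = field(default_factory=dict)
    # gene -> (status, reason, codon_index)
    inversions: list[list[str]] = field(default_factory=list)
    fragments: list[TruthFragment] = field(default_factory=list)
    reference: AnnotatedGenome | None = None
    branch_omega: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Plastome layout
# ---------------------------------------------------------------------------

@dataclass
class _Element:
    kind: str                 # spacer | gene
    seq: str
    name: str = ""
    feature_kind: str = ""    # CDS/tRNA/rRNA/pseudogene for genes
    strand: str = "+"


class _Layout:
    """Editable element lists for LSC, IR (single master copy) and SSC."""

    def __init__(self, regions: dict[str, list[_Element]]):
        self.regions = regions  # keys LSC, IR, SSC

    def find_gene(self, name: str) -> tuple[str, int]:
        for region, elems in self.regions.items():
            for i, e in enumerate(elems):
                if e.kind == "gene" and e.name == name:
                    return region, i
        raise KeyError(f"gene {name!r} not in layout")

    def render(self) -> tuple[str, list[GeneFeature]]:
        """Concatenate LSC | IRb | SSC | IRa with mirrored IR annotation."""
        parts: dict[str, tuple[str, list[tuple[int, int, _Element]]]] = {}
        for region in ("LSC", "IR", "SSC"):
            seq_parts, feats, pos = [], [], 0
            for e in self.regions[region]:
                if e.kind == "gene":
                    feats.append((pos, pos + len(e.seq), e))
                seq_parts.append(e.seq)
                pos += len(e.seq)
            seq = "".join(seq_parts)
            # pin region-junction bases so planted IR boundaries are maximal
            if region in ("LSC", "SSC") and len(seq) >= 2:
                seq = "A" + seq[1:-1] + "A"
            parts[region] = (seq, feats)

        lsc_seq, lsc_feats = parts["LSC"]
        ir_seq, ir_feats = parts["IR"]
        ssc_seq, ssc_feats = parts["SSC"]
        off_irb = len(lsc_seq)
        off_ssc = off_irb + len(ir_seq)
        off_ira = off_ssc + len(ssc_seq)
        total = off_ira + len(ir_seq)

        features: list[GeneFeature] = []
        for s, e, el in lsc_feats:
            features.append(GeneFeature(el.name, el.feature_kind, [(s, e)],
                                        el.strand))
        for s, e, el in ir_feats:  # IRb copy
            features.append(GeneFeature(el.name, el.feature_kind,
                                        [(off_irb + s, off_irb + e)], el.strand))
        for s, e, el in ssc_feats:
            features.append(GeneFeature(el.name, el.feature_kind,
                                        [(off_ssc + s, off_ssc + e)], el.strand))
        ira_seq = revcomp(ir_seq)
        for s, e, el in ir_feats:  # mirrored IRa copy
            ms, me = len(ir_seq) - e, len(ir_seq) - s
            strand = "-" if el.strand == "+" else "+"
            features.append(GeneFeature(el.name, el.feature_kind,
                                        [(off_ira + ms, off_ira + me)], strand))
        genome_seq = lsc_seq + ir_seq + ssc_seq + ira_seq
        assert len(genome_seq) == total
        return genome_seq, features


def _build_layout(config: SimConfig, rng: np.random.Generator) -> _Layout:
    lo, hi = config.spacer_range
    regions: dict[str, list[_Element]] = {"LSC": [], "IR": [], "SSC": []}
    for region in regions:
        regions[region].append(_Element("spacer", _random_dna(rng, int(rng.integers(lo, hi)))))
    for g in config.panel:
        if g.kind == "CDS":
            seq = _random_cds(rng, g.length)
        else:
            seq = _random_dna(rng, g.length)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            placed = revcomp(seq)
        else:
            placed = seq
        regions[g.region].append(_Element("gene", placed, g.name, g.kind, strand))
        regions[g.region].append(
            _Element("spacer", _random_dna(rng, int(rng.integers(lo, hi)))))
    return _Layout(regions)


def _coding_seq(el: _Element) -> str:
    return revcomp(el.seq) if el.strand == "-" else el.seq


def _set_coding_seq(el: _Element, coding: str) -> None:
    el.seq = revcomp(coding) if el.strand == "-" else coding


def _pin_frameshift_position(coding: str, codon: int) -> tuple[int, int]:
    """Base whose deletion is positionally unambiguous, near the codon.

    Deleting a base inside a homopolymer run leaves the gap placement (and
    hence the reported codon) undefined, so the requested codon is shifted
    to the nearest codon holding a base that differs from both neighbours.
    Returns (position, actual codon).
    """
    n_codons = len(coding) // 3
    for delta in range(n_codons):
        for c in (codon + delta, codon - delta):
            if not 2 <= c <= n_codons - 1:
                continue
            base0 = 3 * (c - 1)
            for off in (1, 0, 2):
                p = base0 + off
                if 0 < p < len(coding) - 1 and coding[p] != coding[p - 1] \
                        and coding[p] != coding[p + 1]:
                    return p, c
    raise ValueError("no unambiguous frameshift position in gene")


def simulate_degraded_plastome(config: SimConfig
                               ) -> tuple[AnnotatedGenome, SimulationTruth]:
    """Apply the configured degradation edits to a quadripartite template.

    Returns the degraded genome and the truth record; the un-edited
    reference genome (same seed, same layout) is attached to the truth as
    ``truth.reference``. Edits to IR genes are applied to the master IR copy
    and mirror automatically into both repeats.
    """
    rng = np.random.default_rng(config.seed)
    ref_layout = _build_layout(config, rng)
    ref_seq, ref_feats = ref_layout.render()
    reference = AnnotatedGenome("simref", ref_seq, True, ref_feats)

    # re-build an identical layout to edit (same seed stream)
    rng2 = np.random.default_rng(config.seed)
    layout = _build_layout(config, rng2)

    truth = SimulationTruth(reference=reference)
    panel_by_name = {g.name: g for g in config.panel}
    for g in config.panel:
        truth.gene_status[g.name] = ("intact", "none", 0)

    for edit in config.edits:
        if edit.kind == "inversion":
            _apply_inversion(layout, edit.genes or [])
            truth.inversions.append(list(edit.genes or []))
            continue
        if edit.gene is None or edit.gene not in panel_by_name:
            raise ValueError(f"edit references unknown gene {edit.gene!r}")
        region, idx = layout.find_gene(edit.gene)
        el = layout.regions[region][idx]
        if edit.kind == "delete":
            layout.regions[region].pop(idx)
            truth.gene_status[edit.gene] = ("lost", "none", 0)
            continue
        coding = _coding_seq(el)
        n_codons = len(coding) // 3
        if edit.codon is None or not 1 <= edit.codon <= n_codons:
            raise ValueError(f"edit codon {edit.codon} outside gene {edit.gene} "
                             f"({n_codons} codons)")
        if edit.kind == "premature_stop":
            b = 3 * (edit.codon - 1)
            coding = coding[:b] + "TAA" + coding[b + 3:]
            truth.gene_status[edit.gene] = ("pseudogene", "premature_stop",
                                            edit.codon)
        elif edit.kind == "frameshift":
            p, actual_codon = _pin_frameshift_position(coding, edit.codon)
            coding = coding[:p] + coding[p + 1:]
            truth.gene_status[edit.gene] = ("pseudogene", "frameshift",
                                            actual_codon)
        elif edit.kind == "truncation":
            coding = coding[:3 * (edit.codon - 1)]
            truth.gene_status[edit.gene] = ("pseudogene", "truncation",
                                            edit.codon)
        else:
            raise ValueError(f"unknown edit kind {edit.kind!r}")
        _set_coding_seq(el, coding)
        el.feature_kind = "pseudogene"

    seq, feats = layout.render()
    degraded = AnnotatedGenome("simquery", seq, True, feats)
    return degraded, truth


def _apply_inversion(layout: _Layout, genes: list[str]) -> None:
    if not genes:
        raise ValueError("inversion needs a gene run")
    region, first = layout.find_gene(genes[0])
    region2, last = layout.find_gene(genes[-1])
    if region2 != region:
        raise ValueError("inversion run crosses region boundaries")
    if first > last:
        first, last = last, first
    elems = layout.regions[region]
    run_names = [e.name for e in elems[first:last + 1] if e.kind == "gene"]
    if run_names != list(genes) and run_names != list(reversed(genes)):
        raise ValueError(f"genes {genes} are not a consecutive run (found {run_names})")
    block = elems[first:last + 1]
    inverted = []
    for e in reversed(block):
        seq = revcomp(e.seq)
        strand = e.strand
        if e.kind == "gene":
            strand = "-" if e.strand == "+" else "+"
        inverted.append(_Element(e.kind, seq, e.name, e.feature_kind, strand))
    layout.regions[region][first:last + 1] = inverted


# ---------------------------------------------------------------------------
# Transfer genomes
# ---------------------------------------------------------------------------

def _mutate(seq: str, n_sub: int, rng: np.random.Generator) -> str:
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    for p in positions:
        old = lut[codes[p]]
        new = (old + int(rng.integers(1, 4))) % 4
        codes[p] = _NUCS[new]
    return bytes(codes).decode()


def _spaced_positions(rng: np.random.Generator, length: int, n: int,
                      spacing: int) -> np.ndarray:
    """Sorted insertion positions at least ``spacing`` bp apart.

    Keeps inserted fragments from sharing flank reads, which would merge
    independent transfer events into one chimeric contig.
    """
    if n == 0:
        return np.empty(0, dtype=int)
    if (n - 1) * spacing >= length:
        raise ValueError(f"backbone of {length} bp cannot hold {n} inserts "
                         f"spaced {spacing} bp apart")
    for _ in range(500):
        pos = np.sort(rng.integers(0, length, size=n))
        if n == 1 or np.diff(pos).min() >= spacing:
            return pos
    # fall back to jittered even spacing
    slot = length // n
    jitter = rng.integers(0, max(1, slot - spacing), size=n)
    return np.arange(n) * slot + jitter


def simulate_transfer_genomes(reference: AnnotatedGenome, lost_genes: list[str],
                              config: SimConfig, seed_offset: int = 1
                              ) -> tuple[AnnotatedGenome, AnnotatedGenome,
                                         list[TruthFragment]]:
    """Random mito/nuclear backbones with inserted lost-gene fragments.

    Fragments are cut from the reference copies of genes marked lost, drawn
    from disjoint within-gene windows (so independently diverged copies of
    one gene share no assembly k-mers), mutated to their divergence by
    uniform substitutions, and inserted at random backbone positions.
    """
    rng = np.random.default_rng((config.seed + 7919 * seed_offset) % 2**31)
    spec = config.transfer
    fragments = list(spec.fragments)
    if not fragments:
        comps = rng.choice(["mitochondrial", "nuclear"], size=spec.n_fragments,
                           p=np.array(spec.compartment_weights)
                           / sum(spec.compartment_weights))
        fragments = [FragmentSpec(gene="", compartment=c) for c in comps]

    gene_seqs = {}
    for name in lost_genes:
        feat = reference.feature_by_name(name)
        gene_seqs[name] = reference.feature_sequence(feat)
    next_offset = dict.fromkeys(gene_seqs, 0)

    resolved: list[TruthFragment] = []
    gene_cycle = sorted(gene_seqs)
    g_idx = 0
    for i, frag in enumerate(fragments):
        gene = frag.gene
        length = frag.length or int(np.clip(
            round(float(rng.lognormal(spec.length_log_mu, spec.length_log_sigma))),
            spec.min_length, None))
        if not gene:
            # next gene with room for a disjoint window of this length
            for _ in range(len(gene_cycle)):
                cand = gene_cycle[g_idx % len(gene_cycle)]
                g_idx += 1
                if len(gene_seqs[cand]) - next_offset[cand] >= spec.min_length:
                    gene = cand
                    break
            else:
                raise ValueError("no lost gene has room for another fragment")
        if gene not in gene_seqs:
            raise ValueError(f"fragment gene {gene!r} is not a lost gene")
        avail = len(gene_seqs[gene]) - (frag.source_offset
                                        if frag.source_offset is not None
                                        else next_offset[gene])
        length = min(length, avail)
        if length > len(gene_seqs[gene]):
            raise ValueError(f"fragment longer than source gene {gene}")
        if length < spec.min_length:
            length = min(spec.min_length, len(gene_seqs[gene]))
        offset = (frag.source_offset if frag.source_offset is not None
                  else next_offset[gene])
        if offset + length > len(gene_seqs[gene]):
            offset = max(0, len(gene_seqs[gene]) - length)
        if frag.source_offset is None:
            next_offset[gene] = offset + length
        divergence = frag.divergence if frag.divergence is not None else \
            float(rng.uniform(*spec.divergence_range))
        n_sub = int(round(divergence * length))
        source = gene_seqs[gene][offset:offset + length]
        mutated = _mutate(source, n_sub, rng) if n_sub else source
        resolved.append(TruthFragment(
            fragment_id=f"frag{i}", gene=gene, compartment=frag.compartment,
            length=length, divergence=divergence, n_substitutions=n_sub,
            source_offset=offset, insertion_pos=-1, sequence=mutated))

    genomes = {}
    for comp, length, label in (("mitochondrial", config.mito_len, "simmito"),
                                ("nuclear", config.nuclear_len, "simnuc")):
        backbone = _random_dna(rng, length)
        inserts = [f for f in resolved if f.compartment == comp]
        positions = _spaced_positions(rng, length, len(inserts),
                                      spec.min_insertion_spacing)
        pieces, prev, offset_acc = [], 0, 0
        for frag, pos in zip(inserts, positions):
            pieces.append(backbone[prev:pos])
            frag.insertion_pos = int(pos) + offset_acc
            pieces.append(frag.sequence)
            offset_acc += frag.length
            prev = pos
        pieces.append(backbone[prev:])
        genomes[comp] = AnnotatedGenome(label, "".join(pieces), False, [])
    return genomes["mitochondrial"], genomes["nuclear"], resolved


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def simulate_reads(genomes_with_copy_numbers: list[tuple[AnnotatedGenome, float, str]],
                   config: SimConfig, seed_offset: int = 2) -> list[ReadPair]:
    """Paired-end reads at per-genome depth = copy number, with errors.

    Pair counts are proportional to copy number x genome length; the insert
    is Normal(mean, sd) truncated at twice the read length; substitution
    errors occur at the configured rate; ids encode the truth compartment
    label and pair index. Deterministic for a fixed seed.
    """
    rs = config.reads
    rng = np.random.default_rng((config.seed + 104729 * seed_offset) % 2**31)
    pairs: list[ReadPair] = []
    qual = rs.quality_char * rs.read_len
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    for genome, depth, label in genomes_with_copy_numbers:
        n = len(genome.sequence)
        n_pairs = int(round(depth * n / (2.0 * rs.read_len)))
        if n_pairs <= 0:
            raise ValueError(f"{label}: depth {depth} yields zero read pairs")
        circular = genome.circular
        seq = genome.sequence + (genome.sequence[:2000] if circular else "")
        codes = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
        inserts = np.clip(rng.normal(rs.insert_mean, rs.insert_sd, size=n_pairs),
                          2 * rs.read_len, None).astype(int)
        max_start = n if circular else max(1, n - int(inserts.max()))
        starts = rng.integers(0, max_start, size=n_pairs)
        for i in range(n_pairs):
            s, ins = int(starts[i]), int(inserts[i])
            if not circular and s + ins > n:
                ins = n - s
            frag = codes[s:s + ins]
            if len(frag) < 2 * rs.read_len:  # circular wrap beyond pad
                frag = np.concatenate([frag, codes[:2 * rs.read_len - len(frag)]])
            r1 = frag[:rs.read_len].copy()
            r2 = (3 - frag[-rs.read_len:][::-1]).copy()
            if rs.error_rate > 0:
                for r in (r1, r2):
                    errs = rng.random(rs.read_len) < rs.error_rate
                    n_err = int(errs.sum())
                    if n_err:
                        r[errs] = (r[errs] + rng.integers(1, 4, size=n_err)) % 4
            pairs.append(ReadPair(f"{label}:{i}",
                                  bytes(_NUCS[r1]).decode(),
                                  bytes(_NUCS[r2]).decode(), qual, qual))
    return pairs


# ---------------------------------------------------------------------------
# Transcripts
# ---------------------------------------------------------------------------

def simulate_transcripts(expressed_genes: list[str], genome: AnnotatedGenome,
                         config: SimConfig,
                         planted_fragments: list[str] | None = None,
                         seed_offset: int = 3) -> list[tuple[str, str]]:
    """Transcripts = expressed gene sequences, plus optional positive
    controls carrying a planted fragment inside random UTR-like flanks."""
    rng = np.random.default_rng((config.seed + 15485863 * seed_offset) % 2**31)
    transcripts = []
    for name in expressed_genes:
        feat = genome.feature_by_name(name)
        transcripts.append((f"tx_{name}", genome.feature_sequence(feat)))
    for i, frag in enumerate(planted_fragments or []):
        left = _random_dna(rng, int(rng.integers(50, 150)))
        right = _random_dna(rng, int(rng.integers(50, 150)))
        transcripts.append((f"tx_planted_{i}", left + frag + right))
    return transcripts


# ---------------------------------------------------------------------------
# Codon alignments under branch-specific omega
# ---------------------------------------------------------------------------

def simulate_codon_alignment(tree, spec: CodonSimSpec, seed: int = 0
                             ) -> tuple[sel.CodonAlignment, SimulationTruth]:
    """Evolve codons along the tree under GY94 with per-branch-class omega.

    The root sequence is drawn from the F3x4 stationary distribution; each
    branch applies the exact transition matrix P(t) of its class's rate
    matrix (equivalent in distribution to simulating the jump process).
    """
    if spec.n_codons <= 0:
        raise ValueError("zero codon count")
    rng = np.random.default_rng(seed % 2**31)
    pi = sel.f3x4_frequencies(np.array(spec.positional_freqs))
    omegas = dict(spec.omega_by_class)
    eigs = {cls: sel._EigenQ(sel.rate_matrix(spec.kappa, w, pi), pi)
            for cls, w in omegas.items()}

    if not tree.classes_assigned():
        tree.assign_branch_classes(
            {t: "autotrophic" for t in tree.tip_labels()})

    root = tree.tree.seed_node
    states = {id(root): rng.choice(sel.N_CODONS, size=spec.n_codons, p=pi)}
    rows: dict[str, str] = {}
    truth = SimulationTruth()
    for node in tree.tree.preorder_node_iter():
        if node is root:
            pass
        else:
            t = node.edge.length or 0.0
            cls = tree.node_classes.get(node, "autotrophic")
            truth.branch_omega[tree_label(node)] = omegas[cls]
            parent_states = states[id(node.parent_node)]
            if t <= 0:
                child = parent_states.copy()
            else:
                p = eigs[cls].expm(t)
                cum = np.cumsum(p, axis=1)
                u = rng.random(spec.n_codons)
                child = np.empty(spec.n_codons, dtype=int)
                for s in np.unique(parent_states):
                    mask = parent_states == s
                    child[mask] = np.searchsorted(cum[s], u[mask], side="right")
                child = np.clip(child, 0, sel.N_CODONS - 1)
            states[id(node)] = child
        if node.is_leaf():
            codons = states[id(node)]
            rows[node.taxon.label] = "".join(sel.SENSE_CODONS[s] for s in codons)
    taxa = list(rows)
    return sel.CodonAlignment(taxa, [rows[t] for t in taxa]), truth


def tree_label(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return "|".join(sorted(l.taxon.label for l in node.leaf_iter()))


# ---------------------------------------------------------------------------
# Whole-scenario convenience
# ---------------------------------------------------------------------------

@dataclass
class IgtScenario:
    reference: AnnotatedGenome
    degraded: AnnotatedGenome
    mito: AnnotatedGenome
    nuclear: AnnotatedGenome
    reads: list[ReadPair]
    transcripts: list[tuple[str, str]]
    truth: SimulationTruth


def default_degradation_edits() -> list[Edit]:
    """Degradation mirroring the study system: loss of photosynthesis genes,
    three pseudogenes with stated defect codons, and two inversions."""
    lost = ["psbA", "psbC", "psbD", "psbB", "psbE", "psbJ", "psaA", "psaB",
            "psaC", "petA", "petB", "rbcL", "ycf3", "ndhA", "ndhC", "ndhD",
            "ndhE", "ndhF", "ndhH", "ndhJ", "rpoB", "rpoC1", "atpB", "atpE",
            "atpF", "atpH", "ccsA"]
    # inversions first: after the deletions, the visible reversed runs are
    # a segment containing the intact accD and a segment in the SSC
    edits = [Edit("inversion", genes=["atpB", "rbcL", "accD", "petA"]),
             Edit("inversion", genes=["ndhA", "ndhH", "rps15"])]
    edits += [Edit("delete", g) for g in lost]
    edits.append(Edit("truncation", "atpA", codon=88))
    edits.append(Edit("premature_stop", "atpI", codon=32))
    edits.append(Edit("premature_stop", "ndhB", codon=53))
    return edits


def simulate_igt_scenario(config: SimConfig,
                          expressed_genes: list[str] | None = None,
                          planted_transcript_fragments: list[str] | None = None
                          ) -> IgtScenario:
    """Full study-shaped scenario: degraded plastome, transfer genomes,
    mixed-compartment reads and transcripts, with complete truth."""
    degraded, truth = simulate_degraded_plastome(config)
    lost = sorted(g for g, (st, _, _) in truth.gene_status.items()
                  if st == "lost")
    mito, nuclear, fragments = simulate_transfer_genomes(
        truth.reference, lost, config)
    truth.fragments = fragments
    cp, cm, cn = config.copy_numbers
    reads = simulate_reads([(degraded, cp, "plastid"), (mito, cm, "mito"),
                            (nuclear, cn, "nuclear")], config)
    expressed = expressed_genes if expressed_genes is not None else \
        [g for g, (st, _, _) in truth.gene_status.items() if st == "intact"][:10]
    transcripts = simulate_transcripts(expressed, truth.reference, config,
                                       planted_transcript_fragments)
    return IgtScenario(truth.reference, degraded, mito, nuclear, reads,
                       transcripts, truth)
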