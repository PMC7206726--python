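"""Quadripartite plastome architecture and rearrangement analysis.

Plastomes of photosynthetic plants carry two large inverted repeats (IRa,
IRb) separating a large and a small single-copy region (LSC, SSC). In
degraded plastomes of holoparasites these regions shrink or expand and the
gene order rearranges; this module locates the four regions, summarises
nucleotide composition, reports genes whose region assignment shifted
relative to a reference, and detects gene-order inversions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import AnnotatedGenome, GeneFeature, revcomp

_PAIR = {"A": "T", "C": "G", "G": "C", "T": "A"}


class NoQuadripartite(ValueError):
    """No inverted-repeat pair of the required size exists."""


@dataclass
class QuadripartiteStructure:
    """LSC/IRb/SSC/IRa intervals (0-based half-open, circular) and lengths."""

    genome_id: str
    regions: dict[str, tuple[int, int]]  # keys LSC, IRb, SSC, IRa
    lengths: dict[str, int]
    genome_length: int

    def __post_init__(self) -> None:
        if sum(self.lengths.values()) != self.genome_length:
            raise ValueError("region lengths do not sum to genome length")
        if self.lengths["IRa"] != self.lengths["IRb"]:
            raise ValueError("IR copies differ in length")
        if self.lengths["LSC"] < self.lengths["SSC"]:
            raise ValueError("LSC shorter than SSC")


@dataclass
class CompositionSummary:
    at_fraction: float
    gc_fraction: float
    counted_bases: int
    ambiguous_excluded: int

    @property
    def at_percent(self) -> float:
        return 100.0 * self.at_fraction


@dataclass
class InversionSegment:
    """A maximal run of genes reversed (order and strand) vs the reference."""

    genes: list[str]
    query_span: tuple[int, int]  # index span in the query order, half-open
    note: str = ""

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# IR detection
# ---------------------------------------------------------------------------

def _extend_ir(s2: str, n: int, i0: int, i1: int, j0: int, j1: int,
               max_mismatch_frac: float) -> tuple[int, int, int, int]:
    """Extend an inverted-repeat seed maximally.

    Arms are ``s2[i0:i1]`` and ``s2[j0:j1]`` with the second the reverse
    complement of the first. Outward extension grows (i0--, j1++), inward
    extension grows (i1++, j0--). Ambiguity codes never match. With a
    nonzero mismatch budget extension is greedy and trailing mismatches are
    trimmed.
    """
    mismatches = 0

    def budget_ok(extra: int, arm_len: int) -> bool:
        if max_mismatch_frac == 0.0:
            return False
        return (mismatches + extra) <= max_mismatch_frac * arm_len

    # outward then inward, alternating until no move is possible
    moved = True
    trail_out = trail_in = 0  # trailing-mismatch runs for final trimming
    while moved:
        moved = False
        # outward: compare s2[i0-1] against complement of s2[j1]
        while i0 > 0 and j1 < len(s2) and (j1 - i0) < n:
            a, b = s2[i0 - 1], s2[j1]
            match = _PAIR.get(a) == b and b in _PAIR
            if match:
                i0 -= 1
                j1 += 1
                trail_out = 0
                moved = True
            elif budget_ok(1, (i1 - i0) + 1):
                mismatches += 1
                i0 -= 1
                j1 += 1
                trail_out += 1
                moved = True
            else:
                break
        # inward: compare s2[i1] against complement of s2[j0-1]
        while i1 < j0 - 1:
            a, b = s2[i1], s2[j0 - 1]
            match = _PAIR.get(a) == b and b in _PAIR
            if match:
                i1 += 1
                j0 -= 1
                trail_in = 0
                moved = True
            elif budget_ok(1, (i1 - i0) + 1):
                mismatches += 1
                i1 += 1
                j0 -= 1
                trail_in += 1
                moved = True
            else:
                break
    # trim trailing mismatches so boundaries end on true matches
    i0 += trail_out
    j1 -= trail_out
    i1 -= trail_in
    j0 += trail_in
    return i0, i1, j0, j1


def detect_quadripartite(genome: AnnotatedGenome, min_ir_len: int = 1000,
                         max_mismatch_frac: float = 0.0,
                         seed_k: int = 25) -> QuadripartiteStructure:
    """Locate the maximal disjoint inverted-repeat pair and label regions.

    Finds the longest pair of disjoint inverted repeats of at least
    ``min_ir_len`` bp (seed match of ``seed_k`` exact bases between the
    sequence and its reverse complement, then ungapped extension); the two
    single-copy gaps become LSC (longer) and SSC (shorter). Boundaries are
    maximal: extending either IR end by one base breaks the repeat. Ties
    between equally long pairs go to the leftmost start after canonical
    rotation. Raises :class:`NoQuadripartite` when nothing qualifies.
    """
    seq = genome.sequence
    n = len(seq)
    if n < 2 * min_ir_len:
        raise NoQuadripartite(f"{genome.id}: genome shorter than two IRs")
    s2 = seq + seq if genome.circular else seq
    k = min(seed_k, min_ir_len)

    index: dict[str, list[int]] = {}
    for i in range(n):
        kmer = s2[i:i + k]
        index.setdefault(kmer, []).append(i)

    best: tuple[int, int, int] | None = None  # (arm_len, i0 mod n, j0 mod n)
    seen_keys: set[int] = set()
    for i in range(n):
        rc = revcomp(s2[i:i + k])
        for j in index.get(rc, ()):  # seed: s2[j:j+k] == revcomp(s2[i:i+k])
            j_eff = j if j > i else j + n
            if j_eff == i or j_eff >= i + n:
                continue
            if j_eff + k > len(s2):
                continue
            key = i + j_eff  # anti-diagonal: constant within one IR pair
            if key in seen_keys:
                continue
            seen_keys.add(key)
            if j_eff < i + k:  # overlapping seed (palindrome core) — skip
                continue
            i0, i1, j0, j1 = _extend_ir(s2, n, i, i + k, j_eff, j_eff + k,
                                        max_mismatch_frac)
            arm = i1 - i0
            if arm < min_ir_len or arm != j1 - j0:
                continue
            if j1 - i0 > n:  # arms overlap around the circle
                continue
            cand = (arm, i0 % n, j0 % n)
            if best is None or arm > best[0]:
                best = cand
            elif arm == best[0] and cand[1:] < best[1:]:
                best = cand
    if best is None:
        raise NoQuadripartite(f"{genome.id}: no inverted repeat >= {min_ir_len} bp")

    arm, a, c = best
    b, d = (a + arm) % n, (c + arm) % n
    # gaps between the arms going around the circle: [b, c) and [d, a)
    gap1 = (c - b) % n
    gap2 = (a - d) % n
    if gap1 >= gap2:
        lsc, ssc = (b, c), (d, a)
        irb, ira = (c, d), (a, b)  # IRb follows LSC in canonical orientation
        lsc_len, ssc_len = gap1, gap2
    else:
        lsc, ssc = (d, a), (b, c)
        irb, ira = (a, b), (c, d)
        lsc_len, ssc_len = gap2, gap1
    return QuadripartiteStructure(
        genome_id=genome.id,
        regions={"LSC": lsc, "IRb": irb, "SSC": ssc, "IRa": ira},
        lengths={"LSC": lsc_len, "IRb": arm, "SSC": ssc_len, "IRa": arm},
        genome_length=n,
    )


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def composition_summary(sequence: str) -> CompositionSummary:
    """AT/GC fractions over unambiguous bases only."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    counted = at + gc
    if counted == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T bases")
    return CompositionSummary(at / counted, gc / counted, counted,
                              len(seq) - counted)


# ---------------------------------------------------------------------------
# IR boundary shifts
# ---------------------------------------------------------------------------

def _circular_positions(ival: tuple[int, int], n: int) -> range | list[int]:
    s, e = ival
    if e > s:
        return range(s, e)
    return list(range(s, n)) + list(range(0, e))


def _region_of_feature(feat: GeneFeature, structure: QuadripartiteStructure
                       ) -> tuple[str, bool]:
    """Region containing the majority of the feature span; flag if it
    straddles a boundary."""
    n = structure.genome_length
    overlaps = dict.fromkeys(structure.regions, 0)
    region_of_pos = {}
    for name, ival in structure.regions.items():
        for p in _circular_positions(ival, n):
            region_of_pos[p] = name
    for ival in feat.intervals:
        for p in _circular_positions(ival, n):
            overlaps[region_of_pos[p % n]] += 1
    best = max(overlaps, key=lambda r: (overlaps[r], r))
    straddles = sum(1 for v in overlaps.values() if v > 0) > 1
    return best, straddles


@dataclass
class BoundaryShift:
    gene: str
    region_in_reference: str
    region_in_query: str
    flags: list[str] = field(default_factory=list)


def ir_boundary_shift_report(query: tuple[AnnotatedGenome, QuadripartiteStructure],
                             reference: tuple[AnnotatedGenome, QuadripartiteStructure]
                             ) -> list[BoundaryShift]:
    """Genes whose containing region differs between reference and query.

    IRa/IRb are reported as "IR"; genes present in both IR copies of the
    query but single-copy in the reference are flagged ``duplicated``; genes
    overlapping a region boundary are assigned by majority span and flagged
    ``boundary``.
    """
    q_genome, q_struct = query
    r_genome, r_struct = reference

    def collapse(region: str) -> str:
        return "IR" if region in ("IRa", "IRb") else region

    def regions_by_gene(genome, struct):
        out: dict[str, list[tuple[str, bool]]] = {}
        for f in genome.features:
            out.setdefault(f.name, []).append(_region_of_feature(f, struct))
        return out

    q_map = regions_by_gene(q_genome, q_struct)
    r_map = regions_by_gene(r_genome, r_struct)
    report = []
    for gene in sorted(set(q_map) & set(r_map)):
        q_entries, r_entries = q_map[gene], r_map[gene]
        q_region = collapse(q_entries[0][0])
        r_region = collapse(r_entries[0][0])
        flags = []
        if len(q_entries) > len(r_entries):
            flags.append("duplicated")
        if any(b for _, b in q_entries + r_entries):
            flags.append("boundary")
        if q_region != r_region or "duplicated" in flags:
            report.append(BoundaryShift(gene, r_region, q_region, flags))
    return report


# ---------------------------------------------------------------------------
# Gene-order inversions
# ---------------------------------------------------------------------------

SignedGene = tuple[str, int]  # (name, +1/-1)


def _strips(perm: list[int]) -> list[tuple[int, int]] | None:
    """Decompose a signed permutation into maximal strips.

    Returns half-open index spans of the *reversed* strips (maximal runs of
    descending consecutive negatives) when the decomposition is consistent:
    reversing each such strip in place must yield the identity 1..m.
    Returns None when it does not.
    """
    m = len(perm)
    spans = []
    i = 0
    while i < m:
        v = perm[i]
        if v > 0:
            j = i
            while j + 1 < m and perm[j + 1] == perm[j] + 1 and perm[j + 1] > 0:
                j += 1
            i = j + 1
        else:
            j = i
            while j + 1 < m and perm[j + 1] == perm[j] + 1 and perm[j + 1] < 0:
                j += 1
            spans.append((i, j + 1))
            i = j + 1
    # consistency: apply the reversals and check identity
    test = list(perm)
    for s, e in spans:
        test[s:e] = [-v for v in reversed(test[s:e])]
    if test != list(range(1, m + 1)):
        return None
    return spans


def detect_gene_order_inversions(query_order: list[SignedGene],
                                 reference_order: list[SignedGene],
                                 circular: bool = True) -> list[InversionSegment]:
    """Maximal runs of genes in reversed order and opposite strand.

    Both orders must contain each shared gene exactly once (collapse IR
    duplicates first). The query is canonically rotated (and, if needed,
    flipped) to the orientation that decomposes into the fewest reversal
    segments; applying the reported reversals then reproduces the reference
    order.
    """
    shared = {g for g, _ in query_order} & {g for g, _ in reference_order}
    q = [(g, s) for g, s in query_order if g in shared]
    r = [(g, s) for g, s in reference_order if g in shared]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    if len(q) != len(shared) or len(r) != len(shared):
        raise ValueError("gene orders must contain each shared gene exactly once")

    ref_pos = {g: i + 1 for i, (g, _) in enumerate(r)}
    ref_sign = {g: s for g, s in r}

    def signed_perm(order: list[SignedGene]) -> list[int]:
        return [ref_pos[g] * (1 if s == ref_sign[g] else -1) for g, s in order]

    m = len(q)
    candidates = []  # (n_segments, flip, rotation, spans, order)
    orientations = [(0, q)]
    flipped = [(g, -s) for g, s in reversed(q)]
    orientations.append((1, flipped))
    rotations = range(m) if circular else [0]
    for flip, order in orientations:
        perm0 = signed_perm(order)
        for rot in rotations:
            perm = perm0[rot:] + perm0[:rot]
            spans = _strips(perm)
            if spans is not None:
                candidates.append((len(spans), flip, rot, spans,
                                   order[rot:] + order[:rot]))
    if not candidates:
        # complex rearrangement: report reversed runs in the unrotated query
        perm = signed_perm(q)
        spans = []
        i = 0
        while i < m:
            if perm[i] < 0:
                j = i
                while j + 1 < m and perm[j + 1] == perm[j] + 1 and perm[j + 1] < 0:
                    j += 1
                spans.append((i, j + 1))
                i = j + 1
            else:
                i += 1
        chosen_spans, chosen_order = spans, q
    else:
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        _, _, _, chosen_spans, chosen_order = candidates[0]

    segments = []
    for s, e in chosen_spans:
        genes = [g for g, _ in chosen_order[s:e]]
        note = f"contains {', '.join(genes)}" if len(genes) <= 4 else (
            f"contains {genes[0]}..{genes[-1]} ({len(genes)} genes)")
        segments.append(InversionSegment(genes, (s, e), note))
    return segments


def collapse_ir_duplicates(genome: AnnotatedGenome,
                           structure: QuadripartiteStructure) -> list[SignedGene]:
    """Signed gene order with one entry per gene, keeping the IRb copy.

    Genes duplicated by IR inclusion appear once, represented by the copy
    inside IRb (the first IR after the LSC in canonical orientation); the
    order starts at the LSC start.
    """
    n = structure.genome_length
    lsc_start = structure.regions["LSC"][0]

    def rotated_start(f: GeneFeature) -> int:
        return (f.start - lsc_start) % n

    feats = sorted(genome.features, key=rotated_start)
    irb = structure.regions["IRb"]
    irb_positions = set(p % n for p in _circular_positions(irb, n))
    chosen: dict[str, GeneFeature] = {}
    for f in feats:
        if f.name not in chosen:
            chosen[f.name] = f
        else:
            # prefer the copy whose start lies in IRb
            if f.start in irb_positions and chosen[f.name].start not in irb_positions:
                chosen[f.name] = f
    ordered = sorted(chosen.values(), key=rotated_start)
    return [(f.name, 1 if f.strand == "+" else -1) for f in ordered]
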