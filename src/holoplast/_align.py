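"""Thin wrappers around Bio.Align.PairwiseAligner used across modules.

Nucleotide local alignments use the classic +2/-3 match/mismatch weights
with affine gaps (open -5, extend -2); ambiguity codes always score as
mismatches. Coordinates returned are on the forward strand of the target
even when the best alignment is to the reverse complement. For long
targets an exact-k-mer anchor scan narrows the dynamic programming to a
window around the best anchor cluster; anchor-free queries fall back to a
full scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .genome_io import revcomp


@dataclass
class LocalHit:
    """A local alignment of ``query`` against ``target``."""

    score: float
    identity: float          # percent, matches / alignment columns
    n_columns: int           # aligned columns including gap columns
    n_matches: int
    query_interval: tuple[int, int]   # on the query as given
    target_interval: tuple[int, int]  # on the forward strand of the target
    strand: str                       # strand of target matched: '+' or '-'
    # the target string actually aligned (window, in aligned orientation)
    aligned_target: str = ""
    # per-column walk: (q_pos | None, t_pos | None), t_pos indexing
    # ``aligned_target``; query positions ascending
    columns: list[tuple[int | None, int | None]] = field(default_factory=list)


def _make_aligner(match: float, mismatch: float, gap_open: float,
                  gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _walk_columns(alignment) -> list[tuple[int | None, int | None]]:
    t_blocks, q_blocks = alignment.aligned
    cols: list[tuple[int | None, int | None]] = []
    prev_t = t_blocks[0][0]
    prev_q = q_blocks[0][0]
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for t in range(prev_t, ts):        # target bases skipped: insertion
            cols.append((None, t))
        for q in range(prev_q, qs):        # query bases skipped: deletion
            cols.append((q, None))
        for o in range(te - ts):
            cols.append((qs + o, ts + o))
        prev_t, prev_q = te, qe
    return cols


def _anchor_windows(query: str, target: str, k: int,
                    pad: int) -> list[tuple[str, int, int]]:
    """(strand, start, end) windows around exact k-mer anchor clusters."""
    fwd = {query[i:i + k] for i in range(len(query) - k + 1)}
    rcq = revcomp(query)
    rev = {rcq[i:i + k] for i in range(len(rcq) - k + 1)}
    pos = {"+": [], "-": []}
    for i in range(len(target) - k + 1):
        sub = target[i:i + k]
        if sub in fwd:
            pos["+"].append(i)
        if sub in rev:
            pos["-"].append(i)
    windows = []
    gap_limit = len(query) + pad
    for strand, plist in pos.items():
        if not plist:
            continue
        clusters: list[list[int]] = [[plist[0]]]
        for p in plist[1:]:
            if p - clusters[-1][-1] > gap_limit:
                clusters.append([])
            clusters[-1].append(p)
        best = max(clusters, key=len)
        start = max(0, best[0] - gap_limit)
        end = min(len(target), best[-1] + k + gap_limit)
        windows.append((strand, start, end))
    return windows


def _is_match(col, query: str, t: str) -> bool:
    q, tp = col
    return q is not None and tp is not None and query[q] == t[tp] \
        and query[q] in "ACGT"


def _segment_score(cols, query: str, t: str, gap_open: float,
                   gap_extend: float, match: float, mismatch: float) -> float:
    score = 0.0
    in_gap = False
    for col in cols:
        q, tp = col
        if q is None or tp is None:
            score += gap_extend if in_gap else gap_open
            in_gap = True
        else:
            in_gap = False
            score += match if _is_match(col, query, t) else mismatch
    return score


def _trim_weak_ends(cols, query: str, t: str, match: float, mismatch: float,
                    gap_open: float, gap_extend: float,
                    min_terminal_score: float = 15.0):
    """Drop terminal [indel + weak tail] blocks that are chance extensions.

    A local aligner will happily bridge a small gap into downstream junk
    when a few bases match by chance; a terminal segment beyond the last
    indel run is kept only when it scores at least ``min_terminal_score``
    on its own. Applied at both ends, then trailing non-matches stripped.
    """
    def is_indel(col):
        return col[0] is None or col[1] is None

    changed = True
    while changed and cols:
        changed = False
        # trailing block
        last_indel = max((i for i, c in enumerate(cols) if is_indel(c)),
                         default=None)
        if last_indel is not None:
            run_start = last_indel
            while run_start > 0 and is_indel(cols[run_start - 1]):
                run_start -= 1
            tail = cols[last_indel + 1:]
            if _segment_score(tail, query, t, gap_open, gap_extend,
                              match, mismatch) < min_terminal_score:
                cols = cols[:run_start]
                changed = True
                continue
        # leading block
        first_indel = next((i for i, c in enumerate(cols) if is_indel(c)),
                           None)
        if first_indel is not None:
            run_end = first_indel
            while run_end + 1 < len(cols) and is_indel(cols[run_end + 1]):
                run_end += 1
            head = cols[:first_indel]
            if _segment_score(head, query, t, gap_open, gap_extend,
                              match, mismatch) < min_terminal_score:
                cols = cols[run_end + 1:]
                changed = True
    while cols and not _is_match(cols[-1], query, t):
        cols = cols[:-1]
    while cols and not _is_match(cols[0], query, t):
        cols = cols[1:]
    return cols


def _align_window(aligner, query: str, target: str, strand: str,
                  w_start: int, w_end: int) -> LocalHit | None:
    window = target[w_start:w_end]
    t = window if strand == "+" else revcomp(window)
    try:
        alns = aligner.align(t, query)
        if len(alns) == 0:
            return None
        aln = alns[0]
    except (ValueError, OverflowError, MemoryError):
        return None
    cols = _walk_columns(aln)
    cols = _trim_weak_ends(cols, query, t, aligner.match_score,
                           aligner.mismatch_score, aligner.open_gap_score,
                           aligner.extend_gap_score)
    if not cols:
        return None
    matches = sum(1 for c in cols if _is_match(c, query, t))
    columns = len(cols)
    q_pos = [q for q, _ in cols if q is not None]
    t_pos = [tp for _, tp in cols if tp is not None]
    q_iv = (q_pos[0], q_pos[-1] + 1)
    t_iv = (t_pos[0], t_pos[-1] + 1)
    if strand == "-":
        fwd_iv = (w_start + len(window) - t_iv[1],
                  w_start + len(window) - t_iv[0])
    else:
        fwd_iv = (w_start + t_iv[0], w_start + t_iv[1])
    score = _segment_score(cols, query, t, aligner.open_gap_score,
                           aligner.extend_gap_score, aligner.match_score,
                           aligner.mismatch_score)
    return LocalHit(score=float(score),
                    identity=100.0 * matches / columns if columns else 0.0,
                    n_columns=columns, n_matches=matches,
                    query_interval=q_iv, target_interval=fwd_iv,
                    strand=strand, aligned_target=t, columns=cols)


def best_local_alignment(query: str, target: str, both_strands: bool = True,
                         match: float = 2.0, mismatch: float = -3.0,
                         gap_open: float = -5.0, gap_extend: float = -2.0,
                         min_score: float = 1.0, anchor_k: int = 13,
                         window_pad: int = 2000,
                         fallback_min_score: float | None = None) -> LocalHit | None:
    """Best-scoring local DNA alignment of query within target.

    With ``both_strands`` the reverse complement of the target is also
    searched; target coordinates are reported on the forward strand either
    way. Returns None when no alignment reaches ``min_score``.
    """
    if not query or not target:
        return None
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    candidates: list[LocalHit] = []

    use_anchors = (anchor_k and len(query) >= anchor_k
                   and len(target) > 2 * (len(query) + window_pad))
    if use_anchors:
        windows = _anchor_windows(query, target, anchor_k, window_pad)
        if not both_strands:
            windows = [w for w in windows if w[0] == "+"]
        for strand, start, end in windows:
            hit = _align_window(aligner, query, target, strand, start, end)
            if hit is not None:
                candidates.append(hit)
    if not candidates:
        # anchor-free fallback: score both strands cheaply, traceback only
        # the better one
        strands = ("+", "-") if both_strands else ("+",)
        scores = {}
        for strand in strands:
            t = target if strand == "+" else revcomp(target)
            try:
                scores[strand] = aligner.score(t, query)
            except (ValueError, OverflowError):
                scores[strand] = float("-inf")
        strand = max(scores, key=lambda s: scores[s])
        floor = max(min_score, fallback_min_score or min_score)
        if scores[strand] >= floor:
            hit = _align_window(aligner, query, target, strand, 0, len(target))
            if hit is not None:
                candidates.append(hit)
    if not candidates:
        return None
    best = max(candidates, key=lambda h: h.score)
    return best if best.score >= min_score else None
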