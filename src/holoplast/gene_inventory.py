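"""Reference-guided gene-status classification and content accounting.

Each gene of an autotrophic reference plastome is classified in a query
genome as intact, pseudogene (with mechanism and 1-based codon index of the
first defect) or lost. Pseudogene mechanisms follow the usual organellar
criteria: a premature in-frame stop codon, a frameshifting indel, or a
physical 3' truncation with no downstream similarity. The module also
builds cross-species gene-content matrices, audits pathway retention, and
cross-checks transcriptome expression against qPCR 2^-ddCt fold changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from ._align import best_local_alignment
from .genome_io import AnnotatedGenome, revcomp

#: NCBI translation table for plastid/bacterial genes.
CODON_TABLE = 11
STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODONS = {"ATG", "GTG", "TTG"}


class InvalidReferenceCDS(ValueError):
    """The reference CDS is not a clean in-frame open reading frame."""


@dataclass
class StatusThresholds:
    """Knobs of the intact/pseudogene/lost classifier."""

    lost_identity: float = 60.0      # percent; below -> lost
    lost_coverage: float = 0.30      # fraction of reference CDS aligned
    truncation_frac: float = 0.90    # alignment must reach this codon fraction
    terminal_stop_drift: float = 0.05  # stops within final 5% of codons ignored
    downstream_window: int = 2000    # bp searched for the missing 3' part
    min_downstream_len: int = 30     # bp of downstream similarity that rescues
    rescue_identity: float = 70.0    # percent, for the downstream rescue hit
    rescue_coverage: float = 0.4     # fraction of the missing 3' part matched
    lost_score_min: float = 50.0     # anchor-free alignments below this -> lost
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclass
class GeneStatus:
    gene: str
    status: str                  # intact | pseudogene | lost
    reason: str                  # none | premature_stop | frameshift | truncation
    codon_index: int             # 1-based codon of first defect; 0 if none
    reference_coverage: float    # fraction of reference CDS aligned
    identity: float              # percent over aligned columns

    def __post_init__(self) -> None:
        if self.status == "intact" and (self.reason != "none" or self.codon_index):
            raise ValueError("intact status cannot carry a defect")
        if self.status == "pseudogene" and (self.reason == "none"
                                            or self.codon_index < 1):
            raise ValueError("pseudogene status requires a reason and codon")
        if not 0.0 <= self.reference_coverage <= 1.0:
            raise ValueError("coverage outside [0,1]")


def validate_reference_cds(cds: str) -> None:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise InvalidReferenceCDS(f"length {len(cds)} not a multiple of 3")
    if cds[:3] not in START_CODONS:
        raise InvalidReferenceCDS(f"no start codon (saw {cds[:3]})")
    if cds[-3:] not in STOP_CODONS:
        raise InvalidReferenceCDS(f"no terminal stop codon (saw {cds[-3:]})")
    for i in range(0, len(cds) - 3, 3):
        if cds[i:i + 3] in STOP_CODONS:
            raise InvalidReferenceCDS(f"internal stop at codon {i // 3 + 1}")


def _query_sequence(query) -> tuple[str, bool]:
    if isinstance(query, AnnotatedGenome):
        return query.sequence, query.circular
    return str(query).upper(), False


def classify_gene_status(query, reference_cds: str,
                         thresholds: StatusThresholds | None = None,
                         gene: str = "", kind: str = "CDS") -> GeneStatus:
    """Classify one reference gene as intact / pseudogene / lost in a query.

    The reference CDS is locally aligned to both strands of the query
    (region or whole genome). No alignment at the lost thresholds means the
    gene is lost; otherwise the aligned query is inspected in the reference
    reading frame and the first defect (in column order) decides the
    pseudogene mechanism and codon index. RNA genes (``kind`` not "CDS")
    use only identity/coverage.
    """
    th = thresholds or StatusThresholds()
    ref = reference_cds.upper()
    if kind == "CDS":
        validate_reference_cds(ref)
    target, circular = _query_sequence(query)
    if circular and len(target) > len(ref):
        # allow hits across the origin
        target = target + target[:len(ref)]

    hit = best_local_alignment(ref, target, both_strands=True,
                               match=th.match, mismatch=th.mismatch,
                               gap_open=th.gap_open, gap_extend=th.gap_extend,
                               fallback_min_score=th.lost_score_min)
    if hit is None:
        return GeneStatus(gene, "lost", "none", 0, 0.0, 0.0)
    ref_span = hit.query_interval[1] - hit.query_interval[0]
    coverage = ref_span / len(ref)
    if hit.identity < th.lost_identity or coverage < th.lost_coverage:
        return GeneStatus(gene, "lost", "none", 0, coverage, hit.identity)

    if kind != "CDS":
        if coverage < th.truncation_frac:
            return GeneStatus(gene, "pseudogene", "truncation",
                              hit.query_interval[1] + 1, coverage, hit.identity)
        return GeneStatus(gene, "intact", "none", 0, coverage, hit.identity)

    n_codons = len(ref) // 3
    last_kept_codon = int(np.floor(n_codons * (1.0 - th.terminal_stop_drift)))
    aligned_target = hit.aligned_target  # window, in aligned orientation

    defect = _first_defect(hit.columns, ref, aligned_target, last_kept_codon)
    if defect is not None:
        reason, codon = defect
        return GeneStatus(gene, "pseudogene", reason, codon, coverage,
                          hit.identity)

    ref_end = hit.query_interval[1]
    if ref_end < th.truncation_frac * len(ref):
        # is the missing 3' part present just downstream of the hit?
        downstream_ref = ref[ref_end:]
        t_end = hit.columns[-1][1]
        window = aligned_target[t_end:t_end + th.downstream_window] if t_end else ""
        rescued = False
        if len(downstream_ref) >= th.min_downstream_len and window:
            d_hit = best_local_alignment(downstream_ref, window,
                                         both_strands=False)
            if d_hit and d_hit.identity >= th.rescue_identity \
                    and d_hit.n_matches >= th.min_downstream_len \
                    and (d_hit.query_interval[1] - d_hit.query_interval[0]) \
                    >= th.rescue_coverage * len(downstream_ref):
                rescued = True
        if not rescued:
            return GeneStatus(gene, "pseudogene", "truncation",
                              ref_end // 3 + 1, coverage, hit.identity)
    return GeneStatus(gene, "intact", "none", 0, coverage, hit.identity)


def _first_defect(columns, ref: str, target: str,
                  last_kept_codon: int) -> tuple[str, int] | None:
    """First frameshifting indel or in-frame premature stop, in column order.

    ``columns`` walk the alignment as (ref_pos|None, target_pos|None) with
    ref positions ascending. Codon indices are 1-based counting the start
    codon as codon 1.
    """
    events: list[tuple[int, str, int]] = []  # (column index, reason, codon)

    # indel runs
    i = 0
    while i < len(columns):
        q, t = columns[i]
        if q is None or t is None:
            j = i
            kind_none = "ref" if q is None else "target"
            while j + 1 < len(columns):
                q2, t2 = columns[j + 1]
                if (kind_none == "ref" and q2 is None) or \
                        (kind_none == "target" and t2 is None):
                    j += 1
                else:
                    break
            run = j - i + 1
            if run % 3 != 0:
                # codon containing the first reference base at/after the run
                ref_pos = next((c[0] for c in columns[i:] if c[0] is not None),
                               None)
                if ref_pos is None:
                    ref_pos = next(c[0] for c in reversed(columns[:i])
                                   if c[0] is not None)
                events.append((i, "frameshift", ref_pos // 3 + 1))
            i = j + 1
        else:
            i += 1

    # in-frame stops: ref codons whose three positions are all aligned
    by_ref = {q: (idx, t) for idx, (q, t) in enumerate(columns)
              if q is not None and t is not None}
    for c in range(last_kept_codon):
        triple = [by_ref.get(3 * c + o) for o in range(3)]
        if any(x is None for x in triple):
            continue
        t_pos = [t for _, t in triple]
        if t_pos[1] != t_pos[0] + 1 or t_pos[2] != t_pos[1] + 1:
            continue  # gap inside the codon
        codon = target[t_pos[0]:t_pos[0] + 3]
        if codon in STOP_CODONS:
            events.append((triple[0][0], "premature_stop", c + 1))

    if not events:
        return None
    events.sort()
    _, reason, codon = events[0]
    return reason, codon


# ---------------------------------------------------------------------------
# Gene content matrix
# ---------------------------------------------------------------------------

@dataclass
class GeneContentMatrix:
    """Species x gene matrix of {present, pseudogene, absent} codes."""

    table: pd.DataFrame  # index species, columns genes

    def cell(self, species: str, gene: str) -> str:
        return self.table.loc[species, gene]


_STATUS_TO_CODE = {"intact": "present", "pseudogene": "pseudogene",
                   "lost": "absent"}


def build_gene_content_matrix(genomes: list[AnnotatedGenome],
                              reference: AnnotatedGenome,
                              thresholds: StatusThresholds | None = None,
                              panel: list[str] | None = None) -> GeneContentMatrix:
    """One row per query species, one column per reference-panel gene.

    Cells come from :func:`classify_gene_status` against the whole query
    genome. The panel defaults to every gene of the reference.
    """
    ids = [g.id for g in genomes]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate species ids")
    ref_feats = {f.name: f for f in reference.features
                 if f.kind in ("CDS", "tRNA", "rRNA")}
    if panel is None:
        panel = sorted(ref_feats)
    rows = {}
    for genome in genomes:
        row = {}
        for gene in panel:
            feat = ref_feats[gene]
            cds = reference.feature_sequence(feat)
            status = classify_gene_status(genome, cds, thresholds, gene=gene,
                                          kind=feat.kind)
            row[gene] = _STATUS_TO_CODE[status.status]
        rows[genome.id] = row
    table = pd.DataFrame.from_dict(rows, orient="index")[panel]
    return GeneContentMatrix(table)


# ---------------------------------------------------------------------------
# Pathway audit
# ---------------------------------------------------------------------------

@dataclass
class PathwayAudit:
    pathway: str
    components: dict[str, str]      # gene -> compartment (plastid/nuclear)
    expressed: set[str] = field(default_factory=set)
    missing: set[str] = field(default_factory=set)

    def counts_by_compartment(self) -> pd.DataFrame:
        rows = []
        for comp in sorted(set(self.components.values())):
            genes = {g for g, c in self.components.items() if c == comp}
            rows.append({"compartment": comp, "total": len(genes),
                         "expressed": len(genes & self.expressed),
                         "missing": len(genes & self.missing)})
        return pd.DataFrame(rows)


def read_pathway_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["pathway", "gene", "compartment"], comment="#")
    return df


def pathway_audit(pathway_map, expressed_gene_ids) -> list[PathwayAudit]:
    """Partition each pathway's components into expressed vs missing."""
    if not isinstance(pathway_map, pd.DataFrame):
        pathway_map = read_pathway_map(pathway_map)
    expressed = set(expressed_gene_ids)
    known = set(pathway_map["gene"])
    stray = expressed - known
    if stray:
        warnings.warn(f"{len(stray)} expressed ids absent from the pathway map; "
                      f"ignored: {sorted(stray)[:5]}...")
    audits = []
    for pathway, grp in pathway_map.groupby("pathway", sort=True):
        components = dict(zip(grp["gene"], grp["compartment"]))
        exp = set(components) & expressed
        audits.append(PathwayAudit(pathway, components, exp,
                                   set(components) - exp))
    return audits


# ---------------------------------------------------------------------------
# qPCR cross-check
# ---------------------------------------------------------------------------

def qpcr_crosscheck(ct_table: pd.DataFrame, tpm_table: pd.DataFrame,
                    reference_gene: str, calibrator_sample: str
                    ) -> tuple[pd.DataFrame, float]:
    """Compare 2^-ddCt qPCR fold changes against transcriptome ratios.

    ``ct_table`` columns: gene, sample, ct (replicates allowed, averaged
    first). ``tpm_table`` columns: gene, sample, tpm. Fold change per
    (gene, sample) is 2^-ddCt against the reference gene and the calibrator
    sample; r_squared is the squared Pearson correlation between log2 fold
    changes and log2 transcriptome ratios over non-calibrator samples.
    """
    ct = ct_table.groupby(["gene", "sample"], as_index=False)["ct"].mean()
    if reference_gene not in set(ct["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} missing from Ct table")
    ref_ct = ct[ct["gene"] == reference_gene].set_index("sample")["ct"]
    rows = []
    for gene, grp in ct[ct["gene"] != reference_gene].groupby("gene"):
        g = grp.set_index("sample")["ct"]
        if calibrator_sample not in g.index:
            raise ValueError(f"calibrator sample {calibrator_sample!r} missing "
                             f"for gene {gene}")
        dct = g - ref_ct.loc[g.index]
        ddct = dct - dct.loc[calibrator_sample]
        for sample, v in ddct.items():
            rows.append({"gene": gene, "sample": sample, "ddct": v,
                         "fold_change": 2.0 ** (-v)})
    folds = pd.DataFrame(rows)

    tpm = tpm_table.groupby(["gene", "sample"], as_index=False)["tpm"].mean()
    cal_tpm = tpm[tpm["sample"] == calibrator_sample].set_index("gene")["tpm"]
    merged = folds.merge(tpm, on=["gene", "sample"])
    merged = merged[merged["sample"] != calibrator_sample]
    merged["tpm_ratio"] = merged["tpm"] / merged["gene"].map(cal_tpm)
    x = np.log2(merged["fold_change"].to_numpy(dtype=float))
    y = np.log2(merged["tpm_ratio"].to_numpy(dtype=float))
    if len(x) < 2 or np.allclose(x, x[0]) or np.allclose(y, y[0]):
        r_squared = float("nan")
    else:
        r_squared = float(stats.pearsonr(x, y)[0] ** 2)
    return folds, r_squared


def translate_cds(cds: str, table: int = CODON_TABLE) -> str:
    """Translate an in-frame CDS (terminal stop stripped) to protein."""
    seq = cds.upper()
    if seq[-3:] in STOP_CODONS:
        seq = seq[:-3]
    return str(Seq(seq).translate(table=table))
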