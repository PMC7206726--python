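"""Readers/writers for annotated genomes, reads and trees.

All coordinates held in memory are 0-based half-open. GenBank's 1-based
inclusive coordinates are converted on read and restored on write. A feature
on a circular genome that spans the origin is stored as a *single* interval
``(start, end)`` with ``end <= start``, meaning ``[start, L) + [0, end)``;
every consumer in this package honours that convention.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = set("ACGTNRYSWKMBDHV")

#: Trophic classes used for branch labelling of the species tree.
BRANCH_CLASSES = ("autotrophic", "hemiparasitic", "holoparasitic")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenBankParseError(ValueError):
    """Raised when a GenBank flat file cannot be parsed."""


class FastqPairError(ValueError):
    """Raised on mate-file inconsistencies (count or id mismatch)."""


@dataclass
class GeneFeature:
    """A gene-level feature of an annotated organellar genome.

    ``intervals`` are 0-based half-open; an interval with ``end <= start``
    wraps the origin of a circular genome.
    """

    name: str
    kind: str  # one of {"CDS", "tRNA", "rRNA", "pseudogene"}
    intervals: list[tuple[int, int]]
    strand: str  # "+" or "-"
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"feature {self.name!r}: empty interval list")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name!r}: bad strand {self.strand!r}")

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    def wraps(self) -> bool:
        return any(e <= s for s, e in self.intervals)

    def span_length(self, genome_length: int) -> int:
        total = 0
        for s, e in self.intervals:
            total += (e - s) if e > s else (genome_length - s + e)
        return total


@dataclass
class AnnotatedGenome:
    """Sequence plus gene features of a (usually circular) organellar genome."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise ValueError(f"genome {self.id}: non-IUPAC characters {sorted(bad)}")
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.intervals:
                if not (0 <= s < n and 0 <= e <= n):
                    raise ValueError(
                        f"genome {self.id}: feature {f.name} interval ({s},{e}) "
                        f"outside [0,{n})")
                if e <= s and not self.circular:
                    raise ValueError(
                        f"genome {self.id}: wrapping feature {f.name} on a "
                        "linear genome")
        self.features.sort(key=lambda f: f.start)

    def __len__(self) -> int:
        return len(self.sequence)

    def interval_sequence(self, start: int, end: int) -> str:
        """Forward-strand sequence of a (possibly wrapping) interval."""
        if end > start:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[:end]

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Spliced, strand-oriented sequence of a feature."""
        parts = [self.interval_sequence(s, e) for s, e in feat.intervals]
        seq = "".join(parts)
        return revcomp(seq) if feat.strand == "-" else seq

    def genes(self, kinds: tuple[str, ...] | None = None) -> list[GeneFeature]:
        if kinds is None:
            return list(self.features)
        return [f for f in self.features if f.kind in kinds]

    def feature_by_name(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


@dataclass
class ReadPair:
    """One paired-end read with Sanger-encoded quality strings."""

    id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_KIND_TO_GB = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "pseudogene": "gene"}


def _location_to_intervals(loc, seq_len: int) -> tuple[list[tuple[int, int]], str]:
    strand = "-" if loc.strand == -1 else "+"
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    ivals = [(int(p.start), int(p.end)) for p in parts]
    if strand == "-":
        # Biopython orders minus-strand compound parts 5'->3'; restore
        # genomic order for our representation.
        ivals = sorted(ivals)
    # Merge a two-part location that abuts the origin into one wrapping
    # interval: [x, L) + [0, y)  ->  (x, y).
    if len(ivals) == 2:
        (s1, e1), (s2, e2) = sorted(ivals)
        if s1 == 0 and e2 == seq_len and s2 > e1:
            ivals = [(s2, e1)]
    return ivals, strand


def _is_pseudo(qualifiers: dict) -> bool:
    return "pseudo" in qualifiers or "pseudogene" in qualifiers


def _feature_name(qualifiers: dict, default: str) -> str:
    for key in ("gene", "locus_tag", "product"):
        if key in qualifiers:
            return qualifiers[key][0]
    return default


def read_genbank(path: str | os.PathLike) -> list[AnnotatedGenome]:
    """Parse a GenBank flat file into one :class:`AnnotatedGenome` per record.

    gene/tRNA/rRNA/CDS features become :class:`GeneFeature`; a feature whose
    record marks it ``/pseudo`` (or ``/pseudogene``) gets kind ``pseudogene``.
    """
    with open(path) as fh:
        text = fh.read()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    if not first.startswith("LOCUS"):
        raise GenBankParseError(f"{path}: line 1: expected LOCUS header, got {first[:40]!r}")
    if "ORIGIN" not in text:
        raise GenBankParseError(f"{path}: missing ORIGIN sequence block")
    try:
        records = list(SeqIO.parse(io.StringIO(text), "genbank"))
    except ValueError as exc:  # pragma: no cover - biopython message passthrough
        raise GenBankParseError(f"{path}: {exc}") from exc
    genomes = []
    for rec in records:
        circular = rec.annotations.get("topology", "linear") == "circular"
        seq_len = len(rec.seq)
        feats: list[GeneFeature] = []
        seen: set[tuple[str, tuple, str]] = set()
        # CDS/tRNA/rRNA carry the informative annotation; bare `gene`
        # features are used only for pseudogenes (no product feature).
        gene_feats = [f for f in rec.features if f.type == "gene"]
        product_feats = [f for f in rec.features if f.type in ("CDS", "tRNA", "rRNA")]
        for f in product_feats:
            ivals, strand = _location_to_intervals(f.location, seq_len)
            kind = "pseudogene" if _is_pseudo(f.qualifiers) else f.type
            name = _feature_name(f.qualifiers, f"{f.type}_{ivals[0][0]}")
            key = (name, tuple(ivals), strand)
            if key in seen:
                continue
            seen.add(key)
            notes = f.qualifiers.get("note", [""])[0]
            feats.append(GeneFeature(name, kind, ivals, strand, notes))
        covered = {(f.name) for f in feats}
        for f in gene_feats:
            name = _feature_name(f.qualifiers, "")
            if not name or name in covered:
                continue
            if _is_pseudo(f.qualifiers):
                ivals, strand = _location_to_intervals(f.location, seq_len)
                notes = f.qualifiers.get("note", [""])[0]
                feats.append(GeneFeature(name, "pseudogene", ivals, strand, notes))
                covered.add(name)
        genomes.append(AnnotatedGenome(rec.id or rec.name, str(rec.seq), circular, feats))
    if not genomes:
        raise GenBankParseError(f"{path}: no records found")
    return genomes


def _intervals_to_location(feat: GeneFeature, seq_len: int) -> SimpleLocation | CompoundLocation:
    strand = -1 if feat.strand == "-" else 1
    locs = []
    for s, e in feat.intervals:
        if e > s:
            locs.append(SimpleLocation(s, e, strand))
        else:  # wrapping: [s, L) then [0, e)
            locs.append(SimpleLocation(s, seq_len, strand))
            locs.append(SimpleLocation(0, e, strand))
    if strand == -1 and len(locs) > 1:
        locs = locs[::-1]
    return locs[0] if len(locs) == 1 else CompoundLocation(locs)


def write_genbank(genomes: AnnotatedGenome | Iterable[AnnotatedGenome],
                  path: str | os.PathLike) -> None:
    """Write genomes as a GenBank flat file (inverse of :func:`read_genbank`)."""
    if isinstance(genomes, AnnotatedGenome):
        genomes = [genomes]
    records = []
    for g in genomes:
        rec = SeqRecord(Seq(g.sequence), id=g.id, name=g.id.split(".")[0][:16],
                        description="")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "circular" if g.circular else "linear"
        for f in g.features:
            loc = _intervals_to_location(f, len(g.sequence))
            quals: dict[str, list[str]] = {"gene": [f.name]}
            if f.notes:
                quals["note"] = [f.notes]
            if f.kind == "pseudogene":
                quals["pseudo"] = [""]
            rec.features.append(SeqFeature(loc, type=_KIND_TO_GB[f.kind],
                                           qualifiers=quals))
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file as a list of ``(id, sequence)``, order preserved."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty sequence for record {rec.id!r}")
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _fastq_records(path):
    from Bio.SeqIO.QualityIO import FastqGeneralIterator
    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def _strip_mate_suffix(name: str) -> str:
    base = name.split()[0]
    if len(base) > 2 and base[-2] == "/" and base[-1] in "12":
        return base[:-2]
    return base


def read_fastq_pairs(path1: str | os.PathLike,
                     path2: str | os.PathLike) -> Iterator[ReadPair]:
    """Stream matched read pairs from two FASTQ mate files."""
    import itertools

    it1, it2 = _fastq_records(path1), _fastq_records(path2)
    for idx, (r1, r2) in enumerate(itertools.zip_longest(it1, it2)):
        if r1 is None or r2 is None:
            raise FastqPairError(
                f"mate files differ in record count at record {idx}")
        (id1, s1, q1), (id2, s2, q2) = r1, r2
        b1, b2 = _strip_mate_suffix(id1), _strip_mate_suffix(id2)
        if b1 != b2:
            raise FastqPairError(
                f"record {idx}: mate id mismatch {id1!r} vs {id2!r}")
        yield ReadPair(b1, s1, s2, q1, q2)


def write_fastq_pairs(pairs: Iterable[ReadPair], path1: str | os.PathLike,
                      path2: str | os.PathLike) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class PhyloTree:
    """A phylogeny with optional per-branch trophic-class labels.

    The class of the branch above each node is stored in ``node_classes``
    (keyed by dendropy node). Tip classes come from a user mapping; an
    internal branch takes a class only when *all* its descendant tips share
    it, otherwise it falls back to the background (autotrophic) class.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.node_classes: dict = {}
        labels = self.tip_labels()
        if len(labels) != len(set(labels)):
            raise ValueError("tip labels are not unique")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick_string(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls(tree)

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    # -- branch classes ----------------------------------------------------

    def assign_branch_classes(self, tip_classes: dict[str, str],
                              background: str = "autotrophic") -> None:
        """Label every branch from a tip -> class mapping (see class docs)."""
        for label, cls_name in tip_classes.items():
            if cls_name not in BRANCH_CLASSES:
                raise ValueError(f"unknown class {cls_name!r} for tip {label!r}")
        missing = set(self.tip_labels()) - set(tip_classes)
        if missing:
            raise ValueError(f"tips without a class label: {sorted(missing)}")
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                self.node_classes[node] = tip_classes[node.taxon.label]
            else:
                child_cls = {self.node_classes[c] for c in node.child_nodes()}
                self.node_classes[node] = (child_cls.pop() if len(child_cls) == 1
                                           else background)

    def branch_class(self, node) -> str:
        return self.node_classes[node]

    def classes_assigned(self) -> bool:
        return bool(self.node_classes)


def read_branch_class_tsv(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column (tip, class) TSV sidecar."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tip, cls_name = line.split("\t")[:2]
            mapping[tip] = cls_name
    return mapping


def read_newick(path: str | os.PathLike,
                classes_tsv: str | os.PathLike | None = None,
                background: str = "autotrophic") -> PhyloTree:
    """Read a newick tree, optionally labelling branches from a sidecar TSV."""
    with open(path) as fh:
        tree = PhyloTree.from_newick_string(fh.read())
    if classes_tsv is not None:
        tree.assign_branch_classes(read_branch_class_tsv(classes_tsv),
                                   background=background)
    return tree
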