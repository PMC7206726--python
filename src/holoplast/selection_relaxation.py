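"""GY94 codon-model tests of relaxed purifying selection.

Implements the Goldman-Yang codon substitution model over the 61 sense
codons (translation table 11 shares the standard stop set) with
transition/transversion ratio kappa, per-branch-class dN/dS ratio omega and
F3x4 equilibrium codon frequencies, fitted by maximum likelihood with the
Felsenstein pruning algorithm. Branch models: M0 (one omega for the whole
tree), M2 (parasitic foreground vs autotrophic background), M3
(holoparasitic / hemiparasitic / autotrophic). Nested models are compared
with chi-square likelihood-ratio tests.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from scipy import optimize, stats

from .genome_io import PhyloTree

STOP_CODONS = ("TAA", "TAG", "TGA")
NUCS = "ACGT"
#: the 61 sense codons in lexicographic order
SENSE_CODONS = tuple(a + b + c for a in NUCS for b in NUCS for c in NUCS
                     if a + b + c not in STOP_CODONS)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)
AMINO_ACID = {c: str(Seq(c).translate(table=11)) for c in SENSE_CODONS}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

OMEGA_BOUNDS = (1e-4, 50.0)
KAPPA_BOUNDS = (0.1, 99.0)
BL_BOUNDS = (1e-6, 20.0)

#: Branch-class layouts per model, in omega-class order.
MODEL_CLASSES = {
    "M0": [("autotrophic", 0), ("hemiparasitic", 0), ("holoparasitic", 0)],
    "M2": [("autotrophic", 0), ("hemiparasitic", 1), ("holoparasitic", 1)],
    "M3": [("autotrophic", 0), ("hemiparasitic", 1), ("holoparasitic", 2)],
}
MODEL_N_CLASSES = {"M0": 1, "M2": 2, "M3": 3}


def _single_substitutions():
    """Sparse structure of single-nucleotide codon changes."""
    rows, cols, transition, synonymous = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diff) != 1:
                continue
            rows.append(i)
            cols.append(j)
            transition.append(diff[0] in _TRANSITIONS)
            synonymous.append(AMINO_ACID[ci] == AMINO_ACID[cj])
    return (np.array(rows), np.array(cols), np.array(transition),
            np.array(synonymous))

_SUB_ROWS, _SUB_COLS, _SUB_TS, _SUB_SYN = _single_substitutions()


# ---------------------------------------------------------------------------
# Rate matrix and transition probabilities
# ---------------------------------------------------------------------------

def f3x4_frequencies(positional: np.ndarray) -> np.ndarray:
    """Codon frequencies from 3x4 positional nucleotide frequencies.

    Stop codons are zeroed and the distribution renormalised over the 61
    sense codons.
    """
    positional = np.asarray(positional, dtype=float)
    if positional.shape != (3, 4):
        raise ValueError("positional frequencies must be 3x4 (codon position x ACGT)")
    pi = np.empty(N_CODONS)
    for idx, codon in enumerate(SENSE_CODONS):
        pi[idx] = np.prod([positional[p, NUCS.index(codon[p])]
                           for p in range(3)])
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate positional frequencies")
    return pi / total


def empirical_f3x4(rows: list[str]) -> np.ndarray:
    """Positional nucleotide counts from ungapped codons of an alignment."""
    counts = np.zeros((3, 4))
    for row in rows:
        for i in range(0, len(row), 3):
            codon = row[i:i + 3]
            if codon in CODON_INDEX:
                for p, base in enumerate(codon):
                    counts[p, NUCS.index(base)] += 1
    counts += 1e-9  # guard empty cells
    return counts / counts.sum(axis=1, keepdims=True)


def rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Normalised GY94 rate matrix (mean rate 1, rows sum to zero)."""
    q = np.zeros((N_CODONS, N_CODONS))
    rate = pi[_SUB_COLS].copy()
    rate[_SUB_TS] *= kappa
    rate[~_SUB_SYN] *= omega
    q[_SUB_ROWS, _SUB_COLS] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.dot(pi, np.diag(q))
    if scale <= 0:
        raise ValueError("degenerate rate matrix")
    return q / scale


def synonymous_fraction(kappa: float, omega: float, pi: np.ndarray) -> float:
    """Fraction of the (normalised) substitution rate that is synonymous."""
    q = rate_matrix(kappa, omega, pi)
    flow = pi[_SUB_ROWS] * q[_SUB_ROWS, _SUB_COLS]
    return float(flow[_SUB_SYN].sum() / flow.sum())


class _EigenQ:
    """Symmetric eigendecomposition of a reversible Q for fast P(t)."""

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(pi)
        b = (q * sqrt_pi[:, np.newaxis]) / sqrt_pi[np.newaxis, :]
        b = 0.5 * (b + b.T)  # symmetrise numerical noise
        self.evals, u = np.linalg.eigh(b)
        self.left = u / sqrt_pi[:, np.newaxis]     # D^-1/2 U
        self.right = (u * sqrt_pi[:, np.newaxis]).T  # U^T D^1/2

    def expm(self, t: float) -> np.ndarray:
        p = (self.left * np.exp(self.evals * t)) @ self.right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


def transition_matrix(kappa: float, omega: float, pi: np.ndarray,
                      t: float) -> np.ndarray:
    """P(t) = exp(Qt) for the normalised GY94 model."""
    return _EigenQ(rate_matrix(kappa, omega, pi), pi).expm(t)


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Aligned codon columns per taxon; '---' marks a gap codon."""

    taxa: list[str]
    rows: list[str]  # aligned nucleotide strings, length 3*n_codons

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("rows differ in length")
        (length,) = lengths
        if length % 3:
            raise ValueError("alignment length not a multiple of 3")
        for taxon, row in zip(self.taxa, self.rows):
            for i in range(0, length, 3):
                codon = row[i:i + 3]
                if codon in STOP_CODONS:
                    raise ValueError(
                        f"internal stop codon in {taxon} at codon {i // 3 + 1}")

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3

    def codon(self, taxon_idx: int, codon_idx: int) -> str:
        return self.rows[taxon_idx][3 * codon_idx:3 * codon_idx + 3]


def _align_proteins_mafft(proteins: dict[str, str]) -> dict[str, str]:
    if shutil.which("mafft") is None:  # pragma: no cover
        raise RuntimeError("mafft not found on PATH; cannot align unequal CDSs")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "prot.fa"
        with open(fasta, "w") as fh:
            for name, seq in proteins.items():
                fh.write(f">{name}\n{seq}\n")
        out = subprocess.run(["mafft", "--quiet", "--auto", str(fasta)],
                             capture_output=True, text=True, check=True)
    aligned: dict[str, str] = {}
    name = None
    for line in out.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            aligned[name] = ""
        elif name:
            aligned[name] += line.strip().upper()
    return aligned


def build_codon_alignment(cds_by_taxon: dict[str, str]) -> CodonAlignment:
    """Protein-level alignment back-translated to codons.

    Terminal stop codons are stripped first; an internal stop is an error
    naming the taxon and codon. Identical-length inputs that need no gaps
    skip the external aligner.
    """
    clean: dict[str, str] = {}
    proteins: dict[str, str] = {}
    for taxon, cds in cds_by_taxon.items():
        seq = cds.upper()
        if len(seq) % 3:
            raise ValueError(f"{taxon}: CDS length not a multiple of 3")
        if seq[-3:] in STOP_CODONS:
            seq = seq[:-3]
        for i in range(0, len(seq), 3):
            if seq[i:i + 3] in STOP_CODONS:
                raise ValueError(f"{taxon}: internal stop at codon {i // 3 + 1}")
        clean[taxon] = seq
        proteins[taxon] = str(Seq(seq).translate(table=11))

    lengths = {len(p) for p in proteins.values()}
    if len(lengths) == 1:
        aligned_prot = proteins
    else:
        aligned_prot = _align_proteins_mafft(proteins)

    taxa = list(cds_by_taxon)
    rows = []
    for taxon in taxa:
        cds = clean[taxon]
        out, k = [], 0
        for aa in aligned_prot[taxon]:
            if aa == "-":
                out.append("---")
            else:
                out.append(cds[3 * k:3 * k + 3])
                k += 1
        rows.append("".join(out))
    return CodonAlignment(taxa, rows)


# ---------------------------------------------------------------------------
# Branch model fitting
# ---------------------------------------------------------------------------

@dataclass
class BranchModelSpec:
    """Model name plus branch -> omega-class assignment."""

    model: str  # M0 | M2 | M3
    class_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in MODEL_N_CLASSES:
            raise ValueError(f"unknown model {self.model!r}")
        if not self.class_names:
            mapping = {}
            for name, idx in MODEL_CLASSES[self.model]:
                mapping.setdefault(idx, name if self.model != "M2" else
                                   ("autotrophic" if idx == 0 else "parasitic"))
            self.class_names = mapping

    @property
    def n_classes(self) -> int:
        return MODEL_N_CLASSES[self.model]

    def omega_class(self, branch_class: str) -> int:
        for name, idx in MODEL_CLASSES[self.model]:
            if name == branch_class:
                return idx
        raise ValueError(f"branch class {branch_class!r} not mapped")


@dataclass
class BranchModelFit:
    model: str
    lnl: float
    kappa: float
    omega: dict[int, float]           # omega-class index -> estimate
    class_names: dict[int, str]
    codon_freqs: np.ndarray
    branch_lengths: dict[str, float]  # keyed by bipartition/leafset label
    n_free_params: int
    converged: bool
    omega_available: dict[int, bool]

    def omega_by_name(self) -> dict[str, float]:
        return {self.class_names[i]: w for i, w in self.omega.items()}


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


class _TreeIndex:
    """Static traversal order, leaf assignments and branch classes."""

    def __init__(self, tree: PhyloTree, taxa: list[str], model: str):
        self.nodes = list(tree.tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.root = self.nodes[-1]
        self.taxon_of_leaf = {}
        tip_to_row = {t: i for i, t in enumerate(taxa)}
        for node in self.nodes:
            if node.is_leaf():
                label = node.taxon.label
                if label not in tip_to_row:
                    raise ValueError(f"tree tip {label!r} missing from alignment")
                self.taxon_of_leaf[id(node)] = tip_to_row[label]
        # branches: every non-root node owns the edge above it
        self.branch_nodes = [n for n in self.nodes if n is not self.root]
        spec = BranchModelSpec(model)
        if model != "M0" and not tree.classes_assigned():
            raise ValueError(f"model {model} requires branch-class labels")
        self.branch_class = []
        for n in self.branch_nodes:
            cls = tree.node_classes.get(n, "autotrophic") if model != "M0" \
                else "autotrophic"
            self.branch_class.append(spec.omega_class(cls))
        self.init_lengths = [n.edge.length if n.edge.length else 0.05
                             for n in self.branch_nodes]

    def branch_label(self, node) -> str:
        leaves = sorted(l.taxon.label for l in node.leaf_iter())
        return "|".join(leaves)


def _compress_patterns(alignment: CodonAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Codon-state matrix (taxa x patterns; -1 = gap/ambiguous) and counts."""
    n_tax, n_cod = len(alignment.taxa), alignment.n_codons
    states = np.full((n_tax, n_cod), -1, dtype=np.int16)
    for i in range(n_tax):
        row = alignment.rows[i]
        for j in range(n_cod):
            states[i, j] = CODON_INDEX.get(row[3 * j:3 * j + 3], -1)
    patterns, counts = np.unique(states, axis=1, return_counts=True)
    return patterns, counts.astype(float)


class _Likelihood:
    def __init__(self, alignment: CodonAlignment, tree: PhyloTree, model: str):
        self.tidx = _TreeIndex(tree, alignment.taxa, model)
        self.patterns, self.counts = _compress_patterns(alignment)
        self.pi = f3x4_frequencies(empirical_f3x4(alignment.rows))
        self.n_classes = MODEL_N_CLASSES[model]
        self.n_branches = len(self.tidx.branch_nodes)
        # leaf partials cached: (n_patterns, 61) one-hot / ones
        self.leaf_partials = {}
        n_pat = self.patterns.shape[1]
        for node in self.tidx.nodes:
            if node.is_leaf():
                row = self.tidx.taxon_of_leaf[id(node)]
                part = np.zeros((n_pat, N_CODONS))
                st = self.patterns[row]
                gap = st < 0
                part[np.arange(n_pat)[~gap], st[~gap]] = 1.0
                part[gap, :] = 1.0
                self.leaf_partials[id(node)] = part

    def lnl(self, branch_lengths: np.ndarray, kappa: float,
            omegas: np.ndarray) -> float:
        eigs = [_EigenQ(rate_matrix(kappa, w, self.pi), self.pi)
                for w in omegas]
        pmats = {}
        for b, node in enumerate(self.tidx.branch_nodes):
            cls = self.tidx.branch_class[b]
            pmats[id(node)] = eigs[cls].expm(branch_lengths[b])
        n_pat = self.patterns.shape[1]
        partials: dict[int, np.ndarray] = {}
        log_scale = np.zeros(n_pat)
        for node in self.tidx.nodes:
            if node.is_leaf():
                partials[id(node)] = self.leaf_partials[id(node)]
                continue
            part = np.ones((n_pat, N_CODONS))
            for child in node.child_nodes():
                part *= partials.pop(id(child)) @ pmats[id(child)].T
            mx = part.max(axis=1)
            mx[mx == 0.0] = 1e-300
            part /= mx[:, np.newaxis]
            log_scale += np.log(mx)
            partials[id(node)] = part
        site_l = partials[id(self.tidx.root)] @ self.pi
        site_l[site_l <= 0] = 1e-300
        return float(np.dot(self.counts, np.log(site_l) + log_scale))


def fit_branch_model(alignment: CodonAlignment, tree: PhyloTree,
                     spec: BranchModelSpec | str, n_restarts: int = 3,
                     seed: int = 0, init: BranchModelFit | None = None,
                     maxiter: int = 500) -> BranchModelFit:
    """Maximum-likelihood GY94 branch-model fit.

    Branch lengths (expected substitutions per codon) are re-estimated under
    each model together with the shared kappa and one omega per class, using
    L-BFGS-B on log-transformed parameters with ``n_restarts`` jittered
    starts. Passing a fitted nested model as ``init`` warm-starts the
    optimisation (guaranteeing the nesting inequality up to optimiser
    tolerance). Deterministic for a fixed seed.
    """
    model = spec.model if isinstance(spec, BranchModelSpec) else spec
    mspec = spec if isinstance(spec, BranchModelSpec) else BranchModelSpec(model)
    lik = _Likelihood(alignment, tree, model)
    nb, nc = lik.n_branches, lik.n_classes
    rng = np.random.default_rng(seed)

    lo = np.log(np.array([BL_BOUNDS[0]] * nb + [KAPPA_BOUNDS[0]]
                         + [OMEGA_BOUNDS[0]] * nc))
    hi = np.log(np.array([BL_BOUNDS[1]] * nb + [KAPPA_BOUNDS[1]]
                         + [OMEGA_BOUNDS[1]] * nc))

    def unpack(x):
        v = np.exp(x)
        return v[:nb], v[nb], v[nb + 1:]

    def objective(x):
        bl, kappa, om = unpack(x)
        try:
            return -lik.lnl(bl, kappa, om)
        except (np.linalg.LinAlgError, ValueError):  # pragma: no cover
            return 1e12

    starts = []
    if init is not None:
        bl0 = np.array([init.branch_lengths[lik.tidx.branch_label(n)]
                        for n in lik.tidx.branch_nodes])
        om_init = np.empty(nc)
        init_by_name = init.omega_by_name()
        for idx, name in mspec.class_names.items():
            if name in init_by_name:
                om_init[idx] = init_by_name[name]
            elif len(init.omega) == 1:           # M0 -> any class
                om_init[idx] = init.omega[0]
            elif name in ("hemiparasitic", "holoparasitic") and \
                    "parasitic" in init_by_name:  # M2 -> M3
                om_init[idx] = init_by_name["parasitic"]
            else:
                om_init[idx] = init_by_name.get("autotrophic", 0.5)
        starts.append(np.concatenate([np.log(np.clip(bl0, *BL_BOUNDS)),
                                      [np.log(init.kappa)],
                                      np.log(np.clip(om_init, *OMEGA_BOUNDS))]))
    else:
        bl0 = np.clip(np.array(lik.tidx.init_lengths), *BL_BOUNDS)
        starts.append(np.concatenate([np.log(bl0), [np.log(2.0)],
                                      np.full(nc, np.log(0.5))]))
    while len(starts) < max(1, n_restarts):
        jitter = rng.normal(0.0, 0.5, size=len(starts[0]))
        starts.append(np.clip(starts[0] + jitter, lo, hi))

    best = None
    for x0 in starts:
        res = optimize.minimize(objective, np.clip(x0, lo, hi),
                                method="L-BFGS-B",
                                bounds=list(zip(lo, hi)),
                                options={"maxiter": maxiter, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    bl, kappa, om = unpack(best.x)
    lnl = -float(best.fun)

    branch_lengths = {lik.tidx.branch_label(n): float(bl[b])
                      for b, n in enumerate(lik.tidx.branch_nodes)}
    # per-class synonymous tree length: flags omega as unavailable when the
    # class carries (almost) no synonymous substitutions
    omega_available = {}
    for c in range(nc):
        t_class = sum(bl[b] for b in range(nb) if lik.tidx.branch_class[b] == c)
        ds = t_class * synonymous_fraction(kappa, om[c], lik.pi)
        omega_available[c] = bool(ds >= 1e-4)
    return BranchModelFit(
        model=model, lnl=lnl, kappa=float(kappa),
        omega={c: float(om[c]) for c in range(nc)},
        class_names=dict(mspec.class_names),
        codon_freqs=lik.pi, branch_lengths=branch_lengths,
        n_free_params=nb + 1 + nc,
        converged=bool(best.success or best.fun < 1e11),
        omega_available=omega_available,
    )


def likelihood_ratio_test(null_fit: BranchModelFit,
                          alt_fit: BranchModelFit,
                          tolerance: float = 1e-4) -> LRTResult:
    """Chi-square LRT of two nested branch-model fits."""
    stat = 2.0 * (alt_fit.lnl - null_fit.lnl)
    if stat < -tolerance:
        raise RuntimeError(
            f"alternative lnL below null ({alt_fit.lnl:.4f} < {null_fit.lnl:.4f}); "
            "optimiser failure")
    stat = max(stat, 0.0)
    df = alt_fit.n_free_params - null_fit.n_free_params
    if df <= 0:
        raise ValueError("models are not nested (df <= 0)")
    return LRTResult(stat, df, float(stats.chi2.sf(stat, df)))


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


def relaxation_scan(gene_alignments: dict[str, CodonAlignment],
                    tree: PhyloTree, class_map: dict[str, str] | None = None,
                    alpha: float = 0.05, seed: int = 0,
                    n_restarts: int = 1, bh_correction: bool = False):
    """Per-gene M0/M2/M3 fits with M0-vs-M2 and M2-vs-M3 LRTs.

    Models are warm-started along the nesting chain (M0 -> M2 -> M3). Genes
    missing a tree taxon are skipped with a warning. Returns a DataFrame;
    the ``hemi_gt_holo`` column supports the usual "hemiparasitic omega >
    holoparasitic omega" count across genes.
    """
    import pandas as pd

    if class_map is not None:
        tree.assign_branch_classes(class_map)
    tips = set(tree.tip_labels())
    rows = []
    for k, (gene, aln) in enumerate(sorted(gene_alignments.items())):
        if not tips <= set(aln.taxa):
            warnings.warn(f"gene {gene}: missing taxa, skipped")
            continue
        gene_seed = (seed + 1009 * (k + 1)) % (2 ** 31)
        m0 = fit_branch_model(aln, tree, "M0", n_restarts=n_restarts,
                              seed=gene_seed)
        m2 = fit_branch_model(aln, tree, "M2", n_restarts=n_restarts,
                              seed=gene_seed, init=m0)
        m3 = fit_branch_model(aln, tree, "M3", n_restarts=n_restarts,
                              seed=gene_seed, init=m2)
        lrt02 = likelihood_ratio_test(m0, m2)
        lrt23 = likelihood_ratio_test(m2, m3)
        w3 = m3.omega_by_name()
        avail3 = {m3.class_names[i]: a for i, a in m3.omega_available.items()}
        hemi_gt_holo = (w3["hemiparasitic"] > w3["holoparasitic"]) \
            if (avail3.get("hemiparasitic") and avail3.get("holoparasitic")) \
            else None
        rows.append({
            "gene": gene,
            "lnL_M0": m0.lnl, "lnL_M2": m2.lnl, "lnL_M3": m3.lnl,
            "kappa_M0": m0.kappa,
            "omega_M0": m0.omega[0],
            "omega_background_M2": m2.omega[0],
            "omega_parasitic_M2": m2.omega[1],
            "omega_autotrophic_M3": w3["autotrophic"],
            "omega_hemiparasitic_M3": w3["hemiparasitic"],
            "omega_holoparasitic_M3": w3["holoparasitic"],
            "stat_M0_M2": lrt02.statistic, "df_M0_M2": lrt02.df,
            "p_M0_M2": lrt02.p_value,
            "stat_M2_M3": lrt23.statistic, "df_M2_M3": lrt23.df,
            "p_M2_M3": lrt23.p_value,
            "hemi_gt_holo": hemi_gt_holo,
        })
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    p02, p23 = table["p_M0_M2"], table["p_M2_M3"]
    if bh_correction:
        p02 = _benjamini_hochberg(p02.to_numpy())
        p23 = _benjamini_hochberg(p23.to_numpy())
    table["significant_M0_M2"] = p02 < alpha
    table["significant_M2_M3"] = p23 < alpha
    return table
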