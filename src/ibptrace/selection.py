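"""Branch-model dN/dS inference on codon alignments.

Implements a Goldman–Yang-type codon substitution model over the 61 sense
codons of the standard genetic code, Felsenstein pruning for the
log-likelihood, maximum-likelihood fitting of a two-class branch model
(background ω fixed at 1; foreground ω free in the alternative model),
the one-degree-of-freedom likelihood-ratio test, and Bonferroni control
over a batch of branch tests.

Conventions
-----------
* ω (dN/dS) multiplies nonsynonymous single-nucleotide exchange rates;
  κ multiplies transitions; the generator is scaled so the expected
  substitution rate at equilibrium is 1, i.e. branch lengths are expected
  substitutions per codon site.
* The null model optimizes κ and all branch lengths with ω ≡ 1; the
  alternative holds branch lengths at the null optimum and re-optimizes
  (κ, ω_foreground), warm-started at the null solution so the nesting
  inequality lnL1 ≥ lnL0 holds by construction.
* Gap or ambiguous codons are missing data (conditional likelihood 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .seqcore import CodonAlignment, SequenceError, standard_genetic_code

_CODE = standard_genetic_code()
CODONS = [a + b + c for a, b, c in itertools.product("TCAG", repeat=3)
          if _CODE[a + b + c] != "*"]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
CODON_AA = [_CODE[c] for c in CODONS]
N_CODONS = len(CODONS)  # 61

_PURINES = {"A", "G"}


def _classify_pairs():
    """(i, j, is_transition, is_synonymous) for single-nucleotide neighbours."""
    out = []
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            a, b = diffs[0]
            ts = (a in _PURINES) == (b in _PURINES)
            out.append((i, j, ts, CODON_AA[i] == CODON_AA[j]))
    return out


_PAIRS = _classify_pairs()
_PAIR_I = np.array([p[0] for p in _PAIRS])
_PAIR_J = np.array([p[1] for p in _PAIRS])
_PAIR_TS = np.array([p[2] for p in _PAIRS])
_PAIR_SYN = np.array([p[3] for p in _PAIRS])


class SelectionError(ValueError):
    """Invalid model input or a failed likelihood computation."""


def codon_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """61×61 reversible generator; rows sum to 0; mean rate at equilibrium 1."""
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,) or pi.min() < 0 or not math.isclose(
            float(pi.sum()), 1.0, abs_tol=1e-8):
        raise SelectionError("pi must be a distribution over the 61 sense codons")
    if kappa < 0 or omega < 0:
        raise SelectionError("kappa and omega must be non-negative")
    Q = np.zeros((N_CODONS, N_CODONS))
    rates = pi[_PAIR_J] * np.where(_PAIR_TS, kappa, 1.0) \
        * np.where(_PAIR_SYN, 1.0, omega)
    Q[_PAIR_I, _PAIR_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(np.dot(pi, np.diag(Q)))
    if scale <= 0:
        raise SelectionError("degenerate rate matrix (zero total rate)")
    return Q / scale


@dataclass
class CodonBranchModel:
    """Two-class branch model: κ, per-class ω, codon frequencies."""

    kappa: float
    omega_by_class: dict[str, float]
    pi: np.ndarray
    branch_classes: dict[str, str] = field(default_factory=dict)  # edge id -> class

    def rate_matrix(self, branch_class: str = "background") -> np.ndarray:
        return codon_rate_matrix(self.kappa, self.omega_by_class[branch_class],
                                 self.pi)


class _Propagator:
    """Eigendecomposition of a reversible Q in π-symmetrized form."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self.w = w
        self.left = U / d[:, None] * 1.0
        self.right = (U * d[:, None]).T

    def expm(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.w * t)) @ self.right
        np.clip(P, 1e-300, None, out=P)
        return P


def encode_alignment(aln: CodonAlignment) -> tuple[list[str], np.ndarray]:
    """Codon indices per row/site; -1 marks gap or ambiguous (missing data)."""
    ids = aln.ids()
    X = np.full((len(ids), aln.n_codons), -1, dtype=np.int32)
    for r in range(len(ids)):
        for j in range(aln.n_codons):
            X[r, j] = CODON_INDEX.get(aln.codon(r, j), -1)
    return ids, X


def f1x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """F1x4 codon frequencies: product of pooled nucleotide frequencies,
    renormalized over sense codons."""
    counts = {c: 1.0 for c in "TCAG"}  # +1 smoothing
    for row in aln.rows:
        for ch in row.residues:
            if ch in counts:
                counts[ch] += 1.0
    total = sum(counts.values())
    nt_freq = {c: counts[c] / total for c in "TCAG"}
    pi = np.array([nt_freq[c[0]] * nt_freq[c[1]] * nt_freq[c[2]] for c in CODONS])
    return pi / pi.sum()


def _site_patterns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(X, axis=1, return_counts=True)
    return patterns, counts.astype(float)


class TreeLikelihood:
    """Felsenstein pruning over a fixed rooted tree and codon alignment.

    Edges are identified by the child node; ``edge_classes`` maps the child
    key (leaf taxon label, or internal node id assigned in postorder) to
    'background' or 'foreground'.
    """

    def __init__(self, tree: dendropy.Tree, aln: CodonAlignment,
                 pi: np.ndarray | None = None):
        self.tree = tree.clone(depth=1)
        self.tree.is_rooted = True
        ids, X = encode_alignment(aln)
        leaf_labels = {lf.taxon.label for lf in self.tree.leaf_node_iter()}
        if set(ids) != leaf_labels:
            missing = leaf_labels.symmetric_difference(ids)
            raise SelectionError(
                f"alignment rows and tree leaves disagree: {sorted(missing)}")
        self.pi = f1x4_frequencies(aln) if pi is None else np.asarray(pi)
        self.patterns, self.weights = _site_patterns(X)
        self.row_of = {tid: r for r, tid in enumerate(ids)}
        # postorder node bookkeeping; assign stable ids to internal nodes
        self.postorder = list(self.tree.postorder_node_iter())
        n_int = 0
        self.edge_key = {}
        for nd in self.postorder:
            if nd.is_leaf():
                self.edge_key[id(nd)] = nd.taxon.label
            else:
                self.edge_key[id(nd)] = f"node{n_int}"
                nd.label = nd.label or f"node{n_int}"
                n_int += 1
        self.n_sites = int(self.weights.sum())

    def edge_keys(self) -> list[str]:
        """Edge identifiers (child-node keys) excluding the root."""
        root = self.tree.seed_node
        return [self.edge_key[id(nd)] for nd in self.postorder if nd is not root]

    def loglik(self, kappa: float, omega_by_class: dict[str, float],
               branch_lengths: dict[str, float],
               edge_classes: dict[str, str] | None = None) -> float:
        edge_classes = edge_classes or {}
        props = {cls: _Propagator(codon_rate_matrix(kappa, om, self.pi), self.pi)
                 for cls, om in omega_by_class.items()}
        npat = self.patterns.shape[1]
        partial: dict[int, np.ndarray] = {}
        logscale = 0.0
        root = self.tree.seed_node
        for nd in self.postorder:
            if nd.is_leaf():
                codes = self.patterns[self.row_of[nd.taxon.label]]
                Lv = np.zeros((N_CODONS, npat))
                known = codes >= 0
                Lv[:, ~known] = 1.0
                Lv[codes[known], np.nonzero(known)[0]] = 1.0
            else:
                Lv = np.ones((N_CODONS, npat))
                for ch in nd.child_nodes():
                    key = self.edge_key[id(ch)]
                    t = branch_lengths[key]
                    if t < 0:
                        raise SelectionError(f"negative branch length on {key}")
                    cls = edge_classes.get(key, "background")
                    P = props[cls].expm(t)
                    Lv *= P @ partial.pop(id(ch))
                mx = Lv.max(axis=0)
                mx[mx == 0] = 1.0
                Lv /= mx
                logscale += float(self.weights @ np.log(mx))
            partial[id(nd)] = Lv
        site_lik = self.pi @ partial[id(root)]
        if np.any(site_lik <= 0):
            return -np.inf
        return float(self.weights @ np.log(site_lik)) + logscale


def pruning_loglik(tree: dendropy.Tree, aln: CodonAlignment,
                   model: CodonBranchModel,
                   branch_lengths: dict[str, float] | None = None) -> float:
    """Log-likelihood of the alignment under the model.

    Branch lengths default to the lengths stored on the tree's edges.
    """
    tl = TreeLikelihood(tree, aln, pi=model.pi)
    if branch_lengths is None:
        branch_lengths = {}
        root = tl.tree.seed_node
        for nd in tl.postorder:
            if nd is not root:
                branch_lengths[tl.edge_key[id(nd)]] = float(nd.edge.length or 0.0)
    return tl.loglik(model.kappa, model.omega_by_class, branch_lengths,
                     model.branch_classes)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model: CodonBranchModel
    lnl: float
    branch_lengths: dict[str, float]
    converged: bool


def _foreground_edge(tl: TreeLikelihood, foreground_branch) -> str:
    """Resolve a branch spec (leaf label, internal node label, or an iterable
    of leaf labels naming a clade's stem edge) to an edge key."""
    if isinstance(foreground_branch, str):
        for nd in tl.postorder:
            if tl.edge_key[id(nd)] == foreground_branch or \
                    (nd.label == foreground_branch and nd is not tl.tree.seed_node):
                return tl.edge_key[id(nd)]
        raise SelectionError(f"foreground branch {foreground_branch!r} not in tree")
    want = frozenset(foreground_branch)
    for nd in tl.postorder:
        if nd is tl.tree.seed_node:
            continue
        leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if leaves == want:
            return tl.edge_key[id(nd)]
    raise SelectionError(f"no edge subtends exactly {sorted(want)}")


def fit_branch_model(aln: CodonAlignment, tree: dendropy.Tree,
                     foreground_branch=None, variant: str = "null",
                     pi: np.ndarray | None = None, seed: int = 0,
                     null_fit: "FitResult | None" = None,
                     max_iter: int = 200) -> FitResult:
    """Maximum-likelihood fit of the branch model.

    ``variant='null'`` optimizes κ and all branch lengths with ω ≡ 1.
    ``variant='alt'`` requires ``null_fit`` (or computes one), holds its
    branch lengths fixed and optimizes (κ, ω_foreground) with three
    seed-pinned starts, warm-started at the null optimum.
    """
    tl = TreeLikelihood(tree, aln, pi=pi)
    edges = tl.edge_keys()
    fg = _foreground_edge(tl, foreground_branch) if foreground_branch is not None else None

    if variant == "null":
        x0 = np.concatenate(([math.log(2.0)], np.full(len(edges), math.log(0.2))))

        def nll(x):
            kappa = math.exp(x[0])
            bl = {e: math.exp(v) for e, v in zip(edges, x[1:])}
            return -tl.loglik(kappa, {"background": 1.0}, bl)

        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(-4, 4)] + [(-9, 2.5)] * len(edges),
                       options={"maxiter": max_iter, "ftol": 1e-9})
        kappa = math.exp(res.x[0])
        bl = {e: math.exp(v) for e, v in zip(edges, res.x[1:])}
        model = CodonBranchModel(kappa=kappa, omega_by_class={"background": 1.0},
                                 pi=tl.pi)
        return FitResult(model=model, lnl=-float(res.fun), branch_lengths=bl,
                         converged=bool(res.success))

    if variant != "alt":
        raise SelectionError(f"unknown variant {variant!r}")
    if fg is None:
        raise SelectionError("alternative model needs a foreground branch")
    if null_fit is None:
        null_fit = fit_branch_model(aln, tree, variant="null", pi=pi,
                                    max_iter=max_iter)
    bl = null_fit.branch_lengths
    classes = {fg: "foreground"}

    def nll2(x):
        kappa, om = math.exp(x[0]), math.exp(x[1])
        return -tl.loglik(kappa, {"background": 1.0, "foreground": om},
                          bl, classes)

    k0 = math.log(null_fit.model.kappa)
    rng = np.random.default_rng(seed)
    starts = [np.array([k0, 0.0]),
              np.array([k0, math.log(0.3) + 0.05 * rng.standard_normal()]),
              np.array([k0, math.log(3.0) + 0.05 * rng.standard_normal()])]
    best = None
    for x0 in starts:
        res = minimize(nll2, x0, method="L-BFGS-B",
                       bounds=[(-4, 4), (-7, 5)],
                       options={"maxiter": max_iter, "ftol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    lnl1 = -float(best.fun)
    # nesting guarantee: the null point is itself a feasible alt point
    if lnl1 < null_fit.lnl:
        lnl1 = null_fit.lnl
        best_kappa, best_omega = null_fit.model.kappa, 1.0
    else:
        best_kappa, best_omega = math.exp(best.x[0]), math.exp(best.x[1])
    model = CodonBranchModel(
        kappa=best_kappa,
        omega_by_class={"background": 1.0, "foreground": best_omega},
        pi=tl.pi, branch_classes=classes)
    return FitResult(model=model, lnl=lnl1, branch_lengths=bl,
                     converged=bool(best.success))


# ---------------------------------------------------------------------------
# Likelihood-ratio test and multiple-testing control
# ---------------------------------------------------------------------------

@dataclass
class SelectionTestResult:
    gene: str
    branch: str
    lnl0: float
    lnl1: float
    lrt: float
    df: int
    p: float
    significant: bool = False
    omega_fg: float | None = None


@dataclass
class BonferroniDecision:
    family_alpha: float
    m: int
    corrected_alpha: float
    flags: list[bool]


def lrt(lnl0: float, lnl1: float, df: int = 1) -> tuple[float, float]:
    """LRT statistic 2(lnL1 − lnL0) and its upper-tail χ²(df) p-value.

    A deficit beyond 1e-6 indicates a non-converged alternative fit and
    raises; deficits within tolerance clamp to 0.
    """
    if df < 1:
        raise SelectionError("df must be >= 1")
    stat = 2.0 * (lnl1 - lnl0)
    if stat < -1e-6:
        raise SelectionError(
            f"lnL1 ({lnl1}) < lnL0 ({lnl0}): alternative fit did not converge")
    stat = max(stat, 0.0)
    return stat, float(chi2.sf(stat, df))


def bonferroni(pvals: list[float], family_alpha: float = 0.05) -> BonferroniDecision:
    if not pvals:
        raise SelectionError("empty p-value list")
    for p in pvals:
        if not (0.0 <= p <= 1.0):
            raise SelectionError(f"invalid p-value {p}")
    alpha = family_alpha / len(pvals)
    return BonferroniDecision(family_alpha=family_alpha, m=len(pvals),
                              corrected_alpha=alpha,
                              flags=[p < alpha for p in pvals])


def prune_to_taxa(tree: dendropy.Tree, taxa: set[str]) -> dendropy.Tree:
    t = tree.clone(depth=1)
    keep = [lf.taxon for lf in t.leaf_node_iter() if lf.taxon.label in taxa]
    if len(keep) < 2:
        raise SelectionError("fewer than two taxa left after pruning")
    t.retain_taxa(keep)
    t.is_rooted = True
    return t


def run_table_tests(aln_by_gene: dict[str, CodonAlignment],
                    tree: dendropy.Tree,
                    branch_specs: list[tuple[str, str, object]],
                    family_alpha: float = 0.05,
                    seed: int = 0) -> list[SelectionTestResult]:
    """Run the batch of branch tests behind the published selection table.

    ``branch_specs`` holds (gene, branch label, foreground spec) triples;
    for each, the species tree is pruned to the species carrying the gene,
    both models are fitted, and the LRT computed; Bonferroni is applied
    over the whole batch.
    """
    results = []
    for i, (gene, branch_label, fg) in enumerate(branch_specs):
        aln = aln_by_gene[gene]
        sub = prune_to_taxa(tree, set(aln.ids()))
        try:
            null = fit_branch_model(aln, sub, variant="null")
            alt = fit_branch_model(aln, sub, foreground_branch=fg, variant="alt",
                                   null_fit=null, seed=seed + i)
        except SelectionError as err:
            raise SelectionError(f"gene {gene}, branch {branch_label}: {err}") from err
        stat, p = lrt(null.lnl, alt.lnl, df=1)
        results.append(SelectionTestResult(
            gene=gene, branch=branch_label, lnl0=null.lnl, lnl1=alt.lnl,
            lrt=stat, df=1, p=p,
            omega_fg=alt.model.omega_by_class.get("foreground")))
    if results:
        dec = bonferroni([r.p for r in results], family_alpha)
        for r, flag in zip(results, dec.flags):
            r.significant = flag
    return results


def results_to_tsv(results: list[SelectionTestResult]) -> str:
    lines = ["gene\tbranch\tlnL0\tlnL1\tLRT\tdf\tp_value\tsignificant"]
    for r in results:
        lines.append(f"{r.gene}\t{r.branch}\t{r.lnl0:.3f}\t{r.lnl1:.3f}"
                     f"\t{r.lrt:.3f}\t{r.df}\t{r.p:.3g}\t{'*' if r.significant else ''}")
    return "\n".join(lines) + "\n"
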