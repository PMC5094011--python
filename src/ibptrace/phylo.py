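"""Ancestral state reconstruction and gene trees.

Maximum-parsimony reconstruction of binary presence/absence characters on
a fixed rooted species tree (multifurcations handled natively by the
dynamic program), explicit ACCTRAN/DELTRAN event mapping, Dollo parsimony
(single gain, minimized losses), and distance-based gene trees: pairwise
maximum-likelihood distances under the WAG replacement model (or raw
p-distances), neighbor joining, and nonparametric column-resampling
bootstrap.  The gene trees serve topology checks — duplication detection
and the paralogous-family grouping test — not branch-support fidelity.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from ._wag import WAG_FREQS, WAG_ORDER, wag_rate_matrix
from .seqcore import GAP, Msa, read_newick

EQUIVOCAL = "equivocal"


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Tree bookkeeping helpers (shared with the simulator)
# ---------------------------------------------------------------------------

def label_internal_nodes(tree: dendropy.Tree) -> None:
    """Assign stable labels n0.. to unlabelled internal nodes (postorder)."""
    i = 0
    for nd in tree.postorder_node_iter():
        if not nd.is_leaf():
            if not nd.label:
                nd.label = f"n{i}"
            i += 1


def edge_key(node: dendropy.Node) -> str:
    """Edges are identified by their child node: leaf taxon or node label."""
    return node.taxon.label if node.is_leaf() else node.label


def find_stem_edge(tree: dendropy.Tree, spec) -> dendropy.Node:
    """Child node of the edge named by a leaf label, internal label, or a
    collection of leaf labels (the clade's stem edge)."""
    if isinstance(spec, str):
        for nd in tree.preorder_node_iter():
            if nd is tree.seed_node:
                continue
            if edge_key(nd) == spec:
                return nd
        raise PhyloError(f"no edge named {spec!r}")
    want = frozenset(spec)
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        if frozenset(lf.taxon.label for lf in nd.leaf_iter()) == want:
            return nd
    raise PhyloError(f"no edge subtends exactly {sorted(want)}")


# ---------------------------------------------------------------------------
# Maximum parsimony (Fitch) with exact MPR sets
# ---------------------------------------------------------------------------

@dataclass
class AncestralReconstruction:
    tree: dendropy.Tree
    node_states: dict[str, object]      # key -> 0 | 1 | 'equivocal'
    mpr_sets: dict[str, frozenset]
    parsimony_length: int
    criterion: str = "fitch"
    _cost_down: dict[str, tuple[float, float]] = field(default_factory=dict, repr=False)

    def report_tsv(self) -> str:
        lines = ["node\tstate"]
        for key, st in self.node_states.items():
            lines.append(f"{key}\t{st}")
        return "\n".join(lines) + "\n"


def fitch_ancestral(tree: dendropy.Tree, character: dict[str, int]
                    ) -> AncestralReconstruction:
    """Unordered-parsimony reconstruction of a binary character.

    Computes, by a two-pass dynamic program over {0, 1} (valid for
    multifurcating nodes), the global minimum number of state changes and
    the exact set of states each node takes across all most-parsimonious
    resolutions; a node is reported 'equivocal' when that set is not a
    singleton.
    """
    label_internal_nodes(tree)
    leaves = [lf for lf in tree.leaf_node_iter()]
    for lf in leaves:
        if lf.taxon.label not in character:
            raise PhyloError(f"leaf {lf.taxon.label!r} missing from character")

    INF = float("inf")
    down: dict[int, list[float]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            s = int(character[nd.taxon.label])
            down[id(nd)] = [0.0 if s == 0 else INF, 0.0 if s == 1 else INF]
        else:
            cost = [0.0, 0.0]
            for ch in nd.child_nodes():
                dc = down[id(ch)]
                for s in (0, 1):
                    cost[s] += min(dc[0] + (s != 0), dc[1] + (s != 1))
            down[id(nd)] = cost
    root = tree.seed_node
    best = min(down[id(root)])

    # min changes outside each node's subtree, given the node's state
    up: dict[int, list[float]] = {id(root): [0.0, 0.0]}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        for ch in nd.child_nodes():
            u = [INF, INF]
            for sp in (0, 1):
                base = up[id(nd)][sp]
                if base == INF:
                    continue
                for sib in nd.child_nodes():
                    if sib is ch:
                        continue
                    ds = down[id(sib)]
                    base += min(ds[0] + (sp != 0), ds[1] + (sp != 1))
                for s in (0, 1):
                    u[s] = min(u[s], base + (sp != s))
            up[id(ch)] = u

    node_states: dict[str, object] = {}
    mpr: dict[str, frozenset] = {}
    cost_down: dict[str, tuple[float, float]] = {}
    for nd in tree.preorder_node_iter():
        key = edge_key(nd)
        total = [down[id(nd)][s] + up[id(nd)][s] for s in (0, 1)]
        states = frozenset(s for s in (0, 1) if total[s] == best)
        mpr[key] = states
        node_states[key] = next(iter(states)) if len(states) == 1 else EQUIVOCAL
        cost_down[key] = (down[id(nd)][0], down[id(nd)][1])
    return AncestralReconstruction(tree=tree, node_states=node_states,
                                   mpr_sets=mpr, parsimony_length=int(best),
                                   criterion="fitch", _cost_down=cost_down)


def map_events(rec: AncestralReconstruction, resolution: str = "DELTRAN"
               ) -> list[tuple[str, str]]:
    """Resolve equivocal nodes and list per-branch events.

    Gains are 0→1 branches, losses 1→0; the total always equals the
    parsimony length because the resolution is a dynamic-programming
    traceback over the reconstruction's own cost tables.  DELTRAN delays
    changes toward the tips (ties at the root resolve to absent); ACCTRAN
    accelerates them toward the root (root ties resolve to present).
    """
    if resolution not in ("ACCTRAN", "DELTRAN"):
        raise PhyloError(f"unknown resolution {resolution!r}")
    if rec.criterion == "dollo":
        return dollo_events(rec)
    tree = rec.tree
    prefer_root = 0 if resolution == "DELTRAN" else 1
    resolved: dict[int, int] = {}
    events: list[tuple[str, str]] = []
    for nd in tree.preorder_node_iter():
        key = edge_key(nd)
        d0, d1 = rec._cost_down[key]
        if nd is tree.seed_node:
            cand = {s: (d0, d1)[s] for s in (0, 1)}
            m = min(cand.values())
            tied = [s for s in (0, 1) if cand[s] == m]
            resolved[id(nd)] = prefer_root if prefer_root in tied else tied[0]
            continue
        sp = resolved[id(nd.parent_node)]
        cand = {s: (d0, d1)[s] + (s != sp) for s in (0, 1)}
        m = min(cand.values())
        tied = [s for s in (0, 1) if cand[s] == m]
        if len(tied) == 2:
            choice = sp if resolution == "DELTRAN" else 1 - sp
        else:
            choice = tied[0]
        resolved[id(nd)] = choice
        if choice != sp:
            events.append((key, "gain" if choice == 1 else "loss"))
    return events


def dollo_ancestral(tree: dendropy.Tree, character: dict[str, int]
                    ) -> AncestralReconstruction:
    """Dollo parsimony: exactly one gain at the MRCA of the present leaves,
    losses minimized given that constraint."""
    label_internal_nodes(tree)
    for lf in tree.leaf_node_iter():
        if lf.taxon.label not in character:
            raise PhyloError(f"leaf {lf.taxon.label!r} missing from character")
    present = [lf for lf in tree.leaf_node_iter() if character[lf.taxon.label] == 1]
    if not present:
        raise PhyloError("Dollo parsimony needs at least one present leaf "
                         "(no gain placeable on an all-absent character)")
    if len(present) == 1:
        mrca = present[0]
    else:
        mrca = tree.mrca(taxa=[lf.taxon for lf in present])
    # nodes on paths from the MRCA to present leaves carry the character
    on_path: set[int] = set()
    for lf in present:
        nd = lf
        while nd is not None:
            on_path.add(id(nd))
            if nd is mrca:
                break
            nd = nd.parent_node
    states: dict[str, object] = {}
    mpr: dict[str, frozenset] = {}
    in_subtree: set[int] = {id(nd) for nd in mrca.preorder_iter()}
    losses = 0
    for nd in tree.preorder_node_iter():
        key = edge_key(nd)
        s = 1 if id(nd) in on_path else 0
        states[key] = s
        mpr[key] = frozenset((s,))
        if (nd is not tree.seed_node and id(nd) in in_subtree and nd is not mrca
                and s == 0 and id(nd.parent_node) in on_path):
            losses += 1
    return AncestralReconstruction(tree=tree, node_states=states, mpr_sets=mpr,
                                   parsimony_length=1 + losses, criterion="dollo")


def dollo_events(rec: AncestralReconstruction) -> list[tuple[str, str]]:
    tree = rec.tree
    events: list[tuple[str, str]] = []
    for nd in tree.preorder_node_iter():
        key = edge_key(nd)
        s = rec.node_states[key]
        if nd is tree.seed_node:
            if s == 1:
                events.append(("root", "gain"))
            continue
        sp = rec.node_states[edge_key(nd.parent_node)]
        if sp == 0 and s == 1:
            events.append((key, "gain"))
        elif sp == 1 and s == 0:
            events.append((key, "loss"))
    return events


# ---------------------------------------------------------------------------
# Distance-based gene trees
# ---------------------------------------------------------------------------

_WAG_Q = wag_rate_matrix()
_WAG_W, _WAG_U = np.linalg.eigh(
    (_WAG_Q * np.sqrt(WAG_FREQS)[:, None] / np.sqrt(WAG_FREQS)[None, :]
     + (_WAG_Q * np.sqrt(WAG_FREQS)[:, None] / np.sqrt(WAG_FREQS)[None, :]).T) / 2)
_WAG_LEFT = _WAG_U / np.sqrt(WAG_FREQS)[:, None]
_WAG_RIGHT = (_WAG_U * np.sqrt(WAG_FREQS)[:, None]).T
_WAG_INDEX = {a: i for i, a in enumerate(WAG_ORDER)}


def _wag_P(t: float) -> np.ndarray:
    P = (_WAG_LEFT * np.exp(_WAG_W * t)) @ _WAG_RIGHT
    return np.clip(P, 1e-12, None)


def _pair_counts(a: str, b: str) -> np.ndarray:
    C = np.zeros((20, 20))
    for x, y in zip(a, b):
        i, j = _WAG_INDEX.get(x), _WAG_INDEX.get(y)
        if i is not None and j is not None:
            C[i, j] += 1.0
    return C


def wag_ml_distance(a: str, b: str, max_t: float = 15.0) -> float:
    """Pairwise maximum-likelihood distance under the WAG model
    (rate-homogeneous), in expected substitutions per site."""
    C = _pair_counts(a, b)
    n = C.sum()
    if n == 0:
        return max_t
    lnpi = np.log(WAG_FREQS)[:, None]

    def nll(t):
        return -float((C * (lnpi + np.log(_wag_P(t)))).sum())

    res = minimize_scalar(nll, bounds=(1e-6, max_t), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def p_distance(a: str, b: str) -> float:
    pairs = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
    if not pairs:
        return 1.0
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def _distance_matrix(rows: list, model: str) -> DistanceMatrix:
    n = len(rows)
    D = np.zeros((n, n))
    fn = wag_ml_distance if model == "wag" else p_distance
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = fn(rows[i].residues, rows[j].residues)
    return DistanceMatrix(D, ids=[r.id for r in rows])


@dataclass
class GeneTree:
    tree: dendropy.Tree                      # unrooted topology
    supports: dict[frozenset, float]         # leaf-set bipartition -> 0..100
    bootstrap_n: int

    def support_of(self, group) -> float | None:
        """Bootstrap support (%) of the bipartition splitting off ``group``,
        or None when the main tree lacks that edge."""
        leaves = sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())
        g = frozenset(group)
        if leaves[0] in g:
            g = frozenset(leaves) - g
        return self.supports.get(g)


def _nj_tree(rows: list, model: str) -> dendropy.Tree:
    dm = _distance_matrix(rows, model)
    sk = _skbio_nj(dm)
    buf = io.StringIO()
    sk.write(buf)
    tree = read_newick(buf.getvalue())
    tree.is_rooted = False
    return tree


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial unrooted bipartitions, each encoded as the side not
    containing the lexicographically smallest leaf."""
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = leaves[0]
    all_set = frozenset(leaves)
    out = set()
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if anchor in side:
            side = all_set - side
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return out


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted symmetric bipartition distance."""
    b1, b2 = _bipartitions(t1), _bipartitions(t2)
    return len(b1 ^ b2)


def nj_gene_tree(msa: Msa, distance_model: str = "wag", bootstrap_n: int = 100,
                 seed: int = 0) -> GeneTree:
    """Neighbor-joining gene tree with column-resampling bootstrap supports.

    Stands in for a full maximum-likelihood tree search: distances are
    pairwise ML under rate-homogeneous WAG (or p-distances), which
    preserves the topology signal the duplication and paralogy checks
    need.  Deterministic for a fixed seed.
    """
    if msa.n_rows < 4:
        raise PhyloError("gene tree inference needs >= 4 sequences")
    if distance_model not in ("wag", "p-distance"):
        raise PhyloError(f"unknown distance model {distance_model!r}")
    main = _nj_tree(msa.rows, distance_model)
    main_bips = _bipartitions(main)
    counts = {b: 0 for b in main_bips}
    rng = np.random.default_rng(seed)
    from .seqcore import Sequence
    for _ in range(bootstrap_n):
        cols = rng.integers(msa.length, size=msa.length)
        rows = [Sequence(r.id, "".join(r.residues[c] for c in cols), r.alphabet)
                for r in msa.rows]
        rep = _nj_tree(rows, distance_model)
        for b in _bipartitions(rep):
            if b in counts:
                counts[b] += 1
    supports = {b: 100.0 * c / max(bootstrap_n, 1) for b, c in counts.items()}
    for nd in main.preorder_node_iter():
        if nd is main.seed_node or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        leaves = sorted(lf.taxon.label for lf in main.leaf_node_iter())
        if leaves[0] in side:
            side = frozenset(leaves) - side
        if side in supports:
            nd.label = f"{supports[side]:.0f}"
    return GeneTree(tree=main, supports=supports, bootstrap_n=bootstrap_n)


# ---------------------------------------------------------------------------
# Duplication and paralogy checks
# ---------------------------------------------------------------------------

@dataclass
class DuplicationFlag:
    species: str
    kind: str            # 'recent' (sister copies) | 'ancient' (non-monophyletic)
    leaves: list[str]


def _is_separable(tree: dendropy.Tree, group: set[str]) -> bool:
    """True iff one edge bipartitions the leaves into group vs rest."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    rest = leaves - group
    if not rest:
        return True
    if len(group) == 1:
        return True
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        side = {lf.taxon.label for lf in nd.leaf_iter()}
        if side == group or side == rest:
            return True
    return False


def detect_duplications(gene_tree: GeneTree,
                        species_of: dict[str, str]) -> list[DuplicationFlag]:
    """Flag species whose multiple gene copies look duplicated.

    Copies that are each other's sisters (the species' leaves form their
    own clade) flag 'recent' duplication or assembly redundancy;
    non-monophyletic copies flag a candidate pre-speciation ('ancient')
    duplication.
    """
    tree = gene_tree.tree
    by_species: dict[str, list[str]] = {}
    for lf in tree.leaf_node_iter():
        sp = species_of.get(lf.taxon.label)
        if sp is None:
            raise PhyloError(f"leaf {lf.taxon.label!r} has no species mapping")
        by_species.setdefault(sp, []).append(lf.taxon.label)
    flags = []
    for sp, lv in sorted(by_species.items()):
        if len(lv) < 2:
            continue
        kind = "recent" if _is_separable(tree, set(lv)) else "ancient"
        flags.append(DuplicationFlag(species=sp, kind=kind, leaves=sorted(lv)))
    return flags


def paralogy_test(family_a: Msa, family_b: Msa, distance_model: str = "wag",
                  bootstrap_n: int = 0, seed: int = 0
                  ) -> tuple[bool, GeneTree]:
    """Do family A's sequences nest inside family B's subtree?

    Builds a joint gene tree over both families (rows must share a common
    alignment length) and reports grouped=True when no single edge
    separates A from B — the situation in which A is a paralog arising
    within B.  An A placed as sister to all of B is not grouped.
    """
    ids_a = set(family_a.ids())
    ids_b = set(family_b.ids())
    if ids_a & ids_b:
        raise PhyloError(f"overlapping ids: {sorted(ids_a & ids_b)}")
    if family_a.length != family_b.length:
        raise PhyloError("families must share a common alignment length")
    joint = Msa(family_a.rows + family_b.rows)
    gt = nj_gene_tree(joint, distance_model=distance_model,
                      bootstrap_n=max(bootstrap_n, 1), seed=seed)
    grouped = not _is_separable(gt.tree, ids_a)
    return grouped, gt
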