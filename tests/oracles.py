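"""Independent brute-force oracles shared by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration or an
independent numerical route, never by calling the code path it checks.
"""

import itertools
import math

import numpy as np
from scipy.linalg import expm as scipy_expm

from ibptrace.phmm import AAS, ProfileHMM, encode_protein
from ibptrace.selection import CODON_INDEX, N_CODONS, codon_rate_matrix

_N_AA = len(AAS)


def oracle_forward_bits(profile: ProfileHMM, residues: str) -> float:
    """Sum over all state paths of the profile's local-alignment
    architecture, in linear probability space."""
    x = encode_protein(residues)
    L = len(x)
    k = profile.n_match
    ploop = L / (L + 2.0)
    exit_p = profile.exit_probs()
    bg = profile.background

    def em_odds(j, code):
        if code == _N_AA + 1:      # stop
            return 0.0
        if code == _N_AA:          # X / unknown
            return 1.0
        return profile.match_emissions[j, code] / bg[code]

    def ins_odds(code):
        return 0.0 if code == _N_AA + 1 else 1.0

    def tail(idx):
        return ploop ** (L - idx) * (1.0 - ploop)

    def from_M(idx, j):
        if idx >= L:
            return 0.0
        w = em_odds(j, x[idx])
        if w == 0.0:
            return 0.0
        out = exit_p[j] * tail(idx + 1)
        cont = 1.0 - exit_p[j]
        if cont > 0 and j + 1 < k:
            out += cont * profile.t_mm[j] * from_M(idx + 1, j + 1)
            out += cont * profile.t_mi[j] * from_I(idx + 1, j)
            out += cont * profile.t_md[j] * from_D(idx + 1, j + 1)
        return w * out

    def from_I(idx, j):
        if idx >= L:
            return 0.0
        w = ins_odds(x[idx])
        if w == 0.0:
            return 0.0
        return w * (profile.t_ii[j] * from_I(idx + 1, j)
                    + profile.t_im[j] * from_M(idx + 1, j + 1))

    def from_D(idx, j):
        if j == k - 1:
            return tail(idx)
        return (profile.t_dd[j] * from_D(idx, j + 1)
                + profile.t_dm[j] * from_M(idx, j + 1))

    total = 0.0
    for i0 in range(L):
        flank = ploop ** i0 * (1.0 - ploop)
        for j in range(k):
            total += flank / k * from_M(i0, j)
    r = L / (L + 1.0)
    null_len = r ** L * (1.0 - r)
    if total == 0.0:
        return -math.inf
    return math.log2(total / null_len)


def parsimony_enumeration(tree, character):
    """Exhaustive minimum-change count and per-node optimal state sets for
    a binary character on a rooted tree (any degree)."""
    nodes = list(tree.preorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    leaves = [nd for nd in nodes if nd.is_leaf()]
    best = None
    opt = []
    for combo in itertools.product((0, 1), repeat=len(internal)):
        state = {id(nd): s for nd, s in zip(internal, combo)}
        for lf in leaves:
            state[id(lf)] = character[lf.taxon.label]
        changes = sum(1 for nd in nodes if nd.parent_node is not None
                      and state[id(nd)] != state[id(nd.parent_node)])
        if best is None or changes < best:
            best, opt = changes, [state]
        elif changes == best:
            opt.append(state)
    sets = {id(nd): frozenset(st[id(nd)] for st in opt) for nd in nodes}
    return best, sets


def pruning_3taxon_oracle(aln, kappa, omega_by_class, classes, pi, blens):
    """Brute-force log-likelihood for the rooted tree (A,(B,C)): sums over
    all 61x61 root/inner codon assignments; transition probabilities from
    scipy's Pade matrix exponential."""
    Qs = {c: codon_rate_matrix(kappa, om, pi) for c, om in omega_by_class.items()}

    def P(edge, t):
        return scipy_expm(Qs[classes.get(edge, "background")] * t)

    Pa, Pb = P("A", blens["A"]), P("B", blens["B"])
    Pc, Pu = P("C", blens["C"]), P("inner", blens["inner"])
    idx = {r.id: [CODON_INDEX[r.residues[3 * j:3 * j + 3]]
                  for j in range(len(r.residues) // 3)] for r in aln.rows}
    lnl = 0.0
    for s in range(len(idx["A"])):
        a, b, c = idx["A"][s], idx["B"][s], idx["C"][s]
        total = 0.0
        for r in range(N_CODONS):
            inner = 0.0
            for u in range(N_CODONS):
                inner += Pu[r, u] * Pb[u, b] * Pc[u, c]
            total += pi[r] * Pa[r, a] * inner
        lnl += math.log(total)
    return lnl
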