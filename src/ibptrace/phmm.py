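"""Profile hidden Markov models for remote-homology screening.

A simplified Plan7-like architecture: flanking background states (N, C)
around a linear core of match/insert/delete states, with uniform local
entry into any match state and uniform local exit, single-hit.  Scoring is
log-odds against an i.i.d. background null, so flanking and insert
emissions contribute zero and the reported score is in bits, comparable
across targets.  Stop codons ('*') have zero emission probability in all
core states, which confines matches to stop-free stretches of a translated
frame.

E-values come from an explicit Gumbel calibration on background-random
sequences rather than an analytic formula; the calibration is seed-pinned
and stored next to the profile.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence as TypingSequence

import numpy as np
from scipy.stats import gumbel_r

try:                                  # compiled DP kernels; numpy fallback below
    from numba import njit as _njit
    _HAVE_NUMBA = True
except Exception:                     # pragma: no cover
    _HAVE_NUMBA = False

from .seqcore import AA, NT, Msa, Sequence, SequenceError, translate_six_frames

AAS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AAS)}
_N_AA = len(AAS)
# extended residue codes: 20 = unknown/X (zero log-odds), 21 = stop (forbidden)
_X_CODE = _N_AA
_STOP_CODE = _N_AA + 1

LN2 = math.log(2.0)


class ProfileError(ValueError):
    """Invalid profile construction or scoring input."""


def encode_protein(residues: str) -> np.ndarray:
    out = np.empty(len(residues), dtype=np.int8)
    for i, ch in enumerate(residues.upper()):
        if ch == "*":
            out[i] = _STOP_CODE
        else:
            out[i] = AA_INDEX.get(ch, _X_CODE)
    return out


@dataclass
class ProfileHMM:
    """Position-specific emission/transition model built from a seed MSA."""

    name: str
    match_emissions: np.ndarray      # (k, 20) rows sum to 1
    insert_emissions: np.ndarray     # (k, 20)
    t_mm: np.ndarray                 # (k,) Mj -> Mj+1 (core, before local exit mixing)
    t_mi: np.ndarray
    t_md: np.ndarray
    t_ii: np.ndarray
    t_im: np.ndarray
    t_dd: np.ndarray
    t_dm: np.ndarray
    background: np.ndarray           # (20,)

    def __post_init__(self) -> None:
        k = self.n_match
        if k < 1:
            raise ProfileError("profile needs at least one match state")
        for name, arr, axis_sum in (("match_emissions", self.match_emissions, 1),
                                    ("insert_emissions", self.insert_emissions, 1)):
            s = np.asarray(arr).sum(axis=axis_sum)
            if not np.allclose(s, 1.0, atol=1e-9):
                raise ProfileError(f"{name} rows must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ProfileError("background must sum to 1")
        tri = self.t_mm + self.t_mi + self.t_md
        if not np.allclose(tri, 1.0, atol=1e-9):
            raise ProfileError("match transition triples must sum to 1")
        if not (np.allclose(self.t_ii + self.t_im, 1.0, atol=1e-9)
                and np.allclose(self.t_dd + self.t_dm, 1.0, atol=1e-9)):
            raise ProfileError("insert/delete transition pairs must sum to 1")

    @property
    def n_match(self) -> int:
        return int(np.asarray(self.match_emissions).shape[0])

    # -- local-alignment wrapper parameters (architecture, not learned) -----

    def entry_logprob(self) -> float:
        """Uniform local entry B->Mj."""
        return -math.log(self.n_match)

    def exit_probs(self) -> np.ndarray:
        """Uniform local exit: P(Mj -> E) = 1/(k-j) for 0-based j; M_last -> E = 1."""
        k = self.n_match
        return 1.0 / (k - np.arange(k))

    def match_log_odds(self) -> np.ndarray:
        """(k, 22) log2-free natural-log odds ln(e/bg); X scores 0, '*' -inf."""
        with np.errstate(divide="ignore"):
            lo = np.log(self.match_emissions) - np.log(self.background)[None, :]
        k = self.n_match
        ext = np.full((k, _N_AA + 2), -np.inf)
        ext[:, :_N_AA] = lo
        ext[:, _X_CODE] = 0.0
        return ext

    def to_json(self) -> str:
        payload = {
            "format": "ibptrace-profile", "version": 1, "name": self.name,
            "alphabet": AAS,
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "transitions": {t: getattr(self, t).tolist()
                            for t in ("t_mm", "t_mi", "t_md", "t_ii", "t_im",
                                      "t_dd", "t_dm")},
            "background": self.background.tolist(),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ProfileHMM":
        d = json.loads(text)
        if d.get("format") != "ibptrace-profile":
            raise ProfileError("not an ibptrace profile JSON document")
        tr = {k: np.asarray(v, dtype=float) for k, v in d["transitions"].items()}
        return cls(name=d["name"],
                   match_emissions=np.asarray(d["match_emissions"], dtype=float),
                   insert_emissions=np.asarray(d["insert_emissions"], dtype=float),
                   background=np.asarray(d["background"], dtype=float), **tr)


@dataclass
class EvalueCalibration:
    """Gumbel (EVD) fit to forward bit scores of background-random sequences."""

    lambda_: float
    mu: float
    n_calibration: int
    seed: int
    length: int
    db_size: int = 1

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ProfileError("Gumbel lambda must be positive")
        if self.n_calibration < 200:
            raise ProfileError("calibration needs >= 200 random sequences")

    def evalue(self, bit_score: float, db_size: int | None = None) -> float:
        db = self.db_size if db_size is None else db_size
        return float(db * gumbel_r.sf(bit_score, loc=self.mu, scale=1.0 / self.lambda_))


@dataclass
class HmmHit:
    target_id: str
    frame: int | None
    bit_score: float
    e_value: float
    env_start: int
    env_end: int
    model_start: int
    model_end: int


@dataclass
class DomainCopy:
    start: int
    end: int
    bit_score: float
    e_value: float


@dataclass
class DomainAnnotation:
    domain: str
    copies: list[DomainCopy] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.copies)


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------

def build_profile(msa: Msa, name: str | None = None, match_threshold: float = 0.5,
                  pseudocount_weight: float = 20.0,
                  background: np.ndarray | None = None) -> ProfileHMM:
    """Estimate a profile HMM from a seed alignment.

    Columns whose non-gap fraction is at least ``match_threshold`` become
    match states.  Match emissions are smoothed counts,
    ``(observed + pseudocount_weight * background) / (n + pseudocount_weight)``;
    the background defaults to the amino-acid frequency pooled over the
    whole MSA (uniform if the MSA has no standard residues) and may be
    overridden.  Insert emissions use the background.  Transitions are bigram counts along each row's state
    path with a +1 pseudocount.
    """
    n = msa.n_rows
    if n < 2:
        raise ProfileError("profile building needs an alignment with >= 2 rows")

    cols = []
    for j in range(msa.length):
        col = msa.column(j).upper()
        nongap = sum(1 for c in col if c != "-")
        cols.append((col, nongap / n))
    match_cols = [j for j, (_, f) in enumerate(cols) if f >= match_threshold]
    if not match_cols:
        raise ProfileError("no column passes the match threshold (all-gap alignment?)")
    k = len(match_cols)

    pooled = np.zeros(_N_AA)
    for col, _ in cols:
        for c in col:
            if c in AA_INDEX:
                pooled[AA_INDEX[c]] += 1
    if background is None:
        background = pooled / pooled.sum() if pooled.sum() > 0 \
            else np.full(_N_AA, 1.0 / _N_AA)
        # keep background strictly positive so log-odds stay finite
        if (background == 0).any():
            background = (pooled + 1.0) / (pooled.sum() + _N_AA)
    else:
        background = np.asarray(background, dtype=float)

    match_em = np.zeros((k, _N_AA))
    for mi, j in enumerate(match_cols):
        counts = np.zeros(_N_AA)
        for c in cols[j][0]:
            if c in AA_INDEX:
                counts[AA_INDEX[c]] += 1
        total = counts.sum()
        match_em[mi] = (counts + pseudocount_weight * background) / (
            total + pseudocount_weight) if (total + pseudocount_weight) > 0 else background
        if pseudocount_weight == 0 and total == 0:
            match_em[mi] = background.copy()
    insert_em = np.tile(background, (k, 1))

    # transition counts along each row's M/I/D state path
    is_match = np.zeros(msa.length, dtype=bool)
    is_match[match_cols] = True
    cMM = np.ones(k); cMI = np.ones(k); cMD = np.ones(k)
    cII = np.ones(k); cIM = np.ones(k)
    cDD = np.ones(k); cDM = np.ones(k)
    for row in msa.rows:
        path: list[tuple[str, int]] = []
        mi = -1
        for j, c in enumerate(row.residues.upper()):
            if is_match[j]:
                mi += 1
                path.append(("M" if c != "-" else "D", mi))
            elif c != "-":
                path.append(("I", mi))
        for (s1, j1), (s2, _) in zip(path, path[1:]):
            idx = max(j1, 0)
            if s1 == "M":
                (cMM if s2 == "M" else cMI if s2 == "I" else cMD)[idx] += 1
            elif s1 == "I":
                (cII if s2 == "I" else cIM)[idx] += 1
            else:
                (cDD if s2 == "D" else cDM)[idx] += 1
    tri = cMM + cMI + cMD
    return ProfileHMM(
        name=name or "profile",
        match_emissions=match_em, insert_emissions=insert_em,
        t_mm=cMM / tri, t_mi=cMI / tri, t_md=cMD / tri,
        t_ii=cII / (cII + cIM), t_im=cIM / (cII + cIM),
        t_dd=cDD / (cDD + cDM), t_dm=cDM / (cDD + cDM),
        background=background)


# ---------------------------------------------------------------------------
# Forward / Viterbi scoring
# ---------------------------------------------------------------------------

def _arch_params(profile: ProfileHMM, L: int):
    """Precompute log transition terms of the local-alignment architecture."""
    k = profile.n_match
    ploop = L / (L + 2.0)
    with np.errstate(divide="ignore"):
        lp, lq = math.log(ploop), math.log(1.0 - ploop)
        e = profile.exit_probs()
        ln_exit = np.log(e)
        ln_cont = np.log1p(-e)             # -inf at the last match state
        t_mmx = ln_cont + np.log(profile.t_mm)
        t_mix = ln_cont + np.log(profile.t_mi)
        t_mdx = ln_cont + np.log(profile.t_md)
        t_ii = np.log(profile.t_ii)
        t_im = np.log(profile.t_im)
        t_dd = np.log(profile.t_dd)
        t_dm = np.log(profile.t_dm)
        # null length model: geometric with r = L/(L+1)
        r = L / (L + 1.0)
        ln_null = L * math.log(r) + math.log(1.0 - r)
    entry = profile.entry_logprob()
    C = np.cumsum(t_dd)                    # C[j] = sum_{m<=j} ln tDD[m]
    return k, lp, lq, entry, ln_exit, t_mmx, t_mix, t_mdx, t_ii, t_im, t_dd, t_dm, C, ln_null


def _insert_odds(code: int) -> float:
    return -np.inf if code == _STOP_CODE else 0.0


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _logadd(a, b):
        if a == -np.inf:
            return b
        if b == -np.inf:
            return a
        if a < b:
            a, b = b, a
        return a + math.log1p(math.exp(b - a))

    @_njit(cache=False)
    def _forward_kernel(em, iem, t_mmx, t_im, t_dm, t_mix, t_ii, t_mdx, C,
                        ln_exit, lp, lq, entry):
        L, k = em.shape
        neg = -np.inf
        M = np.full(k, neg)
        I = np.full(k, neg)
        D = np.full(k, neg)
        Mn = np.empty(k)
        In = np.empty(k)
        Dn = np.empty(k)
        total = neg
        for i in range(1, L + 1):
            b_prev = (i - 1) * lp + lq
            for j in range(k):
                acc = b_prev + entry
                if j > 0:
                    acc = _logadd(acc, M[j - 1] + t_mmx[j - 1])
                    acc = _logadd(acc, I[j - 1] + t_im[j - 1])
                    acc = _logadd(acc, D[j - 1] + t_dm[j - 1])
                Mn[j] = em[i - 1, j] + acc
            for j in range(k):
                In[j] = iem[i - 1] + _logadd(M[j] + t_mix[j], I[j] + t_ii[j])
            run = neg
            Dn[0] = neg
            for j in range(1, k):
                run = _logadd(run, Mn[j - 1] + t_mdx[j - 1] - C[j - 1])
                Dn[j] = C[j - 1] + run
            e_i = Dn[k - 1]
            for j in range(k):
                e_i = _logadd(e_i, Mn[j] + ln_exit[j])
            total = _logadd(total, e_i + (L - i) * lp + lq)
            M, Mn = Mn, M
            I, In = In, I
            D, Dn = Dn, D
        return total

    @_njit(cache=False)
    def _viterbi_score_kernel(em, iem, t_mmx, t_im, t_dm, t_mix, t_ii, t_mdx,
                              C, ln_exit, lp, lq, entry):
        L, k = em.shape
        neg = -np.inf
        M = np.full(k, neg)
        I = np.full(k, neg)
        D = np.full(k, neg)
        Mn = np.empty(k)
        In = np.empty(k)
        Dn = np.empty(k)
        best = neg
        for i in range(1, L + 1):
            b_prev = (i - 1) * lp + lq
            for j in range(k):
                acc = b_prev + entry
                if j > 0:
                    v = M[j - 1] + t_mmx[j - 1]
                    if v > acc:
                        acc = v
                    v = I[j - 1] + t_im[j - 1]
                    if v > acc:
                        acc = v
                    v = D[j - 1] + t_dm[j - 1]
                    if v > acc:
                        acc = v
                Mn[j] = em[i - 1, j] + acc
                a = M[j] + t_mix[j]
                b = I[j] + t_ii[j]
                In[j] = iem[i - 1] + (a if a >= b else b)
            run = neg
            Dn[0] = neg
            for j in range(1, k):
                v = Mn[j - 1] + t_mdx[j - 1] - C[j - 1]
                if v > run:
                    run = v
                Dn[j] = C[j - 1] + run
            tail = (L - i) * lp + lq
            e_i = Dn[k - 1]
            for j in range(k):
                v = Mn[j] + ln_exit[j]
                if v > e_i:
                    e_i = v
            if e_i + tail > best:
                best = e_i + tail
            M, Mn = Mn, M
            I, In = In, I
            D, Dn = Dn, D
        return best

    @_njit(cache=False)
    def _viterbi_kernel(em, iem, t_mmx, t_im, t_dm, t_mix, t_ii, t_mdx, C,
                        ln_exit, lp, lq, entry, Ms, Is, Ds, ptrM, ptrI):
        L, k = em.shape
        neg = -np.inf
        for i in range(1, L + 1):
            b_prev = (i - 1) * lp + lq
            for j in range(k):
                best = b_prev + entry
                ptr = 0
                if j > 0:
                    v = Ms[i - 1, j - 1] + t_mmx[j - 1]
                    if v > best:
                        best, ptr = v, 1
                    v = Is[i - 1, j - 1] + t_im[j - 1]
                    if v > best:
                        best, ptr = v, 2
                    v = Ds[i - 1, j - 1] + t_dm[j - 1]
                    if v > best:
                        best, ptr = v, 3
                Ms[i, j] = em[i - 1, j] + best
                ptrM[i, j] = ptr
                a = Ms[i - 1, j] + t_mix[j]
                b = Is[i - 1, j] + t_ii[j]
                if a >= b:
                    Is[i, j] = iem[i - 1] + a
                    ptrI[i, j] = 0
                else:
                    Is[i, j] = iem[i - 1] + b
                    ptrI[i, j] = 1
            run = neg
            Ds[i, 0] = neg
            for j in range(1, k):
                v = Ms[i, j - 1] + t_mdx[j - 1] - C[j - 1]
                if v > run:
                    run = v
                Ds[i, j] = C[j - 1] + run
        best = neg
        bi = 0
        bj = 0
        bstate = 0        # 0 = from M, 1 = from last D
        for i in range(1, L + 1):
            tail = (L - i) * lp + lq
            for j in range(k):
                sc = Ms[i, j] + ln_exit[j] + tail
                if sc > best:
                    best, bi, bj, bstate = sc, i, j, 0
            sc = Ds[i, k - 1] + tail
            if sc > best:
                best, bi, bj, bstate = sc, i, k - 1, 1
        return best, bi, bj, bstate


def forward_bits(profile: ProfileHMM, seq: Sequence) -> float:
    """Log₂-odds forward score of ``seq`` against the profile.

    Sums over all local alignments of the core model to any subsequence;
    -inf when the sequence offers no stop-free residue to match.
    """
    x = encode_protein(seq.residues if isinstance(seq, Sequence) else seq)
    L = len(x)
    if L == 0:
        raise ProfileError("cannot score an empty sequence")
    (k, lp, lq, entry, ln_exit, t_mmx, t_mix, t_mdx,
     t_ii, t_im, t_dd, t_dm, C, ln_null) = _arch_params(profile, L)
    lodds = profile.match_log_odds()

    if _HAVE_NUMBA:
        em = np.ascontiguousarray(lodds[:, x].T)
        iem = np.where(x == _STOP_CODE, -np.inf, 0.0)
        total = _forward_kernel(em, iem, t_mmx, t_im, t_dm, t_mix,
                                t_ii, t_mdx, C, ln_exit, lp, lq, entry)
        return (total - ln_null) / LN2

    neg = -np.inf
    M = np.full(k, neg)
    I = np.full(k, neg)
    D = np.full(k, neg)
    ends = np.full(L, neg)      # E(i) + tail flank terms
    with np.errstate(invalid="ignore", divide="ignore"):
        for i in range(1, L + 1):
            em = lodds[:, x[i - 1]]
            b_prev = (i - 1) * lp + lq
            from_b = b_prev + entry
            shift_m = np.concatenate(([neg], M[:-1] + t_mmx[:-1]))
            shift_i = np.concatenate(([neg], I[:-1] + t_im[:-1]))
            shift_d = np.concatenate(([neg], D[:-1] + t_dm[:-1]))
            m_new = em + np.logaddexp(np.logaddexp(from_b, shift_m),
                                      np.logaddexp(shift_i, shift_d))
            iem = _insert_odds(x[i - 1])
            i_new = iem + np.logaddexp(M + t_mix, I + t_ii)
            a = m_new + t_mdx - C
            acc = np.logaddexp.accumulate(a)
            d_new = np.full(k, neg)
            d_new[1:] = C[:-1] + acc[:-1]
            M, I, D = m_new, i_new, d_new
            e_i = np.logaddexp(_logsumexp(M + ln_exit), D[k - 1])
            ends[i - 1] = e_i + (L - i) * lp + lq
    total = _logsumexp(ends)
    return (total - ln_null) / LN2


def _logsumexp(v: np.ndarray) -> float:
    m = np.max(v)
    if not np.isfinite(m):
        return float(m) if m == -np.inf else float(m)
    return float(m + np.log(np.sum(np.exp(v - m))))


def viterbi_bits(profile: ProfileHMM, seq: Sequence) -> float:
    """Best-path (Viterbi) bit score only; a cheap lower bound on
    :func:`forward_bits`, used as a search prefilter."""
    x = encode_protein(seq.residues if isinstance(seq, Sequence) else seq)
    L = len(x)
    if L == 0:
        raise ProfileError("cannot score an empty sequence")
    (k, lp, lq, entry, ln_exit, t_mmx, t_mix, t_mdx,
     t_ii, t_im, t_dd, t_dm, C, ln_null) = _arch_params(profile, L)
    lodds = profile.match_log_odds()
    if _HAVE_NUMBA:
        em = np.ascontiguousarray(lodds[:, x].T)
        iem = np.where(x == _STOP_CODE, -np.inf, 0.0)
        score = _viterbi_score_kernel(em, iem, t_mmx, t_im, t_dm, t_mix,
                                      t_ii, t_mdx, C, ln_exit, lp, lq, entry)
        return (score - ln_null) / LN2
    bits, _, _ = viterbi(profile, seq)
    return bits


def viterbi(profile: ProfileHMM, seq: Sequence):
    """Best single local alignment: (bits, (env_start, env_end), (m_start, m_end)).

    Envelope coordinates are 0-based half-open on the sequence; model
    coordinates are 0-based half-open over match states.
    """
    x = encode_protein(seq.residues if isinstance(seq, Sequence) else seq)
    L = len(x)
    if L == 0:
        raise ProfileError("cannot score an empty sequence")
    (k, lp, lq, entry, ln_exit, t_mmx, t_mix, t_mdx,
     t_ii, t_im, t_dd, t_dm, C, ln_null) = _arch_params(profile, L)
    lodds = profile.match_log_odds()
    neg = -np.inf

    Ms = np.full((L + 1, k), neg)
    Is = np.full((L + 1, k), neg)
    Ds = np.full((L + 1, k), neg)
    ptrM = np.zeros((L + 1, k), dtype=np.int8)   # 0=B 1=M 2=I 3=D
    ptrI = np.zeros((L + 1, k), dtype=np.int8)   # 0=M 1=I
    if _HAVE_NUMBA:
        em2 = np.ascontiguousarray(lodds[:, x].T)
        iem2 = np.where(x == _STOP_CODE, -np.inf, 0.0)
        score, bi, bj, bstate = _viterbi_kernel(
            em2, iem2, t_mmx, t_im, t_dm, t_mix, t_ii, t_mdx, C, ln_exit,
            lp, lq, entry, Ms, Is, Ds, ptrM, ptrI)
        best = (score, None if score == neg else
                ("D" if bstate else "M", bi, bj))
        return _viterbi_traceback(best, Ms, Is, Ds, ptrM, ptrI, t_mdx, C,
                                  ln_null, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        for i in range(1, L + 1):
            em = lodds[:, x[i - 1]]
            b_prev = (i - 1) * lp + lq
            cand = np.stack([
                np.full(k, b_prev + entry),
                np.concatenate(([neg], Ms[i - 1, :-1] + t_mmx[:-1])),
                np.concatenate(([neg], Is[i - 1, :-1] + t_im[:-1])),
                np.concatenate(([neg], Ds[i - 1, :-1] + t_dm[:-1])),
            ])
            ptrM[i] = np.argmax(cand, axis=0)
            Ms[i] = em + np.max(cand, axis=0)
            iem = _insert_odds(x[i - 1])
            ci = np.stack([Ms[i - 1] + t_mix, Is[i - 1] + t_ii])
            ptrI[i] = np.argmax(ci, axis=0)
            Is[i] = iem + np.max(ci, axis=0)
            a = Ms[i] + t_mdx - C
            acc = np.maximum.accumulate(a)
            Ds[i, 1:] = C[:-1] + acc[:-1]

        # best ending point
        best = (neg, None)
        for i in range(1, L + 1):
            tail = (L - i) * lp + lq
            mj = int(np.argmax(Ms[i] + ln_exit))
            sc = Ms[i, mj] + ln_exit[mj] + tail
            if sc > best[0]:
                best = (sc, ("M", i, mj))
            sc_d = Ds[i, k - 1] + tail
            if sc_d > best[0]:
                best = (sc_d, ("D", i, k - 1))
    return _viterbi_traceback(best, Ms, Is, Ds, ptrM, ptrI, t_mdx, C,
                              ln_null, k)


def _viterbi_traceback(best, Ms, Is, Ds, ptrM, ptrI, t_mdx, C, ln_null, k):
    bits = (best[0] - ln_null) / LN2
    if best[1] is None or not np.isfinite(bits):
        return bits, (0, 0), (0, 0)

    # traceback to the entry match state
    state, i, j = best[1]
    match_pos: list[tuple[int, int]] = []
    while True:
        if state == "D":
            vals = Ms[i, :j] + t_mdx[:j] - C[:j]
            j = int(np.argmax(vals))
            state = "M"
            continue
        if state == "M":
            match_pos.append((i, j))
            p = ptrM[i, j]
            if p == 0:
                break
            if p == 1:
                i, j, state = i - 1, j - 1, "M"
            elif p == 2:
                i, j, state = i - 1, j - 1, "I"
            else:
                i, j, state = i - 1, j - 1, "D"
            continue
        # insert
        if ptrI[i, j] == 0:
            i, state = i - 1, "M"
        else:
            i = i - 1
    match_pos.reverse()
    env = (match_pos[0][0] - 1, match_pos[-1][0])
    mspan = (match_pos[0][1], match_pos[-1][1] + 1)
    return bits, env, mspan


# ---------------------------------------------------------------------------
# Calibration and search
# ---------------------------------------------------------------------------

def random_background_sequence(background: np.ndarray, length: int,
                               rng: np.random.Generator) -> str:
    idx = rng.choice(_N_AA, size=length, p=background)
    return "".join(AAS[i] for i in idx)


def calibrate(profile: ProfileHMM, n: int = 200, length: int = 250,
              seed: int = 0, db_size: int = 1) -> EvalueCalibration:
    """Fit a Gumbel law to forward bit scores of background-random sequences."""
    if n < 200:
        raise ProfileError("calibration needs n >= 200")
    rng = np.random.default_rng(seed)
    scores = np.array([
        forward_bits(profile, Sequence(f"cal{i}", random_background_sequence(
            profile.background, length, rng), AA))
        for i in range(n)])
    if float(np.std(scores)) < 1e-9:
        raise ProfileError("degenerate calibration score variance; increase n or length")
    mu, beta = gumbel_r.fit(scores)
    return EvalueCalibration(lambda_=1.0 / beta, mu=float(mu), n_calibration=n,
                             seed=seed, length=length, db_size=db_size)


def search(profile: ProfileHMM, calibration: EvalueCalibration,
           targets: Iterable[Sequence], e_threshold: float = 1e-14,
           db_size: int | None = None) -> list[HmmHit]:
    """Scan targets (protein, or nucleotide via six frames) for the profile.

    For nucleotide targets the best frame per target is reported.  The
    effective database size defaults to the number of frames actually
    scored.
    """
    targets = list(targets)
    # Viterbi prefilter: a frame whose best-path score sits more than
    # `margin` bits below the score needed to reach the E-value threshold
    # (at db_size 1, the most conservative choice) cannot pass, since the
    # forward score exceeds the Viterbi score by far less than that.
    margin = 15.0
    if math.isfinite(e_threshold) and e_threshold < 1.0:
        s_star = float(gumbel_r.isf(e_threshold, loc=calibration.mu,
                                    scale=1.0 / calibration.lambda_))
    else:
        s_star = -math.inf

    def _score(frame_seq):
        if viterbi_bits(profile, frame_seq) + margin < s_star:
            return None
        return forward_bits(profile, frame_seq)

    scored: list[tuple[Sequence, int | None, float]] = []
    n_frames = 0
    for t in targets:
        if t.alphabet == NT:
            best = None
            for fr in translate_six_frames(t):
                if len(fr) == 0:
                    continue
                n_frames += 1
                b = _score(fr)
                if b is not None and (best is None or b > best[2]):
                    best = (fr, fr.frame, b)
            if best is not None:
                scored.append(best)
        else:
            n_frames += 1
            b = _score(t)
            if b is not None:
                scored.append((t, t.frame, b))
    db = db_size if db_size is not None else max(n_frames, 1)
    hits = []
    for frame_seq, frame, bits in scored:
        ev = calibration.evalue(bits, db_size=db)
        if ev <= e_threshold:
            _, env, mspan = viterbi(profile, frame_seq)
            tid = frame_seq.id.split("|frame")[0]
            hits.append(HmmHit(target_id=tid, frame=frame, bit_score=float(bits),
                               e_value=ev, env_start=env[0], env_end=env[1],
                               model_start=mspan[0], model_end=mspan[1]))
    hits.sort(key=lambda h: (h.e_value, -h.bit_score, h.target_id))
    return hits


def scan_domains(seq: Sequence, domain_profiles: TypingSequence[ProfileHMM],
                 calibrations: TypingSequence[EvalueCalibration],
                 e_threshold: float = 1e-3) -> list[DomainAnnotation]:
    """Greedy non-overlapping placement of significant domain copies.

    Each profile is scanned repeatedly with previously claimed envelopes
    masked out (masked residues behave like stops), so tandem copies are
    recovered one per iteration; across profiles, candidate envelopes are
    accepted best-score-first without overlap.
    """
    candidates: list[tuple[float, float, int, int, str]] = []
    for prof, cal in zip(domain_profiles, calibrations):
        residues = list(seq.residues)
        while True:
            masked = Sequence(seq.id, "".join(residues), AA)
            bits, env, _ = viterbi(prof, masked)
            if not np.isfinite(bits) or env[1] <= env[0]:
                break
            ev = cal.evalue(bits)
            if ev > e_threshold:
                break
            candidates.append((bits, ev, env[0], env[1], prof.name))
            for p in range(env[0], env[1]):
                residues[p] = "*"
    candidates.sort(key=lambda c: -c[0])
    claimed: list[tuple[int, int]] = []
    by_domain: dict[str, list[DomainCopy]] = {}
    for bits, ev, s, e, name in candidates:
        if any(s < ce and e > cs for cs, ce in claimed):
            continue
        claimed.append((s, e))
        by_domain.setdefault(name, []).append(DomainCopy(s, e, bits, ev))
    out = []
    for name in sorted(by_domain):
        copies = sorted(by_domain[name], key=lambda c: c.start)
        out.append(DomainAnnotation(domain=name, copies=copies))
    return out


def hits_to_tsv(hits: Iterable[HmmHit]) -> str:
    lines = ["target_id\tframe\tbit_score\te_value\tenv_start\tenv_end"]
    for h in hits:
        fr = "n/a" if h.frame is None else f"{h.frame:+d}"
        lines.append(f"{h.target_id}\t{fr}\t{h.bit_score:.3f}\t{h.e_value:.3g}"
                     f"\t{h.env_start}\t{h.env_end}")
    return "\n".join(lines) + "\n"
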