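"""Profile HMM construction, forward scoring, calibration, search, domain scan.

The forward algorithm is checked against an independent brute-force
path-enumeration oracle that walks the same local-alignment architecture
recursively in linear probability space.
"""

import math

import numpy as np
import pytest

from oracles import oracle_forward_bits

from ibptrace.phmm import (AAS, DomainAnnotation, ProfileHMM, build_profile,
                           calibrate, encode_protein, forward_bits, scan_domains,
                           search, viterbi)
from ibptrace.seqcore import AA, NT, Msa, Sequence

N_AA = len(AAS)
UNIFORM = np.full(N_AA, 1.0 / N_AA)


def _toy_profile(match_rows, t=None, background=None, name="toy"):
    """Hand-assembled profile with simple positional transitions."""
    em = np.asarray(match_rows, dtype=float)
    k = em.shape[0]
    bg = UNIFORM if background is None else np.asarray(background)
    t = t or {}
    ones = np.ones(k)
    return ProfileHMM(
        name=name, match_emissions=em, insert_emissions=np.tile(bg, (k, 1)),
        t_mm=ones * t.get("mm", 0.8), t_mi=ones * t.get("mi", 0.1),
        t_md=ones * t.get("md", 0.1), t_ii=ones * t.get("ii", 0.4),
        t_im=ones * t.get("im", 0.6), t_dd=ones * t.get("dd", 0.3),
        t_dm=ones * t.get("dm", 0.7), background=bg)


def _one_hot(letter):
    v = np.full(N_AA, 1e-12)
    v[AAS.index(letter)] = 1.0
    return v / v.sum()


class TestBuildProfile:
    def test_degenerate_single_column(self):
        msa = Msa([Sequence(f"r{i}", "A", AA) for i in range(3)])
        prof = build_profile(msa, match_threshold=0.5, pseudocount_weight=0.0)
        assert prof.n_match == 1
        assert prof.match_emissions[0, AAS.index("A")] == pytest.approx(1.0)

    def test_laplace_style_smoothing(self):
        msa = Msa([Sequence("r1", "A", AA), Sequence("r2", "C", AA)])
        prof = build_profile(msa, pseudocount_weight=20.0, background=UNIFORM)
        assert prof.match_emissions[0, AAS.index("A")] == pytest.approx(2.0 / 22.0)
        assert prof.match_emissions[0, AAS.index("C")] == pytest.approx(2.0 / 22.0)
        assert prof.match_emissions[0].sum() == pytest.approx(1.0)

    def test_gappy_columns_become_inserts(self):
        rows = [Sequence("r1", "MA-", AA), Sequence("r2", "MCW", AA),
                Sequence("r3", "M--", AA), Sequence("r4", "MD-", AA)]
        prof = build_profile(Msa(rows), match_threshold=0.5)
        # col 0 (4/4) and col 1 (3/4) are matches; col 2 (1/4) is an insert
        assert prof.n_match == 2

    def test_all_gap_errors(self):
        msa = Msa([Sequence("r1", "--", AA), Sequence("r2", "--", AA)])
        with pytest.raises(Exception):
            build_profile(msa, match_threshold=0.5)

    def test_json_roundtrip(self):
        msa = Msa([Sequence("r1", "MKV", AA), Sequence("r2", "MKI", AA)])
        prof = build_profile(msa)
        back = ProfileHMM.from_json(prof.to_json())
        np.testing.assert_allclose(back.match_emissions, prof.match_emissions)
        np.testing.assert_allclose(back.t_mm, prof.t_mm)


class TestForward:
    def test_single_state_hand_enumeration(self):
        prof = _toy_profile([_one_hot("A")])
        got = forward_bits(prof, Sequence("s", "A", AA))
        # L=1, k=1: one path — enter, emit, exit (prob 1), empty flanks
        ploop = 1 / 3
        odds = (1 - ploop) * prof.match_emissions[0, AAS.index("A")] / (1 / 20) \
            * 1.0 * (1 - ploop)
        null = (1 / 2) * (1 / 2)
        assert got == pytest.approx(math.log2(odds / null), abs=1e-9)
        assert got == pytest.approx(oracle_forward_bits(prof, "A"), abs=1e-9)

    def test_background_profile_scores_near_zero(self):
        prof = _toy_profile([UNIFORM, UNIFORM, UNIFORM])
        bits = forward_bits(prof, Sequence("s", "MKVAWL", AA))
        assert bits <= 1.0

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        letters = list(AAS)
        for trial in range(30):
            k = int(rng.integers(1, 4))
            em = rng.dirichlet(np.full(N_AA, 0.5), size=k)
            t = {"mm": 0.7, "mi": 0.2, "md": 0.1, "ii": 0.5, "im": 0.5,
                 "dd": 0.4, "dm": 0.6}
            prof = _toy_profile(em, t=t)
            L = int(rng.integers(1, 5))
            s = "".join(rng.choice(letters, size=L))
            if trial % 5 == 0 and L > 1:
                s = s[:1] + "*" + s[2:]
            got = forward_bits(prof, Sequence("s", s, AA))
            want = oracle_forward_bits(prof, s)
            if math.isinf(want):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(want, abs=1e-6)

    def test_stop_only_sequence_is_minus_inf(self):
        prof = _toy_profile([_one_hot("A")])
        assert math.isinf(forward_bits(prof, Sequence("s", "***", AA)))

    def test_long_sequence_stays_finite(self):
        rng = np.random.default_rng(1)
        prof = _toy_profile(rng.dirichlet(np.ones(N_AA), size=4))
        s = "".join(rng.choice(list(AAS), size=10_000))
        assert math.isfinite(forward_bits(prof, Sequence("s", s, AA)))

    def test_viterbi_not_above_forward(self):
        rng = np.random.default_rng(5)
        prof = _toy_profile(rng.dirichlet(np.ones(N_AA), size=3))
        for _ in range(10):
            s = "".join(rng.choice(list(AAS), size=12))
            vb, _, _ = viterbi(prof, Sequence("s", s, AA))
            assert vb <= forward_bits(prof, Sequence("s", s, AA)) + 1e-9


@pytest.fixture(scope="module")
def family_profile():
    """Small conserved family and its profile + calibration."""
    rng = np.random.default_rng(99)
    base = "".join(rng.choice(list(AAS), size=120))
    rows = []
    for i in range(6):
        mutated = list(base)
        for p in rng.choice(120, size=12, replace=False):
            mutated[p] = AAS[rng.integers(N_AA)]
        rows.append(Sequence(f"m{i}", "".join(mutated), AA))
    prof = build_profile(Msa(rows), name="fam")
    cal = calibrate(prof, n=200, length=150, seed=0)
    return base, prof, cal


class TestCalibrationAndSearch:
    def test_calibration_deterministic(self, family_profile):
        _, prof, cal = family_profile
        again = calibrate(prof, n=200, length=150, seed=0)
        assert (again.lambda_, again.mu) == (cal.lambda_, cal.mu)

    def test_gumbel_location_property(self, family_profile):
        _, prof, cal = family_profile
        rng = np.random.default_rng(123)
        from ibptrace.phmm import random_background_sequence
        scores = [forward_bits(prof, Sequence("r", random_background_sequence(
            prof.background, 150, rng), AA)) for _ in range(200)]
        frac = np.mean(np.asarray(scores) > cal.mu)
        assert abs(frac - (1 - math.exp(-1))) < 0.12

    def test_evalue_monotone_in_score(self, family_profile):
        _, prof, cal = family_profile
        evs = [cal.evalue(s) for s in (0.0, 5.0, 20.0, 80.0)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_planted_ortholog_recovered(self, family_profile):
        base, prof, cal = family_profile
        rng = np.random.default_rng(17)
        member = Sequence("planted", base, AA)
        decoys = [Sequence(f"d{i}", "".join(rng.choice(list(AAS), size=140)), AA)
                  for i in range(30)]
        hits = search(prof, cal, [member] + decoys, e_threshold=1e-14)
        assert [h.target_id for h in hits] == ["planted"]
        assert hits[0].e_value <= 1e-14

    def test_nucleotide_target_best_frame(self, family_profile):
        base, prof, cal = family_profile
        from ibptrace.synthio import backtranslate_protein
        rng = np.random.default_rng(31)
        nt = backtranslate_protein(base, rng)
        rc = Sequence("tr", nt).reverse_complement().residues
        hits = search(prof, cal, [Sequence("tr", rc)], e_threshold=1e-14)
        assert len(hits) == 1
        assert hits[0].frame < 0

    def test_threshold_monotonicity(self, family_profile):
        base, prof, cal = family_profile
        rng = np.random.default_rng(8)
        targets = [Sequence("m", base, AA)] + [
            Sequence(f"d{i}", "".join(rng.choice(list(AAS), size=120)), AA)
            for i in range(10)]
        loose = {h.target_id for h in search(prof, cal, targets, e_threshold=math.inf)}
        tight = {h.target_id for h in search(prof, cal, targets, e_threshold=1e-14)}
        assert tight <= loose
        assert len(loose) == len(targets)


@pytest.fixture(scope="module")
def zf_profile():
    rng = np.random.default_rng(55)
    motif = "".join(rng.choice(list(AAS), size=23))
    rows = []
    for i in range(5):
        m = list(motif)
        for p in rng.choice(23, size=2, replace=False):
            m[p] = AAS[rng.integers(N_AA)]
        rows.append(Sequence(f"r{i}", "".join(m), AA))
    prof = build_profile(Msa(rows), name="zf-C2H2-like")
    cal = calibrate(prof, n=200, length=80, seed=2)
    return motif, prof, cal


class TestScanDomains:
    def test_twelve_tandem_copies(self, zf_profile):
        motif, prof, cal = zf_profile
        rng = np.random.default_rng(4)
        linkers = ["".join(rng.choice(list(AAS), size=6)) for _ in range(12)]
        protein = "".join(m + l for m, l in zip([motif] * 12, linkers))
        anns = scan_domains(Sequence("p", protein, AA), [prof], [cal])
        assert len(anns) == 1
        assert anns[0].count == 12

    def test_background_sequence_empty(self, zf_profile):
        _, prof, cal = zf_profile
        rng = np.random.default_rng(9)
        s = Sequence("bg", "".join(rng.choice(list(AAS), size=200)), AA)
        assert scan_domains(s, [prof], [cal]) == []

    def test_two_domains_in_coordinate_order(self, zf_profile):
        motif, prof, cal = zf_profile
        rng = np.random.default_rng(10)
        linker = "".join(rng.choice(list(AAS), size=40))
        protein = motif + linker + motif
        anns = scan_domains(Sequence("p", protein, AA), [prof], [cal])
        assert anns[0].count == 2
        c0, c1 = anns[0].copies
        assert c0.end <= c1.start

    def test_padding_invariance(self, zf_profile):
        motif, prof, cal = zf_profile
        rng = np.random.default_rng(12)
        pad = "".join(rng.choice(list(AAS), size=50))
        n_bare = scan_domains(Sequence("p", motif + motif, AA), [prof], [cal])
        n_padded = scan_domains(Sequence("p", pad + motif + motif + pad, AA),
                                [prof], [cal])
        assert n_bare[0].count == n_padded[0].count == 2
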