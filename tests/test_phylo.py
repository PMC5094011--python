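"""Ancestral state reconstruction, event mapping, gene trees, paralogy.

Parsimony results are verified against exhaustive enumeration of all
internal-node state assignments.
"""

import numpy as np
import pytest

from oracles import parsimony_enumeration as enumeration_oracle

from ibptrace.phylo import (EQUIVOCAL, GeneTree, PhyloError, detect_duplications,
                            dollo_ancestral, fitch_ancestral, map_events,
                            nj_gene_tree, paralogy_test, robinson_foulds)
from ibptrace.seqcore import AA, Msa, Sequence, read_newick
from ibptrace.synthio import gen_family, gen_species_tree, FamilyConfig




class TestFitch:
    def test_two_cherry_example(self):
        tree = read_newick("((A,B),(C,D));")
        rec = fitch_ancestral(tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert rec.parsimony_length == 1
        root_key = [k for k, v in rec.mpr_sets.items()
                    if k.startswith("n") and v == frozenset((0, 1))]
        assert rec.node_states[rec.tree.seed_node.label] == EQUIVOCAL
        states = rec.node_states
        cherry_states = sorted(v for k, v in states.items()
                               if k.startswith("n") and v != EQUIVOCAL)
        assert cherry_states == [0, 1]

    def test_constant_character(self):
        tree = read_newick("((A,B),(C,D));")
        rec = fitch_ancestral(tree, {s: 1 for s in "ABCD"})
        assert rec.parsimony_length == 0
        assert all(v == 1 for v in rec.node_states.values())

    def test_missing_leaf_named(self):
        tree = read_newick("((A,B),(C,D));")
        with pytest.raises(PhyloError, match="C"):
            fitch_ancestral(tree, {"A": 1, "B": 0, "D": 0})

    def test_random_trees_match_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for trial in range(100):
            tree = gen_species_tree(8, seed=trial)
            char = {lf.taxon.label: int(rng.integers(2))
                    for lf in tree.leaf_node_iter()}
            rec = fitch_ancestral(tree, char)
            want_len, want_sets = enumeration_oracle(tree, char)
            assert rec.parsimony_length == want_len
            for nd in tree.preorder_node_iter():
                key = nd.taxon.label if nd.is_leaf() else nd.label
                assert rec.mpr_sets[key] == want_sets[id(nd)], (trial, key)

    def test_multifurcation_handled(self):
        tree = read_newick("((A,B,C),(D,E));")
        rec = fitch_ancestral(tree, {"A": 1, "B": 1, "C": 0, "D": 0, "E": 0})
        want_len, _ = enumeration_oracle(tree, {"A": 1, "B": 1, "C": 0,
                                                "D": 0, "E": 0})
        assert rec.parsimony_length == want_len


class TestMapEvents:
    def test_deltran_single_gain_on_cherry_stem(self):
        tree = read_newick("((A,B),(C,D));")
        rec = fitch_ancestral(tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        events = map_events(rec, "DELTRAN")
        assert len(events) == 1
        key, kind = events[0]
        assert kind == "gain"
        # the branch subtending {A, B}
        stem = [nd.label for nd in tree.preorder_node_iter()
                if not nd.is_leaf() and
                {l.taxon.label for l in nd.leaf_iter()} == {"A", "B"}][0]
        assert key == stem

    def test_constant_character_no_events(self):
        tree = read_newick("((A,B),(C,D));")
        rec = fitch_ancestral(tree, {s: 0 for s in "ABCD"})
        assert map_events(rec, "DELTRAN") == []

    def test_event_count_conserved_both_resolutions(self):
        rng = np.random.default_rng(5)
        for trial in range(50):
            tree = gen_species_tree(7, seed=100 + trial)
            char = {lf.taxon.label: int(rng.integers(2))
                    for lf in tree.leaf_node_iter()}
            rec = fitch_ancestral(tree, char)
            for res in ("ACCTRAN", "DELTRAN"):
                assert len(map_events(rec, res)) == rec.parsimony_length

    def test_scattered_presence_matches_oracle_minimum(self):
        tree = read_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        char = {"A": 1, "B": 0, "C": 1, "D": 0, "E": 0, "F": 1, "G": 0, "H": 0}
        rec = fitch_ancestral(tree, char)
        want_len, _ = enumeration_oracle(tree, char)
        assert len(map_events(rec, "DELTRAN")) == want_len


class TestDollo:
    def test_root_gain_two_losses(self):
        tree = read_newick("((A,B),(C,D));")
        rec = dollo_ancestral(tree, {"A": 1, "B": 0, "C": 1, "D": 0})
        events = map_events(rec)
        gains = [e for e in events if e[1] == "gain"]
        losses = [e for e in events if e[1] == "loss"]
        assert len(gains) == 1 and len(losses) == 2
        assert rec.parsimony_length == 3

    def test_cherry_confined_equals_fitch(self):
        tree = read_newick("((A,B),(C,D));")
        char = {"A": 1, "B": 1, "C": 0, "D": 0}
        dollo = dollo_ancestral(tree, char)
        fitch = fitch_ancestral(tree, char)
        assert dollo.parsimony_length == fitch.parsimony_length == 1
        events = map_events(dollo)
        assert events == [(e := events[0][0], "gain")]

    def test_all_absent_errors(self):
        tree = read_newick("((A,B),(C,D));")
        with pytest.raises(PhyloError, match="gain"):
            dollo_ancestral(tree, {s: 0 for s in "ABCD"})

    def test_dollo_never_below_fitch(self):
        rng = np.random.default_rng(9)
        for trial in range(100):
            tree = gen_species_tree(8, seed=300 + trial)
            char = {lf.taxon.label: int(rng.integers(2))
                    for lf in tree.leaf_node_iter()}
            if not any(char.values()):
                continue
            f = fitch_ancestral(tree, char).parsimony_length
            d = dollo_ancestral(tree, char).parsimony_length
            assert d >= f


def _mutate_at(base, positions, rng):
    letters = "ACDEFGHIKLMNPQRSTVWY"
    out = list(base)
    for p in positions:
        out[p] = letters[(letters.index(out[p]) + 1 + int(rng.integers(18))) % 20]
    return "".join(out)


class TestGeneTree:
    def test_nj_recovers_additive_split(self):
        rng = np.random.default_rng(2)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        base1 = "".join(rng.choice(letters, size=120))
        base2 = _mutate_at(base1, rng.choice(120, size=40, replace=False), rng)
        s1 = Sequence("a1", base1, AA)
        s2 = Sequence("a2", _mutate_at(base1, rng.choice(120, 5, replace=False), rng), AA)
        s3 = Sequence("b1", base2, AA)
        s4 = Sequence("b2", _mutate_at(base2, rng.choice(120, 5, replace=False), rng), AA)
        gt = nj_gene_tree(Msa([s1, s2, s3, s4]), distance_model="p-distance",
                          bootstrap_n=10, seed=0)
        from ibptrace.phylo import _bipartitions
        assert frozenset({"b1", "b2"}) in _bipartitions(gt.tree)

    def test_duplicate_pair_full_support(self):
        rng = np.random.default_rng(3)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        base = "".join(rng.choice(letters, size=100))
        far1 = _mutate_at(base, rng.choice(100, 40, replace=False), rng)
        far2 = _mutate_at(base, rng.choice(100, 40, replace=False), rng)
        rows = [Sequence("d1", base, AA), Sequence("d2", base, AA),
                Sequence("x1", far1, AA), Sequence("x2", far2, AA)]
        gt = nj_gene_tree(Msa(rows), distance_model="p-distance",
                          bootstrap_n=20, seed=1)
        assert gt.support_of({"d1", "d2"}) == 100.0

    def test_too_few_rows(self):
        rows = [Sequence(f"r{i}", "MKV", AA) for i in range(3)]
        with pytest.raises(PhyloError):
            nj_gene_tree(Msa(rows))

    def test_simulated_family_topology_recovery(self):
        hits = 0
        for seed in range(20):
            tree = gen_species_tree(8, seed=1000 + seed)
            fam = gen_family(FamilyConfig("fam", [("zf-C2H2", 14)], divergence=0.3,
                                          linker_length=14),
                             tree, seed=seed)
            rows = [Sequence(sp, s, AA) for sp, s in sorted(fam.per_species.items())]
            gt = nj_gene_tree(Msa(rows), distance_model="p-distance",
                              bootstrap_n=1, seed=seed)
            if robinson_foulds(gt.tree, tree) == 0:
                hits += 1
        assert hits >= 18


class TestDuplications:
    @staticmethod
    def _family_rows(seed=0, n=6, div=30):
        rng = np.random.default_rng(seed)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        base = "".join(rng.choice(letters, size=150))
        rows, seqs = [], {}
        for i in range(n):
            s = _mutate_at(base, rng.choice(150, div + 5 * i, replace=False), rng)
            rows.append(Sequence(f"sp{i}_t1", s, AA))
            seqs[f"sp{i}"] = s
        return rows, seqs, rng

    def test_single_copy_species_no_flags(self):
        rows, _, _ = self._family_rows()
        gt = nj_gene_tree(Msa(rows), distance_model="p-distance",
                          bootstrap_n=1, seed=0)
        species_of = {r.id: r.id.split("_")[0] for r in rows}
        assert detect_duplications(gt, species_of) == []

    def test_recent_duplication_flagged(self):
        rows, seqs, rng = self._family_rows(seed=4)
        near = _mutate_at(seqs["sp0"], rng.choice(150, 2, replace=False), rng)
        rows.append(Sequence("sp0_t2", near, AA))
        gt = nj_gene_tree(Msa(rows), distance_model="p-distance",
                          bootstrap_n=1, seed=0)
        species_of = {r.id: r.id.split("_")[0] for r in rows}
        flags = detect_duplications(gt, species_of)
        assert [f.kind for f in flags if f.species == "sp0"] == ["recent"]

    def test_ancient_duplication_flagged(self):
        rows, seqs, rng = self._family_rows(seed=8)
        # sp0's second copy resembles sp4's gene, not sp0's
        stray = _mutate_at(seqs["sp4"], rng.choice(150, 2, replace=False), rng)
        rows.append(Sequence("sp0_t2", stray, AA))
        gt = nj_gene_tree(Msa(rows), distance_model="p-distance",
                          bootstrap_n=1, seed=0)
        species_of = {r.id: r.id.split("_")[0] for r in rows}
        flags = detect_duplications(gt, species_of)
        assert [f.kind for f in flags if f.species == "sp0"] == ["ancient"]


class TestParalogy:
    @staticmethod
    def _rows(base, prefix, n, rng, div=8):
        return [Sequence(f"{prefix}{i}", _mutate_at(
            base, rng.choice(len(base), div, replace=False), rng), AA)
            for i in range(n)]

    def test_separated_families_not_grouped(self):
        rng = np.random.default_rng(6)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        base_a = "".join(rng.choice(letters, size=130))
        base_b = _mutate_at(base_a, rng.choice(130, 60, replace=False), rng)
        fa = Msa(self._rows(base_a, "zw5_", 3, rng))
        fb = Msa(self._rows(base_b, "meics_", 4, rng))
        grouped, _ = paralogy_test(fa, fb, distance_model="p-distance")
        assert grouped is False

    def test_nested_duplicate_grouped(self):
        rng = np.random.default_rng(7)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        base_b = "".join(rng.choice(letters, size=130))
        rows_b = self._rows(base_b, "meics_", 5, rng, div=25)
        # family A arises as a recent duplicate of one B member
        inner = rows_b[2].residues
        fa = Msa(self._rows(inner, "zw5_", 2, rng, div=3))
        grouped, _ = paralogy_test(fa, Msa(rows_b), distance_model="p-distance")
        assert grouped is True

    def test_singleton_outgroup_not_grouped(self):
        rng = np.random.default_rng(11)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        base_b = "".join(rng.choice(letters, size=130))
        rows_b = self._rows(base_b, "meics_", 4, rng, div=10)
        outg = _mutate_at(base_b, rng.choice(130, 70, replace=False), rng)
        fa = Msa([Sequence("zw5_0", outg, AA)])
        grouped, _ = paralogy_test(fa, Msa(rows_b), distance_model="p-distance")
        assert grouped is False

    def test_overlapping_ids_error(self):
        rows = [Sequence("x", "MKVL", AA), Sequence("y", "MKVI", AA)]
        with pytest.raises(PhyloError, match="overlap"):
            paralogy_test(Msa(rows), Msa([Sequence("x", "MKVA", AA),
                                          Sequence("z", "MKIA", AA)]))
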