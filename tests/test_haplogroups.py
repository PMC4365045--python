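"""Tree loading, cumulative states, classification, sub-clade discovery,
motif search, clade origin flagging and the ancestry component."""

import itertools

import numpy as np
import pytest

from mitophylogeo.haplogroups import (
    Classification,
    MotifDatabase,
    MotifRecord,
    ancestry_component,
    classify,
    cumulative_states,
    discover_subclades,
    flag_clade_origin,
    load_tree,
    motif_search,
    node_state_profile,
)
from mitophylogeo.nomenclature import (
    HaplotypeProfile,
    parse_motif,
    restrict_range,
)
from mitophylogeo.simulate import SimulationConfig, simulate_haplotype_for, toy_tree

class TestLoadTree:
    def test_hv9c_toy_tree(self, hv9c_tree):
        node = hv9c_tree.find("HV9c")
        assert node is not None
        assert [v.render() for v in node.defining_variants] == ["T6248C", "@16311"]

    def test_u7a4_nest(self, u7a4_tree):
        names = [n.name for n, _ in u7a4_tree.walk()]
        assert names == [
            "U7a4", "U7a4a", "U7a4a1", "U7a4a1a", "U7a4a1a1", "U7a4a1a1a", "U7a4a1b",
        ]
        assert [v.render() for v in u7a4_tree.find("U7a4a1b").defining_variants] == [
            "T143C", "C12063T", "A15322G",
        ]

    def test_empty_text_rejected(self):
        with pytest.raises(ValueError):
            load_tree("")

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            load_tree("A: T152C\n  A: T195C\n")

    def test_back_mutation_reverts_state(self, hv9c_tree):
        states = cumulative_states(hv9c_tree)
        hv9 = {v.render() for v in states["HV9"].values()}
        hv9c = {v.render() for v in states["HV9c"].values()}
        assert "T16311C" in hv9
        assert hv9c == {"T6248C"}


class TestClassify:
    def test_perfect_match_scores_one(self, hv9c_tree):
        profile = node_state_profile(hv9c_tree, "HV9c1")
        top = classify(profile, hv9c_tree)[0]
        assert top.best_node == "HV9c1"
        assert top.score == 1.0
        assert top.private == ()

    def test_extra_variant_reported_private(self, hv9c_tree):
        base = node_state_profile(hv9c_tree, "HV9c")
        extra = parse_motif("A9000G").variants[0]
        profile = HaplotypeProfile(
            sample_id="x", variants=base.variants + (extra,)
        )
        top = classify(profile, hv9c_tree)[0]
        assert top.best_node == "HV9c"
        assert [v.render() for v in top.private] == ["A9000G"]

    def test_score_monotone_under_expected_deletions(self, u7a4_tree):
        full = node_state_profile(u7a4_tree, "U7a4a1a1a")
        variants = list(full.variants)
        prev = 1.0
        while variants:
            variants.pop()
            profile = HaplotypeProfile(sample_id="x", variants=tuple(variants))
            results = classify(profile, u7a4_tree)
            score = next(r.score for r in results if r.best_node == "U7a4a1a1a")
            assert score <= prev + 1e-12
            prev = score

    def test_empty_tree_rejected(self):
        with pytest.raises(ValueError):
            classify(parse_motif("A73G"), None)

    def test_simulated_profiles_recover_generating_node(self):
        """>=95% of simulated haplotypes classify to their generating node
        or a descendant of it."""
        tree = toy_tree()
        states = cumulative_states(tree)
        names = sorted(states)
        cfg = SimulationConfig(seed=11)
        rng = np.random.default_rng(11)
        ok = 0
        total = 200
        for i in range(total):
            truth = names[rng.integers(len(names))]
            prof = simulate_haplotype_for(truth, states, cfg, rng, f"s{i}")
            best = classify(prof, tree)[0].best_node
            if best in tree.descendant_names(truth):
                ok += 1
        assert ok / total >= 0.95


class TestDiscoverSubclades:
    def test_hv9c1_pattern(self, hv9c_tree):
        parent = node_state_profile(hv9c_tree, "HV9c")
        shared = "G5471A"
        members = [
            HaplotypeProfile("tus92", parent.variants + parse_motif(shared).variants),
            HaplotypeProfile("tus105", parent.variants + parse_motif(shared).variants),
        ]
        proposals = discover_subclades(members, parent, parent_name="HV9c")
        assert len(proposals) == 1
        assert [v.render() for v in proposals[0].defining_variants] == [shared]
        assert proposals[0].name == "HV9c1"
        assert proposals[0].annotations["members"] == ["tus105", "tus92"]

    def test_hotspot_sharing_is_ignored(self, hv9c_tree):
        parent = node_state_profile(hv9c_tree, "HV9c")
        members = [
            HaplotypeProfile("a", parent.variants + parse_motif("T16519C").variants),
            HaplotypeProfile("b", parent.variants + parse_motif("T16519C").variants),
        ]
        assert discover_subclades(members, parent) == []

    def test_single_member_yields_nothing(self, hv9c_tree):
        parent = node_state_profile(hv9c_tree, "HV9c")
        assert discover_subclades([parent], parent) == []

    def test_permutation_invariance(self):
        parent = HaplotypeProfile("p", ())
        members = [
            parse_motif("A1000G-T2000C", "a"),
            parse_motif("A1000G-T2000C-G3000A", "b"),
            parse_motif("A1000G", "c"),
            parse_motif("T5000C", "d"),
        ]
        reference = discover_subclades(members, parent, parent_name="X")

        def flatten(nodes):
            out = []
            for n in nodes:
                for sub, _ in n.walk():
                    out.append(
                        (
                            tuple(v.render() for v in sub.defining_variants),
                            tuple(sub.annotations["members"]),
                        )
                    )
            return sorted(out)

        for perm in itertools.permutations(members):
            assert flatten(discover_subclades(list(perm), parent, parent_name="X")) == flatten(
                reference
            )

    def test_against_brute_force_enumeration(self):
        """Every maximal shared-derived-variant group over 5 toy genomes is
        proposed, per an exhaustive subset enumeration."""
        rng = np.random.default_rng(3)
        parent = HaplotypeProfile("p", ())
        pool = [f"{r}{pos}{a}" for pos, r, a in
                [(1000, "A", "G"), (2000, "T", "C"), (3000, "G", "A"), (4000, "C", "T")]]
        members = []
        for i in range(5):
            toks = sorted(
                set(rng.choice(pool, size=rng.integers(1, 4), replace=False))
            )
            members.append(parse_motif("-".join(toks), f"g{i}"))

        # oracle: for each variant, the set of carriers; expected proposals
        # are the distinct carrier sets of size >= 2
        carrier_sets = {}
        for tok in pool:
            carriers = frozenset(
                m.sample_id for m in members if tok in m.tokens()
            )
            if len(carriers) >= 2:
                carrier_sets.setdefault(carriers, set()).add(tok)

        proposals = discover_subclades(members, parent, parent_name="X")
        got = {}
        for p in proposals:
            for node, _ in p.walk():
                got[frozenset(node.annotations["members"])] = {
                    v.render() for v in node.defining_variants
                }
        assert got == carrier_sets


class TestMotifSearch:
    RANGE = (16024, 16365)

    def _db(self, entries):
        records = [
            MotifRecord(restrict_range(parse_motif(m), *self.RANGE), pop, region)
            for m, pop, region in entries
        ]
        return MotifDatabase(records=records, range=self.RANGE)

    def test_exact_self_match(self):
        db = self._db([("T16126C-A16309G", "Iran", "Near East")])
        hits, tallies = motif_search(["T16126C", "A16309G"], db, max_steps=0)
        assert len(hits) == 1 and tallies == {"Near East": 1}

    def test_j1d_motif_found_in_iraq(self):
        # control-region J1d motif restricted to the shared HVS-I segment
        motif = "C16069T-T16126C-C16193T"
        db = self._db(
            [(motif, "Iraq", "Iraq"), ("T16126C-A16309G", "Iran", "Near East")]
        )
        hits, tallies = motif_search(motif.split("-"), db, max_steps=0)
        assert tallies == {"Iraq": 1}

    def test_alternative_alleles_match_either_state(self):
        db = self._db(
            [
                ("T16126C-A16309G-A16318T", "Iraq", "Near East"),
                ("T16126C-A16309G-A16318C", "Iran", "Near East"),
            ]
        )
        hits, tallies = motif_search(
            ["T16126C", "A16309G", "A16318T/A16318C"], db, max_steps=0
        )
        assert tallies == {"Near East": 2}

    def test_one_step_matches(self):
        db = self._db(
            [
                ("T16126C-A16309G", "x", "A"),          # exact
                ("T16126C", "x", "B"),                  # one missing
                ("T16126C-A16309G-T16356C", "x", "C"),  # one added
                ("T16126C-A16309T", "x", "D"),          # substituted allele
                ("T16126C-T16356C", "x", "E"),          # two steps away
            ]
        )
        _, t0 = motif_search(["T16126C", "A16309G"], db, max_steps=0)
        _, t1 = motif_search(["T16126C", "A16309G"], db, max_steps=1)
        assert t0 == {"A": 1}
        assert t1 == {"B": 1, "C": 1, "D": 1}

    def test_range_mismatch_rejected(self):
        db = self._db([("T16126C", "x", "A")])
        with pytest.raises(ValueError):
            motif_search(["A73G"], db, max_steps=0)

    def test_brute_force_agreement_on_random_db(self):
        rng = np.random.default_rng(5)
        positions = np.arange(16024, 16366)
        motifs = []
        for _ in range(50):
            k = rng.integers(1, 6)
            pos = sorted(rng.choice(positions, size=k, replace=False))
            motifs.append("-".join(f"T{p}C" if rng.random() < 0.7 else f"A{p}C" for p in pos))
        db = self._db([(m, "p", f"r{i%3}") for i, m in enumerate(motifs)])
        query = motifs[17].split("-")

        def brute_steps(q_tokens, rec):
            q = {t[1:-1]: t for t in q_tokens}
            r = {t[1:-1]: t for t in rec.profile.tokens()}
            steps = 0
            for pos_, tok in q.items():
                if r.get(pos_) != tok:
                    steps += 1
            steps += sum(1 for pos_ in r if pos_ not in q)
            return steps

        for max_steps in (0, 1):
            hits, _ = motif_search(query, db, max_steps=max_steps)
            expected = {
                id(rec) for rec in db.records if brute_steps(query, rec) == max_steps
            }
            assert {id(h.record) for h in hits} == expected


class TestFlagAndComponent:
    def test_u7a4_near_east_flag(self, u7a4_tree):
        counts = {"Near East": 6, "South Caucasus": 3}
        pooled = {"Near East": counts["Near East"] + counts["South Caucasus"]}
        assert (
            flag_clade_origin(u7a4_tree, pooled, home_region="Europe", threshold=0.5)
            == "Near East"
        )

    def test_single_region(self, u7a4_tree):
        assert flag_clade_origin(u7a4_tree, {"Europe": 10}, "Tuscany") == "Europe"

    def test_tie_below_threshold_unresolved(self, u7a4_tree):
        assert (
            flag_clade_origin(u7a4_tree, {"A": 1, "B": 1}, "home", threshold=0.6)
            == "unresolved"
        )

    def test_empty_counts_unresolved(self, u7a4_tree):
        assert flag_clade_origin(u7a4_tree, {}, "home") == "unresolved"

    def _cls(self, node, i):
        return Classification(f"s{i}", node, 1.0, (), (), ())

    def test_nine_of_110_rounds_to_8_2(self):
        cls = [self._cls("X", i) for i in range(9)] + [
            self._cls("H", i) for i in range(9, 110)
        ]
        pct = ancestry_component(cls, {"X"})
        assert pct == pytest.approx(8.1818, abs=1e-3)
        assert round(pct, 1) == 8.2

    def test_descendants_count_toward_flagged(self, u7a4_tree):
        cls = [self._cls("U7a4a1a1a", 0), self._cls("U7a4", 1)]
        assert ancestry_component(cls, {"U7a4a1a"}, tree=u7a4_tree) == 50.0

    def test_no_flagged_nodes_zero(self):
        cls = [self._cls("H", i) for i in range(4)]
        assert ancestry_component(cls, set()) == 0.0

    def test_all_flagged_hundred(self):
        cls = [self._cls("X", i) for i in range(4)]
        assert ancestry_component(cls, {"X"}) == 100.0

    def test_empty_sample_set_rejected(self):
        with pytest.raises(ValueError):
            ancestry_component([], {"X"})
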