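import itertools
import warnings

import numpy as np
import pytest
from skbio import TreeNode

from dnatape.lineage_tree import (
    CellRecord,
    CohortMatrix,
    bootstrap_support,
    build_tree,
    cohort_summaries,
    collapse_umis,
    correct_targetbc,
    distance_matrix,
    fitch_parsimony,
    pairwise_shared_matrix,
    robinson_foulds,
    select_complete_cells,
    shared_edits_order_aware,
    tree_bipartitions,
)
from dnatape.tape_sim import CloneSimParams, simulate_clone

WL8 = ["AAAAAAAA", "CCCCAAAA", "GGGGAAAA", "TTTTAAAA"]  # pairwise Hamming 4


def make_cell(cell_id, *tapes, caps=None):
    tapes = {f"T{i}": tuple(t) for i, t in enumerate(tapes)}
    caps = caps or {k: max(len(v), 2) for k, v in tapes.items()}
    return CellRecord(cell_id=cell_id, tapes=tapes, capacities=caps)


class TestCorrectTargetbc:
    def test_exact(self):
        assert correct_targetbc("CCCCAAAA", WL8) == ("CCCCAAAA", "exact")

    def test_single_mismatch_corrected(self):
        assert correct_targetbc("CCCCAAAT", WL8) == ("CCCCAAAA", "corrected")

    def test_distant_dropped(self):
        corrected, reason = correct_targetbc("CCGGAAAA", WL8)
        assert corrected is None
        assert reason == "too-distant"

    def test_close_whitelist_warns(self):
        with pytest.warns(UserWarning, match="Hamming"):
            correct_targetbc("AAAAAAAA", ["AAAAAAAA", "AAAAAAAT"])

    def test_length_mismatch(self):
        assert correct_targetbc("AAAA", WL8)[1] == "length-mismatch"


class TestCollapseUmis:
    def test_single_umi_dropped(self):
        assert collapse_umis([("c1", "u1", "T1", "SEQ")]) == []

    def test_consistent_group_kept(self):
        rows = [("c1", f"u{i}", "T1", "SEQ") for i in range(3)]
        assert collapse_umis(rows) == [("c1", "T1", "SEQ", 3)]

    def test_majority_string_wins(self):
        rows = [("c1", f"u{i}", "T1", "S1") for i in range(3)]
        rows.append(("c1", "u9", "T1", "S2"))
        assert collapse_umis(rows) == [("c1", "T1", "S1", 3)]

    def test_tie_drops_group(self):
        rows = [
            ("c1", "u1", "T1", "S1"),
            ("c1", "u2", "T1", "S2"),
        ]
        assert collapse_umis(rows) == []

    def test_duplicate_umis_counted_once(self):
        rows = [("c1", "u1", "T1", "S1"), ("c1", "u1", "T1", "S1")]
        assert collapse_umis(rows) == []


class TestSelectCompleteCells:
    def test_missing_tape_dropped(self):
        a = make_cell("a", ["AAA"], ["CCC"])
        b = CellRecord("b", {"T0": ("AAA",)}, {"T0": 2})
        cohort, dropped = select_complete_cells([a, b], {"T0": 2, "T1": 2})
        assert cohort.cell_ids == ["a"]
        assert dropped["b"].startswith("missing-tape")

    def test_off_whitelist_dropped(self):
        a = make_cell("a", ["AAA"], ["CCC"])
        b = make_cell("b", ["AAA"], ["GGG"])
        cohort, dropped = select_complete_cells(
            [a, b], {"T0": 2, "T1": 2}, insertbc_whitelist=["AAA", "CCC"]
        )
        assert cohort.cell_ids == ["a"]
        assert "GGG" in dropped["b"]

    def test_no_dropout_keeps_all(self):
        cells = [make_cell(f"c{i}", ["AAA"], ["CCC"]) for i in range(5)]
        cohort, dropped = select_complete_cells(cells, {"T0": 2, "T1": 2})
        assert cohort.n_cells == 5
        assert dropped == {}

    def test_empty_result_rejected(self):
        a = CellRecord("a", {"T0": ("AAA",)}, {"T0": 2})
        with pytest.raises(ValueError):
            select_complete_cells([a], {"T0": 2, "T1": 2})


def shared_oracle(a, b, panel):
    """Independent per-site scan: count while prefixes stay edited-and-equal."""
    total = 0
    for tbc, cap in panel:
        ta = list(a.tapes[tbc]) + [None] * (cap - len(a.tapes[tbc]))
        tb = list(b.tapes[tbc]) + [None] * (cap - len(b.tapes[tbc]))
        for s in range(cap):
            if ta[s] is None or tb[s] is None or ta[s] != tb[s]:
                break
            total += 1
    return total


def random_cohort(rng, n_cells=12, tapes=((3,), (2,), (4,))):
    symbols = ["AAA", "CCC", "GGG"]
    cells = []
    for i in range(n_cells):
        tp, caps = {}, {}
        for t, (cap,) in enumerate(tapes):
            k = int(rng.integers(0, cap + 1))
            tp[f"T{t}"] = tuple(rng.choice(symbols) for _ in range(k))
            caps[f"T{t}"] = cap
        cells.append(CellRecord(f"c{i:02d}", tp, caps))
    panel = [(f"T{t}", cap) for t, (cap,) in enumerate(tapes)]
    return CohortMatrix(cells, panel)


class TestSharedEdits:
    def test_identical_cells(self):
        a = make_cell("a", ["AAA", "CCC"], ["GGG"])
        assert shared_edits_order_aware(a, a, [("T0", 2), ("T1", 2)]) == 3

    def test_site2_match_discounted_after_site1_mismatch(self):
        a = make_cell("a", ["AAA", "CCC"])
        b = make_cell("b", ["GGG", "CCC"])
        assert shared_edits_order_aware(a, b, [("T0", 2)]) == 0

    def test_unedited_site_ends_scan(self):
        a = make_cell("a", ["AAA"])
        b = make_cell("b", ["AAA", "CCC"])
        assert shared_edits_order_aware(a, b, [("T0", 2)]) == 1

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            cohort = random_cohort(rng)
            shared = pairwise_shared_matrix(cohort)
            for i, a in enumerate(cohort.cells):
                for j, b in enumerate(cohort.cells):
                    expected = shared_oracle(a, b, cohort.panel)
                    assert shared[i, j] == expected
                    assert (
                        shared_edits_order_aware(a, b, cohort.panel) == expected
                    )

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(9)
        cohort = random_cohort(rng, n_cells=20)
        shared = pairwise_shared_matrix(cohort)
        assert (shared == shared.T).all()
        edits = np.array([c.n_edits for c in cohort.cells])
        assert (shared <= np.minimum.outer(edits, edits)).all()


class TestDistanceMatrix:
    def test_identical_cells_distance(self):
        # two identical cells with 3 edits on a 4-site panel: d = 4 - 3
        a = make_cell("a", ["AAA", "CCC", "GGG"], caps={"T0": 4})
        b = make_cell("b", ["AAA", "CCC", "GGG"], caps={"T0": 4})
        cohort = CohortMatrix([a, b], [("T0", 4)])
        d = distance_matrix(cohort)
        assert d[0, 1] == 1.0
        assert d[0, 0] == d[1, 1] == 0.0  # self-distance convention

    def test_founder_vs_any(self):
        a = make_cell("a", [], caps={"T0": 5})
        b = make_cell("b", ["AAA", "CCC"], caps={"T0": 5})
        cohort = CohortMatrix([a, b], [("T0", 5)])
        assert distance_matrix(cohort)[0, 1] == 5.0

    def test_range_property(self):
        rng = np.random.default_rng(10)
        cohort = random_cohort(rng, n_cells=15)
        d = distance_matrix(cohort)
        total = cohort.total_sites
        edits = np.array([c.n_edits for c in cohort.cells])
        for i in range(15):
            for j in range(15):
                if i != j:
                    assert total - min(edits[i], edits[j]) <= d[i, j] <= total


class TestBuildTree:
    def test_upgma_closed_form(self):
        d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float)
        res = build_tree(d, ["A", "B", "C"], "upgma")
        ab = res.tree.lca(["A", "B"])
        assert res.tree.find("A").length == pytest.approx(1.0)
        assert ab.length == pytest.approx(2.0)
        assert res.tree.find("C").length == pytest.approx(3.0)

    def test_upgma_ultrametric(self):
        rng = np.random.default_rng(12)
        cohort = random_cohort(rng, n_cells=20)
        res = build_tree(distance_matrix(cohort), cohort.cell_ids, "upgma")
        depths = [t.accumulate_to_ancestor(res.tree) for t in res.tree.tips()]
        assert max(depths) - min(depths) < 1e-9

    def test_nj_recovers_additive_metrics(self):
        # random 4-8 taxon additive metrics from random binary trees
        rng = np.random.default_rng(13)
        for n_taxa in [4, 5, 6, 8]:
            labels = [f"L{i}" for i in range(n_taxa)]
            # build random rooted binary tree with positive branch lengths
            nodes = [TreeNode(name=l, length=None) for l in labels]
            while len(nodes) > 1:
                i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                parent = TreeNode()
                b = nodes.pop(j)
                a = nodes.pop(i)
                for c in (a, b):
                    c.length = float(rng.uniform(0.5, 3.0))
                    parent.append(c)
                nodes.append(parent)
            true_tree = nodes[0]
            dist = np.zeros((n_taxa, n_taxa))
            for i, j in itertools.combinations(range(n_taxa), 2):
                dist[i, j] = dist[j, i] = true_tree.find(
                    labels[i]
                ).distance(true_tree.find(labels[j]))
            res = build_tree(dist, labels, "nj")
            # topology: identical bipartition sets
            assert robinson_foulds(res.tree, true_tree) == 0.0
            # branch lengths: reconstructed leaf-to-leaf distances are exact
            for i, j in itertools.combinations(range(n_taxa), 2):
                got = res.tree.find(labels[i]).distance(res.tree.find(labels[j]))
                assert got == pytest.approx(dist[i, j])

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            build_tree(np.zeros((1, 1)), ["A"])

    def test_asymmetric_rejected(self):
        d = np.array([[0, 1], [2, 0]], float)
        with pytest.raises(ValueError):
            build_tree(d, ["A", "B"])

    def test_reconstruction_beats_permuted_baseline(self):
        params = CloneSimParams(
            generations=10, sample_size=40, seed=3,
            per_tape_per_division_edit_prob=0.3,
        )
        true_tree, records = simulate_clone(params)
        panel = sorted(records[0].capacities.items())
        cohort = CohortMatrix(list(records), panel)
        res = build_tree(distance_matrix(cohort), cohort.cell_ids, "upgma")
        score = robinson_foulds(res.tree, true_tree)
        rng = np.random.default_rng(4)
        baseline = []
        names = cohort.cell_ids
        for _ in range(100):
            perm = dict(zip(names, rng.permutation(names)))
            shuffled = res.tree.copy()
            for tip in shuffled.tips():
                tip.name = perm[tip.name]
            baseline.append(robinson_foulds(shuffled, true_tree))
        assert score < np.percentile(baseline, 5)


def sankoff_oracle(tree, leaf_states):
    """Exhaustive minimum change count over all internal state assignments."""
    tree = tree.copy()
    internals = [n for n in tree.traverse(include_self=True) if not n.is_tip()]
    states = sorted({s for v in leaf_states.values() for s in [v]} | set())
    alphabet = sorted(set(leaf_states.values()))
    best = np.inf
    for combo in itertools.product(alphabet, repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        for tip in tree.tips():
            assign[id(tip)] = leaf_states[tip.name]
        changes = 0
        for node in tree.traverse(include_self=True):
            for child in node.children:
                changes += assign[id(node)] != assign[id(child)]
        best = min(best, changes)
    return int(best)


class TestFitchParsimony:
    def test_two_leaves_same_state(self):
        a = make_cell("a", ["AAA"])
        b = make_cell("b", ["AAA"])
        cohort = CohortMatrix([a, b], [("T0", 2)])
        tree = build_tree(distance_matrix(cohort), ["a", "b"], "upgma").tree
        assert fitch_parsimony(tree, cohort) == 0

    def test_two_leaves_k_differences(self):
        a = make_cell("a", ["AAA", "CCC"], ["GGG"])
        b = make_cell("b", ["CCC", "CCC"], ["AAA"])
        cohort = CohortMatrix([a, b], [("T0", 2), ("T1", 2)])
        tree = build_tree(distance_matrix(cohort), ["a", "b"], "upgma").tree
        assert fitch_parsimony(tree, cohort) == 2

    def test_matches_exhaustive_sankoff(self):
        rng = np.random.default_rng(14)
        for trial in range(15):
            n = int(rng.integers(4, 7))
            cohort = random_cohort(rng, n_cells=n, tapes=((2,), (2,)))
            tree = build_tree(
                distance_matrix(cohort), cohort.cell_ids, "upgma"
            ).tree
            mat, _ = cohort.encode()
            expected = 0
            for site in range(mat.shape[1]):
                leaf_states = {
                    cid: int(mat[i, site])
                    for i, cid in enumerate(cohort.cell_ids)
                }
                expected += sankoff_oracle(tree, leaf_states)
            assert fitch_parsimony(tree, cohort) == expected

    def test_polytomy_resolved_with_warning(self):
        a = make_cell("a", ["AAA"])
        b = make_cell("b", ["CCC"])
        c = make_cell("c", ["GGG"])
        cohort = CohortMatrix([a, b, c], [("T0", 2)])
        tree = TreeNode.read(["(a,b,c);"])
        with pytest.warns(UserWarning, match="polytom"):
            score = fitch_parsimony(tree, cohort)
        assert score == 2


class TestBootstrap:
    def _split_cohort(self):
        # deeply separated clades: every tape's site 1 records the split, so
        # any tape-block resample retains the separation
        cells = []
        for clade, sym in (("x", "AAA"), ("y", "TTT")):
            for i in range(4):
                tapes = {
                    f"T{t}": (sym, "CCC" if i % 2 else "GGG")
                    for t in range(3)
                }
                cells.append(
                    CellRecord(
                        f"{clade}{i}", tapes, {f"T{t}": 2 for t in range(3)}
                    )
                )
        return CohortMatrix(cells, [("T0", 2), ("T1", 2), ("T2", 2)])

    def test_deep_split_full_support(self):
        cohort = self._split_cohort()
        res = bootstrap_support(cohort, n_reps=50, seed=0)
        clade_support = {
            frozenset(t.name for t in node.tips()): float(node.name)
            for node in res.tree.non_tips(include_self=False)
        }
        xs = frozenset(f"x{i}" for i in range(4))
        ys = frozenset(f"y{i}" for i in range(4))
        assert clade_support.get(xs, clade_support.get(ys)) == 100.0

    def test_single_rep_support_binary(self):
        cohort = self._split_cohort()
        res = bootstrap_support(cohort, n_reps=1, seed=1)
        assert set(res.support.values()) <= {0.0, 100.0}

    def test_shuffled_labels_low_support(self):
        rng = np.random.default_rng(15)
        cohort = random_cohort(rng, n_cells=12, tapes=((3,), (3,), (3,), (3,)))
        res = bootstrap_support(cohort, n_reps=30, seed=2)
        mean_support = np.mean(list(res.support.values()))
        assert mean_support < 80.0  # noise cohort: no consistently high support


class TestCohortSummaries:
    def test_founder_only(self):
        cells = [
            CellRecord(
                f"c{i}",
                {"T0": (), "T1": ()},
                {"T0": 5, "T1": 2},
            )
            for i in range(3)
        ]
        s = cohort_summaries(CohortMatrix(cells, [("T0", 5), ("T1", 2)]))
        assert s["edits_per_cell_mean"] == 0.0
        assert s["edits_per_cell_var"] == 0.0
        assert s["active_tapes_mean"] == 2.0
        assert s["n_fully_edited_cells"] == 0

    def test_saturated_cohort(self):
        cells = [
            CellRecord(
                f"c{i}",
                {"T0": ("AAA", "CCC"), "T1": ("GGG",)},
                {"T0": 2, "T1": 1},
            )
            for i in range(3)
        ]
        s = cohort_summaries(CohortMatrix(cells, [("T0", 2), ("T1", 1)]))
        assert s["active_tapes_mean"] == 0.0
        assert s["site_mean_fractions"][0] == 1.0
        assert s["n_fully_edited_cells"] == 3
        assert s["n_cells_with_unique_pattern"] == 0

    def test_pairwise_difference_counts_unedited_mismatch(self):
        a = make_cell("a", ["AAA", "CCC"])
        b = make_cell("b", ["AAA"])
        s = cohort_summaries(CohortMatrix([a, b], [("T0", 2)]))
        assert s["pairwise_diff_mean"] == 1.0
        assert s["nearest_neighbour_mean"] == 1.0

    def test_poisson_like_simulated_cohort(self):
        params = CloneSimParams(
            tape_site_counts=(20,) * 13,
            per_tape_per_division_edit_prob=0.05,
            sample_size=1500,
            seed=16,
        )
        _, records = simulate_clone(params)
        panel = sorted(records[0].capacities.items())
        s = cohort_summaries(CohortMatrix(list(records), panel))
        mu, var = s["edits_per_cell_mean"], s["edits_per_cell_var"]
        assert abs(mu - var) / mu < 0.15
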