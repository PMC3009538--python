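"""Weighted-voting initialisation and the relaxation iteration."""

import numpy as np
import pytest

from gorelax.network import AssociationNetwork
from gorelax.ontology import CompatibilityMatrix
from gorelax.relax import (
    LabelProbabilityMatrix,
    RelaxationOptions,
    _weight_matrix,
    delta,
    init_probabilities,
    neighbor_weights,
    predict,
    relax,
    update_step,
)

from conftest import make_annotations


def star_network(scores: dict[str, float], center: str = "i") -> AssociationNetwork:
    net = AssociationNetwork()
    for j, a in scores.items():
        net.add_edge(center, j, a)
    return net


class TestInitProbabilities:
    def test_weighted_vote_ratio(self):
        net = star_network({"j1": 0.8, "j2": 0.5})
        ann = make_annotations({"j1": {"lk"}, "j2": {"other"}})
        P = init_probabilities(net, ann)
        assert P.probability("i", "lk") == pytest.approx(0.8 / 1.3)

    def test_single_carrying_neighbor_gives_one(self):
        net = star_network({"j1": 0.37})
        ann = make_annotations({"j1": {"lk"}}, terms=["lk"])
        P = init_probabilities(net, ann)
        assert P.probability("i", "lk") == 1.0

    def test_prior_fallback_when_no_neighbor_carries_label(self):
        net = star_network({"j1": 0.8})
        # 62/1444 prior for the absent label
        labels = {"j1": {"l_other"}}
        labels.update({f"bg{i}": {"lk"} for i in range(62)})
        labels.update({f"bg{i + 62}": {"l_other"} for i in range(1444 - 63)})
        ann = make_annotations(labels)
        P = init_probabilities(net, ann)
        assert P.probability("i", "lk") == pytest.approx(62 / 1444, abs=1e-12)

    def test_isolated_protein_gets_priors_for_every_term(self):
        net = star_network({"j1": 0.8})
        net.add_protein("lonely")
        ann = make_annotations({"j1": {"t1"}, "j2_off": {"t2"}})
        P = init_probabilities(net, ann)
        for t in ann.terms:
            assert P.probability("lonely", t) == pytest.approx(ann.term_prior(t))

    def test_hidden_neighbors_do_not_vote(self):
        net = star_network({"j1": 0.8, "j2": 0.5})
        ann = make_annotations({"j1": {"lk"}, "j2": {"lk"}})
        P = init_probabilities(net, ann, hidden={"j2"})
        assert P.probability("i", "lk") == 1.0  # only j1 votes, it carries lk


class TestNeighborWeights:
    def test_score_proportional(self):
        net = star_network({"j1": 0.8, "j2": 0.5})
        w = neighbor_weights(net, "i")
        assert w == pytest.approx({"j1": 0.8 / 1.3, "j2": 0.5 / 1.3})
        assert sum(w.values()) == pytest.approx(1.0)

    def test_single_neighbor(self):
        net = star_network({"j1": 0.3})
        assert neighbor_weights(net, "i") == {"j1": 1.0}

    def test_equal_scores_give_uniform_weights(self):
        net = star_network({f"j{k}": 0.8 for k in range(4)})
        w = neighbor_weights(net, "i")
        assert all(v == pytest.approx(0.25) for v in w.values())

    def test_isolated_protein_has_empty_weights(self):
        net = AssociationNetwork()
        net.add_protein("x")
        assert neighbor_weights(net, "x") == {}


class TestDelta:
    def test_all_ones_compatibility_with_normalized_rows(self):
        terms = ["l1", "l2"]
        C = CompatibilityMatrix(terms, np.ones((2, 2)))
        P = LabelProbabilityMatrix(["i", "j"], terms, np.array([[0.5, 0.5], [0.3, 0.7]]))
        assert delta(P, C, {"j": 1.0}, "l1") == pytest.approx(1.0)

    def test_hand_worked_support(self):
        terms = ["l1", "l2"]
        C = CompatibilityMatrix(terms, np.array([[1.0, 0.5], [0.5, 1.0]]))
        P = LabelProbabilityMatrix(["i", "j"], terms, np.array([[0.5, 0.5], [0.7, 0.3]]))
        assert delta(P, C, {"j": 1.0}, "l1") == pytest.approx(0.85)
        assert delta(P, C, {"j": 1.0}, "l2") == pytest.approx(0.65)

    def test_identity_compatibility_copies_neighbor_row(self):
        terms = ["l1", "l2"]
        C = CompatibilityMatrix(terms, np.eye(2))
        P = LabelProbabilityMatrix(["i", "j"], terms, np.array([[0.5, 0.5], [1.0, 0.0]]))
        assert delta(P, C, {"j": 1.0}, "l1") == pytest.approx(1.0)
        assert delta(P, C, {"j": 1.0}, "l2") == pytest.approx(0.0)

    def test_term_order_mismatch_raises(self):
        C = CompatibilityMatrix(["l2", "l1"], np.eye(2))
        P = LabelProbabilityMatrix(["i"], ["l1", "l2"], np.array([[0.5, 0.5]]))
        with pytest.raises(ValueError):
            delta(P, C, {}, "l1")


def two_node_net() -> AssociationNetwork:
    net = AssociationNetwork()
    net.add_edge("i", "j", 1.0)
    return net


class TestUpdateStep:
    def test_hand_worked_update(self):
        terms = ["l1", "l2"]
        net = two_node_net()
        C = CompatibilityMatrix(terms, np.array([[1.0, 0.5], [0.5, 1.0]]))
        P = LabelProbabilityMatrix(
            ["i", "j"], terms, np.array([[0.5, 0.5], [0.7, 0.3]])
        )
        W = _weight_matrix(net, P.proteins)
        out = update_step(P, C, W)
        # Delta_i = (0.85, 0.65); (0.5*1.85, 0.5*1.65) / 1.75
        assert out.row("i") == pytest.approx([0.925 / 1.75, 0.825 / 1.75])
        assert out.row("i") == pytest.approx([0.52857, 0.47143], abs=5e-6)
        assert out.generation == P.generation + 1

    def test_uniform_compatibility_is_fixed_point(self):
        terms = ["l1", "l2", "l3"]
        net = two_node_net()
        C = CompatibilityMatrix(terms, np.full((3, 3), 0.7))
        vals = np.array([[0.2, 0.3, 0.5], [0.6, 0.1, 0.3]])
        P = LabelProbabilityMatrix(["i", "j"], terms, vals.copy())
        out = update_step(P, C, _weight_matrix(net, P.proteins))
        assert out.values == pytest.approx(vals, abs=1e-12)

    def test_clamped_rows_pass_through(self):
        terms = ["l1", "l2"]
        net = two_node_net()
        C = CompatibilityMatrix(terms, np.array([[1.0, 0.5], [0.5, 1.0]]))
        P = LabelProbabilityMatrix(["i", "j"], terms, np.array([[1.0, 0.0], [0.5, 0.5]]))
        out = update_step(P, C, _weight_matrix(net, P.proteins), clamped={"i"})
        assert out.row("i").tolist() == [1.0, 0.0]

    def test_all_zero_row_left_unchanged_with_warning(self, caplog):
        terms = ["l1", "l2"]
        net = two_node_net()
        C = CompatibilityMatrix(terms, np.eye(2))
        P = LabelProbabilityMatrix(["i", "j"], terms, np.array([[0.0, 0.0], [0.5, 0.5]]))
        out = update_step(P, C, _weight_matrix(net, P.proteins))
        assert out.row("i").tolist() == [0.0, 0.0]
        assert "all-zero" in caplog.text

    def test_unclamped_rows_stay_on_simplex(self):
        rng = np.random.default_rng(0)
        terms = [f"l{k}" for k in range(4)]
        net = AssociationNetwork()
        for i in range(6):
            for j in range(i + 1, 6):
                if rng.random() < 0.6:
                    net.add_edge(f"p{i}", f"p{j}", float(rng.uniform(0.1, 1.0)))
        proteins = sorted(net.proteins)
        vals = rng.dirichlet(np.ones(4), size=len(proteins))
        P = LabelProbabilityMatrix(proteins, terms, vals)
        Cv = rng.uniform(0, 1, (4, 4))
        Cv = (Cv + Cv.T) / 2
        np.fill_diagonal(Cv, 1.0)
        C = CompatibilityMatrix(terms, Cv)
        out = update_step(P, C, _weight_matrix(net, proteins))
        assert out.values.min() >= 0.0
        assert out.values.sum(axis=1) == pytest.approx(np.ones(len(proteins)), abs=1e-9)


class TestRelax:
    def test_uniform_compatibility_converges_in_one_iteration(self):
        terms = ["l1", "l2"]
        net = two_node_net()
        C = CompatibilityMatrix(terms, np.ones((2, 2)))
        P0 = LabelProbabilityMatrix(["i", "j"], terms, np.array([[0.2, 0.8], [0.6, 0.4]]))
        res = relax(net, P0, C)
        assert res.converged
        assert res.iterations == 1

    def test_hidden_between_clamped_anchors_converges_to_their_label(self):
        terms = ["l1", "l2"]
        net = AssociationNetwork()
        net.add_edge("a", "x", 0.9)
        net.add_edge("b", "x", 0.9)
        C = CompatibilityMatrix(terms, np.eye(2))
        P0 = LabelProbabilityMatrix(
            ["a", "b", "x"],
            terms,
            np.array([[1.0, 0.0], [1.0, 0.0], [0.5, 0.5]]),
        )
        res = relax(
            net, P0, C, RelaxationOptions(tolerance=1e-7, max_iterations=500),
            clamped={"a", "b"},
        )
        assert res.probabilities.row("x") == pytest.approx([1.0, 0.0], abs=1e-4)

    def test_huge_tolerance_stops_after_one_iteration(self):
        terms = ["l1", "l2"]
        net = two_node_net()
        C = CompatibilityMatrix(terms, np.array([[1.0, 0.2], [0.2, 1.0]]))
        P0 = LabelProbabilityMatrix(["i", "j"], terms, np.array([[0.2, 0.8], [0.6, 0.4]]))
        res = relax(net, P0, C, RelaxationOptions(tolerance=10.0))
        assert res.iterations == 1 and res.converged

    def test_determinism(self):
        rng = np.random.default_rng(5)
        net = AssociationNetwork()
        for i in range(8):
            for j in range(i + 1, 8):
                if rng.random() < 0.5:
                    net.add_edge(f"p{i}", f"p{j}", float(rng.uniform(0.2, 1.0)))
        proteins = sorted(net.proteins)
        terms = ["a", "b", "c"]
        vals = rng.dirichlet(np.ones(3), size=len(proteins))
        Cv = np.array([[1, 0.4, 0.1], [0.4, 1, 0.3], [0.1, 0.3, 1.0]])
        C = CompatibilityMatrix(terms, Cv)
        runs = [
            relax(net, LabelProbabilityMatrix(list(proteins), terms, vals.copy()), C)
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].probabilities.values, runs[1].probabilities.values)
        assert runs[0].iterations == runs[1].iterations

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        net = AssociationNetwork()
        for i in range(6):
            net.add_edge(f"p{i}", f"p{(i + 1) % 6}", float(rng.uniform(0.3, 1.0)))
        proteins = sorted(net.proteins)
        terms = ["a", "b", "c", "d"]
        vals = rng.dirichlet(np.ones(4), size=len(proteins))
        Cv = rng.uniform(0.1, 0.9, (4, 4))
        Cv = (Cv + Cv.T) / 2
        np.fill_diagonal(Cv, 1.0)
        perm = [2, 0, 3, 1]
        res = relax(net, LabelProbabilityMatrix(list(proteins), terms, vals.copy()),
                    CompatibilityMatrix(terms, Cv))
        res_p = relax(
            net,
            LabelProbabilityMatrix(
                list(proteins), [terms[k] for k in perm], vals[:, perm].copy()
            ),
            CompatibilityMatrix([terms[k] for k in perm], Cv[np.ix_(perm, perm)]),
        )
        assert res_p.probabilities.values == pytest.approx(
            res.probabilities.values[:, perm], abs=1e-12
        )


def naive_relaxation(proteins, terms, values, C, net, clamped, iterations):
    """Triple-loop oracle for the support and update equations."""
    values = values.copy()
    # normalise unclamped rows first, as the production path does
    for i, p in enumerate(proteins):
        if p not in clamped and values[i].sum() > 0:
            values[i] = values[i] / values[i].sum()
    for _ in range(iterations):
        new = values.copy()
        for i, p in enumerate(proteins):
            if p in clamped:
                continue
            nbrs = net.neighbors(p)
            total = sum(nbrs.values())
            if total == 0 or values[i].sum() == 0:
                continue
            deltas = np.zeros(len(terms))
            for k in range(len(terms)):
                for j, a in nbrs.items():
                    jj = proteins.index(j)
                    for l in range(len(terms)):
                        deltas[k] += (a / total) * C[k, l] * values[jj, l]
            unnorm = values[i] * (1 + deltas)
            new[i] = unnorm / unnorm.sum()
        values = new
    return values


@pytest.mark.parametrize("seed", range(6))
def test_vectorized_matches_triple_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 21))
    m = int(rng.integers(2, 9))
    net = AssociationNetwork()
    for i in range(n):
        net.add_protein(f"p{i:02d}")
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:
                net.add_edge(f"p{i:02d}", f"p{j:02d}", float(rng.uniform(0.1, 1.0)))
    proteins = sorted(net.proteins)
    terms = [f"l{k}" for k in range(m)]
    vals = rng.dirichlet(np.ones(m), size=n)
    Cv = rng.uniform(0, 1, (m, m))
    Cv = (Cv + Cv.T) / 2
    np.fill_diagonal(Cv, 1.0)
    clamped = set(rng.choice(proteins, size=n // 4, replace=False))
    iters = int(rng.integers(1, 6))
    res = relax(
        net,
        LabelProbabilityMatrix(list(proteins), terms, vals.copy()),
        CompatibilityMatrix(terms, Cv),
        RelaxationOptions(tolerance=1e-15, max_iterations=iters),
        clamped=clamped,
    )
    oracle = naive_relaxation(proteins, terms, vals, Cv, net, clamped, iters)
    assert res.probabilities.values == pytest.approx(oracle, abs=1e-12)


def test_predict_clamps_training_and_returns_baseline():
    net = AssociationNetwork()
    net.add_edge("a", "x", 0.9)
    net.add_edge("b", "x", 0.8)
    ann = make_annotations({"a": {"l1"}, "b": {"l1", "l2"}})
    C = CompatibilityMatrix(["l1", "l2"], np.array([[1.0, 0.3], [0.3, 1.0]]))
    baseline, res = predict(net, ann, C)
    assert baseline.probability("x", "l1") == pytest.approx(1.0)  # both carry l1
    assert res.probabilities.row("a").tolist() == [1.0, 0.0]
    assert res.probabilities.row("b").tolist() == [1.0, 1.0]
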