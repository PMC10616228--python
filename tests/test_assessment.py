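"""The CMP and MSP-based adaptive assessment engines."""

import numpy as np
import pytest

from pkst.assessment import (
    ItemParams,
    Likelihood,
    cmp_update,
    derive_item_params,
    half_split_select,
    msp_update,
    multiplicative_update,
    run_assessment,
)
from pkst.mspm import SolutionProcess, generate_params, simulate_process
from pkst.spaces import Problem

Q = {s: Problem(s, "s9") for s in ("s1", "s3", "s4", "s7", "s8")}

PROC_S4 = SolutionProcess(Q["s4"], ("s4", "s6", "s8", "s9"))
PROC_S1 = SolutionProcess(Q["s1"], ("s1", "s3", "s5", "s7", "s8", "s9"))


def _random_likelihood(structure, rng):
    w = rng.uniform(size=len(structure))
    return Likelihood(structure, w / w.sum())


def _transients_with_successors(gs):
    for i in sorted(gs.problem_states - {gs.goal}):
        succ = sorted({t for (s, _), t in gs.space.transitions.items()
                       if s == i and t != gs.failure})
        yield i, succ


def _multiplicative_params(gs, rng):
    """Random parameters satisfying β_ij > η_ij (j ≠ f) and η_if > β_if.

    Both rows share the same direction weights, so a smaller failure
    residual for β makes every off-failure β entry dominate.
    """
    from pkst.mspm import TransitionParams

    beta, eta = {}, {}
    for i, succ in _transients_with_successors(gs):
        b_f = float(rng.uniform(0.001, 0.1))
        e_f = float(rng.uniform(0.5, 0.9))
        w = rng.uniform(0.1, 1.0, size=len(succ))
        w = w / w.sum()
        for t, wt in zip(succ, w):
            beta[(i, t)] = float(wt * (1 - b_f))
            eta[(i, t)] = float(wt * (1 - e_f))
        beta[(i, gs.failure)] = b_f
        eta[(i, gs.failure)] = e_f
    for s in (gs.goal, gs.failure):
        beta[(s, s)] = 1.0
        eta[(s, s)] = 1.0
    return TransitionParams(gs.goal, gs.failure, beta, eta)


def _noiseless_params(gs, eps=1e-9):
    """Knowing solvers never slip; unknowing solvers never get lucky."""
    from pkst.mspm import TransitionParams

    beta, eta = {}, {}
    for i, succ in _transients_with_successors(gs):
        for t in succ:
            beta[(i, t)] = (1 - eps) / len(succ)
            eta[(i, t)] = eps / len(succ)
        beta[(i, gs.failure)] = eps
        eta[(i, gs.failure)] = 1 - eps
    for s in (gs.goal, gs.failure):
        beta[(s, s)] = 1.0
        eta[(s, s)] = 1.0
    return TransitionParams(gs.goal, gs.failure, beta, eta)


class TestHalfSplit:
    def test_scores_from_uniform_prior(self, ktol):
        L = Likelihood.uniform(ktol)
        scores = {s: abs(2 * L.mass(q) - 1) for s, q in Q.items()}
        assert scores["s4"] == pytest.approx(1 / 11)
        assert scores["s8"] == pytest.approx(9 / 11)
        for s in ("s1", "s3", "s7"):
            assert scores[s] == pytest.approx(3 / 11)

    def test_selects_s4_first(self, ktol, rng):
        L = Likelihood.uniform(ktol)
        assert half_split_select(L, ktol.domain, rng) == Q["s4"]

    def test_concentrated_likelihood_ties_all_problems(self, ktol):
        w = np.zeros(len(ktol))
        w[-1] = 1.0  # the full state
        L = Likelihood(ktol, w)
        picks = {
            half_split_select(L, ktol.domain, np.random.default_rng(k)).initial
            for k in range(40)
        }
        assert len(picks) > 1  # ties broken at random across the domain

    def test_mass_matches_direct_summation(self, ktol, rng):
        for _ in range(20):
            L = _random_likelihood(ktol, rng)
            for q in ktol.domain:
                direct = sum(
                    float(w)
                    for w, m in zip(L.weights, ktol.masks)
                    if q in ktol.state_set(int(m))
                )
                assert L.mass(q) == pytest.approx(direct, abs=1e-12)

    def test_empty_available_rejected(self, ktol, rng):
        with pytest.raises(ValueError, match="available"):
            half_split_select(Likelihood.uniform(ktol), [], rng)


class TestCmpUpdate:
    def test_posterior_after_correct_s4(self, ktol, example1_item_params):
        L1 = cmp_update(Likelihood.uniform(ktol), Q["s4"], 1, example1_item_params)
        inK = ktol.membership(Q["s4"])
        assert np.allclose(L1.weights[inK], 0.98 / 5.8802)
        assert round(float(L1.weights[inK][0]), 2) == 0.17
        assert L1.weights[~inK] == pytest.approx(4e-5 / 5.8802)  # ≈ 6.8e-6

    def test_normalization_preserved(self, ktol, example1_item_params, rng):
        L = _random_likelihood(ktol, rng)
        for s, r in (("s4", 1), ("s1", 0), ("s8", 1)):
            L = cmp_update(L, Q[s], r, example1_item_params)
            assert L.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_response_rejected(self, ktol, example1_item_params):
        with pytest.raises(ValueError, match="response"):
            cmp_update(Likelihood.uniform(ktol), Q["s4"], 2, example1_item_params)


class TestMultiplicativeRule:
    def test_equivalent_to_bayes_with_converted_zetas(self, ktol, example1_item_params, rng):
        ip = example1_item_params
        for _ in range(50):
            L = _random_likelihood(ktol, rng)
            s = ("s1", "s3", "s4", "s7", "s8")[int(rng.integers(5))]
            r = int(rng.integers(2))
            z1, z0 = ip.zetas(s)
            bayes = cmp_update(L, Q[s], r, ip)
            mult = multiplicative_update(L, Q[s], r, z1, z0)
            assert np.allclose(bayes.weights, mult.weights, atol=1e-14)

    def test_zeta_conversion_value(self, example1_item_params):
        z1, _ = example1_item_params.zetas("s4")
        assert z1 == pytest.approx(24_500)

    def test_unit_zetas_leave_prior_unchanged(self, ktol, rng):
        L = _random_likelihood(ktol, rng)
        out = multiplicative_update(L, Q["s4"], 1, 1.0, 1.0)
        assert np.allclose(out.weights, L.weights)


class TestMspUpdate:
    def test_example_first_process(self, fig2_gs, ktol, table4):
        L = Likelihood.uniform(ktol)
        for i, j in PROC_S4.moves():
            L = msp_update(L, "s4", i, j, table4, "msp3", fig2_gs)
        both = ktol.membership(Q["s4"]) & ktol.membership(Q["s8"])
        neither = ~ktol.membership(Q["s4"]) & ~ktol.membership(Q["s8"])
        assert np.all(np.round(L.weights[both], 2) == 0.17)
        assert np.all(np.round(L.weights[neither], 2) == 0.0)

    def test_example_second_process(self, fig2_gs, ktol, table4):
        L = Likelihood.uniform(ktol)
        for sp in (PROC_S4, PROC_S1):
            for i, j in sp.moves():
                L = msp_update(L, sp.problem.initial, i, j, table4, "msp3", fig2_gs)
        by_set = {
            frozenset(q.initial for q in ktol.state_set(int(m))): float(w)
            for m, w in zip(ktol.masks, L.weights)
        }
        assert round(by_set[frozenset({"s1", "s4", "s7", "s8"})], 2) == 0.07
        assert round(by_set[frozenset({"s1", "s4", "s8"})], 2) == 0.01
        assert by_set[frozenset({"s1", "s3", "s4", "s7", "s8"})] >= 0.9
        assert by_set[frozenset({"s1", "s3", "s4", "s7", "s8"})] == max(by_set.values())

    def test_equal_rates_leave_prior_unchanged(self, fig2_gs, ktol, table4, rng):
        from pkst.mspm import TransitionParams

        beta = dict(table4.beta)
        eta = dict(table4.eta)
        # force β = η on the observed transition (and its failure complement)
        beta[("s8", "s9")] = eta[("s8", "s9")] = 0.9
        beta[("s8", "f")] = eta[("s8", "f")] = 0.1
        params = TransitionParams("s9", "f", beta, eta)
        L = _random_likelihood(ktol, rng)
        out = msp_update(L, "s8", "s8", "s9", params, "msp3", fig2_gs)
        assert np.allclose(out.weights, L.weights)

    def test_consistent_states_gain_mass_on_correct_process(self, fig2_gs, ktol, table4):
        """With β > η off-failure, states holding the sub-solved problems only grow."""
        assert table4.is_multiplicative()
        L = Likelihood.uniform(ktol)
        both = ktol.membership(Q["s4"]) & ktol.membership(Q["s8"])
        before = float(L.weights[both].sum())
        for i, j in PROC_S4.moves():
            L = msp_update(L, "s4", i, j, table4, "msp3", fig2_gs)
            now = float(L.weights[both].sum())
            assert now >= before - 1e-12
            before = now

    def test_theorem_multiplicative_form(self, fig2_gs, ktol, rng):
        """Move updates coincide with ζ = β/η (and η_f/β_f) multiplicative updates."""
        for _ in range(200):
            params = _multiplicative_params(fig2_gs, rng)
            assert params.is_multiplicative()
            L = _random_likelihood(ktol, rng)
            edges = [e for e in params.beta if e[0] not in ("s9", "f")]
            i, j = edges[int(rng.integers(len(edges)))]
            s0 = ("s1", "s3", "s4", "s7", "s8")[int(rng.integers(5))]
            direct = msp_update(L, s0, i, j, params, "msp1", fig2_gs)
            if j == fig2_gs.failure:
                zeta = params.eta[(i, j)] / params.beta[(i, j)]
                mult = multiplicative_update(L, Q[s0], 0, 1.0, zeta)
            else:
                zeta = params.beta[(i, j)] / params.eta[(i, j)]
                mult = multiplicative_update(L, Q[s0], 1, zeta, 1.0)
            assert np.allclose(direct.weights, mult.weights, atol=1e-13)


class TestDeriveItemParams:
    def test_probabilities_in_unit_interval(self, fig2_gs, table4):
        ip = derive_item_params(fig2_gs, table4)
        for s in ("s1", "s3", "s4", "s7", "s8"):
            assert 0 < ip.beta[s] < 1
            assert 0 < ip.eta[s] < 1

    def test_absorption_identity_on_degenerate_chain(self, fig2_gs):
        """β rows that always succeed give β_q ≈ 0 for every problem."""
        from pkst.mspm import TransitionParams

        beta, eta = {}, {}
        for i in fig2_gs.problem_states - {fig2_gs.goal}:
            succ = sorted({t for (s, _), t in fig2_gs.space.transitions.items()
                           if s == i and t != fig2_gs.failure})
            for t in succ:
                beta[(i, t)] = (1 - 1e-9) / len(succ)
                eta[(i, t)] = 0.25 / len(succ)
            beta[(i, fig2_gs.failure)] = 1e-9
            eta[(i, fig2_gs.failure)] = 0.75
        for s in (fig2_gs.goal, fig2_gs.failure):
            beta[(s, s)] = 1.0
            eta[(s, s)] = 1.0
        ip = derive_item_params(fig2_gs, TransitionParams("s9", "f", beta, eta))
        for s in ("s1", "s3", "s4", "s7", "s8"):
            assert ip.beta[s] < 1e-8


class TestRunAssessment:
    def test_cmp_worked_example(self, fig2_gs, ktol, example1_item_params):
        record = run_assessment(
            ktol, fig2_gs, lambda q: 1, "cmp",
            item_params=example1_item_params, threshold=0.5,
            rng=np.random.default_rng(7),
        )
        assert [q.initial for q in record.administered] == ["s4", "s1", "s3"]
        assert {q.initial for q in record.estimate} == {"s1", "s3", "s4", "s7", "s8"}
        assert record.terminated

    def test_msp_worked_example(self, fig2_gs, ktol, table4):
        procs = {Q["s4"]: PROC_S4, Q["s1"]: PROC_S1}
        record = run_assessment(
            ktol, fig2_gs, lambda q: procs[q], "msp3",
            trans_params=table4, threshold=0.5, rng=np.random.default_rng(7),
        )
        assert record.n_questions == 2
        assert [q.initial for q in record.administered] == ["s4", "s1"]
        assert len(record.modal_states) == 1
        assert {q.initial for q in record.modal_states[0]} == {"s1", "s3", "s4", "s7", "s8"}
        assert record.steps[-1].max_likelihood >= 0.9

    def test_threshold_one_exhausts_domain(self, fig2_gs, ktol, example1_item_params):
        record = run_assessment(
            ktol, fig2_gs, lambda q: 1, "cmp",
            item_params=example1_item_params, threshold=1.0,
            rng=np.random.default_rng(0),
        )
        assert record.n_questions == len(ktol.domain)

    def test_cmp_on_dichotomized_equals_scripted_binary(
        self, fig2_gs, ktol, table4, example1_item_params
    ):
        from pkst.mspm import dichotomize

        rng = np.random.default_rng(42)
        K = ("s1", "s3", "s4", "s7", "s8")
        procs = {
            q: simulate_process(q, K, table4, "msp3", fig2_gs, rng)
            for q in ktol.domain
        }
        binary = {q: dichotomize(p, fig2_gs.failure) for q, p in procs.items()}
        rec_proc = run_assessment(
            ktol, fig2_gs, lambda q: dichotomize(procs[q], fig2_gs.failure), "cmp",
            item_params=example1_item_params, rng=np.random.default_rng(1),
        )
        rec_bin = run_assessment(
            ktol, fig2_gs, lambda q: binary[q], "cmp",
            item_params=example1_item_params, rng=np.random.default_rng(1),
        )
        assert rec_proc.administered == rec_bin.administered
        assert np.allclose(rec_proc.final.weights, rec_bin.final.weights)

    def test_noiseless_recovery_of_true_state(self, fig2_gs, ktol, rng):
        """With noiseless data from K0 and a high threshold, modal = K0."""
        params = _noiseless_params(fig2_gs)
        for mask in ktol.masks:
            K0 = ktol.state_set(int(mask))
            initials = frozenset(q.initial for q in K0)
            procs = {
                q: simulate_process(q, initials, params, "msp2", fig2_gs, rng)
                for q in ktol.domain
            }
            record = run_assessment(
                ktol, fig2_gs, lambda q: procs[q], "msp2",
                trans_params=params, threshold=0.95, rng=rng, stop_early=False,
            )
            assert record.estimate == K0

    def test_engine_and_argument_validation(self, fig2_gs, ktol, table4):
        with pytest.raises(ValueError, match="engine"):
            run_assessment(ktol, fig2_gs, lambda q: 1, "irt")
        with pytest.raises(ValueError, match="item_params"):
            run_assessment(ktol, fig2_gs, lambda q: 1, "cmp")
        with pytest.raises(ValueError, match="trans_params"):
            run_assessment(ktol, fig2_gs, lambda q: 1, "msp1")
        with pytest.raises(ValueError, match="threshold"):
            run_assessment(ktol, fig2_gs, lambda q: 1, "msp1",
                           trans_params=table4, threshold=0.3)
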