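"""Reconstruction tests, including an independent brute-force optimum oracle.

The oracle below enumerates every indicator assignment and solves each
continuous subproblem with scipy's SLSQP on an explicit parametrization —
written without reference to the package's solver internals.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import combonet as cn
from combonet.cnr import Hyperparams, build_problem, solve
from combonet.mra import ResponseMatrix


def _brute_force_objective(R_by_line, candidates, prior, target_map, eta, theta, delta=1e-6):
    """Exhaustive minimum of SSR + eta*edges + theta*diffs over all
    indicator assignments, continuous parts via SLSQP."""
    lines = list(R_by_line)
    nodes = R_by_line[lines[0]].nodes
    conds = R_by_line[lines[0]].conditions
    applied = {c: cn.synthetic.parse_condition_id(c) for c in conds}
    svar_keys = sorted(
        {
            (d, lab, t)
            for c in conds
            for d, lab in applied[c]
            for t in target_map[d]
            if t in nodes
        }
    )
    free_edges = [e for e in candidates if e not in prior]
    diff_slots = list(candidates)
    sdiff_slots = sorted({(d, t) for (d, _, t) in svar_keys})

    best = math.inf
    for e_bits in itertools.product((0, 1), repeat=len(free_edges)):
        active = set(prior) | {e for e, b in zip(free_edges, e_bits) if b}
        valid_diffs = [e for e in diff_slots if e in active]
        for d_bits in itertools.product((0, 1), repeat=len(valid_diffs)):
            diffs = {e for e, b in zip(valid_diffs, d_bits) if b}
            for s_bits in itertools.product((0, 1), repeat=len(sdiff_slots)):
                sdiffs = {p for p, b in zip(sdiff_slots, s_bits) if b}
                ssr = _continuous_ssr(
                    R_by_line, nodes, conds, applied, svar_keys, active, diffs, sdiffs, delta
                )
                obj = ssr + eta * len(active) + theta * (len(diffs) + len(sdiffs))
                best = min(best, obj)
    return best


def _continuous_ssr(R_by_line, nodes, conds, applied, svar_keys, active, diffs, sdiffs, delta):
    lines = list(R_by_line)
    # variable layout: r per (edge, group), s per (svar, group)
    var_index = {}

    def groups(per_line):
        return lines if per_line else [None]

    for e in sorted(active):
        for g in groups(e in diffs):
            var_index[("r", e, g)] = len(var_index)
    for d, lab, t in svar_keys:
        for g in groups((d, t) in sdiffs):
            var_index[("s", (d, lab, t), g)] = len(var_index)

    def unpack(x, kind, key, line):
        if (kind, key, line) in var_index:
            return x[var_index[(kind, key, line)]]
        return x[var_index[(kind, key, None)]]

    def ssr_of(x):
        total = 0.0
        for ln in lines:
            Rv = R_by_line[ln].values
            for c in conds:
                for i in nodes:
                    m = -Rv.loc[i, c]
                    for (ti, j) in active:
                        if ti == i:
                            m += unpack(x, "r", (ti, j), ln) * Rv.loc[j, c]
                    for d, lab in applied[c]:
                        if (d, lab, i) in svar_keys:
                            m += unpack(x, "s", (d, lab, i), ln)
                    total += m * m
        return total

    cons = []
    for d, lab, t in svar_keys:
        for g in groups((d, t) in sdiffs):
            idx = var_index[("s", (d, lab, t), g)]
            if lab == "IC50" or ((d, "IC50", t) not in svar_keys):
                cons.append({"type": "ineq", "fun": lambda x, i=idx: -delta - x[i]})
            else:  # IC90 below the IC50 value
                i50 = var_index[("s", (d, "IC50", t), g)]
                cons.append(
                    {"type": "ineq", "fun": lambda x, a=idx, b=i50: x[b] - x[a] - delta}
                )
    x0 = np.full(len(var_index), -0.1)
    res = minimize(ssr_of, x0, method="SLSQP", constraints=cons,
                   options={"maxiter": 300, "ftol": 1e-12})
    return float(res.fun)


@pytest.fixture(scope="module")
def two_node_data():
    """2-node, 2-drug, noiseless two-line dataset with one planted s-difference."""
    design = cn.make_study_design(
        nodes=["MEK1", "ERK1"], drugs=["MEKi", "ERKi"], combo_count=1,
        single_dose_drug=None, seed=21,
    )
    truth = cn.generate_ground_truth(
        design, n_edges=1, n_diffs=1, seed=23, expand_mek_children=False
    )
    responses, _ = cn.simulate_dataset(truth, design, noise_sd=0.0, seed=24)
    return design, truth, responses


class TestBuildProblem:
    def test_full_candidate_set_72_edges(self, noiseless_data):
        responses, _ = noiseless_data
        prob = build_problem(responses, [], cn.synthetic.DEFAULT_TARGET_MAP, Hyperparams())
        assert len(prob.candidate_edges) == 72

    def test_prior_only_mode_no_free_topology(self, noiseless_data, truth):
        responses, _ = noiseless_data
        prob = build_problem(
            responses, truth.edges(), truth.target_map,
            Hyperparams(0.1, math.inf), candidate_edges=truth.edges(),
        )
        assert prob.free_indicator_keys() == []

    def test_theta_inf_fixes_difference_indicators(self, noiseless_data, truth):
        responses, _ = noiseless_data
        prob = build_problem(
            responses, truth.edges(), truth.target_map, Hyperparams(0.1, math.inf)
        )
        kinds = {k[0] for k in prob.free_indicator_keys()}
        assert kinds == {"edge"}

    def test_unknown_drug_raises(self, noiseless_data):
        responses, _ = noiseless_data
        with pytest.raises(ValueError, match="unknown drug"):
            build_problem(responses, [], {"EGFRi": ["EGFR"]}, Hyperparams())

    def test_unmappable_target_raises(self, noiseless_data, truth):
        responses, _ = noiseless_data
        bad_map = dict(truth.target_map)
        bad_map["EGFRi"] = []
        with pytest.raises(ValueError, match="no mappable target"):
            build_problem(responses, [], bad_map, Hyperparams())

    def test_prior_not_in_candidates_raises(self, noiseless_data, truth):
        responses, _ = noiseless_data
        with pytest.raises(ValueError, match="prior edges"):
            build_problem(
                responses, [("AKT1", "EGFR")], truth.target_map, Hyperparams(),
                candidate_edges=[("ERK1", "MEK1")],
            )

    def test_negative_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            Hyperparams(-0.1, 1.0)


class TestSolve:
    def test_noiseless_single_line_recovery(self, noiseless_data, truth):
        responses, _ = noiseless_data
        ln = truth.cell_lines[0]
        res = cn.final_model({ln: responses[ln]}, truth.edges(), math.inf, truth.target_map)
        err = np.abs(res.r[ln].values.to_numpy() - truth.r[ln].values.to_numpy()).max()
        assert err < 1e-4
        assert res.rms < 1e-8

    def test_identical_lines_no_differences(self, noiseless_data, truth):
        responses, _ = noiseless_data
        ln = truth.cell_lines[0]
        dup = {"a": responses[ln], "b": ResponseMatrix(responses[ln].values, "b")}
        res = cn.final_model(dup, truth.edges(), theta=0.5, drug_target_map=truth.target_map)
        assert res.active_differences() == set()

    def test_planted_difference_recovery(self, fitted_model, truth):
        planted = {
            ("diff", key) if kind == "edge" else ("sdiff", key)
            for kind, key in truth.planted_diffs
        }
        assert fitted_model.active_differences() == planted

    def test_s_value_recovery(self, fitted_model, truth):
        for key, val in truth.s_spec.items():
            assert fitted_model.s_values[key] == pytest.approx(val, abs=1e-4)

    def test_dose_ordering_in_solution(self, fitted_model):
        by_pair = {}
        for (ln, d, lab, t), v in fitted_model.s_values.items():
            by_pair.setdefault((ln, d, t), {})[lab] = v
        for labs in by_pair.values():
            assert labs["IC90"] < 0
            if "IC50" in labs:
                assert 0 > labs["IC50"] > labs["IC90"]

    def test_backends_agree(self, tiny_noisy, tiny_truth):
        responses, _ = tiny_noisy
        prob = build_problem(
            responses, [], tiny_truth.target_map, Hyperparams(0.05, 0.5)
        )
        a = solve(prob, backend="bnb")
        b = solve(prob, backend="enumerate")
        assert a.objective == pytest.approx(b.objective, abs=1e-6)

    def test_matches_independent_brute_force(self, two_node_data):
        design, truth, responses = two_node_data
        eta, theta = 0.05, 0.3
        prob = build_problem(responses, [], truth.target_map, Hyperparams(eta, theta))
        res = solve(prob)
        oracle = _brute_force_objective(
            responses, prob.candidate_edges, set(), truth.target_map, eta, theta
        )
        assert res.objective <= oracle + 1e-6

    def test_bounded_vs_unbounded_agree_when_interior(self, tiny_noisy, tiny_truth):
        responses, _ = tiny_noisy
        common = dict(
            prior_edges=tiny_truth.edges(),
            drug_target_map=tiny_truth.target_map,
            hyperparams=Hyperparams(0.1, 0.5),
            candidate_edges=tiny_truth.edges(),
        )
        tight = solve(build_problem(responses, bound=10.0, **common))
        loose = solve(build_problem(responses, bound=1e6, **common))
        max_mag = max(
            np.abs(r.values.to_numpy() + np.eye(len(r.nodes))).max()
            for r in loose.r.values()
        )
        assert max_mag < 9.0  # interior: both encodings must agree
        assert tight.objective == pytest.approx(loose.objective, abs=1e-6)

    def test_objective_monotone_in_eta_theta(self, tiny_noisy, tiny_truth):
        responses, _ = tiny_noisy
        objs = []
        for eta, theta in [(0.01, 0.1), (0.1, 0.1), (1.0, 0.1)]:
            prob = build_problem(responses, [], tiny_truth.target_map, Hyperparams(eta, theta))
            objs.append(solve(prob).objective)
        assert objs == sorted(objs)
        objs_t = []
        for theta in [0.01, 0.1, 1.0]:
            prob = build_problem(responses, [], tiny_truth.target_map, Hyperparams(0.1, theta))
            objs_t.append(solve(prob).objective)
        assert objs_t == sorted(objs_t)

    def test_fit_correlation_reported(self, fitted_model):
        assert 0.99 < fitted_model.fit_correlation <= 1.0

    def test_indicator_overrides_respected(self, noiseless_data, truth):
        responses, _ = noiseless_data
        prob = build_problem(
            responses, truth.edges(), truth.target_map, Hyperparams(0.0, 1.0),
            candidate_edges=truth.edges(),
        )
        kind, key = truth.planted_diffs[0]
        gkey = ("diff", key) if kind == "edge" else ("sdiff", key)
        forced = solve(prob, indicator_overrides={gkey: 0})
        assert forced.indicators[gkey] == 0


class TestCrossval:
    def test_single_grid_point_returned(self, tiny_noisy, tiny_truth):
        responses, _ = tiny_noisy
        hp, added, cv = cn.loocv_select_hyperparams(
            responses, tiny_truth.edges(), tiny_truth.target_map,
            eta_grid=[0.1], theta_grid=[2.0], candidate_edges=tiny_truth.edges(),
        )
        assert (hp.eta, hp.theta) == (0.1, 2.0)
        assert len(cv) == 1

    def test_empty_grid_raises(self, tiny_noisy, tiny_truth):
        responses, _ = tiny_noisy
        with pytest.raises(ValueError, match="non-empty"):
            cn.loocv_select_hyperparams(
                responses, tiny_truth.edges(), tiny_truth.target_map,
                eta_grid=[], theta_grid=[1.0],
            )

    def test_no_combo_conditions_raises(self, tiny_truth, tiny_design):
        design = cn.make_study_design(
            nodes=tiny_design.nodes, drugs=tiny_design.drugs, combo_count=0,
            single_dose_drug=None, seed=5,
        )
        truth = cn.generate_ground_truth(
            design, n_edges=3, n_diffs=0, seed=6, expand_mek_children=False,
            ensure_identifiable=False,
        )
        responses, _ = cn.simulate_dataset(truth, design, noise_sd=0.0, seed=7)
        with pytest.raises(ValueError, match="multi-drug"):
            cn.loocv_select_hyperparams(
                responses, truth.edges(), truth.target_map,
                eta_grid=[0.1], theta_grid=[1.0],
            )

    def test_sparse_regime_beats_unpenalized_full_candidates(self, tiny_noisy, tiny_truth):
        responses, _ = tiny_noisy
        hp, added, cv = cn.loocv_select_hyperparams(
            responses, tiny_truth.edges(), tiny_truth.target_map,
            eta_grid=[0.0, 0.2], theta_grid=[math.inf],
        )
        penalized = cv.loc[(cv.eta == 0.2), "cv_mse"].iloc[0]
        unpenalized = cv.loc[(cv.eta == 0.0), "cv_mse"].iloc[0]
        assert cv["cv_mse"].min() <= unpenalized + 1e-12
        assert min(penalized, unpenalized) == pytest.approx(cv["cv_mse"].min())

    def test_paper_defaults_accepted(self, tiny_noisy, tiny_truth):
        responses, _ = tiny_noisy
        hp, _, _ = cn.loocv_select_hyperparams(
            responses, tiny_truth.edges(), tiny_truth.target_map,
            eta_grid=[0.1], theta_grid=[2.0], candidate_edges=tiny_truth.edges(),
        )
        assert hp == Hyperparams(0.1, 2.0)

    def test_final_model_theta_inf_shared(self, shared_model):
        assert shared_model.active_differences() == set()
        a, b = shared_model.lines
        pd.testing.assert_frame_equal(shared_model.r[a].values, shared_model.r[b].values)
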