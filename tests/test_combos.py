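import itertools
import math

import numpy as np
import pandas as pd
import pytest

import combonet as cn
from combonet.combos import (
    CellLineModel,
    OptimizerConfig,
    optimize_selectivity,
    power_analysis,
    rank_all_triples,
    search_space_size,
    select_controls,
    simulate_combo,
    validation_stats,
)
from combonet.dose import dose_params_dict, fit_dose_params
from combonet.viability import fit_viability_model


@pytest.fixture(scope="module")
def models(fitted_model, noiseless_data, truth, default_design):
    responses, viability = noiseless_data
    vfit = fit_viability_model(responses, viability, form="4c", compute_loocv=False)
    table = fit_dose_params(
        fitted_model.s_values, default_design.dose_levels, fitted_model.lines
    )
    by_line = dose_params_dict(table)
    out = {}
    for ln in truth.cell_lines:
        prm = vfit.params_for(ln)
        out[ln] = CellLineModel(
            name=ln, r=fitted_model.r[ln], dose_params=by_line[ln],
            k_m_akt=prm["K_AKT"], k_m_erk=prm["K_ERK"],
        )
    return out


@pytest.fixture(scope="module")
def caps(default_design):
    return {d: default_design.dose_levels[d]["IC10"] for d in default_design.drugs}


@pytest.fixture(scope="module")
def opt_config(caps):
    return OptimizerConfig(conc_cap=caps)


def _grid_oracle(models, drugs, caps, v_min=None, n=21, target=None):
    """Dense-grid reference for the optimizers."""
    axes = [np.linspace(0, caps[d], n) for d in drugs]
    first, second = list(models)
    best = math.inf
    mesh = np.meshgrid(*axes, indexing="ij")
    flat = [m.ravel() for m in mesh]
    va = models[first].viability_at(drugs, flat)
    vb = models[second].viability_at(drugs, flat)
    if target is not None:
        obj = (va - target) ** 2 + (vb - target) ** 2
        return float(obj.min())
    feasible = vb >= v_min - 1e-12
    return float(np.where(feasible, va, np.inf).min())


class TestSimulateCombo:
    def test_zero_dose_unit_viability(self, models):
        triple = ("EGFRi", "AKTi", "MEKi")
        pred = simulate_combo(models, triple, {d: 0.0 for d in triple})
        assert all(v == pytest.approx(1.0) for v in pred.v.values())
        assert pred.selectivity == pytest.approx(0.0)

    def test_selectivity_antiselectivity_negation(self, models):
        triple = ("EGFRi", "AKTi", "MEKi")
        pred = simulate_combo(models, triple, {d: 0.02 for d in triple})
        assert pred.selectivity == pytest.approx(-pred.anti_selectivity)

    def test_identical_models_zero_selectivity(self, models):
        ln = list(models)[0]
        m = models[ln]
        dup = {
            "a": m,
            "b": CellLineModel(
                name="b", r=m.r, dose_params=m.dose_params,
                k_m_akt=m.k_m_akt, k_m_erk=m.k_m_erk,
            ),
        }
        pred = simulate_combo(dup, ("EGFRi", "AKTi", "MEKi"),
                              {"EGFRi": 0.03, "AKTi": 0.02, "MEKi": 0.01})
        assert pred.selectivity == pytest.approx(0.0, abs=1e-12)

    def test_trained_combo_roundtrip(self, models, truth, default_design, noiseless_data):
        """At a trained two-drug IC50 condition the simulated viability must
        match the training viability (noiseless; exact model recovery)."""
        _, viability = noiseless_data
        combo_ids = [
            cid for cid, app in default_design.conditions.items() if len(app) == 2
        ]
        cid = combo_ids[0]
        applied = default_design.conditions[cid]
        drugs = tuple(d for d, _ in applied)
        conc = {d: default_design.dose_levels[d]["IC50"] for d in drugs}
        pred = simulate_combo(models, drugs, conc)
        vmean = viability.groupby(["cell_line", "condition"])["viability"].mean()
        for ln in models:
            assert pred.v[ln] == pytest.approx(vmean[(ln, cid)], abs=1e-6)

    def test_missing_dose_params_raise(self, models):
        with pytest.raises(KeyError, match="NOSUCH"):
            simulate_combo(models, ("NOSUCH", "AKTi", "MEKi"),
                           {"NOSUCH": 0.1, "AKTi": 0.1, "MEKi": 0.1})


class TestOptimize:
    def test_matches_grid_oracle(self, models, caps, opt_config):
        for triple in [("EGFRi", "AKTi", "MEKi"), ("IGF1Ri", "PI3Ki", "GSK3i")]:
            pred = optimize_selectivity(models, triple, "anti_selective", opt_config)
            first = list(models)[0]
            oracle = _grid_oracle(models, triple, caps, v_min=opt_config.v_min)
            assert pred.v[first] <= oracle + 1e-4

    def test_constraint_respected(self, models, opt_config):
        pred = optimize_selectivity(
            models, ("EGFRi", "AKTi", "MEKi"), "anti_selective", opt_config
        )
        protected = list(models)[1]
        assert pred.v[protected] >= opt_config.v_min - 1e-6
        for d, c in pred.conc.items():
            assert -1e-12 <= c <= opt_config.cap_for(d) + 1e-12

    def test_identical_lines_zero_selectivity(self, models, opt_config):
        ln = list(models)[0]
        m = models[ln]
        dup = {"a": m, "b": CellLineModel("b", m.r, m.dose_params, m.k_m_akt, m.k_m_erk)}
        pred = optimize_selectivity(dup, ("EGFRi", "AKTi", "MEKi"), "selective", opt_config)
        assert pred.selectivity == pytest.approx(0.0, abs=1e-9)

    def test_planted_mechanism_pushes_to_cap(self, caps):
        """If only the unprotected line's AKT responds to a drug, its optimal
        concentration is the cap."""
        nodes = ["AKT1", "ERK1"]
        vals = pd.DataFrame(
            [[-1.0, 0.0], [0.0, -1.0]], index=nodes, columns=nodes
        )
        from combonet.dose import DoseResponseParams
        from combonet.mra import InteractionMatrix

        strong = {("X", "AKT1"): DoseResponseParams(imax=-8.0, ki=0.02)}
        null = {("X", "AKT1"): DoseResponseParams(imax=-1e-9, ki=0.02)}
        m_resp = CellLineModel("resp", InteractionMatrix(vals, "resp"), strong, 1.0, 1.0)
        m_flat = CellLineModel("flat", InteractionMatrix(vals, "flat"), null, 1.0, 1.0)
        cfg = OptimizerConfig(conc_cap=0.1)
        # unprotected = first line ("resp") under anti_selective direction
        pred = optimize_selectivity({"resp": m_resp, "flat": m_flat}, ("X",),
                                    "anti_selective", cfg)
        assert pred.conc["X"] == pytest.approx(0.1, abs=1e-6)

    def test_bad_direction(self, models, opt_config):
        with pytest.raises(ValueError, match="direction"):
            optimize_selectivity(models, ("EGFRi", "AKTi", "MEKi"), "bogus", opt_config)


class TestControls:
    def test_matches_grid_oracle(self, models, caps, opt_config):
        triple = ("EGFRi", "AKTi", "MEKi")
        pred = select_controls(models, triple, opt_config)
        oracle = _grid_oracle(models, triple, caps, target=0.8)
        assert pred.objective <= oracle + 1e-4

    def test_zero_effect_drugs_fixed_objective(self):
        from combonet.dose import DoseResponseParams
        from combonet.mra import InteractionMatrix

        nodes = ["AKT1", "ERK1"]
        vals = pd.DataFrame([[-1.0, 0.0], [0.0, -1.0]], index=nodes, columns=nodes)
        null = {("X", "AKT1"): DoseResponseParams(imax=-1e-12, ki=0.5)}
        m = {
            "a": CellLineModel("a", InteractionMatrix(vals, "a"), null, 1.0, 1.0),
            "b": CellLineModel("b", InteractionMatrix(vals, "b"), null, 1.0, 1.0),
        }
        pred = select_controls(m, ("X",), OptimizerConfig(conc_cap=0.1))
        # viability stuck at 1: objective = 2 * (1 - 0.8)^2 = 0.08
        assert pred.objective == pytest.approx(0.08, abs=1e-9)


class TestRankAll:
    def test_84_triples_for_9_drugs(self, models, opt_config):
        table, preds = rank_all_triples(models, config=opt_config)
        assert len(table) == math.comb(9, 3) == 84
        assert len(preds) == 84

    def test_sorted_descending(self, models, opt_config):
        table, _ = rank_all_triples(models, config=opt_config)
        scores = table["score"].to_numpy()
        assert np.all(np.diff(scores[~np.isnan(scores)]) <= 1e-12)

    def test_infinite_floor_empty(self, models, opt_config):
        table, _ = rank_all_triples(
            models, config=opt_config, anti_selectivity_floor=math.inf
        )
        assert not table["passes_floor"].any()

    def test_too_few_drugs(self, models, opt_config):
        with pytest.raises(ValueError, match="three drugs"):
            rank_all_triples(models, config=opt_config, drugs=["EGFRi", "AKTi"])


class TestPower:
    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        a = np.full(30, 0.2)
        b = np.full(44, 0.2)
        p = power_analysis(a, b, noise_sd=0.25, n_sims=1000, alpha=0.05, seed=1)
        assert p == pytest.approx(0.05, abs=0.02)

    def test_large_effect_high_power(self):
        a = np.full(30, 1.25)  # 5 * noise_sd above b
        b = np.zeros(44)
        p = power_analysis(a, b, noise_sd=0.25, n_sims=500, seed=2)
        assert p >= 0.99

    def test_deterministic(self):
        a, b = np.full(10, 0.3), np.full(12, 0.1)
        kw = dict(noise_sd=0.25, n_sims=300, seed=7)
        assert power_analysis(a, b, **kw) == power_analysis(a, b, **kw)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            power_analysis([], [0.1])


class TestSearchSpace:
    def test_four_way_of_89(self):
        assert search_space_size(89, 4, 1) == 2_441_626

    def test_with_ten_concentrations(self):
        assert search_space_size(89, 4, 10) == 24_416_260_000

    def test_trivial(self):
        assert search_space_size(3, 3, 1) == 1

    def test_invalid(self):
        with pytest.raises(ValueError):
            search_space_size(3, 5, 1)
        with pytest.raises(ValueError):
            search_space_size(3, 2, 0)


class TestValidationStats:
    def _measurements(self, effect, n_combos=6, seed=0, noise=0.01):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_combos):
            for rep in range(8):
                vp = 0.7 + rng.normal(0, noise)
                vm = 0.7 + effect + rng.normal(0, noise)
                rows.append((f"combo{i}", "parental", rep, vp))
                rows.append((f"combo{i}", "mutant", rep, vm))
        return pd.DataFrame(rows, columns=["combo", "cell_line", "replicate", "viability"])

    def test_separated_groups_significant(self):
        pos = self._measurements(0.3, n_combos=12, seed=1)
        neg = self._measurements(0.0, n_combos=12, seed=2)
        neg["combo"] = neg["combo"].str.replace("combo", "ctrl")
        df = pd.concat([pos, neg], ignore_index=True)
        groups = {f"combo{i}": "anti" for i in range(12)}
        groups.update({f"ctrl{i}": "control" for i in range(12)})
        table, summary = validation_stats(df, groups, "parental", "mutant")
        assert summary["pvalue"] < 1e-3
        anti_rows = table[table.group == "anti"]
        assert (anti_rows["p_vs_zero"] < 0.05).all()

    def test_permuted_labels_not_significant(self):
        pos = self._measurements(0.3, seed=3)
        neg = self._measurements(0.0, seed=4)
        neg["combo"] = neg["combo"].str.replace("combo", "ctrl")
        df = pd.concat([pos, neg], ignore_index=True)
        # permute group labels: mix half of each group into the other
        groups = {}
        for i in range(6):
            groups[f"combo{i}"] = "anti" if i % 2 == 0 else "control"
            groups[f"ctrl{i}"] = "anti" if i % 2 == 1 else "control"
        _, summary = validation_stats(df, groups, "parental", "mutant")
        assert summary["pvalue"] > 0.05

    def test_single_replicate_skips_tests(self):
        df = pd.DataFrame(
            [("c1", "parental", 0, 0.9), ("c1", "mutant", 0, 0.8)],
            columns=["combo", "cell_line", "replicate", "viability"],
        )
        table, _ = validation_stats(df, {"c1": "anti"}, "parental", "mutant")
        assert math.isnan(table["p_vs_zero"].iloc[0])

    def test_reference_comparison(self):
        df = self._measurements(0.4, seed=5)
        groups = {f"combo{i}": "anti" for i in range(6)}
        refs = {f"combo{i}": 0.1 for i in range(6)}
        table, _ = validation_stats(df, groups, "parental", "mutant", references=refs)
        assert (table["p_vs_reference"] < 0.05).all()


class TestEndToEnd:
    def test_planted_antiselective_drug_tops_ranking(self):
        """Full pipeline on a synthetic truth whose only between-line
        difference is one drug hitting the first (parental) line much harder:
        that drug must surface in the top-ranked anti-selective triple."""
        design = cn.make_study_design(seed=31)
        truth = cn.generate_ground_truth(design, n_edges=16, n_diffs=0, seed=32)
        parental = truth.cell_lines[0]
        planted = "IGF1Ri"
        for (ln, d, lab, t) in list(truth.s_spec):
            if ln == parental and d == planted:
                truth.s_spec[(ln, d, lab, t)] *= 2.5
        responses, viability = cn.simulate_dataset(
            truth, design, noise_sd=0.0, viability_noise_sd=0.0, seed=33
        )
        model = cn.final_model(responses, truth.edges(), 0.01, truth.target_map)
        vfit = fit_viability_model(responses, viability, form="4c", compute_loocv=False)
        table = fit_dose_params(model.s_values, design.dose_levels, model.lines)
        by_line = dose_params_dict(table)
        models = {
            ln: CellLineModel(
                ln, model.r[ln], by_line[ln],
                vfit.params_for(ln)["K_AKT"], vfit.params_for(ln)["K_ERK"],
            )
            for ln in truth.cell_lines
        }
        caps = {d: design.dose_levels[d]["IC10"] for d in design.drugs}
        ranked, _ = rank_all_triples(
            models, direction="anti_selective", config=OptimizerConfig(conc_cap=caps)
        )
        top = ranked.iloc[0]["drugs"].split("+")
        assert planted in top
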