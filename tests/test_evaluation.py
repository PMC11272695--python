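import random
from dataclasses import replace

import numpy as np
import pytest

from htpbk.compound import PropertySelector
from htpbk.evaluation import (StudyRecord, aggregate_compound, evaluate_strategy,
                              expand_grid, run_grid, simulate_study,
                              stepwise_workflow)
from htpbk.engine import DosingEvent
from htpbk.synthetic import (StudyDesign, SyntheticTruth, ToolSpec,
                             generate_dataset, truth_strategy)


@pytest.fixture(scope="module")
def clean_dataset():
    """Zero-noise synthetic dataset: observations are exactly reproducible."""
    design = StudyDesign(observation_cv=0.0, physiology_weight_sd=0.0,
                         studies_per_compound=(2, 3))
    return generate_dataset(4, SyntheticTruth(design=design, seed=11))


@pytest.fixture(scope="module")
def noisy_dataset():
    design = StudyDesign(studies_per_compound=(2, 3))
    return generate_dataset(4, SyntheticTruth(design=design, seed=12))


class TestAggregateCompound:
    def test_single(self):
        assert aggregate_compound([0.7]) == 0.7

    def test_odd(self):
        assert aggregate_compound([0.2, 0.5, 0.9]) == 0.5

    def test_even_mean_of_central(self):
        assert aggregate_compound([1, 2, 3, 10]) == 2.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_compound([])


class TestSimulateStudy:
    def test_reference_physiology_without_demographics(self, clean_dataset, ref_phys):
        ds = clean_dataset
        study = ds.studies[0]
        pred = simulate_study(study, ds.truth_strategy, ds.compounds, ref_phys)
        # zero-noise observations were generated at reference physiology:
        # the prediction must reproduce them exactly
        assert np.allclose(pred.concentrations, study.observations.concentrations,
                           rtol=1e-12, atol=0)

    def test_demographics_change_prediction(self, clean_dataset, ref_phys):
        ds = clean_dataset
        study = ds.studies[0]
        heavy = StudyRecord(study_id=study.study_id, compound_id=study.compound_id,
                            dosing=study.dosing, observations=study.observations,
                            demographics={"weight": 140.0})
        a = simulate_study(study, ds.truth_strategy, ds.compounds, ref_phys)
        b = simulate_study(heavy, ds.truth_strategy, ds.compounds, ref_phys)
        assert not np.allclose(a.concentrations, b.concentrations)

    def test_infusion_routing(self, clean_dataset, ref_phys):
        ds = clean_dataset
        study = ds.studies[0]
        bolus = replace(study, dosing=DosingEvent(route="iv_bolus", dose=50.0))
        infusion = replace(study, dosing=DosingEvent(route="iv_infusion", dose=50.0,
                                                     infusion_duration=2.0))
        a = simulate_study(bolus, ds.truth_strategy, ds.compounds, ref_phys)
        b = simulate_study(infusion, ds.truth_strategy, ds.compounds, ref_phys)
        assert max(b.concentrations) < max(a.concentrations)

    def test_capsule_without_t80_gets_default(self, clean_dataset, ref_phys):
        ds = clean_dataset
        study = ds.studies[0]
        po = replace(study, dosing=DosingEvent(route="oral", dose=50.0,
                                               formulation="capsule"))
        assert po.dosing.dissolution_time80 == 25.0
        pred = simulate_study(po, ds.truth_strategy, ds.compounds, ref_phys)
        assert max(pred.concentrations) > 0


class TestEvaluateStrategy:
    def test_closed_loop_zero_error(self, clean_dataset, ref_phys):
        ds = clean_dataset
        res = evaluate_strategy(list(ds.studies), ds.truth_strategy, ds.compounds, ref_phys)
        assert res.median_absolute_log2 < 1e-9
        assert res.fold_table_cmax[1.5] == 100.0
        assert not res.failures

    def test_study_order_invariance(self, noisy_dataset, ref_phys):
        ds = noisy_dataset
        studies = list(ds.studies)
        res1 = evaluate_strategy(studies, ds.truth_strategy, ds.compounds, ref_phys)
        shuffled = studies[:]
        random.Random(5).shuffle(shuffled)
        res2 = evaluate_strategy(shuffled, ds.truth_strategy, ds.compounds, ref_phys)
        assert res1.median_absolute_log2 == res2.median_absolute_log2
        assert [c.compound_id for c in res1.compounds] == [c.compound_id for c in res2.compounds]

    def test_strategy_median_is_median_of_compounds(self, noisy_dataset, ref_phys):
        ds = noisy_dataset
        res = evaluate_strategy(list(ds.studies), ds.truth_strategy, ds.compounds, ref_phys)
        import statistics
        expected = statistics.median(c.median_absolute_log2 for c in res.compounds)
        assert res.median_absolute_log2 == pytest.approx(expected)

    def test_missing_compound_recorded_as_failure(self, noisy_dataset, ref_phys):
        ds = noisy_dataset
        compounds = dict(ds.compounds)
        victim = ds.studies[0].compound_id
        compounds.pop(victim)
        res = evaluate_strategy(list(ds.studies), ds.truth_strategy, compounds, ref_phys)
        failed_ids = {sid for sid, _ in res.failures}
        assert any(sid.startswith(victim) for sid in failed_ids)
        assert all(c.compound_id != victim for c in res.compounds)

    def test_all_failures_is_an_error(self, noisy_dataset, ref_phys):
        ds = noisy_dataset
        with pytest.raises(RuntimeError, match="failed"):
            evaluate_strategy(list(ds.studies), ds.truth_strategy, {}, ref_phys)

    def test_empty_dataset_rejected(self, noisy_dataset, ref_phys):
        with pytest.raises(ValueError):
            evaluate_strategy([], truth_strategy(), noisy_dataset.compounds, ref_phys)


class TestGrid:
    def test_product_count(self):
        base = truth_strategy()
        options = {
            "lipophilicity": [("a", {}), ("b", {})],
            "partitioning": [(m, {"partitioning_method": m})
                             for m in ("pksim", "schmitt", "rodgers_rowland",
                                       "poulin_theil", "berezhkovskiy")],
            "pka": [("on", {}), ("off", {"pka_source": None}), ("alt", {})],
        }
        assert len(expand_grid(base, options)) == 2 * 5 * 3

    def test_empty_slot_rejected(self):
        with pytest.raises(ValueError, match="no options"):
            expand_grid(truth_strategy(), {"x": []})

    def test_single_option_grid_equals_evaluate(self, noisy_dataset, ref_phys):
        ds = noisy_dataset
        results = run_grid({"only": [("t", {})]}, list(ds.studies), ds.compounds,
                           ref_phys, ds.truth_strategy)
        assert len(results) == 1
        direct = evaluate_strategy(list(ds.studies), ds.truth_strategy,
                                   ds.compounds, ref_phys)
        assert results[0].median_absolute_log2 == pytest.approx(direct.median_absolute_log2)

    def test_tie_broken_lexicographically(self, noisy_dataset, ref_phys):
        ds = noisy_dataset
        # two identical options must rank by label
        results = run_grid({"slot": [("zzz", {}), ("aaa", {})]},
                           list(ds.studies), ds.compounds, ref_phys, ds.truth_strategy)
        assert [r.label for r in results] == ["slot=aaa", "slot=zzz"]


@pytest.fixture(scope="module")
def tooled_dataset():
    tools = (
        ToolSpec("goodtool", "lipophilicity", "LogD", bias=0.0, sd=0.0),
        ToolSpec("badtool", "lipophilicity", "LogD", bias=0.0, sd=1.2),
        ToolSpec("fu_good", "fu", "fu", bias=0.0, sd=0.0),
        ToolSpec("cl_good", "clearance", "plasma_CL", bias=0.0, sd=0.0),
        ToolSpec("cl_bad", "clearance", "plasma_CL", bias=0.0, sd=1.2),
        ToolSpec("sol_good", "solubility", "aqueous", bias=0.0, sd=0.0),
        ToolSpec("perm_good", "permeability", "CACO2", bias=0.0, sd=0.0),
    )
    design = StudyDesign(studies_per_compound=(2, 3), observation_cv=0.1,
                         physiology_weight_sd=0.0)
    return generate_dataset(6, SyntheticTruth(tools=tools, design=design, seed=21))


class TestStepwiseWorkflow:

    def test_workflow_recovers_zero_error_tools(self, tooled_dataset, ref_phys):
        ds = tooled_dataset
        iv = [s for s in ds.studies if s.route_class == "IV"]
        po = [s for s in ds.studies if s.route_class == "PO"]
        base = ds.truth_strategy
        physchem = {"lipophilicity": [
            ("goodtool", {"lipophilicity_sources": (PropertySelector("goodtool", "LogD"),)}),
            ("badtool", {"lipophilicity_sources": (PropertySelector("badtool", "LogD"),)}),
        ]}
        adme = {"clearance": [
            ("cl_good", {"clearance_source": "cl_good"}),
            ("cl_bad", {"clearance_source": "cl_bad"}),
        ]}
        absorption = {"solubility": [
            ("sol_good", {"solubility_source": PropertySelector("sol_good", "aqueous")}),
        ]}
        wf = stepwise_workflow(iv, po, ds.compounds, ref_phys, base,
                               physchem, adme, absorption)
        assert "goodtool" in wf.step1[0].label
        assert "cl_good" in wf.step2[0].label
        assert wf.step3_all is not None
        # step-3 first pass restricted to liquid formulations
        liquid_ids = {s.study_id for s in po
                      if s.dosing.formulation in ("solution", "suspension")}
        evaluated_ids = {st.study_id for c in wf.step3_liquid[0].compounds
                         for st in c.studies}
        assert evaluated_ids <= liquid_ids

    def test_workflow_requires_both_datasets(self, tooled_dataset, ref_phys):
        ds = tooled_dataset
        with pytest.raises(ValueError, match="IV and PO"):
            stepwise_workflow([], list(ds.studies), ds.compounds, ref_phys,
                              ds.truth_strategy, {"a": [("x", {})]},
                              {"b": [("x", {})]}, {"c": [("x", {})]})
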