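"""Dataset-level evaluation: drive simulations over PK studies, aggregate
per-compound medians, benchmark strategy grids, and the three-step workflow
(physico-chemical sources on IV data, then Fu/clearance sources, then
solubility/permeability sources on PO data).
"""

from __future__ import annotations

import itertools
import logging
import math
import statistics
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from . import clearance as clearance_mod
from . import engine as engine_mod
from . import partitioning as partitioning_mod
from .compound import (CompoundProperties, MissingSlotError,
                       ParameterisationStrategy, resolve_inputs)
from .engine import (ConcentrationTimeProfile, DosingEvent, EngineError,
                     EngineOptions, SimulationSpec)
from .nca import ErrorPair, ProfileMetrics, fold_summaries, nca, profile_log2_errors
from .physiology import Physiology, scale_physiology

log = logging.getLogger(__name__)

LIQUID_FORMULATIONS = ("solution", "suspension")


@dataclass(frozen=True)
class StudyRecord:
    study_id: str
    compound_id: str
    dosing: DosingEvent
    observations: ConcentrationTimeProfile
    demographics: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.observations.times) == 0:
            raise ValueError(f"study {self.study_id}: empty observations")
        if not self.dosing.dose > 0:
            raise ValueError(f"study {self.study_id}: dose must be > 0")

    @property
    def route_class(self) -> str:
        return "PO" if self.dosing.route == "oral" else "IV"


@dataclass(frozen=True)
class StudyResult:
    study_id: str
    errors: ErrorPair
    predicted: ProfileMetrics
    observed: ProfileMetrics

    def log2_ratio(self, which: str) -> float:
        p = getattr(self.predicted, which)
        o = getattr(self.observed, which)
        if p <= 0 or o <= 0:
            return math.nan
        return math.log2(p / o)


@dataclass(frozen=True)
class CompoundResult:
    compound_id: str
    studies: tuple[StudyResult, ...]
    median_absolute_log2: float
    median_relative_log2: float
    median_log2_cmax: float
    median_log2_tmax: float
    median_log2_auc: float


@dataclass(frozen=True)
class StrategyResult:
    strategy: ParameterisationStrategy
    route: str
    compounds: tuple[CompoundResult, ...]
    median_absolute_log2: float
    median_relative_log2: float
    fold_table_cmax: Mapping[float, float]
    fold_table_auc: Mapping[float, float]
    failures: tuple[tuple[str, str], ...] = ()   # (study_id, reason)

    @property
    def label(self) -> str:
        return self.strategy.label


def aggregate_compound(values: Sequence[float]) -> float:
    """Median across studies; the mean of the two central values for even n."""
    vals = [v for v in values]
    if not vals:
        raise ValueError("cannot aggregate an empty value set")
    return float(statistics.median(vals))


def simulate_study(
    study: StudyRecord,
    strategy: ParameterisationStrategy,
    compounds: Mapping[str, CompoundProperties],
    phys: Physiology,
    options: EngineOptions = EngineOptions(),
    conversions=None,
    permeability_coeffs=None,
) -> ConcentrationTimeProfile:
    """Predict one study's profile at its observed timepoints.

    Demographics, when present, scale the reference physiology; otherwise
    the reference (healthy adult male) is used unchanged.
    """
    if study.compound_id not in compounds:
        raise MissingSlotError(f"no property data for compound {study.compound_id!r}")
    compound = compounds[study.compound_id]
    route = "oral" if study.dosing.route == "oral" else "iv"
    params = resolve_inputs(compound, strategy, route, conversions=conversions)

    if params.permeability_pending_engine:
        perm = engine_mod.engine_permeability(
            params.mw, params.lipophilicity, coeffs=permeability_coeffs)
        params = replace(params, permeability=perm, permeability_pending_engine=False)

    demo = dict(study.demographics or {})
    if demo:
        subject_phys = scale_physiology(
            phys,
            sex=demo.get("sex"),
            age=demo.get("age"),
            weight=demo.get("weight"),
            height=demo.get("height"),
        )
    else:
        subject_phys = phys

    partition = partitioning_mod.compute_partition_set(
        strategy.partitioning_method, params, subject_phys)
    clear = clearance_mod.assemble_clearance(strategy, params, subject_phys)

    spec = SimulationSpec(
        resolved=params,
        partition=partition,
        clearance=clear,
        phys=subject_phys,
        dosing=study.dosing,
        output_times=study.observations.times,
        options=options,
    )
    profile = engine_mod.simulate(spec)
    return replace(profile, compound_id=study.compound_id, study_id=study.study_id)


def evaluate_strategy(
    dataset: Sequence[StudyRecord],
    strategy: ParameterisationStrategy,
    compounds: Mapping[str, CompoundProperties],
    phys: Physiology,
    options: EngineOptions = EngineOptions(),
    conversions=None,
    permeability_coeffs=None,
) -> StrategyResult:
    """Per-study metrics → per-compound medians → strategy-level medians.

    Failed simulations (unresolvable inputs, integration errors) are
    excluded from the medians but recorded in ``failures``.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")

    by_compound: dict[str, list[StudyResult]] = {}
    failures: list[tuple[str, str]] = []
    routes = {s.route_class for s in dataset}
    for study in sorted(dataset, key=lambda s: (s.compound_id, s.study_id)):
        try:
            pred = simulate_study(study, strategy, compounds, phys, options,
                                  conversions, permeability_coeffs)
            errors = profile_log2_errors(pred, study.observations)
            res = StudyResult(
                study_id=study.study_id,
                errors=errors,
                predicted=nca(pred),
                observed=nca(study.observations),
            )
        except (MissingSlotError, EngineError, ValueError) as exc:
            failures.append((study.study_id, f"{type(exc).__name__}: {exc}"))
            continue
        by_compound.setdefault(study.compound_id, []).append(res)

    if not by_compound:
        raise RuntimeError(
            f"all {len(dataset)} simulations failed for strategy {strategy.label!r}; "
            f"first failure: {failures[0] if failures else 'n/a'}"
        )

    compound_results = []
    for cid in sorted(by_compound):
        studies = tuple(by_compound[cid])

        def med(values):
            vals = [v for v in values if not math.isnan(v)]
            return aggregate_compound(vals) if vals else math.nan

        compound_results.append(CompoundResult(
            compound_id=cid,
            studies=studies,
            median_absolute_log2=med(s.errors.absolute_log2 for s in studies),
            median_relative_log2=med(s.errors.relative_log2 for s in studies),
            median_log2_cmax=med(s.log2_ratio("cmax") for s in studies),
            median_log2_tmax=med(s.log2_ratio("tmax") for s in studies),
            median_log2_auc=med(s.log2_ratio("auc_0_last") for s in studies),
        ))

    def strat_median(values):
        vals = [v for v in values if not math.isnan(v)]
        return aggregate_compound(vals) if vals else math.nan

    cmax_pairs = [(2.0 ** c.median_log2_cmax, 1.0) for c in compound_results
                  if not math.isnan(c.median_log2_cmax)]
    auc_pairs = [(2.0 ** c.median_log2_auc, 1.0) for c in compound_results
                 if not math.isnan(c.median_log2_auc)]

    return StrategyResult(
        strategy=strategy,
        route="/".join(sorted(routes)),
        compounds=tuple(compound_results),
        median_absolute_log2=strat_median(c.median_absolute_log2 for c in compound_results),
        median_relative_log2=strat_median(c.median_relative_log2 for c in compound_results),
        fold_table_cmax=fold_summaries(cmax_pairs) if cmax_pairs else {},
        fold_table_auc=fold_summaries(auc_pairs) if auc_pairs else {},
        failures=tuple(failures),
    )


# ---------------------------------------------------------------------------
# strategy grids


GridOption = tuple[str, dict]   # (option label, strategy-field overrides)


def expand_grid(base: ParameterisationStrategy,
                slot_options: Mapping[str, Sequence[GridOption]]
                ) -> list[ParameterisationStrategy]:
    """Cartesian product of slot options applied over a base strategy."""
    if not slot_options:
        raise ValueError("slot_options must be non-empty")
    slots = sorted(slot_options)
    for slot in slots:
        if not slot_options[slot]:
            raise ValueError(f"slot {slot!r} has no options")
    strategies = []
    for combo in itertools.product(*(slot_options[s] for s in slots)):
        fields: dict = {}
        labels = []
        for (opt_label, overrides), slot in zip(combo, slots):
            fields.update(overrides)
            labels.append(f"{slot}={opt_label}")
        label = "|".join(labels)
        strategies.append(replace(base, label=label, **fields))
    return strategies


def run_grid(
    slot_options: Mapping[str, Sequence[GridOption]],
    dataset: Sequence[StudyRecord],
    compounds: Mapping[str, CompoundProperties],
    phys: Physiology,
    base: ParameterisationStrategy,
    options: EngineOptions = EngineOptions(),
    conversions=None,
    permeability_coeffs=None,
) -> list[StrategyResult]:
    """Evaluate every slot combination; ranked by median absolute log2 error
    (ties broken lexicographically by strategy label)."""
    strategies = expand_grid(base, slot_options)
    results = []
    for strat in strategies:
        try:
            results.append(evaluate_strategy(
                dataset, strat, compounds, phys, options, conversions, permeability_coeffs))
        except RuntimeError as exc:
            log.warning("strategy %s skipped: %s", strat.label, exc)
    results.sort(key=lambda r: (
        r.median_absolute_log2 if not math.isnan(r.median_absolute_log2) else math.inf,
        r.label,
    ))
    return results


@dataclass(frozen=True)
class WorkflowResult:
    step1: tuple[StrategyResult, ...]
    step2: tuple[StrategyResult, ...]
    step3_liquid: tuple[StrategyResult, ...]
    step3_all: Optional[StrategyResult]
    selected: ParameterisationStrategy


def stepwise_workflow(
    dataset_iv: Sequence[StudyRecord],
    dataset_po: Sequence[StudyRecord],
    compounds: Mapping[str, CompoundProperties],
    phys: Physiology,
    base: ParameterisationStrategy,
    physchem_options: Mapping[str, Sequence[GridOption]],
    adme_options: Mapping[str, Sequence[GridOption]],
    absorption_options: Mapping[str, Sequence[GridOption]],
    options: EngineOptions = EngineOptions(),
    conversions=None,
    permeability_coeffs=None,
) -> WorkflowResult:
    """Three-step evaluation.

    Step 1 ranks physico-chemical sources on the IV data with the base
    strategy's benchmark clearance/Fu held fixed; step 2 ranks Fu/clearance
    sources on IV data with the step-1 winner's physico-chemical choices;
    step 3 ranks solubility/permeability sources on the liquid-formulation
    PO subset, and the winning full strategy is re-evaluated on all PO data.
    """
    if not dataset_iv or not dataset_po:
        raise ValueError("both IV and PO datasets are required")
    if base.fu_source is None or base.clearance_source is None:
        raise ValueError("base strategy must carry benchmark fu/clearance sources for step 1")

    common = dict(options=options, conversions=conversions,
                  permeability_coeffs=permeability_coeffs)

    step1 = run_grid(physchem_options, dataset_iv, compounds, phys, base, **common)
    best1 = step1[0].strategy

    step2 = run_grid(adme_options, dataset_iv, compounds, phys,
                     replace(best1, label=base.label), **common)
    best2 = step2[0].strategy

    liquid = [s for s in dataset_po
              if s.dosing.formulation in LIQUID_FORMULATIONS]
    if not liquid:
        raise ValueError("no liquid-formulation PO studies for step 3")
    step3 = run_grid(absorption_options, liquid, compounds, phys,
                     replace(best2, label=base.label), **common)
    best3 = step3[0].strategy

    selected = replace(best3, label=f"{base.label}|selected")
    step3_all = evaluate_strategy(dataset_po, selected, compounds, phys, **common)

    return WorkflowResult(
        step1=tuple(step1), step2=tuple(step2),
        step3_liquid=tuple(step3), step3_all=step3_all,
        selected=selected,
    )
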