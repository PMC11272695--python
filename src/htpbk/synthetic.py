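"""Synthetic ground truth: compounds, emulated prediction tools and noisy
multi-study concentration–time datasets.

The generator mirrors the structure the evaluation machinery expects from a
curated human PK dataset — several studies per compound, IV and PO routes,
four formulation labels, sparse log-spaced sampling and multiplicative
inter-study noise — while persisting the generating truth so that recovery
can be scored.  Distribution choices are defaults only; nothing downstream
depends on them beyond positivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import clearance as clearance_mod
from . import engine as engine_mod
from . import partitioning as partitioning_mod
from .compound import (CompoundProperties, ParameterisationStrategy,
                       PropertyRecord, PropertySelector, resolve_inputs)
from .engine import (ConcentrationTimeProfile, DosingEvent, EngineOptions,
                     SimulationSpec)
from .evaluation import StudyRecord
from .physiology import Physiology, reference_human, scale_physiology

#: IVIVE factor implied by the reference physiology: L/h of liver clearance
#: per unit CLint (µl/min/10^6 cells); used to make truth CLint consistent
#: with truth plasma clearance.
_FORMULATIONS = ("solution", "suspension", "capsule", "tablet")


@dataclass(frozen=True)
class PropertyRanges:
    mw: tuple[float, float] = (150.0, 900.0)
    logd_mean: float = 2.0
    logd_sd: float = 1.5
    logd_bounds: tuple[float, float] = (-3.0, 7.0)
    fu: tuple[float, float] = (0.01, 1.0)
    plasma_cl: tuple[float, float] = (0.5, 50.0)       # L/h
    solubility: tuple[float, float] = (1.0, 1e4)       # mg/L
    permeability: tuple[float, float] = (3e-5, 3e-2)   # cm/min, 3 decades
    max_pka_sites: int = 2


@dataclass(frozen=True)
class ToolSpec:
    """One emulated prediction source: a log-scale bias and error SD."""

    name: str
    property: str
    subtype: str
    bias: float = 0.0   # log10-scale shift
    sd: float = 0.0     # log10-scale error SD

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("tool error SD must be >= 0")


@dataclass(frozen=True)
class StudyDesign:
    routes: tuple[str, ...] = ("iv", "po")
    studies_per_compound: tuple[int, int] = (1, 6)
    dose_range_mg: tuple[float, float] = (1.0, 500.0)
    n_timepoints: tuple[int, int] = (8, 14)
    t_end_iv: float = 24.0
    t_end_po: float = 36.0
    first_time_iv: float = 1.0 / 12.0
    first_time_po: float = 0.25
    formulations: tuple[str, ...] = _FORMULATIONS
    observation_cv: float = 0.25
    physiology_weight_sd: float = 0.1   # log-normal SD on subject weight


@dataclass(frozen=True)
class SyntheticTruth:
    ranges: PropertyRanges = field(default_factory=PropertyRanges)
    tools: tuple[ToolSpec, ...] = ()
    design: StudyDesign = field(default_factory=StudyDesign)
    seed: int = 0


@dataclass(frozen=True)
class SyntheticDataset:
    studies: tuple[StudyRecord, ...]
    compounds: Mapping[str, CompoundProperties]
    truth_strategy: ParameterisationStrategy
    seed: int

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for cid, comp in sorted(self.compounds.items()):
            for rec in comp.records:
                if rec.source != "truth":
                    continue
                rows.append({"compound_id": cid, "property": rec.property,
                             "subtype": rec.subtype, "value": rec.value,
                             "source": rec.source, "MW": comp.mw, "unit": rec.unit})
        return pd.DataFrame(rows)


def truth_strategy(partitioning_method: str = "pksim") -> ParameterisationStrategy:
    """Strategy reading every slot from the generating truth source."""
    return ParameterisationStrategy(
        label="truth",
        lipophilicity_sources=(PropertySelector("truth", "LogD"),),
        consensus=False,
        pka_source="truth",
        partitioning_method=partitioning_method,
        fu_source="truth",
        clearance_source="truth",
        clearance_mode="plasma",
        renal_passive=False,
        solubility_source=PropertySelector("truth", "aqueous"),
        permeability_source=PropertySelector("truth", "CACO2"),
        permeability_scaling="direct",
    )


def sample_compound(rng: np.random.Generator, ranges: PropertyRanges = PropertyRanges(),
                    compound_id: str = "C0") -> CompoundProperties:
    """Draw one ground-truth compound from the configured marginals."""
    mw = float(rng.uniform(*ranges.mw))
    logd = float(np.clip(rng.normal(ranges.logd_mean, ranges.logd_sd), *ranges.logd_bounds))

    def loguni(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    fu = loguni(*ranges.fu)
    cl = loguni(*ranges.plasma_cl)
    sol = loguni(*ranges.solubility)
    perm = loguni(*ranges.permeability)

    phys = reference_human()
    clint_unit_scale = clearance_mod.scale_clint_to_liver(1.0, phys)
    clint = cl / clint_unit_scale   # truth CLint consistent with truth plasma CL

    records = [
        PropertyRecord("lipophilicity", "LogD", logd, "truth"),
        PropertyRecord("fu", "fu", fu, "truth"),
        PropertyRecord("clearance", "plasma_CL", cl, "truth", unit="L/h"),
        PropertyRecord("clearance", "hepatocyte_CLint", clint, "truth", unit="ul/min/1e6cells"),
        PropertyRecord("solubility", "aqueous", sol, "truth"),
        PropertyRecord("permeability", "CACO2", perm, "truth"),
    ]
    n_pka = int(rng.integers(0, ranges.max_pka_sites + 1))
    for _ in range(n_pka):
        if rng.uniform() < 0.5:
            records.append(PropertyRecord("pKa", "base", float(rng.uniform(5.0, 10.5)), "truth"))
        else:
            records.append(PropertyRecord("pKa", "acid", float(rng.uniform(3.0, 9.0)), "truth"))
    return CompoundProperties(compound_id=compound_id, mw=mw, records=tuple(records))


def emulate_tool_predictions(truth: CompoundProperties, tools: Sequence[ToolSpec],
                             rng: np.random.Generator) -> list[PropertyRecord]:
    """Perturbed per-tool copies of the truth records.

    Multiplicative-scale properties get ``truth * 10^(bias + eps)``;
    lipophilicity (already a log quantity) gets an additive shift; fu is
    perturbed on the log10-odds scale and clamped to (0, 1].
    """
    if not tools:
        raise ValueError("tool_specs must be non-empty")
    out: list[PropertyRecord] = []
    for tool in tools:
        src = truth.select(tool.property, subtype=tool.subtype, source="truth")
        if not src:
            raise ValueError(
                f"truth compound {truth.compound_id} has no "
                f"{tool.property}/{tool.subtype} record to emulate from"
            )
        base = src[0]
        eps = tool.bias + rng.normal(0.0, tool.sd) if tool.sd > 0 else tool.bias
        if tool.property == "lipophilicity":
            value = base.value + eps
        elif tool.property == "fu":
            odds = math.log10(base.value / max(1.0 - base.value, 1e-12)) + eps
            value = min(1.0, 1.0 / (1.0 + 10.0 ** (-odds)))
        else:
            value = base.value * 10.0 ** eps
        out.append(PropertyRecord(tool.property, tool.subtype, value, tool.name,
                                  unit=base.unit))
    return out


def _sample_times(rng: np.random.Generator, design: StudyDesign, route: str) -> np.ndarray:
    n = int(rng.integers(design.n_timepoints[0], design.n_timepoints[1] + 1))
    t0 = design.first_time_iv if route == "iv" else design.first_time_po
    t_end = design.t_end_iv if route == "iv" else design.t_end_po
    return np.exp(np.linspace(np.log(t0), np.log(t_end), n))


def generate_dataset(
    n_compounds: int,
    spec: SyntheticTruth = SyntheticTruth(),
    phys: Optional[Physiology] = None,
    engine_options: EngineOptions = EngineOptions(),
) -> SyntheticDataset:
    """Ground-truth compounds + emulated tools + noisy observed studies.

    Observations are engine simulations under the truth parameters with a
    per-study log-normally perturbed physiology and multiplicative
    log-normal observation noise; the same seed reproduces the dataset
    exactly.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    design = spec.design
    if design.observation_cv < 0 or design.physiology_weight_sd < 0:
        raise ValueError("noise parameters must be >= 0")
    rng = np.random.default_rng(spec.seed)
    ref = phys if phys is not None else reference_human()
    strat = truth_strategy()

    sigma_obs = math.sqrt(math.log(1.0 + design.observation_cv ** 2))

    compounds: dict[str, CompoundProperties] = {}
    studies: list[StudyRecord] = []
    for ci in range(n_compounds):
        cid = f"SYN{ci:04d}"
        truth = sample_compound(rng, spec.ranges, compound_id=cid)
        records = list(truth.records)
        if spec.tools:
            records.extend(emulate_tool_predictions(truth, spec.tools, rng))
        compound = replace(truth, records=tuple(records))
        compounds[cid] = compound

        n_studies = int(rng.integers(design.studies_per_compound[0],
                                     design.studies_per_compound[1] + 1))
        for si in range(n_studies):
            route = design.routes[int(rng.integers(0, len(design.routes)))]
            dose = float(np.exp(rng.uniform(np.log(design.dose_range_mg[0]),
                                            np.log(design.dose_range_mg[1]))))
            if route == "iv":
                if rng.uniform() < 0.3:
                    dosing = DosingEvent(route="iv_infusion", dose=dose,
                                         infusion_duration=float(rng.uniform(0.25, 2.0)))
                else:
                    dosing = DosingEvent(route="iv_bolus", dose=dose)
            else:
                form = design.formulations[int(rng.integers(0, len(design.formulations)))]
                dosing = DosingEvent(route="oral", dose=dose, formulation=form)

            times = _sample_times(rng, design, route)

            if design.physiology_weight_sd > 0:
                weight = ref.body_weight * float(
                    np.exp(rng.normal(0.0, design.physiology_weight_sd)))
                subject = scale_physiology(ref, weight=weight)
            else:
                subject = ref

            params = resolve_inputs(compound, strat, route)
            partition = partitioning_mod.compute_partition_set(
                strat.partitioning_method, params, subject)
            clear = clearance_mod.assemble_clearance(strat, params, subject)
            sim = engine_mod.simulate(SimulationSpec(
                resolved=params, partition=partition, clearance=clear,
                phys=subject, dosing=dosing, output_times=times,
                options=engine_options,
            ))
            conc = np.asarray(sim.concentrations)
            if design.observation_cv > 0:
                conc = conc * np.exp(rng.normal(0.0, sigma_obs, size=conc.shape))
            obs = ConcentrationTimeProfile(
                times=tuple(float(t) for t in times),
                concentrations=tuple(float(c) for c in conc),
                compound_id=cid,
                study_id=f"{cid}-S{si}",
            )
            studies.append(StudyRecord(
                study_id=f"{cid}-S{si}", compound_id=cid,
                dosing=dosing, observations=obs,
            ))

    return SyntheticDataset(
        studies=tuple(studies), compounds=compounds,
        truth_strategy=strat, seed=spec.seed,
    )
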