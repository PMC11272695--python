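"""Whole-body flow-limited PBK engine.

Topology: venous blood → lung → arterial blood → perfused organs → venous
blood, with gut and spleen draining through the liver (portal route).  All
tissues are flow-limited: organ venous outflow concentration is
``C_tissue / (Kp / BP)``.  Elimination is hepatic (on unbound liver
concentration, intrinsic mode), systemic plasma clearance and/or passive
renal clearance (both on venous plasma).

Oral dosing adds a well-mixed gut lumen: the dose dissolves following the
formulation's 80%-dissolution-time schedule, dissolved concentration is
capped at the solubility, absorption is permeability × area × dissolved
concentration into the liver inflow (first pass), and unabsorbed material
leaves the lumen with a fixed transit residence time.

Intravenous dosing makes the system linear and time-invariant, so it is
propagated exactly with matrix exponentials; oral dosing is integrated with
a stiff ODE solver.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .clearance import ClearanceSpec
from .compound import ResolvedParameters
from .partitioning import PartitionSet
from .physiology import PORTAL_ORGANS, Physiology

ROUTES = ("iv_bolus", "iv_infusion", "oral")
FORMULATIONS = ("solution", "suspension", "capsule", "tablet")
SOLID_FORMULATIONS = ("capsule", "tablet")

#: default 80% dissolution times (min) per solid formulation
DEFAULT_T80_MIN = {"capsule": 25.0, "tablet": 40.0}

CM_PER_MIN_TO_L_PER_H_PER_CM2 = 60.0 / 1000.0   # cm/min * cm^2 * mg/L -> mg/h


class EngineError(RuntimeError):
    pass


@dataclass(frozen=True)
class DosingEvent:
    route: str
    dose: float                                  # mg
    infusion_duration: float = 0.0               # h, iv_infusion only
    formulation: Optional[str] = None            # oral only
    dissolution_time80: Optional[float] = None   # min, solid formulations

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"route must be one of {ROUTES}, got {self.route!r}")
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")
        if self.route == "iv_infusion":
            if not self.infusion_duration > 0:
                raise ValueError("iv_infusion requires infusion_duration > 0")
        elif self.infusion_duration not in (0, 0.0):
            raise ValueError("infusion_duration only applies to iv_infusion")
        if self.route == "oral":
            form = self.formulation or "solution"
            if form not in FORMULATIONS:
                raise ValueError(f"unknown formulation {form!r}")
            object.__setattr__(self, "formulation", form)
            if form in SOLID_FORMULATIONS:
                t80 = self.dissolution_time80
                if t80 is None:
                    object.__setattr__(self, "dissolution_time80", DEFAULT_T80_MIN[form])
                elif not t80 > 0:
                    raise ValueError("dissolution_time80 must be > 0 for solid formulations")


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    times: tuple[float, ...]            # h
    concentrations: tuple[float, ...]   # mg/L
    compartment: str = "venous_plasma"
    compound_id: str = ""
    study_id: str = ""

    def __post_init__(self) -> None:
        if len(self.times) != len(self.concentrations):
            raise ValueError("times and concentrations must have equal length")
        t = np.asarray(self.times)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        c = np.asarray(self.concentrations)
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise ValueError("concentrations must be finite and >= 0")


@dataclass(frozen=True)
class EngineOptions:
    blood_plasma_ratio: float = 1.0
    lumen_volume: float = 1.0            # L
    absorption_area: float = 2.5e4       # cm^2
    transit_time: float = 3.5            # h, mean lumen residence time
    rtol: float = 1e-8
    atol: float = 1e-10                  # mg
    dissolution_rate_cap: float = 50.0   # 1/h, cap on the dissolution hazard


@dataclass(frozen=True)
class SimulationSpec:
    resolved: ResolvedParameters
    partition: PartitionSet
    clearance: ClearanceSpec
    phys: Physiology
    dosing: DosingEvent
    output_times: Sequence[float]
    options: EngineOptions = field(default_factory=EngineOptions)

    def __post_init__(self) -> None:
        t = np.asarray(self.output_times, dtype=float)
        if t.size == 0:
            raise ValueError("output_times must be non-empty")
        if np.any(t < 0):
            raise ValueError("output_times must be >= 0")


@dataclass(frozen=True)
class SimulationResult:
    profile: ConcentrationTimeProfile
    mass_balance_max_rel_error: float
    fraction_absorbed: float            # NaN for IV routes
    states: Mapping[str, np.ndarray]


# ---------------------------------------------------------------------------
# standalone operations


def dissolved_fraction(formulation: str, t80_min: Optional[float], t_min: float) -> float:
    """Fraction of a dose dissolved ``t_min`` minutes after administration.

    Solutions and suspensions are fully dissolved at t=0.  Solid
    formulations follow a linear ramp hitting 0.80 at t80 and 1.0 at
    1.25*t80 (constant slope 0.8/t80).
    """
    if t_min < 0:
        raise ValueError("t must be >= 0")
    if formulation not in FORMULATIONS:
        raise ValueError(f"unknown formulation {formulation!r}")
    if formulation not in SOLID_FORMULATIONS:
        return 1.0
    if t80_min is None:
        t80_min = DEFAULT_T80_MIN[formulation]
    if not t80_min > 0:
        raise ValueError("t80 must be > 0 for solid formulations")
    return min(0.8 * t_min / t80_min, 1.0)


def caco2_scaling_factor(predicted: Sequence[float], target: Sequence[float]) -> float:
    """Geometric-mean ratio mapping tool-predicted permeabilities onto the
    engine's scale; applying it zeroes the mean log10 ratio."""
    pred = np.asarray(predicted, dtype=float)
    targ = np.asarray(target, dtype=float)
    if pred.shape != targ.shape or pred.size < 3:
        raise ValueError("need >= 3 paired permeability values")
    if np.any(pred <= 0) or np.any(targ <= 0):
        raise ValueError("permeabilities must be strictly positive")
    return float(10.0 ** np.mean(np.log10(targ) - np.log10(pred)))


def load_permeability_coeffs(path=None) -> dict:
    if path is None:
        text = resources.files("htpbk.data").joinpath("permeability_coeffs.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = json.loads(text)
    return {"a": doc["a"], "b": doc["b"], "c": doc["c"]}


def engine_permeability(mw: float, logma: float, coeffs: Optional[Mapping[str, float]] = None
                        ) -> float:
    """Internal permeability surrogate: a * 10^(b*logMA) * MW^c [cm/min]."""
    if coeffs is None:
        coeffs = load_permeability_coeffs()
    for key in ("a", "b", "c"):
        if key not in coeffs:
            raise ValueError(f"permeability coefficients missing {key!r}")
    if not mw > 0:
        raise ValueError("MW must be positive")
    return coeffs["a"] * 10.0 ** (coeffs["b"] * logma) * mw ** coeffs["c"]


# ---------------------------------------------------------------------------
# state layout and system matrix


class _Layout:
    """Index bookkeeping for the state vector."""

    def __init__(self, phys: Physiology):
        self.tissues = [o.name for o in phys.perfused_organs]
        self.idx = {name: i for i, name in enumerate(self.tissues)}
        n = len(self.tissues)
        self.art = n
        self.ven = n + 1
        self.elim_hep = n + 2
        self.elim_ren = n + 3
        self.elim_pl = n + 4
        self.lumen_undis = n + 5
        self.lumen_dis = n + 6
        self.transited = n + 7
        self.n_states = n + 8


def _build_matrix(spec: SimulationSpec, lay: _Layout) -> np.ndarray:
    """Linear part of dA/dt = M A (distribution + elimination, amounts in mg)."""
    phys = spec.phys
    bp = spec.options.blood_plasma_ratio
    kp = spec.partition.kp
    M = np.zeros((lay.n_states, lay.n_states))

    v_art = phys.organ("arterial_blood").volume
    v_ven = phys.organ("venous_blood").volume
    co = phys.cardiac_output

    q_portal_total = 0.0
    liver = lay.idx["liver"]
    for organ in phys.perfused_organs:
        if organ.name == "lung":
            continue
        i = lay.idx[organ.name]
        q = organ.blood_flow
        # arterial inflow
        M[i, lay.art] += q / v_art
        if organ.name in PORTAL_ORGANS:
            q_portal_total += q
        # venous outflow coefficient (per unit amount in the organ)
        k_out = q * bp / (kp[organ.name] * organ.volume)
        M[i, i] -= k_out
        if organ.name in PORTAL_ORGANS:
            M[liver, i] += k_out
        elif organ.name == "liver":
            pass  # handled below with total hepatic flow
        else:
            M[lay.ven, i] += k_out

    # liver: outflow carries hepatic artery + portal flow
    liv_organ = phys.organ("liver")
    q_liv_total = liv_organ.blood_flow + q_portal_total
    k_liv_out = q_liv_total * bp / (kp["liver"] * liv_organ.volume)
    M[liver, liver] -= k_liv_out
    M[lay.ven, liver] += k_liv_out
    # overwrite the generic outflow added in the loop for the liver
    M[liver, liver] += liv_organ.blood_flow * bp / (kp["liver"] * liv_organ.volume)

    # lung between venous and arterial blood
    lung_organ = phys.organ("lung")
    lung = lay.idx["lung"]
    M[lung, lay.ven] += co / v_ven
    k_lung_out = co * bp / (kp["lung"] * lung_organ.volume)
    M[lung, lung] -= k_lung_out
    M[lay.art, lung] += k_lung_out
    M[lay.ven, lay.ven] -= co / v_ven
    M[lay.art, lay.art] -= co / v_art

    # elimination
    cl = spec.clearance
    fu = spec.resolved.fu
    if cl.mode == "intrinsic" and cl.intrinsic_liver_cl > 0:
        k = cl.intrinsic_liver_cl * fu / (kp["liver"] * liv_organ.volume)
        M[liver, liver] -= k
        M[lay.elim_hep, liver] += k
    if cl.mode == "plasma" and cl.plasma_cl > 0:
        k = cl.plasma_cl / (bp * v_ven)
        M[lay.ven, lay.ven] -= k
        M[lay.elim_pl, lay.ven] += k
    if cl.renal_cl > 0:
        k = cl.renal_cl / (bp * v_ven)
        M[lay.ven, lay.ven] -= k
        M[lay.elim_ren, lay.ven] += k

    return M


# ---------------------------------------------------------------------------
# propagation


def _propagate_linear(M: np.ndarray, y0: np.ndarray, u: np.ndarray,
                      times: np.ndarray) -> np.ndarray:
    """Exact propagation of dy/dt = M y + u at the requested times."""
    n = len(y0)
    if np.any(u != 0.0):
        aug = np.zeros((n + 1, n + 1))
        aug[:n, :n] = M
        aug[:n, n] = u
        y = np.concatenate([y0, [1.0]])
        out = np.empty((len(times), n))
        t_prev = 0.0
        for k, t in enumerate(times):
            if t > t_prev:
                y = expm(aug * (t - t_prev)) @ y
                t_prev = t
            out[k] = y[:n]
        return out
    out = np.empty((len(times), n))
    y = y0.copy()
    t_prev = 0.0
    for k, t in enumerate(times):
        if t > t_prev:
            y = expm(M * (t - t_prev)) @ y
            t_prev = t
        out[k] = y
    return out


def _simulate_iv(spec: SimulationSpec, lay: _Layout, times: np.ndarray) -> np.ndarray:
    M = _build_matrix(spec, lay)
    y0 = np.zeros(lay.n_states)
    dose = spec.dosing.dose
    if spec.dosing.route == "iv_bolus":
        y0[lay.ven] = dose
        return _propagate_linear(M, y0, np.zeros(lay.n_states), times)

    # infusion: constant input over [0, T], then free decay
    T = spec.dosing.infusion_duration
    u = np.zeros(lay.n_states)
    u[lay.ven] = dose / T
    t_on = times[times <= T]
    t_off = times[times > T]
    out = np.empty((len(times), lay.n_states))
    n_on = len(t_on)
    if n_on:
        out[:n_on] = _propagate_linear(M, y0, u, t_on)
    y_T = _propagate_linear(M, y0, u, np.array([T]))[-1]
    if len(t_off):
        out[n_on:] = _propagate_linear(M, y_T, np.zeros(lay.n_states), t_off - T)
    return out


def _simulate_oral(spec: SimulationSpec, lay: _Layout, times: np.ndarray) -> np.ndarray:
    M = _build_matrix(spec, lay)
    opts = spec.options
    dosing = spec.dosing
    dose = dosing.dose
    resolved = spec.resolved

    if resolved.permeability is None:
        raise EngineError(
            f"{resolved.compound_id}: oral simulation without a resolved permeability "
            "(engine-equation permeability must be finalised before simulation)"
        )
    perm = resolved.permeability
    sol = resolved.solubility if resolved.solubility is not None else math.inf
    if sol <= 0:
        raise EngineError(f"{resolved.compound_id}: non-positive solubility {sol}")

    k_transit = 1.0 / opts.transit_time
    ka_coef = perm * opts.absorption_area * CM_PER_MIN_TO_L_PER_H_PER_CM2  # (mg/L -> mg/h)
    liver = lay.idx["liver"]
    solid = dosing.formulation in SOLID_FORMULATIONS
    t80_h = (dosing.dissolution_time80 or 0.0) / 60.0
    slope = 0.8 / t80_h if solid and t80_h > 0 else 0.0
    cap = opts.dissolution_rate_cap

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = M @ y
        a_und = max(y[lay.lumen_undis], 0.0)
        a_dis = max(y[lay.lumen_dis], 0.0)
        c_dis = a_dis / opts.lumen_volume
        # dissolution: hazard of the linear schedule, saturation-limited
        if solid and a_und > 0.0:
            f = min(slope * t, 1.0)
            hazard = slope / (1.0 - f) if f < 1.0 else cap
            hazard = min(hazard, cap)
            sat = max(0.0, 1.0 - c_dis / sol) if math.isfinite(sol) else 1.0
            diss = hazard * sat * a_und
        else:
            diss = 0.0
        absorb = ka_coef * min(c_dis, sol)
        dy[lay.lumen_undis] += -diss - k_transit * a_und
        dy[lay.lumen_dis] += diss - k_transit * a_dis - absorb
        dy[lay.transited] += k_transit * (a_und + a_dis)
        dy[liver] += absorb
        return dy

    y0 = np.zeros(lay.n_states)
    if solid:
        y0[lay.lumen_undis] = dose
    else:
        y0[lay.lumen_dis] = dose

    t_end = float(times[-1]) if times[-1] > 0 else 1.0
    t_eval = times[times > 0]
    sol_ivp = solve_ivp(
        rhs, (0.0, t_end), y0, method="LSODA",
        t_eval=t_eval if len(t_eval) else None,
        rtol=opts.rtol, atol=opts.atol, max_step=max(t_end / 20.0, 0.05),
    )
    if not sol_ivp.success:
        raise EngineError(
            f"integrator failed for {resolved.compound_id}: {sol_ivp.message}; "
            f"dose={dose}, formulation={dosing.formulation}, perm={perm}, sol={sol}"
        )
    out = np.empty((len(times), lay.n_states))
    j = 0
    for k, t in enumerate(times):
        if t == 0.0:
            out[k] = y0
        else:
            out[k] = sol_ivp.y[:, j]
            j += 1
    return out


def simulate_full(spec: SimulationSpec) -> SimulationResult:
    """Run one simulation and return the profile plus diagnostics."""
    lay = _Layout(spec.phys)
    times = np.asarray(sorted(spec.output_times), dtype=float)
    dose = spec.dosing.dose

    if dose == 0.0:
        zeros = np.zeros((len(times), lay.n_states))
        states = zeros
    elif spec.dosing.route in ("iv_bolus", "iv_infusion"):
        states = _simulate_iv(spec, lay, times)
    else:
        states = _simulate_oral(spec, lay, times)

    # negative-state guard (solver noise tolerated, real negativity is a bug)
    floor = -max(1e-9 * max(dose, 1.0), 10 * spec.options.atol)
    if states.min() < floor:
        raise EngineError(
            f"negative state beyond tolerance ({states.min():.3e}) for "
            f"{spec.resolved.compound_id} {spec.dosing.route}"
        )
    states = np.clip(states, 0.0, None)

    # mass balance
    if dose > 0:
        if spec.dosing.route == "iv_infusion":
            administered = dose * np.minimum(times / spec.dosing.infusion_duration, 1.0)
        else:
            administered = np.full_like(times, dose)
        total = states.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(total - administered) / dose
        rel[administered == 0] = 0.0
        mb_err = float(np.max(rel))
    else:
        mb_err = 0.0

    bp = spec.options.blood_plasma_ratio
    v_ven = spec.phys.organ("venous_blood").volume
    conc = states[:, lay.ven] / v_ven / bp

    profile = ConcentrationTimeProfile(
        times=tuple(float(t) for t in times),
        concentrations=tuple(float(c) for c in conc),
        compound_id=spec.resolved.compound_id,
    )
    if spec.dosing.route == "oral" and dose > 0:
        in_body = dose - states[-1, lay.lumen_undis] - states[-1, lay.lumen_dis] \
            - states[-1, lay.transited]
        fa = float(in_body / dose)
    else:
        fa = float("nan")

    named = {"amounts": states, "times": times,
             "eliminated_hepatic": states[:, lay.elim_hep],
             "eliminated_renal": states[:, lay.elim_ren],
             "eliminated_plasma": states[:, lay.elim_pl]}
    return SimulationResult(profile=profile, mass_balance_max_rel_error=mb_err,
                            fraction_absorbed=fa, states=named)


def simulate(spec: SimulationSpec) -> ConcentrationTimeProfile:
    """Simulate a dosing event; returns the venous plasma profile."""
    return simulate_full(spec).profile
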