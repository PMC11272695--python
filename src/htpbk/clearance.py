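"""Elimination specification: IVIVE scaling of hepatocyte CLint, plasma
clearance handling and passive renal clearance with its on/off rule.

Hepatocyte intrinsic clearance (µl/min/10^6 cells) is scaled to a whole-liver
clearance with hepatocellularity × liver density × liver volume and converted
to L/h.  Plasma-clearance inputs already represent all systemic elimination,
so passive renal clearance is only ever added on top of hepatocyte-scaled
CLint, never on top of plasma clearance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .compound import ParameterisationStrategy, ResolvedParameters
from .physiology import Physiology

log = logging.getLogger(__name__)

UL_PER_MIN_TO_L_PER_H = 60.0 / 1e6


@dataclass(frozen=True)
class ClearanceSpec:
    """Elimination terms the engine applies.  Exactly one hepatic mode is
    active; renal_CL is forced to zero in plasma mode."""

    mode: str                       # plasma | intrinsic
    plasma_cl: float = 0.0          # L/h (plasma mode)
    intrinsic_liver_cl: float = 0.0 # L/h (intrinsic mode)
    renal_cl: float = 0.0           # L/h

    def __post_init__(self) -> None:
        if self.mode not in ("plasma", "intrinsic"):
            raise ValueError(f"mode must be plasma|intrinsic, got {self.mode!r}")
        if min(self.plasma_cl, self.intrinsic_liver_cl, self.renal_cl) < 0:
            raise ValueError("clearance terms must be >= 0")
        if self.mode == "plasma" and self.intrinsic_liver_cl != 0.0:
            raise ValueError("plasma mode must not carry an intrinsic clearance")
        if self.mode == "intrinsic" and self.plasma_cl != 0.0:
            raise ValueError("intrinsic mode must not carry a plasma clearance")
        if self.mode == "plasma" and self.renal_cl != 0.0:
            raise ValueError("renal clearance must be zero in plasma mode")


def scale_clint_to_liver(clint: float, phys: Physiology) -> float:
    """Scale in vitro CLint (µl/min/10^6 cells) to whole-liver clearance (L/h).

    clint * hepatocellularity [cells/g] * liver density [g/ml] * liver
    volume [ml], evaluated per 10^6 cells, then µl/min → L/h.
    """
    if clint < 0:
        raise ValueError(f"CLint must be >= 0, got {clint}")
    ul_per_min = (clint * (phys.hepatocellularity / 1e6)
                  * phys.liver_density * phys.liver_volume_ml)
    return ul_per_min * UL_PER_MIN_TO_L_PER_H


def renal_passive_clearance(fu: float, phys: Physiology) -> float:
    """Passive renal clearance: glomerular filtration of the unbound fraction."""
    if not 0.0 <= fu <= 1.0:
        raise ValueError(f"fu must lie in [0,1], got {fu}")
    return phys.gfr * fu


def assemble_clearance(
    strategy: ParameterisationStrategy,
    params: ResolvedParameters,
    phys: Physiology,
) -> ClearanceSpec:
    """Build the engine's elimination spec from resolved inputs.

    Plasma mode: the clearance value (scaled by body weight when declared
    per kg) becomes the plasma clearance; any renal flag is ignored with a
    warning.  Intrinsic mode: CLint is IVIVE-scaled to the liver and renal
    clearance GFR×fu is added when the strategy asks for it.
    """
    if params.clearance_mode == "plasma":
        value = params.clearance_value
        if params.clearance_unit == "L/h/kg":
            value = value * phys.body_weight
        if strategy.renal_passive:
            log.warning(
                "strategy %s: renal_passive ignored in plasma-clearance mode "
                "(plasma CL already includes renal elimination)", strategy.label,
            )
        return ClearanceSpec(mode="plasma", plasma_cl=value, renal_cl=0.0)

    liver_cl = scale_clint_to_liver(params.clearance_value, phys)
    renal = renal_passive_clearance(params.fu, phys) if strategy.renal_passive else 0.0
    return ClearanceSpec(mode="intrinsic", intrinsic_liver_cl=liver_cl, renal_cl=renal)
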