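"""Reference human physiology and demographic scaling.

The reference table (organ volumes, regional blood flows, tissue
compositions) is compiled from published reference-man values and shipped as
versioned package data.  Every simulation draws its anatomy from a
:class:`Physiology` object, either the reference adult male or a
demographically scaled copy of it.

Conventions
-----------
* Volumes in litres, flows in L/h, GFR in L/h.
* ``liver.blood_flow`` is the hepatic-artery contribution only; gut and
  spleen venous outflow passes through the liver (portal route), so the sum
  of all systemic organ arterial flows equals cardiac output (= lung flow).
* Composition fractions are mass fractions of tissue wet weight.
"""

from __future__ import annotations

import copy
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

log = logging.getLogger(__name__)

#: Organs whose venous outflow drains through the liver instead of pooling
#: directly into venous blood.
PORTAL_ORGANS = ("gut", "spleen")

#: Compartments that are blood pools, not perfused tissues.
BLOOD_COMPARTMENTS = ("arterial_blood", "venous_blood")

_COMPOSITION_KEYS = (
    "water",
    "neutral_lipid",
    "phospholipid",
    "protein",
    "acidic_phospholipid",
)


@dataclass(frozen=True)
class OrganSpec:
    """One organ: volume, arterial blood flow and tissue composition."""

    name: str
    volume: float
    blood_flow: float
    composition: Mapping[str, float] = field(default_factory=dict)
    eliminating: bool = False

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ValueError(f"organ {self.name!r}: volume must be > 0, got {self.volume}")
        if self.blood_flow < 0:
            raise ValueError(f"organ {self.name!r}: blood_flow must be >= 0")
        if self.name not in BLOOD_COMPARTMENTS and self.name != "lung":
            if not self.blood_flow > 0:
                raise ValueError(f"perfused organ {self.name!r} needs blood_flow > 0")
        total = 0.0
        for key, frac in self.composition.items():
            if key not in _COMPOSITION_KEYS:
                raise ValueError(f"organ {self.name!r}: unknown composition key {key!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"organ {self.name!r}: fraction {key}={frac} outside [0,1]")
            total += frac
        if total > 1.0 + 1e-9:
            raise ValueError(f"organ {self.name!r}: composition fractions sum to {total} > 1")


@dataclass(frozen=True)
class Physiology:
    """Whole-body anatomy: organ set plus renal/hepatic scaling constants."""

    organs: Sequence[OrganSpec]
    gfr: float                      # L/h
    hepatocellularity: float        # cells/g liver
    liver_density: float            # g/ml
    body_weight: float              # kg
    demographics: Mapping[str, object] = field(default_factory=dict)
    version: str = "unversioned"

    def __post_init__(self) -> None:
        for val, name in ((self.gfr, "gfr"), (self.hepatocellularity, "hepatocellularity"),
                          (self.liver_density, "liver_density"), (self.body_weight, "body_weight")):
            if not val > 0:
                raise ValueError(f"{name} must be strictly positive, got {val}")
        names = [o.name for o in self.organs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate organ names")
        self._check_flow_balance()

    def _check_flow_balance(self) -> None:
        co = self.cardiac_output
        systemic = sum(
            o.blood_flow
            for o in self.organs
            if o.name != "lung" and o.name not in BLOOD_COMPARTMENTS
        )
        if co > 0 and abs(systemic - co) > 1e-9 * co:
            raise ValueError(
                f"flow balance violated: systemic flows sum to {systemic}, cardiac output {co}"
            )

    @property
    def cardiac_output(self) -> float:
        return self.organ("lung").blood_flow

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(f"no organ named {name!r}")

    @property
    def organ_names(self) -> list[str]:
        return [o.name for o in self.organs]

    @property
    def perfused_organs(self) -> list[OrganSpec]:
        """All tissues in the flow loop (everything except the blood pools)."""
        return [o for o in self.organs if o.name not in BLOOD_COMPARTMENTS]

    @property
    def liver_volume_ml(self) -> float:
        return self.organ("liver").volume * 1000.0

    @property
    def total_volume(self) -> float:
        return sum(o.volume for o in self.organs)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "body_weight_kg": self.body_weight,
            "gfr_L_per_h": self.gfr,
            "hepatocellularity_cells_per_g": self.hepatocellularity,
            "liver_density_g_per_ml": self.liver_density,
            "demographics": dict(self.demographics),
            "organs": [
                {
                    "name": o.name,
                    "volume": o.volume,
                    "blood_flow": o.blood_flow,
                    "composition": dict(o.composition),
                    "eliminating": o.eliminating,
                }
                for o in self.organs
            ],
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "Physiology":
        organs = [
            OrganSpec(
                name=o["name"],
                volume=o["volume"],
                blood_flow=o["blood_flow"],
                composition=o.get("composition", {}),
                eliminating=o.get("eliminating", False),
            )
            for o in doc["organs"]
        ]
        return cls(
            organs=organs,
            gfr=doc["gfr_L_per_h"],
            hepatocellularity=doc["hepatocellularity_cells_per_g"],
            liver_density=doc["liver_density_g_per_ml"],
            body_weight=doc["body_weight_kg"],
            demographics=doc.get("demographics", {}),
            version=doc.get("version", "unversioned"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Physiology":
        return cls.from_dict(json.loads(text))


def load_tissue_composition() -> dict[str, dict[str, float]]:
    """Composition fractions per tissue (plus ``plasma`` and ``blood_cells``)."""
    text = resources.files("htpbk.data").joinpath("tissue_composition.csv").read_text()
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    header = lines[0].split(",")
    out: dict[str, dict[str, float]] = {}
    for line in lines[1:]:
        cells = line.split(",")
        out[cells[0]] = {k: float(v) for k, v in zip(header[1:], cells[1:])}
    return out


def reference_human() -> Physiology:
    """The shipped healthy-adult-male reference physiology.

    Deterministic: every call returns an equal object.  Hepatocellularity is
    1.1e8 cells/g and liver density 1.05 g/ml exactly.
    """
    doc = json.loads(resources.files("htpbk.data").joinpath("reference_human.json").read_text())
    comp = load_tissue_composition()
    for organ in doc["organs"]:
        organ["composition"] = comp.get(organ["name"], comp["plasma"] if "blood" in organ["name"] else {})
    return Physiology.from_dict(doc)


def scale_physiology(
    phys: Physiology,
    sex: Optional[str] = None,
    age: Optional[float] = None,
    weight: Optional[float] = None,
    height: Optional[float] = None,
) -> Physiology:
    """Scale a reference physiology to a subject's demographics.

    Only body weight drives scaling: organ volumes scale linearly with
    weight, blood flows and GFR with weight^0.75 (standard allometry).  Sex,
    age and height are recorded in the demographics of the returned object
    but do not alter the anatomy (no alternative reference table is
    shipped); a note is logged when they are supplied.
    """
    if weight is not None and not weight > 0:
        raise ValueError(f"weight must be positive, got {weight}")
    if height is not None and not height > 0:
        raise ValueError(f"height must be positive, got {height}")

    demo = dict(phys.demographics)
    for key, val in (("sex", sex), ("age_y", age), ("height_cm", height)):
        if val is not None:
            demo[key] = val
    if (sex is not None or age is not None or height is not None):
        log.info("sex/age/height noted but not used for scaling (no alternative reference table)")

    if weight is None or weight == phys.body_weight:
        if weight is not None:
            demo["weight_kg"] = weight
        return Physiology(
            organs=copy.deepcopy(list(phys.organs)),
            gfr=phys.gfr,
            hepatocellularity=phys.hepatocellularity,
            liver_density=phys.liver_density,
            body_weight=phys.body_weight,
            demographics=demo,
            version=phys.version,
        )

    ratio = weight / phys.body_weight
    vol_scale = ratio
    flow_scale = math.pow(ratio, 0.75)
    demo["weight_kg"] = weight
    organs = [
        OrganSpec(
            name=o.name,
            volume=o.volume * vol_scale,
            blood_flow=o.blood_flow * flow_scale,
            composition=dict(o.composition),
            eliminating=o.eliminating,
        )
        for o in phys.organs
    ]
    return Physiology(
        organs=organs,
        gfr=phys.gfr * flow_scale,
        hepatocellularity=phys.hepatocellularity,
        liver_density=phys.liver_density,
        body_weight=weight,
        demographics=demo,
        version=phys.version,
    )
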