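"""Tissue:plasma partition coefficients (Kp) under five published method families.

Implemented methods
-------------------
``poulin_theil``
    Composition-based lipid/water partitioning normalised to plasma, with a
    tissue fraction-unbound correction derived from the tissue:plasma
    binding-protein ratio.
``berezhkovskiy``
    The same composition ratio with the tissue-binding correction dropped
    (fu_t taken equal to fu_p); the published variant's peripheral
    correction affects volume-of-distribution bookkeeping, not the
    concentration ratio used by a flow-limited model.
``rodgers_rowland``
    Ionisation-aware partitioning: intracellular/extracellular water at
    their own pH, neutral-lipid/phospholipid partitioning of the neutral
    species, acidic-phospholipid binding for ionised bases and
    binding-protein association for acids/neutrals.
``schmitt``
    Membrane-affinity based: phospholipid partitioning of the neutral and
    (attenuated) ionised species plus neutral-lipid partitioning.
``pksim``
    The published membrane-affinity form: aqueous fraction plus total lipid
    weighted by the membrane partition coefficient, scaled by plasma
    fraction unbound ("pksim_standard, published form").

Because both numerator and denominator of the composition-based methods
(Poulin & Theil, Berezhkovskiy) contain the lipid partition term, their Kp
values saturate as lipophilicity grows, whereas the membrane-affinity
methods grow without bound — the robustness difference at very high
lipophilicity that the evaluation step probes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .compound import ResolvedParameters
from .physiology import Physiology, load_tissue_composition

METHODS = ("pksim", "schmitt", "rodgers_rowland", "poulin_theil", "berezhkovskiy")

PH_PLASMA = 7.4
PH_INTRACELLULAR = 7.0
PH_BLOOD_CELLS = 7.22

#: attenuation of membrane affinity for ionised species (Schmitt-type term)
IONISED_MEMBRANE_FACTOR = 0.05

#: fraction of tissue water treated as extracellular in the ionisation-aware method
EXTRACELLULAR_WATER_FRACTION = 0.35


@dataclass(frozen=True)
class PartitionSet:
    method: str
    kp: Mapping[str, float]   # organ name -> tissue:plasma ratio

    def __post_init__(self) -> None:
        for organ, v in self.kp.items():
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"Kp for {organ!r} must be finite and > 0, got {v}")


def fraction_neutral(pka_set: Sequence[tuple[float, str]], ph: float) -> float:
    """Henderson–Hasselbalch neutral fraction at a given pH.

    Each ionisation term is 10^(pKa-pH) for a base and 10^(pH-pKa) for an
    acid; an empty pKa set means the compound is fully neutral.
    """
    total = 0.0
    for pka, kind in pka_set:
        if not math.isfinite(pka):
            raise ValueError(f"non-finite pKa {pka}")
        if kind == "base":
            total += 10.0 ** (pka - ph)
        elif kind == "acid":
            total += 10.0 ** (ph - pka)
        else:
            raise ValueError(f"pKa type must be acid|base, got {kind!r}")
    return 1.0 / (1.0 + total)


def _octanol_partition(params: ResolvedParameters) -> float:
    """10^lipophilicity used as the neutral-species lipid partition coefficient."""
    return 10.0 ** params.lipophilicity


def _membrane_partition(params: ResolvedParameters) -> float:
    """Membrane affinity coefficient; LogMA feeds it directly, other
    subtypes are used as-is (conversions happen upstream when the strategy
    requests them)."""
    return 10.0 ** params.lipophilicity


def _composition_term(P: float, comp: Mapping[str, float]) -> float:
    """P*(f_nl + 0.3 f_ph) + (f_w + 0.7 f_ph): lipid+water solvation capacity."""
    return (P * (comp["neutral_lipid"] + 0.3 * comp["phospholipid"])
            + comp["water"] + 0.7 * comp["phospholipid"])


def _poulin_theil_kp(P: float, fu: float, tissue: Mapping[str, float],
                     plasma: Mapping[str, float], tissue_binding: bool) -> float:
    num = _composition_term(P, tissue)
    den = _composition_term(P, plasma)
    kp = num / den
    if tissue_binding and fu < 1.0:
        # fu_t from the tissue:plasma binding-protein ratio; equal protein
        # content (plasma-like tissue) leaves Kp untouched
        pr = tissue["protein"] / plasma["protein"] if plasma["protein"] > 0 else 1.0
        fu_t = 1.0 / (1.0 + (1.0 - fu) / fu * pr)
        kp *= fu / fu_t
    return kp


def _rodgers_rowland_kp(params: ResolvedParameters, tissue: Mapping[str, float],
                        plasma: Mapping[str, float],
                        blood_cells: Mapping[str, float]) -> float:
    P = _octanol_partition(params)
    fu = params.fu
    fn_p = fraction_neutral(params.pka, PH_PLASMA)
    fn_iw = fraction_neutral(params.pka, PH_INTRACELLULAR)

    f_iw = tissue["water"] * (1.0 - EXTRACELLULAR_WATER_FRACTION)
    f_ew = tissue["water"] * EXTRACELLULAR_WATER_FRACTION

    # partitioning of the neutral species into neutral lipid + phospholipid
    lipid_term = (P * tissue["neutral_lipid"]
                  + (0.3 * P + 0.7) * tissue["phospholipid"]) * fn_p

    kpu = f_ew + (fn_p / fn_iw) * f_iw + lipid_term

    is_ionised_base = any(kind == "base" and pka > PH_PLASMA for pka, kind in params.pka)
    if is_ionised_base:
        ka_ap = _acidic_phospholipid_association(params, P, blood_cells)
        base_pka = max(pka for pka, kind in params.pka if kind == "base")
        kpu += ka_ap * tissue["acidic_phospholipid"] * (10.0 ** (base_pka - PH_INTRACELLULAR)) * fn_p
    else:
        # acids & neutrals associate with tissue binding proteins, scaled
        # from the plasma binding the fu value implies
        plasma_lipid = (P * plasma["neutral_lipid"]
                        + (0.3 * P + 0.7) * plasma["phospholipid"]) * fn_p
        ka_pr = max(0.0, (1.0 / fu - 1.0 - plasma_lipid)) / plasma["protein"]
        kpu += ka_pr * tissue["protein"] * 0.5   # half the plasma binding-protein avidity

    return max(kpu * fu, 1e-9)


def _acidic_phospholipid_association(params: ResolvedParameters, P: float,
                                     blood_cells: Mapping[str, float]) -> float:
    """Association constant to acidic phospholipids back-calculated from a
    blood-cell partition consistent with a blood:plasma ratio of 1."""
    fu = params.fu
    base_pka = max(pka for pka, kind in params.pka if kind == "base")
    fn_p = fraction_neutral(params.pka, PH_PLASMA)
    fn_bc = fraction_neutral(params.pka, PH_BLOOD_CELLS)
    hematocrit = 0.45
    # B:P = 1 with the hematocrit split gives a unit blood-cell:plasma ratio
    kpu_bc = 1.0 / fu
    water_term = (fn_p / fn_bc) * blood_cells["water"]
    lipid_term = (P * blood_cells["neutral_lipid"]
                  + (0.3 * P + 0.7) * blood_cells["phospholipid"]) * fn_p
    residual = kpu_bc - water_term - lipid_term
    denom = blood_cells["acidic_phospholipid"] * (10.0 ** (base_pka - PH_BLOOD_CELLS)) * fn_p
    if denom <= 0:
        return 0.0
    return max(residual, 0.0) / denom


def _schmitt_kp(params: ResolvedParameters, tissue: Mapping[str, float]) -> float:
    K_ma = _membrane_partition(params)
    fn = fraction_neutral(params.pka, PH_PLASMA)
    k_ph = fn * K_ma + (1.0 - fn) * IONISED_MEMBRANE_FACTOR * K_ma
    k_nl = fn * K_ma
    kpu = (tissue["water"]
           + k_ph * tissue["phospholipid"]
           + k_nl * tissue["neutral_lipid"]
           + 0.163 * tissue["protein"])
    return max(kpu * params.fu, 1e-9)


def _pksim_kp(params: ResolvedParameters, tissue: Mapping[str, float]) -> float:
    K = _membrane_partition(params)
    fn = fraction_neutral(params.pka, PH_PLASMA)
    k_eff = K * (fn + (1.0 - fn) * IONISED_MEMBRANE_FACTOR)
    kpu = tissue["water"] + k_eff * (tissue["neutral_lipid"] + tissue["phospholipid"])
    return max(kpu * params.fu, 1e-9)


def compute_partition_set(
    method: str,
    params: ResolvedParameters,
    phys: Physiology,
    composition: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> PartitionSet:
    """Kp for every perfused organ under the requested method.

    ``composition`` defaults to the shipped tissue-composition table; organ
    compositions attached to the physiology take precedence when present.
    """
    if method not in METHODS:
        raise ValueError(f"unknown partitioning method {method!r}; choose from {METHODS}")
    if not math.isfinite(params.lipophilicity):
        raise ValueError("lipophilicity required for partitioning")
    if not (0.0 < params.fu <= 1.0):
        raise ValueError(f"fu must lie in (0,1] for partitioning, got {params.fu}")

    table = dict(composition) if composition is not None else load_tissue_composition()
    plasma = table["plasma"]
    blood_cells = table.get("blood_cells", plasma)

    kp: dict[str, float] = {}
    for organ in phys.perfused_organs:
        comp = dict(organ.composition) if organ.composition else table.get(organ.name)
        if comp is None:
            raise ValueError(f"no composition available for organ {organ.name!r}")
        if method == "poulin_theil":
            P = _octanol_partition(params)
            fn = fraction_neutral(params.pka, PH_PLASMA)
            # only the neutral species partitions into lipid
            P_eff = P * fn + (1.0 - fn) * 0.0 + 1e-12
            value = _poulin_theil_kp(P_eff, params.fu, comp, plasma, tissue_binding=True)
        elif method == "berezhkovskiy":
            P = _octanol_partition(params)
            fn = fraction_neutral(params.pka, PH_PLASMA)
            P_eff = P * fn + 1e-12
            value = _poulin_theil_kp(P_eff, params.fu, comp, plasma, tissue_binding=False)
        elif method == "rodgers_rowland":
            value = _rodgers_rowland_kp(params, comp, plasma, blood_cells)
        elif method == "schmitt":
            value = _schmitt_kp(params, comp)
        else:  # pksim
            value = _pksim_kp(params, comp)
        kp[organ.name] = max(value, 1e-9)
    return PartitionSet(method=method, kp=kp)


def export_composition_csv(path) -> None:
    """Dump the composition table used for partitioning (inspection aid)."""
    table = load_tissue_composition()
    keys = ["water", "neutral_lipid", "phospholipid", "protein", "acidic_phospholipid"]
    with open(path, "w") as fh:
        fh.write("tissue," + ",".join(keys) + "\n")
        for tissue, comp in table.items():
            fh.write(tissue + "," + ",".join(str(comp[k]) for k in keys) + "\n")
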