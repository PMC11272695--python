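"""Source-tagged compound properties and strategy resolution.

A compound carries a bag of :class:`PropertyRecord` values, each tagged with
the property it describes (lipophilicity, pKa, fu, solubility, clearance,
permeability), a subtype (e.g. LogP vs LogD vs LogMA) and the source that
produced it (a prediction tool, "measured", "in_vivo", or "truth" for
synthetic data).  A :class:`ParameterisationStrategy` names one source per
parameter slot; :func:`resolve_inputs` turns compound + strategy into the
concrete numbers a simulation needs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import pandas as pd

log = logging.getLogger(__name__)

PROPERTIES = ("lipophilicity", "pKa", "fu", "solubility", "clearance", "permeability")
PARTITION_METHODS = ("pksim", "schmitt", "rodgers_rowland", "poulin_theil", "berezhkovskiy")


@dataclass(frozen=True)
class PropertyRecord:
    """One value for one property of one compound from one source."""

    property: str      # one of PROPERTIES
    subtype: str       # e.g. LogP/LogD/LogMA, acid/base, aqueous/FaSSIF, plasma_CL/hepatocyte_CLint, CACO2/MDCK
    value: float
    source: str
    unit: str = ""     # canonical units implied when empty

    def __post_init__(self) -> None:
        if self.property not in PROPERTIES:
            raise ValueError(f"unknown property {self.property!r}")
        if self.property == "fu" and not 0.0 <= self.value <= 1.0:
            raise ValueError(f"fu must lie in [0,1], got {self.value}")
        if self.property in ("solubility", "clearance", "permeability") and self.value < 0:
            raise ValueError(f"{self.property} must be >= 0, got {self.value}")


@dataclass(frozen=True)
class CompoundProperties:
    compound_id: str
    mw: float          # g/mol
    records: tuple[PropertyRecord, ...] = ()

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise ValueError(f"{self.compound_id}: MW must be positive")
        if self.mw >= 900:
            warnings.warn(
                f"{self.compound_id}: MW {self.mw} outside the modelled chemical space (< 900 Da)"
            )

    def select(self, prop: str, subtype: Optional[str] = None,
               source: Optional[str] = None) -> list[PropertyRecord]:
        out = []
        for r in self.records:
            if r.property != prop:
                continue
            if subtype is not None and r.subtype != subtype:
                continue
            if source is not None and r.source != source:
                continue
            out.append(r)
        return out


@dataclass(frozen=True)
class LipophilicityConversion:
    input_subtype: str
    slope: float
    intercept: float
    citation: str = ""


@dataclass(frozen=True)
class PropertySelector:
    """Names the (source, subtype) pair a strategy slot reads from."""

    source: str
    subtype: Optional[str] = None


@dataclass(frozen=True)
class ParameterisationStrategy:
    """One complete choice of input source/method per parameter slot."""

    label: str
    lipophilicity_sources: tuple[PropertySelector, ...]
    consensus: bool = False
    conversion: Optional[str] = None          # key into the conversion config
    pka_source: Optional[str] = None          # None => treat compounds as neutral
    partitioning_method: str = "pksim"
    fu_source: str = "measured"
    clearance_source: str = "in_vivo"
    clearance_mode: str = "plasma"            # plasma | intrinsic
    renal_passive: bool = False
    solubility_source: Optional[PropertySelector] = None
    permeability_source: Optional[PropertySelector] = None
    permeability_scaling: str = "direct"      # direct | scaled | engine_equation
    permeability_scaling_factor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.partitioning_method not in PARTITION_METHODS:
            raise ValueError(f"unknown partitioning method {self.partitioning_method!r}")
        if self.clearance_mode not in ("plasma", "intrinsic"):
            raise ValueError(f"clearance_mode must be plasma|intrinsic, got {self.clearance_mode!r}")
        if self.permeability_scaling not in ("direct", "scaled", "engine_equation"):
            raise ValueError(f"unknown permeability scaling {self.permeability_scaling!r}")
        if not self.lipophilicity_sources:
            raise ValueError("at least one lipophilicity source required")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "lipophilicity": {
                "sources": [{"source": s.source, "subtype": s.subtype}
                            for s in self.lipophilicity_sources],
                "consensus": self.consensus,
                "conversion": self.conversion,
            },
            "pka_source": self.pka_source,
            "partitioning_method": self.partitioning_method,
            "fu_source": self.fu_source,
            "clearance": {"source": self.clearance_source, "mode": self.clearance_mode},
            "renal_passive": self.renal_passive,
            "solubility": (
                {"source": self.solubility_source.source, "subtype": self.solubility_source.subtype}
                if self.solubility_source else None
            ),
            "permeability": (
                {
                    "source": self.permeability_source.source,
                    "subtype": self.permeability_source.subtype,
                    "scaling": self.permeability_scaling,
                    "scaling_factor": self.permeability_scaling_factor,
                }
                if self.permeability_source else None
            ),
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ParameterisationStrategy":
        lip = doc["lipophilicity"]
        sol = doc.get("solubility")
        perm = doc.get("permeability")
        return cls(
            label=doc["label"],
            lipophilicity_sources=tuple(
                PropertySelector(s["source"], s.get("subtype")) for s in lip["sources"]
            ),
            consensus=lip.get("consensus", len(lip["sources"]) > 1),
            conversion=lip.get("conversion"),
            pka_source=doc.get("pka_source"),
            partitioning_method=doc.get("partitioning_method", "pksim"),
            fu_source=doc.get("fu_source", "measured"),
            clearance_source=doc.get("clearance", {}).get("source", "in_vivo"),
            clearance_mode=doc.get("clearance", {}).get("mode", "plasma"),
            renal_passive=doc.get("renal_passive", False),
            solubility_source=PropertySelector(sol["source"], sol.get("subtype")) if sol else None,
            permeability_source=PropertySelector(perm["source"], perm.get("subtype")) if perm else None,
            permeability_scaling=perm.get("scaling", "direct") if perm else "direct",
            permeability_scaling_factor=perm.get("scaling_factor") if perm else None,
        )

    @classmethod
    def from_json_file(cls, path) -> "ParameterisationStrategy":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def load_named_strategy(name: str) -> ParameterisationStrategy:
    """Load one of the shipped strategy configs (e.g. ``best_overall``)."""
    text = resources.files("htpbk.data.strategies").joinpath(f"{name}.json").read_text()
    return ParameterisationStrategy.from_dict(json.loads(text))


@dataclass(frozen=True)
class ResolvedParameters:
    """Concrete per-compound parameter set after applying a strategy."""

    compound_id: str
    mw: float
    lipophilicity: float
    lipophilicity_subtype: str
    pka: tuple[tuple[float, str], ...]        # (value, "acid"|"base")
    fu: float
    clearance_value: float
    clearance_mode: str                        # plasma | intrinsic
    clearance_unit: str = "L/h"                # L/h | L/h/kg | ul/min/1e6cells
    solubility: Optional[float] = None         # mg/L
    permeability: Optional[float] = None       # cm/min; None when engine equation pending
    permeability_pending_engine: bool = False


class MissingSlotError(KeyError):
    """A strategy names a (property, source) pair the compound does not have."""


def load_conversions(path=None) -> dict[str, LipophilicityConversion]:
    if path is None:
        text = resources.files("htpbk.data").joinpath("lipophilicity_conversions.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = json.loads(text)
    return {
        name: LipophilicityConversion(
            input_subtype=c["input_subtype"], slope=c["slope"],
            intercept=c["intercept"], citation=c.get("citation", ""),
        )
        for name, c in doc["conversions"].items()
    }


def consensus_value(records: Sequence[PropertyRecord]) -> float:
    """Arithmetic mean of same-subtype records from several sources."""
    if not records:
        raise ValueError("consensus_value needs at least one record")
    props = {r.property for r in records}
    if len(props) != 1:
        raise ValueError(f"mixed properties in consensus: {sorted(props)}")
    return sum(r.value for r in records) / len(records)


def convert_lipophilicity(value: float, subtype: str, conv: LipophilicityConversion) -> float:
    """Map a LogP/LogD value onto the membrane-affinity (LogMA) scale."""
    if subtype != conv.input_subtype:
        raise ValueError(
            f"conversion expects subtype {conv.input_subtype!r}, got {subtype!r}"
        )
    return conv.slope * value + conv.intercept


def load_property_table(table, mw_lookup: Optional[Mapping[str, float]] = None
                        ) -> dict[str, CompoundProperties]:
    """Read a compound-property table into ``{compound_id: CompoundProperties}``.

    ``table`` may be a path (CSV or XLSX) or a DataFrame with columns
    ``compound_id, property, subtype, value, source, MW`` (``unit`` optional).
    Duplicate (compound, property, subtype, source) rows are averaged with a
    warning.  Malformed rows are reported with their row numbers.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        path = str(table)
        if path.endswith((".xlsx", ".xls")):
            df = pd.read_excel(path)
        else:
            df = pd.read_csv(path)

    mandatory = ["compound_id", "property", "subtype", "value", "source", "MW"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"property table missing mandatory columns: {missing}")
    if df.empty:
        return {}

    bad_rows: list[str] = []
    df = df.copy()
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["MW"] = pd.to_numeric(df["MW"], errors="coerce")
    for idx in df.index[df["value"].isna() | df["MW"].isna()]:
        bad_rows.append(f"row {idx}: non-numeric value or MW")
    if bad_rows:
        raise ValueError("malformed property rows: " + "; ".join(bad_rows))

    dup_keys = ["compound_id", "property", "subtype", "source"]
    n_before = len(df)
    grouped = df.groupby(dup_keys, as_index=False).agg(
        value=("value", "mean"), MW=("MW", "first"),
        unit=("unit", "first") if "unit" in df.columns else ("value", "size"),
    )
    if "unit" not in df.columns:
        grouped["unit"] = ""
    grouped["unit"] = grouped["unit"].fillna("")
    if len(grouped) < n_before:
        warnings.warn(f"averaged {n_before - len(grouped)} duplicate property rows")

    out: dict[str, CompoundProperties] = {}
    for cid, sub in grouped.groupby("compound_id"):
        mw = float(sub["MW"].iloc[0])
        if mw_lookup and cid in mw_lookup:
            mw = float(mw_lookup[cid])
        records = []
        for _, row in sub.iterrows():
            value, unit = _normalise_units(
                row["property"], row["subtype"], float(row["value"]), str(row["unit"]), mw
            )
            records.append(PropertyRecord(
                property=row["property"], subtype=row["subtype"],
                value=value, source=row["source"], unit=unit,
            ))
        out[str(cid)] = CompoundProperties(compound_id=str(cid), mw=mw, records=tuple(records))
    return out


def _normalise_units(prop: str, subtype: str, value: float, unit: str, mw: float
                     ) -> tuple[float, str]:
    """Convert declared alternative units onto the canonical scale."""
    unit = unit.strip()
    if prop == "solubility":
        if unit in ("", "mg/L"):
            return value, ""
        if unit == "g/L":
            return value * 1000.0, ""
        if unit == "mol/L":
            return value * mw * 1000.0, ""
        if unit == "umol/L":
            return value * mw / 1000.0, ""
        raise ValueError(f"unknown solubility unit {unit!r}")
    if prop == "clearance":
        if unit in ("", "L/h", "ul/min/1e6cells"):
            return value, unit
        if unit == "L/h/kg":
            return value, unit
        if unit == "ml/min":
            return value * 60.0 / 1000.0, "L/h"
        raise ValueError(f"unknown clearance unit {unit!r}")
    if prop == "permeability":
        if unit in ("", "cm/min"):
            return value, ""
        if unit == "cm/s":
            return value * 60.0, ""
        if unit == "1e-6cm/s":
            return value * 1e-6 * 60.0, ""
        raise ValueError(f"unknown permeability unit {unit!r}")
    return value, unit


def resolve_inputs(
    compound: CompoundProperties,
    strategy: ParameterisationStrategy,
    route: str,
    conversions: Optional[Mapping[str, LipophilicityConversion]] = None,
) -> ResolvedParameters:
    """Resolve a strategy into one concrete parameter set for a compound.

    Deterministic and independent of record ordering.  Raises
    :class:`MissingSlotError` naming the compound and slot when a required
    record is absent, including solubility/permeability for the PO route.
    """
    oral = route == "oral" or route.lower() == "po"

    # lipophilicity: gather, optionally convert, optionally average
    lip_values: list[float] = []
    lip_subtypes: list[str] = []
    for sel in strategy.lipophilicity_sources:
        recs = compound.select("lipophilicity", subtype=sel.subtype, source=sel.source)
        if not recs:
            raise MissingSlotError(
                f"{compound.compound_id}: no lipophilicity record for source "
                f"{sel.source!r} subtype {sel.subtype!r}"
            )
        val = consensus_value(recs)
        subtype = recs[0].subtype
        if strategy.conversion:
            conv_table = conversions if conversions is not None else load_conversions()
            if strategy.conversion not in conv_table:
                raise KeyError(f"unknown lipophilicity conversion {strategy.conversion!r}")
            val = convert_lipophilicity(val, subtype, conv_table[strategy.conversion])
            subtype = "LogMA"
        lip_values.append(val)
        lip_subtypes.append(subtype)
    if len(lip_values) > 1 and not strategy.consensus:
        raise ValueError(
            f"strategy {strategy.label!r}: several lipophilicity sources without consensus flag"
        )
    lipophilicity = sum(lip_values) / len(lip_values)
    lip_subtype = lip_subtypes[0] if len(set(lip_subtypes)) == 1 else "mixed"

    # pKa: empty set when no source configured (all compounds treated neutral)
    pka: tuple[tuple[float, str], ...] = ()
    if strategy.pka_source is not None:
        recs = compound.select("pKa", source=strategy.pka_source)
        pka = tuple(sorted((r.value, r.subtype) for r in recs))

    fu_recs = compound.select("fu", source=strategy.fu_source)
    if not fu_recs:
        raise MissingSlotError(
            f"{compound.compound_id}: no fu record for source {strategy.fu_source!r}"
        )
    fu = consensus_value(fu_recs)

    cl_subtype = "plasma_CL" if strategy.clearance_mode == "plasma" else "hepatocyte_CLint"
    cl_recs = compound.select("clearance", subtype=cl_subtype, source=strategy.clearance_source)
    if not cl_recs:
        raise MissingSlotError(
            f"{compound.compound_id}: no clearance record ({cl_subtype}) for source "
            f"{strategy.clearance_source!r}"
        )
    clearance_value = consensus_value(cl_recs)
    clearance_unit = cl_recs[0].unit or (
        "L/h" if strategy.clearance_mode == "plasma" else "ul/min/1e6cells"
    )

    solubility = None
    permeability = None
    pending = False
    if oral:
        if strategy.solubility_source is None or strategy.permeability_source is None:
            raise MissingSlotError(
                f"{compound.compound_id}: PO route requires solubility and permeability sources"
            )
        sol_sel = strategy.solubility_source
        sol_recs = compound.select("solubility", subtype=sol_sel.subtype, source=sol_sel.source)
        if not sol_recs:
            raise MissingSlotError(
                f"{compound.compound_id}: no solubility record for source {sol_sel.source!r}"
            )
        solubility = consensus_value(sol_recs)

        if strategy.permeability_scaling == "engine_equation":
            pending = True
        else:
            perm_sel = strategy.permeability_source
            perm_recs = compound.select("permeability", subtype=perm_sel.subtype,
                                        source=perm_sel.source)
            if not perm_recs:
                raise MissingSlotError(
                    f"{compound.compound_id}: no permeability record for source {perm_sel.source!r}"
                )
            permeability = consensus_value(perm_recs)
            if strategy.permeability_scaling == "scaled":
                if strategy.permeability_scaling_factor is None:
                    raise ValueError(
                        f"strategy {strategy.label!r}: scaled permeability needs a scaling factor"
                    )
                permeability = permeability * strategy.permeability_scaling_factor

    return ResolvedParameters(
        compound_id=compound.compound_id,
        mw=compound.mw,
        lipophilicity=lipophilicity,
        lipophilicity_subtype=lip_subtype,
        pka=pka,
        fu=fu,
        clearance_value=clearance_value,
        clearance_mode=strategy.clearance_mode,
        clearance_unit=clearance_unit,
        solubility=solubility,
        permeability=permeability,
        permeability_pending_engine=pending,
    )
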