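"""Readers/writers for study and property tables, result export and run
manifests.

The canonical study table is long-format (one row per observed timepoint)
with columns ``study_id, compound_id, route, dose_mg, infusion_duration_h,
formulation, dissolution_time80_min, sex, age_y, weight_kg, height_cm,
time_h, conc_mg_per_L``.  A :class:`ColumnMap` renames differently labelled
columns (e.g. a supplementary workbook's layout) onto that schema and may
declare alternative units which are converted on load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .engine import ConcentrationTimeProfile, DosingEvent
from .evaluation import StrategyResult, StudyRecord

CANONICAL_STUDY_COLUMNS = (
    "study_id", "compound_id", "route", "dose_mg", "infusion_duration_h",
    "formulation", "dissolution_time80_min", "sex", "age_y", "weight_kg",
    "height_cm", "time_h", "conc_mg_per_L",
)
MANDATORY_STUDY_COLUMNS = ("study_id", "compound_id", "route", "dose_mg",
                           "time_h", "conc_mg_per_L")

_ROUTE_ALIASES = {
    "iv": "iv", "intravenous": "iv", "i.v.": "iv", "iv_bolus": "iv",
    "iv_infusion": "iv_infusion", "infusion": "iv_infusion",
    "po": "oral", "oral": "oral", "p.o.": "oral",
}
_FORMULATION_ALIASES = {
    "solution": "solution", "sol": "solution",
    "suspension": "suspension", "susp": "suspension",
    "capsule": "capsule", "cap": "capsule",
    "tablet": "tablet", "tab": "tablet",
}


@dataclass(frozen=True)
class ColumnMap:
    """Canonical field -> source column names, plus unit declarations."""

    columns: Mapping[str, str] = field(default_factory=dict)
    units: Mapping[str, str] = field(default_factory=dict)   # {"conc": "nmol/L", "time": "min"}
    sheet: Optional[str] = None

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        rename = {src: canon for canon, src in self.columns.items() if src in df.columns}
        return df.rename(columns=rename)


def _convert_conc(values: pd.Series, unit: str, mw: Optional[pd.Series]) -> pd.Series:
    unit = (unit or "mg/L").strip()
    if unit == "mg/L":
        return values
    if unit in ("ug/L", "ng/mL"):
        return values / 1000.0
    if unit == "ug/mL":
        return values
    if unit in ("umol/L", "nmol/L"):
        if mw is None:
            raise ValueError(f"concentration unit {unit!r} requires molecular weights")
        factor = 1e-3 if unit == "umol/L" else 1e-6
        return values * mw * factor
    raise ValueError(f"unknown concentration unit {unit!r}")


def load_study_table(
    path,
    colmap: Optional[ColumnMap] = None,
    mw_lookup: Optional[Mapping[str, float]] = None,
) -> list[StudyRecord]:
    """Load a study table (CSV/XLSX/DataFrame) into validated StudyRecords.

    Raises with row-level diagnostics on unmapped mandatory columns,
    non-numeric values, non-increasing times or non-positive doses.
    """
    colmap = colmap or ColumnMap()
    if isinstance(path, pd.DataFrame):
        df = path.copy()
    else:
        p = str(path)
        if p.endswith((".xlsx", ".xls")):
            df = pd.read_excel(p, sheet_name=colmap.sheet or 0)
        else:
            df = pd.read_csv(p)
    df = colmap.apply(df)

    missing = [c for c in MANDATORY_STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"study table missing mandatory columns: {missing}")

    time_unit = colmap.units.get("time", "h")
    if time_unit == "min":
        df["time_h"] = pd.to_numeric(df["time_h"], errors="coerce") / 60.0
    elif time_unit != "h":
        raise ValueError(f"unknown time unit {time_unit!r}")

    df["time_h"] = pd.to_numeric(df["time_h"], errors="coerce")
    df["conc_mg_per_L"] = pd.to_numeric(df["conc_mg_per_L"], errors="coerce")
    df["dose_mg"] = pd.to_numeric(df["dose_mg"], errors="coerce")
    bad = df.index[df[["time_h", "conc_mg_per_L", "dose_mg"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"non-numeric time/conc/dose at rows {list(bad[:10])}")

    conc_unit = colmap.units.get("conc", "mg/L")
    mw_series = None
    if conc_unit in ("umol/L", "nmol/L"):
        if "MW" in df.columns:
            mw_series = pd.to_numeric(df["MW"], errors="coerce")
        elif mw_lookup:
            mw_series = df["compound_id"].map(mw_lookup)
        if mw_series is None or mw_series.isna().any():
            raise ValueError(f"unit {conc_unit!r} needs MW per compound (column or lookup)")
    df["conc_mg_per_L"] = _convert_conc(df["conc_mg_per_L"], conc_unit, mw_series)

    records: list[StudyRecord] = []
    errors: list[str] = []
    for sid, grp in df.groupby("study_id", sort=True):
        grp = grp.reset_index()
        first = grp.iloc[0]
        route_raw = str(first["route"]).strip().lower()
        if route_raw not in _ROUTE_ALIASES:
            errors.append(f"study {sid}: unknown route {route_raw!r}")
            continue
        route = _ROUTE_ALIASES[route_raw]
        dose = float(first["dose_mg"])
        if not dose > 0:
            errors.append(f"study {sid}: non-positive dose {dose} (row {first['index']})")
            continue

        infusion = 0.0
        if "infusion_duration_h" in grp.columns:
            val = pd.to_numeric(first.get("infusion_duration_h"), errors="coerce")
            infusion = 0.0 if pd.isna(val) else float(val)
        if route == "iv":
            route_final = "iv_infusion" if infusion > 0 else "iv_bolus"
        elif route == "iv_infusion":
            route_final = "iv_infusion"
            if infusion <= 0:
                errors.append(f"study {sid}: infusion route without a positive duration")
                continue
        else:
            route_final = "oral"

        formulation = None
        t80 = None
        if route_final == "oral":
            raw = str(first.get("formulation", "") or "").strip().lower()
            formulation = _FORMULATION_ALIASES.get(raw, "solution" if not raw else None)
            if formulation is None:
                errors.append(f"study {sid}: unknown formulation {raw!r}")
                continue
            if "dissolution_time80_min" in grp.columns:
                val = pd.to_numeric(first.get("dissolution_time80_min"), errors="coerce")
                t80 = None if pd.isna(val) else float(val)

        times = grp["time_h"].to_numpy()
        if len(times) > 1 and not (pd.Series(times).diff().dropna() > 0).all():
            bad_row = int(grp["index"][pd.Series(times).diff().fillna(1.0) <= 0].iloc[0])
            errors.append(f"study {sid}: non-increasing times (row {bad_row})")
            continue

        demo = {}
        for canon, key in (("sex", "sex"), ("age_y", "age"),
                           ("weight_kg", "weight"), ("height_cm", "height")):
            if canon in grp.columns:
                val = first[canon]
                if pd.notna(val) and val != "":
                    demo[key] = val if key == "sex" else float(val)

        try:
            dosing = DosingEvent(route=route_final, dose=dose,
                                 infusion_duration=infusion if route_final == "iv_infusion" else 0.0,
                                 formulation=formulation, dissolution_time80=t80)
            obs = ConcentrationTimeProfile(
                times=tuple(float(t) for t in times),
                concentrations=tuple(max(float(c), 0.0) for c in grp["conc_mg_per_L"]),
                compound_id=str(first["compound_id"]), study_id=str(sid),
            )
            records.append(StudyRecord(study_id=str(sid), compound_id=str(first["compound_id"]),
                                       dosing=dosing, observations=obs, demographics=demo))
        except ValueError as exc:
            errors.append(f"study {sid}: {exc}")

    if errors:
        raise ValueError("study table diagnostics:\n  " + "\n  ".join(errors))
    return records


def studies_to_frame(studies: Sequence[StudyRecord]) -> pd.DataFrame:
    rows = []
    for s in studies:
        for t, c in zip(s.observations.times, s.observations.concentrations):
            rows.append({
                "study_id": s.study_id, "compound_id": s.compound_id,
                "route": s.dosing.route, "dose_mg": s.dosing.dose,
                "infusion_duration_h": s.dosing.infusion_duration,
                "formulation": s.dosing.formulation or "",
                "dissolution_time80_min": s.dosing.dissolution_time80,
                "sex": s.demographics.get("sex", ""),
                "age_y": s.demographics.get("age", ""),
                "weight_kg": s.demographics.get("weight", ""),
                "height_cm": s.demographics.get("height", ""),
                "time_h": t, "conc_mg_per_L": c,
            })
    return pd.DataFrame(rows, columns=list(CANONICAL_STUDY_COLUMNS))


def write_study_table(studies: Sequence[StudyRecord], path) -> None:
    studies_to_frame(studies).to_csv(path, index=False, float_format="%.12g")


def profile_to_frame(profiles: Sequence[ConcentrationTimeProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for t, c in zip(p.times, p.concentrations):
            rows.append({"study_id": p.study_id, "compound_id": p.compound_id,
                         "time_h": t, "conc_mg_per_L": c})
    return pd.DataFrame(rows)


def config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_results(
    results: Sequence[StrategyResult],
    out_dir,
    seed: Optional[int] = None,
    extra_manifest: Optional[Mapping] = None,
) -> dict[str, str]:
    """Write per-study, per-compound and per-strategy CSVs plus a JSON run
    manifest (seed, package version, config hash)."""
    if not results:
        raise ValueError("write_results needs at least one StrategyResult")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    study_rows, compound_rows, strategy_rows = [], [], []
    for res in results:
        for comp in res.compounds:
            for st in comp.studies:
                study_rows.append({
                    "strategy": res.label, "compound_id": comp.compound_id,
                    "study_id": st.study_id,
                    "relative_log2": st.errors.relative_log2,
                    "absolute_log2": st.errors.absolute_log2,
                    "n_points": st.errors.n_points,
                    "n_excluded": st.errors.n_excluded,
                    "cmax_pred": st.predicted.cmax, "cmax_obs": st.observed.cmax,
                    "tmax_pred": st.predicted.tmax, "tmax_obs": st.observed.tmax,
                    "auc_pred": st.predicted.auc_0_last, "auc_obs": st.observed.auc_0_last,
                })
            compound_rows.append({
                "strategy": res.label, "compound_id": comp.compound_id,
                "n_studies": len(comp.studies),
                "median_absolute_log2": comp.median_absolute_log2,
                "median_relative_log2": comp.median_relative_log2,
                "median_log2_cmax": comp.median_log2_cmax,
                "median_log2_tmax": comp.median_log2_tmax,
                "median_log2_auc": comp.median_log2_auc,
            })
        row = {
            "strategy": res.label, "route": res.route,
            "n_compounds": len(res.compounds), "n_failures": len(res.failures),
            "median_absolute_log2": res.median_absolute_log2,
            "median_relative_log2": res.median_relative_log2,
        }
        for k, v in res.fold_table_cmax.items():
            row[f"cmax_within_{k:g}fold_pct"] = v
        for k, v in res.fold_table_auc.items():
            row[f"auc_within_{k:g}fold_pct"] = v
        strategy_rows.append(row)

    paths = {}
    for name, rows in (("per_study", study_rows), ("per_compound", compound_rows),
                       ("strategies", strategy_rows)):
        path = out / f"{name}.csv"
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
        paths[name] = str(path)

    failures = [{"strategy": r.label, "study_id": sid, "reason": reason}
                for r in results for sid, reason in r.failures]
    if failures:
        fpath = out / "failures.csv"
        pd.DataFrame(failures).to_csv(fpath, index=False)
        paths["failures"] = str(fpath)

    try:
        from importlib.metadata import version
        pkg_version = version("htpbk")
    except Exception:   # pragma: no cover - not installed
        pkg_version = "unknown"
    manifest = {
        "seed": seed,
        "package_version": pkg_version,
        "n_strategies": len(results),
        "config_hash": config_hash([r.strategy.to_dict() for r in results]),
        "strategies": [r.strategy.to_dict() for r in results],
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    paths["manifest"] = str(mpath)
    return paths


def plot_overlay(studies: Sequence[StudyRecord], path, dose_normalised: bool = True):
    """Optional dose-normalised consistency plot of the source data."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for s in studies:
        conc = [c / s.dosing.dose if dose_normalised else c
                for c in s.observations.concentrations]
        ax.plot(s.observations.times, conc, marker="o", ms=3, lw=0.8, alpha=0.6,
                label=s.study_id)
    ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("conc / dose (1/L)" if dose_normalised else "conc (mg/L)")
    if len(studies) <= 12:
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
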