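"""Panel-level reporting: selectivity arithmetic, activity-unit
calibration and rendered summary tables.

The rendered tables mirror the conventions of kinetic panel reports:
IC50 cells carry "mean ± SD" or ">10"; k_app cells carry "value ± SD"
with a Rev./Irrev. suffix; "*" marks series where a rate constant
cannot be determined by curve fitting; "N.D." marks entries that were
never measured. Numeric cells are rendered to two significant figures;
a machine-readable JSON twin keeps full precision.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .kinetics import MECHANISM_IRREVERSIBLE, MECHANISM_REVERSIBLE, RateProfile

_ENZYME_ORDER = ["trypsin3", "beta_tryptase", "thrombin", "upa", "catg", "chymotrypsin", "ne"]


def _data_path(name: str):
    return resources.files("slowbind.data").joinpath(name)


def load_published_kapp() -> pd.DataFrame:
    """Published k_app panel (M⁻¹ s⁻¹) with mechanism labels."""
    return pd.read_csv(_data_path("kapp_panel.csv"))


def load_published_equilibrium() -> pd.DataFrame:
    """Published apparent K1 / KI* panel (μM) for the reversible probes."""
    return pd.read_csv(_data_path("equilibrium_panel.csv"))


def load_published_ic50() -> pd.DataFrame:
    """Published preincubation IC50 panel (μM) for the tagged probes."""
    return pd.read_csv(_data_path("ic50_panel.csv"))


def selectivity_fold(profile_target, profile_off) -> float:
    """k_app(target enzyme) / k_app(off-target enzyme) for one compound.

    Accepts :class:`RateProfile` objects or anything with ``compound_id``
    and ``k_app`` attributes. Undefined k_app on either side raises
    (report such cells as "N.D.").
    """
    if profile_target.compound_id != profile_off.compound_id:
        raise ConfigError(
            "selectivity folds compare one compound across enzymes; got "
            f"{profile_target.compound_id!r} vs {profile_off.compound_id!r}"
        )
    kt, ko = profile_target.k_app, profile_off.k_app
    if not (isinstance(kt, (int, float)) and math.isfinite(kt) and kt > 0):
        raise ConfigError("target k_app is undefined; fold not computable (N.D.)")
    if not (isinstance(ko, (int, float)) and math.isfinite(ko) and ko > 0):
        raise ConfigError("off-target k_app is undefined; fold not computable (N.D.)")
    return kt / ko


def selectivity_lower_bound(profile_target, detection_limit: float) -> float:
    """Lower bound ">X" on the fold when the off-target rate is below the
    assay's smallest estimable k_app."""
    if detection_limit <= 0:
        raise ConfigError("detection_limit must be > 0")
    return profile_target.k_app / detection_limit


def activity_units(rate_signal: float, calibration_slope: float) -> float:
    """Convert a signal rate (AU/min) into enzyme activity in U/L.

    ``calibration_slope`` is AU per μM of product from a standard curve;
    (AU/min) / (AU/μM) = μM/min = μmol·L⁻¹·min⁻¹ ≡ U/L with
    1 U = 1 μmol/min.
    """
    if calibration_slope <= 0:
        raise ConfigError("calibration slope must be > 0")
    return rate_signal / calibration_slope


def fit_standard_curve(concentrations, signals) -> tuple[float, float]:
    """Linear standard curve (e.g. AMC): returns (slope AU/μM, intercept AU)."""
    res = stats.linregress(np.asarray(concentrations, float), np.asarray(signals, float))
    return float(res.slope), float(res.intercept)


@dataclass
class PanelEntry:
    """One compound-enzyme cell of the panel."""

    ic50: float = math.nan           # μM (mean)
    ic50_sd: float = math.nan
    ic50_censor: str = "value"       # value | gt10 | nd
    k_app: float = math.nan          # M⁻¹ s⁻¹
    k_app_sd: float = math.nan
    mechanism: str = ""              # irreversible | reversible_slow_binding | ""
    curve_fit_impossible: bool = False
    K1: float = math.nan             # μM
    KIstar: float = math.nan         # μM


@dataclass
class PanelRecord:
    compound_id: str
    entries: dict[str, PanelEntry] = field(default_factory=dict)


def profile_to_entry(profile: RateProfile) -> PanelEntry:
    return PanelEntry(
        k_app=profile.k_app,
        k_app_sd=profile.k_app_se,
        mechanism=profile.mechanism,
        curve_fit_impossible=not math.isfinite(profile.k_app),
        K1=profile.K1_app,
        KIstar=profile.KIstar_app,
    )


def _sig2(x: float) -> str:
    return f"{x:.2g}"


def _mech_suffix(mechanism: str) -> str:
    return {MECHANISM_REVERSIBLE: "Rev.", MECHANISM_IRREVERSIBLE: "Irrev."}.get(mechanism, "")


def _ic50_cell(e: PanelEntry) -> str:
    if e.ic50_censor == "gt10":
        return ">10"
    if e.ic50_censor == "nd" or not math.isfinite(e.ic50):
        return "N.D."
    cell = _sig2(e.ic50)
    if math.isfinite(e.ic50_sd):
        cell += f" ± {_sig2(e.ic50_sd)}"
    return cell


def _kapp_cell(e: PanelEntry) -> str:
    if e.curve_fit_impossible:
        suffix = _mech_suffix(e.mechanism)
        return ("* " + suffix).strip()
    if not math.isfinite(e.k_app):
        return "N.D."
    cell = _sig2(e.k_app)
    if math.isfinite(e.k_app_sd):
        cell += f" ± {_sig2(e.k_app_sd)}"
    suffix = _mech_suffix(e.mechanism)
    return (cell + " " + suffix).strip() if suffix else cell


def render_panel(records: list[PanelRecord]) -> dict[str, str]:
    """Render the panel into delimited-text tables plus a JSON twin.

    Pure and deterministic: identical inputs give byte-identical output,
    with rows ordered by compound then enzyme. Returns a mapping of
    file name to file content; footnotes explain "*" and "N.D.".
    """
    if not records:
        raise ConfigError("render_panel needs at least one record")
    records = sorted(records, key=lambda r: r.compound_id)
    enzymes = sorted(
        {e for r in records for e in r.entries},
        key=lambda e: (_ENZYME_ORDER.index(e) if e in _ENZYME_ORDER else 99, e),
    )

    def table(cell_fn, title: str) -> str:
        lines = [title, "compound\t" + "\t".join(enzymes)]
        for r in records:
            cells = [
                cell_fn(r.entries[e]) if e in r.entries else "N.D." for e in enzymes
            ]
            lines.append(r.compound_id + "\t" + "\t".join(cells))
        lines.append("# * rate constant not determinable by curve fitting")
        lines.append("# N.D. not determined")
        return "\n".join(lines) + "\n"

    payload = {
        r.compound_id: {
            enzyme: {
                k: (None if isinstance(v, float) and not math.isfinite(v) else v)
                for k, v in vars(entry).items()
            }
            for enzyme, entry in sorted(r.entries.items())
        }
        for r in records
    }
    return {
        "ic50_panel.tsv": table(_ic50_cell, "# preincubation IC50 (uM), mean +/- SD"),
        "kapp_panel.tsv": table(_kapp_cell, "# k_app (M^-1 s^-1), mean +/- SD, Rev./Irrev."),
        "panel.json": json.dumps(payload, indent=2, sort_keys=True) + "\n",
    }


def write_panel(records: list[PanelRecord], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, content in render_panel(records).items():
        p = out_dir / name
        p.write_text(content)
        written.append(p)
    return written


def records_from_published() -> list[PanelRecord]:
    """Build PanelRecords from the bundled published panel tables."""
    kapp = load_published_kapp()
    ic50 = load_published_ic50()
    eq = load_published_equilibrium()
    records: dict[str, PanelRecord] = {}

    def rec(compound: str) -> PanelRecord:
        return records.setdefault(compound, PanelRecord(compound_id=str(compound)))

    for _, row in kapp.iterrows():
        entry = rec(row["compound"]).entries.setdefault(row["enzyme"], PanelEntry())
        entry.k_app = float(row["kapp"]) if pd.notna(row["kapp"]) else math.nan
        entry.k_app_sd = float(row["kapp_sd"]) if pd.notna(row["kapp_sd"]) else math.nan
        entry.mechanism = row["mechanism"] if pd.notna(row["mechanism"]) else ""
        entry.curve_fit_impossible = row["status"] == "curve_fit_impossible"
    for _, row in ic50.iterrows():
        entry = rec(row["compound"]).entries.setdefault(row["enzyme"], PanelEntry())
        entry.ic50 = float(row["ic50_uM"]) if pd.notna(row["ic50_uM"]) else math.nan
        entry.ic50_sd = float(row["ic50_sd"]) if pd.notna(row["ic50_sd"]) else math.nan
        entry.ic50_censor = row["censor"]
    for _, row in eq.iterrows():
        entry = rec(row["compound"]).entries.setdefault(row["enzyme"], PanelEntry())
        if pd.notna(row["K1_uM"]):
            entry.K1 = float(row["K1_uM"])
        if pd.notna(row["KIstar_uM"]):
            entry.KIstar = float(row["KIstar_uM"])
    return sorted(records.values(), key=lambda r: r.compound_id)
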