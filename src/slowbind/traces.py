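"""Delimited-text import/export of progress-curve traces.

Long format, one row per time point, mandatory header:

    curve_id,time_s,signal_au,inhibitor_uM,enzyme_uM,enzyme_id

Comma is the default delimiter; tab is accepted. Decimal point is '.'.
On import, ``enzyme_id`` is resolved against the bundled assay defaults
(or a user-supplied assay mapping) so downstream validity flags can use
Km/S0; unknown enzymes load with no assay attached.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .assays import DEFAULT_ASSAYS, EnzymeAssay
from .errors import ConfigError
from .simulate import ProgressCurve

COLUMNS = ["curve_id", "time_s", "signal_au", "inhibitor_uM", "enzyme_uM", "enzyme_id"]


def traces_to_frame(curves: list[ProgressCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        enzyme_id = c.assay.enzyme_id if c.assay is not None else ""
        rows.append(
            pd.DataFrame(
                {
                    "curve_id": c.curve_id,
                    "time_s": c.times,
                    "signal_au": c.signal,
                    "inhibitor_uM": c.inhibitor_conc,
                    "enzyme_uM": c.enzyme_conc,
                    "enzyme_id": enzyme_id,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_traces(curves: list[ProgressCurve], path: str | Path, sep: str = ",") -> None:
    if sep not in (",", "\t"):
        raise ConfigError("separator must be comma or tab")
    traces_to_frame(curves).to_csv(path, sep=sep, index=False)


def read_traces(
    path: str | Path,
    sep: str | None = None,
    assays: dict[str, EnzymeAssay] | None = None,
) -> list[ProgressCurve]:
    """Read traces; ``sep=None`` sniffs comma versus tab from the header."""
    path = Path(path)
    if sep is None:
        header = path.open().readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing required columns {sorted(missing)}")
    assays = assays if assays is not None else DEFAULT_ASSAYS
    curves = []
    for curve_id, grp in df.groupby("curve_id", sort=False):
        grp = grp.sort_values("time_s")
        enzyme_id = str(grp["enzyme_id"].iloc[0])
        curves.append(
            ProgressCurve(
                curve_id=str(curve_id),
                times=grp["time_s"].to_numpy(dtype=float),
                signal=grp["signal_au"].to_numpy(dtype=float),
                inhibitor_conc=float(grp["inhibitor_uM"].iloc[0]),
                enzyme_conc=float(grp["enzyme_uM"].iloc[0]),
                assay=assays.get(enzyme_id),
            )
        )
    return curves
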