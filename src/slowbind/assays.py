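"""Continuous protease assay conditions.

Each :class:`EnzymeAssay` describes one plate-reader assay: substrate
Michaelis constant ``Km`` and working concentration ``S0`` (both in μM,
run at S0 = Km for the bundled panel), turnover number ``kcat`` (s⁻¹),
detection mode (pNA absorbance or AMC fluorescence) and the linear
signal coefficient (AU per μM of released chromophore/fluorophore).

Units convention used throughout the package: concentrations in μM,
time in s, first-order rates in s⁻¹, association rates in μM⁻¹ s⁻¹.
Second-order rate constants are converted to M⁻¹ s⁻¹ only at reporting
boundaries.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import yaml

from .errors import ConfigError

DETECTION_MODES = ("absorbance_pNA", "fluorescence_AMC")

#: Reference enzyme concentration (μM) used to pick default kcat values:
#: 1 nM enzyme keeps pseudo-first-order conditions for sub-μM inhibitors.
REFERENCE_ENZYME_CONC = 1e-3

#: Default trace cadence: 30 min sampled every 10 s (plate-reader like).
DEFAULT_DURATION = 1800.0
DEFAULT_N_POINTS = 181


@dataclass(frozen=True)
class EnzymeAssay:
    """One continuous protease activity assay."""

    enzyme_id: str
    Km: float                      # substrate Michaelis constant, μM
    S0: float                      # substrate concentration, μM
    kcat: float                    # turnover number, s⁻¹
    detection: str = "fluorescence_AMC"
    signal_coeff: float = 1.0      # AU per μM product
    temperature_C: float = 37.0
    pH: float = 8.0

    def __post_init__(self) -> None:
        if not (self.Km > 0 and math.isfinite(self.Km)):
            raise ConfigError(f"{self.enzyme_id}: Km must be positive, got {self.Km}")
        if not (self.S0 > 0 and math.isfinite(self.S0)):
            raise ConfigError(f"{self.enzyme_id}: S0 must be positive, got {self.S0}")
        if not (self.kcat >= 0 and math.isfinite(self.kcat)):
            raise ConfigError(f"{self.enzyme_id}: kcat must be >= 0, got {self.kcat}")
        if self.signal_coeff <= 0:
            raise ConfigError(f"{self.enzyme_id}: signal_coeff must be > 0")
        if self.detection not in DETECTION_MODES:
            raise ConfigError(
                f"{self.enzyme_id}: unknown detection {self.detection!r}; "
                f"expected one of {DETECTION_MODES}"
            )

    @property
    def competition_factor(self) -> float:
        """Substrate competition factor 1 + S0/Km (2.0 when run at S0=Km)."""
        return 1.0 + self.S0 / self.Km

    def product_rate(self, enzyme_conc: float) -> float:
        """Uninhibited Michaelis–Menten product release rate (μM/s)."""
        return self.kcat * enzyme_conc * self.S0 / (self.Km + self.S0)

    def signal_rate(self, enzyme_conc: float) -> float:
        """Uninhibited signal slope (AU/s)."""
        return self.signal_coeff * self.product_rate(enzyme_conc)


def _default_kcat(S0: float) -> float:
    # ~5% substrate conversion over 30 min at the 1 nM reference enzyme
    # concentration and S0 = Km: kcat * E * T / (Km + S0) = 0.05.
    return 0.05 * 2.0 * S0 / (DEFAULT_DURATION * REFERENCE_ENZYME_CONC)


def _make_default(enzyme_id: str, Km: float, detection: str, pH: float) -> EnzymeAssay:
    coeff = 0.0105 if detection == "absorbance_pNA" else 1.0
    return EnzymeAssay(
        enzyme_id=enzyme_id,
        Km=Km,
        S0=Km,
        kcat=_default_kcat(Km),
        detection=detection,
        signal_coeff=coeff,
        pH=pH,
    )


#: Bundled panel conditions: substrate at its Km for each protease.
DEFAULT_ASSAYS: dict[str, EnzymeAssay] = {
    a.enzyme_id: a
    for a in (
        _make_default("trypsin3", 22.5, "fluorescence_AMC", 8.0),
        _make_default("beta_tryptase", 250.0, "fluorescence_AMC", 8.0),
        _make_default("thrombin", 15.0, "fluorescence_AMC", 8.3),
        _make_default("upa", 80.0, "absorbance_pNA", 8.1),
        _make_default("catg", 130.0, "fluorescence_AMC", 8.0),
        _make_default("chymotrypsin", 58.0, "fluorescence_AMC", 8.3),
        _make_default("ne", 500.0, "fluorescence_AMC", 8.0),
    )
}

_ASSAY_KEYS = {"Km", "S0", "kcat", "detection", "signal_coeff", "temperature_C", "pH"}


def default_noise_sd(
    assay: EnzymeAssay,
    enzyme_conc: float = REFERENCE_ENZYME_CONC,
    duration: float = DEFAULT_DURATION,
    fraction: float = 0.01,
) -> float:
    """Detection noise SD as a fraction of the uninhibited dynamic range.

    The default (1%) is the package's model of plate-reader noise relative
    to the signal swing of the uninhibited 30-min trace.
    """
    return fraction * assay.signal_rate(enzyme_conc) * duration


def load_assay_config(path: str | Path) -> dict[str, EnzymeAssay]:
    """Load assay definitions from a YAML key-value file.

    The file maps enzyme_id -> {Km, S0, kcat, detection, signal_coeff,
    temperature_C, pH}. Entries override the bundled defaults per enzyme;
    unknown keys are errors, not warnings.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return dict(DEFAULT_ASSAYS)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping of enzyme_id to settings")
    assays = dict(DEFAULT_ASSAYS)
    for enzyme_id, settings in raw.items():
        if not isinstance(settings, dict):
            raise ConfigError(f"{path}: entry {enzyme_id!r} must be a mapping")
        unknown = set(settings) - _ASSAY_KEYS
        if unknown:
            raise ConfigError(
                f"{path}: unknown keys {sorted(unknown)} for enzyme {enzyme_id!r}"
            )
        base = assays.get(enzyme_id)
        if base is None:
            if "Km" not in settings:
                raise ConfigError(f"{path}: new enzyme {enzyme_id!r} must define Km")
            km = float(settings["Km"])
            base = EnzymeAssay(
                enzyme_id=enzyme_id,
                Km=km,
                S0=float(settings.get("S0", km)),
                kcat=float(settings.get("kcat", _default_kcat(km))),
            )
        fields = {k: (str(v) if k == "detection" else float(v)) for k, v in settings.items()}
        assays[enzyme_id] = replace(base, **fields)
    return assays
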