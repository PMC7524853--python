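"""Simulation configurations and the strain x hexose preset matrix.

The presets encode, per strain and hexose, the qualitative behaviour of the
Snf1–Mig1 system after a shift from ethanol to a repressing sugar:

* an initial nuclear-accumulation peak (amplitude ``A``) whenever the cell
  can phosphorylate the sugar at all,
* adapted-phase nucleocytoplasmic shuttling (pulse rate ``λ`` > 0) only when
  Hxk2 — or, on fructose, Hxk1 — is present or overexpressed,
* derepression of a destabilized SUC2-promoter reporter where shuttling (and
  hence repression) is lost, and
* hexokinase-overexpression toxicity on mannose, modelled as cell death above
  an expression-marker threshold.

Numeric magnitudes are free parameters documented in ``data/presets.yaml``;
only the orderings between conditions are meaningful.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import yaml

__all__ = ["ReporterParams", "SimulationConfig", "preset", "STRAINS", "HEXOSES"]

STRAINS = ("wt", "hxk1Δ", "hxk2Δ", "hxk1Δhxk2Δ", "+HXK1", "+HXK2", "+GLK1")
HEXOSES = ("glucose", "fructose", "mannose")

# ASCII-friendly aliases accepted anywhere a strain name is taken.
_STRAIN_ALIASES = {
    "wt": "wt",
    "wild type": "wt",
    "wildtype": "wt",
    "hxk1": "hxk1Δ",
    "hxk1d": "hxk1Δ",
    "hxk1δ": "hxk1Δ",
    "hxk1delta": "hxk1Δ",
    "hxk2": "hxk2Δ",
    "hxk2d": "hxk2Δ",
    "hxk2δ": "hxk2Δ",
    "hxk2delta": "hxk2Δ",
    "hxk1hxk2": "hxk1Δhxk2Δ",
    "hxk1dhxk2d": "hxk1Δhxk2Δ",
    "hxk1δhxk2δ": "hxk1Δhxk2Δ",
    "double": "hxk1Δhxk2Δ",
    "+hxk1": "+HXK1",
    "phxk1": "+HXK1",
    "+hxk2": "+HXK2",
    "phxk2": "+HXK2",
    "+glk1": "+GLK1",
    "pglk1": "+GLK1",
}


class ConfigurationError(ValueError):
    """Raised for unknown strains/hexoses or invalid simulation parameters."""


def canonical_strain(strain: str) -> str:
    key = strain.strip().lower()
    if key in _STRAIN_ALIASES:
        return _STRAIN_ALIASES[key]
    raise ConfigurationError(
        f"unknown strain {strain!r}; known: {', '.join(STRAINS)}"
    )


def canonical_hexose(hexose: str) -> str:
    key = hexose.strip().lower()
    if key not in HEXOSES:
        raise ConfigurationError(
            f"unknown hexose {hexose!r}; known: {', '.join(HEXOSES)}"
        )
    return key


@dataclass(frozen=True)
class ReporterParams:
    """Kinetics of a destabilized promoter-reporter fluorophore.

    Production runs at ``repressed_rate`` (leaky background) until
    ``derepression_onset`` and at ``derepressed_rate`` afterwards; the
    immature product becomes fluorescent after ``maturation_delay`` and the
    fluorescent pool turns over with first-order ``degradation_rate``.
    ``derepression_onset=None`` means the promoter never derepresses.
    """

    repressed_rate: float = 0.575  # AU/min
    derepressed_rate: float = 0.575  # AU/min
    maturation_delay: float = 30.0  # min
    degradation_rate: float = 0.023  # 1/min
    derepression_onset: Optional[float] = None  # min, None = never

    def __post_init__(self) -> None:
        if self.repressed_rate < 0 or self.derepressed_rate < 0:
            raise ConfigurationError("reporter production rates must be >= 0")
        if self.maturation_delay < 0:
            raise ConfigurationError("maturation_delay must be >= 0")
        if self.degradation_rate <= 0:
            raise ConfigurationError(
                "degradation_rate must be > 0 (destabilized reporter)"
            )
        if self.derepression_onset is not None and self.derepression_onset < 0:
            raise ConfigurationError("derepression_onset must be >= 0 or None")


@dataclass(frozen=True)
class SimulationConfig:
    """One strain x hexose condition of the localization-index generator.

    The ground-truth localization index of each cell is

    ``index(t) = b                                   for t < 0``
    ``index(t) = b + A·kernel(t) + (L−b)·rise(t) + pulses(t)   for t >= 0``

    with a gamma-shaped initial-response kernel peaking at ``peak_time`` and
    decaying with ``decay_tau``, a plateau relaxing to ``plateau_level``, and
    Gaussian-bump shuttling pulses arriving after ``pulse_start`` as a
    stationary renewal process with mean rate ``pulse_rate``.
    """

    strain: str = "wt"
    hexose: str = "glucose"
    n_cells: int = 50
    seed: int = 0
    initial_amplitude: float = 1.5  # A, index units
    peak_time: float = 30.0  # t_peak, min
    decay_tau: float = 60.0  # min
    plateau_level: float = 0.35  # L, index units
    pulse_rate: float = 2.0  # λ, pulses/hour
    pulse_height_mean: float = 0.4  # index units
    pulse_height_sd: float = 0.12  # index units
    pulse_width: float = 10.0  # FWHM, min
    pulse_start: float = 240.0  # min; pulses only in the adapted phase
    basal_level: float = 0.05  # b, index units
    noise_sd: float = 0.05  # per-sample measurement noise, index units
    responder_fraction: float = 1.0
    jitter_cv: float = 0.3  # log-normal cell-to-cell CV on A, λ, heights
    reporter: ReporterParams = field(default_factory=ReporterParams)
    reporter_noise_sd: float = 2.0  # AU
    death_fraction: float = 0.0
    death_expr_threshold: Optional[float] = None  # AU; None = no toxicity
    expression_marker_median: float = 100.0  # AU
    expression_marker_sigma: float = 0.15  # log-scale SD
    dose_response_k: Optional[float] = None  # AU; half-saturation of rescue

    def __post_init__(self) -> None:
        if self.initial_amplitude < 0:
            raise ConfigurationError("initial_amplitude must be >= 0")
        if self.decay_tau <= 0 or self.peak_time <= 0:
            raise ConfigurationError("peak_time and decay_tau must be > 0")
        if self.pulse_rate < 0:
            raise ConfigurationError("pulse_rate must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for name in ("responder_fraction", "death_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _load_preset_table() -> dict:
    text = resources.files("migshuttle.data").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


_PRESET_TABLE: Optional[dict] = None


def preset(
    strain: str, hexose: str, n_cells: int = 50, seed: int = 0
) -> SimulationConfig:
    """Simulation config for one strain x hexose condition.

    Raises :class:`ConfigurationError` for unknown strains or hexoses.
    """
    global _PRESET_TABLE
    if _PRESET_TABLE is None:
        _PRESET_TABLE = _load_preset_table()
    strain = canonical_strain(strain)
    hexose = canonical_hexose(hexose)
    table = _PRESET_TABLE
    d = copy.deepcopy(table["defaults"])
    cond = table["conditions"][strain][hexose]

    rep = d["reporter"]
    rep_override = cond.get("reporter")
    onset = None
    derepressed_rate = rep["repressed_rate"]
    if rep_override is not None:
        onset = rep_override["onset"]
        derepressed_rate = rep["repressed_rate"] * rep_override["fold"]
    reporter = ReporterParams(
        repressed_rate=rep["repressed_rate"],
        derepressed_rate=derepressed_rate,
        maturation_delay=rep["maturation_delay"],
        degradation_rate=rep["degradation_rate"],
        derepression_onset=onset,
    )

    death_threshold = cond.get("death_threshold", d["death_expr_threshold"])
    return SimulationConfig(
        strain=strain,
        hexose=hexose,
        n_cells=n_cells,
        seed=seed,
        initial_amplitude=float(cond["A"]),
        peak_time=float(cond.get("peak_time", d["peak_time"])),
        decay_tau=float(cond.get("decay_tau", d["decay_tau"])),
        plateau_level=float(cond["L"]),
        pulse_rate=float(cond["rate"]),
        pulse_height_mean=float(d["pulse_height_mean"]),
        pulse_height_sd=float(d["pulse_height_sd"]),
        pulse_width=float(d["pulse_width"]),
        pulse_start=float(d["pulse_start"]),
        basal_level=float(d["basal_level"]),
        noise_sd=float(d["noise_sd"]),
        responder_fraction=float(d["responder_fraction"]),
        jitter_cv=float(d["jitter_cv"]),
        reporter=reporter,
        reporter_noise_sd=float(d["reporter_noise_sd"]),
        death_fraction=0.3 if death_threshold is not None else 0.0,
        death_expr_threshold=death_threshold,
        expression_marker_median=float(cond.get("expr_median", d["expression_marker_median"])),
        expression_marker_sigma=float(cond.get("expr_sigma", d["expression_marker_sigma"])),
        dose_response_k=cond.get("dose_k", d["dose_response_k"]),
    )
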