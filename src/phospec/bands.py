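"""Oscillator-model deconvolution of assigned bands and Beer's-law quantification.

A preprocessed spectrum is modeled, window by window, as a sum of oscillators
(Gaussian by default; Lorentzian optional) fitted by bounded nonlinear least
squares (lmfit / trust-region reflective).  Each biochemical signature is
bound to a band center and fit window by a :class:`BandAssignment`; by Beer's
law the closed-form band area is proportional to the molar concentration of
the absorber, so ``concentration = area * beer_coefficient`` on a relative
scale (the default coefficients are 1, matching normalized-absorbance data).

The fingerprint region is congested: the two phosphate bands (P=O stretch
~1200 cm^-1 for inorganic phosphate, P-O-H/P-O-C deformation ~980 cm^-1 for
organic phosphate) and the cellulose ether band (~1160 cm^-1) all ride on the
broad polysaccharide C-O-C absorption around 1000 cm^-1.  Windows are
therefore fitted jointly: 900-1300 cm^-1 with four oscillators (Po, broad
polysaccharide, cellulose, Pi), 1450-1620 cm^-1 with two (lignin ~1510,
Amide II ~1550), and 1650-1780 cm^-1 with one (lipid carbonyl ~1710).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

from .io import Spectrum, SpectrumSet
from .synthetic import BAND_CENTERS

__all__ = [
    "BandAssignment",
    "Oscillator",
    "PeakFitResult",
    "ChemProfile",
    "FitConfig",
    "FitError",
    "UnmatchedBandError",
    "default_assignments",
    "fit_oscillators",
    "band_area",
    "quantify_profile",
    "quantify_set",
    "pi_po_ratio",
]

log = logging.getLogger(__name__)


class FitError(RuntimeError):
    pass


class UnmatchedBandError(FitError):
    """No fitted oscillator lies within the matching tolerance of a band center."""


@dataclass(frozen=True)
class Oscillator:
    """One band lineshape: center (cm^-1), half-width parameter, peak amplitude."""

    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"oscillator width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ValueError(f"oscillator amplitude must be >= 0, got {self.amplitude}")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unsupported lineshape {self.shape!r}")

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-0.5 * ((grid - self.center) / self.width) ** 2)
        return self.amplitude / (1.0 + ((grid - self.center) / self.width) ** 2)

    @property
    def area(self) -> float:
        """Closed-form lineshape area (absorbance * cm^-1)."""
        if self.shape == "gaussian":
            return self.amplitude * self.width * math.sqrt(2.0 * math.pi)
        return self.amplitude * self.width * math.pi


@dataclass(frozen=True)
class BandAssignment:
    """A named biochemical signature bound to a band center and fit window."""

    name: str
    center: float
    fit_window: tuple[float, float]
    beer_coefficient: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.fit_window
        if not lo <= self.center < hi:
            raise ValueError(
                f"{self.name}: center {self.center} outside window [{lo}, {hi})"
            )
        if self.beer_coefficient <= 0:
            raise ValueError(f"{self.name}: beer_coefficient must be > 0")


_PHOSPHATE_WINDOW = (900.0, 1300.0)
_AROMATIC_WINDOW = (1450.0, 1620.0)
_CARBONYL_WINDOW = (1650.0, 1780.0)


def default_assignments() -> list[BandAssignment]:
    """Standard leaf-tissue band assignments (Beer coefficients 1 = relative scale)."""
    return [
        BandAssignment("Po", BAND_CENTERS["Po"], _PHOSPHATE_WINDOW),
        BandAssignment("poly", BAND_CENTERS["poly"], _PHOSPHATE_WINDOW),
        BandAssignment("cellulose", BAND_CENTERS["cellulose"], _PHOSPHATE_WINDOW),
        BandAssignment("Pi", BAND_CENTERS["Pi"], _PHOSPHATE_WINDOW),
        BandAssignment("lignin", BAND_CENTERS["lignin"], _AROMATIC_WINDOW),
        BandAssignment("amide", BAND_CENTERS["amide"], _AROMATIC_WINDOW),
        BandAssignment("lipid", BAND_CENTERS["lipid"], _CARBONYL_WINDOW),
    ]


@dataclass
class PeakFitResult:
    oscillators: list[Oscillator]
    residual_rms: float
    converged: bool
    region: tuple[float, float]
    initial_residual_rms: float = float("nan")
    n_evaluations: int = 0


@dataclass
class ChemProfile:
    """Per-sample quantified signatures on a relative concentration scale."""

    sample_id: str
    concentrations: dict[str, float]
    cl_ratio: float | None
    residual_rms: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    def as_row(self) -> dict:
        row = {"sample_id": self.sample_id, **self.concentrations}
        row["cl_ratio"] = self.cl_ratio
        row["converged"] = self.converged
        for win, rms in self.residual_rms.items():
            row[f"residual_rms_{win}"] = rms
        return row


@dataclass(frozen=True)
class FitConfig:
    """Deconvolution controls: lineshape, initialization and bounds."""

    shape: str = "gaussian"
    init_width: float = 10.0         # cm^-1, sharp bands
    broad_init_width: float = 50.0   # cm^-1, the broad polysaccharide band
    width_bounds: tuple[float, float] = (2.0, 120.0)
    center_slack: float = 15.0       # max shift of a center during fitting
    match_tolerance: float = 15.0    # assignment-to-oscillator matching, cm^-1
    lignin_floor: float = 1e-6       # C/L undefined below this lignin level
    po_floor: float = 1e-6           # Pi/Po undefined below this Po level
    max_nfev: int = 4000
    broad_bands: tuple[str, ...] = ("poly",)
    # free per-window baseline term absorbing residual baseline-correction
    # error (rubber-band chords sit above a convex baseline between bands)
    window_baseline: str = "linear"  # none | constant | linear
    window_baseline_bound: float = 0.2


def fit_oscillators(
    spectrum: Spectrum,
    region: tuple[float, float],
    init: Sequence[Oscillator],
    bounds: dict | None = None,
    config: FitConfig | None = None,
) -> PeakFitResult:
    """Bounded least-squares fit of a sum of oscillators over ``[lo, hi)``.

    ``init`` supplies one starting oscillator per band; ``bounds`` may
    override ``center_slack``, ``width_bounds`` and ``amplitude_max``.  The
    returned residual RMS never exceeds the residual of the initial guess.
    """
    cfg = config or FitConfig()
    if not init:
        raise FitError("need at least one initial oscillator")
    lo, hi = region
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers < hi)
    if mask.sum() < 3:
        raise FitError(f"region [{lo}, {hi}) covers fewer than 3 grid points")
    x = spectrum.wavenumbers[mask]
    y = spectrum.absorbance[mask]

    bounds = bounds or {}
    slack = float(bounds.get("center_slack", cfg.center_slack))
    w_lo, w_hi = bounds.get("width_bounds", cfg.width_bounds)
    amp_max = float(bounds.get("amplitude_max", np.inf))
    if not all(map(math.isfinite, (slack, w_lo, w_hi))):
        raise FitError("bounds must be finite")

    params = lmfit.Parameters()
    for i, osc in enumerate(init):
        if not lo - slack <= osc.center < hi + slack:
            raise FitError(
                f"initial oscillator center {osc.center} outside region [{lo}, {hi})"
            )
        if not w_lo <= osc.width <= w_hi or osc.amplitude > amp_max:
            raise FitError(f"initial oscillator {i} violates the fit bounds")
        params.add(f"c{i}", value=osc.center, min=osc.center - slack, max=osc.center + slack)
        params.add(f"w{i}", value=osc.width, min=w_lo, max=w_hi)
        params.add(f"a{i}", value=osc.amplitude, min=0.0, max=amp_max)

    x_mid = 0.5 * (x[0] + x[-1])
    n_base = {"none": 0, "constant": 1, "linear": 2}[cfg.window_baseline]
    for j in range(n_base):
        bb = cfg.window_baseline_bound
        params.add(f"b{j}", value=0.0, min=-bb, max=bb)

    shapes = [osc.shape for osc in init]

    def model(p: lmfit.Parameters) -> np.ndarray:
        out = np.zeros_like(x)
        for i, shape in enumerate(shapes):
            c, w, a = p[f"c{i}"].value, p[f"w{i}"].value, p[f"a{i}"].value
            if shape == "gaussian":
                out += a * np.exp(-0.5 * ((x - c) / w) ** 2)
            else:
                out += a / (1.0 + ((x - c) / w) ** 2)
        if n_base >= 1:
            out = out + p["b0"].value
        if n_base >= 2:
            out = out + p["b1"].value * (x - x_mid) / 100.0
        return out

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return model(p) - y

    init_rms = float(np.sqrt(np.mean(residual(params) ** 2)))
    if init_rms == 0.0:
        fitted = list(init)
        return PeakFitResult(fitted, 0.0, True, (lo, hi), 0.0, 0)

    result = lmfit.minimize(
        residual, params, method="least_squares", max_nfev=cfg.max_nfev
    )
    rms = float(np.sqrt(np.mean(result.residual**2)))
    if rms > init_rms:  # solver cannot worsen the start; keep the guess if it did
        fitted = list(init)
        rms = init_rms
        converged = False
    else:
        fitted = [
            Oscillator(
                result.params[f"c{i}"].value,
                result.params[f"w{i}"].value,
                max(result.params[f"a{i}"].value, 0.0),
                shapes[i],
            )
            for i in range(len(init))
        ]
        converged = bool(result.success) and result.nfev < cfg.max_nfev
    return PeakFitResult(fitted, rms, converged, (lo, hi), init_rms, int(result.nfev))


def band_area(
    fit: PeakFitResult, assignment: BandAssignment, config: FitConfig | None = None
) -> float:
    """Closed-form area of the fitted oscillator matched (nearest) to a band center."""
    cfg = config or FitConfig()
    if not fit.converged:
        raise FitError(f"{assignment.name}: fit did not converge; refusing band area")
    if not fit.oscillators:
        raise UnmatchedBandError(f"{assignment.name}: fit contains no oscillators")
    centers = np.array([o.center for o in fit.oscillators])
    i = int(np.argmin(np.abs(centers - assignment.center)))
    if abs(centers[i] - assignment.center) > cfg.match_tolerance:
        raise UnmatchedBandError(
            f"{assignment.name}: nearest oscillator at {centers[i]:.1f} cm^-1 is "
            f"beyond the {cfg.match_tolerance} cm^-1 matching tolerance of "
            f"{assignment.center:.1f}"
        )
    return fit.oscillators[i].area


def _initial_oscillators(
    spectrum: Spectrum,
    assignments: Sequence[BandAssignment],
    region: tuple[float, float],
    cfg: FitConfig,
) -> list[Oscillator]:
    lo, hi = region
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers < hi)
    floor = float(spectrum.absorbance[mask].min()) if mask.any() else 0.0
    oscs = []
    for a in assignments:
        j = int(np.argmin(np.abs(spectrum.wavenumbers - a.center)))
        local = float(spectrum.absorbance[j]) - min(floor, 0.0)
        amp = max(local, 1e-6)
        width = cfg.broad_init_width if a.name in cfg.broad_bands else cfg.init_width
        oscs.append(Oscillator(a.center, width, amp, cfg.shape))
    return oscs


def quantify_profile(
    spectrum: Spectrum,
    assignments: Sequence[BandAssignment] | None = None,
    fit_config: FitConfig | None = None,
) -> ChemProfile:
    """Deconvolve a preprocessed spectrum into its biochemical profile.

    Assignments sharing a fit window are fitted jointly (so the overlapping
    1510/1550 and 980/1160/1200 bands constrain each other); each signature's
    relative concentration is its fitted band area times its Beer
    coefficient.  The cellulose/lignin ratio is reported only when the lignin
    concentration clears the configured floor.
    """
    cfg = fit_config or FitConfig()
    assignments = list(assignments) if assignments is not None else default_assignments()
    windows: dict[tuple[float, float], list[BandAssignment]] = {}
    for a in assignments:
        windows.setdefault(a.fit_window, []).append(a)

    concentrations: dict[str, float] = {}
    residuals: dict[str, float] = {}
    converged = True
    for region, group in windows.items():
        init = _initial_oscillators(spectrum, group, region, cfg)
        try:
            fit = fit_oscillators(spectrum, region, init, config=cfg)
        except FitError as err:
            names = ",".join(a.name for a in group)
            raise FitError(f"fit failed for signature(s) {names}: {err}") from err
        key = f"{region[0]:g}-{region[1]:g}"
        residuals[key] = fit.residual_rms
        converged &= fit.converged
        for a in group:
            try:
                area = band_area(fit, a, cfg)
            except FitError as err:
                raise type(err)(f"signature {a.name!r}: {err}") from err
            concentrations[a.name] = area * a.beer_coefficient

    cl = None
    if "cellulose" in concentrations and concentrations.get("lignin", 0.0) >= cfg.lignin_floor:
        cl = concentrations["cellulose"] / concentrations["lignin"]
    return ChemProfile(spectrum.sample_id, concentrations, cl, residuals, converged)


def quantify_set(
    sset: SpectrumSet,
    assignments: Sequence[BandAssignment] | None = None,
    fit_config: FitConfig | None = None,
) -> pd.DataFrame:
    """Quantify every spectrum in a set; returns one profile row per sample."""
    rows = []
    for sp in sset:
        profile = quantify_profile(sp, assignments, fit_config)
        row = profile.as_row()
        for k in ("plant_id", "site", "timepoint", "series", "p_conc_uM", "n_conc_mM"):
            if k in sset.metadata.columns:
                row[k] = sset.metadata.loc[sp.sample_id, k]
        rows.append(row)
    return pd.DataFrame(rows)


def pi_po_ratio(profile: ChemProfile, config: FitConfig | None = None) -> float:
    """Inorganic/organic phosphate ratio — the senescence remobilization index."""
    cfg = config or FitConfig()
    pi = profile.concentrations.get("Pi")
    po = profile.concentrations.get("Po")
    if pi is None or po is None:
        raise FitError("profile lacks Pi and/or Po concentrations")
    if po < cfg.po_floor:
        raise FitError(
            f"Po concentration {po:g} below floor {cfg.po_floor:g}; Pi/Po undefined"
        )
    return pi / po
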