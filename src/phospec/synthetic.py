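"""Forward model for ATR-FTIR leaf spectra under controlled P/N nutrition.

Emulates two study designs with known ground truth:

* **Lab sand-culture design** — five medium-P levels (1, 10, 30, 150, 500 uM
  at optimal 6 mM N) and five medium-N levels (0.01, 0.1, 0.3, 1.5, 6 mM at
  optimal 500 uM P).  The optimal condition (500 uM P, 6 mM N) is shared
  between the two series, giving 9 distinct conditions x 9 replicate plants;
  three plants at the lowest P level die, leaving 78.  Each plant yields
  triplicate technical spectra.

* **Field season** — two sites contrasting in plant-available P, 30 plants
  per site sampled at five timepoints T1..T5.  Leaf inorganic phosphate (Pi)
  rises through the season and spikes at senescence (T5) on the high-P site,
  organic phosphate (Po) plateaus near T4 and declines at T5 there, the
  cellulose/lignin (C/L) ratio declines as tissue lignifies, and second-year
  biomass increases with the senescence-time Pi/Po ratio.

A spectrum is a sum of Gaussian oscillators (one per biochemical band, plus a
broad polysaccharide absorption near 1000 cm^-1), a smooth low-order
polynomial baseline drawn per plant, and i.i.d. Gaussian noise per
measurement.  Band amplitudes are deterministic dose-response functions of
medium P and N, times a lognormal plant-to-plant factor.

The dose-response calibration solves the C/L jump height in closed form so
that the latent C/L ratio at 500 uM P is exactly 3x its mean over the 1, 10
and 30 uM conditions; all other curve shapes are qualitative and exposed in
:class:`DoseResponseParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Spectrum, SpectrumSet, default_grid

__all__ = [
    "P_LEVELS_UM",
    "N_LEVELS_MM",
    "OPTIMAL_P_UM",
    "OPTIMAL_N_MM",
    "BAND_CENTERS",
    "BAND_SIGMAS",
    "SIGNATURES",
    "DoseResponseParams",
    "GeneratorConfig",
    "FieldParams",
    "make_design",
    "dose_response",
    "simulate_spectrum",
    "simulate_lab_dataset",
    "simulate_field_dataset",
    "simulate_field_truth",
    "gaussian_band",
    "gaussian_area",
]

P_LEVELS_UM: tuple[float, ...] = (1.0, 10.0, 30.0, 150.0, 500.0)
N_LEVELS_MM: tuple[float, ...] = (0.01, 0.1, 0.3, 1.5, 6.0)
OPTIMAL_P_UM = 500.0
OPTIMAL_N_MM = 6.0

# Band centers (cm^-1) follow the standard leaf-tissue assignments:
# P-O-H / P-O-C deformation (organic phosphate) ~980, broad polysaccharide
# C-O-C absorption ~1000, cellulose ether C-O-C ~1160, phosphoryl P=O
# (inorganic phosphate) ~1200, lignin aromatic C=C ~1510, Amide II ~1550,
# lipid carbonyl ~1710.
BAND_CENTERS: dict[str, float] = {
    "Po": 980.0,
    "poly": 1000.0,
    "cellulose": 1160.0,
    "Pi": 1200.0,
    "lignin": 1510.0,
    "amide": 1550.0,
    "lipid": 1710.0,
}
BAND_SIGMAS: dict[str, float] = {
    "Po": 12.0,
    "poly": 55.0,
    "cellulose": 12.0,
    "Pi": 10.0,
    "lignin": 12.0,
    "amide": 12.0,
    "lipid": 14.0,
}
#: the six quantified biochemical signatures (excludes the broad band)
SIGNATURES: tuple[str, ...] = ("Pi", "Po", "cellulose", "lignin", "amide", "lipid")

_LP_MAX = math.log10(OPTIMAL_P_UM)  # 2.699 decades


def _sigmoid(x: float | np.ndarray) -> float | np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class DoseResponseParams:
    """Dose-response curve shapes for band amplitudes vs medium P and N.

    The cellulose threshold sits between 30 and 150 uM P (a logistic in
    log10 P centered at ``cl_center`` decades); ``cl_jump`` is *solved*, not
    set, so the latent C/L ratio at 500 uM P is ``cl_fold`` times its mean
    over the sub-150 uM levels.
    """

    cl_base: float = 0.8          # C/L ratio at the lowest P
    cl_slope: float = 0.15        # gentle C/L rise per decade of P
    cl_center: float = 1.82       # logistic center, log10 uM (~66 uM)
    cl_width: float = 0.15        # logistic width, decades
    cl_fold: float = 3.0          # calibrated 500-uM / sub-150-uM contrast
    lignin_base: float = 0.45
    # gradual lignin decrease per decade of P; kept below the C/L log-slope at
    # high P so cellulose (= C/L x lignin) stays non-decreasing up to 500 uM
    lignin_slope: float = 0.02
    pi_base: float = 0.08
    pi_span: float = 0.42
    po_base: float = 0.15
    po_span: float = 0.25
    lipid_base: float = 0.12
    lipid_stress: float = 0.26    # extra lipid under severe P limitation
    lipid_n_span: float = 0.06
    amide_base: float = 0.14
    amide_n_span: float = 0.16
    amide_stress: float = 0.12    # amide accumulation under P starvation
    stress_center: float = 0.5    # log10 uM where P-stress relief is centered
    stress_width: float = 0.4
    poly_base: float = 0.45
    poly_cellulose_coupling: float = 0.3

    @property
    def cl_jump(self) -> float:
        """Logistic jump height giving exactly ``cl_fold`` latent C/L contrast."""
        lp_low = [math.log10(p) for p in (1.0, 10.0, 30.0)]
        s = [float(_sigmoid((lp - self.cl_center) / self.cl_width)) for lp in lp_low]
        s_hi = float(_sigmoid((_LP_MAX - self.cl_center) / self.cl_width))
        mean_lp = sum(lp_low) / 3.0
        mean_s = sum(s) / 3.0
        # solve a + c*LP + b*s_hi = F * (a + c*mean_lp + b*mean_s) for b
        a, c, F = self.cl_base, self.cl_slope, self.cl_fold
        return ((F - 1.0) * a + c * (F * mean_lp - _LP_MAX)) / (s_hi - F * mean_s)

    def cl_ratio(self, p_conc: float | np.ndarray) -> float | np.ndarray:
        lp = np.log10(p_conc)
        return (
            self.cl_base
            + self.cl_slope * lp
            + self.cl_jump * _sigmoid((lp - self.cl_center) / self.cl_width)
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Noise and sampling configuration shared by lab and field simulations."""

    noise_sd: float = 0.004          # additive absorbance noise per measurement
    # lognormal sigma of plant-level amplitudes, calibrated so the spectral
    # information content matches the near-interpolating linear map between
    # leaf spectra and medium P that the study design presumes
    plant_log_sd: float = 0.05
    baseline_offset_max: float = 0.05
    baseline_slope_max: float = 0.03
    baseline_curve_max: float = 0.05
    grid_lo: float = 600.0
    grid_hi: float = 4000.0
    grid_step: float = 2.0
    n_replicates: int = 9
    n_technical: int = 3
    drop_dead: bool = True           # remove the 3 dead plants at 1 uM P
    dose: DoseResponseParams = field(default_factory=DoseResponseParams)

    def grid(self) -> np.ndarray:
        return default_grid(self.grid_lo, self.grid_hi, self.grid_step)


def dose_response(
    p_conc: float,
    n_conc: float,
    params: DoseResponseParams | None = None,
) -> dict[str, float]:
    """Latent band amplitudes for a plant grown at (``p_conc`` uM P, ``n_conc`` mM N).

    Encodes the lab dose-response structure: cellulose jumps between 30 and
    150 uM P, lignin declines gradually with P, Pi and Po rise with P, lipid
    and amide are elevated under severe P limitation, amide and lipid rise
    with N, and the implied C/L ratio at 500 uM P is 3x its sub-150 uM mean.
    """
    d = params or DoseResponseParams()
    if p_conc <= 0 or n_conc <= 0:
        raise ValueError(f"concentrations must be positive, got P={p_conc}, N={n_conc}")
    lp = math.log10(p_conc)
    ln = math.log10(n_conc)
    n_frac = (ln - math.log10(N_LEVELS_MM[0])) / (
        math.log10(N_LEVELS_MM[-1]) - math.log10(N_LEVELS_MM[0])
    )
    n_frac = min(max(n_frac, 0.0), 1.0)
    stress = float(_sigmoid(-(lp - d.stress_center) / d.stress_width))

    lignin = d.lignin_base - d.lignin_slope * lp
    cellulose = float(d.cl_ratio(p_conc)) * lignin
    amps = {
        "Pi": d.pi_base + d.pi_span * lp / _LP_MAX,
        "Po": d.po_base + d.po_span * lp / _LP_MAX,
        "cellulose": cellulose,
        "lignin": lignin,
        "amide": d.amide_base + d.amide_n_span * n_frac + d.amide_stress * stress,
        "lipid": d.lipid_base + d.lipid_stress * stress + d.lipid_n_span * n_frac,
    }
    amps["poly"] = d.poly_base + d.poly_cellulose_coupling * cellulose
    if any(v < 0 for v in amps.values()):
        raise ValueError("dose-response parameters produced a negative amplitude")
    return amps


def make_design(
    seed: int = 0,
    n_replicates: int | None = None,
    drop_dead: bool = True,
    conditions: Sequence[tuple[str, float, float]] | None = None,
) -> pd.DataFrame:
    """Enumerate the sand-culture design: one record per surviving plant.

    Nine distinct conditions (five P levels at optimal N, five N levels at
    optimal P, the all-optimal condition shared and counted once) with 9
    replicates each; with ``drop_dead`` the three casualties at 1 uM P are
    removed, leaving 78 plants.  ``conditions`` overrides the condition list
    as ``(series, p_uM, n_mM)`` triples.
    """
    reps = 9 if n_replicates is None else int(n_replicates)
    if reps < 1:
        raise ValueError("n_replicates must be >= 1")
    if conditions is None:
        conditions = [("P-series", p, OPTIMAL_N_MM) for p in P_LEVELS_UM]
        conditions += [
            ("N-series", OPTIMAL_P_UM, n) for n in N_LEVELS_MM if n != OPTIMAL_N_MM
        ]
    rows = []
    for series, p, n in conditions:
        n_dead = 3 if (drop_dead and p == min(P_LEVELS_UM) and series == "P-series") else 0
        n_dead = min(n_dead, reps)
        for r in range(reps - n_dead):
            rows.append(
                {
                    "plant_id": f"{series[0]}_p{p:g}_n{n:g}_r{r + 1}",
                    "series": series,
                    "p_conc_uM": p,
                    "n_conc_mM": n,
                    "replicate": r + 1,
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- lineshapes

def gaussian_band(
    grid: np.ndarray, center: float, sigma: float, amplitude: float
) -> np.ndarray:
    """Gaussian oscillator: ``A * exp(-(v-c)^2 / (2 sigma^2))``."""
    return amplitude * np.exp(-0.5 * ((grid - center) / sigma) ** 2)


def gaussian_area(amplitude: float, sigma: float) -> float:
    """Closed-form area of a Gaussian band: ``A * sigma * sqrt(2 pi)``."""
    return amplitude * sigma * math.sqrt(2.0 * math.pi)


def _baseline(grid: np.ndarray, coeffs: Sequence[float]) -> np.ndarray:
    # low-order polynomial in a normalized coordinate so coefficients are
    # grid-scale free; convex by construction when the curvature term is >= 0
    z = (grid - 2300.0) / 1700.0
    out = np.zeros_like(grid)
    for k, c in enumerate(coeffs):
        out += c * z**k
    return out


def simulate_spectrum(
    amplitudes: Mapping[str, float],
    noise_sd: float = 0.0,
    baseline_params: Sequence[float] = (),
    seed: int | np.random.Generator = 0,
    grid: np.ndarray | None = None,
    sample_id: str = "synthetic",
    metadata: Mapping | None = None,
) -> Spectrum:
    """Render one spectrum: sum of Gaussian bands + polynomial baseline + noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty wavenumber grid")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    absorb = _baseline(grid, baseline_params)
    for name, amp in amplitudes.items():
        if name not in BAND_CENTERS:
            raise KeyError(f"unknown band {name!r}; known: {sorted(BAND_CENTERS)}")
        absorb = absorb + gaussian_band(grid, BAND_CENTERS[name], BAND_SIGMAS[name], amp)
    if noise_sd > 0:
        absorb = absorb + rng.normal(0.0, noise_sd, size=grid.size)
    return Spectrum(grid, absorb, sample_id, dict(metadata or {}))


def _plant_amplitudes(
    base: Mapping[str, float], rng: np.random.Generator, log_sd: float
) -> dict[str, float]:
    return {
        k: v * float(np.exp(rng.normal(0.0, log_sd))) for k, v in base.items()
    }


def _draw_baseline(rng: np.random.Generator, cfg: GeneratorConfig) -> tuple[float, ...]:
    return (
        float(rng.uniform(0.0, cfg.baseline_offset_max)),
        float(rng.uniform(-cfg.baseline_slope_max, cfg.baseline_slope_max)),
        float(rng.uniform(0.0, cfg.baseline_curve_max)),
    )


def simulate_lab_dataset(
    seed: int = 0, config: GeneratorConfig | None = None
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Simulate the full lab design: triplicate spectra per surviving plant.

    Returns the spectra (234 by default) and a ground-truth table with one
    row per plant carrying its condition, latent amplitudes and true C/L
    ratio — the oracle for every downstream recovery test.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    design = make_design(seed, n_replicates=cfg.n_replicates, drop_dead=cfg.drop_dead)
    grid = cfg.grid()
    spectra: list[Spectrum] = []
    truth_rows = []
    for rec in design.itertuples(index=False):
        base = dose_response(rec.p_conc_uM, rec.n_conc_mM, cfg.dose)
        amps = _plant_amplitudes(base, rng, cfg.plant_log_sd)
        baseline = _draw_baseline(rng, cfg)
        truth_rows.append(
            {
                "plant_id": rec.plant_id,
                "series": rec.series,
                "p_conc_uM": rec.p_conc_uM,
                "n_conc_mM": rec.n_conc_mM,
                **{f"amp_{k}": v for k, v in amps.items()},
                "true_cl_ratio": amps["cellulose"] / amps["lignin"],
            }
        )
        for t in range(cfg.n_technical):
            sid = f"{rec.plant_id}_t{t + 1}"
            spectra.append(
                simulate_spectrum(
                    amps,
                    cfg.noise_sd,
                    baseline,
                    rng,
                    grid,
                    sample_id=sid,
                    metadata={
                        "plant_id": rec.plant_id,
                        "series": rec.series,
                        "p_conc_uM": rec.p_conc_uM,
                        "n_conc_mM": rec.n_conc_mM,
                        "technical_rep": t + 1,
                    },
                )
            )
    return SpectrumSet.from_spectra(spectra), pd.DataFrame(truth_rows)


# ------------------------------------------------------------------ field

@dataclass(frozen=True)
class FieldParams:
    """Field-season configuration: site contrast and seasonal multipliers.

    ``site_effect`` in [0, 1] scales every site difference; at 0 the two
    sites are statistically identical.  Seasonal multipliers are indexed
    T1..T5 and interpolate between the low-P and high-P site trajectories.
    """

    n_plants_per_site: int = 30
    site_effect: float = 1.0
    low_p_mean_uM: float = 30.0
    high_p_mean_uM: float = 120.0
    latent_p_log_sd: float = 0.2
    timepoint_log_sd: float = 0.05   # independent sampling-time jitter per component
    n_mean_mM: float = 1.5
    pi_mult_low: tuple[float, ...] = (0.70, 0.80, 0.95, 1.15, 1.30)
    pi_mult_high: tuple[float, ...] = (0.70, 0.95, 1.10, 1.25, 1.80)
    po_mult_low: tuple[float, ...] = (0.80, 0.92, 1.00, 1.05, 1.00)
    po_mult_high: tuple[float, ...] = (0.80, 0.95, 1.05, 1.10, 0.80)
    lignin_mult: tuple[float, ...] = (0.85, 0.95, 1.05, 1.15, 1.25)
    cellulose_mult: tuple[float, ...] = (1.10, 1.05, 1.00, 0.92, 0.85)
    biomass_intercept_g: float = 300.0
    biomass_slope_g: float = 150.0    # grams per natural-log unit of T5 Pi/Po
    biomass_noise_g: float = 30.0


TIMEPOINTS = ("T1", "T2", "T3", "T4", "T5")
SITES = ("low-P-site", "high-P-site")


def simulate_field_truth(
    seed: int = 0,
    site_params: FieldParams | None = None,
    config: GeneratorConfig | None = None,
    _rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Ground-truth field table only (no spectra): one row per plant-timepoint.

    Identical to the table returned by :func:`simulate_field_dataset` at the
    same seed (spectral noise is drawn from a separate child stream there).
    """
    fp = site_params or FieldParams()
    cfg = config or GeneratorConfig()
    rng = _rng if _rng is not None else np.random.default_rng(seed)
    e = fp.site_effect
    rows = []
    for site in SITES:
        # site latent-P mean interpolates toward the low-P mean as e -> 0
        if site == "high-P-site":
            mean_p = fp.low_p_mean_uM * (fp.high_p_mean_uM / fp.low_p_mean_uM) ** e
        else:
            mean_p = fp.low_p_mean_uM
        pi_m = tuple(
            lo + e * (hi - lo)
            for lo, hi in zip(fp.pi_mult_low, fp.pi_mult_high)
        ) if site == "high-P-site" else fp.pi_mult_low
        po_m = tuple(
            lo + e * (hi - lo)
            for lo, hi in zip(fp.po_mult_low, fp.po_mult_high)
        ) if site == "high-P-site" else fp.po_mult_low
        for j in range(fp.n_plants_per_site):
            pid = f"{site}_plant{j + 1:02d}"
            latent_p = float(
                mean_p * np.exp(rng.normal(0.0, fp.latent_p_log_sd))
            )
            base = dose_response(latent_p, fp.n_mean_mM, cfg.dose)
            plant = _plant_amplitudes(base, rng, cfg.plant_log_sd)
            t5_ratio = None
            plant_rows = []
            for t_idx, tp in enumerate(TIMEPOINTS):
                amps = dict(plant)
                amps["Pi"] = plant["Pi"] * pi_m[t_idx]
                amps["Po"] = plant["Po"] * po_m[t_idx]
                amps["lignin"] = plant["lignin"] * fp.lignin_mult[t_idx]
                amps["cellulose"] = plant["cellulose"] * fp.cellulose_mult[t_idx]
                # each sampling visit sees an independently varying leaf
                for k in SIGNATURES:
                    amps[k] *= float(np.exp(rng.normal(0.0, fp.timepoint_log_sd)))
                amps["poly"] = (
                    cfg.dose.poly_base
                    + cfg.dose.poly_cellulose_coupling * amps["cellulose"]
                )
                sid = f"{pid}_{tp}"
                if tp == "T5":
                    t5_ratio = amps["Pi"] / amps["Po"]
                plant_rows.append(
                    {
                        "sample_id": sid,
                        "plant_id": pid,
                        "site": site,
                        "timepoint": tp,
                        "latent_available_P_uM": latent_p,
                        **{f"amp_{k}": v for k, v in amps.items()},
                        "true_cl_ratio": amps["cellulose"] / amps["lignin"],
                        "true_pi_po_ratio": amps["Pi"] / amps["Po"],
                    }
                )
            biomass = (
                fp.biomass_intercept_g
                + fp.biomass_slope_g * math.log(t5_ratio)
                + float(rng.normal(0.0, fp.biomass_noise_g))
            )
            for r in plant_rows:
                r["second_year_biomass_g"] = biomass
            rows.extend(plant_rows)
    return pd.DataFrame(rows)


def simulate_field_dataset(
    seed: int = 0,
    site_params: FieldParams | None = None,
    config: GeneratorConfig | None = None,
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Simulate the two-site field season: 2 sites x 30 plants x 5 timepoints.

    Returns one spectrum per plant-timepoint (300 by default) and the
    ground-truth table from :func:`simulate_field_truth` (latent available P,
    per-timepoint amplitudes, second-year biomass).  Baselines and
    measurement noise come from a child random stream, so the truth table is
    bit-identical to a truth-only call at the same seed.
    """
    fp = site_params or FieldParams()
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    table = simulate_field_truth(seed, fp, cfg, _rng=rng)
    render_rng = rng.spawn(1)[0]
    grid = cfg.grid()
    amp_cols = {c: c[len("amp_"):] for c in table.columns if c.startswith("amp_")}
    spectra: list[Spectrum] = []
    baseline_of_plant: dict[str, tuple[float, ...]] = {}
    for row in table.itertuples(index=False):
        pid = row.plant_id
        if pid not in baseline_of_plant:
            baseline_of_plant[pid] = _draw_baseline(render_rng, cfg)
        amps = {band: getattr(row, col) for col, band in amp_cols.items()}
        spectra.append(
            simulate_spectrum(
                amps, cfg.noise_sd, baseline_of_plant[pid], render_rng, grid,
                sample_id=row.sample_id,
                metadata={
                    "plant_id": pid, "site": row.site, "timepoint": row.timepoint,
                },
            )
        )
    return SpectrumSet.from_spectra(spectra), table
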