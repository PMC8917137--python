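"""Spectral preprocessing: baseline correction, normalization, replicate averaging.

The pipeline order is fixed as **baseline -> aggregate -> normalize** (the
stages do not commute: replicate averaging after per-spectrum normalization
would weight replicates by their individual maxima).  :func:`run_preprocess`
enforces the order and records provenance on the output metadata.

Baseline methods:

* ``rubber-band`` — subtract the lower convex hull of the trace (parameter
  free; the estimated baseline lies at or below the signal everywhere).
* ``als`` — asymmetric least squares (Whittaker smoother with asymmetric
  weights; smoothness ``lam``, asymmetry ``p``).
* ``polynomial`` — iterative polynomial fitting with clipping of points
  above the current fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .io import Spectrum, SpectrumSet, SpectraError, restrict_region

__all__ = [
    "PreprocessConfig",
    "baseline_correct",
    "baseline_correct_set",
    "normalize_max",
    "normalize_set",
    "aggregate_replicates",
    "run_preprocess",
]

log = logging.getLogger(__name__)

BASELINE_METHODS = ("rubber-band", "als", "polynomial")
NORMALIZATION_SCOPES = ("per-spectrum-global-max", "per-spectrum-region-max", "none")


@dataclass
class PreprocessConfig:
    """Preprocessing parameters; defaults follow the fingerprint-region setup."""

    region: tuple[float, float] = (800.0, 1800.0)   # modeling window, cm^-1
    baseline_method: str = "rubber-band"
    als_lam: float = 1e5
    als_p: float = 0.01
    als_n_iter: int = 10
    poly_degree: int = 2
    poly_n_iter: int = 12
    normalization_scope: str = "per-spectrum-region-max"
    normalization_region: tuple[float, float] = (800.0, 1800.0)
    replicate_policy: str = "average"               # or "keep-all"
    replicate_key: str = "plant_id"

    def __post_init__(self) -> None:
        if self.baseline_method not in BASELINE_METHODS:
            raise ValueError(f"baseline_method must be one of {BASELINE_METHODS}")
        if self.normalization_scope not in NORMALIZATION_SCOPES:
            raise ValueError(f"normalization_scope must be one of {NORMALIZATION_SCOPES}")
        if self.replicate_policy not in ("average", "keep-all"):
            raise ValueError("replicate_policy must be 'average' or 'keep-all'")


# ----------------------------------------------------------------- baseline

def _lower_hull_baseline(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lower convex hull of (x, y), interpolated onto x (Andrew monotone chain)."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # pop i2 if it lies on or above the chord i1 -> i
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (x[i] - x[i1]) * (y[i2] - y[i1])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(x, x[hull], y[hull])


def _als_baseline(y: np.ndarray, lam: float, p: float, n_iter: int) -> np.ndarray:
    n = y.size
    d2 = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    penalty = lam * (d2.T @ d2)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        W = sp.diags(w)
        z = spsolve((W + penalty).tocsc(), w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def _poly_baseline(x: np.ndarray, y: np.ndarray, degree: int, n_iter: int) -> np.ndarray:
    span = float(np.ptp(x))
    xs = (x - x.mean()) / (span if span > 0 else 1.0)
    work = y.copy()
    fit = np.zeros_like(y)
    for _ in range(n_iter):
        coeffs = np.polynomial.polynomial.polyfit(xs, work, degree)
        fit = np.polynomial.polynomial.polyval(xs, coeffs)
        work = np.minimum(work, fit)  # clip peaks so the fit sinks to the base
    return fit


def estimate_baseline(spectrum: Spectrum, config: PreprocessConfig | None = None) -> np.ndarray:
    cfg = config or PreprocessConfig()
    y = spectrum.absorbance
    if not np.all(np.isfinite(y)):
        raise SpectraError(f"spectrum {spectrum.sample_id!r}: non-finite absorbance")
    if y.size < 10:
        raise SpectraError("baseline estimation needs >= 10 grid points")
    x = spectrum.wavenumbers
    if cfg.baseline_method == "rubber-band":
        return _lower_hull_baseline(x, y)
    if cfg.baseline_method == "als":
        return _als_baseline(y, cfg.als_lam, cfg.als_p, cfg.als_n_iter)
    return _poly_baseline(x, y, cfg.poly_degree, cfg.poly_n_iter)


def baseline_correct(spectrum: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Return the spectrum minus its estimated baseline."""
    base = estimate_baseline(spectrum, config)
    return Spectrum(
        spectrum.wavenumbers,
        spectrum.absorbance - base,
        spectrum.sample_id,
        dict(spectrum.metadata),
    )


def baseline_correct_set(sset: SpectrumSet, config: PreprocessConfig | None = None) -> SpectrumSet:
    corrected = np.vstack(
        [baseline_correct(sp, config).absorbance for sp in sset]
    )
    return sset.with_absorbance(corrected)


# ------------------------------------------------------------ normalization

def normalize_max(
    spectrum: Spectrum,
    scope: str = "per-spectrum-global-max",
    region: tuple[float, float] | None = None,
) -> Spectrum:
    """Scale so the maximum over the configured scope equals 1 (shape preserved)."""
    if scope == "none":
        return spectrum
    if scope == "per-spectrum-region-max":
        if region is None:
            raise ValueError("region-max normalization needs a (lo, hi) region")
        lo, hi = region
        mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers < hi)
        if not mask.any():
            raise SpectraError(f"normalization region [{lo}, {hi}) misses the grid")
        peak = float(spectrum.absorbance[mask].max())
    elif scope == "per-spectrum-global-max":
        peak = float(spectrum.absorbance.max())
    else:
        raise ValueError(f"unknown normalization scope {scope!r}")
    if peak <= 0:
        raise SpectraError(
            f"spectrum {spectrum.sample_id!r}: nonpositive maximum {peak}; cannot normalize"
        )
    return Spectrum(
        spectrum.wavenumbers,
        spectrum.absorbance / peak,
        spectrum.sample_id,
        dict(spectrum.metadata),
    )


def normalize_set(
    sset: SpectrumSet,
    scope: str = "per-spectrum-region-max",
    region: tuple[float, float] | None = (800.0, 1800.0),
) -> SpectrumSet:
    rows = [normalize_max(sp, scope, region).absorbance for sp in sset]
    return sset.with_absorbance(np.vstack(rows))


# -------------------------------------------------------------- replicates

def aggregate_replicates(
    sset: SpectrumSet,
    policy: str = "average",
    group_key: str = "plant_id",
    condition_keys: tuple[str, ...] | None = None,
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Average technical replicates and tabulate pointwise dispersion.

    Replicates are grouped by ``group_key`` in the metadata.  With
    ``policy='average'`` the output has one spectrum per group (the pointwise
    mean, id = group label); ``'keep-all'`` passes spectra through unchanged.
    The dispersion table has one row per condition (``condition_keys``, or
    per group when absent) and one column per grid point, holding the
    pointwise sample standard deviation (ddof=1) across that condition's
    spectra; ``n_spectra`` is carried in the row index.
    """
    if group_key not in sset.metadata.columns:
        raise SpectraError(f"metadata lacks replicate group column {group_key!r}")
    groups = sset.metadata.groupby(group_key, sort=False).groups
    for label, idx in groups.items():
        if len(idx) == 0:
            raise SpectraError(f"replicate group {label!r} has zero members")

    id_pos = {sid: i for i, sid in enumerate(sset.sample_ids)}

    # dispersion per condition (pooled over that condition's spectra)
    if condition_keys is None:
        candidates = ("p_conc_uM", "n_conc_mM")
        condition_keys = tuple(k for k in candidates if k in sset.metadata.columns)
    if condition_keys:
        cond_groups = sset.metadata.groupby(list(condition_keys), sort=False).groups
        names = list(condition_keys)
    else:
        cond_groups = groups
        names = [group_key]
    sd_rows, index_rows = [], []
    for label, idx in cond_groups.items():
        rows = [id_pos[s] for s in idx]
        block = sset.absorbance[rows]
        sd = block.std(axis=0, ddof=1) if block.shape[0] > 1 else np.zeros(block.shape[1])
        key = label if isinstance(label, tuple) else (label,)
        sd_rows.append(sd)
        index_rows.append((*key, block.shape[0]))
    dispersion = pd.DataFrame(
        np.vstack(sd_rows),
        index=pd.MultiIndex.from_tuples(index_rows, names=[*names, "n_spectra"]),
        columns=sset.wavenumbers,
    )

    if policy == "keep-all":
        return sset, dispersion
    if policy != "average":
        raise ValueError("policy must be 'average' or 'keep-all'")

    ids, mat_rows, meta_rows = [], [], []
    for label, idx in groups.items():
        rows = [id_pos[s] for s in idx]
        mat_rows.append(sset.absorbance[rows].mean(axis=0))
        ids.append(str(label))
        meta = sset.metadata.loc[idx[0]].to_dict()
        meta.pop("technical_rep", None)
        meta_rows.append(meta)
    meta_df = pd.DataFrame(meta_rows, index=pd.Index(ids, name="sample_id"))
    return SpectrumSet(sset.wavenumbers, np.vstack(mat_rows), ids, meta_df), dispersion


# ----------------------------------------------------------------- pipeline

def run_preprocess(
    sset: SpectrumSet, config: PreprocessConfig | None = None
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Full preprocessing chain in the fixed order restrict -> baseline -> aggregate -> normalize."""
    cfg = config or PreprocessConfig()
    out = restrict_region(sset, *cfg.region)
    out = baseline_correct_set(out, cfg)
    if cfg.replicate_policy == "average" and cfg.replicate_key in out.metadata.columns:
        out, dispersion = aggregate_replicates(out, "average", cfg.replicate_key)
    else:
        out, dispersion = aggregate_replicates(
            out, "keep-all", cfg.replicate_key
        ) if cfg.replicate_key in out.metadata.columns else (out, pd.DataFrame())
    out = normalize_set(out, cfg.normalization_scope, cfg.normalization_region)
    out.metadata.attrs["provenance"] = [
        f"restrict[{cfg.region[0]},{cfg.region[1]})",
        f"baseline:{cfg.baseline_method}",
        f"aggregate:{cfg.replicate_policy}",
        f"normalize:{cfg.normalization_scope}",
    ]
    return out, dispersion
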