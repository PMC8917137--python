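"""Group comparisons and seasonal-trend summaries over quantified profiles.

Mirrors the field analyses: two-sample t-tests between sites or consecutive
timepoints (Welch by default, classical Student available), Holm-adjusted
consecutive-timepoint families, a rank-correlation test of the association
between the senescence-time Pi/Po ratio and second-year biomass, and
site x timepoint summary tables of signatures and predicted available P.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "AssociationResult",
    "StatsError",
    "compare_groups",
    "pairwise_timepoints",
    "ratio_biomass_association",
    "season_table",
    "TIMEPOINT_ORDER",
]

log = logging.getLogger(__name__)

TIMEPOINT_ORDER = ("T1", "T2", "T3", "T4", "T5")


class StatsError(ValueError):
    pass


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    variant: str = "welch"
    p_adjusted: float | None = None


@dataclass
class AssociationResult:
    coefficient: float
    p_value: float
    n: int
    method: str = "spearman"


def _clean(values, label: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise StatsError(f"group {label!r} needs >= 2 finite values, got {arr.size}")
    return arr


def compare_groups(
    values_a,
    values_b,
    variant: str = "welch",
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison:
    """Two-sample t-test (two-sided). ``variant='student'`` pools variances."""
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    a = _clean(values_a, label_a)
    b = _clean(values_b, label_b)
    if variant == "student" and a.var(ddof=1) + b.var(ddof=1) == 0.0:
        if np.allclose(a.mean(), b.mean()):
            # identical constant samples: no evidence of a difference
            return GroupComparison(
                label_a, label_b, 0.0, 1.0, float(a.mean()), float(b.mean()),
                a.size, b.size, variant,
            )
        raise StatsError("zero pooled variance with unequal means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return GroupComparison(
        label_a,
        label_b,
        float(res.statistic),
        float(res.pvalue),
        float(a.mean()),
        float(b.mean()),
        int(a.size),
        int(b.size),
        variant,
    )


def pairwise_timepoints(
    profiles: pd.DataFrame,
    signature: str,
    site: str | None = None,
    variant: str = "welch",
    adjust: str = "holm",
    timepoint_col: str = "timepoint",
) -> list[GroupComparison]:
    """Consecutive-timepoint comparisons (T1-T2 ... T4-T5), multiplicity adjusted.

    ``profiles`` must carry ``timepoint`` (and ``site`` when filtering) plus
    the signature column.  Timepoints with fewer than two plants are skipped
    with a log entry; the Holm adjustment runs across the family actually
    compared.
    """
    df = profiles if site is None else profiles[profiles["site"] == site]
    if signature not in df.columns:
        raise StatsError(f"profiles lack signature column {signature!r}")
    present = [
        t for t in TIMEPOINT_ORDER
        if (df[timepoint_col] == t).sum() >= 2
    ]
    skipped = [t for t in TIMEPOINT_ORDER if t not in present]
    for t in skipped:
        log.warning("timepoint %s missing or underpopulated; skipped", t)
    if len(present) < 2:
        raise StatsError("need >= 2 populated timepoints for pairwise comparisons")
    comparisons = []
    for t1, t2 in zip(present[:-1], present[1:]):
        comparisons.append(
            compare_groups(
                df.loc[df[timepoint_col] == t1, signature],
                df.loc[df[timepoint_col] == t2, signature],
                variant=variant,
                label_a=t1,
                label_b=t2,
            )
        )
    if adjust != "none" and comparisons:
        _, p_adj, _, _ = multipletests(
            [c.p_value for c in comparisons], method=adjust
        )
        for c, p in zip(comparisons, p_adj):
            c.p_adjusted = float(p)
    return comparisons


def ratio_biomass_association(
    t5_ratios, biomass, method: str = "spearman"
) -> AssociationResult:
    """Rank correlation between the senescence Pi/Po ratio and second-year biomass."""
    r = np.asarray(t5_ratios, dtype=float)
    b = np.asarray(biomass, dtype=float)
    if r.shape != b.shape:
        raise StatsError(f"unpaired inputs: {r.shape} vs {b.shape}")
    keep = np.isfinite(r) & np.isfinite(b)
    r, b = r[keep], b[keep]
    if r.size < 3:
        raise StatsError(f"need >= 3 paired observations, got {r.size}")
    if np.all(r == r[0]) or np.all(b == b[0]):
        raise StatsError("constant input: rank correlation undefined")
    if method != "spearman":
        raise ValueError("only the spearman association is implemented")
    res = stats.spearmanr(r, b)
    return AssociationResult(float(res.statistic), float(res.pvalue), int(r.size))


def season_table(
    profiles: pd.DataFrame,
    predictions: pd.Series | None = None,
    signatures: Sequence[str] = ("Pi", "Po", "cellulose", "lignin", "amide", "lipid", "cl_ratio"),
) -> pd.DataFrame:
    """Site x timepoint summary of signature means/SDs and predicted available P.

    ``predictions`` (indexed by sample_id, original units) is merged on the
    profiles' ``sample_id``; a key mismatch raises with the offending ids.
    With no predictions the table carries profile columns only and is flagged
    via ``table.attrs['has_predictions']``.
    """
    for col in ("site", "timepoint"):
        if col not in profiles.columns:
            raise StatsError(f"profiles lack required column {col!r}")
    df = profiles.copy()
    has_pred = predictions is not None and len(predictions) > 0
    if has_pred:
        if "sample_id" not in df.columns:
            raise StatsError("profiles lack 'sample_id'; cannot merge predictions")
        missing = sorted(set(df["sample_id"]) - set(predictions.index))
        if missing:
            raise StatsError(
                f"predictions missing for {len(missing)} samples, e.g. {missing[:5]}"
            )
        df["predicted_available_P"] = df["sample_id"].map(predictions)
    present = [s for s in signatures if s in df.columns]
    agg_cols = present + (["predicted_available_P"] if has_pred else [])
    grouped = df.groupby(["site", "timepoint"], sort=True)[agg_cols]
    table = grouped.agg(["mean", "std", "count"])
    table.columns = [f"{sig}_{stat}" for sig, stat in table.columns]
    table = table.reset_index()
    table["timepoint"] = pd.Categorical(
        table["timepoint"], categories=TIMEPOINT_ORDER, ordered=True
    )
    table = table.sort_values(["site", "timepoint"]).reset_index(drop=True)
    table.attrs["has_predictions"] = bool(has_pred)
    return table
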