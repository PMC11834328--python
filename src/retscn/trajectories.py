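"""Age-trajectory regressions, correlation comparisons and group-mean tests.

For every layer x region (a sector, or an inner/outer ring average) and each
group, thickness is regressed on age by ordinary least squares; the age
association is summarised by the Pearson correlation r with its two-sided
p-value (t distribution, n-2 df).  The groups' age associations are compared
with Fisher's r-to-z transform,

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)),

two-sided p from the standard normal, and the family of comparisons is
corrected with the Benjamini-Hochberg step-up FDR procedure.  Group mean
thickness is compared with a two-sample t-test (Welch by default).

A direct slope-difference test (normal theory on b1-b2 with the OLS standard
errors) is available as a sensitivity analysis, since comparing correlations
and comparing slopes are not the same contrast when the groups' variances
differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    PRIMARY_LAYERS,
    CohortTable,
    Group,
    Layer,
    region_value,
)

#: Default analysis regions: the central subfield and the two ring averages.
DEFAULT_REGIONS: tuple[str, ...] = ("C", "Avg_I", "Avg_O")

#: Default analysis layers: the 7 primaries plus the 3 composites.
DEFAULT_LAYERS: tuple[Layer, ...] = PRIMARY_LAYERS + (Layer.IR, Layer.OR, Layer.TRT)


@dataclass
class RegressionResult:
    group: Group
    layer: Layer
    region: str
    slope: float
    intercept: float
    r: float
    p: float
    n: int
    stderr: float = np.nan


@dataclass
class SlopeComparison:
    layer: Layer
    region: str
    r_hc: float
    n_hc: int
    r_dwor: float
    n_dwor: int
    z: float
    p: float
    q: float = np.nan


@dataclass
class GroupMeanComparison:
    layer: Layer
    region: str
    mean_hc: float
    sd_hc: float
    n_hc: int
    mean_dwor: float
    sd_dwor: float
    n_dwor: int
    t: float
    p: float


def _region_values(
    cohort: CohortTable, group: Group, layer: Layer, region: str, scheme=None
) -> np.ndarray:
    sub = cohort.subset(group)
    return np.array([region_value(r, layer, region, scheme) for r in sub.records])


def fit_age_regression(
    cohort: CohortTable,
    group: Group,
    layer: Layer,
    region: str,
    scheme: Mapping | None = None,
) -> RegressionResult:
    """OLS of thickness on age (intercept included) within one group."""
    sub = cohort.subset(group)
    n = len(sub)
    if n < 4:
        raise ValueError(f"group {group.value} has {n} eyes; at least 4 required")
    ages = sub.ages()
    values = _region_values(cohort, group, layer, region, scheme)
    if np.ptp(ages) == 0:
        raise ValueError("zero age variance; regression undefined")
    if np.ptp(values) == 0:
        warnings.warn(
            f"{layer.value}_{region} has zero thickness variance in "
            f"{group.value}; reporting r=0",
            stacklevel=2,
        )
        return RegressionResult(
            group, layer, region, 0.0, float(values[0]), 0.0, 1.0, n, 0.0
        )
    fit = stats.linregress(ages, values)
    return RegressionResult(
        group=group,
        layer=layer,
        region=region,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        n=n,
        stderr=float(fit.stderr),
    )


def fisher_r_to_z(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """z-test for the difference of two independent Pearson correlations."""
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError(f"|r| must be < 1 for the Fisher transform, got {r}")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError(f"need n > 3 per group, got {n}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def slope_difference_test(
    fit1: RegressionResult, fit2: RegressionResult
) -> tuple[float, float]:
    """Normal-theory test on b1 - b2 with the OLS slope standard errors."""
    z = (fit1.slope - fit2.slope) / np.hypot(fit1.stderr, fit2.stderr)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def compare_group_means(
    cohort: CohortTable,
    layer: Layer,
    region: str,
    scheme: Mapping | None = None,
    variant: str = "welch",
) -> GroupMeanComparison:
    """Two-sample t-test on per-eye thickness in one layer x region."""
    vals = {
        g: _region_values(cohort, g, layer, region, scheme) for g in Group
    }
    for g, v in vals.items():
        if len(v) < 2:
            raise ValueError(f"group {g.value} has {len(v)} eyes; at least 2 required")
    a, b = vals[Group.HC], vals[Group.DWOR]
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
        t, p = float(t), float(p)
    return GroupMeanComparison(
        layer=layer,
        region=region,
        mean_hc=float(a.mean()),
        sd_hc=float(a.std(ddof=1)),
        n_hc=len(a),
        mean_dwor=float(b.mean()),
        sd_dwor=float(b.std(ddof=1)),
        n_dwor=len(b),
        t=t,
        p=p,
    )


def trajectory_report(
    cohort: CohortTable,
    layers: Sequence[Layer] = DEFAULT_LAYERS,
    regions: Sequence[str] = DEFAULT_REGIONS,
    scheme: Mapping | None = None,
) -> pd.DataFrame:
    """Full per-(layer, region) trajectory table.

    One row per layer x region with both groups' regression summaries, the
    between-group Fisher z and p, and the BH-adjusted q over the whole table
    (the default FDR family is every comparison in the report).
    """
    rows = []
    for layer in layers:
        for region in regions:
            fit_hc = fit_age_regression(cohort, Group.HC, layer, region, scheme)
            fit_dw = fit_age_regression(cohort, Group.DWOR, layer, region, scheme)
            z, p = fisher_r_to_z(fit_hc.r, fit_hc.n, fit_dw.r, fit_dw.n)
            rows.append(
                {
                    "layer": layer.value,
                    "region": region,
                    "slope_hc": fit_hc.slope,
                    "intercept_hc": fit_hc.intercept,
                    "r_hc": fit_hc.r,
                    "p_hc": fit_hc.p,
                    "n_hc": fit_hc.n,
                    "slope_dwor": fit_dw.slope,
                    "intercept_dwor": fit_dw.intercept,
                    "r_dwor": fit_dw.r,
                    "p_dwor": fit_dw.p,
                    "n_dwor": fit_dw.n,
                    "z": z,
                    "p": p,
                }
            )
    df = pd.DataFrame(rows)
    df["q"] = fdr_adjust(df["p"].to_numpy())
    return df


def group_means_report(
    cohort: CohortTable,
    layers: Sequence[Layer] = DEFAULT_LAYERS,
    regions: Sequence[str] = DEFAULT_REGIONS,
    scheme: Mapping | None = None,
    variant: str = "welch",
) -> pd.DataFrame:
    """Group mean +/- SD and t-test per layer x region."""
    rows = []
    for layer in layers:
        for region in regions:
            c = compare_group_means(cohort, layer, region, scheme, variant)
            rows.append(
                {
                    "layer": layer.value,
                    "region": region,
                    "mean_hc": c.mean_hc,
                    "sd_hc": c.sd_hc,
                    "mean_dwor": c.mean_dwor,
                    "sd_dwor": c.sd_dwor,
                    "t": c.t,
                    "p": c.p,
                }
            )
    return pd.DataFrame(rows)
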