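"""Normalized T1 error statistics across vendors and field strengths.

Measured T1 values span two orders of magnitude across the sphere array, so
all comparisons run on the normalized percent error

    dT1 = 100 * (T1 - T1_NMR) / T1_NMR,

where T1_NMR is the NMR-traceable reference value of the sphere.  Errors are
grouped by scanner vendor and static field strength; a two-way fixed-effects
ANOVA tests the vendor x field interaction, and when the fields are analyzed
separately (simple main effects) each sphere gets a one-way ANOVA across
vendors followed by Tukey-Kramer honestly-significant-difference pairwise
comparisons (valid for unequal group sizes).  ``propagate_bias`` carries a
vendor's bias and dispersion onto a clinical tissue T1 range to show the
span of values that vendor would report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BiasRecord",
    "StatResult",
    "normalized_error",
    "records_frame",
    "group_summary",
    "two_way_anova",
    "per_sphere_pairwise",
    "propagate_bias",
]

ALPHA = 0.05


def normalized_error(t1_measured_ms, t1_nmr_ms):
    """Percent deviation of measured T1 from the NMR reference value."""
    t1_nmr = np.asarray(t1_nmr_ms, dtype=float)
    if np.any(t1_nmr <= 0):
        raise ValueError("reference T1 must be positive")
    return 100.0 * (np.asarray(t1_measured_ms, dtype=float) - t1_nmr) / t1_nmr


@dataclass(frozen=True)
class BiasRecord:
    """One measured sphere: normalized error plus grouping labels."""

    sphere_index: int  # 1..14
    t1_measured_ms: float
    t1_nmr_ms: float
    vendor: str
    field_tesla: float
    modality: str  # "IR" | "VFA"
    system_index: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.sphere_index <= 14:
            raise ValueError("sphere_index must be in 1..14")
        if self.t1_nmr_ms <= 0:
            raise ValueError("reference T1 must be positive")

    @property
    def normalized_error_pct(self) -> float:
        return float(normalized_error(self.t1_measured_ms, self.t1_nmr_ms))


def records_frame(records: Sequence[BiasRecord] | pd.DataFrame) -> pd.DataFrame:
    """Normalize a record sequence (or pass through a DataFrame) to a table."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "normalized_error_pct" not in df:
            df["normalized_error_pct"] = normalized_error(
                df["t1_measured_ms"], df["t1_nmr_ms"]
            )
        return df
    rows = [{
        "sphere_index": r.sphere_index,
        "t1_measured_ms": r.t1_measured_ms,
        "t1_nmr_ms": r.t1_nmr_ms,
        "vendor": r.vendor,
        "field_tesla": r.field_tesla,
        "modality": r.modality,
        "system_index": r.system_index,
        "normalized_error_pct": r.normalized_error_pct,
    } for r in records]
    return pd.DataFrame(rows)


@dataclass
class StatResult:
    """Per-sphere ANOVA and Tukey-Kramer pairwise comparisons at one field."""

    anova_p: pd.Series  # per-sphere one-way ANOVA p across vendors
    pairwise: pd.DataFrame  # sphere, t1_nmr_ms, group1, group2, meandiff, p_adj, reject
    group_means: pd.DataFrame  # per sphere x vendor mean and 95% CI
    field_tesla: float | None = None
    modality: str | None = None
    interaction_p: float | None = None

    def pairwise_table(self) -> pd.DataFrame:
        """Pivot pairwise p-values into a spheres x vendor-pair table."""
        t = self.pairwise.copy()
        t["pair"] = t["group1"].astype(str) + " v. " + t["group2"].astype(str)
        return t.pivot(index="t1_nmr_ms", columns="pair", values="p_adj").sort_index(
            ascending=False
        )


def group_summary(
    records,
    group_by: str = "vendor",
    value: str = "normalized_error_pct",
) -> pd.DataFrame:
    """Per-sphere per-group mean with a Student-t 95% confidence interval.

    Singleton groups report their mean with NaN CI bounds and are flagged in
    the ``singleton`` column.
    """
    df = records_frame(records)
    out = []
    for (sphere, grp), sub in df.groupby(["sphere_index", group_by], sort=True):
        v = sub[value].to_numpy(dtype=float)
        n = v.size
        mean = v.mean()
        if n >= 2:
            half = sps.t.ppf(1 - ALPHA / 2, n - 1) * v.std(ddof=1) / np.sqrt(n)
            lo, hi = mean - half, mean + half
        else:
            lo = hi = np.nan
        out.append({
            "sphere_index": sphere,
            "t1_nmr_ms": sub["t1_nmr_ms"].iloc[0],
            group_by: grp,
            "n": n,
            "mean": mean,
            "ci_low": lo,
            "ci_high": hi,
            "singleton": n < 2,
        })
    return pd.DataFrame(out)


def two_way_anova(records, typ: int = 3):
    """Fixed-effects two-way ANOVA of normalized error on vendor and field.

    Uses sum-to-zero contrasts with Type III (marginal) sums of squares by
    default, which handles unbalanced designs; Type II is available via
    ``typ=2``.  Returns ``(interaction_p, anova_table)``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = records_frame(records)
    for factor in ("vendor", "field_tesla"):
        if df[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs at least 2 levels")
    model = smf.ols(
        "normalized_error_pct ~ C(vendor, Sum) * C(field_tesla, Sum)", data=df
    ).fit()
    table = sm.stats.anova_lm(model, typ=typ)
    inter = [i for i in table.index if ":" in i][0]
    return float(table.loc[inter, "PR(>F)"]), table


def per_sphere_pairwise(records, field_tesla: float, modality: str) -> StatResult:
    """Simple-main-effects analysis at one field strength and modality.

    For each sphere individually: one-way ANOVA of normalized error across
    vendors, then all pairwise vendor comparisons with the Tukey-Kramer HSD
    adjustment (unequal group sizes allowed).  Spheres observed by fewer
    than two vendors are skipped with a warning.
    """
    import warnings

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = records_frame(records)
    df = df[(df["field_tesla"] == field_tesla) & (df["modality"] == modality)]
    if df.empty:
        raise ValueError("no records at the requested field and modality")
    if df["vendor"].nunique() < 2:
        raise ValueError("pairwise comparison requires at least 2 vendors")

    anova_p = {}
    pairwise_rows = []
    for sphere, sub in df.groupby("sphere_index"):
        counts = sub.groupby("vendor").size()
        vendors = counts[counts >= 2].index
        if len(vendors) < 2:
            warnings.warn(f"sphere {sphere}: fewer than 2 vendor groups, skipped")
            continue
        sub = sub[sub["vendor"].isin(vendors)]
        groups = [g["normalized_error_pct"].to_numpy() for _, g in sub.groupby("vendor")]
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            # all observations identical: no variance anywhere, nothing to test
            anova_p[sphere] = 1.0
            for i, v1 in enumerate(vendors):
                for v2 in vendors[i + 1:]:
                    pairwise_rows.append({
                        "sphere_index": sphere,
                        "t1_nmr_ms": sub["t1_nmr_ms"].iloc[0],
                        "group1": v1, "group2": v2,
                        "meandiff": 0.0, "p_adj": 1.0,
                        "ci_low": 0.0, "ci_high": 0.0, "reject": False,
                    })
            continue
        f, p = sps.f_oneway(*groups)
        anova_p[sphere] = float(p)
        hsd = pairwise_tukeyhsd(
            sub["normalized_error_pct"].to_numpy(), sub["vendor"].to_numpy(), alpha=ALPHA
        )
        from itertools import combinations

        pairs = list(combinations(hsd.groupsunique, 2))
        for (g1, g2), md, p, (lo, hi), rej in zip(
            pairs, hsd.meandiffs, hsd.pvalues, hsd.confint, hsd.reject
        ):
            pairwise_rows.append({
                "sphere_index": sphere,
                "t1_nmr_ms": sub["t1_nmr_ms"].iloc[0],
                "group1": g1,
                "group2": g2,
                "meandiff": float(md),
                "p_adj": float(p),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "reject": bool(rej),
            })

    columns = ["sphere_index", "t1_nmr_ms", "group1", "group2",
               "meandiff", "p_adj", "ci_low", "ci_high", "reject"]
    return StatResult(
        anova_p=pd.Series(anova_p, name="anova_p", dtype=float).rename_axis("sphere_index"),
        pairwise=pd.DataFrame(pairwise_rows, columns=columns),
        group_means=group_summary(df),
        field_tesla=field_tesla,
        modality=modality,
    )


def propagate_bias(
    tissue_mean_ms: float,
    tissue_sd_ms: float,
    bias_pct: float,
    dispersion_pct: float,
) -> tuple[float, float]:
    """Expected measured T1 range for a tissue under a given bias/dispersion.

    Applies the vendor's relative bias +/- dispersion multiplicatively to the
    tissue range [mean - sd, mean + sd], returning the widest interval
    consistent with the stated figures:

        [ (1 + (bias - disp)/100) (mean - sd),
          (1 + (bias + disp)/100) (mean + sd) ].
    """
    if tissue_mean_ms <= 0:
        raise ValueError("tissue mean T1 must be positive")
    if dispersion_pct < 0:
        raise ValueError("dispersion must be nonnegative")
    lo = (1.0 + (bias_pct - dispersion_pct) / 100.0) * (tissue_mean_ms - tissue_sd_ms)
    hi = (1.0 + (bias_pct + dispersion_pct) / 100.0) * (tissue_mean_ms + tissue_sd_ms)
    return float(lo), float(hi)


def plot_bias_profile(summary: pd.DataFrame, ax=None, group_by: str = "vendor"):
    """Bias-versus-T1 profile: per-vendor mean normalized error with 95% CI
    bars against reference T1 on a log axis."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for grp, sub in summary.groupby(group_by):
        sub = sub.sort_values("t1_nmr_ms")
        err = np.vstack([
            sub["mean"] - sub["ci_low"], sub["ci_high"] - sub["mean"]
        ])
        ax.errorbar(sub["t1_nmr_ms"], sub["mean"], yerr=err, fmt="o-",
                    capsize=3, label=str(grp))
    ax.set_xscale("log")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("reference T1 (ms)")
    ax.set_ylabel("normalized error (%)")
    ax.legend(title=group_by)
    return ax
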