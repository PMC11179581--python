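"""Robust outlier removal (ROUT) and group-comparison wrappers.

Per-worm metric columns routinely contain gross outliers (clumped worms,
debris, mis-gated events). ROUT combines a robust fit — here the one-sample
case, a robust location — with a robust residual scale (RSDR) and an
FDR-controlled decision about which extreme points to call outliers, at a
user-set maximum false-discovery rate Q (default 1%).

The group comparisons mirror the contracts used downstream of outlier removal:
Welch's unpaired t test, and one-way ANOVA followed by Šidák- or
Dunnett-adjusted pairwise contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RoutConfig",
    "RoutResult",
    "TestResult",
    "rout_clean",
    "compare_two",
    "anova_with_adjustment",
    "sidak_adjust",
]


@dataclass(frozen=True)
class RoutConfig:
    """ROUT settings: Q is the maximum desired FDR of outlier calls."""

    q: float = 0.01
    max_iter: int = 100
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 0.5:
            raise ValueError("Q must be in (0, 0.5)")


@dataclass
class RoutResult:
    kept: np.ndarray
    removed: list[tuple[float, float]]  # (value, BH-adjusted p)
    center: float
    rsdr: float
    small_n: bool = False  # True when n < 10 and no removal was attempted

    @property
    def n_removed(self) -> int:
        return len(self.removed)


_TUKEY_C = 4.685  # redescending biweight tuning constant (95% Gaussian efficiency)
_ROUT_MIN_N = 10


def _robust_location(x: np.ndarray, max_iter: int, tol: float) -> float:
    """Iteratively reweighted location with Tukey's biweight, from the median."""
    center = float(np.median(x))
    scale = 1.4826 * float(np.median(np.abs(x - center)))
    if scale == 0:
        return center
    for _ in range(max_iter):
        u = (x - center) / (_TUKEY_C * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            break
        new_center = float(np.sum(w * x) / w.sum())
        resid = x - new_center
        mad = float(np.median(np.abs(resid)))
        if mad > 0:
            scale = 1.4826 * mad
        if abs(new_center - center) <= tol * max(1.0, abs(center)):
            center = new_center
            break
        center = new_center
    return center


def rout_clean(values: Sequence[float], config: RoutConfig = RoutConfig()) -> RoutResult:
    """Partition values into kept inliers and FDR-flagged outliers.

    Procedure: (1) robust location by iteratively reweighted estimation with a
    redescending (Tukey biweight) weight function, initialized at the median;
    (2) RSDR as the 68.27th percentile of absolute residuals scaled by
    N/(N-1); (3) a two-tailed p per point from t = residual / RSDR with N-1
    degrees of freedom; (4) outliers flagged by the Benjamini-Hochberg step-up
    procedure at rate Q, so the largest residuals are tested first. Below
    n = 10 no removal is attempted and ``small_n`` is set.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    if x.size < _ROUT_MIN_N:
        return RoutResult(kept=x, removed=[], center=float(np.median(x)),
                          rsdr=0.0, small_n=True)

    center = _robust_location(x, config.max_iter, config.tol)
    resid = x - center
    n = x.size
    rsdr = float(np.percentile(np.abs(resid), 68.27)) * n / (n - 1)
    if rsdr == 0:
        return RoutResult(kept=x, removed=[], center=center, rsdr=0.0)

    t = np.abs(resid) / rsdr
    p = 2.0 * stats.t.sf(t, df=n - 1)
    order = np.argsort(p)  # ascending p == descending |residual|
    adj = np.empty(n)
    # BH step-up: adjusted p, monotone from the largest p downwards
    running = 1.0
    for rank in range(n - 1, -1, -1):
        val = p[order[rank]] * n / (rank + 1)
        running = min(running, val)
        adj[order[rank]] = running
    flag = adj <= config.q
    removed = [(float(x[i]), float(adj[i])) for i in np.flatnonzero(flag)]
    return RoutResult(kept=x[~flag], removed=removed, center=center, rsdr=rsdr)


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class TestResult:
    comparison: str
    statistic: float
    p: float
    adjusted_p: float
    method: str
    mean_diff: float
    ci95: tuple[float, float]

    def as_row(self) -> dict:
        return {
            "comparison": self.comparison,
            "method": self.method,
            "statistic": self.statistic,
            "p": self.p,
            "adjusted_p": self.adjusted_p,
            "mean_diff": self.mean_diff,
            "ci95_lo": self.ci95[0],
            "ci95_hi": self.ci95[1],
        }


def compare_two(a: Sequence[float], b: Sequence[float], label: str = "a vs b") -> TestResult:
    """Welch's unpaired two-sample t test with the 95% CI of the mean difference."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(0.95)
    return TestResult(
        comparison=label,
        statistic=float(res.statistic),
        p=float(res.pvalue),
        adjusted_p=float(res.pvalue),
        method="t_unpaired",
        mean_diff=float(a.mean() - b.mean()),
        ci95=(float(ci.low), float(ci.high)),
    )


def sidak_adjust(p: float, m: int) -> float:
    """Šidák family-wise adjustment for m planned contrasts: 1 - (1-p)^m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


def anova_with_adjustment(
    groups: Sequence[tuple[str, Sequence[float]]],
    contrasts: Sequence[tuple[str, str]] | None = None,
    method: str = "sidak",
    control: str | None = None,
) -> list[TestResult]:
    """One-way ANOVA followed by multiplicity-adjusted pairwise contrasts.

    ``method="sidak"``: pooled-variance t per planned contrast, Šidák-adjusted
    over the m contrasts; CIs at the Šidák-adjusted per-comparison confidence.
    ``method="dunnett"``: many-to-one comparisons against ``control`` with
    p-values from the multivariate-t distribution (scipy's implementation);
    the contrast list is ignored (all groups vs control).
    """
    data = {label: np.asarray(list(vals), dtype=float) for label, vals in groups}
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    for label, vals in data.items():
        if vals.size < 2:
            raise ValueError(f"group {label!r} needs at least 2 values")

    if method == "dunnett":
        if control is None or control not in data:
            raise ValueError("dunnett requires a designated control group")
        others = [lab for lab in data if lab != control]
        res = stats.dunnett(*[data[lab] for lab in others], control=data[control])
        ci = res.confidence_interval(0.95)
        out = []
        for i, lab in enumerate(others):
            diff = float(data[lab].mean() - data[control].mean())
            out.append(
                TestResult(
                    comparison=f"{lab} vs {control}",
                    statistic=float(res.statistic[i]),
                    p=float(res.pvalue[i]),
                    adjusted_p=float(res.pvalue[i]),  # already family-wise
                    method="anova_dunnett",
                    mean_diff=diff,
                    ci95=(float(ci.low[i]), float(ci.high[i])),
                )
            )
        return out

    if method != "sidak":
        raise ValueError(f"unknown adjustment method {method!r}")
    if not contrasts:
        raise ValueError("sidak requires an explicit list of planned contrasts")
    for pair in contrasts:
        for lab in pair:
            if lab not in data:
                raise ValueError(f"contrast references unknown group {lab!r}")

    # pooled within-group variance over all groups (classical one-way decomposition)
    n_total = sum(v.size for v in data.values())
    k = len(data)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_within = n_total - k
    ms_within = ss_within / df_within
    m = len(contrasts)
    alpha_pc = 1.0 - (1.0 - 0.05) ** (1.0 / m)  # Šidák per-comparison alpha
    tcrit = stats.t.ppf(1.0 - alpha_pc / 2.0, df_within)

    out = []
    for lab_a, lab_b in contrasts:
        a, b = data[lab_a], data[lab_b]
        se = math.sqrt(ms_within * (1.0 / a.size + 1.0 / b.size))
        diff = float(a.mean() - b.mean())
        tstat = diff / se if se > 0 else 0.0
        p = float(2.0 * stats.t.sf(abs(tstat), df_within))
        out.append(
            TestResult(
                comparison=f"{lab_a} vs {lab_b}",
                statistic=float(tstat),
                p=p,
                adjusted_p=min(1.0, sidak_adjust(p, m)),
                method="anova_sidak",
                mean_diff=diff,
                ci95=(diff - tcrit * se, diff + tcrit * se),
            )
        )
    return out
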