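"""Nested limits of agreement with MOVER confidence bounds.

The agreement between a reduced sampling design and the full design is
summarized Bland-Altman style on the paired differences

    d_ij = full-design value - reduced-design value

for plot i (the nesting subject) and sampling event j (the replicate
within plot). The nested model

    d_ij = mu + b_i + e_ij,   b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_e^2)

partitions the difference variance into a between-plot and a within-plot
(event-to-event) component, so repeated events on the same plot are not
treated as independent plots. The limits of agreement are

    mu +/- z * sqrt(sigma_b^2 + sigma_e^2)

with z the standard-normal quantile for the chosen agreement proportion.
Uncertainty in the limits themselves is expressed through MOVER bounds
("method of variance estimates recovery"): a confidence bound for the
mean is combined with a modified-large-sample (MLS) chi-square bound for
the variance components, and the two are composed by the MOVER
square-root rule. The outer bounds are one-sided at the analysis level:
the upper MOVER bound exceeds the true upper limit with probability equal
to the level (certified by Monte-Carlo coverage in the test suite).

Estimation is one-way random-effects ANOVA on the (possibly unbalanced)
plot means: the bias is the unweighted mean of plot means (plots are the
inferential subjects and are equally weighted under imbalance); the
within-plot variance is the pooled residual variance; the between-plot
component is recovered from the variance of plot means and truncated at
zero. With a single difference per plot the model degrades gracefully to
the classical unreplicated Bland-Altman limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .indicators import IndicatorSet, indicator_family


class InsufficientSubjectsError(ValueError):
    """Fewer than two plots: the nested analysis is not identified."""


@dataclass(frozen=True)
class AcceptanceCriteria:
    """Acceptable-difference rules for a reduced design.

    A design is acceptable for an indicator when (1) the bias confidence
    interval contains zero and (2) the MOVER outer bounds lie within the
    family threshold of the bias: 5 percentage points for cover and the
    gap classes, 5 cm for height, 2 species for the species count. The
    defaults match standard field-crew calibration limits.
    """

    max_halfwidth: dict[str, float] = field(
        default_factory=lambda: {"cover": 5.0, "gap": 5.0, "height": 5.0, "species": 2.0}
    )
    require_unbiased: bool = True

    def threshold(self, indicator: str) -> float:
        family = indicator_family(indicator)
        try:
            return self.max_halfwidth[family]
        except KeyError:
            raise KeyError(f"no threshold configured for family {family!r}") from None


class NestedLoA:
    """Nested limits-of-agreement model for plot-nested difference samples.

    Parameters
    ----------
    d : array_like
        Differences (full-design minus reduced-design indicator values).
    groups : array_like
        Plot identifier for each difference; events within a plot are the
        nested replicates.

    Examples
    --------
    >>> model = NestedLoA([1, 3, -1, 1, 0, 2], ["A", "A", "B", "B", "C", "C"])
    >>> res = model.fit(level=0.95)
    >>> round(res.bias, 6)
    1.0
    """

    def __init__(self, d, groups):
        d = np.asarray(d, dtype=float)
        groups = np.asarray(groups)
        if d.shape != groups.shape:
            raise ValueError("d and groups must have the same length")
        if d.size == 0:
            raise InsufficientSubjectsError("no differences supplied")
        if not np.all(np.isfinite(d)):
            raise ValueError("differences must be finite")
        order = np.argsort(groups, kind="stable")
        self.d = d[order]
        self.groups = groups[order]
        self.group_labels, self.n_i = np.unique(self.groups, return_counts=True)
        self.k = len(self.group_labels)
        self.N = d.size
        if self.k < 2:
            raise InsufficientSubjectsError(
                f"nested LoA needs >= 2 plots, got {self.k}"
            )

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, value_col: str = "d", group_col: str = "plot_id"
    ) -> "NestedLoA":
        return cls(data[value_col].to_numpy(), data[group_col].to_numpy())

    def fit(self, level: float = 0.95) -> "NestedLoAResults":
        """Estimate bias, variance components, limits and MOVER bounds.

        ``level`` is used both as the agreement proportion (the share of
        differences the limits are meant to contain) and as the
        confidence level of the bias CI and MOVER bounds.
        """
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        k, N = self.k, self.N
        means = np.array(
            [self.d[self.groups == g].mean() for g in self.group_labels]
        )
        bias = means.mean()
        sm2 = means.var(ddof=1)  # variance of plot means, df k-1
        sse = float(
            sum(
                ((self.d[self.groups == g] - m) ** 2).sum()
                for g, m in zip(self.group_labels, means)
            )
        )
        if N > k:
            sigma_e2 = sse / (N - k)
            c = float((1.0 / self.n_i).sum()) / k  # E[sm2] = sigma_b2 + c*sigma_e2
            sigma_b2 = max(0.0, sm2 - c * sigma_e2)
            sigma2 = sigma_b2 + sigma_e2
            # MLS components for the total-variance bound: the plot-mean
            # variance (df k-1) carries sigma_b2 + c*sigma_e2; the residual
            # (df N-k) supplies the remaining (1-c) share of sigma_e2.
            if sigma_b2 > 0:
                components = [(1.0, sm2, k - 1), (1.0 - c, sigma_e2, N - k)]
            else:
                components = [(1.0, sigma_e2, N - k)]
        else:
            # one difference per plot: classical unreplicated Bland-Altman
            sigma_e2 = 0.0
            sigma_b2 = sm2
            sigma2 = sm2
            components = [(1.0, sm2, k - 1)]

        sigma = float(np.sqrt(sigma2))
        z = float(stats.norm.ppf((1 + level) / 2))
        halfwidth = z * sigma

        se_bias = float(np.sqrt(sm2 / k))
        t_two = float(stats.t.ppf((1 + level) / 2, k - 1))
        bias_ci = (bias - t_two * se_bias, bias + t_two * se_bias)

        # One-sided component bounds at the analysis level, MOVER-composed
        # around each limit.
        t_one = float(stats.t.ppf(level, k - 1))
        up = np.sqrt(
            sum(
                (a * G * (df / stats.chi2.ppf(1 - level, df) - 1)) ** 2
                for a, G, df in components
                if df > 0 and G > 0
            )
        )
        lo = np.sqrt(
            sum(
                (a * G * (1 - df / stats.chi2.ppf(level, df))) ** 2
                for a, G, df in components
                if df > 0 and G > 0
            )
        )
        sigma_up = max(float(np.sqrt(sigma2 + up)), sigma)
        sigma_lo = min(float(np.sqrt(max(sigma2 - lo, 0.0))), sigma)

        limit_lo = bias - halfwidth
        limit_hi = bias + halfwidth
        mover_hi = limit_hi + float(
            np.sqrt((t_one * se_bias) ** 2 + (z * (sigma_up - sigma)) ** 2)
        )
        mover_lo = limit_lo - float(
            np.sqrt((t_one * se_bias) ** 2 + (z * (sigma - sigma_lo)) ** 2)
        )

        return NestedLoAResults(
            model=self,
            level=level,
            bias=float(bias),
            bias_se=se_bias,
            bias_ci=bias_ci,
            sigma_b2=float(sigma_b2),
            sigma_e2=float(sigma_e2),
            sigma=sigma,
            agree_halfwidth=float(halfwidth),
            limit_lo=float(limit_lo),
            limit_hi=float(limit_hi),
            mover_lo=float(mover_lo),
            mover_hi=float(mover_hi),
            k=k,
            N=N,
        )


@dataclass
class NestedLoAResults:
    """Fitted nested limits of agreement for one indicator/design pair."""

    model: NestedLoA
    level: float
    bias: float
    bias_se: float
    bias_ci: tuple[float, float]
    sigma_b2: float
    sigma_e2: float
    sigma: float
    agree_halfwidth: float
    limit_lo: float
    limit_hi: float
    mover_lo: float
    mover_hi: float
    k: int
    N: int

    def evaluate(self, indicator: str, criteria: AcceptanceCriteria | None = None) -> dict:
        """Pass flags against the acceptable-difference criteria."""
        criteria = criteria or AcceptanceCriteria()
        return evaluate_criteria(self, indicator, criteria)

    def summary(self) -> str:
        lines = [
            "Nested limits of agreement",
            "=" * 54,
            f"plots (k): {self.k:>6d}    differences (N): {self.N:>6d}",
            f"level:     {self.level:>6.2f}",
            "-" * 54,
            f"bias (mean difference)    {self.bias:>12.4f}",
            f"  {100 * self.level:.0f}% CI                  "
            f"({self.bias_ci[0]:.4f}, {self.bias_ci[1]:.4f})",
            f"between-plot var sigma_b2 {self.sigma_b2:>12.4f}",
            f"within-plot var  sigma_e2 {self.sigma_e2:>12.4f}",
            f"agreement half-width      {self.agree_halfwidth:>12.4f}",
            f"limits of agreement       ({self.limit_lo:.4f}, {self.limit_hi:.4f})",
            f"MOVER outer bounds        ({self.mover_lo:.4f}, {self.mover_hi:.4f})",
            "=" * 54,
        ]
        return "\n".join(lines)

    def as_row(self) -> dict:
        """Flat dict of the estimates, for results tables."""
        return {
            "level": self.level,
            "bias": self.bias,
            "bias_lo": self.bias_ci[0],
            "bias_hi": self.bias_ci[1],
            "sigma_b2": self.sigma_b2,
            "sigma_e2": self.sigma_e2,
            "agree_halfwidth": self.agree_halfwidth,
            "limit_lo": self.limit_lo,
            "limit_hi": self.limit_hi,
            "mover_lo": self.mover_lo,
            "mover_hi": self.mover_hi,
            "k": self.k,
            "N": self.N,
        }


def fit_nested_loa(diffs: pd.DataFrame, level: float = 0.95) -> NestedLoAResults:
    """Convenience wrapper: fit from a long differences frame.

    ``diffs`` needs columns ``plot_id`` and ``d``.
    """
    return NestedLoA.from_dataframe(diffs).fit(level=level)


def compute_differences(
    full: dict[tuple[str, str], IndicatorSet],
    sub: dict[tuple[str, str], IndicatorSet],
) -> pd.DataFrame:
    """Long table of d = full - subsample per (plot, event, indicator).

    Cells where either side is undefined are excluded pairwise. Positive
    d means the reduced design underestimates the indicator.
    """
    keys = sorted(set(full) & set(sub))
    if not keys:
        raise ValueError("no overlapping (plot_id, event_id) keys")
    rows = []
    for key in keys:
        fvals, svals = full[key].as_dict(), sub[key].as_dict()
        for name, fv in fvals.items():
            sv = svals[name]
            if fv is None or sv is None:
                continue
            rows.append(
                {"plot_id": key[0], "event_id": key[1], "indicator": name,
                 "d": float(fv) - float(sv)}
            )
    return pd.DataFrame(rows, columns=["plot_id", "event_id", "indicator", "d"])


def evaluate_criteria(
    result: NestedLoAResults, indicator: str, criteria: AcceptanceCriteria
) -> dict:
    """Apply the two acceptable-difference rules to a fitted result."""
    threshold = criteria.threshold(indicator)
    unbiased = result.bias_ci[0] <= 0.0 <= result.bias_ci[1]
    reach = max(result.mover_hi - result.bias, result.bias - result.mover_lo)
    within = reach <= threshold
    passed = within and (unbiased or not criteria.require_unbiased)
    return {
        "flag_unbiased": bool(unbiased),
        "flag_interval": bool(within),
        "passed": bool(passed),
    }


def check_difference_normality(diffs: pd.DataFrame, group_cols=("indicator",)) -> pd.DataFrame:
    """Shapiro-Wilk diagnostics for the difference distributions.

    Reported per group, never gating: the analysis proceeds regardless.
    Constant difference sets are reported with NaN statistics.
    """
    group_cols = [c for c in group_cols if c in diffs.columns]
    rows = []
    grouped = diffs.groupby(group_cols) if group_cols else [((), diffs)]
    for key, sub in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        d = sub["d"].to_numpy(dtype=float)
        if len(d) < 3 or np.ptp(d) == 0:
            w, p, note = np.nan, np.nan, "degenerate (constant or n < 3)"
        else:
            w, p = stats.shapiro(d)
            note = ""
        rows.append({**dict(zip(group_cols, key)), "n": len(d),
                     "shapiro_w": w, "p_value": p, "note": note})
    return pd.DataFrame(rows)
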