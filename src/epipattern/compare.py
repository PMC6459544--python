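"""Group-level comparisons: mean +/- SEM summaries, percent changes,
the monolayer diameter -> cell-number predictor, and Welch t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EstimationError, InsufficientDataError, ParameterError
from .patterns import SUMMARY_STATISTICS

__all__ = [
    "WelchResult",
    "percent_change",
    "predicted_density_change",
    "welch_t_test",
    "significance_tier",
    "condition_summary",
    "compare_conditions",
    "PRINTED_CLAIMS",
    "run_reproduction_suite",
]


def percent_change(reference_mean: float, test_mean: float) -> float:
    """Signed percent change ``100 * (test - reference) / reference``.

    Negative values are reductions; render a reduction as its positive
    magnitude ("reduced by X%").
    """
    if reference_mean == 0:
        raise ParameterError("percent change undefined for zero reference mean")
    return 100.0 * (test_mean - reference_mean) / reference_mean


def predicted_density_change(delta_diameter: float) -> float:
    """Predicted percent change in cells per unit area of a 2D monolayer
    when the linear cell diameter changes by the fraction ``delta_diameter``.

    Cells tile a fixed area, so the count scales with the inverse square of
    the linear size: returns ``100 * ((1 + delta)**-2 - 1)``.
    """
    if delta_diameter <= -1.0:
        raise ParameterError("delta_diameter must exceed -1")
    return 100.0 * ((1.0 + delta_diameter) ** -2 - 1.0)


@dataclass(frozen=True)
class WelchResult:
    """Two-tailed Welch (unequal-variance) t-test result."""

    t: float
    df: float
    p: float
    degenerate: bool = False  # both variances zero: t/p undefined

    @property
    def tier(self) -> str:
        return significance_tier(self.p)


def significance_tier(p: float) -> str:
    """Map a p-value to the conventional star tiers."""
    if not math.isfinite(p):
        return "NS"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def welch_t_test(sample_a, sample_b) -> WelchResult:
    """Two-tailed t-test with unequal variances (Welch-Satterthwaite df).

    ``t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b)`` with the sample
    (n-1) variances; ``p`` is the two-tailed tail probability of Student's t
    at ``|t|``.

    Raises
    ------
    InsufficientDataError
        If either sample has fewer than two values.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise InsufficientDataError(
            f"welch_t_test needs >= 2 finite values per sample (got {na}, {nb})"
        )
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return WelchResult(t=0.0, df=float(na + nb - 2), p=1.0, degenerate=True)
        return WelchResult(
            t=math.copysign(math.inf, a.mean() - b.mean()),
            df=float(na + nb - 2),
            p=0.0,
            degenerate=True,
        )
    sa = va / na
    sb = vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p=min(p, 1.0))


# ---------------------------------------------------------------------------
# cohort-level tables


def condition_summary(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean and SEM of every statistic column.

    SEM uses the (n-1) sample standard deviation divided by sqrt(n); for a
    single embryo the mean is the value and the SEM is reported as NaN.

    Returns a long table with columns
    ``condition, statistic, n_embryos, mean, sem``.
    """
    if len(summaries) == 0:
        raise EstimationError("no embryos to summarize")
    stats_cols = [c for c in SUMMARY_STATISTICS if c in summaries.columns]
    rows = []
    for cond, grp in summaries.groupby("condition", sort=False):
        for col in stats_cols:
            vals = grp[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            n = len(vals)
            mean = float(vals.mean()) if n else float("nan")
            sem = float(vals.std(ddof=1) / math.sqrt(n)) if n >= 2 else float("nan")
            rows.append(
                {
                    "condition": cond,
                    "statistic": col,
                    "n_embryos": n,
                    "mean": mean,
                    "sem": sem,
                }
            )
    return pd.DataFrame(rows)


def compare_conditions(
    summaries: pd.DataFrame,
    reference: str,
    tests: list[str],
    statistics: list[str] | None = None,
) -> pd.DataFrame:
    """Contrast each test condition against the reference, per statistic.

    For every statistic and test condition: percent change of the group
    means, Welch t-test over the per-embryo values, and a significance tier.
    Statistics that are degenerate for a contrast (undefined in every embryo,
    or fewer than two embryos per group) get NaN test fields.

    Returns columns
    ``statistic, reference, test, ref_mean, test_mean, pct_change, t, df, p, tier``.
    """
    present = set(summaries["condition"].unique())
    for label in [reference, *tests]:
        if label not in present:
            raise ParameterError(f"condition {label!r} not present in summaries")
    if statistics is None:
        statistics = [c for c in SUMMARY_STATISTICS if c in summaries.columns]
    ref_grp = summaries.loc[summaries["condition"] == reference]
    rows = []
    for test in tests:
        test_grp = summaries.loc[summaries["condition"] == test]
        for col in statistics:
            a = ref_grp[col].to_numpy(dtype=float)
            b = test_grp[col].to_numpy(dtype=float)
            a = a[np.isfinite(a)]
            b = b[np.isfinite(b)]
            ref_mean = float(a.mean()) if len(a) else float("nan")
            test_mean = float(b.mean()) if len(b) else float("nan")
            if len(a) and ref_mean != 0 and len(b):
                pct = percent_change(ref_mean, test_mean)
            else:
                pct = float("nan")
            try:
                res = welch_t_test(a, b)
                t, df, p, tier = res.t, res.df, res.p, res.tier
            except InsufficientDataError:
                t = df = p = float("nan")
                tier = "NS"
            rows.append(
                {
                    "statistic": col,
                    "reference": reference,
                    "test": test,
                    "ref_mean": ref_mean,
                    "test_mean": test_mean,
                    "pct_change": pct,
                    "t": t,
                    "df": df,
                    "p": p,
                    "tier": tier,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# printed-claim reproduction suite

#: Published group means and the percent reductions printed alongside them.
#: ``exact`` claims reproduce the printed figure at one-decimal rounding from
#: the printed means; the rest are near-misses attributable to rounding of
#: unreported per-embryo data and are checked at a loose tolerance only.
PRINTED_CLAIMS = [
    # (name, kind, reference value, test value, printed %, exact, tolerance pp)
    ("stem_count_het", "reduction", 1222.5, 1062.3, 13.1, True, 0.05),
    ("stem_count_hom", "reduction", 1222.5, 935.0, 23.5, True, 0.05),
    ("kerat_count_het", "reduction", 1165.1, 1004.0, 13.8, True, 0.05),
    ("kerat_count_hom", "reduction", 1165.1, 894.25, 23.2, True, 0.05),
    ("kerat_brdu_pct_het", "reduction", 87.3, 77.3, 11.5, True, 0.05),
    ("kerat_brdu_pct_hom", "reduction", 87.3, 64.7, 25.3, False, 0.75),
    ("iono_brdu_pct_hom", "reduction", 72.5, 54.7, 24.7, False, 0.75),
    ("monolayer_smaller_cells", "density_pred", -0.079, None, 17.9, True, 0.05),
    ("monolayer_larger_cells", "density_pred", 0.052, None, -9.7, False, 0.15),
]


def run_reproduction_suite() -> pd.DataFrame:
    """Recompute every printed percent-change claim from its printed inputs.

    Returns a table with the computed value, the printed value, whether the
    claim is checked exactly (one-decimal rounding) or at a documented
    near-miss tolerance, and a pass flag.
    """
    rows = []
    for name, kind, ref, test, printed, exact, tol in PRINTED_CLAIMS:
        if kind == "reduction":
            computed = -percent_change(ref, test)  # reduction magnitude
        elif kind == "density_pred":
            computed = predicted_density_change(ref)
            printed = abs(printed) * math.copysign(1.0, computed)
        else:  # pragma: no cover
            raise ValueError(kind)
        if exact:
            ok = round(computed, 1) == printed
        else:
            ok = abs(computed - printed) <= tol
        rows.append(
            {
                "claim": name,
                "computed": computed,
                "printed": printed,
                "mode": "exact" if exact else f"near-miss (+/-{tol} pp)",
                "passed": bool(ok),
            }
        )
    return pd.DataFrame(rows)
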