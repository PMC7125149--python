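"""Compositional statistics for sucrose-gradient fraction profiles, plus
Welch's unequal-variance t-test and ΔΔCt qPCR quantification.

A polysome gradient is summarised as four pools — free (F), monosome
(M, 40S-60S-80S), light polysome (LP) and heavy polysome (HP). Raw
per-replicate abundances are made comparable across gradients by the
closure operator (divide by the total so the components sum to 1), after
which fraction differences such as HP − F are compared between conditions
with Welch's two-sided t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

#: Ordered gradient pools of a four-part profile.
PROFILE_FRACTIONS = ("F", "M", "LP", "HP")


class WelchResult(NamedTuple):
    """Welch t statistic, Welch–Satterthwaite df, two-sided p.

    ``degenerate`` marks the zero-variance/equal-means convention
    (t = 0, p = 1).
    """

    t: float
    df: float
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class FractionDifferenceTest:
    """Between-condition Welch test of a per-replicate fraction difference.

    ``mean_diff`` maps condition label -> mean of (minuend − subtrahend)
    over that condition's closed replicate profiles. A higher mean
    difference means greater relative abundance in the minuend pool.
    """

    minuend: str
    subtrahend: str
    mean_diff: dict[str, float]
    t: float
    df: float
    p: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# closure


def close_composition(profile: Sequence[float] | np.ndarray) -> np.ndarray:
    """Apply the closure operator: divide each component by the total.

    Accepts a 1-D profile or an (n, k) stack of profiles; each row of the
    result sums to 1. Idempotent and scale-invariant. An all-zero profile
    is degenerate and rejected.
    """
    arr = np.asarray(profile, dtype=float)
    if (arr < 0).any():
        raise ValidationError("composition components must be non-negative")
    total = arr.sum(axis=-1, keepdims=True)
    if (total <= 0).any():
        raise ValidationError("all-zero profile cannot be closed")
    return arr / total


def close_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Close every replicate row of a profile table (condition, replicate, F, M, LP, HP)."""
    out = profiles.copy()
    out[list(PROFILE_FRACTIONS)] = close_composition(
        profiles[list(PROFILE_FRACTIONS)].to_numpy()
    )
    return out


# ---------------------------------------------------------------------------
# fraction differences


def fraction_difference(closed_profiles: pd.DataFrame, minuend: str,
                        subtrahend: str) -> tuple[pd.DataFrame, pd.Series]:
    """Per-replicate closed-fraction difference and per-condition means.

    Returns ``(per_replicate, means)`` where ``per_replicate`` has columns
    condition, replicate, difference and ``means`` maps condition to the
    arithmetic mean difference. On closed profiles every difference lies
    in [−1, 1].
    """
    for label in (minuend, subtrahend):
        if label not in PROFILE_FRACTIONS:
            raise ValidationError(
                f"unknown fraction label {label!r}; expected one of {PROFILE_FRACTIONS}"
            )
    if minuend == subtrahend:
        raise ValidationError("minuend and subtrahend must differ")
    per_rep = closed_profiles[["condition", "replicate"]].copy()
    per_rep["difference"] = (
        closed_profiles[minuend].to_numpy() - closed_profiles[subtrahend].to_numpy()
    )
    means = per_rep.groupby("condition", sort=False)["difference"].mean()
    return per_rep, means


def test_fraction_difference(profiles: pd.DataFrame, minuend: str, subtrahend: str,
                             conditions: tuple[str, str] | None = None,
                             closed: bool = False,
                             alternative: str = "two-sided") -> FractionDifferenceTest:
    """Close profiles, form (minuend − subtrahend) per replicate, and run
    Welch's t-test (two-sided by default) between the two conditions."""
    table = profiles if closed else close_profiles(profiles)
    per_rep, means = fraction_difference(table, minuend, subtrahend)
    if conditions is None:
        labels = list(dict.fromkeys(per_rep["condition"]))
        if len(labels) != 2:
            raise ValidationError(
                f"expected exactly 2 conditions, found {labels}; pass conditions="
            )
        conditions = (labels[0], labels[1])
    a = per_rep.loc[per_rep["condition"] == conditions[0], "difference"].to_numpy()
    b = per_rep.loc[per_rep["condition"] == conditions[1], "difference"].to_numpy()
    res = welch_t_test(a, b, alternative=alternative)
    return FractionDifferenceTest(
        minuend=minuend, subtrahend=subtrahend,
        mean_diff={c: float(means[c]) for c in conditions},
        t=res.t, df=res.df, p=res.p, degenerate=res.degenerate,
    )


# ---------------------------------------------------------------------------
# Welch's t-test


def _welch_from_stats(m1, v1, n1, m2, v2, n2):
    """Vectorised Welch t, Welch–Satterthwaite df and two-sided p from
    group means, unbiased variances and sizes.

    Conventions for degenerate inputs: both variances zero and equal means
    -> t = 0, p = 1; zero variance with unequal means -> infinite t, p = 0.
    """
    m1, v1, m2, v2 = (np.asarray(x, dtype=float) for x in (m1, v1, m2, v2))
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    degenerate = se2 == 0
    equal_means = degenerate & (diff == 0)
    sep_means = degenerate & (diff != 0)
    t = np.where(equal_means, 0.0, t)
    t = np.where(sep_means, np.where(diff > 0, np.inf, -np.inf), t)
    df = np.where(degenerate, n1 + n2 - 2, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(equal_means, 1.0, p)
    return t, df, p, degenerate


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float],
                 alternative: str = "two-sided") -> WelchResult:
    """Welch's unequal-variance t-test, t computed on a − b.

    ``alternative`` is "two-sided" (default), "greater" (mean a > mean b)
    or "less". Each group needs at least 2 values. Identical constant
    groups return the conventional (t = 0, p = 1) flagged as degenerate.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 values for Welch's t-test")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("groups must contain finite values")
    t, df, p, deg = _welch_from_stats(
        a.mean(), a.var(ddof=1), a.size, b.mean(), b.var(ddof=1), b.size
    )
    t, df = float(t), float(df)
    if alternative == "greater":
        p = 1.0 if deg and t == 0 else float(stats.t.sf(t, df))
    elif alternative == "less":
        p = 1.0 if deg and t == 0 else float(stats.t.cdf(t, df))
    return WelchResult(t, df, float(p), bool(deg))


def test_fraction_pairs(profiles: pd.DataFrame,
                        pairs: Sequence[tuple[str, str]] | None = None,
                        conditions: tuple[str, str] | None = None,
                        bh: bool = False,
                        alternative: str = "two-sided") -> pd.DataFrame:
    """Welch-test several fraction differences at once.

    ``pairs`` defaults to all 6 unordered pool pairs (as minuend, subtrahend
    in profile order). Comparisons are reported at nominal significance by
    default; ``bh=True`` adds a Benjamini–Hochberg ``q`` column across the
    tested pairs.
    """
    from .diffexpr import bh_adjust  # local import: avoids a module cycle

    if pairs is None:
        pairs = [(b, a) for i, a in enumerate(PROFILE_FRACTIONS)
                 for b in PROFILE_FRACTIONS[i + 1:]]
    closed = close_profiles(profiles)
    rows = []
    for minuend, subtrahend in pairs:
        res = test_fraction_difference(closed, minuend, subtrahend,
                                       conditions=conditions, closed=True,
                                       alternative=alternative)
        row = {"minuend": minuend, "subtrahend": subtrahend}
        row.update({f"mean_diff_{c}": v for c, v in res.mean_diff.items()})
        row.update({"t": res.t, "df": res.df, "p": res.p,
                    "degenerate": res.degenerate})
        rows.append(row)
    out = pd.DataFrame(rows)
    if bh:
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# ΔΔCt quantification


def ddct_fold_change(records: pd.DataFrame, control_label: str) -> pd.DataFrame:
    """Relative qPCR quantification by the ΔΔCt (Livak) method.

    ``records`` needs columns condition, ct_target, ct_reference (reference
    = the normalisation control gene, e.g. Gapdh). Per sample
    ΔCt = Ct_target − Ct_reference; per condition ΔΔCt = mean ΔCt(condition)
    − mean ΔCt(control); fold change = 2^(−ΔΔCt), so the control condition
    has fold 1 by construction. The replicate spread is reported as the SD
    of ΔCt.
    """
    required = ["condition", "ct_target", "ct_reference"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValidationError(f"Ct table missing columns: {missing}")
    ct_t = pd.to_numeric(records["ct_target"], errors="coerce")
    ct_r = pd.to_numeric(records["ct_reference"], errors="coerce")
    if ct_t.isna().any() or ct_r.isna().any():
        raise ValidationError("missing or non-numeric Ct value")
    if (ct_t <= 0).any() or (ct_r <= 0).any():
        raise ValidationError("Ct values must be positive")
    if control_label not in set(records["condition"]):
        raise ValidationError(f"control condition {control_label!r} not present")
    work = records.assign(dct=ct_t - ct_r)
    grouped = work.groupby("condition", sort=False)["dct"]
    summary = grouped.agg(mean_dct="mean", sd_dct="std", n="count").reset_index()
    control_dct = summary.loc[summary["condition"] == control_label, "mean_dct"].iloc[0]
    summary["ddct"] = summary["mean_dct"] - control_dct
    summary["fold_change"] = 2.0 ** (-summary["ddct"])
    return summary
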