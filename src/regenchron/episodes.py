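"""Punctuated-episode detection and temporal-structure summaries.

A punctuated transcriptional episode is an interval whose adjacent-day
contrast yields significantly more significant probesets than the
immediately preceding interval's contrast.  Each consecutive pair of
adjacent contrasts is compared with McNemar's test on the paired
per-probe significance calls, and the family of comparisons is
Bonferroni-controlled at 0.05 — on the reference 20-day schedule that is
18 comparisons and a per-comparison threshold of 0.05/18 ≈ 0.0028.

The remaining operations summarise the baseline (day-0) call matrix:
up/down divergence counts per day, the cumulative curve of first
detection times, and the histogram of how many contrasts each probe was
significant in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from regenchron.differential import parse_contrast_label

#: b+c below which the exact binomial replaces the chi-square approximation.
EXACT_THRESHOLD = 25


def _is_sig(calls: pd.Series) -> np.ndarray:
    return calls.isin(("up", "down")).to_numpy()


@dataclass(frozen=True)
class PairedCalls:
    """2x2 pairing of per-probe significance across two adjacent contrasts.

    ``a``: significant in both; ``b``: earlier only; ``c``: later only;
    ``d``: neither.  Significance is direction-blind (up or down).
    """

    contrast_earlier: str
    contrast_later: str
    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p_value: float
    direction: Literal["increase", "decrease", "none"]
    method: Literal["chi2_cc", "exact_binomial"]


@dataclass(frozen=True)
class EpisodeCall:
    """Decision for one interval: is it a punctuated episode?"""

    interval: tuple[float, float]
    contrast_earlier: str
    contrast_later: str
    flagged: bool
    b: int
    c: int
    statistic: float
    p_value: float
    direction: str
    method: str
    family_alpha: float
    n_comparisons: int
    adjusted_threshold: float


def paired_significance_counts(
    calls_earlier: pd.Series, calls_later: pd.Series
) -> PairedCalls:
    """Build the McNemar 2x2 from two adjacent contrasts' call vectors.

    Both vectors must cover the same probe universe in the same order.
    """
    if not calls_earlier.index.equals(calls_later.index):
        raise ValueError("call vectors cover different probe universes")
    se = _is_sig(calls_earlier)
    sl = _is_sig(calls_later)
    return PairedCalls(
        contrast_earlier=str(calls_earlier.name),
        contrast_later=str(calls_later.name),
        a=int((se & sl).sum()),
        b=int((se & ~sl).sum()),
        c=int((~se & sl).sum()),
        d=int((~se & ~sl).sum()),
    )


def mcnemar_test(
    paired: PairedCalls,
    method: Literal["auto", "chi2_cc", "exact_binomial"] = "auto",
) -> McNemarResult:
    """McNemar's test of marginal homogeneity on a paired 2x2.

    With ``method="auto"`` (the default) the continuity-corrected
    chi-square statistic ``(|b-c|-1)^2/(b+c)`` with a 1-df upper tail is
    used, switching to the exact two-sided binomial(b+c, 1/2) when the
    discordant count is below 25.  ``|b-c| <= 1`` (including ``b+c=0``)
    clamps to p = 1 under either method.
    """
    b, c = paired.b, paired.c
    n_disc = b + c
    statistic = 0.0 if n_disc == 0 else (abs(b - c) - 1) ** 2 / n_disc
    if method == "auto":
        method = "exact_binomial" if n_disc < EXACT_THRESHOLD else "chi2_cc"
    if method == "exact_binomial":
        if abs(b - c) <= 1:
            p = 1.0
        else:
            p = min(1.0, 2.0 * float(stats.binom.sf(max(b, c) - 1, n_disc, 0.5)))
    elif method == "chi2_cc":
        p = 1.0 if abs(b - c) <= 1 else float(stats.chi2.sf(statistic, df=1))
    else:
        raise ValueError(f"unknown method {method!r}")
    direction = "increase" if c > b else ("decrease" if b > c else "none")
    return McNemarResult(statistic=statistic, p_value=p, direction=direction, method=method)


def detect_episodes(
    adjacent_calls: pd.DataFrame,
    mode: Literal["increase", "decrease"] = "increase",
    family_alpha: float = 0.05,
) -> list[EpisodeCall]:
    """Flag punctuated episodes across consecutive adjacent contrasts.

    *adjacent_calls* is the probe x contrast call matrix from the
    adjacent scheme, columns in schedule order.  Every consecutive
    column pair is McNemar-compared; an interval is flagged when the
    discordance direction matches *mode* and the two-sided p-value falls
    strictly below the Bonferroni-adjusted threshold
    ``family_alpha / (n_contrasts - 1)``.

    The first adjacent contrast has no predecessor and is never itself
    an episode candidate; it appears only as the earlier member of the
    first comparison.
    """
    labels = list(adjacent_calls.columns)
    if len(labels) < 2:
        raise ValueError("need >= 2 adjacent contrasts to compare")
    n_comparisons = len(labels) - 1
    threshold = family_alpha / n_comparisons
    calls: list[EpisodeCall] = []
    for earlier, later in zip(labels[:-1], labels[1:]):
        paired = paired_significance_counts(adjacent_calls[earlier], adjacent_calls[later])
        res = mcnemar_test(paired)
        calls.append(
            EpisodeCall(
                interval=parse_contrast_label(later),
                contrast_earlier=earlier,
                contrast_later=later,
                flagged=(res.direction == mode and res.p_value < threshold),
                b=paired.b,
                c=paired.c,
                statistic=res.statistic,
                p_value=res.p_value,
                direction=res.direction,
                method=res.method,
                family_alpha=family_alpha,
                n_comparisons=n_comparisons,
                adjusted_threshold=threshold,
            )
        )
    return calls


def episodes_table(calls: list[EpisodeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "interval": [c.contrast_later for c in calls],
            "flagged": [c.flagged for c in calls],
            "b": [c.b for c in calls],
            "c": [c.c for c in calls],
            "statistic": [c.statistic for c in calls],
            "p_value": [c.p_value for c in calls],
            "direction": [c.direction for c in calls],
            "method": [c.method for c in calls],
            "adjusted_threshold": [c.adjusted_threshold for c in calls],
        }
    )


@dataclass
class DivergenceSummary:
    """Per-day up/down counts versus baseline, with totals."""

    per_day: pd.DataFrame  # columns: day, n_up, n_down, n_sig
    grand_total: int  # significant test results summed over days
    n_unique: int  # distinct probes significant at any day


def baseline_divergence_counts(baseline_calls: pd.DataFrame) -> DivergenceSummary:
    """Count up/down probes per post-baseline day from the day-0 call matrix."""
    rows = []
    for label in baseline_calls.columns:
        _, day_b = parse_contrast_label(label)
        col = baseline_calls[label]
        n_up = int((col == "up").sum())
        n_down = int((col == "down").sum())
        rows.append({"day": day_b, "n_up": n_up, "n_down": n_down, "n_sig": n_up + n_down})
    per_day = pd.DataFrame(rows)
    sig_any = baseline_calls.isin(("up", "down")).any(axis=1)
    return DivergenceSummary(
        per_day=per_day,
        grand_total=int(per_day["n_sig"].sum()),
        n_unique=int(sig_any.sum()),
    )


def cumulative_first_detection(
    baseline_calls: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Earliest significant day per probe, and the cumulative discovery curve.

    Returns ``(records, curve)``: *records* has one row per probe ever
    significant versus day 0 with its ``earliest_day``; *curve* gives,
    per post-baseline day, the cumulative number of distinct probes
    detected by then.  The curve is non-decreasing and terminates at the
    unique-significant count.
    """
    sig = baseline_calls.isin(("up", "down"))
    days = [parse_contrast_label(lab)[1] for lab in baseline_calls.columns]
    order = np.argsort(days)
    records = []
    first_day = np.full(len(sig), np.nan)
    sig_values = sig.to_numpy()
    for pos in order[::-1]:
        first_day[sig_values[:, pos]] = days[pos]
    for probe, day in zip(baseline_calls.index, first_day):
        if np.isfinite(day):
            records.append({"probe_id": probe, "earliest_day": day})
    records_df = pd.DataFrame(records, columns=["probe_id", "earliest_day"])
    sorted_days = [days[i] for i in order]
    cumulative = [
        int(np.isfinite(first_day[first_day <= d]).sum()) if np.isfinite(d) else 0
        for d in sorted_days
    ]
    curve = pd.DataFrame({"day": sorted_days, "cumulative": cumulative})
    return records_df, curve


def times_significant_histogram(baseline_calls: pd.DataFrame) -> pd.Series:
    """Histogram of how many baseline contrasts each probe is significant in.

    Support is 1..n_contrasts; never-significant probes are excluded, so
    the histogram mass equals the unique-significant probe count.
    """
    counts = baseline_calls.isin(("up", "down")).sum(axis=1)
    counts = counts[counts > 0]
    hist = counts.value_counts().sort_index()
    hist.index.name = "n_significant_days"
    hist.name = "n_probes"
    return hist
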