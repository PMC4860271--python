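"""Per-probeset two-group Welch tests with fold-change filtering.

Differential calls follow the study design this package supports: each
contrast compares the replicate groups of two scheduled days with a
two-tailed Welch (unequal-variance) t test on log2 intensities, and a
probe is called ``up`` or ``down`` only when both the p-value threshold
(default 0.01 per test, no multiplicity correction) and a minimum
absolute log2 mean difference (default log2(1.5)) are met.  Two contrast
schemes are provided: every post-baseline day against day 0, and every
pair of adjacent scheduled days.

``delta_log2`` is later-minus-earlier throughout, so ``up`` means higher
expression at the later day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from regenchron.io import schedule_of

Call = Literal["up", "down", "ns"]

#: 1.5-fold expression change on the log2 scale.
FC_1_5_LOG2 = math.log2(1.5)


@dataclass(frozen=True)
class DEConfig:
    """Significance and fold-change thresholds for differential calls.

    ``p_threshold`` is applied per test with ``<=`` (no correction across
    probes or contrasts); ``fc_threshold_log2`` is the exact log2 of the
    1.5-fold cutoff by default.  ``apply_fc_filter=False`` disables the
    fold-change criterion (used e.g. for null-calibration checks).
    """

    p_threshold: float = 0.01
    fc_threshold_log2: float = FC_1_5_LOG2
    apply_fc_filter: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.fc_threshold_log2 < 0:
            raise ValueError("fc_threshold_log2 must be non-negative")


@dataclass(frozen=True)
class ContrastSpec:
    day_a: float
    day_b: float
    scheme: Literal["baseline", "adjacent"]

    def __post_init__(self) -> None:
        if not self.day_a < self.day_b:
            raise ValueError("day_a must precede day_b")
        if self.scheme == "baseline" and self.day_a != 0:
            raise ValueError("baseline contrasts compare against day 0")

    @property
    def label(self) -> str:
        return f"{self.day_a:g}-{self.day_b:g}"


def parse_contrast_label(label: str) -> tuple[float, float]:
    a, b = label.split("-")
    return float(a), float(b)


class WelchResult(NamedTuple):
    t_statistic: float
    welch_df: float
    p_value: float


def welch_t_test(values_a, values_b) -> WelchResult:
    """Two-tailed Welch t test of group b against group a.

    The statistic is ``(mean_b - mean_a) / sqrt(s_a^2/n_a + s_b^2/n_b)``
    with Welch-Satterthwaite degrees of freedom.  When both groups have
    zero variance the test degenerates: equal means give ``t=0, p=1``,
    unequal means ``p=0`` (callers flag and exclude such probes).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in test input")
    t, df, p, _ = _welch_arrays(a[None, :], b[None, :])
    return WelchResult(float(t[0]), float(df[0]), float(p[0]))


def _welch_arrays(A: np.ndarray, B: np.ndarray):
    """Vectorised Welch test over rows of A (group a) and B (group b)."""
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va, vb = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    sa, sb = va / na, vb / nb
    se2 = sa + sb
    delta = mb - ma
    degenerate = se2 == 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(se2)
        df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    df = np.where(degenerate, na + nb - 2, df)
    t = np.where(degenerate & (delta == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, np.where(delta == 0, 1.0, 0.0), p)
    return t, df, p, degenerate


def _group_values(matrix: pd.DataFrame, samples: pd.DataFrame, day: float) -> np.ndarray:
    ids = samples.loc[samples["day"] == day, "sample_id"].tolist()
    if len(ids) < 2:
        raise ValueError(f"day {day:g} absent or has < 2 replicates")
    return matrix[ids].to_numpy()


def run_contrast(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    spec: ContrastSpec,
    config: DEConfig = DEConfig(),
) -> pd.DataFrame:
    """Test every probe for the contrast *spec*.

    Returns one row per probe with ``t_statistic``, ``welch_df``,
    ``p_value``, ``q_value`` (Benjamini-Hochberg within the contrast,
    reported for reference only — calls never use it), ``delta_log2``,
    ``call`` and a ``degenerate`` flag for zero-variance probes.
    """
    A = _group_values(matrix, samples, spec.day_a)
    B = _group_values(matrix, samples, spec.day_b)
    t, df, p, degenerate = _welch_arrays(A, B)
    delta = B.mean(axis=1) - A.mean(axis=1)

    call = np.full(len(matrix), "ns", dtype=object)
    sig = p <= config.p_threshold
    if config.apply_fc_filter:
        up = sig & (delta >= config.fc_threshold_log2)
        down = sig & (delta <= -config.fc_threshold_log2)
    else:
        up = sig & (delta > 0)
        down = sig & (delta < 0)
    call[up] = "up"
    call[down] = "down"
    call[degenerate] = "ns"

    return pd.DataFrame(
        {
            "probe_id": matrix.index,
            "t_statistic": t,
            "welch_df": df,
            "p_value": p,
            "q_value": multipletests(p, method="fdr_bh")[1],
            "delta_log2": delta,
            "call": call,
            "degenerate": degenerate,
        }
    )


@dataclass
class ContrastSetResult:
    """Results of one contrast scheme across the whole schedule.

    ``calls`` is the probe x contrast call matrix (values up/down/ns);
    ``summaries`` counts up/down per contrast; ``results`` holds the full
    per-probe tables keyed by contrast label.
    """

    scheme: str
    specs: list[ContrastSpec]
    results: dict[str, pd.DataFrame]
    calls: pd.DataFrame
    summaries: pd.DataFrame


def _run_contrast_set(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    specs: list[ContrastSpec],
    config: DEConfig,
    scheme: str,
) -> ContrastSetResult:
    results: dict[str, pd.DataFrame] = {}
    calls = {}
    rows = []
    for spec in specs:
        res = run_contrast(matrix, samples, spec, config)
        results[spec.label] = res
        calls[spec.label] = res["call"].to_numpy()
        n_up = int((res["call"] == "up").sum())
        n_down = int((res["call"] == "down").sum())
        rows.append(
            {
                "contrast": spec.label,
                "day_a": spec.day_a,
                "day_b": spec.day_b,
                "n_up": n_up,
                "n_down": n_down,
                "n_sig": n_up + n_down,
            }
        )
    call_matrix = pd.DataFrame(calls, index=matrix.index.copy())
    summaries = pd.DataFrame(rows)
    return ContrastSetResult(scheme, specs, results, call_matrix, summaries)


def baseline_specs(samples: pd.DataFrame) -> list[ContrastSpec]:
    days = schedule_of(samples)
    if days[0] != 0:
        raise ValueError("baseline scheme requires day 0 in the schedule")
    return [ContrastSpec(0.0, d, "baseline") for d in days[1:]]


def adjacent_specs(samples: pd.DataFrame) -> list[ContrastSpec]:
    days = schedule_of(samples)
    return [ContrastSpec(a, b, "adjacent") for a, b in zip(days[:-1], days[1:])]


def run_baseline_contrasts(
    matrix: pd.DataFrame, samples: pd.DataFrame, config: DEConfig = DEConfig()
) -> ContrastSetResult:
    """Compare every post-baseline day against day 0, in schedule order."""
    return _run_contrast_set(matrix, samples, baseline_specs(samples), config, "baseline")


def run_adjacent_contrasts(
    matrix: pd.DataFrame, samples: pd.DataFrame, config: DEConfig = DEConfig()
) -> ContrastSetResult:
    """Compare every pair of consecutive scheduled days."""
    return _run_contrast_set(matrix, samples, adjacent_specs(samples), config, "adjacent")
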