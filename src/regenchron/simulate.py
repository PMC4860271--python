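"""Synthetic replicated log2 expression time courses with ground truth.

The generator emulates the statistical structure of a dense regeneration
time-course experiment: a fixed sampling schedule of 20 days spanning
0-28 days post-amputation (DPA), 10 biological replicates per day, and
probes drawn from a small set of trajectory archetypes observed in
regenerating limb tissue:

``flat``
    null probes, constant mean.
``immediate_early``
    a sharp induction at 0.5 DPA that decays, re-pulsing at day 7
    (the immediate-early gene signature, e.g. fos/egr1).
``step`` / ``step@<day>``
    an abrupt shift arriving at a boundary day (default day 3) that
    persists for the rest of the series.
``ramp``
    a gradual increase beginning after day 2.
``dip_9_10``
    a transient decrease whose minimum falls at day 10 (extracellular
    matrix genes at the pre-bud / early-bud transition).
``late_ramp_22_24``
    an increase confined to days after 22 (palette-stage genes).
``muscle_decline``
    a monotone decline from day 0 through day 12 that then stays low;
    these probes additionally share a per-sample random effect so that
    replicate estimates are correlated across the group, as seen for
    muscle structural genes during stump histolysis.
``gradual_drift``
    a slow linear drift across the whole series.

Noise is Gaussian on the log2 scale and homoscedastic.  All randomness
comes from a single seeded generator with a documented draw order
(baselines, scales, group effects, noise); archetype assignment is a
deterministic function of the configuration, so two seeds share the same
truth structure and differ only in the random draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Sampling schedule of the reference experiment, in days post-amputation.
REFERENCE_SCHEDULE: tuple[float, ...] = (
    0, 0.5, 1, 1.5, 2, 3, 4, 5, 7, 9, 10, 12, 14, 16, 18, 20, 22, 24, 26, 28,
)

ARCHETYPES = (
    "flat",
    "immediate_early",
    "step",
    "ramp",
    "dip_9_10",
    "late_ramp_22_24",
    "muscle_decline",
    "gradual_drift",
)

_DIP_KNOTS = ((5.0, 0.0), (7.0, -0.35), (9.0, -0.7), (10.0, -1.0), (12.0, -0.5), (14.0, -0.15), (16.0, 0.0))


def archetype_mean_profile(
    name: str, schedule: Sequence[float], effect_size: float = 1.0
) -> np.ndarray:
    """Noiseless mean log2 profile of an archetype over *schedule*.

    ``step`` accepts an optional boundary suffix, e.g. ``step@20`` places
    the persistent jump at the arrival of day 20.  Profiles are relative
    to the probe's baseline (the flat archetype is identically zero).
    """
    days = np.asarray(sorted(schedule), dtype=float)
    if days.size == 0:
        raise ValueError("empty schedule")
    e = float(effect_size)
    base = name
    boundary = None
    if name.startswith("step@"):
        base = "step"
        boundary = float(name.split("@", 1)[1])
    last = days[-1]
    if base == "flat":
        return np.zeros_like(days)
    if base == "step":
        b = 3.0 if boundary is None else boundary
        return np.where(days >= b, e, 0.0)
    if base == "immediate_early":
        out = np.zeros_like(days)
        first = (days >= 0.5) & (days < 7.0)
        out[first] = e * np.exp(-(days[first] - 0.5) / 0.75)
        second = days >= 7.0
        out[second] = e * np.exp(-(days[second] - 7.0) / 2.0)
        return out
    if base == "ramp":
        return np.where(days > 2.0, e * (days - 2.0) / max(last - 2.0, 1.0), 0.0)
    if base == "dip_9_10":
        knots_x = np.array([k[0] for k in _DIP_KNOTS])
        knots_y = np.array([k[1] for k in _DIP_KNOTS]) * e
        return np.interp(days, knots_x, knots_y, left=0.0, right=0.0)
    if base == "late_ramp_22_24":
        return np.where(days > 22.0, e * (days - 22.0) / max(last - 22.0, 1.0), 0.0)
    if base == "muscle_decline":
        return -2.0 * e * np.minimum(days, 12.0) / 12.0
    if base == "gradual_drift":
        return e * days / max(last, 1.0)
    raise ValueError(f"unknown archetype {name!r}")


@dataclass
class SimConfig:
    """Configuration of one synthetic time-course experiment.

    Parameters are on the log2 scale.  ``archetype_mix`` maps archetype
    names (``step`` may carry a boundary suffix, ``step@20``) to
    proportions summing to 1.  ``scale_choices`` are the per-probe
    multipliers applied to the archetype profile, drawn uniformly; the
    default leaves every non-null probe at the nominal ``effect_size``.
    """

    n_probes: int = 1000
    schedule: tuple[float, ...] = REFERENCE_SCHEDULE
    n_replicates: int = 10
    archetype_mix: Mapping[str, float] = field(default_factory=lambda: {"flat": 1.0})
    effect_size: float = 1.0
    noise_sd: float = 0.5
    group_effect_sd: float = 0.5
    baseline_range: tuple[float, float] = (4.0, 12.0)
    scale_choices: tuple[float, ...] = (1.0,)
    change_threshold_log2: float = math.log2(1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.noise_sd < 0 or self.group_effect_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        total = float(sum(self.archetype_mix.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype_mix proportions sum to {total}, not 1")
        if len(set(self.schedule)) != len(self.schedule):
            raise ValueError("schedule days must be distinct")
        for name in self.archetype_mix:
            archetype_mean_profile(name, self.schedule, 1.0)  # validates the name
        if not self.scale_choices:
            raise ValueError("scale_choices must be non-empty")


@dataclass
class SimTruth:
    """Ground truth emitted with a simulated matrix.

    ``probes`` records archetype, baseline and scale per probe;
    ``noiseless`` holds the noise-free mean per (probe, day); ``groups``
    maps correlated-effect group names to their member probes; and
    ``true_changes`` lists, for every adjacent day interval, the probes
    whose noiseless means differ by at least the configured threshold.
    """

    probes: pd.DataFrame
    noiseless: pd.DataFrame
    groups: dict[str, list[str]]
    change_threshold_log2: float

    @property
    def schedule(self) -> list[float]:
        return list(self.noiseless.columns)

    def changed_probes(
        self, day_a: float, day_b: float, threshold: float | None = None
    ) -> frozenset[str]:
        """Probes whose noiseless mean shifts by >= *threshold* between two days."""
        thr = self.change_threshold_log2 if threshold is None else threshold
        delta = (self.noiseless[day_b] - self.noiseless[day_a]).abs()
        return frozenset(self.noiseless.index[delta >= thr - 1e-12])

    @property
    def true_changes(self) -> dict[tuple[float, float], frozenset[str]]:
        sched = self.schedule
        return {
            (a, b): self.changed_probes(a, b)
            for a, b in zip(sched[:-1], sched[1:])
        }


def _assign_archetypes(mix: Mapping[str, float], n: int) -> list[str]:
    """Deterministic largest-remainder apportionment of probes to archetypes."""
    names = list(mix.keys())
    exact = np.array([mix[k] * n for k in names], dtype=float)
    counts = np.floor(exact).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    for i in range(short):
        counts[order[i]] += 1
    labels: list[str] = []
    for name, c in zip(names, counts):
        labels.extend([name] * int(c))
    return labels


def sample_name(day: float, replicate: int) -> str:
    return f"d{day:g}_r{replicate}"


def simulate_timecourse(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a replicated log2 expression time course.

    Each cell is ``baseline + scale * profile(day) + group_effect(sample)
    + N(0, noise_sd^2)``.  Probes of the ``muscle_decline`` archetype form
    one group sharing a per-sample Gaussian effect of sd
    ``group_effect_sd``, so their replicate estimates co-vary.

    Returns the matrix (probes x samples), the sample table, and the
    :class:`SimTruth` ground truth.  Identical configurations (including
    the seed) reproduce identical output.
    """
    rng = np.random.default_rng(config.seed)
    days = sorted(config.schedule)
    n_days, n_rep = len(days), config.n_replicates
    n_probes = config.n_probes

    probe_ids = [f"probe{i:05d}" for i in range(n_probes)]
    archetypes = _assign_archetypes(config.archetype_mix, n_probes)

    sample_rows = [
        (sample_name(day, rep), day, rep)
        for day in days
        for rep in range(1, n_rep + 1)
    ]
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "day", "replicate"])
    samples["stage"] = pd.NA
    sample_days = samples["day"].to_numpy()
    day_index = np.searchsorted(days, sample_days)

    # draw order: baselines, scales, per-(sample, group) effects, noise
    baselines = rng.uniform(*config.baseline_range, size=n_probes)
    scales = np.asarray(config.scale_choices, dtype=float)[
        rng.integers(0, len(config.scale_choices), size=n_probes)
    ]

    profile_by_name = {
        name: archetype_mean_profile(name, days, config.effect_size)
        for name in config.archetype_mix
    }
    profiles = np.stack([profile_by_name[a] for a in archetypes])  # probes x days
    noiseless = baselines[:, None] + scales[:, None] * profiles

    values = noiseless[:, day_index].copy()

    groups: dict[str, list[str]] = {}
    muscle_mask = np.array([a == "muscle_decline" for a in archetypes])
    if muscle_mask.any():
        groups["muscle"] = [p for p, m in zip(probe_ids, muscle_mask) if m]
        per_sample_effect = rng.normal(0.0, config.group_effect_sd, size=len(samples))
        values[muscle_mask, :] += per_sample_effect[None, :]

    values += rng.normal(0.0, config.noise_sd, size=values.shape)

    matrix = pd.DataFrame(
        values, index=pd.Index(probe_ids, name="probe_id"), columns=samples["sample_id"].tolist()
    )
    probes = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "archetype": archetypes,
            "baseline": baselines,
            "scale": scales,
            "group": ["muscle" if m else "" for m in muscle_mask],
        }
    )
    truth = SimTruth(
        probes=probes,
        noiseless=pd.DataFrame(noiseless, index=pd.Index(probe_ids, name="probe_id"), columns=days),
        groups=groups,
        change_threshold_log2=config.change_threshold_log2,
    )
    return matrix, samples, truth


def replicate_group_correlation(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    truth: SimTruth,
    archetype: str = "muscle_decline",
    day_window: tuple[float, float] = (7.0, 12.0),
) -> float:
    """Mean pairwise correlation of replicate deviations within a group.

    For each probe of *archetype* and each sample in *day_window*, the
    deviation is the observed value minus the probe's replicate mean for
    that day.  Returns the mean pairwise Pearson correlation of these
    deviation vectors across probes — near zero without a shared
    per-sample effect, approaching 1 as the group effect dominates noise.
    """
    ids = truth.probes.loc[truth.probes["archetype"] == archetype, "probe_id"].tolist()
    if len(ids) < 2:
        raise ValueError(f"need >= 2 probes of archetype {archetype!r}")
    lo, hi = day_window
    keep = samples[(samples["day"] >= lo) & (samples["day"] <= hi)]
    if keep.empty:
        raise ValueError("no samples inside day window")
    sub = matrix.loc[ids, keep["sample_id"].tolist()]
    day_of = keep.set_index("sample_id")["day"]
    deviations = sub.sub(sub.T.groupby(day_of).transform("mean").T)
    corr = np.corrcoef(deviations.to_numpy())
    n = corr.shape[0]
    off = corr[np.triu_indices(n, k=1)]
    return float(np.mean(off))
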