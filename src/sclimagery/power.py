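"""Statistical power of the test-scene contrast.

The squats test scene is excluded from the main analysis and instead anchors
a power computation: the per-participant difference between the test scene's
mean normalized SCL and the mean over the six imagery scenes gives a mean
difference and standard deviation, hence a standardized mean difference
d = Δ/SD.  Achieved power of the one-sample t test on those differences is
computed exactly from the noncentral t distribution (noncentrality d·√n),
with a seeded Monte-Carlo estimator as an independent check.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerReport:
    """Inputs and result of an achieved-power computation."""

    mean_diff: float
    sd: float
    smd: float
    alpha: float
    n: int
    sides: int
    power: float

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    def __str__(self) -> str:  # human-readable report
        tail = "two-sided" if self.sides == 2 else "one-sided"
        return (f"mean difference {self.mean_diff:g}, SD {self.sd:g} -> "
                f"SMD d = {self.smd:.2f}; one-sample t test, n = {self.n}, "
                f"alpha = {self.alpha:g} ({tail}): power = {100 * self.power:.2f}%")


def smd(mean_diff: float, sd: float) -> float:
    """Standardized mean difference d = mean difference / SD (full precision)."""
    if sd <= 0:
        raise ValueError(f"standard deviation must be positive, got {sd}")
    return mean_diff / sd


def power_t(d: float, n: int, alpha: float = 0.05, sides: int = 2) -> float:
    """Exact power of the one-sample t test at effect size ``d``.

    Under the alternative the t statistic follows a noncentral t distribution
    with ``n − 1`` degrees of freedom and noncentrality ``d·√n``; power is
    the probability it falls in the rejection region.  At ``d = 0`` the
    two-sided power equals ``alpha``.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 observations, got {n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if sides not in (1, 2):
        raise ValueError(f"sides must be 1 or 2, got {sides}")
    df = n - 1
    nc = d * np.sqrt(n)
    if sides == 2:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
    tcrit = stats.t.ppf(1.0 - alpha, df)
    return float(stats.nct.sf(tcrit, df, nc))


def power_mc(d: float, n: int, alpha: float = 0.05, sides: int = 2,
             reps: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo power estimate: rejection rate over simulated samples.

    Draws ``reps`` normal samples of size ``n`` with mean ``d`` and unit SD
    and counts how often the t statistic clears the critical value.  Used as
    an oracle for :func:`power_t`; requires at least 10,000 replicates.
    """
    if reps < 10_000:
        raise ValueError(f"need reps >= 10000 for a stable estimate, got {reps}")
    if n < 2:
        raise ValueError(f"need n >= 2 observations, got {n}")
    rng = np.random.default_rng(seed)
    x = rng.normal(d, 1.0, size=(reps, n))
    t = np.sqrt(n) * x.mean(axis=1) / x.std(axis=1, ddof=1)
    df = n - 1
    if sides == 2:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(np.mean(np.abs(t) > tcrit))
    tcrit = stats.t.ppf(1.0 - alpha, df)
    return float(np.mean(t > tcrit))


def power_report(mean_diff: float, sd: float, n: int, alpha: float = 0.05,
                 sides: int = 2) -> PowerReport:
    """Full report from a measured contrast: SMD plus achieved power."""
    d = smd(mean_diff, sd)
    return PowerReport(mean_diff=mean_diff, sd=sd, smd=d, alpha=alpha, n=n,
                       sides=sides, power=power_t(d, n, alpha, sides))


def test_scene_contrast(summaries) -> tuple[float, float, int]:
    """Per-participant test-vs-scenes contrast from script summaries.

    For each participant with a test-scene summary and at least one retained
    imagery scene, the difference (test mean nSCL − mean of retained scene
    means) is formed; returns its mean, sample SD and the number of
    participants contributing.  The test scene is used regardless of its
    retained flag — it is excluded from mSCL, not from the power analysis.
    """
    diffs = []
    for _, grp in summaries.groupby("participant_id", sort=False):
        test = grp[grp["is_test_scene"]]
        scenes = grp[~grp["is_test_scene"] & grp["retained"]]
        if test.empty or scenes.empty:
            continue
        diffs.append(float(test["mean_nscl"].iloc[0] - scenes["mean_nscl"].mean()))
    if len(diffs) < 2:
        raise ValueError("need at least two participants with a test-scene contrast")
    arr = np.asarray(diffs)
    return float(arr.mean()), float(arr.std(ddof=1)), arr.size
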