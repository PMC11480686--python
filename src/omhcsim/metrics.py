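"""Outcome metrics, policy comparisons, and distributional validation.

Five metrics summarise a run, overall and per demographic stratum:

* mean chat rating (1-5 stars, higher better);
* percentage of blocked pairs (lower better);
* matching success rate: matched seekers / all seekers who entered the
  queue, in percent;
* mean waiting time of matched seekers (minutes);
* mean waiting time of seekers who reneged (their patience + 1).

Seekers still queueing when the horizon ends are neither matched nor
reneged: they are excluded from both waiting-time averages but stay in the
success-rate denominator.  Demographic strata use seeker-side membership:
adults vs underaged (age <= 18 at the reference year) and gender minority
(non-cisgender) vs not.

Policy arms are compared with one-tailed Welch t tests over per-replicate
metric values (each seeded run contributes one observation, respecting
independence across replicates); significance is flagged at the .05 and
.001 thresholds.  No multiple-testing correction is applied across the
metric grid — flags mirror raw per-test thresholds.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .engine import SimulationRun
from .population import GENDER_MINORITY

__all__ = [
    "GROUPS",
    "MetricsReport",
    "ComparisonResult",
    "compute_metrics",
    "compare_policies",
    "pearson_validation",
    "patience_validation",
]

GROUPS = ("adults", "underaged", "non_gender_minority", "gender_minority")

METRIC_NAMES = (
    "mean_rating",
    "pct_blocked",
    "matching_success_rate",
    "mean_wait_matched",
    "mean_wait_unmatched",
)


@dataclass
class MetricsReport:
    mean_rating: float | None
    pct_blocked: float | None
    matching_success_rate: float | None
    mean_wait_matched: float | None
    mean_wait_unmatched: float | None
    n_chats: int
    n_seekers: int
    n_dropouts: int
    per_group: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_frame(self) -> pd.DataFrame:
        """Overall + per-group metrics as one table (rows = strata)."""
        rows = {"overall": {m: getattr(self, m) for m in METRIC_NAMES}}
        for g, d in self.per_group.items():
            rows[g] = {m: d.get(m) for m in METRIC_NAMES}
        return pd.DataFrame(rows).T[list(METRIC_NAMES)]


def _group_masks(gender: pd.Series, birth_year: pd.Series, reference_year: int) -> dict:
    underaged = (reference_year - birth_year) <= 18
    gm = gender.isin(list(GENDER_MINORITY))
    return {
        "adults": ~underaged,
        "underaged": underaged,
        "non_gender_minority": ~gm,
        "gender_minority": gm,
    }


def _subset_metrics(chats: pd.DataFrame, drops: pd.DataFrame, n_seekers: int) -> dict:
    out = {"n_chats": int(len(chats)), "n_seekers": int(n_seekers),
           "n_dropouts": int(len(drops))}
    rated = chats["rating"].dropna() if len(chats) else pd.Series(dtype=float)
    out["mean_rating"] = float(rated.mean()) if len(rated) else None
    out["pct_blocked"] = float(100.0 * chats["blocked"].mean()) if len(chats) else None
    out["matching_success_rate"] = (
        100.0 * len(chats) / n_seekers if n_seekers else None
    )
    out["mean_wait_matched"] = float(chats["wait_minutes"].mean()) if len(chats) else None
    out["mean_wait_unmatched"] = float(drops["wait_at_drop"].mean()) if len(drops) else None
    return out


def compute_metrics(run: SimulationRun) -> MetricsReport:
    """Summarise a finished run into the five outcome metrics.

    An empty run (or a stratum with no chats) reports absent metrics with a
    warning rather than NaN noise.
    """
    chats = run.chats_frame()
    drops = run.dropouts_frame()
    reference_year = run.config.profile.reference_year
    n_seekers = run.n_seekers_generated

    overall = _subset_metrics(chats, drops, n_seekers)
    if overall["mean_rating"] is None:
        warnings.warn("run has no rated chats; rating/blocking metrics are absent")

    per_group = {}
    if len(chats) or len(drops):
        chat_masks = (
            _group_masks(chats["seeker_gender"], chats["seeker_birth_year"], reference_year)
            if len(chats)
            else {g: pd.Series(dtype=bool) for g in GROUPS}
        )
        drop_masks = (
            _group_masks(drops["seeker_gender"], drops["seeker_birth_year"], reference_year)
            if len(drops)
            else {g: pd.Series(dtype=bool) for g in GROUPS}
        )
        for g in GROUPS:
            g_chats = chats[chat_masks[g]] if len(chats) else chats
            g_drops = drops[drop_masks[g]] if len(drops) else drops
            # group denominator: matched + reneged of the group (still-waiting
            # seekers carry no demographics in the log and are a sliver)
            per_group[g] = _subset_metrics(g_chats, g_drops,
                                           len(g_chats) + len(g_drops))
    return MetricsReport(per_group=per_group, **overall)


@dataclass
class ComparisonResult:
    metric: str
    direction: str  # "greater" | "less": alternative for treatment vs baseline
    baseline_values: list
    treatment_values: list
    t_stat: float
    p_value: float
    significant_05: bool
    significant_001: bool

    def to_dict(self):
        return dataclasses.asdict(self)


def compare_policies(baseline: list, treatment: list, metric: str,
                     direction: str = "greater") -> ComparisonResult:
    """One-tailed Welch t test of a metric between two policy arms.

    ``baseline`` and ``treatment`` are lists of :class:`MetricsReport`, one
    per replicate.  ``direction`` states the alternative hypothesis for the
    treatment arm relative to baseline.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    if len(baseline) < 2 or len(treatment) < 2:
        raise ValueError("need >= 2 replicates per arm")

    def extract(reports):
        vals = []
        for r in reports:
            v = getattr(r, metric)
            if v is None:
                raise ValueError(f"metric {metric!r} absent in a replicate")
            vals.append(float(v))
        return vals

    b, t = extract(baseline), extract(treatment)
    res = stats.ttest_ind(t, b, equal_var=False, alternative=direction)
    return ComparisonResult(
        metric=metric,
        direction=direction,
        baseline_values=b,
        treatment_values=t,
        t_stat=float(res.statistic),
        p_value=float(res.pvalue),
        significant_05=bool(res.pvalue < 0.05),
        significant_001=bool(res.pvalue < 0.001),
    )


def pearson_validation(dist_a, dist_b) -> float:
    """Pearson r between two aligned binned series (>= 3 bins each)."""
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1-d series with >= 3 bins")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a series; correlation undefined")
    r, _ = stats.pearsonr(a, b)
    return float(r)


def patience_validation(profile, samples, kmax: int = 30) -> float:
    """Pearson r between a sampled patience histogram and the profile's
    target integer-minute density evaluated at the same bins."""
    from .population import duration_pmf

    samples = np.asarray(samples)
    hist = np.bincount(np.minimum(samples, kmax), minlength=kmax + 1)[1:]
    target = duration_pmf(profile.patience_mean, profile.patience_sd,
                          profile.patience_family, kmax)
    return pearson_validation(hist / hist.sum(), target)
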