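"""Synthetic population of support seekers and volunteer counselors.

An online mental health community (OMHC) is modelled as two agent classes:
*support seekers*, who join a live queue and wait to be picked for a 1-on-1
chat, and *volunteer counselors*, who each take exactly one chat and then go
offline.  This module generates those agents minute by minute so that their
attribute and duration distributions match the study platform's published
statistics:

* patience (queue reneging time): lognormal, mean 4.16 / SD 3.27 minutes;
* chat length: lognormal, mean 17.67 / SD 15.42 minutes;
* counselor decision time: exponential with rate 1.25 per minute;
* concurrently online agents: ~113.26 seekers and ~102.49 counselors on
  average over a week;
* five gender categories and an 18-topic vocabulary in which
  "self-improvement" is the modal topic, followed by "dating", "parents"
  and "depression".

Durations are drawn from a moment-matched continuous family (lognormal by
default, since empirical waiting and chat times are right-skewed) and then
rounded to whole minutes with a floor of one minute, preserving the stated
means on the 1-minute simulation clock.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError

__all__ = [
    "GENDERS",
    "GENDER_MINORITY",
    "TOPICS",
    "PopulationProfile",
    "SeekerAgent",
    "CounselorAgent",
    "ArrivalSchedule",
    "default_profile",
    "sample_patience",
    "sample_chat_length",
    "sample_decision_delay",
    "generate_agents",
    "build_arrival_schedule",
    "duration_pmf",
]

GENDERS = ("female", "male", "nonbinary", "transgender_female", "transgender_male")

#: Non-cisgender categories; used for the gender-minority stratum and the
#: filter policy's gender-minority pool.
GENDER_MINORITY = frozenset({"nonbinary", "transgender_female", "transgender_male"})

#: The platform's 18-topic vocabulary.
TOPICS = (
    "self-improvement",
    "dating",
    "parents",
    "depression",
    "anxiety",
    "romantic relationships",
    "stress",
    "family",
    "lonely",
    "suicide",
    "pandemic",
    "overwhelming",
    "sexuality",
    "LGBTQ",
    "intimacy",
    "home",
    "dissociative identity",
    "health",
)

_DIST_SUM_TOL = 1e-9


# ---------------------------------------------------------------------------
# agent records
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class SeekerAgent:
    """A support seeker waiting in the live queue.

    ``patience`` is the number of minutes the seeker is willing to spend in
    the queue before cancelling the request; the engine drops the seeker once
    their waited minutes strictly exceed it.
    """

    id: str
    arrival_minute: int
    gender: str
    birth_year: int
    topic: str
    patience: int
    state: str = "waiting"  # waiting | chatting | matched_done | dropped


@dataclass(slots=True)
class CounselorAgent:
    """A volunteer counselor; takes one chat, then goes offline for good.

    ``decision_delay`` is the continuous time (minutes) the counselor browses
    the queue before picking someone; drawn once at generation.
    ``arrival_phase`` is the uniform within-minute offset of the arrival, so
    the counselor becomes eligible to pick in minute
    ``arrival_minute + floor(arrival_phase + decision_delay)`` — an unbiased
    discretisation of the continuous decision time onto the minute clock.
    ``idle_timeout`` bounds how long an unmatched counselor stays online.
    """

    id: str
    arrival_minute: int
    gender: str
    birth_year: int
    topics: tuple
    decision_delay: float
    idle_timeout: int
    arrival_phase: float = 0.0
    state: str = "available"  # available | chatting | offline

    @property
    def ready_minute(self) -> int:
        return self.arrival_minute + int(self.arrival_phase + self.decision_delay)


# ---------------------------------------------------------------------------
# profile
# ---------------------------------------------------------------------------


def _validate_dist(name, dist, keys=None):
    if not dist:
        raise ConfigurationError(f"{name}: empty distribution")
    total = float(sum(dist.values()))
    if abs(total - 1.0) > _DIST_SUM_TOL:
        raise ConfigurationError(f"{name}: probabilities sum to {total!r}, not 1")
    if any(p < 0 for p in dist.values()):
        raise ConfigurationError(f"{name}: negative probability")
    if keys is not None:
        unknown = set(dist) - set(keys)
        if unknown:
            raise ConfigurationError(f"{name}: unknown categories {sorted(unknown)}")


@dataclass
class PopulationProfile:
    """Distributional description of the agent population.

    All categorical distributions are ``{category: probability}`` mappings
    summing to one.  Duration parameters are the target mean/SD of the
    *continuous* moment-matched family; integerisation happens at sampling
    time.  ``arrival_targets`` holds the weekly mean/SD of concurrently
    online agents used to calibrate the arrival schedule.
    """

    seeker_gender_dist: dict
    counselor_gender_dist: dict
    seeker_birth_year_dist: dict
    counselor_birth_year_dist: dict
    topic_dist: dict
    patience_mean: float = 4.16
    patience_sd: float = 3.27
    patience_family: str = "lognormal"
    chat_length_mean: float = 17.67
    chat_length_sd: float = 15.42
    chat_length_family: str = "lognormal"
    decision_rate: float = 1.25
    arrival_targets: dict = field(
        default_factory=lambda: {
            "seeker_online_mean": 113.26,
            "seeker_online_sd": 22.56,
            "counselor_online_mean": 102.49,
            "counselor_online_sd": 25.07,
        }
    )
    counselor_idle_factor: float = 3.0
    counselor_topics_max: int = 3
    reference_year: int = 2021

    def __post_init__(self):
        self.validate()

    def validate(self):
        _validate_dist("seeker_gender_dist", self.seeker_gender_dist, GENDERS)
        _validate_dist("counselor_gender_dist", self.counselor_gender_dist, GENDERS)
        _validate_dist("seeker_birth_year_dist", self.seeker_birth_year_dist)
        _validate_dist("counselor_birth_year_dist", self.counselor_birth_year_dist)
        _validate_dist("topic_dist", self.topic_dist)
        if len(self.topic_dist) != len(TOPICS):
            raise ConfigurationError(
                f"topic_dist must cover the {len(TOPICS)}-topic vocabulary, "
                f"got {len(self.topic_dist)} topics"
            )
        for label, mean, sd in (
            ("patience", self.patience_mean, self.patience_sd),
            ("chat_length", self.chat_length_mean, self.chat_length_sd),
        ):
            if mean <= 0 or sd <= 0:
                raise ConfigurationError(f"{label}: mean and sd must be positive")
        if self.decision_rate <= 0:
            raise ConfigurationError("decision_rate must be positive")
        if not 1 <= self.counselor_topics_max <= len(TOPICS):
            raise ConfigurationError("counselor_topics_max out of range")
        if self.counselor_idle_factor <= 0:
            raise ConfigurationError("counselor_idle_factor must be positive")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # JSON keys are strings; keep birth years round-trippable
        d["seeker_birth_year_dist"] = {str(k): v for k, v in self.seeker_birth_year_dist.items()}
        d["counselor_birth_year_dist"] = {
            str(k): v for k, v in self.counselor_birth_year_dist.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationProfile":
        d = dict(d)
        for key in ("seeker_birth_year_dist", "counselor_birth_year_dist"):
            if key in d:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        return cls(**d)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PopulationProfile":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    # -- derived quantities -------------------------------------------------

    def underaged_share(self, side: str = "seeker") -> float:
        """Probability that an agent is aged <= 18 at the reference year."""
        dist = self.seeker_birth_year_dist if side == "seeker" else self.counselor_birth_year_dist
        return sum(p for y, p in dist.items() if self.reference_year - y <= 18)

    def gender_minority_share(self, side: str = "seeker") -> float:
        dist = self.seeker_gender_dist if side == "seeker" else self.counselor_gender_dist
        return sum(p for g, p in dist.items() if g in GENDER_MINORITY)


# ---------------------------------------------------------------------------
# default profile
# ---------------------------------------------------------------------------


def _topic_defaults() -> dict:
    # synthetic defaults: only the printed top-4 ranking is empirical
    # (self-improvement > dating > parents > depression); the remaining mass
    # decays smoothly across the vocabulary.
    probs = [
        0.125, 0.095, 0.085, 0.075, 0.065, 0.060, 0.055, 0.050, 0.050,
        0.045, 0.045, 0.040, 0.040, 0.035, 0.035, 0.035, 0.030, 0.035,
    ]
    d = dict(zip(TOPICS, probs))
    total = sum(d.values())
    return {k: v / total for k, v in d.items()}


def _birth_year_defaults(reference_year: int, underaged_share: float, min_age: int,
                         max_age: int, decay: float) -> dict:
    """Discrete birth-year distribution with a fixed underaged (<=18) share.

    Teen years (min_age..18) share ``underaged_share`` uniformly; adult ages
    get exponentially decaying weight, emulating the young-adult skew of
    online peer-support platforms.
    """
    years = {}
    teen_ages = list(range(min_age, 19))
    for a in teen_ages:
        years[reference_year - a] = underaged_share / len(teen_ages)
    adult_ages = list(range(19, max_age + 1))
    w = np.exp(-(np.arange(len(adult_ages))) / decay)
    w = (1.0 - underaged_share) * w / w.sum()
    for a, p in zip(adult_ages, w):
        years[reference_year - a] = float(p)
    return years


def default_profile() -> PopulationProfile:
    """The packaged synthetic default profile.

    Duration moments, the arrival targets, the decision rate, the gender
    category set and the topic ranking are the platform's published
    statistics.  The remaining shares are synthetic defaults chosen so that
    (a) all five gender categories and both vulnerable strata are non-empty
    and (b) the seeker-side strata weights (underaged ~17.8%, gender
    minority ~5%) are consistent with the platform's published group-level
    rating/blocking marginals.
    """
    return PopulationProfile(
        seeker_gender_dist={
            "female": 0.64,
            "male": 0.31,
            "nonbinary": 0.03,
            "transgender_female": 0.01,
            "transgender_male": 0.01,
        },
        counselor_gender_dist={
            "female": 0.60,
            "male": 0.34,
            "nonbinary": 0.03,
            "transgender_female": 0.015,
            "transgender_male": 0.015,
        },
        seeker_birth_year_dist=_birth_year_defaults(2021, 0.1784, 13, 70, 12.0),
        counselor_birth_year_dist=_birth_year_defaults(2021, 0.15, 15, 75, 14.0),
        topic_dist=_topic_defaults(),
    )


# ---------------------------------------------------------------------------
# duration sampling
# ---------------------------------------------------------------------------


def _lognormal_params(mean: float, sd: float):
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_continuous(mean, sd, family, rng, size):
    if sd <= 0 or mean <= 0:
        raise ConfigurationError("duration mean and sd must be positive")
    if family == "lognormal":
        mu, sigma = _lognormal_params(mean, sd)
        return rng.lognormal(mu, sigma, size)
    if family == "gamma":
        shape = (mean / sd) ** 2
        return rng.gamma(shape, sd**2 / mean, size)
    if family == "exponential":
        return rng.exponential(mean, size)
    raise ConfigurationError(f"unknown duration family {family!r}")


def _integerize(x):
    """Round continuous minutes to the 1-minute clock, floored at 1."""
    return np.maximum(1, np.rint(x)).astype(np.int64)


def sample_patience(profile: PopulationProfile, rng: np.random.Generator, size=None):
    """Draw integer patience minutes (>= 1) from the moment-matched family."""
    x = _draw_continuous(
        profile.patience_mean, profile.patience_sd, profile.patience_family, rng, size
    )
    out = _integerize(x)
    return int(out) if size is None else out


def sample_chat_length(profile: PopulationProfile, rng: np.random.Generator, size=None):
    """Draw integer chat length minutes (>= 1) from the moment-matched family."""
    x = _draw_continuous(
        profile.chat_length_mean, profile.chat_length_sd, profile.chat_length_family, rng, size
    )
    out = _integerize(x)
    return int(out) if size is None else out


def sample_decision_delay(profile: PopulationProfile, rng: np.random.Generator, size=None):
    """Draw a counselor decision delay (continuous minutes, exponential)."""
    if profile.decision_rate <= 0:
        raise ConfigurationError("decision_rate must be positive")
    out = rng.exponential(1.0 / profile.decision_rate, size)
    return float(out) if size is None else out


def duration_pmf(mean: float, sd: float, family: str, kmax: int) -> np.ndarray:
    """Exact pmf of the integerised duration on 1..kmax (tail lumped at kmax).

    The integerisation is round-half-to-nearest with a floor at one minute,
    so ``P(k) = F(k+0.5) - F(k-0.5)`` for k >= 2 and ``P(1) = F(1.5)``.
    """
    if family == "lognormal":
        mu, sigma = _lognormal_params(mean, sd)
        dist = stats.lognorm(s=sigma, scale=math.exp(mu))
    elif family == "gamma":
        shape = (mean / sd) ** 2
        dist = stats.gamma(shape, scale=sd**2 / mean)
    elif family == "exponential":
        dist = stats.expon(scale=mean)
    else:
        raise ConfigurationError(f"unknown duration family {family!r}")
    edges = np.arange(1, kmax + 1) + 0.5
    cdf = dist.cdf(edges)
    pmf = np.diff(np.concatenate([[0.0], cdf]))
    pmf[-1] += 1.0 - cdf[-1]
    return pmf


# ---------------------------------------------------------------------------
# categorical sampling helpers
# ---------------------------------------------------------------------------


class _Categorical:
    """Cumulative-probability sampler with stable category order."""

    def __init__(self, dist: dict):
        self.categories = list(dist.keys())
        self.p = np.asarray([dist[c] for c in self.categories], dtype=float)
        self.cum = np.cumsum(self.p)
        self.cum[-1] = 1.0

    def draw(self, rng, size):
        idx = np.searchsorted(self.cum, rng.random(size), side="right")
        return idx


class _ProfileSamplers:
    """Per-profile precomputed samplers; cached on the profile instance."""

    def __init__(self, profile: PopulationProfile):
        self.seeker_gender = _Categorical(profile.seeker_gender_dist)
        self.counselor_gender = _Categorical(profile.counselor_gender_dist)
        self.seeker_year = _Categorical(profile.seeker_birth_year_dist)
        self.counselor_year = _Categorical(profile.counselor_birth_year_dist)
        self.topic = _Categorical(profile.topic_dist)


def _samplers(profile: PopulationProfile) -> _ProfileSamplers:
    s = getattr(profile, "_samplers_cache", None)
    if s is None:
        s = _ProfileSamplers(profile)
        profile._samplers_cache = s
    return s


# ---------------------------------------------------------------------------
# arrival schedule
# ---------------------------------------------------------------------------


@dataclass
class ArrivalSchedule:
    """Per-minute arrival plan for one simulation horizon.

    Two modes:

    ``online_target`` (default)
        A top-up controller: each minute the engine generates
        ``max(0, target(t) - currently_online)`` new agents per side, so the
        number of concurrently online agents (waiting + chatting) tracks the
        platform's observed weekly curve.  With a flat template the targets
        are the published weekly means.

    ``poisson``
        Stationary Poisson arrivals whose rates are solved from the
        steady-state relation online ≈ arrival rate × mean online sojourn.
    """

    mode: str
    horizon: int
    seeker_target: np.ndarray  # per-minute target online count (online_target)
    counselor_target: np.ndarray
    seeker_rate: float = 0.0  # per-minute Poisson rate (poisson mode)
    counselor_rate: float = 0.0

    def arrivals(self, minute: int, online_seekers: int, online_counselors: int,
                 rng: np.random.Generator):
        """Number of (seekers, counselors) to generate this minute."""
        if self.mode == "poisson":
            return int(rng.poisson(self.seeker_rate)), int(rng.poisson(self.counselor_rate))
        ds = self.seeker_target[minute] - online_seekers
        dc = self.counselor_target[minute] - online_counselors
        return _stochastic_round(ds, rng), _stochastic_round(dc, rng)


def _stochastic_round(x: float, rng) -> int:
    if x <= 0:
        return 0
    base = int(x)
    frac = x - base
    return base + (1 if rng.random() < frac else 0)


def _mean_integer_duration(mean, sd, family, kmax=600) -> float:
    pmf = duration_pmf(mean, sd, family, kmax)
    return float(np.sum(pmf * np.arange(1, kmax + 1)))


def _solve_poisson_rates(profile: PopulationProfile):
    """Steady-state arrival rates for the stationary-Poisson mode.

    Counselors: online sojourn = decision delay (the minute-clock
    discretisation with a uniform arrival phase is unbiased) + chat length.  Seekers: sojourn mixes matched
    (wait + chat) and reneged (patience + 1) paths; the matched fraction and
    conditional waits come from a uniform-selection hazard model solved by
    fixed point.
    """
    t = profile.arrival_targets
    e_chat = _mean_integer_duration(
        profile.chat_length_mean, profile.chat_length_sd, profile.chat_length_family
    )
    e_pick = 1.0 / profile.decision_rate
    lam_c = t["counselor_online_mean"] / (e_pick + e_chat)

    pat_pmf = duration_pmf(profile.patience_mean, profile.patience_sd,
                           profile.patience_family, 200)
    ks = np.arange(1, len(pat_pmf) + 1)

    def online_seekers(lam_s):
        m = min(1.0, lam_c / lam_s)
        # hazard q solving matched fraction = 1 - E[q^(T+1)]
        lo, hi = 1e-6, 1 - 1e-6
        for _ in range(80):
            q = 0.5 * (lo + hi)
            if 1.0 - float(np.sum(pat_pmf * q ** (ks + 1))) > m:
                lo = q
            else:
                hi = q
        q = 0.5 * (lo + hi)
        p = 1.0 - q
        # E[w * 1(matched)] with opportunities at waits 0..T
        s_cum = np.cumsum(np.arange(0, len(pat_pmf) + 1) * q ** np.arange(0, len(pat_pmf) + 1))
        e_w_matched = p * float(np.sum(pat_pmf * s_cum[ks])) / max(m, 1e-12)
        drop_w = pat_pmf * q ** (ks + 1)
        e_drop = float(np.sum((ks + 1) * drop_w) / max(np.sum(drop_w), 1e-12))
        matched_rate = lam_s * m
        return matched_rate * (e_w_matched + e_chat) + (lam_s - matched_rate) * e_drop

    target = t["seeker_online_mean"]
    lo, hi = lam_c, lam_c
    if online_seekers(lam_c * 1.0000001) > target:
        raise ConfigurationError(
            "seeker online target unreachable: even at matching rate ~1 the "
            f"steady-state online count exceeds {target}"
        )
    hi = lam_c * 2
    while online_seekers(hi) < target:
        hi *= 2
        if hi > 1e4:
            raise ConfigurationError("seeker online target unreachable (diverged)")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if online_seekers(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), lam_c


def build_arrival_schedule(profile: PopulationProfile, horizon_minutes: int,
                           rng: np.random.Generator, mode: str = "online_target",
                           weekly_template=None) -> ArrivalSchedule:
    """Build the arrival plan for ``horizon_minutes`` one-minute periods.

    ``weekly_template`` is an optional array of positive multipliers (any
    length; tiled over the horizon) applied to both online-count targets,
    for reproducing a periodic weekly load curve.  The default flat template
    targets the published weekly means.
    """
    if horizon_minutes < 0:
        raise ConfigurationError("horizon must be >= 0")
    t = profile.arrival_targets
    if mode == "poisson":
        lam_s, lam_c = _solve_poisson_rates(profile)
        z = np.zeros(max(horizon_minutes, 1))
        return ArrivalSchedule("poisson", horizon_minutes, z, z,
                               seeker_rate=lam_s, counselor_rate=lam_c)
    if mode != "online_target":
        raise ConfigurationError(f"unknown arrival mode {mode!r}")
    if weekly_template is None:
        mult = np.ones(max(horizon_minutes, 1))
    else:
        weekly_template = np.asarray(weekly_template, dtype=float)
        if np.any(weekly_template < 0):
            raise ConfigurationError("weekly template must be nonnegative")
        reps = int(np.ceil(max(horizon_minutes, 1) / len(weekly_template)))
        mult = np.tile(weekly_template, reps)[: max(horizon_minutes, 1)]
    return ArrivalSchedule(
        "online_target",
        horizon_minutes,
        seeker_target=t["seeker_online_mean"] * mult,
        counselor_target=t["counselor_online_mean"] * mult,
    )


# ---------------------------------------------------------------------------
# agent generation
# ---------------------------------------------------------------------------


def generate_agents(minute: int, profile: PopulationProfile, schedule: ArrivalSchedule,
                    rng: np.random.Generator, online_seekers: int = 0,
                    online_counselors: int = 0, id_counters=None):
    """Generate this minute's newly arriving agents.

    ``online_seekers`` / ``online_counselors`` are the current counts of
    online agents (waiting + chatting), consumed by the top-up arrival mode.
    ``id_counters`` is an optional two-element list [next_seeker, next_counselor]
    mutated in place so ids stay unique across calls.
    """
    n_s, n_c = schedule.arrivals(minute, online_seekers, online_counselors, rng)
    if id_counters is None:
        id_counters = [0, 0]
    sam = _samplers(profile)
    seekers = []
    counselors = []
    if n_s:
        g_idx = sam.seeker_gender.draw(rng, n_s)
        y_idx = sam.seeker_year.draw(rng, n_s)
        t_idx = sam.topic.draw(rng, n_s)
        pat = sample_patience(profile, rng, n_s)
        for i in range(n_s):
            seekers.append(
                SeekerAgent(
                    id=f"s{id_counters[0]}",
                    arrival_minute=minute,
                    gender=sam.seeker_gender.categories[g_idx[i]],
                    birth_year=sam.seeker_year.categories[y_idx[i]],
                    topic=sam.topic.categories[t_idx[i]],
                    patience=int(pat[i]),
                )
            )
            id_counters[0] += 1
    if n_c:
        g_idx = sam.counselor_gender.draw(rng, n_c)
        y_idx = sam.counselor_year.draw(rng, n_c)
        delays = sample_decision_delay(profile, rng, n_c)
        phases = rng.random(n_c)
        timeouts = _integerize(
            profile.counselor_idle_factor
            * _draw_continuous(profile.patience_mean, profile.patience_sd,
                               profile.patience_family, rng, n_c)
        )
        for i in range(n_c):
            k = int(rng.integers(1, profile.counselor_topics_max + 1))
            t_drawn = sam.topic.draw(rng, 3 * k)  # oversample, dedupe, trim
            topics = []
            for j in t_drawn:
                topic = sam.topic.categories[j]
                if topic not in topics:
                    topics.append(topic)
                if len(topics) == k:
                    break
            counselors.append(
                CounselorAgent(
                    id=f"c{id_counters[1]}",
                    arrival_minute=minute,
                    gender=sam.counselor_gender.categories[g_idx[i]],
                    birth_year=sam.counselor_year.categories[y_idx[i]],
                    topics=tuple(topics),
                    decision_delay=float(delays[i]),
                    idle_timeout=int(timeouts[i]),
                    arrival_phase=float(phases[i]),
                )
            )
            id_counters[1] += 1
    return seekers, counselors
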