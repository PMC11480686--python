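"""Stochastic chat-outcome model: 1-5 star ratings and blocking.

The study platform evaluated simulated chats with random-forest predictors
trained on its proprietary chat logs.  Those predictors cannot travel with
this package, so chats are scored by a transparent parametric stand-in:

* the rating is drawn from an ordered-categories (proportional-odds)
  construction — a base star distribution defines logistic cutpoints, and a
  latent score shifts the cumulative probabilities.  The latent score is the
  sum of a per-group calibrated shift and optional pair-level modifiers
  (topic match, gender match, age proximity), all zero by default;
* blocking is a Bernoulli draw whose log-odds are a per-group calibrated
  intercept plus the same modifiers.

Groups are the seeker-side 2x2 strata adult/underaged x gender-minority/not.
`calibrate` fits the per-group parameters so simulated group marginals
reproduce a target table (by default the platform's published
replication-baseline marginals), then verifies the fit by Monte Carlo.

The interface is pluggable: any object with ``predict_rating`` /
``predict_block`` of the same signature can replace this model where real
training data exist.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .exceptions import CalibrationError, ConfigurationError
from .population import GENDER_MINORITY, PopulationProfile

__all__ = [
    "AGE_GROUPS",
    "GENDER_GROUPS",
    "OutcomeModelParams",
    "ChatOutcome",
    "replication_targets",
    "seeker_groups",
    "pair_features",
    "predict_rating",
    "predict_block",
    "star_distribution",
    "calibrate",
    "sample_pair_outcomes",
]

AGE_GROUPS = ("adults", "underaged")
GENDER_GROUPS = ("non_gender_minority", "gender_minority")

#: Star-share shape of the replication baseline (proportions of 1..5 stars),
#: used as the anchor distribution from which the logistic cutpoints are built.
REPLICATION_STAR_SHAPE = (0.1496, 0.0464, 0.0608, 0.0926, 0.6506)

_MODIFIER_NAMES = ("topic_match", "gender_match", "age_proximity")


def replication_targets() -> dict:
    """The published replication-baseline outcome marginals (group-level mean
    star ratings and blocked-pair percentages)."""
    return {
        "rating": {
            "adults": 4.00,
            "underaged": 4.28,
            "non_gender_minority": 4.06,
            "gender_minority": 3.80,
        },
        "block_pct": {
            "adults": 6.73,
            "underaged": 1.85,
            "non_gender_minority": 5.45,
            "gender_minority": 12.31,
        },
    }


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


def _cutpoints_from_shape(shape) -> tuple:
    p = np.asarray(shape, dtype=float)
    if p.size != 5 or np.any(p < 0):
        raise ConfigurationError("star shape must be 5 nonnegative probabilities")
    p = p / p.sum()
    cum = np.cumsum(p)[:4]
    cum = np.clip(cum, 1e-9, 1 - 1e-9)
    return tuple(float(math.log(c / (1 - c))) for c in cum)


@dataclass
class OutcomeModelParams:
    """Calibrated group-level outcome parameters plus pair-level modifiers.

    ``rating_shift`` / ``block_logit`` are keyed by (age_group, gender_group)
    cells.  ``modifiers`` maps feature name -> {"rating": shift, "block":
    log-odds shift}; they default to zero ("demographics-only" mode) and are
    only activated by explicitly labelled scenario configs.
    """

    cutpoints: tuple = field(default_factory=lambda: _cutpoints_from_shape(REPLICATION_STAR_SHAPE))
    rating_shift: dict = field(
        default_factory=lambda: {(a, g): 0.0 for a in AGE_GROUPS for g in GENDER_GROUPS}
    )
    block_logit: dict = field(
        default_factory=lambda: {(a, g): math.log(0.0586 / (1 - 0.0586))
                                 for a in AGE_GROUPS for g in GENDER_GROUPS}
    )
    modifiers: dict = field(
        default_factory=lambda: {m: {"rating": 0.0, "block": 0.0} for m in _MODIFIER_NAMES}
    )
    reference_year: int = 2021
    calibrated: bool = False

    def validate(self):
        if len(self.cutpoints) != 4 or any(
            self.cutpoints[i] >= self.cutpoints[i + 1] for i in range(3)
        ):
            raise ConfigurationError("cutpoints must be 4 strictly increasing reals")
        for d in (self.rating_shift, self.block_logit):
            for a in AGE_GROUPS:
                for g in GENDER_GROUPS:
                    v = d[(a, g)]
                    if not math.isfinite(v):
                        raise ConfigurationError("non-finite group parameter")
        for m, eff in self.modifiers.items():
            if m not in _MODIFIER_NAMES:
                raise ConfigurationError(f"unknown modifier {m!r}")
            if not all(math.isfinite(v) for v in eff.values()):
                raise ConfigurationError(f"non-finite modifier {m!r}")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rating_shift"] = {f"{a}|{g}": v for (a, g), v in self.rating_shift.items()}
        d["block_logit"] = {f"{a}|{g}": v for (a, g), v in self.block_logit.items()}
        d["cutpoints"] = list(self.cutpoints)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OutcomeModelParams":
        d = dict(d)
        d["cutpoints"] = tuple(d["cutpoints"])
        d["rating_shift"] = {tuple(k.split("|")): v for k, v in d["rating_shift"].items()}
        d["block_logit"] = {tuple(k.split("|")): v for k, v in d["block_logit"].items()}
        return cls(**d)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "OutcomeModelParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(slots=True)
class ChatOutcome:
    rating: int
    blocked: bool


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def seeker_groups(seeker, reference_year: int):
    """(age_group, gender_group) cell of a seeker."""
    age = "underaged" if (reference_year - seeker.birth_year) <= 18 else "adults"
    gm = "gender_minority" if seeker.gender in GENDER_MINORITY else "non_gender_minority"
    return age, gm


def pair_features(seeker, counselor) -> dict:
    """Pair-level covariates feeding the modifiers."""
    gap = abs(seeker.birth_year - counselor.birth_year)
    return {
        "topic_match": 1.0 if seeker.topic in counselor.topics else 0.0,
        "gender_match": 1.0 if seeker.gender == counselor.gender else 0.0,
        "age_proximity": max(0.0, 1.0 - gap / 40.0),
    }


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def star_distribution(params: OutcomeModelParams, eta: float) -> np.ndarray:
    """Analytic star pmf for latent shift ``eta`` (vectorised over eta)."""
    c = np.asarray(params.cutpoints)
    eta = np.asarray(eta, dtype=float)
    cum = _sigmoid(c - eta[..., None])  # P(star <= k), k = 1..4
    cum = np.concatenate([cum, np.ones(eta.shape + (1,))], axis=-1)
    return np.diff(np.concatenate([np.zeros(eta.shape + (1,)), cum], axis=-1), axis=-1)


def _mean_star(params: OutcomeModelParams, eta) -> float:
    c = np.asarray(params.cutpoints)
    return float(5.0 - np.sum(_sigmoid(c - eta)))


def _warn_uncalibrated(params):
    if not params.calibrated:
        warnings.warn(
            "outcome model parameters are uncalibrated; using base distributions as-is",
            stacklevel=3,
        )


def _latent(params, seeker, counselor, kind):
    cell = seeker_groups(seeker, params.reference_year)
    base = params.rating_shift[cell] if kind == "rating" else params.block_logit[cell]
    feats = pair_features(seeker, counselor)
    return base + sum(params.modifiers[m][kind] * feats[m] for m in params.modifiers)


def predict_rating(seeker, counselor, params: OutcomeModelParams,
                   rng: np.random.Generator) -> int:
    """Sample a 1-5 star rating for a matched pair."""
    _warn_uncalibrated(params)
    eta = _latent(params, seeker, counselor, "rating")
    u = rng.random()
    cum = 0.0
    for k, c in enumerate(params.cutpoints, start=1):
        cum = 1.0 / (1.0 + math.exp(eta - c))  # sigmoid(c - eta)
        if u < cum:
            return k
    return 5


def predict_block(seeker, counselor, params: OutcomeModelParams,
                  rng: np.random.Generator) -> bool:
    """Sample whether either side of a matched pair blocks the other."""
    _warn_uncalibrated(params)
    z = _latent(params, seeker, counselor, "block")
    p = 1.0 / (1.0 + math.exp(-z))
    return bool(rng.random() < p)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def _cell_weights(profile: PopulationProfile) -> dict:
    """Seeker-side 2x2 cell probabilities (gender and birth year are drawn
    independently by the generator, so the cells factorise)."""
    wu = profile.underaged_share("seeker")
    wg = profile.gender_minority_share("seeker")
    return {
        ("adults", "non_gender_minority"): (1 - wu) * (1 - wg),
        ("adults", "gender_minority"): (1 - wu) * wg,
        ("underaged", "non_gender_minority"): wu * (1 - wg),
        ("underaged", "gender_minority"): wu * wg,
    }


def _group_cells(group):
    if group in AGE_GROUPS:
        return [(group, g) for g in GENDER_GROUPS]
    return [(a, group) for a in AGE_GROUPS]


def _solve_additive(targets: dict, weights: dict, value_of_cell, lo=-30.0, hi=30.0,
                    sweeps=60, tol=1e-10):
    """Fit cell parameter x[cell] = alpha[age] + beta[gender] so that the
    weighted group marginals of ``value_of_cell(x)`` match ``targets``.

    ``value_of_cell(x)`` must be strictly increasing in x (mean star or block
    probability).  Coordinate descent over the four group offsets; each step
    is a 1-d root solve.  Groups with zero weight or absent from the target
    table are skipped.
    """
    alpha = {a: 0.0 for a in AGE_GROUPS}
    beta = {g: 0.0 for g in GENDER_GROUPS}

    def marginal(group, alpha, beta):
        cells = _group_cells(group)
        w = np.array([weights[c] for c in cells])
        if w.sum() == 0:
            return None
        v = np.array([value_of_cell(alpha[c[0]] + beta[c[1]]) for c in cells])
        return float(np.sum(w * v) / w.sum())

    last = None
    for _ in range(sweeps):
        for group in list(AGE_GROUPS) + list(GENDER_GROUPS):
            if group not in targets:
                continue
            is_age = group in AGE_GROUPS
            cur = marginal(group, alpha, beta)
            if cur is None:
                continue

            def f(x):
                if is_age:
                    a2 = dict(alpha, **{group: x})
                    return marginal(group, a2, beta) - targets[group]
                b2 = dict(beta, **{group: x})
                return marginal(group, alpha, b2) - targets[group]

            if f(lo) > 0 or f(hi) < 0:
                raise CalibrationError(
                    f"target for group {group!r} unreachable within parameter bounds"
                )
            x = brentq(f, lo, hi, xtol=1e-12)
            if is_age:
                alpha[group] = x
            else:
                beta[group] = x
        vec = tuple(alpha.values()) + tuple(beta.values())
        if last is not None and max(abs(a - b) for a, b in zip(vec, last)) < tol:
            break
        last = vec
    return {(a, g): alpha[a] + beta[g] for a in AGE_GROUPS for g in GENDER_GROUPS}


def calibrate(targets: dict, profile: PopulationProfile, n_sim: int = 100_000,
              rng=None, tol_rating: float = 0.02, tol_block_pp: float = 0.3,
              max_iter: int = 5, star_shape=REPLICATION_STAR_SHAPE) -> OutcomeModelParams:
    """Fit group-level outcome parameters to a target marginal table.

    ``targets`` has the shape of :func:`replication_targets`: per-group mean
    star ratings under ``"rating"`` and blocked percentages under
    ``"block_pct"`` (either key may be omitted).  The additive group model is
    solved by coordinate root-finding on the model's exact group marginals,
    sweeping the four group offsets until the largest residual is within
    tolerance (``max_iter`` restarts with more sweeps before giving up).
    An ``n_sim``-pair Monte Carlo draw then estimates the achieved marginals
    for the calibration report; the analytic residuals, not the Monte Carlo
    ones, decide convergence, since a small stratum's sampling error at
    feasible ``n_sim`` exceeds the blocking tolerance.

    The fitted report is attached as ``params.calibration_report``.
    """
    rng = np.random.default_rng(rng)
    params = OutcomeModelParams(cutpoints=_cutpoints_from_shape(star_shape),
                                reference_year=profile.reference_year)
    weights = _cell_weights(profile)

    rating_targets = dict(targets.get("rating", {}))
    block_targets = dict(targets.get("block_pct", {}))

    def analytic_marginal(kind, group):
        cells = _group_cells(group)
        w = np.array([weights[c] for c in cells])
        if w.sum() == 0:
            return None
        if kind == "rating":
            v = np.array([_mean_star(params, params.rating_shift[c]) for c in cells])
        else:
            v = np.array(
                [100.0 / (1.0 + math.exp(-params.block_logit[c])) for c in cells]
            )
        return float(np.sum(w * v) / w.sum())

    resid = {}
    for it in range(1, max_iter + 1):
        sweeps = 60 * it
        if rating_targets:
            params.rating_shift = _solve_additive(
                rating_targets, weights, lambda x: _mean_star(params, x), sweeps=sweeps
            )
        if block_targets:
            params.block_logit = _solve_additive(
                {k: v / 100.0 for k, v in block_targets.items()},
                weights,
                lambda x: 1.0 / (1.0 + math.exp(-x)),
                sweeps=sweeps,
            )
        ok = True
        for group, tval in rating_targets.items():
            m = analytic_marginal("rating", group)
            if m is None:
                continue
            resid[("rating", group)] = m - tval
            ok &= abs(m - tval) <= tol_rating
        for group, tval in block_targets.items():
            m = analytic_marginal("block_pct", group)
            if m is None:
                continue
            resid[("block_pct", group)] = m - tval
            ok &= abs(m - tval) <= tol_block_pp
        if ok:
            break
    else:
        raise CalibrationError(
            f"calibration did not converge after {max_iter} iterations",
            residuals=resid,
        )
    params.calibrated = True
    params.validate()

    df = sample_pair_outcomes(profile, params, n_sim, rng)
    achieved_r, achieved_b = {}, {}
    for group in rating_targets:
        mask = _group_mask(df, group)
        if mask.any():
            achieved_r[group] = float(df.loc[mask, "rating"].mean())
    for group in block_targets:
        mask = _group_mask(df, group)
        if mask.any():
            achieved_b[group] = float(df.loc[mask, "blocked"].mean() * 100.0)
    params.calibration_report = {
        "targets": targets,
        "n_sim": int(n_sim),
        "iterations": it,
        "analytic_residuals": {f"{k[0]}:{k[1]}": v for k, v in resid.items()},
        "achieved_monte_carlo": {"rating": achieved_r, "block_pct": achieved_b},
    }
    return params


def _group_mask(df, group):
    if group in AGE_GROUPS:
        return df["age_group"] == group
    return df["gender_group"] == group


def sample_pair_outcomes(profile: PopulationProfile, params: OutcomeModelParams,
                         n: int, rng: np.random.Generator):
    """Draw outcomes for ``n`` matched pairs sampled from the profile.

    Pairs are independent seeker/counselor draws from the demographic
    profile (modifiers, if nonzero, use the sampled pair covariates).
    Returns a DataFrame with seeker strata, rating and blocked columns.
    """
    import pandas as pd

    from .population import _samplers  # shared categorical samplers

    rng = np.random.default_rng(rng)
    sam = _samplers(profile)
    s_gender = np.array(sam.seeker_gender.categories)[sam.seeker_gender.draw(rng, n)]
    s_year = np.array(sam.seeker_year.categories)[sam.seeker_year.draw(rng, n)]
    s_topic_idx = sam.topic.draw(rng, n)
    c_gender = np.array(sam.counselor_gender.categories)[sam.counselor_gender.draw(rng, n)]
    c_year = np.array(sam.counselor_year.categories)[sam.counselor_year.draw(rng, n)]
    # counselor topic lists reduced to the membership indicator of the
    # seeker's topic; probability the seeker's topic is covered by a k-list
    topic_p = np.array([profile.topic_dist[t] for t in profile.topic_dist])
    k = rng.integers(1, profile.counselor_topics_max + 1, size=n)
    p_seeker_topic = topic_p[s_topic_idx]
    cover = 1.0 - (1.0 - p_seeker_topic) ** k
    topic_match = rng.random(n) < cover

    age_group = np.where(params.reference_year - s_year <= 18, "underaged", "adults")
    gm = np.isin(s_gender, list(GENDER_MINORITY))
    gender_group = np.where(gm, "gender_minority", "non_gender_minority")

    feats = {
        "topic_match": topic_match.astype(float),
        "gender_match": (s_gender == c_gender).astype(float),
        "age_proximity": np.maximum(0.0, 1.0 - np.abs(s_year - c_year) / 40.0),
    }
    mod_r = sum(params.modifiers[m]["rating"] * feats[m] for m in params.modifiers)
    mod_b = sum(params.modifiers[m]["block"] * feats[m] for m in params.modifiers)

    eta = np.array(
        [params.rating_shift[(a, g)] for a, g in zip(age_group, gender_group)]
    ) + mod_r
    cum = _sigmoid(np.asarray(params.cutpoints)[None, :] - eta[:, None])
    u = rng.random(n)
    rating = 1 + np.sum(u[:, None] >= cum, axis=1)

    z = np.array(
        [params.block_logit[(a, g)] for a, g in zip(age_group, gender_group)]
    ) + mod_b
    blocked = rng.random(n) < _sigmoid(z)

    return pd.DataFrame(
        {
            "age_group": age_group,
            "gender_group": gender_group,
            "topic_match": feats["topic_match"].astype(bool),
            "rating": rating.astype(int),
            "blocked": blocked,
        }
    )
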