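import math

import numpy as np
import pytest
from scipy import stats

import omhcsim as om
from omhcsim.exceptions import ConfigurationError
from omhcsim.population import (
    _draw_continuous,
    build_arrival_schedule,
    duration_pmf,
    generate_agents,
)


def test_duration_families_recover_target_moments(profile):
    """Continuous moment matching and integerisation both preserve the
    published patience / chat-length means."""
    rng = np.random.default_rng(11)
    # closed-form lognormal moment matching, continuous draws at n = 1e6
    x = _draw_continuous(4.16, 3.27, "lognormal", rng, 1_000_000)
    assert x.mean() == pytest.approx(4.16, rel=0.01)
    assert x.std() == pytest.approx(3.27, rel=0.01)
    sigma2 = math.log(1 + (3.27 / 4.16) ** 2)
    mu = math.log(4.16) - sigma2 / 2
    assert np.log(x).mean() == pytest.approx(mu, abs=0.01)

    pat = om.sample_patience(profile, rng, 100_000)
    assert pat.mean() == pytest.approx(4.16, rel=0.02)
    assert pat.min() >= 1 and np.issubdtype(pat.dtype, np.integer)

    chat = om.sample_chat_length(profile, rng, 100_000)
    assert chat.mean() == pytest.approx(17.67, rel=0.02)
    assert chat.std() == pytest.approx(15.42, rel=0.05)
    assert chat.min() >= 1


def test_decision_delay_is_exponential(profile):
    rng = np.random.default_rng(5)
    d = om.sample_decision_delay(profile, rng, 100_000)
    assert d.min() >= 0
    assert d.mean() == pytest.approx(1 / 1.25, rel=0.02)
    # implied probability of deciding within one minute: 1 - exp(-lambda)
    assert (d < 1).mean() == pytest.approx(1 - math.exp(-1.25), abs=0.01)


def test_invalid_duration_parameters_raise(profile):
    rng = np.random.default_rng(0)
    bad = om.default_profile()
    bad.patience_sd = -1.0
    with pytest.raises(ConfigurationError):
        om.sample_patience(bad, rng)
    bad2 = om.default_profile()
    bad2.patience_family = "weibull"
    with pytest.raises(ConfigurationError):
        om.sample_patience(bad2, rng)


def test_duration_pmf_is_normalised_and_matches_sampling(profile):
    pmf = duration_pmf(4.16, 3.27, "lognormal", 60)
    assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
    rng = np.random.default_rng(3)
    draws = om.sample_patience(profile, rng, 200_000)
    emp = np.bincount(np.minimum(draws, 60), minlength=61)[1:] / len(draws)
    assert np.abs(emp - pmf).max() < 0.005


def _degenerate_profile():
    p = om.default_profile()
    p.seeker_gender_dist = {"female": 1.0}
    p.counselor_gender_dist = {"male": 1.0}
    p.seeker_birth_year_dist = {1990: 1.0}
    p.counselor_birth_year_dist = {1985: 1.0}
    topic = {t: 0.0 for t in om.TOPICS}
    topic["depression"] = 1.0
    p.topic_dist = topic
    p._samplers_cache = None
    return p


def test_degenerate_profile_fixes_all_attributes():
    p = _degenerate_profile()
    rng = np.random.default_rng(1)
    sched = build_arrival_schedule(p, 10, rng)
    seekers, counselors = generate_agents(0, p, sched, rng, 0, 0)
    assert len(seekers) > 0 and len(counselors) > 0
    for s in seekers:
        assert (s.gender, s.birth_year, s.topic) == ("female", 1990, "depression")
    for c in counselors:
        assert c.gender == "male" and c.topics == ("depression",)
        assert 1 <= len(c.topics) <= 3


def test_modal_topic_and_categorical_frequencies(profile):
    rng = np.random.default_rng(42)
    sched = build_arrival_schedule(profile, 1, rng)
    seekers = []
    counters = [0, 0]
    while len(seekers) < 100_000:
        s, _ = generate_agents(0, profile, sched, rng, 0, 200, id_counters=counters)
        seekers.extend(s)
    topics = [s.topic for s in seekers]
    counts = {t: topics.count(t) for t in om.TOPICS}
    assert max(counts, key=counts.get) == "self-improvement"
    n = len(seekers)
    # frequencies within one percentage point of the configured probabilities
    for t, p in profile.topic_dist.items():
        assert abs(counts[t] / n - p) < 0.01
    # chi-square goodness of fit not rejected at alpha = .01
    expected = np.array([profile.topic_dist[t] * n for t in om.TOPICS])
    observed = np.array([counts[t] for t in om.TOPICS])
    assert stats.chisquare(observed, expected).pvalue > 0.01
    genders = np.array([s.gender for s in seekers])
    for g, p in profile.seeker_gender_dist.items():
        assert abs((genders == g).mean() - p) < 0.01


def test_same_seed_gives_identical_agent_streams(profile):
    def stream(seed):
        rng = np.random.default_rng(seed)
        sched = build_arrival_schedule(profile, 5, rng)
        out = []
        counters = [0, 0]
        for minute in range(5):
            s, c = generate_agents(minute, profile, sched, rng, 0, 0, id_counters=counters)
            out.extend([(a.id, a.gender, a.birth_year, a.topic, a.patience) for a in s])
            out.extend([(a.id, a.gender, a.topics, a.decision_delay) for a in c])
        return out

    assert stream(99) == stream(99)
    assert stream(99) != stream(100)


def test_zero_arrival_template_generates_no_agents(profile):
    rng = np.random.default_rng(0)
    sched = build_arrival_schedule(profile, 50, rng, weekly_template=[0.0])
    for minute in range(50):
        s, c = generate_agents(minute, profile, sched, rng, 0, 0)
        assert s == [] and c == []


def test_profile_validation_errors():
    p = om.default_profile()
    with pytest.raises(ConfigurationError, match="sum"):
        om.PopulationProfile(**{**p.to_dict(), "seeker_gender_dist": {"female": 0.9}})
    with pytest.raises(ConfigurationError, match="positive"):
        om.PopulationProfile(**{**p.to_dict(), "decision_rate": 0.0})
    short_topics = dict(list(p.topic_dist.items())[:17])
    total = sum(short_topics.values())
    short_topics = {k: v / total for k, v in short_topics.items()}
    with pytest.raises(ConfigurationError, match="18"):
        om.PopulationProfile(**{**p.to_dict(), "topic_dist": short_topics})


def test_profile_json_round_trip(tmp_path, profile):
    path = tmp_path / "p.json"
    profile.to_json(path)
    back = om.PopulationProfile.from_json(path)
    assert back.to_dict() == profile.to_dict()


def test_packaged_default_profile_fixture_matches_code():
    from importlib import resources

    with resources.files("omhcsim").joinpath("profiles/default_profile.json").open() as fh:
        import json

        packaged = json.load(fh)
    assert om.PopulationProfile.from_dict(packaged).to_dict() == om.default_profile().to_dict()


def test_poisson_solver_unreachable_target_raises(profile):
    p = om.default_profile()
    p.arrival_targets = dict(p.arrival_targets)
    # fewer online seekers than counselor throughput alone implies
    p.arrival_targets["seeker_online_mean"] = 1.0
    rng = np.random.default_rng(0)
    with pytest.raises(ConfigurationError, match="unreachable"):
        build_arrival_schedule(p, 100, rng, mode="poisson")
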