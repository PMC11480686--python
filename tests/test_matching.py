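import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import omhcsim as om
from omhcsim.exceptions import ConfigurationError
from omhcsim.matching import PreferenceProblem, encode_agent

from oracle_matching import (
    enumerate_stable_matchings,
    random_instance,
    seeker_optimal_matching,
)


# ---------------------------------------------------------------------------
# deferred acceptance
# ---------------------------------------------------------------------------


def test_da_trivial_cases():
    ms = om.deferred_acceptance(PreferenceProblem({"s0": ["c0"]}, {"c0": ["s0"]}))
    assert ms.pairs == [("s0", "c0")]
    ms = om.deferred_acceptance(PreferenceProblem({}, {}))
    assert ms.pairs == [] and ms.unmatched_seekers == []
    # empty preference list leaves the seeker unmatched
    ms = om.deferred_acceptance(
        PreferenceProblem({"s0": [], "s1": ["c0"]}, {"c0": ["s1", "s0"]})
    )
    assert ms.pairs == [("s1", "c0")]
    assert ms.unmatched_seekers == ["s0"]


def test_da_one_sided_acceptability_is_respected():
    # counselor does not rank s0 at all -> cannot be matched with it
    ms = om.deferred_acceptance(PreferenceProblem({"s0": ["c0"]}, {"c0": []}))
    assert ms.pairs == []


@pytest.mark.parametrize("seed", range(120))
def test_da_equals_enumeration_oracle(seed):
    """Output equals the seeker-optimal stable matching found by exhaustive
    enumeration plus a blocking-pair check, on random instances <= 5x5."""
    rng = np.random.default_rng(1000 + seed)
    sp, cp = random_instance(rng, max_side=5)
    ms = om.deferred_acceptance(PreferenceProblem(sp, cp))
    got = dict(ms.pairs)
    assert got == seeker_optimal_matching(sp, cp)
    assert got in enumerate_stable_matchings(sp, cp)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_da_output_is_stable(seed):
    """No blocking pair exists in any deferred-acceptance output (<= 8x8)."""
    rng = np.random.default_rng(seed)
    sp, cp = random_instance(rng, max_side=8)
    ms = om.deferred_acceptance(PreferenceProblem(sp, cp))
    matched = dict(ms.pairs)
    inv = {c: s for s, c in matched.items()}
    srank = {s: {c: r for r, c in enumerate(sp[s])} for s in sp}
    crank = {c: {s: r for r, s in enumerate(cp[c])} for c in cp}
    for s in sp:
        for c in sp[s]:
            if s not in crank.get(c, {}):
                continue
            s_prefers = s not in matched or srank[s][c] < srank[s][matched[s]]
            c_prefers = c not in inv or crank[c][s] < crank[c][inv[c]]
            assert not (s_prefers and c_prefers), f"blocking pair {s},{c}"


# ---------------------------------------------------------------------------
# preference construction
# ---------------------------------------------------------------------------


def _wait_setup(seeker_factory, counselor_factory):
    # waits at minute 10: A 5, B 2, C 9
    seekers = [
        seeker_factory(arrival_minute=5, id="A"),
        seeker_factory(arrival_minute=8, id="B"),
        seeker_factory(arrival_minute=1, id="C"),
    ]
    counselors = [counselor_factory(id="x"), counselor_factory(id="y")]
    return seekers, counselors


def test_fcfs_ranks_by_decreasing_wait(seeker_factory, counselor_factory):
    seekers, counselors = _wait_setup(seeker_factory, counselor_factory)
    policy = om.PolicySpec("fcfs", recommendation_take_prob=1.0)
    prob = om.build_preferences(policy, seekers, counselors, 10, np.random.default_rng(0))
    assert prob.counselor_prefs["x"] == ["C", "A", "B"]
    assert prob.counselor_prefs["y"] == ["C", "A", "B"]


def test_lcfs_ranks_by_increasing_wait(seeker_factory, counselor_factory):
    seekers, counselors = _wait_setup(seeker_factory, counselor_factory)
    policy = om.PolicySpec("lcfs", recommendation_take_prob=1.0)
    prob = om.build_preferences(policy, seekers, counselors, 10, np.random.default_rng(0))
    assert prob.counselor_prefs["x"] == ["B", "A", "C"]


def test_fcfs_matches_longest_waiting_with_interchangeable_counselors(
    seeker_factory, counselor_factory
):
    """With take-prob 1 and fewer counselors than seekers, the matched set is
    exactly the longest-waiting seekers."""
    rng = np.random.default_rng(7)
    seekers = [seeker_factory(arrival_minute=20 - w, id=f"s{w}") for w in range(12)]
    counselors = [counselor_factory(id=f"c{j}") for j in range(5)]
    policy = om.PolicySpec("fcfs", recommendation_take_prob=1.0)
    prob = om.build_preferences(policy, seekers, counselors, 20, rng)
    ms = om.deferred_acceptance(prob)
    matched = {s for s, _ in ms.pairs}
    assert matched == {f"s{w}" for w in range(11, 6, -1)}


def test_topic_policy_prioritises_expertise_match(seeker_factory, counselor_factory):
    s = seeker_factory(topic="anxiety", id="s")
    cs = [
        counselor_factory(topics=("dating",), id="cd"),
        counselor_factory(topics=("anxiety", "stress"), id="ca"),
    ]
    policy = om.PolicySpec("topic", recommendation_take_prob=1.0)
    prob = om.build_preferences(policy, [s], cs, 0, np.random.default_rng(0))
    assert prob.seeker_prefs["s"][0] == "ca"
    assert prob.counselor_prefs["ca"] == ["s"]


def test_age_policy_prefers_closer_birth_years(seeker_factory, counselor_factory):
    s = seeker_factory(birth_year=1990, id="s")
    cs = [
        counselor_factory(birth_year=1960, id="old"),
        counselor_factory(birth_year=1992, id="near"),
    ]
    prob = om.build_preferences(
        om.PolicySpec("age", recommendation_take_prob=1.0), [s], cs, 0,
        np.random.default_rng(0),
    )
    assert prob.seeker_prefs["s"] == ["near", "old"]


def test_recommendation_noise_randomises_some_lists(seeker_factory, counselor_factory):
    seekers = [seeker_factory(arrival_minute=-w, id=f"s{w}") for w in range(8)]
    counselors = [counselor_factory(id=f"c{j}") for j in range(200)]
    policy = om.PolicySpec("fcfs", recommendation_take_prob=0.9)
    prob = om.build_preferences(policy, seekers, counselors, 0, np.random.default_rng(3))
    ranked = ["s7", "s6", "s5", "s4", "s3", "s2", "s1", "s0"]
    frac_follow = np.mean([prob.counselor_prefs[f"c{j}"] == ranked for j in range(200)])
    assert 0.8 < frac_follow < 0.98  # ~90% follow the recommendation


def test_unknown_policy_rejected():
    with pytest.raises(ConfigurationError):
        om.PolicySpec("rating_optimized")
    with pytest.raises(ConfigurationError):
        om.build_preferences(om.PolicySpec("replication"), [], [], 0,
                             np.random.default_rng(0))


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------


def test_similarity_identical_and_orthogonal(seeker_factory, counselor_factory):
    a = seeker_factory(gender="female", birth_year=1990, topic="dating")
    b = counselor_factory(gender="female", birth_year=1990, topics=("dating",))
    assert om.similarity_score(a, b) == pytest.approx(1.0)
    # no shared nonzero components: different gender/topic, birth year at the
    # scaling floor
    c = seeker_factory(gender="male", birth_year=1940, topic="stress")
    d = counselor_factory(gender="nonbinary", birth_year=1940, topics=("home",))
    d.birth_year = 1940
    v = om.similarity_score(c, d)
    assert v == pytest.approx(0.0)


def test_similarity_matches_direct_formula(seeker_factory, counselor_factory):
    a = seeker_factory(gender="nonbinary", birth_year=1975, topic="anxiety")
    b = counselor_factory(gender="nonbinary", birth_year=2000,
                          topics=("anxiety", "stress", "dating"))
    va, vb = encode_agent(a), encode_agent(b)
    expected = float(np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb)))
    assert om.similarity_score(a, b) == pytest.approx(expected)
    assert om.similarity_score(b, a) == pytest.approx(expected)  # symmetry
    # multi-hot scaling: counselor topic slots are 1/sqrt(3) each
    assert vb[6:].max() == pytest.approx(1 / np.sqrt(3))


# ---------------------------------------------------------------------------
# pools
# ---------------------------------------------------------------------------


def test_pool_assignment(seeker_factory):
    assert om.assign_pool(seeker_factory(birth_year=2005, gender="female"), 2021) == "underaged"
    assert om.assign_pool(seeker_factory(birth_year=1991, gender="nonbinary"), 2021) == "gender_minority"
    assert om.assign_pool(seeker_factory(birth_year=1981, gender="male"), 2021) == "general"
    # dual membership follows precedence
    dual = seeker_factory(birth_year=2006, gender="transgender_male")
    assert om.assign_pool(dual, 2021) == "underaged"
    assert om.assign_pool(dual, 2021, precedence=("gender_minority", "underaged")) == "gender_minority"
    missing = seeker_factory()
    missing.birth_year = None
    with pytest.raises(ConfigurationError):
        om.assign_pool(missing, 2021)


# ---------------------------------------------------------------------------
# replication policy
# ---------------------------------------------------------------------------


def test_replication_match_edge_cases(seeker_factory, counselor_factory):
    rng = np.random.default_rng(0)
    assert om.replication_match([], [counselor_factory()], rng).pairs == []
    ms = om.replication_match(
        [seeker_factory(id="s")], [counselor_factory(id=f"c{i}") for i in range(3)], rng
    )
    assert len(ms.pairs) == 1 and len(ms.unmatched_counselors) == 2


def test_replication_match_picks_uniformly(seeker_factory, counselor_factory):
    rng = np.random.default_rng(123)
    s0, s1 = seeker_factory(id="s0"), seeker_factory(id="s1")
    c = counselor_factory(id="c")
    wins = 0
    trials = 100_000
    for _ in range(trials):
        ms = om.replication_match([s0, s1], [c], rng)
        wins += ms.pairs[0][0] == "s0"
    assert wins / trials == pytest.approx(0.5, abs=0.01)


def test_preference_problem_text_round_trip():
    prob = PreferenceProblem({"s0": ["c1", "c0"], "s1": []}, {"c0": ["s0"], "c1": ["s1", "s0"]})
    back = PreferenceProblem.from_text(prob.to_text())
    assert back.seeker_prefs == prob.seeker_prefs
    assert back.counselor_prefs == prob.counselor_prefs
    back.validate()
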