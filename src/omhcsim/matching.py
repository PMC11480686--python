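"""Two-sided matching between support seekers and volunteer counselors.

The algorithmic policies build per-round preference lists and resolve them
with the applicant-proposing deferred acceptance algorithm (Gale-Shapley),
which yields the applicant-optimal stable matching for the submitted lists.
The replication policy instead mimics the study platform's status quo:
counselors self-select a waiting seeker uniformly at random once their
decision delay has elapsed.  The filter policy applies the same random
self-selection but hard-partitions agents into three protection pools
(underaged, gender-minority, general) and forbids cross-pool pairs.

Policy names:

========== =============================================================
replication  random self-selection after an exponential decision delay
fcfs         counselors rank seekers by decreasing waiting time
lcfs         counselors rank seekers by increasing waiting time
similarity   both sides rank by cosine similarity of demographic vectors
age          both sides rank by birth-year proximity
gender       same gender identity ranked first on both sides
topic        expertise match (seeker topic in counselor list) ranked first
filter       random self-selection restricted to same protection pool
========== =============================================================

Under every algorithmic policy a counselor follows the policy's ranking
with probability ``recommendation_take_prob`` (default 0.9) and otherwise
uses a uniformly random ranking — the platform's 90/10 recommendation rule.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .population import GENDER_MINORITY

__all__ = [
    "POLICY_NAMES",
    "DA_POLICIES",
    "PolicySpec",
    "PreferenceProblem",
    "MatchSet",
    "deferred_acceptance",
    "build_preferences",
    "similarity_score",
    "encode_agent",
    "assign_pool",
    "replication_match",
]

POLICY_NAMES = ("replication", "fcfs", "lcfs", "similarity", "age", "gender", "topic", "filter")

#: Policies resolved through preference lists + deferred acceptance.
DA_POLICIES = ("fcfs", "lcfs", "similarity", "age", "gender", "topic")


@dataclass
class PolicySpec:
    """Which matching policy runs each simulation period, and its knobs."""

    name: str
    recommendation_take_prob: float = 0.9
    tie_break_seed: int = 0
    #: birth-year range used for min-max scaling in the similarity encoding
    similarity_year_range: tuple = (1940, 2010)
    #: pool precedence for agents who are both underaged and gender-minority
    pool_precedence: tuple = ("underaged", "gender_minority")

    def __post_init__(self):
        if self.name not in POLICY_NAMES:
            raise ConfigurationError(
                f"unknown policy {self.name!r}; expected one of {POLICY_NAMES}"
            )
        if not 0.0 <= self.recommendation_take_prob <= 1.0:
            raise ConfigurationError("recommendation_take_prob must be in [0, 1]")


@dataclass
class PreferenceProblem:
    """Ordered preference lists for one matching round (capacity 1 per side)."""

    seeker_prefs: dict  # seeker_id -> list of counselor ids, best first
    counselor_prefs: dict  # counselor_id -> list of seeker ids, best first

    def validate(self):
        for sid, prefs in self.seeker_prefs.items():
            if len(set(prefs)) != len(prefs):
                raise ConfigurationError(f"duplicate entries in prefs of {sid}")
            for cid in prefs:
                if cid not in self.counselor_prefs:
                    raise ConfigurationError(f"{sid} ranks unknown counselor {cid}")
        for cid, prefs in self.counselor_prefs.items():
            if len(set(prefs)) != len(prefs):
                raise ConfigurationError(f"duplicate entries in prefs of {cid}")
            for sid in prefs:
                if sid not in self.seeker_prefs:
                    raise ConfigurationError(f"{cid} ranks unknown seeker {sid}")

    # plain-text round trip (one line per agent: "id: p1 p2 ...") for
    # debugging and oracle tests
    def to_text(self) -> str:
        lines = ["[seekers]"]
        for sid in self.seeker_prefs:
            lines.append(f"{sid}: " + " ".join(self.seeker_prefs[sid]))
        lines.append("[counselors]")
        for cid in self.counselor_prefs:
            lines.append(f"{cid}: " + " ".join(self.counselor_prefs[cid]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PreferenceProblem":
        seekers, counselors = {}, {}
        current = None
        for raw in text.splitlines():
            line = raw.strip()
            if not line:
                continue
            if line == "[seekers]":
                current = seekers
                continue
            if line == "[counselors]":
                current = counselors
                continue
            if current is None:
                raise ConfigurationError("preference text must start with a section header")
            agent, _, rest = line.partition(":")
            current[agent.strip()] = rest.split()
        return cls(seekers, counselors)


@dataclass
class MatchSet:
    """Result of one matching round."""

    pairs: list = field(default_factory=list)  # (seeker_id, counselor_id)
    unmatched_seekers: list = field(default_factory=list)
    unmatched_counselors: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# deferred acceptance
# ---------------------------------------------------------------------------


def deferred_acceptance(problem: PreferenceProblem) -> MatchSet:
    """Applicant-proposing deferred acceptance (seekers propose).

    Each unmatched seeker applies to the next counselor on their list; each
    counselor holds the applicant it ranks highest and rejects the rest;
    the process repeats until no rejections are issued.  The result is the
    seeker-optimal stable matching with respect to the submitted lists.
    Counselors absent from a seeker's list (and vice versa) are treated as
    unacceptable.
    """
    rank = {
        cid: {sid: r for r, sid in enumerate(prefs)}
        for cid, prefs in problem.counselor_prefs.items()
    }
    next_choice = {sid: 0 for sid in problem.seeker_prefs}
    held = {}  # counselor_id -> seeker_id
    free = deque(problem.seeker_prefs)
    matched_seeker = {}
    while free:
        sid = free.popleft()
        prefs = problem.seeker_prefs[sid]
        placed = False
        while next_choice[sid] < len(prefs):
            cid = prefs[next_choice[sid]]
            next_choice[sid] += 1
            crank = rank.get(cid)
            if crank is None or sid not in crank:
                continue  # counselor does not rank this seeker: auto-reject
            incumbent = held.get(cid)
            if incumbent is None:
                held[cid] = sid
                matched_seeker[sid] = cid
                placed = True
                break
            if crank[sid] < crank[incumbent]:
                held[cid] = sid
                matched_seeker[sid] = cid
                del matched_seeker[incumbent]
                free.append(incumbent)
                placed = True
                break
        if not placed:
            matched_seeker.pop(sid, None)
    pairs = sorted(matched_seeker.items())
    matched_c = set(matched_seeker.values())
    return MatchSet(
        pairs=pairs,
        unmatched_seekers=[s for s in problem.seeker_prefs if s not in matched_seeker],
        unmatched_counselors=[c for c in problem.counselor_prefs if c not in matched_c],
    )


# ---------------------------------------------------------------------------
# similarity encoding
# ---------------------------------------------------------------------------

_GENDER_INDEX = {g: i for i, g in enumerate(("female", "male", "nonbinary",
                                             "transgender_female", "transgender_male"))}


def encode_agent(agent, year_range=(1940, 2010)) -> np.ndarray:
    """Mixed-attribute vector: one-hot gender (5 slots), min-max scaled birth
    year (1 slot), topic slots (18) — one-hot for a seeker's single topic,
    multi-hot scaled by 1/sqrt(k) for a counselor's k-topic list."""
    from .population import TOPICS

    v = np.zeros(5 + 1 + len(TOPICS))
    v[_GENDER_INDEX[agent.gender]] = 1.0
    lo, hi = year_range
    v[5] = min(1.0, max(0.0, (agent.birth_year - lo) / (hi - lo)))
    topics = getattr(agent, "topics", None)
    if topics is None:
        topics = (agent.topic,)
    scale = 1.0 / np.sqrt(len(topics))
    idx = {t: i for i, t in enumerate(TOPICS)}
    for t in topics:
        v[6 + idx[t]] = scale
    return v


def similarity_score(a, b, year_range=(1940, 2010)) -> float:
    """Cosine similarity of two encoded agents, in [0, 1] (0 for a zero vector)."""
    va, vb = encode_agent(a, year_range), encode_agent(b, year_range)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(va, vb) / (na * nb))


# ---------------------------------------------------------------------------
# protection pools
# ---------------------------------------------------------------------------


def assign_pool(agent, reference_year: int, precedence=("underaged", "gender_minority")) -> str:
    """Pool label for the filter policy: underaged (age <= 18 at the
    reference year), gender_minority (non-cisgender), or general.

    Agents who belong to both protected groups take the first matching label
    in ``precedence``.
    """
    if agent.birth_year is None:
        raise ConfigurationError(f"agent {agent.id} has no birth year; age is mandatory")
    flags = {
        "underaged": (reference_year - agent.birth_year) <= 18,
        "gender_minority": agent.gender in GENDER_MINORITY,
    }
    for label in precedence:
        if flags.get(label):
            return label
    return "general"


# ---------------------------------------------------------------------------
# replication policy
# ---------------------------------------------------------------------------


def replication_match(seekers, counselors, rng: np.random.Generator,
                      pools=None) -> MatchSet:
    """Random self-selection: each ready counselor (in randomised order)
    picks a uniformly random waiting seeker; no seeker is picked twice.

    ``pools`` optionally maps agent id -> pool label; when given, a
    counselor only considers seekers in its own pool (filter policy).
    """
    seeker_ids = [s.id for s in seekers]
    counselor_ids = [c.id for c in counselors]
    remaining = list(seeker_ids)
    pairs = []
    order = list(counselor_ids)
    if order:
        rng.shuffle(order)
    for cid in order:
        if not remaining:
            break
        if pools is None:
            j = int(rng.integers(len(remaining)))
            pairs.append((remaining.pop(j), cid))
        else:
            eligible = [i for i, sid in enumerate(remaining) if pools[sid] == pools[cid]]
            if not eligible:
                continue
            j = eligible[int(rng.integers(len(eligible)))]
            pairs.append((remaining.pop(j), cid))
    matched_s = {s for s, _ in pairs}
    matched_c = {c for _, c in pairs}
    return MatchSet(
        pairs=sorted(pairs),
        unmatched_seekers=[s for s in seeker_ids if s not in matched_s],
        unmatched_counselors=[c for c in counselor_ids if c not in matched_c],
    )


# ---------------------------------------------------------------------------
# preference construction for the DA policies
# ---------------------------------------------------------------------------


def _order_by(keys, ids, rng):
    """ids sorted by descending key; ties broken by a seeded random draw."""
    tie = rng.random(len(ids))
    order = sorted(range(len(ids)), key=lambda i: (-keys[i], tie[i]))
    return [ids[i] for i in order]


def build_preferences(policy: PolicySpec, seekers, counselors, minute: int,
                      rng: np.random.Generator) -> PreferenceProblem:
    """Ordered preference lists for one round of the named DA policy.

    Counselor-side rankings follow the policy's criterion; seeker-side
    rankings use the same criterion where it is two-sided (similarity, age,
    gender, topic) and a seeded random permutation where the criterion is
    one-sided (fcfs, lcfs rank seekers by waiting time, which seekers cannot
    mirror).  After ranking, each counselor's list is replaced by a uniform
    random permutation with probability ``1 - recommendation_take_prob``.
    """
    if policy.name not in DA_POLICIES:
        raise ConfigurationError(
            f"policy {policy.name!r} does not use preference lists"
        )
    sids = [s.id for s in seekers]
    cids = [c.id for c in counselors]
    seeker_prefs = {}
    counselor_prefs = {}

    if policy.name in ("fcfs", "lcfs"):
        waits = [minute - s.arrival_minute for s in seekers]
        sign = 1.0 if policy.name == "fcfs" else -1.0
        ranked = _order_by([sign * w for w in waits], sids, rng)
        for c in counselors:
            counselor_prefs[c.id] = list(ranked)
        for s in seekers:
            perm = list(cids)
            rng.shuffle(perm)
            seeker_prefs[s.id] = perm
    elif policy.name == "similarity":
        svec = np.array([encode_agent(s, policy.similarity_year_range) for s in seekers])
        cvec = np.array([encode_agent(c, policy.similarity_year_range) for c in counselors])
        sn = np.linalg.norm(svec, axis=1, keepdims=True)
        cn = np.linalg.norm(cvec, axis=1, keepdims=True)
        sn[sn == 0] = 1.0
        cn[cn == 0] = 1.0
        score = (svec / sn) @ (cvec / cn).T  # seekers x counselors
        for i, s in enumerate(seekers):
            seeker_prefs[s.id] = _order_by(score[i], cids, rng)
        for j, c in enumerate(counselors):
            counselor_prefs[c.id] = _order_by(score[:, j], sids, rng)
    elif policy.name == "age":
        sy = np.array([s.birth_year for s in seekers], dtype=float)
        cy = np.array([c.birth_year for c in counselors], dtype=float)
        gap = -np.abs(sy[:, None] - cy[None, :])  # closer in age = higher
        for i, s in enumerate(seekers):
            seeker_prefs[s.id] = _order_by(gap[i], cids, rng)
        for j, c in enumerate(counselors):
            counselor_prefs[c.id] = _order_by(gap[:, j], sids, rng)
    elif policy.name == "gender":
        for s in seekers:
            same = [1.0 if c.gender == s.gender else 0.0 for c in counselors]
            seeker_prefs[s.id] = _order_by(same, cids, rng)
        for c in counselors:
            same = [1.0 if s.gender == c.gender else 0.0 for s in seekers]
            counselor_prefs[c.id] = _order_by(same, sids, rng)
    elif policy.name == "topic":
        for s in seekers:
            match = [1.0 if s.topic in c.topics else 0.0 for c in counselors]
            seeker_prefs[s.id] = _order_by(match, cids, rng)
        for c in counselors:
            match = [1.0 if s.topic in c.topics else 0.0 for s in seekers]
            counselor_prefs[c.id] = _order_by(match, sids, rng)

    # 90/10 recommendation rule: occasional random self-selection
    p_take = policy.recommendation_take_prob
    if p_take < 1.0:
        for cid in cids:
            if rng.random() >= p_take:
                perm = list(counselor_prefs[cid])
                rng.shuffle(perm)
                counselor_prefs[cid] = perm
    return PreferenceProblem(seeker_prefs, counselor_prefs)
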