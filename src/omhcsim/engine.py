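"""Discrete-time simulation engine (1-minute periods).

Each simulation period advances the world in a fixed phase order:

1. chats whose length has elapsed end; their counselors go offline for good;
2. seekers whose waited minutes strictly exceed their patience renege and
   are logged as dropouts (wait = patience + 1); idle counselors past their
   timeout go offline;
3. new agents arrive per the arrival schedule and are online immediately;
4. the configured matching policy runs over all available agents;
5. matched pairs start chatting: the chat length is drawn, the outcome model
   scores the pair, and both agents leave the matching pool.

"Online" means waiting or chatting; the per-minute queue log records both
counts after phase 5.  A chat started at minute *m* with length *L* occupies
minutes *m* .. *m+L-1* and its counselor goes offline at *m+L*.  The wait of
a matched seeker is ``match_minute - arrival_minute`` and can never exceed
the seeker's patience.
"""

from __future__ import annotations

import heapq
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .matching import (
    PolicySpec,
    assign_pool,
    build_preferences,
    deferred_acceptance,
    replication_match,
)
from .outcomes import OutcomeModelParams, predict_block, predict_rating
from .population import (
    ArrivalSchedule,
    PopulationProfile,
    build_arrival_schedule,
    default_profile,
    generate_agents,
    sample_chat_length,
)

__all__ = ["SimulationConfig", "ChatSession", "SimulationRun", "step", "run"]


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one simulation run."""

    policy: PolicySpec
    profile: PopulationProfile = field(default_factory=default_profile)
    outcome_params: OutcomeModelParams | None = None
    horizon_minutes: int = 10_080  # one week
    seed: int = 0
    n_replicates: int = 1
    arrival_mode: str = "online_target"
    weekly_template: list | None = None
    #: minimum chat length (minutes) for a rating to be recorded; 0 = every
    #: chat receives an outcome draw
    rating_length_threshold: int = 0

    def __post_init__(self):
        if self.horizon_minutes < 0:
            raise ConfigurationError("horizon_minutes must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")


@dataclass(slots=True)
class ChatSession:
    """One matched pair, with the seeker-side demographics the metrics need."""

    seeker_id: str
    counselor_id: str
    wait_minutes: int
    start_minute: int
    length_minutes: int
    rating: int | None
    blocked: bool
    seeker_gender: str
    seeker_birth_year: int
    seeker_topic: str
    counselor_gender: str
    counselor_birth_year: int
    topic_match: bool


class SimulationRun:
    """Complete event log of one run.

    Conservation invariant: every generated seeker appears exactly once among
    chats, dropouts, or the still-waiting set at the horizon; every counselor
    takes at most one chat.
    """

    def __init__(self, config: SimulationConfig, seed: int):
        self.config = config
        self.seed = seed
        self.chats: list[ChatSession] = []
        self.dropouts: list[dict] = []
        self.still_waiting: list[dict] = []
        self.queue_log_seekers: list[int] = []
        self.queue_log_counselors: list[int] = []
        self.n_seekers_generated = 0
        self.n_counselors_generated = 0
        self.n_counselor_timeouts = 0

    # -- views --------------------------------------------------------------

    def chats_frame(self) -> pd.DataFrame:
        cols = [
            "seeker_id", "counselor_id", "wait_minutes", "start_minute",
            "length_minutes", "rating", "blocked", "seeker_gender",
            "seeker_birth_year", "seeker_topic", "counselor_gender",
            "counselor_birth_year", "topic_match",
        ]
        return pd.DataFrame(
            [{c: getattr(ch, c) for c in cols} for ch in self.chats], columns=cols
        )

    def dropouts_frame(self) -> pd.DataFrame:
        cols = ["seeker_id", "wait_at_drop", "seeker_gender", "seeker_birth_year",
                "seeker_topic"]
        return pd.DataFrame(self.dropouts, columns=cols)

    def queue_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "minute": np.arange(len(self.queue_log_seekers)),
                "online_seekers": self.queue_log_seekers,
                "online_counselors": self.queue_log_counselors,
            }
        )

    def matching_success_rate(self) -> float:
        """Matched seekers / all generated seekers, in percent."""
        if self.n_seekers_generated == 0:
            return float("nan")
        return 100.0 * len(self.chats) / self.n_seekers_generated

    def conservation_ok(self) -> bool:
        total = len(self.chats) + len(self.dropouts) + len(self.still_waiting)
        one_chat_each = len({c.counselor_id for c in self.chats}) == len(self.chats)
        return total == self.n_seekers_generated and one_chat_each

    # -- export -------------------------------------------------------------

    def to_csv(self, out_dir: str):
        os.makedirs(out_dir, exist_ok=True)
        self.chats_frame().to_csv(os.path.join(out_dir, "chats.csv"), index=False)
        self.dropouts_frame().to_csv(os.path.join(out_dir, "dropouts.csv"), index=False)
        self.queue_frame().to_csv(os.path.join(out_dir, "queue.csv"), index=False)
        from . import __version__

        meta = {
            "seed": self.seed,
            "policy": self.config.policy.name,
            "horizon_minutes": self.config.horizon_minutes,
            "arrival_mode": self.config.arrival_mode,
            "n_seekers_generated": self.n_seekers_generated,
            "n_counselors_generated": self.n_counselors_generated,
            "package_version": __version__,
        }
        with open(os.path.join(out_dir, "meta.json"), "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)


class _World:
    """Mutable engine state."""

    def __init__(self, config: SimulationConfig, schedule: ArrivalSchedule,
                 outcome_params: OutcomeModelParams, seed: int):
        self.config = config
        self.schedule = schedule
        self.outcome_params = outcome_params
        self.waiting = []  # SeekerAgent, arrival order
        self.counselors = []  # available CounselorAgent
        self.chats_heap = []  # (end_minute, tiebreak, seeker, counselor)
        self._heap_count = 0
        self.id_counters = [0, 0]
        self.run = SimulationRun(config, seed)

    @property
    def n_chatting(self) -> int:
        return len(self.chats_heap)


def step(world: _World, minute: int, rng: np.random.Generator):
    """Advance the world by one simulation period (see module docstring)."""
    cfg = world.config
    runlog = world.run

    # 1. chat endings
    while world.chats_heap and world.chats_heap[0][0] <= minute:
        _, _, seeker, counselor = heapq.heappop(world.chats_heap)
        seeker.state = "matched_done"
        counselor.state = "offline"

    # 2. reneging seekers and timed-out counselors
    kept = []
    for s in world.waiting:
        waited = minute - s.arrival_minute
        if waited > s.patience:
            s.state = "dropped"
            runlog.dropouts.append(
                {
                    "seeker_id": s.id,
                    "wait_at_drop": waited,
                    "seeker_gender": s.gender,
                    "seeker_birth_year": s.birth_year,
                    "seeker_topic": s.topic,
                }
            )
        else:
            kept.append(s)
    world.waiting = kept
    kept_c = []
    for c in world.counselors:
        if minute - c.arrival_minute > c.idle_timeout:
            c.state = "offline"
            runlog.n_counselor_timeouts += 1
        else:
            kept_c.append(c)
    world.counselors = kept_c

    # 3. arrivals
    online_s = len(world.waiting) + world.n_chatting
    online_c = len(world.counselors) + world.n_chatting
    new_s, new_c = generate_agents(
        minute, cfg.profile, world.schedule, rng,
        online_seekers=online_s, online_counselors=online_c,
        id_counters=world.id_counters,
    )
    world.waiting.extend(new_s)
    world.counselors.extend(new_c)
    runlog.n_seekers_generated += len(new_s)
    runlog.n_counselors_generated += len(new_c)

    # 4. matching among available agents
    ready = [c for c in world.counselors if minute >= c.ready_minute]
    pairs = []
    if world.waiting and ready:
        policy = cfg.policy
        if policy.name == "replication":
            ms = replication_match(world.waiting, ready, rng)
            pairs = ms.pairs
        elif policy.name == "filter":
            pools = {
                a.id: assign_pool(a, cfg.profile.reference_year, policy.pool_precedence)
                for a in world.waiting + ready
            }
            ms = replication_match(world.waiting, ready, rng, pools=pools)
            pairs = ms.pairs
        else:
            problem = build_preferences(policy, world.waiting, ready, minute, rng)
            ms = deferred_acceptance(problem)
            pairs = ms.pairs

    # 5. chat starts
    if pairs:
        by_id_s = {s.id: s for s in world.waiting}
        by_id_c = {c.id: c for c in world.counselors}
        matched_s, matched_c = set(), set()
        for sid, cid in pairs:
            s, c = by_id_s[sid], by_id_c[cid]
            length = sample_chat_length(cfg.profile, rng)
            rating = None
            if length >= cfg.rating_length_threshold:
                rating = predict_rating(s, c, world.outcome_params, rng)
            blocked = predict_block(s, c, world.outcome_params, rng)
            s.state = "chatting"
            c.state = "chatting"
            runlog.chats.append(
                ChatSession(
                    seeker_id=sid,
                    counselor_id=cid,
                    wait_minutes=minute - s.arrival_minute,
                    start_minute=minute,
                    length_minutes=length,
                    rating=rating,
                    blocked=blocked,
                    seeker_gender=s.gender,
                    seeker_birth_year=s.birth_year,
                    seeker_topic=s.topic,
                    counselor_gender=c.gender,
                    counselor_birth_year=c.birth_year,
                    topic_match=s.topic in c.topics,
                )
            )
            world._heap_count += 1
            heapq.heappush(world.chats_heap, (minute + length, world._heap_count, s, c))
            matched_s.add(sid)
            matched_c.add(cid)
        world.waiting = [s for s in world.waiting if s.id not in matched_s]
        world.counselors = [c for c in world.counselors if c.id not in matched_c]

    runlog.queue_log_seekers.append(len(world.waiting) + world.n_chatting)
    runlog.queue_log_counselors.append(len(world.counselors) + world.n_chatting)


def run(config: SimulationConfig, seed: int | None = None,
        progress=None) -> SimulationRun:
    """Execute a full simulation run and return its event log.

    ``seed`` overrides ``config.seed`` (used by replicate drivers).
    ``progress`` is an optional callable invoked every 1000 steps with the
    current minute.  Identical config + seed produce identical logs.
    """
    if seed is None:
        seed = config.seed
    if config.outcome_params is None:
        from .outcomes import calibrate, replication_targets

        config.outcome_params = calibrate(
            replication_targets(), config.profile, n_sim=50_000, rng=12345
        )
    rng = np.random.default_rng(seed)
    schedule = build_arrival_schedule(
        config.profile, config.horizon_minutes, rng,
        mode=config.arrival_mode, weekly_template=config.weekly_template,
    )
    world = _World(config, schedule, config.outcome_params, seed)
    for minute in range(config.horizon_minutes):
        step(world, minute, rng)
        if progress is not None and minute % 1000 == 0:
            progress(minute)
    # chats in progress at the horizon stay in the log (they are matched);
    # seekers still queueing are recorded for the conservation ledger
    for s in world.waiting:
        world.run.still_waiting.append(
            {"seeker_id": s.id, "waited": config.horizon_minutes - 1 - s.arrival_minute}
        )
    return world.run
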