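"""Brute-force oracles for two-sided matching, independent of the package's
deferred-acceptance implementation.  Only practical for tiny instances."""

import numpy as np


def random_instance(rng, max_side=6):
    """Random preference problem with possibly truncated lists."""
    ns = int(rng.integers(1, max_side + 1))
    nc = int(rng.integers(1, max_side + 1))
    seekers = [f"s{i}" for i in range(ns)]
    counselors = [f"c{j}" for j in range(nc)]
    sp, cp = {}, {}
    for s in seekers:
        k = int(rng.integers(0, nc + 1))
        sp[s] = list(rng.permutation(counselors)[:k])
    for c in counselors:
        k = int(rng.integers(0, ns + 1))
        cp[c] = list(rng.permutation(seekers)[:k])
    return sp, cp


def _mutually_acceptable(sp, cp):
    return [(s, c) for s in sp for c in sp[s] if s in cp.get(c, [])]


def enumerate_stable_matchings(sp, cp):
    """All stable matchings by exhaustive recursion over individually
    rational assignments plus a blocking-pair check."""
    seekers = list(sp)
    acceptable = _mutually_acceptable(sp, cp)
    acc_by_s = {s: [c for (s2, c) in acceptable if s2 == s] for s in seekers}
    srank = {s: {c: r for r, c in enumerate(sp[s])} for s in sp}
    crank = {c: {s: r for r, s in enumerate(cp[c])} for c in cp}

    def stable(assign):
        inv = {c: s for s, c in assign.items() if c is not None}
        for s, c in acceptable:
            mc = assign.get(s)  # seeker's current counselor (or None)
            s_prefers = mc is None or srank[s][c] < srank[s][mc]
            ms = inv.get(c)
            c_prefers = ms is None or crank[c][s] < crank[c][ms]
            if s_prefers and c_prefers:
                return False
        return True

    results = []

    def rec(i, assign, used):
        if i == len(seekers):
            if stable(assign):
                results.append({s: c for s, c in assign.items() if c is not None})
            return
        s = seekers[i]
        assign[s] = None
        rec(i + 1, assign, used)
        for c in acc_by_s[s]:
            if c not in used:
                assign[s] = c
                used.add(c)
                rec(i + 1, assign, used)
                used.discard(c)
        assign[s] = None

    rec(0, {}, set())
    return results


def seeker_optimal_matching(sp, cp):
    """The applicant-optimal stable matching: each matched seeker gets their
    best partner over all stable matchings (lattice property)."""
    stables = enumerate_stable_matchings(sp, cp)
    assert stables, "at least the empty-check should find one stable matching"
    srank = {s: {c: r for r, c in enumerate(sp[s])} for s in sp}
    best = {}
    for m in stables:
        for s, c in m.items():
            if s not in best or srank[s][c] < srank[s][best[s]]:
                best[s] = c
    # every seeker matched in any stable matching is matched in all of them
    # (rural hospitals theorem), so `best` is itself the seeker-optimal one
    return best
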