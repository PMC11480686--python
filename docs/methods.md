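# Methods

## Model overview

`omhcsim` simulates a two-sided peer-support queue in discrete one-minute
periods. Support seekers arrive, wait, and either start a chat or renege
when their patience runs out; volunteer counselors arrive, browse for an
exponentially distributed decision time, take exactly one chat, and go
offline when it ends. Within each period the engine applies a fixed phase
order: (1) chat endings, (2) reneging and counselor idle-timeouts,
(3) arrivals, (4) matching, (5) chat starts. The ordering is a modelling
choice (the platform's event ordering within a minute is unobservable);
placing endings first means a counselor freed in minute *m* can never be
re-matched (counselors are single-chat), and placing arrivals before
matching means a seeker can be matched in their arrival minute with wait 0.

"Online" always means waiting **or** chatting. The per-minute queue log
records both sides' online counts after phase 5.

## Agent generation

Demographics are drawn independently per agent: gender (five categories:
female, male, nonbinary, transgender female, transgender male), birth year,
and — for seekers — one topic of interest from the 18-topic vocabulary, or
— for counselors — a 1–3 topic expertise list (uniform list length,
distinct topics from the same distribution).

Duration families. Patience and chat length are lognormal, moment-matched
to the platform's published mean/SD (patience 4.16/3.27 min, chat
17.67/15.42 min) via σ² = ln(1 + (sd/mean)²), μ = ln(mean) − σ²/2. The
lognormal is the default because empirical waiting and chat durations are
right-skewed; gamma and exponential families are available in the profile.
Continuous draws are rounded half-to-even to whole minutes with a floor of
one minute. Rounding (rather than ceiling) is deliberate: ceiling would
shift every integer mean by ≈ +0.5 min and break the published moments on
the 1-minute clock; the floor at 1 affects < 0.4% of patience mass and
leaves the means within Monte-Carlo error of their targets.

Counselor decision delays are exponential with rate 1.25/min (mean 0.8
min). Because picks happen on the minute clock, naive discretisation
matters: making a counselor eligible at `ceil(delay)` minutes would inflate
their mean pre-pick residency from 0.8 to 1.4 min. Each counselor therefore
receives a uniform within-minute arrival phase *u*, and becomes eligible in
minute `arrival + floor(u + delay)`; since E[floor(u + d)] = E[d] exactly,
the discretisation is unbiased. This matters quantitatively: by the
accounting identities below, the weekly matching rate moves by ~6
percentage points between the two discretisations.

Counselors who never find an eligible seeker (possible under the filter
policy's pool restriction) leave after an idle timeout drawn from the
patience family scaled by 3× — a knob with no published counterpart,
needed so the online counselor count can equilibrate; in unfiltered runs
it triggers rarely (~0.3% of counselors) because seekers are always
available.

Default attribute distributions. The platform publishes no demographic
shares, so the packaged profile is synthetic with three constraints: all
five gender categories occur; the topic ranking follows the published
order (self-improvement > dating > parents > depression); and the
seeker-side strata weights are chosen for consistency with the published
group-level outcome table. That table pins them surprisingly tightly:
writing the overall mean as the weighted mean of group means forces
P(underaged) ≈ 0.178 from both the rating and the blocking rows, and
P(gender minority) ≈ 0.060 from blocking vs ≈ 0.038 from ratings (the
printed rows are mutually inconsistent at two decimals); the default uses
0.05, which leaves all four group marginals exactly attainable and both
overall values inside the calibration tolerances.

## Arrival process

The default arrival mode is a **top-up controller**: each minute, each side
generates `max(0, target − currently_online)` new agents (stochastic
rounding of the fractional part), holding the mean online counts at the
published weekly means of 113.26 seekers and 102.49 counselors. A flat
target is the default; a periodic weekly template can modulate it.

A stationary-Poisson mode is also provided, with rates solved from the
steady-state relation *online ≈ arrival rate × mean online sojourn* (the
counselor side is solved directly; the seeker side by a fixed point over a
uniform-selection hazard model of the queue). The top-up controller is the
default for a substantive reason: with stationary arrivals the number of
chats per minute is pinned by counselor supply, so the weekly matching
*rate* is the same for every policy and the sandbox cannot distinguish
queue disciplines. Under the top-up controller a policy that prevents
reneging (e.g. serving the longest-waiting first) needs fewer replacement
arrivals, which is exactly how policy-dependent matching rates emerge.

## Matching

The six algorithmic policies construct per-round preference lists and
resolve them with applicant-proposing deferred acceptance (seekers
propose), yielding the seeker-optimal stable matching for the submitted
lists. Conventions:

* counselor-side rankings follow the policy's criterion; seeker-side
  rankings mirror it where it is two-sided (similarity, age, gender,
  topic) and are seeded random permutations where it is one-sided
  (fcfs/lcfs rank by the *seeker's* waiting time, which seekers cannot
  mirror);
* ties are broken by a fresh seeded random draw per round (stable sort);
* the 90/10 recommendation rule is implemented as preference-list noise:
  with probability 0.1 a counselor's list is replaced by a uniform random
  permutation before deferred acceptance runs, preserving the algorithm's
  semantics while honouring per-counselor randomness;
* counselors participate in a round only once their decision delay has
  elapsed, under every policy, keeping counselor-side timing comparable
  across arms.

The similarity encoding (the platform publishes none) is one-hot gender
(5 slots), min–max-scaled birth year over 1940–2010 (1 slot), and topic
slots — one-hot for the seeker's topic, multi-hot scaled by 1/√k for a
counselor's k-topic list — compared by cosine; a zero vector scores 0.

The replication policy bypasses preference lists entirely: ready
counselors, in randomised order, each pick a uniformly random waiting
seeker. The filter policy applies the same random self-selection within
hard pools (underaged ≤ 18 at the reference year, gender minority =
non-cisgender, general; dual members default to the underaged pool,
configurable). Pool ages are computed against the profile's reference year
(default 2021, the simulation epoch).

Patience semantics: a seeker is dropped in the phase-2 check of the first
minute where `minute − arrival > patience` (strict), so a dropout's logged
wait is exactly patience + 1 and a matched seeker's wait
(`match minute − arrival`) can never exceed their patience.

## Chat outcomes

Ratings use an ordered-categories construction: the replication star-share
shape (15.0 / 4.6 / 6.1 / 9.3 / 65.1% for 1–5 stars) defines logistic
cutpoints; a latent score — per-stratum calibrated shift plus optional
pair-level modifiers (topic match, gender match, age proximity ∈ [0, 1]) —
shifts the cumulative probabilities. Blocking is Bernoulli with per-stratum
calibrated log-odds plus the same modifiers. Strata are the seeker-side
2×2 cells adult/underaged × gender-minority/not. All modifiers default to
zero ("demographics-only" mode): policies then affect *who* is matched but
not the outcome distribution conditional on demographics. Scenario configs
that activate modifiers are deliberately labelled as not data-fitted. The
reported rating metric is the mean of sampled stars (not
probability-weighted class scores).

Calibration (`outcomes.calibrate`) fits the per-cell parameters additively
(age effect + gender effect) by coordinate root-finding against the target
group marginals, computed *exactly* through the link; convergence is
declared on these analytic marginals (rating within ±0.02 stars, blocking
within ±0.3 pp), and a Monte-Carlo draw is attached to the report for
inspection. The Monte-Carlo estimates are not the convergence criterion
because a 5% stratum's sampling error at feasible sample sizes (≈0.5 pp at
n = 100,000) exceeds the blocking tolerance. The model is pluggable: any
object with the same `predict_rating` / `predict_block` signature (e.g. a
classifier trained on real chat logs) can replace it.

## Statistics

Metric definitions follow the platform's evaluation: matching success rate
counts matched seekers over all generated seekers; seekers still queueing
at the horizon are excluded from both waiting-time averages but kept in the
success-rate denominator; chats running past the horizon count as matched.
Policy comparisons are one-tailed Welch t tests over per-replicate run
means — the replicate, not the chat, is the independent unit — with flags
at .05 and .001 and no multiple-testing correction across the metric grid
(mirroring how such tables are usually reported; the per-chat unit is
available behind a flag for rating/blocking). Distributional validation
uses Pearson correlation between aligned binned series; zero-variance
series are an error, not r = NaN.

## Reproduction scale and known discrepancies

All headline quantities are computed at full scale: one simulated week is
10,080 one-minute periods with ≈100 concurrent agents (~3 s per replicate
on one core); the acceptance script runs 30 such weeks (10 seeds ×
replication/FCFS/LCFS) plus the outcome-model calibration.

The simulator reproduces the published online counts essentially exactly,
the policy ordering (FCFS > replication > LCFS in matching rate, with
FCFS-longer and LCFS-shorter matched waits), the generator moments, and
the calibrated outcome marginals. It does **not** reproduce the published
replication-baseline matching rate (ours ≈ 73.0% vs 78.35%) or mean
matched wait (≈ 1.4 vs 3.19 min), and LCFS lands at ≈ 66.4% vs 74.81%.
This is structural, not a tuning residue. Little's law pins the chat
throughput from the counselor side, r ≈ L_c / (E[decision] + E[chat]) ≈
5.5 chats/min, and the seeker side must then satisfy
L_s = r·(E[wait|matched] + E[chat]) + (λ_s − r)·E[reneged sojourn].
With L_s = 113.26 and L_c = 102.49 these identities force the matching
rate and the matched wait to move together: a matched wait of 3.19 min
would force a matching rate near 94%, and a matching rate of 78.35% would
force a matched wait near 1.7 min — no queue with the published duration
moments satisfies both published values at once, under any reading of
"online" (waiting-only or waiting + chatting, either side). The simulator
sits at the self-consistent point its moment-matched lognormal patience
implies. A heavier-tailed empirical patience distribution (unavailable
here; only its first two moments are published) would lengthen matched
waits and raise the matching rate toward the published figures.

## What the synthetic generator does and does not emulate

It emulates: the published duration moments and their skew, the weekly
mean online loads, the five-category gender structure with non-empty
minority strata, the 18-topic vocabulary with the published head ranking,
and outcome disparities across age/gender-minority strata. It does not
emulate: the diurnal/weekly load curve (published only as a figure;
supported via a user template but defaulting to flat), correlations
between demographics and topics or patience, repeat visits by the same
seeker, counselors taking multiple simultaneous chats, racial/cultural
attributes, or any text content of chats. Passing tests therefore certify
the mechanism — queue dynamics, stable matching, calibration algebra — not
fidelity to any particular real community.

## Degenerate inputs and numerical conventions

Zero-arrival templates, empty matching rounds, horizon 0, and zero-chat
runs are all defined no-ops (metrics report absent values with a warning
rather than NaN). Categorical samplers use cumulative-probability inversion
with the final bin clamped to 1. Calibration root-finding uses Brent's
method on [−30, 30] with xtol 1e-12; unreachable targets raise with the
residual table. Seeds: every replicate seed is derived as
`SeedSequence([master, policy_index, replicate_index])` reduced below 2³¹;
equal config + seed reproduces byte-identical event logs.
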