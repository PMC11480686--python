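"""Experiment orchestration: replicate grids of policies vs the baseline.

An experiment runs ``n_replicates`` seeded simulations for each policy,
computes the metric reports, and compares every non-replication arm against
the replication baseline with one-tailed Welch t tests.  Replicate seeds are
a pure function of (master seed, policy index, replicate index), so an
identical spec reproduces byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .engine import SimulationConfig, run
from .exceptions import ConfigurationError
from .matching import PolicySpec
from .metrics import METRIC_NAMES, MetricsReport, compare_policies, compute_metrics

__all__ = ["ExperimentSpec", "derive_seed", "run_experiment"]

REPORT_SCHEMA_VERSION = 1

#: expected direction of improvement for each metric (alternative hypothesis
#: tested for a treatment arm, mirroring "the higher/lower the better")
_METRIC_DIRECTIONS = {
    "mean_rating": "greater",
    "pct_blocked": "less",
    "matching_success_rate": "greater",
    "mean_wait_matched": "less",
    "mean_wait_unmatched": "greater",
}


def derive_seed(master_seed: int, policy_index: int, replicate_index: int) -> int:
    """Deterministic replicate seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(policy_index), int(replicate_index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ExperimentSpec:
    """A grid of policies to compare under a shared simulation template."""

    policies: list  # list[PolicySpec]
    base_config: SimulationConfig
    n_replicates: int = 10
    master_seed: int = 0
    output_dir: str | None = None
    compare: bool = True

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        names = [p.name for p in self.policies]
        if self.compare and len(names) > 1 and "replication" not in names:
            raise ConfigurationError(
                "comparisons require the replication baseline among the policies"
            )


def run_experiment(spec: ExperimentSpec, progress=None) -> dict:
    """Run the full grid and return the experiment report (JSON-ready dict).

    Per-run failures are caught and marked as missing cells rather than
    aborting the grid.
    """
    if spec.base_config.outcome_params is None:
        from .outcomes import calibrate, replication_targets

        spec.base_config.outcome_params = calibrate(
            replication_targets(), spec.base_config.profile, n_sim=50_000, rng=12345
        )
    reports: dict[str, list] = {}
    failures: list = []
    runs_meta = []
    for pi, policy in enumerate(spec.policies):
        arm = []
        for ri in range(spec.n_replicates):
            seed = derive_seed(spec.master_seed, pi, ri)
            cfg = dataclasses.replace(spec.base_config, policy=policy, seed=seed)
            try:
                sim = run(cfg)
                rep = compute_metrics(sim)
                arm.append(rep)
                runs_meta.append({"policy": policy.name, "replicate": ri, "seed": seed})
                if spec.output_dir:
                    sim.to_csv(os.path.join(spec.output_dir, f"{policy.name}_{ri}"))
            except Exception as exc:  # pragma: no cover - defensive
                failures.append({"policy": policy.name, "replicate": ri,
                                 "seed": seed, "error": repr(exc)})
            if progress is not None:
                progress(policy.name, ri)
        reports[policy.name] = arm

    table = {
        name: {
            m: _arm_mean(arm, m) for m in METRIC_NAMES
        } | {"n_replicates": len(arm)}
        for name, arm in reports.items()
    }

    comparisons = {}
    if spec.compare and "replication" in reports and len(reports) > 1:
        base = reports["replication"]
        for name, arm in reports.items():
            if name == "replication" or len(arm) < 2 or len(base) < 2:
                continue
            comparisons[name] = {}
            for m, direction in _METRIC_DIRECTIONS.items():
                try:
                    cmp = compare_policies(base, arm, m, direction)
                except ValueError:
                    comparisons[name][m] = None
                    continue
                comparisons[name][m] = {
                    "direction": direction,
                    "t": cmp.t_stat,
                    "p": cmp.p_value,
                    "significant_05": cmp.significant_05,
                    "significant_001": cmp.significant_001,
                }

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "master_seed": spec.master_seed,
        "n_replicates": spec.n_replicates,
        "policies": [p.name for p in spec.policies],
        "metrics": table,
        "comparisons": comparisons,
        "runs": runs_meta,
        "failures": failures,
    }
    if spec.output_dir:
        os.makedirs(spec.output_dir, exist_ok=True)
        with open(os.path.join(spec.output_dir, "experiment.json"), "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _arm_mean(arm: list, metric: str):
    vals = [getattr(r, metric) for r in arm if getattr(r, metric) is not None]
    return float(np.mean(vals)) if vals else None


def metric_reports(report: dict) -> dict:
    """Flat {policy: {metric: mean}} view of an experiment report."""
    return {k: {m: v[m] for m in METRIC_NAMES} for k, v in report["metrics"].items()}
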