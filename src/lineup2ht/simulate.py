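"""Synthetic lineup data and parameter-recovery studies.

The generator mirrors the study design the estimator assumes: in each
condition, every participant contributes two culprit-present and two
culprit-absent lineup decisions, and all decisions are independent draws
from the model's category probabilities.  Participant-level dependence
(shared ability across a participant's four decisions) is deliberately not
simulated — the analysis model assumes independence, and the generator
produces exactly the world in which that assumption holds.

Randomness contract: one root seed; each (condition, replicate) pair gets
its own deterministic substream, so adding conditions or replicates never
perturbs the draws of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .estimation import FitOptions, ResponseCounts, fit
from .model import (
    ConditionParameters,
    LineupCondition,
    ModelSpec,
    category_probabilities,
    collapse_parameters,
)

__all__ = [
    "SimulationDesign",
    "RecoveryReport",
    "simulate_counts",
    "parameter_recovery",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Data-generating setup: conditions, true parameters, decisions per
    participant (two CP and two CA lineups by default, as in the study
    design) and a root seed."""

    conditions: tuple[LineupCondition, ...]
    generating_parameters: Mapping[str, ConditionParameters]
    lineups_per_participant_cp: int = 2
    lineups_per_participant_ca: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        for c in self.conditions:
            if c.n_participants <= 0:
                raise ValueError(
                    f"condition {c.label!r} needs n_participants > 0 to simulate"
                )
            if c.label not in self.generating_parameters:
                raise ValueError(f"no generating parameters for {c.label!r}")
        if self.lineups_per_participant_cp < 1 or self.lineups_per_participant_ca < 1:
            raise ValueError("lineups per participant must be positive")


def _rng_for(seed: int, condition_index: int, replicate: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(condition_index, replicate))
    return np.random.default_rng(ss)


def simulate_counts(
    design: SimulationDesign, replicate: int = 0
) -> list[ResponseCounts]:
    """Draw one synthetic dataset from the model.

    Per condition, the CP tree total is ``lineups_per_participant_cp x
    n_participants`` and the three CP counts are one multinomial draw from
    the model's CP category probabilities; likewise for the CA tree.
    Deterministic given (seed, replicate).
    """
    out = []
    for i, cond in enumerate(design.conditions):
        theta = design.generating_parameters[cond.label]
        probs = category_probabilities(theta, cond.sampling_constant)
        rng = _rng_for(design.seed, i, replicate)
        cp = rng.multinomial(
            design.lineups_per_participant_cp * cond.n_participants, probs.cp
        )
        ca = rng.multinomial(
            design.lineups_per_participant_ca * cond.n_participants, probs.ca
        )
        out.append(
            ResponseCounts(
                condition_label=cond.label,
                cp_suspect=int(cp[0]),
                cp_filler=int(cp[1]),
                cp_reject=int(cp[2]),
                ca_suspect=int(ca[0]),
                ca_filler=int(ca[1]),
                ca_reject=int(ca[2]),
            )
        )
    return out


@dataclass(frozen=True)
class RecoveryReport:
    """Aggregate of repeated simulate-then-fit rounds, per free parameter."""

    parameter_names: tuple[str, ...]
    generating_values: dict[str, float]
    mean_estimates: dict[str, float]
    bias: dict[str, float]
    empirical_sd: dict[str, float]
    mean_model_se: dict[str, float]
    coverage: dict[str, float]
    replications: int
    n_failed: int = 0
    failures: tuple[str, ...] = field(default=())


def parameter_recovery(
    design: SimulationDesign,
    spec: ModelSpec,
    replications: int,
    seed: int | None = None,
    options: FitOptions | None = None,
) -> RecoveryReport:
    """Repeatedly simulate from ``design`` and refit ``spec``.

    ``spec`` must nest the generating structure: parameters its restriction
    map equates must genuinely be equal in ``design.generating_parameters``
    (checked via the collapse map).  Reports per-parameter bias, empirical
    SD, mean model-based SE, and coverage of +/-1.96 SE Wald intervals.
    Replicates whose fit raises are excluded and counted, never silently
    dropped.
    """
    if replications < 1:
        raise ValueError("replications must be positive")
    if seed is not None:
        design = SimulationDesign(
            conditions=design.conditions,
            generating_parameters=design.generating_parameters,
            lineups_per_participant_cp=design.lineups_per_participant_cp,
            lineups_per_participant_ca=design.lineups_per_participant_ca,
            seed=seed,
        )
    truth = collapse_parameters(spec, design.generating_parameters)
    names = spec.free_parameter_names
    estimates, ses = [], []
    failures = []
    for r in range(replications):
        data = simulate_counts(design, replicate=r)
        try:
            res = fit(spec, data, options)
        except (RuntimeError, ValueError) as exc:
            failures.append(f"replicate {r}: {exc}")
            continue
        estimates.append([res.estimates[n] for n in names])
        ses.append([res.standard_errors[n] for n in names])
    if not estimates:
        raise RuntimeError(
            f"all {replications} replicates failed to fit; first failure: "
            f"{failures[0]}"
        )
    est = np.array(estimates)
    se = np.array(ses)
    mean_est = est.mean(axis=0)
    with np.errstate(invalid="ignore"):
        covered = np.abs(est - truth) <= 1.96 * se
    coverage = np.where(np.isnan(se).all(axis=0), np.nan, np.nanmean(covered, axis=0))
    return RecoveryReport(
        parameter_names=names,
        generating_values=dict(zip(names, truth)),
        mean_estimates=dict(zip(names, mean_est)),
        bias=dict(zip(names, mean_est - truth)),
        empirical_sd=dict(zip(names, est.std(axis=0, ddof=1) if est.shape[0] > 1 else np.zeros(len(names)))),
        mean_model_se=dict(zip(names, np.nanmean(se, axis=0))),
        coverage=dict(zip(names, coverage)),
        replications=len(estimates),
        n_failed=len(failures),
        failures=tuple(failures),
    )
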