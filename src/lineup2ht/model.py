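"""Core of the two-high-threshold (2-HT) eyewitness identification model.

The model is a multinomial processing tree for lineup decisions.  Each
experimental condition yields two observation trees: culprit-present (CP)
lineups and culprit-absent (CA) lineups, each with three observable response
categories (suspect identification, filler identification, lineup rejection).
Four latent probabilities drive the tree:

``dP``
    detection of the culprit's presence (CP lineups only),
``dA``
    detection of the culprit's absence (CA lineups only),
``b``
    biased selection of the suspect (the suspect stands out in an unfair
    lineup),
``g``
    guessing-based selection among the lineup members.

Guessing-based selection hits the suspect with the fixed random-sampling
probability ``c = 1 / lineup size``; ``c`` is a known design constant of each
condition, never an estimated parameter.  Equality restrictions across
conditions (e.g. a single ``b`` shared by all conditions) are expressed by a
:class:`ModelSpec`, which maps every (parameter, condition) cell either to a
named free parameter or to a fixed numeric value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "LineupCondition",
    "ConditionParameters",
    "CategoryProbabilities",
    "ModelSpec",
    "category_probabilities",
    "expand_parameters",
    "collapse_parameters",
    "degrees_of_freedom",
    "information_rank",
]

#: The four latent parameters of the tree, in canonical order.
PARAM_NAMES: tuple[str, ...] = ("dP", "dA", "b", "g")

#: Observable response categories, CP tree then CA tree, in canonical order.
CATEGORY_NAMES: tuple[str, ...] = (
    "cp_suspect",
    "cp_filler",
    "cp_reject",
    "ca_suspect",
    "ca_filler",
    "ca_reject",
)

#: Tolerance for |sampling_constant - 1/lineup_size|; admits 5-decimal
#: roundings such as 0.33333 and 0.16667.
SAMPLING_CONSTANT_TOL = 5e-5


def _check_probability(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class LineupCondition:
    """One experimental cell of a lineup study.

    Parameters
    ----------
    label
        Short identifier, e.g. ``"seq3"`` for three-person sequential lineups.
    lineup_format
        ``"sequential"`` or ``"simultaneous"``.
    lineup_size
        Number of persons shown (suspect plus fillers), at least 2.
    sampling_constant
        The random-sampling probability ``1 / lineup_size``.  Stored
        explicitly so that rounded constants (0.33333, 0.16667) can be used
        verbatim; defaults to the exact reciprocal.
    n_participants
        Participants assigned to this condition (0 when unknown).
    """

    label: str
    lineup_format: str
    lineup_size: int
    sampling_constant: float | None = None
    n_participants: int = 0

    def __post_init__(self) -> None:
        if self.lineup_format not in ("sequential", "simultaneous"):
            raise ValueError(
                f"lineup_format must be 'sequential' or 'simultaneous', "
                f"got {self.lineup_format!r}"
            )
        if self.lineup_size < 2:
            raise ValueError(f"lineup_size must be >= 2, got {self.lineup_size}")
        if self.n_participants < 0:
            raise ValueError("n_participants must be nonnegative")
        if self.sampling_constant is None:
            object.__setattr__(self, "sampling_constant", 1.0 / self.lineup_size)
        c = self.sampling_constant
        if not (0.0 < c <= 1.0):
            raise ValueError(f"sampling_constant must lie in (0, 1], got {c}")
        if abs(c - 1.0 / self.lineup_size) > SAMPLING_CONSTANT_TOL:
            raise ValueError(
                f"sampling_constant {c} is not 1/{self.lineup_size} "
                f"within {SAMPLING_CONSTANT_TOL}"
            )


@dataclass(frozen=True)
class ConditionParameters:
    """The four latent probabilities of one condition's tree."""

    dP: float
    dA: float
    b: float
    g: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            _check_probability(name, getattr(self, name))

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}


@dataclass(frozen=True)
class CategoryProbabilities:
    """The six observable category probabilities of one condition."""

    cp_suspect: float
    cp_filler: float
    cp_reject: float
    ca_suspect: float
    ca_filler: float
    ca_reject: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in CATEGORY_NAMES])

    @property
    def cp(self) -> tuple[float, float, float]:
        return (self.cp_suspect, self.cp_filler, self.cp_reject)

    @property
    def ca(self) -> tuple[float, float, float]:
        return (self.ca_suspect, self.ca_filler, self.ca_reject)


def category_probabilities(
    theta: ConditionParameters, c: float
) -> CategoryProbabilities:
    """Evaluate the 2-HT tree equations for one condition.

    The culprit-present tree: presence detection (``dP``) identifies the
    culprit outright; otherwise biased selection (``b``) identifies the
    suspect; otherwise guessing-based selection (``g``) picks the suspect with
    the sampling probability ``c`` or a filler with ``1 - c``; no selection
    rejects the lineup.  The culprit-absent tree is the mirror image with
    absence detection ``dA`` leading to a correct rejection.

    Parameters
    ----------
    theta
        Latent probabilities for the condition.
    c
        Random-sampling constant, ``1 / lineup size``.
    """
    if not (0.0 <= c <= 1.0) or math.isnan(c):
        raise ValueError(f"sampling constant c must lie in [0, 1], got {c!r}")
    dP, dA, b, g = theta.dP, theta.dA, theta.b, theta.g
    return CategoryProbabilities(
        cp_suspect=dP + (1 - dP) * b + (1 - dP) * (1 - b) * g * c,
        cp_filler=(1 - dP) * (1 - b) * g * (1 - c),
        cp_reject=(1 - dP) * (1 - b) * (1 - g),
        ca_suspect=(1 - dA) * b + (1 - dA) * (1 - b) * g * c,
        ca_filler=(1 - dA) * (1 - b) * g * (1 - c),
        ca_reject=dA + (1 - dA) * (1 - b) * (1 - g),
    )


Restriction = str | float
RestrictionMap = Mapping[tuple[str, str], Restriction]


@dataclass(frozen=True)
class ModelSpec:
    """A 2-HT model for several conditions plus parameter restrictions.

    ``restrictions`` assigns every (parameter name, condition label) cell
    either a free-parameter name (a string; cells sharing a name share the
    estimate) or a fixed numeric value in [0, 1].  ``free_parameter_names``
    orders the distinct free parameters; if omitted it is derived by first
    appearance over conditions in order, parameters in canonical order.
    """

    conditions: tuple[LineupCondition, ...]
    restrictions: Mapping[tuple[str, str], Restriction]
    free_parameter_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        conditions = tuple(self.conditions)
        object.__setattr__(self, "conditions", conditions)
        if not conditions:
            raise ValueError("ModelSpec needs at least one condition")
        labels = [c.label for c in conditions]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate condition labels: {labels}")
        restrictions = dict(self.restrictions)
        seen: list[str] = []
        for cond in conditions:
            for param in PARAM_NAMES:
                key = (param, cond.label)
                if key not in restrictions:
                    raise ValueError(f"restriction missing for {key}")
                r = restrictions[key]
                if isinstance(r, str):
                    if r not in seen:
                        seen.append(r)
                elif isinstance(r, (int, float)) and not isinstance(r, bool):
                    _check_probability(f"fixed value for {key}", float(r))
                    restrictions[key] = float(r)
                else:
                    raise TypeError(f"restriction for {key} must be str or float")
        extra = set(restrictions) - {
            (p, c.label) for c in conditions for p in PARAM_NAMES
        }
        if extra:
            raise ValueError(f"restrictions reference unknown cells: {sorted(extra)}")
        names = tuple(self.free_parameter_names) or tuple(seen)
        if sorted(names) != sorted(seen) or len(set(names)) != len(names):
            raise ValueError(
                f"free_parameter_names {names} do not match the names used in "
                f"restrictions {seen}"
            )
        object.__setattr__(self, "restrictions", restrictions)
        object.__setattr__(self, "free_parameter_names", names)

    @property
    def n_free(self) -> int:
        return len(self.free_parameter_names)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.conditions)

    def condition(self, label: str) -> LineupCondition:
        for c in self.conditions:
            if c.label == label:
                return c
        raise KeyError(label)

    # -- fast lookup tables used by the likelihood ------------------------
    def index_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-condition (n_cond, 4) tables: free-parameter index (-1 where
        fixed) and fixed values (0 where free), in PARAM_NAMES order."""
        pos = {name: i for i, name in enumerate(self.free_parameter_names)}
        idx = np.full((len(self.conditions), len(PARAM_NAMES)), -1, dtype=int)
        fixed = np.zeros_like(idx, dtype=float)
        for i, cond in enumerate(self.conditions):
            for j, param in enumerate(PARAM_NAMES):
                r = self.restrictions[(param, cond.label)]
                if isinstance(r, str):
                    idx[i, j] = pos[r]
                else:
                    fixed[i, j] = r
        return idx, fixed

    def sampling_constants(self) -> np.ndarray:
        return np.array([c.sampling_constant for c in self.conditions])


def expand_parameters(
    spec: ModelSpec, free_values: Sequence[float]
) -> dict[str, ConditionParameters]:
    """Map a free-parameter vector to per-condition parameters.

    Cells sharing a free-parameter name receive the same value; fixed cells
    receive their declared constants.  Returns a dict keyed by condition
    label, in the spec's condition order.
    """
    values = np.asarray(free_values, dtype=float)
    if values.shape != (spec.n_free,):
        raise ValueError(
            f"expected {spec.n_free} free values, got shape {values.shape}"
        )
    for name, v in zip(spec.free_parameter_names, values):
        _check_probability(name, v)
    idx, fixed = spec.index_tables()
    if values.size:
        theta = np.where(idx >= 0, values[np.clip(idx, 0, None)], fixed)
    else:
        theta = fixed
    return {
        cond.label: ConditionParameters(*theta[i])
        for i, cond in enumerate(spec.conditions)
    }


def collapse_parameters(
    spec: ModelSpec, per_condition: Mapping[str, ConditionParameters]
) -> np.ndarray:
    """Inverse of :func:`expand_parameters` on consistent input.

    Raises if conditions sharing a free parameter carry different values or
    a fixed cell deviates from its declared constant.
    """
    out = np.full(spec.n_free, np.nan)
    pos = {name: i for i, name in enumerate(spec.free_parameter_names)}
    for cond in spec.conditions:
        theta = per_condition[cond.label]
        for param in PARAM_NAMES:
            r = spec.restrictions[(param, cond.label)]
            v = getattr(theta, param)
            if isinstance(r, str):
                k = pos[r]
                if not np.isnan(out[k]) and abs(out[k] - v) > 1e-12:
                    raise ValueError(
                        f"inconsistent values for free parameter {r!r}"
                    )
                out[k] = v
            elif abs(v - r) > 1e-12:
                raise ValueError(
                    f"condition {cond.label!r} sets {param}={v} but the spec "
                    f"fixes it to {r}"
                )
    return out


def degrees_of_freedom(spec: ModelSpec) -> int:
    """Goodness-of-fit degrees of freedom of the spec.

    Each condition contributes two multinomial trees with two free category
    probabilities each, so df = 4 * n_conditions - n_free_parameters.
    """
    df = 4 * len(spec.conditions) - spec.n_free
    if df < 0:
        raise ValueError(
            f"model is over-parameterized ({spec.n_free} free parameters for "
            f"{4 * len(spec.conditions)} category degrees of freedom); it is "
            "not testable"
        )
    return df


def information_rank(
    spec: ModelSpec, free_values: Sequence[float], step: float = 1e-6
) -> int:
    """Rank of the expected Fisher information at ``free_values``.

    The information matrix is J^T W J with J the Jacobian of all category
    probabilities with respect to the free parameters (central differences)
    and W the diagonal of inverse category probabilities.  A rank below the
    number of free parameters signals local non-identifiability (e.g. a
    saturated single-condition model with all four parameters free).
    """
    values = np.asarray(free_values, dtype=float)
    cs = spec.sampling_constants()

    def all_probs(v: np.ndarray) -> np.ndarray:
        theta = expand_parameters(spec, np.clip(v, 0.0, 1.0))
        return np.concatenate(
            [
                category_probabilities(theta[c.label], cs[i]).as_array()
                for i, c in enumerate(spec.conditions)
            ]
        )

    p0 = all_probs(values)
    jac = np.empty((p0.size, spec.n_free))
    for k in range(spec.n_free):
        up, dn = values.copy(), values.copy()
        up[k] = min(up[k] + step, 1.0)
        dn[k] = max(dn[k] - step, 0.0)
        jac[:, k] = (all_probs(up) - all_probs(dn)) / (up[k] - dn[k])
    w = 1.0 / np.clip(p0, 1e-10, None)
    info = jac.T @ (jac * w[:, None])
    return int(np.linalg.matrix_rank(info, tol=1e-8))
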