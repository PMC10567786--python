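"""Maximum-likelihood estimation of the 2-HT lineup model.

Observed data are six category counts per condition (suspect / filler /
rejection, separately for culprit-present and culprit-absent lineups).  Each
tree is treated as an independent multinomial, so a participant's several
lineup decisions count as independent observations — the standard assumption
in this model family, documented rather than relaxed here.

Fitting maximizes the multinomial log-likelihood over the free parameters on
the probability scale with a box-constrained quasi-Newton optimizer and a
multi-start policy.  Goodness of fit is the likelihood-ratio statistic
G² = 2 Σ obs·ln(obs/exp) against the saturated model; standard errors come
from the observed information (finite-difference Hessian of the negative
log-likelihood at the MLE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .model import (
    CATEGORY_NAMES,
    ConditionParameters,
    ModelSpec,
    degrees_of_freedom,
    expand_parameters,
)

__all__ = [
    "ResponseCounts",
    "FitOptions",
    "FitResult",
    "log_likelihood",
    "g_squared",
    "fit",
    "standard_errors",
]

#: A free parameter closer than this to 0 or 1 is treated as on the boundary;
#: its standard error is reported as undefined (NaN).
BOUNDARY_TOL = 1e-4


@dataclass(frozen=True)
class ResponseCounts:
    """Observed category counts for one condition (CP then CA tree)."""

    condition_label: str
    cp_suspect: int
    cp_filler: int
    cp_reject: int
    ca_suspect: int
    ca_filler: int
    ca_reject: int

    def __post_init__(self) -> None:
        for name in CATEGORY_NAMES:
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in CATEGORY_NAMES], dtype=float)

    @property
    def cp_total(self) -> int:
        return self.cp_suspect + self.cp_filler + self.cp_reject

    @property
    def ca_total(self) -> int:
        return self.ca_suspect + self.ca_filler + self.ca_reject


@dataclass(frozen=True)
class FitOptions:
    """Multi-start optimizer policy.

    ``n_starts`` runs: the first from all parameters at 0.5, the rest from
    uniform random draws governed by ``seed``.  Starts whose final
    log-likelihood is within ``agree_tol`` of the best are counted as
    agreeing, a cheap diagnostic for a rugged likelihood.
    """

    n_starts: int = 10
    seed: int = 0
    ftol: float = 1e-12
    gtol: float = 1e-6
    max_iter: int = 2000
    agree_tol: float = 1e-6
    #: a start that ends without formal convergence still counts if its
    #: projected gradient is below this (the likelihood is on the counts
    #: scale, where finite-difference gradients carry ~1e-5 noise)
    stationarity_tol: float = 1e-3


@dataclass(frozen=True)
class FitResult:
    """MLEs plus fit diagnostics for one spec/data combination."""

    spec: ModelSpec
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    expected_counts: dict[str, np.ndarray]
    log_likelihood: float
    g_squared: float
    df: int
    p_value: float
    converged: bool
    n_starts_agreeing: int

    @property
    def free_values(self) -> np.ndarray:
        return np.array(
            [self.estimates[n] for n in self.spec.free_parameter_names]
        )

    def condition_parameters(self) -> dict[str, ConditionParameters]:
        return expand_parameters(self.spec, self.free_values)


def _prepare(
    spec: ModelSpec, data: Sequence[ResponseCounts]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Validate data against spec; return counts, tree totals and lookup
    tables aligned with the spec's condition order."""
    by_label: dict[str, ResponseCounts] = {}
    for rc in data:
        if rc.condition_label in by_label:
            raise ValueError(f"duplicate counts for condition {rc.condition_label!r}")
        by_label[rc.condition_label] = rc
    missing = [l for l in spec.labels if l not in by_label]
    extra = [l for l in by_label if l not in spec.labels]
    if missing or extra:
        raise ValueError(
            f"data/spec condition mismatch: missing {missing}, unexpected {extra}"
        )
    counts = np.stack([by_label[l].as_array() for l in spec.labels])
    for l in spec.labels:
        rc = by_label[l]
        n = spec.condition(l).n_participants
        if n and (rc.cp_total != 2 * n or rc.ca_total != 2 * n):
            warnings.warn(
                f"condition {l!r}: tree totals ({rc.cp_total}, {rc.ca_total}) "
                f"differ from 2 x n_participants = {2 * n}",
                stacklevel=3,
            )
    idx, fixed = spec.index_tables()
    return counts, spec.sampling_constants(), idx, fixed


def _category_probs(
    free: np.ndarray, idx: np.ndarray, fixed: np.ndarray, cs: np.ndarray
) -> np.ndarray:
    """Vectorized category probabilities, shape (n_cond, 6)."""
    theta = np.where(idx >= 0, free[np.clip(idx, 0, None)], fixed) if free.size else fixed
    dP, dA, b, g = theta[:, 0], theta[:, 1], theta[:, 2], theta[:, 3]
    gc = (1 - b) * g * cs
    gf = (1 - b) * g * (1 - cs)
    gr = (1 - b) * (1 - g)
    return np.column_stack(
        [
            dP + (1 - dP) * (b + gc),
            (1 - dP) * gf,
            (1 - dP) * gr,
            (1 - dA) * (b + gc),
            (1 - dA) * gf,
            dA + (1 - dA) * gr,
        ]
    )


def log_likelihood(
    spec: ModelSpec, data: Sequence[ResponseCounts], free_values: Sequence[float]
) -> float:
    """Multinomial log-likelihood Σ counts·log(probability).

    The convention 0·log 0 = 0 applies; a zero-probability category with a
    positive count yields -inf.  Multinomial coefficients are omitted (they
    cancel from every likelihood ratio used here).
    """
    counts, cs, idx, fixed = _prepare(spec, data)
    free = np.asarray(free_values, dtype=float)
    if free.shape != (spec.n_free,):
        raise ValueError(f"expected {spec.n_free} free values, got {free.shape}")
    p = _category_probs(free, idx, fixed, cs)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, counts * np.log(p), 0.0)
    if np.isnan(terms).any():  # count > 0 on p == 0
        return -np.inf
    return float(terms.sum())


def _saturated_log_likelihood(counts: np.ndarray) -> float:
    total = 0.0
    for tree in (counts[:, :3], counts[:, 3:]):
        n = tree.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(tree > 0, tree * np.log(tree / n), 0.0)
        total += terms.sum()
    return float(total)


def g_squared(observed: np.ndarray, expected: np.ndarray) -> float:
    """Likelihood-ratio statistic 2 Σ obs·ln(obs/exp) over all categories.

    Categories with zero observed count contribute nothing; a positive count
    on zero expectancy makes the statistic infinite.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(observed > 0, observed * np.log(observed / expected), 0.0)
    if np.isnan(terms).any() or np.isinf(terms).any():
        warnings.warn("expected count is 0 where observed > 0: G^2 is infinite")
        return float("inf")
    return float(2.0 * terms.sum())


def fit(
    spec: ModelSpec,
    data: Sequence[ResponseCounts],
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the spec to observed counts by maximum likelihood.

    Raises if the spec is over-parameterized or no optimizer start converges.
    """
    options = options or FitOptions()
    df = degrees_of_freedom(spec)
    counts, cs, idx, fixed = _prepare(spec, data)
    tree_totals = np.column_stack(
        [counts[:, :3].sum(axis=1), counts[:, 3:].sum(axis=1)]
    )
    if (tree_totals <= 0).any():
        raise ValueError("every condition needs positive CP and CA tree totals")

    def nll(free: np.ndarray) -> float:
        p = _category_probs(free, idx, fixed, cs)
        p = np.clip(p, 1e-300, None)
        return -float((counts * np.log(p)).sum())

    nfree = spec.n_free
    if nfree == 0:
        best_x = np.empty(0)
        converged, agreeing = True, 1
    else:
        rng = np.random.default_rng(options.seed)
        opt_kwargs = dict(
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * nfree,
            options={
                "ftol": options.ftol,
                "gtol": options.gtol,
                "maxiter": options.max_iter,
                "maxfun": 50 * options.max_iter,
            },
        )
        def stationary(res) -> bool:
            # projected gradient: at a bound only the infeasible direction
            # counts against stationarity
            g = np.asarray(res.jac, dtype=float)
            pg = np.where(res.x <= 0.0, np.minimum(g, 0.0), g)
            pg = np.where(res.x >= 1.0, np.maximum(pg, 0.0), pg)
            return bool(np.max(np.abs(pg)) <= options.stationarity_tol)

        results = []
        for s in range(options.n_starts):
            x0 = np.full(nfree, 0.5) if s == 0 else rng.uniform(0.01, 0.99, nfree)
            res = optimize.minimize(nll, x0, **opt_kwargs)
            if not res.success:
                # an over-tight ftol can abort the line search one step from
                # the optimum; polish from the endpoint at scipy's default
                res = optimize.minimize(
                    nll, res.x, method="L-BFGS-B", bounds=opt_kwargs["bounds"]
                )
            results.append(res)
        successes = [r for r in results if r.success or stationary(r)]
        if not successes:
            raise RuntimeError(
                "optimizer failed to converge from all "
                f"{options.n_starts} starts: {results[0].message}"
            )
        best = min(successes, key=lambda r: r.fun)
        best_x = np.clip(best.x, 0.0, 1.0)
        converged = True
        agreeing = sum(1 for r in successes if r.fun - best.fun <= options.agree_tol)

    p_hat = _category_probs(best_x, idx, fixed, cs)
    expected = np.column_stack(
        [p_hat[:, :3] * tree_totals[:, :1], p_hat[:, 3:] * tree_totals[:, 1:]]
    )
    g2 = g_squared(counts, expected)
    estimates = dict(zip(spec.free_parameter_names, best_x))
    ses = standard_errors(spec, data, estimates)
    return FitResult(
        spec=spec,
        estimates=estimates,
        standard_errors=ses,
        expected_counts={l: expected[i] for i, l in enumerate(spec.labels)},
        log_likelihood=-nll(best_x) if nfree else log_likelihood(spec, data, best_x),
        g_squared=g2,
        df=df,
        p_value=float(stats.chi2.sf(g2, df)) if df > 0 else float("nan"),
        converged=converged,
        n_starts_agreeing=agreeing,
    )


def _observed_information(
    spec: ModelSpec, data: Sequence[ResponseCounts], free: np.ndarray, step: float
) -> np.ndarray:
    """Central-difference Hessian of the negative log-likelihood."""
    counts, cs, idx, fixed = _prepare(spec, data)

    def nll(x: np.ndarray) -> float:
        p = _category_probs(np.clip(x, 0.0, 1.0), idx, fixed, cs)
        p = np.clip(p, 1e-300, None)
        return -float((counts * np.log(p)).sum())

    n = free.size
    hess = np.empty((n, n))
    h = np.full(n, step)
    for i in range(n):
        for j in range(i, n):
            ei = np.eye(1, n, i)[0] * h[i]
            ej = np.eye(1, n, j)[0] * h[j]
            if i == j:
                val = (nll(free + ei) - 2 * nll(free) + nll(free - ei)) / h[i] ** 2
            else:
                val = (
                    nll(free + ei + ej)
                    - nll(free + ei - ej)
                    - nll(free - ei + ej)
                    + nll(free - ei - ej)
                ) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    return hess


def standard_errors(
    spec: ModelSpec,
    data: Sequence[ResponseCounts],
    estimates: Mapping[str, float],
    step: float = 1e-5,
) -> dict[str, float]:
    """Observed-information standard errors on the probability scale.

    Square roots of the diagonal of the inverse finite-difference Hessian of
    the negative log-likelihood.  Parameters on the [0, 1] boundary get NaN
    (a Wald SE is meaningless there); a singular information matrix flags all
    free parameters as NaN and warns with the matrix rank.
    """
    names = spec.free_parameter_names
    free = np.array([estimates[n] for n in names], dtype=float)
    if free.size == 0:
        return {}
    ses = dict.fromkeys(names, float("nan"))
    interior = (free > BOUNDARY_TOL) & (free < 1.0 - BOUNDARY_TOL)
    if not interior.any():
        return ses
    # restrict the information matrix to interior parameters
    info = _observed_information(spec, data, free, step)
    sub = info[np.ix_(interior, interior)]
    try:
        cov = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular observed information (rank "
            f"{np.linalg.matrix_rank(sub)} of {sub.shape[0]}); SEs undefined"
        )
        return ses
    diag = np.diag(cov)
    if (diag <= 0).any():
        warnings.warn(
            "observed information is not positive definite at the estimates; "
            "SEs for the affected parameters are undefined"
        )
    se_interior = np.sqrt(np.where(diag > 0, diag, np.nan))
    for name, se in zip(np.array(names)[interior], se_interior):
        ses[str(name)] = float(se)
    return ses
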