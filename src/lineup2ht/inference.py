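"""Nested-model likelihood-ratio tests for the 2-HT lineup model.

Hypotheses about the latent processes are tested by comparing a base model
against a restricted model in which a parameter is additionally equated
across conditions: ΔG² = G²(restricted) - G²(base) is referred to a central
chi-square at Δdf = the number of free parameters lost.

The two contrast families the lineup-size design calls for are shipped as
presets:

``size_dP`` / ``size_g``
    equate dP (or g) across lineup sizes *within* each presentation format;
``format_dP`` / ``format_g``
    equate dP (or g) across formats *within* each lineup size.

With four conditions in a 2 (size) x 2 (format) design each preset removes
two free parameters, hence Δdf = 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from scipy import stats

from .estimation import FitOptions, FitResult, ResponseCounts, fit
from .model import ModelSpec, PARAM_NAMES

__all__ = [
    "NestedTestResult",
    "compare_nested",
    "chi_square_upper_tail",
    "equate_within",
    "contrast_spec",
    "CONTRAST_PRESETS",
]


@dataclass(frozen=True)
class NestedTestResult:
    """ΔG² test of a parameter restriction."""

    label: str
    delta_g_squared: float
    delta_df: int
    p_value: float
    base_fit: FitResult
    restricted_fit: FitResult


def chi_square_upper_tail(statistic: float, df: int) -> float:
    """Upper-tail probability of the central chi-square distribution."""
    if statistic < 0:
        raise ValueError(f"statistic must be nonnegative, got {statistic}")
    if df < 1:
        raise ValueError(f"df must be a positive integer, got {df}")
    return float(stats.chi2.sf(statistic, df))


def _cell_classes(spec: ModelSpec) -> dict[tuple[str, str], object]:
    """Map each (param, label) cell to its identity: the free-parameter name
    or the fixed value."""
    return {key: spec.restrictions[key] for key in spec.restrictions}


def assert_nested(base: ModelSpec, restricted: ModelSpec) -> None:
    """Check that ``restricted`` coarsens ``base``'s restriction map.

    Every base equivalence class (cells sharing a free parameter) must map to
    a single restricted class, and every cell fixed in the base must be fixed
    to the same value in the restricted spec.  Violations raise with the
    offending parameter blocks named.
    """
    if base.labels != restricted.labels:
        raise ValueError(
            f"specs cover different conditions: {base.labels} vs {restricted.labels}"
        )
    violations = []
    by_class: dict[str, set] = {}
    for cond in base.conditions:
        for param in PARAM_NAMES:
            key = (param, cond.label)
            rb = base.restrictions[key]
            rr = restricted.restrictions[key]
            if isinstance(rb, str):
                by_class.setdefault(rb, set()).add(rr)
            elif not isinstance(rr, str) and abs(rr - rb) <= 1e-12:
                continue
            else:
                violations.append(
                    f"{key}: fixed to {rb} in base but {rr!r} in restricted"
                )
    for name, targets in by_class.items():
        if len(targets) > 1:
            violations.append(
                f"base free parameter {name!r} maps to multiple restricted "
                f"assignments {sorted(map(repr, targets))}"
            )
    if violations:
        raise ValueError(
            "restricted spec is not nested in the base spec:\n  "
            + "\n  ".join(violations)
        )


def compare_nested(
    base_spec: ModelSpec,
    restricted_spec: ModelSpec,
    data: Sequence[ResponseCounts],
    options: FitOptions | None = None,
    label: str | None = None,
) -> NestedTestResult:
    """Fit both specs to the same data and test the restriction.

    Both fits share the same multi-start policy and seed so reports are
    deterministic.  Δdf must be positive: comparing a spec against itself
    (or any reparameterization of equal size) is rejected.
    """
    assert_nested(base_spec, restricted_spec)
    delta_df = base_spec.n_free - restricted_spec.n_free
    if delta_df <= 0:
        raise ValueError(
            "restricted spec removes no free parameters (delta df = "
            f"{delta_df}); there is nothing to test"
        )
    options = options or FitOptions()
    base_fit = fit(base_spec, data, options)
    restricted_fit = fit(restricted_spec, data, options)
    delta_g2 = restricted_fit.g_squared - base_fit.g_squared
    if delta_g2 < -1e-6:
        raise RuntimeError(
            f"restricted fit beat the base fit by {-delta_g2:.3g} in G^2; "
            "the base fit did not converge to its optimum"
        )
    delta_g2 = max(delta_g2, 0.0)
    return NestedTestResult(
        label=label or f"{base_spec.n_free} vs {restricted_spec.n_free} free",
        delta_g_squared=delta_g2,
        delta_df=delta_df,
        p_value=chi_square_upper_tail(delta_g2, delta_df),
        base_fit=base_fit,
        restricted_fit=restricted_fit,
    )


def equate_within(
    spec: ModelSpec, param: str, group_by: Callable[[object], object]
) -> ModelSpec:
    """Restricted spec equating ``param`` across conditions within groups.

    ``group_by`` maps a :class:`~lineup2ht.model.LineupCondition` to a group
    key; all of the group's free cells for ``param`` are merged into one free
    parameter named ``{param}_{group}``.  Cells fixed to a constant are left
    untouched.
    """
    if param not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {param!r}")
    restrictions = dict(spec.restrictions)
    groups: dict[object, list[str]] = {}
    for cond in spec.conditions:
        groups.setdefault(group_by(cond), []).append(cond.label)
    for group, labels in groups.items():
        free_labels = [
            l for l in labels if isinstance(spec.restrictions[(param, l)], str)
        ]
        if len(free_labels) < 2:
            continue
        merged = f"{param}_{group}"
        for l in free_labels:
            restrictions[(param, l)] = merged
    return ModelSpec(conditions=spec.conditions, restrictions=restrictions)


def contrast_spec(spec: ModelSpec, preset: str) -> ModelSpec:
    """Build the restricted spec for a named contrast preset."""
    try:
        param, grouping = CONTRAST_PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown contrast preset {preset!r}; available: "
            f"{sorted(CONTRAST_PRESETS)}"
        ) from None
    return equate_within(spec, param, grouping)


#: preset name -> (parameter, grouping). ``size_*`` equates across sizes
#: within format (group = format); ``format_*`` across formats within size.
CONTRAST_PRESETS: dict[str, tuple[str, Callable]] = {
    "size_dP": ("dP", lambda c: c.lineup_format),
    "size_g": ("g", lambda c: c.lineup_format),
    "format_dP": ("dP", lambda c: c.lineup_size),
    "format_g": ("g", lambda c: c.lineup_size),
}
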