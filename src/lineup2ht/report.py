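"""Human- and machine-readable reports for fits and tests.

Presentation rounding follows the field's convention — parameters, SEs and
G² to 2 decimals, p-values to 3 — but only at this layer; every number in
the JSON form is emitted at full precision so reports are diffable and
byte-identical across runs of the same configuration.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np

from .estimation import FitResult
from .inference import NestedTestResult
from .model import CATEGORY_NAMES

__all__ = ["fit_to_dict", "test_to_dict", "format_fit", "format_test", "to_json"]


def _fmt_p(p: float) -> str:
    return "< 0.001" if p < 0.0005 else f"= {p:.3f}"


def fit_to_dict(res: FitResult) -> dict:
    return {
        "free_parameters": list(res.spec.free_parameter_names),
        "estimates": {k: float(v) for k, v in res.estimates.items()},
        "standard_errors": {
            k: (None if np.isnan(v) else float(v))
            for k, v in res.standard_errors.items()
        },
        "expected_counts": {
            label: dict(zip(CATEGORY_NAMES, map(float, row)))
            for label, row in res.expected_counts.items()
        },
        "log_likelihood": float(res.log_likelihood),
        "g_squared": float(res.g_squared),
        "df": int(res.df),
        "p_value": float(res.p_value),
        "converged": bool(res.converged),
        "n_starts_agreeing": int(res.n_starts_agreeing),
    }


def test_to_dict(res: NestedTestResult) -> dict:
    return {
        "label": res.label,
        "delta_g_squared": float(res.delta_g_squared),
        "delta_df": int(res.delta_df),
        "p_value": float(res.p_value),
        "base": fit_to_dict(res.base_fit),
        "restricted": fit_to_dict(res.restricted_fit),
    }


def format_fit(res: FitResult) -> str:
    lines = [
        f"Goodness of fit: G2({res.df}) = {res.g_squared:.2f}, "
        f"p {_fmt_p(res.p_value)}",
        f"Log-likelihood: {res.log_likelihood:.4f}   "
        f"(starts agreeing: {res.n_starts_agreeing})",
        "",
        f"{'parameter':<14}{'estimate':>10}{'SE':>10}",
    ]
    for name in res.spec.free_parameter_names:
        se = res.standard_errors[name]
        se_s = f"{se:.2f}" if not np.isnan(se) else "undef"
        lines.append(f"{name:<14}{res.estimates[name]:>10.2f}{se_s:>10}")
    lines.append("")
    lines.append(
        f"{'condition':<12}" + "".join(f"{n:>12}" for n in CATEGORY_NAMES)
    )
    for label, row in res.expected_counts.items():
        lines.append(f"{label:<12}" + "".join(f"{v:>12.1f}" for v in row))
    return "\n".join(lines)


def format_test(res: NestedTestResult) -> str:
    return (
        f"{res.label}: dG2({res.delta_df}) = {res.delta_g_squared:.2f}, "
        f"p {_fmt_p(res.p_value)}"
    )


def to_json(obj: dict | Sequence, indent: int = 2) -> str:
    return json.dumps(obj, indent=indent, sort_keys=False)
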