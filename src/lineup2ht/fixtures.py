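"""Packaged study fixtures: the two lineup-size experiments.

Both four-condition datasets (2 lineup sizes x 2 presentation formats, six
response counts each) ship with the package, together with the matching base
model specs (condition-specific dP and g, shared b and dA, the study's
sampling constants).  ``table1(1)`` / ``table1(2)`` return them ready to fit.
"""

from __future__ import annotations

import json
from importlib import resources

from .estimation import ResponseCounts
from .io import read_counts, read_model_spec
from .model import LineupCondition, ModelSpec

__all__ = ["table1", "base_spec", "published_results", "fixture_path"]

_FIXTURES = {1: ("exp1_base.yaml", "exp1_counts.tsv"), 2: ("exp2_base.yaml", "exp2_counts.tsv")}


def fixture_path(name: str):
    """Path to a packaged data file (context-manager free; files are real on
    disk for a source install)."""
    return resources.files("lineup2ht.data").joinpath(name)


def table1(experiment: int) -> tuple[ModelSpec, list[ResponseCounts]]:
    """Base model spec and observed counts for experiment 1 or 2."""
    try:
        spec_name, counts_name = _FIXTURES[experiment]
    except KeyError:
        raise ValueError(
            f"unknown experiment {experiment!r}; choose 1 or 2"
        ) from None
    return read_model_spec(fixture_path(spec_name)), read_counts(
        fixture_path(counts_name)
    )


def base_spec(conditions: tuple[LineupCondition, ...] | list[LineupCondition]) -> ModelSpec:
    """Construct the standard base model for arbitrary conditions:
    condition-specific dP and g, one b and one dA shared by all."""
    restrictions = {}
    for c in conditions:
        restrictions[("dP", c.label)] = f"dP_{c.label}"
        restrictions[("g", c.label)] = f"g_{c.label}"
        restrictions[("b", c.label)] = "b"
        restrictions[("dA", c.label)] = "dA"
    return ModelSpec(conditions=tuple(conditions), restrictions=restrictions)


def published_results() -> dict:
    """The published analysis numbers the `replicate` command checks against."""
    with fixture_path("published_results.json").open() as fh:
        return json.load(fh)
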