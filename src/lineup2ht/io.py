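"""Reading and writing counts files and model-spec files.

Counts file: tab- (or comma-) delimited text, one row per condition, fixed
header::

    condition  cp_suspect  cp_filler  cp_reject  ca_suspect  ca_filler  ca_reject

Model-spec file: a YAML document with a ``conditions`` list (label, format,
size, sampling constant, n) and a ``restrictions`` block mapping each of
dP/dA/b/g per condition label either to a free-parameter name (string) or to
a fixed numeric value.  Example::

    conditions:
      - {label: seq3, lineup_format: sequential, lineup_size: 3,
         sampling_constant: 0.33333, n_participants: 382}
    restrictions:
      dP: {seq3: dP_seq3}
      dA: {seq3: dA}
      b:  {seq3: 0.0}
      g:  {seq3: g_seq3}
    free_parameters: [dP_seq3, dA, g_seq3]   # optional, fixes ordering

Both formats round-trip losslessly through the functions here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .estimation import ResponseCounts
from .model import CATEGORY_NAMES, LineupCondition, ModelSpec, PARAM_NAMES

__all__ = [
    "read_counts",
    "write_counts",
    "read_model_spec",
    "write_model_spec",
    "counts_to_frame",
]

COUNTS_COLUMNS = ("condition", *CATEGORY_NAMES)


def counts_to_frame(data: Sequence[ResponseCounts]) -> pd.DataFrame:
    rows = [
        {"condition": rc.condition_label, **{n: getattr(rc, n) for n in CATEGORY_NAMES}}
        for rc in data
    ]
    return pd.DataFrame(rows, columns=list(COUNTS_COLUMNS))


def read_counts(path: str | Path) -> list[ResponseCounts]:
    """Read a delimited counts file (tab or comma separated)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"counts file {path} is missing columns {missing}; expected header "
            f"{list(COUNTS_COLUMNS)}"
        )
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                ResponseCounts(
                    condition_label=str(row["condition"]),
                    **{n: int(row[n]) for n in CATEGORY_NAMES},
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"counts file {path}, row {i + 2}: {exc}") from exc
    return out


def write_counts(data: Sequence[ResponseCounts], path: str | Path) -> None:
    counts_to_frame(data).to_csv(path, sep="\t", index=False)


def spec_to_dict(spec: ModelSpec) -> dict:
    conditions = [
        {
            "label": c.label,
            "lineup_format": c.lineup_format,
            "lineup_size": c.lineup_size,
            "sampling_constant": c.sampling_constant,
            "n_participants": c.n_participants,
        }
        for c in spec.conditions
    ]
    restrictions = {
        param: {
            c.label: spec.restrictions[(param, c.label)] for c in spec.conditions
        }
        for param in PARAM_NAMES
    }
    return {
        "conditions": conditions,
        "restrictions": restrictions,
        "free_parameters": list(spec.free_parameter_names),
    }


def spec_from_dict(doc: dict) -> ModelSpec:
    try:
        raw_conditions = doc["conditions"]
        raw_restrictions = doc["restrictions"]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"model-spec document lacks required block: {exc}") from exc
    conditions = tuple(
        LineupCondition(
            label=str(c["label"]),
            lineup_format=c["lineup_format"],
            lineup_size=int(c["lineup_size"]),
            sampling_constant=c.get("sampling_constant"),
            n_participants=int(c.get("n_participants", 0)),
        )
        for c in raw_conditions
    )
    restrictions = {}
    for param, per_label in raw_restrictions.items():
        if param not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {param!r} in restrictions block")
        for label, target in per_label.items():
            restrictions[(param, str(label))] = target
    return ModelSpec(
        conditions=conditions,
        restrictions=restrictions,
        free_parameter_names=tuple(doc.get("free_parameters", ())),
    )


def read_model_spec(path: str | Path) -> ModelSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        return spec_from_dict(doc)
    except ValueError as exc:
        raise ValueError(f"model-spec file {path}: {exc}") from exc


def write_model_spec(spec: ModelSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)
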