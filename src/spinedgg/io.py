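"""File I/O: JSON graph snapshots and YAML run configuration.

Snapshot schema (JSON object): ``clock``, ``seed``, ``actin`` (list of node
records with id, pos, pointers, subtype, monomer counts), ``membrane``
(vertex records forming one CCW cycle), ``attachments``, ``bundles``,
``pools``, ``rng_state``.  Round trip is exact: ``read(write(s)) == s``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import fields

import yaml

from .engine import RunConfig
from .params import ModelParams
from .state import SimState


def write_snapshot(state: SimState, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(state.to_dict(), fh, indent=1)


def read_snapshot(path: str) -> SimState:
    with open(path) as fh:
        d = json.load(fh)
    for key in ("clock", "actin", "membrane", "n_actin_rows", "n_mem_rows"):
        if key not in d:
            raise ValueError(f"snapshot {path}: missing required key {key!r}")
    return SimState.from_dict(d)


_RUN_KEYS = {f.name for f in fields(RunConfig)} - {"params", "rule_groups"}


def read_config(path: str) -> RunConfig:
    """Parse a YAML run configuration.

    Top-level keys mirror RunConfig (``t_end`` is required); model constants
    go under ``params`` with their ModelParams names.  Unknown keys warn but
    do not fail; malformed YAML raises with the offending location.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"config {path}: expected a mapping at top level")
    if "t_end" not in doc:
        raise ValueError(f"config {path}: missing required key 't_end'")
    params = ModelParams.from_dict(doc.get("params", {}) or {})
    kwargs = {}
    for k, v in doc.items():
        if k == "params":
            continue
        if k == "rule_groups":
            kwargs[k] = frozenset(v)
        elif k in _RUN_KEYS:
            kwargs[k] = v
        else:
            warnings.warn(f"config {path}: ignoring unknown key {k!r}")
    return RunConfig(params=params, **kwargs)


def write_config(config: RunConfig, path: str) -> None:
    doc = {f.name: getattr(config, f.name) for f in fields(RunConfig)
           if f.name not in ("params", "rule_groups")}
    doc["rule_groups"] = sorted(config.rule_groups)
    doc["params"] = config.params.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
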