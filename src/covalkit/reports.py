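"""Machine-readable JSON fit reports.

Reports are self-describing: they embed the software version, the exact
configuration, input checksums, and the methodological decisions taken
(conversion conventions, windows, mass-table provenance), so deterministic
analyses re-run from a report reproduce it bitwise.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from . import __version__
from .io import sha256_of


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return {"__inf__": math.copysign(1, f)} if math.isinf(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def build_report(command: str, results, config: dict | None = None,
                 inputs=None, decisions: dict | None = None) -> dict:
    report = {
        "software": {"name": "covalkit", "version": __version__},
        "command": command,
        "config": _jsonable(config or {}),
        "inputs": [{"path": str(p), "sha256": sha256_of(p)} for p in (inputs or [])],
        "decisions": _jsonable(decisions or {}),
        "results": _jsonable(results),
    }
    return report


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
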