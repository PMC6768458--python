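"""Result serialization: schema-stable CSV/JSON export with metadata."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import sympy as sp

from . import __version__
from .bifurcation import BifurcationDiagram
from .lna import CovarianceResult
from .meanfield import FieldSamples, Trajectory
from .model_dsl import ReactionModel, serialize_model
from .multiagent import AgentTrajectory
from .ssa import EnsembleResult, StateTrajectory

__all__ = ["export_results", "model_hash"]


def model_hash(model: ReactionModel) -> str:
    return hashlib.sha256(serialize_model(model).encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (sp.Basic, sp.MatrixBase)):
        return str(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (complex, np.complexfloating)):
        return {"re": float(obj.real), "im": float(obj.imag)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
            if not f.name.startswith("_")
        }
    return obj


def _metadata(result, extra: dict | None = None) -> dict:
    meta = {"version": __version__, "type": type(result).__name__}
    for attr in ("seed", "dt"):
        if hasattr(result, attr) and getattr(result, attr) is not None:
            meta[attr] = _jsonable(getattr(result, attr))
    if extra:
        meta.update(_jsonable(extra))
    return meta


def export_results(result, path, format: str = "csv", metadata: dict | None = None) -> Path:
    """Write a result object to ``path`` as CSV or JSON.

    CSV layouts: trajectories as ``t,var1,var2,...``; field samples as
    ``x[,y],dx[,dy],speed``; bifurcation diagrams as
    ``branch_id,param,response,stability,special_point_kind``.  JSON exports
    carry the full object (symbolic expressions as canonical strings, floats
    at full double precision) plus a metadata block.
    """
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        payload = {"metadata": _metadata(result, metadata), "result": _jsonable(result)}
        if isinstance(result, CovarianceResult):
            payload["result"] = {
                "C": _jsonable(result.covariance),
                "fixed_point": _jsonable(result.fixed_point),
                "ellipse": {
                    "center": _jsonable(result.ellipse_center),
                    "axes": _jsonable(result.ellipse_axes),
                    "lengths": _jsonable(result.ellipse_lengths),
                },
                "eigvec_projections": _jsonable(result.eigvec_projections),
            }
        path.write_text(json.dumps(payload, indent=1, default=_jsonable))
        return path
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    if isinstance(result, Trajectory):
        df = pd.DataFrame(result.states, columns=list(result.variables))
        df.insert(0, "t", result.times)
    elif isinstance(result, (StateTrajectory,)):
        df = pd.DataFrame(result.states, columns=list(result.species))
        df.insert(0, "t", result.jump_times)
    elif isinstance(result, AgentTrajectory):
        df = pd.DataFrame(result.counts, columns=list(result.states))
        df.insert(0, "t", result.times)
    elif isinstance(result, FieldSamples):
        dim = result.points.shape[1]
        cols = {}
        cols["x"] = result.points[:, 0]
        if dim == 2:
            cols["y"] = result.points[:, 1]
        cols["dx"] = result.vectors[:, 0]
        if dim == 2:
            cols["dy"] = result.vectors[:, 1]
        cols["speed"] = result.speed
        df = pd.DataFrame(cols)
    elif isinstance(result, BifurcationDiagram):
        rows = []
        for bid, b in enumerate(result.branches):
            resp = result.response_values(b)
            kinds = {i: "" for i in range(len(b))}
            for spt in b.special_points:
                i = int(np.argmin(np.abs(b.parameter_values - spt.parameter)))
                kinds[i] = spt.kind
            for i in range(len(b)):
                rows.append(
                    (bid, b.parameter_values[i], resp[i], bool(b.stability[i]), kinds[i])
                )
        df = pd.DataFrame(
            rows, columns=["branch_id", "param", "response", "stability", "special_point_kind"]
        )
    elif isinstance(result, EnsembleResult):
        df = pd.DataFrame(result.final_states, columns=list(result.species))
        df.insert(0, "run", np.arange(result.runs))
    else:
        raise TypeError(f"no CSV layout for {type(result).__name__}; use format='json'")
    df.to_csv(path, index=False, float_format="%.17g")
    return path
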