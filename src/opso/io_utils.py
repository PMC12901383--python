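"""File I/O helpers: atomic writes, run configs, result serialization."""

from __future__ import annotations

import dataclasses
import json
import os
import platform
import sys
import tempfile
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError

__all__ = [
    "atomic_write_text",
    "write_yaml",
    "read_yaml",
    "write_json",
    "write_runs_csv",
    "write_summary_csv",
    "write_convergence_csv",
    "run_log",
]


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write-then-rename so readers never observe a partial file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(path: str | Path, payload: Any) -> None:
    atomic_write_text(path, json.dumps(_jsonable(payload), indent=2) + "\n")


def write_yaml(path: str | Path, payload: dict) -> None:
    atomic_write_text(path, yaml.safe_dump(_jsonable(payload), sort_keys=True))


def read_yaml(path: str | Path) -> dict:
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except OSError as exc:
        raise FormatError(f"cannot read config {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise FormatError(f"malformed config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError(f"config {path} must be a mapping")
    return data


def write_runs_csv(path: str | Path, results: list) -> None:
    """One row per run: seed, best_fitness, evaluations."""
    df = pd.DataFrame(
        {
            "seed": [r.seed for r in results],
            "best_fitness": [r.best_fitness for r in results],
            "evaluations": [r.evaluations for r in results],
        }
    )
    atomic_write_text(path, df.to_csv(index=False))


def write_summary_csv(path: str | Path, results: list, label: str) -> None:
    """Mean/std/min/max of the final best fitness across runs."""
    finals = np.array([r.best_fitness for r in results], dtype=float)
    df = pd.DataFrame(
        [
            {
                "algorithm": label,
                "runs": len(results),
                "fitness_mean": finals.mean(),
                "fitness_std": finals.std(ddof=0) if len(finals) > 1 else 0.0,
                "fitness_min": finals.min(),
                "fitness_max": finals.max(),
            }
        ]
    )
    atomic_write_text(path, df.to_csv(index=False))


def write_convergence_csv(path: str | Path, results: list) -> None:
    """Long-format convergence curves: run seed, iteration, gbest fitness."""
    frames = []
    for r in results:
        frames.append(
            pd.DataFrame(
                {
                    "seed": r.seed,
                    "iteration": np.arange(1, len(r.history) + 1),
                    "gbest_fitness": r.history,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["seed", "iteration", "gbest_fitness"]
    )
    atomic_write_text(path, df.to_csv(index=False))


def run_log(config: dict, started: datetime, finished: datetime) -> dict:
    """Provenance record written next to every command's outputs."""
    return {
        "config": config,
        "started": started.isoformat(),
        "finished": finished.isoformat(),
        "python": sys.version.split()[0],
        "platform": platform.platform(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }


def now() -> datetime:
    return datetime.now(timezone.utc)
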