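"""Episode CSV files, configuration loading and result serialization.

Episode files are long-format CSV with one header row and columns
``episode_id,k,t,brac,tac``: ``k`` is the 1-based sample index, ``t = k*tau``
the observation time, ``brac`` the input u_{k-1} held on the preceding
interval and ``tac`` the observation at time k*tau.  Floats are written with
17 significant digits so write -> read round trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .likelihood import Episode

__all__ = ["read_episodes", "write_episodes", "load_config",
           "write_json", "consistency_table"]

_COLUMNS = ["episode_id", "k", "t", "brac", "tac"]
_T_TOL = 1e-9


class EpisodeFileError(ValueError):
    """Malformed episode CSV."""


def read_episodes(path) -> list[Episode]:
    """Parse an episode CSV, validating index contiguity and the time column."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise EpisodeFileError(f"{path}: missing columns {missing}")
    for col in ("k", "t", "brac", "tac"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise EpisodeFileError(f"{path}: non-numeric values in column {col!r}")
    episodes = []
    for eid, g in df.groupby("episode_id", sort=True):
        g = g.reset_index()
        k = g["k"].to_numpy()
        if k[0] != 1 or np.any(np.diff(k) != 1):
            jump = int(np.flatnonzero(np.r_[k[0] != 1, np.diff(k) != 1])[0])
            raise EpisodeFileError(
                f"{path}: episode {eid!r} has non-contiguous sample index at "
                f"file row {int(g['index'][jump]) + 2}")
        tau = float(g["t"].iloc[0])  # t = k*tau with k starting at 1
        if np.any(np.abs(g["t"].to_numpy() - k * tau) > _T_TOL):
            bad = int(np.flatnonzero(np.abs(g["t"].to_numpy() - k * tau) > _T_TOL)[0])
            raise EpisodeFileError(
                f"{path}: episode {eid!r} time column inconsistent with k*tau at "
                f"file row {int(g['index'][bad]) + 2}")
        episodes.append(Episode(id=str(eid), tau=tau,
                                u=g["brac"].to_numpy(), obs=g["tac"].to_numpy()))
    return episodes


def write_episodes(episodes, path) -> None:
    """Write episodes in the long CSV format with lossless float precision."""
    frames = []
    for ep in episodes:
        k = np.arange(1, ep.n + 1)
        frames.append(pd.DataFrame({
            "episode_id": ep.id, "k": k, "t": k * ep.tau,
            "brac": ep.u, "tac": ep.obs,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def load_config(path) -> dict:
    """Load a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    """Deterministic JSON output (sorted keys, repr-exact floats)."""
    Path(path).write_text(json.dumps(_jsonable(obj), sort_keys=True, indent=1) + "\n")


def consistency_table(result) -> pd.DataFrame:
    """Tidy two-column table (size, statistic) for a refinement/consistency ladder."""
    name = {"m": "D", "M": "Dbar_M", "N": "Dbar_N"}[result.kind]
    return pd.DataFrame({result.kind: result.sizes(), name: result.values()})
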