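"""Trajectory persistence: compressed columnar arrays + JSON sidecar.

A trajectory is stored as ``<stem>.npz`` holding the event columns
(t, d, n1, n2, n3) and ``<stem>.json`` holding the generating configuration,
seed and software version.  Reading round-trips the arrays bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .dynamics import Trajectory

__all__ = ["write_trajectory", "read_trajectory"]


def _stem(path) -> Path:
    p = Path(path)
    return p.with_suffix("") if p.suffix in {".npz", ".json"} else p


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write ``traj`` to ``<path>.npz`` + ``<path>.json``; returns the npz path."""
    stem = _stem(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(stem.with_suffix(".npz"), t=traj.t, d=traj.d,
                        n1=traj.n[:, 0], n2=traj.n[:, 1], n3=traj.n[:, 2])
    sidecar = {
        "t_end": traj.t_end,
        "seed": traj.seed,
        "rep_index": traj.rep_index,
        "meta": traj.meta,
        "software_version": __version__,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return stem.with_suffix(".npz")


def read_trajectory(path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    stem = _stem(path)
    with np.load(stem.with_suffix(".npz")) as z:
        t = z["t"]
        d = z["d"]
        n = np.stack([z["n1"], z["n2"], z["n3"]], axis=1).astype(np.int16)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    return Trajectory(t=t, d=d, n=n, t_end=sidecar["t_end"],
                      seed=sidecar["seed"], rep_index=sidecar["rep_index"],
                      meta=sidecar.get("meta", {}))
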