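"""CSV / JSON / checkpoint I/O and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .coarse_grainer import EncoderSpec, InvertibleEncoder
from .dynamics import DynamicsPair
from .ei_measures import TransitionMatrix
from .training import NISPlus

__all__ = [
    "write_timeseries_csv", "read_timeseries_csv", "read_tpm_csv",
    "write_dataset", "read_dataset", "write_manifest",
    "save_checkpoint", "load_checkpoint",
]


def write_timeseries_csv(path, X: np.ndarray) -> None:
    """One row per time step, header x1..xp."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    cols = [f"x{j + 1}" for j in range(X.shape[1])]
    pd.DataFrame(X, columns=cols).to_csv(path, index=False)


def read_timeseries_csv(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=np.float64)


def read_tpm_csv(path) -> TransitionMatrix:
    """n x n transition matrix, header row optional."""
    first = pd.read_csv(path, header=None, nrows=1)
    has_header = not np.issubdtype(first.dtypes.iloc[0], np.number)
    df = pd.read_csv(path, header=0 if has_header else None)
    return TransitionMatrix(df.to_numpy(dtype=np.float64))


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir, command: str, config: dict, seeds: dict,
                   inputs=(), outputs=()) -> Path:
    """Record everything needed to reproduce a seeded run bitwise."""
    out_dir = Path(out_dir)
    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "inputs": [str(p) for p in inputs],
        "outputs": {str(p): _sha256(p) for p in outputs},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def write_dataset(out_dir, trajectories, config: dict, command: str,
                  seeds: dict) -> list[Path]:
    """Write one CSV per trajectory plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, traj in enumerate(trajectories):
        p = out_dir / f"traj_{k:04d}.csv"
        write_timeseries_csv(p, traj)
        paths.append(p)
    write_manifest(out_dir, command, config, seeds, outputs=paths)
    return paths


def read_dataset(in_dir) -> list[np.ndarray]:
    paths = sorted(Path(in_dir).glob("traj_*.csv"))
    if not paths:
        raise FileNotFoundError(f"no traj_*.csv files in {in_dir}")
    return [read_timeseries_csv(p) for p in paths]


# ----------------------------------------------------------------------
# Model checkpoints: parameter blob (.npz) + JSON sidecar metadata
# ----------------------------------------------------------------------

def save_checkpoint(model: NISPlus, path) -> None:
    path = Path(path)
    enc, dyn = model.encoder_, model.dynamics_
    arrays = (enc.state_arrays()
              + [p.data for p in dyn.f.parameters()]
              + [p.data for p in dyn.g.parameters()])
    np.savez(path.with_suffix(".npz"),
             **{f"p{i}": a for i, a in enumerate(arrays)})
    meta = {
        "params": model.get_params(),
        "p": enc.p,
        "q": enc.q,
        "sigma": model.sigma_.tolist(),
        "range_L": np.asarray(model.range_L_).tolist(),
        "history": model.history_,
        "diverged": model.diverged_,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def load_checkpoint(path) -> NISPlus:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    params = meta["params"]
    for key in ("range_L", "bandwidth"):
        if isinstance(params.get(key), str) and params[key] != "auto":
            params[key] = float(params[key])
    model = NISPlus(**params)
    p, q = int(meta["p"]), int(meta["q"])
    model.n_features_in_ = p
    model.encoder_ = InvertibleEncoder(EncoderSpec(
        p=p, q=q, n_coupling_layers=model.n_coupling_layers,
        hidden_width=model.hidden_width, init_seed=model.seed))
    model.dynamics_ = DynamicsPair.create(
        q, model.dyn_hidden, np.random.default_rng([model.seed, 1]))
    blob = np.load(path.with_suffix(".npz"))
    arrays = [blob[f"p{i}"] for i in range(len(blob.files))]
    n_enc = len(model.encoder_.parameters()) + 2  # + center, rotation
    model.encoder_.load_state_arrays(arrays[:n_enc])
    rest = arrays[n_enc:]
    f_params = model.dynamics_.f.parameters()
    g_params = model.dynamics_.g.parameters()
    for prm, a in zip(f_params + g_params, rest):
        prm.data[...] = a
    model.sigma_ = np.asarray(meta["sigma"], dtype=np.float64)
    model.range_L_ = np.asarray(meta["range_L"], dtype=np.float64)
    model.history_ = meta["history"]
    model.diverged_ = bool(meta["diverged"])
    model.j_ = model.history_[-1]["j_bits"] if model.history_ else float("nan")
    return model
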