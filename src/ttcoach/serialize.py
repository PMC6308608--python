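"""On-disk containers for model parameters and latent trajectories.

Model parameters are stored as a directory of named ``.npy`` arrays plus a
``manifest.json`` describing the architecture; ``.npy`` files are
byte-deterministic, so repeated saves of identical parameters hash
identically. Trajectories are delimited text (stroke metadata + one row
per time step of latent coordinates).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import ScalerParams
from .dmm import GenerativeParams, InferenceParams, LatentTrajectory
from .lstm_core import ClassifierParams, LSTMCellParams


def _save_container(path, arrays: dict, manifest: dict) -> str:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    names = {}
    for name, arr in arrays.items():
        fname = name.replace("/", "_").replace(".", "_") + ".npy"
        np.save(path / fname, np.asarray(arr, dtype=np.float64))
        names[name] = fname
    manifest = dict(manifest)
    manifest["arrays"] = names
    with open(path / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return str(path)


def _load_container(path) -> tuple[dict, dict]:
    path = Path(path)
    with open(path / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    arrays = {
        name: np.load(path / fname) for name, fname in manifest["arrays"].items()
    }
    return arrays, manifest


def save_classifier(params: ClassifierParams, path) -> str:
    arrays = dict(params.named_arrays())
    manifest = {
        "kind": "lstm_classifier",
        "direction": params.direction,
        "hidden": params.hidden,
        "input_size": params.input_size,
        "n_classes": params.n_classes,
        "levels": params.levels,
    }
    return _save_container(path, arrays, manifest)


def load_classifier(path) -> ClassifierParams:
    arrays, man = _load_container(path)
    if man.get("kind") != "lstm_classifier":
        raise ValueError(f"{path}: not a classifier container")
    dirs = ("f", "b") if man["direction"] == "bi" else ("f",)
    cells = {}
    for lvl in range(1, man["levels"] + 1):
        for d in dirs:
            cells[(lvl, d)] = LSTMCellParams(
                Wx=arrays[f"l{lvl}{d}.Wx"],
                Wh=arrays[f"l{lvl}{d}.Wh"],
                b=arrays[f"l{lvl}{d}.b"],
            )
    return ClassifierParams(
        direction=man["direction"],
        hidden=man["hidden"],
        input_size=man["input_size"],
        n_classes=man["n_classes"],
        cells=cells,
        W_out=arrays["readout.W"],
        b_out=arrays["readout.b"],
        levels=man["levels"],
    )


def save_dmm(gen: GenerativeParams, inf: InferenceParams, path) -> str:
    arrays = {f"gen.{k}": t.data for k, t in gen.parameters()}
    arrays.update({f"inf.{k}": t.data for k, t in inf.parameters()})
    manifest = {
        "kind": "dmm",
        "latent_dim": gen.latent_dim,
        "obs_dim": gen.obs_dim,
        "net_hidden": gen.transition.hidden,
        "const_var": gen.transition.const_var,
        "summary_dim": inf.summary_dim,
        "post_hidden": inf.posterior.hidden,
    }
    return _save_container(path, arrays, manifest)


def load_dmm(path) -> tuple[GenerativeParams, InferenceParams]:
    arrays, man = _load_container(path)
    if man.get("kind") != "dmm":
        raise ValueError(f"{path}: not a state-space model container")
    gen = GenerativeParams.create(
        man["latent_dim"], man["obs_dim"], hidden=man["net_hidden"],
        const_var=man["const_var"],
    )
    inf = InferenceParams.create(
        man["latent_dim"], man["obs_dim"], summary_dim=man["summary_dim"],
        hidden=man["post_hidden"],
    )
    for k, t in gen.parameters():
        t.data = arrays[f"gen.{k}"]
    for k, t in inf.parameters():
        t.data = arrays[f"inf.{k}"]
    return gen, inf


def save_scaler(sp: ScalerParams, path) -> str:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {"data_min": sp.data_min.tolist(), "data_max": sp.data_max.tolist()},
            fh,
        )
    return str(path)


def load_scaler(path) -> ScalerParams:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return ScalerParams(np.array(d["data_min"]), np.array(d["data_max"]))


def save_trajectories(trajectories: list[LatentTrajectory], path) -> str:
    rows = []
    for tr in trajectories:
        for t in range(tr.z.shape[0]):
            row = {
                "subject": tr.subject_id,
                "skill": tr.skill_id,
                "rep": tr.rep_index,
                "split": tr.split,
                "t_index": t,
            }
            row.update({f"z{j}": tr.z[t, j] for j in range(tr.z.shape[1])})
            rows.append(row)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# ttcoach latent trajectories v1\n")
        pd.DataFrame(rows).to_csv(fh, index=False, float_format="%.12g")
    return str(path)


def load_trajectories(path) -> list[LatentTrajectory]:
    df = pd.read_csv(path, comment="#")
    zcols = sorted(
        [c for c in df.columns if c.startswith("z")], key=lambda c: int(c[1:])
    )
    out = []
    for (subj, skill, rep, split), grp in df.groupby(
        ["subject", "skill", "rep", "split"], sort=False
    ):
        z = grp.sort_values("t_index")[zcols].to_numpy(dtype=float)
        out.append(LatentTrajectory(str(subj), str(skill), int(rep), str(split), z))
    return out
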