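"""End-to-end coaching pipeline: one config, seven serialized stages.

Stages: simulate the recording session -> fit the scaler and train the
classifier -> freeze it -> train the augmented state-space network on its
embeddings -> holdout-validate the latent trajectories (repeating with a
fresh training seed up to ``max_rounds`` times if unsatisfactory) -> render
the reference plots -> run the comparison harness on the held-out strokes.
Every stage output lands in the artifact directory and is listed, with a
SHA-256 hash, in ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import coaching, dmm, lstm_core, pruning, serialize, synthetic_imu
from .dataio import apply_scaler, fit_scaler, write_stroke_table

log = logging.getLogger("ttcoach")


def _from_dict(cls, d: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    return cls(**d)


@dataclass
class GeneratorSection:
    reps_per_cell: int = 10
    train_reps: int = 7
    separation_floor: float = 0.05
    beginner_amplitude_jitter_sd: float = 0.25
    beginner_timing_jitter_sd: float = 0.20
    beginner_noise_sd: float = 0.10
    beginner_form_amplitude_sd: float = 0.40
    beginner_form_timing_sd: float = 0.30
    coach_amplitude_jitter_sd: float = 0.05
    coach_timing_jitter_sd: float = 0.04
    coach_noise_sd: float = 0.05


@dataclass
class ClassifierSection:
    direction: str = "bi"
    hidden: int = 38
    epochs: int = 300
    batch_size: int = 10
    learning_rate: float = 2e-3
    l2: float = 1e-4


@dataclass
class PruningSection:
    enabled: bool = False
    sparsity: float = 0.9
    retrain_epochs: int = 100


@dataclass
class DMMSection:
    latent_dim: int = 2
    epochs: int = 500
    learning_rate: float = 1e-2
    net_hidden: int = 32
    summary_dim: int = 32
    n_samples: int = 1


@dataclass
class CoachingSection:
    method: str = "resample"
    max_rounds: int = 3
    min_cells_pass: int = 9


@dataclass
class PipelineConfig:
    """Structured, round-trippable configuration; unknown keys rejected."""

    seed: int = 0
    out_dir: str = "ttcoach_run"
    generator: GeneratorSection = field(default_factory=GeneratorSection)
    classifier: ClassifierSection = field(default_factory=ClassifierSection)
    pruning: PruningSection = field(default_factory=PruningSection)
    dmm: DMMSection = field(default_factory=DMMSection)
    coaching: CoachingSection = field(default_factory=CoachingSection)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sections = {
            "generator": GeneratorSection,
            "classifier": ClassifierSection,
            "pruning": PruningSection,
            "dmm": DMMSection,
            "coaching": CoachingSection,
        }
        kwargs = {}
        for name, sec_cls in sections.items():
            if name in d:
                kwargs[name] = _from_dict(sec_cls, d.pop(name), name)
        top = {f.name for f in dataclasses.fields(cls)} - set(sections)
        unknown = set(d) - top
        if unknown:
            raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def generator_config(self) -> synthetic_imu.GeneratorConfig:
        g = self.generator
        styles = {
            "coach": synthetic_imu.SubjectStyle(
                "coach", g.coach_amplitude_jitter_sd, g.coach_timing_jitter_sd,
                g.coach_noise_sd,
            ),
            "beginner": synthetic_imu.SubjectStyle(
                "beginner", g.beginner_amplitude_jitter_sd,
                g.beginner_timing_jitter_sd, g.beginner_noise_sd,
                g.beginner_form_amplitude_sd, g.beginner_form_timing_sd,
            ),
        }
        return synthetic_imu.GeneratorConfig(
            reps_per_cell=g.reps_per_cell,
            train_reps=g.train_reps,
            separation_floor=g.separation_floor,
            seed=self.seed,
            styles=styles,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_tree(path: Path) -> dict:
    out = {}
    if path.is_dir():
        for p in sorted(path.rglob("*")):
            if p.is_file():
                out[str(p.relative_to(path.parent))] = _sha256(p)
    else:
        out[path.name] = _sha256(path)
    return out


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute all pipeline stages; returns a result summary dict.

    Raises with the failing stage's name on error; outputs of completed
    stages are left in place.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result: dict = {"status": "running", "rounds": [], "stages": {}}
    manifest: dict = {"outputs": {}}

    def record(stage: str, path: Path):
        manifest["outputs"].update(_hash_tree(Path(path)))
        result["stages"].setdefault(stage, []).append(str(path))

    stage = "simulate"
    try:
        gcfg = config.generator_config()
        dataset = synthetic_imu.synth_dataset(gcfg)
        table_path = out / "strokes.csv"
        write_stroke_table(dataset, table_path)
        record(stage, table_path)
        log.info("simulate: %d strokes written", len(dataset))

        stage = "scale"
        train = dataset.subset("train")
        test = dataset.subset("test")
        scaler = fit_scaler(train)
        train_s = apply_scaler(scaler, train)
        test_s = apply_scaler(scaler, test)
        scaler_path = out / "scaler.json"
        serialize.save_scaler(scaler, scaler_path)
        record(stage, scaler_path)

        satisfactory = False
        validation = {}
        for round_i in range(config.coaching.max_rounds + 1):
            round_seed = config.seed + 1000 * round_i

            stage = "train-classifier"
            tcfg = lstm_core.TrainConfig(
                learning_rate=config.classifier.learning_rate,
                epochs=config.classifier.epochs,
                batch_size=config.classifier.batch_size,
                l2=config.classifier.l2,
                seed=round_seed,
            )
            clf, curves = lstm_core.train_classifier(
                train_s, tcfg, direction=config.classifier.direction,
                hidden=config.classifier.hidden, test=test_s,
            )
            clf_dir = out / "classifier"
            serialize.save_classifier(clf, clf_dir)
            _write_curves(curves, out / "learning_curves.csv")
            record(stage, clf_dir)
            record(stage, out / "learning_curves.csv")

            stage = "evaluate"
            report = lstm_core.evaluate(clf, test_s)
            eval_path = out / "eval_report.json"
            _dump_json(
                {
                    "confusion": report.confusion.tolist(),
                    **report.as_percentages(),
                },
                eval_path,
            )
            record(stage, eval_path)

            if config.pruning.enabled:
                stage = "prune"
                mask = pruning.compute_mask(clf, config.pruning.sparsity)
                pcfg = dataclasses.replace(tcfg, epochs=config.pruning.retrain_epochs)
                clf_pruned, _ = pruning.retrain_pruned(clf, mask, train_s, pcfg)
                pruned_report = lstm_core.evaluate(clf_pruned, test_s)
                counts = lstm_core.count_params(clf)["brute_force"]
                prune_path = out / "prune_report.json"
                _dump_json(
                    {
                        "sparsity": config.pruning.sparsity,
                        "initial_params": counts,
                        "remaining": pruning.remaining_after_prune(
                            counts, config.pruning.sparsity
                        ),
                        "before": report.as_percentages(),
                        "after": pruned_report.as_percentages(),
                    },
                    prune_path,
                )
                serialize.save_classifier(clf_pruned, out / "classifier_pruned")
                record(stage, prune_path)
                record(stage, out / "classifier_pruned")

            stage = "train-dmm"
            emb_train = dmm.embed_dataset(clf, train_s)
            dcfg = dmm.DMMTrainConfig(
                epochs=config.dmm.epochs,
                learning_rate=config.dmm.learning_rate,
                seed=round_seed,
                n_samples=config.dmm.n_samples,
                hidden=config.dmm.net_hidden,
                summary_dim=config.dmm.summary_dim,
                net_hidden=config.dmm.net_hidden,
            )
            gen, inf, elbo_curve = dmm.train_dmm(
                emb_train, config.dmm.latent_dim, dcfg
            )
            dmm_dir = out / "dmm"
            serialize.save_dmm(gen, inf, dmm_dir)
            np.savetxt(out / "elbo_curve.csv", np.asarray(elbo_curve),
                       header="mean_elbo", comments="# ")
            record(stage, dmm_dir)
            record(stage, out / "elbo_curve.csv")

            stage = "latent"
            train_trajs = dmm.infer_trajectories(gen, inf, clf, train_s)
            test_trajs = dmm.infer_trajectories(gen, inf, clf, test_s)
            traj_path = out / "trajectories.csv"
            serialize.save_trajectories(train_trajs + test_trajs, traj_path)
            record(stage, traj_path)

            stage = "validate"
            library = coaching.ReferenceLibrary.build(train_trajs)
            validation = coaching.holdout_validate(
                library, test_trajs, method=config.coaching.method
            )
            n_pass = sum(v["passed"] for v in validation.values())
            result["rounds"].append(
                {"round": round_i, "seed": round_seed, "cells_passed": n_pass}
            )
            log.info("validate round %d: %d/%d cells passed", round_i, n_pass,
                     len(validation))
            if n_pass >= config.coaching.min_cells_pass:
                satisfactory = True
                break

        val_path = out / "validation.json"
        _dump_json(
            {
                "satisfactory": satisfactory,
                "cells": {
                    f"{s}/{k}": {key: _jsonable(val) for key, val in v.items()}
                    for (s, k), v in validation.items()
                },
            },
            val_path,
        )
        record("validate", val_path)

        stage = "report"
        fig_dir = out / "figures"
        paths = coaching.render_trajectories(train_trajs + test_trajs, fig_dir)
        for p in paths:
            record(stage, Path(p))

        stage = "compare"
        bundle = coaching.PipelineBundle(scaler, clf, gen, inf, library)
        rows = []
        for s in test.strokes:  # unscaled: coach_compare applies the scaler
            rep = coaching.coach_compare(s, bundle, method=config.coaching.method)
            rows.append(
                {
                    "subject": s.subject_id,
                    "skill": s.skill_id,
                    "rep": s.rep_index,
                    "closest_subject": rep.closest[0],
                    "closest_skill": rep.closest[1],
                    "closest_distance": rep.distances[rep.closest],
                    "pred_subject": rep.classifier_prediction[0],
                    "pred_skill": rep.classifier_prediction[1],
                }
            )
        import pandas as pd

        cmp_path = out / "comparison.csv"
        pd.DataFrame(rows).to_csv(cmp_path, index=False, float_format="%.12g")
        record(stage, cmp_path)
    except Exception:
        result["status"] = f"failed at stage: {stage}"
        _dump_json(result, out / "result.json")
        log.exception("pipeline failed at stage %s", stage)
        raise

    result["status"] = "satisfactory" if satisfactory else "unsatisfactory"
    result["validation_cells_passed"] = sum(v["passed"] for v in validation.values())
    _dump_json(result, out / "result.json")
    manifest["outputs"] = dict(sorted(manifest["outputs"].items()))
    _dump_json(manifest, out / "manifest.json")
    return result


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, np.bool_):
        return bool(v)
    return v


def _dump_json(obj, path):
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)


def _write_curves(curves: dict, path):
    import pandas as pd

    df = pd.DataFrame({k: v for k, v in curves.items() if v})
    df.index.name = "epoch"
    df.to_csv(path, float_format="%.8g")
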