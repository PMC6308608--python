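"""Coach/beginner reference trajectories, holdout validation and feedback.

The coaching loop compares a player's latent stroke trajectory against a
library of per-(subject, skill) reference trajectories built from training
data. Validation checks that held-out strokes land closest to their own
cell's summary trajectory; the comparison report ranks all cells by
distance so a beginner can see which reference their motion resembles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataio import ScalerParams, StrokeSequence
from .dmm import (
    GenerativeParams,
    InferenceParams,
    LatentTrajectory,
    embed_sequence,
    infer_trajectory,
)
from .lstm_core import ClassifierParams, run_stack


def _resample(z: np.ndarray, T: int) -> np.ndarray:
    """Linear time-resampling of a (Ta, L) trajectory to T points."""
    Ta, L = z.shape
    if Ta == T:
        return z
    told = np.linspace(0.0, 1.0, Ta)
    tnew = np.linspace(0.0, 1.0, T)
    return np.stack([np.interp(tnew, told, z[:, j]) for j in range(L)], axis=1)


def trajectory_distance(
    a: LatentTrajectory | np.ndarray,
    b: LatentTrajectory | np.ndarray,
    method: str = "resample",
) -> float:
    """Distance between two latent trajectories.

    Default: mean pointwise Euclidean distance after linear time-resampling
    to the longer of the two lengths (symmetric, >= 0, 0 iff identical
    after resampling). ``method='dtw'`` uses dynamic time warping instead
    (mean cost along the optimal alignment path).
    """
    za = a.z if isinstance(a, LatentTrajectory) else np.asarray(a, float)
    zb = b.z if isinstance(b, LatentTrajectory) else np.asarray(b, float)
    if za.shape[1] != zb.shape[1]:
        raise ValueError(
            f"latent_dim mismatch: {za.shape[1]} vs {zb.shape[1]}"
        )
    if method == "dtw":
        return _dtw_distance(za, zb)
    T = max(za.shape[0], zb.shape[0])
    ra, rb = _resample(za, T), _resample(zb, T)
    return float(np.mean(np.linalg.norm(ra - rb, axis=1)))


def _dtw_distance(za: np.ndarray, zb: np.ndarray) -> float:
    """Classic O(Ta*Tb) dynamic time warping on pointwise Euclidean cost."""
    Ta, Tb = za.shape[0], zb.shape[0]
    cost = np.linalg.norm(za[:, None] - zb[None], axis=2)
    acc = np.full((Ta + 1, Tb + 1), np.inf)
    acc[0, 0] = 0.0
    steps = np.zeros((Ta + 1, Tb + 1), dtype=np.int64)
    for i in range(1, Ta + 1):
        for j in range(1, Tb + 1):
            opts = (acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1])
            k = int(np.argmin(opts))
            prev_ij = ((i - 1, j - 1), (i - 1, j), (i, j - 1))[k]
            acc[i, j] = cost[i - 1, j - 1] + opts[k]
            steps[i, j] = steps[prev_ij] + 1
    return float(acc[Ta, Tb] / steps[Ta, Tb])


@dataclass
class ReferenceLibrary:
    """Per-(subject, skill) training trajectories and their pointwise mean."""

    trajectories: dict = field(default_factory=dict)  # cell -> [LatentTrajectory]
    summaries: dict = field(default_factory=dict)  # cell -> (T, L) mean path

    @classmethod
    def build(cls, train_trajectories: list[LatentTrajectory]) -> "ReferenceLibrary":
        lib = cls()
        for tr in train_trajectories:
            lib.trajectories.setdefault((tr.subject_id, tr.skill_id), []).append(tr)
        for cell, trs in lib.trajectories.items():
            shapes = {t.z.shape for t in trs}
            if len(shapes) > 1:
                raise ValueError(f"cell {cell}: inconsistent trajectory shapes")
            lib.summaries[cell] = np.mean([t.z for t in trs], axis=0)
        return lib

    def cells(self) -> list[tuple[str, str]]:
        return sorted(self.summaries.keys())


@dataclass
class SimilarityReport:
    """Ranked distances of one query stroke to every reference cell."""

    query_subject: str | None
    query_skill: str | None
    distances: dict  # cell -> float
    ranking: list  # cells sorted by distance
    closest: tuple[str, str]
    classifier_prediction: tuple[str, str]


def holdout_validate(
    library: ReferenceLibrary,
    test_trajectories: list[LatentTrajectory],
    method: str = "resample",
) -> dict:
    """Nearest-own-cell validation of held-out latent trajectories.

    For each (subject, skill) cell: the mean distance of that cell's test
    trajectories to its own summary, the best competing cell's mean
    distance, and the margin (best other - own). A cell passes when its
    own summary is strictly the nearest of all summaries.
    """
    by_cell: dict[tuple, list] = {}
    for tr in test_trajectories:
        by_cell.setdefault((tr.subject_id, tr.skill_id), []).append(tr)
    results = {}
    for cell in library.cells():
        trs = by_cell.get(cell, [])
        if not trs:
            warnings.warn(f"no test trajectories for cell {cell}; skipped",
                          stacklevel=2)
            continue
        mean_d = {
            other: float(
                np.mean(
                    [trajectory_distance(t, summ, method=method) for t in trs]
                )
            )
            for other, summ in library.summaries.items()
        }
        own = mean_d[cell]
        others = {k: v for k, v in mean_d.items() if k != cell}
        best_other_cell = min(others, key=others.get)
        best_other = others[best_other_cell]
        results[cell] = {
            "own_distance": own,
            "best_other_distance": best_other,
            "best_other_cell": best_other_cell,
            "margin": best_other - own,
            "passed": own < min(others.values()),
        }
    return results


@dataclass
class PipelineBundle:
    """Everything needed to score a new stroke: frozen classifier, trained
    state-space model, scaler and reference library."""

    scaler: ScalerParams
    classifier: ClassifierParams
    gen: GenerativeParams
    inf: InferenceParams
    library: ReferenceLibrary

    def __post_init__(self):
        feat = self.classifier.hidden * (2 if self.classifier.direction == "bi" else 1)
        if self.gen.obs_dim != feat or self.inf.obs_dim != feat:
            raise ValueError(
                f"inconsistent bundle: classifier embeds into {feat} dims but "
                f"the state-space model expects {self.gen.obs_dim}"
            )


def coach_compare(
    query: StrokeSequence,
    bundle: PipelineBundle,
    method: str = "resample",
) -> SimilarityReport:
    """Scale -> embed -> infer latent trajectory -> rank reference cells.

    Also reports the classifier's own (subject, skill) prediction as a
    cross-check on the trajectory-based ranking.
    """
    if not bundle.library.summaries:
        raise ValueError("reference library is empty")
    span = bundle.scaler.data_max - bundle.scaler.data_min
    safe = np.where(span == 0, 1.0, span)
    scaled = (query.samples - bundle.scaler.data_min) / safe
    emb = embed_sequence(bundle.classifier, scaled)
    z = infer_trajectory(bundle.gen, bundle.inf, emb)
    distances = {
        cell: trajectory_distance(z, summ, method=method)
        for cell, summ in bundle.library.summaries.items()
    }
    ranking = sorted(distances, key=distances.get)
    scores = run_stack(bundle.classifier, scaled)["scores"]
    from .dataio import LabelSpec

    pred = LabelSpec().split_index(int(np.argmax(scores)))
    return SimilarityReport(
        query_subject=query.subject_id,
        query_skill=query.skill_id,
        distances=distances,
        ranking=ranking,
        closest=ranking[0],
        classifier_prediction=pred,
    )


def improvement_curve(
    bundle: PipelineBundle,
    gen_config,
    skill: str,
    lams=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_strokes: int = 10,
    seed: int = 0,
    method: str = "resample",
) -> list[float]:
    """Closed-loop practice harness: distance to the coach reference as the
    beginner's style is stepped toward the coach's.

    For each blend fraction lam the beginner's style parameters (jitter,
    noise and habitual form error) are interpolated toward the coach's and
    ``n_strokes`` fresh practice strokes of ``skill`` are scored against
    the coach's reference trajectory for that skill. Per-stroke random
    substreams are shared across lam values (paired comparison), so the
    returned mean-distance curve isolates the effect of improving style.
    """
    from . import synthetic_imu as si

    templates = si.build_templates(gen_config)
    by_name = {t.skill_id: t for t in templates}
    if skill not in by_name:
        raise KeyError(f"unknown skill {skill!r}")
    template = by_name[skill]
    ki = list(by_name).index(skill)
    coach = gen_config.styles["coach"]
    beginner = gen_config.styles["beginner"]
    curve = []
    for lam in lams:
        style = beginner.blend_toward(coach, lam)
        form = si.subject_form(template, style, si._rng(seed, 6, 1, ki))
        dists = []
        for rep in range(n_strokes):
            samples = si.synth_stroke(
                form, style, si._rng(seed, 7, ki, rep), gen_config
            )
            stroke = StrokeSequence("beginner", skill, rep, "test", samples)
            report = coach_compare(stroke, bundle, method=method)
            dists.append(report.distances[("coach", skill)])
        curve.append(float(np.mean(dists)))
    return curve


def render_trajectories(
    trajectories: list[LatentTrajectory],
    out_dir,
    dims: tuple[int, int] = (0, 1),
) -> list[str]:
    """One panel per (subject, skill): train = blue dashed, test = red solid.

    Written as SVG with fixed hash salt and no date metadata so re-renders
    are byte-stable. Returns the file paths in deterministic order.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from pathlib import Path

    if not trajectories:
        raise ValueError("no trajectories to render")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_cell: dict[tuple, list] = {}
    for tr in trajectories:
        by_cell.setdefault((tr.subject_id, tr.skill_id), []).append(tr)
    paths = []
    with matplotlib.rc_context({"svg.hashsalt": "ttcoach"}):
        for subject, skill in sorted(by_cell):
            fig, ax = plt.subplots(figsize=(4, 3))
            for tr in by_cell[(subject, skill)]:
                x = tr.z[:, dims[0]]
                y = tr.z[:, dims[1]] if tr.z.shape[1] > 1 else np.arange(len(x))
                if tr.split == "train":
                    ax.plot(x, y, "b--", linewidth=1, alpha=0.8)
                else:
                    ax.plot(x, y, "r-", linewidth=1.2)
            ax.set_title(f"{subject} / {skill}")
            ax.set_xlabel(f"z[{dims[0]}]")
            ax.set_ylabel(f"z[{dims[1]}]")
            fig.tight_layout()
            path = out_dir / f"latent_{subject}_{skill}.svg"
            fig.savefig(path, metadata={"Date": None})
            plt.close(fig)
            paths.append(str(path))
    return paths
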