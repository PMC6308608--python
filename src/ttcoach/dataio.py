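"""Stroke-table I/O, label encoding, min-max scaling and split bookkeeping.

The on-disk "stroke table" is a delimited text file (one row per time
sample) with five metadata columns followed by the 18 sensor channels:

    subject,skill,rep,split,t_index,m1_acc_x,...,m3_gyr_z

UTF-8, '.' decimal, '#' comment lines. Human-inspectable and diff-able.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

SUBJECTS = ("coach", "beginner")
SKILLS = (
    "forehand_stroke",
    "forehand_drive",
    "forehand_cut",
    "backhand_drive",
    "backhand_short",
)

_MODULES = ("m1", "m2", "m3")
_SENSORS = ("acc", "gyr")
_AXES = ("x", "y", "z")
#: canonical channel order: module-major, then sensor, then axis
CHANNEL_NAMES = tuple(
    f"{m}_{s}_{a}" for m in _MODULES for s in _SENSORS for a in _AXES
)
_META_COLS = ("subject", "skill", "rep", "split", "t_index")


class StrokeTableError(ValueError):
    """Raised for malformed stroke-table files."""


@dataclass(frozen=True)
class LabelSpec:
    """Joint (subject, skill) label space: index = subject_index*5 + skill_index."""

    subjects: tuple[str, ...] = SUBJECTS
    skills: tuple[str, ...] = SKILLS

    @property
    def n_classes(self) -> int:
        return len(self.subjects) * len(self.skills)

    def joint_index(self, subject: str, skill: str) -> int:
        try:
            si = self.subjects.index(subject)
        except ValueError:
            raise KeyError(f"unknown subject {subject!r}; expected {self.subjects}")
        try:
            ki = self.skills.index(skill)
        except ValueError:
            raise KeyError(f"unknown skill {skill!r}; expected {self.skills}")
        return si * len(self.skills) + ki

    def split_index(self, joint: int) -> tuple[str, str]:
        n = len(self.skills)
        return self.subjects[joint // n], self.skills[joint % n]


@dataclass
class StrokeSequence:
    """One stroke: a T x C real matrix plus its labels."""

    subject_id: str
    skill_id: str
    rep_index: int
    split: str  # "train" | "test"
    samples: np.ndarray  # (T, C)
    sample_rate_hz: float = 5.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise ValueError("samples must be a T x C matrix with T >= 1")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("stroke samples must be finite")
        if self.split not in ("train", "test"):
            raise ValueError(f"split must be 'train' or 'test', got {self.split!r}")


@dataclass
class StrokeDataset:
    """An ordered collection of strokes sharing T and C, plus the label space."""

    strokes: list[StrokeSequence] = field(default_factory=list)
    labels: LabelSpec = field(default_factory=LabelSpec)

    def __post_init__(self):
        shapes = {s.samples.shape for s in self.strokes}
        if len(shapes) > 1:
            raise ValueError(f"strokes have inconsistent shapes: {shapes}")

    def __len__(self) -> int:
        return len(self.strokes)

    def subset(self, split: str) -> "StrokeDataset":
        return StrokeDataset(
            [s for s in self.strokes if s.split == split], self.labels
        )

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack strokes into (N, T, C) with joint-label vector (N,)."""
        X = np.stack([s.samples for s in self.strokes])
        y = np.array(
            [self.labels.joint_index(s.subject_id, s.skill_id) for s in self.strokes],
            dtype=np.int64,
        )
        return X, y


@dataclass
class ScalerParams:
    """Per-channel min/max fitted on the training split only."""

    data_min: np.ndarray  # (C,)
    data_max: np.ndarray  # (C,)

    def __post_init__(self):
        self.data_min = np.asarray(self.data_min, dtype=np.float64)
        self.data_max = np.asarray(self.data_max, dtype=np.float64)
        if np.any(self.data_max < self.data_min):
            raise ValueError("max must be >= min per channel")


def one_hot(labels: LabelSpec, subject: str, skill: str) -> np.ndarray:
    """One-hot vector of length n_classes with a single 1 at the joint index."""
    v = np.zeros(labels.n_classes)
    v[labels.joint_index(subject, skill)] = 1.0
    return v


def fit_scaler(train: StrokeDataset) -> ScalerParams:
    """Fit per-channel min-max on the training split (never on test data)."""
    seqs = [s for s in train.strokes if s.split == "train"]
    if not seqs:
        raise ValueError("no training strokes to fit the scaler on")
    flat = np.concatenate([s.samples for s in seqs], axis=0)  # (N*T, C)
    mm = MinMaxScaler().fit(flat)
    return ScalerParams(mm.data_min_, mm.data_max_)


def apply_scaler(sp: ScalerParams, dataset: StrokeDataset) -> StrokeDataset:
    """Map each channel to (x - min)/(max - min); test values are not clipped.

    A constant channel (max == min) maps to 0.0 with a warning.
    """
    span = sp.data_max - sp.data_min
    const = span == 0
    if np.any(const):
        warnings.warn(
            f"constant channel(s) {np.nonzero(const)[0].tolist()} mapped to 0.0",
            stacklevel=2,
        )
    safe = np.where(const, 1.0, span)
    out = []
    for s in dataset.strokes:
        scaled = (s.samples - sp.data_min) / safe
        scaled[:, const] = 0.0
        out.append(replace(s, samples=scaled))
    return StrokeDataset(out, dataset.labels)


# -- stroke-table text format ---------------------------------------------


def write_stroke_table(dataset: StrokeDataset, path) -> str:
    """Serialize a dataset to the long-format delimited stroke table."""
    rows = []
    for s in dataset.strokes:
        T = s.samples.shape[0]
        meta = pd.DataFrame(
            {
                "subject": s.subject_id,
                "skill": s.skill_id,
                "rep": s.rep_index,
                "split": s.split,
                "t_index": np.arange(T),
            }
        )
        chans = pd.DataFrame(s.samples, columns=list(CHANNEL_NAMES[: s.samples.shape[1]]))
        rows.append(pd.concat([meta, chans], axis=1))
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=list(_META_COLS) + list(CHANNEL_NAMES)
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# ttcoach stroke table v1\n")
        table.to_csv(fh, index=False, float_format="%.12g")
    return str(path)


def read_stroke_table(path) -> StrokeDataset:
    """Parse a stroke table; malformed input raises with the offending line."""
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise StrokeTableError(f"{path}: empty file, no stroke table found")
    if df.empty and df.columns.size == 0:
        raise StrokeTableError(f"{path}: empty file, no stroke table found")
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise StrokeTableError(
            f"{path}: line 2: malformed header, missing columns {missing}"
        )
    chan_cols = [c for c in df.columns if c not in _META_COLS]
    labels = LabelSpec()
    strokes: list[StrokeSequence] = []
    # +3: 1-based lines, one comment line, one header line
    for (subj, skill, rep, split), grp in df.groupby(
        ["subject", "skill", "rep", "split"], sort=False
    ):
        first_line = int(grp.index[0]) + 3
        t = grp["t_index"].to_numpy()
        if not np.array_equal(t, np.arange(len(t))):
            raise StrokeTableError(
                f"{path}: line {first_line}: ragged stroke "
                f"({subj}, {skill}, rep {rep}): t_index not contiguous 0..T-1"
            )
        vals = grp[chan_cols].to_numpy(dtype=np.float64)
        if np.isnan(vals).any():
            raise StrokeTableError(
                f"{path}: line {first_line}: non-numeric or missing channel "
                f"value in stroke ({subj}, {skill}, rep {rep})"
            )
        try:
            labels.joint_index(str(subj), str(skill))
        except KeyError as e:
            raise StrokeTableError(f"{path}: line {first_line}: {e.args[0]}")
        strokes.append(
            StrokeSequence(str(subj), str(skill), int(rep), str(split), vals)
        )
    T_counts = {s.samples.shape[0] for s in strokes}
    if len(T_counts) > 1:
        raise StrokeTableError(
            f"{path}: strokes have inconsistent lengths {sorted(T_counts)}; "
            "one stroke is ragged"
        )
    return StrokeDataset(strokes, labels)


def datasets_equal(a: StrokeDataset, b: StrokeDataset, rtol: float = 1e-11) -> bool:
    """Equality up to floating-text round-trip precision."""
    if len(a) != len(b):
        return False
    for sa, sb in zip(a.strokes, b.strokes):
        if (sa.subject_id, sa.skill_id, sa.rep_index, sa.split) != (
            sb.subject_id,
            sb.skill_id,
            sb.rep_index,
            sb.split,
        ):
            return False
        if sa.samples.shape != sb.samples.shape:
            return False
        if not np.allclose(sa.samples, sb.samples, rtol=rtol, atol=1e-300):
            return False
    return True
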