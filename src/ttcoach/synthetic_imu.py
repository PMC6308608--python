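"""Synthetic IMU stroke generator with the factorial design of the study.

Emulates a wearable-sensor table-tennis recording session: 2 subjects
(coach, beginner) x 5 skills x 10 repetitions, each stroke a 5.4 s window
sampled at 5 Hz (27 time points) on 18 channels (3 sensor modules, each
with a tri-axial accelerometer and gyroscope). Skills are distinguished by
smooth per-channel motion templates (sums of Gaussian bumps); the beginner
executes the *same* templates as the coach but with larger amplitude and
timing jitter, so subject separability is tunable by one knob. Additive
i.i.d. Gaussian noise models the sensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import SKILLS, SUBJECTS, LabelSpec, StrokeDataset, StrokeSequence


class SeparationError(RuntimeError):
    """Template drawing could not reach the requested skill separation."""


@dataclass(frozen=True)
class MotionTemplate:
    """Smooth per-channel signal model for one skill: sums of Gaussian bumps.

    Channel c at time t evaluates to sum_k amp[c,k] * exp(-(t-ctr[c,k])^2 /
    (2 width[c,k]^2)). Stands in for the (undisclosed) real stroke motions.
    """

    skill_id: str
    amplitudes: np.ndarray  # (C, K)
    centers: np.ndarray  # (C, K), seconds in [0, duration]
    widths: np.ndarray  # (C, K), seconds, > 0

    def __post_init__(self):
        for name in ("amplitudes", "centers", "widths"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=np.float64)
            )
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")
        if np.any(self.widths <= 0):
            raise ValueError("widths must be > 0")

    def evaluate(self, times: np.ndarray) -> np.ndarray:
        """Noiseless template at the given sample times -> (T, C)."""
        t = np.asarray(times)[:, None, None]  # (T,1,1)
        bumps = self.amplitudes[None] * np.exp(
            -((t - self.centers[None]) ** 2) / (2.0 * self.widths[None] ** 2)
        )
        return bumps.sum(axis=2)  # (T, C)


@dataclass(frozen=True)
class SubjectStyle:
    """Execution-style parameters; coach defaults are strictly tighter.

    The jitter SDs model stroke-to-stroke scatter around the subject's own
    mean execution. The form SDs model the *systematic* part of a
    beginner's error: a seeded, per-(subject, skill) morph of the canonical
    motion (habitually mis-scaled and mis-timed bumps) that is constant
    across repetitions. Coaches execute the canonical form (form SDs 0).
    """

    subject_id: str
    amplitude_jitter_sd: float  # relative, unitless
    timing_jitter_sd: float  # seconds
    noise_sd: float  # sensor units
    form_amplitude_sd: float = 0.0  # relative, unitless
    form_timing_sd: float = 0.0  # seconds

    def __post_init__(self):
        if (
            min(
                self.amplitude_jitter_sd,
                self.timing_jitter_sd,
                self.noise_sd,
                self.form_amplitude_sd,
                self.form_timing_sd,
            )
            < 0
        ):
            raise ValueError("style standard deviations must be >= 0")

    def blend_toward(self, other: "SubjectStyle", lam: float) -> "SubjectStyle":
        """Interpolate all style parameters toward ``other`` (lam=1 -> other).

        The practice-improvement dial: stepping a beginner's style toward
        the coach's models skill acquisition in a closed coaching loop.
        """
        import dataclasses as _dc

        f = lambda a, b: (1 - lam) * a + lam * b
        return _dc.replace(
            self,
            amplitude_jitter_sd=f(self.amplitude_jitter_sd, other.amplitude_jitter_sd),
            timing_jitter_sd=f(self.timing_jitter_sd, other.timing_jitter_sd),
            noise_sd=f(self.noise_sd, other.noise_sd),
            form_amplitude_sd=f(self.form_amplitude_sd, other.form_amplitude_sd),
            form_timing_sd=f(self.form_timing_sd, other.form_timing_sd),
        )


#: default styles: the beginner habitually deforms the canonical motion
#: (form SDs) and scatters more around their own mean execution (jitter
#: SDs), with noisier sensor contact.
COACH_STYLE = SubjectStyle("coach", 0.05, 0.04, 0.05, 0.0, 0.0)
BEGINNER_STYLE = SubjectStyle("beginner", 0.25, 0.20, 0.10, 0.40, 0.30)
DEFAULT_STYLES = {"coach": COACH_STYLE, "beginner": BEGINNER_STYLE}


@dataclass(frozen=True)
class GeneratorConfig:
    """Factorial design of the recording session."""

    n_subjects: int = 2
    n_skills: int = 5
    reps_per_cell: int = 10
    train_reps: int = 7
    n_modules: int = 3
    sample_rate_hz: float = 5.0
    duration_s: float = 5.4
    seed: int = 0
    n_bumps: int = 3
    separation_floor: float = 0.05  # min pairwise mean-squared skill difference
    styles: dict = field(default_factory=lambda: dict(DEFAULT_STYLES))

    @property
    def samples_per_stroke(self) -> int:
        return round(self.duration_s * self.sample_rate_hz)

    @property
    def n_channels(self) -> int:
        return self.n_modules * 6

    def sample_times(self) -> np.ndarray:
        return np.arange(self.samples_per_stroke) / self.sample_rate_hz


def _rng(seed: int, *tag: int) -> np.random.Generator:
    """Counter-style substream: one master seed plus integer tags."""
    return np.random.default_rng(np.random.SeedSequence((seed, *tag)))


def build_templates(
    config: GeneratorConfig, seed: int | None = None, max_retries: int = 20
) -> list[MotionTemplate]:
    """Draw one motion template per skill, enforcing pairwise separation.

    Deterministic given the seed. Raises :class:`SeparationError` when the
    configured separation floor cannot be met within ``max_retries`` draws.
    """
    seed = config.seed if seed is None else seed
    times = config.sample_times()
    C, K = config.n_channels, config.n_bumps
    for attempt in range(max_retries):
        rng = _rng(seed, 0, attempt)
        templates = []
        for skill in SKILLS[: config.n_skills]:
            amp = rng.uniform(-1.0, 1.0, size=(C, K))
            # push amplitudes away from zero so every channel carries signal
            amp = np.sign(amp) * (0.3 + 0.7 * np.abs(amp))
            ctr = rng.uniform(0.15 * config.duration_s, 0.85 * config.duration_s, (C, K))
            wid = rng.uniform(0.25, 0.9, size=(C, K))
            templates.append(MotionTemplate(skill, amp, ctr, wid))
        evals = [t.evaluate(times) for t in templates]
        sep = min(
            float(np.mean((evals[i] - evals[j]) ** 2))
            for i in range(len(evals))
            for j in range(i + 1, len(evals))
        )
        if sep >= config.separation_floor:
            return templates
    raise SeparationError(
        f"could not draw {config.n_skills} templates with pairwise mean-squared "
        f"difference >= {config.separation_floor} in {max_retries} attempts"
    )


def synth_stroke(
    template: MotionTemplate,
    style: SubjectStyle,
    rng: np.random.Generator,
    config: GeneratorConfig | None = None,
) -> np.ndarray:
    """Simulate one stroke: jittered template evaluation plus sensor noise.

    Jitter model: a per-stroke global time shift plus independent per-bump,
    per-channel center shifts, all ~ N(0, timing_jitter_sd) — a sloppy
    execution desynchronizes the motion components that a clean one keeps
    aligned — and a per-channel amplitude scale 1 + N(0,
    amplitude_jitter_sd); finally i.i.d. Gaussian noise per sample per
    channel. Returns a (T, C) matrix.
    """
    config = config or GeneratorConfig()
    times = config.sample_times()
    C, K = template.amplitudes.shape
    if style.timing_jitter_sd:
        centers = (
            template.centers
            + rng.normal(0.0, style.timing_jitter_sd)
            + rng.normal(0.0, style.timing_jitter_sd, size=(C, K))
        )
    else:
        centers = template.centers
    scale = 1.0 + (
        rng.normal(0.0, style.amplitude_jitter_sd, size=(C, K))
        if style.amplitude_jitter_sd
        else np.zeros((C, K))
    )
    jittered = MotionTemplate(
        template.skill_id, template.amplitudes * scale, centers, template.widths
    )
    clean = jittered.evaluate(times)
    noise = (
        rng.normal(0.0, style.noise_sd, size=clean.shape)
        if style.noise_sd
        else np.zeros_like(clean)
    )
    out = clean + noise
    if not np.all(np.isfinite(out)):
        raise ValueError("synthesized stroke contains non-finite values")
    return out


def subject_form(
    template: MotionTemplate, style: SubjectStyle, rng: np.random.Generator
) -> MotionTemplate:
    """The subject's habitual mean execution of a skill.

    A seeded morph of the canonical template: per-bump amplitude scales
    1 + N(0, form_amplitude_sd) and center shifts N(0, form_timing_sd).
    Identity when both form SDs are zero (the coach default).
    """
    if style.form_amplitude_sd == 0 and style.form_timing_sd == 0:
        return template
    shape = template.amplitudes.shape
    amp = template.amplitudes * (1.0 + rng.normal(0, style.form_amplitude_sd, shape))
    ctr = template.centers + rng.normal(0, style.form_timing_sd, shape)
    return MotionTemplate(template.skill_id, amp, ctr, template.widths)


def synth_dataset(
    config: GeneratorConfig | None = None,
    templates: list[MotionTemplate] | None = None,
) -> StrokeDataset:
    """Generate the full balanced design as a :class:`StrokeDataset`.

    Every (subject, skill) cell receives exactly ``reps_per_cell`` strokes,
    the first ``train_reps`` of which are marked train (7/3 at defaults).
    Per-stroke random substreams are derived from the master seed by
    counter, so the dataset is reproducible stroke-by-stroke.
    """
    config = config or GeneratorConfig()
    if templates is None:
        templates = build_templates(config)
    strokes: list[StrokeSequence] = []
    for si, subject in enumerate(SUBJECTS[: config.n_subjects]):
        style = config.styles[subject]
        for ki, template in enumerate(templates):
            form = subject_form(template, style, _rng(config.seed, 6, si, ki))
            for rep in range(config.reps_per_cell):
                rng = _rng(config.seed, 1, si, ki, rep)
                samples = synth_stroke(form, style, rng, config)
                strokes.append(
                    StrokeSequence(
                        subject_id=subject,
                        skill_id=template.skill_id,
                        rep_index=rep,
                        split="train" if rep < config.train_reps else "test",
                        samples=samples,
                        sample_rate_hz=config.sample_rate_hz,
                    )
                )
    return StrokeDataset(strokes, LabelSpec())


def count_single_axis_training_sequences(
    dataset: StrokeDataset, config: GeneratorConfig | None = None
) -> int:
    """Single-axis training sequence count: one per (stroke, channel).

    At the defaults this is 2 subjects x 5 skills x 7 training reps x
    (3 axes x 2 sensors x 3 modules) = 1260.
    """
    train = [s for s in dataset.strokes if s.split == "train"]
    return sum(s.samples.shape[1] for s in train)


def nearest_template_assignment(
    dataset: StrokeDataset, templates: list[MotionTemplate], config: GeneratorConfig
) -> float:
    """Fraction of strokes whose nearest template (L2) is their true skill.

    Oracle used to verify the separability dial: with all style jitters at
    zero this must be exactly 1.0.
    """
    times = config.sample_times()
    evals = np.stack([t.evaluate(times) for t in templates])  # (S, T, C)
    names = [t.skill_id for t in templates]
    hits = 0
    for s in dataset.strokes:
        d = ((evals - s.samples[None]) ** 2).sum(axis=(1, 2))
        hits += names[int(np.argmin(d))] == s.skill_id
    return hits / len(dataset.strokes)
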