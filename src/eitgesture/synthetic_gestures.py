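"""Synthetic dynamic-gesture datasets from the simulated arm phantom.

Each of the five dynamic gestures (fist, open palm, pistol, pinch index,
"six") is modelled as a set of circular muscle sub-regions whose
conductivity ramps smoothly from baseline to a gesture-specific peak over
the 40-step measurement horizon.  Gestures "pistol" and "six" deliberately
share their dominant active region, so the two classes are the closest
pair in measurement space and produce the confusability seen in real
recordings.  Study layout: participants x gestures x sets x iterations,
with per-participant anatomy/baseline variation, multiplicative
measurement noise, and three interference conditions (arm shake,
re-worn electrodes, cross-day drift).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import forward_model as fm
from .protocols import DrivePattern, build_schedule, get_pattern

__all__ = [
    "GESTURE_NAMES",
    "Region",
    "GestureClassModel",
    "StudyDesign",
    "NoiseParams",
    "ParticipantEffect",
    "InterferenceContext",
    "GestureSample",
    "Dataset",
    "DatasetSplit",
    "make_class_models",
    "default_design",
    "draw_participant_effect",
    "participant_phantom",
    "trajectory_voltages",
    "trajectory_grid",
    "TimingParams",
    "apply_interference",
    "generate_sample",
    "generate_dataset",
    "split_dataset",
    "first_order_difference",
    "dataset_to_frame",
    "dataset_from_frame",
]

GESTURE_NAMES = ("fist", "open_palm", "pistol", "pinch_index", "six")

CONDITIONS = ("normal", "shake", "electrode_move", "cross_day")


@dataclass(frozen=True)
class Region:
    """Circular muscle sub-region with a peak conductivity change (S/m).

    ``ramp`` optionally gives the region its own activation window
    (muscle groups engage sequentially during a gesture); regions without
    one follow the class-level ramp."""

    cx: float
    cy: float
    radius: float
    delta_sigma: float
    ramp: tuple[float, float] | None = None


@dataclass(frozen=True)
class GestureClassModel:
    """Conductivity trajectory model for one gesture class.

    ``ramp = (start, end)`` are fractions of the 40-step horizon between
    which the smoothstep activation rises from 0 to 1.
    """

    class_id: int
    name: str
    active_regions: tuple[Region, ...]
    ramp: tuple[float, float]
    similarity_link: int | None = None

    def activation(self, t: np.ndarray | int,
                   region: "Region | None" = None) -> np.ndarray:
        """Monotone smoothstep activation on time index t in [0, 39],
        using the region's own ramp window when it has one."""
        tau = np.asarray(t, dtype=float) / 39.0
        lo, hi = self.ramp if region is None or region.ramp is None else region.ramp
        s = np.clip((tau - lo) / (hi - lo), 0.0, 1.0)
        return 3.0 * s**2 - 2.0 * s**3


# Reference gesture parameterization.  Classes 2 (pistol) and 4 ("six")
# share the dominant (18, -12) flexor-side region (with identical onset)
# and differ only in weak secondary regions, making them the closest
# class pair.  Regions within a class engage sequentially, giving each
# gesture a multi-phase temporal signature.
_CLASS_TABLE: tuple[GestureClassModel, ...] = (
    GestureClassModel(0, "fist",
                      (Region(0.0, -18.0, 8.0, 0.22, ramp=(0.05, 0.55)),
                       Region(20.0, 10.0, 6.0, 0.12, ramp=(0.35, 0.85))),
                      ramp=(0.10, 0.70)),
    GestureClassModel(1, "open_palm",
                      (Region(0.0, 20.0, 8.0, -0.18, ramp=(0.15, 0.70)),
                       Region(-20.0, -8.0, 6.0, 0.10, ramp=(0.45, 0.95))),
                      ramp=(0.20, 0.90)),
    GestureClassModel(2, "pistol",
                      (Region(18.0, -12.0, 7.0, 0.20, ramp=(0.10, 0.60)),
                       Region(-15.0, 14.0, 5.0, 0.08, ramp=(0.40, 0.90))),
                      ramp=(0.15, 0.80)),
    GestureClassModel(3, "pinch_index",
                      (Region(-22.0, 4.0, 6.0, 0.15, ramp=(0.20, 0.75)),
                       Region(8.0, 16.0, 5.0, -0.12, ramp=(0.50, 0.95))),
                      ramp=(0.25, 0.85)),
    GestureClassModel(4, "six",
                      (Region(18.0, -12.0, 7.0, 0.20, ramp=(0.10, 0.60)),
                       Region(-5.0, -24.0, 5.0, 0.08, ramp=(0.45, 0.90))),
                      ramp=(0.15, 0.80), similarity_link=2),
)


def make_class_models(seed: int = 0) -> tuple[GestureClassModel, ...]:
    """The five gesture class models.

    The parameterization is a fixed study condition, so the same models
    are returned for every seed; the argument is kept so callers can
    thread a master seed through uniformly.
    """
    del seed
    return _CLASS_TABLE


@dataclass(frozen=True)
class StudyDesign:
    """Participants x gestures x sets x iterations layout.

    ``sets_per_iteration`` may be a single count or one count per
    iteration (used for the cross-day layout where the last day is
    larger).  For the cross-day condition "iteration" means "day".
    """

    n_participants: int = 5
    n_gestures: int = 5
    sets_per_iteration: int | tuple[int, ...] = 40
    n_iterations: int = 4
    condition: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if min(self.n_participants, self.n_gestures, self.n_iterations) < 1:
            raise ValueError("all design counts must be >= 1")
        if isinstance(self.sets_per_iteration, tuple):
            if len(self.sets_per_iteration) != self.n_iterations:
                raise ValueError("one sets count per iteration required")
            if min(self.sets_per_iteration) < 1:
                raise ValueError("all design counts must be >= 1")
        elif self.sets_per_iteration < 1:
            raise ValueError("all design counts must be >= 1")

    def sets_for(self, iteration: int) -> int:
        if isinstance(self.sets_per_iteration, tuple):
            return self.sets_per_iteration[iteration]
        return self.sets_per_iteration

    @property
    def n_samples(self) -> int:
        return self.n_participants * self.n_gestures * sum(
            self.sets_for(i) for i in range(self.n_iterations)
        )


def default_design(condition: str = "normal", seed: int = 0, **overrides) -> StudyDesign:
    """The study layout used for each condition.

    normal / shake: 5 x 5 x 40 x 4 iterations (4000 samples);
    electrode_move: 6 sessions (6000 samples);
    cross_day: 3 days with 40/40/50 sets (3250 samples).
    """
    base = dict(n_participants=5, n_gestures=5, sets_per_iteration=40,
                n_iterations=4, condition=condition, seed=seed)
    if condition == "electrode_move":
        base["n_iterations"] = 6
    elif condition == "cross_day":
        base["n_iterations"] = 3
        base["sets_per_iteration"] = (40, 40, 50)
    base.update(overrides)
    return StudyDesign(**base)


@dataclass(frozen=True)
class NoiseParams:
    """Measurement noise model.

    ``sigma_rel``: multiplicative Gaussian noise per reading;
    ``floor``: additive Gaussian voltage floor (V);
    ``sigma_switch``: extra multiplicative error on readings taken right
    after the excitation pair switches, while the current source and the
    RMS detector are still settling against a changing load.  Fixed
    excitation patterns incur this on one step only; cyclic excitation
    on one step per block.
    """

    sigma_rel: float = 0.02
    floor: float = 1.0e-6
    sigma_switch: float = 0.10

    def __post_init__(self) -> None:
        if self.sigma_rel < 0 or self.floor < 0 or self.sigma_switch < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class ParticipantEffect:
    """Per-participant anatomy scaling and baseline conductivity factor."""

    scale_x: float = 1.0
    scale_y: float = 1.0
    sigma_scale: float = 1.0


@dataclass(frozen=True)
class InterferenceContext:
    """Session-level measurement perturbations.

    shake: as the arm swings downward during acquisition the soft tissue
    shifts relative to the ring (a rotation ramping from 0 to
    ``shake_rot``) and the baseline conductivity drifts by ``shake_amp``;
    electrode_move: constant ring rotation from re-worn electrodes;
    cross_day: per-day baseline factor plus small electrode jitter.
    """

    condition: str = "normal"
    ring_rotation: float = 0.0
    shake_amp: float = 0.0
    shake_rot: float = 0.0
    day_factor: float = 1.0


def _rng(*key: int) -> np.random.Generator:
    """Deterministic child generator from an integer key path."""
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def draw_participant_effect(seed: int, participant: int,
                            spread: float = 0.05) -> ParticipantEffect:
    """Anatomy axes and baseline sigma each vary ~N(1, spread), clipped
    to +-2*spread (default +-10%)."""
    r = _rng(seed, 17, participant)
    draw = lambda: 1.0 + float(np.clip(r.normal(0.0, spread), -2 * spread, 2 * spread))
    return ParticipantEffect(scale_x=draw(), scale_y=draw(), sigma_scale=draw())


_SHAKE_AMP_RANGE = (0.01, 0.03)
_SHAKE_ROT_RANGE = (np.pi / 32, np.pi / 16)  # magnitude; sign is random
_ELECTRODE_MOVE_MAX = np.pi / 8  # half the inter-electrode spacing
_CROSS_DAY_JITTER = np.pi / 32
_CROSS_DAY_SIGMA = 0.02


def apply_interference(condition: str, seed: int, participant: int,
                       iteration: int) -> InterferenceContext:
    """Draw the session-level interference context for one (participant,
    iteration).  ``normal`` returns the identity context."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if condition == "normal":
        return InterferenceContext(condition=condition)
    r = _rng(seed, 23, participant, iteration)
    if condition == "shake":
        amp = float(r.uniform(*_SHAKE_AMP_RANGE))
        rot = float(r.uniform(*_SHAKE_ROT_RANGE) * r.choice([-1.0, 1.0]))
        return InterferenceContext(condition=condition, shake_amp=amp,
                                   shake_rot=rot)
    if condition == "electrode_move":
        rot = float(r.uniform(-_ELECTRODE_MOVE_MAX, _ELECTRODE_MOVE_MAX))
        return InterferenceContext(condition=condition, ring_rotation=rot)
    # cross_day: iteration indexes the day
    day = float(np.exp(r.normal(0.0, _CROSS_DAY_SIGMA)))
    rot = float(r.uniform(-_CROSS_DAY_JITTER, _CROSS_DAY_JITTER))
    return InterferenceContext(condition=condition, ring_rotation=rot,
                               day_factor=day)


@dataclass(frozen=True)
class GestureSample:
    """One 40-element voltage-amplitude sequence with its metadata."""

    voltages: np.ndarray
    label: int
    participant: int = 0
    iteration: int = 0
    condition: str = "normal"

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, dtype=float)
        if v.ndim != 1 or len(v) != 40:
            raise ValueError("a gesture sample holds exactly 40 voltages")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("voltage amplitudes must be finite and >= 0")
        object.__setattr__(self, "voltages", v)


@dataclass(frozen=True)
class Dataset:
    """A collection of gesture samples from one drive pattern."""

    samples: tuple[GestureSample, ...]
    pattern_name: str
    design: StudyDesign | None = None

    def __len__(self) -> int:
        return len(self.samples)

    def X(self) -> np.ndarray:
        return np.stack([s.voltages for s in self.samples])

    def y(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    def iterations(self) -> np.ndarray:
        return np.array([s.iteration for s in self.samples], dtype=int)


@dataclass(frozen=True)
class DatasetSplit:
    train: Dataset
    test: Dataset


def participant_phantom(effect: ParticipantEffect,
                        mesh_h: float = fm.MESH_H_COARSE) -> fm.ArmPhantom:
    """Reference phantom scaled to one participant's anatomy."""
    sx, sy = effect.scale_x, effect.scale_y
    sr = 0.5 * (sx + sy)
    outer = fm.Ellipse(0.0, 0.0, 40.0 * sx, 30.0 * sy)
    bones = tuple(
        fm.Ellipse(b.cx * sx, b.cy * sy, b.ra * sr, b.rb * sr, b.angle)
        for b in (fm.Ellipse(-14.0, 4.0, 7.0, 5.0, angle=0.35),
                  fm.Ellipse(13.0, 2.0, 6.0, 4.5, angle=-0.35))
    )
    return fm.build_phantom(
        outer=outer, bones=bones,
        sigma_muscle=fm.SIGMA_MUSCLE * effect.sigma_scale,
        mesh_h=mesh_h,
    )


def _scaled_region_masks(
    phantom: fm.ArmPhantom, model: GestureClassModel, effect: ParticipantEffect
) -> list[tuple[np.ndarray, Region]]:
    sx, sy = effect.scale_x, effect.scale_y
    sr = 0.5 * (sx + sy)
    return [
        (phantom.region_mask(reg.cx * sx, reg.cy * sy, reg.radius * sr), reg)
        for reg in model.active_regions
    ]


def _smoothstep01(tau: np.ndarray) -> np.ndarray:
    s = np.clip(tau, 0.0, 1.0)
    return 3.0 * s**2 - 2.0 * s**3


def trajectory_voltages(
    phantom: fm.ArmPhantom,
    model: GestureClassModel,
    pattern: DrivePattern | str,
    effect: ParticipantEffect = ParticipantEffect(),
    context: InterferenceContext = InterferenceContext(),
    current: fm.DriveCurrent = fm.DriveCurrent(),
) -> np.ndarray:
    """Noise-free 40-step measurement vector for one gesture execution.

    Element conductivity at step t is
    ``base * day_factor * (1 - shake_amp * smoothstep(t/39))`` plus the
    gesture's ramped region deltas; the ring rotation is the session
    offset plus, under shake, a rotation ramping with the arm swing.
    """
    schedule = build_schedule(pattern)
    masks = _scaled_region_masks(phantom, model, effect)
    base = phantom.element_sigma * context.day_factor

    def sigma_at(t: int) -> np.ndarray:
        g = 1.0 - context.shake_amp * float(_smoothstep01(np.asarray(t / 39.0)))
        sig = base * g
        for mask, reg in masks:
            act = float(model.activation(t, reg))
            sig = sig + reg.delta_sigma * act * mask
        return sig

    def rotation_at(t: int) -> float:
        swing = float(_smoothstep01(np.asarray(t / 39.0)))
        return context.ring_rotation + context.shake_rot * swing

    return fm.measure(schedule, sigma_at, current, phantom=phantom,
                      ring_rotation=rotation_at)


def trajectory_grid(
    phantom: fm.ArmPhantom,
    model: GestureClassModel,
    pattern: DrivePattern | str,
    effect: ParticipantEffect = ParticipantEffect(),
    context: InterferenceContext = InterferenceContext(),
    current: fm.DriveCurrent = fm.DriveCurrent(),
) -> np.ndarray:
    """Time-resolved measurement grid G[t, k]: the amplitude schedule step
    k would read if taken at physical time index t.

    The diagonal G[t, t] is the nominal (perfectly timed) trajectory of
    :func:`trajectory_voltages`; off-diagonal entries let samples be
    drawn with per-execution timing variability.  One forward solve per
    (time step, distinct excitation): 40 solves for fixed patterns, 320
    for the cyclic pattern.
    """
    schedule = build_schedule(pattern)
    masks = _scaled_region_masks(phantom, model, effect)
    base = phantom.element_sigma * context.day_factor
    n = len(schedule)
    grid = np.empty((n, n))
    for t in range(n):
        tau = t / 39.0
        g = 1.0 - context.shake_amp * float(_smoothstep01(np.asarray(tau)))
        sig = base * g
        for mask, reg in masks:
            sig = sig + reg.delta_sigma * float(model.activation(t, reg)) * mask
        rot = context.ring_rotation + context.shake_rot * float(
            _smoothstep01(np.asarray(tau))
        )
        sols: dict = {}
        for exc, meas, k in schedule:
            if exc not in sols:
                sols[exc] = fm.solve_forward(phantom, exc, current, sigma=sig,
                                             ring_rotation=rot)
            grid[t, k] = abs(sols[exc].boundary_voltage(meas))
    return grid


@dataclass(frozen=True)
class TimingParams:
    """Per-execution gesture-timing variability: each sample's activation
    runs at a random speed with a random onset shift, emulating how
    volunteers never repeat a dynamic gesture with identical timing."""

    speed_sigma: float = 0.08
    speed_max_dev: float = 0.2
    shift_sigma: float = 0.04
    shift_max: float = 0.1

    def draw(self, rng: np.random.Generator) -> tuple[float, float]:
        speed = 1.0 + float(np.clip(rng.normal(0.0, self.speed_sigma),
                                    -self.speed_max_dev, self.speed_max_dev))
        shift = float(np.clip(rng.normal(0.0, self.shift_sigma),
                              -self.shift_max, self.shift_max))
        return speed, shift


def _warp_sample(grid: np.ndarray, speed: float, shift: float) -> np.ndarray:
    """Read each schedule step off the time-resolved grid at the warped
    time tau' = clip(speed * (tau - shift), 0, 1), linearly interpolated."""
    n = len(grid)
    tau = np.arange(n) / (n - 1.0)
    warped = np.clip(speed * (tau - shift), 0.0, 1.0) * (n - 1.0)
    t_axis = np.arange(n, dtype=float)
    return np.array([
        np.interp(warped[k], t_axis, grid[:, k]) for k in range(n)
    ])


def _add_noise(v: np.ndarray, noise: NoiseParams, rng: np.random.Generator,
               switch_mask: np.ndarray | None = None) -> np.ndarray:
    out = v * (1.0 + noise.sigma_rel * rng.standard_normal(len(v)))
    if switch_mask is not None and noise.sigma_switch > 0:
        trans = 1.0 + noise.sigma_switch * rng.standard_normal(len(v))
        out = np.where(switch_mask, out * trans, out)
    out = out + noise.floor * rng.standard_normal(len(v))
    return np.clip(out, 0.0, None)


def generate_sample(
    model: GestureClassModel,
    pattern: DrivePattern | str,
    participant_effect: ParticipantEffect = ParticipantEffect(),
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    context: InterferenceContext = InterferenceContext(),
    timing: TimingParams | None = TimingParams(),
    mesh_h: float = fm.MESH_H_COARSE,
    phantom: fm.ArmPhantom | None = None,
) -> GestureSample:
    """Simulate a single labelled gesture sample.

    ``timing=None`` disables per-execution timing variability, yielding
    the nominal trajectory plus measurement noise."""
    if phantom is None:
        phantom = participant_phantom(participant_effect, mesh_h=mesh_h)
    rng = _rng(seed, 31)
    if timing is None:
        clean = trajectory_voltages(phantom, model, pattern,
                                    effect=participant_effect, context=context)
    else:
        grid = trajectory_grid(phantom, model, pattern,
                               effect=participant_effect, context=context)
        clean = _warp_sample(grid, *timing.draw(rng))
    switch = fm.excitation_switch_steps(build_schedule(pattern))
    noisy = _add_noise(clean, noise, rng, switch_mask=switch)
    return GestureSample(voltages=noisy, label=model.class_id,
                         condition=context.condition)


def generate_dataset(
    design: StudyDesign,
    pattern: DrivePattern | str = "fixed_opposite",
    noise: NoiseParams = NoiseParams(),
    timing: TimingParams | None = TimingParams(),
    mesh_h: float = fm.MESH_H_COARSE,
) -> Dataset:
    """Simulate the full study: every participant performs every gesture
    ``sets`` times per iteration under the design's condition.

    Per-participant effects are drawn once per participant; interference
    contexts once per (participant, iteration) session; execution timing
    and measurement noise per sample.  Time-resolved trajectory grids are
    cached per (participant, context, class): repeats within a session
    share physics and differ by timing and noise.
    """
    pattern_obj = get_pattern(pattern) if isinstance(pattern, str) else pattern
    models = make_class_models(design.seed)
    if design.n_gestures > len(models):
        raise ValueError("design requests more gestures than defined classes")
    switch = fm.excitation_switch_steps(build_schedule(pattern_obj))
    samples: list[GestureSample] = []
    for p in range(design.n_participants):
        effect = draw_participant_effect(design.seed, p)
        phantom = participant_phantom(effect, mesh_h=mesh_h)
        cache: dict[tuple, np.ndarray] = {}
        for it in range(design.n_iterations):
            ctx = apply_interference(design.condition, design.seed, p, it)
            ctx_key = (ctx.ring_rotation, ctx.shake_amp, ctx.shake_rot,
                       ctx.day_factor)
            for c in range(design.n_gestures):
                key = (c,) + ctx_key
                if key not in cache:
                    if timing is None:
                        cache[key] = trajectory_voltages(
                            phantom, models[c], pattern_obj,
                            effect=effect, context=ctx,
                        )
                    else:
                        cache[key] = trajectory_grid(
                            phantom, models[c], pattern_obj,
                            effect=effect, context=ctx,
                        )
                for s in range(design.sets_for(it)):
                    rng = _rng(design.seed, 31, p, it, c, s)
                    if timing is None:
                        clean = cache[key]
                    else:
                        clean = _warp_sample(cache[key], *timing.draw(rng))
                    samples.append(GestureSample(
                        voltages=_add_noise(clean, noise, rng,
                                            switch_mask=switch),
                        label=c, participant=p, iteration=it,
                        condition=design.condition,
                    ))
    return Dataset(samples=tuple(samples), pattern_name=pattern_obj.name,
                   design=design)


def split_dataset(dataset: Dataset, rule: str = "last_iteration") -> DatasetSplit:
    """Split train/test by session: every iteration (or day) except the
    last trains, the last tests.  Under the default designs this gives
    3000/1000 (normal, shake), 5000/1000 (electrode_move) and 2000/1250
    (cross_day)."""
    if rule != "last_iteration":
        raise ValueError(f"unknown split rule {rule!r}")
    its = dataset.iterations()
    if len(np.unique(its)) < 2:
        raise ValueError("split requires at least two iterations/days")
    last = its.max()
    train = tuple(s for s in dataset.samples if s.iteration != last)
    test = tuple(s for s in dataset.samples if s.iteration == last)
    return DatasetSplit(
        train=Dataset(train, dataset.pattern_name, dataset.design),
        test=Dataset(test, dataset.pattern_name, dataset.design),
    )


def first_order_difference(voltages: Sequence[float] | np.ndarray) -> np.ndarray:
    """Successive differences, length-preserving: out[0] = 0,
    out[t] = v[t] - v[t-1]."""
    v = np.asarray(voltages, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a 1-D sequence of length >= 2")
    out = np.empty_like(v)
    out[0] = 0.0
    out[1:] = np.diff(v)
    return out


def dataset_to_frame(dataset: Dataset) -> pd.DataFrame:
    """Tabular form: columns v00..v39, label, participant, iteration,
    condition, pattern."""
    cols = {f"v{i:02d}": np.array([s.voltages[i] for s in dataset.samples])
            for i in range(40)}
    cols["label"] = dataset.y()
    cols["participant"] = np.array([s.participant for s in dataset.samples])
    cols["iteration"] = dataset.iterations()
    cols["condition"] = [s.condition for s in dataset.samples]
    cols["pattern"] = dataset.pattern_name
    return pd.DataFrame(cols)


def dataset_from_frame(frame: pd.DataFrame) -> Dataset:
    vcols = [f"v{i:02d}" for i in range(40)]
    samples = tuple(
        GestureSample(
            voltages=row[vcols].to_numpy(dtype=float),
            label=int(row["label"]),
            participant=int(row.get("participant", 0)),
            iteration=int(row.get("iteration", 0)),
            condition=str(row.get("condition", "normal")),
        )
        for _, row in frame.iterrows()
    )
    pattern = str(frame["pattern"].iloc[0]) if "pattern" in frame else "unknown"
    return Dataset(samples=samples, pattern_name=pattern)
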