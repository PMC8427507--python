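"""Synthetic pose trajectories and footfall events for symmetrical dog gaits.

The original recordings behind this pipeline (biplanar cineradiography of
four German Shepherd Dogs walking and trotting on a treadmill) are not
publicly deposited, so this module emulates them: every degree of freedom of
the pelvis (world frame) and of L7/L6 (relative to the adjoining caudal
bone) is a periodic per-stride waveform defined by extremum anchors
(phase-of-cycle, value), with

* the peak-to-trough range (ROM) and extremum phases (TOO) taken from the
  published per-gait summary statistics,
* stride-to-stride jitter of both ROM and phase at the published standard
  deviations,
* additive Gaussian frame noise below the stated measurement accuracy of the
  rotoscoping method (~1.5 deg rotation, ~0.1 cm translation), and
* the treadmill-driven near-linear craniocaudal drift realised as a
  periodic within-stride ramp.

Between its anchors the waveform is a periodic monotone (PCHIP) cubic, so
the noise-free curve attains exactly the anchor extrema and nothing else --
harmonic sums cannot place asymmetric extrema such as maxima at 2.8 % and
54.3 % of the cycle.

Relative L7/L6 trajectories are composed into world poses through the
kinematics module, so an analyzer must invert the bone chain to recover
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .kinematics import BONES, DOFS, BoneChain, compose_chain
from .stride import GaitEvents

#: Default additive frame noise, about one-third of the measurement accuracy
#: of the rotoscoping method (1.5 deg / 0.1 cm): sub-accuracy wiggles are
#: treated as non-events by the analysis, so the generator stays below them.
ROTATION_NOISE_SD_DEG = 0.5
TRANSLATION_NOISE_SD_CM = 0.03

#: Stride-to-stride SD of the duty factor (published as +/- 0.01).
DUTY_JITTER_SD = 0.01

#: Stride-to-stride SD of stride duration, as a fraction of the mean.
DURATION_JITTER_FRAC = 0.02

LIMBS = ("LH", "RH", "LF", "RF")


class TemplateError(ValueError):
    """A DOF template's anchors are malformed."""


@dataclass(frozen=True)
class DOFTemplate:
    """Periodic waveform of one DOF over the stride cycle.

    ``anchors`` are (phase in [0, 1), value) pairs, sorted by phase, whose
    values strictly alternate between local maxima and minima around the
    cycle; ``rom`` is the peak-to-trough range and must equal
    max(values) - min(values).
    """

    anchors: tuple[tuple[float, float], ...]
    rom: float
    phase_jitter_sd: float = 0.0
    rom_jitter_sd: float = 0.0
    noise_sd: float = 0.0
    drift_per_stride: float = 0.0

    def __post_init__(self) -> None:
        anchors = tuple((float(p), float(v)) for p, v in self.anchors)
        object.__setattr__(self, "anchors", anchors)
        phases = np.array([p for p, _ in anchors])
        values = np.array([v for _, v in anchors])
        if len(anchors) < 2:
            raise TemplateError("need at least one maximum and one minimum")
        if np.any(phases < 0) or np.any(phases >= 1):
            raise TemplateError("anchor phases must lie in [0, 1)")
        if np.any(np.diff(phases) <= 0):
            raise TemplateError("anchor phases must be strictly increasing")
        if self.rom < 0:
            raise TemplateError("rom must be non-negative")
        # alternation around the circle: consecutive differences (incl. wrap)
        # must flip sign
        diffs = np.diff(np.append(values, values[0]))
        if np.any(diffs == 0) or np.any(diffs[:-1] * diffs[1:] >= 0):
            raise TemplateError("anchor values must alternate max/min")
        if abs((values.max() - values.min()) - self.rom) > 1e-9:
            raise TemplateError(
                f"anchor range {values.max() - values.min()} != rom {self.rom}"
            )

    @property
    def anchor_kinds(self) -> tuple[str, ...]:
        """'max'/'min' label per anchor, inferred from the alternation."""
        values = np.array([v for _, v in self.anchors])
        nxt = np.roll(values, -1)
        return tuple("max" if v > n else "min" for v, n in zip(values, nxt))

    def interpolator(self) -> PchipInterpolator:
        """Periodic monotone cubic through the anchors (phase wraps mod 1)."""
        phases = np.array([p for p, _ in self.anchors])
        values = np.array([v for _, v in self.anchors])
        ext_p = np.concatenate([phases - 1.0, phases, phases + 1.0])
        ext_v = np.concatenate([values, values, values])
        return PchipInterpolator(ext_p, ext_v)

    def evaluate(self, phase) -> np.ndarray:
        """Noise-free waveform at arbitrary phases (wrapped into [0, 1))."""
        return self.interpolator()(np.mod(phase, 1.0))


@dataclass(frozen=True)
class GaitPreset:
    """Everything needed to simulate one gait: timing plus 18 DOF templates."""

    name: str
    gait: str
    duty_factor: float
    stride_duration_s: float
    limb_phase_offsets: dict[str, float]
    templates: dict[str, dict[str, DOFTemplate]]
    duty_jitter_sd: float = DUTY_JITTER_SD

    def __post_init__(self) -> None:
        if not (0.0 < self.duty_factor < 1.0):
            raise ValueError("duty_factor must be in (0, 1)")
        if self.stride_duration_s <= 0:
            raise ValueError("stride_duration_s must be positive")
        for limb, off in self.limb_phase_offsets.items():
            if not (0.0 <= off < 1.0):
                raise ValueError(f"{limb}: phase offset {off} outside [0, 1)")


@dataclass(frozen=True)
class TrialSpec:
    """How much data to simulate and with which stochastic components."""

    n_strides: int = 6
    frame_rate: float = 100.0
    seed: int = 0
    noise_enabled: bool = True
    jitter_enabled: bool = True

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


def _tmpl(rom, anchors, phase_sd=0.0, rom_sd=0.0, noise_sd=ROTATION_NOISE_SD_DEG):
    """Symmetric template: 'max' anchors at +rom/2, 'min' anchors at -rom/2."""
    pairs = tuple(
        (p, rom / 2.0 if kind == "max" else -rom / 2.0) for p, kind in anchors
    )
    return DOFTemplate(
        anchors=pairs,
        rom=rom,
        phase_jitter_sd=phase_sd,
        rom_jitter_sd=rom_sd,
        noise_sd=noise_sd,
    )


def _ttmpl(rom, anchors, phase_sd=0.0, rom_sd=0.0):
    return _tmpl(rom, anchors, phase_sd, rom_sd, noise_sd=TRANSLATION_NOISE_SD_CM)


def _walk_templates() -> dict[str, dict[str, DOFTemplate]]:
    # Pelvic axial rotation dominates at a walk: ROM 12.1 +/- 4.7 deg with
    # direction changes at 29.0 +/- 9.0 % and 86.8 +/- 10.1 % of the cycle.
    pelvis = {
        "rx": _tmpl(12.1, [(0.290, "max"), (0.868, "min")], 0.095, 4.7),
        "ry": _tmpl(10.9, [(0.433, "max"), (0.960, "min")], 0.040, 0.8),
        "rz": _tmpl(
            7.8,
            [(0.028, "max"), (0.306, "min"), (0.543, "max"), (0.804, "min")],
            0.032,
            2.5,
        ),
        # treadmill-dominated near-linear craniocaudal drift: periodic ramp,
        # cranial within the stride, reset around touch-down
        "tx": _ttmpl(2.6, [(0.020, "min"), (0.930, "max")], 0.020, 0.6),
        "ty": _ttmpl(
            3.6,
            [(0.036, "max"), (0.574, "min"), (0.812, "max"), (0.920, "min")],
            0.040,
            0.8,
        ),
        "tz": _ttmpl(3.5, [(0.250, "min"), (0.750, "max")], 0.050, 1.6),
    }
    # L7 axial rotation mirrors the pelvis (inverse oscillation).
    l7 = {
        "rx": _tmpl(3.0, [(0.290, "min"), (0.868, "max")], 0.100, 0.5),
        "ry": _tmpl(
            3.6,
            [(0.150, "max"), (0.400, "min"), (0.650, "max"), (0.900, "min")],
            0.100,
            0.6,
        ),
        # irregular bi/triphasic at a walk with no published anchors; phases
        # chosen near quadrature with pelvic rz so no sagittal inverse
        # oscillation is synthesised at a walk (it is a trot-only finding)
        "rz": _tmpl(
            3.6,
            [(0.120, "max"), (0.370, "min"), (0.620, "max"), (0.870, "min")],
            0.100,
            0.7,
        ),
        "tx": _ttmpl(0.15, [(0.300, "max"), (0.800, "min")], 0.100, 0.05),
        "ty": _ttmpl(0.10, [(0.400, "max"), (0.900, "min")], 0.100, 0.03),
        "tz": _ttmpl(0.10, [(0.250, "max"), (0.700, "min")], 0.100, 0.03),
    }
    # L6 follows L7's axial rotation with a mild delay.
    l6 = {
        "rx": _tmpl(2.5, [(0.340, "min"), (0.918, "max")], 0.120, 0.4),
        "ry": _tmpl(
            3.4,
            [(0.100, "max"), (0.350, "min"), (0.600, "max"), (0.850, "min")],
            0.120,
            1.0,
        ),
        "rz": _tmpl(
            3.1,
            [(0.250, "max"), (0.500, "min"), (0.750, "max"), (0.970, "min")],
            0.100,
            0.9,
        ),
        "tx": _ttmpl(0.10, [(0.350, "max"), (0.850, "min")], 0.100, 0.03),
        "ty": _ttmpl(0.10, [(0.450, "max"), (0.950, "min")], 0.100, 0.03),
        "tz": _ttmpl(0.10, [(0.200, "max"), (0.650, "min")], 0.100, 0.03),
    }
    return {"pelvis": pelvis, "L7": l7, "L6": l6}


def _trot_templates() -> dict[str, dict[str, DOFTemplate]]:
    pelvis = {
        # published trot rx ROM 6.1 +/- 5.7 deg: jitter SD capped at half the
        # mean so single strides keep a well-defined waveform sign
        "rx": _tmpl(6.1, [(0.330, "max"), (0.855, "min")], 0.147, 3.05),
        "ry": _tmpl(9.0, [(0.393, "max"), (0.919, "min")], 0.094, 0.9),
        # no trot-specific extremum phases are published for pelvic rz; the
        # walk anchors are reused with the trot ROM
        "rz": _tmpl(
            6.7,
            [(0.028, "max"), (0.306, "min"), (0.543, "max"), (0.804, "min")],
            0.032,
            1.9,
        ),
        "tx": _ttmpl(
            2.9,
            [(0.060, "max"), (0.310, "min"), (0.560, "max"), (0.810, "min")],
            0.040,
            0.6,
        ),
        "ty": _ttmpl(
            3.6,
            [(0.175, "min"), (0.435, "max"), (0.705, "min"), (0.932, "max")],
            0.050,
            0.6,
        ),
        "tz": _ttmpl(2.6, [(0.250, "min"), (0.750, "max")], 0.050, 0.7),
    }
    l7 = {
        "rx": _tmpl(3.0, [(0.330, "min"), (0.855, "max")], 0.120, 0.3),
        "ry": _tmpl(
            3.4,
            [(0.150, "max"), (0.400, "min"), (0.650, "max"), (0.900, "min")],
            0.120,
            1.0,
        ),
        # the one strongly stride-locked intervertebral DOF: L7 sagittal
        # rotation at a trot, ROM 5.1 +/- 0.5 deg, maxima 30.0/83.8 %,
        # minima 9.6/57.7 %
        "rz": _tmpl(
            5.1,
            [(0.096, "min"), (0.300, "max"), (0.577, "min"), (0.838, "max")],
            0.040,
            0.5,
        ),
        # craniocaudal L7 translation is biphasic at a trot and anti-phase
        # with L7 sagittal rotation (train-coupler motion of the junction)
        "tx": _ttmpl(
            0.20,
            [(0.060, "max"), (0.318, "min"), (0.553, "max"), (0.815, "min")],
            0.040,
            0.05,
        ),
        "ty": _ttmpl(0.10, [(0.400, "max"), (0.900, "min")], 0.100, 0.03),
        "tz": _ttmpl(0.10, [(0.250, "max"), (0.700, "min")], 0.100, 0.03),
    }
    l6 = {
        "rx": _tmpl(2.3, [(0.380, "min"), (0.905, "max")], 0.120, 0.2),
        "ry": _tmpl(
            3.9,
            [(0.100, "max"), (0.350, "min"), (0.600, "max"), (0.850, "min")],
            0.120,
            0.4,
        ),
        "rz": _tmpl(
            3.3,
            [(0.224, "max"), (0.363, "min"), (0.707, "max"), (0.803, "min")],
            0.070,
            0.3,
        ),
        "tx": _ttmpl(0.10, [(0.350, "max"), (0.850, "min")], 0.100, 0.03),
        "ty": _ttmpl(0.10, [(0.450, "max"), (0.950, "min")], 0.100, 0.03),
        "tz": _ttmpl(0.10, [(0.200, "max"), (0.650, "min")], 0.100, 0.03),
    }
    return {"pelvis": pelvis, "L7": l7, "L6": l6}


def builtin_presets() -> dict[str, GaitPreset]:
    """Presets encoding the published per-gait kinematic summary values.

    ``walk``: duty factor 0.7, lateral-sequence footfall (LH, LF, RH, RF at
    quarter-cycle spacing).  ``trot``: duty factor 0.4, diagonal couplets
    (LH+RF, RH+LF half a cycle apart).  ``trot_gsd3``: the one deviant
    animal's trot with duty factor 0.5, off by default.
    """
    walk = GaitPreset(
        name="walk",
        gait="walk",
        duty_factor=0.7,
        stride_duration_s=1.0,
        limb_phase_offsets={"LH": 0.0, "LF": 0.25, "RH": 0.5, "RF": 0.75},
        templates=_walk_templates(),
    )
    trot = GaitPreset(
        name="trot",
        gait="trot",
        duty_factor=0.4,
        stride_duration_s=0.5,
        limb_phase_offsets={"LH": 0.0, "RF": 0.0, "RH": 0.5, "LF": 0.5},
        templates=_trot_templates(),
    )
    trot_gsd3 = replace(trot, name="trot_gsd3", duty_factor=0.5)
    return {"walk": walk, "trot": trot, "trot_gsd3": trot_gsd3}


def mean_pattern(template: DOFTemplate, n_samples: int) -> np.ndarray:
    """Noise-free mean waveform sampled at *n_samples* phases on [0, 1].

    The first and last samples coincide (periodicity); the sampled range
    equals the template ROM up to the grid resolution.
    """
    if n_samples < 2 * len(template.anchors):
        raise TemplateError(
            f"n_samples={n_samples} too coarse for {len(template.anchors)} anchors"
        )
    phases = np.linspace(0.0, 1.0, n_samples)
    return np.asarray(template.evaluate(phases), dtype=float)


def _stride_schedule(
    preset: GaitPreset, spec: TrialSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Reference-limb touch-down times (n+1) and per-stride duty factors (n)."""
    T = preset.stride_duration_s
    n = spec.n_strides
    if spec.jitter_enabled:
        durations = T * (1.0 + DURATION_JITTER_FRAC * rng.standard_normal(n))
        durations = np.clip(durations, 0.5 * T, 1.5 * T)
        duties = np.clip(
            preset.duty_factor + preset.duty_jitter_sd * rng.standard_normal(n),
            0.05,
            0.95,
        )
    else:
        durations = np.full(n, T)
        duties = np.full(n, preset.duty_factor)
    touch_downs = np.concatenate([[0.0], np.cumsum(durations)])
    return touch_downs, duties


def generate_events(preset: GaitPreset, spec: TrialSpec) -> GaitEvents:
    """Footfall events for all limbs over *n_strides* reference cycles.

    Each limb gets n_strides + 1 touch-downs (the terminal one closes the
    last stride) and n_strides lift-offs.  Same seed, same output.
    """
    rng = np.random.default_rng(spec.seed)
    touch_downs_ref, duties = _stride_schedule(preset, spec, rng)
    durations = np.diff(touch_downs_ref)
    tds: dict[str, np.ndarray] = {}
    los: dict[str, np.ndarray] = {}
    for limb in LIMBS:
        if limb not in preset.limb_phase_offsets:
            continue
        off = preset.limb_phase_offsets[limb]
        td = np.concatenate(
            [
                touch_downs_ref[:-1] + off * durations,
                [touch_downs_ref[-1] + off * durations[-1]],
            ]
        )
        lo = td[:-1] + duties * durations
        tds[limb] = td
        los[limb] = lo
    return GaitEvents(touch_downs=tds, lift_offs=los)


def _dof_signal(
    template: DOFTemplate,
    t: np.ndarray,
    touch_downs: np.ndarray,
    spec: TrialSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """One DOF's time series over the whole trial.

    Per stride i the template is phase-shifted by delta_i and amplitude-scaled
    by s_i (jitter), then evaluated at the local phase; frame noise and the
    within-stride drift ramp are added on top.  Random draws happen
    unconditionally so that toggling noise/jitter does not shift the stream
    of the other components.
    """
    n = len(touch_downs) - 1
    deltas = template.phase_jitter_sd * rng.standard_normal(n)
    rel_sd = template.rom_jitter_sd / template.rom if template.rom > 0 else 0.0
    scales = np.clip(1.0 + rel_sd * rng.standard_normal(n), 0.1, None)
    noise = rng.standard_normal(len(t))
    if not spec.jitter_enabled:
        deltas = np.zeros(n)
        scales = np.ones(n)
    idx = np.clip(np.searchsorted(touch_downs, t, side="right") - 1, 0, n - 1)
    local_phase = (t - touch_downs[idx]) / (
        touch_downs[idx + 1] - touch_downs[idx]
    )
    # frames past the final touch-down (grid rounding) hold the cycle end
    local_phase = np.clip(local_phase, 0.0, 1.0)
    interp = template.interpolator()
    values = scales[idx] * interp(np.mod(local_phase - deltas[idx], 1.0))
    values = values + template.drift_per_stride * local_phase
    if spec.noise_enabled and template.noise_sd > 0:
        values = values + template.noise_sd * noise
    return values


def generate_trial(
    preset: GaitPreset, spec: TrialSpec
) -> tuple[BoneChain, GaitEvents]:
    """Simulate one trial: world bone-chain trajectories plus gait events.

    Pelvis DOFs are generated directly in the world frame; L7 and L6 DOFs are
    generated in their caudal-neighbor frames and composed into world poses,
    so recovering the templates requires the relative-motion decomposition.
    """
    events = generate_events(preset, spec)
    touch_downs = events.touch_downs["LH"]
    total = touch_downs[-1]
    n_frames = int(np.ceil(total * spec.frame_rate - 1e-9)) + 1
    t = np.arange(n_frames) / spec.frame_rate
    rng = np.random.default_rng([spec.seed, 1])
    rel: dict[str, pd.DataFrame] = {}
    for bone in BONES:
        df = pd.DataFrame({"time_s": t})
        for dof in DOFS:
            df[dof] = _dof_signal(
                preset.templates[bone][dof], t, touch_downs, spec, rng
            )
        rel[bone] = df
    chain = compose_chain(
        pelvis_world=rel["pelvis"],
        relative={"L7": rel["L7"], "L6": rel["L6"]},
        frame_rate=spec.frame_rate,
    )
    return chain, events
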