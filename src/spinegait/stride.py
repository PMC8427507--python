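"""Gait-event processing and stride-cycle normalization.

A stride is the interval between consecutive touch-downs of the reference
limb (left hindlimb by convention).  The duty factor is the stance fraction
of that limb: (lift-off - touch-down) / stride duration.  To compare strides
with different stance/swing splits, every per-stride signal is warped with a
two-piece linear map that sends [touch-down, lift-off] onto
[0 %, 100*duty %] and [lift-off, next touch-down] onto [100*duty %, 100 %]
of a common target duty factor, then sampled on a fixed 101-point phase grid
(0-100 % inclusive, the conventional grid in gait analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_PHASES = 101
#: Phase grid in percent of the stride cycle, 0..100 inclusive.
PHASE_GRID = np.linspace(0.0, 100.0, N_PHASES)

REFERENCE_LIMB = "LH"


class InsufficientEventsError(ValueError):
    """Not enough footfall events to define a complete stride."""


class MalformedEventsError(ValueError):
    """Footfall events violate touch-down / lift-off alternation."""


class CoverageError(ValueError):
    """A signal does not span the stride segment it should be warped over."""


@dataclass(frozen=True)
class GaitEvents:
    """Per-limb footfall times in seconds.

    ``touch_downs[limb]`` and ``lift_offs[limb]`` are increasing arrays; each
    lift-off falls inside (touch_down_i, touch_down_{i+1}].  A terminal
    touch-down without a following lift-off is allowed (it closes the last
    stride).
    """

    touch_downs: dict[str, np.ndarray]
    lift_offs: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        tds = {l: np.asarray(v, dtype=float) for l, v in self.touch_downs.items()}
        los = {
            l: np.asarray(self.lift_offs.get(l, []), dtype=float) for l in tds
        }
        object.__setattr__(self, "touch_downs", tds)
        object.__setattr__(self, "lift_offs", los)
        for limb in tds:
            td = tds[limb]
            lo = los[limb]
            if np.any(np.diff(td) <= 0) or np.any(np.diff(lo) <= 0):
                raise MalformedEventsError(f"{limb}: event times not increasing")
            for i, t in enumerate(lo):
                if i >= len(td):
                    raise MalformedEventsError(f"{limb}: lift-off without touch-down")
                nxt = td[i + 1] if i + 1 < len(td) else np.inf
                if not (td[i] < t <= nxt):
                    raise MalformedEventsError(
                        f"{limb}: lift-off {t} s outside stance window of "
                        f"touch-down {td[i]} s"
                    )

    @property
    def limbs(self) -> tuple[str, ...]:
        return tuple(self.touch_downs)


@dataclass(frozen=True)
class StrideSegment:
    """One stride of the reference limb: [start, end), stance ends at stance_end."""

    start_s: float
    stance_end_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (self.start_s < self.stance_end_s <= self.end_s):
            raise MalformedEventsError(
                f"invalid segment {self.start_s}, {self.stance_end_s}, {self.end_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def duty_factor(self) -> float:
        return (self.stance_end_s - self.start_s) / self.duration_s


@dataclass
class NormalizedCurve:
    """One DOF resampled onto 0-100 % of the reference-limb stride cycle."""

    values: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_PHASES,):
            raise ValueError(
                f"normalized curve must have {N_PHASES} samples, "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized curve contains non-finite values")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != (N_PHASES,):
                raise ValueError("SD envelope length mismatch")


def duty_factor(events: GaitEvents, limb: str = REFERENCE_LIMB) -> float:
    """Mean stance fraction of *limb* over its complete strides."""
    if limb not in events.touch_downs:
        raise InsufficientEventsError(f"no events recorded for limb {limb!r}")
    td = events.touch_downs[limb]
    lo = events.lift_offs[limb]
    fractions = []
    for i in range(len(td) - 1):
        in_stride = lo[(lo > td[i]) & (lo <= td[i + 1])]
        if in_stride.size:
            fractions.append((in_stride[0] - td[i]) / (td[i + 1] - td[i]))
    if not fractions:
        raise InsufficientEventsError(
            f"{limb}: no complete stride (need touch-down, lift-off, touch-down)"
        )
    return float(np.mean(fractions))


def segment_strides(
    events: GaitEvents, reference_limb: str = REFERENCE_LIMB
) -> list[StrideSegment]:
    """One segment per consecutive reference-limb touch-down pair."""
    if reference_limb not in events.touch_downs:
        raise InsufficientEventsError(f"no events for reference limb {reference_limb!r}")
    td = events.touch_downs[reference_limb]
    lo = events.lift_offs[reference_limb]
    if len(td) < 2:
        raise InsufficientEventsError(
            f"{reference_limb}: need at least 2 touch-downs, got {len(td)}"
        )
    segments = []
    for i in range(len(td) - 1):
        inside = lo[(lo > td[i]) & (lo <= td[i + 1])]
        if inside.size != 1:
            raise MalformedEventsError(
                f"{reference_limb}: stride {i} has {inside.size} lift-offs, expected 1"
            )
        segments.append(
            StrideSegment(start_s=float(td[i]), stance_end_s=float(inside[0]),
                          end_s=float(td[i + 1]))
        )
    return segments


def normalize_stride(
    time_s: np.ndarray,
    values: np.ndarray,
    segment: StrideSegment,
    target_duty: float,
) -> NormalizedCurve:
    """Warp one stride of a signal onto the 101-point phase grid.

    Piecewise-linear time warp: stance [start, stance_end] maps onto
    [0, 100*target_duty] % and swing [stance_end, end] onto
    [100*target_duty, 100] %; values are then linearly interpolated.
    """
    time_s = np.asarray(time_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if not (0.0 < target_duty < 1.0):
        raise ValueError(f"target_duty must be in (0, 1), got {target_duty}")
    if time_s[0] > segment.start_s + 1e-9 or time_s[-1] < segment.end_s - 1e-9:
        raise CoverageError(
            f"signal spans [{time_s[0]}, {time_s[-1]}] s but segment needs "
            f"[{segment.start_s}, {segment.end_s}] s"
        )
    split = 100.0 * target_duty
    sample_t = np.where(
        PHASE_GRID <= split,
        segment.start_s
        + (PHASE_GRID / split) * (segment.stance_end_s - segment.start_s),
        segment.stance_end_s
        + ((PHASE_GRID - split) / (100.0 - split))
        * (segment.end_s - segment.stance_end_s),
    )
    return NormalizedCurve(values=np.interp(sample_t, time_s, values))


def mean_curve(curves: list[NormalizedCurve]) -> NormalizedCurve:
    """Pointwise mean across strides with a sample-SD envelope."""
    if not curves:
        raise ValueError("mean_curve requires at least one curve")
    stack = np.vstack([c.values for c in curves])
    sd = (
        stack.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros(N_PHASES)
    )
    return NormalizedCurve(values=stack.mean(axis=0), sd=sd)


def detrend_translation(
    time_s: np.ndarray,
    values: np.ndarray,
    segments: list[StrideSegment],
    mode: str = "linear-per-stride",
) -> np.ndarray:
    """Remove a per-stride least-squares linear trend from a translation.

    ``mode='none'`` returns the signal unchanged.  Rotations are never
    detrended by the pipeline; this is for treadmill-dominated translations.
    """
    if mode == "none":
        return np.asarray(values, dtype=float).copy()
    if mode != "linear-per-stride":
        raise ValueError(f"unknown detrend mode {mode!r}")
    time_s = np.asarray(time_s, dtype=float)
    out = np.asarray(values, dtype=float).copy()
    last_end = max(seg.end_s for seg in segments) if segments else None
    for seg in segments:
        # half-open [start, end) so shared stride boundaries are fit once;
        # the final segment keeps its endpoint
        mask = (time_s >= seg.start_s - 1e-12) & (time_s < seg.end_s - 1e-12)
        if seg.end_s == last_end:
            mask |= np.isclose(time_s, seg.end_s, atol=1e-12)
        if mask.sum() < 2:
            continue
        t = time_s[mask]
        coeffs = np.polyfit(t, out[mask], 1)
        out[mask] = out[mask] - np.polyval(coeffs, t)
    return out
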