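"""Per-DOF motion descriptors: range of motion, extremum timing, phase class.

Three summaries are reported per bone x DOF x gait, mirroring how treadmill
kinematics of the lumbosacral region are conventionally described:

* ROM - peak-to-trough amplitude over the stride;
* TOO - phase (% of the stride cycle) of each maximum/minimum, aggregated
  across strides with circular statistics because extrema routinely straddle
  the 0 %/100 % boundary (e.g. 96 +/- 4 %);
* phase class - monophasic / biphasic / triphasic / irregular, counting only
  direction changes whose prominence exceeds a threshold.  The default
  thresholds equal the measurement accuracy of the rotoscoping method
  (1.5 deg rotation, 0.1 cm translation): momentary sub-accuracy reversals
  are not genuine direction changes.

Curves are smoothed with a centred circular moving average (default window
5 % of the stride) before extremum detection; detected extrema are then
refined on the unsmoothed curve with a three-point parabolic fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import circmean, circstd

from .kinematics import BONES, DOFS, ROTATION_DOFS
from .stride import (
    N_PHASES,
    NormalizedCurve,
    duty_factor,
    mean_curve,
    normalize_stride,
    segment_strides,
)

logger = logging.getLogger(__name__)

PHASE_CLASSES = ("monophasic", "biphasic", "triphasic", "irregular")


class ClassificationError(ValueError):
    """Extrema handed to the phase classifier do not alternate max/min."""


@dataclass(frozen=True)
class ExtremumEvent:
    """One genuine direction change of a normalized curve."""

    phase_pct: float
    value: float
    kind: str  # "max" or "min"
    prominence: float


@dataclass
class MotionDescriptor:
    """Summary of one bone x DOF x gait combination."""

    bone: str
    dof: str
    gait: str
    rom: float
    rom_sd: float
    extrema: list[ExtremumEvent]
    phase_class: str
    too_mean_sd: list[tuple[str, float, float]] = field(default_factory=list)


def range_of_motion(curve: NormalizedCurve) -> float:
    """Peak-to-trough amplitude (max minus min) of the curve."""
    return float(np.max(curve.values) - np.min(curve.values))


#: Window (grid points, ~% of stride) of the peak-preserving quadratic
#: (Savitzky-Golay) filter used for the trial-level reference ROM.
_ROM_REF_WINDOW = 7

#: Maximum circular shift (grid points, ~% of stride) searched when
#: registering a stride curve to the trial mean curve.
_REGISTRATION_MAX_SHIFT = 33


def _reference_rom(mean: NormalizedCurve, threshold: float) -> float:
    """Trial-level ROM of the across-stride mean curve, noise-suppressed.

    The mean curve is smoothed with a peak-preserving local quadratic
    (Savitzky-Golay) filter, and the ROM is read between its detected
    extrema rather than as a global range, so uncorrelated frame noise does
    not enter as an extreme-value statistic over the whole cycle.
    """
    period = mean.values[:-1]
    smoothed = sps.savgol_filter(period, _ROM_REF_WINDOW, 2, mode="wrap")
    scurve = NormalizedCurve(values=np.append(smoothed, smoothed[0]))
    extrema = find_extrema(scurve, threshold, smooth_window_pct=0.0)
    if len(extrema) >= 2:
        values = [e.value for e in extrema]
        return max(values) - min(values)
    return range_of_motion(scurve)


def per_stride_roms(
    curves: list[NormalizedCurve], threshold: float
) -> np.ndarray:
    """Noise-robust per-stride ROM estimates.

    Each stride's amplitude is the least-squares scale of the stride curve
    against the circularly best-aligned trial mean curve (alignment absorbs
    stride-to-stride phase jitter), multiplied by the reference ROM of the
    mean curve.  A raw per-stride max-minus-min would overestimate small
    amplitudes under measurement noise by an extreme-value bias; the
    matched-amplitude estimate is unbiased to first order.
    """
    mean = mean_curve(curves)
    rom_ref = _reference_rom(mean, threshold)
    period = mean.values[:-1]
    centred = period - period.mean()
    denom = float((centred**2).sum())
    if denom == 0.0 or rom_ref == 0.0:
        return np.zeros(len(curves))
    roms = []
    for curve in curves:
        c = curve.values[:-1]
        c = c - c.mean()
        best = max(
            float((c * np.roll(centred, d)).sum()) / denom
            for d in range(-_REGISTRATION_MAX_SHIFT, _REGISTRATION_MAX_SHIFT + 1)
        )
        roms.append(max(best, 0.0) * rom_ref)
    return np.asarray(roms)


def smooth_curve(curve: NormalizedCurve, window_pct: float = 5.0) -> NormalizedCurve:
    """Centred circular moving average over *window_pct* of the stride."""
    if window_pct <= 0:
        return NormalizedCurve(values=curve.values.copy())
    period = curve.values[:-1]  # last sample repeats phase 0
    w = max(1, int(round(window_pct)))
    if w % 2 == 0:
        w += 1
    kernel = np.ones(w) / w
    padded = np.concatenate([period[-(w // 2):], period, period[: w // 2]])
    smoothed = np.convolve(padded, kernel, mode="valid")
    return NormalizedCurve(values=np.append(smoothed, smoothed[0]))


def _refine_extremum(period: np.ndarray, index: int, kind: str, half_window: int):
    """Sub-grid extremum location via a parabola on the unsmoothed curve."""
    n = len(period)
    offsets = np.arange(-half_window, half_window + 1)
    window = period[(index + offsets) % n]
    local = np.argmax(window) if kind == "max" else np.argmin(window)
    centre = (index + offsets[local]) % n
    y0, y1, y2 = (period[(centre + d) % n] for d in (-1, 0, 1))
    denom = y0 - 2 * y1 + y2
    if abs(denom) < 1e-12:
        return float(centre), float(y1)
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    value = y1 - 0.25 * (y0 - y2) * shift
    return float((centre + shift) % n), float(value)


def find_extrema(
    curve: NormalizedCurve,
    threshold: float,
    smooth_window_pct: float = 5.0,
) -> list[ExtremumEvent]:
    """Genuine direction changes of the circularly continued curve.

    Local extrema are detected on the smoothed curve with topographic
    prominence >= *threshold* (circular continuation via tiling), alternation
    is enforced by discarding the weaker of any same-kind neighbors, and
    phases/values are refined on the raw curve.  Phases are in [0, 100).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    smoothed = smooth_curve(curve, smooth_window_pct).values[:-1]
    period = curve.values[:-1]
    n = len(period)
    if np.ptp(smoothed) == 0:
        return []
    tiled = np.tile(smoothed, 3)
    found: list[tuple[int, str, float]] = []
    for kind, sign in (("max", 1.0), ("min", -1.0)):
        peaks, props = sps.find_peaks(
            sign * tiled, prominence=0.0, plateau_size=(1, None)
        )
        for p, prom in zip(peaks, props["prominences"]):
            if n <= p < 2 * n and prom >= threshold - 1e-12:
                found.append((p - n, kind, float(prom)))
    found.sort(key=lambda e: e[0])
    # enforce max/min alternation around the circle: drop the less extreme of
    # any same-kind adjacent pair (these arise when a sub-threshold reversal
    # between them was discarded)
    changed = True
    while changed and len(found) > 1:
        changed = False
        for i in range(len(found)):
            j = (i + 1) % len(found)
            ki, kj = found[i][1], found[j][1]
            if ki == kj:
                vi, vj = smoothed[found[i][0]], smoothed[found[j][0]]
                if (vi >= vj) == (ki == "max"):
                    found.pop(j)
                else:
                    found.pop(i)
                changed = True
                break
    half_window = max(1, int(round(smooth_window_pct)) // 2)
    events = []
    for index, kind, prom in found:
        phase, value = _refine_extremum(period, index, kind, half_window)
        events.append(
            ExtremumEvent(
                phase_pct=phase * 100.0 / n,
                value=value,
                kind=kind,
                prominence=prom,
            )
        )
    events.sort(key=lambda e: e.phase_pct)
    return events


def classify_phase(extrema: list[ExtremumEvent]) -> str:
    """Mono/bi/triphasic from the number of max-min pairs per cycle."""
    if not extrema:
        return "irregular"
    kinds = [e.kind for e in sorted(extrema, key=lambda e: e.phase_pct)]
    for a, b in zip(kinds, kinds[1:] + kinds[:1]):
        if len(kinds) > 1 and a == b:
            raise ClassificationError(f"extrema do not alternate: {kinds}")
    n_max = kinds.count("max")
    n_min = kinds.count("min")
    if n_max == n_min and 1 <= n_max <= 3:
        return PHASE_CLASSES[n_max - 1]
    return "irregular"


def _circular_distance(a: float, b: float, period: float = 100.0) -> float:
    d = abs(a - b) % period
    return min(d, period - d)


def too_statistics(
    per_stride_extrema: list[list[ExtremumEvent]],
    reference: list[ExtremumEvent] | None = None,
) -> list[tuple[str, float, float]]:
    """Circular mean +/- SD (% of stride) of each extremum across strides.

    Strides are matched to the reference extremum set (default: the set of
    the modal-count strides' first representative) by nearest circular phase
    within each kind; strides whose extremum count differs from the
    reference are flagged irregular and excluded with a log notice.
    """
    usable = [e for e in per_stride_extrema if e]
    if not usable:
        return []
    if reference is None:
        counts = [len(e) for e in usable]
        modal = max(set(counts), key=counts.count)
        reference = next(e for e in usable if len(e) == modal)
    matched_phases: list[list[float]] = [[] for _ in reference]
    n_excluded = 0
    for stride_extrema in per_stride_extrema:
        if len(stride_extrema) != len(reference):
            n_excluded += 1
            continue
        used: set[int] = set()
        ok = True
        assignment = []
        for ref in reference:
            candidates = [
                (i, _circular_distance(e.phase_pct, ref.phase_pct))
                for i, e in enumerate(stride_extrema)
                if e.kind == ref.kind and i not in used
            ]
            if not candidates:
                ok = False
                break
            best = min(candidates, key=lambda c: c[1])[0]
            used.add(best)
            assignment.append(stride_extrema[best].phase_pct)
        if not ok:
            n_excluded += 1
            continue
        for slot, phase in zip(matched_phases, assignment):
            slot.append(phase)
    if n_excluded:
        logger.info(
            "too_statistics: excluded %d/%d strides with irregular extremum counts",
            n_excluded,
            len(per_stride_extrema),
        )
    out = []
    for ref, phases in zip(reference, matched_phases):
        if not phases:
            continue
        arr = np.asarray(phases, dtype=float)
        # Bessel-style correction so the circular SD matches the sample SD
        # convention of printed "mean +/- SD" tables at small dispersion
        n = len(arr)
        bessel = np.sqrt(n / (n - 1)) if n > 1 else 0.0
        out.append(
            (
                ref.kind,
                float(circmean(arr, high=100.0, low=0.0)),
                float(circstd(arr, high=100.0, low=0.0)) * bessel,
            )
        )
    return out


def summarize_trial(
    relative_trajectories: dict[str, pd.DataFrame],
    events,
    config,
    gait: str = "",
) -> pd.DataFrame:
    """Full descriptor pipeline: segment, normalize, describe, aggregate.

    Returns one row per bone x DOF with mean +/- SD of the per-stride ROM
    (registered-amplitude estimator, see :func:`per_stride_roms`), the phase
    class of the across-stride mean curve, and circular TOO statistics for
    each extremum of that mean curve.
    """
    segments = segment_strides(events, config.reference_limb)
    target_duty = (
        config.target_duty
        if config.target_duty is not None
        else duty_factor(events, config.reference_limb)
    )
    rows = []
    for bone in BONES:
        if bone not in relative_trajectories:
            continue
        df = relative_trajectories[bone]
        time_s = df["time_s"].to_numpy()
        for dof in DOFS:
            threshold = (
                config.rotation_threshold_deg
                if dof in ROTATION_DOFS
                else config.translation_threshold_cm
            )
            values = df[dof].to_numpy()
            curves = [
                normalize_stride(time_s, values, seg, target_duty)
                for seg in segments
            ]
            roms = per_stride_roms(curves, threshold)
            mean = mean_curve(curves)
            extrema = find_extrema(mean, threshold, config.smooth_window_pct)
            try:
                phase_class = classify_phase(extrema)
            except ClassificationError:
                phase_class = "irregular"
            per_stride = [
                find_extrema(c, threshold, config.smooth_window_pct)
                for c in curves
            ]
            too = too_statistics(per_stride, reference=extrema or None)
            row = {
                "bone": bone,
                "dof": dof,
                "gait": gait,
                "rom_mean": float(roms.mean()),
                "rom_sd": float(roms.std(ddof=1)) if len(roms) > 1 else 0.0,
                "phase_class": phase_class,
                "n_extrema": len(extrema),
            }
            for k, (kind, mu, sd) in enumerate(too, start=1):
                row[f"extremum_{k}_kind"] = kind
                row[f"extremum_{k}_phase_mean"] = mu
                row[f"extremum_{k}_phase_sd"] = sd
            rows.append(row)
    return pd.DataFrame(rows)
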