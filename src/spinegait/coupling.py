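"""Inter-signal structure: cosine-Fourier spectra and rank correlations.

Two questions are asked of the recovered motion curves.  First, do two bones
oscillate inversely along the same axis?  This is read off the discrete
Fourier decomposition of the continuous (unwarped) recording, truncated to a
whole number of strides, with the frequency axis in cycles per stride: if
the signed cosine amplitudes at the shared dominant frequency have opposite
signs, the bones are counter-phased at stride frequency (the signal mean is
removed first, so the sign reflects phase at stride start).  Second, how
similar are curves across strides, bones, or animals?  That is quantified
with Spearman's rank correlation, with mild/moderate/strong labels at
configurable |rho| thresholds.

Phase-warped curves are never fed to the Fourier analysis: the duty-factor
warp is piecewise-linear in time and would alias stride-frequency content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stride import NormalizedCurve


class InsufficientSpanError(ValueError):
    """Signal shorter than the two full strides a spectrum needs."""


class SpectrumAlignmentError(ValueError):
    """Two spectra do not share a frequency grid."""


class UndefinedCorrelationError(ValueError):
    """Rank correlation undefined (zero variance in one argument's ranks)."""


#: Default |rho| thresholds for the mild / moderate / strong labels.
STRENGTH_MILD = 0.4
STRENGTH_STRONG = 0.7

#: A main-oscillation amplitude below this fraction of the larger of the two
#: compared main amplitudes is treated as noise (relation indeterminate).
NOISE_FLOOR_FRAC = 0.1


@dataclass(frozen=True)
class CosineSpectrum:
    """Signed cosine/sine decomposition with frequencies in cycles per stride."""

    frequencies: np.ndarray
    cosine_amplitudes: np.ndarray
    sine_amplitudes: np.ndarray
    main_index: int

    @property
    def main_frequency(self) -> float:
        return float(self.frequencies[self.main_index])

    @property
    def main_amplitude(self) -> float:
        return float(self.cosine_amplitudes[self.main_index])


@dataclass(frozen=True)
class CouplingReport:
    """Rank-correlation verdict for one signal pair."""

    pair: tuple[str, str]
    rho: float
    relation: str  # inverse | in_phase | uncoupled
    strength: str  # mild | moderate | strong


def cosine_spectrum(
    values: np.ndarray,
    frame_rate: float,
    stride_duration_s: float,
) -> CosineSpectrum:
    """Discrete Fourier decomposition of a recording, per-stride frequency axis.

    The signal is truncated to the largest whole number of strides (>= 2
    required), its mean removed, and decomposed as
    ``x(t) = sum_k a_k cos(2 pi f_k t) + b_k sin(2 pi f_k t)`` with ``f_k``
    in cycles per stride.  The main oscillation is the non-DC component with
    the largest |cosine amplitude|.
    """
    values = np.asarray(values, dtype=float)
    frames_per_stride = stride_duration_s * frame_rate
    n_strides = int(np.floor((len(values) / frames_per_stride) + 1e-9))
    if n_strides < 2:
        raise InsufficientSpanError(
            f"signal spans {len(values) / frames_per_stride:.2f} strides; need >= 2"
        )
    n = int(round(n_strides * frames_per_stride))
    x = values[:n] - values[:n].mean()
    spectrum = np.fft.rfft(x)
    a = 2.0 * spectrum.real / n
    b = -2.0 * spectrum.imag / n
    a[0] = spectrum.real[0] / n
    if n % 2 == 0:
        a[-1] = spectrum.real[-1] / n
        b[-1] = 0.0
    freqs = np.arange(len(a)) / n_strides  # cycles per stride
    main_index = int(np.argmax(np.abs(a[1:]))) + 1
    return CosineSpectrum(
        frequencies=freqs,
        cosine_amplitudes=a,
        sine_amplitudes=b,
        main_index=main_index,
    )


def inverse_oscillation(
    a: CosineSpectrum,
    b: CosineSpectrum,
    noise_floor_frac: float = NOISE_FLOOR_FRAC,
) -> str:
    """Relation of two same-axis oscillations at their shared dominant frequency.

    Returns ``inverse`` when the signed cosine amplitudes at the common
    dominant frequency have opposite signs, ``in_phase`` when they agree, and
    ``indeterminate`` when either amplitude falls below the noise floor
    (default 10 % of the larger of the two main amplitudes).  Symmetric in
    its arguments.
    """
    if len(a.frequencies) != len(b.frequencies) or not np.allclose(
        a.frequencies, b.frequencies
    ):
        raise SpectrumAlignmentError("spectra are on different frequency grids")
    if abs(a.main_amplitude) >= abs(b.main_amplitude):
        k = a.main_index
    else:
        k = b.main_index
    amp_a = a.cosine_amplitudes[k]
    amp_b = b.cosine_amplitudes[k]
    floor = noise_floor_frac * max(abs(a.main_amplitude), abs(b.main_amplitude))
    if min(abs(amp_a), abs(amp_b)) < floor:
        return "indeterminate"
    return "inverse" if np.sign(amp_a) != np.sign(amp_b) else "in_phase"


def rank_correlation(x, y) -> float:
    """Spearman's rho: Pearson correlation of average-ranked data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in ranks")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def strength_label(
    rho: float, mild: float = STRENGTH_MILD, strong: float = STRENGTH_STRONG
) -> str:
    a = abs(rho)
    if a > strong:
        return "strong"
    if a >= mild:
        return "moderate"
    return "mild"


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman rho across a set of curves, plus a scalar summary."""

    rho: pd.DataFrame
    strength: pd.DataFrame
    median_abs_rho: float


def stride_correlation_matrix(
    curves: dict[str, NormalizedCurve],
    mild: float = STRENGTH_MILD,
    strong: float = STRENGTH_STRONG,
) -> CorrelationMatrix:
    """Pairwise rho between labelled curves (strides, bones, or animals).

    The summary statistic is the median |rho| over distinct pairs -- a single
    number for "how common is the motion pattern" within the grouping.
    """
    labels = list(curves)
    n = len(labels)
    rho = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = rank_correlation(curves[labels[i]].values, curves[labels[j]].values)
            rho[i, j] = rho[j, i] = r
    rho_df = pd.DataFrame(rho, index=labels, columns=labels)
    strength_df = rho_df.map(lambda r: strength_label(r, mild, strong))
    off_diag = rho[np.triu_indices(n, k=1)]
    median_abs = float(np.median(np.abs(off_diag))) if off_diag.size else float("nan")
    return CorrelationMatrix(
        rho=rho_df, strength=strength_df, median_abs_rho=median_abs
    )


def coupling_test(
    a: NormalizedCurve,
    b: NormalizedCurve,
    pair: tuple[str, str] = ("a", "b"),
    mild: float = STRENGTH_MILD,
    strong: float = STRENGTH_STRONG,
) -> CouplingReport:
    """Rank-correlation coupling verdict between two mean curves.

    The canonical pairs for the lumbosacral junction are (L7 tx, L7 rz) --
    the craniocaudal-translation / sagittal-rotation coupling -- and the
    pelvis-vs-L7 same-axis rotations.
    """
    rho = rank_correlation(a.values, b.values)
    if abs(rho) < mild:
        relation = "uncoupled"
    else:
        relation = "inverse" if rho < 0 else "in_phase"
    return CouplingReport(
        pair=pair,
        rho=rho,
        relation=relation,
        strength=strength_label(rho, mild, strong),
    )
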