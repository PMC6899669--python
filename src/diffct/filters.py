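"""FBP filtering and geometric/redundancy correction weights.

The reconstruction filter is the diagonal matrix K of the pseudoinverse
factorisation x = A^T F^H K F p: detector rows are Fourier-transformed,
multiplied per frequency, and transformed back.  Two equivalent views are
provided: the ideal ramp |omega| defined directly in the frequency domain,
and the band-limited Ram-Lak kernel defined in the spatial domain (its DFT
approaches the ramp).  Divergent-beam reconstruction additionally needs the
cosine (geometric) pre-weight and, for short scans, Parker's sin^2
redundancy weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScanGeometry, fan_angles, half_fan_angle, short_scan_range
from .projectors import ProjectionStack

__all__ = [
    "FrequencyFilter",
    "WeightMap",
    "ramlak_kernel",
    "ramp_frequency_filter",
    "filter_projections",
    "cosine_weights",
    "parker_weights",
    "pad_length_for",
]


@dataclass(frozen=True)
class FrequencyFilter:
    """Per-frequency weights over the real-input half spectrum.

    ``weights[k]`` multiplies frequency ``k / (pad_length * detector_spacing)``
    cycles/mm; index 0 is DC, the last index is Nyquist.
    """

    weights: np.ndarray
    pad_length: int
    detector_spacing: float

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size != self.pad_length // 2 + 1:
            raise ValueError(f"need pad_length//2+1={self.pad_length // 2 + 1} "
                             f"weights, got {w.size}")
        if np.any(w < 0):
            raise ValueError("filter weights must be non-negative")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class WeightMap:
    """Multiplicative per-(view, pixel) weights, same shape as the stack."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "values", v)

    def apply(self, stack: ProjectionStack) -> ProjectionStack:
        if self.values.shape != stack.values.shape:
            raise ValueError(f"weight shape {self.values.shape} does not match "
                             f"stack shape {stack.values.shape}")
        return ProjectionStack(stack.values * self.values, stack.geometry)


def pad_length_for(n: int) -> int:
    """Smallest power of two >= 2n (zero padding against wrap-around)."""
    p = 1
    while p < 2 * n:
        p *= 2
    return p


def ramlak_kernel(n: int, tau: float) -> np.ndarray:
    """Band-limited spatial ramp kernel h(-m..m), n odd taps, spacing tau mm.

    h(0) = 1/(4 tau^2); h(k) = -1/(k^2 pi^2 tau^2) for odd k; 0 for even k.
    """
    if n % 2 == 0 or n < 1:
        raise ValueError(f"tap count must be odd and positive, got {n}")
    if tau <= 0:
        raise ValueError(f"detector spacing must be > 0, got {tau}")
    m = n // 2
    k = np.arange(-m, m + 1)
    h = np.zeros(n)
    h[m] = 1.0 / (4.0 * tau ** 2)
    odd = (k % 2) != 0
    h[odd] = -1.0 / (k[odd] ** 2 * np.pi ** 2 * tau ** 2)
    return h


def ramp_frequency_filter(n_pad: int, tau: float) -> FrequencyFilter:
    """Ideal ramp |omega| on the half spectrum, in cycles/mm.

    weights[k] = k / (n_pad * tau) rises linearly from 0 at DC to 1/(2 tau)
    at Nyquist; with this scale, backprojecting the filtered rows with the
    angular increment reconstructs absolute attenuation values.
    """
    if n_pad < 2:
        raise ValueError(f"n_pad must be >= 2, got {n_pad}")
    if tau <= 0:
        raise ValueError(f"detector spacing must be > 0, got {tau}")
    freqs = np.fft.rfftfreq(n_pad, d=tau)
    return FrequencyFilter(np.abs(freqs), n_pad, tau)


def filter_projections(stack: ProjectionStack, filt: FrequencyFilter
                       ) -> ProjectionStack:
    """Filter every detector row: zero-pad, FFT, multiply, inverse, crop."""
    n = stack.values.shape[-1]
    if filt.pad_length < n:
        raise ValueError(f"pad_length {filt.pad_length} shorter than detector "
                         f"row length {n}")
    spec = np.fft.rfft(stack.values, n=filt.pad_length, axis=-1)
    out = np.fft.irfft(spec * filt.weights, n=filt.pad_length, axis=-1)[..., :n]
    return ProjectionStack(out, stack.geometry)


def cosine_weights(geom: ScanGeometry) -> WeightMap:
    """Geometric pre-weight cos(gamma) for divergent beams.

    Fan: SDD/sqrt(SDD^2 + s^2) per detector coordinate s (equivalently
    SID/sqrt(SID^2 + s'^2) on the isocenter-rescaled detector); cone:
    SDD/sqrt(SDD^2 + u^2 + v^2) with (u, v) the physical offsets from the
    principal point.
    """
    if geom.beam == "parallel2d":
        raise ValueError("cosine weights are undefined for a parallel beam")
    sdd = geom.source_detector_distance
    if geom.beam == "fan2d":
        s = geom.detector.coordinates()
        w = sdd / np.sqrt(sdd ** 2 + s ** 2)
        return WeightMap(np.broadcast_to(w, geom.stack_shape).copy())
    u = geom.detector.coordinates(1)
    v = geom.detector.coordinates(0)
    w = sdd / np.sqrt(sdd ** 2 + u[None, :] ** 2 + v[:, None] ** 2)
    return WeightMap(np.broadcast_to(w, geom.stack_shape).copy())


def parker_weight(beta, gamma, gamma_max: float):
    """Parker's sin^2 short-scan weight at view angle ``beta`` (relative to
    the first view) and signed fan angle ``gamma``; broadcasts over arrays.

    In this detector convention (gamma signed along the +u axis, source
    rotating counterclockwise) a ray (beta, gamma) is measured a second time
    at (beta + pi - 2*gamma, -gamma), and the weights of the pair sum to one:

    * entering wedge, 0 <= b <= 2(gamma_max + gamma):
      w = sin^2( (pi/4) b / (gamma_max + gamma) )
    * interior: w = 1
    * exiting wedge, pi + 2*gamma <= b <= pi + 2*gamma_max:
      w = sin^2( (pi/4) (pi + 2*gamma_max - b) / (gamma_max - gamma) )
    """
    b = np.asarray(beta, dtype=float)
    g = np.asarray(gamma, dtype=float)
    b, g = np.broadcast_arrays(b, g)
    w = np.ones(b.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_in = np.sin((np.pi / 4.0) * b / (gamma_max + g)) ** 2
        w_out = np.sin((np.pi / 4.0) * (np.pi + 2.0 * gamma_max - b)
                       / (gamma_max - g)) ** 2
    w = np.where(b < 2.0 * (gamma_max + g), w_in, w)
    w = np.where(b > np.pi + 2.0 * g, w_out, w)
    w = np.where(b < 0, 0.0, w)
    w = np.where(b > np.pi + 2.0 * gamma_max, 0.0, w)
    return np.clip(np.nan_to_num(w, nan=0.0), 0.0, 1.0)


def parker_weights(geom: ScanGeometry) -> WeightMap:
    """Parker redundancy weights for every (view, pixel) of a short scan.

    Requires the angular range to equal pi + 2*gamma_max (within 1e-6); view
    angles are shifted so the first view is beta = 0.  See
    :func:`parker_weight` for the piecewise definition.
    """
    if geom.beam == "parallel2d":
        raise ValueError("Parker weights are undefined for a parallel beam")
    gmax = half_fan_angle(geom)
    required = short_scan_range(geom)
    if abs(geom.angular_range - required) > 1e-6:
        raise ValueError(f"Parker weights need the short-scan range "
                         f"pi + 2*gamma_max = {required:.6f} rad, "
                         f"got {geom.angular_range:.6f}")
    gamma = fan_angles(geom)                      # (n_u,)
    beta = geom.angles - geom.angles[0]           # (n_views,)
    w = parker_weight(beta[:, None], gamma[None, :], gmax)
    if geom.beam == "cone3d":
        w = np.broadcast_to(w[:, None, :], geom.stack_shape).copy()
    return WeightMap(w)
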