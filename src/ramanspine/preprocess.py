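"""Raw-counts to Raman-fingerprint processing chain.

Order of operations, applied to every acquisition:

1. dark-count subtraction (laser-off frame),
2. instrument-response correction (elementwise division by a calibrated
   positive sensitivity vector),
3. Savitzky-Golay smoothing (order 3, window 11, per accumulation),
4. averaging of the repeated accumulations at a site,
5. baseline removal with a bubble (rolling-circle) morphological estimator,
6. standard-normal-variate (SNV) normalization.

The result is a unitless fingerprint with zero mean and unit (population)
standard deviation, invariant to global intensity scale, to any smooth
additive background wider than the bubble width, and to any strictly
positive response that is supplied for correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .synth import InvalidArgumentError, RawAcquisition, SpectralAxis


class DegenerateInputError(ValueError):
    """Raised when an input is formally valid but carries no usable signal."""


@dataclass(frozen=True)
class InstrumentResponse:
    """Per-bin multiplicative detector sensitivity (strictly positive)."""

    response: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.response, dtype=float)
        if np.any(r <= 0) or not np.all(np.isfinite(r)):
            raise InvalidArgumentError("response entries must be finite and > 0")
        object.__setattr__(self, "response", r)

    @classmethod
    def flat(cls, n: int) -> "InstrumentResponse":
        return cls(response=np.ones(n))


@dataclass
class Fingerprint:
    """Fully preprocessed, SNV-normalized Raman spectrum with provenance."""

    intensities: np.ndarray
    axis: SpectralAxis
    provenance: list[tuple[str, dict]] = field(default_factory=list)
    tissue_label: str = "unknown"
    site_metadata: dict = field(default_factory=dict)


@dataclass
class PreprocessParams:
    sg_order: int = 3
    sg_window: int = 11
    min_bubble_width: float = 100.0   # cm^-1
    snv: bool = True


def subtract_dark(acq: RawAcquisition) -> np.ndarray:
    """Remove the laser-off dark frame from every accumulation."""
    if acq.dark.shape[0] != acq.counts.shape[1]:
        raise InvalidArgumentError("dark frame length mismatch")
    return acq.counts - acq.dark[None, :]


def correct_response(spectrum: np.ndarray, response: InstrumentResponse) -> np.ndarray:
    """Divide out the instrument sensitivity, elementwise."""
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape[-1] != response.response.shape[0]:
        raise InvalidArgumentError("spectrum/response length mismatch")
    return spectrum / response.response


def smooth_sg(spectrum: np.ndarray, order: int = 3, window: int = 11) -> np.ndarray:
    """Savitzky-Golay least-squares smoothing with mirror edge padding."""
    spectrum = np.asarray(spectrum, dtype=float)
    if window % 2 == 0:
        raise InvalidArgumentError("window must be odd")
    if order >= window:
        raise InvalidArgumentError("order must be below window")
    if spectrum.shape[-1] < window:
        raise InvalidArgumentError("spectrum shorter than window")
    return savgol_filter(spectrum, window_length=window, polyorder=order,
                         axis=-1, mode="mirror")


def average_accumulations(accumulations: np.ndarray) -> np.ndarray:
    """Arithmetic mean over the repeated exposures at one site."""
    accumulations = np.atleast_2d(np.asarray(accumulations, dtype=float))
    if accumulations.shape[0] < 1 or accumulations.size == 0:
        raise InvalidArgumentError("need at least one accumulation")
    return accumulations.mean(axis=0)


def _bubble_arcs(x: np.ndarray, y: np.ndarray, min_width: float) -> np.ndarray:
    """Upper envelope of the largest circles fitting under (x, y).

    Interval recursion: raise a circular arc spanning the interval until it
    touches the spectrum from below; the touch point splits the interval;
    recurse while the interval is wider than *min_width*.  Intervals
    touching a spectrum edge use half-bubbles anchored at the edge so the
    baseline does not curl down at the boundaries.  x and y are normalized
    to [0, 1] before the geometry is applied.
    """
    n = x.size
    xs = (x - x[0]) / (x[-1] - x[0])
    baseline = np.full(n, -np.inf)
    scale = x[-1] - x[0]
    stack: list[tuple[int, int, bool]] = [(0, n - 1, True)]
    while stack:
        lo, hi, first = stack.pop()
        if hi - lo < 2:
            continue
        width = (xs[hi] - xs[lo]) * scale
        if width < min_width and not first:
            continue
        c = 0.5 * (xs[lo] + xs[hi])
        radius = 0.5 * (xs[hi] - xs[lo])
        seg = xs[lo:hi + 1]
        arc = np.sqrt(np.maximum(radius ** 2 - (seg - c) ** 2, 0.0)) - radius
        lift = y[lo:hi + 1] - arc
        t = int(np.argmin(lift))
        baseline[lo:hi + 1] = np.maximum(baseline[lo:hi + 1], arc + lift[t])
        touch = lo + t
        # split at the touch point; an endpoint touch shrinks by one
        # sample so every child interval is strictly smaller
        if touch == lo:
            children = ((lo + 1, hi),)
        elif touch == hi:
            children = ((lo, hi - 1),)
        else:
            children = ((lo, touch), (touch, hi))
        for a, b in children:
            if b - a >= 2:
                stack.append((a, b, False))
    return np.minimum(baseline, y)


def remove_baseline(spectrum: np.ndarray, axis: SpectralAxis,
                    min_bubble_width: float = 100.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Split a spectrum into (raman, baseline) with a bubble estimator.

    The baseline is the upper envelope of circles grown under the spectrum
    (no structure narrower than *min_bubble_width*); the Raman part is
    defined as the exact residual, so ``raman + baseline`` reconstructs the
    input bit-for-bit and the baseline never exceeds the input.  The
    spectrum is mirror-padded by one bubble width so the envelope does not
    droop at the edges, and the envelope's touch-point scallops are evened
    out with a smoothing pass before the residual is taken.
    """
    y = np.asarray(spectrum, dtype=float)
    if not np.all(np.isfinite(y)):
        raise InvalidArgumentError("spectrum must be finite")
    if min_bubble_width <= axis.resolution:
        raise InvalidArgumentError("bubble width must exceed the axis resolution")
    yr = y.max() - y.min()
    if yr == 0:
        return np.zeros_like(y), y.copy()
    n = y.size
    pad = min(int(np.ceil(min_bubble_width / axis.resolution)), n - 2)
    yp = np.concatenate([y[pad:0:-1], y, y[-2:-pad - 2:-1]])
    xp = axis.wavenumbers[0] + axis.resolution * (np.arange(yp.size) - pad)
    yn = (yp - yp.min()) / yr
    env = _bubble_arcs(xp, yn, min_bubble_width)[pad:pad + n] * yr + yp.min()
    win = min(int(1.4 * min_bubble_width / axis.resolution) | 1, (n - 1) | 1)
    if win >= 5:
        env = smooth_sg(env, order=2, window=win)
    base = np.minimum(env, y)
    return y - base, base


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard-normal-variate scaling: zero mean, unit population sd."""
    spectrum = np.asarray(spectrum, dtype=float)
    sd = spectrum.std()     # population (divide-by-n) convention
    if sd == 0:
        raise DegenerateInputError("constant spectrum cannot be SNV-normalized")
    return (spectrum - spectrum.mean()) / sd


def preprocess_pipeline(acq: RawAcquisition,
                        response: InstrumentResponse | None = None,
                        params: PreprocessParams | None = None) -> Fingerprint:
    """Full six-step chain from raw acquisition to SNV fingerprint."""
    params = params or PreprocessParams()
    response = response or InstrumentResponse.flat(len(acq.axis))
    provenance: list[tuple[str, dict]] = []

    x = subtract_dark(acq)
    provenance.append(("subtract_dark", {}))
    x = correct_response(x, response)
    provenance.append(("correct_response", {}))
    x = smooth_sg(x, order=params.sg_order, window=params.sg_window)
    provenance.append(("smooth_sg", {"order": params.sg_order,
                                     "window": params.sg_window}))
    x = average_accumulations(x)
    provenance.append(("average_accumulations", {"n": acq.counts.shape[0]}))
    x, _ = remove_baseline(x, acq.axis, params.min_bubble_width)
    provenance.append(("remove_baseline",
                       {"min_bubble_width": params.min_bubble_width}))
    if params.snv:
        x = snv(x)
        provenance.append(("snv", {"denominator": "population"}))
    return Fingerprint(intensities=x, axis=acq.axis, provenance=provenance,
                       tissue_label=acq.tissue_label,
                       site_metadata=dict(acq.site_metadata))


def preprocess_dataset(acquisitions, response=None, params=None) -> list[Fingerprint]:
    """Apply the pipeline to every acquisition of a dataset."""
    return [preprocess_pipeline(a, response, params) for a in acquisitions]
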