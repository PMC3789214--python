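"""Shared signal representations and primitives.

Band-pass filtering, analytic envelope/phase, Welch spectral estimation and
frequency-band definitions (canonical and individualized around the alpha
peak frequency) used by every biomarker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps


class InvalidArgumentError(ValueError):
    """Raised when an operation's preconditions are violated."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [low_edge, high_edge) in Hz."""

    name: str
    low_edge: float
    high_edge: float

    def __post_init__(self) -> None:
        if not (0 < self.low_edge < self.high_edge):
            raise InvalidArgumentError(
                f"band {self.name}: need 0 < low ({self.low_edge}) < high "
                f"({self.high_edge})"
            )

    @property
    def width(self) -> float:
        return self.high_edge - self.low_edge

    @property
    def center(self) -> float:
        return 0.5 * (self.low_edge + self.high_edge)


#: Canonical bands. Edges are half-open [low, high) on the frequency grid so
#: the shared 13 Hz edge of alpha/beta is not double-counted.
DELTA = BandDefinition("delta", 1.0, 3.0)
THETA = BandDefinition("theta", 4.0, 7.0)
ALPHA = BandDefinition("alpha", 8.0, 13.0)
BETA = BandDefinition("beta", 13.0, 30.0)
GAMMA = BandDefinition("gamma", 30.0, 45.0)
BROADBAND = BandDefinition("broadband", 1.0, 45.0)

CANONICAL_BANDS = {b.name: b for b in (DELTA, THETA, ALPHA, BETA, GAMMA)}


@dataclass
class Recording:
    """A multichannel EEG recording: channel x sample matrix in microvolts."""

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    subject_id: str = ""
    visit: int = 1
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("data must be channel x sample (2-D)")
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("data contains non-finite samples")
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling_rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise InvalidArgumentError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class Spectrum:
    """One-sided power spectral density per channel (uV^2/Hz)."""

    frequencies: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs) or (n_freqs,)
    window_length: float = 4.0
    overlap: float = 0.5

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise InvalidArgumentError("frequencies must be strictly increasing")
        if np.any(self.power < 0):
            raise InvalidArgumentError("power must be non-negative")

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def band_mask(self, band: BandDefinition) -> np.ndarray:
        """Half-open [low, high) membership on the frequency grid."""
        return (self.frequencies >= band.low_edge) & (self.frequencies < band.high_edge)

    def band_power(self, band: BandDefinition) -> np.ndarray | float:
        """Integrated power in a band (rectangle rule on the PSD grid)."""
        m = self.band_mask(band)
        return np.sum(np.atleast_2d(self.power)[:, m], axis=1).squeeze() * self.df


@dataclass(frozen=True)
class IndividualBands:
    """Sub-bands anchored to the individual alpha peak frequency (APF)."""

    apf: float
    alpha1: BandDefinition
    alpha2: BandDefinition
    alpha3: BandDefinition
    beta_ind: BandDefinition
    fallback: bool = False


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def bandpass_filter(x: np.ndarray, band: BandDefinition, sampling_rate: float,
                    order: int | None = None) -> np.ndarray:
    """Zero-phase FIR band-pass filter.

    A linear-phase windowed-sinc FIR applied forward-backward
    (``filtfilt``) so phase-based biomarkers see no group delay.
    Transition widths scale with the band edges to keep >=20 dB
    attenuation one octave outside the band.
    """
    x = np.asarray(x, dtype=float)
    nyq = sampling_rate / 2.0
    if band.high_edge > nyq:
        raise InvalidArgumentError(
            f"band {band.name} upper edge {band.high_edge} exceeds Nyquist {nyq}"
        )
    trans = max(0.5, 0.15 * band.low_edge)
    if order is None:
        # Hamming-window FIR: transition width ~3.3 fs / numtaps
        order = int(3.3 * sampling_rate / trans) | 1
    if x.shape[-1] < 3 * order:
        raise InvalidArgumentError(
            f"signal length {x.shape[-1]} < 3x filter length {order}"
        )
    taps = sps.firwin(order, [max(band.low_edge - trans / 2, 0.05),
                              min(band.high_edge + trans / 2, nyq - 1e-6)],
                      pass_zero=False, fs=sampling_rate)
    # symmetric (linear-phase) FIR + centered convolution = zero phase
    return sps.fftconvolve(x, np.atleast_2d(taps) if x.ndim == 2 else taps,
                           mode="same", axes=-1)


def analytic_envelope_phase(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude envelope and unwrapped instantaneous phase (Hilbert).

    Returns ``(envelope, phase)``; for an all-zero input the phase is NaN
    (undefined).
    """
    x = np.asarray(x, dtype=float)
    analytic = sps.hilbert(x, axis=-1)
    env = np.abs(analytic)
    with np.errstate(invalid="ignore"):
        phase = np.unwrap(np.angle(analytic), axis=-1)
    zero = ~np.any(x != 0, axis=-1)
    if np.ndim(zero) == 0:
        if zero:
            phase = np.full_like(phase, np.nan)
    else:
        phase[zero] = np.nan
    return env, phase


def welch_psd(x: np.ndarray, sampling_rate: float, window_length: float = 4.0,
              overlap: float = 0.5) -> Spectrum:
    """Welch PSD with Hann windows.

    Defaults (4 s windows, 50% overlap) give 0.25 Hz resolution, enough to
    resolve ~1 Hz-wide spectral peaks. Satisfies Parseval: the integral of
    the PSD matches the variance of the (detrended) signal.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_length * sampling_rate))
    if x.shape[-1] < nperseg:
        raise InvalidArgumentError("window longer than signal")
    f, p = sps.welch(x, fs=sampling_rate, nperseg=nperseg,
                     noverlap=int(nperseg * overlap), detrend="constant",
                     axis=-1)
    return Spectrum(frequencies=f, power=p, window_length=window_length,
                    overlap=overlap)


def individualized_bands(apf: float) -> IndividualBands:
    """Sub-bands anchored on the individual alpha peak frequency.

    alpha1 = [APF-4, APF-2], alpha2 = [APF-2, APF], alpha3 = [APF, APF+2],
    individualized beta = [APF+2, 30]. Outside the sanity range 6-14 Hz the
    canonical 10 Hz anchor is used and the result flagged as a fallback.
    """
    fallback = not (6.0 <= apf <= 14.0)
    a = 10.0 if fallback else float(apf)
    return IndividualBands(
        apf=a,
        alpha1=BandDefinition("alpha1", a - 4, a - 2),
        alpha2=BandDefinition("alpha2", a - 2, a),
        alpha3=BandDefinition("alpha3", a, a + 2),
        beta_ind=BandDefinition("beta_ind", a + 2, 30.0),
        fallback=fallback,
    )
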