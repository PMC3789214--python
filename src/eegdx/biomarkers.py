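"""Per-channel EEG biomarker battery.

Implements every biomarker family of the battery: spectral band features
and power ratios, 1/f-corrected spectral peak fitting, Hjorth / Barlow /
Wackermann descriptors, detrended fluctuation analysis (DFA) and
multifractal DFA width of amplitude envelopes, oscillation-burst and
stable-phase-burst life-time statistics, envelope distribution statistics,
inter-channel envelope correlations, and windowed frequency-stability
measures. ``extract_battery`` assembles them into a biomarker x channel
tensor following a declarative registry.

Undefined values (too little data, absent peaks, missing channels) are
stored as NaN, never silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal as sps, stats

from .signal_core import (
    ALPHA, BETA, BROADBAND, CANONICAL_BANDS, DELTA, GAMMA, THETA,
    BandDefinition, InvalidArgumentError, Recording, Spectrum,
    analytic_envelope_phase, bandpass_filter, individualized_bands, welch_psd,
)

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SpectralPeak:
    """A Gaussian peak above the 1/f baseline. Width is FWHM in Hz."""

    center: float = np.nan
    width: float = np.nan
    corrected_power: float = np.nan
    uncorrected_power: float = np.nan
    present: bool = False
    second: "SpectralPeak | None" = None


@dataclass
class BurstStatistics:
    """95th-percentile duration/size of supra-threshold (or stable-phase)
    events; undefined when fewer than 20 events are observed."""

    duration_p95: float = np.nan
    size_p95: float = np.nan
    n_bursts: int = 0
    defined: bool = False


@dataclass
class BiomarkerTensor:
    """Biomarker x channel value matrix with a canonical name registry.

    Channel-independent biomarkers (Wackermann's three) are replicated
    across channels so the matrix stays rectangular.
    """

    values: np.ndarray
    biomarker_names: list[str]
    channel_labels: list[str]
    subject_id: str = ""
    visit: int = 1
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.biomarker_names), len(self.channel_labels)):
            raise InvalidArgumentError("tensor shape does not match names/labels")

    def row(self, name: str) -> np.ndarray:
        return self.values[self.biomarker_names.index(name)]


# ---------------------------------------------------------------------------
# Spectral features
# ---------------------------------------------------------------------------

def spectral_band_features(spectrum: Spectrum, band: BandDefinition,
                           broadband: BandDefinition = BROADBAND) -> dict:
    """Classical band descriptors of a single-channel PSD.

    relative_power is normalized by the 1-45 Hz broadband power;
    central_frequency is the power-weighted mean frequency in the band,
    bandwidth the power-weighted standard deviation around it, and
    spectral_edge the frequency below which 90% of in-band power lies.
    """
    p = np.atleast_2d(spectrum.power)[0] if np.ndim(spectrum.power) > 1 else spectrum.power
    m = spectrum.band_mask(band)
    f, pw = spectrum.frequencies[m], np.asarray(p)[m]
    total = pw.sum() * spectrum.df
    nan = dict.fromkeys(
        ["absolute_power", "relative_power", "central_frequency",
         "power_at_central_frequency", "bandwidth", "spectral_edge"], np.nan)
    if total <= 0 or f.size == 0:
        return nan
    bb = np.asarray(p)[spectrum.band_mask(broadband)].sum() * spectrum.df
    cf = float(np.sum(f * pw) / pw.sum())
    bw = float(np.sqrt(np.sum(pw * (f - cf) ** 2) / pw.sum()))
    cum = np.cumsum(pw)
    edge = float(f[np.searchsorted(cum, 0.9 * cum[-1])])
    return {
        "absolute_power": float(total),
        "relative_power": float(total / bb) if bb > 0 else np.nan,
        "central_frequency": cf,
        "power_at_central_frequency": float(pw[np.argmin(np.abs(f - cf))]),
        "bandwidth": bw,
        "spectral_edge": edge,
    }


def power_ratio(spectrum: Spectrum, band_a: BandDefinition,
                band_b: BandDefinition) -> float:
    """Band-power ratio a/b; NaN when the denominator power is zero."""
    p = np.atleast_2d(spectrum.power)[0] if np.ndim(spectrum.power) > 1 else spectrum.power
    p = np.asarray(p)
    pa = p[spectrum.band_mask(band_a)].sum() * spectrum.df
    pb = p[spectrum.band_mask(band_b)].sum() * spectrum.df
    return float(pa / pb) if pb > 0 else np.nan


_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # sigma -> FWHM


def _fit_baseline(freqs: np.ndarray, power: np.ndarray,
                  fit_range: tuple[float, float] = (1.0, 45.0),
                  exclude: tuple[float, float] = (6.0, 14.0),
                  n_iter: int = 3) -> tuple[np.ndarray, float]:
    """Robust log-log linear 1/f baseline.

    Ordinary least squares of log power on log frequency over ``fit_range``
    excluding the alpha region, then iteratively dropping points more than
    2 residual SDs *above* the line (oscillatory peaks bias upward only).
    Returns the baseline evaluated on the full grid (linear power units)
    and the residual SD in linear units around the fitted line.
    """
    sel = (freqs >= fit_range[0]) & (freqs <= fit_range[1]) & (power > 0)
    sel &= ~((freqs > exclude[0]) & (freqs < exclude[1]))
    lf, lp = np.log10(freqs[sel]), np.log10(power[sel])
    keep = np.ones(lf.size, dtype=bool)
    coef = np.polyfit(lf, lp, 1)
    for _ in range(n_iter):
        coef = np.polyfit(lf[keep], lp[keep], 1)
        resid = lp - np.polyval(coef, lf)
        keep = resid < 2.0 * resid[keep].std()
    with np.errstate(divide="ignore"):
        base = 10.0 ** np.polyval(coef, np.log10(np.maximum(freqs, 1e-12)))
    resid_lin = power[sel][keep] - base[sel][keep]
    return base, float(resid_lin.std())


def _fit_one_gaussian(f: np.ndarray, y: np.ndarray,
                      band: BandDefinition, df: float):
    """Least-squares Gaussian on baseline-corrected power; None on failure."""
    y0 = float(y.max())
    if y0 <= 0:
        return None
    c0 = float(f[np.argmax(y)])
    try:
        popt, _ = optimize.curve_fit(
            lambda x, a, c, s: a * np.exp(-0.5 * ((x - c) / s) ** 2),
            f, y, p0=[y0, c0, 2 * df],
            bounds=([0, band.low_edge, df / 2],
                    [10 * max(y0, 1e-12), band.high_edge, band.width]),
            maxfev=2000)
    except RuntimeError:
        return None
    return popt  # amplitude, center, sigma


def fit_spectral_peak(spectrum: Spectrum, search_band: BandDefinition,
                      baseline_fit_range: tuple[float, float] = (1.0, 45.0),
                      ) -> SpectralPeak:
    """Fit a 1/f baseline, then a Gaussian to the residual peak.

    The peak is declared present only when its fitted amplitude exceeds one
    standard deviation of the baseline residuals; a second Gaussian is
    attempted on the residual and reported when it independently passes the
    same criterion.
    """
    p = np.atleast_2d(spectrum.power)[0] if np.ndim(spectrum.power) > 1 else spectrum.power
    p = np.asarray(p, dtype=float)
    m = spectrum.band_mask(search_band)
    if m.sum() < 5:
        raise InvalidArgumentError("spectrum does not resolve the search band")
    base, resid_sd = _fit_baseline(spectrum.frequencies, p, baseline_fit_range)
    f, y = spectrum.frequencies[m], (p - base)[m]

    def build(popt) -> SpectralPeak | None:
        if popt is None:
            return None
        amp, center, sigma = popt
        if amp < resid_sd:
            return None
        return SpectralPeak(
            center=float(center), width=float(sigma * _FWHM),
            corrected_power=float(amp),
            uncorrected_power=float(amp + np.interp(center, spectrum.frequencies, base)),
            present=True)

    first = build(_fit_one_gaussian(f, y, search_band, spectrum.df))
    if first is None:
        return SpectralPeak(present=False)
    resid = y - first.corrected_power * np.exp(
        -0.5 * ((f - first.center) / (first.width / _FWHM)) ** 2)
    second = build(_fit_one_gaussian(f, resid, search_band, spectrum.df))
    if second is not None and abs(second.center - first.center) < first.width:
        second = None  # refit of the same peak, not an independent one
    first.second = second
    return first


def alpha_theta_transition(spectrum: Spectrum, apf: float) -> tuple[float, bool]:
    """Frequency of minimum power between theta and the alpha peak.

    Searches [4 Hz, APF]; returns ``(frequency, at_boundary)`` where the
    flag marks a degenerate monotone spectrum. NaN when APF is undefined.
    """
    if not np.isfinite(apf):
        return np.nan, True
    p = np.atleast_2d(spectrum.power)[0] if np.ndim(spectrum.power) > 1 else spectrum.power
    m = (spectrum.frequencies >= 4.0) & (spectrum.frequencies <= apf)
    if m.sum() < 3:
        return np.nan, True
    f, pw = spectrum.frequencies[m], np.asarray(p)[m]
    i = int(np.argmin(pw))
    return float(f[i]), i in (0, pw.size - 1)


# ---------------------------------------------------------------------------
# Time-domain descriptors
# ---------------------------------------------------------------------------

def hjorth_parameters(x: np.ndarray, sampling_rate: float) -> dict:
    """Hjorth activity (uV^2), mobility and complexity.

    Mobility is reported in rad/s: the discrete first-difference estimate
    of sqrt(var(x')/var(x)) multiplied by the sampling rate. For a pure
    sinusoid of frequency f, mobility = 2*pi*f and complexity = 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InvalidArgumentError("need at least 3 samples")
    activity = float(np.var(x))
    if activity == 0:
        return {"activity": 0.0, "mobility": np.nan, "complexity": np.nan}
    d1 = np.diff(x) * sampling_rate
    d2 = np.diff(x, 2) * sampling_rate ** 2
    mob = np.sqrt(np.var(d1) / activity)
    mob_d = np.sqrt(np.var(d2) / np.var(d1))
    return {"activity": activity, "mobility": float(mob),
            "complexity": float(mob_d / mob)}


def barlow_parameters(x: np.ndarray, sampling_rate: float) -> dict:
    """Barlow's mean amplitude, mean frequency and spectral purity.

    Ratio-of-derivatives formulation on spectral moments m0 = var(x),
    m2 = var(x'), m4 = var(x''): mean_frequency = sqrt(m2/m0)/2pi (Hz),
    spectral_purity = m2/sqrt(m0*m4) in [0, 1] (1 for a pure sinusoid).
    mean_amplitude is the time-averaged rectified signal, i.e. 2A/pi for a
    sinusoid of amplitude A.
    """
    x = np.asarray(x, dtype=float)
    m0 = np.var(x)
    out = {"mean_amplitude": float(np.mean(np.abs(x))),
           "mean_frequency": np.nan, "spectral_purity": np.nan}
    if m0 == 0:
        return out
    m2 = np.var(np.diff(x) * sampling_rate)
    m4 = np.var(np.diff(x, 2) * sampling_rate ** 2)
    out["mean_frequency"] = float(np.sqrt(m2 / m0) / (2 * np.pi))
    if m4 > 0:
        out["spectral_purity"] = float(m2 / np.sqrt(m0 * m4))
    return out


def wackermann_parameters(recording: Recording,
                          band: BandDefinition = BROADBAND) -> dict:
    """Wackermann's global descriptors of the multichannel field.

    Average-referenced, band-limited data: global field strength Sigma
    (RMS over channels and time), global frequency Phi (ratio-of-
    derivatives, Hz) and spatial complexity Omega (exponential entropy of
    the normalized channel-covariance eigenvalues, in [1, n_channels]).
    Because the field is average-referenced first, the covariance has rank
    at most n_channels - 1, so Omega approaches n - 1 (not n) for fully
    independent channels.
    """
    if recording.n_channels < 2:
        return {"global_field_strength": np.nan, "global_frequency": np.nan,
                "spatial_complexity": np.nan}
    v = bandpass_filter(recording.data, band, recording.sampling_rate)
    v = v - v.mean(axis=0, keepdims=True)
    sigma = float(np.sqrt(np.mean(v ** 2)))
    d = np.diff(v, axis=1) * recording.sampling_rate
    phi = float(np.sqrt(np.sum(np.var(d, axis=1)) / np.sum(np.var(v, axis=1)))
                / (2 * np.pi))
    cov = np.cov(v)
    lam = np.linalg.eigvalsh(cov)
    lam = np.clip(lam, 0, None)
    lam = lam / lam.sum()
    ent = -np.sum(lam[lam > 0] * np.log(lam[lam > 0]))
    return {"global_field_strength": sigma, "global_frequency": phi,
            "spatial_complexity": float(np.exp(ent))}


# ---------------------------------------------------------------------------
# Fluctuation analysis (DFA / MFDFA)
# ---------------------------------------------------------------------------

def _window_resid_var(profile: np.ndarray, size: int, overlap: float) -> np.ndarray:
    """Variance of linear-detrend residuals in sliding windows of ``size``."""
    n = profile.size
    step = max(int(size * (1 - overlap)), 1)
    starts = np.arange(0, n - size + 1, step)
    idx = starts[:, None] + np.arange(size)[None, :]
    y = profile[idx]
    t = np.arange(size, dtype=float)
    t = t - t.mean()
    var_t = np.mean(t ** 2)
    ym = y.mean(axis=1, keepdims=True)
    cov = (y - ym) @ t / size
    var_y = np.mean((y - ym) ** 2, axis=1)
    return np.maximum(var_y - cov ** 2 / var_t, 1e-300)


def _dfa_profile_sizes(x: np.ndarray, sampling_rate: float,
                       window_range: tuple[float, float] | None,
                       n_sizes: int = 12) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    if window_range is None:
        window_range = (1.0, x.size / sampling_rate / 10.0)
    s_min, s_max = window_range
    if x.size < 4 * s_max * sampling_rate:
        raise InvalidArgumentError("signal too short for the DFA window range")
    profile = np.cumsum(x - x.mean())
    sizes = np.unique(np.geomspace(s_min * sampling_rate, s_max * sampling_rate,
                                   n_sizes).astype(int))
    sizes = sizes[sizes >= 4]
    return profile, sizes


def dfa_exponent(x: np.ndarray, sampling_rate: float,
                 window_range: tuple[float, float] | None = None,
                 overlap: float = 0.5) -> float:
    """Detrended fluctuation analysis exponent.

    Cumulative profile, linear detrending in logarithmically spaced windows
    (default 1 s to one-tenth of the signal length, 50% overlap),
    least-squares slope of log F vs log window size. White noise gives 0.5,
    a random walk 1.5; >0.5 indicates persistent long-range correlations.
    """
    profile, sizes = _dfa_profile_sizes(x, sampling_rate, window_range)
    logf = [0.5 * np.log10(np.mean(_window_resid_var(profile, s, overlap)))
            for s in sizes]
    return float(np.polyfit(np.log10(sizes), logf, 1)[0])


DEFAULT_Q = tuple(q for q in range(-5, 6) if q != 0)


def mfdfa_width(x: np.ndarray, sampling_rate: float,
                q_range=DEFAULT_Q,
                window_range: tuple[float, float] | None = None,
                overlap: float = 0.5) -> float:
    """Multifractal DFA spectral width: max_q h(q) - min_q h(q).

    Generalized fluctuation functions F_q(s) = (mean_w F_w^q)^(1/q) with
    the q=0 limit by logarithmic averaging; h(q) is the slope of
    log F_q(s). A monofractal signal has width ~0.
    """
    profile, sizes = _dfa_profile_sizes(x, sampling_rate, window_range)
    if np.ptp(x) == 0:
        return np.nan
    qs = np.asarray(q_range, dtype=float)
    log_fq = np.empty((sizes.size, qs.size))
    for i, s in enumerate(sizes):
        rv = _window_resid_var(profile, s, overlap)  # F_w^2 per window
        for j, q in enumerate(qs):
            if q == 0:
                log_fq[i, j] = 0.5 * np.mean(np.log10(rv))
            else:
                log_fq[i, j] = np.log10(np.mean(rv ** (q / 2.0))) / q
    ls = np.log10(sizes)
    h = np.polyfit(ls, log_fq, 1)[0]
    return float(h.max() - h.min())


# ---------------------------------------------------------------------------
# Burst life-time statistics
# ---------------------------------------------------------------------------

def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of maximal True runs."""
    d = np.diff(mask.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts, stops))


def oscillation_bursts(envelope: np.ndarray, sampling_rate: float,
                       threshold: float | None = None) -> BurstStatistics:
    """95th-percentile duration and size of supra-threshold envelope bursts.

    A burst is a maximal run of samples where the envelope exceeds the
    threshold (default: the envelope median); its size is the integrated
    envelope area above the threshold. Undefined with fewer than 20 bursts.
    """
    envelope = np.asarray(envelope, dtype=float)
    thr = float(np.median(envelope)) if threshold is None else threshold
    mask = envelope > thr
    if not mask.any() or mask.all():
        return BurstStatistics()
    runs = _runs_above(mask)
    if len(runs) < 20:
        return BurstStatistics(n_bursts=len(runs))
    durations = np.array([(b - a) / sampling_rate for a, b in runs])
    sizes = np.array([np.sum(envelope[a:b] - thr) / sampling_rate for a, b in runs])
    return BurstStatistics(duration_p95=float(np.percentile(durations, 95)),
                           size_p95=float(np.percentile(sizes, 95)),
                           n_bursts=len(runs), defined=True)


def phase_bursts(phase: np.ndarray, sampling_rate: float) -> BurstStatistics:
    """Stable-phase bursts: periods between phase slips.

    A slip sample is a negative instantaneous-frequency excursion
    (discrete phase derivative < 0); consecutive slip samples merge into
    one slip event. Duration is the stable period length in seconds; size
    is the phase advance (rad) over the period. With no slips the whole
    signal is one flagged period.
    """
    phase = np.asarray(phase, dtype=float)
    if not np.all(np.isfinite(phase)):
        return BurstStatistics()
    dphi = np.diff(phase)
    slip = dphi < 0
    if not slip.any():
        return BurstStatistics(duration_p95=phase.size / sampling_rate,
                               size_p95=float(phase[-1] - phase[0]), n_bursts=1)
    stable_runs = _runs_above(~slip)
    if len(stable_runs) < 20:
        return BurstStatistics(n_bursts=len(stable_runs))
    durations = np.array([(b - a) / sampling_rate for a, b in stable_runs])
    sizes = np.array([phase[b] - phase[a] for a, b in stable_runs])
    return BurstStatistics(duration_p95=float(np.percentile(durations, 95)),
                           size_p95=float(np.percentile(sizes, 95)),
                           n_bursts=len(stable_runs), defined=True)


# ---------------------------------------------------------------------------
# Envelope statistics & correlations
# ---------------------------------------------------------------------------

def envelope_statistics(envelope: np.ndarray) -> dict:
    """Moments and order statistics of the envelope sample distribution.

    Kurtosis is the excess kurtosis (Gaussian -> 0); range is max - min.
    """
    e = np.asarray(envelope, dtype=float)
    if e.size < 100:
        raise InvalidArgumentError("need at least 100 envelope samples")
    degenerate = np.ptp(e) == 0
    return {
        "kurtosis": np.nan if degenerate else float(stats.kurtosis(e, fisher=True)),
        "skewness": np.nan if degenerate else float(stats.skew(e)),
        "interquartile_range": float(np.subtract(*np.percentile(e, [75, 25]))),
        "median": float(np.median(e)),
        "range": float(np.ptp(e)),
        "variance": float(np.var(e)),
    }


def envelope_correlation(envelopes: np.ndarray) -> np.ndarray:
    """Spearman correlation matrix between channel amplitude envelopes."""
    if envelopes.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 channels")
    ranks = stats.rankdata(envelopes, axis=1)
    return np.corrcoef(ranks)


# ---------------------------------------------------------------------------
# Frequency stability
# ---------------------------------------------------------------------------

def frequency_stability(x: np.ndarray, sampling_rate: float,
                        band: BandDefinition, window_length: float = 5.0,
                        n_wavelet_freqs: int = 16) -> dict:
    """Windowed frequency-stability measures of a band-limited signal.

    The signal is split into non-overlapping windows (default 5 s). Per
    window: the power-weighted central frequency of the periodogram inside
    the band, the band frequency with maximal Morlet-wavelet power, the
    number of oscillation cycle peaks, and the positive instantaneous
    (wrapped) phase values. Returns dispersion statistics across windows
    (SD and IQR of the two frequency tracks) and {median, IQR} of the
    phase-positive and cycles-per-window distributions.
    """
    x = np.asarray(x, dtype=float)
    w = int(round(window_length * sampling_rate))
    n_win = x.size // w
    keys = ["sd_central_freq", "iqr_central_freq", "sd_max_wavelet_freq",
            "iqr_max_wavelet_freq", "phase_positive_median",
            "phase_positive_iqr", "cycles_per_window_median",
            "cycles_per_window_iqr"]
    if n_win < 10:
        return dict.fromkeys(keys, np.nan)

    # Morlet scalogram on a coarse in-band grid, built in the frequency
    # domain (one FFT of the signal; per scale a Gaussian-windowed inverse)
    freqs = np.linspace(band.low_edge + 0.25, band.high_edge - 0.25,
                        n_wavelet_freqs)
    n_fft = int(2 ** np.ceil(np.log2(x.size)))
    X = np.fft.fft(x, n_fft)
    fgrid = np.fft.fftfreq(n_fft, d=1.0 / sampling_rate)
    win_power = np.empty((n_wavelet_freqs, n_win))
    for i, f0 in enumerate(freqs):
        sd_t = 7.0 / (2 * np.pi * f0)  # 7-cycle Morlet, seconds
        H = np.exp(-2 * np.pi ** 2 * sd_t ** 2 * (fgrid - f0) ** 2)
        H[fgrid < 0] = 0.0  # analytic
        tf = np.abs(np.fft.ifft(X * H)[:x.size]) ** 2
        win_power[i] = tf[:n_win * w].reshape(n_win, w).mean(axis=1)
    maxw = freqs[np.argmax(win_power, axis=0)]

    # batched periodogram per window
    segs = x[:n_win * w].reshape(n_win, w)
    spec = np.abs(np.fft.rfft(segs * np.hanning(w), axis=1)) ** 2
    f = np.fft.rfftfreq(w, d=1.0 / sampling_rate)
    m = (f >= band.low_edge) & (f < band.high_edge)
    psum = spec[:, m].sum(axis=1)
    with np.errstate(invalid="ignore"):
        cfs = np.where(psum > 0, spec[:, m] @ f[m] / psum, np.nan)

    wrapped = np.angle(sps.hilbert(x))
    cycles, phases = [], []
    for k in range(n_win):
        peaks, _ = sps.find_peaks(segs[k])
        cycles.append(peaks.size)
        ph = wrapped[k * w:(k + 1) * w]
        phases.append(np.median(ph[ph > 0]) if np.any(ph > 0) else np.nan)
    phases, cycles = np.asarray(phases), np.asarray(cycles, dtype=float)
    iqr = lambda v: float(np.subtract(*np.nanpercentile(v, [75, 25])))
    return {
        "sd_central_freq": float(np.nanstd(cfs)),
        "iqr_central_freq": iqr(cfs),
        "sd_max_wavelet_freq": float(np.nanstd(maxw)),
        "iqr_max_wavelet_freq": iqr(maxw),
        "phase_positive_median": float(np.nanmedian(phases)),
        "phase_positive_iqr": iqr(phases),
        "cycles_per_window_median": float(np.nanmedian(cycles)),
        "cycles_per_window_iqr": iqr(cycles),
    }


# ---------------------------------------------------------------------------
# Registry and battery extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiomarkerDef:
    """One registry row: a named biomarker and how to compute it."""

    name: str
    family: str  # envelope | spectral | ratio | freqstab | broadband
    band: str | None = None
    component: str | None = None


_ENVELOPE_COMPONENTS = [
    "env_corr_cz", "env_kurtosis", "env_skewness", "env_iqr", "env_median",
    "env_range", "env_variance", "dfa", "mfdfa_width",
    "burst_duration_p95", "burst_size_p95",
    "phase_burst_duration_p95", "phase_burst_size_p95",
]
_SPECTRAL_COMPONENTS = [
    "absolute_power", "relative_power", "central_frequency",
    "power_at_central_frequency", "bandwidth", "spectral_edge",
]
_SPECTRAL_BANDS = ["delta", "theta", "alpha", "beta", "gamma",
                   "alpha1", "alpha2", "alpha3", "beta_ind"]
_RATIOS = [("theta", "alpha"), ("gamma", "delta"), ("delta", "alpha"),
           ("theta", "beta"), ("alpha", "beta"), ("alpha1", "alpha"),
           ("alpha1", "beta"), ("alpha3", "alpha2")]
_FREQSTAB_COMPONENTS = ["sd_central_freq", "iqr_central_freq",
                        "sd_max_wavelet_freq", "iqr_max_wavelet_freq"]
_BROADBAND_COMPONENTS = [
    "hjorth_activity", "hjorth_mobility", "hjorth_complexity",
    "barlow_amplitude", "barlow_frequency", "barlow_spectral_purity",
    "wackermann_gfs", "wackermann_gf", "wackermann_omega",
    "alpha_peak_freq", "alpha_peak_width", "alpha_peak_corrected_power",
    "alpha_peak_uncorrected_power",
    "alpha2_peak_freq", "alpha2_peak_width", "alpha2_peak_corrected_power",
    "beta_peak_freq", "beta_peak_width", "beta_peak_corrected_power",
    "beta_peak_uncorrected_power",
    "beta2_peak_freq", "beta2_peak_width", "beta2_peak_corrected_power",
    "alpha_theta_transition",
    "phase_positive_median", "phase_positive_iqr",
    "cycles_per_window_median", "cycles_per_window_iqr",
]


def default_registry() -> list[BiomarkerDef]:
    """The default 175-row biomarker registry.

    13 envelope-family markers for each of the 5 classical bands (65), 6
    spectral markers for the 5 classical + 4 individualized bands (54), 8
    pairwise band power ratios, 4 windowed frequency-stability dispersion
    markers per classical band (20), and 28 broadband markers.
    """
    rows: list[BiomarkerDef] = []
    for band in CANONICAL_BANDS:
        for comp in _ENVELOPE_COMPONENTS:
            rows.append(BiomarkerDef(f"{band}_{comp}", "envelope", band, comp))
    for band in _SPECTRAL_BANDS:
        for comp in _SPECTRAL_COMPONENTS:
            rows.append(BiomarkerDef(f"{band}_{comp}", "spectral", band, comp))
    for a, b in _RATIOS:
        rows.append(BiomarkerDef(f"power_ratio_{a}_{b}", "ratio", a, b))
    for band in CANONICAL_BANDS:
        for comp in _FREQSTAB_COMPONENTS:
            rows.append(BiomarkerDef(f"{band}_freqstab_{comp}", "freqstab",
                                     band, comp))
    for comp in _BROADBAND_COMPONENTS:
        rows.append(BiomarkerDef(comp, "broadband", "broadband", comp))
    return rows


def fast_registry() -> list[BiomarkerDef]:
    """A reduced registry for quick cohort-scale runs: alpha/beta envelope
    markers, the spectral sets of alpha and beta, the theta/alpha ratio and
    the beta peak parameters."""
    keep_env = ["env_corr_cz", "env_range", "env_variance", "dfa"]
    rows = [BiomarkerDef(f"{b}_{c}", "envelope", b, c)
            for b in ("alpha", "beta") for c in keep_env]
    rows += [BiomarkerDef(f"{b}_{c}", "spectral", b, c)
             for b in ("alpha", "beta")
             for c in ("relative_power", "central_frequency", "bandwidth")]
    rows.append(BiomarkerDef("power_ratio_theta_alpha", "ratio", "theta", "alpha"))
    rows += [BiomarkerDef(c, "broadband", "broadband", c)
             for c in ("beta_peak_freq", "beta_peak_width",
                       "beta_peak_corrected_power", "hjorth_mobility")]
    return rows


def registry_to_frame(registry: list[BiomarkerDef]):
    import pandas as pd
    return pd.DataFrame([r.__dict__ for r in registry])


def save_registry(registry: list[BiomarkerDef], path) -> None:
    """Write a registry as a YAML list of {name, family, band, component}."""
    import yaml
    with open(path, "w") as f:
        yaml.safe_dump([r.__dict__ for r in registry], f, sort_keys=False)


def load_registry(path) -> list[BiomarkerDef]:
    import yaml
    with open(path) as f:
        rows = yaml.safe_load(f)
    try:
        return [BiomarkerDef(**row) for row in rows]
    except TypeError as e:
        raise InvalidArgumentError(f"malformed registry config: {e}") from e


ALPHA_SEARCH = BandDefinition("alpha_search", 6.0, 14.0)
BETA_SEARCH = BandDefinition("beta_search", 13.0, 30.0)


def _channel_spectrum(spectrum: Spectrum, ch: int) -> Spectrum:
    return Spectrum(spectrum.frequencies, np.atleast_2d(spectrum.power)[ch],
                    spectrum.window_length, spectrum.overlap)


def extract_battery(recording: Recording,
                    registry: list[BiomarkerDef] | None = None,
                    welch_window: float = 4.0,
                    dfa_window_range: tuple[float, float] | None = None,
                    ) -> BiomarkerTensor:
    """Compute the full biomarker battery of a recording.

    Returns a biomarker x channel tensor with one row per registry entry.
    Individualized bands are anchored per channel on that channel's fitted
    alpha peak (falling back to a 10 Hz anchor when no peak is present).
    Deterministic given the recording and registry.
    """
    registry = default_registry() if registry is None else registry
    fs = recording.sampling_rate
    n_ch = recording.n_channels
    values = np.full((len(registry), n_ch), np.nan)
    row_of = {r.name: i for i, r in enumerate(registry)}
    families = {r.family for r in registry}

    def put(name: str, ch: int | slice, val) -> None:
        if name in row_of:
            values[row_of[name], ch] = val

    psd = welch_psd(recording.data, fs, window_length=welch_window)

    # per-channel peak fits (alpha and beta, shared by several families)
    need_peaks = bool(families & {"spectral", "ratio", "broadband"})
    alpha_peaks: list[SpectralPeak] = []
    beta_peaks: list[SpectralPeak] = []
    if need_peaks:
        for ch in range(n_ch):
            sp = _channel_spectrum(psd, ch)
            alpha_peaks.append(fit_spectral_peak(sp, ALPHA_SEARCH))
            beta_peaks.append(fit_spectral_peak(sp, BETA_SEARCH))

    def channel_bands(ch: int) -> dict:
        apf = alpha_peaks[ch].center if alpha_peaks[ch].present else np.nan
        ib = individualized_bands(apf if np.isfinite(apf) else 99.0)
        return {**CANONICAL_BANDS, "alpha1": ib.alpha1, "alpha2": ib.alpha2,
                "alpha3": ib.alpha3, "beta_ind": ib.beta_ind}

    # ---- envelope family ------------------------------------------------
    env_bands = sorted({r.band for r in registry if r.family == "envelope"})
    for band_name in env_bands:
        band = CANONICAL_BANDS[band_name]
        filt = bandpass_filter(recording.data, band, fs)
        env, phase = analytic_envelope_phase(filt)
        if "env_corr_cz" in {r.component for r in registry
                             if r.family == "envelope" and r.band == band_name}:
            if "Cz" in recording.channel_labels and n_ch >= 2:
                cz = recording.channel_labels.index("Cz")
                corr = envelope_correlation(env)[:, cz]
                put(f"{band_name}_env_corr_cz", slice(None), corr)
        for ch in range(n_ch):
            e = env[ch]
            es = envelope_statistics(e)
            put(f"{band_name}_env_kurtosis", ch, es["kurtosis"])
            put(f"{band_name}_env_skewness", ch, es["skewness"])
            put(f"{band_name}_env_iqr", ch, es["interquartile_range"])
            put(f"{band_name}_env_median", ch, es["median"])
            put(f"{band_name}_env_range", ch, es["range"])
            put(f"{band_name}_env_variance", ch, es["variance"])
            try:
                put(f"{band_name}_dfa", ch, dfa_exponent(e, fs, dfa_window_range))
                put(f"{band_name}_mfdfa_width", ch,
                    mfdfa_width(e, fs, window_range=dfa_window_range))
            except InvalidArgumentError:
                pass
            ob = oscillation_bursts(e, fs)
            if ob.defined:
                put(f"{band_name}_burst_duration_p95", ch, ob.duration_p95)
                put(f"{band_name}_burst_size_p95", ch, ob.size_p95)
            pb = phase_bursts(phase[ch], fs)
            if pb.defined:
                put(f"{band_name}_phase_burst_duration_p95", ch, pb.duration_p95)
                put(f"{band_name}_phase_burst_size_p95", ch, pb.size_p95)

    # ---- spectral family and ratios -------------------------------------
    if families & {"spectral", "ratio"}:
        for ch in range(n_ch):
            sp = _channel_spectrum(psd, ch)
            bands = channel_bands(ch)
            for r in registry:
                if r.family == "spectral":
                    feats = spectral_band_features(sp, bands[r.band])
                    put(r.name, ch, feats[r.component])
                elif r.family == "ratio":
                    put(r.name, ch, power_ratio(sp, bands[r.band],
                                                bands[r.component]))

    # ---- frequency stability --------------------------------------------
    fs_bands = sorted({r.band for r in registry if r.family == "freqstab"})
    for band_name in fs_bands:
        band = CANONICAL_BANDS[band_name]
        filt = bandpass_filter(recording.data, band, fs)
        for ch in range(n_ch):
            st = frequency_stability(filt[ch], fs, band, n_wavelet_freqs=8)
            for comp in _FREQSTAB_COMPONENTS:
                put(f"{band_name}_freqstab_{comp}", ch, st[comp])

    # ---- broadband family ------------------------------------------------
    if "broadband" in families:
        wanted = {r.component for r in registry if r.family == "broadband"}
        bb = bandpass_filter(recording.data, BROADBAND, fs)
        if wanted & {"wackermann_gfs", "wackermann_gf", "wackermann_omega"} \
                and n_ch >= 2:
            wk = wackermann_parameters(recording)
            put("wackermann_gfs", slice(None), wk["global_field_strength"])
            put("wackermann_gf", slice(None), wk["global_frequency"])
            put("wackermann_omega", slice(None), wk["spatial_complexity"])
        for ch in range(n_ch):
            if wanted & {"hjorth_activity", "hjorth_mobility", "hjorth_complexity"}:
                hj = hjorth_parameters(bb[ch], fs)
                put("hjorth_activity", ch, hj["activity"])
                put("hjorth_mobility", ch, hj["mobility"])
                put("hjorth_complexity", ch, hj["complexity"])
            if wanted & {"barlow_amplitude", "barlow_frequency",
                         "barlow_spectral_purity"}:
                bl = barlow_parameters(bb[ch], fs)
                put("barlow_amplitude", ch, bl["mean_amplitude"])
                put("barlow_frequency", ch, bl["mean_frequency"])
                put("barlow_spectral_purity", ch, bl["spectral_purity"])
            for prefix, peak in (("alpha", alpha_peaks[ch] if need_peaks else None),
                                 ("beta", beta_peaks[ch] if need_peaks else None)):
                if peak is None or not peak.present:
                    continue
                put(f"{prefix}_peak_freq", ch, peak.center)
                put(f"{prefix}_peak_width", ch, peak.width)
                put(f"{prefix}_peak_corrected_power", ch, peak.corrected_power)
                put(f"{prefix}_peak_uncorrected_power", ch, peak.uncorrected_power)
                if peak.second is not None:
                    tag = "alpha2" if prefix == "alpha" else "beta2"
                    put(f"{tag}_peak_freq", ch, peak.second.center)
                    put(f"{tag}_peak_width", ch, peak.second.width)
                    put(f"{tag}_peak_corrected_power", ch,
                        peak.second.corrected_power)
            if "alpha_theta_transition" in wanted and need_peaks:
                apf = alpha_peaks[ch].center if alpha_peaks[ch].present else np.nan
                trans, at_bound = alpha_theta_transition(
                    _channel_spectrum(psd, ch), apf)
                if not at_bound:
                    put("alpha_theta_transition", ch, trans)
            if wanted & {"phase_positive_median", "phase_positive_iqr",
                         "cycles_per_window_median", "cycles_per_window_iqr"}:
                st = frequency_stability(bb[ch], fs, BROADBAND,
                                         n_wavelet_freqs=8)
                put("phase_positive_median", ch, st["phase_positive_median"])
                put("phase_positive_iqr", ch, st["phase_positive_iqr"])
                put("cycles_per_window_median", ch, st["cycles_per_window_median"])
                put("cycles_per_window_iqr", ch, st["cycles_per_window_iqr"])

    return BiomarkerTensor(values=values,
                           biomarker_names=[r.name for r in registry],
                           channel_labels=list(recording.channel_labels),
                           subject_id=recording.subject_id,
                           visit=recording.visit, group=recording.group)
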