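"""Synthetic eyes-closed resting EEG cohorts.

Generates multichannel recordings with the statistical structure the
biomarker analysis assumes: a 1/f^chi broadband background, bursty
narrowband alpha/beta oscillations with controllable spectral peak
parameters and long-range temporal correlations of the amplitude envelope,
a tunable theta/alpha power balance, linear channel mixing, additive sensor
noise, and a longitudinal two-visit structure in which a subset of subjects
lacks the second visit.

Oscillations are synthesized as narrowband-filtered Gaussian noise
(Gaussian-shaped spectral peak) multiplied by a positive, power-law
correlated modulator, which gives independent control of the spectral peak
width and of the envelope's detrended-fluctuation (DFA) exponent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_core import InvalidArgumentError, Recording

#: Default montage: the 10-20 sites of the reference recording setup,
#: excluding the ear electrodes A1/A2.
DEFAULT_CHANNELS = [
    "Fp2", "Fp1", "FT9", "FT10", "F8", "F7", "F4", "F3", "T4", "T3",
    "C4", "C3", "T6", "T5", "P4", "P3", "O2", "O1", "Fz", "Cz", "Pz",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OscillationSpec:
    """Parameters of one narrowband oscillatory component.

    relative_amplitude is the oscillation RMS relative to the RMS of the
    broadband background within the peak's own band (center +- 3 widths).
    envelope_memory_exponent is the target DFA exponent of the amplitude
    envelope; 0.5 means an uncorrelated envelope.
    """

    center_frequency: float
    peak_width: float = 1.5
    relative_amplitude: float = 1.0
    burst_timescale: float = 1.0
    envelope_memory_exponent: float = 0.7

    def __post_init__(self) -> None:
        if self.center_frequency <= 0 or self.peak_width <= 0:
            raise InvalidArgumentError("center_frequency and peak_width must be > 0")
        if self.relative_amplitude < 0:
            raise InvalidArgumentError("relative_amplitude must be >= 0")
        if self.envelope_memory_exponent <= 0:
            raise InvalidArgumentError("envelope_memory_exponent must be > 0")


@dataclass(frozen=True)
class SubjectVariability:
    """Between-subject random effects within a group.

    Each subject draws one coherent set of offsets (shared across visits,
    so longitudinal group trends survive): additive Gaussian jitter on
    oscillation center frequencies and on the background exponent,
    multiplicative log-normal jitter on peak widths, relative amplitudes
    and the theta/alpha target. Defaults are sized so group contrasts of
    ~2 Hz in the beta peak overlap between subjects, as in clinical
    cohorts. ``SubjectVariability.none()`` disables all jitter.
    """

    center_sd: float = 1.0          # Hz
    width_rel_sd: float = 0.2       # log-normal sigma
    amplitude_rel_sd: float = 0.25  # log-normal sigma
    ratio_rel_sd: float = 0.25      # log-normal sigma
    exponent_sd: float = 0.08       # on chi
    memory_sd: float = 0.05         # on the envelope DFA target

    @classmethod
    def none(cls) -> "SubjectVariability":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GroupSpec:
    """One clinical group: per-visit oscillation parameters and group-level
    spectral features."""

    label: str
    n_subjects: int
    oscillations: dict  # visit -> {"alpha": OscillationSpec, "beta": OscillationSpec}
    background_exponent: float = 1.0
    theta_alpha_power_ratio: float | None = None
    inter_channel_mixing: np.ndarray | None = None  # channels x sources
    subject_variability: SubjectVariability = field(
        default_factory=SubjectVariability)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidArgumentError("n_subjects must be >= 1")
        if not (0 <= self.background_exponent <= 2):
            raise InvalidArgumentError("background_exponent must be in [0, 2]")
        if self.inter_channel_mixing is not None:
            m = np.asarray(self.inter_channel_mixing, dtype=float)
            if not np.all(np.isfinite(m)) or np.any(~np.any(m != 0, axis=1)):
                raise InvalidArgumentError(
                    "mixing rows must be finite with at least one nonzero entry"
                )

    def spec_for(self, visit: int, component: str) -> OscillationSpec | None:
        per_visit = self.oscillations.get(visit, self.oscillations.get(1, {}))
        return per_visit.get(component)


@dataclass(frozen=True)
class CohortSpec:
    """The whole synthetic cohort: groups, montage, recording parameters and
    the longitudinal visit structure."""

    groups: tuple
    n_channels: int = 21
    channel_labels: tuple = tuple(DEFAULT_CHANNELS)
    sampling_rate: float = 500.0
    duration: float = 120.0
    fraction_without_second_visit: float | dict = 0.0
    master_seed: int = 0
    sensor_snr_db: float = 20.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * 45.0:
            raise InvalidArgumentError("sampling_rate must exceed 90 Hz (2 x 45 Hz)")
        if self.duration < 60.0:
            raise InvalidArgumentError("duration must be >= 60 s")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidArgumentError("channel_labels must be unique")
        if len(self.channel_labels) != self.n_channels:
            raise InvalidArgumentError("channel_labels length must equal n_channels")

    def missing_fraction(self, label: str) -> float:
        f = self.fraction_without_second_visit
        frac = f.get(label, 0.0) if isinstance(f, dict) else f
        if not (0 <= frac <= 1):
            raise InvalidArgumentError("fraction_without_second_visit must be in [0,1]")
        return frac


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _powerlaw_noise(n: int, exponent: float, sampling_rate: float,
                    rng: np.random.Generator,
                    low_cut: float | None = None,
                    high_cut: float | None = None) -> np.ndarray:
    """Gaussian noise with PSD proportional to 1/f^exponent, unit variance.

    Optional band limits flatten the spectrum below ``low_cut`` and zero it
    above ``high_cut``.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    amp = np.ones_like(f)
    fref = np.maximum(f, f[1] if low_cut is None else low_cut)
    amp = fref ** (-exponent / 2.0)
    amp[0] = 0.0  # zero mean
    if high_cut is not None:
        amp[f > high_cut] = 0.0
    shaped = np.fft.irfft(spec * amp, n=n)
    sd = shaped.std()
    if sd > 0:
        shaped /= sd
    return shaped


def generate_background(duration: float, sampling_rate: float, exponent: float,
                        seed) -> np.ndarray:
    """Unit-variance, zero-mean 1/f^exponent background signal.

    The Welch log-log spectral slope over 1-45 Hz is -exponent to within
    the estimator's scatter.
    """
    if duration <= 0 or sampling_rate <= 0:
        raise InvalidArgumentError("duration and sampling_rate must be positive")
    n = int(round(duration * sampling_rate))
    if n < 2 ** 12:
        raise InvalidArgumentError("need at least 2^12 samples")
    if not (0 <= exponent <= 2):
        raise InvalidArgumentError("exponent must be in [0, 2]")
    rng = np.random.default_rng(seed)
    x = _powerlaw_noise(n, exponent, sampling_rate, rng)
    return x - x.mean()


def generate_oscillation(spec: OscillationSpec, duration: float,
                         sampling_rate: float, seed) -> np.ndarray:
    """Bursty narrowband oscillation.

    Carrier: Gaussian noise spectrally shaped to a Gaussian peak at
    ``center_frequency`` with FWHM ``peak_width``. Modulator: the
    exponential of a power-law correlated Gaussian process band-limited at
    1/(2 pi burst_timescale), whose spectral exponent is chosen so the
    final envelope's DFA exponent approaches ``envelope_memory_exponent``.
    Output RMS equals ``relative_amplitude`` (the caller rescales against
    its background's in-band RMS).
    """
    from scipy.signal import hilbert

    nyq = sampling_rate / 2.0
    if spec.center_frequency + 3 * spec.peak_width >= nyq:
        raise InvalidArgumentError("center + 3*width must stay below Nyquist")
    n = int(round(duration * sampling_rate))
    rng = np.random.default_rng(seed)
    if spec.relative_amplitude == 0:
        return np.zeros(n)

    # Carrier phase from Gaussian-spectrum noise (FWHM -> sigma_f); only
    # the phase is kept so the envelope is controlled entirely by the
    # modulator below.
    sigma_f = spec.peak_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    shape = np.exp(-0.5 * ((f - spec.center_frequency) / sigma_f) ** 2)
    carrier = np.fft.irfft(np.fft.rfft(white) * shape, n=n)
    phase = np.angle(hilbert(carrier))

    # Positive clipped-linear modulator with a 1/f^(2h-1) spectrum between
    # 1/duration and max(1/(2 pi burst_timescale), 1 Hz): its DFA exponent
    # (and hence the envelope's) approaches h over multi-second windows.
    h = spec.envelope_memory_exponent
    f_c = 1.0 / (2.0 * np.pi * max(spec.burst_timescale, 1e-3))
    z = _powerlaw_noise(n, max(2.0 * h - 1.0, 0.0), sampling_rate, rng,
                        low_cut=1.0 / duration, high_cut=max(f_c, 1.0))
    mod = np.clip(1.0 + 0.8 * z, 0.05, None)
    x = mod * np.cos(phase)
    x /= x.std()
    return x * spec.relative_amplitude


def _inband_rms(x: np.ndarray, sampling_rate: float, low: float, high: float) -> float:
    """RMS of the part of ``x`` inside [low, high] Hz (spectral mask)."""
    n = x.size
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    frac = np.sum(np.abs(spec[(f >= low) & (f <= high)]) ** 2) / np.sum(np.abs(spec) ** 2)
    return float(x.std() * np.sqrt(frac))


def _make_source(group: GroupSpec, visit: int, duration: float,
                 sampling_rate: float, seed_seq: np.random.SeedSequence) -> np.ndarray:
    """One independent source: background + alpha + beta (+ theta balance)."""
    seeds = seed_seq.spawn(4)
    bg = generate_background(duration, sampling_rate, group.background_exponent,
                             seeds[0])
    x = bg.copy()
    specs = {name: group.spec_for(visit, name) for name in ("alpha", "beta")}
    for osc, sd in zip(specs.values(), seeds[1:3]):
        if osc is None or osc.relative_amplitude == 0:
            continue
        half = 3 * osc.peak_width
        ref = _inband_rms(bg, sampling_rate,
                          max(osc.center_frequency - half, 0.5),
                          osc.center_frequency + half)
        unit = generate_oscillation(replace(osc, relative_amplitude=1.0),
                                    duration, sampling_rate, sd)
        x = x + unit * osc.relative_amplitude * ref

    if group.theta_alpha_power_ratio is not None:
        # Solve for the theta-component amplitude that brings the
        # theta(4-7)/alpha(8-13) band-power ratio to the target; if the
        # background alone already exceeds it, no theta is added.
        p_theta = _inband_rms(x, sampling_rate, 4.0, 7.0) ** 2
        p_alpha = _inband_rms(x, sampling_rate, 8.0, 13.0) ** 2
        need = group.theta_alpha_power_ratio * p_alpha - p_theta
        if need > 0:
            theta = OscillationSpec(center_frequency=5.5, peak_width=1.5,
                                    relative_amplitude=1.0, burst_timescale=1.0,
                                    envelope_memory_exponent=0.6)
            unit = generate_oscillation(theta, duration, sampling_rate, seeds[3])
            x = x + unit * np.sqrt(need)
    return x


def generate_recording(group: GroupSpec, cohort: CohortSpec, subject_id: str,
                       visit: int, seed) -> Recording:
    """One subject-visit recording: mixed independent sources + sensor noise."""
    n_ch = cohort.n_channels
    mixing = group.inter_channel_mixing
    if mixing is None:
        mixing = np.eye(n_ch)
    mixing = np.asarray(mixing, dtype=float)
    if mixing.shape[0] != n_ch:
        raise InvalidArgumentError(
            f"mixing has {mixing.shape[0]} rows for {n_ch} channels"
        )
    n_sources = mixing.shape[1]
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    src_seeds = seq.spawn(n_sources + 1)
    sources = np.stack([
        _make_source(group, visit, cohort.duration, cohort.sampling_rate, s)
        for s in src_seeds[:n_sources]
    ])
    data = mixing @ sources
    # additive white sensor noise at fixed SNR per channel
    noise_rng = np.random.default_rng(src_seeds[-1])
    snr_lin = 10.0 ** (cohort.sensor_snr_db / 10.0)
    noise_sd = data.std(axis=1, keepdims=True) / np.sqrt(snr_lin)
    data = data + noise_sd * noise_rng.standard_normal(data.shape)
    return Recording(data=data, sampling_rate=cohort.sampling_rate,
                     channel_labels=list(cohort.channel_labels),
                     subject_id=subject_id, visit=visit, group=group.label)


def sample_subject_spec(group: GroupSpec, seed) -> GroupSpec:
    """Draw one subject's realization of the group parameters.

    One coherent set of random effects per subject, applied identically to
    every visit, so within-subject longitudinal changes follow the group's
    per-visit specs.
    """
    v = group.subject_variability
    rng = np.random.default_rng(seed)
    comps = sorted({c for per in group.oscillations.values() for c in per})
    d_center = {c: rng.normal(0.0, v.center_sd) for c in comps}
    f_width = {c: float(np.exp(rng.normal(0.0, v.width_rel_sd))) for c in comps}
    f_amp = {c: float(np.exp(rng.normal(0.0, v.amplitude_rel_sd))) for c in comps}
    d_mem = {c: rng.normal(0.0, v.memory_sd) for c in comps}
    new_osc = {}
    for visit, per in group.oscillations.items():
        new_osc[visit] = {
            c: replace(
                o,
                center_frequency=max(o.center_frequency + d_center[c], 1.0),
                peak_width=o.peak_width * f_width[c],
                relative_amplitude=o.relative_amplitude * f_amp[c],
                envelope_memory_exponent=float(
                    np.clip(o.envelope_memory_exponent + d_mem[c], 0.51, 1.2)))
            for c, o in per.items()}
    ratio = group.theta_alpha_power_ratio
    if ratio is not None:
        ratio = float(ratio * np.exp(rng.normal(0.0, v.ratio_rel_sd)))
    chi = float(np.clip(group.background_exponent
                        + rng.normal(0.0, v.exponent_sd), 0.0, 2.0))
    return replace(group, oscillations=new_osc,
                   theta_alpha_power_ratio=ratio, background_exponent=chi)


def generate_cohort(cohort: CohortSpec) -> tuple[dict, "pandas.DataFrame"]:
    """Generate the full cohort.

    Returns ``(recordings, subjects)`` where ``recordings`` maps
    ``(subject_id, visit)`` to a Recording and ``subjects`` is a table with
    columns subject_id, group, has_visit2. Every subject has a visit-1
    recording; per group, exactly ``round(fraction * n)`` subjects (the
    last ones in enumeration order) lack visit 2. The whole cohort is a
    pure function of the spec including ``master_seed``.
    """
    import pandas as pd

    recordings: dict = {}
    rows = []
    for gi, group in enumerate(cohort.groups):
        frac = cohort.missing_fraction(group.label)
        n_missing = int(round(frac * group.n_subjects))
        for si in range(group.n_subjects):
            sid = f"{group.label}-{si:03d}"
            has_v2 = si < group.n_subjects - n_missing
            visits = (1, 2) if has_v2 else (1,)
            subj_group = sample_subject_spec(
                group, np.random.SeedSequence(entropy=cohort.master_seed,
                                              spawn_key=(gi, si, 0)))
            for visit in visits:
                seq = np.random.SeedSequence(
                    entropy=cohort.master_seed, spawn_key=(gi, si, visit))
                recordings[(sid, visit)] = generate_recording(
                    subj_group, cohort, sid, visit, seq)
            rows.append({"subject_id": sid, "group": group.label,
                         "has_visit2": has_v2})
    return recordings, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_group_specs() -> tuple[GroupSpec, GroupSpec]:
    """The default two-group conditions.

    Beta peak centers follow the reported group medians (MCI-stable
    17.6 / 16.9 Hz and AD-converter 19.6 / 19.3 Hz at visits 1/2); the
    AD-converter group additionally has a wider beta peak, lower relative
    alpha power and a higher theta/alpha ratio (EEG slowing), with a
    slightly steeper 1/f background.
    """
    mci = GroupSpec(
        label="MCI-stable", n_subjects=39,
        oscillations={
            1: {"alpha": OscillationSpec(10.0, 1.5, 1.2, 1.0, 0.75),
                "beta": OscillationSpec(17.6, 2.0, 0.8, 0.5, 0.65)},
            2: {"alpha": OscillationSpec(10.0, 1.5, 1.2, 1.0, 0.75),
                "beta": OscillationSpec(16.9, 2.0, 0.8, 0.5, 0.65)},
        },
        background_exponent=1.0, theta_alpha_power_ratio=0.30,
    )
    ad = GroupSpec(
        label="AD-converter", n_subjects=25,
        oscillations={
            1: {"alpha": OscillationSpec(9.5, 1.5, 0.9, 1.0, 0.70),
                "beta": OscillationSpec(19.6, 3.0, 0.8, 0.5, 0.60)},
            2: {"alpha": OscillationSpec(9.5, 1.5, 0.9, 1.0, 0.70),
                "beta": OscillationSpec(19.3, 3.0, 0.8, 0.5, 0.60)},
        },
        background_exponent=1.1, theta_alpha_power_ratio=0.55,
    )
    return mci, ad


def default_cohort_spec(master_seed: int = 0, duration: float = 120.0,
                        n_subjects: tuple[int, int] | None = None) -> CohortSpec:
    """Default cohort mirroring the study's n-structure.

    39 MCI-stable + 25 AD-converter subjects; second visits available for
    17 + 17 (i.e. 22 + 8 subjects lack one).
    """
    mci, ad = default_group_specs()
    if n_subjects is not None:
        mci = replace(mci, n_subjects=n_subjects[0])
        ad = replace(ad, n_subjects=n_subjects[1])
    return CohortSpec(
        groups=(mci, ad),
        fraction_without_second_visit={"MCI-stable": 22 / 39, "AD-converter": 8 / 25},
        master_seed=master_seed,
        duration=duration,
    )
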