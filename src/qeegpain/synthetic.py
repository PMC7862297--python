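"""Synthetic single-channel ambulatory EEG cohorts.

Generates labeled walking-EEG sessions with a known spectral structure so
the whole analysis chain (preprocessing, band-power features, group
statistics, classification) can be exercised and validated without any
recorded data.

Signal model
------------
A session is a Gaussian random signal synthesized in the frequency
domain. Its one-sided power spectral density is

    S(f) = S0(f) * g(f)^2,    S0(f) = f^(-beta) + sum_k a_k N(f; c_k, bw_k)

where ``S0`` is a 1/f^beta background plus Gaussian oscillation bumps
(alpha and beta rhythms by default) and ``g(f)`` is a dimensionless
amplitude gain: the product of the pain-level gain for the 1-Hz band
containing ``f`` (``level_gain``, defined at integer frequencies 1-35 Hz)
and a per-subject log-normal gain ``exp(subject_effect)``. Each rFFT bin
receives an independent complex-Gaussian coefficient with that variance,
so the expected periodogram equals S(f) exactly and
:func:`spectral_profile` is available in closed form as the ground-truth
oracle for recovery tests.

On top of the stationary background, two walking artifacts are
superimposed: short broadband EMG bursts (band-limited high-frequency
noise, Hann-enveloped) and slow motion transients (enveloped ~1.5 Hz
sway). Both are parameterized by rate, duration and amplitude relative
to the background RMS.

The default cohort emulates the study design this package targets:
23 subjects, two sessions each (pre- and post-intervention walk), 420 s
per session, and pain-quartile counts none=16, mild=8, moderate=15,
severe=7 across the 46 sessions, with every pre session at NRS >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, LayoutError, SessionError
from .pain import CLASS_ORDER, PainQuartile, nrs_to_quartile, quartile_nrs_range

__all__ = [
    "GeneratorConfig",
    "EEGSession",
    "CohortManifest",
    "default_level_gain",
    "generate_session",
    "generate_cohort",
    "spectral_profile",
]

N_FEATURES = 35  # integer frequencies 1..35 Hz


def default_level_gain() -> dict[str, np.ndarray]:
    """Default per-quartile amplitude gain vectors at 1-35 Hz.

    The qualitative pattern follows the group contrasts the analysis is
    meant to expose: the moderate group is elevated at 1-2 Hz relative
    to every other group; the severe group is elevated at 4-6, 11-16, 18
    and 24 Hz; the mild group carries a small broad 3-10 Hz elevation
    (enough to be learnable, too small to dominate). Magnitudes are a
    documented calibration that places default out-of-fold classifier
    accuracy in a realistic 60-90% band; they are not measured values.
    """
    gain = {label: np.ones(N_FEATURES) for label in CLASS_ORDER}
    idx = lambda hz: np.asarray(hz) - 1  # noqa: E731 - frequency -> index
    gain["mild"][idx(range(3, 11))] = 1.12
    gain["moderate"][idx([1, 2])] = 1.40
    gain["moderate"][idx([4, 11, 12, 13])] = 1.15
    gain["severe"][idx([4])] = 1.30
    gain["severe"][idx([5, 6, 11, 12, 13, 14, 15, 16, 18, 24])] = 1.50
    return gain


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort.

    Parameters
    ----------
    sample_rate_hz
        Sampling rate. The consumer device class never documents one;
        512 Hz is typical and is the default.
    session_duration_s
        Recording length per session (default 420 s = 7 min:
        a 5-min walk flanked by 1-min rests).
    cohort_layout
        Sessions per pain quartile; defaults to none=16, mild=8,
        moderate=15, severe=7 (46 sessions).
    n_subjects
        Number of subjects; each contributes one pre and one post
        session, so ``2 * n_subjects`` must equal the layout total.
    level_gain
        Map quartile label -> 35-vector of strictly positive amplitude
        multipliers applied to the baseline spectrum at 1-35 Hz.
    background_exponent
        Slope beta of the 1/f^beta background.
    oscillations
        List of (center_hz, bandwidth_hz, relative_amplitude) Gaussian
        bumps added to the background PSD.
    emg_burst
        (rate_per_min, duration_s, band_low_hz, band_high_hz,
        relative_amplitude) of walking EMG bursts.
    motion_transient
        (rate_per_min, duration_s, relative_amplitude) of slow motion
        artifacts.
    subject_effect_sd
        SD of the per-subject log amplitude gain, shared by both of a
        subject's sessions.
    seed
        Master seed; every downstream draw derives from it.
    """

    sample_rate_hz: float = 512.0
    session_duration_s: float = 420.0
    cohort_layout: dict[str, int] = field(
        default_factory=lambda: {"none": 16, "mild": 8, "moderate": 15, "severe": 7}
    )
    n_subjects: int = 23
    level_gain: dict[str, np.ndarray] = field(default_factory=default_level_gain)
    background_exponent: float = 1.0
    oscillations: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(10.0, 2.0, 2.0), (20.0, 4.0, 0.5)]
    )
    emg_burst: tuple[float, float, float, float, float] = (4.0, 0.5, 30.0, 100.0, 2.0)
    motion_transient: tuple[float, float, float] = (2.0, 1.0, 4.0)
    subject_effect_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ConfigError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        if self.session_duration_s <= 0:
            raise ConfigError(f"session_duration_s must be positive, got {self.session_duration_s}")
        for label, count in self.cohort_layout.items():
            if label not in CLASS_ORDER:
                raise ConfigError(f"unknown quartile in cohort_layout: {label!r}")
            if count < 0:
                raise ConfigError(f"cohort_layout[{label!r}] must be >= 0, got {count}")
        for label in CLASS_ORDER:
            vec = np.asarray(self.level_gain.get(label))
            if vec.shape != (N_FEATURES,):
                raise ConfigError(f"level_gain[{label!r}] must be a {N_FEATURES}-vector")
            if not np.all(vec > 0):
                raise ConfigError(f"level_gain[{label!r}] must be strictly positive")
        rate, dur, lo, hi, amp = self.emg_burst
        if min(rate, dur, amp) < 0:
            raise ConfigError("emg_burst rate, duration and amplitude must be nonnegative")
        if not 0 < lo < hi:
            raise ConfigError("emg_burst band must satisfy 0 < low < high")
        if hi >= self.sample_rate_hz / 2:
            raise ConfigError(
                f"emg_burst band_high_hz {hi} must be below Nyquist {self.sample_rate_hz / 2}"
            )
        m_rate, m_dur, m_amp = self.motion_transient
        if min(m_rate, m_dur, m_amp) < 0:
            raise ConfigError("motion_transient parameters must be nonnegative")
        if self.subject_effect_sd < 0:
            raise ConfigError("subject_effect_sd must be nonnegative")

    def scaled_separation(self, scale: float) -> "GeneratorConfig":
        """Copy of this config with level-gain contrasts shrunk toward 1.

        ``scale=1`` is identity; ``scale=0`` makes all quartiles
        spectrally identical. Used for difficulty-sweep experiments.
        """
        shrunk = {
            label: 1.0 + scale * (np.asarray(vec, dtype=float) - 1.0)
            for label, vec in self.level_gain.items()
        }
        return replace(self, level_gain=shrunk)


@dataclass
class EEGSession:
    """One subject-phase raw recording with its NRS label."""

    subject_id: str
    phase: str  # "pre" | "post"
    nrs: int
    sample_rate_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.phase not in ("pre", "post"):
            raise SessionError(f"phase must be 'pre' or 'post', got {self.phase!r}")
        if not 0 <= self.nrs <= 10:
            raise SessionError(f"nrs must be in [0, 10], got {self.nrs}")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise SessionError(f"session {self.key} contains non-finite samples")

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.phase)

    @property
    def quartile(self) -> PainQuartile:
        return nrs_to_quartile(self.nrs)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz


@dataclass
class CohortManifest:
    """A generated cohort: sessions plus label bookkeeping."""

    sessions: list[EEGSession]
    quartile_counts: dict[str, int]
    seed_used: int

    def __post_init__(self) -> None:
        observed: dict[str, int] = {label: 0 for label in CLASS_ORDER}
        for session in self.sessions:
            observed[session.quartile.label] += 1
        declared = {label: self.quartile_counts.get(label, 0) for label in CLASS_ORDER}
        if observed != declared:
            raise LayoutError(
                f"quartile_counts {declared} inconsistent with member sessions {observed}"
            )

    def __len__(self) -> int:
        return len(self.sessions)

    def labels(self) -> dict[tuple[str, str], tuple[int, str]]:
        """(subject_id, phase) -> (nrs, quartile label)."""
        return {s.key: (s.nrs, s.quartile.label) for s in self.sessions}


# ---------------------------------------------------------------------------
# spectral model


def _baseline_psd(freqs_hz: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Unnormalized background PSD S0(f) at the given frequencies (f > 0)."""
    f = np.asarray(freqs_hz, dtype=float)
    psd = np.zeros_like(f)
    pos = f > 0
    psd[pos] = f[pos] ** (-config.background_exponent)
    for center, bandwidth, rel_amp in config.oscillations:
        sigma = bandwidth / 2.355  # FWHM -> SD
        psd += rel_amp * np.exp(-0.5 * ((f - center) / sigma) ** 2)
    return psd


def _band_gain(freqs_hz: np.ndarray, gain_vector: np.ndarray) -> np.ndarray:
    """Amplitude gain per frequency: level gain of the containing 1-Hz band.

    Band f covers [f - 0.5, f + 0.5); frequencies outside 0.5-35.5 Hz get
    unit gain.
    """
    band = np.floor(np.asarray(freqs_hz, dtype=float) + 0.5).astype(int)
    gains = np.ones_like(freqs_hz, dtype=float)
    in_range = (band >= 1) & (band <= N_FEATURES)
    gains[in_range] = np.asarray(gain_vector, dtype=float)[band[in_range] - 1]
    return gains


def _session_psd(
    freqs_hz: np.ndarray, quartile: PainQuartile, subject_effect: float, config: GeneratorConfig
) -> np.ndarray:
    amp_gain = _band_gain(freqs_hz, config.level_gain[quartile.label]) * np.exp(subject_effect)
    return _baseline_psd(freqs_hz, config) * amp_gain**2


def spectral_profile(
    quartile: PainQuartile | str,
    config: GeneratorConfig,
    subject_effect: float = 0.0,
    grid_hz: float = 0.05,
) -> np.ndarray:
    """Closed-form expected band power at integer frequencies 1-35 Hz.

    Returns, for each integer frequency f, the mean of the model PSD
    S0(f) * gain^2 over the band [f - 0.5, f + 0.5), evaluated on a fine
    deterministic grid (no sampling). This is the ground-truth oracle
    for spectral-recovery tests: pipeline band powers converge to this
    profile up to one overall scale factor (z-normalization removes
    absolute scale) and the band-pass filter response.
    """
    if isinstance(quartile, str):
        quartile = PainQuartile.from_label(quartile)
    profile = np.empty(N_FEATURES)
    for f in range(1, N_FEATURES + 1):
        grid = np.arange(f - 0.5, f + 0.5, grid_hz)
        profile[f - 1] = _session_psd(grid, quartile, subject_effect, config).mean()
    return profile


# ---------------------------------------------------------------------------
# session synthesis


def _synthesize_background(
    n_samples: int,
    rate_hz: float,
    quartile: PainQuartile,
    subject_effect: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one realization of the stationary colored-noise background.

    Frequency-domain synthesis: rFFT bin k gets an independent complex
    Gaussian coefficient with E|X_k|^2 = S(f_k) * fs * n / 2, which makes
    the one-sided PSD of the inverse transform equal S(f) in expectation.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / rate_hz)
    psd = _session_psd(freqs, quartile, subject_effect, config)
    sigma = np.sqrt(psd * rate_hz * n_samples / 2.0)
    coeffs = sigma * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    coeffs /= np.sqrt(2.0)
    coeffs[0] = 0.0  # zero mean
    if n_samples % 2 == 0:
        coeffs[-1] = coeffs[-1].real * np.sqrt(2.0)  # Nyquist bin is real
    return np.fft.irfft(coeffs, n=n_samples)


def _add_emg_bursts(
    x: np.ndarray, rate_hz: float, config: GeneratorConfig, rng: np.random.Generator
) -> None:
    """Superimpose Hann-enveloped band-limited EMG bursts in place."""
    rate_per_min, duration_s, lo, hi, rel_amp = config.emg_burst
    n_burst = int(rng.poisson(rate_per_min * len(x) / rate_hz / 60.0))
    if n_burst == 0 or rel_amp == 0 or duration_s == 0:
        return
    burst_len = max(int(round(duration_s * rate_hz)), 8)
    background_rms = float(np.std(x))
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate_hz, output="sos")
    envelope = sps.windows.hann(burst_len)
    for start in rng.integers(0, max(len(x) - burst_len, 1), size=n_burst):
        noise = sps.sosfilt(sos, rng.standard_normal(burst_len))
        rms = float(np.std(noise)) or 1.0
        x[start : start + burst_len] += rel_amp * background_rms * envelope * noise / rms


def _add_motion_transients(
    x: np.ndarray, rate_hz: float, config: GeneratorConfig, rng: np.random.Generator
) -> None:
    """Superimpose slow enveloped sway transients (~1.5 Hz) in place."""
    rate_per_min, duration_s, rel_amp = config.motion_transient
    n_events = int(rng.poisson(rate_per_min * len(x) / rate_hz / 60.0))
    if n_events == 0 or rel_amp == 0 or duration_s == 0:
        return
    event_len = max(int(round(duration_s * rate_hz)), 8)
    background_rms = float(np.std(x))
    t = np.arange(event_len) / rate_hz
    envelope = sps.windows.hann(event_len)
    for start in rng.integers(0, max(len(x) - event_len, 1), size=n_events):
        phase = rng.uniform(0, 2 * np.pi)
        sway = np.sin(2 * np.pi * 1.5 * t + phase)
        x[start : start + event_len] += rel_amp * background_rms * envelope * sway


def generate_session(
    config: GeneratorConfig,
    quartile: PainQuartile | str,
    subject_effect: float,
    seed: int,
    subject_id: str = "S00",
    phase: str = "pre",
) -> EEGSession:
    """Generate one labeled synthetic session.

    The session's expected band amplitude at frequency f is
    baseline(f) * level_gain[quartile][f] * exp(subject_effect); its NRS
    is drawn uniformly from the quartile's range; EMG and motion
    artifacts are superimposed per config. Identical arguments produce
    bitwise-identical output.
    """
    if isinstance(quartile, str):
        quartile = PainQuartile.from_label(quartile)
    config.validate()
    rng = np.random.default_rng(seed)
    n_samples = int(round(config.session_duration_s * config.sample_rate_hz))
    x = _synthesize_background(
        n_samples, config.sample_rate_hz, quartile, subject_effect, config, rng
    )
    _add_emg_bursts(x, config.sample_rate_hz, config, rng)
    _add_motion_transients(x, config.sample_rate_hz, config, rng)
    lo, hi = quartile_nrs_range(quartile)
    nrs = int(rng.integers(lo, hi + 1))
    return EEGSession(
        subject_id=subject_id,
        phase=phase,
        nrs=nrs,
        sample_rate_hz=config.sample_rate_hz,
        samples=x,
    )


# ---------------------------------------------------------------------------
# cohort assembly


def _arrange_layout(config: GeneratorConfig) -> tuple[list[str], list[str]]:
    """Split the quartile layout into per-subject (pre, post) quartiles.

    Rule: severe sessions are always pre (pre-intervention pain was
    >= NRS 1 and severe pain motivates intervention), `none` sessions are
    always post; mild/moderate fill the remainder with moderate
    preferentially pre. Raises LayoutError when no valid arrangement
    exists (odd total, more `none` or `severe` sessions than subjects).
    """
    counts = {label: int(config.cohort_layout.get(label, 0)) for label in CLASS_ORDER}
    total = sum(counts.values())
    if total == 0:
        return [], []
    if total % 2:
        raise LayoutError(f"layout total {total} is odd; sessions come in pre/post pairs")
    n_subjects = total // 2
    if config.n_subjects != n_subjects:
        raise LayoutError(
            f"n_subjects={config.n_subjects} inconsistent with layout total {total} "
            f"({total} sessions require {n_subjects} subjects)"
        )
    if counts["none"] > n_subjects:
        raise LayoutError(
            f"{counts['none']} pain-free sessions but only {n_subjects} subjects: "
            "every pre session must have NRS >= 1"
        )
    if counts["severe"] > n_subjects:
        raise LayoutError(f"{counts['severe']} severe sessions exceed {n_subjects} subjects")
    pre: list[str] = ["severe"] * counts["severe"]
    pool = {"moderate": counts["moderate"], "mild": counts["mild"]}
    for label in ("moderate", "mild"):  # moderate preferentially pre
        take = min(pool[label], n_subjects - len(pre))
        pre.extend([label] * take)
        pool[label] -= take
    if len(pre) < n_subjects:
        raise LayoutError("not enough NRS >= 1 sessions to fill the pre phase")
    post = ["none"] * counts["none"] + ["mild"] * pool["mild"] + ["moderate"] * pool["moderate"]
    # pair worst pre with best post outcome (sorted by severity)
    severity = {label: i for i, label in enumerate(CLASS_ORDER)}
    pre.sort(key=severity.get, reverse=True)
    post.sort(key=severity.get)
    return pre, post


def generate_cohort(config: GeneratorConfig | None = None) -> CohortManifest:
    """Generate the full labeled cohort.

    Subject random effects are drawn once per subject and shared by that
    subject's pre and post sessions; per-session seeds derive
    deterministically from ``config.seed``.
    """
    config = config or GeneratorConfig()
    config.validate()
    pre, post = _arrange_layout(config)
    n_subjects = len(pre)
    rng = np.random.default_rng(config.seed)
    subject_effects = rng.normal(0.0, config.subject_effect_sd, size=n_subjects)
    session_seeds = rng.integers(0, 2**31, size=2 * n_subjects)
    sessions: list[EEGSession] = []
    for i in range(n_subjects):
        subject_id = f"S{i + 1:02d}"
        for j, (phase, quartile) in enumerate((("pre", pre[i]), ("post", post[i]))):
            sessions.append(
                generate_session(
                    config,
                    quartile,
                    subject_effect=float(subject_effects[i]),
                    seed=int(session_seeds[2 * i + j]),
                    subject_id=subject_id,
                    phase=phase,
                )
            )
    counts = {label: 0 for label in CLASS_ORDER}
    for label in pre + post:
        counts[label] += 1
    return CohortManifest(sessions=sessions, quartile_counts=counts, seed_used=config.seed)
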