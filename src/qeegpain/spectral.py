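"""Band-power feature extraction: 35 per-frequency features per window.

Each 30-s window is reduced to its averaged-periodogram power spectral
density (Welch's method: tapered, overlapping subsegments), then to 35
features: the mean PSD over the 1-Hz band [f - 0.5, f + 0.5) for each
integer frequency f = 1..35 Hz. Features are power (normalized
units^2/Hz); an amplitude mode (square root) exists for plotting.

The default subsegment length is 4 s (0.25 Hz resolution) with a Hann
taper and 50% overlap: with the coarser 0.5-Hz resolution a Hann-tapered
on-bin tone leaks one bin (0.5 Hz) sideways, placing a sixth of its
power outside its 1-Hz band; at 0.25 Hz resolution the leakage stays
inside the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import CoverageError, LabelError, SessionError
from .pain import CLASS_ORDER
from .preprocessing import CleanSegmentSet
from .synthetic import N_FEATURES, CohortManifest

__all__ = [
    "PsdConfig",
    "Psd",
    "FeatureDataset",
    "window_psd",
    "integer_band_power",
    "build_feature_dataset",
    "expected_feature_profile",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [f"f{f:02d}" for f in range(1, N_FEATURES + 1)]
META_COLUMNS = ["subject_id", "phase", "window_index", "nrs", "quartile", "artifact_flag"]


class Psd(NamedTuple):
    """A one-sided power spectral density estimate."""

    frequencies: np.ndarray
    power: np.ndarray


@dataclass
class PsdConfig:
    subsegment_length_s: float = 4.0
    overlap_fraction: float = 0.5
    taper: str = "hann"
    detrend: str = "constant"  # "none" | "constant"

    def validate(self) -> None:
        if self.subsegment_length_s <= 0:
            raise SessionError("subsegment_length_s must be positive")
        if not 0 <= self.overlap_fraction < 1:
            raise SessionError("overlap_fraction must be in [0, 1)")
        if self.detrend not in ("none", "constant"):
            raise SessionError(f"detrend must be 'none' or 'constant', got {self.detrend!r}")


def window_psd(window: np.ndarray, rate_hz: float, config: PsdConfig | None = None) -> Psd:
    """Averaged-periodogram PSD of one window (Welch's method)."""
    config = config or PsdConfig()
    config.validate()
    window = np.asarray(window, dtype=float)
    nperseg = int(round(config.subsegment_length_s * rate_hz))
    if len(window) < nperseg:
        raise SessionError(
            f"window of {len(window)} samples is shorter than one "
            f"{config.subsegment_length_s:g}-s subsegment ({nperseg} samples)"
        )
    freqs, power = sps.welch(
        window,
        fs=rate_hz,
        window=config.taper if config.taper != "none" else "boxcar",
        nperseg=nperseg,
        noverlap=int(round(config.overlap_fraction * nperseg)),
        detrend=False if config.detrend == "none" else "constant",
    )
    return Psd(frequencies=freqs, power=power)


def integer_band_power(psd: Psd) -> np.ndarray:
    """Mean PSD over [f - 0.5, f + 0.5) for integer f = 1..35 Hz.

    Requires the PSD grid to cover 0.5-35.5 Hz.
    """
    freqs = np.asarray(psd.frequencies, dtype=float)
    power = np.asarray(psd.power, dtype=float)
    if freqs.min() > 0.5 or freqs.max() < 35.5 - (freqs[1] - freqs[0] if len(freqs) > 1 else 0):
        raise CoverageError(
            f"PSD covers {freqs.min():g}-{freqs.max():g} Hz; features need 0.5-35.5 Hz"
        )
    features = np.empty(N_FEATURES)
    for f in range(1, N_FEATURES + 1):
        in_band = (freqs >= f - 0.5) & (freqs < f + 0.5)
        if not np.any(in_band):
            raise CoverageError(f"no PSD bins inside the {f} Hz band [{f - 0.5}, {f + 0.5})")
        features[f - 1] = power[in_band].mean()
    return features


def expected_feature_profile(
    quartile,
    gen_config,
    preprocess_config=None,
    psd_config: PsdConfig | None = None,
    subject_effect: float = 0.0,
    grid_hz: float = 0.0125,
) -> np.ndarray:
    """Model-implied expectation of the 35 pipeline features, up to scale.

    Predicts what :func:`build_feature_dataset` measures on a generated
    session: the generator's closed-form PSD is multiplied by the
    band-pass power response (squared for zero-phase filtering),
    convolved with the taper's spectral kernel (periodogram smoothing /
    leakage), sampled on the Welch bin grid and band-averaged. Because
    z-normalization removes absolute signal scale, the result is an
    expectation up to one overall scalar; recovery tests fit that scalar
    and compare shapes.

    Artifacts are not modeled; use artifact-free generator configs when
    comparing against simulation.
    """
    from .preprocessing import bandpass_power_response
    from .synthetic import _session_psd
    from .pain import PainQuartile as _PQ

    psd_config = psd_config or PsdConfig()
    psd_config.validate()
    if isinstance(quartile, str):
        quartile = _PQ.from_label(quartile)
    fs = gen_config.sample_rate_hz
    nperseg = int(round(psd_config.subsegment_length_s * fs))
    bin_hz = 1.0 / psd_config.subsegment_length_s
    grid = np.arange(0.0, N_FEATURES + 4.0, grid_hz)
    psd = _session_psd(grid, quartile, subject_effect, gen_config)
    if preprocess_config is not None:
        psd = psd * bandpass_power_response(grid, fs, preprocess_config)
    # spectral kernel of the taper, truncated to +-2 Hz
    taper = sps.get_window(psd_config.taper if psd_config.taper != "none" else "boxcar", nperseg)
    n_pad = int(round(fs / grid_hz))
    kernel = np.fft.fftshift(np.abs(np.fft.fft(taper, n_pad)) ** 2)
    offsets = (np.arange(n_pad) - n_pad // 2) * grid_hz
    kernel = kernel[np.abs(offsets) <= 2.0]
    kernel /= kernel.sum()
    smoothed = np.convolve(psd, kernel, mode="same")
    stride = max(int(round(bin_hz / grid_hz)), 1)
    profile = np.empty(N_FEATURES)
    for f in range(1, N_FEATURES + 1):
        in_band = (grid >= f - 0.5) & (grid < f + 0.5)
        profile[f - 1] = smoothed[in_band][::stride].mean()
    return profile


@dataclass
class FeatureDataset:
    """The window-level analysis table: one row per 30-s window.

    ``frame`` holds metadata columns (subject_id, phase, window_index,
    nrs, quartile, artifact_flag) plus feature columns f01..f35; rows are
    sorted by (subject_id, phase, window_index). ``session_key`` values
    group windows that share a recording, for grouped cross-validation.
    """

    frame: pd.DataFrame
    class_order: list[str] = field(default_factory=lambda: list(CLASS_ORDER))

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS + FEATURE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise LabelError(f"feature table is missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def features(self) -> np.ndarray:
        """(n_windows, 35) float matrix."""
        return self.frame[FEATURE_COLUMNS].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        """Quartile label per row."""
        return self.frame["quartile"].to_numpy(dtype=object)

    @property
    def session_keys(self) -> np.ndarray:
        """'subject/phase' grouping key per row."""
        return (self.frame["subject_id"].astype(str) + "/" + self.frame["phase"]).to_numpy()

    def amplitude_features(self) -> np.ndarray:
        """Square-root (amplitude) view of the power features, for plots."""
        return np.sqrt(self.features)


def build_feature_dataset(
    segment_sets: Iterable[CleanSegmentSet],
    labels: CohortManifest | Mapping[tuple[str, str], tuple[int, str]],
    psd_config: PsdConfig | None = None,
    drop_flagged: bool = False,
) -> FeatureDataset:
    """Assemble the window-by-frequency analysis table.

    One row per window, labeled from the cohort manifest; deterministic
    row order (sorted by subject, phase, window index). ``drop_flagged``
    excludes artifact-flagged windows (default keeps them, flagged).
    """
    psd_config = psd_config or PsdConfig()
    label_map = labels.labels() if isinstance(labels, CohortManifest) else dict(labels)
    records: list[dict] = []
    for segments in segment_sets:
        if segments.key not in label_map:
            raise LabelError(
                f"no manifest entry for session subject={segments.key[0]!r} "
                f"phase={segments.key[1]!r}"
            )
        nrs, quartile = label_map[segments.key]
        for index, window in enumerate(segments.windows):
            flagged = bool(segments.artifact_flags[index])
            if drop_flagged and flagged:
                continue
            power = integer_band_power(
                window_psd(window, segments.effective_sample_rate_hz, psd_config)
            )
            record = {
                "subject_id": segments.subject_id,
                "phase": segments.phase,
                "window_index": index,
                "nrs": int(nrs),
                "quartile": quartile,
                "artifact_flag": flagged,
            }
            record.update(zip(FEATURE_COLUMNS, power))
            records.append(record)
    frame = pd.DataFrame.from_records(records, columns=META_COLUMNS + FEATURE_COLUMNS)
    frame = frame.sort_values(["subject_id", "phase", "window_index"], kind="stable")
    frame = frame.reset_index(drop=True)
    return FeatureDataset(frame=frame)
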