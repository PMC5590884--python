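"""Signal conditioning and spectral feature extraction.

Each trial is low-pass filtered (zero-lag Butterworth; 6 Hz for joint
kinematics/kinetics, 30 Hz for GRFs by default), segmented into one gait cycle
from the vertical GRF, linearly resampled to a fixed cycle length, and reduced
to the modulus of its discrete Fourier transform per variable. Discarding the
phase removes the absolute timing of the cycle while keeping its temporal
structure, so circularly time-shifted copies of a trial map to identical
feature rows. The per-trial 30 x n_bins spectra are flattened variable-major
into one row of the feature matrix M (default full-cohort shape 200 x 1500).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .catalog import N_VARIABLES, VARIABLE_NAMES, VERTICAL_GRF_INDEX, is_grf
from .cohort import Cohort, Trial
from .errors import DataError, EventDetectionError, ParameterError

CycleMode = str  # "auto" | "full" | "stance"


@dataclasses.dataclass
class PreprocessConfig:
    """Settings for the waveform -> feature-row pipeline.

    kinematic_cutoff_hz / grf_cutoff_hz
        Low-pass cutoffs for the joint and GRF channels (Hz).
    filter_order
        Design order of the one-pass Butterworth; forward-backward application
        doubles the effective roll-off.
    event_threshold_bw
        Vertical-GRF threshold (in BW) defining stance contact.
    n_samples
        Number of equally spaced points the cycle is resampled to.
    n_bins
        One-sided spectrum bins retained per variable, DC included. The default
        pair (100, 50) makes the 50 bins the full one-sided band; frequencies
        are then in cycles per gait cycle.
    cycle_mode
        "full": heel strike to the next ipsilateral heel strike, error if the
        second contact is absent. "stance": heel strike to toe off. "auto":
        full when a second contact exists, else stance.
    """

    kinematic_cutoff_hz: float = 6.0
    grf_cutoff_hz: float = 30.0
    filter_order: int = 4
    event_threshold_bw: float = 0.02
    n_samples: int = 100
    n_bins: int = 50
    cycle_mode: CycleMode = "auto"

    def __post_init__(self) -> None:
        if self.filter_order < 1:
            raise ParameterError("filter_order must be >= 1")
        if self.n_samples < 4:
            raise ParameterError("n_samples must be >= 4")
        if self.n_bins < 1 or self.n_bins > self.n_samples // 2 + 1:
            raise ParameterError(
                f"n_bins must be in [1, n_samples//2 + 1] = [1, {self.n_samples // 2 + 1}]"
            )
        if self.cycle_mode not in ("auto", "full", "stance"):
            raise ParameterError(f"unknown cycle_mode {self.cycle_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def butterworth_zero_lag(
    x: np.ndarray, fs: float, cutoff: float, order: int = 4
) -> np.ndarray:
    """Forward-backward (zero phase) Butterworth low-pass filter.

    The effective magnitude response is the square of the one-pass response.
    The signal must exceed the filtfilt warm-up of ``3 * (2 * order + 1)``
    samples.
    """
    x = np.asarray(x, dtype=float)
    if cutoff <= 0 or cutoff >= fs / 2:
        raise ParameterError(
            f"cutoff must lie in (0, Nyquist) = (0, {fs / 2} Hz); got {cutoff}"
        )
    b, a = sps.butter(order, cutoff, btype="low", fs=fs)
    padlen = 3 * (2 * order + 1)  # filtfilt default for a transfer-function filter
    if x.shape[-1] <= padlen:
        raise ParameterError(
            f"signal too short for zero-lag filtering: need > {padlen} samples, got {x.shape[-1]}"
        )
    return sps.filtfilt(b, a, x, axis=-1)


def detect_gait_events(
    vertical_grf: np.ndarray, fs: float, threshold: float = 0.02
) -> tuple[int, int]:
    """Locate heel strike and toe off from the vertical GRF.

    Heel strike is the first sample rising above ``threshold`` (BW); toe off is
    the first subsequent sample falling below it. Raises
    :class:`EventDetectionError` when no supra-threshold stance exists or the
    force never returns below threshold.
    """
    f = np.asarray(vertical_grf, dtype=float)
    above = f > threshold
    if not above.any():
        raise EventDetectionError(
            f"no stance phase: vertical GRF never exceeds {threshold} BW"
        )
    heel_strike = int(np.argmax(above))
    below_after = ~above[heel_strike:]
    if not below_after.any():
        raise EventDetectionError("stance never ends: force stays above threshold")
    toe_off = heel_strike + int(np.argmax(below_after))
    return heel_strike, toe_off


def detect_cycle_span(
    vertical_grf: np.ndarray,
    fs: float,
    threshold: float = 0.02,
    cycle_mode: CycleMode = "auto",
) -> tuple[int, int]:
    """Span of one gait cycle as a half-open sample range ``[start, end)``.

    A full cycle runs from heel strike to the next ipsilateral heel strike,
    identified as the next supra-threshold rise after toe off. In "stance"
    mode (or "auto" with no second contact) the span is heel strike to toe off.
    """
    heel_strike, toe_off = detect_gait_events(vertical_grf, fs, threshold)
    f = np.asarray(vertical_grf, dtype=float)
    rise = f[toe_off:] > threshold
    if rise.any():
        next_heel_strike = toe_off + int(np.argmax(rise))
    else:
        next_heel_strike = None
    if cycle_mode == "full" or (cycle_mode == "auto" and next_heel_strike is not None):
        if next_heel_strike is None:
            raise EventDetectionError(
                "cycle_mode='full' but no second foot contact found after toe off"
            )
        return heel_strike, next_heel_strike
    return heel_strike, toe_off


def normalize_cycle(
    waveform: np.ndarray, start: int, end: int, n_samples: int
) -> np.ndarray:
    """Linearly resample ``waveform[start:end]`` onto ``n_samples`` points.

    Both endpoints of the span are included, so ``n_samples == end - start``
    is the identity. ``end`` is exclusive, as in slicing.
    """
    w = np.asarray(waveform, dtype=float)
    if not (0 <= start < end <= w.shape[-1]):
        raise ParameterError(f"invalid span [{start}, {end}) for length {w.shape[-1]}")
    if end - start < 2:
        raise ParameterError("degenerate span: need at least 2 samples")
    if n_samples < 4:
        raise ParameterError("n_samples must be >= 4")
    positions = np.linspace(start, end - 1, n_samples)
    return np.interp(positions, np.arange(w.shape[-1]), w)


def power_spectrum(waveform: np.ndarray, n_bins: int = 50) -> np.ndarray:
    """One-sided modulus spectrum (|DFT|) at bins ``0..n_bins-1``, DC included.

    Invariant to circular time shifts of the input — the property that lets
    trials with arbitrary cycle phasing share a feature space.
    """
    w = np.asarray(waveform, dtype=float)
    max_bins = w.shape[-1] // 2 + 1
    if n_bins < 1 or n_bins > max_bins:
        raise ParameterError(
            f"n_bins must be in [1, {max_bins}] for {w.shape[-1]} samples; got {n_bins}"
        )
    return np.abs(np.fft.rfft(w, axis=-1))[..., :n_bins]


def filtered_waveforms(trial: Trial, config: PreprocessConfig) -> np.ndarray:
    """All 30 channels of a trial after their group-specific low-pass filters."""
    out = np.empty_like(trial.waveforms)
    for j, name in enumerate(VARIABLE_NAMES):
        cutoff = config.grf_cutoff_hz if is_grf(name) else config.kinematic_cutoff_hz
        out[:, j] = butterworth_zero_lag(
            trial.waveforms[:, j], trial.sampling_rate_hz, cutoff, config.filter_order
        )
    return out


def normalized_cycles(trial: Trial, config: PreprocessConfig) -> np.ndarray:
    """Filter, segment and cycle-normalise one trial.

    Returns an ``(n_samples, 30)`` array: each variable over 0-100% of the
    gait cycle. The cycle span is detected on the filtered vertical GRF.
    """
    filtered = filtered_waveforms(trial, config)
    start, end = detect_cycle_span(
        filtered[:, VERTICAL_GRF_INDEX],
        trial.sampling_rate_hz,
        config.event_threshold_bw,
        config.cycle_mode,
    )
    cycles = np.empty((config.n_samples, N_VARIABLES))
    for j in range(N_VARIABLES):
        cycles[:, j] = normalize_cycle(filtered[:, j], start, end, config.n_samples)
    return cycles


def spectra_from_cycles(cycles: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-variable modulus spectra of an ``(n_samples, 30)`` cycle block -> ``(30, n_bins)``."""
    return power_spectrum(cycles.T, n_bins)


@dataclasses.dataclass
class FeatureMatrix:
    """The input matrix M: one flattened spectral row per trial.

    ``features`` is ``(n_trials, 30 * n_bins)`` with variable-major flattening
    (variable 1 bins 0..n_bins-1, then variable 2, ...). ``index`` records the
    stable row order (subject, condition, repeat).
    """

    features: np.ndarray
    index: pd.DataFrame  # columns: subject_id, condition, repeat
    n_bins: int
    config: PreprocessConfig | None = None

    def __post_init__(self) -> None:
        if self.features.shape[1] != N_VARIABLES * self.n_bins:
            raise DataError(
                f"feature width {self.features.shape[1]} != 30 * n_bins = {N_VARIABLES * self.n_bins}"
            )
        if len(self.index) != self.features.shape[0]:
            raise DataError("index length does not match feature rows")

    @property
    def n_trials(self) -> int:
        return self.features.shape[0]

    @property
    def labels(self) -> np.ndarray:
        return self.index["condition"].to_numpy()

    @property
    def subject_ids(self) -> np.ndarray:
        return self.index["subject_id"].to_numpy()

    @property
    def subjects(self) -> list[str]:
        return sorted(set(self.index["subject_id"]))

    def rows_for_subjects(self, subjects) -> np.ndarray:
        """Boolean row mask selecting the given subjects."""
        subjects = set(subjects)
        return self.index["subject_id"].isin(subjects).to_numpy()

    def spectra(self, row: int) -> np.ndarray:
        """Un-flatten one trial row back to its ``(30, n_bins)`` spectra."""
        return self.features[row].reshape(N_VARIABLES, self.n_bins)

    # -- persistence ---------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Metadata columns followed by the flattened spectral bins."""
        cols = [f"{v}_bin{b:02d}" for v in VARIABLE_NAMES for b in range(self.n_bins)]
        df = pd.concat(
            [self.index.reset_index(drop=True), pd.DataFrame(self.features, columns=cols)],
            axis=1,
        )
        df.to_csv(path, index=False)

    def save(self, path: str | Path) -> None:
        """Binary (.npz) container for fast reload."""
        np.savez_compressed(
            path,
            features=self.features,
            subject_id=self.index["subject_id"].to_numpy(dtype=object).astype(str),
            condition=self.index["condition"].to_numpy(dtype=object).astype(str),
            repeat=self.index["repeat"].to_numpy(dtype=int),
            n_bins=self.n_bins,
            config=json.dumps(self.config.to_dict() if self.config else None),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FeatureMatrix":
        with np.load(path, allow_pickle=False) as z:
            index = pd.DataFrame(
                {
                    "subject_id": z["subject_id"].astype(str),
                    "condition": z["condition"].astype(str),
                    "repeat": z["repeat"].astype(int),
                }
            )
            cfg = json.loads(str(z["config"]))
            return cls(
                features=z["features"],
                index=index,
                n_bins=int(z["n_bins"]),
                config=PreprocessConfig(**cfg) if cfg else None,
            )


def build_feature_matrix(
    cohort: Cohort, config: PreprocessConfig | None = None
) -> FeatureMatrix:
    """Run the full per-trial pipeline over a cohort and stack the rows.

    Row order follows the cohort's trial order and is recorded in the index.
    Any trial failing event detection aborts the build with an error naming it.
    """
    config = config or PreprocessConfig()
    rows = np.empty((cohort.n_trials, N_VARIABLES * config.n_bins))
    meta = []
    for i, trial in enumerate(cohort.trials):
        try:
            cycles = normalized_cycles(trial, config)
        except EventDetectionError as exc:
            raise EventDetectionError(f"trial {trial.key}: {exc}") from exc
        rows[i] = spectra_from_cycles(cycles, config.n_bins).ravel()
        meta.append(trial.key)
    index = pd.DataFrame(meta, columns=["subject_id", "condition", "repeat"])
    return FeatureMatrix(features=rows, index=index, n_bins=config.n_bins, config=config)
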