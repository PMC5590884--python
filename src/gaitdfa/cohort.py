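"""Cohort data model and tabular I/O.

A trial is one gait cycle's worth of the 30 catalog waveforms plus metadata
(subject, condition, trial repeat, sampling rate). On disk a cohort is a
directory of per-trial CSV files (one row per time sample, one column per
catalog variable, UTF-8, '.' decimal separator, mandatory header) indexed by a
``manifest.csv`` with columns ``subject_id, condition, repeat, sampling_rate_hz,
file``. The load/write round trip is lossless to text-serialisation precision.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import CONDITIONS, N_VARIABLES, VARIABLE_NAMES
from .errors import CohortError

MANIFEST_COLUMNS = ("subject_id", "condition", "repeat", "sampling_rate_hz", "file")
MANIFEST_NAME = "manifest.csv"

#: Minimum number of time samples a trial must carry.
MIN_SAMPLES = 4


@dataclasses.dataclass
class Trial:
    """One recorded gait cycle: 30 waveforms with identifying metadata.

    ``waveforms`` is a ``(T, 30)`` float array whose columns follow the catalog
    order; ``T`` may differ between trials before cycle-length normalisation.
    """

    subject_id: str
    condition: str
    repeat_index: int
    sampling_rate_hz: float
    waveforms: np.ndarray

    def __post_init__(self) -> None:
        self.waveforms = np.asarray(self.waveforms, dtype=float)
        if self.condition not in CONDITIONS:
            raise CohortError(
                f"trial {self.key}: condition {self.condition!r} not in {CONDITIONS}"
            )
        if self.waveforms.ndim != 2 or self.waveforms.shape[1] != N_VARIABLES:
            raise CohortError(
                f"trial {self.key}: waveforms must be (T, {N_VARIABLES}), "
                f"got {self.waveforms.shape}"
            )
        if self.waveforms.shape[0] < MIN_SAMPLES:
            raise CohortError(f"trial {self.key}: needs at least {MIN_SAMPLES} samples")
        if not np.isfinite(self.waveforms).all():
            raise CohortError(f"trial {self.key}: non-finite samples present")
        if self.sampling_rate_hz <= 0:
            raise CohortError(f"trial {self.key}: sampling rate must be positive")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.subject_id, self.condition, self.repeat_index)

    @property
    def n_samples(self) -> int:
        return self.waveforms.shape[0]

    def waveform(self, name: str) -> np.ndarray:
        """Return one named variable's samples as a 1-D array."""
        return self.waveforms[:, VARIABLE_NAMES.index(name)]


@dataclasses.dataclass
class Cohort:
    """An ordered collection of trials with unique (subject, condition, repeat) keys."""

    trials: list[Trial]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, int]] = set()
        for t in self.trials:
            if t.key in seen:
                raise CohortError(f"duplicate trial key {t.key}")
            seen.add(t.key)

    @property
    def subjects(self) -> list[str]:
        """Sorted unique subject ids."""
        return sorted({t.subject_id for t in self.trials})

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trial_counts(self) -> pd.DataFrame:
        """Per-subject trial counts per condition (subjects x conditions)."""
        rows = [(t.subject_id, t.condition) for t in self.trials]
        df = pd.DataFrame(rows, columns=["subject_id", "condition"])
        counts = df.value_counts().unstack(fill_value=0)
        return counts.reindex(columns=list(CONDITIONS), fill_value=0)


@dataclasses.dataclass
class ValidationReport:
    """Outcome of :func:`validate_cohort`: overall pass flag plus findings."""

    passed: bool
    messages: list[str]
    counts: pd.DataFrame


def _trial_filename(trial: Trial) -> str:
    return f"{trial.subject_id}_{trial.condition}_{trial.repeat_index:02d}.csv"


def write_cohort(cohort: Cohort, root_path: str | Path) -> Path:
    """Write each trial as a CSV and a manifest; returns the manifest path.

    Waveform values are serialised with 17 significant digits so that a reload
    reproduces them to double precision.
    """
    root = Path(root_path)
    trials_dir = root / "trials"
    trials_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for trial in cohort.trials:
        fname = _trial_filename(trial)
        df = pd.DataFrame(trial.waveforms, columns=list(VARIABLE_NAMES))
        df.to_csv(trials_dir / fname, index=False, float_format="%.17g")
        records.append(
            {
                "subject_id": trial.subject_id,
                "condition": trial.condition,
                "repeat": trial.repeat_index,
                "sampling_rate_hz": trial.sampling_rate_hz,
                "file": f"trials/{fname}",
            }
        )
    manifest = root / MANIFEST_NAME
    pd.DataFrame.from_records(records, columns=list(MANIFEST_COLUMNS)).to_csv(
        manifest, index=False
    )
    return manifest


def load_cohort(root_path: str | Path, manifest: str | Path | None = None) -> Cohort:
    """Load a cohort from ``root_path`` using its manifest.

    Variable columns are reordered to catalog order regardless of the order in
    the trial files. A missing variable column, a duplicate trial key or a
    non-numeric cell is a hard error naming the offending file and column.
    """
    root = Path(root_path)
    manifest_path = Path(manifest) if manifest is not None else root / MANIFEST_NAME
    if not manifest_path.exists():
        raise CohortError(f"manifest not found: {manifest_path}")
    mdf = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in mdf.columns]
    if missing:
        raise CohortError(f"manifest {manifest_path} lacks columns {missing}")
    if len(mdf) == 0:
        raise CohortError("no trials: manifest is empty")

    trials: list[Trial] = []
    for row in mdf.itertuples(index=False):
        fpath = root / str(row.file)
        if not fpath.exists():
            raise CohortError(f"waveform file missing: {fpath}")
        df = pd.read_csv(fpath)
        absent = [v for v in VARIABLE_NAMES if v not in df.columns]
        if absent:
            raise CohortError(f"file {fpath}: missing variable column(s) {absent}")
        df = df[list(VARIABLE_NAMES)]
        non_numeric = df.columns[
            [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
        ]
        if len(non_numeric):
            col = non_numeric[0]
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise CohortError(
                f"file {fpath}: non-numeric cell in column {col!r}, row {int(bad[0]) + 2}"
            )
        if df.isna().any().any():
            col = df.columns[df.isna().any()][0]
            raise CohortError(f"file {fpath}: missing sample in column {col!r}")
        trials.append(
            Trial(
                subject_id=str(row.subject_id),
                condition=str(row.condition),
                repeat_index=int(row.repeat),
                sampling_rate_hz=float(row.sampling_rate_hz),
                waveforms=df.to_numpy(dtype=float),
            )
        )
    return Cohort(trials=trials)


def validate_cohort(cohort: Cohort, trials_per_condition: int | None = None) -> ValidationReport:
    """Report per-subject trial balance; never raises.

    Passes when every subject carries an equal, non-zero number of trials of
    each condition (and exactly ``trials_per_condition`` of each when given).
    """
    messages: list[str] = []
    if cohort.n_trials == 0:
        return ValidationReport(False, ["no subjects"], pd.DataFrame())
    counts = cohort.trial_counts()
    passed = True
    for subject, row in counts.iterrows():
        per_cond = [int(row[c]) for c in CONDITIONS]
        if len(set(per_cond)) != 1 or per_cond[0] == 0:
            passed = False
            messages.append(
                f"subject {subject}: imbalanced trials "
                + ", ".join(f"{c}={int(row[c])}" for c in CONDITIONS)
            )
        elif trials_per_condition is not None and per_cond[0] != trials_per_condition:
            passed = False
            messages.append(
                f"subject {subject}: {per_cond[0]} trials per condition, "
                f"expected {trials_per_condition}"
            )
    if passed:
        messages.append(
            f"{len(counts)} subjects, {cohort.n_trials} trials, balanced per condition"
        )
    return ValidationReport(passed, messages, counts)
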