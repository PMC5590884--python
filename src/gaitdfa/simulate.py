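"""Seeded synthetic gait cohorts with a planted, recoverable condition effect.

The generator emulates the statistical structure the pipeline consumes — not
biomechanical realism. Each joint variable is a sum of a few cycle-locked
harmonics whose amplitudes and phases vary between subjects (individual gait
signatures) and, more weakly, between trials (step-to-step variability plus
measurement noise). The vertical GRF is a non-negative double-peaked stance
profile repeated at the next ipsilateral contact, so threshold event detection
finds a full gait cycle; AP/ML GRFs are stance-windowed oscillations.

The two conditions differ only on a named subset of "discriminating"
variables (default: the ankle-dominant set — transverse-plane ankle angle and
power, sagittal ankle angle, coronal ankle moment), where the positive
condition (shod) adds a fixed harmonic signature scaled by
``condition_effect_size``. "Generic" subjects express this cohort-wide
pattern; "singular" subjects deviate from it, either by expressing the effect
in shuffled (non-discriminating) variables or with opposite sign. Training on
generic subjects is what the subset optimisation is meant to discover.

Randomness is one hierarchical stream (cohort -> subject -> condition ->
trial), so the same seed is bitwise reproducible and adding trials does not
perturb existing ones.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .catalog import (
    GRF_VARIABLES,
    N_VARIABLES,
    VARIABLE_NAMES,
    variable_index,
)
from .cohort import Cohort, Trial
from .errors import ParameterError

DEFAULT_DISCRIMINATING = (
    "ankle_angle_transverse",
    "ankle_power_transverse",
    "ankle_angle_sagittal",
    "ankle_moment_coronal",
)

SINGULAR_MODES = ("shuffled-variables", "opposite-sign")

# stance-profile shape constants (fractions of the gait cycle / BW)
_STANCE_FRACTION = 0.35
_IMPACT_CENTER, _IMPACT_WIDTH, _IMPACT_PEAK = 0.07, 0.025, 1.6
_ACTIVE_CENTER, _ACTIVE_WIDTH, _ACTIVE_PEAK = 0.17, 0.06, 2.4
_AP_AMPLITUDE = 0.25
_ML_AMPLITUDE = 0.08


@dataclasses.dataclass
class SimConfig:
    """Cohort-generation settings.

    The defaults mirror the reference study design: 20 subjects, 5 trials per
    condition per subject (200 trials), with the condition effect planted in
    the four ankle-dominant variables. ``subject_effect_sd`` (relative
    amplitude / phase spread between subjects) dominates ``trial_noise_sd``
    (between trials of one subject), as in real gait data where individual
    signatures outweigh step-to-step variation. ``condition_effect_size`` is
    the RMS amplitude of the planted shod-barefoot signature relative to the
    unit-scale base waveforms.
    """

    n_subjects: int = 20
    trials_per_condition: int = 5
    sampling_rate_hz: float = 200.0
    cycle_duration_s: float = 0.72
    harmonics: int = 6
    subject_effect_sd: float = 0.2
    trial_noise_sd: float = 0.05
    condition_effect_size: float = 0.35
    discriminating_variables: tuple[str, ...] = DEFAULT_DISCRIMINATING
    n_singular_subjects: int = 4
    singular_mode: str = "shuffled-variables"
    variable_scales: dict | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("need at least 2 subjects")
        if self.trials_per_condition < 1:
            raise ParameterError("need at least 1 trial per condition")
        if self.harmonics < 1:
            raise ParameterError("need at least 1 harmonic")
        for field in ("subject_effect_sd", "trial_noise_sd", "condition_effect_size"):
            if getattr(self, field) < 0:
                raise ParameterError(f"{field} must be >= 0")
        unknown = [v for v in self.discriminating_variables if v not in VARIABLE_NAMES]
        if unknown:
            raise ParameterError(f"unknown discriminating variable(s): {unknown}")
        if not 0 <= self.n_singular_subjects < self.n_subjects:
            raise ParameterError("n_singular_subjects must be < n_subjects")
        if self.singular_mode not in SINGULAR_MODES:
            raise ParameterError(f"singular_mode must be one of {SINGULAR_MODES}")
        if self.sampling_rate_hz <= 0 or self.cycle_duration_s <= 0:
            raise ParameterError("sampling rate and cycle duration must be positive")
        if self.variable_scales:
            unknown = [v for v in self.variable_scales if v not in VARIABLE_NAMES]
            if unknown:
                raise ParameterError(f"unknown variable(s) in variable_scales: {unknown}")

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.sampling_rate_hz * self.cycle_duration_s))

    @property
    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    @property
    def singular_subjects(self) -> list[str]:
        """Singular subjects are the last ids — deterministic by design, so the
        planted truth is a pure function of the config."""
        return self.subject_ids[self.n_subjects - self.n_singular_subjects :]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["discriminating_variables"] = list(self.discriminating_variables)
        return d


def planted_truth(config: SimConfig) -> dict:
    """Machine-readable ground truth for recovery tests; JSON round-trippable."""
    return {
        "discriminating_variables": list(config.discriminating_variables),
        "singular_subjects": config.singular_subjects,
        "singular_mode": config.singular_mode,
        "condition_effect_size": config.condition_effect_size,
        "rng_seed": config.rng_seed,
    }


def _cohort_templates(rng: np.random.Generator, config: SimConfig):
    """Cohort-level constants: base harmonic templates and the effect contrasts.

    The condition effect is an amplitude/spectral-content shift: shod scales
    the harmonic amplitudes of an affected variable by ``1 +
    condition_effect_size * contrast_h``. Modulating the amplitudes of the
    harmonics already present (rather than adding an independent random-phase
    component) makes the shift first-order visible in the modulus spectrum for
    every affected variable. Each variable's contrast vector is normalised so
    the relative RMS amplitude change equals ``condition_effect_size``.
    """
    H = config.harmonics
    decay = 1.0 / np.arange(1, H + 1)
    amps = rng.uniform(0.5, 1.5, size=(N_VARIABLES, H)) * decay
    phases = rng.uniform(0, 2 * np.pi, size=(N_VARIABLES, H))
    contrasts = rng.normal(size=(N_VARIABLES, H))
    norm = np.sqrt(np.sum((contrasts * amps) ** 2, axis=1) / np.sum(amps**2, axis=1))
    contrasts /= norm[:, None]
    return amps, phases, contrasts


def _stance_profile(tau: np.ndarray, impact_gain: float, active_gain: float) -> np.ndarray:
    """Vertical GRF (BW) over cycle fraction ``tau`` (periodic; zero in flight)."""
    tau = np.mod(tau, 1.0)
    f = _IMPACT_PEAK * impact_gain * np.exp(-(((tau - _IMPACT_CENTER) / _IMPACT_WIDTH) ** 2))
    f += _ACTIVE_PEAK * active_gain * np.exp(-(((tau - _ACTIVE_CENTER) / _ACTIVE_WIDTH) ** 2))
    return np.where(tau < _STANCE_FRACTION + 0.05, f, 0.0)


def _stance_window(tau: np.ndarray) -> np.ndarray:
    tau = np.mod(tau, 1.0)
    inside = tau < _STANCE_FRACTION
    return np.where(inside, np.sin(np.pi * tau / _STANCE_FRACTION) ** 2, 0.0)


def generate_cohort(config: SimConfig | None = None) -> Cohort:
    """Generate a seeded cohort in catalog layout.

    Trials are ordered subject-major, shod before barefoot, repeats ascending.
    Identical configs yield bitwise-identical cohorts.
    """
    config = config or SimConfig()
    root = np.random.SeedSequence(config.rng_seed)
    template_ss, *subject_ss = root.spawn(1 + config.n_subjects)
    amps, phases, contrasts = _cohort_templates(np.random.default_rng(template_ss), config)

    H = config.harmonics
    fs = config.sampling_rate_hz
    n_total = int(round(1.35 * config.samples_per_cycle))
    tau = np.arange(n_total) / fs / config.cycle_duration_s  # cycle fraction
    harm = np.arange(1, H + 1)
    base_arg = 2 * np.pi * np.outer(harm, tau)  # (H, T)

    disc_idx = np.array([variable_index(v) for v in config.discriminating_variables])
    singular = set(config.singular_subjects)
    grf_idx = {variable_index(v) for v in GRF_VARIABLES}
    vz = variable_index("grf_vertical")
    vap = variable_index("grf_anterior_posterior")
    vml = variable_index("grf_medial_lateral")
    scales = np.ones(N_VARIABLES)
    if config.variable_scales:
        for name, s in config.variable_scales.items():
            scales[variable_index(name)] = float(s)

    trials: list[Trial] = []
    for subj_i, subject in enumerate(config.subject_ids):
        s_subject, s_shod, s_barefoot = subject_ss[subj_i].spawn(3)
        rng_subject = np.random.default_rng(s_subject)
        sub_gain = 1.0 + rng_subject.normal(0, config.subject_effect_sd, (N_VARIABLES, H))
        sub_phase = rng_subject.normal(0, config.subject_effect_sd, (N_VARIABLES, H))
        grf_sub_gain = 1.0 + rng_subject.normal(0, config.subject_effect_sd / 2, 3)

        # where this subject expresses the condition effect
        if subject in singular and config.singular_mode == "shuffled-variables":
            candidates = np.setdiff1d(np.arange(N_VARIABLES), disc_idx)
            effect_idx = rng_subject.choice(candidates, size=len(disc_idx), replace=False)
            effect_sign = 1.0
        elif subject in singular:  # opposite-sign
            effect_idx = disc_idx
            effect_sign = -1.0
        else:
            effect_idx = disc_idx
            effect_sign = 1.0

        for condition, cond_ss in (("shod", s_shod), ("barefoot", s_barefoot)):
            trial_ss = cond_ss.spawn(config.trials_per_condition)
            for rep in range(config.trials_per_condition):
                rng = np.random.default_rng(trial_ss[rep])
                trial_gain = 1.0 + rng.normal(0, config.trial_noise_sd, (N_VARIABLES, H))
                trial_phase = rng.normal(0, config.trial_noise_sd, (N_VARIABLES, H))

                A = amps * sub_gain * trial_gain  # (V, H)
                if condition == "shod" and config.condition_effect_size > 0:
                    A = A.copy()
                    A[effect_idx] *= (
                        1.0
                        + effect_sign * config.condition_effect_size * contrasts[effect_idx]
                    )
                ph = phases + sub_phase + trial_phase
                wave = np.einsum(
                    "vh,vht->vt", A, np.sin(base_arg[None, :, :] + ph[:, :, None])
                )
                wave += rng.normal(0, config.trial_noise_sd, wave.shape)
                wave *= scales[:, None]

                # GRF channels overwrite their harmonic placeholders;
                # contact-timing jitter scales with the trial-noise knob
                # (0.004 of a cycle at the default sd)
                timing = rng.normal(0, 0.08 * config.trial_noise_sd)
                gz = grf_sub_gain[2] * (1.0 + rng.normal(0, config.trial_noise_sd))
                vertical = _stance_profile(tau - timing, gz, gz)
                window = _stance_window(tau - timing)
                ap = (
                    -_AP_AMPLITUDE
                    * grf_sub_gain[0]
                    * (1.0 + rng.normal(0, config.trial_noise_sd))
                    * np.sin(2 * np.pi * np.mod(tau - timing, 1.0) / _STANCE_FRACTION)
                    * window
                )
                ml = (
                    _ML_AMPLITUDE
                    * grf_sub_gain[1]
                    * (1.0 + rng.normal(0, config.trial_noise_sd))
                    * np.sin(3 * np.pi * np.mod(tau - timing, 1.0) / _STANCE_FRACTION)
                    * window
                )
                for gi, g in ((vz, vertical), (vap, ap), (vml, ml)):
                    if condition == "shod" and gi in set(effect_idx) and gi in grf_idx:
                        g = g * (1.0 + effect_sign * config.condition_effect_size)
                    wave[gi] = g * scales[gi]
                # stance-proportional jitter keeps the flight phase at exact zero
                wave[vz] += rng.normal(0, config.trial_noise_sd * 0.05, n_total) * window
                wave[vz] = np.maximum(wave[vz], 0.0)

                trials.append(
                    Trial(
                        subject_id=subject,
                        condition=condition,
                        repeat_index=rep + 1,
                        sampling_rate_hz=fs,
                        waveforms=wave.T.copy(),
                    )
                )
    return Cohort(trials=trials)


def write_dataset(config: SimConfig, root_path: str | Path) -> Path:
    """Generate a cohort and write it (plus ``truth.json``) to ``root_path``."""
    from .cohort import write_cohort

    root = Path(root_path)
    cohort = generate_cohort(config)
    manifest = write_cohort(cohort, root)
    (root / "truth.json").write_text(json.dumps(planted_truth(config), indent=2))
    (root / "sim_config.json").write_text(json.dumps(config.to_dict(), indent=2))
    return manifest
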