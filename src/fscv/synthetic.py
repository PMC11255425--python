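"""Synthetic multichannel FSCV recordings with known ground truth.

No raw in-vivo recordings are deposited for this kind of experiment, so the
generator stands in for the animal: it emulates stimulated dopamine
transients riding on drifting, noisy voltammogram backgrounds across a
16-channel carbon-fiber array, with cross-fiber sensitivity heterogeneity,
channel dropout and slow pH drift.  Everything is seed-deterministic, and the
ground truth (true concentration trace, per-channel sensitivity, true ES DA
and τ) is returned and serializable, so every pipeline stage can be verified
quantitatively.

Signal model per channel::

    scan(t) = background·(1 + drift(t))
              + [DA](t)/1000 · sensitivity · da_template
              + pH(t) · ph_template
              + white noise

with [DA](t) evolving as release-per-pulse impulses with first-order
reuptake, ``dc/dt = r(t) − c/τ``.

Realism anchors: stimulated release of order 10²–10³ nM at 30–60 Hz trains of
15–60 pulses; cross-fiber coefficient of variation of stimulated release
≈ 0.27; post-preprocessing baseline current SD well below the 0.4 nA
stability bound used to qualify electrodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .waveform import RampWaveform, StimEvent
from .raw_io import ScanStream, write_raw
from .preprocess import lowpass_scan_filter
from .chemometrics import TrainingSet
from .kinetics import es_da_release

__all__ = [
    "GroundTruth",
    "RecordingConfig",
    "GroupSpec",
    "CohortDesign",
    "simulate_kinetics",
    "make_templates",
    "synthesize_scan",
    "make_training_set",
    "generate_recording",
    "generate_cohort",
    "default_cohort_design",
]


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def simulate_kinetics(
    stim: StimEvent,
    release_per_pulse_nM: float = 20.0,
    tau_s: float = 1.0,
    duration_s: float = 30.0,
    dt: float = 0.1,
) -> "tuple[np.ndarray, np.ndarray]":
    """Dopamine concentration trace for one stimulation train.

    Each stimulus pulse releases ``release_per_pulse_nM`` instantaneously and
    clearance is first order with time constant ``tau_s``; the trace is the
    exact superposition ``c(t) = Σ_{t_p < t} r·exp(−(t−t_p)/τ)`` over pulses
    already delivered (a pulse contributes strictly after its instant),
    evaluated on a grid of spacing ``dt`` (the scan period).
    """
    if release_per_pulse_nM < 0 or tau_s <= 0 or dt <= 0 or duration_s <= 0:
        raise ValueError("kinetic parameters must be positive")
    times = np.arange(int(round(duration_s / dt))) * dt
    if stim is None or stim.pulse_count == 0:
        return times, np.zeros_like(times)
    stim.validate_within(duration_s)
    lags = times[:, None] - stim.pulse_times()[None, :]
    conc = release_per_pulse_nM * np.where(lags > 0, np.exp(-lags / tau_s), 0.0).sum(axis=1)
    return times, conc


# ---------------------------------------------------------------------------
# Voltammogram templates
# ---------------------------------------------------------------------------

def _voltage_gaussian(v: np.ndarray, mask: np.ndarray, center_v: float, sigma_v: float) -> np.ndarray:
    g = np.exp(-0.5 * ((v - center_v) / sigma_v) ** 2)
    return np.where(mask, g, 0.0)


def make_templates(
    waveform: RampWaveform,
    background_amplitude_nA: float = 300.0,
    ph_amplitude_nA_per_pH: float = 30.0,
) -> "dict[str, np.ndarray]":
    """Analyte and background voltammogram shapes for one scan.

    The dopamine template has an oxidation peak near +0.6 V on the rising
    limb and a reduction trough near −0.2 V on the falling limb, normalized
    to unit oxidation peak (so amplitude in nA = concentration in µM times
    sensitivity in nA/µM).  The pH template is a distinct broad signature
    scaled to nA per pH unit.  The background emulates the large capacitive
    charging current (sign follows dV/dt) and is returned in nA.
    """
    v = waveform.voltage_sequence()
    n = waveform.samples_per_scan
    rising = np.arange(n) < n // 2
    falling = ~rising

    da = (
        _voltage_gaussian(v, rising, 0.6, 0.15)
        - 0.4 * _voltage_gaussian(v, falling, -0.2, 0.12)
    )
    da = da / np.max(da)

    ph = (
        _voltage_gaussian(v, rising, 1.0, 0.25)
        - 0.6 * _voltage_gaussian(v, falling, 0.3, 0.20)
        + 0.3 * _voltage_gaussian(v, rising, -0.1, 0.15)
    )
    ph = ph / np.max(np.abs(ph)) * ph_amplitude_nA_per_pH

    # charging current: +C on the rising limb, −C falling, with soft edges
    # and a mild potential-dependent curvature
    square = np.where(rising, 1.0, -1.0)
    edge = np.exp(-0.5 * ((np.arange(n) - n // 2) / (0.01 * n)) ** 2)
    square = square * (1 - edge)
    background = background_amplitude_nA * square * (1.0 + 0.1 * (v - v.mean()))

    return {"background": background, "da": da, "ph": ph}


def synthesize_scan(
    da_nM: float,
    ph_shift: float,
    waveform: RampWaveform,
    templates: "dict[str, np.ndarray]",
    sensitivity_nA_per_uM: float = 10.0,
) -> np.ndarray:
    """One voltammogram: background + dopamine + pH components (no noise)."""
    for key in ("background", "da", "ph"):
        if templates[key].shape[0] != waveform.samples_per_scan:
            raise ValueError(f"template '{key}' does not match the waveform length")
    return (
        templates["background"]
        + (da_nM / 1000.0) * sensitivity_nA_per_uM * templates["da"]
        + ph_shift * templates["ph"]
    )


def make_training_set(
    waveform: "RampWaveform | None" = None,
    templates: "dict[str, np.ndarray] | None" = None,
    sensitivity_nA_per_uM: float = 10.0,
    da_magnitudes_uM: "tuple[float, ...]" = (0.25, 0.5, 1.0, 2.0, 4.0),
    acidic_shifts: "tuple[float, ...]" = (-0.2, -0.1, -0.05),
    basic_shifts: "tuple[float, ...]" = (0.1, 0.2),
    noise_sd_nA: float = 0.0,
    lowpass: bool = True,
    seed: "int | None" = 0,
) -> TrainingSet:
    """Labeled reference voltammograms in the standard 5 DA + 3 acid + 2 basic
    composition.

    References are background-corrected (the static background cancels in the
    drift-removal stage, so it does not appear here) and, like measurement
    scans, passed through the per-scan low-pass filter.  DA rows are labeled
    by their oxidation-peak current in nA (magnitude × sensitivity); the
    conversion to concentration happens downstream through the calibration
    factor.  pH rows are labeled by their pH shift (acidic negative).
    """
    waveform = waveform or RampWaveform()
    templates = templates or make_templates(waveform)
    rng = np.random.default_rng(seed)

    rows, analytes, mags = [], [], []
    for m in da_magnitudes_uM:
        rows.append(m * sensitivity_nA_per_uM * templates["da"])
        analytes.append("DA")
        mags.append(m * sensitivity_nA_per_uM)
    for s in acidic_shifts:
        rows.append(s * templates["ph"])
        analytes.append("acidic_pH")
        mags.append(s)
    for s in basic_shifts:
        rows.append(s * templates["ph"])
        analytes.append("basic_pH")
        mags.append(s)

    spectra = np.vstack(rows)
    if noise_sd_nA > 0:
        spectra = spectra + rng.normal(0, noise_sd_nA, spectra.shape)
    if lowpass:
        stream = ScanStream(
            channel_id=0,
            scans=spectra,
            scan_times=np.arange(spectra.shape[0]) * waveform.period,
            waveform=waveform,
        )
        spectra = lowpass_scan_filter(stream).scans
    return TrainingSet(spectra=spectra, analytes=analytes,
                       magnitudes=np.array(mags), units="nA")


# ---------------------------------------------------------------------------
# Full recording generator
# ---------------------------------------------------------------------------

@dataclass
class RecordingConfig:
    """Study conditions for one synthetic 16-channel recording.

    Defaults emulate a stabilized electrode in a standard 30 s stimulation
    recording: 60 Hz 30-pulse train 5 s in, release scaled to give stimulated
    peaks of a few hundred nM, cross-fiber sensitivity CV 0.27, additive
    white noise of 0.1 nA per sample and slow multiplicative background
    drift (exponential charging settling plus a smoothed random walk).
    """

    duration_s: float = 30.0
    n_channels: int = 16
    stim: "StimEvent | None" = field(default_factory=StimEvent)
    release_per_pulse_nM: float = 20.0
    tau_s: float = 1.0
    sensitivity_mean_nA_per_uM: float = 10.0
    sensitivity_cv: float = 0.27
    noise_sd_nA: float = 0.1
    background_amplitude_nA: float = 300.0
    drift_exp_frac: float = 0.02          # charging settling amplitude, rel. to bg
    drift_exp_tau_s: float = 120.0
    drift_rw_frac_per_scan: float = 2e-5  # random-walk step SD, rel. to bg
    drift_rw_smooth_s: float = 5.0
    ph_drift_amplitude: float = 0.02      # slow pH wander, pH units
    ph_drift_period_s: float = 60.0
    dead_channels: "tuple[int, ...]" = ()

    def waveform(self) -> RampWaveform:
        return RampWaveform()


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    seed: int
    times: np.ndarray
    conc_nM: np.ndarray
    es_da_nM: float
    tau_s: float
    sensitivities_nA_per_uM: np.ndarray
    per_channel_es_da_nM: np.ndarray
    noise_sd_nA: float
    dead_channels: "tuple[int, ...]"

    def to_json(self, path: "str | Path") -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        d["dead_channels"] = list(d["dead_channels"])
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: "str | Path") -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        for k in ("times", "conc_nM", "sensitivities_nA_per_uM", "per_channel_es_da_nM"):
            d[k] = np.asarray(d[k], dtype=float)
        d["dead_channels"] = tuple(d["dead_channels"])
        return cls(**d)


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def generate_recording(
    config: "RecordingConfig | None" = None,
    seed: int = 0,
    out_dir: "str | Path | None" = None,
) -> "tuple[list[ScanStream], GroundTruth]":
    """Generate one multichannel recording, optionally writing the raw dialect.

    Per-channel sensitivities are drawn log-normally with the dispersion set
    by ``sensitivity_cv`` (mean preserved), so the apparent per-channel ES DA
    under a single cohort calibration factor reproduces the target
    cross-fiber coefficient of variation.  Same seed ⇒ byte-identical output.
    """
    config = config or RecordingConfig()
    rng = np.random.default_rng(seed)
    waveform = config.waveform()
    templates = make_templates(waveform, config.background_amplitude_nA)

    times, conc = simulate_kinetics(
        config.stim,
        config.release_per_pulse_nM,
        config.tau_s,
        config.duration_s,
        dt=waveform.period,
    )
    n_scans = times.size

    if config.stim is not None:
        truth_kr = es_da_release(times, conc, config.stim)
        es_da_true = truth_kr.es_da
    else:
        es_da_true = 0.0

    if config.sensitivity_cv > 0:
        sigma = np.sqrt(np.log1p(config.sensitivity_cv**2))
        sens = config.sensitivity_mean_nA_per_uM * rng.lognormal(
            -sigma**2 / 2.0, sigma, config.n_channels
        )
    else:
        sens = np.full(config.n_channels, config.sensitivity_mean_nA_per_uM)
    sens = sens.copy()
    for ch in config.dead_channels:
        sens[ch] = 0.0

    ph_phase = rng.uniform(0, 2 * np.pi)
    ph_t = config.ph_drift_amplitude * np.sin(
        2 * np.pi * times / config.ph_drift_period_s + ph_phase
    )

    smooth_w = max(1, int(round(config.drift_rw_smooth_s * waveform.repetition_rate)))
    streams = []
    for ch in range(config.n_channels):
        drift = config.drift_exp_frac * np.exp(-times / config.drift_exp_tau_s)
        if config.drift_rw_frac_per_scan > 0:
            rw = np.cumsum(rng.normal(0, config.drift_rw_frac_per_scan, n_scans))
            drift = drift + _smooth(rw, smooth_w)
        scans = (
            (1.0 + drift)[:, None] * templates["background"][None, :]
            + (conc / 1000.0 * sens[ch])[:, None] * templates["da"][None, :]
            + ph_t[:, None] * templates["ph"][None, :]
        )
        if config.noise_sd_nA > 0:
            scans = scans + rng.normal(0, config.noise_sd_nA, scans.shape)
        streams.append(
            ScanStream(
                channel_id=ch,
                scans=scans,
                scan_times=times.copy(),
                waveform=waveform,
                meta={"seed": seed},
            )
        )

    apparent = es_da_true * sens / config.sensitivity_mean_nA_per_uM
    truth = GroundTruth(
        seed=seed,
        times=times,
        conc_nM=conc,
        es_da_nM=es_da_true,
        tau_s=config.tau_s,
        sensitivities_nA_per_uM=sens,
        per_channel_es_da_nM=apparent,
        noise_sd_nA=config.noise_sd_nA,
        dead_channels=tuple(config.dead_channels),
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        write_raw(streams, out_dir)
        truth.to_json(out_dir / "truth.json")
    return streams, truth


# ---------------------------------------------------------------------------
# Cohort generator (fiber-level summary tables)
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """One experimental group in a chronic cohort design."""

    n_animals: int = 5
    es_da_mean_nM: float = 500.0
    tau_mean_s: float = 1.0
    es_da_week_slope: float = 0.0  # fractional change per week (sensitization)
    tau_week_slope: float = 0.0


@dataclass
class CohortDesign:
    """Groups × weeks × stimulation-parameter chronic design.

    Values are generated at the fiber level from the same distributional
    model as the raw-recording generator: a fixed log-normal fiber
    sensitivity multiplier (CV ``fiber_cv``, shared across weeks — the
    repeated-measures structure), multiplicative group/week/parameter
    effects, log-normal trial noise, and Bernoulli missingness emulating
    fibers that fail the response threshold on a given day.
    """

    groups: "dict[str, GroupSpec]"
    weeks: int = 4
    param_multipliers: "dict[str, float]" = field(
        default_factory=lambda: {"60Hz30p": 1.0, "60Hz60p": 1.4}
    )
    fibers_per_animal: int = 16
    fiber_cv: float = 0.27
    trial_noise_cv: float = 0.10
    tau_trial_cv: float = 0.15
    missing_rate: float = 0.0
    animal_sd: float = 0.0  # log-scale SD of an animal-level multiplier


def default_cohort_design(
    sensitization_slope: float = 0.0,
    n_animals: int = 5,
    missing_rate: float = 0.0,
) -> CohortDesign:
    """Two-group (male/female gonadectomized) 4-week, two-parameter design."""
    return CohortDesign(
        groups={
            "CAST_male": GroupSpec(n_animals=n_animals,
                                   es_da_week_slope=sensitization_slope),
            "OVX_female": GroupSpec(n_animals=n_animals,
                                    es_da_week_slope=sensitization_slope),
        },
        missing_rate=missing_rate,
    )


def generate_cohort(
    design: CohortDesign,
    seed: int = 0,
) -> "tuple['pandas.DataFrame', dict]":
    """Fiber-level ES DA / τ table for a chronic cohort, plus the truth table.

    Returns a long-format DataFrame with columns ``group, animal, fiber,
    week, param, es_da_nM, tau_s`` and a dict of the true cell means and
    effect parameters used.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    sigma_fiber = np.sqrt(np.log1p(design.fiber_cv**2)) if design.fiber_cv > 0 else 0.0
    sigma_trial = np.sqrt(np.log1p(design.trial_noise_cv**2)) if design.trial_noise_cv > 0 else 0.0
    sigma_tau = np.sqrt(np.log1p(design.tau_trial_cv**2)) if design.tau_trial_cv > 0 else 0.0

    rows = []
    truth_means = {}
    for gname, spec in design.groups.items():
        for a in range(spec.n_animals):
            animal_id = f"{gname}_a{a:02d}"
            animal_mult = (
                rng.lognormal(-design.animal_sd**2 / 2, design.animal_sd)
                if design.animal_sd > 0 else 1.0
            )
            fiber_mults = (
                rng.lognormal(-sigma_fiber**2 / 2, sigma_fiber, design.fibers_per_animal)
                if sigma_fiber > 0 else np.ones(design.fibers_per_animal)
            )
            for f in range(design.fibers_per_animal):
                fiber_id = f"{animal_id}_f{f:02d}"
                for week in range(1, design.weeks + 1):
                    week_es = 1.0 + spec.es_da_week_slope * (week - 1)
                    week_tau = 1.0 + spec.tau_week_slope * (week - 1)
                    for pname, pmult in design.param_multipliers.items():
                        truth_means[(gname, week, pname)] = (
                            spec.es_da_mean_nM * pmult * week_es
                        )
                        if design.missing_rate > 0 and rng.random() < design.missing_rate:
                            continue
                        es = (
                            spec.es_da_mean_nM * pmult * week_es
                            * animal_mult * fiber_mults[f]
                            * (rng.lognormal(-sigma_trial**2 / 2, sigma_trial)
                               if sigma_trial > 0 else 1.0)
                        )
                        tau = (
                            spec.tau_mean_s * week_tau
                            * (rng.lognormal(-sigma_tau**2 / 2, sigma_tau)
                               if sigma_tau > 0 else 1.0)
                        )
                        rows.append({
                            "group": gname, "animal": animal_id, "fiber": fiber_id,
                            "week": week, "param": pname,
                            "es_da_nM": es, "tau_s": tau,
                        })
    table = pd.DataFrame(rows)
    truth = {
        "cell_means_nM": {f"{g}|week{w}|{p}": m for (g, w, p), m in truth_means.items()},
        "fiber_cv": design.fiber_cv,
        "slopes": {g: s.es_da_week_slope for g, s in design.groups.items()},
        "seed": seed,
    }
    return table, truth
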