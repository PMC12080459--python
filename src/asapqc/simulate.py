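"""Synthetic ASAP-MS acquisitions, cohorts and probe cooling curves.

Every downstream stage of the pipeline can be exercised without instrument
data using the generators here, which emulate the acquisition protocol the
pipeline targets:

* scans every 0.9 s on a 1 Da m/z grid spanning 10-1000;
* a 30 s background insertion (empty probe in the hot ion source) showing a
  flat, non-decaying plateau of residual-calibrant signal above baseline;
* 25 s sample insertions whose TIC rises within a single scan and decays as
  ``baseline + A * exp(-t / tau)``;
* the saturation pathology (too much sample: high signal that does not
  decay), modelled as a decay time constant far exceeding the insertion;
* contaminant peaks from lens-tissue residue at m/z 257, 275, 285 (and 338
  for one brand), superposed on the sample profile;
* per-user spectral offsets and additive/multiplicative per-batch shifts for
  multi-sample cohorts.

All randomness flows through a single ``rng_seed``, so fixed seeds give
bit-identical streams. Ground truth (window positions, true unit-area
profiles, planted shifts) is stored alongside the generated data so recovery
tests never need to re-derive it.

The module also provides the exponential probe-tip cooling model
``T(t) = T_amb + (T0 - T_amb) * exp(-k t)`` and a least-squares fit for it,
used to reason about how long the probe must cool before sample loading.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .acquisition import ScanStream
from .errors import ValidationError
from .repeatability import FeatureMatrix

#: lens-tissue contaminant peaks (m/z, intensity relative to sample-profile area)
DEFAULT_CONTAMINANTS = ((257.0, 0.03), (275.0, 0.01), (285.0, 0.02))
#: additional contaminant peak seen for one lens-tissue brand
BRAND1_EXTRA_CONTAMINANT = (338.0, 0.025)


def default_mz_grid() -> np.ndarray:
    """1 Da bin centres spanning m/z 10-1000 (991 bins)."""
    return np.arange(10.0, 1001.0, 1.0)


def synthetic_metabolite_profile(
    mz_grid: np.ndarray, seed: int = 12345, n_peaks: int = 60
) -> np.ndarray:
    """A fixed, unit-area metabolite-like spectral profile.

    A mixture of narrow Gaussian peaks with positions weighted towards low
    m/z (small molecules dominate ASAP-MS metabolite spectra) on a weak
    chemical-noise floor. Deterministic for a given seed, independent of any
    acquisition seed, so cohorts share a common base spectrum.
    """
    rng = np.random.default_rng(seed)
    grid = np.asarray(mz_grid, dtype=float)
    lo, hi = grid[0], grid[-1]
    positions = lo + (hi - lo) * rng.beta(1.2, 3.0, size=n_peaks)
    heights = rng.lognormal(mean=0.0, sigma=1.0, size=n_peaks)
    widths = rng.uniform(0.6, 1.8, size=n_peaks)
    profile = np.zeros_like(grid)
    for p, h, w in zip(positions, heights, widths):
        profile += h * np.exp(-0.5 * ((grid - p) / w) ** 2)
    profile += 0.02 * profile.max() * np.exp(-(grid - lo) / 400.0)
    return profile / profile.sum()


def _residual_calibrant_profile(mz_grid: np.ndarray) -> np.ndarray:
    """Unit-area background profile: residual tuning-mix peaks plus a drifting floor."""
    grid = np.asarray(mz_grid, dtype=float)
    # tuning mixes are ladders of roughly evenly spaced reference masses
    peaks = np.arange(118.0, 1000.0, 122.0)
    profile = np.zeros_like(grid)
    for p in peaks:
        profile += np.exp(-0.5 * ((grid - p) / 0.7) ** 2)
    profile += 0.3 * np.exp(-(grid - grid[0]) / 250.0)
    return profile / profile.sum()


# ---------------------------------------------------------------------------
# acquisition generator
# ---------------------------------------------------------------------------


@dataclass
class AcquisitionConfig:
    """Parameters of one synthetic acquisition.

    Intensity parameters are TIC counts: ``baseline_level`` is the idle TIC,
    ``background_amplitude`` the extra TIC of the flat background plateau
    while the empty probe sits in the source, and ``insertion_amplitude`` the
    initial extra TIC of a sample burst. ``baseline_noise_sd`` is the
    per-bin Gaussian noise standard deviation (truncated at zero).
    """

    scan_period_s: float = 0.9
    mz_grid: np.ndarray = field(default_factory=default_mz_grid)
    baseline_level: float = 100.0
    baseline_noise_sd: float = 0.05
    background_window_s: float = 30.0
    background_amplitude: float = 2000.0
    n_insertions: int = 3
    insertion_duration_s: float = 25.0
    insertion_amplitude: float = 1.0e4
    decay_time_constant_s: float = 6.0
    contaminant_peaks: Sequence[tuple[float, float]] = DEFAULT_CONTAMINANTS
    saturation: bool = False
    lead_in_s: float = 30.0
    gap_s: float = 30.0
    tail_s: float = 30.0
    sample_profile: np.ndarray | None = None
    background_profile: np.ndarray | None = None
    rng_seed: int = 0

    def validate(self) -> None:
        if self.scan_period_s <= 0:
            raise ValidationError("scan_period_s must be positive")
        grid = np.asarray(self.mz_grid, dtype=float)
        if grid.ndim != 1 or grid.size == 0:
            raise ValidationError("m/z grid must be non-empty")
        if np.any(np.diff(grid) <= 0):
            raise ValidationError("m/z grid must be strictly increasing")
        for name in (
            "baseline_level",
            "baseline_noise_sd",
            "background_amplitude",
            "insertion_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.decay_time_constant_s <= 0:
            raise ValidationError("decay_time_constant_s must be positive")
        if self.n_insertions < 0:
            raise ValidationError("n_insertions must be non-negative")
        for mz, rel in self.contaminant_peaks:
            if rel < 0:
                raise ValidationError("contaminant intensities must be non-negative")


def _nearest_bin(grid: np.ndarray, mz: float) -> int:
    return int(np.argmin(np.abs(grid - mz)))


def contaminated_profile(
    profile: np.ndarray,
    mz_grid: np.ndarray,
    contaminant_peaks: Sequence[tuple[float, float]],
) -> np.ndarray:
    """Superpose contaminant peaks on a unit-area profile and renormalize.

    Each ``(mz, rel)`` adds ``rel`` (as a fraction of the profile's area) at
    the nearest grid bin.
    """
    out = np.asarray(profile, dtype=float).copy()
    area = out.sum()
    for mz, rel in contaminant_peaks:
        out[_nearest_bin(np.asarray(mz_grid, float), mz)] += rel * area
    return out / out.sum()


def generate_acquisition(config: AcquisitionConfig) -> ScanStream:
    """Generate one synthetic acquisition as a :class:`ScanStream`.

    The timeline is: idle lead-in, a flat background plateau of
    ``background_window_s``, then ``n_insertions`` sample bursts separated by
    idle cooling gaps, and an idle tail. Scan times are exact multiples of
    the scan period. With ``n_insertions=0`` the stream is pure flat baseline
    (no probe ever enters the source). Ground truth is stored under
    ``stream.annotations``: window scan ranges and the true unit-area sample
    profile (with contaminants).
    """
    config.validate()
    grid = np.asarray(config.mz_grid, dtype=float)
    n_bins = grid.size
    rng = np.random.default_rng(config.rng_seed)

    if config.n_insertions == 0:
        total = config.lead_in_s + config.background_window_s + config.tail_s
        segments: list[tuple[float, float, str]] = []
    else:
        t = config.lead_in_s
        segments = [(t, t + config.background_window_s, "background")]
        t += config.background_window_s
        for _ in range(config.n_insertions):
            t += config.gap_s
            segments.append((t, t + config.insertion_duration_s, "sample"))
            t += config.insertion_duration_s
        total = t + config.tail_s

    n_scans = int(np.floor(total / config.scan_period_s))
    times = np.arange(n_scans) * config.scan_period_s

    baseline_spectrum = np.full(n_bins, config.baseline_level / n_bins)
    background_profile = (
        np.asarray(config.background_profile, dtype=float)
        if config.background_profile is not None
        else _residual_calibrant_profile(grid)
    )
    base_profile = (
        np.asarray(config.sample_profile, dtype=float)
        if config.sample_profile is not None
        else synthetic_metabolite_profile(grid)
    )
    sample_profile = contaminated_profile(base_profile, grid, config.contaminant_peaks)

    tau = 1.0e9 if config.saturation else config.decay_time_constant_s
    intensities = np.tile(baseline_spectrum, (n_scans, 1))
    windows = []
    for start_s, end_s, kind in segments:
        mask = (times >= start_s) & (times < end_s)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        # residual-calibrant background is present whenever the probe is in
        # the source, for background and sample insertions alike
        intensities[idx] += config.background_amplitude * background_profile
        if kind == "sample":
            amp = config.insertion_amplitude * np.exp(-(times[idx] - start_s) / tau)
            intensities[idx] += np.outer(amp, sample_profile)
        windows.append({"start_scan": int(idx[0]), "end_scan": int(idx[-1]) + 1, "kind": kind})

    if config.baseline_noise_sd > 0:
        intensities = intensities + rng.normal(
            0.0, config.baseline_noise_sd, size=intensities.shape
        )
        np.clip(intensities, 0.0, None, out=intensities)

    return ScanStream(
        mz_grid=grid,
        times=times,
        intensities=intensities,
        source_id=f"sim-seed{config.rng_seed}",
        annotations={
            "windows": windows,
            "true_sample_profile": sample_profile,
            "saturation": config.saturation,
        },
    )


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------


@dataclass
class CohortDesign:
    """Design of a multi-sample cohort with planted biology and batch structure.

    Defaults mirror the batch-effect study design: six patients, two brain
    regions per patient (12 samples), one acquisition per sample, two batches
    each containing both regions of three patients. Batch shifts act on the
    unit-area spectra of the shifted batch only: the additive shift is a
    per-bin offset (in unit-area intensity units) and the multiplicative
    shift a per-bin factor. ``user_offset_sd`` plants a per-user additive
    spectral offset; ``within_sample_noise_sd`` is per-bin replicate noise.
    """

    n_patients: int = 6
    sample_types: Sequence[str] = ("cerebellum", "cortex")
    n_replicates_per_sample: int = 1
    batch_assignment: Mapping[str, str] | None = None
    batch_shift_additive: np.ndarray | None = None
    batch_shift_multiplicative: np.ndarray | None = None
    shifted_batch: str = "batch2"
    user_assignment: Mapping[tuple[str, int], str] | None = None
    user_offset_sd: float = 0.0
    biological_signature: Mapping[str, np.ndarray] | None = None
    within_sample_noise_sd: float = 1.0e-5
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("need at least one patient")
        if len(self.sample_types) < 1:
            raise ValidationError("need at least one sample type")
        if self.n_replicates_per_sample < 1:
            raise ValidationError("every sample needs at least one replicate")
        if self.user_offset_sd < 0 or self.within_sample_noise_sd < 0:
            raise ValidationError("noise standard deviations must be non-negative")

    def sample_ids(self) -> list[str]:
        return [
            f"P{p + 1}-{t}"
            for p in range(self.n_patients)
            for t in self.sample_types
        ]


def default_type_signatures(
    mz_grid: np.ndarray,
    sample_types: Sequence[str],
    seed: int = 20240601,
    n_marker_bins: int = 40,
    effect: float = 0.4,
) -> dict[str, np.ndarray]:
    """Unit-area per-type mean spectra sharing a common base profile.

    Each type up-weights its own disjoint, seeded set of marker bins by
    ``effect`` (relative), emulating region-specific metabolite patterns.
    """
    grid = np.asarray(mz_grid, dtype=float)
    base = synthetic_metabolite_profile(grid)
    rng = np.random.default_rng(seed)
    order = rng.permutation(grid.size)
    signatures = {}
    for i, t in enumerate(sample_types):
        mask = np.zeros(grid.size)
        mask[order[i * n_marker_bins : (i + 1) * n_marker_bins]] = 1.0
        sig = base * (1.0 + effect * mask)
        signatures[t] = sig / sig.sum()
    return signatures


def default_batch_shift(mz_grid: np.ndarray, seed: int = 20240602) -> np.ndarray:
    """Canonical additive per-bin batch shift (unit-area intensity units).

    A day-to-day drift touching many bins coherently: 60 seeded bins gain a
    constant offset of 5e-4, i.e. roughly half the typical peak height of a
    unit-area spectrum, large enough to dominate the leading principal
    component as observed for data recorded in two batches on separate days.
    """
    grid = np.asarray(mz_grid, dtype=float)
    rng = np.random.default_rng(seed)
    shift = np.zeros(grid.size)
    shift[rng.permutation(grid.size)[:60]] = 5.0e-4
    return shift


def two_batch_design(
    mz_grid: np.ndarray | None = None,
    two_day: bool = True,
    rng_seed: int = 0,
    n_patients: int = 6,
) -> CohortDesign:
    """The 12-sample, two-region, two-batch study design.

    ``two_day=False`` gives the single-day control arm (batch labels present
    but no planted shift); ``two_day=True`` plants the canonical additive
    batch shift on the second batch. Patients are randomised to batches with
    each batch containing both regions of three patients.
    """
    grid = default_mz_grid() if mz_grid is None else np.asarray(mz_grid, float)
    design = CohortDesign(n_patients=n_patients, rng_seed=rng_seed)
    rng = np.random.default_rng(rng_seed + 7)
    patients = rng.permutation(design.n_patients)
    assignment = {}
    for i, p in enumerate(patients):
        batch = "batch1" if i < design.n_patients // 2 else "batch2"
        for t in design.sample_types:
            assignment[f"P{p + 1}-{t}"] = batch
    return replace(
        design,
        batch_assignment=assignment,
        batch_shift_additive=default_batch_shift(grid) if two_day else None,
        biological_signature=default_type_signatures(grid, design.sample_types),
    )


def cohort_truth_matrix(
    design: CohortDesign, mz_grid: np.ndarray
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Noise-free ground-truth spectra and metadata for a cohort design.

    Rows (one per sample x replicate) are the per-type mean spectra with the
    planted batch shift applied to samples of the shifted batch; replicate
    noise and user offsets are not included, so planted shifts are exactly
    recoverable as differences of batch means.
    """
    design.validate()
    grid = np.asarray(mz_grid, dtype=float)
    signatures = (
        dict(design.biological_signature)
        if design.biological_signature is not None
        else default_type_signatures(grid, design.sample_types)
    )
    for t, sig in signatures.items():
        if np.any(np.asarray(sig) < 0):
            raise ValidationError(f"type signature for {t!r} has negative bins")

    ids = design.sample_ids()
    assignment = (
        dict(design.batch_assignment)
        if design.batch_assignment is not None
        else {s: "batch1" for s in ids}
    )
    unknown = set(assignment) - set(ids)
    if unknown:
        raise ValidationError(
            f"batch assignment references unknown samples: {sorted(unknown)}"
        )
    missing = set(ids) - set(assignment)
    if missing:
        raise ValidationError(
            f"batch assignment missing samples: {sorted(missing)}"
        )

    add = (
        np.zeros(grid.size)
        if design.batch_shift_additive is None
        else np.broadcast_to(
            np.asarray(design.batch_shift_additive, float), (grid.size,)
        ).copy()
    )
    mult = (
        np.ones(grid.size)
        if design.batch_shift_multiplicative is None
        else np.broadcast_to(
            np.asarray(design.batch_shift_multiplicative, float), (grid.size,)
        ).copy()
    )

    rows, meta = [], []
    for sample_id in ids:
        patient, sample_type = sample_id.split("-", 1)
        batch = assignment[sample_id]
        truth = signatures[sample_type].copy()
        if batch == design.shifted_batch:
            truth = truth * mult + add
        for rep in range(design.n_replicates_per_sample):
            user = (
                design.user_assignment.get((sample_id, rep), "user1")
                if design.user_assignment is not None
                else "user1"
            )
            rows.append(truth)
            meta.append(
                {
                    "sample_id": sample_id,
                    "patient": patient,
                    "sample_type": sample_type,
                    "batch": batch,
                    "user": user,
                    "replicate": rep,
                }
            )
    index = [f"{m['sample_id']}-r{m['replicate']}" for m in meta]
    truth_matrix = FeatureMatrix(
        intensities=pd.DataFrame(np.vstack(rows), index=index, columns=grid),
        metadata=pd.DataFrame(meta, index=index),
    )
    return truth_matrix, truth_matrix.metadata.copy()


def generate_cohort(
    design: CohortDesign, config: AcquisitionConfig
) -> tuple[list[ScanStream], FeatureMatrix, pd.DataFrame]:
    """Generate raw streams, ground-truth spectra and metadata for a cohort.

    One acquisition stream (background insertion plus one sample insertion)
    is produced per sample x replicate; its insertion profile is the
    ground-truth spectrum perturbed by the per-user offset and per-replicate
    noise. Streams, the noise-free truth matrix and the metadata table are
    returned together.
    """
    design.validate()
    config.validate()
    grid = np.asarray(config.mz_grid, dtype=float)
    truth, metadata = cohort_truth_matrix(design, grid)

    rng = np.random.default_rng(design.rng_seed)
    users = sorted(set(metadata["user"]))
    user_offsets = {
        u: rng.normal(0.0, design.user_offset_sd, size=grid.size)
        if design.user_offset_sd > 0
        else np.zeros(grid.size)
        for u in users
    }

    streams = []
    for i, (acq_id, meta_row) in enumerate(metadata.iterrows()):
        profile = truth.values[i].copy()
        profile += user_offsets[meta_row["user"]]
        if design.within_sample_noise_sd > 0:
            profile += rng.normal(0.0, design.within_sample_noise_sd, size=grid.size)
        np.clip(profile, 0.0, None, out=profile)
        acq_config = replace(
            config,
            n_insertions=1,
            sample_profile=profile,
            contaminant_peaks=(),  # contaminants live in the profiles if planted
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        stream = generate_acquisition(acq_config)
        stream.source_id = str(acq_id)
        stream.annotations["metadata"] = dict(meta_row)
        streams.append(stream)
    return streams, truth, metadata


# ---------------------------------------------------------------------------
# probe-tip cooling model
# ---------------------------------------------------------------------------


@dataclass
class CoolingCurve:
    """Measured probe-tip cooling curve (mean over ``n_repeats`` measurements)."""

    times: np.ndarray
    temperatures: np.ndarray
    n_repeats: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.times.shape != self.temperatures.shape:
            raise ValidationError("times and temperatures differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("cooling-curve times must be strictly increasing")
        if not np.all(np.isfinite(self.temperatures)):
            raise ValidationError("temperatures must be finite")


@dataclass(frozen=True)
class CoolingFit:
    """Fitted Newtonian-cooling parameters."""

    T_amb: float
    T0: float
    k: float
    residual_rms: float


def cooling_temperature(T0: float, T_amb: float, k: float, t) -> np.ndarray | float:
    """Newtonian cooling: ``T(t) = T_amb + (T0 - T_amb) * exp(-k t)``."""
    if k <= 0:
        raise ValidationError("cooling rate k must be positive")
    t = np.asarray(t, dtype=float)
    out = T_amb + (T0 - T_amb) * np.exp(-k * t)
    return float(out) if out.ndim == 0 else out


def two_point_cooling_rate(
    T_amb: float, t1: float, T1: float, t2: float, T2: float
) -> float:
    """Closed-form rate through two anchor temperatures at fixed ambient.

    Solving the exponential model through ``(t1, T1)`` and ``(t2, T2)`` gives
    ``k = ln((T1 - T_amb) / (T2 - T_amb)) / (t2 - t1)``.
    """
    if t2 == t1:
        raise ValidationError("anchor times must differ")
    if (T1 - T_amb) <= 0 or (T2 - T_amb) <= 0:
        raise ValidationError("anchor temperatures must exceed ambient")
    return float(np.log((T1 - T_amb) / (T2 - T_amb)) / (t2 - t1))


def generate_cooling_curve(
    T_amb: float,
    T0: float,
    k: float,
    times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    n_repeats: int = 10,
    rng_seed: int = 0,
) -> CoolingCurve:
    """Synthetic cooling curve: exponential decay sampled once per second.

    ``n_repeats`` noisy realizations are averaged, as in a thermal-camera
    protocol that averages repeat measurements.
    """
    if times is None:
        times = np.arange(0.0, 31.0, 1.0)
    times = np.asarray(times, dtype=float)
    ideal = cooling_temperature(T0, T_amb, k, times)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        reps = ideal + rng.normal(0.0, noise_sd, size=(n_repeats, times.size))
        temps = reps.mean(axis=0)
    else:
        temps = np.asarray(ideal, dtype=float)
    return CoolingCurve(times=times, temperatures=temps, n_repeats=n_repeats)


def fit_cooling(curve: CoolingCurve, T_amb_fixed: float | None = None) -> CoolingFit:
    """Least-squares fit of the exponential cooling model.

    With ``T_amb_fixed`` given, only ``(T0, k)`` are free. Requires at least
    three distinct time points and non-constant temperatures.
    """
    t, T = curve.times, curve.temperatures
    if np.unique(t).size < 3:
        raise ValidationError("cooling fit needs >= 3 distinct time points")
    if np.ptp(T) == 0:
        raise ValidationError("cooling fit undefined for constant temperatures")

    T0_guess = float(T.max())
    Tamb_guess = float(T.min()) if T_amb_fixed is None else T_amb_fixed
    span = max(T0_guess - Tamb_guess, 1e-6)
    k_guess = 1.0 / max(t[-1] - t[0], 1e-6)

    if T_amb_fixed is None:
        popt, _ = curve_fit(
            lambda tt, T0, Tamb, k: Tamb + (T0 - Tamb) * np.exp(-k * tt),
            t,
            T,
            p0=(T0_guess, Tamb_guess - 0.1 * span, k_guess),
            maxfev=10000,
        )
        T0_fit, Tamb_fit, k_fit = popt
    else:
        popt, _ = curve_fit(
            lambda tt, T0, k: T_amb_fixed + (T0 - T_amb_fixed) * np.exp(-k * tt),
            t,
            T,
            p0=(T0_guess, k_guess),
            maxfev=10000,
        )
        T0_fit, k_fit = popt
        Tamb_fit = T_amb_fixed
    if k_fit <= 0:
        raise ValidationError("cooling fit produced a non-positive rate")
    resid = T - cooling_temperature(T0_fit, Tamb_fit, k_fit, t)
    return CoolingFit(
        T_amb=float(Tamb_fit),
        T0=float(T0_fit),
        k=float(k_fit),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )
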