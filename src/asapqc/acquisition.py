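"""Raw acquisition processing: scan streams to unit-area sample spectra.

An ASAP-MS acquisition is a sequence of full mass-spectral scans recorded at a
fixed cadence (one scan every 900 ms on the instrument this pipeline targets).
The probe is first inserted empty to record a background measurement, then
re-inserted loaded with sample one or more times; each insertion shows up as a
rapid rise in the total ion count (TIC) followed by an exponential-like decay
as the sample is vaporised and depleted.

This module reconstructs that structure from the raw scan stream:

1. :func:`compute_tic` sums each scan over the m/z grid,
2. :func:`detect_insertions` segments the TIC into insertion windows using a
   robust (median + k·MAD) threshold on the TIC,
3. :func:`average_window` reduces each window to a mean spectrum with
   per-bin standard deviations,
4. :func:`subtract_background` removes the background spectrum,
5. :func:`normalize_unit_area` scales each corrected spectrum to unit area,
6. :func:`flag_saturation` marks windows whose TIC does not decay (too much
   sample loaded), and
7. :func:`process_acquisition` chains the above into per-sample spectra plus
   a single averaged spectrum per acquisition.

Scan streams are read and written as long-format CSV
(``scan_index,time_s,mz,intensity``); mzML input is supported through
pyteomics with on-the-fly binning onto the 1 Da grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ProcessingError, ValidationError

logger = logging.getLogger(__name__)

#: Default half-open m/z acceptance range in Da; bins outside are dropped on read.
MZ_RANGE = (10.0, 1001.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ScanStream:
    """A time-ordered sequence of scans on a common m/z grid.

    Parameters
    ----------
    mz_grid
        Bin centres in Da, strictly increasing.
    times
        Scan start times in seconds, strictly increasing.
    intensities
        Array of shape ``(n_scans, n_bins)``; non-negative counts.
    source_id
        Label identifying the acquisition (file stem, sample id, ...).
    annotations
        Free-form provenance; the synthetic generator stores ground-truth
        window positions and the true sample profile here.
    """

    mz_grid: np.ndarray
    times: np.ndarray
    intensities: np.ndarray
    source_id: str = ""
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz_grid = np.asarray(self.mz_grid, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mz_grid.ndim != 1 or self.mz_grid.size == 0:
            raise ValidationError("m/z grid must be a non-empty 1-D array")
        if np.any(np.diff(self.mz_grid) <= 0):
            raise ValidationError("m/z grid must be strictly increasing")
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValidationError("scan stream must contain at least one scan")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("scan times must be strictly increasing")
        if self.intensities.shape != (self.times.size, self.mz_grid.size):
            raise ValidationError(
                f"intensity array shape {self.intensities.shape} does not match "
                f"({self.times.size} scans, {self.mz_grid.size} bins)"
            )
        if np.any(self.intensities < 0):
            raise ValidationError("intensities must be non-negative")

    @property
    def n_scans(self) -> int:
        return self.times.size

    @property
    def scan_period_s(self) -> float:
        """Median inter-scan interval in seconds."""
        if self.n_scans < 2:
            return float("nan")
        return float(np.median(np.diff(self.times)))


@dataclass(frozen=True)
class InsertionWindow:
    """A half-open run of scans ``[start_scan, end_scan)`` covering one probe insertion."""

    start_scan: int
    end_scan: int
    kind: str = "sample"  # "background" | "sample"
    peak_tic: float = float("nan")
    decay_ratio: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start_scan < self.end_scan):
            raise ValidationError(
                f"invalid window [{self.start_scan}, {self.end_scan})"
            )
        if self.kind not in ("background", "sample"):
            raise ValidationError(f"unknown window kind {self.kind!r}")

    @property
    def n_scans(self) -> int:
        return self.end_scan - self.start_scan


@dataclass
class AveragedSpectrum:
    """Per-bin mean and sample standard deviation over one insertion window."""

    mz_grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_scans: int
    window: InsertionWindow | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.n_scans < 1:
            raise ValidationError("averaged spectrum needs at least one scan")
        if np.any(self.sd < 0):
            raise ValidationError("standard deviations must be non-negative")


@dataclass
class SampleSpectrum:
    """Background-corrected, unit-area spectrum with provenance.

    ``intensities`` sums to 1 within 1e-9 and is elementwise non-negative.
    ``provenance`` carries sample id, sample type, user, batch, replicate and
    acquisition id where known; ``qc_flags`` collects labels such as
    ``"saturation"``.
    """

    mz_grid: np.ndarray
    intensities: np.ndarray
    provenance: dict = field(default_factory=dict)
    qc_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(self.intensities < 0):
            raise ValidationError("sample spectrum must be non-negative")
        total = self.intensities.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"sample spectrum must have unit area (got {total!r})"
            )


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the TIC threshold segmentation.

    baseline_fraction
        Fraction of the lowest TIC values used to estimate the baseline and
        MAD; 1.0 uses the full series (plain median).
    k_mad
        Threshold is ``baseline + k_mad * MAD``.
    min_window_s
        Windows spanning less time than this are discarded.
    merge_gap_s
        Above-threshold runs separated by less than this are merged.
    """

    baseline_fraction: float = 1.0
    k_mad: float = 5.0
    min_window_s: float = 5.0
    merge_gap_s: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.baseline_fraction <= 1.0):
            raise ValidationError("baseline_fraction must be in (0, 1]")
        if self.k_mad <= 0:
            raise ValidationError("k_mad must be positive")
        if self.min_window_s < 0 or self.merge_gap_s < 0:
            raise ValidationError("window durations must be non-negative")


@dataclass(frozen=True)
class ProcessParams:
    """Parameters of the full acquisition-processing chain."""

    detection: DetectionParams = DetectionParams()
    clip_negative: bool = True
    tail_fraction: float = 0.2
    decay_ratio_max: float = 0.5
    #: optional half-open [lo, hi) m/z filter applied before normalization
    mz_range: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ("scan_index", "time_s", "mz", "intensity")


def write_scan_stream(stream: ScanStream, path: str | Path) -> None:
    """Write a stream as long-format CSV (``scan_index,time_s,mz,intensity``)."""
    path = Path(path)
    n_scans, n_bins = stream.intensities.shape
    frame = pd.DataFrame(
        {
            "scan_index": np.repeat(np.arange(n_scans), n_bins),
            "time_s": np.repeat(stream.times, n_bins),
            "mz": np.tile(stream.mz_grid, n_scans),
            "intensity": stream.intensities.ravel(),
        }
    )
    frame.to_csv(path, index=False, float_format="%.10g")


def _read_csv_stream(path: Path) -> ScanStream:
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"scan stream file {path} is empty") from None
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(
            f"scan stream file {path} is missing columns {missing}"
        )
    if frame.empty:
        raise ValidationError(f"scan stream file {path} contains no scans")
    in_range = (frame["mz"] >= MZ_RANGE[0]) & (frame["mz"] < MZ_RANGE[1])
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.info("%s: dropped %d rows outside m/z %s", path, n_dropped, MZ_RANGE)
        frame = frame[in_range]
    # robust to arbitrary row order: sort scans by time, bins by m/z
    frame = frame.sort_values(["time_s", "mz"], kind="mergesort")
    wide = frame.pivot_table(
        index=["scan_index", "time_s"], columns="mz", values="intensity"
    )
    if wide.isna().any().any():
        raise ValidationError(
            f"scan stream file {path} has inconsistent m/z grids across scans"
        )
    wide = wide.sort_index(level="time_s")
    times = wide.index.get_level_values("time_s").to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValidationError(f"scan times in {path} are not strictly increasing")
    return ScanStream(
        mz_grid=wide.columns.to_numpy(dtype=float),
        times=times,
        intensities=wide.to_numpy(dtype=float),
        source_id=path.stem,
    )


def _read_mzml_stream(path: Path, mz_grid: np.ndarray | None = None) -> ScanStream:
    from pyteomics import mzml  # deferred: only needed for mzML input

    if mz_grid is None:
        mz_grid = np.arange(MZ_RANGE[0], MZ_RANGE[1], 1.0)
    edges = np.concatenate([mz_grid - 0.5, [mz_grid[-1] + 0.5]])
    times: list[float] = []
    rows: list[np.ndarray] = []
    with mzml.read(str(path)) as reader:
        for spectrum in reader:
            scan = spectrum["scanList"]["scan"][0]
            t = scan["scan start time"]
            unit = getattr(t, "unit_info", "minute")
            t_s = float(t) * 60.0 if unit in ("minute", None) else float(t)
            binned, _ = np.histogram(
                spectrum["m/z array"], bins=edges, weights=spectrum["intensity array"]
            )
            times.append(t_s)
            rows.append(binned)
    if not rows:
        raise ValidationError(f"mzML file {path} contains no spectra")
    return ScanStream(
        mz_grid=mz_grid,
        times=np.asarray(times),
        intensities=np.vstack(rows),
        source_id=path.stem,
    )


def read_scan_stream(path: str | Path, format: str | None = None) -> ScanStream:
    """Read a scan stream from long-format CSV or mzML.

    Parameters
    ----------
    path
        Input file. Format is inferred from the suffix unless given.
    format
        ``"csv"`` or ``"mzml"``.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"scan stream file {path} does not exist")
    fmt = format or ("mzml" if path.suffix.lower() == ".mzml" else "csv")
    if fmt == "csv":
        return _read_csv_stream(path)
    if fmt == "mzml":
        return _read_mzml_stream(path)
    raise ValidationError(f"unknown scan stream format {fmt!r}")


# ---------------------------------------------------------------------------
# TIC and segmentation
# ---------------------------------------------------------------------------


def compute_tic(stream: ScanStream) -> pd.Series:
    """Total ion count per scan: the integrated signal across the mass range.

    Returns a series indexed by scan time in seconds.
    """
    if stream.n_scans < 1:
        raise ValidationError("cannot compute TIC of an empty stream")
    return pd.Series(
        stream.intensities.sum(axis=1), index=stream.times, name="tic"
    )


def detect_insertions(
    tic: pd.Series,
    params: DetectionParams = DetectionParams(),
    first_is_background: bool = True,
) -> list[InsertionWindow]:
    """Segment a TIC series into probe-insertion windows.

    The baseline is the median of the (optionally lower-quantile-restricted)
    TIC, the noise scale its median absolute deviation about that baseline,
    and scans exceeding ``baseline + k_mad * MAD`` form candidate runs. Runs
    closer than ``merge_gap_s`` are merged, and runs spanning less than
    ``min_window_s`` are discarded. Following the acquisition protocol, the
    first detected window is labelled ``background`` and the rest ``sample``
    (disable with ``first_is_background=False``).

    A constant TIC (zero MAD, no excursions) yields an empty list.
    """
    values = np.asarray(tic.values, dtype=float)
    times = np.asarray(tic.index, dtype=float)
    if values.size < 10:
        raise ValidationError("insertion detection needs at least 10 scans")

    if params.baseline_fraction < 1.0:
        k = max(1, int(round(params.baseline_fraction * values.size)))
        subset = np.sort(values)[:k]
    else:
        subset = values
    baseline = float(np.median(subset))
    mad = float(np.median(np.abs(subset - baseline)))
    threshold = baseline + params.k_mad * mad

    above = values > threshold
    if not above.any():
        return []

    # maximal runs of consecutive above-threshold scans, as [start, end)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    runs = list(zip(edges[::2], edges[1::2]))

    merged: list[list[int]] = [list(runs[0])]
    for start, end in runs[1:]:
        gap = times[start] - times[merged[-1][1] - 1]
        if gap < params.merge_gap_s:
            merged[-1][1] = end
        else:
            merged.append([start, end])

    period = float(np.median(np.diff(times)))
    windows: list[InsertionWindow] = []
    for start, end in merged:
        span = times[end - 1] - times[start] + period
        if span < params.min_window_s:
            continue
        kind = (
            "background"
            if first_is_background and not windows
            else "sample"
        )
        windows.append(
            InsertionWindow(
                start_scan=int(start),
                end_scan=int(end),
                kind=kind,
                peak_tic=float(values[start:end].max()),
            )
        )
    return windows


def average_window(stream: ScanStream, window: InsertionWindow) -> AveragedSpectrum:
    """Mean and sample standard deviation (ddof=1) of the scans in a window.

    A single-scan window has sd identically zero.
    """
    if window.end_scan > stream.n_scans:
        raise ValidationError(
            f"window [{window.start_scan}, {window.end_scan}) exceeds "
            f"{stream.n_scans} scans"
        )
    block = stream.intensities[window.start_scan : window.end_scan]
    if block.shape[0] == 0:
        raise ValidationError("cannot average an empty window")
    mean = block.mean(axis=0)
    sd = (
        block.std(axis=0, ddof=1)
        if block.shape[0] > 1
        else np.zeros_like(mean)
    )
    return AveragedSpectrum(
        mz_grid=stream.mz_grid, mean=mean, sd=sd, n_scans=block.shape[0], window=window
    )


def subtract_background(
    sample: AveragedSpectrum,
    background: AveragedSpectrum,
    clip_negative: bool = True,
) -> np.ndarray:
    """Elementwise ``sample.mean - background.mean`` on a shared m/z grid.

    Bins driven negative by the subtraction are clipped to zero by default;
    unit-area normalization of signed spectra is unstable otherwise.
    """
    if sample.mz_grid.shape != background.mz_grid.shape or np.any(
        sample.mz_grid != background.mz_grid
    ):
        raise ValidationError("sample and background are on different m/z grids")
    corrected = sample.mean - background.mean
    if clip_negative:
        corrected = np.clip(corrected, 0.0, None)
    return corrected


def normalize_unit_area(v: np.ndarray) -> np.ndarray:
    """Scale a spectrum to unit area under the spectrum (sum of bins = 1)."""
    v = np.asarray(v, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValidationError(
            "cannot normalize a spectrum with non-positive total intensity "
            "(empty or fully background-subtracted spectrum)"
        )
    return v / total


def flag_saturation(
    tic: pd.Series,
    window: InsertionWindow,
    tail_fraction: float = 0.2,
    decay_ratio_max: float = 0.5,
    baseline: float | None = None,
) -> tuple[bool, float]:
    """Detect saturation: high signal that does not decay over the window.

    The decay ratio is the baseline-subtracted mean TIC over the final
    ``tail_fraction`` of the window divided by the baseline-subtracted peak
    TIC. A well-behaved insertion decays towards baseline (ratio near 0); a
    saturated one stays near its peak (ratio near 1). Returns
    ``(flagged, decay_ratio)``.
    """
    if window.n_scans < 5:
        raise ValidationError("saturation check needs a window of >= 5 scans")
    if not (0 < tail_fraction < 1):
        raise ValidationError("tail_fraction must be in (0, 1)")
    values = np.asarray(tic.values, dtype=float)[window.start_scan : window.end_scan]
    if baseline is None:
        baseline = float(np.median(np.asarray(tic.values, dtype=float)))
    peak = float(values.max())
    if peak <= baseline:
        return False, 0.0
    n_tail = max(1, int(np.ceil(tail_fraction * values.size)))
    ratio = float((values[-n_tail:].mean() - baseline) / (peak - baseline))
    return ratio > decay_ratio_max, ratio


@dataclass
class ProcessedAcquisition:
    """Output of :func:`process_acquisition`."""

    sample_spectra: list[SampleSpectrum]
    averaged: SampleSpectrum
    windows: list[InsertionWindow]
    background: AveragedSpectrum


def process_acquisition(
    stream: ScanStream,
    provenance: dict | None = None,
    params: ProcessParams = ProcessParams(),
) -> ProcessedAcquisition:
    """Full chain: TIC, segmentation, averaging, subtraction, normalization.

    Each detected sample window yields a background-corrected unit-area
    :class:`SampleSpectrum`; the per-acquisition spectrum is the mean of those
    per-insertion spectra, renormalized. Saturation flags are attached to the
    affected spectra and propagated to the averaged spectrum.
    """
    provenance = dict(provenance or {})
    provenance.setdefault("acquisition_id", stream.source_id)

    tic = compute_tic(stream)
    windows = detect_insertions(tic, params.detection)
    background_windows = [w for w in windows if w.kind == "background"]
    sample_windows = [w for w in windows if w.kind == "sample"]
    if not background_windows:
        raise ProcessingError(
            f"no background window detected in {stream.source_id!r}; record a "
            "background insertion before the sample insertions or annotate the "
            "background window explicitly"
        )
    if not sample_windows:
        raise ProcessingError(
            f"no sample windows detected in {stream.source_id!r}"
        )

    baseline = float(np.median(tic.values))
    background = average_window(stream, background_windows[0])

    grid = stream.mz_grid
    keep = slice(None)
    if params.mz_range is not None:
        lo, hi = params.mz_range
        keep = (grid >= lo) & (grid < hi)
        if not np.any(keep):
            raise ValidationError(f"m/z range {params.mz_range} selects no bins")
        grid = grid[keep]

    spectra: list[SampleSpectrum] = []
    for i, window in enumerate(sample_windows):
        averaged = average_window(stream, window)
        corrected = subtract_background(averaged, background, params.clip_negative)
        corrected = corrected[keep]
        flags = set()
        flagged, ratio = flag_saturation(
            tic,
            window,
            tail_fraction=params.tail_fraction,
            decay_ratio_max=params.decay_ratio_max,
            baseline=baseline,
        )
        if flagged:
            flags.add("saturation")
        spectra.append(
            SampleSpectrum(
                mz_grid=grid,
                intensities=normalize_unit_area(corrected),
                provenance={**provenance, "insertion": i},
                qc_flags=flags,
            )
        )

    stacked = np.vstack([s.intensities for s in spectra])
    averaged_spectrum = SampleSpectrum(
        mz_grid=grid,
        intensities=normalize_unit_area(stacked.mean(axis=0)),
        provenance=provenance,
        qc_flags=set().union(*(s.qc_flags for s in spectra)),
    )
    return ProcessedAcquisition(
        sample_spectra=spectra,
        averaged=averaged_spectrum,
        windows=windows,
        background=background,
    )
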