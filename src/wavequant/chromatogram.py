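"""Single-ion chromatograms: extraction, peak regions, overlap splitting, areas.

An extracted-ion chromatogram (XIC) is the intensity of a narrow m/z
window traced across successive spectra of an LC-MS run. Peptide
quantification integrates the de-noised XIC of the light and the heavy
isotopic partner over their elution peak, after background subtraction,
and takes the area ratio.

Regions are closed scan-number intervals; internal index arithmetic is
0-based. Areas are trapezoidal integrals over retention time (seconds),
so they carry physical units (intensity * s) and tolerate uneven scan
spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import EmptyInputError, NoPeakFoundError

__all__ = [
    "Chromatogram",
    "PeakRegion",
    "extract_xic",
    "find_peak_region",
    "locate_region",
    "flank_statistics",
    "split_overlap",
    "estimate_background",
    "peak_area",
]


@dataclass
class Chromatogram:
    """Intensity of one m/z window across scans.

    scan_numbers strictly ascending; retention_times in seconds;
    intensities non-negative, all the same length.
    """

    scan_numbers: np.ndarray
    retention_times: np.ndarray
    intensities: np.ndarray
    mz_center: float = 0.0
    mz_tolerance: float = 0.5

    def __post_init__(self) -> None:
        self.scan_numbers = np.asarray(self.scan_numbers, dtype=int)
        self.retention_times = np.asarray(self.retention_times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        n = self.scan_numbers.size
        if n < 1 or self.retention_times.size != n or self.intensities.size != n:
            raise ValueError("scan_numbers, retention_times, intensities must share length >= 1")
        if n > 1 and not np.all(np.diff(self.scan_numbers) > 0):
            raise ValueError("scan_numbers must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return int(self.scan_numbers.size)

    def index_of_scan(self, scan: int) -> int:
        """0-based index of the chromatogram point nearest *scan*."""
        i = int(np.searchsorted(self.scan_numbers, scan))
        if i >= len(self):
            return len(self) - 1
        if i > 0 and abs(self.scan_numbers[i - 1] - scan) <= abs(self.scan_numbers[i] - scan):
            return i - 1
        return i


@dataclass
class PeakRegion:
    """One isotopic partner's elution peak: boundaries, apex, background, area."""

    start_scan: int
    end_scan: int
    apex_scan: int
    background: float = 0.0
    area: float = 0.0
    split_from_overlap: bool = False

    def __post_init__(self) -> None:
        if not self.start_scan <= self.apex_scan <= self.end_scan:
            raise ValueError("requires start_scan <= apex_scan <= end_scan")
        if self.background < 0 or self.area < 0:
            raise ValueError("background and area must be >= 0")


def extract_xic(
    spectra_source: Iterable,
    mz_center: float,
    mz_tolerance: float = 0.5,
    scan_window: tuple[int, int] | None = None,
    ppm: bool = False,
) -> Chromatogram:
    """Build the XIC of *mz_center* +/- *mz_tolerance* from a spectra stream.

    *spectra_source* yields ``(scan, rt_seconds, mz_array, intensity_array)``
    or ``(rt_seconds, mz_array, intensity_array)`` (scans then numbered
    from 1). Per scan the intensity is the sum of all peaks within
    tolerance (absolute Th by default, ppm of mz_center if *ppm*); scans
    with no matching peak get intensity 0.
    """
    if mz_tolerance <= 0:
        raise ValueError("mz_tolerance must be > 0")
    tol = mz_center * mz_tolerance * 1e-6 if ppm else mz_tolerance
    scans, rts, vals = [], [], []
    for i, rec in enumerate(spectra_source):
        if len(rec) == 4:
            scan, rt, mz, inten = rec
        else:
            rt, mz, inten = rec
            scan = i + 1
        scan = int(scan)
        if scan_window is not None and not scan_window[0] <= scan <= scan_window[1]:
            continue
        mz = np.asarray(mz, dtype=float)
        inten = np.asarray(inten, dtype=float)
        hit = np.abs(mz - mz_center) <= tol
        scans.append(scan)
        rts.append(float(rt))
        vals.append(float(inten[hit].sum()) if hit.any() else 0.0)
    if not scans:
        raise EmptyInputError("spectra source yielded no scans (empty or window excluded all)")
    return Chromatogram(
        scan_numbers=np.array(scans),
        retention_times=np.array(rts),
        intensities=np.array(vals),
        mz_center=mz_center,
        mz_tolerance=mz_tolerance,
    )


def _provisional_background(denoised: np.ndarray) -> float:
    """Lower-decile floor of the trace, used before a region exists."""
    return float(max(np.percentile(denoised, 10), 0.0))


def find_peak_region(
    chrom: Chromatogram,
    seed_scan: int,
    denoised: Sequence[float],
    background: float | None = None,
    boundary_factor: float = 0.05,
    search_window: int = 50,
    noise_level: float = 0.0,
) -> PeakRegion:
    """Locate the elution peak nearest *seed_scan* on the de-noised trace.

    The apex is the maximum of *denoised* within +/- *search_window*
    scans of the seed (ties break to the earlier scan). Boundaries walk
    outward from the apex until the trace decays to
    background + max(boundary_factor * (apex - background), 2 * noise_level):
    the stop level must clear both the stated fraction of the peak
    height and the residual noise band, or baseline fluctuations keep
    the walk alive far past the peak. A valley that stays above the
    level does not end the region: two overlapping peaks deliberately
    land in one region, which :func:`split_overlap` then separates. A
    trace that never rises above background near the seed raises
    :class:`NoPeakFoundError`.
    """
    y = np.asarray(denoised, dtype=float)
    if y.size != len(chrom):
        raise ValueError("denoised trace must match chromatogram length")
    if not chrom.scan_numbers[0] <= seed_scan <= chrom.scan_numbers[-1]:
        raise ValueError(f"seed scan {seed_scan} outside chromatogram range")
    bg = _provisional_background(y) if background is None else float(background)

    i_seed = chrom.index_of_scan(seed_scan)
    lo = max(0, i_seed - search_window)
    hi = min(y.size - 1, i_seed + search_window)
    window = y[lo : hi + 1]
    apex = lo + int(np.argmax(window))  # argmax -> first (earlier) scan on ties
    apex_height = y[apex] - bg
    if apex_height <= 0:
        raise NoPeakFoundError(
            f"no intensity above background {bg:g} within {search_window} scans of scan {seed_scan}"
        )
    level = bg + max(boundary_factor * apex_height, 2.0 * noise_level)

    start = apex
    while start > 0 and y[start - 1] > level:
        start -= 1
    end = apex
    while end < y.size - 1 and y[end + 1] > level:
        end += 1
    return PeakRegion(
        start_scan=int(chrom.scan_numbers[start]),
        end_scan=int(chrom.scan_numbers[end]),
        apex_scan=int(chrom.scan_numbers[apex]),
        background=bg,
    )


def split_overlap(
    chrom: Chromatogram,
    region: PeakRegion,
    denoised: Sequence[float],
    expected_rt: float,
    valley_fraction: float = 0.5,
) -> PeakRegion:
    """Separate two overlapping elution peaks inside *region*.

    If the de-noised trace within the region has a valley whose depth
    below the smaller flanking apex exceeds *valley_fraction* of that
    apex's height above background, the region is split at the valley
    minimum and the sub-region whose apex retention time is closest to
    *expected_rt* is returned (flagged ``split_from_overlap``). With no
    qualifying valley — a single peak, or two fully merged ones — the
    region is returned unchanged. The result never extends beyond the
    input region.
    """
    y = np.asarray(denoised, dtype=float)
    s = chrom.index_of_scan(region.start_scan)
    e = chrom.index_of_scan(region.end_scan)
    seg = y[s : e + 1]
    bg = region.background
    apexes, _ = find_peaks(seg)
    # boundary maxima count as apexes too (a region may start mid-slope)
    if seg.size >= 2 and seg[0] > seg[1]:
        apexes = np.concatenate(([0], apexes))
    if seg.size >= 2 and seg[-1] > seg[-2]:
        apexes = np.concatenate((apexes, [seg.size - 1]))
    if apexes.size < 2:
        return region

    best = None  # (relative depth, valley index)
    for a, b in zip(apexes[:-1], apexes[1:]):
        valley = a + int(np.argmin(seg[a : b + 1]))
        smaller = min(seg[a], seg[b])
        height = smaller - bg
        if height <= 0:
            continue
        depth = (smaller - seg[valley]) / height
        if depth > valley_fraction and (best is None or depth > best[0]):
            best = (depth, valley)
    if best is None:
        return region

    valley = best[1]
    halves = [(s, s + valley), (s + valley, e)]
    candidates = []
    for lo, hi in halves:
        apex = lo + int(np.argmax(y[lo : hi + 1]))
        candidates.append((abs(chrom.retention_times[apex] - expected_rt), lo, hi, apex))
    _, lo, hi, apex = min(candidates, key=lambda t: t[0])
    return PeakRegion(
        start_scan=int(chrom.scan_numbers[lo]),
        end_scan=int(chrom.scan_numbers[hi]),
        apex_scan=int(chrom.scan_numbers[apex]),
        background=bg,
        split_from_overlap=True,
    )


def flank_statistics(
    chrom: Chromatogram,
    region: PeakRegion,
    denoised: Sequence[float],
    flank_width: int = 10,
) -> tuple[float, float]:
    """(background, noise level) from the windows flanking a region.

    Background is the flank median (never negative); the noise level is
    the MAD-based robust standard deviation of the flank around it. With
    no flanks at all, falls back to the lower decile of the in-region
    trace and zero noise.
    """
    y = np.asarray(denoised, dtype=float)
    s = chrom.index_of_scan(region.start_scan)
    e = chrom.index_of_scan(region.end_scan)
    flank = np.concatenate((y[max(0, s - flank_width) : s], y[e + 1 : e + 1 + flank_width]))
    if flank.size == 0:
        return float(max(np.percentile(y[s : e + 1], 10), 0.0)), 0.0
    med = float(np.median(flank))
    sigma = float(1.4826 * np.median(np.abs(flank - med)))
    return max(med, 0.0), sigma


def locate_region(
    chrom: Chromatogram,
    seed_scan: int,
    denoised: Sequence[float],
    boundary_factor: float = 0.05,
    search_window: int = 50,
    flank_width: int = 10,
) -> PeakRegion:
    """Two-pass peak region determination, the pipeline's standard protocol.

    A provisional region (trace-decile background) bootstraps a flank
    estimate of background and residual noise; the boundaries are then
    re-walked with that background and a noise-aware stop level, and the
    background is re-estimated from the final region's flanks. For a
    clean trace the result equals a single :func:`find_peak_region`
    pass.
    """
    provisional = find_peak_region(
        chrom, seed_scan, denoised,
        boundary_factor=boundary_factor, search_window=search_window,
    )
    bg, noise = flank_statistics(chrom, provisional, denoised, flank_width)
    region = find_peak_region(
        chrom, seed_scan, denoised,
        background=bg, boundary_factor=boundary_factor,
        search_window=search_window, noise_level=noise,
    )
    region.background, _ = flank_statistics(chrom, region, denoised, flank_width)
    return region


def estimate_background(
    chrom: Chromatogram,
    region: PeakRegion,
    denoised: Sequence[float],
    flank_width: int = 10,
) -> float:
    """Background level from the flanks of a peak region.

    Median of the de-noised intensities in windows of *flank_width*
    scans immediately outside the region (both sides pooled). When the
    region touches both chromatogram ends, falls back to the lower
    decile of the in-region intensities. Never negative.
    """
    y = np.asarray(denoised, dtype=float)
    s = chrom.index_of_scan(region.start_scan)
    e = chrom.index_of_scan(region.end_scan)
    flank = np.concatenate((y[max(0, s - flank_width) : s], y[e + 1 : e + 1 + flank_width]))
    if flank.size:
        return float(max(np.median(flank), 0.0))
    return float(max(np.percentile(y[s : e + 1], 10), 0.0))


def peak_area(
    chrom: Chromatogram,
    region: PeakRegion,
    denoised: Sequence[float],
    background: float | None = None,
) -> float:
    """Background-subtracted trapezoidal area of the region over retention time."""
    y = np.asarray(denoised, dtype=float)
    bg = region.background if background is None else float(background)
    s = chrom.index_of_scan(region.start_scan)
    e = chrom.index_of_scan(region.end_scan)
    above = np.maximum(y[s : e + 1] - bg, 0.0)
    if e == s:
        return 0.0
    return float(np.trapezoid(above, chrom.retention_times[s : e + 1]))
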