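"""Synthetic light/heavy chromatogram pairs with known ground truth.

Emulates the additive signal model the de-noiser assumes: a clean trace
s(t) — a baseline plus Gaussian elution peaks — observed with Gaussian
white noise n(t) of known sigma, clipped at zero (intensities are
physically non-negative). Gaussian elution profiles give closed-form
true areas, amplitude * sigma_seconds * sqrt(2*pi), so every stage of
the pipeline can be checked against analytic truth: extraction,
de-noising, region finding, integration and ratio recovery.

A light/heavy pair shares peak geometry; light amplitudes are the heavy
ones scaled by the mixing ratio, and each partner gets an independent
noise realization. Mixing ratios of interest span 0.5-2 (1:2 through
2:1), the dynamic range over which isotope-label LC-MS quantification
is considered reliable.

Clipping at zero slightly biases the noise near an empty baseline, so
standard fixtures keep baseline >= 3 * noise_sigma, where the bias is
negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np

from .chromatogram import Chromatogram

__all__ = ["SyntheticSpec", "generate_chromatogram", "generate_pair", "generate_spectra"]

SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic chromatogram (or light/heavy pair).

    peaks: list of (apex_scan, amplitude, sigma_scans) for the heavy
    partner; mixing_ratio scales light amplitudes. Identical spec + seed
    always reproduces identical output.
    """

    n_scans: int = 128
    scan_interval: float = 1.0  # seconds
    peaks: tuple[tuple[float, float, float], ...] = ((64.0, 100.0, 5.0),)
    baseline: float = 15.0
    noise_sigma: float = 5.0
    seed: int = 0
    mixing_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.n_scans < 1 or self.scan_interval <= 0:
            raise ValueError("n_scans must be >= 1 and scan_interval > 0")
        if self.noise_sigma < 0 or self.baseline < 0:
            raise ValueError("noise_sigma and baseline must be >= 0")
        if self.mixing_ratio <= 0:
            raise ValueError("mixing_ratio must be > 0")
        for apex, amp, sig in self.peaks:
            if amp <= 0 or sig <= 0:
                raise ValueError("peak amplitudes and widths must be > 0")
        object.__setattr__(self, "peaks", tuple(tuple(p) for p in self.peaks))


def _clean_trace(spec: SyntheticSpec) -> np.ndarray:
    t = np.arange(spec.n_scans, dtype=float)
    y = np.full(spec.n_scans, spec.baseline, dtype=float)
    for apex, amp, sig in spec.peaks:
        y += amp * np.exp(-0.5 * ((t - apex) / sig) ** 2)
    return y


def true_peak_areas(spec: SyntheticSpec) -> list[float]:
    """Analytic area of each peak: amplitude * sigma_seconds * sqrt(2*pi)."""
    return [amp * sig * spec.scan_interval * SQRT_2PI for _, amp, sig in spec.peaks]


def generate_chromatogram(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[Chromatogram, list[float]]:
    """One noisy chromatogram plus the analytic true area of each peak."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    clean = _clean_trace(spec)
    noisy = clean + rng.normal(0.0, spec.noise_sigma, spec.n_scans) if spec.noise_sigma else clean
    chrom = Chromatogram(
        scan_numbers=np.arange(1, spec.n_scans + 1),
        retention_times=np.arange(spec.n_scans, dtype=float) * spec.scan_interval,
        intensities=np.maximum(noisy, 0.0),
    )
    return chrom, true_peak_areas(spec)


def generate_pair(spec: SyntheticSpec) -> tuple[Chromatogram, Chromatogram, float]:
    """(light, heavy, true_ratio): shared geometry, independent noise.

    Heavy uses the spec as given (seed ``spec.seed``); light scales the
    amplitudes by ``spec.mixing_ratio`` and draws its noise from seed
    ``spec.seed + 1``.
    """
    heavy, _ = generate_chromatogram(spec)
    light_spec = replace(
        spec,
        peaks=tuple((apex, amp * spec.mixing_ratio, sig) for apex, amp, sig in spec.peaks),
    )
    light, _ = generate_chromatogram(light_spec, seed=spec.seed + 1)
    return light, heavy, spec.mixing_ratio


def generate_spectra(
    spec: SyntheticSpec, mz_light: float, mz_heavy: float
) -> list[tuple[int, float, np.ndarray, np.ndarray]]:
    """Toy centroid spectra tracing a light/heavy pair.

    One spectrum per scan with exactly two sticks, at *mz_light* and
    *mz_heavy*, whose intensities follow the generated pair. Extracting
    an XIC at either m/z reproduces the corresponding chromatogram
    exactly; the records round-trip through the mzML writer/reader.
    """
    if mz_light == mz_heavy:
        raise ValueError("light and heavy m/z must differ")
    light, heavy, _ = generate_pair(spec)
    spectra = []
    for i in range(spec.n_scans):
        spectra.append(
            (
                int(light.scan_numbers[i]),
                float(light.retention_times[i]),
                np.array([mz_light, mz_heavy]) if mz_light < mz_heavy
                else np.array([mz_heavy, mz_light]),
                np.array([light.intensities[i], heavy.intensities[i]]) if mz_light < mz_heavy
                else np.array([heavy.intensities[i], light.intensities[i]]),
            )
        )
    return spectra
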