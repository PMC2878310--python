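"""Orthonormal discrete wavelet transform for finite 1-D signals.

Thin, contract-checked layer over PyWavelets restricted to orthogonal
filter banks. Orthogonality is what makes the downstream de-noising
machinery sound: the transform preserves signal energy (Parseval), so a
noise level estimated on coefficients is directly comparable to the
noise level of the trace, and zeroing coefficients removes exactly the
corresponding energy from the reconstruction.

Conventions
-----------
* ``details[0]`` is the finest scale (scale 1), ``details[-1]`` the
  coarsest (scale J).
* Default boundary handling is periodic (PyWavelets "periodization"),
  which keeps both perfect reconstruction and exact energy conservation
  when the padded length is a multiple of ``2**levels``.
* Signals whose length is not a multiple of ``2**levels`` are padded
  with edge replication up to the next multiple; the padding is recorded
  on the decomposition and stripped after reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt

from .errors import (
    DecompositionTooDeepError,
    MalformedDecompositionError,
    UnsupportedWaveletError,
)

__all__ = ["FilterBank", "WaveletDecomposition", "make_filter_bank", "dwt", "idwt"]

_MODE_MAP = {"periodic": "periodization", "symmetric": "symmetric"}


@dataclass(frozen=True)
class FilterBank:
    """Analysis filter pair of an orthonormal wavelet.

    ``highpass`` is the quadrature mirror of ``lowpass`` (alternating-sign
    reversal, up to an overall sign that is pure convention). For any
    orthonormal bank the lowpass taps satisfy sum = sqrt(2) and
    sum of squares = 1.
    """

    name: str
    lowpass: np.ndarray
    highpass: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lowpass", np.asarray(self.lowpass, dtype=float))
        object.__setattr__(self, "highpass", np.asarray(self.highpass, dtype=float))

    def _pywt(self) -> pywt.Wavelet:
        return pywt.Wavelet(self.name)


@dataclass
class WaveletDecomposition:
    """Approximation + per-scale detail coefficients of one signal.

    ``original_length`` is the pre-padding signal length; ``pad_width``
    how many edge-replicated samples were appended before analysis.
    """

    approx: np.ndarray
    details: list[np.ndarray]  # finest first
    levels: int
    filter_bank: FilterBank
    original_length: int
    boundary_mode: str = "periodic"
    pad_width: int = 0

    @property
    def padded_length(self) -> int:
        return self.original_length + self.pad_width

    def coefficient_energy(self) -> float:
        """Total energy of all coefficients (approx + every detail scale)."""
        e = float(np.sum(self.approx**2))
        for d in self.details:
            e += float(np.sum(d**2))
        return e

    def copy(self) -> "WaveletDecomposition":
        return WaveletDecomposition(
            approx=self.approx.copy(),
            details=[d.copy() for d in self.details],
            levels=self.levels,
            filter_bank=self.filter_bank,
            original_length=self.original_length,
            boundary_mode=self.boundary_mode,
            pad_width=self.pad_width,
        )


def make_filter_bank(name: str) -> FilterBank:
    """Return the orthonormal analysis filter bank called *name*.

    Supported names are PyWavelets' discrete orthogonal families
    (``haar``, ``dbN``, ``symN``, ``coifN``, ...). Non-orthogonal or
    unknown names raise :class:`UnsupportedWaveletError`.
    """
    try:
        w = pywt.Wavelet(name)
    except ValueError as exc:
        raise UnsupportedWaveletError(f"unknown wavelet {name!r}") from exc
    if not w.orthogonal:
        raise UnsupportedWaveletError(
            f"wavelet {name!r} is not orthogonal; only orthonormal banks are supported"
        )
    return FilterBank(name=name, lowpass=np.asarray(w.dec_lo), highpass=np.asarray(w.dec_hi))


def _resolve_mode(boundary_mode: str) -> str:
    try:
        return _MODE_MAP[boundary_mode]
    except KeyError:
        raise ValueError(
            f"boundary_mode must be one of {sorted(_MODE_MAP)}, got {boundary_mode!r}"
        ) from None


def dwt(
    signal: Sequence[float],
    bank: FilterBank,
    levels: int,
    boundary_mode: str = "periodic",
) -> WaveletDecomposition:
    """Decompose *signal* into *levels* dyadic scales.

    Requires ``len(signal) >= 2**levels``; shorter signals raise
    :class:`DecompositionTooDeepError`. Lengths that are not a multiple
    of ``2**levels`` are edge-padded (see module docstring).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    n = x.size
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if n < 2**levels:
        raise DecompositionTooDeepError(
            f"signal of length {n} cannot support {levels} levels (needs >= {2**levels})"
        )
    block = 2**levels
    pad = (-n) % block
    if pad:
        x = np.pad(x, (0, pad), mode="edge")
    mode = _resolve_mode(boundary_mode)
    coeffs = pywt.wavedec(x, bank._pywt(), mode=mode, level=levels)
    approx = coeffs[0]
    details = list(reversed(coeffs[1:]))  # finest first
    return WaveletDecomposition(
        approx=np.asarray(approx, dtype=float),
        details=[np.asarray(d, dtype=float) for d in details],
        levels=levels,
        filter_bank=bank,
        original_length=n,
        boundary_mode=boundary_mode,
        pad_width=pad,
    )


def expected_detail_lengths(
    padded_length: int, bank: FilterBank, levels: int, boundary_mode: str
) -> tuple[int, list[int]]:
    """(approx length, per-scale detail lengths, finest first) for the cascade."""
    mode = _resolve_mode(boundary_mode)
    w = bank._pywt()
    lengths = []
    n = padded_length
    for _ in range(levels):
        n = pywt.dwt_coeff_len(n, w.dec_len, mode=mode)
        lengths.append(n)
    return n, lengths


def idwt(decomposition: WaveletDecomposition) -> np.ndarray:
    """Inverse transform; exact (1e-8) round trip with :func:`dwt`.

    Raises :class:`MalformedDecompositionError` if coefficient sequence
    lengths do not match the analysis cascade recorded on the object.
    """
    dec = decomposition
    if len(dec.details) != dec.levels:
        raise MalformedDecompositionError(
            f"expected {dec.levels} detail sequences, found {len(dec.details)}"
        )
    approx_len, det_lens = expected_detail_lengths(
        dec.padded_length, dec.filter_bank, dec.levels, dec.boundary_mode
    )
    if dec.approx.size != approx_len:
        raise MalformedDecompositionError(
            f"approximation length {dec.approx.size} != expected {approx_len}"
        )
    for j, (d, want) in enumerate(zip(dec.details, det_lens), start=1):
        if d.size != want:
            raise MalformedDecompositionError(
                f"detail scale {j} has length {d.size}, expected {want}"
            )
    coeffs = [dec.approx] + list(reversed(dec.details))
    mode = _resolve_mode(dec.boundary_mode)
    x = pywt.waverec(coeffs, dec.filter_bank._pywt(), mode=mode)
    return np.asarray(x, dtype=float)[: dec.original_length]
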