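"""Exception hierarchy for wavequant.

All errors derive from :class:`WavequantError` so callers can catch the
package's failures with a single except clause; most also derive from
``ValueError`` because they signal invalid arguments.
"""


class WavequantError(Exception):
    """Base class for all wavequant errors."""


class UnsupportedWaveletError(WavequantError, ValueError):
    """Requested wavelet family/member is unknown or not orthogonal."""


class DecompositionTooDeepError(WavequantError, ValueError):
    """Signal too short for the requested number of decomposition levels."""


class MalformedDecompositionError(WavequantError, ValueError):
    """Coefficient sequences inconsistent with the recorded cascade geometry."""


class InsufficientDataError(WavequantError, ValueError):
    """An estimator was handed an empty or too-small sample."""


class InvalidLengthError(WavequantError, ValueError):
    """Signal length outside the valid domain of a formula (e.g. N < 2)."""


class InvalidParameterError(WavequantError, ValueError):
    """A tuning parameter lies outside its documented range."""


class InsufficientScalesError(WavequantError, ValueError):
    """Cross-scale correlation requires at least two detail scales."""


class EmptyInputError(WavequantError, ValueError):
    """An input container (spectra stream, table) held no usable records."""


class NoPeakFoundError(WavequantError):
    """No chromatographic peak rises above background near the seed scan."""


class InvalidAreaError(WavequantError, ValueError):
    """A peak area was negative (areas are physically non-negative)."""
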