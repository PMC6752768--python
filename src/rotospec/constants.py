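"""Physical constants and instrument defaults shared across the package.

All quantities are SI. Human-facing unit conversions (S/cm^2, um) live in
report writers, never here.
"""

from scipy.constants import epsilon_0 as EPSILON_0  # 8.8541878128e-12 F/m

#: Instrument frequency band over which rotation spectra are acquired (Hz).
DEFAULT_BAND_HZ = (3e3, 10e6)

#: Root-mean-square rotating-field magnitude at the cell position (V/m).
DEFAULT_E_RMS = 14e3

#: Default number of frequency points per spectrum (log-spaced over the band).
DEFAULT_N_FREQUENCIES = 20

__all__ = [
    "EPSILON_0",
    "DEFAULT_BAND_HZ",
    "DEFAULT_E_RMS",
    "DEFAULT_N_FREQUENCIES",
]
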