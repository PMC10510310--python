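"""Band-limited sub-sample shifting of uniformly sampled spectra.

A spectrum sampled on a uniform frequency grid is shifted along its axis by
multiplying its discrete Fourier transform by a linear phase ramp.  The
signal is mirror-padded before transforming so that the circular wrap-around
inherent to the DFT does not leak intensity from one edge of the window to
the other; shifts used here (≤ ~80 Hz) are always small relative to the
padded window.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fractional_shift"]


def fractional_shift(y: np.ndarray, shift_samples: float) -> np.ndarray:
    """Return ``y`` displaced by ``shift_samples`` grid steps (positive = to
    higher index) using FFT phase-ramp interpolation."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if shift_samples == 0:
        return y.copy()
    pad = max(16, int(abs(shift_samples)) + 8, n // 4)
    # reflect-pad to suppress circular wrap-around artifacts
    yp = np.concatenate([y[pad:0:-1], y, y[-2 : -2 - pad : -1]])
    m = yp.size
    k = np.fft.rfftfreq(m)
    spec = np.fft.rfft(yp) * np.exp(-2j * np.pi * k * shift_samples)
    if m % 2 == 0:
        # keep the Nyquist bin real so the inverse transform stays real-valued
        spec[-1] = spec[-1].real
    out = np.fft.irfft(spec, m)
    return out[pad : pad + n]
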