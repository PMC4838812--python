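"""Shared fixtures: reference parameter set and published equilibrium data."""

from __future__ import annotations

import numpy as np
import pytest

from wendling import ModelParameters

# Published equilibria of the four standard regimes (A=5, G=20, p=90),
# rounded to 3 decimals: B -> list of (y_out, y0..y4, stability label).
TABLE_EQUILIBRIA = {
    45: [
        (-0.124, (0.008, 6.097, 5.882, 0.339, 0.174), "stable"),
        (2.526, (0.031, 11.777, 8.962, 0.290, 0.266), "unstable"),
        (5.087, (0.094, 30.864, 25.749, 0.028, 0.763), "unstable"),
    ],
    38: [
        (1.018, (0.014, 7.037, 5.600, 0.419, 0.166), "stable"),
        (1.781, (0.022, 8.553, 6.358, 0.415, 0.188), "unstable"),
        (5.416, (0.105, 31.220, 25.768, 0.036, 0.764), "unstable"),
    ],
    37: [
        (5.466, (0.106, 31.254, 25.750, 0.037, 0.763), "unstable"),
    ],
    8: [
        (10.004, (0.226, 31.500, 19.258, 2.238, 0.571), "stable"),
    ],
}

# Published eigenvalue spectra (1-decimal) for the same equilibria,
# keyed by (B, y_out).
TABLE_SPECTRA = {
    (45, -0.124): [-178.1, -65.9, -50.0, -50.0, -24.0 + 24.5j, -24.0 - 24.5j,
                   -352.4 + 24.5j, -352.4 - 24.5j, -101.7 + 83.1j, -101.7 - 83.1j],
    (45, 2.526): [-241.4, -60.7, -50.0, -50.0, -30.3, 48.7,
                  -99.5 + 156.0j, -99.5 - 156.0j, -358.7 + 42.7j, -358.7 - 42.7j],
    (45, 5.087): [-181.9, -78.5, -50.0, -50.0, -134.4 + 98.9j, -134.4 - 98.9j,
                  15.9 + 78.8j, 15.9 - 78.8j, -351.3 + 19.0j, -351.3 - 19.0j],
    (38, 1.018): [-197.9, -63.2, -50.0, -50.0, -100.0 + 107.1j, -100.0 - 107.1j,
                  -14.2 + 14.0j, -14.2 - 14.0j, -355.2 + 35.9j, -355.2 - 35.9j],
    (38, 1.781): [-216.7, -61.8, -50.0, -50.0, -25.0, 17.1,
                  -357.6 + 42.5j, -357.6 - 42.5j, -99.2 + 129.5j, -99.2 - 129.5j],
    (38, 5.416): [-142.3, -84.0, -50.0, -50.0, -155.6 + 91.8j, -155.6 - 91.8j,
                  20.3 + 89.2j, 20.3 - 89.2j, -351.5 + 21.4j, -351.5 - 21.4j],
    (37, 5.466): [-137.8, -84.7, -50.0, -50.0, -157.9 + 91.9j, -157.9 - 91.9j,
                  20.7 + 90.2j, 20.7 - 90.2j, -351.6 + 21.9j, -351.6 - 21.9j],
    (8, 10.004): [-172.0, -59.3, -50.0, -50.0, -352.2 + 23.6j, -352.2 - 23.6j,
                  -32.6 + 9.8j, -32.6 - 9.8j, -99.5 + 77.1j, -99.5 - 77.1j],
}


@pytest.fixture
def params() -> ModelParameters:
    """Reference configuration: A=5, G=20, drive N(90, 30^2)."""
    return ModelParameters(A=5.0, G=20.0)


@pytest.fixture
def quiet_params(params) -> ModelParameters:
    """Same configuration with the input noise switched off."""
    from dataclasses import replace

    return replace(params, input_variance=0.0)


def sorted_spectrum(eigs) -> np.ndarray:
    """Canonical ordering for spectrum comparison."""
    return np.sort_complex(np.asarray(eigs, dtype=complex))


def spectral_mismatch(a, b, chebyshev: bool = False) -> float:
    """Largest eigenvalue distance under an optimal one-to-one pairing.

    Sorting complex spectra mispairs conjugate partners whose real parts
    agree only to round-off, so compare via optimal assignment instead.
    With ``chebyshev=True`` the distance is max(|d_re|, |d_im|) per pair,
    matching tables printed as separate real/imaginary columns.
    """
    from scipy.optimize import linear_sum_assignment

    a = np.asarray(a, dtype=complex)
    b = np.asarray(b, dtype=complex)
    assert a.shape == b.shape
    d = a[:, None] - b[None, :]
    cost = (np.maximum(np.abs(d.real), np.abs(d.imag)) if chebyshev
            else np.abs(d))
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].max())
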