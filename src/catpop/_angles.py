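"""Circular helpers shared across modules.

All angles are radians on [0, 2*pi) internally; degrees only appear at the
CLI boundary.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_angle(angle):
    """Map angle(s) onto [0, 2*pi)."""
    return np.mod(angle, TWO_PI)


def circ_diff(a, b):
    """Signed smallest angular difference a - b, in (-pi, pi]."""
    return np.angle(np.exp(1j * (np.asarray(a, dtype=float) - np.asarray(b, dtype=float))))


def circ_dist(a, b):
    """Absolute circular distance between angles, in [0, pi]."""
    return np.abs(circ_diff(a, b))


def circ_mean(angles, weights=None):
    """Weighted circular mean of angles, on [0, 2*pi)."""
    angles = np.asarray(angles, dtype=float)
    z = np.exp(1j * angles)
    if weights is not None:
        z = z * np.asarray(weights, dtype=float)
    return wrap_angle(np.angle(z.sum()))
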