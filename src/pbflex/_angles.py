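"""Angle arithmetic on the (-180, 180] degree convention."""

from __future__ import annotations

import numpy as np


def wrap_degrees(angle):
    """Map angles (degrees) into (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def angular_difference(a, b):
    """Minimal signed difference a - b in degrees, in (-180, 180]."""
    return wrap_degrees(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def angular_rmsd(window, reference):
    """Root-mean-square angular deviation (degrees) with 360 deg wraparound.

    Both arguments are length-8 dihedral windows; NaN entries mark undefined
    angles and make the result NaN.
    """
    d = angular_difference(window, reference)
    return float(np.sqrt(np.mean(np.square(d), axis=-1)))
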