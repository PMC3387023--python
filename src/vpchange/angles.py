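"""Orientation space conventions.

Physical orientations live on [-90, 90) degrees. All circular machinery
(Von Mises densities, circular distances) operates in an internal doubled
space obtained by mapping the physical half-circle onto the full circle
[-pi, pi) radians: internal = physical_deg * pi / 90. Conversion happens
only at I/O boundaries; files always store physical degrees.
"""
from __future__ import annotations

import numpy as np

__all__ = ["to_internal", "to_physical", "wrap", "wrap_physical", "circ_dist"]

_SCALE = np.pi / 90.0


def wrap(angle):
    """Wrap internal-space angles to [-pi, pi)."""
    return np.mod(np.asarray(angle, dtype=float) + np.pi, 2.0 * np.pi) - np.pi


def wrap_physical(deg):
    """Wrap physical orientations to [-90, 90) degrees."""
    return np.mod(np.asarray(deg, dtype=float) + 90.0, 180.0) - 90.0


def to_internal(deg):
    """Physical degrees in [-90, 90) -> internal radians in [-pi, pi)."""
    return wrap(np.asarray(deg, dtype=float) * _SCALE)


def to_physical(rad):
    """Internal radians in [-pi, pi) -> physical degrees in [-90, 90)."""
    return wrap_physical(np.asarray(rad, dtype=float) / _SCALE)


def circ_dist(a, b):
    """Absolute circular distance between internal-space angles, in [0, pi]."""
    return np.abs(wrap(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))
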