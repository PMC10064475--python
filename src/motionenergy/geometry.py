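"""Angle conventions and the screen/math coordinate conversion.

Two frames are used throughout the package:

* **math frame** — x rightward, y *upward*; angles in degrees, measured
  counter-clockwise from +x. All trigonometry is done here.
* **screen frame** — x rightward, y *downward* (image convention); angles
  measured *clockwise as displayed* from +x, so +90 deg points down the
  screen. All public interfaces (flow fields, channel directions, ring
  phases) use this frame; "clockwise" always means clockwise on screen.

The two frames differ only by the sign of y, hence a single involutive
conversion ``screen_from_math`` (= ``math_from_screen``) that negates the
angle. Angles are normalised to the half-open interval (-180, 180].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_deg",
    "screen_from_math",
    "math_from_screen",
    "unit_vector_screen",
    "screen_angle_of",
]


def wrap_deg(angle_deg):
    """Wrap angle(s) in degrees to (-180, 180]."""
    a = np.asarray(angle_deg, dtype=float)
    wrapped = -np.mod(-a + 180.0, 360.0) + 180.0
    return wrapped if wrapped.ndim else float(wrapped)


def screen_from_math(angle_deg):
    """Convert a math-frame (y-up, CCW-positive) angle to screen frame.

    The screen frame has y down and clockwise-positive angles, so the
    conversion is a sign flip followed by wrapping. It is its own inverse.
    """
    return wrap_deg(-np.asarray(angle_deg, dtype=float))


# The conversion is involutive; give the inverse its own name for clarity.
math_from_screen = screen_from_math


def unit_vector_screen(angle_screen_deg):
    """Unit vector(s) in *image* coordinates (dx, dy-down) for screen angles.

    Because the screen angle is measured clockwise with y pointing down,
    the image-coordinate components are simply (cos, sin) of the angle.
    """
    a = np.deg2rad(np.asarray(angle_screen_deg, dtype=float))
    return np.cos(a), np.sin(a)


def screen_angle_of(dx, dy_down):
    """Screen-frame angle in (-180, 180] of image-coordinate vector(s).

    ``dy_down`` is positive downward on screen. Zero vectors map to 0; use
    the vector magnitude to flag undefined directions.
    """
    ang = np.rad2deg(np.arctan2(np.asarray(dy_down, float), np.asarray(dx, float)))
    return wrap_deg(ang)
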