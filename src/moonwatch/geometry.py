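"""Projection geometry between ground-track bearings and image-plane angles.

A bird flying horizontally with compass bearing beta (clockwise from north)
is observed along the line of sight toward the moon at azimuth A and
altitude angle theta.  In a camera whose image x axis is horizontal
(zero roll), the apparent motion decomposes as

    u     =  sin(beta - A)               (image-horizontal, rightward +)
    w_up  = -cos(beta - A) * sin(theta)  (image-vertical, upward +)

so a bird flying away from the observer (beta = A) sinks toward the
horizon.  Pixel coordinates put y downward; all public functions here use
the pixel convention ``image_angle = atan2(dy, dx)`` degrees.

The map is invertible away from theta -> 0 (foreshortening collapses all
bearings onto the horizontal axis) given the *direction* of motion, which
resolves the beta vs beta+180 line ambiguity.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "bearing_to_image_angle",
    "image_angle_to_bearing",
    "apparent_speed_factor",
    "wrap_bearing",
    "wrap_signed",
]


def wrap_bearing(deg):
    """Wrap an angle to the compass range [0, 360)."""
    r = np.asarray(deg) % 360.0
    return np.where(r >= 360.0, 0.0, r)  # guard: tiny negatives wrap to 360.0


def wrap_signed(deg):
    """Wrap an angle difference to (-180, 180]."""
    d = (-np.asarray(deg)) % 360.0
    return -np.where(d >= 180.0, d - 360.0, d)


def _apply_roll_flips(dx, dy, roll_deg, flip_x, flip_y, inverse=False):
    if inverse:
        if flip_x:
            dx = -dx
        if flip_y:
            dy = -dy
        r = np.deg2rad(roll_deg)
    else:
        r = np.deg2rad(-roll_deg)
    c, s = np.cos(r), np.sin(r)
    dx, dy = c * dx - s * dy, s * dx + c * dy
    if not inverse:
        if flip_x:
            dx = -dx
        if flip_y:
            dy = -dy
    return dx, dy


def bearing_to_image_angle(
    bearing_deg,
    moon_azimuth_deg,
    moon_altitude_deg,
    camera_roll_deg=0.0,
    flip_x=False,
    flip_y=False,
):
    """Image-plane direction of motion (degrees, atan2(dy,dx), y down) for a
    horizontal flight at the given compass bearing."""
    psi = np.deg2rad(np.asarray(bearing_deg) - moon_azimuth_deg)
    dx = np.sin(psi)
    dy = np.cos(psi) * np.sin(np.deg2rad(moon_altitude_deg))  # dy = -w_up
    dx, dy = _apply_roll_flips(dx, dy, camera_roll_deg, flip_x, flip_y)
    return np.rad2deg(np.arctan2(dy, dx)) % 360.0


def image_angle_to_bearing(
    image_angle_deg,
    moon_azimuth_deg,
    moon_altitude_deg,
    camera_roll_deg=0.0,
    flip_x=False,
    flip_y=False,
):
    """Invert :func:`bearing_to_image_angle`.

    Raises ``ValueError`` when the moon altitude is below 1e-3 deg (the
    inversion is singular at the horizon).
    """
    theta = np.deg2rad(moon_altitude_deg)
    if np.sin(theta) < 1e-5:
        raise ValueError("bearing inversion ill-conditioned: moon at horizon")
    a = np.deg2rad(np.asarray(image_angle_deg))
    dx, dy = np.cos(a), np.sin(a)
    dx, dy = _apply_roll_flips(dx, dy, camera_roll_deg, flip_x, flip_y, inverse=True)
    psi = np.arctan2(dx, dy / np.sin(theta))
    return (np.rad2deg(psi) + moon_azimuth_deg) % 360.0


def apparent_speed_factor(bearing_deg, moon_azimuth_deg, moon_altitude_deg):
    """Ratio of apparent angular speed to (ground speed / slant distance).

    Equals 1 for motion perpendicular to the line of sight and sin(theta)
    for motion along the azimuth direction.
    """
    psi = np.deg2rad(np.asarray(bearing_deg) - moon_azimuth_deg)
    th = np.deg2rad(moon_altitude_deg)
    return np.sqrt(np.sin(psi) ** 2 + (np.cos(psi) * np.sin(th)) ** 2)
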