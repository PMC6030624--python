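"""Local transverse-Mercator projection centred on the breeding colony.

GPS fixes are analysed in a planar metric coordinate system so that step
lengths, turning angles, kernel bandwidths and convex-hull areas are all in
metres/kilometres.  Rather than a fixed UTM zone, each analysis uses a
transverse Mercator aligned on the colony longitude, which gives the same
geometry near the colony while remaining portable to any study site.

Spherical transverse-Mercator formulas on an authalic-radius sphere are used;
over a few hundred kilometres the difference from the ellipsoidal projection
is far below the GPS error of the loggers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Authalic Earth radius in metres.
EARTH_RADIUS_M = 6_371_007.2


@dataclass(frozen=True)
class LocalProjection:
    """Transverse Mercator with the central meridian on ``lon0``.

    ``(lon0, lat0)`` maps to ``(0, 0)``; x grows eastward, y northward,
    both in metres.
    """

    lon0: float
    lat0: float
    radius: float = EARTH_RADIUS_M

    def forward(self, lon, lat):
        """Project lon/lat degrees to planar ``(x, y)`` metres."""
        lam = np.radians(np.asarray(lon, dtype=float) - self.lon0)
        phi = np.radians(np.asarray(lat, dtype=float))
        phi0 = np.radians(self.lat0)
        b = np.cos(phi) * np.sin(lam)
        b = np.clip(b, -1.0 + 1e-15, 1.0 - 1e-15)
        x = self.radius * np.arctanh(b)
        y = self.radius * (np.arctan2(np.tan(phi), np.cos(lam)) - phi0)
        return x, y

    def inverse(self, x, y):
        """Planar metres back to lon/lat degrees."""
        xs = np.asarray(x, dtype=float) / self.radius
        ys = np.asarray(y, dtype=float) / self.radius + np.radians(self.lat0)
        phi = np.arcsin(np.clip(np.sin(ys) / np.cosh(xs), -1.0, 1.0))
        lam = np.arctan2(np.sinh(xs), np.cos(ys))
        return self.lon0 + np.degrees(lam), np.degrees(phi)


def bearing(x0, y0, x1, y1):
    """Planar bearing from point 0 to point 1, radians in (-pi, pi].

    0 = north, pi/2 = east (compass-style but in radians, signed).
    """
    ang = np.arctan2(np.asarray(x1) - x0, np.asarray(y1) - y0)
    return wrap_angle(ang)


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return out if out.ndim else float(out)
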