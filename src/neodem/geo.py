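"""Equal-area projection helpers.

Hull areas and region geometry are computed on a plane, not on raw
longitude/latitude: degrees are not an area metric. Points are projected with
a spherical Lambert azimuthal equal-area (LAEA) projection centred on the
point cloud, so polygon areas come out in km² and are preserved by the
projection (up to the spherical-vs-ellipsoidal approximation, well below the
tolerances used anywhere in this package).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


@dataclass(frozen=True)
class LambertAzimuthalEqualArea:
    """Spherical LAEA projection centred at (lon0, lat0), coordinates in km."""

    lon0: float
    lat0: float
    radius: float = EARTH_RADIUS_KM

    def forward(self, lon, lat):
        """Project degrees -> (x, y) km."""
        lam = np.radians(np.asarray(lon, dtype=float)) - np.radians(self.lon0)
        phi = np.radians(np.asarray(lat, dtype=float))
        phi0 = np.radians(self.lat0)
        denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
        # antipode of the projection centre maps to infinity; clamp for safety
        denom = np.maximum(denom, 1e-12)
        k = np.sqrt(2.0 / denom)
        x = self.radius * k * np.cos(phi) * np.sin(lam)
        y = self.radius * k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam))
        return x, y

    def inverse(self, x, y):
        """Unproject (x, y) km -> (lon, lat) degrees."""
        x = np.asarray(x, dtype=float) / self.radius
        y = np.asarray(y, dtype=float) / self.radius
        phi0 = np.radians(self.lat0)
        rho = np.hypot(x, y)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
        with np.errstate(invalid="ignore"):
            sin_phi = np.cos(c) * np.sin(phi0) + np.where(
                rho > 0, y * np.sin(c) * np.cos(phi0) / np.where(rho > 0, rho, 1.0), 0.0
            )
            phi = np.arcsin(np.clip(sin_phi, -1.0, 1.0))
            lam = np.arctan2(
                x * np.sin(c),
                rho * np.cos(c) * np.cos(phi0) - y * np.sin(c) * np.sin(phi0),
            )
        lam = np.where(rho > 0, lam, 0.0)
        return np.degrees(lam) + self.lon0, np.degrees(phi)

    @classmethod
    def centered_on(cls, lon, lat) -> "LambertAzimuthalEqualArea":
        """Projection centred on the centroid of a point cloud."""
        return cls(lon0=float(np.mean(lon)), lat0=float(np.mean(lat)))


def destination_point(lon0: float, lat0: float, bearing_deg, distance_km):
    """Great-circle destination from (lon0, lat0) along a bearing.

    Vectorised over bearing/distance; returns (lon, lat) in degrees.
    """
    theta = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    phi0 = np.radians(lat0)
    lam0 = np.radians(lon0)
    phi = np.arcsin(np.sin(phi0) * np.cos(delta) + np.cos(phi0) * np.sin(delta) * np.cos(theta))
    lam = lam0 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi0),
        np.cos(delta) - np.sin(phi0) * np.sin(phi),
    )
    return np.degrees(lam), np.degrees(phi)


def great_circle_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km (haversine), vectorised."""
    phi1, phi2 = np.radians(np.asarray(lat1, float)), np.radians(np.asarray(lat2, float))
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2, float)) - np.radians(np.asarray(lon1, float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
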