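"""Reduction of q-space GIWAXS images to 1D sector and azimuthal profiles.

Works on images already mapped to scattering-vector coordinates: a 2D
intensity grid indexed by (q_z rows, q_xy columns).  The azimuth chi is
measured from the q_z (out-of-plane) axis, chi = atan2(|q_xy|, q_z) in
degrees, so chi = 0 is straight up and chi = 90 lies along q_xy.  By default
the two signed sides are folded (mirrored about the q_z axis).

Conventions: pixel-center binning, equal-weight averaging of unmasked
pixels (no solid-angle or polarization corrections), and flagged -- never
silently interpolated -- empty bins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "QSpaceImage",
    "Profile1D",
    "AzimuthalProfile",
    "sector_profile",
    "linear_baseline_subtract",
    "azimuthal_profile",
    "wavelength_from_energy",
    "write_image",
    "read_image",
    "write_profile1d",
    "read_profile1d",
    "write_azimuthal",
    "read_azimuthal",
]

#: hc in keV * Angstrom
HC_KEV_A = 12.3984


def wavelength_from_energy(energy_kev: float) -> float:
    """X-ray wavelength in Angstrom from photon energy in keV."""
    if energy_kev <= 0:
        raise ValueError("photon energy must be > 0")
    return HC_KEV_A / energy_kev


@dataclass
class QSpaceImage:
    """2D intensity grid on (q_xy, q_z) axes with an optional invalid-pixel mask.

    ``intensity`` has shape (len(q_z), len(q_xy)); ``mask`` is True where a
    pixel is invalid (e.g. the missing wedge).  ``geometry`` carries
    arbitrary metadata (typically a GeometryConfig).
    """

    intensity: np.ndarray
    q_xy: np.ndarray
    q_z: np.ndarray
    mask: np.ndarray | None = None
    geometry: Any = None

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.q_xy = np.asarray(self.q_xy, dtype=float)
        self.q_z = np.asarray(self.q_z, dtype=float)
        if self.intensity.shape != (len(self.q_z), len(self.q_xy)):
            raise ValueError("intensity shape must be (len(q_z), len(q_xy))")
        for ax, name in ((self.q_xy, "q_xy"), (self.q_z, "q_z")):
            if len(ax) > 1 and not (np.all(np.diff(ax) > 0) or np.all(np.diff(ax) < 0)):
                raise ValueError(f"{name} axis must be monotone")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.intensity.shape:
                raise ValueError("mask shape must match intensity")

    def q_map(self) -> np.ndarray:
        qxy, qz = np.meshgrid(self.q_xy, self.q_z)
        return np.hypot(qxy, qz)

    def chi_map(self, fold: bool = True) -> np.ndarray:
        """Azimuth in degrees; folded to [0, 90] or signed in [-90, 90]."""
        if not fold:
            return self.chi_signed()
        qxy, qz = np.meshgrid(self.q_xy, self.q_z)
        return np.degrees(np.arctan2(np.abs(qxy), qz))

    def chi_signed(self) -> np.ndarray:
        qxy, qz = np.meshgrid(self.q_xy, self.q_z)
        return np.degrees(np.arctan2(qxy, qz))


@dataclass
class Profile1D:
    """Mean intensity vs q on uniform bins; zero-pixel bins are NaN-flagged."""

    q: np.ndarray
    intensity: np.ndarray
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def valid(self) -> np.ndarray:
        return self.counts > 0


@dataclass
class AzimuthalProfile:
    """Background-subtracted intensity vs azimuth chi (degrees)."""

    chi: np.ndarray
    intensity: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)


def sector_profile(
    img: QSpaceImage,
    chi_min: float,
    chi_max: float,
    q_min: float = 0.2,
    q_max: float = 2.2,
    n_bins: int = 500,
    fold: bool = True,
) -> Profile1D:
    """Per-q-bin mean of unmasked pixels inside the azimuthal sector.

    With ``fold=True`` (default) the sector is mirrored about the q_z axis,
    i.e. a pixel is accepted when either its signed chi or its reflection
    falls inside [chi_min, chi_max].
    """
    if not chi_min < chi_max:
        raise ValueError("require chi_min < chi_max")
    if not q_min < q_max:
        raise ValueError("require q_min < q_max")
    q = img.q_map()
    chi = img.chi_signed()
    in_sector = (chi >= chi_min) & (chi <= chi_max)
    if fold:
        in_sector |= (-chi >= chi_min) & (-chi <= chi_max)
    ok = in_sector & (q >= q_min) & (q <= q_max)
    if img.mask is not None:
        ok &= ~img.mask
    edges = np.linspace(q_min, q_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    qs = q[ok]
    counts, _ = np.histogram(qs, bins=edges)
    sums, _ = np.histogram(qs, bins=edges, weights=img.intensity[ok])
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if counts.sum() == 0:
        warnings.warn("sector contains no valid pixels; all bins flagged")
    meta = {"chi_min": chi_min, "chi_max": chi_max, "fold": fold}
    return Profile1D(centers, mean, counts, meta)


def linear_baseline_subtract(
    p: Profile1D, fit_window: tuple[float, float] = (1.9, 2.2)
) -> Profile1D:
    """Fit a line on the high-q window and subtract it over the full range."""
    lo, hi = fit_window
    sel = (p.q >= lo) & (p.q <= hi) & p.valid
    if sel.sum() < 2:
        raise ValueError(f"baseline window [{lo}, {hi}] has fewer than 2 valid bins")
    slope, intercept = np.polyfit(p.q[sel], p.intensity[sel], 1)
    out = p.intensity - (slope * p.q + intercept)
    meta = dict(p.meta)
    meta["baseline_subtracted"] = {"slope": float(slope), "intercept": float(intercept),
                                   "window": [float(lo), float(hi)]}
    return Profile1D(p.q.copy(), out, p.counts.copy(), meta)


def azimuthal_profile(
    img: QSpaceImage,
    q_lo: float = 1.0,
    q_hi: float = 1.3,
    bg_lo: float = 0.5,
    bg_hi: float = 0.6,
    chi_bin_deg: float = 1.0,
    fold: bool = True,
) -> AzimuthalProfile:
    """Azimuthal profile of the annulus [q_lo, q_hi] minus the background band.

    Per-chi-bin mean over the signal annulus minus per-chi-bin mean over the
    background annulus [bg_lo, bg_hi]; bins where either annulus has no
    valid pixel are flagged.
    """
    q = img.q_map()
    chi = img.chi_map(fold=True) if fold else img.chi_signed()
    lo_chi, hi_chi = (0.0, 90.0) if fold else (-90.0, 90.0)
    n = int(round((hi_chi - lo_chi) / chi_bin_deg))
    edges = np.linspace(lo_chi, hi_chi, n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    unmasked = np.ones_like(q, dtype=bool) if img.mask is None else ~img.mask

    def band_mean(a, b):
        sel = (q >= a) & (q <= b) & unmasked
        cnt, _ = np.histogram(chi[sel], bins=edges)
        tot, _ = np.histogram(chi[sel], bins=edges, weights=img.intensity[sel])
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan), cnt

    sig, cnt_s = band_mean(q_lo, q_hi)
    bg, cnt_b = band_mean(bg_lo, bg_hi)
    valid = (cnt_s > 0) & (cnt_b > 0)
    out = np.where(valid, sig - bg, np.nan)
    meta = {"q_window": [q_lo, q_hi], "bg_window": [bg_lo, bg_hi], "fold": fold}
    return AzimuthalProfile(centers, out, valid, meta)


# ---------------------------------------------------------------------------
# File I/O: TIFF + JSON sidecar for images, CSV for profiles


def write_image(img: QSpaceImage, path) -> None:
    import tifffile

    path = str(path)
    tifffile.imwrite(path, img.intensity.astype(np.float32))
    side = {
        "q_xy": img.q_xy.tolist(),
        "q_z": img.q_z.tolist(),
        "mask_true_indices": (
            None if img.mask is None else np.argwhere(img.mask).tolist()
        ),
    }
    if img.geometry is not None and hasattr(img.geometry, "__dict__"):
        side["geometry"] = {
            k: v for k, v in vars(img.geometry).items() if np.isscalar(v)
        }
    with open(path + ".json", "w") as fh:
        json.dump(side, fh)


def read_image(path) -> QSpaceImage:
    import tifffile

    path = str(path)
    intensity = tifffile.imread(path).astype(float)
    with open(path + ".json") as fh:
        side = json.load(fh)
    mask = None
    if side.get("mask_true_indices") is not None:
        mask = np.zeros_like(intensity, dtype=bool)
        idx = np.array(side["mask_true_indices"], dtype=int)
        if len(idx):
            mask[idx[:, 0], idx[:, 1]] = True
    return QSpaceImage(
        intensity, np.array(side["q_xy"]), np.array(side["q_z"]), mask=mask
    )


def write_profile1d(p: Profile1D, path) -> None:
    pd.DataFrame({"q": p.q, "intensity": p.intensity, "counts": p.counts}).to_csv(
        path, index=False
    )


def read_profile1d(path) -> Profile1D:
    df = pd.read_csv(path)
    return Profile1D(
        df["q"].to_numpy(), df["intensity"].to_numpy(), df["counts"].to_numpy()
    )


def write_azimuthal(a: AzimuthalProfile, path) -> None:
    pd.DataFrame(
        {"chi_deg": a.chi, "intensity": a.intensity, "valid": a.valid.astype(int)}
    ).to_csv(path, index=False)


def read_azimuthal(path) -> AzimuthalProfile:
    df = pd.read_csv(path)
    return AzimuthalProfile(
        df["chi_deg"].to_numpy(),
        df["intensity"].to_numpy(),
        df["valid"].to_numpy().astype(bool),
    )
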