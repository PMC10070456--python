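"""Pole-figure stitching, texture FWHM and the relative crystallinity index.

A fixed-incidence GIWAXS image cannot reach azimuths near the q_z axis (the
missing wedge); a rocking scan fills that range.  ``stitch`` joins the two
azimuthal profiles of the (110/1-10) ring into a complete chi pole figure
on [0, 90] degrees by fitting one scale factor on an overlap window (the
rocking-scan exposure relative to the image is not known a priori).

From the pole figure: ``crystallinity_index`` evaluates the orientation-
weighted integral of I(chi) sin(chi) over [0, pi/2] (trapezoid rule, chi in
radians) -- proportional to the amount of oriented crystalline material --
and ``polefigure_fwhm`` measures the full width at half maximum of the
texture peak above a floor taken as the median intensity over the top
quartile of the chi range (the pole figure of a background-subtracted ring
still carries a chi-constant offset from imperfect background matching).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reduction import AzimuthalProfile

__all__ = [
    "PoleFigure",
    "StitchError",
    "stitch",
    "fold_azimuthal",
    "floor_level",
    "crystallinity_index",
    "polefigure_fwhm",
    "write_polefigure",
    "read_polefigure",
]


class StitchError(RuntimeError):
    """Overlap window too small or degenerate for scale estimation."""


@dataclass
class PoleFigure:
    """Stitched I(chi) on [0, 90] degrees with per-bin provenance.

    ``provenance`` holds 'image', 'rocking' or 'overlap' per bin; bins with
    no data are NaN in ``intensity`` and marked 'gap'.
    """

    chi: np.ndarray
    intensity: np.ndarray
    provenance: np.ndarray
    scale: float = 1.0
    scale_flipped: bool = False

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.intensity)


def fold_azimuthal(profile: AzimuthalProfile) -> AzimuthalProfile:
    """Fold a signed chi profile onto [0, 90] by averaging the two sides."""
    chi = profile.chi
    if chi.min() >= 0:
        return profile
    folded = np.sort(np.unique(np.round(np.abs(chi), 9)))
    inten = np.full(len(folded), np.nan)
    valid = np.zeros(len(folded), bool)
    for i, c in enumerate(folded):
        sel = (np.abs(np.abs(chi) - c) < 1e-9) & profile.valid
        if np.any(sel):
            inten[i] = profile.intensity[sel].mean()
            valid[i] = True
    return AzimuthalProfile(folded, inten, valid, dict(profile.meta))


def stitch(
    image_profile: AzimuthalProfile,
    rocking_profile: AzimuthalProfile,
    overlap: tuple[float, float] = (8.0, 15.0),
) -> PoleFigure:
    """Join image and rocking azimuthal profiles into a [0, 90] pole figure.

    The scalar s minimizing sum((image - s*rocking)^2) over the overlap
    window scales the rocking profile; scaled rocking fills chi below the
    image's valid range, overlap bins are averaged, and the image alone
    covers the rest.  A negative fitted s triggers a warning and an
    absolute-value fallback.
    """
    img = fold_azimuthal(image_profile)
    rock = fold_azimuthal(rocking_profile)
    lo, hi = overlap
    if not lo < hi:
        raise StitchError("overlap window must be increasing")

    chi = img.chi
    rock_on_img = np.full(len(chi), np.nan)
    if np.any(rock.valid):
        rchi, rint = rock.chi[rock.valid], rock.intensity[rock.valid]
        inside = (chi >= rchi.min() - 1e-9) & (chi <= rchi.max() + 1e-9)
        rock_on_img[inside] = np.interp(chi[inside], rchi, rint)

    img_ok = img.valid & np.isfinite(img.intensity)
    rock_ok = np.isfinite(rock_on_img)
    ov = img_ok & rock_ok & (chi >= lo) & (chi <= hi)
    if ov.sum() < 3:
        raise StitchError(
            f"overlap [{lo}, {hi}] deg has {int(ov.sum())} valid bins; need >= 3"
        )
    denom = float(np.sum(rock_on_img[ov] ** 2))
    if denom == 0:
        raise StitchError("rocking profile vanishes on the overlap window")
    s = float(np.sum(img.intensity[ov] * rock_on_img[ov]) / denom)
    flipped = False
    if s < 0:
        warnings.warn("negative stitch scale; using absolute value")
        s, flipped = abs(s), True

    out = np.full(len(chi), np.nan)
    prov = np.full(len(chi), "gap", dtype=object)
    only_rock = rock_ok & ~img_ok
    out[only_rock] = s * rock_on_img[only_rock]
    prov[only_rock] = "rocking"
    only_img = img_ok & ~ov
    out[only_img] = img.intensity[only_img]
    prov[only_img] = "image"
    out[ov] = 0.5 * (img.intensity[ov] + s * rock_on_img[ov])
    prov[ov] = "overlap"
    return PoleFigure(chi, out, np.asarray(prov), scale=s, scale_flipped=flipped)


def floor_level(pf: PoleFigure) -> float:
    """Median intensity over the top quartile of the chi range."""
    chi = pf.chi
    cut = chi.min() + 0.75 * (chi.max() - chi.min())
    sel = (chi >= cut) & pf.valid
    if not np.any(sel):
        raise ValueError("no valid bins in the top-chi quartile")
    return float(np.median(pf.intensity[sel]))


def crystallinity_index(pf: PoleFigure, allow_gaps: bool = False) -> float:
    """Trapezoidal integral of sin(chi) I(chi) d(chi) over [0, pi/2]."""
    if not np.all(pf.valid):
        if not allow_gaps:
            raise ValueError(
                "pole figure has flagged bins; pass allow_gaps=True to drop them"
            )
        warnings.warn("dropping flagged pole-figure bins from the integral")
    sel = pf.valid
    chi_rad = np.radians(pf.chi[sel])
    return float(np.trapezoid(np.sin(chi_rad) * pf.intensity[sel], chi_rad))


def polefigure_fwhm(pf: PoleFigure) -> float:
    """FWHM (degrees) of the texture peak above the top-quartile floor.

    Half-maximum crossings are located by linear interpolation.  When the
    peak sits at the chi = 0 edge (out-of-plane texture folded to [0, 90])
    the width is twice the one-sided half width, by symmetry.
    """
    sel = pf.valid
    chi, inten = pf.chi[sel], pf.intensity[sel]
    if len(chi) < 5:
        raise ValueError("too few valid bins for a FWHM")
    floor = floor_level(pf)
    ipk = int(np.argmax(inten))
    peak = inten[ipk]
    if peak <= floor:
        raise ValueError("no peak above the floor; FWHM undefined")
    half = floor + 0.5 * (peak - floor)

    def crossing(idx_range):
        prev = ipk
        for i in idx_range:
            if inten[i] < half:
                x0, x1 = chi[prev], chi[i]
                y0, y1 = inten[prev], inten[i]
                return x0 + (half - y0) * (x1 - x0) / (y1 - y0)
            prev = i
        return None

    right = crossing(range(ipk + 1, len(chi)))
    left = crossing(range(ipk - 1, -1, -1))
    if right is None and left is None:
        raise ValueError("no half-maximum crossing found; FWHM undefined")
    if left is None:
        # peak truncated at the fold axis (chi = 0): width by symmetry
        return 2.0 * right
    if right is None:
        return 2.0 * (90.0 - left) if chi.max() > 89.0 else 2.0 * (chi[ipk] - left)
    return right - left


def write_polefigure(pf: PoleFigure, path) -> None:
    pd.DataFrame(
        {"chi_deg": pf.chi, "intensity": pf.intensity, "provenance": pf.provenance}
    ).to_csv(path, index=False)


def read_polefigure(path) -> PoleFigure:
    df = pd.read_csv(path)
    return PoleFigure(
        df["chi_deg"].to_numpy(),
        df["intensity"].to_numpy(),
        df["provenance"].to_numpy(),
    )
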