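"""Synthetic GIWAXS patterns emulating hydrated/dried onion epidermis.

Generates ground-truth q-space detector images and rocking-scan azimuthal
profiles so the whole reduction/fitting/pole-figure chain can be exercised
against known parameters.  A pattern is a sum of components, each Gaussian
in |q|, either isotropic (amorphous pectin/cuticle rings) or modulated by a
Gaussian in azimuth chi (out-of-plane-textured cellulose reflections, or
in-plane-textured wax peaks), on top of a linear instrumental baseline,
with optional Poisson counting noise.

The ``preset`` factory encodes the two experimental states:

* hydrated -- cellulose (110/1-10) at q = 2*pi/5.57 with 0.240 1/A FWHM and
  (200) at 2*pi/4.03, peak-height ratio 0.52, both textured out-of-plane
  with a 38.3-degree chi FWHM; isotropic pectin ring at 0.85 1/A and
  cuticle ring at 1.41 1/A (0.77 FWHM).
* dried -- (110/1-10) at 2*pi/5.52 with 0.277 FWHM, (200) at 2*pi/4.02,
  ratio 0.86, texture 40.0 degrees; pectin at 0.89, cuticle width 0.54.

Widths not printed anywhere ((200) and pectin q widths) are fixture
choices, 0.22 and 0.35 1/A.  The dried cellulose amplitude is scaled so
that the sin(chi)-weighted crystalline index matches the hydrated preset,
emulating the observation that drying does not change the oriented
crystalline content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .reduction import (
    AzimuthalProfile,
    HC_KEV_A,
    Profile1D,
    QSpaceImage,
    wavelength_from_energy,
)

__all__ = [
    "GeometryConfig",
    "ComponentSpec",
    "PatternSpec",
    "preset",
    "render_qspace_image",
    "render_rocking_profile",
    "expected_sector_profile",
    "expected_azimuthal_signal",
    "render_sector_profile1d",
]

_4LN2 = 4.0 * math.log(2.0)


@dataclass(frozen=True)
class GeometryConfig:
    """Idealized q-space detector geometry.

    Images are generated directly in (q_xy, q_z); real-detector effects
    (refraction, Ewald curvature, beam footprint) are collapsed into the
    optional missing-wedge mask of half-angle ``missing_wedge_halfangle``
    about the q_z axis, which emulates the azimuth range a fixed-incidence
    measurement cannot reach.
    """

    photon_energy_kev: float = 12.7
    incidence_angle_deg: float = 0.12
    shape: tuple[int, int] = (470, 940)  # (n_qz, n_qxy)
    q_xy_range: tuple[float, float] = (-2.35, 2.35)
    q_z_range: tuple[float, float] = (0.0, 2.35)
    missing_wedge_halfangle: float = 0.0

    def __post_init__(self):
        if self.photon_energy_kev <= 0:
            raise ValueError("photon energy must be > 0")
        if self.missing_wedge_halfangle < 0:
            raise ValueError("missing wedge half-angle must be >= 0")
        for rng in (self.q_xy_range, self.q_z_range):
            if not all(np.isfinite(rng)) or not rng[0] < rng[1]:
                raise ValueError("axis ranges must be finite and increasing")

    @property
    def wavelength(self) -> float:
        return wavelength_from_energy(self.photon_energy_kev)

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        nz, nxy = self.shape
        return (
            np.linspace(*self.q_xy_range, nxy),
            np.linspace(*self.q_z_range, nz),
        )


@dataclass(frozen=True)
class ComponentSpec:
    """One scattering component: Gaussian in |q|, optionally textured in chi.

    ``texture`` is None for an isotropic ring, or ("out-of-plane", fwhm_chi)
    / ("in-plane", fwhm_chi) for a Gaussian azimuthal kernel centered on
    chi = 0 (the q_z axis) or chi = 90 degrees respectively.
    """

    kind: str
    center_q: float
    fwhm_q: float
    height: float
    texture: tuple[str, float] | None = None

    def __post_init__(self):
        if min(self.center_q, self.fwhm_q, self.height) <= 0:
            raise ValueError("center_q, fwhm_q and height must be > 0")
        if self.texture is not None:
            orient, w = self.texture
            if orient not in ("out-of-plane", "in-plane"):
                raise ValueError(f"unknown texture orientation {orient!r}")
            if w <= 0:
                raise ValueError("texture fwhm_chi must be > 0")

    @property
    def center_chi(self) -> float:
        if self.texture is None:
            raise ValueError("isotropic component has no texture center")
        return 0.0 if self.texture[0] == "out-of-plane" else 90.0


@dataclass
class PatternSpec:
    """Sum of components + linear baseline + Poisson noise level.

    ``exposure`` scales counting statistics: observed = Poisson(I * exposure)
    / exposure; exposure 0 means noiseless.
    """

    components: list[ComponentSpec]
    baseline_slope: float = -40.0
    baseline_intercept: float = 150.0
    #: counting-statistics scale: observed = Poisson(I * exposure)/exposure.
    #: The default puts peak pixels at a few 10^3 detected photons, typical
    #: of a synchrotron GIWAXS exposure, so counting noise sits well below
    #: sample-to-sample variation.
    exposure: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.exposure < 0:
            raise ValueError("exposure must be >= 0 (0 = noiseless)")

    def baseline(self, q):
        return self.baseline_intercept + self.baseline_slope * np.asarray(q)

    def component(self, kind: str) -> ComponentSpec:
        for c in self.components:
            if c.kind == kind:
                return c
        raise KeyError(kind)


# Generator ground truth for the two experimental states.  Cellulose
# centers are 2*pi/d with the reported reference d-spacings; amorphous
# centers/widths are the reported fit values; unprinted widths are
# fixture choices.  The
# dried cellulose amplitude factor 0.514 equalizes the sin(chi)-weighted
# crystalline index between states (closed-form calculation; see methods).
_PRESETS = {
    "hydrated": dict(
        d110=5.57, fwhm110=0.240, d200=4.03, fwhm200=0.22, ratio=0.52,
        texture_fwhm=38.3, amor1_q=0.85, amor1_w=0.35, amor1_h=260.0,
        amor2_q=1.41, amor2_w=0.77, amor2_h=230.0, h200=400.0,
    ),
    "dried": dict(
        d110=5.52, fwhm110=0.277, d200=4.02, fwhm200=0.22, ratio=0.86,
        texture_fwhm=40.0, amor1_q=0.89, amor1_w=0.35, amor1_h=230.0,
        amor2_q=1.41, amor2_w=0.54, amor2_h=230.0, h200=400.0 * 0.514,
    ),
}


def preset(state: str) -> PatternSpec:
    """PatternSpec for the 'hydrated' or 'dried' reference state."""
    try:
        p = _PRESETS[state]
    except KeyError:
        raise ValueError(f"unknown state {state!r}; expected 'hydrated' or 'dried'")
    texture = ("out-of-plane", p["texture_fwhm"])
    comps = [
        ComponentSpec("amorphous1", p["amor1_q"], p["amor1_w"], p["amor1_h"]),
        ComponentSpec("amorphous2", p["amor2_q"], p["amor2_w"], p["amor2_h"]),
        ComponentSpec("110", 2 * math.pi / p["d110"], p["fwhm110"],
                      p["ratio"] * p["h200"], texture),
        ComponentSpec("200", 2 * math.pi / p["d200"], p["fwhm200"],
                      p["h200"], texture),
    ]
    return PatternSpec(components=comps)


def wax_components() -> list[ComponentSpec]:
    """Optional in-plane-textured cuticular wax peaks for sector-cut tests."""
    return [
        ComponentSpec("wax1", 1.50, 0.04, 120.0, ("in-plane", 20.0)),
        ComponentSpec("wax2", 1.70, 0.04, 90.0, ("in-plane", 20.0)),
    ]


def _gauss(x, center, fwhm):
    return np.exp(-_4LN2 * ((np.asarray(x) - center) / fwhm) ** 2)


def _expected_intensity(spec: PatternSpec, q: np.ndarray, chi: np.ndarray) -> np.ndarray:
    out = spec.baseline(q) * np.ones_like(q)
    for c in spec.components:
        radial = c.height * _gauss(q, c.center_q, c.fwhm_q)
        if c.texture is None:
            out = out + radial
        else:
            out = out + radial * _gauss(chi, c.center_chi, c.texture[1])
    return out


def render_qspace_image(spec: PatternSpec, geom: GeometryConfig) -> QSpaceImage:
    """Render the expected pattern on the geometry's grid, add Poisson noise.

    Deterministic for a fixed ``spec.seed``; raises if the expected
    intensity is negative anywhere (unphysical spec).
    """
    q_xy, q_z = geom.axes()
    qxy, qz = np.meshgrid(q_xy, q_z)
    q = np.hypot(qxy, qz)
    chi = np.degrees(np.arctan2(np.abs(qxy), qz))
    expected = _expected_intensity(spec, q, chi)
    if np.any(expected < 0):
        raise ValueError("pattern spec yields negative expected intensity")
    if spec.exposure > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = rng.poisson(expected * spec.exposure) / spec.exposure
    else:
        intensity = expected
    mask = None
    if geom.missing_wedge_halfangle > 0:
        mask = chi < geom.missing_wedge_halfangle
    return QSpaceImage(intensity, q_xy, q_z, mask=mask, geometry=geom)


def _gauss_window_mean(center, fwhm, lo, hi):
    """Mean of a unit-height Gaussian over [lo, hi] (erf closed form)."""
    k = math.sqrt(_4LN2) / fwhm
    return (
        math.sqrt(math.pi)
        / (2.0 * k * (hi - lo))
        * (erf(k * (hi - center)) - erf(k * (lo - center)))
    )


def _gauss_annulus_mean(center, fwhm, lo, hi):
    """q-weighted mean of a unit Gaussian over an annulus [lo, hi].

    Pixels of a Cartesian q-space grid populate an annulus with density
    proportional to q, so the per-chi-bin pixel average weights the radial
    profile by q: int q G dq / int q dq (closed form).
    """
    k = math.sqrt(_4LN2) / fwhm
    e_hi, e_lo = k * (hi - center), k * (lo - center)
    num = center * math.sqrt(math.pi) / (2.0 * k) * (erf(e_hi) - erf(e_lo)) - (
        math.exp(-e_hi**2) - math.exp(-e_lo**2)
    ) / (2.0 * k * k)
    return num / (0.5 * (hi * hi - lo * lo))


def expected_azimuthal_signal(
    spec: PatternSpec,
    chi,
    q_window=(1.0, 1.3),
    bg_window=(0.5, 0.6),
) -> np.ndarray:
    """Noise-free azimuthal profile the annulus reduction would measure.

    Mean over the signal annulus minus mean over the background band, both
    taken of the full pattern (baseline and isotropic rings included), as a
    function of chi.  This is what both the image-derived azimuthal profile
    and an ideal rocking scan converge to.
    """
    chi = np.asarray(chi, dtype=float)
    out = np.zeros_like(chi)
    for lo, hi, sign in (q_window + (1.0,), bg_window + (-1.0,)):
        # q-weighted baseline mean: int q (a + b q) dq / int q dq
        base_mean = spec.baseline_intercept + spec.baseline_slope * (
            2.0 / 3.0 * (hi**3 - lo**3) / (hi**2 - lo**2)
        )
        term = np.full_like(chi, base_mean)
        for c in spec.components:
            radial = c.height * _gauss_annulus_mean(c.center_q, c.fwhm_q, lo, hi)
            ang = 1.0 if c.texture is None else _gauss(
                np.abs(chi), c.center_chi, c.texture[1]
            )
            term = term + radial * ang
        out = out + sign * term
    return out


def render_rocking_profile(
    spec: PatternSpec,
    chi_range: tuple[float, float] = (-20.0, 20.0),
    chi_step: float = 0.5,
    scale: float = 1.0,
    seed: int | None = None,
    counts_per_bin: float = 200.0,
) -> AzimuthalProfile:
    """Rocking-scan azimuthal profile near chi = 0 at the (110/1-10) ring.

    The noiseless profile is ``scale`` times the annulus-minus-background
    azimuthal signal of the pattern (texture kernels plus the same isotropic
    residual an image reduction carries), so it matches the image-derived
    profile up to one overall scalar.  With ``seed`` given and
    ``spec.exposure > 0``, Poisson noise is sampled for the signal and
    background bands separately at ``counts_per_bin`` effective counts.
    """
    lo, hi = chi_range
    if lo < -90 or hi > 90 or lo >= hi:
        raise ValueError("chi_range must be increasing and within [-90, 90]")
    n = int(round((hi - lo) / chi_step))
    chi = lo + (np.arange(n) + 0.5) * chi_step
    base = expected_azimuthal_signal(spec, chi)
    if scale == 0:
        return AzimuthalProfile(chi, np.zeros_like(chi), np.ones_like(chi, bool),
                                {"scale": 0.0})
    if seed is not None and spec.exposure > 0:
        rng = np.random.default_rng(seed)
        # sample the two annulus means separately so each is non-negative
        sig = base + _positive_part_offset(spec)
        off = _positive_part_offset(spec)
        lam_s = np.maximum(sig, 0) * counts_per_bin
        lam_b = np.maximum(off, 0) * counts_per_bin
        noisy = (
            rng.poisson(lam_s) / counts_per_bin
            - rng.poisson(np.full_like(chi, lam_b)) / counts_per_bin
        )
        intensity = scale * noisy
    else:
        intensity = scale * base
    return AzimuthalProfile(chi, intensity, np.ones_like(chi, bool),
                            {"scale": scale})


def _positive_part_offset(spec: PatternSpec) -> float:
    """Background-band mean intensity (used to keep Poisson rates >= 0)."""
    lo, hi = 0.5, 0.6
    val = spec.baseline_intercept + spec.baseline_slope * (
        2.0 / 3.0 * (hi**3 - lo**3) / (hi**2 - lo**2)
    )
    for c in spec.components:
        if c.texture is None:
            val += c.height * _gauss_annulus_mean(c.center_q, c.fwhm_q, lo, hi)
    return float(val)


def expected_sector_profile(
    spec: PatternSpec, chi_lo: float, chi_hi: float, q
) -> np.ndarray:
    """Analytic sector-cut profile: baseline + components with their
    azimuthal kernels averaged uniformly over the sector.

    Matches the pixel reduction in the limit of fine pixels/bins; used as
    the exact-identity path for fit-recovery checks.
    """
    q = np.asarray(q, dtype=float)
    out = spec.baseline(q).astype(float)
    for c in spec.components:
        radial = c.height * _gauss(q, c.center_q, c.fwhm_q)
        if c.texture is None:
            fac = 1.0
        else:
            # fold the sector about chi = 0 and average the kernel over it
            lo, hi = abs(min(chi_lo, chi_hi, key=abs)), max(abs(chi_lo), abs(chi_hi))
            if chi_lo < 0 < chi_hi:
                lo, hi = 0.0, max(abs(chi_lo), abs(chi_hi))
            fac = _gauss_window_mean(c.center_chi, c.texture[1], lo, hi)
        out = out + fac * radial
    return out


def render_sector_profile1d(
    spec: PatternSpec,
    chi_lo: float = -17.0,
    chi_hi: float = 17.0,
    q_min: float = 0.2,
    q_max: float = 2.2,
    n_bins: int = 500,
) -> Profile1D:
    """Noiseless analytic render of the sector profile as a Profile1D."""
    edges = np.linspace(q_min, q_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    vals = expected_sector_profile(spec, chi_lo, chi_hi, centers)
    return Profile1D(centers, vals, np.ones_like(centers, dtype=int),
                     {"analytic": True, "chi_min": chi_lo, "chi_max": chi_hi})
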