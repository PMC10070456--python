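"""Orientation-averaged wide-angle scattering via the Debye equation.

For an assembly of atoms with (q-independent) scattering factors f_i at
mutual distances r_ij, the isotropically averaged intensity is

    I(q) = sum_i f_i^2  +  2 sum_{i<j} f_i f_j sin(q r_ij) / (q r_ij).

The pairwise double sum is accelerated with a weighted pair-distance
histogram: pair contributions are accumulated into distance bins of width
``bin_width`` and the sinc kernel is evaluated once per bin.  Scattering
factors default to electron counts (f = Z), which preserves peak positions
and relative ordering at wide angles.

Also provides the solvent-subtraction convention
I(q) = I_sample(q) - (1 - v) I_buffer(q) (v = solute volume fraction) and
normalization of a profile to its maximum inside a q window, as used when
comparing fibril-model curves scaled to the (200) peak.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .microfibril import MicrofibrilModel

__all__ = [
    "ScatteringProfile",
    "SolventParams",
    "GridMismatchError",
    "NormalizationError",
    "debye_profile",
    "brute_force_debye",
    "solvent_subtract",
    "normalize_to_window_max",
    "read_profile_csv",
    "write_profile_csv",
    "ELECTRON_COUNTS",
]

ELECTRON_COUNTS = {"H": 1.0, "C": 6.0, "N": 7.0, "O": 8.0}


class GridMismatchError(ValueError):
    """Profiles are defined on different q grids."""


class NormalizationError(ValueError):
    """Normalization window is empty or its maximum is not positive."""


@dataclass(frozen=True)
class SolventParams:
    """Solute volume fraction v in [0, 1] for buffer subtraction."""

    v: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.v <= 1.0:
            raise ValueError("solute volume fraction must be within [0, 1]")


@dataclass
class ScatteringProfile:
    """Intensity versus scattering-vector magnitude q (1/A)."""

    q: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be matching 1-D arrays")
        if len(self.q) and np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")


def _form_factors(model: MicrofibrilModel) -> np.ndarray:
    try:
        return np.array([ELECTRON_COUNTS[e] for e in model.elements])
    except KeyError as exc:
        raise ValueError(f"no scattering factor for element {exc}") from exc


def debye_profile(
    model: MicrofibrilModel,
    q_grid: np.ndarray,
    bin_width: float = 0.01,
    chunk: int = 512,
) -> ScatteringProfile:
    """Debye intensity of *model* on *q_grid* via a pair-distance histogram."""
    if model.n_atoms == 0:
        raise ValueError("model has no atoms")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    q = np.asarray(q_grid, dtype=float)
    xyz = model.coords
    f = _form_factors(model)
    n = len(xyz)
    self_term = float(np.sum(f * f))
    if n == 1:
        return ScatteringProfile(q, np.full_like(q, self_term), "debye")

    span = xyz.max(axis=0) - xyz.min(axis=0)
    dmax = float(np.linalg.norm(span)) + bin_width
    edges = np.arange(0.0, dmax + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    # all ordered pairs (i != j); the histogram then holds 2 * sum_{i<j}
    for i0 in range(0, n, chunk):
        block = xyz[i0 : i0 + chunk]
        d = np.sqrt(
            np.maximum(
                np.sum(block * block, axis=1)[:, None]
                + np.sum(xyz * xyz, axis=1)[None, :]
                - 2.0 * block @ xyz.T,
                0.0,
            )
        )
        w = f[i0 : i0 + chunk, None] * f[None, :]
        rows = np.arange(i0, min(i0 + chunk, n)) - i0
        w[rows, rows + i0] = 0.0  # drop self-pairs
        hist += np.histogram(d.ravel(), bins=edges, weights=w.ravel())[0]

    r = 0.5 * (edges[:-1] + edges[1:])
    keep = hist != 0
    r, w = r[keep], hist[keep]
    # np.sinc(x) = sin(pi x)/(pi x); handles q=0 via the sinc limit
    intensity = self_term + w @ np.sinc(np.outer(r, q) / np.pi)
    return ScatteringProfile(q, intensity, label="debye")


def brute_force_debye(model: MicrofibrilModel, q_grid: np.ndarray) -> ScatteringProfile:
    """Direct O(N^2) Debye double sum (independent reference, small N only)."""
    if model.n_atoms == 0:
        raise ValueError("model has no atoms")
    q = np.asarray(q_grid, dtype=float)
    xyz = model.coords
    f = _form_factors(model)
    out = np.full(len(q), np.sum(f * f))
    n = len(xyz)
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(xyz[i] - xyz[j]))
            out += 2.0 * f[i] * f[j] * np.sinc(q * r / np.pi)
    return ScatteringProfile(q, out, label="debye-brute")


def solvent_subtract(
    sample: ScatteringProfile,
    buffer: ScatteringProfile,
    params: SolventParams,
) -> ScatteringProfile:
    """I(q) = I_sample(q) - (1 - v) I_buffer(q); may go negative."""
    if sample.q.shape != buffer.q.shape or not np.allclose(sample.q, buffer.q):
        raise GridMismatchError("sample and buffer are on different q grids")
    out = sample.intensity - (1.0 - params.v) * buffer.intensity
    return ScatteringProfile(sample.q.copy(), out, label=f"{sample.label}-subtracted")


def normalize_to_window_max(
    profile: ScatteringProfile, q_lo: float, q_hi: float
) -> ScatteringProfile:
    """Divide by the maximum intensity inside [q_lo, q_hi]."""
    sel = (profile.q >= q_lo) & (profile.q <= q_hi)
    if not np.any(sel):
        raise NormalizationError(f"window [{q_lo}, {q_hi}] contains no grid points")
    peak = float(np.max(profile.intensity[sel]))
    if peak <= 0:
        raise NormalizationError("window maximum is not positive")
    return replace(profile, intensity=profile.intensity / peak)


def write_profile_csv(profile: ScatteringProfile, path) -> None:
    pd.DataFrame({"q": profile.q, "intensity": profile.intensity}).to_csv(
        path, index=False
    )


def read_profile_csv(path, label: str = "") -> ScatteringProfile:
    df = pd.read_csv(path)
    if not {"q", "intensity"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'q' and 'intensity'")
    return ScatteringProfile(df["q"].to_numpy(), df["intensity"].to_numpy(), label)
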