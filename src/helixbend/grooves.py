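"""Major/minor groove-width profiles from cross-strand phosphate geometry.

Convention (fixed once by calibration to the ideal A-form anchor, then
frozen): each strand's phosphorus atoms form a refined polyline over
residue index (boxcar-smoothed over 3 nodes, linearly interpolated at
0.1-step resolution); for base-pair step s the major (minor) groove width
is the minimal distance between the strand-I polyline near the step
midpoint and the strand-II polyline over a fixed cross-strand index-offset
window centred on the calibrated branch minimum.  The ideal A-form build
measures 12.2 A — "around 12 A", and deliberately above the 12 A collapse
threshold, since the relaxed A-form is by definition not collapsed.  Steps
whose cross-strand window runs off the end of the helix are undefined
(NaN) and excluded from all means and counts.  No van-der-Waals
subtraction is applied by default (``subtract_vdw`` offers the
conventional 5.8 A).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import PairingMap, infer_pairing
from .io import Conformation, StructureError

__all__ = ["GrooveProfile", "CollapseReport", "groove_widths", "count_collapsed"]

#: Centres of the cross-strand index-offset windows, in summed-index units
#: j = x + u - N - 1 (x: strand-I fractional index, u: strand-II fractional
#: index); frozen at the branch minima of the calibrated ideal build.
MAJOR_OFFSET_CENTER = -4.47
MINOR_OFFSET_CENTER = 4.02
#: Half-width of the strand-II window around the branch centre.
_U_HALF_WINDOW = 1.5
#: Half-width of the strand-I search interval around the step midpoint.
_X_HALF_WINDOW = 0.5
_RESOLUTION = 0.1
_SMOOTH_NODES = 3


@dataclass(frozen=True)
class GrooveProfile:
    """Per-step groove widths; NaN marks undefined positions."""

    Mgw: np.ndarray
    mgw: np.ndarray
    step_count: int

    @property
    def defined_major(self) -> np.ndarray:
        return self.Mgw[np.isfinite(self.Mgw)]

    @property
    def defined_minor(self) -> np.ndarray:
        return self.mgw[np.isfinite(self.mgw)]

    def mean_major(self) -> float:
        """Mean over the defined (interior) major-groove values."""
        vals = self.defined_major
        return float(np.mean(vals)) if vals.size else float("nan")


@dataclass(frozen=True)
class CollapseReport:
    threshold: float
    collapsed_indices: tuple[int, ...]
    count: int


def _phosphate_polyline(c: Conformation, chain: str) -> np.ndarray:
    """P positions indexed by residue (NaN rows where P is absent)."""
    arr = c.atoms
    n = c.n_pairs
    out = np.full((n, 3), np.nan)
    m = (arr.chain_id == chain) & (arr.atom_name == "P")
    for rid, xyz in zip(arr.res_id[m], c.coords[m]):
        out[rid - 1] = xyz
    return out


def _interpolate(poly: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Refined fine polyline: boxcar-smoothed nodes, linear interpolation."""
    n = len(poly)
    ok = np.isfinite(poly[:, 0])
    sm = poly.copy()
    h = _SMOOTH_NODES // 2
    for i in np.flatnonzero(ok):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        sm[i] = np.nanmean(poly[lo:hi], axis=0)
    idx = np.arange(1, n + 1, dtype=float)
    lo, hi = idx[ok][0], idx[ok][-1]
    xs = np.arange(lo, hi + 1e-9, _RESOLUTION)
    pts = np.column_stack([np.interp(xs, idx[ok], sm[ok, k]) for k in range(3)])
    return xs, pts


def groove_widths(
    c: Conformation,
    pm: PairingMap | None = None,
    subtract_vdw: float = 0.0,
) -> GrooveProfile:
    """Per-step major/minor groove-width profile of one conformation.

    ``subtract_vdw`` subtracts a phosphate van-der-Waals allowance (the
    conventional value is 5.8 A) from every defined width; the default
    reports raw P-P distances, which is the calibrated convention.
    """
    if pm is None:
        pm = infer_pairing(c)
    n = pm.n_pairs
    if n < 2:
        raise StructureError("need at least two base pairs")
    p_i = _phosphate_polyline(c, pm.chain_i)
    p_ii = _phosphate_polyline(c, pm.chain_ii)
    if np.all(~np.isfinite(p_i[:, 0])) or np.all(~np.isfinite(p_ii[:, 0])):
        import warnings

        warnings.warn("no phosphates found: groove profile undefined", stacklevel=2)
        nanarr = np.full(n - 1, np.nan)
        return GrooveProfile(Mgw=nanarr, mgw=nanarr.copy(), step_count=n - 1)

    xs_i, f_i = _interpolate(p_i)
    xs_ii, f_ii = _interpolate(p_ii)

    major = np.full(n - 1, np.nan)
    minor = np.full(n - 1, np.nan)
    for s in range(1, n):
        x0 = s + 0.5
        mx = (xs_i >= x0 - _X_HALF_WINDOW - 1e-9) & (xs_i <= x0 + _X_HALF_WINDOW + 1e-9)
        if not np.any(mx):
            continue
        uc = n + 0.5 - s  # strand-II fractional index aligned with the step
        for center, out in ((MAJOR_OFFSET_CENTER, major), (MINOR_OFFSET_CENTER, minor)):
            u_lo = uc + center - _U_HALF_WINDOW
            u_hi = uc + center + _U_HALF_WINDOW
            if u_lo < xs_ii[0] - 1e-9 or u_hi > xs_ii[-1] + 1e-9:
                continue  # window off the helix end: undefined
            mu = (xs_ii >= u_lo - 1e-9) & (xs_ii <= u_hi + 1e-9)
            d = np.linalg.norm(
                f_i[mx][:, None, :] - f_ii[mu][None, :, :], axis=2
            )
            out[s - 1] = d.min()
    if subtract_vdw:
        major = major - subtract_vdw
        minor = minor - subtract_vdw
    return GrooveProfile(Mgw=major, mgw=minor, step_count=n - 1)


def count_collapsed(g: GrooveProfile, threshold: float = 12.0) -> CollapseReport:
    """Count defined steps whose major-groove width lies below threshold."""
    if threshold <= 0:
        raise ValueError("collapse threshold must be positive")
    idx = tuple(
        int(s + 1)
        for s in range(g.step_count)
        if np.isfinite(g.Mgw[s]) and g.Mgw[s] < threshold
    )
    return CollapseReport(threshold=threshold, collapsed_indices=idx, count=len(idx))
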