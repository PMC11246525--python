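"""Gap-free monthly VI reconstruction by fine/coarse sensor fusion.

The winter-wheat season runs October (planting year) through May (harvest
year), giving 8 monthly slots.  The fine sensor (Landsat-like: sparse
revisit, cloud gaps) is composited to monthly maxima; the coarse sensor
(MODIS-like: dense revisit, coarse pixels) is cloud-masked, temporally
interpolated, composited, Savitzky–Golay smoothed, and bilinearly resampled
to the fine grid.  Fine gaps are then substituted with the resampled coarse
value (no inter-sensor bias correction), any residual gaps are interpolated
in time, and the final series is SG-smoothed once more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import datetime as _dt

import numpy as np
from scipy.signal import savgol_filter

from .raster import RasterCube, resample_bilinear

__all__ = [
    "SeasonSpec",
    "SGParams",
    "FusionResult",
    "monthly_max_composite",
    "temporal_interpolate",
    "sg_smooth",
    "fuse",
    "SLOT_NAMES",
]

#: Month abbreviations for the 8 season slots, in season order.
SLOT_NAMES = ("Oct", "Nov", "Dec", "Jan", "Feb", "Mar", "Apr", "May")

_SLOT_MONTHS = (10, 11, 12, 1, 2, 3, 4, 5)


@dataclass(frozen=True)
class SeasonSpec:
    """The 8 month-slots Oct(harvest_year-1) .. May(harvest_year)."""

    harvest_year: int

    @property
    def slots(self) -> list[tuple[int, int]]:
        return [
            (self.harvest_year - 1 if m >= 10 else self.harvest_year, m)
            for m in _SLOT_MONTHS
        ]

    @property
    def slot_dates(self) -> list[_dt.date]:
        """Nominal mid-month timestamp (the 15th) per slot."""
        return [_dt.date(y, m, 15) for y, m in self.slots]


@dataclass(frozen=True)
class SGParams:
    """Savitzky–Golay window (odd, >= 3) and polynomial order (< window)."""

    window: int = 5
    polyorder: int = 2

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if not 0 <= self.polyorder < self.window:
            raise ValueError("polyorder must satisfy 0 <= polyorder < window")


@dataclass
class FusionResult:
    """Fused cube plus bookkeeping of where values came from.

    ``filled`` is the pre-smoothing cube (fine where fine was valid, then
    resampled coarse, then temporal interpolation); ``smoothed`` is the final
    SG-smoothed product.  ``source`` codes per slot/pixel: 0 = no data,
    1 = fine, 2 = coarse substitution, 3 = temporal interpolation.
    """

    filled: RasterCube
    smoothed: RasterCube
    source: np.ndarray
    gap_stats: dict = field(default_factory=dict)


def monthly_max_composite(cube: RasterCube, season: SeasonSpec) -> RasterCube:
    """Per-pixel maximum of valid observations in each of the 8 slot months.

    Maximum-value compositing suppresses residual cloud contamination, which
    biases VI values low.  Pixels with no valid observation in a month stay
    invalid in that slot.
    """
    slots = season.slots
    obs_months = [(t.year, t.month) for t in cube.timestamps]
    if not any(m in slots for m in obs_months):
        raise ValueError("cube timestamps fall entirely outside the season span")
    vals = cube.values_array()
    ok = cube.valid_array()
    out_vals = np.zeros((8,) + cube.spec.shape)
    out_ok = np.zeros((8,) + cube.spec.shape, bool)
    for k, slot in enumerate(slots):
        idx = [i for i, m in enumerate(obs_months) if m == slot]
        if not idx:
            continue
        v = np.where(ok[idx], vals[idx], -np.inf)
        any_ok = ok[idx].any(axis=0)
        out_vals[k] = np.where(any_ok, v.max(axis=0), 0.0)
        out_ok[k] = any_ok
    return RasterCube.from_arrays(cube.spec, season.slot_dates, out_vals, out_ok)


def temporal_interpolate(cube: RasterCube) -> RasterCube:
    """Fill per-pixel gaps along the time axis.

    Interior gaps are linearly interpolated in slot index between the nearest
    valid neighbors; leading/trailing gaps take the nearest valid value.
    Pixels with zero valid slots remain invalid throughout (the caller is
    expected to report them).  Originally valid values are unchanged.
    """
    if len(cube) == 0:
        raise ValueError("empty cube")
    vals = cube.values_array()
    ok = cube.valid_array()
    T = vals.shape[0]
    flat_v = vals.reshape(T, -1)
    flat_ok = ok.reshape(T, -1)
    n_valid = flat_ok.sum(axis=0)
    out = flat_v.copy()
    t = np.arange(T)
    needs_fill = np.nonzero((n_valid > 0) & (n_valid < T))[0]
    for p in needs_fill:
        m = flat_ok[:, p]
        out[~m, p] = np.interp(t[~m], t[m], flat_v[m, p])
    out_ok = np.broadcast_to(n_valid > 0, flat_ok.shape).copy()
    return RasterCube.from_arrays(
        cube.spec,
        cube.timestamps,
        out.reshape(vals.shape),
        out_ok.reshape(ok.shape),
    )


def sg_smooth(cube: RasterCube, params: SGParams = SGParams()) -> RasterCube:
    """Savitzky–Golay least-squares smoothing along the time axis.

    Edges are handled by fitting the polynomial to the first/last full window
    and evaluating it at the edge positions, so any series that is globally a
    polynomial of degree <= polyorder is reproduced exactly everywhere.
    Requires a gap-free cube (run :func:`temporal_interpolate` first); pixels
    invalid at every slot pass through untouched and stay invalid.
    """
    T = len(cube)
    if T < params.window:
        raise ValueError(f"window {params.window} exceeds series length {T}")
    ok = cube.valid_array()
    per_pixel = ok.sum(axis=0)
    if np.any((per_pixel > 0) & (per_pixel < T)):
        raise ValueError("cube has partial gaps; run temporal_interpolate first")
    vals = cube.values_array()
    smoothed = savgol_filter(vals, params.window, params.polyorder, axis=0, mode="interp")
    smoothed = np.where(ok, smoothed, 0.0)
    return RasterCube.from_arrays(cube.spec, cube.timestamps, smoothed, ok)


def fuse(
    fine_monthly: RasterCube,
    coarse_monthly: RasterCube,
    sg: SGParams = SGParams(),
) -> FusionResult:
    """Fill fine-sensor monthly gaps from the coarse sensor and smooth.

    ``fine_monthly`` must be on the fine grid and ``coarse_monthly`` on the
    coarse grid, both with the same 8 slots; the coarse cube is expected to
    be already gap-filled and SG-smoothed.  The coarse cube is bilinearly
    resampled to the fine grid per slot; each output pixel takes the fine
    value where valid, else the resampled coarse value, else temporal
    interpolation.  Pixels with no valid source in any slot are excluded and
    counted in ``gap_stats``.
    """
    if fine_monthly.timestamps != coarse_monthly.timestamps:
        raise ValueError("fine and coarse cubes must share the same slots")
    spec = fine_monthly.spec
    T = len(fine_monthly)

    coarse_fine = [resample_bilinear(layer, spec) for layer in coarse_monthly.layers]
    fv = fine_monthly.values_array()
    fo = fine_monthly.valid_array()
    cv = np.stack([g.values for g in coarse_fine])
    co = np.stack([g.valid for g in coarse_fine])

    vals = np.where(fo, fv, np.where(co, cv, 0.0))
    ok = fo | co
    source = np.zeros((T,) + spec.shape, dtype=np.int8)
    source[fo] = 1
    source[~fo & co] = 2

    filled = temporal_interpolate(RasterCube.from_arrays(spec, fine_monthly.timestamps, vals, ok))
    interp_mask = filled.valid_array() & ~ok
    source[interp_mask] = 3

    smoothed = sg_smooth(filled, sg)
    n_pix = spec.n_rows * spec.n_cols
    gap_stats = {
        "n_pixels": int(n_pix),
        "fine_valid_slots": int(fo.sum()),
        "coarse_substituted_slots": int((source == 2).sum()),
        "interpolated_slots": int((source == 3).sum()),
        "dead_pixels": int(n_pix - (ok.any(axis=0)).sum()),
    }
    return FusionResult(filled=filled, smoothed=smoothed, source=source, gap_stats=gap_stats)
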