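"""Forward and inverse model of the denaturing-gel readout.

Forward: single-stranded fragments migrate a distance that is linear in
log10(length), d = a − b·log10(L); a lane is the sum of Gaussian bands, one
per fragment species, with area proportional to molecule count (the label
sits on one end, so band intensity is molar, not mass-weighted).

Inverse: local-maximum band detection with intensity-weighted centroids
("middle of the band"), then piecewise-linear interpolation of log10(length)
against a marker ladder — the same interpolation a densitometrist performs
against size standards run in the flanking lanes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .params import InvalidParameterError
from .race import FragmentSet


class RangeError(ValueError):
    """A fragment length falls outside the gel's validity range."""


class ExtrapolationError(ValueError):
    """A band migrated outside the marker span; no silent extrapolation."""


@dataclass(frozen=True)
class GelParams:
    """Migration constants for one gel.

    ``a_mm`` is the migration offset (distance of a hypothetical 1-nt
    fragment), ``b_mm`` the slope per decade of length, ``sigma_mm`` the
    Gaussian band point-spread.  Defaults place the whole 100–5000 nt
    validity range at positive migration distances.
    """

    a_mm: float = 120.0
    b_mm: float = 30.0
    sigma_mm: float = 0.8
    min_length_nt: int = 100
    max_length_nt: int = 5000

    def __post_init__(self) -> None:
        if not self.b_mm > 0:
            raise InvalidParameterError("b_mm must be > 0")
        if not self.sigma_mm > 0:
            raise InvalidParameterError("sigma_mm must be > 0")
        if not 0 < self.min_length_nt < self.max_length_nt:
            raise InvalidParameterError("bad length validity range")


Marker = Tuple[float, float]  # (length_nt, distance_mm)


def migration_distance(length_nt: float, gel: GelParams) -> float:
    """Migration distance d = a − b·log10(length), strictly decreasing in
    length.  Lengths outside the gel's validity range are rejected."""
    if not gel.min_length_nt <= length_nt <= gel.max_length_nt:
        raise RangeError(
            f"length {length_nt} nt outside gel validity "
            f"[{gel.min_length_nt}, {gel.max_length_nt}]"
        )
    return gel.a_mm - gel.b_mm * math.log10(length_nt)


def make_marker_ladder(
    lengths_nt: Sequence[float], gel: GelParams
) -> List[Marker]:
    """Render a marker ladder on a gel: (length, migration distance) pairs,
    sorted by decreasing length (increasing distance)."""
    return [
        (float(L), migration_distance(L, gel))
        for L in sorted(lengths_nt, reverse=True)
    ]


def interpolate_length(distance_mm: float, markers: Sequence[Marker]) -> float:
    """Estimate fragment length from migration distance by piecewise-linear
    interpolation in (distance, log10 length) space.

    Exact at marker points.  Distances outside the marker span raise
    :class:`ExtrapolationError`.
    """
    if len(markers) < 2:
        raise InvalidParameterError("need at least two markers")
    pts = sorted(markers, key=lambda m: m[1])  # ascending distance
    dists = np.array([m[1] for m in pts])
    logl = np.array([math.log10(m[0]) for m in pts])
    if np.any(np.diff(dists) <= 0):
        raise InvalidParameterError("marker distances must be distinct")
    if not dists[0] <= distance_mm <= dists[-1]:
        raise ExtrapolationError(
            f"distance {distance_mm:.2f} mm outside marker span "
            f"[{dists[0]:.2f}, {dists[-1]:.2f}]"
        )
    return float(10.0 ** np.interp(distance_mm, dists, logl))


@dataclass(frozen=True)
class GelLane:
    """One rendered densitometry profile plus its marker ladder."""

    distance_mm: np.ndarray
    intensity: np.ndarray
    markers: Tuple[Marker, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.distance_mm.shape != self.intensity.shape:
            raise InvalidParameterError("profile grids must match")
        if np.any(self.intensity < 0):
            raise InvalidParameterError("intensities must be >= 0")


def render_lane(
    frags: FragmentSet,
    gel: GelParams,
    markers: Sequence[Marker],
    grid_step_mm: float = 0.05,
    band_jitter_mm: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    metadata: Optional[dict] = None,
) -> GelLane:
    """Render a fragment population as a densitometry profile.

    Each fragment species contributes a Gaussian band centered at its
    migration distance with area proportional to its count; the full-length
    (uncut) strand is rendered the same way.  Species outside the gel's
    length-validity range are not rendered (they run off the gel), exactly
    as on a physical gel.  ``band_jitter_mm`` adds a Gaussian measurement
    offset per species (requires ``rng``).
    """
    grid = np.arange(0.0, gel.a_mm + grid_step_mm, grid_step_mm)
    profile = np.zeros_like(grid)
    species = list(frags.fragments)
    if frags.full_length_count > 0:
        species.append((frags.substrate.length_nt, frags.full_length_count))
    if band_jitter_mm > 0 and rng is None:
        raise InvalidParameterError("band_jitter_mm > 0 requires an rng")
    for length, count in species:
        if not gel.min_length_nt <= length <= gel.max_length_nt:
            continue
        center = migration_distance(length, gel)
        if band_jitter_mm > 0:
            center += float(rng.normal(0.0, band_jitter_mm))
        profile += (
            count
            / (gel.sigma_mm * math.sqrt(2 * math.pi))
            * np.exp(-0.5 * ((grid - center) / gel.sigma_mm) ** 2)
        )
    meta = {
        "substrate": frags.substrate.name,
        "substrate_length_nt": frags.substrate.length_nt,
        "chi_status": frags.substrate.chi_status,
        "inhibitor_uM": frags.inhibitor_uM,
        "n_molecules": frags.n_molecules,
    }
    if metadata:
        meta.update(metadata)
    return GelLane(
        distance_mm=grid,
        intensity=profile,
        markers=tuple(sorted(markers, key=lambda m: -m[0])),
        metadata=meta,
    )


@dataclass(frozen=True)
class Band:
    """One detected band: centroid position, integrated intensity, width."""

    distance_mm: float
    intensity: float
    width_mm: float


def detect_bands(lane: GelLane, min_rel_intensity: float = 0.05) -> List[Band]:
    """Detect bands as local maxima above ``min_rel_intensity`` × the lane
    maximum.

    The reported position is the intensity-weighted centroid within the
    peak's window (the "middle of the band"), the window running between
    the valleys separating it from neighbouring peaks.  Bands closer than
    about one point-spread merge into a single maximum and are reported as
    one band.  An empty or flat lane yields an empty list, not an error.
    """
    y = lane.intensity
    x = lane.distance_mm
    if y.size == 0 or float(y.max()) <= 0.0:
        return []
    height = min_rel_intensity * float(y.max())
    peaks, _ = find_peaks(y, height=height)
    if peaks.size == 0:
        return []
    step = float(x[1] - x[0]) if x.size > 1 else 1.0
    floor = 1e-4 * float(y.max())
    bands: List[Band] = []
    for k, p in enumerate(peaks):
        # window: from the valley (or floor crossing) on each side
        lo = peaks[k - 1] if k > 0 else 0
        hi = peaks[k + 1] if k + 1 < len(peaks) else y.size - 1
        left = p
        while left > lo and y[left - 1] > floor and y[left - 1] <= y[left]:
            left -= 1
        right = p
        while right < hi and y[right + 1] > floor and y[right + 1] <= y[right]:
            right += 1
        w = slice(left, right + 1)
        area = float(np.sum(y[w]) * step)
        centroid = float(np.sum(x[w] * y[w]) / np.sum(y[w]))
        # FWHM within the window
        half = y[p] / 2.0
        above = np.where(y[w] >= half)[0]
        width = float((above[-1] - above[0] + 1) * step) if above.size else step
        bands.append(Band(distance_mm=centroid, intensity=area, width_mm=width))
    return sorted(bands, key=lambda b: b.distance_mm)
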