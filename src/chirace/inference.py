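"""Analysis stage: band-length estimation, product-vs-substrate fits, and
dose-response fitting.

The race model predicts a labeled end-stop product of length
S·(1 − x/y) − advance, so across substrates the product length is linear in
substrate length with slope 1 − x/y and a (negative) intercept whose
magnitude is the swing advance.  One OLS fit per inhibitor concentration
recovers both; the dose-response IC50 comes from a four-parameter logistic
fit to the solubilization assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .gel import Band, ExtrapolationError, GelLane, detect_bands, interpolate_length
from .params import InvalidParameterError


class FitError(RuntimeError):
    """A regression or curve fit could not be performed."""


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise InvalidParameterError("n_points must be >= 2")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise InvalidParameterError("r_squared must be in [0, 1]")


@dataclass(frozen=True)
class RecoveredParams:
    """Race-model parameters implied by one product-vs-substrate fit."""

    ratio: float  # x/y = 1 - slope
    advance_nt: float  # −intercept, clamped at 0
    tau_ms: float  # advance / v_B
    intercept_clamped: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.ratio <= 1:
            raise InvalidParameterError("ratio must be in (0, 1]")
        if self.advance_nt < 0:
            raise InvalidParameterError("advance_nt must be >= 0")


@dataclass(frozen=True)
class DoseResponseFit:
    ic50_uM: float
    hill: float
    top: float
    bottom: float
    se_ic50: float

    def __post_init__(self) -> None:
        if not self.ic50_uM > 0:
            raise InvalidParameterError("ic50_uM must be > 0")
        if not self.top > self.bottom:
            raise InvalidParameterError("top must exceed bottom")


@dataclass(frozen=True)
class BandLength:
    """One detected band converted to length.  ``length_nt`` is None when
    the band migrated outside the marker span (flagged, never dropped)."""

    length_nt: Optional[float]
    intensity: float
    distance_mm: float
    is_full_length: bool = False
    in_marker_span: bool = True


def estimate_band_lengths(
    lane: GelLane,
    min_rel_intensity: float = 0.05,
    full_length_tol: float = 0.02,
) -> List[BandLength]:
    """Detect bands in a lane and interpolate each against the markers.

    The full-length (uncut-strand) band is identified as any band within
    ``full_length_tol`` (relative) of the substrate length recorded in the
    lane metadata and flagged rather than dropped.  Bands outside the
    marker span are returned with ``length_nt=None`` and
    ``in_marker_span=False``.
    """
    sub_len = lane.metadata.get("substrate_length_nt")
    out: List[BandLength] = []
    for band in detect_bands(lane, min_rel_intensity=min_rel_intensity):
        try:
            length = interpolate_length(band.distance_mm, lane.markers)
        except ExtrapolationError:
            out.append(
                BandLength(
                    length_nt=None,
                    intensity=band.intensity,
                    distance_mm=band.distance_mm,
                    in_marker_span=False,
                )
            )
            continue
        is_full = (
            sub_len is not None
            and abs(length - sub_len) <= full_length_tol * sub_len
        )
        out.append(
            BandLength(
                length_nt=length,
                intensity=band.intensity,
                distance_mm=band.distance_mm,
                is_full_length=is_full,
            )
        )
    return out


def product_band(
    lane: GelLane, min_rel_intensity: float = 0.05
) -> Optional[BandLength]:
    """The most intense sub-full-length, in-span band of a lane (the cut
    product), or None if the lane shows only the full-length strand."""
    candidates = [
        b
        for b in estimate_band_lengths(lane, min_rel_intensity=min_rel_intensity)
        if b.length_nt is not None and not b.is_full_length
    ]
    if not candidates:
        return None
    return max(candidates, key=lambda b: b.intensity)


def fit_product_vs_substrate(
    points: Sequence[Tuple[float, float]]
) -> LinearFit:
    """Ordinary least squares of labeled product length on substrate length.

    Classical standard errors; with exactly two points the line is exact
    and the SEs are undefined (returned as NaN)."""
    if len(points) < 2 or len({p[0] for p in points}) < 2:
        raise FitError("need >= 2 points with distinct substrate lengths")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if len(points) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        return LinearFit(
            slope=float(slope),
            intercept=float(intercept),
            se_slope=math.nan,
            se_intercept=math.nan,
            n_points=2,
            r_squared=1.0,
        )
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        se_slope=float(res.stderr),
        se_intercept=float(res.intercept_stderr),
        n_points=len(points),
        r_squared=min(float(res.rvalue**2), 1.0),
    )


def recover_ratio_and_delay(
    fit: LinearFit, v_b_nt_per_ms: float = 1.0
) -> RecoveredParams:
    """Invert a product-vs-substrate fit into race-model parameters:
    ratio x/y = 1 − slope, advance = −intercept, swing time = advance/v_B.

    A positive intercept (unphysical: the nuclease cannot cut behind the
    slow motor) clamps the advance to 0 with a flag."""
    if not 0 < fit.slope < 1:
        raise FitError(f"slope {fit.slope:.4g} outside (0, 1)")
    if not v_b_nt_per_ms > 0:
        raise InvalidParameterError("v_b_nt_per_ms must be > 0")
    clamped = fit.intercept > 0
    advance = 0.0 if clamped else -fit.intercept
    return RecoveredParams(
        ratio=1.0 - fit.slope,
        advance_nt=advance,
        tau_ms=advance / v_b_nt_per_ms,
        intercept_clamped=clamped,
    )


def _logistic4(I, top, bottom, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (I / ic50) ** hill)


def fit_dose_response(
    points: Sequence[Tuple[float, float]],
    proportional_error: bool = True,
) -> DoseResponseFit:
    """Four-parameter logistic fit of activity fraction vs inhibitor
    concentration by nonlinear least squares.

    Initial guesses: top/bottom from the data extremes, Hill 1, IC50 at the
    concentration whose mean activity is nearest half-maximal.  Requires at
    least four distinct concentrations including one near zero, so the top
    plateau is anchored.

    Radioactive-solubilization replicates scatter in proportion to their
    mean (constant CV), so by default the residuals are iteratively
    reweighted by the fitted response (sigma ∝ model, three reweighting
    passes); set ``proportional_error=False`` for an unweighted fit."""
    conc = np.asarray([p[0] for p in points], dtype=float)
    act = np.asarray([p[1] for p in points], dtype=float)
    levels = np.unique(conc)
    if levels.size < 4:
        raise FitError("need >= 4 distinct concentrations")
    if levels.min() > 0.05 * levels.max():
        raise FitError("need a near-zero concentration to anchor the top")
    top0 = float(act.max())
    bottom0 = float(act.min())
    half = (top0 + bottom0) / 2.0
    pos = levels[levels > 0]
    means = np.array([act[conc == c].mean() for c in pos])
    ic50_0 = float(pos[np.argmin(np.abs(means - half))])
    p0 = (top0, bottom0, max(ic50_0, 1e-3), 1.0)
    bounds = (
        [0.0, -0.5, 1e-6, 0.2],
        [2.0 * max(top0, 1.0), max(top0, 1.0), 1e6, 8.0],
    )
    try:
        popt, pcov = optimize.curve_fit(
            _logistic4, conc, act, p0=p0, bounds=bounds, maxfev=20000
        )
        if proportional_error:
            for _ in range(3):
                mu = _logistic4(conc, *popt)
                sigma = np.maximum(np.abs(mu), 0.02 * float(np.max(np.abs(mu))))
                popt, pcov = optimize.curve_fit(
                    _logistic4,
                    conc,
                    act,
                    p0=popt,
                    sigma=sigma,
                    bounds=bounds,
                    maxfev=20000,
                )
    except (RuntimeError, ValueError) as exc:
        raise FitError(
            f"dose-response fit failed to converge (p0={p0}): {exc}"
        ) from exc
    top, bottom, ic50, hill = (float(v) for v in popt)
    with np.errstate(invalid="ignore"):
        se_ic50 = float(np.sqrt(np.abs(pcov[2, 2])))
    return DoseResponseFit(
        ic50_uM=ic50, hill=hill, top=top, bottom=bottom, se_ic50=se_ic50
    )


def analyze_cutting_lanes(
    lanes: Iterable[GelLane],
    chi_status: Optional[str] = "chi0",
    v_b_nt_per_ms: float = 1.0,
) -> dict:
    """Per-concentration product-vs-substrate fits over a set of lanes.

    Groups lanes by inhibitor concentration (optionally filtering to one
    Chi status; the Chi-less lanes isolate the end-stop product), extracts
    the cut-product band of each lane, fits product length vs substrate
    length, and inverts each fit into (ratio, advance, swing time).
    Concentrations without at least two substrate lengths bearing a product
    band (e.g. 0 μM) are skipped.
    """
    by_conc: dict = {}
    for lane in lanes:
        if chi_status is not None and lane.metadata.get("chi_status") != chi_status:
            continue
        band = product_band(lane)
        if band is None:
            continue
        key = float(lane.metadata["inhibitor_uM"])
        by_conc.setdefault(key, []).append(
            (float(lane.metadata["substrate_length_nt"]), band.length_nt)
        )
    results: dict = {}
    for conc in sorted(by_conc):
        pts = by_conc[conc]
        if len({p[0] for p in pts}) < 2:
            continue
        fit = fit_product_vs_substrate(pts)
        rec = recover_ratio_and_delay(fit, v_b_nt_per_ms=v_b_nt_per_ms)
        results[conc] = {"fit": fit, "recovered": rec, "points": pts}
    return results
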