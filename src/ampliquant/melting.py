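"""Melting-curve analysis.

Pipeline per reaction: smooth the raw (temperature, fluorescence) series with
a simplified supersmoother (local-linear fits, span selected by leave-one-out
cross-validation from a small ladder); normalize away the temperature-dependent but
dissociation-independent fluorescence loss (bilinear, exponential, or
combined); differentiate; call peaks on the negative first derivative with
height and width cut-offs; validate the peak position against the expected
product Tm; partition the normalized fluorescence loss among peaks; and,
when a saturating dye was used, rescale Cq/N0 by the correct-product
fluorescence fraction to remove artifact bias.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .amplification import AmplificationAnalysis
from .data import MeltCurve, RunData
from .errors import (
    InsufficientDataError,
    NormalizationError,
    QuantificationError,
    UndefinedEfficiencyError,
    ValidationError,
)

log = logging.getLogger(__name__)

FLAG_NO_EXPECTED_PEAK = "no_expected_peak"
FLAG_MULTIPLE_PRODUCTS = "multiple_products"
FLAG_NO_PEAKS = "no_peaks"


@dataclass
class MeltConfig:
    """Tunables of the melting-curve analysis.

    ``min_peak_height_frac`` and ``max_peak_width`` are the peak-quality
    cut-offs: a candidate is kept when its delta height reaches the given
    fraction of the sum of all candidate delta heights and its
    inflection-point width does not exceed ``max_peak_width`` degC.  Peaks
    within ``tm_tolerance`` degC of the expected product Tm count as the
    intended product.
    """

    normalization: str = "combined"  # bilinear | exponential | combined
    tm_tolerance: float = 1.0
    min_peak_height_frac: float = 0.05
    max_peak_width: float = 5.0
    dye_saturating: bool = False
    apply_correction: bool = True
    anchor_frac: float = 0.10
    smoother_spans: tuple[float, ...] = (0.005, 0.05, 0.2, 0.5)

    def validate(self) -> None:
        if not self.tm_tolerance > 0:
            raise ValidationError("tm_tolerance must be > 0")
        if not 0 < self.min_peak_height_frac < 1:
            raise ValidationError("min_peak_height_frac must be in (0, 1)")
        if not self.max_peak_width > 0:
            raise ValidationError("max_peak_width must be > 0")
        if self.normalization not in ("bilinear", "exponential", "combined"):
            raise ValidationError(
                f"unknown normalization {self.normalization!r}")


@dataclass
class MeltPeak:
    """One called melting peak.

    ``delta_height`` is the -dF/dT value at the apex minus the average -dF/dT
    at the two inflection points; ``width`` the temperature range between the
    inflection points; ``fluorescence`` the normalized fluorescence loss
    across the peak and ``fraction`` its share of the total loss over all
    retained peaks.
    """

    tm: float
    delta_height: float
    width: float
    fluorescence: float | None = None
    fraction: float | None = None
    is_expected: bool = False
    apex_index: int = 0
    left_index: int = 0
    right_index: int = 0
    # integration bounds for the fluorescence loss (inflection indices,
    # clipped at the -dF/dT valley between overlapping neighbours)
    fl_left_index: int = 0
    fl_right_index: int = 0


@dataclass
class MeltResult:
    well: str
    sample_id: str = ""
    target_id: str = ""
    peaks: list[MeltPeak] = field(default_factory=list)
    correction_factor: float | None = None
    corrected_cq: float | None = None
    corrected_n0: float | None = None
    flags: set[str] = field(default_factory=set)
    messages: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# smoothing


def _local_linear(x: np.ndarray, y: np.ndarray, half: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Local-linear fit with a symmetric window of ``2*half + 1`` points
    (clipped at the series ends).  Returns (fitted values, absolute
    leave-one-out residuals)."""
    n = x.size
    fit = np.empty(n)
    loo = np.empty(n)
    for i in range(n):
        a = max(0, i - half)
        b = min(n, i + half + 1)
        xs = x[a:b]
        ys = y[a:b]
        m = xs.size
        xm = xs.mean()
        sxx = float(np.sum((xs - xm) ** 2))
        slope = float(np.sum((xs - xm) * (ys - ys.mean())) / sxx)
        val = ys.mean() + slope * (x[i] - xm)
        fit[i] = val
        lev = 1.0 / m + (x[i] - xm) ** 2 / sxx
        lev = min(lev, 1.0 - 1e-9)
        loo[i] = abs(y[i] - val) / (1.0 - lev)
    return fit, loo


def smooth_melt(temperatures: np.ndarray, fluorescence: np.ndarray,
                config: MeltConfig | None = None) -> np.ndarray:
    """Simplified supersmoother.

    Local-linear fits are computed for a small ladder of spans and the span
    with the smallest mean leave-one-out residual wins (with a mild
    preference for larger spans among near-ties).  On smooth input the
    smallest span is selected, so noiseless curves pass through essentially
    unchanged and peak positions are not displaced.
    """
    cfg = config or MeltConfig()
    t = np.asarray(temperatures, float)
    y = np.asarray(fluorescence, float)
    n = t.size
    if n < 20:
        raise InsufficientDataError(f"need >= 20 melt points, got {n}")
    halves = sorted({max(1, int(round(frac * n / 2))) for frac in cfg.smoother_spans})
    fits = []
    means = []
    for h in halves:
        fit, loo = _local_linear(t, y, h)
        fits.append(fit)
        means.append(float(loo.mean()))
    best = min(means)
    # bass preference: the largest span whose cross-validated residual is
    # within 15% of the best stabilizes the derivative without displacing
    # peaks (on noiseless data the smallest span always wins outright)
    idx = max(i for i, m in enumerate(means) if m <= 1.15 * best)
    return fits[idx]


# ---------------------------------------------------------------------------
# normalization


def _anchor_masks(t: np.ndarray, frac: float) -> tuple[np.ndarray, np.ndarray]:
    span = t[-1] - t[0]
    return t <= t[0] + frac * span, t >= t[-1] - frac * span


def _trend(t: np.ndarray, f: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t[mask], f[mask], 1)
    return float(slope), float(intercept)


def _bilinear(t: np.ndarray, f: np.ndarray, frac: float) -> np.ndarray:
    low, high = _anchor_masks(t, frac)
    s_up, i_up = _trend(t, f, low)  # pre-melt (high-fluorescence) trend
    s_lo, i_lo = _trend(t, f, high)  # post-melt trend
    upper = i_up + s_up * t
    lower = i_lo + s_lo * t
    denom = upper - lower
    if np.any(denom <= 0.0):
        raise NormalizationError(
            "upper trend does not exceed lower trend over the whole range")
    return (f - lower) / denom


def _exponential_divide(t: np.ndarray, f: np.ndarray, frac: float) -> np.ndarray:
    """Divide out an exponential background whose slopes match the observed
    melting-curve slopes at the start and end anchor temperatures.  When the
    anchor slopes do not describe a decaying exponential (flat or linear
    background), the series is returned unchanged."""
    low, high = _anchor_masks(t, frac)
    s1, _ = _trend(t, f, low)
    s2, _ = _trend(t, f, high)
    t1 = float(t[low].mean())
    t2 = float(t[high].mean())
    if s1 >= -1e-12 or s2 >= -1e-12:
        return f.copy()
    ratio = s2 / s1
    if ratio <= 0.0 or abs(math.log(ratio)) < 1e-9:
        return f.copy()
    k = math.log(ratio) / (t2 - t1)
    a = s1 / (k * math.exp(k * t1))
    if a <= 0.0:
        return f.copy()
    b = a * np.exp(k * t)
    # keep the pre-melt level: rescale so the background is 1 at the start
    b = b / b[0]
    return f / b


def normalize_melt(temperatures: np.ndarray, smoothed: np.ndarray,
                   method: str = "combined",
                   anchor_frac: float = 0.10) -> np.ndarray:
    """Remove the dissociation-independent fluorescence decrease.

    ``bilinear`` fits straight trend lines through the lowest and highest
    ``anchor_frac`` of the temperature range and expresses the curve as the
    height above the lower trend relative to the trend separation;
    ``exponential`` divides out an exponential background anchored on the
    start/end slopes; ``combined`` runs the bilinear step after the
    exponential one.  The result is approximately 1 before and 0 after the
    melt transitions.
    """
    t = np.asarray(temperatures, float)
    f = np.asarray(smoothed, float)
    if method == "bilinear":
        return _bilinear(t, f, anchor_frac)
    if method == "exponential":
        g = _exponential_divide(t, f, anchor_frac)
        low, high = _anchor_masks(t, anchor_frac)
        g_hi = float(g[low].mean())
        g_lo = float(g[high].mean())
        if g_hi <= g_lo:
            raise NormalizationError("degenerate anchors after exponential step")
        return (g - g_lo) / (g_hi - g_lo)
    if method == "combined":
        g = _exponential_divide(t, f, anchor_frac)
        return _bilinear(t, g, anchor_frac)
    raise ValidationError(f"unknown normalization method {method!r}")


def derivatives(temperatures: np.ndarray, normalized: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """(-dF/dT, d2F/dT2) by central differences (one-sided at the ends)."""
    t = np.asarray(temperatures, float)
    f = np.asarray(normalized, float)
    if t.size < 5:
        raise InsufficientDataError("need >= 5 points for derivatives")
    d1 = np.gradient(f, t)
    d2 = np.gradient(d1, t)
    return -d1, d2


# ---------------------------------------------------------------------------
# peak calling


def _refine_apex(t: np.ndarray, g: np.ndarray, i: int) -> float:
    """Parabolic sub-grid refinement of a discrete maximum position."""
    if i <= 0 or i >= t.size - 1:
        return float(t[i])
    y0, y1, y2 = g[i - 1], g[i], g[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0.0:
        return float(t[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    return float(t[i] + delta * (t[i + 1] - t[i]))


def _nearest_extremum(d2: np.ndarray, start: int, direction: int) -> int | None:
    """Index of the nearest local extremum of the second derivative on one
    side of a peak apex."""
    n = d2.size
    j = start + direction
    while 1 <= j <= n - 2:
        left = d2[j] - d2[j - 1]
        right = d2[j + 1] - d2[j]
        if left * right < 0.0:
            return j
        j += direction
    return None


def _nearest_valley(g: np.ndarray, start: int, direction: int) -> int:
    """Fallback bound: nearest local minimum of -dF/dT (or the series end)."""
    n = g.size
    j = start + direction
    while 1 <= j <= n - 2:
        if g[j] <= g[j - 1] and g[j] <= g[j + 1]:
            return j
        j += direction
    return 0 if direction < 0 else n - 1


def call_melt_peaks(temperatures: np.ndarray, first_deriv: np.ndarray,
                    second_deriv: np.ndarray,
                    config: MeltConfig | None = None) -> list[MeltPeak]:
    """Call melting peaks from the derivative series.

    Candidates are the local maxima of -dF/dT.  Each candidate's inflection
    points are the nearest flanking extrema of the second derivative (falling
    back to the -dF/dT valley on a side without one).  Candidates are
    retained when their delta height reaches ``min_peak_height_frac`` of the
    summed candidate delta heights and their width does not exceed
    ``max_peak_width``.  Fluorescence integration bounds of overlapping
    neighbours are split at the -dF/dT valley between the apexes.

    The derivative series is conditioned with the same simplified
    supersmoother before candidate detection; differencing amplifies any
    residual measurement noise and would otherwise fragment real peaks into
    grid-scale wiggles.  On noiseless input this is a no-op.
    """
    cfg = config or MeltConfig()
    t = np.asarray(temperatures, float)
    g = np.asarray(first_deriv, float)
    n = t.size
    if n >= 20:
        g = smooth_melt(t, g, cfg)
        d2 = -np.gradient(g, t)
    else:
        d2 = np.asarray(second_deriv, float)
    candidates: list[MeltPeak] = []
    for i in range(1, n - 1):
        if not (g[i] > g[i - 1] and g[i] >= g[i + 1] and g[i] > 0.0):
            continue
        li = _nearest_extremum(d2, i, -1)
        if li is None:
            li = _nearest_valley(g, i, -1)
        ri = _nearest_extremum(d2, i, +1)
        if ri is None:
            ri = _nearest_valley(g, i, +1)
        if not li < i < ri:
            continue
        delta_height = float(g[i] - 0.5 * (g[li] + g[ri]))
        if delta_height <= 0.0:
            continue
        candidates.append(MeltPeak(
            tm=_refine_apex(t, g, i),
            delta_height=delta_height,
            width=float(t[ri] - t[li]),
            apex_index=i, left_index=li, right_index=ri,
            fl_left_index=li, fl_right_index=ri,
        ))
    if not candidates:
        return []
    total = sum(p.delta_height for p in candidates)
    retained = [p for p in candidates
                if p.delta_height >= cfg.min_peak_height_frac * total
                and p.width <= cfg.max_peak_width]
    retained.sort(key=lambda p: p.tm)
    # split overlapping integration regions at the valley between apexes
    for a, b in zip(retained, retained[1:]):
        seg = g[a.apex_index : b.apex_index + 1]
        boundary = a.apex_index + int(np.argmin(seg))
        if a.fl_right_index > boundary:
            a.fl_right_index = boundary
        if b.fl_left_index < boundary:
            b.fl_left_index = boundary
    return retained


def match_expected_tm(peaks: list[MeltPeak], expected_tm: float | None,
                      tol: float = 1.0) -> tuple[list[MeltPeak], set[str]]:
    """Mark the peak representing the intended product and collect flags.

    A peak is the intended product when its Tm lies within ``tol`` degC of
    the expected temperature; with several peaks inside the window only the
    closest counts.  Flags: ``no_peaks``, ``multiple_products`` (more than
    one retained peak) and ``no_expected_peak``.
    """
    flags: set[str] = set()
    if not peaks:
        flags.add(FLAG_NO_PEAKS)
        return peaks, flags
    if len(peaks) > 1:
        flags.add(FLAG_MULTIPLE_PRODUCTS)
    if expected_tm is None:
        return peaks, flags
    inside = [p for p in peaks if abs(p.tm - expected_tm) <= tol]
    for p in peaks:
        p.is_expected = False
    if not inside:
        flags.add(FLAG_NO_EXPECTED_PEAK)
    else:
        closest = min(inside, key=lambda p: abs(p.tm - expected_tm))
        closest.is_expected = True
    return peaks, flags


def peak_fluorescence_fractions(temperatures: np.ndarray,
                                normalized: np.ndarray,
                                peaks: list[MeltPeak]) -> list[MeltPeak]:
    """Fluorescence loss per peak and its share of the total.

    The loss is the drop of the normalized curve between the peak's
    integration bounds; fractions over all retained peaks sum to one.
    """
    f = np.asarray(normalized, float)
    if not peaks:
        raise QuantificationError("no peaks to quantify")
    total = 0.0
    for p in peaks:
        p.fluorescence = float(f[p.fl_left_index] - f[p.fl_right_index])
        total += p.fluorescence
    if total <= 0.0:
        raise QuantificationError("zero total peak fluorescence")
    for p in peaks:
        p.fraction = p.fluorescence / total
    return peaks


@dataclass
class QuantCorrection:
    corrected_cq: float | None
    corrected_n0: float | None
    applied: bool
    flag: str | None = None


def correct_quantification(cq: float, n0: float, fraction: float,
                           e_tar: float, dye_saturating: bool
                           ) -> QuantCorrection:
    """Remove artifact bias from Cq/N0 using the correct-peak fraction.

    corrected_n0 = fraction * n0 and corrected_cq = cq - log(fraction)/
    log(e_tar), which preserves corrected_n0 = Nq / e_tar**corrected_cq.
    Only valid with a saturating DNA-binding dye; otherwise the correction is
    reported as not applicable.
    """
    if not dye_saturating:
        return QuantCorrection(None, None, False,
                               flag="correction requires a saturating dye")
    if fraction <= 0.0:
        return QuantCorrection(None, None, False,
                               flag="zero correct-product fluorescence")
    if fraction > 1.0:
        raise ValidationError(f"fraction {fraction} must be in (0, 1]")
    if not e_tar > 1.0:
        raise UndefinedEfficiencyError(f"e_tar={e_tar} must be > 1")
    corrected_n0 = fraction * n0
    corrected_cq = cq - math.log(fraction) / math.log(e_tar)
    return QuantCorrection(corrected_cq, corrected_n0, True)


def analyze_melting(run: RunData,
                    amp_results: AmplificationAnalysis | None = None,
                    config: MeltConfig | None = None) -> dict[str, MeltResult]:
    """Full melting-curve analysis of a run.

    Per reaction with melting data: smooth, normalize, differentiate, call
    peaks, validate against the expected Tm of the reaction's target, and
    quantify peak fluorescence fractions.  When amplification results are
    supplied, the dye is saturating and exactly one expected peak was found,
    the Cq/N0 of the reaction are corrected by the correct-peak fraction
    (disable via ``config.apply_correction``).  Reactions without melting
    data are skipped with a log entry.
    """
    cfg = config or MeltConfig()
    cfg.validate()
    out: dict[str, MeltResult] = {}
    for rec in sorted(run.reactions, key=lambda r: r.well):
        if not rec.mdp:
            log.info("well %s: no melting data, skipped", rec.well)
            continue
        mc = MeltCurve.from_record(rec)
        res = MeltResult(rec.well, rec.sample_id, rec.target_id)
        try:
            sm = smooth_melt(mc.temperatures, mc.fluorescence, cfg)
            norm = normalize_melt(mc.temperatures, sm, cfg.normalization,
                                  cfg.anchor_frac)
            g, d2 = derivatives(mc.temperatures, norm)
            peaks = call_melt_peaks(mc.temperatures, g, d2, cfg)
        except (InsufficientDataError, NormalizationError) as exc:
            res.flags.add(FLAG_NO_PEAKS)
            res.messages.append(f"warning: {exc}")
            out[rec.well] = res
            continue
        expected = run.targets[rec.target_id].expected_tm
        peaks, flags = match_expected_tm(peaks, expected, cfg.tm_tolerance)
        res.flags |= flags
        if peaks:
            try:
                peak_fluorescence_fractions(mc.temperatures, norm, peaks)
            except QuantificationError as exc:
                res.messages.append(f"warning: {exc}")
        res.peaks = peaks
        expected_peaks = [p for p in peaks if p.is_expected]
        if (cfg.apply_correction and amp_results is not None
                and len(expected_peaks) == 1
                and expected_peaks[0].fraction is not None):
            p = expected_peaks[0]
            rr = amp_results.reactions.get(rec.well)
            assay = amp_results.assays.get(rec.target_id)
            dye_sat = (cfg.dye_saturating
                       or run.targets[rec.target_id].dye_saturating)
            if (rr is not None and assay is not None
                    and rr.cq is not None and rr.n0 is not None
                    and assay.e_tar > 1.0):
                corr = correct_quantification(rr.cq, rr.n0, p.fraction,
                                              assay.e_tar, dye_sat)
                if corr.applied:
                    res.correction_factor = p.fraction
                    res.corrected_cq = corr.corrected_cq
                    res.corrected_n0 = corr.corrected_n0
                elif corr.flag:
                    res.messages.append(f"note: {corr.flag}")
        out[rec.well] = res
    return out
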