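"""Amplification-curve analysis.

Per reaction: baseline estimation by bisection on the equality of the two
half-slopes of the log-linear exponential phase, identification of the
exponential phase (start of the continuous rise up to the second derivative
maximum, SDM), and a log-linear efficiency fit.  Per assay (all reactions
sharing a target): a window of linearity (W-o-L), a fluorescence band on the
log axis, is shifted downward to minimize the coefficient of variation of the
individual efficiencies, with optional skewness-directed Grubbs (or fixed
band) outlier exclusion iterated to a fixed point.  Per run: one common
quantification threshold Nq inside the exponential phase of all reactions;
each reaction's Cq is called on an ideal curve through the centre of its
exponential phase using the assay mean efficiency, and the target quantity is

    N0 = Nq / E_tar ** Cq

in threshold-fluorescence units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import AmplificationCurve, RunData
from .errors import (
    AnalysisError,
    AssayError,
    InsufficientDataError,
    NoAmplificationError,
    UndefinedEfficiencyError,
    ValidationError,
    WindowInvalidError,
)

log = logging.getLogger(__name__)

AMPLIFIED = "amplified"
NOT_AMPLIFIED = "not_amplified"
NO_PLATEAU = "no_plateau"

# flags attached to ReactionResult
FLAG_NO_AMPLIFICATION = "no_amplification"
FLAG_NO_PLATEAU = "no_plateau"
FLAG_BASELINE_ERROR = "baseline_error"
FLAG_EFFICIENCY_OUTLIER = "efficiency_outlier"
FLAG_CONTROL_ERROR = "control_error"
FLAG_EXCLUDED = "excluded"


@dataclass
class AnalysisConfig:
    """Tunables of the amplification analysis.

    slope_diff_tol
        Convergence criterion of the baseline bisection: the absolute
        difference between the log10 slopes of the two exponential-phase
        halves (per cycle).  At efficiency 1.8 a slope difference of 1e-4
        corresponds to an efficiency difference of about 4e-4.
    min_window_cycles
        Minimum number of consecutive cycles for any efficiency fit.
    exclude_no_plateau
        Exclude reactions that never reach a plateau from the W-o-L setting.
    outlier_mode
        'grubbs' (skewness-directed iterative Grubbs test), 'fixed_band'
        (median +/- fixed_band_halfwidth) or 'none'.
    """

    slope_diff_tol: float = 1e-4
    min_window_cycles: int = 3
    exclude_no_plateau: bool = True
    outlier_mode: str = "grubbs"
    fixed_band_halfwidth: float = 0.05
    grubbs_alpha: float = 0.05
    # detection heuristics (exposed; see docs/methods.md)
    no_amp_rise_factor: float = 7.0
    plateau_slope_ratio: float = 0.25
    # W-o-L band: fixed width on the log10-fluorescence axis, stepped
    # downward.  Four doublings, so the band spans >= 4 cycles even at the
    # theoretical maximum efficiency of 2.
    wol_band_width: float = math.log10(16.0)
    wol_band_step_frac: float = 0.1
    # candidate W-o-L cycles are kept at least this many log10 units below
    # each reaction's SDM fluorescence: at the SDM the reaction is already
    # deep in the transition phase, so fitting right up to it would bias the
    # efficiency downward
    wol_sdm_margin: float = math.log10(4.0)
    # efficiency spreads below this are treated as degenerate by the
    # outlier tests (no exclusion)
    outlier_min_sd: float = 1e-3
    baseline_max_iter: int = 100
    outlier_iter_cap: int = 10

    def validate(self) -> None:
        if not self.slope_diff_tol > 0:
            raise ValidationError("slope_diff_tol must be > 0")
        if self.min_window_cycles < 3:
            raise ValidationError("min_window_cycles must be >= 3")
        if not 0 < self.grubbs_alpha < 1:
            raise ValidationError("grubbs_alpha must be in (0, 1)")
        if self.outlier_mode not in ("none", "fixed_band", "grubbs"):
            raise ValidationError(f"unknown outlier_mode {self.outlier_mode!r}")


@dataclass
class BaselineFit:
    baseline: float
    status: str  # 'ok' | 'baseline_error'
    corrected: np.ndarray


@dataclass
class ExponentialPhase:
    start_cycle: int
    sdm_cycle: int
    centre_cycle: float
    centre_fluor: float
    lower_fluor: float  # corrected fluorescence at the phase start
    upper_fluor: float  # corrected fluorescence at the SDM


@dataclass
class ReactionResult:
    well: str
    sample_id: str
    target_id: str
    sample_type: str
    status: str
    baseline: BaselineFit | None = None
    phase: ExponentialPhase | None = None
    indiv_efficiency: float | None = None
    cq: float | None = None
    n0: float | None = None
    flags: set[str] = field(default_factory=set)
    messages: list[str] = field(default_factory=list)


@dataclass
class AssayResult:
    target_id: str
    window: tuple[float, float]  # (upper_fluor, lower_fluor) of the W-o-L
    efficiencies: dict[str, float]
    included: dict[str, bool]
    e_tar: float
    cv: float
    flags: set[str] = field(default_factory=set)


@dataclass
class RunThreshold:
    nq: float


@dataclass
class AmplificationAnalysis:
    """Bundle returned by :func:`analyze_amplification`."""

    reactions: dict[str, ReactionResult]
    assays: dict[str, AssayResult]
    threshold: RunThreshold
    config: AnalysisConfig


# ---------------------------------------------------------------------------
# per-reaction primitives


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares y on x; returns (slope, intercept, r_squared)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_tot = float(np.sum((y - ym) ** 2))
    if ss_tot == 0.0:
        return slope, intercept, 1.0
    resid = y - (intercept + slope * x)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return slope, intercept, r2


def _smooth3(y: np.ndarray) -> np.ndarray:
    s = np.convolve(y, np.ones(3) / 3.0, mode="same")
    s[0] = (y[0] + y[1]) / 2.0
    s[-1] = (y[-1] + y[-2]) / 2.0
    return s


def _sdm_index(f: np.ndarray) -> int:
    """Index of the second derivative maximum (central second difference of a
    3-point-smoothed series; ties broken to the earlier cycle).  The second
    difference is invariant to a constant baseline shift, so raw or corrected
    fluorescence give the same answer."""
    s = _smooth3(np.asarray(f, float))
    d2 = s[2:] - 2.0 * s[1:-1] + s[:-2]
    return int(np.argmax(d2)) + 1


def _phase_start_index(corr: np.ndarray, sdm_i: int) -> int:
    """First index of the maximal strictly-increasing, strictly-positive run
    of corrected fluorescence ending at the SDM."""
    i = sdm_i
    while i > 0 and corr[i - 1] > 0.0 and corr[i] > corr[i - 1]:
        i -= 1
    return i


def detect_amplification(curve: AmplificationCurve,
                         config: AnalysisConfig | None = None) -> str:
    """Classify a raw curve as amplified / not_amplified / no_plateau.

    A reaction is not amplified when its total rise above the early-cycle
    level stays below a noise-scaled multiple; it has no plateau when the
    final cycles still rise steeply relative to the maximum per-cycle slope.
    """
    cfg = config or AnalysisConfig()
    f = np.asarray(curve.fluorescence, float)
    if f.size < 10:
        raise InsufficientDataError(
            f"well {curve.well!r}: need >= 10 cycles, got {f.size}"
        )
    early = f[:6]
    noise = float(np.std(np.diff(early)))
    scale = max(float(np.max(np.abs(f))), 1.0)
    rise = float(np.max(f) - np.median(early))
    if rise < cfg.no_amp_rise_factor * noise + 1e-9 * scale:
        return NOT_AMPLIFIED
    d = np.diff(f)
    if float(np.mean(d[-5:])) > cfg.plateau_slope_ratio * float(np.max(d)):
        return NO_PLATEAU
    return AMPLIFIED


def _half_slopes(f: np.ndarray, sdm_i: int,
                 baseline: float) -> tuple[float, float] | None:
    """Slopes of log10(fluor - baseline) vs cycle for the lower and upper
    halves (by cycle) of the exponential phase, re-detected for this baseline
    candidate.  Odd counts give the middle cycle to the lower half.  Returns
    None when the candidate leaves too few positive points."""
    corr = f - baseline
    if corr[sdm_i] <= 0.0:
        return None
    s = _phase_start_index(corr, sdm_i)
    idx = np.arange(s, sdm_i + 1)
    if idx.size < 4:
        return None
    lo_n = (idx.size + 1) // 2
    lo, up = idx[:lo_n], idx[lo_n:]
    slope_lo, _, _ = _ols(lo, np.log10(corr[lo]))
    slope_up, _, _ = _ols(up, np.log10(corr[up]))
    return slope_lo, slope_up


def estimate_baseline(curve: AmplificationCurve,
                      config: AnalysisConfig | None = None) -> BaselineFit:
    """Estimate the amplification-independent baseline of one reaction.

    The candidate baseline starts too high (99% of the minimum fluorescence
    over the candidate exponential region) and is lowered step-wise until the
    upper half-slope of the log-linear exponential phase becomes steeper than
    the lower half-slope; the candidate is then raised one step, the step is
    halved, and the search iterates until the two slopes differ by less than
    ``slope_diff_tol``.  Ground-phase cycles are never part of the fit.
    """
    cfg = config or AnalysisConfig()
    f = np.asarray(curve.fluorescence, float)
    if f.size < 10:
        raise InsufficientDataError(
            f"well {curve.well!r}: need >= 10 cycles, got {f.size}"
        )
    sdm_i = _sdm_index(f)
    # candidate exponential region at zero baseline
    s0 = _phase_start_index(f - min(0.0, float(f.min())), sdm_i)
    region_min = float(f[s0 : sdm_i + 1].min()) if sdm_i >= s0 else float(f.min())
    b0 = 0.99 * region_min
    span = float(f.max() - f.min())
    step = max(abs(b0) * 0.25, span * 1e-3, 1e-12)
    b = b0
    status = "baseline_error"
    for _ in range(cfg.baseline_max_iter):
        hs = _half_slopes(f, sdm_i, b)
        if hs is None:
            b -= step
            continue
        slope_lo, slope_up = hs
        if (abs(slope_up - slope_lo) < cfg.slope_diff_tol
                and slope_lo > 0.0 and slope_up > 0.0):
            status = "ok"
            break
        if slope_up > slope_lo:  # baseline has become too low
            b += step
            step *= 0.5
        else:
            b -= step
    return BaselineFit(baseline=float(b), status=status, corrected=f - b)


def find_exponential_phase(corrected: np.ndarray,
                           cycles: np.ndarray,
                           config: AnalysisConfig | None = None,
                           no_plateau: bool = False) -> ExponentialPhase:
    """Locate the exponential phase of a baseline-corrected curve.

    The phase runs from the first cycle of the continuous fluorescence rise to
    the SDM (or to the last cycle when the reaction never leaves the
    exponential phase).  The phase centre is the point (mean cycle, geometric
    mean fluorescence), which lies on the log-linear fit through the phase.
    """
    cfg = config or AnalysisConfig()
    corr = np.asarray(corrected, float)
    cycles = np.asarray(cycles, int)
    sdm_i = (corr.size - 1) if no_plateau else _sdm_index(corr)
    if corr[sdm_i] <= 0.0:
        raise NoAmplificationError("no positive fluorescence at the phase end")
    s = _phase_start_index(corr, sdm_i)
    if sdm_i - s + 1 < cfg.min_window_cycles:
        raise NoAmplificationError(
            f"exponential run of {sdm_i - s + 1} cycles is shorter than "
            f"min_window_cycles={cfg.min_window_cycles}"
        )
    seg = slice(s, sdm_i + 1)
    logf = np.log10(corr[seg])
    slope, intercept, _ = _ols(cycles[seg], logf)
    if slope <= 0.0:
        raise NoAmplificationError("non-increasing exponential phase")
    centre_fluor = float(10.0 ** logf.mean())
    centre_cycle = (math.log10(centre_fluor) - intercept) / slope
    return ExponentialPhase(
        start_cycle=int(cycles[s]),
        sdm_cycle=int(cycles[sdm_i]),
        centre_cycle=float(centre_cycle),
        centre_fluor=centre_fluor,
        lower_fluor=float(corr[s]),
        upper_fluor=float(corr[sdm_i]),
    )


def fit_log_linear(corrected: np.ndarray,
                   cycles: np.ndarray,
                   window: tuple[int, int],
                   config: AnalysisConfig | None = None
                   ) -> tuple[float, float, float]:
    """OLS of log10(corrected fluorescence) on cycle over a cycle window.

    Returns (slope, intercept, efficiency) with efficiency = 10**slope.
    """
    cfg = config or AnalysisConfig()
    corr = np.asarray(corrected, float)
    cycles = np.asarray(cycles, int)
    lo, hi = window
    mask = (cycles >= lo) & (cycles <= hi)
    if int(mask.sum()) < cfg.min_window_cycles:
        raise WindowInvalidError(
            f"window {window} spans {int(mask.sum())} cycles; "
            f"need >= {cfg.min_window_cycles}"
        )
    vals = corr[mask]
    if np.any(vals <= 0.0):
        raise WindowInvalidError(f"window {window} contains non-positive fluorescence")
    slope, intercept, _ = _ols(cycles[mask], np.log10(vals))
    return float(slope), float(intercept), float(10.0**slope)


# ---------------------------------------------------------------------------
# per-assay window of linearity


@dataclass
class PreparedReaction:
    """A baseline-corrected reaction ready for assay-level fitting."""

    well: str
    cycles: np.ndarray
    corrected: np.ndarray
    phase: ExponentialPhase


def _band_fit(r: PreparedReaction, log_lo: float, log_hi: float,
              min_cycles: int, sdm_margin: float = 0.0
              ) -> tuple[float, float] | None:
    """Efficiency and R^2 fitted from the phase cycles whose corrected
    fluorescence falls inside the log10 band [log_lo, log_hi], staying
    ``sdm_margin`` log10 units below the reaction's SDM fluorescence."""
    mask = (r.cycles >= r.phase.start_cycle) & (r.cycles <= r.phase.sdm_cycle)
    cyc = r.cycles[mask]
    corr = r.corrected[mask]
    pos = corr > 0.0
    cyc, corr = cyc[pos], corr[pos]
    logf = np.log10(corr)
    cap = math.log10(r.phase.upper_fluor) - sdm_margin
    sel = (logf >= log_lo) & (logf <= min(log_hi, cap))
    if int(sel.sum()) < min_cycles:
        return None
    slope, _, r2 = _ols(cyc[sel], logf[sel])
    return float(10.0**slope), float(r2)


def optimize_window_of_linearity(assay_curves: dict[str, PreparedReaction],
                                 config: AnalysisConfig | None = None,
                                 target_id: str = "") -> AssayResult:
    """Place the W-o-L band to minimize the CV of individual efficiencies.

    The band has a fixed width on the log10-fluorescence axis and is stepped
    downward from the highest phase fluorescence; at each position every
    reaction with at least ``min_window_cycles`` cycles inside the band gets a
    log-linear efficiency.  The position minimizing the CV wins; among
    positions whose CV ties to machine precision the one whose worst per-
    reaction R^2 is best wins (so that noiseless replicate assays settle in
    the truly log-linear part of the phase), with remaining ties broken to the
    higher band.
    """
    cfg = config or AnalysisConfig()
    wells = sorted(assay_curves)
    if not wells:
        raise AssayError(f"assay {target_id!r}: no valid reactions")
    width = cfg.wol_band_width
    if len(wells) == 1:
        r = assay_curves[wells[0]]
        hi = math.log10(r.phase.upper_fluor) - cfg.wol_sdm_margin
        fit = _band_fit(r, hi - width, hi, cfg.min_window_cycles,
                        cfg.wol_sdm_margin)
        if fit is None:
            mask = ((r.cycles >= r.phase.start_cycle)
                    & (r.cycles <= r.phase.sdm_cycle)
                    & (r.corrected > 0.0))
            slope, _, _ = _ols(r.cycles[mask], np.log10(r.corrected[mask]))
            e = float(10.0**slope)
        else:
            e = fit[0]
        return AssayResult(
            target_id=target_id,
            window=(10.0**hi, 10.0 ** (hi - width)),
            efficiencies={wells[0]: e},
            included={wells[0]: True},
            e_tar=e,
            cv=float("nan"),
            flags={"single_reaction"},
        )

    tops = [math.log10(assay_curves[w].phase.upper_fluor) - cfg.wol_sdm_margin
            for w in wells]
    bottoms = [math.log10(assay_curves[w].phase.lower_fluor) for w in wells]
    top = max(tops)
    bottom = min(bottoms)
    step = width * cfg.wol_band_step_frac
    best = None  # (cv, -r2_min, band_rank, hi, effs)
    rank = 0
    hi = top
    while hi >= bottom:
        effs: dict[str, float] = {}
        r2s: list[float] = []
        for w in wells:
            fit = _band_fit(assay_curves[w], hi - width, hi,
                            cfg.min_window_cycles, cfg.wol_sdm_margin)
            if fit is not None:
                effs[w] = fit[0]
                r2s.append(fit[1])
        if len(effs) >= 2:
            vals = np.array(list(effs.values()))
            cv = float(np.std(vals, ddof=1) / np.mean(vals))
            r2_min = min(r2s)
            cand = (cv, r2_min, rank, hi, effs)
            if best is None:
                best = cand
            else:
                b_cv, b_r2, b_rank, _, _ = best[:5]
                if cv < b_cv - 1e-12:
                    best = cand
                elif abs(cv - b_cv) <= 1e-12 and r2_min > b_r2 + 1e-12:
                    best = cand
                # equal cv and r2: keep earlier (higher) band
        hi -= step
        rank += 1
    if best is None:
        raise AssayError(
            f"assay {target_id!r}: no band position yields >= "
            f"{cfg.min_window_cycles} cycles for >= 2 reactions"
        )
    _, _, _, hi, effs = best
    vals = np.array(list(effs.values()))
    return AssayResult(
        target_id=target_id,
        window=(10.0**hi, 10.0 ** (hi - width)),
        efficiencies=dict(effs),
        included={w: True for w in effs},
        e_tar=float(np.mean(vals)),
        cv=float(np.std(vals, ddof=1) / np.mean(vals)),
    )


def _grubbs_critical(n: int, alpha: float) -> float:
    """One-sided Grubbs critical value from the t-distribution formula."""
    t = stats.t.ppf(1.0 - alpha / n, n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def detect_efficiency_outliers(efficiencies, mode: str = "grubbs",
                               alpha: float = 0.05,
                               halfwidth: float = 0.05,
                               skew_tol: float = 1e-3,
                               min_sd: float = 1e-3) -> np.ndarray:
    """Inclusion mask over a list of individual PCR efficiencies.

    ``grubbs``: compute the sample skewness (adjusted Fisher-Pearson); test
    the extreme value on the skewed side with a one-sided Grubbs test at
    ``alpha`` (two-sided on the larger deviation when |skewness| is below
    ``skew_tol``); exclude and repeat until no rejection.  ``fixed_band``:
    exclude efficiencies outside median +/- ``halfwidth``.  ``none``: include
    everything.  Grubbs is undefined below n = 3: all included.  A standard
    deviation below ``min_sd`` (efficiency units) is treated as degenerate:
    such spreads are far below any meaningful efficiency difference and
    nothing is excluded.
    """
    vals = np.asarray(list(efficiencies), float)
    mask = np.ones(vals.size, dtype=bool)
    if mode == "none" or vals.size == 0:
        return mask
    if mode == "fixed_band":
        med = float(np.median(vals))
        mask = np.abs(vals - med) <= halfwidth
        return mask
    if mode != "grubbs":
        raise ValidationError(f"unknown outlier_mode {mode!r}")
    while int(mask.sum()) >= 3:
        active = np.flatnonzero(mask)
        x = vals[active]
        n = x.size
        sd = float(np.std(x, ddof=1))
        mean = float(np.mean(x))
        if sd <= min_sd:
            break
        skew = float(stats.skew(x, bias=False))
        if skew > skew_tol:
            j = int(np.argmax(x))
            a = alpha
        elif skew < -skew_tol:
            j = int(np.argmin(x))
            a = alpha
        else:
            j = int(np.argmax(np.abs(x - mean)))
            a = alpha / 2.0  # two-sided on the larger deviation
        g = abs(x[j] - mean) / sd
        if g > _grubbs_critical(n, a):
            mask[active[j]] = False
        else:
            break
    return mask


def iterate_assay(assay_curves: dict[str, PreparedReaction],
                  config: AnalysisConfig | None = None,
                  target_id: str = "") -> AssayResult:
    """Alternate W-o-L optimization and outlier detection to a fixed point.

    The window is optimized on the included reactions only; efficiencies are
    then re-fitted for every reaction in the final band so that excluded
    reactions are still reported (and later receive Cq/N0 from the assay
    efficiency).  An oscillating inclusion mask stops at the iteration cap and
    keeps the mask with the most inclusions.
    """
    cfg = config or AnalysisConfig()
    wells = sorted(assay_curves)
    included = set(wells)
    seen: list[frozenset] = []
    result = None
    all_effs: dict[str, float] = {}
    for _ in range(max(1, cfg.outlier_iter_cap)):
        subset = {w: assay_curves[w] for w in sorted(included)}
        result = optimize_window_of_linearity(subset, cfg, target_id)
        if "single_reaction" in result.flags:
            return result
        log_hi = math.log10(result.window[0])
        log_lo = math.log10(result.window[1])
        all_effs = {}
        for w in wells:
            fit = _band_fit(assay_curves[w], log_lo, log_hi,
                            cfg.min_window_cycles, cfg.wol_sdm_margin)
            if fit is not None:
                all_effs[w] = fit[0]
        order = sorted(all_effs)
        mask = detect_efficiency_outliers(
            [all_effs[w] for w in order], cfg.outlier_mode,
            cfg.grubbs_alpha, cfg.fixed_band_halfwidth,
            min_sd=cfg.outlier_min_sd)
        new_included = {w for w, m in zip(order, mask) if m}
        if new_included == included:
            break
        fs = frozenset(new_included)
        if fs in seen:
            log.warning("assay %s: oscillating outlier mask; keeping the "
                        "largest inclusion set", target_id)
            cycle_start = seen.index(fs)
            options = seen[cycle_start:] + [fs]
            included = set(max(options, key=len))
            subset = {w: assay_curves[w] for w in sorted(included)}
            result = optimize_window_of_linearity(subset, cfg, target_id)
            break
        seen.append(frozenset(included))
        included = new_included
    assert result is not None
    inc_vals = np.array([all_effs[w] for w in sorted(included) if w in all_effs])
    if inc_vals.size == 0:
        inc_vals = np.array(list(result.efficiencies.values()))
        included = set(result.efficiencies)
    e_tar = float(np.mean(inc_vals))
    cv = (float(np.std(inc_vals, ddof=1) / np.mean(inc_vals))
          if inc_vals.size > 1 else float("nan"))
    return AssayResult(
        target_id=target_id,
        window=result.window,
        efficiencies=dict(all_effs) if all_effs else dict(result.efficiencies),
        included={w: (w in included) for w in (all_effs or result.efficiencies)},
        e_tar=e_tar,
        cv=cv,
        flags=set(result.flags),
    )


# ---------------------------------------------------------------------------
# run-level threshold, Cq and N0


def set_common_threshold(phases: dict[str, ExponentialPhase]
                         ) -> tuple[RunThreshold, set[str]]:
    """One quantification threshold for the whole run.

    Nq is the geometric mean of the bounds of the intersection of all valid
    reactions' exponential-phase fluorescence ranges.  When the intersection
    is empty, Nq falls back to the geometric mean of all phase centres and
    every reaction whose phase excludes Nq is returned as flagged.
    """
    if not phases:
        raise AnalysisError("no valid reactions for threshold setting")
    lo = max(p.lower_fluor for p in phases.values())
    hi = min(p.upper_fluor for p in phases.values())
    flagged: set[str] = set()
    if 0.0 < lo < hi:
        nq = math.sqrt(lo * hi)
    else:
        centres = np.array([p.centre_fluor for p in phases.values()])
        nq = float(np.exp(np.mean(np.log(centres))))
        flagged = {w for w, p in phases.items()
                   if not (p.lower_fluor <= nq <= p.upper_fluor)}
    return RunThreshold(nq=float(nq)), flagged


def call_cq(phase: ExponentialPhase, e_tar: float, nq: float) -> float:
    """Fractional cycle at which the ideal curve through the phase centre,
    with the assay mean efficiency, reaches the common threshold."""
    if not e_tar > 1.0:
        raise UndefinedEfficiencyError(f"e_tar={e_tar} must be > 1")
    if not nq > 0.0:
        raise AnalysisError(f"nq={nq} must be > 0")
    return phase.centre_cycle + math.log(nq / phase.centre_fluor) / math.log(e_tar)


def compute_n0(nq: float, e_tar: float, cq: float) -> float:
    """Efficiency-corrected target quantity N0 = Nq / E_tar**Cq."""
    if not nq > 0.0:
        raise AnalysisError(f"nq={nq} must be > 0")
    if not e_tar > 1.0:
        raise UndefinedEfficiencyError(f"e_tar={e_tar} must be > 1")
    if cq < 0.0:
        raise AnalysisError(f"cq={cq} must be >= 0")
    return nq / e_tar**cq


def classify_reaction(status: str, flags: set[str], sample_type: str
                      ) -> tuple[set[str], list[str], bool]:
    """Sample-type aware error/warning classification of one reaction.

    Returns (flags, messages, suppress_n0).  Amplification in a negative
    control and absence of amplification in a positive control are errors
    (``control_error``); errors too severe for automatic quantification
    suppress N0 while leaving Cq and the individual efficiency reported so
    the user can compute N0 = Nq / E**Cq manually.
    """
    fl = set(flags)
    msgs: list[str] = []
    suppress = False
    amplified = FLAG_NO_AMPLIFICATION not in fl and status != NOT_AMPLIFIED
    if FLAG_BASELINE_ERROR in fl:
        msgs.append("error: baseline estimation failed")
        suppress = True
    if sample_type == "negative_control" and amplified:
        fl.add(FLAG_CONTROL_ERROR)
        msgs.append("error: amplification in negative control")
        suppress = True
    if sample_type == "positive_control" and not amplified:
        fl.add(FLAG_CONTROL_ERROR)
        msgs.append("error: no amplification in positive control")
    if sample_type == "unknown" and not amplified:
        msgs.append("warning: no amplification")
    if FLAG_NO_PLATEAU in fl:
        msgs.append("warning: no plateau")
    if FLAG_EFFICIENCY_OUTLIER in fl:
        msgs.append("warning: deviating PCR efficiency")
    return fl, msgs, suppress


def analyze_amplification(run: RunData,
                          config: AnalysisConfig | None = None
                          ) -> AmplificationAnalysis:
    """Full amplification-curve analysis of one run.

    Orchestrates detection, baseline estimation and phase finding per
    reaction, the W-o-L / outlier iteration per assay, the common threshold
    per run, and Cq/N0 calling plus classification per reaction.  Results are
    deterministic for a fixed input and configuration.
    """
    cfg = config or AnalysisConfig()
    cfg.validate()
    records = sorted((r for r in run.reactions if r.adp), key=lambda r: r.well)
    if not records:
        raise AnalysisError("run has no reactions with amplification data")

    results: dict[str, ReactionResult] = {}
    prepared: dict[str, PreparedReaction] = {}
    for rec in records:
        stype = run.samples[rec.sample_id].sample_type
        curve = AmplificationCurve.from_record(rec)
        rr = ReactionResult(rec.well, rec.sample_id, rec.target_id, stype,
                            status=NOT_AMPLIFIED)
        try:
            rr.status = detect_amplification(curve, cfg)
        except InsufficientDataError as exc:
            rr.flags.add(FLAG_NO_AMPLIFICATION)
            rr.messages.append(f"warning: {exc}")
            results[rec.well] = rr
            continue
        if rr.status == NOT_AMPLIFIED:
            rr.flags.add(FLAG_NO_AMPLIFICATION)
        else:
            rr.baseline = estimate_baseline(curve, cfg)
            if rr.baseline.status != "ok":
                rr.flags.add(FLAG_BASELINE_ERROR)
            else:
                try:
                    rr.phase = find_exponential_phase(
                        rr.baseline.corrected, curve.cycles, cfg,
                        no_plateau=(rr.status == NO_PLATEAU))
                except NoAmplificationError as exc:
                    rr.flags.add(FLAG_NO_AMPLIFICATION)
                    rr.messages.append(f"warning: {exc}")
            if rr.status == NO_PLATEAU:
                rr.flags.add(FLAG_NO_PLATEAU)
                if cfg.exclude_no_plateau:
                    rr.flags.add(FLAG_EXCLUDED)
        if rr.phase is not None:
            prepared[rec.well] = PreparedReaction(
                rec.well, curve.cycles,
                rr.baseline.corrected, rr.phase)
        results[rec.well] = rr

    # per-assay efficiency
    assays: dict[str, AssayResult] = {}
    for target in sorted({results[w].target_id for w in prepared}):
        subset = {w: prepared[w] for w in prepared
                  if results[w].target_id == target
                  and FLAG_EXCLUDED not in results[w].flags}
        excluded_wells = [w for w in prepared
                          if results[w].target_id == target and w not in subset]
        if not subset:
            continue
        try:
            assay = iterate_assay(subset, cfg, target)
        except AssayError as exc:
            log.warning("%s", exc)
            continue
        # efficiencies for excluded (no-plateau) reactions in the final band
        log_hi = math.log10(assay.window[0])
        log_lo = math.log10(assay.window[1])
        for w in excluded_wells:
            fit = _band_fit(prepared[w], log_lo, log_hi,
                            cfg.min_window_cycles, cfg.wol_sdm_margin)
            if fit is not None:
                assay.efficiencies[w] = fit[0]
                assay.included[w] = False
        for w, e in assay.efficiencies.items():
            results[w].indiv_efficiency = e
            if w in subset and not assay.included.get(w, True):
                results[w].flags.add(FLAG_EFFICIENCY_OUTLIER)
        assays[target] = assay

    phases = {w: prepared[w].phase for w in prepared}
    if not phases:
        for rr in results.values():
            if not rr.flags:
                rr.flags.add(FLAG_NO_AMPLIFICATION)
        raise AnalysisError("no analyzable reactions in the run")
    threshold, thr_flagged = set_common_threshold(phases)
    for w in thr_flagged:
        results[w].messages.append(
            "warning: common threshold outside the exponential phase")

    for w in sorted(results):
        rr = results[w]
        assay = assays.get(rr.target_id)
        if rr.phase is not None and assay is not None and assay.e_tar > 1.0:
            rr.cq = call_cq(rr.phase, assay.e_tar, threshold.nq)
            rr.n0 = compute_n0(threshold.nq, assay.e_tar, rr.cq)
        rr.flags, msgs, suppress = classify_reaction(
            rr.status, rr.flags, rr.sample_type)
        rr.messages.extend(msgs)
        if suppress:
            rr.n0 = None
    return AmplificationAnalysis(reactions=results, assays=assays,
                                 threshold=threshold, config=cfg)
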