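"""Ground-truth simulators for amplification and melting curves.

The amplification model is a logistic-limited recurrence, the minimal model
producing the four canonical phases of a qPCR curve (ground, exponential,
transition, plateau):

    N_1 = n0_true
    N_{c+1} = N_c * (1 + (E - 1) * (1 - N_c / plateau))

observed as F_c = (baseline + N_c) * (1 + eps_c) with seeded multiplicative
Gaussian noise.  The melting model is a sum of logistic dissociation
transitions over a linear temperature-dependent background:

    F(T) = intercept + slope * T + sum_i amp_i / (1 + exp((T - tm_i) / s_i))

Each simulator returns the curve plus a truth record (exact Cq at any
threshold for amplification; exact Tm values and amplitude shares for
melting), so every analysis stage can be tested without external data.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import (
    AmplificationCurve,
    MeltCurve,
    ReactionRecord,
    RunData,
    SampleInfo,
    TargetInfo,
)
from .errors import PlanError


@dataclass
class AmpSimParams:
    """Parameters of one simulated amplification reaction.

    ``n0_true`` is the signal at the first measured cycle (fluorescence
    units); the truth record also reports the cycle-0 extrapolation
    n0_true / efficiency_true, which is the quantity the analysis estimates.
    """

    n0_true: float = 1e-2
    efficiency_true: float = 1.9
    baseline_true: float = 50.0
    plateau: float = 5000.0
    n_cycles: int = 40
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 1.0 < self.efficiency_true <= 2.0:
            raise PlanError("efficiency_true must be in (1, 2]")
        if not self.plateau > self.baseline_true >= 0.0:
            raise PlanError("need plateau > baseline_true >= 0")


@dataclass
class AmpTruth:
    """Noiseless ground truth of one simulated amplification reaction."""

    n0_true: float
    n0: float  # cycle-0 extrapolation: n0_true / efficiency_true
    efficiency: float
    baseline: float
    plateau: float
    signal: np.ndarray  # noiseless N_c, c = 1..n_cycles

    def cq_at(self, threshold: float) -> float:
        """Exact fractional cycle at which the noiseless signal crosses the
        threshold (log-linear interpolation between cycles)."""
        n = self.signal
        if threshold <= n[0]:
            return 1.0
        above = np.flatnonzero(n >= threshold)
        if above.size == 0:
            raise ValueError(f"threshold {threshold} never reached")
        i = int(above[0])
        frac = ((math.log(threshold) - math.log(n[i - 1]))
                / (math.log(n[i]) - math.log(n[i - 1])))
        return float(i + frac)  # cycles are 1-based: crossing in (i, i+1]


def simulate_amplification_curve(p: AmpSimParams,
                                 rng: np.random.Generator | None = None
                                 ) -> tuple[AmplificationCurve, AmpTruth]:
    p.validate()
    if rng is None:
        rng = np.random.default_rng(p.seed)
    n = np.empty(p.n_cycles)
    n[0] = p.n0_true
    for c in range(p.n_cycles - 1):
        n[c + 1] = n[c] * (1.0 + (p.efficiency_true - 1.0) * (1.0 - n[c] / p.plateau))
    eps = rng.normal(0.0, p.noise_sd, p.n_cycles) if p.noise_sd > 0 else np.zeros(p.n_cycles)
    f = (p.baseline_true + n) * (1.0 + eps)
    cycles = np.arange(1, p.n_cycles + 1)
    curve = AmplificationCurve("", "", "", cycles, f)
    truth = AmpTruth(
        n0_true=p.n0_true,
        n0=p.n0_true / p.efficiency_true,
        efficiency=p.efficiency_true,
        baseline=p.baseline_true,
        plateau=p.plateau,
        signal=n,
    )
    return curve, truth


@dataclass
class MeltSimParams:
    """Parameters of one simulated melting curve."""

    products: list[tuple[float, float, float]] = field(default_factory=list)
    # each product: (tm degC, steepness degC, amplitude fluorescence)
    background: tuple[float, float] = (2.0, -0.01)  # (intercept, slope per degC)
    t_range: tuple[float, float, float] = (65.0, 95.0, 0.1)  # start, stop, step
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi, step = self.t_range
        if not (hi > lo and step > 0):
            raise PlanError("invalid t_range")
        for tm, s, a in self.products:
            if not a > 0:
                raise PlanError("product amplitudes must be > 0")
            if not lo <= tm <= hi:
                raise PlanError(f"tm {tm} outside t_range")
            if not s > 0:
                raise PlanError("product steepness must be > 0")


@dataclass
class MeltTruth:
    tms: list[float]
    amplitudes: list[float]
    shares: list[float]


def simulate_melt_curve(p: MeltSimParams,
                        rng: np.random.Generator | None = None
                        ) -> tuple[MeltCurve, MeltTruth]:
    p.validate()
    if rng is None:
        rng = np.random.default_rng(p.seed)
    lo, hi, step = p.t_range
    t = np.arange(lo, hi + step / 2.0, step)
    f = p.background[0] + p.background[1] * t
    for tm, s, a in p.products:
        f = f + a / (1.0 + np.exp((t - tm) / s))
    if p.noise_sd > 0:
        f = f * (1.0 + rng.normal(0.0, p.noise_sd, t.size))
    total = sum(a for _, _, a in p.products)
    truth = MeltTruth(
        tms=[tm for tm, _, _ in p.products],
        amplitudes=[a for _, _, a in p.products],
        shares=[a / total for _, _, a in p.products] if total > 0 else [],
    )
    return MeltCurve("", "", "", t, f), truth


# ---------------------------------------------------------------------------
# whole-plate generation


@dataclass
class WellPlan:
    well: str
    sample_id: str
    sample_type: str
    target_id: str
    amp: AmpSimParams | None = None
    melt: MeltSimParams | None = None


@dataclass
class PlatePlan:
    """A plate layout with per-well simulation parameters.

    Negative-control wells are simulated as baseline plus noise only (no
    exponential signal, no melt products).  ``truth_threshold`` is the
    fluorescence level at which the truth table reports the exact Cq.
    """

    run_id: str = "sim_run"
    wells: list[WellPlan] = field(default_factory=list)
    expected_tm: dict[str, float] = field(default_factory=dict)
    dye_saturating: bool = True
    truth_threshold: float | None = None

    def validate(self) -> None:
        names = [w.well for w in self.wells]
        if len(names) != len(set(names)):
            dupes = sorted({w for w in names if names.count(w) > 1})
            raise PlanError(f"duplicate wells in plan: {dupes}")


def generate_synthetic_run(plan: PlatePlan, seed: int = 0
                           ) -> tuple[RunData, pd.DataFrame]:
    """Simulate a complete plate; returns RunData plus a per-well truth table.

    Per-well random streams are spawned deterministically from ``seed`` and
    the well position, so the output is reproducible and independent of the
    order in which wells are listed.
    """
    plan.validate()
    run = RunData(run_id=plan.run_id)
    rows = []
    root = np.random.SeedSequence(seed)
    for i, wp in enumerate(sorted(plan.wells, key=lambda w: w.well)):
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(i,))
        rng = np.random.default_rng(child)
        if wp.sample_id not in run.samples:
            run.samples[wp.sample_id] = SampleInfo(wp.sample_id, wp.sample_type)
        if wp.target_id not in run.targets:
            run.targets[wp.target_id] = TargetInfo(
                wp.target_id,
                expected_tm=plan.expected_tm.get(wp.target_id),
                dye_saturating=plan.dye_saturating,
            )
        rec = ReactionRecord(wp.well, wp.sample_id, wp.target_id)
        row: dict = {"well": wp.well, "sample": wp.sample_id,
                     "sample_type": wp.sample_type, "target": wp.target_id}
        if wp.amp is not None:
            ap = wp.amp
            if wp.sample_type == "negative_control":
                ap = replace(ap, n0_true=0.0)
            if ap.n0_true > 0:
                curve, truth = simulate_amplification_curve(ap, rng)
                fluor = curve.fluorescence
                row.update(e_true=truth.efficiency, n0_true=truth.n0_true,
                           n0=truth.n0, baseline=truth.baseline)
                if plan.truth_threshold is not None:
                    try:
                        row["cq_true"] = truth.cq_at(plan.truth_threshold)
                    except ValueError:
                        row["cq_true"] = float("nan")
            else:  # flat baseline + noise
                eps = (rng.normal(0.0, ap.noise_sd, ap.n_cycles)
                       if ap.noise_sd > 0 else np.zeros(ap.n_cycles))
                fluor = ap.baseline_true * (1.0 + eps)
                row.update(e_true=float("nan"), n0_true=0.0, n0=0.0,
                           baseline=ap.baseline_true)
            rec.adp = [(c, float(v))
                       for c, v in zip(range(1, ap.n_cycles + 1), fluor)]
        if wp.melt is not None:
            mp = wp.melt
            if wp.sample_type == "negative_control":
                mp = replace(mp, products=[])
            mcurve, mtruth = simulate_melt_curve(mp, rng)
            rec.mdp = [(float(t), float(v))
                       for t, v in zip(mcurve.temperatures, mcurve.fluorescence)]
            row["tm_true"] = "|".join(repr(v) for v in mtruth.tms)
            row["share_true"] = "|".join(repr(v) for v in mtruth.shares)
        run.reactions.append(rec)
        rows.append(row)
    run.validate()
    return run, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plate plans as flat files

_PLAN_COLUMNS = ["well", "sample", "sample_type", "target", "expected_tm",
                 "efficiency", "n0", "baseline", "plateau", "n_cycles",
                 "noise_sd", "melt_products", "melt_background", "melt_range",
                 "melt_noise_sd"]


def save_plan(plan: PlatePlan, path) -> None:
    """Serialize a plate plan as a TSV (one row per well)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["#run_id", plan.run_id,
                    "dye_saturating", str(plan.dye_saturating).lower(),
                    "truth_threshold",
                    "" if plan.truth_threshold is None else repr(plan.truth_threshold)])
        w.writerow(_PLAN_COLUMNS)
        for wp in plan.wells:
            a = wp.amp
            m = wp.melt
            w.writerow([
                wp.well, wp.sample_id, wp.sample_type, wp.target_id,
                "" if plan.expected_tm.get(wp.target_id) is None
                else repr(plan.expected_tm[wp.target_id]),
                "" if a is None else repr(a.efficiency_true),
                "" if a is None else repr(a.n0_true),
                "" if a is None else repr(a.baseline_true),
                "" if a is None else repr(a.plateau),
                "" if a is None else a.n_cycles,
                "" if a is None else repr(a.noise_sd),
                "" if m is None else "|".join(
                    f"{tm}:{s}:{amp}" for tm, s, amp in m.products),
                "" if m is None else f"{m.background[0]}:{m.background[1]}",
                "" if m is None else ":".join(str(v) for v in m.t_range),
                "" if m is None else repr(m.noise_sd),
            ])


def load_plan(path) -> PlatePlan:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows or not rows[0] or rows[0][0] != "#run_id":
        raise PlanError(f"{path}: not a plate plan (missing #run_id header)")
    head = rows[0]
    plan = PlatePlan(run_id=head[1],
                     dye_saturating=head[3].lower() == "true",
                     truth_threshold=float(head[5]) if head[5] else None)
    header = rows[1]
    if header != _PLAN_COLUMNS:
        raise PlanError(f"{path}: unexpected plan columns {header}")
    for row in rows[2:]:
        if not row:
            continue
        rec = dict(zip(_PLAN_COLUMNS, row))
        amp = None
        if rec["efficiency"]:
            amp = AmpSimParams(
                n0_true=float(rec["n0"]),
                efficiency_true=float(rec["efficiency"]),
                baseline_true=float(rec["baseline"]),
                plateau=float(rec["plateau"]),
                n_cycles=int(rec["n_cycles"]),
                noise_sd=float(rec["noise_sd"]),
            )
        melt = None
        if rec["melt_range"]:
            products = []
            if rec["melt_products"]:
                for part in rec["melt_products"].split("|"):
                    tm, s, a = part.split(":")
                    products.append((float(tm), float(s), float(a)))
            bi, bs = rec["melt_background"].split(":")
            t0, t1, ts = rec["melt_range"].split(":")
            melt = MeltSimParams(products=products,
                                 background=(float(bi), float(bs)),
                                 t_range=(float(t0), float(t1), float(ts)),
                                 noise_sd=float(rec["melt_noise_sd"]))
        plan.wells.append(WellPlan(rec["well"], rec["sample"],
                                   rec["sample_type"], rec["target"],
                                   amp=amp, melt=melt))
        if rec["expected_tm"]:
            plan.expected_tm[rec["target"]] = float(rec["expected_tm"])
    plan.validate()
    return plan


def demo_plan(n_replicates: int = 4, noise_sd: float = 0.0,
              truth_threshold: float = 500.0) -> PlatePlan:
    """A small demonstration plate: four assays with efficiencies 1.7-2.0,
    starting quantities spanning six decades, one positive and two negative
    controls, single-product melting curves at assay-specific Tm values."""
    plan = PlatePlan(run_id="demo",
                     expected_tm={"T1": 82.0, "T2": 84.0, "T3": 86.0, "T4": 88.0},
                     truth_threshold=truth_threshold)
    effs = {"T1": 1.7, "T2": 1.8, "T3": 1.9, "T4": 2.0}
    n0s = [10.0 ** (-1 - 5 * i / max(1, n_replicates - 1))
           for i in range(n_replicates)]
    rows = "ABCDEFGH"
    for ti, (target, e) in enumerate(sorted(effs.items())):
        for ri in range(n_replicates):
            well = f"{rows[ti]}{ri + 1}"
            plan.wells.append(WellPlan(
                well, f"S{ri + 1}", "unknown", target,
                amp=AmpSimParams(n0_true=n0s[ri], efficiency_true=e,
                                 baseline_true=50.0, plateau=5000.0,
                                 n_cycles=45, noise_sd=noise_sd),
                melt=MeltSimParams(
                    products=[(plan.expected_tm[target], 0.8, 1.0)],
                    background=(2.0, -0.01), t_range=(65.0, 95.0, 0.1),
                    noise_sd=noise_sd),
            ))
    plan.wells.append(WellPlan(
        "E1", "PC", "positive_control", "T3",
        amp=AmpSimParams(n0_true=1e-2, efficiency_true=1.9,
                         baseline_true=50.0, plateau=5000.0,
                         n_cycles=45, noise_sd=noise_sd),
        melt=MeltSimParams(products=[(86.0, 0.8, 1.0)],
                           background=(2.0, -0.01),
                           t_range=(65.0, 95.0, 0.1), noise_sd=noise_sd)))
    for i in (1, 2):
        plan.wells.append(WellPlan(
            f"F{i}", f"NC{i}", "negative_control", "T3",
            amp=AmpSimParams(n0_true=0.0, efficiency_true=1.9,
                             baseline_true=50.0, plateau=5000.0,
                             n_cycles=45, noise_sd=max(noise_sd, 1e-4)),
            melt=MeltSimParams(products=[], background=(2.0, -0.01),
                               t_range=(65.0, 95.0, 0.1),
                               noise_sd=max(noise_sd, 1e-4))))
    return plan
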