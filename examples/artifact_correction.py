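"""Detect and correct artifact co-amplification from the melting curve.

Well D8 amplifies a mixture of 75% artifact (Tm 79 degC) and 25% correct
product (Tm 85 degC).  The amplification curve alone looks perfect; only the
melting analysis reveals the artifact.  With a saturating dye the fraction of
melt-peak fluorescence in the correct-product peak (~0.25) becomes a
correction factor: corrected N0 = fraction * N0, and Cq shifts later by
-log(fraction)/log(E) cycles.
"""

from ampliquant import (
    AmpSimParams,
    MeltSimParams,
    PlatePlan,
    WellPlan,
    analyze_amplification,
    analyze_melting,
    generate_synthetic_run,
)

plan = PlatePlan(run_id="mix", expected_tm={"T1": 85.0}, dye_saturating=True)
clean = MeltSimParams(products=[(85.0, 0.8, 1.0)], background=(2.0, -0.01))
for i, n0 in enumerate((1e-2, 1e-4), start=1):
    plan.wells.append(WellPlan(
        f"A{i}", f"S{i}", "unknown", "T1",
        amp=AmpSimParams(n0_true=n0, efficiency_true=1.9, n_cycles=45),
        melt=clean))
plan.wells.append(WellPlan(
    "D8", "mix_sample", "unknown", "T1",
    amp=AmpSimParams(n0_true=1e-3, efficiency_true=1.9, n_cycles=45),
    melt=MeltSimParams(products=[(79.0, 0.8, 0.75), (85.0, 0.8, 0.25)],
                       background=(2.0, -0.01))))

run, _ = generate_synthetic_run(plan, seed=0)
amp = analyze_amplification(run)
melt = analyze_melting(run, amp)

mr = melt["D8"]
rr = amp.reactions["D8"]
print("peaks in well D8:")
for p in mr.peaks:
    label = "correct product" if p.is_expected else "artifact"
    print(f"  Tm {p.tm:6.2f} degC  fraction {p.fraction:.3f}  ({label})")
print(f"flags: {sorted(mr.flags)}")
print(f"uncorrected: Cq = {rr.cq:.3f}, N0 = {rr.n0:.4e}")
print(f"correction factor = {mr.correction_factor:.3f}")
print(f"corrected:   Cq = {mr.corrected_cq:.3f}, N0 = {mr.corrected_n0:.4e}")
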