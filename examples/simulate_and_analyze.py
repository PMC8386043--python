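"""Simulate a small qPCR plate and run the amplification-curve analysis.

Builds the built-in demo plate (four assays with PCR efficiencies 1.7, 1.8,
1.9 and 2.0, starting quantities spanning six decades, plus controls),
analyzes it, and prints the per-assay efficiencies and a few per-reaction
quantities.  The printed e_tar values should sit within ~0.01 of the
simulated efficiencies; N0 is the efficiency-corrected starting quantity in
threshold-fluorescence units and doubles as the quantity you would feed into
expression ratios.
"""

from ampliquant import analyze_amplification, demo_plan, generate_synthetic_run

plan = demo_plan(n_replicates=4, noise_sd=0.0)
run, truth = generate_synthetic_run(plan, seed=1)
amp = analyze_amplification(run)

print(f"common quantification threshold Nq = {amp.threshold.nq:.4g}")
for target in sorted(amp.assays):
    a = amp.assays[target]
    used = sum(a.included.values())
    print(f"assay {target}: E_tar = {a.e_tar:.4f}  (CV {a.cv:.2e}, "
          f"{used}/{len(a.included)} reactions)")

print("\nwell   sample  Cq       N0          true N0")
truth = truth.set_index("well")
for well in sorted(amp.reactions):
    rr = amp.reactions[well]
    if rr.cq is None:
        print(f"{well:5s}  {rr.sample_id:6s}  -        -           "
              f"(flags: {','.join(sorted(rr.flags)) or 'none'})")
        continue
    print(f"{well:5s}  {rr.sample_id:6s}  {rr.cq:7.3f}  {rr.n0:.4e}  "
          f"{truth.loc[well, 'n0']:.4e}")
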