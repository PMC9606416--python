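"""Relative transgene copy number from qPCR amplification curves.

Simulates a 40-cycle plate (triplicates; eGFP vs the references GAPDH and
B2m plus an inter-run calibrator) encoding known copy-number ratios, calls
crossing points by the second-derivative-maximum method, and quantifies.
"""

from safeharbor import quantify
from safeharbor.simulate import SimScenario, simulate_qpcr_plate

scenario = SimScenario(seed=42, cp_noise_sd=0.1)
curves, _ = simulate_qpcr_plate(scenario)
results = quantify(curves["run1"], "eGFP", ["GAPDH", "B2m"], efficiency=2.0)

truth = dict(zip((f"S{i+1}" for i in range(5)), scenario.true_ratios))
print("sample  true   estimate   sd")
for r in sorted(results, key=lambda r: truth[r.sample]):
    print(
        f"{r.sample:6s}  {truth[r.sample]:4.1f}   "
        f"{r.relative_amount:7.3f}   {r.sd:.3f}"
    )

# Each estimate is E^(mean reference CP - target CP), normalized to the
# calibrator and pooled over triplicates x both reference genes; at 0.1
# cycle CP noise the true ratios are recovered within a few percent.
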