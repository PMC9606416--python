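"""Predict safe-harbor integration sites from histone-modification peaks.

Builds a synthetic peak scenario with 20 planted harbor regions and 60
decoys (gene-proximal, heterochromatin-overlapped, sub-minimum-width),
runs the screen, and compares the predictions with the planted truth.
"""

from safeharbor import identify_sites
from safeharbor.simulate import SimScenario, plant_harbors

scenario = SimScenario(seed=42)
data = plant_harbors(scenario)
sites = identify_sites(data.peaks, data.tss_index, scenario.harbor_params)

truth = {(iv.contig, iv.start, iv.end) for iv in data.truth}
hits = {
    (s.interval.contig, s.interval.start, s.interval.end) for s in sites
} & truth

print(f"planted harbors : {len(truth)}")
print(f"predicted sites : {len(sites)}")
print(f"exact matches   : {len(hits)}")
for s in sites[:3]:
    print(
        f"  {s.interval}  width={s.length} bp  "
        f"nearest TSS {s.nearest_tss_distance:.0f} bp"
    )

# Every predicted site is intergenic (>=5 kb from any TSS), carries both
# activating marks at both timepoints, avoids all H3K9me3, and is >=600 bp
# wide; with clean inputs the screen recovers the planted truth exactly.
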