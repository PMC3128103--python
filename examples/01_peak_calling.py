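"""Call peaks with permutation FDR on one simulated ChIP sample.

Generates a 300-promoter synthetic study, takes the Sirt6 ChIP sample at
15 min of TNF-α, biweight-centres the probe log2 ratios, scans each
promoter window for enriched intervals and attaches permutation FDRs.
Printed: number of planted binding events, number of confident peaks, and
the three strongest peaks (window coordinates: 0 = 3250 bp upstream of the
TSS).
"""

from chipdyn import (
    SampleKey,
    SimulationParams,
    call_peaks,
    estimate_fdr,
    normalize_biweight,
    simulate_chip_signals,
    simulate_truth,
    simulate_universe,
)

params = SimulationParams(n_genes=300, seed=42)
truth = simulate_truth(params, simulate_universe(params))
signals = simulate_chip_signals(truth)

sample = SampleKey("chip", "Sirt6", "WT", 15)
probes = normalize_biweight(signals[sample])
peaks = estimate_fdr(call_peaks(probes), probes, n_permutations=25, seed=1)

planted = int(truth.occupancy[("Sirt6", "WT")][15].sum())
confident = [p for p in peaks if p.fdr <= 0.1]
print(f"planted Sirt6 binding events at 15 min: {planted}")
print(f"peaks called at FDR <= 0.1:             {len(confident)}")
print("strongest peaks (gene, window span, mean log2 ratio, FDR):")
for p in sorted(confident, key=lambda p: -p.score)[:3]:
    print(f"  {p.gene_id}  [{p.start}, {p.end})  score={p.score:.2f}  fdr={p.fdr:.3f}")
print("A score of ~0.7 log2 units is the bump mass averaged over the merged")
print("probe run; FDR is the expected fraction of equally-scoring permutation")
print("artifacts among the calls.")
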