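"""Classify temporal occupancy dynamics over a TNF-α time course.

Runs the full ChIP stage (peaks, FDR, knockout-control subtraction) on a
simulated study, builds the per-gene 4-timepoint Sirt6 occupancy pattern in
wild-type cells, and tallies the dynamics classes: genes bound only before
stimulation (baseline_vacated), newly recruited genes (induced), and the
oscillatory on/off/on pattern (periodic) the time course is designed around.
"""

from chipdyn import SimulationParams, dynamics_counts, simulate_chip_signals, simulate_truth, simulate_universe
from chipdyn.config import PipelineConfig
from chipdyn.pipeline import occupancy_frame, process_chip
from chipdyn.simulate import SIRT6_TIMEPOINTS

params = SimulationParams(n_genes=800, seed=7)
annotations = simulate_universe(params)
truth = simulate_truth(params, annotations)
chip = process_chip(simulate_chip_signals(truth), annotations, PipelineConfig(seed=7))

occ = occupancy_frame(chip, "Sirt6", "WT", truth.genes, SIRT6_TIMEPOINTS)
counts = dynamics_counts(occ)
print("Sirt6 occupancy dynamics in WT (genes per class):")
print(counts.to_string())
bound_any = int((occ.sum(axis=1) > 0).sum())
print(f"\ngenes bound at >=1 timepoint: {bound_any} "
      f"({int(occ[0].sum())} already bound before TNF-α)")
print("'periodic' genes are engaged at 15 min, released at 30, re-engaged at 60 —")
print("the planted oscillation; 'baseline_vacated' genes lose Sirt6 after stimulation.")
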