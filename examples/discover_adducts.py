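"""Full adduct-discovery workflow on a synthetic mouse-brain-like raster.

Generates a 32x32 dataset with 20 planted parent/DHB-adduct pairs, matrix
clusters and background noise, then runs: blank subtraction -> all-pairs
Δmass -> registry matching -> per-pixel Pearson correlation -> r > 0.1
screen, and scores the result against the planted ground truth.
"""

from msiadducts import default_registry
from msiadducts.massdiff import build_pairs, delta_histogram
from msiadducts.pipeline import run_pipeline, score_against_truth
from msiadducts.synthesize import SyntheticSpec, generate

spec = SyntheticSpec(seed=1)
matrix, truth, blank = generate(spec)
print(f"dataset: {matrix.n_peaks} peaks x {matrix.n_pixels} pixels "
      f"({len(truth.pairs)} planted adduct pairs, {blank.n_peaks} matrix peaks)")

result = run_pipeline(matrix, blank=blank, registry=default_registry("DHB"),
                      screen="rcut", r_min=0.1)
print(f"blank subtraction removed {result.blank_report.n_removed} matrix peaks")

hist = delta_histogram(build_pairs(result.matrix.mz), binwidth=0.005)
top = hist.top(3)
print("most crowded Δmass bins (bin center / pair count):")
for _, row in top.iterrows():
    print(f"  {row['center']:9.4f} Da   {int(row['count'])} pairs")

print("\nper-adduct-type summary (fraction of total peaks):")
print(result.summary.to_string(index=False))

scores = score_against_truth(result, truth)
print(f"\nrecovery vs ground truth: sensitivity {scores['sensitivity']:.2f}, "
      f"precision {scores['precision']:.2f}")
print("A crowded bin near 136.016 Da is the DHB-H2O matrix-adduct signature;")
print("sensitivity/precision of 1.00 mean every planted pair was recovered and")
print("nothing spurious survived the spatial-correlation screen.")
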