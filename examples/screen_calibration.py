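"""How the three false-positive screens behave on planted vs background pairs.

True adducts co-localize with their parent ion, so their ion images correlate
strongly across pixels; chance mass matches between unrelated peaks do not.
This script measures all three screens (Bonferroni, Storey q-values, direct
r cutoff) on a raster with 40 planted pairs and 400 uncorrelated noise peaks.
"""

import numpy as np

from msiadducts import default_registry
from msiadducts.massdiff import build_pairs, match_adducts
from msiadducts.preprocess import ToleranceModel
from msiadducts.spatial_stats import apply_screen, correlate_pairs
from msiadducts.synthesize import SyntheticSpec, generate

spec = SyntheticSpec(width=32, height=32, n_parents=40, n_background=400,
                     n_matrix_peaks=0, seed=7)
matrix, truth, _ = generate(spec)

t = ToleranceModel(ppm=5)
matched = match_adducts(build_pairs(matrix.mz), default_registry("DHB"), t)
screened = apply_screen(correlate_pairs(matrix, matched), screen="rcut", r_min=0.3)

is_planted = np.zeros(len(screened), dtype=bool)
for _, row in truth.pairs.iterrows():
    is_planted |= (
        (np.abs(screened["parent_mz"] - row["parent_mz"]) <= t.p * row["parent_mz"])
        & (np.abs(screened["adduct_mz"] - row["adduct_mz"]) <= t.p * row["adduct_mz"])
    ).to_numpy()

planted = screened[is_planted]
background = screened[~is_planted]
print(f"{len(matched)} mass-matched pairs: {len(planted)} planted, "
      f"{len(background)} chance matches")
print(f"median r: planted {planted['r'].median():.3f}, "
      f"background {background['r'].median():.3f}")
for screen in ("bonferroni", "qvalue", "rcut"):
    col = f"passed_{screen}"
    print(f"{screen:11s} pass rate: planted {planted[col].mean():5.1%}  "
          f"background {background[col].mean():5.1%}")
print("\nHigh planted pass rates with near-zero background pass rates show the")
print("spatial screens separating true adducts from coincidental mass matches.")
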