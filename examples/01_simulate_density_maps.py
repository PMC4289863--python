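"""Simulate per-component density maps and score a model against them.

Builds the three-component toy assembly (a large helical bundle, a two-helix
ligand analog and a kinked peptide), synthesizes 4 Å-resolution maps on a
1 Å grid from the true coordinates, and shows how the cross-correlation
coefficient (CCC) separates a correct placement from a displaced one.
"""

import numpy as np

import ectofit as ef

bench = ef.make_fitting_benchmark(seed=0)

print("components:", ", ".join(bench.component_names))
print(f"combined map: dims {bench.combined_map.dims}, "
      f"spacing {bench.combined_map.spacing} Å, "
      f"resolution {bench.combined_map.resolution} Å")

ccc_truth = ef.ccc(bench.truth.select_all(), bench.combined_map)
ccc_start = ef.ccc(bench.start.select_all(), bench.combined_map)
print(f"CCC of the ground-truth model:  {ccc_truth:.4f}")
print(f"CCC of the displaced start:     {ccc_start:.4f}")
print(f"start Cα-RMSD from truth:       {bench.start_rmsd:.2f} Å")

# A CCC near 1 means the model explains the map; the displaced start scores
# far lower because its components sit partly outside their densities.

ef.write_mrc(bench.combined_map, "combined_map.mrc")
back = ef.read_mrc("combined_map.mrc")
print(f"MRC round-trip max abs error:   "
      f"{np.abs(back.values - bench.combined_map.values).max():.2e}")
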