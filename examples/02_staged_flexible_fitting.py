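"""Staged map-guided flexible fitting with known ground truth.

Runs the three-stage protocol — big component + peptide first (ligand analog
positionally restrained), then the ligand analog (peptide restrained), then
everything free — and reports the per-stage cross-correlation and the final
Cα-RMSD against the planted truth.
"""

import ectofit as ef
from ectofit.fitting import run_protocol
from ectofit.synthetic import benchmark_protocol

bench = ef.make_fitting_benchmark(seed=0)
stages, restraints = benchmark_protocol(bench)

print(f"start: Cα-RMSD {bench.start_rmsd:.2f} Å, "
      f"CCC {ef.ccc(bench.start.select_all(), bench.combined_map):.3f}")

result = run_protocol(bench.start, stages, restraints,
                      reference=bench.truth, ccc_map=bench.combined_map,
                      seed=17)

for stage in stages:
    idx = max(i for i, lab in enumerate(result.stage_labels)
              if lab == stage.label)
    print(f"after {stage.label:<18} CCC {result.ccc_series[idx]:.3f}  "
          f"Cα-RMSD {result.rmsd_series[idx]:.2f} Å")

ca = bench.truth.select_all().calpha()
final_rmsd = ef.rmsd(result.final.xyz[ca.indices], bench.truth.xyz[ca.indices])
print(f"final: Cα-RMSD {final_rmsd:.2f} Å, "
      f"CCC {ef.ccc(result.final.select_all(), bench.combined_map):.3f}")
print("(CCC rises stage over stage; a final RMSD below 1 Å means the "
      "planted conformation was recovered)")

result.to_frame().to_csv("fit_trace.tsv", sep="\t", index=False)
print("per-frame trace with stage markers written to fit_trace.tsv")
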