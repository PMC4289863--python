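"""Screen receptor conformations for zero overlap with a ligand's density.

Emulates the search for receptor states able to accommodate a ligand: 49
decoy conformations intrude into the ligand's density region; one planted
conformation stays clear.  With zero overlap tolerance only the planted
conformation may pass, and it must rank first.
"""

import numpy as np

import ectofit as ef
from ectofit.docking import screen_ensemble, screen_frame

toy = ef.make_docking_toy(seed=0)
rng = np.random.default_rng(5)
base = toy.cplx.subset(toy.cplx.annotations["receptor"])
lig_com = toy.planted_ligand_xyz.mean(axis=0)
toward = lig_com - base.xyz.mean(axis=0)
toward /= np.linalg.norm(toward)

conformations, ids = [base.copy()], ["planted"]
for k in range(49):
    decoy = base.copy()
    decoy.xyz += toward * rng.uniform(12.0, 26.0) + rng.normal(scale=1.0, size=3)
    conformations.append(decoy)
    ids.append(f"decoy{k:02d}")
for c in conformations:
    c.add_annotation("arm", np.arange(c.n_atoms))

records = screen_ensemble(conformations, toy.ligand_map, "arm",
                          overlap_tol=0.0, clash_tol=0, ids=ids)
df = screen_frame(records, overlap_tol=0.0, clash_tol=0)
print(df.head(5).to_string(index=False))
passed = [r.conformation_id for r in records if r.passed]
print(f"\npassed with zero overlap tolerance: {passed}")
print("(overlap is the fraction of heavy atoms inside the super-threshold "
      "density reserved for the ligand; 0 means the conformation can "
      "accommodate it)")
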