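# Domain boundaries and hinge-triplet convention for the insulin-receptor
# ectodomain (IR-delta-beta homodimer, subunit chains A and B).
#
# Boundaries are configuration data, not code: published hinge-angle values
# depend on the residue ranges and the (arm, vertex, arm) triplets used, so
# reproducing a particular study's numbers may require calibrating this file
# to that study's conventions.  The F2 insert segment can be excluded by
# splitting its ranges, as shown commented out below.

domains:
  - {name: L1, chain: A, ranges: [[1, 157]]}
  - {name: CR, chain: A, ranges: [[158, 310]]}
  - {name: L2, chain: A, ranges: [[311, 470]]}
  - {name: F1, chain: A, ranges: [[471, 595]]}
  - {name: F2, chain: A, ranges: [[596, 808]]}
  # F2 with the insert domain excluded:
  # - {name: F2, chain: A, ranges: [[596, 655], [756, 808]]}
  - {name: F3, chain: A, ranges: [[809, 906]]}
  - {name: L1, chain: B, ranges: [[1, 157]]}
  - {name: CR, chain: B, ranges: [[158, 310]]}
  - {name: L2, chain: B, ranges: [[311, 470]]}
  - {name: F1, chain: B, ranges: [[471, 595]]}
  - {name: F2, chain: B, ranges: [[596, 808]]}
  - {name: F3, chain: B, ranges: [[809, 906]]}

# Hinge "X-Y" is the angle at the junction domain's center of mass between
# the centers of mass of the flanking domains.
hinges:
  - {name: L1-L2, arm_a: L1, vertex: CR, arm_b: L2}
  - {name: L2-F1, arm_a: CR, vertex: L2, arm_b: F1}
  - {name: F1-F2, arm_a: L2, vertex: F1, arm_b: F2}
  - {name: F2-F3, arm_a: F1, vertex: F2, arm_b: F3}
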