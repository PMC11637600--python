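"""Where do the errors come from?  Audit every insertion individually.

Each placed leaf is compared against the edge where the reference (true)
tree would attach it, counting the edges between the two; the leaf is then
relocated to its reference position so errors do not compound.  With noisy
finite-length sequences most placements land within a couple of edges of
the right spot — the basis for correcting them locally afterwards.
"""

import numpy as np

from sparsenj import SNJConfig, SequenceDistanceOracle, simulate_dataset
from sparsenj.experiments import insertion_error_audit

for m in (500, 5000, 50_000):
    disp = []
    for seed in (0, 1, 2):
        truth, seqs = simulate_dataset(n=100, m=m, seed=seed)
        oracle = SequenceDistanceOracle(seqs, model="jc")
        disp += insertion_error_audit(truth.topology, seqs.taxa, oracle,
                                      SNJConfig(mode="enhanced", seed=seed))
    disp = np.asarray(disp)
    print(f"m={m:6d}: {np.mean(disp == 0):.0%} of insertions exact, "
          f"median displacement {np.median(disp):.0f} edges, "
          f"mean {disp.mean():.2f}")
print("Longer alignments push the displacement distribution toward zero "
      "(finite-sample consistency at work).")
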