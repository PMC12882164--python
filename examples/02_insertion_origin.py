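"""Map an inserted sequence back to its origin locus ("two-way hit").

Builds a small random reference, plants a 440 bp donor copy at 2%
divergence, and runs the seed-and-extend search. The reported identity
estimates the substitution divergence between the insertion and its source.
"""

import numpy as np

from svprio.config import PipelineConfig
from svprio.insertion import map_insertion_origin
from svprio.synth import _mutate

rng = np.random.default_rng(17)
reference = {"chr16": "".join(rng.choice(list("ACGT"), 80_000))}
donor = reference["chr16"][60_000:60_440]  # the segment an insertion copied

for divergence in (0.0, 0.02, 0.10):
    query = _mutate(donor, divergence, rng)
    hits = map_insertion_origin(query, reference, PipelineConfig())
    if hits:
        h = hits[0]
        print(f"divergence {divergence:4.0%}: origin {h.target} strand {h.strand} "
              f"identity {h.identity:.3f} over {h.aligned_length} bp")
    else:
        print(f"divergence {divergence:4.0%}: no origin at the 95% identity cutoff")

print("\nAn exact copy realigns at identity 1.000; a 2%-diverged copy near"
      "\n0.980 (still above the 95% reporting cutoff); a 10%-diverged copy"
      "\nfalls below the cutoff and is correctly not reported.")
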