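"""Counter-based random streams.

Every stochastic draw in the simulation comes from a Philox generator keyed by
(master seed, stream tag, cycle).  Uniform variates are indexed by individual
position, so two scenario runs over the same population consume identical
random numbers for each individual and event slot (common random numbers), and
any run is exactly reproducible from its seed.
"""

from __future__ import annotations

import numpy as np

# Event-slot tags.  The per-cycle disease slots are drawn in this fixed order.
TAG_POPULATION = 0
TAG_BASELINE = 1
TAG_UTILIZATION = 2
TAG_CARIES = 3
TAG_TREATMENT = 4
TAG_ABSCESS = 5
TAG_TOOTHLOSS = 6
TAG_MORTALITY = 7
TAG_RESIDUAL = 8


def stream(seed: int, tag: int, cycle: int = 0) -> np.random.Generator:
    """Return an independent generator for (seed, tag, cycle)."""
    key = np.array(
        [np.uint64(seed) & np.uint64(0xFFFFFFFFFFFFFFFF),
         (np.uint64(tag) << np.uint64(32)) | np.uint64(cycle)],
        dtype=np.uint64,
    )
    return np.random.Generator(np.random.Philox(key=key))


def uniforms(seed: int, tag: int, cycle: int, n: int) -> np.ndarray:
    """Uniform(0,1) variates for n individuals in a given (tag, cycle) slot."""
    return stream(seed, tag, cycle).random(n)


def derive_seed(master_seed: int, index: int) -> int:
    """Derive a child seed (e.g. one per PSA draw) from a master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0])
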