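"""Derivation of per-stage random streams from a single master seed.

Every random draw in the pipeline descends from the master seed through a
named stream, so a staged permutation run (50 permutations, then 200 more)
reproduces bit-for-bit the result of a single 250-permutation run.
"""

from __future__ import annotations

import numpy as np

# Stream identifiers. Values are arbitrary but frozen: changing them changes
# every downstream random draw.
STREAM_FOLDS = 1
STREAM_PERMUTATION = 2
STREAM_SUBGROUP_FOLDS = 3
STREAM_SCENARIO = 4


def stream_rng(master_seed: int, stream: int, *index: int) -> np.random.Generator:
    """Generator for stream ``stream`` (and optional sub-index) of a master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(stream), *map(int, index)]))


def permutation_for(master_seed: int, b: int, n: int) -> np.ndarray:
    """The b-th permutation of ``n`` subject indices under a master seed.

    b = 0 is always the identity, so the observed statistic is counted in its
    own permutation null. Each b > 0 has its own derived stream, which makes
    the permutation list a pure function of (master_seed, b) and lets a run be
    extended without re-drawing earlier permutations.
    """
    if b == 0:
        return np.arange(n)
    return stream_rng(master_seed, STREAM_PERMUTATION, b).permutation(n)
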