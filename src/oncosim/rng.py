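"""Named, year-keyed random streams.

Every stochastic event class (births, background deaths, incidence of each
cancer, ...) draws from its own PCG64 stream keyed by (seed, purpose, year).
Uniform variates within a stream are consumed positionally, with position ==
individual id.  Because streams are seeded independently of simulation state,
a paired counterfactual/intervention run with the same seed sees *identical*
uniforms for every event class — the common-random-numbers contract that
makes scenario differences attributable to the intervention alone.
"""
from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, purpose: str, year: int = 0) -> np.random.Generator:
    """Return a fresh generator for one (seed, purpose, year) triple."""
    if seed < 0:
        raise ValueError("seed must be non-negative")
    key = zlib.crc32(purpose.encode("utf8"))
    ss = np.random.SeedSequence(entropy=(int(seed), int(key), int(year)))
    return np.random.Generator(np.random.PCG64(ss))
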