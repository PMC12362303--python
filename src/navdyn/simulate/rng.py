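"""Named RNG substreams derived from one master seed.

Every stochastic stage draws from its own substream so that, e.g., motion can
be regenerated without disturbing the BOLD noise draws.
"""

from __future__ import annotations

import numpy as np

SUBSTREAMS: tuple[str, ...] = (
    "design",
    "truth",
    "streams",
    "motion",
    "bold_canonical",
    "bold_noise",
    "gaze",
    "behavior",
    "perm",
)


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Generator for the named substream of a master seed."""
    if name not in SUBSTREAMS:
        raise KeyError(f"unknown RNG substream: {name!r}")
    idx = SUBSTREAMS.index(name)
    seq = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(idx,))
    return np.random.default_rng(seq)
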