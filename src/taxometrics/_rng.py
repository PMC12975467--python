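"""Seed management: one master seed, independent per-stage streams.

Each pipeline stage draws from its own generator seeded by (master seed,
stage id), so enabling or disabling one stage (e.g. the CCFI profile)
never perturbs another stage's random stream.
"""

from __future__ import annotations

import numpy as np

_STAGE_IDS = {
    "methods": 11,
    "comparison_dim": 12,
    "comparison_tax": 13,
    "profile": 14,
    "simulate": 15,
    "sensitivity": 16,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    if stage not in _STAGE_IDS:
        raise KeyError(f"unknown stage {stage!r}")
    return np.random.default_rng([int(seed), _STAGE_IDS[stage]])
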