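"""Deterministic seed derivation.

Every source of randomness in the package is keyed off one master seed.
Child seeds are derived through :class:`numpy.random.SeedSequence` with a
context tuple (e.g. ``(master, subject_index)``), so independent stages get
statistically independent streams while the whole run stays a pure function
of the master seed.  Derived seeds are reduced below 2**31 so they are valid
for scikit-learn ``random_state`` arguments.
"""

from __future__ import annotations

import numpy as np


def derive_seed(master: int, *context: int) -> int:
    """Derive a child seed < 2**31 from a master seed and integer context."""
    ss = np.random.SeedSequence([int(master), *map(int, context)])
    return int(ss.generate_state(1)[0] % (2**31))


def derive_rng(master: int, *context: int) -> np.random.Generator:
    """A fresh Generator keyed on (master, *context)."""
    return np.random.default_rng(np.random.SeedSequence([int(master), *map(int, context)]))
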