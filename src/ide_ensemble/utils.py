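"""Small shared helpers: seed fan-out and exceptions."""

from __future__ import annotations

import numpy as np


class ConfigurationError(ValueError):
    """A configuration field is invalid; the message names the field."""


class ImputationError(RuntimeError):
    """Imputation cannot proceed (no complete donor, empty cohort)."""


class DegenerateDataError(RuntimeError):
    """A dataset lacks the class structure an operation requires."""


def child_seed(master: int, *keys: int) -> int:
    """Derive a reproducible child seed (< 2**31) from a master seed.

    Stage/fold/round indices are folded into a :class:`numpy.random.SeedSequence`
    entropy pool so that every pipeline stage draws from an independent stream.
    """
    ss = np.random.SeedSequence([int(master)] + [int(k) for k in keys])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
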