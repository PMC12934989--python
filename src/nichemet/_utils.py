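"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np

#: Epsilon used to keep proportions strictly inside (0, 1) before a logit
#: transform, which is undefined at the boundaries.  Shared by the subject
#: metadata reader, the concordance analysis and the evenness regression.
LOGIT_EPS = 1e-6


def clamp_unit(x, eps: float = LOGIT_EPS):
    """Clamp values (scalar or array) into [eps, 1 - eps]."""
    return np.clip(np.asarray(x, dtype=float), eps, 1.0 - eps)


def logit(x, eps: float = LOGIT_EPS):
    """Logit transform with boundary clamping."""
    p = clamp_unit(x, eps)
    return np.log(p / (1.0 - p))


def as_float_array(x, name: str = "array") -> np.ndarray:
    from .exceptions import ValidationError

    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def derive_seed(master: int, offset: int) -> int:
    """Derive a per-stage seed from the master seed by a fixed offset.

    Keeps derived seeds in the 32-bit range accepted by most RNG front-ends.
    """
    return int((int(master) * 1_000_003 + offset) % (2**31 - 1))
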