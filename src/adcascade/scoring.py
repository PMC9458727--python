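"""Leave-last-visit-out prediction-accuracy score shared by all predictors."""

from __future__ import annotations

import math

__all__ = ["prediction_accuracy"]


def prediction_accuracy(held_out: float, predicted: float) -> float:
    """PA = 100 * (1 - |held_out - predicted| / |held_out|), in percent.

    100 means an exact hit; the score is unbounded below and symmetric in
    over-/under-shoot.  A zero-valued held-out observation makes the relative
    error undefined: returns NaN so callers can skip it in summaries.
    """
    if held_out == 0:
        return math.nan
    return 100.0 * (1.0 - abs(held_out - predicted) / abs(held_out))
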