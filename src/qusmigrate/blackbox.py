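"""Black-box contract around the victim model.

The migration engine may touch the victim only through an input-output score
interface: no parameters, gradients, architecture, or training data leak
through. The interface validates patch format, mimicking a closed system that
rejects malformed inputs.
"""

from __future__ import annotations

import numpy as np

from .models import predict_scores
from .preprocess import PatchSet

__all__ = ["VictimInterface", "query"]


class VictimInterface:
    """Opaque score oracle over a trained victim model.

    By default continuous sigmoid scores are returned (the pipeline
    thresholds them itself); ``hard_labels=True`` restricts the interface to
    {0, 1} outputs for stricter threat models. ``query_count`` tracks the
    number of patches scored.
    """

    def __init__(self, model, expected_shape: tuple[int, int], hard_labels: bool = False):
        # the model is captured in a closure so the public surface exposes
        # only query(); nothing else of the victim is reachable through it
        def _score(x: np.ndarray) -> np.ndarray:
            return predict_scores(model, x)

        self._score = _score
        self.expected_shape = tuple(expected_shape)
        self.hard_labels = hard_labels
        self.query_count = 0

    def query(self, patches) -> np.ndarray:
        """Score a batch of victim-format patches (victim sampling rate,
        z-scored, expected height x width)."""
        x = patches.patches if isinstance(patches, PatchSet) else np.asarray(patches)
        if x.ndim != 3 or x.shape[1:] != self.expected_shape:
            raise ValueError(
                f"victim interface expects patches of shape {self.expected_shape}, "
                f"got {x.shape[1:] if x.ndim == 3 else x.shape}"
            )
        scores = self._score(x)
        self.query_count += len(x)
        if self.hard_labels:
            return (scores >= 0.5).astype(float)
        return scores


def query(iface: VictimInterface, patches) -> np.ndarray:
    return iface.query(patches)
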