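"""Independent closed-form oracles used by the test suite."""

import math

import numpy as np


def ritter_depth(x, t, h0, g=9.81):
    """Inviscid dam-break rarefaction: dam at x=0, depth h0 left, dry right."""
    c0 = math.sqrt(g * h0)
    xi = np.asarray(x) / t
    return np.where(
        xi < -c0, h0, np.where(xi < 2 * c0, (2 * c0 - xi) ** 2 / (9 * g), 0.0)
    )
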