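"""Independent brute-force oracles used to check the analytic path."""

import numpy as np


def grid_peak(centers, sigma, step=1e-4, pad=1.0):
    """Dense-grid maximum of the Gaussian superposition.

    Deliberately independent of lasamatch.find_peak: plain exhaustive
    evaluation over [min - pad, max + pad] at ``step``.
    """
    cs = np.asarray(list(centers), dtype=float)
    if cs.size == 0:
        return 0.0, 0.0
    xs = np.arange(cs.min() - pad, cs.max() + pad + step, step)
    f = np.exp(-((cs[:, None] - xs[None, :]) ** 2) / sigma).sum(axis=0)
    i = int(np.argmax(f))
    return float(xs[i]), float(f[i])
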