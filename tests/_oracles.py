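"""Independent brute-force oracles shared across test modules."""

import numpy as np


def brute_force_hpd(draws, mass):
    """Exhaustive shortest-window scan; first window wins on ties."""
    d = np.sort(np.asarray(draws, float))
    n = d.size
    h = int(np.ceil(mass * n))
    best = None
    for i in range(n - h + 1):
        w = d[i + h - 1] - d[i]
        if best is None or w < best[0]:
            best = (w, float(d[i]), float(d[i + h - 1]))
    return best[1], best[2]
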