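import numpy as np

from abcells.geometry import Polygon


def blob_polygon(center, radius, n=24, seed=0):
    """Random star-convex test polygon."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = radius * (1 + rng.uniform(-0.2, 0.2, n))
    return Polygon(np.c_[center[0] + r * np.cos(t), center[1] + r * np.sin(t)])
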