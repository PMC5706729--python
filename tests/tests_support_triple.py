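"""Helper: minimal donor–hydrogen–acceptor system with prescribed geometry."""

import numpy as np

from oligotop import Conformation


def make_triple(d_a: float, angle_deg: float) -> Conformation:
    """N-H donor and O acceptor with D-A distance ``d_a`` (Å) and D-H-A
    angle ``angle_deg``; donor and acceptor in distinct residues."""
    n = np.zeros(3)
    h = np.array([0.1, 0.0, 0.0])
    ang = np.radians(180.0 - angle_deg)
    direction = np.array([np.cos(ang), np.sin(ang), 0.0])
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if np.linalg.norm(h + mid * direction - n) * 10 < d_a:
            lo = mid
        else:
            hi = mid
    a = h + ((lo + hi) / 2) * direction
    return Conformation(
        ["N", "H", "O"], ["N", "H", "O"], [1, 1, 2], ["ALA", "ALA", "ALA"],
        ["A", "A", "B"], np.vstack([n, h, a]),
    )
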