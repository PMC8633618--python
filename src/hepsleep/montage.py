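"""Standard 10-20 scalp montage geometry and channel adjacency.

Spatio-temporal clustering needs to know which electrodes are spatial
neighbors.  Neighborhoods are derived from schematic 2-D template positions
of the 10-20 system (top view, nose up, unit head radius), with a distance
threshold chosen so that the median channel has about four neighbors on the
19-channel montage.  The older T3/T4/T5/T6 labels are used, matching
clinical polysomnography montages; the modern T7/T8/P7/P8 aliases are
accepted.
"""

from __future__ import annotations

import numpy as np

# Schematic top-view 2-D coordinates (x: left-negative, y: anterior-positive).
POSITIONS_1020: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95),
    "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59),
    "F3": (-0.42, 0.48),
    "Fz": (0.0, 0.48),
    "F4": (0.42, 0.48),
    "F8": (0.81, 0.59),
    "T3": (-1.0, 0.0),
    "C3": (-0.5, 0.0),
    "Cz": (0.0, 0.0),
    "C4": (0.5, 0.0),
    "T4": (1.0, 0.0),
    "T5": (-0.81, -0.59),
    "P3": (-0.42, -0.48),
    "Pz": (0.0, -0.48),
    "P4": (0.42, -0.48),
    "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95),
    "O2": (0.31, -0.95),
}

_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

#: Distance threshold on the unit-head template.  0.62 yields a median of 4
#: neighbors per channel on the full 19-channel montage.
DEFAULT_NEIGHBOR_THRESHOLD = 0.62


def template_positions(labels: list[str]) -> np.ndarray:
    """Return the (n, 2) template coordinates for ``labels``.

    Raises ``KeyError`` for a label that is not a 10-20 scalp site.
    """
    pos = []
    for lab in labels:
        key = _ALIASES.get(lab, lab)
        if key not in POSITIONS_1020:
            raise KeyError(f"no 10-20 template position for channel {lab!r}")
        pos.append(POSITIONS_1020[key])
    return np.asarray(pos, dtype=float)


def channel_adjacency(
    labels: list[str], threshold: float = DEFAULT_NEIGHBOR_THRESHOLD
) -> np.ndarray:
    """Boolean (n, n) spatial neighbor matrix; symmetric and irreflexive."""
    pos = template_positions(labels)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = d <= threshold
    np.fill_diagonal(adj, False)
    return adj
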