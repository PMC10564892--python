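"""The D-score: a cyclic dihedral-space dissimilarity for groove-bound peptides.

Two peptides with the same anchor class are compared on the central window of
their backbones — the stretch that T-cell receptors read out — by summing, at
each window position p, the cyclic angular difference

    D(theta1, theta2) = 2 * (1 - cos(theta1 - theta2))

over both phi_p and psi_p.  The window is P4..P7 for the Δ7 anchor class
(nonamers, 8 angle terms), P4..P6 for Δ6 and P4..P8 for Δ8.  A pair whose
D-score is at or below the class threshold (1.5 for Δ7, scaled by the angle
count for the other classes) counts as structurally similar: "neighbors".
Because the score lives entirely in internal coordinates it is blind to
rigid-body motion and, unlike a Cartesian RMSD, cannot be fooled by
compensating displacements downstream of a single large torsion change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SUMMATION_WINDOWS",
    "angle_diff",
    "dscore",
    "per_position_dscore",
    "neighbor_threshold",
    "DscoreMatrix",
    "build_matrix",
]

# Central summation window (1-based, inclusive) per anchor class.
SUMMATION_WINDOWS = {6: (4, 6), 7: (4, 7), 8: (4, 8)}

# Neighbor criterion for the canonical Δ7 window (8 angle terms).
DELTA7_THRESHOLD = 1.5
DELTA7_ANGLE_COUNT = 8


def angle_diff(theta1, theta2):
    """Cyclic difference D(theta1, theta2) = 2(1 - cos(theta1 - theta2)).

    Angles in degrees; result in [0, 4], periodic in 360.  NaN inputs
    propagate.
    """
    t1 = np.asarray(theta1, dtype=float)
    t2 = np.asarray(theta2, dtype=float)
    out = 2.0 * (1.0 - np.cos(np.radians(t1 - t2)))
    if out.ndim == 0:
        return float(out)
    return out


def _window(anchor_class: int) -> range:
    try:
        lo, hi = SUMMATION_WINDOWS[anchor_class]
    except KeyError:
        raise ValueError(
            f"unsupported anchor class {anchor_class!r}; expected one of {sorted(SUMMATION_WINDOWS)}"
        ) from None
    return range(lo, hi + 1)


def neighbor_threshold(anchor_class: int) -> float:
    """Class-scaled neighbor criterion.

    The Δ7 criterion is 1.5 over 8 angle terms; other classes scale
    proportionally to their angle count (Δ6: 1.125 over 6 terms, Δ8: 1.875
    over 10).  The scaled values are an inference from the stated
    proportionality, not independently published numbers.
    """
    window = _window(anchor_class)
    n_angles = 2 * len(window)
    return DELTA7_THRESHOLD * n_angles / DELTA7_ANGLE_COUNT


def per_position_dscore(a, b, anchor_class: int) -> np.ndarray:
    """Per-position D(phi) + D(psi) over the class window.

    ``a`` and ``b`` are PeptideBackbone-like objects exposing ``phi`` and
    ``psi`` arrays in degrees.  The vector sums to the total D-score.
    """
    window = _window(anchor_class)
    out = np.empty(len(window))
    for k, p in enumerate(window):
        i = p - 1
        terms = (
            angle_diff(a.phi[i], b.phi[i]),
            angle_diff(a.psi[i], b.psi[i]),
        )
        out[k] = terms[0] + terms[1]
    if not np.isfinite(out).all():
        raise ValueError("undefined dihedral inside the summation window")
    return out


def dscore(a, b, anchor_class: int = 7) -> float:
    """Total D-score between two same-class peptide backbones."""
    return float(per_position_dscore(a, b, anchor_class).sum())


@dataclass
class DscoreMatrix:
    """Pairwise D-scores plus the thresholded neighbor adjacency.

    ``scores`` is symmetric with a zero diagonal; ``adjacency`` applies the
    class-scaled neighbor criterion off-diagonal (self never counts as its
    own neighbor).
    """

    ids: list[str]
    scores: np.ndarray
    adjacency: np.ndarray
    anchor_class: int
    threshold: float
    excluded: list[str]

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)

    def neighbor_counts(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def neighbors_of(self, sid: str) -> list[str]:
        i = self.ids.index(sid)
        return [self.ids[j] for j in np.flatnonzero(self.adjacency[i])]


def build_matrix(backbones: dict, anchor_class: int = 7,
                 threshold: float | None = None) -> DscoreMatrix:
    """All-against-all D-scores for a named set of same-class backbones.

    ``backbones`` maps structure id -> PeptideBackbone.  Structures with an
    undefined dihedral inside the class window are excluded (and listed in
    ``excluded``) rather than imputed.
    """
    if threshold is None:
        threshold = neighbor_threshold(anchor_class)
    window = [p - 1 for p in _window(anchor_class)]

    usable, excluded = [], []
    for sid, bb in backbones.items():
        ok = all(
            np.isfinite(bb.phi[i]) and np.isfinite(bb.psi[i]) for i in window
        )
        (usable if ok else excluded).append(sid)

    n = len(usable)
    phis = np.array([[backbones[sid].phi[i] for i in window] for sid in usable])
    psis = np.array([[backbones[sid].psi[i] for i in window] for sid in usable])
    angles = np.concatenate([phis, psis], axis=1)  # (n, 2w)
    diff = np.radians(angles[:, None, :] - angles[None, :, :])
    scores = (2.0 * (1.0 - np.cos(diff))).sum(axis=2)
    np.fill_diagonal(scores, 0.0)

    adjacency = scores <= threshold
    np.fill_diagonal(adjacency, False)
    return DscoreMatrix(
        ids=usable,
        scores=scores,
        adjacency=adjacency,
        anchor_class=anchor_class,
        threshold=float(threshold),
        excluded=excluded,
    )
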