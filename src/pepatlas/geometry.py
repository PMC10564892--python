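"""Backbone geometry: dihedral extraction, internal-coordinate chain building,
anchor classification and superposition.

Peptides bound in the HLA-I groove are compared in a groove-fixed frame: the
platform (first 180 heavy-chain residues) provides the reference, while the
peptide's own shape lives in its backbone dihedral angles.  This module holds
the quantitative layer those comparisons rest on: measuring phi/psi from
coordinates, rebuilding Cartesian chains from dihedrals by sequential
natural-extension reference-frame (NeRF) placement with ideal covalent
geometry, locating the anchor residues against the B/F-pocket probes
(platform residues 24 and 123), and Kabsch superposition for RMSD readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "IDEAL_GEOMETRY",
    "PPII_PHI",
    "PPII_PSI",
    "PeptideBackbone",
    "AnchorClassification",
    "RamachandranSurface",
    "compute_dihedrals",
    "dihedral",
    "build_backbone",
    "anchor_distance_grid",
    "rama_anchor_surface",
    "assign_anchors",
    "superpose_and_rmsd",
]

# Ideal covalent backbone geometry (Angstrom / degrees).  Bond lengths are
# Engh-Huber-style; the alpha carbon is kept tetrahedral (109.5), as simple
# fragment builders idealise it, and the peptide bond is planar trans
# (omega = 180).  With these constants a uniform PPII nonamer spans
# 21.47 A between the P2 and P9 alpha carbons.
IDEAL_GEOMETRY = {
    "b_n_ca": 1.458,
    "b_ca_c": 1.525,
    "b_c_n": 1.329,
    "b_c_o": 1.231,
    "a_n_ca_c": 109.5,
    "a_ca_c_n": 117.2,
    "a_c_n_ca": 121.7,
    "a_ca_c_o": 120.5,
}

# Ideal polyproline-II helix dihedrals.
PPII_PHI = -75.0
PPII_PSI = 145.0

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC convention.

    Accepts arrays broadcastable to (..., 3); returns degrees in (-180, 180].
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    # components of b0, b2 perpendicular to b1
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    return np.where(np.isclose(ang, -180.0), 180.0, ang)


def _wrap_angle(theta):
    """Wrap degrees into (-180, 180]."""
    t = (np.asarray(theta, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(np.isclose(t, -180.0), 180.0, t)


def nerf_place(a, b, c, bond: float, angle_deg, torsion_deg) -> np.ndarray:
    """Place atom d given the three preceding atoms a-b-c.

    d is at distance ``bond`` from c, with angle b-c-d ``angle_deg`` and
    torsion a-b-c-d ``torsion_deg``.  All positional arguments broadcast over
    leading dimensions, so a whole family of chains can be extended at once.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(np.asarray(angle_deg, dtype=float))
    chi = np.radians(np.asarray(torsion_deg, dtype=float))

    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)

    d_local = np.stack(
        [
            -bond * np.cos(theta) * np.ones_like(chi),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ],
        axis=-1,
    )
    frame = np.stack([bc, m, n], axis=-1)  # columns are the local basis
    return c + np.einsum("...ij,...j->...i", frame, d_local)


@dataclass
class PeptideBackbone:
    """Backbone heavy atoms plus derived phi/psi for one peptide chain.

    coords has shape (n, 4, 3) ordered N, CA, C, O.  phi[0] and psi[-1] are
    NaN (undefined at the termini).
    """

    sequence: str
    coords: np.ndarray
    phi: np.ndarray = field(default=None)  # type: ignore[assignment]
    psi: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (4, 3):
            raise ValueError("coords must have shape (n, 4, 3) for N, CA, C, O")
        if len(self.sequence) != self.coords.shape[0]:
            raise ValueError("sequence length and coordinate count disagree")
        if self.phi is None or self.psi is None:
            self.phi, self.psi = compute_dihedrals(self.coords)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def ca(self) -> np.ndarray:
        return self.coords[:, 1]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PeptideBackbone":
        new = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return PeptideBackbone(self.sequence, new)


def compute_dihedrals(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue (phi, psi) in degrees from backbone coordinates.

    ``coords`` is (n, 4, 3) with atoms N, CA, C, O.  phi_i needs C(i-1) and is
    NaN at the first residue; psi_i needs N(i+1) and is NaN at the last.
    Residues with any non-finite backbone atom yield NaN at every angle that
    involves them.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    N, CA, C = coords[:, 0], coords[:, 1], coords[:, 2]
    for i in range(n):
        if i > 0 and np.isfinite([C[i - 1], N[i], CA[i], C[i]]).all():
            phi[i] = dihedral(C[i - 1], N[i], CA[i], C[i])
        if i < n - 1 and np.isfinite([N[i], CA[i], C[i], N[i + 1]]).all():
            psi[i] = dihedral(N[i], CA[i], C[i], N[i + 1])
    return phi, psi


def build_backbone(
    length: int,
    phi,
    psi,
    sequence: str | None = None,
    geometry: dict | None = None,
) -> PeptideBackbone:
    """Build a Cartesian backbone chain from per-residue dihedrals.

    Atoms are placed sequentially with fixed ideal bond lengths and angles and
    a planar trans peptide bond (omega = 180).  ``phi``/``psi`` may be scalars
    (uniform chain) or length-``length`` sequences; phi[0] and psi[-1] are
    ignored by construction (psi[-1] still orients the terminal carbonyl O).

    The build/measure pair is exact: compute_dihedrals on the result recovers
    the requested angles to numerical precision.
    """
    if length < 2:
        raise ValueError("need at least two residues to build a chain")
    g = dict(IDEAL_GEOMETRY)
    if geometry:
        g.update(geometry)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (length,)).copy()
    psi = np.broadcast_to(np.asarray(psi, dtype=float), (length,)).copy()
    if not (np.isfinite(phi[1:]).all() and np.isfinite(psi[:-1]).all()):
        raise ValueError("interior dihedrals must be finite")
    if sequence is None:
        sequence = "G" * length
    if len(sequence) != length:
        raise ValueError("sequence length mismatch")

    coords = np.zeros((length, 4, 3))
    # First residue: N at origin, CA on x, C in the xy-plane.
    coords[0, 0] = [0.0, 0.0, 0.0]
    coords[0, 1] = [g["b_n_ca"], 0.0, 0.0]
    ang = np.radians(g["a_n_ca_c"])
    coords[0, 2] = coords[0, 1] + g["b_ca_c"] * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, length):
        pN, pCA, pC = coords[i - 1, 0], coords[i - 1, 1], coords[i - 1, 2]
        psi_prev = psi[i - 1] if np.isfinite(psi[i - 1]) else 180.0
        nN = nerf_place(pN, pCA, pC, g["b_c_n"], g["a_ca_c_n"], psi_prev)
        nCA = nerf_place(pCA, pC, nN, g["b_n_ca"], g["a_c_n_ca"], 180.0)  # omega
        nC = nerf_place(pC, nN, nCA, g["b_ca_c"], g["a_n_ca_c"], phi[i])
        coords[i, 0], coords[i, 1], coords[i, 2] = nN, nCA, nC

    # Carbonyl oxygens: O_i anti to N_{i+1} across the sp2 carbon.
    for i in range(length):
        psi_i = psi[i] if np.isfinite(psi[i]) else 180.0
        coords[i, 3] = nerf_place(
            coords[i, 0], coords[i, 1], coords[i, 2],
            g["b_c_o"], g["a_ca_c_o"], psi_i + 180.0,
        )
    return PeptideBackbone(sequence, coords)


def anchor_distance_grid(phi_grid, psi_grid, length: int = 9,
                         anchors: tuple[int, int] = (2, 9)) -> np.ndarray:
    """Ca(anchor1)-Ca(anchor2) distance of uniform-dihedral chains, vectorised.

    ``phi_grid``/``psi_grid`` are broadcast-compatible arrays of dihedrals in
    degrees; every chain in the family shares one (phi, psi) at all residues.
    Anchors use 1-based peptide numbering.
    """
    g = IDEAL_GEOMETRY
    phi = np.asarray(phi_grid, dtype=float)
    psi = np.asarray(psi_grid, dtype=float)
    phi, psi = np.broadcast_arrays(phi, psi)
    shape = phi.shape

    N = np.zeros(shape + (3,))
    CA = np.zeros(shape + (3,))
    C = np.zeros(shape + (3,))
    CA[..., 0] = g["b_n_ca"]
    ang = np.radians(g["a_n_ca_c"])
    C[..., 0] = CA[..., 0] - g["b_ca_c"] * np.cos(ang)
    C[..., 1] = g["b_ca_c"] * np.sin(ang)

    ca_track = {1: CA.copy()}
    for i in range(2, length + 1):
        nN = nerf_place(N, CA, C, g["b_c_n"], g["a_ca_c_n"], psi)
        nCA = nerf_place(CA, C, nN, g["b_n_ca"], g["a_c_n_ca"], 180.0)
        nC = nerf_place(C, nN, nCA, g["b_ca_c"], g["a_n_ca_c"], phi)
        N, CA, C = nN, nCA, nC
        if i in anchors:
            ca_track[i] = CA.copy()
    return np.linalg.norm(ca_track[anchors[1]] - ca_track[anchors[0]], axis=-1)


@dataclass
class RamachandranSurface:
    """Anchor distance of a uniform-dihedral nonamer over the full (phi, psi) lattice."""

    phi: np.ndarray          # 1-D grid, degrees
    psi: np.ndarray          # 1-D grid, degrees
    distance: np.ndarray     # (len(phi), len(psi)) Angstrom
    mask: np.ndarray         # boolean, distance within [lo, hi]
    dist_lo: float
    dist_hi: float

    def mask_at(self, phi: float, psi: float) -> bool:
        i = int(np.argmin(np.abs(self.phi - phi)))
        j = int(np.argmin(np.abs(self.psi - psi)))
        return bool(self.mask[i, j])

    def distance_at(self, phi: float, psi: float) -> float:
        i = int(np.argmin(np.abs(self.phi - phi)))
        j = int(np.argmin(np.abs(self.psi - psi)))
        return float(self.distance[i, j])


def rama_anchor_surface(length: int = 9, dist_lo: float = 17.5,
                        dist_hi: float = 20.0, step: float = 1.0) -> RamachandranSurface:
    """Scan the Ramachandran lattice for uniform chains with a groove-compatible anchor span.

    For every (phi, psi) on a ``step``-degree lattice from -180 to +180
    (both endpoints kept; the duplicated column is deliberate), a free
    uniform-dihedral chain of ``length`` residues is built and its P2-P(length)
    Ca distance recorded.  The mask marks cells whose distance falls inside
    [dist_lo, dist_hi] — for the canonical nonamer window 17.5-20.0 A this is
    the region a groove-bound chain can occupy, and the ideal PPII point
    (-75, +145) sits outside it at 21.4 A.
    """
    if not dist_lo < dist_hi:
        raise ValueError("dist_lo must be below dist_hi")
    grid = np.arange(-180.0, 180.0 + step / 2, step)
    P, S = np.meshgrid(grid, grid, indexing="ij")
    dist = anchor_distance_grid(P, S, length=length, anchors=(2, length))
    mask = (dist >= dist_lo) & (dist <= dist_hi)
    return RamachandranSurface(grid, grid.copy(), dist, mask, dist_lo, dist_hi)


@dataclass
class AnchorClassification:
    """Anchor residues of a groove-bound peptide and their separation.

    b_anchor / f_anchor are 1-based peptide positions nearest (Ca-Ca) to the
    B- and F-pocket probes; anchor_class is their sequence separation and
    anchor_distance the Ca-Ca span in Angstrom.
    """

    b_anchor: int
    f_anchor: int
    anchor_class: int
    anchor_distance: float
    valid: bool = True

    @property
    def delta(self) -> int:
        return self.anchor_class


def assign_anchors(complex_) -> AnchorClassification:
    """Classify a curated complex by its anchor residues.

    The probe Ca atoms are platform residues 24 (B pocket) and 123 (F pocket).
    b_anchor is the peptide position whose Ca lies nearest probe 24 (ties:
    lowest index), f_anchor nearest probe 123 (ties: highest index).
    """
    probe_b = complex_.platform_ca(24)
    probe_f = complex_.platform_ca(123)
    pep_ca = complex_.peptide_backbone().ca
    d_b = np.linalg.norm(pep_ca - probe_b, axis=1)
    d_f = np.linalg.norm(pep_ca - probe_f, axis=1)
    b_anchor = int(np.flatnonzero(np.isclose(d_b, d_b.min()))[0]) + 1
    f_anchor = int(np.flatnonzero(np.isclose(d_f, d_f.min()))[-1]) + 1
    dist = float(np.linalg.norm(pep_ca[f_anchor - 1] - pep_ca[b_anchor - 1]))
    valid = b_anchor < f_anchor
    return AnchorClassification(
        b_anchor=b_anchor,
        f_anchor=f_anchor,
        anchor_class=f_anchor - b_anchor,
        anchor_distance=dist,
        valid=valid,
    )


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rotation/translation taking ``mobile`` onto ``target``.

    Returns (R, t, rmsd_of_fit) with x_fit = x @ R.T + t.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(target - mu_t, mobile - mu_m)
    R = rot.as_matrix()
    t = mu_t - mu_m @ R.T
    rmsd = float(rssd / np.sqrt(len(mobile)))
    return R, t, rmsd


def superpose_and_rmsd(a, b, peptide_positions=None, atom_set: str = "backbone") -> float:
    """Groove-frame peptide RMSD between two curated complexes.

    The platforms are superposed on their Ca atoms (Kabsch); the peptide RMSD
    is then evaluated over ``peptide_positions`` (1-based; default: all) and
    ``atom_set`` ("ca", "backbone" = N/CA/C/O) without refitting, so genuine
    peptide displacement within the groove is what remains.
    """
    pa = a.platform_ca_array()
    pb = b.platform_ca_array()
    if pa.shape != pb.shape:
        raise ValueError("platforms must have matching residue counts")
    R, t, _ = kabsch(pb, pa)

    bb_a = a.peptide_backbone()
    bb_b = b.peptide_backbone()
    n = len(bb_a)
    if peptide_positions is None:
        peptide_positions = range(1, n + 1)
    idx = [p - 1 for p in peptide_positions]
    if max(idx) >= n or max(idx) >= len(bb_b):
        raise ValueError("requested peptide positions out of range")
    if len(bb_a) != len(bb_b) and any(i >= min(len(bb_a), len(bb_b)) for i in idx):
        raise ValueError("peptide lengths differ at requested positions")

    if atom_set == "ca":
        xa = bb_a.coords[idx, 1]
        xb = bb_b.coords[idx, 1]
    elif atom_set == "backbone":
        xa = bb_a.coords[idx].reshape(-1, 3)
        xb = bb_b.coords[idx].reshape(-1, 3)
    else:
        raise ValueError(f"unknown atom_set {atom_set!r}")
    xb = xb @ R.T + t
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
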