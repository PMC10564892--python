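"""Synthetic fixtures: toy complexes, backbone families and feature tables.

Everything downstream of raw crystal structures can be exercised without any
download: this module fabricates (a) toy peptide/platform coordinate files
that satisfy the curation contract, (b) families of peptide backbones with
controlled dihedral spread around a centre, and (c) candidate-model feature
tables with a planted monotone relation between features and true model
error, for the regression layer.

None of this is physically realistic — the platform is a dummy scaffold
whose only load-bearing geometry is the two pocket-probe Cα positions
(platform residues 24 and 123), and the reference alleles are synthetic
sequences, not IPD-IMGT/HLA records.  Docstrings say so where it matters.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curation import Atom, ResidueRecord, CuratedComplex
from .geometry import PeptideBackbone, build_backbone

__all__ = [
    "synthetic_reference_alleles",
    "write_reference_fasta",
    "SyntheticComplexSpec",
    "make_complex",
    "make_backbone_family",
    "SyntheticFeatureSpec",
    "make_feature_table",
    "motif_scorer",
]

AA1 = "ACDEFGHIKLMNPQRSTVWY"
AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def synthetic_reference_alleles(names=("A*02:01", "B*57:01"), length: int = 180,
                                divergence: float = 0.4, seed: int = 7) -> dict[str, str]:
    """Deterministic SYNTHETIC stand-in allele sequences (not real HLA).

    The first allele is a random 180-mer; each subsequent allele mutates a
    ``divergence`` fraction of its positions, so alleles are mutually
    distinguishable by alignment identity while all remaining >50% identical
    to each other (as real platform sequences are).
    """
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list(AA1), size=length))
    refs = {names[0]: base}
    for name in names[1:]:
        seq = list(base)
        k = int(divergence * length)
        pos = rng.choice(length, size=k, replace=False)
        for p in pos:
            seq[p] = rng.choice([a for a in AA1 if a != seq[p]])
        refs[name] = "".join(seq)
    return refs


def write_reference_fasta(path, references: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name in sorted(references):
            fh.write(f">{name}\n{references[name]}\n")


@dataclass
class SyntheticComplexSpec:
    """Recipe for one toy complex.

    phi/psi means and stddevs are per-residue (scalars broadcast); anchors
    name the peptide positions that the pocket probes (platform residues 24
    and 123) are placed nearest to.
    """

    pdb_id: str = "TOY1"
    peptide_sequence: str = "GLAFSGVAK"
    phi_mean: float | np.ndarray = -75.0
    psi_mean: float | np.ndarray = 145.0
    phi_std: float | np.ndarray = 0.0
    psi_std: float | np.ndarray = 0.0
    anchors: tuple[int, int] = (2, 9)
    seed: int = 0
    allele: str = "A*02:01"
    references: dict = field(default_factory=synthetic_reference_alleles)
    resolution: float = 1.9
    release_date: str = "2016-01-12"
    extra_chain_distance: float | None = None  # place an "other" chain this far from the peptide
    zero_occupancy_atom: tuple[int, str] | None = None  # (peptide position, atom name)

    def __post_init__(self):
        n = len(self.peptide_sequence)
        if not 1 <= self.anchors[0] < self.anchors[1] <= n:
            raise ValueError("anchor positions must be ordered and within the peptide")
        if np.any(np.asarray(self.phi_std) < 0) or np.any(np.asarray(self.psi_std) < 0):
            raise ValueError("dihedral stddevs must be non-negative")


def _residue_from_template(name3: str, seqid: int, origin: np.ndarray) -> ResidueRecord:
    # minimal backbone template around a local origin (Angstrom offsets)
    offs = {
        "N": np.array([-1.2, 0.0, 0.0]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([1.3, 0.6, 0.0]),
        "O": np.array([1.5, 1.8, 0.2]),
    }
    atoms = {
        a: Atom(a, origin + off, occ=1.0, element=a[0]) for a, off in offs.items()
    }
    return ResidueRecord(name3, seqid, atoms)


def make_complex(spec: SyntheticComplexSpec, out_path=None) -> CuratedComplex:
    """Build a toy curated complex (and optionally write it as PDB).

    The peptide is built from dihedrals sampled around the spec means; the
    platform is a dummy 180-residue scaffold strung along a line 15 A below
    the peptide, except that the probe residues 24 and 123 are placed 3 A
    from the requested anchor Cα atoms so anchor assignment recovers the
    spec.  Identical seeds give byte-identical files.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(spec.peptide_sequence)
    phi = np.broadcast_to(np.asarray(spec.phi_mean, dtype=float), (n,)).copy()
    psi = np.broadcast_to(np.asarray(spec.psi_mean, dtype=float), (n,)).copy()
    phi = phi + rng.normal(0.0, np.broadcast_to(np.asarray(spec.phi_std, float), (n,)))
    psi = psi + rng.normal(0.0, np.broadcast_to(np.asarray(spec.psi_std, float), (n,)))
    bb = build_backbone(n, phi, psi, sequence=spec.peptide_sequence)

    peptide = []
    for i, aa in enumerate(spec.peptide_sequence):
        atoms = {
            a: Atom(a, bb.coords[i, j].copy(), occ=1.0, element=a[0])
            for j, a in enumerate(("N", "CA", "C", "O"))
        }
        peptide.append(ResidueRecord(AA3[aa], i + 1, atoms))
    if spec.zero_occupancy_atom is not None:
        pos, aname = spec.zero_occupancy_atom
        peptide[pos - 1].atoms[aname].occ = 0.0

    ref_seq = spec.references[spec.allele]
    platform = []
    ca = bb.ca

    def probe_point(anchor_pos: int) -> np.ndarray:
        # point 3 A from the anchor Ca, in the direction (from a fixed
        # Fibonacci-sphere scan) with the most clearance from every other
        # Ca, so the anchor is unambiguously the nearest residue
        i = anchor_pos - 1
        others = np.delete(ca, i, axis=0)
        k = np.arange(200)
        golden = np.pi * (3.0 - np.sqrt(5.0))
        z = 1.0 - 2.0 * (k + 0.5) / len(k)
        rad = np.sqrt(1.0 - z ** 2)
        dirs = np.stack([rad * np.cos(golden * k), rad * np.sin(golden * k), z], axis=1)
        points = ca[i] + 3.0 * dirs
        clearance = np.linalg.norm(
            others[None, :, :] - points[:, None, :], axis=2
        ).min(axis=1)
        best = points[int(np.argmax(clearance))]
        if clearance.max() <= 3.0:
            raise ValueError("impossible anchor geometry for this dihedral draw")
        return best

    probe = {24: probe_point(spec.anchors[0]), 123: probe_point(spec.anchors[1])}
    for i, aa in enumerate(ref_seq):
        seqid = i + 1
        if seqid in probe:
            origin = probe[seqid]
        else:
            origin = np.array([4.0 * i, 0.0, -15.0])
        platform.append(_residue_from_template(AA3[aa], seqid, origin))

    curated = CuratedComplex(
        pdb_id=spec.pdb_id,
        platform=platform,
        peptide=peptide,
        allotype=spec.allele,
        resolution=spec.resolution,
        release_date=spec.release_date,
    )

    if out_path is not None:
        st = curated.to_structure()
        if spec.extra_chain_distance is not None:
            import gemmi

            chain = gemmi.Chain("X")
            anchor = bb.ca[4]
            for k in range(3):
                r = gemmi.Residue()
                r.name = "ALA"
                r.seqid = gemmi.SeqId(k + 1, " ")
                a = gemmi.Atom()
                a.name = "CA"
                a.pos = gemmi.Position(
                    anchor[0] + spec.extra_chain_distance,
                    anchor[1] + 4.0 * k,
                    anchor[2],
                )
                a.occ = 1.0
                a.element = gemmi.Element("C")
                r.add_atom(a)
                chain.add_residue(r)
            st[0].add_chain(chain)
            st.setup_entities()
        st.write_pdb(str(out_path))
    return curated


def make_backbone_family(n: int, center: tuple[float, float] = (-75.0, 145.0),
                         spread: float = 2.0, length: int = 9, seed: int = 0,
                         prefix: str = "fam") -> dict[str, PeptideBackbone]:
    """n backbones with dihedrals Gaussian-perturbed around a shared centre.

    Small ``spread`` (degrees) keeps all members mutual neighbors under the
    class D-score criterion; large spread scatters them.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = {}
    for k in range(n):
        phi = center[0] + rng.normal(0.0, spread, size=length)
        psi = center[1] + rng.normal(0.0, spread, size=length)
        out[f"{prefix}{k:03d}"] = build_backbone(length, phi, psi)
    return out


@dataclass
class SyntheticFeatureSpec:
    """Recipe for a candidate-model feature table with planted signal.

    The first ``n_informative`` features are affine in the true D-score plus
    Gaussian noise; the rest are pure noise.  Peptide sequences are random
    nonamers so homolog filtering has something to chew on.
    """

    n_targets: int = 20
    n_templates: int = 10
    n_features: int = 129
    n_informative: int = 3
    noise_std: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_features < 3:
            raise ValueError("need at least 3 features")
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")


def _random_peptides(rng, count: int, length: int = 9) -> list[str]:
    return ["".join(rng.choice(list(AA1), size=length)) for _ in range(count)]


def make_feature_table(spec: SyntheticFeatureSpec) -> pd.DataFrame:
    """Candidate table: one row per (target, template) with features and true D-score.

    true_dscore is sampled per pair from a folded normal spanning the
    realistic 0-8 range, with one low-error template per target so selection
    has a correct answer; informative features are affine transforms of it.
    """
    rng = np.random.default_rng(spec.seed)
    targets = [f"T{i:03d}" for i in range(spec.n_targets)]
    templates = [f"R{i:03d}" for i in range(spec.n_templates)]
    t_peps = _random_peptides(rng, spec.n_targets)
    r_peps = _random_peptides(rng, spec.n_templates)

    coef = rng.uniform(0.5, 2.0, size=spec.n_informative)
    intercept = rng.uniform(-1.0, 1.0, size=spec.n_informative)

    rows = []
    for ti, tid in enumerate(targets):
        best = rng.integers(spec.n_templates)
        for ri, rid in enumerate(templates):
            if ri == best:
                true_d = float(rng.uniform(0.2, 1.2))
            else:
                true_d = float(np.abs(rng.normal(3.0, 1.8))) + 0.3
            feats = np.empty(spec.n_features)
            feats[: spec.n_informative] = (
                coef * true_d + intercept + rng.normal(0.0, spec.noise_std, spec.n_informative)
            )
            feats[spec.n_informative:] = rng.normal(size=spec.n_features - spec.n_informative)
            rows.append(
                {
                    "target_id": tid,
                    "template_id": rid,
                    "target_peptide": t_peps[ti],
                    "template_peptide": r_peps[ri],
                    "true_dscore": true_d,
                    **{f"f{k+1}": feats[k] for k in range(spec.n_features)},
                }
            )
    return pd.DataFrame(rows)


def motif_scorer(motif: dict[int, str], strength: float = 5.0, noise: float = 1.0,
                 seed: int = 0):
    """Surrogate sequence scorer with a planted motif (lower score = better).

    Deterministic per sequence: the pseudo-noise is derived from a CRC of the
    sequence and the seed, so identical inputs score identically regardless
    of evaluation order.  Stands in for an external energy function in tests;
    no physics is implied.
    """

    def score(seq: str) -> float:
        matches = sum(1 for pos, aa in motif.items() if seq[pos - 1] == aa)
        h = zlib.crc32(f"{seed}:{seq}".encode()) / 0xFFFFFFFF
        return -strength * matches + noise * (h - 0.5)

    return score
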