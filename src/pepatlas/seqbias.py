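"""Sequence-space enumeration and per-position bias analysis.

A fixed peptide backbone imposes its own sequence preferences: side chains
must avoid steric clashes with the groove and with each other, and can pick
up backbone contacts available only in that conformation.  To expose such
biases, the central positions (P3..P8) of a nonamer are enumerated over
reduced per-position alphabets, each candidate is scored by an external
energy function (or the packaged surrogate), the lowest-energy top fraction
is retained, and the retained set is summarised as a position probability
matrix (PPM) compared against a reference peptide set by per-position
Kullback-Leibler divergence.

The energy scoring itself is pluggable: any callable mapping a sequence to a
scalar (lower = better) works, so externally produced score tables slot in
unchanged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import rel_entr

__all__ = [
    "AMINO_ACIDS",
    "PPM_FLOOR",
    "load_alphabets",
    "default_alphabets",
    "enumerate_space",
    "space_size",
    "ScoredSequence",
    "top_fraction",
    "build_ppm",
    "kl_divergence",
]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

# Zero cells of a PPM default to this probability; columns are deliberately
# not renormalised afterwards (the floor patches zeros only).
PPM_FLOOR = 0.02


def load_alphabets(path) -> dict[int, tuple[str, ...]]:
    """Read per-position alphabets from TSV (position <TAB> comma-joined residues).

    Lines starting with '#' are comments.  Proline must be present at every
    position (it is the one residue whose backbone restraint always matters).
    """
    out: dict[int, tuple[str, ...]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pos_s, aas = line.split("\t")
        aa = tuple(sorted({a.strip() for a in aas.split(",") if a.strip()}))
        if not aa:
            raise ValueError(f"empty alphabet at position {pos_s}")
        bad = set(aa) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"unknown residues {sorted(bad)} at position {pos_s}")
        if "P" not in aa:
            raise ValueError(f"proline missing from position {pos_s}")
        out[int(pos_s)] = aa
    if not out:
        raise ValueError(f"no alphabets found in {path}")
    return out


def default_alphabets() -> dict[int, tuple[str, ...]]:
    """The packaged example alphabets for P3..P8 (sizes multiply to 784,080)."""
    ref = resources.files("pepatlas").joinpath("data/position_alphabets.tsv")
    with resources.as_file(ref) as p:
        return load_alphabets(p)


def space_size(alphabets: dict[int, tuple[str, ...]]) -> int:
    n = 1
    for aa in alphabets.values():
        n *= len(aa)
    return n


def enumerate_space(alphabets: dict[int, tuple[str, ...]],
                    flank_n: str = "", flank_c: str = ""):
    """Deterministic lexicographic iterator over the variable-position product.

    Yields full sequences ``flank_n + variable + flank_c`` with the variable
    part running over the cartesian product of the position alphabets in
    ascending position order.  Use :func:`space_size` for the count without
    materialising.
    """
    positions = sorted(alphabets)
    sets = [tuple(sorted(alphabets[p])) for p in positions]
    if any(len(s) == 0 for s in sets):
        raise ValueError("empty alphabet")
    for combo in itertools.product(*sets):
        yield flank_n + "".join(combo) + flank_c


@dataclass(frozen=True)
class ScoredSequence:
    """A candidate peptide with its total energy (arbitrary units, lower = better)."""

    sequence: str
    score: float


def top_fraction(scored, fraction: float = 0.01) -> list[ScoredSequence]:
    """Retain the floor(fraction * N) lowest-score entries.

    Ties are broken by position in the input sequence order, so the result is
    deterministic for a fixed input ordering.  With the canonical 784,080
    candidates and fraction 0.01 this keeps exactly 7,840.
    """
    scored = list(scored)
    n_keep = int(np.floor(fraction * len(scored)))
    if n_keep == 0:
        return []
    order = sorted(range(len(scored)), key=lambda i: (scored[i].score, i))
    return [scored[i] for i in order[:n_keep]]


def build_ppm(sequences, floor: float = PPM_FLOOR) -> pd.DataFrame:
    """Position probability matrix over the 20 amino acids.

    Rows are 1-based positions, columns amino acids.  Cells that would be
    zero are set to ``floor``; the columns are NOT renormalised afterwards,
    so each position row sums to slightly more than 1 when any residue is
    absent.  (Downstream KL uses the matrix exactly as built.)
    """
    sequences = [s.sequence if isinstance(s, ScoredSequence) else s for s in sequences]
    if not sequences:
        raise ValueError("no sequences")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences must share one length")
    counts = np.zeros((L, len(AMINO_ACIDS)))
    col = {a: j for j, a in enumerate(AMINO_ACIDS)}
    for s in sequences:
        for i, a in enumerate(s):
            counts[i, col[a]] += 1
    freqs = counts / len(sequences)
    freqs[freqs == 0.0] = floor
    return pd.DataFrame(freqs, index=range(1, L + 1), columns=list(AMINO_ACIDS))


def kl_divergence(p: pd.DataFrame, q: pd.DataFrame, position: int) -> float:
    """Per-position KL divergence sum_a p(a) ln(p(a)/q(a)), in nats.

    ``p`` and ``q`` are PPMs as built by :func:`build_ppm`; the floor
    guarantees q > 0.  Asymmetric by construction.
    """
    if list(p.columns) != list(q.columns):
        raise ValueError("PPMs must share one alphabet")
    pv = p.loc[position].to_numpy(dtype=float)
    qv = q.loc[position].to_numpy(dtype=float)
    val = float(rel_entr(pv, qv).sum())
    if not np.isfinite(val):
        raise ValueError("non-finite KL divergence")
    return val
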