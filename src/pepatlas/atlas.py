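"""Discrete peptide backbones: greedy selection of conformational representatives.

Crystallographic sampling of groove-bound peptides is sparse and biased, so
rather than density-based clustering the representative set is built by a
greedy dominating-set heuristic on the neighbor graph: repeatedly take the
structure with the most remaining neighbors as a representative ("discrete
peptide backbone"), remove it and its neighbors, and continue until every
structure is accounted for.  Zero-neighbor structures survive as singleton
representatives, which is the point — rare conformations must not be
absorbed into common ones.

Also here: the historical re-run of the selection on date-truncated subsets,
a 2-D PCA featurization of the central window dihedrals (sines, so the
circular quantities embed continuously), and supertype composition of each
representative's neighbor set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .dscore import DscoreMatrix

__all__ = [
    "Representative",
    "BackboneAtlas",
    "greedy_select",
    "historical_analysis",
    "pca_features",
    "supertype_composition",
]


@dataclass
class Representative:
    structure_id: str
    neighbor_ids: list[str]
    rank: int

    @property
    def set_size(self) -> int:
        return 1 + len(self.neighbor_ids)


@dataclass
class BackboneAtlas:
    """Ordered representatives with their neighbor sets.

    The neighbor sets are disjoint and, together with the representatives,
    cover every input structure exactly once.
    """

    representatives: list[Representative]
    covered: list[str]
    anchor_class: int
    threshold: float

    def __len__(self) -> int:
        return len(self.representatives)

    def representative_ids(self) -> list[str]:
        return [r.structure_id for r in self.representatives]

    def assignment(self) -> dict[str, str]:
        """structure id -> representative id (representatives map to themselves)."""
        out = {}
        for rep in self.representatives:
            out[rep.structure_id] = rep.structure_id
            for nid in rep.neighbor_ids:
                out[nid] = rep.structure_id
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "anchor_class": self.anchor_class,
                "threshold": self.threshold,
                "covered": self.covered,
                "representatives": [
                    {
                        "structure_id": r.structure_id,
                        "rank": r.rank,
                        "neighbor_ids": r.neighbor_ids,
                    }
                    for r in self.representatives
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "BackboneAtlas":
        d = json.loads(text)
        reps = [
            Representative(r["structure_id"], list(r["neighbor_ids"]), r["rank"])
            for r in d["representatives"]
        ]
        return cls(reps, list(d["covered"]), d["anchor_class"], d["threshold"])


def greedy_select(matrix: DscoreMatrix) -> BackboneAtlas:
    """Iterative max-neighbor extraction on the adjacency matrix.

    Each round, neighbor counts are recomputed on the remaining structures;
    the structure with the most remaining neighbors (ties: lexicographically
    smallest id) is taken as a representative and removed together with its
    remaining neighbors.  Structures with zero neighbors end up as singleton
    representatives.
    """
    ids = list(matrix.ids)
    adj = matrix.adjacency.copy()
    remaining = np.ones(len(ids), dtype=bool)
    reps: list[Representative] = []
    rank = 0
    while remaining.any():
        sub = adj & remaining[None, :] & remaining[:, None]
        counts = sub.sum(axis=1)
        counts[~remaining] = -1
        best = counts.max()
        tied = np.flatnonzero(counts == best)
        pick = min(tied, key=lambda i: ids[i])
        neigh = np.flatnonzero(sub[pick])
        reps.append(
            Representative(ids[pick], sorted(ids[j] for j in neigh), rank)
        )
        remaining[pick] = False
        remaining[neigh] = False
        rank += 1
    return BackboneAtlas(
        representatives=reps,
        covered=ids,
        anchor_class=matrix.anchor_class,
        threshold=matrix.threshold,
    )


def historical_analysis(matrix: DscoreMatrix, release_years: dict[str, int]):
    """Cumulative structure and representative counts per release year.

    For each year present in ``release_years`` (and any later year up to the
    maximum), the greedy selection is rerun from scratch on the subset of
    structures released up to and including that year.  Returns a list of
    (year, n_structures, n_representatives) tuples in ascending year order.
    """
    years = sorted(set(release_years[sid] for sid in matrix.ids))
    out = []
    for year in years:
        keep = [sid for sid in matrix.ids if release_years[sid] <= year]
        idx = [matrix.ids.index(sid) for sid in keep]
        sub = DscoreMatrix(
            ids=keep,
            scores=matrix.scores[np.ix_(idx, idx)],
            adjacency=matrix.adjacency[np.ix_(idx, idx)],
            anchor_class=matrix.anchor_class,
            threshold=matrix.threshold,
            excluded=[],
        )
        atlas = greedy_select(sub)
        out.append((year, len(keep), len(atlas)))
    return out


def pca_features(backbones: dict, window: tuple[int, int] = (4, 7)):
    """2-D PCA embedding of sin(phi), sin(psi) over the central window.

    Features are the sines of the window dihedrals (8 features for P4..P7),
    standardised to zero mean and unit variance before PCA.  Returns
    (ids, embedding (n, 2), explained_variance_ratio (2,)).
    """
    ids = list(backbones)
    if len(ids) < 3:
        raise ValueError("PCA featurization needs at least 3 structures")
    lo, hi = window
    cols = range(lo - 1, hi)
    feats = np.array(
        [
            np.concatenate(
                [
                    np.sin(np.radians([backbones[s].phi[i] for i in cols])),
                    np.sin(np.radians([backbones[s].psi[i] for i in cols])),
                ]
            )
            for s in ids
        ]
    )
    # constant features have zero variance; StandardScaler leaves them at 0
    scaled = StandardScaler().fit_transform(feats)
    pca = PCA(n_components=2)
    emb = pca.fit_transform(scaled)
    return ids, emb, pca.explained_variance_ratio_


def supertype_composition(
    atlas: BackboneAtlas,
    allotypes: dict[str, str],
    supertypes: dict[str, str],
) -> dict[str, dict[str, float]]:
    """Supertype proportions within each representative's set.

    The set includes the representative itself.  Allotypes absent from the
    supertype table fall into an "unassigned" bucket.  Proportions sum to 1
    per representative.
    """
    out = {}
    for rep in atlas.representatives:
        members = [rep.structure_id] + rep.neighbor_ids
        counts: dict[str, int] = {}
        for sid in members:
            allo = allotypes.get(sid)
            st = supertypes.get(allo, "unassigned") if allo else "unassigned"
            counts[st] = counts.get(st, 0) + 1
        total = len(members)
        out[rep.structure_id] = {k: v / total for k, v in sorted(counts.items())}
    return out
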