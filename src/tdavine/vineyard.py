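"""Vineyards: stacked diagrams linked by spatial proximity of loops.

A persistence diagram says nothing about *where* a loop lives.  The
vineyard augments the time-stacked H1 diagrams with edges between every
pair of features at consecutive time indices, weighted by the Hausdorff
distance -- in 3-D stereotactic space, amplitude excluded -- between their
representative loops, and shaded so that spatially coincident loops link
darkly.  A "vine" is a temporally coherent, spatially constrained chain of
features, possibly intermittent; stripping the diagrams down to one vine
produces the per-timepoint inputs of the task-responsiveness test.

Representative loops are not canonical, so edge shading is deterministic
but not stable under data perturbation; determinism is the contract here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .core import MaskRegion, ValidationError
from .homology import Diagram, Feature

DEFAULT_D_REF = 4.0
DEFAULT_MIN_PERSISTENCE = 0.8


def hausdorff3(A: np.ndarray, B: np.ndarray) -> float:
    """Symmetric Euclidean Hausdorff distance between 3-D point sets."""
    A = np.atleast_2d(np.asarray(A, dtype=float))[:, :3]
    B = np.atleast_2d(np.asarray(B, dtype=float))[:, :3]
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValidationError("Hausdorff distance of an empty set")
    d = cdist(A, B)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


@dataclass(frozen=True)
class VineyardEdge:
    t: int                    # edge joins diagrams at t and t+1
    from_feature: str
    to_feature: str
    spatial_distance: float
    shade: float              # clamp(1 - d/d_ref, 0, 1); 1 = coincident


@dataclass(frozen=True)
class Vineyard:
    diagrams: tuple[Diagram, ...]
    edges: tuple[VineyardEdge, ...]
    d_ref: float

    def feature(self, feature_id: str) -> Feature:
        for d in self.diagrams:
            for f in d.features:
                if f.id == feature_id:
                    return f
        raise KeyError(feature_id)


def build_vineyard(
    diagrams: list[Diagram], d_ref: float = DEFAULT_D_REF, prune: bool = True
) -> Vineyard:
    """Link all cross pairs of H1 features at consecutive time indices.

    ``prune`` drops shade-0 edges (distance >= d_ref) from storage; the
    linear clamp makes shade 0 an exact prunability criterion, so this is
    purely a storage optimization.
    """
    if d_ref <= 0:
        raise ValidationError("d_ref must be positive")
    edges = []
    for da, db in zip(diagrams, diagrams[1:]):
        for fa in da.select(1):
            for fb in db.select(1):
                d = hausdorff3(fa.representative, fb.representative)
                shade = min(1.0, max(0.0, 1.0 - d / d_ref))
                if prune and shade == 0.0:
                    continue
                edges.append(VineyardEdge(da.t, fa.id, fb.id, d, shade))
    return Vineyard(tuple(diagrams), tuple(edges), float(d_ref))


@dataclass(frozen=True)
class VineSelection:
    """Diagrams stripped down to one region-constrained vine.

    ``per_t_features`` holds, for each time index, the (possibly empty)
    retained H1 features: intermittent vines are legal and meaningful --
    absence at a time index is itself signal for the downstream test.
    """

    region: MaskRegion
    min_persistence: float
    per_t_features: tuple[tuple[Feature, ...], ...]
    r_max: float

    def to_diagrams(self) -> list[Diagram]:
        return [
            Diagram(t=t, features=fs, r_max=self.r_max)
            for t, fs in enumerate(self.per_t_features)
        ]

    @property
    def n_present(self) -> int:
        return sum(1 for fs in self.per_t_features if fs)


def extract_vine(
    vineyard: Vineyard,
    region: MaskRegion,
    min_persistence: float = DEFAULT_MIN_PERSISTENCE,
) -> VineSelection:
    """Strip each diagram to H1 features of the given vine.

    A feature is retained when its persistence (truncated features count
    ``r_max - birth``) reaches ``min_persistence`` and its representative's
    centroid lies in ``region``.  Centroid membership is robust to single
    stray vertices of the representative.
    """
    per_t = []
    for diag in vineyard.diagrams:
        keep = tuple(
            f for f in diag.select(1)
            if f.persistence >= min_persistence and bool(region.contains(f.centroid)[0])
        )
        per_t.append(keep)
    return VineSelection(
        region=region,
        min_persistence=float(min_persistence),
        per_t_features=tuple(per_t),
        r_max=vineyard.diagrams[0].r_max if vineyard.diagrams else np.inf,
    )


@dataclass(frozen=True)
class VineCandidate:
    region: MaskRegion
    score: float
    n_timepoints: int
    total_persistence: float
    feature_ids: tuple[str, ...] = field(default=(), compare=False)


def rank_vines(
    vineyard: Vineyard,
    d_link: float | None = None,
    min_persistence: float = 0.0,
) -> list[VineCandidate]:
    """Deterministic, auditable surrogate for manual vine selection.

    Features at consecutive time indices are chained greedily whenever the
    Hausdorff distance between their representatives is at most ``d_link``
    (default ``d_ref / 2``); each connected chain is scored by
    (total persistence) x (number of distinct time indices) and returned as
    its representative bounding box padded by ``d_link / 2``, best first.
    """
    if len(vineyard.diagrams) < 2:
        raise ValidationError("a vineyard needs at least two timepoints")
    if d_link is None:
        d_link = vineyard.d_ref / 2.0
    feats = {
        f.id: f
        for d in vineyard.diagrams
        for f in d.select(1)
        if f.persistence >= min_persistence
    }
    g = nx.Graph()
    g.add_nodes_from(feats)
    for e in vineyard.edges:
        if (
            e.spatial_distance <= d_link
            and e.from_feature in feats
            and e.to_feature in feats
        ):
            g.add_edge(e.from_feature, e.to_feature)
    candidates = []
    for comp in nx.connected_components(g):
        members = [feats[i] for i in comp]
        n_t = len({f.t for f in members})
        if n_t < 2:
            continue
        total = sum(f.persistence for f in members)
        pts = np.vstack([f.representative for f in members])
        pad = d_link / 2.0
        region = MaskRegion.from_bounds(pts.min(axis=0) - pad, pts.max(axis=0) + pad)
        candidates.append(
            VineCandidate(
                region=region,
                score=total * n_t,
                n_timepoints=n_t,
                total_persistence=total,
                feature_ids=tuple(sorted(comp)),
            )
        )
    candidates.sort(key=lambda c: (-c.score, c.feature_ids))
    return candidates
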