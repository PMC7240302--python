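"""Axon position within the lobula plate and position-based subtype calls.

The axon reference point of each neuron is normalised against the local
anteroposterior extent of the lobula plate: 0 is the most posterior edge,
1 the most anterior edge, both evaluated at the proximodistal position the
reference point occupies. Normalised positions fall into four clusters, one
per lobula-plate layer; each layer receives axons of exactly one subtype
(layer 1 <-> a, 2 <-> b, 3 <-> c, 4 <-> d).

Whether layer 1 sits at the posterior (position 0) or anterior (position 1)
end of the normalised axis cannot be fixed from anatomy described in text
alone, so the mapping is an explicit ``layer_order`` parameter with
``posterior_first`` as the documented default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .config import SUBTYPES

__all__ = [
    "LobulaPlateFrame",
    "RelativePosition",
    "AxonPositionRecord",
    "relative_axon_position",
    "AxonPositionClusterer",
    "cluster_axon_positions",
    "classify_subtype_from_axon",
    "dendrite_axon_consistency",
    "ConsistencyReport",
    "LAYER_TO_SUBTYPE",
]

#: each lobula-plate layer receives axons from exactly one subtype.
LAYER_TO_SUBTYPE = {1: "a", 2: "b", 3: "c", 4: "d"}

LAYER_ORDERS = ("posterior_first", "anterior_first")


@dataclass
class LobulaPlateFrame:
    """Anterior/posterior lobula-plate edges per proximodistal position.

    Edges are linearly interpolated between the tabulated proximodistal
    coordinates; querying outside the tabulated range is an error.
    """

    proximodistal: np.ndarray
    posterior_edge: np.ndarray
    anterior_edge: np.ndarray

    def __post_init__(self) -> None:
        self.proximodistal = np.asarray(self.proximodistal, float)
        self.posterior_edge = np.asarray(self.posterior_edge, float)
        self.anterior_edge = np.asarray(self.anterior_edge, float)
        n = len(self.proximodistal)
        if n < 2 or len(self.posterior_edge) != n or len(self.anterior_edge) != n:
            raise ValueError("frame needs >= 2 rows of equal length")
        if np.any(np.diff(self.proximodistal) <= 0):
            raise ValueError("proximodistal coordinates must be strictly increasing")
        if np.any(self.anterior_edge == self.posterior_edge):
            raise ValueError("anterior and posterior edges must differ everywhere")

    @classmethod
    def rectangle(
        cls, pd_range: Sequence[float], posterior: float, anterior: float
    ) -> "LobulaPlateFrame":
        """Rectangular frame: constant edges over ``pd_range``."""
        lo, hi = float(pd_range[0]), float(pd_range[1])
        return cls(
            proximodistal=np.array([lo, hi]),
            posterior_edge=np.array([posterior, posterior], float),
            anterior_edge=np.array([anterior, anterior], float),
        )

    @classmethod
    def from_csv(cls, path) -> "LobulaPlateFrame":
        df = pd.read_csv(path)
        return cls(
            proximodistal=df["proximodistal"].to_numpy(),
            posterior_edge=df["posterior_edge"].to_numpy(),
            anterior_edge=df["anterior_edge"].to_numpy(),
        )

    def edges_at(self, pd_coord: float) -> tuple[float, float]:
        pd_coord = float(pd_coord)
        if pd_coord < self.proximodistal[0] or pd_coord > self.proximodistal[-1]:
            raise ValueError(
                f"proximodistal coordinate {pd_coord} outside the frame range "
                f"[{self.proximodistal[0]}, {self.proximodistal[-1]}]"
            )
        post = float(np.interp(pd_coord, self.proximodistal, self.posterior_edge))
        ant = float(np.interp(pd_coord, self.proximodistal, self.anterior_edge))
        return post, ant


class RelativePosition(NamedTuple):
    """Normalised anteroposterior position, clamped to [0, 1]."""

    value: float
    out_of_bounds: bool


def relative_axon_position(reference_point, frame: LobulaPlateFrame) -> RelativePosition:
    """Normalised position of an axon reference point within the plate.

    ``reference_point`` is (proximodistal, anteroposterior). The position is
    the distance from the posterior edge divided by the local
    anteroposterior extent, so the posterior edge maps to 0 and the
    anterior edge to 1. Points beyond an edge are clamped and flagged.
    """
    pd_coord, ap_coord = float(reference_point[0]), float(reference_point[1])
    post, ant = frame.edges_at(pd_coord)
    frac = (ap_coord - post) / (ant - post)
    out = bool(frac < 0.0 or frac > 1.0)
    return RelativePosition(float(np.clip(frac, 0.0, 1.0)), out)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class AxonPositionClusterer(ClusterMixin, BaseEstimator):
    """1-D k-means over normalised axon positions with deterministic
    quantile initialisation.

    Initial centers sit at the (2i-1)/2k quantiles of the data, removing any
    seed dependence; fitted clusters are reported in ascending positional
    order. ``boundaries_`` are the midpoints between adjacent cluster means
    and define the layer bins used by :meth:`predict` (a position exactly on
    a boundary assigns to the lower cluster).
    """

    def __init__(self, n_clusters: int = 4):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        x = np.asarray(X, float).reshape(-1)
        k = self.n_clusters
        if np.unique(x).size < k:
            raise ValueError(f"need at least {k} distinct position values")
        quantiles = (2 * np.arange(1, k + 1) - 1) / (2 * k)
        init = np.quantile(x, quantiles).reshape(-1, 1)
        km = KMeans(n_clusters=k, init=init, n_init=1, random_state=0)
        raw = km.fit_predict(x.reshape(-1, 1))
        order = np.argsort(km.cluster_centers_.ravel())
        relabel = np.empty(k, dtype=int)
        relabel[order] = np.arange(k)
        self.cluster_centers_ = np.sort(km.cluster_centers_.ravel())
        self.labels_ = relabel[raw]
        self.boundaries_ = (self.cluster_centers_[:-1] + self.cluster_centers_[1:]) / 2.0
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "boundaries_")
        x = np.asarray(X, float).reshape(-1)
        # side="left": a position exactly on a boundary goes to the lower bin
        return np.searchsorted(self.boundaries_, x, side="left")


def cluster_axon_positions(positions, k: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Cluster positions into ``k`` ascending groups.

    Returns (assignments in ascending positional order, the k-1 ordered
    boundaries between adjacent cluster means).
    """
    clu = AxonPositionClusterer(n_clusters=k).fit(positions)
    return clu.labels_, clu.boundaries_


# ---------------------------------------------------------------------------
# subtype calls
# ---------------------------------------------------------------------------

@dataclass
class AxonPositionRecord:
    """Layer and subtype call for one neuron's axon position."""

    neuron_id: Optional[str]
    raw_coordinate: Optional[tuple]
    relative_position: float
    layer_call: int
    subtype_call: str
    out_of_bounds: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.relative_position <= 1.0):
            raise ValueError("relative_position must lie in [0, 1]")
        if LAYER_TO_SUBTYPE.get(self.layer_call) != self.subtype_call:
            raise ValueError(
                f"layer {self.layer_call} and subtype {self.subtype_call!r} "
                "violate the layer<->subtype map"
            )


def classify_subtype_from_axon(
    position: float,
    boundaries,
    layer_order: str = "posterior_first",
    neuron_id: Optional[str] = None,
    raw_coordinate=None,
    out_of_bounds: bool = False,
) -> AxonPositionRecord:
    """Call the subtype from a normalised axon position.

    The position is binned by the three ordered boundaries into four
    positional groups (an exact boundary hit assigns to the lower group);
    groups map to layers 1-4 in ``layer_order`` direction and layers to
    subtypes via the fixed layer<->subtype table.
    """
    b = np.asarray(boundaries, float).reshape(-1)
    if b.size != 3:
        raise ValueError("boundaries must have length 3")
    if np.any(np.diff(b) < 0):
        raise ValueError("boundaries must be sorted ascending")
    if layer_order not in LAYER_ORDERS:
        raise ValueError(f"layer_order must be one of {LAYER_ORDERS}")
    group = int(np.searchsorted(b, float(position), side="left"))
    layer = group + 1 if layer_order == "posterior_first" else 4 - group
    return AxonPositionRecord(
        neuron_id=neuron_id,
        raw_coordinate=raw_coordinate,
        relative_position=float(position),
        layer_call=layer,
        subtype_call=LAYER_TO_SUBTYPE[layer],
        out_of_bounds=out_of_bounds,
    )


# ---------------------------------------------------------------------------
# dendrite / axon agreement
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyReport:
    """Agreement between dendrite-based and axon-based subtype calls."""

    per_neuron: pd.DataFrame
    agreement: float


def dendrite_axon_consistency(
    dendrite_calls: Sequence[str],
    axon_calls: Sequence[str],
    neuron_ids: Optional[Sequence] = None,
) -> ConsistencyReport:
    """Per-neuron agreement flags and the population agreement fraction."""
    d = np.asarray(dendrite_calls)
    a = np.asarray(axon_calls)
    if d.shape != a.shape:
        raise ValueError("call vectors must have equal length")
    agree = d == a
    if neuron_ids is None:
        neuron_ids = list(range(len(d)))
    per = pd.DataFrame(
        {
            "neuron_id": list(neuron_ids),
            "dendrite_call": d,
            "axon_call": a,
            "agree": agree,
        }
    )
    return ConsistencyReport(per_neuron=per, agreement=float(agree.mean()) if len(d) else float("nan"))
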