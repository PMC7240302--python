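"""Neuron skeletons and SWC input/output.

A :class:`NeuronSkeleton` is a labelled tree of 3-D nodes with dendrite and
axon compartments plus two designated reference nodes: the dendrite's first
branching point (the origin of orientation vectors) and an axon reference
node (the point whose position within the lobula plate is normalised).

SWC conventions: 1-based node ids; structure codes 1 = soma, 2 = axon,
3 = dendrite; the root's parent is -1. The designated reference nodes are
persisted as comment headers so a round trip through SWC is lossless, while
plain 7-column SWC from other tools still parses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

SWC_SOMA = 1
SWC_AXON = 2
SWC_DENDRITE = 3

_COLUMNS = ["node_id", "structure", "x", "y", "z", "radius", "parent_id"]


class SkeletonError(ValueError):
    """Raised for malformed skeletons or missing compartments."""


@dataclass
class NeuronSkeleton:
    """Labelled tree of 3-D nodes with compartment annotations.

    Attributes
    ----------
    nodes : pandas.DataFrame
        Columns ``node_id, structure, x, y, z, radius, parent_id``.
    dendrite_branch_node : int, optional
        Designated first branching point of the dendrite (node id).
    axon_reference_node : int, optional
        Designated axon reference node (node id); its position is used for
        lobula-plate layer calls.
    metadata : dict
        Free-form annotations (neuron id, units, axon reference convention).
    """

    nodes: pd.DataFrame
    dendrite_branch_node: Optional[int] = None
    axon_reference_node: Optional[int] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.nodes.columns]
        if missing:
            raise SkeletonError(f"missing node columns: {missing}")
        if self.nodes["node_id"].duplicated().any():
            raise SkeletonError("duplicate node ids")

    # ------------------------------------------------------------------
    def _compartment(self, code: int) -> pd.DataFrame:
        return self.nodes[self.nodes["structure"] == code]

    @property
    def dendrite_nodes(self) -> pd.DataFrame:
        return self._compartment(SWC_DENDRITE)

    @property
    def axon_nodes(self) -> pd.DataFrame:
        return self._compartment(SWC_AXON)

    def has_dendrite(self) -> bool:
        return not self.dendrite_nodes.empty

    def node_coord(self, node_id: int) -> np.ndarray:
        row = self.nodes[self.nodes["node_id"] == node_id]
        if row.empty:
            raise SkeletonError(f"no node with id {node_id}")
        return row[["x", "y", "z"]].to_numpy(float)[0]

    def dendrite_points(self) -> np.ndarray:
        """(N, 3) coordinates of all dendrite nodes."""
        return self.dendrite_nodes[["x", "y", "z"]].to_numpy(float)

    def axon_reference_point(self) -> np.ndarray:
        if self.axon_reference_node is None:
            raise SkeletonError("skeleton has no designated axon reference node")
        return self.node_coord(self.axon_reference_node)

    # ------------------------------------------------------------------
    def _edge_table(self, structure: Optional[int] = None) -> pd.DataFrame:
        child = self.nodes[self.nodes["parent_id"] != -1]
        if structure is not None:
            child = child[child["structure"] == structure]
        return child.merge(
            self.nodes[["node_id", "x", "y", "z", "radius"]],
            left_on="parent_id",
            right_on="node_id",
            suffixes=("", "_p"),
        )

    def segments(self, structure: Optional[int] = None) -> list:
        """(parent_xyz, child_xyz, parent_radius, child_radius) per edge."""
        e = self._edge_table(structure)
        parents = e[["x_p", "y_p", "z_p"]].to_numpy(float)
        childs = e[["x", "y", "z"]].to_numpy(float)
        return [
            (parents[i], childs[i], float(e["radius_p"].iat[i]), float(e["radius"].iat[i]))
            for i in range(len(e))
        ]

    def dendrite_cable_volume(self) -> float:
        """Total dendrite cable volume, modelling each edge as a truncated
        cone (frustum) between parent and child radii."""
        e = self._edge_table(structure=SWC_DENDRITE)
        if e.empty:
            return 0.0
        d = e[["x", "y", "z"]].to_numpy(float) - e[["x_p", "y_p", "z_p"]].to_numpy(float)
        length = np.linalg.norm(d, axis=1)
        rp = e["radius_p"].to_numpy(float)
        rc = e["radius"].to_numpy(float)
        return float((np.pi * length * (rp * rp + rp * rc + rc * rc) / 3.0).sum())

    # ------------------------------------------------------------------
    def to_swc(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# SWC skeleton (1=soma 2=axon 3=dendrite)\n")
            if self.dendrite_branch_node is not None:
                fh.write(f"# dendrite_branch_node {int(self.dendrite_branch_node)}\n")
            if self.axon_reference_node is not None:
                fh.write(f"# axon_reference_node {int(self.axon_reference_node)}\n")
            for key in ("neuron_id", "units"):
                if key in self.metadata:
                    fh.write(f"# {key} {self.metadata[key]}\n")
            for _, r in self.nodes.iterrows():
                fh.write(
                    f"{int(r['node_id'])} {int(r['structure'])} "
                    f"{r['x']:.6f} {r['y']:.6f} {r['z']:.6f} "
                    f"{r['radius']:.6f} {int(r['parent_id'])}\n"
                )

    @classmethod
    def from_swc(cls, path) -> "NeuronSkeleton":
        rows = []
        dendrite_branch = axon_ref = None
        metadata: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    parts = line[1:].split()
                    if len(parts) == 2 and parts[0] == "dendrite_branch_node":
                        dendrite_branch = int(parts[1])
                    elif len(parts) == 2 and parts[0] == "axon_reference_node":
                        axon_ref = int(parts[1])
                    elif len(parts) == 2 and parts[0] in ("neuron_id", "units"):
                        metadata[parts[0]] = parts[1]
                    continue
                fields = line.split()
                if len(fields) != 7:
                    raise SkeletonError(f"malformed SWC line: {line!r}")
                rows.append(
                    [
                        int(fields[0]),
                        int(fields[1]),
                        float(fields[2]),
                        float(fields[3]),
                        float(fields[4]),
                        float(fields[5]),
                        int(fields[6]),
                    ]
                )
        if not rows:
            raise SkeletonError(f"no nodes in SWC file {path}")
        nodes = pd.DataFrame(rows, columns=_COLUMNS)
        return cls(
            nodes=nodes,
            dendrite_branch_node=dendrite_branch,
            axon_reference_node=axon_ref,
            metadata=metadata,
        )
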