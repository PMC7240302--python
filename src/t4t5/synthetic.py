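"""Synthetic T4/T5 neurons, images, expression matrices and cell-body tables.

Every generator draws from a :class:`numpy.random.Generator` seeded
deterministically from a single integer, and returns ground-truth labels
alongside the data, so the downstream morphometry, axon-geometry and
expression analyses can be exercised end to end without any external data.

What is emulated
----------------
* Four dendrite orientations ~90 degrees apart (opposite-direction subtype
  pairs a/b and c/d), as von Mises-distributed branch directions around a
  subtype-specific generating angle.
* Stage-dependent arbor size: branch counts follow a piecewise-linear
  profile that grows from 24 to a 72 h APF maximum and is pruned into
  adulthood.
* Four axon-position clusters on the normalised [0, 1] anteroposterior axis
  of a rectangular lobula-plate frame (one layer per subtype).
* Neuroblast clones of four neurons (2 T4 + 2 T5, subtype pairs {a,b} or
  {c,d}) sharing a retinotopic position.
* An eight-cluster (T4/T5 x a-d) single-cell count matrix with a marker
  program: a T4-vs-T5 type marker, a,b / c,d / b,c subtype-pair markers,
  a single-subtype marker, late-only and switching genes, housekeeping,
  mitochondrial-like and heat-shock-like gene groups, and engineered
  QC-failing cells.
* Cell-body fluorescence tables in which b,c cell bodies carry a configured
  enrichment of the Grain channel over a background shared by a,d and
  Lim1-negative cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .codes import decode_tf_code, encode_subtype, perturb_code
from .config import CELL_TYPES, SUBTYPES, SimulationConfig
from .skeleton import SWC_AXON, SWC_DENDRITE, SWC_SOMA, NeuronSkeleton, SkeletonError

__all__ = [
    "GroundTruthRecord",
    "Population",
    "generate_neuron",
    "rasterize_dendrite",
    "generate_population",
    "generate_expression",
    "generate_cellbody_table",
    "sample_counts",
    "write_expression",
    "read_expression",
]


@dataclass
class GroundTruthRecord:
    """Ground truth for one simulated neuron."""

    neuron_id: str
    cell_type: str  # T4 | T5
    subtype: str  # original subtype a-d
    stage: object
    clone_id: str
    retinotopic_position: tuple
    perturbation: str = "none"
    realized_subtype: str = ""  # subtype after any TF-code perturbation
    generating_angle: float = float("nan")
    n_branches: int = 0

    def __post_init__(self) -> None:
        if not self.realized_subtype:
            self.realized_subtype = self.subtype


def _rng(seed, *key: int) -> np.random.Generator:
    """Deterministic child generator derived from a global seed.

    ``seed`` may be an int or a sequence of ints (an already-derived key).
    """
    if seed is None:
        seed = 0
    base = [int(s) for s in seed] if isinstance(seed, (list, tuple)) else [int(seed)]
    return np.random.default_rng(base + [int(k) for k in key])


# ---------------------------------------------------------------------------
# neurons
# ---------------------------------------------------------------------------

def branch_angles(
    rng: np.random.Generator, mean_deg: float, kappa: float, n: int
) -> np.ndarray:
    """Draw ``n`` branch directions (degrees in [0, 360)).

    von Mises around ``mean_deg`` with concentration ``kappa``; ``kappa=0``
    is uniform on the circle and ``kappa=inf`` collapses onto the mean.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if math.isinf(kappa):
        return np.full(n, mean_deg % 360.0)
    if kappa == 0:
        return rng.uniform(0.0, 360.0, size=n)
    ang = np.degrees(rng.vonmises(np.radians(mean_deg), kappa, size=n))
    return ang % 360.0


def generate_neuron(
    subtype: str,
    stage,
    config: SimulationConfig,
    seed: Optional[int] = None,
    *,
    cell_type: str = "T4",
    neuron_id: str = "n0",
    soma: Sequence[float] = (20.0, -5.0, 0.0),
) -> tuple[NeuronSkeleton, dict]:
    """Simulate one T4/T5 neuron skeleton.

    The dendrite consists of branch segments emanating from a designated
    first-branch node, with directions drawn von Mises around the subtype's
    generating angle; the branch count scales with developmental stage. The
    axon runs from the soma into the lobula-plate frame; its terminal (the
    designated axon reference node) sits at a normalised anteroposterior
    position drawn Normal(layer_center[subtype], layer_sd).

    Returns the skeleton and an info dict with the generating parameters.
    """
    if subtype not in SUBTYPES:
        raise ValueError(f"unknown subtype: {subtype!r}")
    config.require_stage(stage)
    if cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell type: {cell_type!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    mean_angle = config.angle_of(subtype)
    profile = float(config.growth_profile[stage])
    n_branches = max(8, int(round(config.branch_points_max * profile)))

    soma = np.asarray(soma, float)
    rows = []
    rows.append([1, SWC_SOMA, *soma, 2.0, -1])

    # axon: straight path from the soma into the plate, terminal = reference
    p = rng.normal(config.layer_center_of(subtype), config.layer_sd)
    terminal = np.array([soma[0], p * config.plate_extent, 10.0])
    n_axon = 4
    prev = 1
    nid = 2
    for i in range(1, n_axon + 1):
        frac = i / n_axon
        xyz = soma + frac * (terminal - soma)
        rows.append([nid, SWC_AXON, *xyz, 0.5, prev])
        prev = nid
        nid += 1
    axon_reference = prev

    # dendrite: trunk to the first branch point, then radial branch segments
    branch_pt = soma + np.array([2.0, 0.0, 0.0])
    rows.append([nid, SWC_DENDRITE, *branch_pt, 0.6, 1])
    branch_node = nid
    nid += 1
    angles = branch_angles(rng, mean_angle, config.kappa, n_branches)
    lengths = config.branch_length * rng.uniform(0.5, 1.0, size=n_branches)
    for ang, length in zip(angles, lengths):
        tip = branch_pt + length * np.array(
            [math.cos(math.radians(ang)), math.sin(math.radians(ang)), 0.0]
        )
        rows.append([nid, SWC_DENDRITE, *tip, 0.3, branch_node])
        nid += 1

    nodes = pd.DataFrame(
        rows, columns=["node_id", "structure", "x", "y", "z", "radius", "parent_id"]
    )
    skel = NeuronSkeleton(
        nodes=nodes,
        dendrite_branch_node=branch_node,
        axon_reference_node=axon_reference,
        metadata={
            "neuron_id": neuron_id,
            "units": "um",
            "axon_reference_convention": "terminal",
        },
    )
    info = {
        "subtype": subtype,
        "cell_type": cell_type,
        "stage": stage,
        "generating_angle": mean_angle,
        "n_branches": n_branches,
        "axon_position_true": float(p),
        "branch_angles": angles,
    }
    return skel, info


def rasterize_dendrite(
    skeleton: NeuronSkeleton,
    pixel_size: float = 0.5,
    noise_level: float = 0.0,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Render the dendrite's 2-D projection as a 16-bit grayscale image.

    Dendrite segments (projected onto the x-y plane, +y mapped to -row so
    angles stay counterclockwise from +x) are drawn at a fixed foreground
    level; Gaussian background noise of standard deviation ``noise_level``
    is added. Returns the image and the (row, col) pixel of the dendrite's
    first branching point.
    """
    from skimage.draw import line as skline

    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    segs = skeleton.segments(structure=SWC_DENDRITE)
    if not segs:
        raise SkeletonError("skeleton has no dendrite segment to rasterize")

    pts = np.array([q for seg in segs for q in (seg[0][:2], seg[1][:2])])
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    margin = 2
    width = int(np.ceil((xmax - xmin) / pixel_size)) + 2 * margin + 1
    height = int(np.ceil((ymax - ymin) / pixel_size)) + 2 * margin + 1

    def to_px(xy):
        col = int(round((xy[0] - xmin) / pixel_size)) + margin
        row = int(round((ymax - xy[1]) / pixel_size)) + margin
        return row, col

    img = np.zeros((height, width), dtype=np.float64)
    foreground = 1000.0
    for p0, p1, _, _ in segs:
        r0, c0 = to_px(p0[:2])
        r1, c1 = to_px(p1[:2])
        rr, cc = skline(r0, c0, r1, c1)
        img[rr, cc] = foreground

    if noise_level > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_level, size=img.shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    if skeleton.dendrite_branch_node is not None:
        bp = skeleton.node_coord(skeleton.dendrite_branch_node)[:2]
    else:
        bp = segs[0][0][:2]
    return img, to_px(bp)


# ---------------------------------------------------------------------------
# populations and clones
# ---------------------------------------------------------------------------

#: subtype composition of the two neuroblast clone flavours: each clone is
#: 2 T4 + 2 T5 sharing one retinotopic position, with subtype pair {a,b}
#: or {c,d}.
CLONE_FLAVOURS = {
    "ab": [("T4", "a"), ("T5", "a"), ("T4", "b"), ("T5", "b")],
    "cd": [("T4", "c"), ("T5", "c"), ("T4", "d"), ("T5", "d")],
}


@dataclass
class Population:
    """A simulated population: skeletons plus a ground-truth table."""

    skeletons: dict
    ground_truth: pd.DataFrame
    config: SimulationConfig
    seed: Optional[int] = None
    perturbation: str = "none"

    def __len__(self) -> int:
        return len(self.skeletons)

    def write(self, outdir, images: bool = False, pixel_size: float = 0.5,
              noise_level: float = 0.0) -> None:
        """Write SWC skeletons, the ground-truth CSV, a parameter YAML and
        (optionally) rasterised dendrite TIFFs."""
        import tifffile

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        swc_dir = outdir / "swc"
        swc_dir.mkdir(exist_ok=True)
        for nid, skel in self.skeletons.items():
            skel.to_swc(swc_dir / f"{nid}.swc")
        self.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
        self.config.to_yaml(outdir / "params.yaml")
        if images:
            img_dir = outdir / "images"
            img_dir.mkdir(exist_ok=True)
            for k, (nid, skel) in enumerate(self.skeletons.items()):
                img, bp = rasterize_dendrite(
                    skel, pixel_size=pixel_size, noise_level=noise_level,
                    seed=None if self.seed is None else _rng(self.seed, 7, k),
                )
                tifffile.imwrite(img_dir / f"{nid}.tif", img)
                with open(img_dir / f"{nid}.branchpoint.txt", "w") as fh:
                    fh.write(f"{bp[0]} {bp[1]}\n")


def generate_population(
    config: SimulationConfig,
    seed: Optional[int] = None,
    perturbation: str = "none",
    stages: Optional[Sequence] = None,
    conversion_penetrance: float = 1.0,
) -> Population:
    """Simulate clones of T4/T5 neurons across stages.

    Per stage, ``n_neurons_per_subtype`` neurons of each subtype and cell
    type are produced, organised into 4-neuron clones (2 T4 + 2 T5, subtype
    pairs {a,b} or {c,d}) sharing a retinotopic position. A TF-code
    perturbation (``overexpression`` or ``knockdown``) is applied to each
    neuron's code *before* morphogenesis: morphology follows the decoded
    (realized) subtype. ``conversion_penetrance`` < 1 leaves a random
    fraction of neurons unconverted.
    """
    if perturbation not in ("none", "overexpression", "knockdown"):
        raise ValueError(f"unknown perturbation mode: {perturbation!r}")
    if seed is None:
        seed = config.seed
    if stages is None:
        stages = list(config.stages)
    for st in stages:
        config.require_stage(st)

    clone_rng = _rng(seed, 1)
    records = []
    skeletons = {}
    counter = 0
    for stage in stages:
        for i in range(config.n_neurons_per_subtype):
            for flavour, members in CLONE_FLAVOURS.items():
                clone_id = f"s{stage}-{flavour}-{i}"
                retino = (
                    float(clone_rng.uniform(0.2, 0.8) * config.plate_length),
                    float(clone_rng.uniform(0.0, config.plate_length)),
                )
                for cell_type, subtype in members:
                    realized = subtype
                    if perturbation != "none":
                        convert = clone_rng.random() < conversion_penetrance
                        if convert:
                            realized = decode_tf_code(
                                perturb_code(encode_subtype(subtype), perturbation)
                            )
                    neuron_id = f"{cell_type}{subtype}-{clone_id}-{counter}"
                    skel, info = generate_neuron(
                        realized,
                        stage,
                        config,
                        seed=_rng(seed, 2, counter),
                        cell_type=cell_type,
                        neuron_id=neuron_id,
                        soma=(retino[0], -5.0, 0.0),
                    )
                    skeletons[neuron_id] = skel
                    records.append(
                        {
                            "neuron_id": neuron_id,
                            "cell_type": cell_type,
                            "subtype": subtype,
                            "realized_subtype": realized,
                            "stage": stage,
                            "clone_id": clone_id,
                            "retino_x": retino[0],
                            "retino_y": retino[1],
                            "perturbation": perturbation,
                            "generating_angle": info["generating_angle"],
                            "n_branches": info["n_branches"],
                            "axon_position_true": info["axon_position_true"],
                        }
                    )
                    counter += 1
    gt = pd.DataFrame.from_records(records)
    return Population(
        skeletons=skeletons,
        ground_truth=gt,
        config=config,
        seed=seed,
        perturbation=perturbation,
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def sample_counts(
    rng: np.random.Generator, mean, dispersion: float, size=None
) -> np.ndarray:
    """Negative-binomial counts with mean ``mean`` and size ``dispersion``.

    Var = mean + mean^2 / dispersion; ``dispersion=inf`` is the Poisson
    limit.
    """
    mean = np.asarray(mean, float)
    if np.isinf(dispersion):
        return rng.poisson(mean, size=size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


_CLUSTERS = [f"{t}{s}" for t in CELL_TYPES for s in SUBTYPES]


def _marker_table(config: SimulationConfig) -> pd.DataFrame:
    """Gene annotation table: category flags and generative program."""
    rows = []

    def add(name, program, tf=False, membrane=False, mito=False, hsp=False):
        rows.append(
            dict(gene=name, program=program, is_tf=tf, is_membrane=membrane,
                 is_mito_like=mito, is_hsp_like=hsp)
        )

    add("TfAP-2", "type_marker", tf=True)
    add("dac", "stable:ab", tf=True)
    add("ab", "stable:ab", tf=True)
    add("omb", "stable:cd", tf=True)
    add("pros", "stable:cd", tf=True)
    add("grain", "stable:bc", tf=True)
    add("beat-IV", "stable:bc", membrane=True)
    add("CG34353", "stable:bc", membrane=True)
    add("side-IV", "stable:b", membrane=True)
    add("zld", "late:ab", tf=True)
    add("fz2", "late:cd", membrane=True)
    add("kuz", "switch:ab>cd", membrane=True)
    add("Lac", "switch:bc>ad", membrane=True)
    for g in ("RpL32", "Act5C", "nSyb", "Gapdh1", "elav", "CadN", "Syt1", "brp"):
        add(g, "housekeeping")
    for g in ("mt:CoI", "mt:CoII", "mt:ND5"):
        add(g, "mito", mito=True)
    for g in ("Hsp26", "Hsp70Bb"):
        add(g, "hsp", hsp=True)
    add("CG99999", "rare")
    return pd.DataFrame(rows)


#: housekeeping / mito / hsp baseline means (counts per cell).
_HK_MEAN = 50.0
_MITO_MEAN = 4.0
_HSP_MEAN = 3.0
_RARE_MEAN = 1e-4


def _marked_subtypes(program: str, stage) -> frozenset:
    """Subtype set a program gene marks at ``stage`` (within each type)."""
    kind, _, spec = program.partition(":")
    if kind == "stable":
        return frozenset(spec)
    if kind == "late":
        return frozenset(spec) if stage >= 60 else frozenset()
    if kind == "switch":
        early, late = spec.split(">")
        if stage <= 36:
            return frozenset(early)
        if stage >= 60:
            return frozenset(late)
        return frozenset()  # transition stage: uniform
    return frozenset()


def _gene_mean(row, cluster: str, stage, config: SimulationConfig) -> float:
    """Expected counts of one gene in one (type, subtype) cluster."""
    on = config.nb_mean
    off = config.nb_mean / config.marker_fold
    program = row["program"]
    cell_type, subtype = cluster[:2], cluster[2]
    if program == "type_marker":
        return on if cell_type == "T4" else off
    if program == "housekeeping":
        return _HK_MEAN
    if program == "mito":
        return _MITO_MEAN
    if program == "hsp":
        return _HSP_MEAN
    if program == "rare":
        return _RARE_MEAN
    kind = program.partition(":")[0]
    marked = _marked_subtypes(program, stage)
    if not marked:
        # non-differential at this stage: late genes are uniformly off
        # before onset, switching genes sit at an intermediate level.
        return off if kind == "late" else on / 2.0
    return on if subtype in marked else off


def expected_mean_matrix(config: SimulationConfig, stage) -> pd.DataFrame:
    """(cluster x gene) expected-count matrix of the generative program."""
    var = _marker_table(config)
    data = {
        row["gene"]: [_gene_mean(row, cl, stage, config) for cl in _CLUSTERS]
        for _, row in var.iterrows()
    }
    return pd.DataFrame(data, index=_CLUSTERS)


def generate_expression(config: SimulationConfig, seed: Optional[int] = None):
    """Simulate stage-wise single-cell count matrices as one AnnData.

    Counts are negative binomial per gene per cluster around the marker
    program of :func:`expected_mean_matrix`. Per stage,
    ``qc_low_count_cells`` cells are scaled to fall below the 200-UMI floor
    and ``qc_stressed_cells`` cells carry inflated mitochondrial-like or
    heat-shock-like counts (>10% of totals); their failure mode is recorded
    in ``obs["qc_fail"]``.

    Ground truth carried in the result: ``obs`` cluster/type/subtype
    labels, ``var`` category flags, and ``uns`` entries ``marker_spec``,
    ``stable_markers``, ``expected_dynamics`` and ``marker_program``.
    """
    import anndata as ad

    if seed is None:
        seed = config.seed
    rng = _rng(seed, 3)
    var = _marker_table(config).set_index("gene")
    genes = var.index.to_list()
    mito_idx = np.where(var["is_mito_like"].to_numpy())[0]
    hsp_idx = np.where(var["is_hsp_like"].to_numpy())[0]

    blocks = []
    obs_rows = []
    for stage in config.expression_stages:
        means = expected_mean_matrix(config, stage)
        for ci, cluster in enumerate(_CLUSTERS):
            mu = means.loc[cluster].to_numpy()
            n = config.n_cells_per_cluster
            counts = sample_counts(
                rng, np.tile(mu, (n, 1)), config.nb_dispersion
            )
            blocks.append(counts)
            for j in range(n):
                obs_rows.append(
                    dict(stage=stage, cluster=cluster, cell_type=cluster[:2],
                         subtype=cluster[2], qc_fail="none")
                )
        # engineered QC failures, spread round-robin across clusters
        for j in range(config.qc_low_count_cells):
            cluster = _CLUSTERS[j % len(_CLUSTERS)]
            mu = means.loc[cluster].to_numpy() * 0.1
            blocks.append(sample_counts(rng, mu, config.nb_dispersion)[None, :])
            obs_rows.append(
                dict(stage=stage, cluster=cluster, cell_type=cluster[:2],
                     subtype=cluster[2], qc_fail="low_count")
            )
        for j in range(config.qc_stressed_cells):
            cluster = _CLUSTERS[(j + 3) % len(_CLUSTERS)]
            mu = means.loc[cluster].to_numpy().copy()
            if j % 2 == 0:
                mu[mito_idx] = _HK_MEAN * 2  # mito fraction >> 10%
                fail = "mito"
            else:
                mu[hsp_idx] = _HK_MEAN * 3  # hsp fraction >> 10%
                fail = "hsp"
            blocks.append(sample_counts(rng, mu, config.nb_dispersion)[None, :])
            obs_rows.append(
                dict(stage=stage, cluster=cluster, cell_type=cluster[:2],
                     subtype=cluster[2], qc_fail=fail)
            )

    X = np.vstack(blocks).astype(np.int64)
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell{k}" for k in range(len(obs))]
    adata = ad.AnnData(X=X, obs=obs, var=var.copy())
    adata.obs["total_counts"] = X.sum(axis=1)
    adata.obs["detected_genes"] = (X > 0).sum(axis=1)

    stable = var.index[var["program"].str.startswith("stable")].to_list()
    stable = ["TfAP-2"] + stable  # the type marker is differential at all stages
    dynamics = {}
    program_truth = {}
    for gene, row in var.iterrows():
        prog = row["program"]
        kind = prog.partition(":")[0]
        if kind == "type_marker":
            dynamics[gene] = "type_specific"
        elif kind == "stable":
            dynamics[gene] = "stable_subtype_specific"
        elif kind == "late":
            dynamics[gene] = "late_only"
        elif kind == "switch":
            dynamics[gene] = "switching"
        else:
            continue
        program_truth[gene] = {
            str(st): sorted(_marked_subtypes(prog, st))
            for st in config.expression_stages
        }
    adata.uns["marker_spec"] = {
        "type_marker": "TfAP-2",
        "ab_marker": "dac",
        "cd_marker": "omb",
        "bc_marker": "grain",
    }
    adata.uns["stable_markers"] = stable
    adata.uns["expected_dynamics"] = dynamics
    adata.uns["marker_program"] = program_truth
    adata.uns["config"] = config.to_dict()
    return adata


def write_expression(adata, outdir) -> None:
    """Write counts as MatrixMarket (genes x cells, 1-based) with gene and
    cell CSV sidecars and a YAML parameter echo."""
    import scipy.io
    import scipy.sparse as sp
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if sp.issparse(X):
        X = X.toarray()
    scipy.io.mmwrite(
        str(outdir / "matrix.mtx"), sp.csr_matrix(X.T.astype(np.int64)),
        field="integer",
    )
    adata.var.reset_index(names="gene").to_csv(outdir / "genes.csv", index=False)
    adata.obs.reset_index(names="cell_id").to_csv(outdir / "cells.csv", index=False)
    params = {k: adata.uns[k] for k in ("marker_spec", "config") if k in adata.uns}
    with open(outdir / "params.yaml", "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=False)


def read_expression(outdir):
    """Read a matrix written by :func:`write_expression` back into AnnData."""
    import anndata as ad
    import scipy.io

    outdir = Path(outdir)
    X = np.asarray(scipy.io.mmread(str(outdir / "matrix.mtx")).todense()).T
    var = pd.read_csv(outdir / "genes.csv").set_index("gene")
    obs = pd.read_csv(outdir / "cells.csv").set_index("cell_id")
    return ad.AnnData(X=X.astype(np.int64), obs=obs, var=var)


# ---------------------------------------------------------------------------
# cell-body fluorescence
# ---------------------------------------------------------------------------

def generate_cellbody_table(
    config: SimulationConfig, seed: Optional[int] = None
) -> pd.DataFrame:
    """Simulate per-optic-lobe cell-body fluorescence measurements.

    Each lobe contributes ``cells_per_lobe`` Lim1-positive T4/T5 cell bodies
    (split evenly over subtypes) and ``n_background_per_lobe`` Lim1-negative
    background cell bodies. The Grain-channel intensity of b and c cells is
    ``grain_enrichment`` times the lobe's background level; a, d and
    background cells share the background distribution. Marker columns:
    ``lim1_positive`` (any T4/T5), ``dac_positive`` (subtypes a, b),
    ``gal4_positive`` (the b,c reporter).
    """
    if seed is None:
        seed = config.seed
    rng = _rng(seed, 4)
    rows = []
    per_subtype = max(1, config.cells_per_lobe // 4)
    for lobe in range(config.n_lobes):
        base = 100.0 * rng.uniform(0.8, 1.2)

        def intensity(enrich=1.0):
            noise = rng.normal(1.0, config.intensity_cv) if config.intensity_cv > 0 else 1.0
            return base * enrich * max(noise, 0.05)

        for subtype in SUBTYPES:
            enrich = config.grain_enrichment if subtype in ("b", "c") else 1.0
            for _ in range(per_subtype):
                rows.append(
                    dict(
                        lobe_id=f"lobe{lobe}",
                        lim1_positive=True,
                        dac_positive=subtype in ("a", "b"),
                        gal4_positive=subtype in ("b", "c"),
                        subtype=subtype,
                        mean_intensity=intensity(enrich),
                    )
                )
        for _ in range(config.n_background_per_lobe):
            rows.append(
                dict(
                    lobe_id=f"lobe{lobe}",
                    lim1_positive=False,
                    dac_positive=False,
                    gal4_positive=False,
                    subtype="",
                    mean_intensity=intensity(),
                )
            )
    return pd.DataFrame(rows)
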