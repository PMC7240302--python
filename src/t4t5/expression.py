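"""Expression-side analyses: QC, normalisation, threshold-based differential
expression, marker-driven cluster identity, expression dynamics and the
Grain cell-body enrichment score.

All operations take an :class:`anndata.AnnData` of raw counts (cells x
genes) with boolean gene-category flags (``is_mito_like``, ``is_hsp_like``)
in ``var``.

Filtering rules
---------------
* QC: cells need >= 200 total counts and <= 10% mitochondrial-like and
  <= 10% heat-shock-like counts; genes must be detected in >= 3 cells.
* Differential expression between two clusters is threshold-based, not a
  significance test: a gene passes for cluster A over cluster B iff its
  detection fraction in A is >= 0.5, the fraction difference (A - B) is
  >= 0.5, and the fold change of mean normalised expression (with
  pseudocount 0.01) is >= 2. The twofold requirement follows the plain
  "twofold change" reading; threshold and pseudocount are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .codes import TFCode, encode_subtype
from .config import SUBTYPES

__all__ = [
    "qc_filter",
    "normalize_counts",
    "detection_fraction",
    "DEGRecord",
    "pairwise_deg",
    "stage_consistent_degs",
    "StageConsistency",
    "assign_cluster_identity",
    "NonSeparableMarkerError",
    "StageStatus",
    "categorize_dynamics",
    "grain_score",
    "codes_from_cluster_means",
]

NORMALIZED_LAYER = "normalized"
LOG_LAYER = "lognorm"


def _dense(X) -> np.ndarray:
    import scipy.sparse as sp

    if sp.issparse(X):
        return np.asarray(X.todense())
    return np.asarray(X)


def _category_mask(adata, flag: str, prefixes: tuple) -> np.ndarray:
    """Boolean gene mask from a var flag, falling back to name prefixes."""
    if flag in adata.var.columns:
        return adata.var[flag].to_numpy(bool)
    names = adata.var_names.astype(str)
    return np.array([n.startswith(prefixes) for n in names])


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(
    adata,
    min_counts: int = 200,
    min_cells: int = 3,
    max_mito_frac: float = 0.10,
    max_hsp_frac: float = 0.10,
):
    """Remove low-quality cells and rarely detected genes.

    Cells are filtered first (total counts below ``min_counts``;
    mitochondrial-like or heat-shock-like fraction above the caps), then
    genes detected (count > 0) in fewer than ``min_cells`` of the surviving
    cells. Both passes are recomputed on the surviving submatrix and
    repeated to a fixpoint, so the output never contains a violating entity
    and re-filtering it is a no-op. Returns the filtered copy and a report
    listing every removal with its reason.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty expression matrix")
    out = adata.copy()
    removals = []
    mito = _category_mask(out, "is_mito_like", ("mt:",))
    hsp = _category_mask(out, "is_hsp_like", ("Hsp",))
    round_no = 0
    while True:
        round_no += 1
        X = _dense(out.X)
        totals = X.sum(axis=1)
        mito_frac = np.divide(
            X[:, mito].sum(axis=1), totals, out=np.zeros_like(totals, float),
            where=totals > 0,
        )
        hsp_frac = np.divide(
            X[:, hsp].sum(axis=1), totals, out=np.zeros_like(totals, float),
            where=totals > 0,
        )
        bad_low = totals < min_counts
        bad_mito = mito_frac > max_mito_frac
        bad_hsp = hsp_frac > max_hsp_frac
        bad_cell = bad_low | bad_mito | bad_hsp
        for i in np.nonzero(bad_cell)[0]:
            reason = (
                "low_counts" if bad_low[i]
                else "mito_fraction" if bad_mito[i]
                else "hsp_fraction"
            )
            value = (
                float(totals[i]) if bad_low[i]
                else float(mito_frac[i]) if bad_mito[i]
                else float(hsp_frac[i])
            )
            removals.append(
                dict(entity="cell", name=str(out.obs_names[i]), reason=reason,
                     value=value, round=round_no)
            )
        if bad_cell.any():
            out = out[~bad_cell].copy()
            X = _dense(out.X)
            mito = _category_mask(out, "is_mito_like", ("mt:",))
            hsp = _category_mask(out, "is_hsp_like", ("Hsp",))

        detected_in = (X > 0).sum(axis=0)
        bad_gene = detected_in < min_cells
        for j in np.nonzero(bad_gene)[0]:
            removals.append(
                dict(entity="gene", name=str(out.var_names[j]), reason="few_cells",
                     value=int(detected_in[j]), round=round_no)
            )
        if bad_gene.any():
            out = out[:, ~bad_gene].copy()
            mito = _category_mask(out, "is_mito_like", ("mt:",))
            hsp = _category_mask(out, "is_hsp_like", ("Hsp",))
        if not bad_cell.any() and not bad_gene.any():
            break
        if out.n_obs == 0 or out.n_vars == 0:
            break
    X = _dense(out.X)
    out.obs["total_counts"] = X.sum(axis=1)
    out.obs["detected_genes"] = (X > 0).sum(axis=1)
    report = pd.DataFrame(removals, columns=["entity", "name", "reason", "value", "round"])
    out.uns["qc"] = dict(
        min_counts=min_counts, min_cells=min_cells,
        max_mito_frac=max_mito_frac, max_hsp_frac=max_hsp_frac,
        n_cells_removed=int((report["entity"] == "cell").sum()),
        n_genes_removed=int((report["entity"] == "gene").sum()),
    )
    return out, report


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def normalize_counts(adata, target_sum: float = 1e4):
    """Per-cell depth normalisation to ``target_sum`` followed by log(1+x).

    Adds layers ``"normalized"`` (depth-scaled counts) and ``"lognorm"``;
    parameters are recorded in ``uns["normalization"]``. Cells with zero
    totals (which cannot occur after QC) are an error.
    """
    import scanpy as sc

    X = _dense(adata.X)
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("cannot normalise a cell with zero total counts")
    out = adata.copy()
    norm = sc.pp.normalize_total(out, target_sum=target_sum, inplace=False)["X"]
    out.layers[NORMALIZED_LAYER] = _dense(norm)
    out.layers[LOG_LAYER] = np.log1p(out.layers[NORMALIZED_LAYER])
    out.uns["normalization"] = dict(target_sum=target_sum, log="natural log1p")
    return out


def detection_fraction(adata, mask: np.ndarray, min_count: int = 1) -> np.ndarray:
    """Per-gene fraction of cells in ``mask`` with count >= ``min_count``."""
    X = _dense(adata.X)[mask]
    if X.shape[0] == 0:
        raise ValueError("empty cell group")
    return (X >= min_count).mean(axis=0)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

@dataclass
class DEGRecord:
    """One gene passing the threshold filter for one directed cluster pair."""

    gene: str
    cluster_high: str
    cluster_low: str
    frac_high: float
    frac_low: float
    fold_change: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_high <= 1.0 and 0.0 <= self.frac_low <= 1.0):
            raise ValueError("detection fractions must lie in [0, 1]")
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")


def pairwise_deg(
    adata,
    labels: Union[str, Sequence],
    cluster_a: str,
    cluster_b: str,
    min_frac: float = 0.5,
    min_diff_frac: float = 0.5,
    fc_threshold: float = 2.0,
    eps: float = 0.01,
    min_count: int = 1,
) -> pd.DataFrame:
    """Threshold-based differential expression between two clusters.

    A gene passes for ``cluster_a`` over ``cluster_b`` iff its detection
    fraction in A is >= ``min_frac``, the fraction difference (A - B) is
    >= ``min_diff_frac``, and the fold change
    ``(mean_norm_A + eps) / (mean_norm_B + eps)`` is >= ``fc_threshold``.
    Both directions are evaluated; the result is ordered by gene name, then
    direction. Requires the ``"normalized"`` layer from
    :func:`normalize_counts`.
    """
    lab = adata.obs[labels].to_numpy() if isinstance(labels, str) else np.asarray(labels)
    for c in (cluster_a, cluster_b):
        if c not in set(lab):
            raise ValueError(f"unknown cluster label: {c!r}")
    if NORMALIZED_LAYER not in adata.layers:
        raise ValueError("run normalize_counts first (missing 'normalized' layer)")
    mask_a = lab == cluster_a
    mask_b = lab == cluster_b
    frac_a = detection_fraction(adata, mask_a, min_count)
    frac_b = detection_fraction(adata, mask_b, min_count)
    norm = np.asarray(adata.layers[NORMALIZED_LAYER])
    mean_a = norm[mask_a].mean(axis=0)
    mean_b = norm[mask_b].mean(axis=0)

    records = []
    for hi, lo, f_hi, f_lo, m_hi, m_lo in (
        (cluster_a, cluster_b, frac_a, frac_b, mean_a, mean_b),
        (cluster_b, cluster_a, frac_b, frac_a, mean_b, mean_a),
    ):
        fc = (m_hi + eps) / (m_lo + eps)
        passes = (f_hi >= min_frac) & ((f_hi - f_lo) >= min_diff_frac) & (fc >= fc_threshold)
        for j in np.nonzero(passes)[0]:
            rec = DEGRecord(
                gene=str(adata.var_names[j]),
                cluster_high=hi,
                cluster_low=lo,
                frac_high=float(f_hi[j]),
                frac_low=float(f_lo[j]),
                fold_change=float(fc[j]),
            )
            records.append(rec.__dict__)
    df = pd.DataFrame(
        records,
        columns=["gene", "cluster_high", "cluster_low", "frac_high", "frac_low",
                 "fold_change"],
    )
    return df.sort_values(["gene", "cluster_high"], kind="stable").reset_index(drop=True)


@dataclass
class StageConsistency:
    """Any-stage (union) and all-stage (intersection) DEG sets."""

    union: set
    intersection: set
    stages_per_gene: dict


def stage_consistent_degs(per_stage: Mapping) -> StageConsistency:
    """Combine per-stage DEG sets.

    Returns the union (genes differential at any stage), the intersection
    (genes passing at every stage) and, per gene, the list of stages at
    which it passed.
    """
    if len(per_stage) == 0:
        raise ValueError("need at least one stage set")
    sets = {st: set(genes) for st, genes in per_stage.items()}
    union = set().union(*sets.values())
    inter = set.intersection(*sets.values())
    stages_per_gene = {
        g: [st for st, s in sets.items() if g in s] for g in sorted(union)
    }
    return StageConsistency(union=union, intersection=inter,
                            stages_per_gene=stages_per_gene)


# ---------------------------------------------------------------------------
# cluster identity
# ---------------------------------------------------------------------------

class NonSeparableMarkerError(ValueError):
    """A marker fails the midpoint separability rule; carries the marker name."""

    def __init__(self, marker: str, message: str = ""):
        self.marker = marker
        super().__init__(message or f"marker {marker!r} does not separate the groups")


def _split_by_marker(values: pd.Series, n_high: int, marker: str):
    """Split clusters into a high and a low group under the midpoint rule.

    The top ``n_high`` clusters by marker level form the high group; the
    threshold is the midpoint between the two groupwise means and every
    high value must exceed it while every low value stays below.
    """
    order = values.sort_values(ascending=False)
    high = order.index[:n_high]
    low = order.index[n_high:]
    thr = (order.loc[high].mean() + order.loc[low].mean()) / 2.0
    if not (order.loc[high].min() > thr and order.loc[low].max() < thr):
        raise NonSeparableMarkerError(marker)
    return list(high), list(low)


def assign_cluster_identity(
    cluster_means: pd.DataFrame, marker_spec: Mapping[str, str]
) -> dict:
    """Map eight clusters onto (T4|T5, subtype a-d) from marker levels.

    ``cluster_means`` is clusters x genes (mean expression per cluster);
    ``marker_spec`` names the ``type_marker`` (high in T4), the
    ``ab_marker``, ``cd_marker`` and ``bc_marker``. Each split uses the
    midpoint-of-group-means rule and errors, naming the marker, when the
    groups overlap. Returns a complete bijection cluster -> (type, subtype).
    """
    if cluster_means.shape[0] != 8:
        raise ValueError("expected exactly 8 clusters")
    for key in ("type_marker", "ab_marker", "cd_marker", "bc_marker"):
        if key not in marker_spec:
            raise ValueError(f"marker_spec missing {key!r}")
        if marker_spec[key] not in cluster_means.columns:
            raise ValueError(f"marker gene {marker_spec[key]!r} not in profiles")

    t4, t5 = _split_by_marker(
        cluster_means[marker_spec["type_marker"]], 4, marker_spec["type_marker"]
    )
    mapping = {}
    for cell_type, members in (("T4", t4), ("T5", t5)):
        sub = cluster_means.loc[members]
        ab, cd = _split_by_marker(
            sub[marker_spec["ab_marker"]], 2, marker_spec["ab_marker"]
        )
        # cross-check with the reciprocal c,d marker
        cd_check, _ = _split_by_marker(
            sub[marker_spec["cd_marker"]], 2, marker_spec["cd_marker"]
        )
        if set(cd_check) != set(cd):
            raise NonSeparableMarkerError(
                marker_spec["cd_marker"],
                f"markers {marker_spec['ab_marker']!r} and "
                f"{marker_spec['cd_marker']!r} disagree on the a,b/c,d split",
            )
        b, a = _split_by_marker(
            sub.loc[ab, marker_spec["bc_marker"]], 1, marker_spec["bc_marker"]
        )
        c, d = _split_by_marker(
            sub.loc[cd, marker_spec["bc_marker"]], 1, marker_spec["bc_marker"]
        )
        for cluster, subtype in (
            (a[0], "a"), (b[0], "b"), (c[0], "c"), (d[0], "d")
        ):
            mapping[cluster] = (cell_type, subtype)
    return mapping


def codes_from_cluster_means(
    cluster_means: pd.DataFrame, marker_spec: Mapping[str, str]
) -> dict:
    """TF code per cluster, derived from expression by the midpoint rule."""
    identity = assign_cluster_identity(cluster_means, marker_spec)
    return {cl: encode_subtype(sub) for cl, (_, sub) in identity.items()}


# ---------------------------------------------------------------------------
# expression dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageStatus:
    """Differential-expression status of one gene at one stage."""

    t4_subtypes: frozenset = frozenset()
    t5_subtypes: frozenset = frozenset()
    type_level: bool = False


REQUIRED_DYNAMICS_STAGES = (36, 48, 60, 72)
DYNAMICS_CATEGORIES = (
    "type_specific", "stable_subtype_specific", "late_only", "switching"
)


def _as_status(value) -> StageStatus:
    if isinstance(value, StageStatus):
        return value
    s = frozenset(value)
    return StageStatus(t4_subtypes=s, t5_subtypes=s)


def categorize_dynamics(per_stage: Mapping) -> str:
    """Assign one of four expression-dynamics categories to a gene.

    ``per_stage`` maps each numeric stage (hours APF; must cover 36-72) to
    either a set of marked subtypes (shared by T4 and T5) or a
    :class:`StageStatus` with per-type sets and a type-level flag.

    Categories: ``type_specific`` (differential only between the T4 and T5
    groups, or subtype-specific in only one type); ``late_only``
    (subtype-differential exclusively at stages >= 60); ``switching`` (the
    marked subtype set changes between differential stages — including
    transient single-early-stage patterns); ``stable_subtype_specific``
    (a constant subtype set at >= 2 consecutive stages).
    """
    stages = sorted(per_stage)
    if not set(REQUIRED_DYNAMICS_STAGES) <= set(stages):
        missing = sorted(set(REQUIRED_DYNAMICS_STAGES) - set(stages))
        raise ValueError(f"dynamics need stages {missing}")
    status = {st: _as_status(per_stage[st]) for st in stages}

    any_type_level = any(s.type_level for s in status.values())
    t4_any = any(s.t4_subtypes for s in status.values())
    t5_any = any(s.t5_subtypes for s in status.values())
    if not t4_any and not t5_any:
        if any_type_level:
            return "type_specific"
        raise ValueError("gene is never differential; no category applies")
    if t4_any != t5_any:  # subtype-specific in only one of the two types
        return "type_specific"

    diff_stages = [
        st for st in stages if status[st].t4_subtypes or status[st].t5_subtypes
    ]
    if all(st >= 60 for st in diff_stages):
        return "late_only"
    patterns = [(status[st].t4_subtypes, status[st].t5_subtypes) for st in diff_stages]
    if any(p != patterns[0] for p in patterns[1:]):
        return "switching"
    # constant pattern: stable if it spans >= 2 consecutive stages
    idx = [stages.index(st) for st in diff_stages]
    consecutive = any(j - i == 1 for i, j in zip(idx, idx[1:]))
    if consecutive:
        return "stable_subtype_specific"
    return "switching"


# ---------------------------------------------------------------------------
# Grain cell-body enrichment
# ---------------------------------------------------------------------------

def _subtype_from_markers(row) -> str:
    # Lim1 marks T4/T5; Dac splits a,b from c,d; the b,c reporter (Gal4)
    # splits b from a and c from d.
    if row["dac_positive"]:
        return "b" if row["gal4_positive"] else "a"
    return "c" if row["gal4_positive"] else "d"


def grain_score(
    table: pd.DataFrame, groupby: str = "lobe_id", min_background: int = 10
) -> pd.DataFrame:
    """Grain-channel enrichment per subtype and optic lobe.

    For each lobe, the mean intensity of each subtype's cell bodies is
    divided by the mean intensity of that lobe's Lim1-negative background
    cell bodies (at least ten are required). Subtypes are read from the
    marker columns (Lim1, Dac, the b,c reporter), not from any ground-truth
    column. The score is invariant to global intensity rescaling.
    """
    required = {"mean_intensity", "lim1_positive", "dac_positive", "gal4_positive"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    groups = table.groupby(groupby) if groupby in table.columns else [("all", table)]
    rows = []
    for lobe, df in groups:
        background = df[~df["lim1_positive"].astype(bool)]
        if len(background) < min_background:
            raise ValueError(
                f"group {lobe!r} has {len(background)} background cell bodies; "
                f"need >= {min_background}"
            )
        bg_mean = background["mean_intensity"].mean()
        t4t5 = df[df["lim1_positive"].astype(bool)].copy()
        t4t5["called_subtype"] = t4t5.apply(_subtype_from_markers, axis=1)
        for subtype in SUBTYPES:
            sub = t4t5[t4t5["called_subtype"] == subtype]
            if sub.empty:
                raise ValueError(f"group {lobe!r} has no subtype-{subtype} cell body")
            rows.append(
                dict(
                    group=lobe,
                    subtype=subtype,
                    score=float(sub["mean_intensity"].mean() / bg_mean),
                    n_cells=int(len(sub)),
                    n_background=int(len(background)),
                )
            )
    return pd.DataFrame(rows)
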