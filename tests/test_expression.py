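"""QC, normalisation, threshold DEG, identity, dynamics and the Grain score."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from t4t5 import synthetic as syn
from t4t5.config import SimulationConfig
from t4t5.expression import (
    NonSeparableMarkerError,
    StageStatus,
    assign_cluster_identity,
    categorize_dynamics,
    detection_fraction,
    grain_score,
    normalize_counts,
    pairwise_deg,
    qc_filter,
    stage_consistent_degs,
)

MARKER_SPEC = {
    "type_marker": "TfAP-2",
    "ab_marker": "dac",
    "cd_marker": "omb",
    "bc_marker": "grain",
}


def toy_adata(X, genes=None, mito=None, hsp=None, clusters=None):
    X = np.asarray(X)
    genes = genes or [f"g{j}" for j in range(X.shape[1])]
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["is_mito_like"] = [g in (mito or []) for g in genes]
    var["is_hsp_like"] = [g in (hsp or []) for g in genes]
    obs = pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])])
    if clusters is not None:
        obs["cluster"] = clusters
    return ad.AnnData(X=X.astype(np.int64), obs=obs, var=var)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_oracle(X, mito_cols, hsp_cols, min_counts=200, min_cells=3):
    """Independent enumeration of the QC rules, iterated to a fixpoint."""
    cells = list(range(X.shape[0]))
    genes = list(range(X.shape[1]))
    while True:
        changed = False
        keep_cells = []
        for i in cells:
            total = sum(X[i, j] for j in genes)
            m = sum(X[i, j] for j in genes if j in mito_cols)
            h = sum(X[i, j] for j in genes if j in hsp_cols)
            ok = total >= min_counts and (total == 0 or (m / total <= 0.1 and h / total <= 0.1))
            if ok:
                keep_cells.append(i)
            else:
                changed = True
        cells = keep_cells
        keep_genes = []
        for j in genes:
            detected = sum(1 for i in cells if X[i, j] > 0)
            if detected >= min_cells:
                keep_genes.append(j)
            else:
                changed = True
        genes = keep_genes
        if not changed:
            return cells, genes


def test_qc_toy_matches_enumeration_oracle():
    """10-cell toy: one 12%-mito cell and one 2-cell gene are removed."""
    X = np.full((10, 6), 30)
    X[:, 0] = 180             # totals comfortably above the UMI floor
    X[:, 5] = 5               # mito-like gene, ~1.5% of counts normally
    X[:, 4] = 0
    X[[2, 5], 4] = 7          # gene 4 detected in exactly 2 cells
    X[3, 5] = 0
    total3 = X[3].sum()
    X[3, 5] = int(round(0.12 / 0.88 * total3))  # 12% of the new total is mito
    adata = toy_adata(X, mito=["g5"])
    filtered, report = qc_filter(adata)
    cells, genes = qc_oracle(X, mito_cols={5}, hsp_cols=set())
    assert list(filtered.obs_names) == [f"c{i}" for i in cells]
    assert list(filtered.var_names) == [f"g{j}" for j in genes]
    removed = set(zip(report["entity"], report["name"]))
    assert removed == {("cell", "c3"), ("gene", "g4")}
    assert np.array_equal(np.asarray(filtered.X), X[np.ix_(cells, genes)])


def test_qc_umi_floor_boundaries():
    X = np.zeros((6, 3), dtype=int)
    X[0] = [50, 50, 50]    # 150 total -> removed
    X[1] = [100, 50, 50]   # exactly 200 -> retained
    X[2:] = [200, 100, 100]
    adata = toy_adata(X)
    filtered, report = qc_filter(adata)
    assert "c0" not in filtered.obs_names and "c1" in filtered.obs_names
    assert report.loc[report["name"] == "c0", "reason"].item() == "low_counts"


def test_qc_gene_floor_boundary():
    X = np.zeros((5, 2), dtype=int)
    X[:, 0] = 250  # every cell passes the UMI floor on gene 0 alone
    X[[0, 1, 2], 1] = 60  # detected in exactly 3 cells -> retained
    filtered, _ = qc_filter(toy_adata(X))
    assert "g1" in filtered.var_names


def test_qc_idempotent_on_simulated_data(default_expression):
    sub = default_expression[default_expression.obs["stage"] == 36].copy()
    once, report1 = qc_filter(sub)
    twice, report2 = qc_filter(once)
    assert len(report2) == 0
    assert once.shape == twice.shape
    # no violating entity survives
    X = np.asarray(once.X)
    assert (X.sum(axis=1) >= 200).all()
    mito = once.var["is_mito_like"].to_numpy()
    assert (X[:, mito].sum(axis=1) / X.sum(axis=1) <= 0.10).all()
    assert ((X > 0).sum(axis=0) >= 3).all()


def test_qc_rejects_empty_matrix():
    with pytest.raises(ValueError):
        qc_filter(toy_adata(np.zeros((0, 3))))


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def test_normalize_counts_arithmetic():
    adata = toy_adata(np.array([[10, 0], [5, 5]]))
    out = normalize_counts(adata, target_sum=10)
    assert np.allclose(out.layers["normalized"][0], [10, 0])
    assert np.allclose(out.layers["lognorm"][0], [np.log(11), 0.0])
    assert np.allclose(out.layers["normalized"].sum(axis=1), 10)


def test_normalize_is_depth_invariant():
    X = np.array([[3, 7, 10], [6, 14, 20]])  # second cell = doubled first
    out = normalize_counts(toy_adata(X))
    assert np.allclose(out.layers["normalized"][0], out.layers["normalized"][1])


def test_normalize_rejects_zero_total_cell():
    with pytest.raises(ValueError):
        normalize_counts(toy_adata(np.array([[0, 0], [1, 2]])))


# ---------------------------------------------------------------------------
# pairwise DEG
# ---------------------------------------------------------------------------

def deg_oracle(norm_a, norm_b, raw_a, raw_b, min_frac=0.5, min_diff=0.5,
               fc=2.0, eps=0.01):
    """Independent per-gene rule evaluation for the a-over-b direction."""
    passing = []
    for j in range(norm_a.shape[1]):
        fa = float((raw_a[:, j] > 0).mean())
        fb = float((raw_b[:, j] > 0).mean())
        fold = (norm_a[:, j].mean() + eps) / (norm_b[:, j].mean() + eps)
        if fa >= min_frac and (fa - fb) >= min_diff and fold >= fc:
            passing.append(j)
    return passing


def _deg_toy():
    rng = np.random.default_rng(7)
    n = 20
    # 6 genes spanning pass/fail combinations of the three thresholds
    a = np.zeros((n, 6), dtype=int)
    b = np.zeros((n, 6), dtype=int)
    a[:, 0] = rng.poisson(30, n) + 1          # clean pass: frac 1 vs 0
    a[:, 1] = rng.poisson(30, n) + 1          # fails min_diff: b also detects
    b[:, 1] = rng.poisson(25, n) + 1
    a[: n // 2, 2] = 40                       # frac 0.5 boundary, fc large
    a[:, 3] = 20                              # fc ~1: fails fold change
    b[:, 3] = 19
    a[: int(0.6 * n), 4] = 30                 # frac 0.6 vs 0.4: diff 0.2 fails
    b[: int(0.4 * n), 4] = 30
    b[:, 5] = rng.poisson(30, n) + 1          # passes in the b direction
    X = np.vstack([a, b])
    labels = ["A"] * n + ["B"] * n
    # every cell has positive total (gene 0 for A cells, gene 5 for B cells)
    return normalize_counts(toy_adata(X, clusters=labels)), n


def test_deg_toy_matches_rule_oracle():
    adata, n = _deg_toy()
    # re-derive raw detection on the +1-shifted matrix the filter saw
    raw = np.asarray(adata.X)
    norm = adata.layers["normalized"]
    out = pairwise_deg(adata, "cluster", "A", "B")
    got_a = set(out.loc[out["cluster_high"] == "A", "gene"])
    got_b = set(out.loc[out["cluster_high"] == "B", "gene"])
    want_a = {f"g{j}" for j in deg_oracle(norm[:n], norm[n:], raw[:n], raw[n:])}
    want_b = {f"g{j}" for j in deg_oracle(norm[n:], norm[:n], raw[n:], raw[:n])}
    assert got_a == want_a
    assert got_b == want_b


def test_deg_simple_rules():
    n = 10
    X = np.zeros((2 * n, 3), dtype=int)
    X[:n, 0] = 50                    # gene 0: frac (1, 0), huge fold
    X[: int(0.6 * n), 1] = 50        # gene 1: frac 0.6 vs 0.4
    X[n : n + int(0.4 * n), 1] = 50
    X[:, 2] = 50                     # housekeeping keeps every total positive
    adata = normalize_counts(toy_adata(X, clusters=["A"] * n + ["B"] * n))
    out = pairwise_deg(adata, "cluster", "A", "B")
    assert set(out["gene"]) == {"g0"}
    with pytest.raises(ValueError):
        pairwise_deg(adata, "cluster", "A", "Z")


def test_deg_antisymmetric_direction():
    """With min_diff_frac >= 0.5 no gene can pass in both directions."""
    rng = np.random.default_rng(3)
    X = rng.poisson(5, size=(40, 8)) + 1
    adata = normalize_counts(toy_adata(X, clusters=["A"] * 20 + ["B"] * 20))
    out = pairwise_deg(adata, "cluster", "A", "B")
    both = set(out.loc[out["cluster_high"] == "A", "gene"]) & set(
        out.loc[out["cluster_high"] == "B", "gene"]
    )
    assert not both


def test_detection_fraction_requires_cells():
    adata = toy_adata(np.ones((3, 2)))
    with pytest.raises(ValueError):
        detection_fraction(adata, np.zeros(3, bool))


# ---------------------------------------------------------------------------
# stage consistency
# ---------------------------------------------------------------------------

def test_stage_union_and_intersection():
    out = stage_consistent_degs({36: {"A", "B"}, 48: {"B", "C"}})
    assert out.union == {"A", "B", "C"}
    assert out.intersection == {"B"}
    assert out.stages_per_gene == {"A": [36], "B": [36, 48], "C": [48]}
    single = stage_consistent_degs({60: {"X"}})
    assert single.union == single.intersection == {"X"}
    with pytest.raises(ValueError):
        stage_consistent_degs({})


def test_stage_intersection_excludes_late_marker(config):
    """A stage series with an always-on marker and a late-only marker keeps
    only the former in the all-stage set."""
    sets = {
        st: {"grain"} | ({"zld"} if st >= 60 else set())
        for st in (36, 48, 60, 72)
    }
    out = stage_consistent_degs(sets)
    assert out.intersection == {"grain"}
    assert out.union == {"grain", "zld"}


# ---------------------------------------------------------------------------
# cluster identity
# ---------------------------------------------------------------------------

def _cluster_means(config):
    means = syn.expected_mean_matrix(config, 48)
    return means[["TfAP-2", "dac", "omb", "grain"]]


def test_identity_assignment_recovers_ground_truth(config):
    mapping = assign_cluster_identity(_cluster_means(config), MARKER_SPEC)
    assert mapping == {f"{t}{s}": (t, s) for t in ("T4", "T5") for s in "abcd"}


def test_identity_assignment_is_order_equivariant(config):
    means = _cluster_means(config)
    rng = np.random.default_rng(0)
    shuffled = means.iloc[rng.permutation(len(means))]
    assert assign_cluster_identity(shuffled, MARKER_SPEC) == assign_cluster_identity(
        means, MARKER_SPEC
    )


def test_identity_assignment_flags_non_separable_marker(config):
    means = _cluster_means(config).copy()
    means["TfAP-2"] = 1.0  # type marker equal in all clusters
    with pytest.raises(NonSeparableMarkerError) as err:
        assign_cluster_identity(means, MARKER_SPEC)
    assert err.value.marker == "TfAP-2"


def test_identity_assignment_requires_eight_clusters(config):
    with pytest.raises(ValueError):
        assign_cluster_identity(_cluster_means(config).iloc[:6], MARKER_SPEC)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def test_dynamics_categories():
    stages = (36, 48, 60, 72)
    stable = {st: {"b", "c"} for st in stages}
    assert categorize_dynamics(stable) == "stable_subtype_specific"
    late = {st: ({"a", "b"} if st >= 60 else set()) for st in stages}
    assert categorize_dynamics(late) == "late_only"
    switching = {36: {"a", "b"}, 48: {"c", "d"}, 60: set(), 72: set()}
    assert categorize_dynamics(switching) == "switching"


def test_dynamics_type_specific_variants():
    stages = (36, 48, 60, 72)
    type_level = {st: StageStatus(type_level=True) for st in stages}
    assert categorize_dynamics(type_level) == "type_specific"
    one_type_only = {
        st: StageStatus(t4_subtypes=frozenset("ab")) for st in stages
    }
    assert categorize_dynamics(one_type_only) == "type_specific"


def test_dynamics_requires_core_stages():
    with pytest.raises(ValueError):
        categorize_dynamics({36: {"a"}, 48: {"a"}})


def test_dynamics_transient_early_pattern_is_switching():
    stages = (36, 48, 60, 72)
    transient = {st: ({"a", "b"} if st == 36 else set()) for st in stages}
    assert categorize_dynamics(transient) == "switching"


# ---------------------------------------------------------------------------
# Grain score
# ---------------------------------------------------------------------------

def test_grain_score_exact_values():
    cfg = SimulationConfig(grain_enrichment=3.0, intensity_cv=0.0)
    table = syn.generate_cellbody_table(cfg, seed=0)
    scores = grain_score(table)
    for _, row in scores.iterrows():
        expected = 3.0 if row["subtype"] in ("b", "c") else 1.0
        assert np.isclose(row["score"], expected)


def test_grain_score_scale_invariant():
    cfg = SimulationConfig()
    table = syn.generate_cellbody_table(cfg, seed=3)
    s1 = grain_score(table)
    scaled = table.assign(mean_intensity=table["mean_intensity"] * 37.5)
    s2 = grain_score(scaled)
    assert np.allclose(s1["score"], s2["score"])


def test_grain_score_bc_exceed_ad_at_defaults():
    table = syn.generate_cellbody_table(SimulationConfig(), seed=0)
    scores = grain_score(table).groupby("subtype")["score"].mean()
    assert min(scores["b"], scores["c"]) > max(scores["a"], scores["d"])


def test_grain_score_requires_background():
    cfg = SimulationConfig(n_background_per_lobe=5)
    table = syn.generate_cellbody_table(cfg, seed=0)
    with pytest.raises(ValueError):
        grain_score(table)
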