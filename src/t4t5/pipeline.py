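"""End-to-end in-silico experiments.

Three experiments mirror the study's logic on synthetic data:

* **wildtype** — simulate an unperturbed population; quantify dendrite
  orientation histograms and volumes across stages, normalised axon
  positions, subtype calls from both modalities, and their agreement.
* **perturbation** — apply a Grain gain- or loss-of-function to every
  neuron's TF code *before* morphogenesis (identity conversion, the
  mechanism the data support, rather than axon retargeting), then classify
  the perturbed neurons against unperturbed references. Overexpression
  should send every axon to layers 2 or 3 with matching dendrite
  orientations and make every 4-neuron clone homogeneous (4xb or 4xc);
  knockdown should send every axon to layers 1 or 4.
* **expression** — simulate stage-wise count matrices, run QC,
  normalisation, marker-based cluster identity, per-stage threshold DEG
  filtering, stage-consistency sets and dynamics categorisation, and report
  recovery of the configured marker program.
"""

from __future__ import annotations

import datetime
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import axon as ax
from . import expression as xp
from . import morphometry as mm
from . import synthetic as syn
from .codes import PERTURBATION_MODES
from .config import SUBTYPES, SimulationConfig

logger = logging.getLogger("t4t5.pipeline")

__all__ = [
    "ExperimentReport",
    "run_wildtype_experiment",
    "run_perturbation_experiment",
    "run_expression_experiment",
]


@dataclass
class ExperimentReport:
    """Artifacts of one experiment run."""

    neurons: pd.DataFrame
    clones: pd.DataFrame
    summary: dict
    config: dict
    seed: Optional[int]
    mode: str
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now().isoformat(timespec="seconds")
    )

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.neurons.to_csv(outdir / "neurons.csv", index=False)
        self.clones.to_csv(outdir / "clones.csv", index=False)
        payload = dict(
            summary=self.summary, config=self.config, seed=self.seed,
            mode=self.mode, timestamp=self.timestamp,
        )
        with open(outdir / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def _default_frame(config: SimulationConfig) -> ax.LobulaPlateFrame:
    return ax.LobulaPlateFrame.rectangle(
        (0.0, config.plate_length), posterior=0.0, anterior=config.plate_extent
    )


def _quantify_population(pop: syn.Population, frame: ax.LobulaPlateFrame):
    """Histograms, axon positions and volumes for every neuron."""
    gt = pop.ground_truth
    hists = {}
    rows = []
    for _, rec in gt.iterrows():
        skel = pop.skeletons[rec["neuron_id"]]
        hist = mm.histogram_from_skeleton(skel)
        hists[rec["neuron_id"]] = hist
        rel = ax.relative_axon_position(skel.axon_reference_point()[:2], frame)
        rows.append(
            dict(
                neuron_id=rec["neuron_id"],
                relative_position=rel.value,
                out_of_bounds=rel.out_of_bounds,
                dendrite_volume=mm.dendrite_volume(skel),
                n_vectors=hist.n_vectors,
            )
        )
    return hists, pd.DataFrame(rows)


def _stage_references(gt: pd.DataFrame, hists: dict, by: str = "realized_subtype"):
    """Per-(stage, subtype) mean reference histograms."""
    refs: dict = {}
    for (stage, subtype), grp in gt.groupby(["stage", by], observed=True, sort=False):
        avg = mm.average_histograms([hists[n] for n in grp["neuron_id"]])
        refs.setdefault(stage, {})[subtype] = mm.PolarHistogram(
            bin_masses=avg.mean / avg.mean.sum(),
            bin_edges=avg.bin_edges,
            n_vectors=int(np.mean([hists[n].n_vectors for n in grp["neuron_id"]])),
        )
    return refs


def run_perturbation_experiment(
    config: SimulationConfig,
    mode: str,
    seed: Optional[int] = None,
    stages: Optional[Sequence] = None,
    conversion_penetrance: float = 1.0,
) -> ExperimentReport:
    """Simulate, quantify and classify a (possibly perturbed) population.

    References for the dendrite call and boundaries for the axon call come
    from an unperturbed control population simulated with a derived seed,
    mirroring the comparison of perturbed single neurons against wild-type
    subtype averages. ``mode="none"`` reproduces the wildtype experiment.
    """
    if mode not in PERTURBATION_MODES:
        raise ValueError(f"unknown perturbation mode: {mode!r}")
    if seed is None:
        seed = config.seed
    if stages is None:
        stages = list(config.stages)
    frame = _default_frame(config)

    logger.info("simulating control population (mode=%s, seed=%s)", mode, seed)
    control = syn.generate_population(config, seed=[int(seed), 101], stages=stages)
    ctrl_hists, ctrl_q = _quantify_population(control, frame)
    references = _stage_references(control.ground_truth, ctrl_hists)
    _, boundaries = ax.cluster_axon_positions(
        ctrl_q["relative_position"].to_numpy(), k=4
    )

    logger.info("simulating experimental population")
    pop = syn.generate_population(
        config, seed=seed, perturbation=mode, stages=stages,
        conversion_penetrance=conversion_penetrance,
    )
    hists, quant = _quantify_population(pop, frame)
    gt = pop.ground_truth.merge(quant, on="neuron_id")

    dendrite_calls, tie_flags, axon_calls, layer_calls = [], [], [], []
    for _, rec in gt.iterrows():
        label, tie = mm.classify_by_dendrite(
            hists[rec["neuron_id"]], references[rec["stage"]]
        )
        dendrite_calls.append(label)
        tie_flags.append(tie)
        record = ax.classify_subtype_from_axon(
            rec["relative_position"], boundaries, neuron_id=rec["neuron_id"],
            out_of_bounds=bool(rec["out_of_bounds"]),
        )
        axon_calls.append(record.subtype_call)
        layer_calls.append(record.layer_call)
    gt["dendrite_call"] = dendrite_calls
    gt["dendrite_tie"] = tie_flags
    gt["axon_call"] = axon_calls
    gt["layer_call"] = layer_calls
    gt["agree"] = gt["dendrite_call"] == gt["axon_call"]

    clones = (
        gt.groupby("clone_id")
        .agg(
            stage=("stage", "first"),
            subtypes_true=("realized_subtype", lambda s: "".join(sorted(s))),
            subtypes_called=("axon_call", lambda s: "".join(sorted(s))),
            n=("neuron_id", "size"),
        )
        .reset_index()
    )
    clones["homogeneous"] = clones["subtypes_called"].map(lambda s: len(set(s)) == 1)

    layer_fractions = (
        gt["layer_call"].value_counts(normalize=True).reindex([1, 2, 3, 4], fill_value=0.0)
    )
    # normalised volume trajectory per stage (normalised to the max stage mean)
    vol_by_stage = gt.groupby("stage", sort=False)["dendrite_volume"].mean()
    vol_norm = mm.normalize_volumes(vol_by_stage.to_numpy())
    summary = dict(
        n_neurons=int(len(gt)),
        dendrite_call_accuracy=float((gt["dendrite_call"] == gt["realized_subtype"]).mean()),
        axon_call_accuracy=float((gt["axon_call"] == gt["realized_subtype"]).mean()),
        dendrite_axon_agreement=float(gt["agree"].mean()),
        layer_fractions={int(k): float(v) for k, v in layer_fractions.items()},
        fraction_layers_2_3=float(gt["layer_call"].isin([2, 3]).mean()),
        fraction_layers_1_4=float(gt["layer_call"].isin([1, 4]).mean()),
        clone_homogeneous_fraction=float(clones["homogeneous"].mean()),
        mean_volume_by_stage={str(k): float(v) for k, v in vol_by_stage.items()},
        normalized_volume_by_stage={
            str(k): float(v) for k, v in zip(vol_by_stage.index, vol_norm)
        },
        axon_boundaries=[float(b) for b in boundaries],
    )
    logger.info(
        "mode=%s: dendrite acc %.3f, axon acc %.3f, agreement %.3f",
        mode, summary["dendrite_call_accuracy"], summary["axon_call_accuracy"],
        summary["dendrite_axon_agreement"],
    )
    return ExperimentReport(
        neurons=gt, clones=clones, summary=summary, config=config.to_dict(),
        seed=seed, mode=mode,
    )


def run_wildtype_experiment(
    config: SimulationConfig,
    seed: Optional[int] = None,
    stages: Optional[Sequence] = None,
) -> ExperimentReport:
    """Unperturbed end-to-end run (identical to mode ``"none"``)."""
    return run_perturbation_experiment(config, "none", seed=seed, stages=stages)


# ---------------------------------------------------------------------------
# expression experiment
# ---------------------------------------------------------------------------

def _marked_sets_for_gene(
    deg: pd.DataFrame, gene: str, clusters_by_type: dict
) -> xp.StageStatus:
    """Marked subtype sets per type from a stage's pairwise DEG table.

    Within a type, subtype s belongs to the marked set when the gene passes
    s-over-s' for at least one other subtype s' of that type.
    """
    sets = {}
    for cell_type, clusters in clusters_by_type.items():
        rows = deg[
            (deg["gene"] == gene)
            & deg["cluster_high"].isin(clusters)
            & deg["cluster_low"].isin(clusters)
        ]
        sets[cell_type] = frozenset(c[2] for c in rows["cluster_high"].unique())
    return xp.StageStatus(t4_subtypes=sets.get("T4", frozenset()),
                          t5_subtypes=sets.get("T5", frozenset()))


def run_expression_experiment(
    config: SimulationConfig, seed: Optional[int] = None
) -> dict:
    """Simulate, filter and decode the stage-wise expression programme.

    Returns a report dict with per-stage cluster-identity accuracy, the
    any-stage and all-stage DEG sets, per-gene dynamics categories and
    their agreement with the generator's configured program.
    """
    if seed is None:
        seed = config.seed
    adata = syn.generate_expression(config, seed=seed)
    marker_spec = adata.uns["marker_spec"]
    stable_truth = set(adata.uns["stable_markers"])
    dynamics_truth = dict(adata.uns["expected_dynamics"])

    per_stage_sets = {}
    per_stage_deg = {}
    identity_accuracy = {}
    type_level_sets = {}
    clusters_by_type = {
        "T4": [c for c in syn._CLUSTERS if c.startswith("T4")],
        "T5": [c for c in syn._CLUSTERS if c.startswith("T5")],
    }
    for stage in config.expression_stages:
        sub = adata[adata.obs["stage"] == stage].copy()
        filtered, qc_report = xp.qc_filter(sub)
        filtered = xp.normalize_counts(filtered)
        logger.info(
            "stage %s: %d cells kept, %d removals", stage, filtered.n_obs,
            len(qc_report),
        )
        norm = filtered.layers[xp.NORMALIZED_LAYER]
        means = (
            pd.DataFrame(norm, index=filtered.obs["cluster"].to_numpy(),
                         columns=filtered.var_names)
            .groupby(level=0, observed=True)
            .mean()
        )
        mapping = xp.assign_cluster_identity(means, marker_spec)
        correct = sum(
            1 for cl, (t, s) in mapping.items() if cl == f"{t}{s}"
        )
        identity_accuracy[stage] = correct / len(mapping)

        frames = []
        for ca, cb in itertools.combinations(sorted(set(filtered.obs["cluster"])), 2):
            frames.append(xp.pairwise_deg(filtered, "cluster", ca, cb))
        deg = pd.concat(frames, ignore_index=True)
        per_stage_deg[stage] = deg
        per_stage_sets[stage] = set(deg["gene"])
        type_deg = xp.pairwise_deg(filtered, "cell_type", "T4", "T5")
        type_level_sets[stage] = set(type_deg["gene"])

    consistency = xp.stage_consistent_degs(per_stage_sets)

    all_diff_genes = sorted(
        consistency.union | set().union(*type_level_sets.values())
    )
    categories = {}
    for gene in all_diff_genes:
        per_stage_status = {
            stage: xp.StageStatus(
                t4_subtypes=_marked_sets_for_gene(
                    per_stage_deg[stage], gene, clusters_by_type
                ).t4_subtypes,
                t5_subtypes=_marked_sets_for_gene(
                    per_stage_deg[stage], gene, clusters_by_type
                ).t5_subtypes,
                type_level=gene in type_level_sets[stage],
            )
            for stage in config.expression_stages
        }
        try:
            categories[gene] = xp.categorize_dynamics(per_stage_status)
        except ValueError:
            categories[gene] = "uncategorized"

    dynamics_match = {
        g: categories.get(g) == cat for g, cat in dynamics_truth.items()
    }
    report = dict(
        identity_accuracy={str(k): v for k, v in identity_accuracy.items()},
        union_degs=sorted(consistency.union),
        intersection_degs=sorted(consistency.intersection),
        stable_markers_expected=sorted(stable_truth),
        stable_markers_recovered=sorted(consistency.intersection & stable_truth),
        intersection_matches_stable=set(consistency.intersection) == stable_truth,
        dynamics_categories=categories,
        dynamics_expected=dynamics_truth,
        dynamics_match_fraction=float(np.mean(list(dynamics_match.values()))),
        seed=seed,
    )
    return report
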