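"""Simulation configuration.

A single :class:`SimulationConfig` object parameterises every generator in
:mod:`t4t5.synthetic` and the end-to-end experiments in :mod:`t4t5.pipeline`.
Defaults encode the study conditions the analyses assume: four dendrite
orientations 90 degrees apart with opposite-direction subtype pairs (a,b) and
(c,d), four axon-target layers at evenly spaced positions on the normalised
anteroposterior axis, an arbor-size profile that grows monotonically between
36 and 72 h APF and is pruned between 72 h APF and the adult stage, and an
overdispersed (negative-binomial) count model for single-cell expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping, Sequence

import yaml

#: Developmental stages, in hours after puparium formation (APF) plus "adult".
DEFAULT_STAGES: tuple = (24, 36, 48, 60, 72, "adult")

#: Generating dendrite-orientation angle per subtype, degrees CCW from +x.
#: Only the relative geometry matters: (a,b) and (c,d) are opposite pairs
#: 90 degrees apart from each other, mirroring the four cardinal motion
#: directions the subtypes prefer.
DEFAULT_SUBTYPE_ANGLES: Mapping[str, float] = {
    "a": 0.0,
    "b": 180.0,
    "c": 90.0,
    "d": 270.0,
}

#: Relative dendrite arbor size per stage (piecewise linear in stage order):
#: monotone growth from 24 h to a 72 h APF maximum, then pruning into adulthood.
DEFAULT_GROWTH_PROFILE: Mapping[Any, float] = {
    24: 0.15,
    36: 0.30,
    48: 0.55,
    60: 0.80,
    72: 1.00,
    "adult": 0.75,
}

SUBTYPES: tuple = ("a", "b", "c", "d")
CELL_TYPES: tuple = ("T4", "T5")


class ConfigError(ValueError):
    """Raised when a :class:`SimulationConfig` violates an invariant."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic T4/T5 study.

    Parameters
    ----------
    n_neurons_per_subtype : int
        Neurons simulated per subtype, per cell type (T4/T5), per stage.
    stages : sequence
        Ordered developmental stages (hours APF, plus ``"adult"``).
    kappa : float
        von Mises concentration of dendritic branch directions around the
        subtype's generating angle. ``0`` gives uniform directions,
        ``inf`` collapses every branch onto the generating angle.
    subtype_angles : mapping
        Subtype -> generating angle in degrees (CCW from +x). The (a,b) and
        (c,d) pairs must be 180 degrees apart (opposite preferred motion
        directions).
    layer_centers : sequence of 4 floats
        Mean normalised anteroposterior axon position per subtype
        (a, b, c, d), strictly increasing, in (0, 1).
    layer_sd : float
        Standard deviation of axon positions in normalised units.
    nb_mean, nb_dispersion : float
        Negative-binomial mean of an "on" marker gene and shared dispersion
        (size) parameter of the count model. ``nb_dispersion=inf`` gives the
        Poisson limit.
    seed : int
        Global seed; every sub-generator derives a child seed from it.
    """

    n_neurons_per_subtype: int = 4
    stages: Sequence = DEFAULT_STAGES
    kappa: float = 3.0
    subtype_angles: dict = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_ANGLES)
    )
    layer_centers: Sequence[float] = (0.2, 0.4, 0.6, 0.8)
    layer_sd: float = 0.03
    nb_mean: float = 10.0
    nb_dispersion: float = 5.0
    seed: int = 0

    # --- morphology ---------------------------------------------------------
    #: branch count at the 72 h APF arbor-size maximum; scaled per stage by
    #: ``growth_profile``.
    branch_points_max: int = 240
    #: mean branch segment length, micrometres.
    branch_length: float = 6.0
    growth_profile: dict = field(
        default_factory=lambda: dict(DEFAULT_GROWTH_PROFILE)
    )
    #: extent of the rectangular lobula-plate frame along the anteroposterior
    #: axis, micrometres (normalised position p maps to p * plate_extent).
    plate_extent: float = 40.0
    #: proximodistal length of the rectangular frame, micrometres.
    plate_length: float = 40.0

    # --- expression ---------------------------------------------------------
    #: stages at which single-cell expression is profiled (no adult dataset).
    expression_stages: Sequence = (24, 36, 48, 60, 72)
    n_cells_per_cluster: int = 60
    #: mean fold between a marker's "on" and "off" clusters.
    marker_fold: float = 50.0
    #: per stage, cells constructed to fail the 200-UMI floor.
    qc_low_count_cells: int = 3
    #: per stage, cells constructed to fail the 10% mito / hsp caps.
    qc_stressed_cells: int = 3

    # --- cell-body fluorescence --------------------------------------------
    n_lobes: int = 4
    cells_per_lobe: int = 60
    n_background_per_lobe: int = 10
    #: Grain-channel intensity of b,c cell bodies relative to the background
    #: distribution shared by a,d and Lim1-negative cells.
    grain_enrichment: float = 3.0
    #: multiplicative coefficient of variation of cell-body intensities.
    intensity_cv: float = 0.08

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_neurons_per_subtype < 1:
            raise ConfigError("n_neurons_per_subtype must be a positive integer")
        if self.kappa < 0:
            raise ConfigError("kappa must be >= 0")
        if self.layer_sd <= 0:
            raise ConfigError("layer_sd must be > 0")
        centers = list(self.layer_centers)
        if len(centers) != 4:
            raise ConfigError("layer_centers must have exactly 4 entries")
        if any(not (0.0 < c < 1.0) for c in centers):
            raise ConfigError("layer_centers must lie in (0, 1)")
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ConfigError("layer_centers must be strictly increasing")
        angles = self.subtype_angles
        if set(angles) != set(SUBTYPES):
            raise ConfigError("subtype_angles must map exactly a, b, c, d")
        vals = [angles[s] % 360.0 for s in SUBTYPES]
        if len({round(v, 9) for v in vals}) != 4:
            raise ConfigError("subtype_angles must be pairwise distinct")
        for s1, s2 in (("a", "b"), ("c", "d")):
            diff = (angles[s1] - angles[s2]) % 360.0
            if abs(diff - 180.0) > 1e-9:
                raise ConfigError(
                    f"subtype_angles[{s1}] and [{s2}] must differ by 180 degrees"
                )
        if not set(self.growth_profile) >= set(self.stages):
            raise ConfigError("growth_profile must cover every stage")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ConfigError("nb_mean and nb_dispersion must be > 0")
        if self.marker_fold <= 1:
            raise ConfigError("marker_fold must exceed 1")

    # ------------------------------------------------------------------
    def require_stage(self, stage) -> None:
        if stage not in list(self.stages):
            raise ValueError(f"unknown stage: {stage!r}")

    def angle_of(self, subtype: str) -> float:
        if subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype: {subtype!r}")
        return float(self.subtype_angles[subtype])

    def layer_center_of(self, subtype: str) -> float:
        if subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype: {subtype!r}")
        return float(self.layer_centers[SUBTYPES.index(subtype)])

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["layer_centers"] = list(self.layer_centers)
        d["expression_stages"] = list(self.expression_stages)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("subtype_angles", "growth_profile"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = {
                    (k if k == "adult" or not isinstance(k, str) or not k.isdigit() else int(k)): v
                    for k, v in kwargs[key].items()
                }
        return cls(**kwargs)
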