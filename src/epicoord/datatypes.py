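"""Core data containers shared across the pipeline.

The universal carrier is :class:`MethylationDataset`: a probes x samples
matrix of beta values, M-values or per-probe z-scores, together with a
case/control label per sample and a probe annotation table.

Annotation tables are plain :class:`pandas.DataFrame` objects indexed by
probe id with columns ``chromosome`` (e.g. ``"chr1"``), ``position``
(1-based bp), ``island_relation`` (one of ``island``, ``shore``, ``shelf``,
``open_sea``), ``gene`` (symbol or empty string) and ``flags`` (frozenset of
exclusion flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

ISLAND_RELATIONS = ("island", "shore", "shelf", "open_sea")
EXCLUSION_FLAGS = ("cross_reactive", "sex_chromosome", "age_associated")
SEX_CHROMOSOMES = ("chrX", "chrY")
SCALES = ("beta", "M", "zscore")
GROUPS = ("case", "control")

ANNOTATION_COLUMNS = ("chromosome", "position", "island_relation", "gene", "flags")


def validate_annotation(annotation: pd.DataFrame) -> None:
    """Raise ``ValueError`` if an annotation table violates its contract."""
    missing = set(ANNOTATION_COLUMNS) - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if not annotation.index.is_unique:
        raise ValueError("probe ids in annotation are not unique")
    if (annotation["position"] < 1).any():
        raise ValueError("annotation positions must be >= 1")
    bad = set(annotation["island_relation"]) - set(ISLAND_RELATIONS)
    if bad:
        raise ValueError(f"unknown island_relation values: {sorted(bad)}")


@dataclass
class MethylationDataset:
    """Probes x samples methylation matrix with group labels and annotation.

    Parameters
    ----------
    values
        DataFrame with probe ids as index and sample ids as columns.
    group
        Series mapping sample id to ``"case"`` or ``"control"``.
    annotation
        Probe annotation table covering (at least) all probes in ``values``.
    scale
        One of ``"beta"``, ``"M"`` or ``"zscore"``.
    """

    values: pd.DataFrame
    group: pd.Series
    annotation: pd.DataFrame
    scale: str = "M"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if not self.values.index.is_unique:
            raise ValueError("probe ids are not unique")
        if list(self.values.columns) != list(self.group.index):
            self.group = self.group.reindex(self.values.columns)
        if self.group.isna().any():
            raise ValueError("every sample needs a group label")
        bad = set(self.group) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        missing = self.values.index.difference(self.annotation.index)
        if len(missing):
            raise ValueError(
                f"{len(missing)} probes missing from annotation, e.g. {missing[0]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def case_mask(self) -> np.ndarray:
        return (self.group == "case").to_numpy()

    def restrict_group(self, group: str) -> "MethylationDataset":
        """Return the dataset restricted to samples of one group."""
        if group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        keep = self.group[self.group == group].index
        return MethylationDataset(
            values=self.values[keep],
            group=self.group.loc[keep],
            annotation=self.annotation,
            scale=self.scale,
        )

    def restrict_probes(self, probe_ids: Sequence[str]) -> "MethylationDataset":
        return MethylationDataset(
            values=self.values.loc[list(probe_ids)],
            group=self.group,
            annotation=self.annotation,
            scale=self.scale,
        )


@dataclass
class DMRSpec:
    """A planted run of equally spaced probes forming one region."""

    chromosome: str
    start: int
    probe_count: int = 8
    spacing: int = 250

    @property
    def end(self) -> int:
        return self.start + (self.probe_count - 1) * self.spacing


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-group methylome generator.

    Defaults encode the study conditions the generator emulates: 22 cases
    versus 138 controls, ~10% of probes planted as differentially
    methylated (dmp_effect in M-value units), a latent-factor block of
    coordinated DMPs sharing correlation with a set of background CpGs, and
    two spatial DMP runs forming regions.
    """

    n_probes: int = 2000
    n_cases: int = 22
    n_controls: int = 138
    n_dmps: int = 200
    dmp_effect: float = 2.0
    n_factors: int = 1
    loading_strength_by_group: dict = field(
        default_factory=lambda: {"case": 1.5, "control": 1.0}
    )
    n_coordinated_dmps: int = 100
    n_hyperedge_cpgs: int = 500
    dmr_specs: list = field(
        default_factory=lambda: [
            DMRSpec("chr1", 100_000, 8, 250),
            DMRSpec("chr2", 500_000, 8, 200),
        ]
    )
    noise_sd: float = 1.0
    seed: int = 0
    n_chromosomes: int = 6
    flag_fractions: dict = field(
        default_factory=lambda: {"cross_reactive": 0.02, "age_associated": 0.02}
    )
    probes_per_gene: int = 5
    unannotated_gene_fraction: float = 0.1

    def validate(self) -> None:
        for name in ("n_probes", "n_cases", "n_controls", "n_dmps", "n_factors",
                     "n_coordinated_dmps", "n_hyperedge_cpgs", "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_dmps > self.n_probes:
            raise ValueError("n_dmps cannot exceed n_probes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_coordinated_dmps > self.n_dmps:
            raise ValueError("n_coordinated_dmps cannot exceed n_dmps")
        for g in GROUPS:
            if g not in self.loading_strength_by_group:
                raise ValueError(f"loading_strength_by_group missing {g!r}")
        for frac in self.flag_fractions.values():
            if not 0 <= frac <= 1:
                raise ValueError("flag fractions must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure of a simulated methylome."""

    dmp_ids: set
    dmr_intervals: list  # list of (chromosome, start, end)
    factor_loadings: dict  # group -> DataFrame (probes x factors)
    coordinated_cluster_ids: set
    hyperedge_cpg_ids: set

    def to_jsonable(self) -> dict:
        return {
            "dmp_ids": sorted(self.dmp_ids),
            "dmr_intervals": [list(iv) for iv in self.dmr_intervals],
            "factor_loadings": {
                g: {"index": list(df.index), "values": df.to_numpy().tolist()}
                for g, df in self.factor_loadings.items()
            },
            "coordinated_cluster_ids": sorted(self.coordinated_cluster_ids),
            "hyperedge_cpg_ids": sorted(self.hyperedge_cpg_ids),
        }

    @classmethod
    def from_jsonable(cls, obj: dict) -> "GroundTruth":
        loadings = {
            g: pd.DataFrame(rec["values"], index=rec["index"])
            for g, rec in obj["factor_loadings"].items()
        }
        return cls(
            dmp_ids=set(obj["dmp_ids"]),
            dmr_intervals=[tuple(iv) for iv in obj["dmr_intervals"]],
            factor_loadings=loadings,
            coordinated_cluster_ids=set(obj["coordinated_cluster_ids"]),
            hyperedge_cpg_ids=set(obj["hyperedge_cpg_ids"]),
        )


@dataclass
class IncidenceMatrix:
    """Binary DMP x CpG matrix of retained correlations (hypergraph incidence)."""

    values: pd.DataFrame  # binary, rows = DMP ids, cols = background CpG ids
    threshold_used: float


@dataclass
class CentralCluster:
    """Hierarchically refined cluster of highly coordinated DMPs."""

    members: list
    n_clusters_cut: int
    mean_internal_dimension: float
    linkage_method: str = "average"
    metric: str = "euclidean"


@dataclass
class EntropyResult:
    """Observed hypergraph entropy against a random-CpG null."""

    entropy: float
    n_edges: int
    null_values: np.ndarray
    empirical_p: float


@dataclass
class PathwayEntropyComparison:
    """Bayesian comparison of per-pathway hypergraph entropy between groups."""

    pathway_id: str
    entropy_case: np.ndarray
    entropy_control: np.ndarray
    posterior_difference: np.ndarray
    ci_low: float
    ci_high: float
    significant: bool


@dataclass
class SilencedNetwork:
    """Direct-association structure after silencing indirect correlations."""

    node_ids: list
    G: np.ndarray  # observed association matrix, unit diagonal
    S: np.ndarray  # silenced (direct) scores, symmetrized
    Z: np.ndarray  # z-scores of off-diagonal S
    edges: pd.DataFrame  # columns: probe_i, probe_j, z, label
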