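"""Trait-table simulators for the two transmission regimes under test.

The inference pipeline asks two questions of a binary cultural inventory:
does between-group similarity decay with geography (neutral,
interaction-mediated transmission), and is between-group diversity
suppressed along lineage lines (purifying selection)?  The generators here
produce tables with exactly those covariance structures, so every pipeline
stage can be exercised end to end without external data:

``simulate_neutral_ibd``
    each trait arises in one origin group and is adopted by every other
    group independently with probability ``exp(-d / decay_length)`` in the
    pairwise distance ``d`` — the canonical isolation-by-distance kernel —
    followed by independent presence/absence noise flips.

``simulate_lineage_bias``
    a core fraction of traits is retained by everyone; each remaining trait
    is favored by a random subset of lineages (language families), with
    non-favoring groups retaining it only at a low probability.  Because
    lineages are assigned independently of the map, the resulting language
    signal is uncorrelated with geography by construction.

Both are equilibrium samplers: transmission is modeled as independent
per-trait adoption, not a time-stepped contagion, because the downstream
statistics consume only the stationary presence/absence pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model_matrices import (
    BorderList,
    GeoTable,
    LanguageClassification,
    LanguageScheme,
    border_matrix,
    greatcircle_matrix,
    language_matrix,
)
from .trait_matrix import Code, PairwiseMatrix, TraitTable

__all__ = [
    "GroupLayout",
    "SimulationParams",
    "simulate_neutral_ibd",
    "simulate_lineage_bias",
    "make_plains_fixture",
]


@dataclass
class GroupLayout:
    """Geographic and lineage scaffolding shared by both simulators."""

    geo: GeoTable
    borders: BorderList
    classification: LanguageClassification

    def __post_init__(self) -> None:
        if set(self.geo.labels) != set(self.classification.groups):
            raise ValueError("coordinate and classification group sets differ")

    @property
    def groups(self) -> list[str]:
        return list(self.geo.labels)

    def distance_matrix(self) -> PairwiseMatrix:
        return greatcircle_matrix(self.geo)

    def border_share_matrix(self) -> PairwiseMatrix:
        return border_matrix(self.groups, self.borders)

    def language_matrix(self, scheme: LanguageScheme | None = None) -> PairwiseMatrix:
        cls = LanguageClassification(
            {g: self.classification.family_of(g) for g in self.groups},
            {g: self.classification.subgroup_of(g) for g in self.groups},
        )
        return language_matrix(cls, scheme or LanguageScheme())


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generators.

    n_traits
        inventory size; 82 matches a ceremony-scale trait list, 200 gives
        tighter matrices for benchmarking.
    decay_length
        e-folding distance (km for geographic layouts) of the adoption
        kernel; ~500 km makes immediate Plains neighbours likely adopters
        and far pairs unlikely ones.
    innovation_origin
        "uniform" draws each trait's origin group uniformly.
    core_fraction
        share of traits retained by every group in the lineage-bias model.
    lineage_retention
        retention probability of a trait in groups whose lineage does not
        favor it.
    noise_flip
        independent per-cell flip rate applied last (observation error and
        idiosyncratic gain/loss).
    """

    n_traits: int = 200
    decay_length: float = 500.0
    innovation_origin: str = "uniform"
    core_fraction: float = 0.6
    lineage_retention: float = 0.1
    noise_flip: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_traits < 1:
            raise ValueError("n_traits must be positive")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")
        for name in ("core_fraction", "lineage_retention", "noise_flip"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.innovation_origin != "uniform":
            raise ValueError("only uniform innovation origins are implemented")

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=seed)


def _trait_labels(n: int) -> list[str]:
    return [f"T{k + 1:03d}" for k in range(n)]


def _finish_table(layout: GroupLayout, present: np.ndarray, rng, noise_flip: float) -> TraitTable:
    if noise_flip > 0:
        flips = rng.random(present.shape) < noise_flip
        present = present ^ flips
    cells = np.where(present, int(Code.PRESENT), int(Code.ABSENT)).astype(np.int8)
    return TraitTable(layout.groups, _trait_labels(present.shape[1]), cells)


def simulate_neutral_ibd(layout: GroupLayout, params: SimulationParams) -> TraitTable:
    """Neutral isolation-by-distance trait table.

    Reproducible for a given ``params.seed``; expected pairwise similarity
    decreases monotonically with distance.
    """
    groups = layout.groups
    n = len(groups)
    if n < 2:
        raise ValueError("layout must contain at least two groups")
    rng = np.random.default_rng(params.seed)
    D = layout.distance_matrix().values
    adopt_p = np.exp(-D / params.decay_length)
    origins = rng.integers(n, size=params.n_traits)
    present = rng.random((n, params.n_traits)) < adopt_p[:, origins]
    present[origins, np.arange(params.n_traits)] = True
    return _finish_table(layout, present, rng, params.noise_flip)


def simulate_lineage_bias(layout: GroupLayout, params: SimulationParams) -> TraitTable:
    """Lineage-biased trait table (purifying-selection regime).

    A ``core_fraction`` of traits is universal; each remaining trait is
    favored by a random nonempty subset of language families — favoring
    groups always retain it, others retain with ``lineage_retention``.
    """
    groups = layout.groups
    n = len(groups)
    if n < 2:
        raise ValueError("layout must contain at least two groups")
    rng = np.random.default_rng(params.seed)
    families = sorted({layout.classification.family_of(g) for g in groups})
    fam_idx = np.array(
        [families.index(layout.classification.family_of(g)) for g in groups]
    )
    n_core = int(round(params.core_fraction * params.n_traits))
    present = np.zeros((n, params.n_traits), dtype=bool)
    present[:, :n_core] = True
    for t in range(n_core, params.n_traits):
        favored = rng.random(len(families)) < 0.5
        if not favored.any():
            favored[rng.integers(len(families))] = True
        in_favored = favored[fam_idx]
        present[:, t] = in_favored | (rng.random(n) < params.lineage_retention)
    return _finish_table(layout, present, rng, params.noise_flip)


def make_plains_fixture() -> GroupLayout:
    """Nine-group High Plains layout for synthetic runs.

    Group names and the four-family classification (Algonquian with an
    Arapahoan subgroup, Siouan with a Dakotan subgroup, Kiowa-Tanoan,
    Athabaskan) follow the standard ethnolinguistic literature.  The
    coordinates and border pairs are SYNTHETIC placeholder territory
    centers — plausible for the mid-late 19th century, adequate for
    simulation and benchmarking, but not the deposited survey values; load
    an authoritative coordinate table for any real-data analysis.
    """
    geo = GeoTable(
        [
            "Blackfoot",
            "Sarsi",
            "GrosVentre",
            "Assiniboine",
            "Crow",
            "Cheyenne",
            "Arapaho",
            "Teton",
            "Kiowa",
        ],
        np.array([48.8, 51.5, 48.2, 48.5, 45.5, 44.0, 42.5, 44.5, 35.5]),
        np.array(
            [-112.0, -113.5, -108.5, -105.0, -108.0, -103.5, -106.5, -101.5, -99.0]
        ),
    )
    borders = BorderList.from_pairs(
        [
            ("Blackfoot", "Sarsi"),
            ("Blackfoot", "GrosVentre"),
            ("Blackfoot", "Crow"),
            ("Sarsi", "GrosVentre"),
            ("GrosVentre", "Assiniboine"),
            ("GrosVentre", "Crow"),
            ("Assiniboine", "Teton"),
            ("Crow", "Cheyenne"),
            ("Crow", "Teton"),
            ("Crow", "Arapaho"),
            ("Cheyenne", "Teton"),
            ("Cheyenne", "Arapaho"),
            ("Cheyenne", "Kiowa"),
            ("Arapaho", "Kiowa"),
        ]
    )
    classification = LanguageClassification(
        {
            "Blackfoot": "Algonquian",
            "Sarsi": "Athabaskan",
            "GrosVentre": "Algonquian",
            "Assiniboine": "Siouan",
            "Crow": "Siouan",
            "Cheyenne": "Algonquian",
            "Arapaho": "Algonquian",
            "Teton": "Siouan",
            "Kiowa": "Kiowa-Tanoan",
        },
        {
            "Arapaho": "Arapahoan",
            "GrosVentre": "Arapahoan",
            "Assiniboine": "Dakotan",
            "Teton": "Dakotan",
        },
    )
    return GroupLayout(geo, borders, classification)
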