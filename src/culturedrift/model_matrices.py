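"""Hypothesis ("model") matrices for matrix-comparison tests.

An observed cultural distance matrix is interrogated by correlating it
against pairwise matrices that each encode one candidate determinant of
between-group similarity:

* great-circle geographic distance between territory center points
  (isolation-by-distance: interaction intensity decays with distance);
* a binary border-share matrix (0 = shared territorial boundary,
  1 = no shared boundary — i.e. coded as a distance);
* tiered language-similarity matrices built from a family/subgroup
  classification with fixed percent-similarity levels;
* a scalar Euclidean control matrix (e.g. absolute sample-size
  differences, to rule out collection-effort artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .trait_matrix import DiagonalPolicy, PairwiseMatrix, Polarity

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoTable",
    "BorderList",
    "LanguageClassification",
    "LanguageScheme",
    "greatcircle_matrix",
    "border_matrix",
    "language_matrix",
    "euclidean_scalar_matrix",
    "read_geo_table",
    "read_border_list",
    "read_language_classification",
]

#: IUGG mean Earth radius
EARTH_RADIUS_KM = 6371.0088


@dataclass
class GeoTable:
    """Decimal-degree center-point coordinates, one per group (N/E positive)."""

    labels: list[str]
    latitudes: np.ndarray
    longitudes: np.ndarray

    def __post_init__(self) -> None:
        self.latitudes = np.asarray(self.latitudes, dtype=float)
        self.longitudes = np.asarray(self.longitudes, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate group label in coordinate table")
        if self.latitudes.shape != (n,) or self.longitudes.shape != (n,):
            raise ValueError("one coordinate pair required per group")
        if (np.abs(self.latitudes) > 90).any():
            raise ValueError("latitude outside [-90, 90]")
        if (np.abs(self.longitudes) > 180).any():
            raise ValueError("longitude outside [-180, 180]")


@dataclass
class BorderList:
    """Unordered group pairs that share a territorial boundary."""

    pairs: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        cleaned: set[frozenset[str]] = set()
        for p in self.pairs:
            pair = frozenset(p)
            if len(pair) != 2:
                raise ValueError(f"border pair must join two distinct groups: {sorted(p)}")
            cleaned.add(pair)
        self.pairs = cleaned

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "BorderList":
        return cls({frozenset(p) for p in pairs})

    def shares(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.pairs


@dataclass
class LanguageClassification:
    """group -> (language family, optional subgroup within the family)."""

    families: dict[str, str]
    subgroups: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.families:
            self.subgroups.setdefault(g, None)
        extra = set(self.subgroups) - set(self.families)
        if extra:
            raise ValueError(f"subgroup given for unclassified group(s): {sorted(extra)}")

    @property
    def groups(self) -> list[str]:
        return list(self.families)

    def family_of(self, g: str) -> str:
        return self.families[g]

    def subgroup_of(self, g: str) -> str | None:
        return self.subgroups.get(g)


@dataclass(frozen=True)
class LanguageScheme:
    """Tiered percent similarities for classification-derived matrices.

    ``interfamily_pct`` applies to groups from different language families,
    ``intrafamily_pct`` to same family / different subgroup, and
    ``intrasubgroup_pct`` to same subgroup.  ``overrides`` are applied last
    as explicit (pair, percent) exceptions — e.g. raising particular
    within-subgroup pairs above the generic tier.
    """

    interfamily_pct: float = 5.0
    intrafamily_pct: float = 50.0
    intrasubgroup_pct: float = 80.0
    overrides: tuple[tuple[frozenset[str], float], ...] = ()

    def __post_init__(self) -> None:
        tiers = (self.interfamily_pct, self.intrafamily_pct, self.intrasubgroup_pct)
        if not all(0 <= t <= 100 for t in tiers):
            raise ValueError("scheme percentages must lie in [0, 100]")
        if not (
            self.interfamily_pct <= self.intrafamily_pct <= self.intrasubgroup_pct
        ):
            raise ValueError("scheme tiers must be non-decreasing")

    def with_overrides(
        self, pairs: Iterable[tuple[str, str]], pct: float
    ) -> "LanguageScheme":
        new = tuple((frozenset(p), float(pct)) for p in pairs)
        return LanguageScheme(
            self.interfamily_pct,
            self.intrafamily_pct,
            self.intrasubgroup_pct,
            self.overrides + new,
        )


def greatcircle_matrix(
    geo: GeoTable, radius_km: float = EARTH_RADIUS_KM
) -> PairwiseMatrix:
    """Pairwise great-circle distances (haversine) on a sphere, in km.

    The haversine form is numerically stable for the short arcs typical of
    regional group layouts, where the spherical law of cosines loses
    precision.
    """
    if len(geo.labels) < 2:
        raise ValueError("need at least two groups")
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    lat = np.radians(geo.latitudes)
    lon = np.radians(geo.longitudes)
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    )
    d = 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return PairwiseMatrix(list(geo.labels), d, Polarity.DISTANCE, DiagonalPolicy.ZERO)


def border_matrix(groups: Sequence[str], borders: BorderList) -> PairwiseMatrix:
    """Binary border-share matrix, coded as a distance.

    Off-diagonal cells are 0 where the two groups share a territorial
    boundary (proximity) and 1 where they do not.
    """
    known = set(groups)
    for pair in borders.pairs:
        unknown = pair - known
        if unknown:
            raise ValueError(f"border pair references unknown group(s): {sorted(unknown)}")
    n = len(groups)
    vals = np.ones((n, n), dtype=float)
    np.fill_diagonal(vals, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            if borders.shares(groups[i], groups[j]):
                vals[i, j] = vals[j, i] = 0.0
    return PairwiseMatrix(list(groups), vals, Polarity.DISTANCE, DiagonalPolicy.ZERO)


def language_matrix(
    cls: LanguageClassification, scheme: LanguageScheme
) -> PairwiseMatrix:
    """Percent-similarity matrix from a family/subgroup classification.

    Tier selection per pair: same family *and* same named subgroup →
    ``intrasubgroup_pct``; same family otherwise → ``intrafamily_pct``;
    different families → ``interfamily_pct``.  Groups without a named
    subgroup never match at the subgroup tier, even within one family.
    Overrides are applied after tier assignment.  Diagonal is 100.
    """
    groups = cls.groups
    n = len(groups)
    if n < 2:
        raise ValueError("need at least two classified groups")
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = groups[i], groups[j]
            if cls.family_of(gi) != cls.family_of(gj):
                pct = scheme.interfamily_pct
            else:
                si, sj = cls.subgroup_of(gi), cls.subgroup_of(gj)
                if si is not None and si == sj:
                    pct = scheme.intrasubgroup_pct
                else:
                    pct = scheme.intrafamily_pct
            vals[i, j] = vals[j, i] = pct
    known = set(groups)
    for pair, pct in scheme.overrides:
        if not pair <= known:
            raise ValueError(
                f"override pair {sorted(pair)} not in the classified group set"
            )
        a, b = sorted(pair)
        i, j = groups.index(a), groups.index(b)
        vals[i, j] = vals[j, i] = float(pct)
    return PairwiseMatrix(groups, vals, Polarity.SIMILARITY, DiagonalPolicy.ONE)


def euclidean_scalar_matrix(values: Mapping[str, float]) -> PairwiseMatrix:
    """Absolute-difference distance matrix of one scalar per group."""
    groups = list(values)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    v = np.array([float(values[g]) for g in groups])
    if not np.isfinite(v).all():
        raise ValueError("non-finite scalar value")
    d = np.abs(v[:, None] - v[None, :])
    return PairwiseMatrix(groups, d, Polarity.DISTANCE, DiagonalPolicy.ZERO)


def read_geo_table(path: str | Path) -> GeoTable:
    """Read ``group,lat,lon`` CSV (decimal degrees, N/E positive)."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected columns group,lat,lon")
    return GeoTable(
        [str(g) for g in df.iloc[:, 0]],
        df.iloc[:, 1].to_numpy(dtype=float),
        df.iloc[:, 2].to_numpy(dtype=float),
    )


def read_border_list(path: str | Path) -> BorderList:
    """Read a two-column CSV of border-sharing group pairs."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns of group names")
    return BorderList.from_pairs(
        (str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])
    )


def read_language_classification(path: str | Path) -> LanguageClassification:
    """Read ``group,family,subgroup`` CSV; empty subgroup means none."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected columns group,family,subgroup")
    families = {str(r.iloc[0]): str(r.iloc[1]) for _, r in df.iterrows()}
    subgroups = {
        str(r.iloc[0]): (str(r.iloc[2]) or None) for _, r in df.iterrows()
    }
    return LanguageClassification(families, subgroups)
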