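"""Binary trait tables and Jaccard pairwise matrices.

Cultural inventories are recorded as group × trait presence/absence tables in
which individual cells may additionally be flagged *questionable* (the source
ethnography could not establish presence or absence).  This module holds the
two central containers of the pipeline — :class:`TraitTable` and
:class:`PairwiseMatrix` — and the conversion between them: the Jaccard
association computed pairwise over groups, with questionable cells handled by
pairwise deletion (the conservative default) or by recoding as present (the
sensitivity variant).

The Jaccard coefficient deliberately ignores joint absences: for two groups
with ``a`` shared presences, ``b``/``c`` presences private to either group and
``d`` joint absences, similarity is ``S = a / (a + b + c)`` and distance
``D = 1 - S``.  Joint absences are uninformative when absence may reflect
observational bias rather than true absence, which is the rule for
ethnographic trait lists.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Code",
    "MissingPolicy",
    "Polarity",
    "DiagonalPolicy",
    "JaccardCounts",
    "TraitTable",
    "PairwiseMatrix",
    "read_trait_table",
    "write_trait_table",
    "jaccard_counts",
    "jaccard_matrix",
    "offdiag_vector",
    "read_pairwise_csv",
    "write_pairwise_csv",
    "DEFAULT_DIALECT",
]


class Code(enum.IntEnum):
    """Cell codes of a trait table."""

    ABSENT = 0
    PRESENT = 1
    QUESTIONABLE = -1


class MissingPolicy(str, enum.Enum):
    """How questionable cells enter the Jaccard computation.

    PAIRWISE_DELETE
        A trait questionable in *either* member of a pair is excluded from
        that pair's counts only (it still contributes to other pairs).
    RECODE_PRESENT
        Questionable cells are treated as presences everywhere.
    """

    PAIRWISE_DELETE = "pairwise_delete"
    RECODE_PRESENT = "recode_present"


class Polarity(str, enum.Enum):
    DISTANCE = "distance"
    SIMILARITY = "similarity"


class DiagonalPolicy(str, enum.Enum):
    ZERO = "zero"
    ONE = "one"
    EXCLUDED = "excluded"


#: default text ↔ code mapping for trait-table CSV cells
DEFAULT_DIALECT: Mapping[str, Code] = {
    "1": Code.PRESENT,
    "0": Code.ABSENT,
    "?": Code.QUESTIONABLE,
}


@dataclass(frozen=True)
class JaccardCounts:
    """The 2 × 2 presence/absence contingency counts for one pair of groups.

    Attributes
    ----------
    a : traits present in both groups
    b : traits present only in the first group
    c : traits present only in the second group
    d : traits absent in both groups
    n_deleted : traits removed by pairwise deletion (questionable in either)
    """

    a: int
    b: int
    c: int
    d: int
    n_deleted: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d, self.n_deleted) < 0:
            raise ValueError("Jaccard counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d + self.n_deleted

    @property
    def similarity(self) -> float:
        """Jaccard similarity ``a / (a + b + c)``; joint absences ignored."""
        denom = self.a + self.b + self.c
        if denom == 0:
            raise ZeroDivisionError(
                "Jaccard undefined: no scorable presences in either group"
            )
        return self.a / denom

    @property
    def distance(self) -> float:
        return 1.0 - self.similarity


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


@dataclass
class TraitTable:
    """A group × trait table of presence/absence/questionable codes.

    ``cells`` is an int8 array with values drawn from :class:`Code`,
    shaped ``(len(group_labels), len(trait_labels))``.  Label order is
    meaningful and preserved through I/O — downstream pair ordering
    derives from it.
    """

    group_labels: list[str]
    trait_labels: list[str]
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        _check_unique(self.group_labels, "group")
        _check_unique(self.trait_labels, "trait")
        if self.cells.shape != (len(self.group_labels), len(self.trait_labels)):
            raise ValueError(
                f"cell block shape {self.cells.shape} inconsistent with "
                f"{len(self.group_labels)} groups × {len(self.trait_labels)} traits"
            )
        valid = np.isin(self.cells, [int(c) for c in Code])
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid cell code {self.cells[i, j]} at group "
                f"{self.group_labels[i]!r}, trait {self.trait_labels[j]!r}"
            )

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def n_traits(self) -> int:
        return len(self.trait_labels)

    def row(self, group: str) -> np.ndarray:
        return self.cells[self.group_labels.index(group)]

    def reorder_groups(self, order: Sequence[str]) -> "TraitTable":
        """Return a copy with groups rearranged to ``order`` (a permutation)."""
        if sorted(order) != sorted(self.group_labels):
            raise ValueError("order must be a permutation of the group labels")
        idx = [self.group_labels.index(g) for g in order]
        return TraitTable(list(order), list(self.trait_labels), self.cells[idx])

    def to_frame(self, dialect: Mapping[str, Code] = DEFAULT_DIALECT) -> pd.DataFrame:
        rev = {int(code): text for text, code in dialect.items()}
        data = np.vectorize(rev.__getitem__)(self.cells)
        return pd.DataFrame(data, index=self.group_labels, columns=self.trait_labels)


def read_trait_table(
    path: str | Path, dialect: Mapping[str, Code] | None = None
) -> TraitTable:
    """Read a trait-table CSV: header = trait labels, first column = groups.

    Cells are mapped to codes through ``dialect`` (default ``1``/``0``/``?``).
    Unmappable cells raise a :class:`ValueError` naming the offending
    row and column.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: trait table has no data rows/columns")
    groups = [str(g) for g in df.index]
    traits = [str(t) for t in df.columns]
    cells = np.empty(df.shape, dtype=np.int8)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            token = str(raw[i, j]).strip()
            if token not in dialect:
                raise ValueError(
                    f"{path}: unmappable cell {token!r} at group {groups[i]!r}, "
                    f"trait {traits[j]!r}"
                )
            cells[i, j] = int(dialect[token])
    return TraitTable(groups, traits, cells)


def write_trait_table(
    table: TraitTable,
    path: str | Path,
    dialect: Mapping[str, Code] = DEFAULT_DIALECT,
) -> None:
    table.to_frame(dialect).to_csv(path, index_label="group")


def jaccard_counts(
    row_i: np.ndarray,
    row_j: np.ndarray,
    missing_policy: MissingPolicy = MissingPolicy.PAIRWISE_DELETE,
) -> JaccardCounts:
    """Contingency counts for one pair of code vectors.

    Under ``PAIRWISE_DELETE`` a trait questionable in either vector is
    counted only in ``n_deleted``; under ``RECODE_PRESENT`` questionable
    cells become presences and nothing is deleted.
    """
    x = np.asarray(row_i, dtype=np.int8)
    y = np.asarray(row_j, dtype=np.int8)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"trait vectors must be 1-d and equal length, got {x.shape} vs {y.shape}")
    missing_policy = MissingPolicy(missing_policy)
    if missing_policy is MissingPolicy.RECODE_PRESENT:
        x = np.where(x == Code.QUESTIONABLE, Code.PRESENT, x)
        y = np.where(y == Code.QUESTIONABLE, Code.PRESENT, y)
        keep = np.ones_like(x, dtype=bool)
    else:
        keep = (x != Code.QUESTIONABLE) & (y != Code.QUESTIONABLE)
    xi, yi = x[keep] == Code.PRESENT, y[keep] == Code.PRESENT
    return JaccardCounts(
        a=int(np.sum(xi & yi)),
        b=int(np.sum(xi & ~yi)),
        c=int(np.sum(~xi & yi)),
        d=int(np.sum(~xi & ~yi)),
        n_deleted=int(x.size - keep.sum()),
    )


def jaccard_matrix(
    table: TraitTable,
    missing_policy: MissingPolicy = MissingPolicy.PAIRWISE_DELETE,
    polarity: Polarity = Polarity.DISTANCE,
) -> "PairwiseMatrix":
    """All-pairs Jaccard matrix of a trait table.

    Counts are computed with matrix products over the boolean presence /
    scorable masks, which is exactly the per-pair contingency tally.  A pair
    with no scorable presences at all (``a + b + c == 0``) has no defined
    Jaccard value and raises, naming the pair.
    """
    if table.n_groups < 2:
        raise ValueError("need at least two groups for a pairwise matrix")
    missing_policy = MissingPolicy(missing_policy)
    polarity = Polarity(polarity)
    cells = table.cells
    if missing_policy is MissingPolicy.RECODE_PRESENT:
        present = cells != Code.ABSENT
        scorable = np.ones_like(present)
    else:
        present = cells == Code.PRESENT
        scorable = cells != Code.QUESTIONABLE
    P = present.astype(np.int64)
    A = scorable.astype(np.int64)
    a = P @ P.T
    # a presence is always scorable, so cross terms already respect deletion
    b = P @ (A - P).T
    c = (A - P) @ P.T
    denom = a + b + c
    bad = (denom == 0) & ~np.eye(table.n_groups, dtype=bool)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "Jaccard undefined for pair "
            f"({table.group_labels[i]!r}, {table.group_labels[j]!r}): "
            "no scorable presences in either group"
        )
    with np.errstate(invalid="ignore"):
        sim = np.where(denom > 0, a / np.maximum(denom, 1), 1.0)
    np.fill_diagonal(sim, 1.0)
    if polarity is Polarity.DISTANCE:
        return PairwiseMatrix(
            list(table.group_labels), 1.0 - sim, Polarity.DISTANCE, DiagonalPolicy.ZERO
        )
    return PairwiseMatrix(
        list(table.group_labels), sim, Polarity.SIMILARITY, DiagonalPolicy.ONE
    )


@dataclass
class PairwiseMatrix:
    """A labeled symmetric group × group matrix with explicit polarity.

    The polarity declares whether large values mean *far apart* (DISTANCE)
    or *alike* (SIMILARITY); it is carried through the pipeline so that the
    direction of every statistic is auditable.  The diagonal is stored but
    excluded from all statistics — only intergroup pairs carry information.
    """

    labels: list[str]
    values: np.ndarray
    polarity: Polarity = Polarity.DISTANCE
    diagonal_policy: DiagonalPolicy = DiagonalPolicy.ZERO

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.polarity = Polarity(self.polarity)
        self.diagonal_policy = DiagonalPolicy(self.diagonal_policy)
        _check_unique(self.labels, "group")
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        off = ~np.eye(n, dtype=bool)
        if not np.isfinite(self.values[off]).all():
            raise ValueError("non-finite off-diagonal value in pairwise matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-9, equal_nan=True):
            raise ValueError("pairwise matrix is not symmetric")
        if self.polarity is Polarity.DISTANCE and (self.values[off] < 0).any():
            raise ValueError("negative off-diagonal value in a DISTANCE matrix")

    @property
    def n(self) -> int:
        return len(self.labels)

    def offdiag(self) -> np.ndarray:
        """Upper-triangle values in row-major (i < j) order."""
        return offdiag_vector(self)

    def pair_labels(self) -> list[tuple[str, str]]:
        iu, ju = np.triu_indices(self.n, k=1)
        return [(self.labels[i], self.labels[j]) for i, j in zip(iu, ju)]

    def reorder(self, order: Sequence[str]) -> "PairwiseMatrix":
        if sorted(order) != sorted(self.labels):
            raise ValueError("order must be a permutation of the labels")
        idx = [self.labels.index(g) for g in order]
        return PairwiseMatrix(
            list(order),
            self.values[np.ix_(idx, idx)],
            self.polarity,
            self.diagonal_policy,
        )

    def as_distance(self, scale: float = 1.0) -> "PairwiseMatrix":
        """Flip a similarity to a distance as ``scale - value`` (identity if
        already a distance).  ``scale`` is the similarity of identity (1 for
        Jaccard, 100 for percent matrices)."""
        if self.polarity is Polarity.DISTANCE:
            return self
        return PairwiseMatrix(
            list(self.labels),
            scale - self.values,
            Polarity.DISTANCE,
            DiagonalPolicy.ZERO,
        )


def offdiag_vector(m: PairwiseMatrix) -> np.ndarray:
    """Flatten a pairwise matrix to its n(n-1)/2 upper-triangle values.

    Order is row-major over pairs (i, j) with i < j — (0,1), (0,2), …,
    (1,2), … — fixed so that paired statistics across two matrices with the
    same label order compare like with like.
    """
    if m.n < 2:
        raise ValueError("need n >= 2 for an off-diagonal vector")
    iu = np.triu_indices(m.n, k=1)
    return m.values[iu].copy()


def write_pairwise_csv(m: PairwiseMatrix, path: str | Path) -> None:
    """Write square labeled CSV with a leading ``# polarity:`` metadata line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# polarity: {m.polarity.value}\n")
        pd.DataFrame(m.values, index=m.labels, columns=m.labels).to_csv(
            fh, index_label="group"
        )


def read_pairwise_csv(
    path: str | Path, polarity: Polarity | None = None
) -> PairwiseMatrix:
    """Read a square labeled matrix CSV (first row and column are labels).

    A leading ``# polarity: …`` comment line, if present, supplies the
    polarity; an explicit ``polarity`` argument overrides it.  Plain square
    matrices without metadata (the deposited-table layout) default to
    DISTANCE.
    """
    path = Path(path)
    sniffed: Polarity | None = None
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "polarity:" in first:
                sniffed = Polarity(first.split("polarity:")[1].strip())
            df = pd.read_csv(fh, index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, index_col=0)
    pol = polarity if polarity is not None else (sniffed or Polarity.DISTANCE)
    labels = [str(x) for x in df.index]
    if [str(c) for c in df.columns] != labels:
        raise ValueError(f"{path}: row and column labels differ")
    diag = (
        DiagonalPolicy.ZERO
        if Polarity(pol) is Polarity.DISTANCE
        else DiagonalPolicy.ONE
    )
    return PairwiseMatrix(labels, df.to_numpy(dtype=float), Polarity(pol), diag)
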