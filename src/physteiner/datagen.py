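"""Synthetic drug-feature tables with planted therapeutic classes.

The pipeline consumes a binary drug x feature matrix whose columns fall into
named category blocks (chemical, therapeutic, protein, phenotype in the
motivating application) together with a mapping of drugs to therapeutic
subclasses. This module generates such data with a *planted-core* model: every
subclass reserves a disjoint run of feature columns (its "core"), and class
members switch those columns on with a high rate while every other entry is
background noise. Because Jaccard similarity is driven by shared present
features, the two rates directly control how much more similar same-class
drugs are than unrelated ones, which makes subnetwork recovery testable
without any external dataset.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from physteiner.errors import FormatError, ParameterError

__all__ = [
    "FeatureTable",
    "ClassMembership",
    "generate_feature_table",
    "write_feature_table",
    "load_feature_table",
    "write_class_membership",
    "load_class_membership",
]

#: Feature-category block sizes of the reference drug dataset
#: (chemical, therapeutic, protein, phenotype).
DEFAULT_BLOCK_SIZES: tuple[int, ...] = (881, 719, 775, 1385)


@dataclass(frozen=True)
class FeatureTable:
    """A binary drug x feature matrix with category block structure.

    Parameters
    ----------
    drug_ids
        Ordered, unique drug identifiers (one per matrix row).
    matrix
        2-D array of 0/1 values, shape ``(len(drug_ids), sum(block_sizes))``.
    block_sizes
        Number of feature columns per category, in column order.
    """

    drug_ids: tuple[str, ...]
    matrix: np.ndarray
    block_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))
        object.__setattr__(self, "block_sizes", tuple(self.block_sizes))
        mat = np.asarray(self.matrix, dtype=np.uint8)
        object.__setattr__(self, "matrix", mat)
        if len(self.drug_ids) < 2:
            raise ParameterError("a feature table needs at least 2 drugs")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ParameterError("drug_ids must be unique")
        if not self.block_sizes or any(b <= 0 for b in self.block_sizes):
            raise ParameterError("block_sizes must be non-empty positive counts")
        if mat.ndim != 2 or mat.shape != (len(self.drug_ids), sum(self.block_sizes)):
            raise ParameterError(
                f"matrix shape {mat.shape} does not match "
                f"{len(self.drug_ids)} drugs x {sum(self.block_sizes)} features"
            )
        if not np.isin(mat, (0, 1)).all():
            raise ParameterError("matrix entries must be 0/1")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_features(self) -> int:
        return int(self.matrix.shape[1])

    def row(self, drug_id: str) -> np.ndarray:
        """Feature vector of one drug."""
        return self.matrix[self.drug_ids.index(drug_id)]


@dataclass(frozen=True)
class ClassMembership:
    """Drug-to-subclass assignments plus the derived superclass.

    ``subclass_sets`` maps each subclass label to its member drugs;
    ``superclass_set`` is the union over all subclasses (the analogue of a
    whole ATC class when subclasses are its subdivisions); ``class_of`` maps
    each classified drug to the set of subclasses it belongs to.
    """

    subclass_sets: Mapping[str, frozenset[str]]
    class_of: Mapping[str, frozenset[str]] = field(default_factory=dict)
    superclass_set: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        subs = {label: frozenset(members) for label, members in self.subclass_sets.items()}
        object.__setattr__(self, "subclass_sets", subs)
        union: set[str] = set()
        class_of: dict[str, set[str]] = {}
        for label, members in subs.items():
            union |= members
            for d in members:
                class_of.setdefault(d, set()).add(label)
        object.__setattr__(self, "superclass_set", frozenset(union))
        object.__setattr__(
            self, "class_of", {d: frozenset(ls) for d, ls in class_of.items()}
        )

    def members(self, subclass: str) -> frozenset[str]:
        try:
            return self.subclass_sets[subclass]
        except KeyError:
            raise KeyError(f"unknown subclass {subclass!r}") from None


def generate_feature_table(
    n_drugs: int,
    block_sizes: Sequence[int] = DEFAULT_BLOCK_SIZES,
    classes: Sequence[tuple[str, int]] = (),
    within_class_feature_rate: float = 0.9,
    background_rate: float | tuple[float, float] = (0.1, 0.4),
    shared_core_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[FeatureTable, ClassMembership]:
    """Generate a binary feature table with planted classes.

    Each class reserves ``round(shared_core_fraction * n_features)`` feature
    columns as its core; cores of different classes are disjoint, allocated
    left to right across the concatenated blocks. Class members set core
    columns to 1 with probability ``within_class_feature_rate``; every other
    entry (including all entries of unclassified drugs) is 1 with the drug's
    background rate.

    ``background_rate`` may be a single probability (every drug annotated at
    the same density) or a ``(low, high)`` pair, in which case each drug
    draws its own rate uniformly from that interval. Real pharmacological
    annotation density varies strongly between drugs, and this heterogeneity
    is what spreads pairwise Jaccard costs over a wide band (roughly 0.6-1.0
    with the defaults, the bulk below 0.9) instead of collapsing them onto a
    single value; threshold-based edge deletion needs that spread to leave a
    connected graph. Planted class pairs remain systematically cheaper than
    background pairs.

    Returns
    -------
    (FeatureTable, ClassMembership)
        Deterministic given ``seed``.
    """
    if isinstance(background_rate, (tuple, list)):
        lo, hi = background_rate
        if not (0.0 <= lo <= hi <= 1.0):
            raise ParameterError(
                f"background_rate range must satisfy 0 <= low <= high <= 1, got {background_rate}"
            )
    elif not 0.0 <= background_rate <= 1.0:
        raise ParameterError(f"background_rate must lie in [0, 1], got {background_rate}")
    for name, value in (
        ("within_class_feature_rate", within_class_feature_rate),
        ("shared_core_fraction", shared_core_fraction),
    ):
        if not 0.0 <= value <= 1.0:
            raise ParameterError(f"{name} must lie in [0, 1], got {value}")
    if n_drugs < 2:
        raise ParameterError("n_drugs must be at least 2")
    if not block_sizes or any(int(b) <= 0 for b in block_sizes):
        raise ParameterError("block_sizes must be non-empty positive counts")
    labels = [label for label, _ in classes]
    if len(set(labels)) != len(labels):
        raise ParameterError("class labels must be unique")
    if any(count < 1 for _, count in classes):
        raise ParameterError("class member counts must be positive")
    total_members = sum(count for _, count in classes)
    if total_members > n_drugs:
        raise ParameterError(
            f"classes require {total_members} drugs but only {n_drugs} available"
        )

    n_features = int(sum(block_sizes))
    core_size = int(round(shared_core_fraction * n_features))
    if classes and core_size * len(classes) > n_features:
        raise ParameterError(
            f"{len(classes)} disjoint cores of {core_size} columns do not fit "
            f"in {n_features} features; lower shared_core_fraction"
        )

    width = max(3, len(str(n_drugs)))
    drug_ids = tuple(f"drug{i:0{width}d}" for i in range(1, n_drugs + 1))

    rng = np.random.default_rng(seed)
    if isinstance(background_rate, (tuple, list)):
        lo, hi = background_rate
        per_drug_rate = rng.uniform(lo, hi, size=(n_drugs, 1))
    else:
        per_drug_rate = np.full((n_drugs, 1), float(background_rate))
    matrix = (rng.random((n_drugs, n_features)) < per_drug_rate).astype(np.uint8)

    subclass_sets: dict[str, frozenset[str]] = {}
    row_start = 0
    col_start = 0
    for label, count in classes:
        rows = slice(row_start, row_start + count)
        cols = slice(col_start, col_start + core_size)
        core = rng.random((count, core_size)) < within_class_feature_rate
        matrix[rows, cols] = core.astype(np.uint8)
        subclass_sets[label] = frozenset(drug_ids[row_start : row_start + count])
        row_start += count
        col_start += core_size

    table = FeatureTable(drug_ids=drug_ids, matrix=matrix, block_sizes=tuple(int(b) for b in block_sizes))
    membership = ClassMembership(subclass_sets=subclass_sets)
    return table, membership


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as TSV (header = feature names, first column = drug id)."""
    path = Path(path)
    n = table.n_features
    width = len(str(n))
    header = ["drug_id"] + [f"f{k:0{width}d}" for k in range(1, n + 1)]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for drug, row in zip(table.drug_ids, table.matrix):
            writer.writerow([drug] + [str(int(x)) for x in row])


def load_feature_table(path: str | Path, block_sizes: Sequence[int]) -> FeatureTable:
    """Load a TSV feature table written by :func:`write_feature_table`.

    Raises
    ------
    FormatError
        On a non-binary cell (naming its row and column) or a duplicate
        drug id; also when the column count disagrees with ``block_sizes``.
    """
    path = Path(path)
    drug_ids: list[str] = []
    rows: list[list[int]] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        n_cols = len(header) - 1
        if n_cols != sum(block_sizes):
            raise FormatError(
                f"{path}: {n_cols} feature columns but block_sizes sum to {sum(block_sizes)}"
            )
        seen: set[str] = set()
        for r, record in enumerate(reader, start=2):
            if not record:
                continue
            drug = record[0]
            if drug in seen:
                raise FormatError(f"{path}: duplicate drug id {drug!r} at line {r}")
            seen.add(drug)
            if len(record) - 1 != n_cols:
                raise FormatError(f"{path}: line {r} has {len(record) - 1} cells, expected {n_cols}")
            row: list[int] = []
            for c, cell in enumerate(record[1:], start=1):
                if cell not in ("0", "1"):
                    raise FormatError(
                        f"{path}: non-binary cell {cell!r} at drug {drug!r}, column {header[c]!r}"
                    )
                row.append(int(cell))
            drug_ids.append(drug)
            rows.append(row)
    return FeatureTable(
        drug_ids=tuple(drug_ids),
        matrix=np.array(rows, dtype=np.uint8),
        block_sizes=tuple(int(b) for b in block_sizes),
    )


def write_class_membership(membership: ClassMembership, path: str | Path) -> None:
    """Write memberships as TSV with columns drug_id, subclass_label (one row per membership)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["drug_id", "subclass_label"])
        for label in sorted(membership.subclass_sets):
            for drug in sorted(membership.subclass_sets[label]):
                writer.writerow([drug, label])


def load_class_membership(path: str | Path) -> ClassMembership:
    """Load a membership TSV written by :func:`write_class_membership`."""
    path = Path(path)
    subclass_sets: dict[str, set[str]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["drug_id", "subclass_label"]:
            raise FormatError(f"{path}: expected header 'drug_id\\tsubclass_label'")
        for r, record in enumerate(reader, start=2):
            if not record:
                continue
            if len(record) != 2:
                raise FormatError(f"{path}: line {r} does not have exactly 2 columns")
            drug, label = record
            subclass_sets.setdefault(label, set()).add(drug)
    return ClassMembership(
        subclass_sets={label: frozenset(m) for label, m in subclass_sets.items()}
    )
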