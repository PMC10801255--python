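"""Core data containers, Dirichlet non-IID partitioning, and group index maps.

A federated simulation needs three things before any training happens: the
pooled tabular dataset, a disjoint assignment of its rows to clients, and a
map from rows to the fairness groups over which performance will be
equalized (clients, attribute value-combinations, both, or occupied
client x attribute cells).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LEVELS = ("client", "attribute", "multilevel", "agnostic")


@dataclass
class TabularDataset:
    """Feature matrix plus integer labels and named categorical attributes.

    Parameters
    ----------
    features : (n, d) float array
    labels : (n,) int array with values in {0..K-1}
    attributes : mapping of column name -> (n,) int array of contiguous codes
    feature_names : optional list of d column names
    attribute_value_labels : optional mapping name -> list of value labels
    """

    features: np.ndarray
    labels: np.ndarray
    attributes: dict[str, np.ndarray] = field(default_factory=dict)
    feature_names: list[str] | None = None
    attribute_value_labels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n = self.features.shape[0]
        if self.labels.shape != (n,):
            raise ValueError("labels length must match feature rows")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain NaN/Inf; clean the table first")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative integer codes")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        for name, col in self.attributes.items():
            col = np.asarray(col, dtype=int)
            if col.shape != (n,):
                raise ValueError(f"attribute {name!r} length mismatch")
            codes = np.unique(col)
            if codes.min() < 0 or not np.array_equal(codes, np.arange(len(codes))):
                raise ValueError(
                    f"attribute {name!r} codes must be contiguous from 0"
                )
            self.attributes[name] = col
        if self.feature_names is None:
            self.feature_names = [f"x{j}" for j in range(self.features.shape[1])]

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1


def load_table(
    path,
    label_column: str,
    attribute_columns: list[str] | None = None,
    feature_columns: list[str] | None = None,
    sep: str = ",",
) -> TabularDataset:
    """Read a delimited table and label-encode the categorical columns.

    ``feature_columns`` defaults to every column that is neither the label
    nor an attribute.  Attribute columns also remain available as features
    only if explicitly listed in ``feature_columns``.
    """
    df = pd.read_csv(path, sep=sep)
    attribute_columns = list(attribute_columns or [])
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not in table")
    for col in attribute_columns:
        if col not in df.columns:
            raise ValueError(f"attribute column {col!r} not in table")
    if df.isna().any().any():
        raise ValueError("table contains missing values; drop or impute first")
    if feature_columns is None:
        feature_columns = [
            c for c in df.columns if c != label_column and c not in attribute_columns
        ]
    labels, _ = pd.factorize(df[label_column], sort=True)
    attributes: dict[str, np.ndarray] = {}
    value_labels: dict[str, list[str]] = {}
    for col in attribute_columns:
        codes, uniques = pd.factorize(df[col], sort=True)
        attributes[col] = codes.astype(int)
        value_labels[col] = [str(v) for v in uniques]
    feats = df[feature_columns].to_numpy(dtype=float)
    return TabularDataset(
        features=feats,
        labels=labels.astype(int),
        attributes=attributes,
        feature_names=list(feature_columns),
        attribute_value_labels=value_labels,
    )


@dataclass
class FederatedPartition:
    """Disjoint assignment of dataset rows to ``n_clients`` simulated clients."""

    client_rows: list[np.ndarray]
    alpha: float
    seed: int

    def __post_init__(self) -> None:
        self.client_rows = [np.asarray(r, dtype=int) for r in self.client_rows]

    @property
    def n_clients(self) -> int:
        return len(self.client_rows)

    @property
    def n_rows(self) -> int:
        return sum(len(r) for r in self.client_rows)

    def client_of_row(self, n_rows: int | None = None) -> np.ndarray:
        """Inverse map: row index -> client index."""
        n = n_rows if n_rows is not None else self.n_rows
        out = np.full(n, -1, dtype=int)
        for i, rows in enumerate(self.client_rows):
            out[rows] = i
        return out

    def validate_covering(self, n_rows: int) -> None:
        """Check the client sets are disjoint and cover 0..n_rows-1 exactly."""
        allrows = np.concatenate(self.client_rows) if self.client_rows else np.array([], int)
        if len(allrows) != n_rows or not np.array_equal(np.sort(allrows), np.arange(n_rows)):
            raise ValueError("partition is not a disjoint covering of the rows")

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "seed": self.seed,
                "client_rows": [r.tolist() for r in self.client_rows],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FederatedPartition":
        obj = json.loads(text)
        return cls(
            client_rows=[np.asarray(r, int) for r in obj["client_rows"]],
            alpha=obj["alpha"],
            seed=obj["seed"],
        )


def _largest_remainder(quota: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` closest to the fractional quotas.

    Ties on the fractional parts are broken by client index (stable sort).
    """
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    frac = quota - base
    order = np.argsort(-frac, kind="stable")
    base[order[:short]] += 1
    return base


def partition_dirichlet(
    dataset: TabularDataset,
    n_clients: int,
    alpha: float,
    seed: int,
    min_per_client: int = 2,
    max_retries: int = 100,
    rows: np.ndarray | None = None,
) -> FederatedPartition:
    """Partition rows across clients with label-skew drawn from a Dirichlet.

    For each class a proportion vector over clients is drawn from the
    symmetric Dirichlet with concentration ``alpha``; the class's rows are
    shuffled and allocated to clients by largest-remainder rounding of the
    proportions.  Small ``alpha`` concentrates each class on few clients
    (strong heterogeneity); large ``alpha`` approaches an even split.

    ``rows`` restricts the partition to a subset of the dataset's rows
    (used when repartitioning held-out data for agnostic evaluation).
    Deterministic given ``seed``.
    """
    if n_clients < 1:
        raise ValueError("n_clients must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    pool = np.arange(dataset.n_rows) if rows is None else np.asarray(rows, int)
    if len(pool) < n_clients * min_per_client:
        raise ValueError(
            f"cannot give {n_clients} clients >= {min_per_client} rows "
            f"from {len(pool)} rows"
        )
    labels = dataset.labels[pool]
    classes = np.unique(labels)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E3779B9]))
    for attempt in range(max_retries + 1):
        buckets: list[list[np.ndarray]] = [[] for _ in range(n_clients)]
        for k in classes:
            rows_k = pool[labels == k]
            rows_k = rng.permutation(rows_k)
            props = rng.dirichlet(np.full(n_clients, alpha))
            counts = _largest_remainder(props * len(rows_k), len(rows_k))
            stops = np.cumsum(counts)[:-1]
            for i, chunk in enumerate(np.split(rows_k, stops)):
                buckets[i].append(chunk)
        client_rows = [
            np.sort(np.concatenate(b)) if b else np.array([], int) for b in buckets
        ]
        sizes = [len(r) for r in client_rows]
        if min(sizes) >= min_per_client:
            part = FederatedPartition(client_rows=client_rows, alpha=alpha, seed=seed)
            if rows is None:
                part.validate_covering(dataset.n_rows)
            return part
    raise ValueError(
        f"Dirichlet partition infeasible: alpha={alpha}, n_clients={n_clients}, "
        f"min_per_client={min_per_client} not met after {max_retries} retries "
        f"(last sizes {sizes})"
    )


def split_train_test(
    partition: FederatedPartition,
    dataset: TabularDataset,
    test_fraction: float,
    seed: int,
) -> tuple[FederatedPartition, FederatedPartition]:
    """Per-client train/test split, stratified by label where possible.

    Within each client the rows are split label-by-label so train and test
    keep the client's class mix; a (client, label) cell with fewer than 2
    rows falls back to an unstratified draw for that cell (logged).
    Returns two partitions over the same clients with disjoint row sets.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51ED270B]))
    train_sets, test_sets = [], []
    for ci, rows in enumerate(partition.client_rows):
        rows = np.asarray(rows, int)
        n_test_target = int(round(test_fraction * len(rows)))
        labs = dataset.labels[rows]
        test_mask = np.zeros(len(rows), dtype=bool)
        for k in np.unique(labs):
            idx = np.flatnonzero(labs == k)
            if len(idx) < 2:
                logger.debug(
                    "client %d label %d has %d row(s); unstratified fallback",
                    ci, k, len(idx),
                )
                continue
            take = int(round(test_fraction * len(idx)))
            chosen = rng.choice(idx, size=take, replace=False)
            test_mask[chosen] = True
        # per-cell rounding can drift from the per-client target; top up or
        # trim randomly so every client lands on round(test_fraction * rows)
        delta = n_test_target - int(test_mask.sum())
        if delta > 0:
            pool = np.flatnonzero(~test_mask)
            chosen = rng.choice(pool, size=min(delta, len(pool)), replace=False)
            test_mask[chosen] = True
        elif delta < 0:
            pool = np.flatnonzero(test_mask)
            chosen = rng.choice(pool, size=min(-delta, len(pool)), replace=False)
            test_mask[chosen] = False
        train_sets.append(np.sort(rows[~test_mask]))
        test_sets.append(np.sort(rows[test_mask]))
    train = FederatedPartition(train_sets, alpha=partition.alpha, seed=seed)
    test = FederatedPartition(test_sets, alpha=partition.alpha, seed=seed)
    return train, test


@dataclass
class GroupingScheme:
    """Row -> fairness-group index map for one fairness level.

    For ``multilevel`` both the client map and the attribute map are kept;
    ``group_of_row``/``n_groups`` then mirror the client map for uniform
    downstream handling.  For ``agnostic`` each group is an occupied
    (client, attribute-value-combination) cell, indices compacted.
    """

    level: str
    group_of_row: np.ndarray
    n_groups: int
    client_group_of_row: np.ndarray | None = None
    attribute_group_of_row: np.ndarray | None = None
    n_attribute_groups: int | None = None
    source_attributes: list[str] = field(default_factory=list)
    group_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.group_of_row = np.asarray(self.group_of_row, dtype=int)
        present = np.unique(self.group_of_row[self.group_of_row >= 0])
        if not np.array_equal(present, np.arange(self.n_groups)):
            raise ValueError("group indices must be contiguous 0..n_groups-1, all non-empty")

    def group_sizes(self, rows: np.ndarray | None = None) -> np.ndarray:
        g = self.group_of_row if rows is None else self.group_of_row[rows]
        return np.bincount(g, minlength=self.n_groups)

    def to_json(self) -> str:
        obj = {
            "level": self.level,
            "n_groups": self.n_groups,
            "group_of_row": self.group_of_row.tolist(),
            "source_attributes": self.source_attributes,
            "group_labels": self.group_labels,
        }
        if self.attribute_group_of_row is not None:
            obj["attribute_group_of_row"] = self.attribute_group_of_row.tolist()
            obj["n_attribute_groups"] = self.n_attribute_groups
        return json.dumps(obj)


def _attribute_codes(
    dataset: TabularDataset, attribute_columns: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Compact codes for observed value-combinations of the named columns."""
    for col in attribute_columns:
        if col not in dataset.attributes:
            raise ValueError(f"unknown attribute column {col!r}")
    cols = [dataset.attributes[c] for c in attribute_columns]
    combo = np.stack(cols, axis=1)
    uniq, codes = np.unique(combo, axis=0, return_inverse=True)
    labels = ["/".join(str(v) for v in row) for row in uniq]
    return codes.astype(int), labels


def build_grouping(
    dataset: TabularDataset,
    partition: FederatedPartition,
    level: str,
    attribute_columns: list[str] | None = None,
) -> GroupingScheme:
    """Construct the row->group map realizing one fairness level.

    client      groups are the N clients.
    attribute   groups are observed value-combinations of the named columns.
    multilevel  both maps retained (client map is the primary index).
    agnostic    groups are occupied (client x attribute-combination) cells,
                empty cells dropped and indices compacted.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    client_map = partition.client_of_row(dataset.n_rows)
    if (client_map < 0).any():
        raise ValueError("partition does not cover the dataset rows")
    if level == "client":
        return GroupingScheme(
            level=level,
            group_of_row=client_map,
            n_groups=partition.n_clients,
            group_labels=[f"client{i}" for i in range(partition.n_clients)],
        )
    if not attribute_columns:
        raise ValueError(f"attribute_columns required for level={level!r}")
    attr_map, attr_labels = _attribute_codes(dataset, attribute_columns)
    if level == "attribute":
        return GroupingScheme(
            level=level,
            group_of_row=attr_map,
            n_groups=len(attr_labels),
            source_attributes=list(attribute_columns),
            group_labels=attr_labels,
        )
    if level == "multilevel":
        return GroupingScheme(
            level=level,
            group_of_row=client_map,
            n_groups=partition.n_clients,
            client_group_of_row=client_map,
            attribute_group_of_row=attr_map,
            n_attribute_groups=len(attr_labels),
            source_attributes=list(attribute_columns),
            group_labels=[f"client{i}" for i in range(partition.n_clients)],
        )
    # agnostic: occupied client x attribute cells, compacted
    pair = np.stack([client_map, attr_map], axis=1)
    uniq, codes = np.unique(pair, axis=0, return_inverse=True)
    labels = [f"client{c}|{attr_labels[a]}" for c, a in uniq]
    return GroupingScheme(
        level=level,
        group_of_row=codes.astype(int),
        n_groups=len(uniq),
        client_group_of_row=client_map,
        attribute_group_of_row=attr_map,
        n_attribute_groups=len(attr_labels),
        source_attributes=list(attribute_columns),
        group_labels=labels,
    )
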