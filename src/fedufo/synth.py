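"""Synthetic clinical-tabular federated benchmarks.

Generates K-class Gaussian-mixture tabular data with two controllable
axes of difficulty: client heterogeneity (Dirichlet label skew with
concentration ``alpha``) and attribute-conditional covariate shift
(each attribute value displaces the feature means by a fixed unit
vector scaled by ``attribute_shift``), so that some attribute groups
and some clients are genuinely harder than others and fairness
interventions have something to correct.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .data import (
    FederatedPartition,
    GroupingScheme,
    TabularDataset,
    build_grouping,
    partition_dirichlet,
    split_train_test,
)


@dataclass(frozen=True)
class AttributeSpec:
    """One categorical attribute: name, number of values, mixing proportions."""

    name: str
    n_values: int
    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.proportions) != self.n_values:
            raise ValueError("proportions length must equal n_values")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if min(self.proportions) <= 0:
            raise ValueError("proportions must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic federated benchmark.

    Defaults describe a moderately separable, strongly heterogeneous
    4-client cohort: ``class_separation`` is the exact pairwise distance
    between class-conditional feature means (in units of the noise SD,
    which is 1), ``attribute_shift`` the mean displacement per attribute
    value, and ``alpha`` the Dirichlet label-skew concentration.
    """

    n: int = 2000
    d: int = 12
    K: int = 3
    n_clients: int = 4
    alpha: float = 0.1
    attribute_spec: tuple[AttributeSpec, ...] = (
        AttributeSpec("sex", 2, (0.5, 0.5)),
    )
    class_separation: float = 2.5
    attribute_shift: float = 1.5
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_separation < 0 or self.attribute_shift < 0:
            raise ValueError("separations must be non-negative")
        if not 0 <= self.label_noise < 1:
            raise ValueError("label_noise must be in [0, 1)")
        if self.K < 2 or self.n < 1 or self.d < 1 or self.n_clients < 1:
            raise ValueError("n, d, K, n_clients must be positive (K >= 2)")
        if self.class_separation > 0 and self.d < self.K - 1:
            raise ValueError(
                f"d={self.d} cannot hold {self.K} class means at pairwise "
                f"distance {self.class_separation}; need d >= K-1"
            )

    def to_dict(self) -> dict:
        obj = dataclasses.asdict(self)
        obj["attribute_spec"] = [
            {"name": a.name, "n_values": a.n_values, "proportions": list(a.proportions)}
            for a in self.attribute_spec
        ]
        return obj

    @classmethod
    def from_dict(cls, obj: dict) -> "SyntheticSpec":
        obj = dict(obj)
        if "attribute_spec" in obj:  # absent key keeps the class default
            obj["attribute_spec"] = tuple(
                AttributeSpec(a["name"], a["n_values"], tuple(a["proportions"]))
                for a in obj["attribute_spec"]
            )
        return cls(**obj)


def _simplex_means(K: int, d: int, separation: float) -> np.ndarray:
    """K points in R^d with every pairwise distance exactly ``separation``.

    Vertices of the regular (K-1)-simplex, centered, embedded in the
    first K-1 coordinates.
    """
    if separation == 0:
        return np.zeros((K, d))
    eye = np.eye(K)
    centered = eye - eye.mean(axis=0)
    # orthonormal basis of the (K-1)-dim affine hull
    u, s, _ = np.linalg.svd(centered.T, full_matrices=False)
    coords = centered @ u[:, : K - 1]
    # identity vertices are sqrt(2) apart
    coords *= separation / np.sqrt(2.0)
    means = np.zeros((K, d))
    means[:, : K - 1] = coords
    return means


def generate_population(spec: SyntheticSpec) -> TabularDataset:
    """Draw the i.i.d. population table described by ``spec``.

    Row recipe: attribute values ~ their mixing proportions; label ~
    uniform class prior; features = class mean + attribute displacement +
    standard Gaussian noise; label flipped to a random other class with
    probability ``label_noise``.  Deterministic given ``spec.seed``.
    """
    root = np.random.SeedSequence([spec.seed, 0x5EEDDA7A])
    s_attr, s_label, s_noise, s_disp, s_flip = root.spawn(5)
    rng_attr = np.random.default_rng(s_attr)
    rng_label = np.random.default_rng(s_label)
    rng_noise = np.random.default_rng(s_noise)
    rng_disp = np.random.default_rng(s_disp)
    rng_flip = np.random.default_rng(s_flip)

    means = _simplex_means(spec.K, spec.d, spec.class_separation)

    # fixed unit displacement per (attribute, value), drawn once per seed
    displacements: dict[str, np.ndarray] = {}
    for a in spec.attribute_spec:
        vecs = rng_disp.standard_normal((a.n_values, spec.d))
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        displacements[a.name] = vecs

    attributes: dict[str, np.ndarray] = {}
    shift = np.zeros((spec.n, spec.d))
    for a in spec.attribute_spec:
        vals = rng_attr.choice(a.n_values, size=spec.n, p=a.proportions)
        attributes[a.name] = vals.astype(int)
        shift += spec.attribute_shift * displacements[a.name][vals]

    labels = rng_label.integers(0, spec.K, size=spec.n)
    features = means[labels] + shift + rng_noise.standard_normal((spec.n, spec.d))

    if spec.label_noise > 0:
        flip = rng_flip.random(spec.n) < spec.label_noise
        offset = rng_flip.integers(1, spec.K, size=spec.n)
        labels = np.where(flip, (labels + offset) % spec.K, labels)

    value_labels = {
        a.name: [f"{a.name}{v}" for v in range(a.n_values)] for a in spec.attribute_spec
    }
    return TabularDataset(
        features=features,
        labels=labels.astype(int),
        attributes=attributes,
        attribute_value_labels=value_labels,
    )


@dataclass
class Benchmark:
    """Everything a federated run consumes, from one generator call."""

    dataset: TabularDataset
    partition: FederatedPartition
    train: FederatedPartition
    test: FederatedPartition
    groupings: dict[str, GroupingScheme]
    manifest: dict = field(default_factory=dict)

    @property
    def attribute_columns(self) -> list[str]:
        return self.manifest.get("attribute_columns", list(self.dataset.attributes))


def make_benchmark(
    spec: SyntheticSpec,
    test_fraction: float = 0.2,
    attribute_columns: list[str] | None = None,
    min_per_client: int = 10,
) -> Benchmark:
    """Generate population, Dirichlet-partition it, 80/20-split each client,
    and build the groupings for all four fairness levels.

    ``min_per_client`` is stricter here than in the raw partition so that
    every client keeps rows on both sides of the train/test split and
    per-client metrics stay defined even at extreme heterogeneity.
    The manifest records every parameter and derived seed so the benchmark
    regenerates byte-identically from the manifest alone.
    """
    dataset = generate_population(spec)
    part_seed = spec.seed + 1
    split_seed = spec.seed + 2
    partition = partition_dirichlet(
        dataset, spec.n_clients, spec.alpha, seed=part_seed,
        min_per_client=min_per_client,
    )
    train, test = split_train_test(partition, dataset, test_fraction, seed=split_seed)
    attribute_columns = attribute_columns or [spec.attribute_spec[0].name]
    groupings = {
        level: build_grouping(dataset, partition, level, attribute_columns)
        for level in ("client", "attribute", "multilevel", "agnostic")
    }
    manifest = {
        "spec": spec.to_dict(),
        "test_fraction": test_fraction,
        "attribute_columns": attribute_columns,
        "min_per_client": min_per_client,
        "partition_seed": part_seed,
        "split_seed": split_seed,
    }
    return Benchmark(
        dataset=dataset,
        partition=partition,
        train=train,
        test=test,
        groupings=groupings,
        manifest=manifest,
    )


def benchmark_from_manifest(manifest: dict | str) -> Benchmark:
    """Regenerate a benchmark exactly from its JSON manifest."""
    if isinstance(manifest, str):
        manifest = json.loads(manifest)
    spec = SyntheticSpec.from_dict(manifest["spec"])
    return make_benchmark(
        spec,
        test_fraction=manifest["test_fraction"],
        attribute_columns=manifest["attribute_columns"],
        min_per_client=manifest.get("min_per_client", 10),
    )
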