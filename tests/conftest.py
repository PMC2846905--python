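import numpy as np
import pytest

from mrsclassify import (
    ClassDefinition,
    ClassSpec,
    DesignMatrix,
    PeakSpec,
    RegionOfInterest,
    build_design_matrix,
    default_scenario,
    generate_class_dataset,
)

THREE_CLASSES = [
    ClassDefinition("low-grade m", ["mm"]),
    ClassDefinition("aggressive", ["gl", "me"]),
    ClassDefinition("low-grade g", ["a2", "oa", "od"]),
]


def make_blob_dm(
    n_per_class=10, n_features=4, n_classes=3, separation=8.0, seed=0
) -> DesignMatrix:
    """Well-separated Gaussian blobs as a design matrix."""
    rng = np.random.default_rng(seed)
    rows, ys = [], []
    for c in range(n_classes):
        centre = np.zeros(n_features)
        centre[c % n_features] = separation * (c + 1)
        rows.append(centre + rng.normal(size=(n_per_class, n_features)))
        ys += [c] * n_per_class
    X = np.vstack(rows)
    return DesignMatrix(
        X=X,
        y=np.array(ys),
        case_ids=[f"case_{i}" for i in range(len(ys))],
        feature_labels=[("DS1", 4.0 - 0.1 * j) for j in range(n_features)],
        class_names=[f"class{c}" for c in range(n_classes)],
    )


def random_dm(n=30, p=5, n_classes=3, seed=0) -> DesignMatrix:
    """Random (weakly structured) design matrix."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = rng.integers(0, n_classes, size=n)
    # ensure every class has at least two members
    for c in range(n_classes):
        y[2 * c] = c
        y[2 * c + 1] = c
    X[np.arange(n), y % p] += 1.5
    return DesignMatrix(
        X=X,
        y=y,
        case_ids=[f"c{i}" for i in range(n)],
        feature_labels=[("DS1", 4.0 - 0.02 * j) for j in range(p)],
        class_names=[f"class{c}" for c in range(n_classes)],
    )


@pytest.fixture
def small_scenario():
    """A reduced copy of the packaged scenario for fast tests."""
    return default_scenario(n_cases_per_class=8)


@pytest.fixture
def small_dataset(small_scenario):
    return generate_class_dataset(small_scenario, seed=11)


@pytest.fixture
def small_dm(small_dataset):
    return build_design_matrix(
        small_dataset, THREE_CLASSES, RegionOfInterest(4.5, 0.5)
    )


@pytest.fixture
def two_peak_specs():
    """Two synthetic classes separated by a single peak amplitude."""
    shared = [PeakSpec(3.0, 0.1, 6.0, 0.5)]
    return [
        ClassSpec("A", ["aa"], shared + [PeakSpec(1.5, 0.1, 12.0, 0.5)], 10, 1.0),
        ClassSpec("B", ["bb"], shared + [PeakSpec(1.5, 0.1, 2.0, 0.5)], 10, 1.0),
    ]
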