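"""In-memory data model for MRS classification studies.

A :class:`Spectrum` is one frequency-domain trace on a descending ppm
(chemical-shift) axis. A :class:`Case` groups the spectra of one subject
with its tissue-type code, and an :class:`MrsDataset` holds the cases of
a study. Classifier inputs are built by cutting a region of interest out
of each case's spectrum (optionally concatenating a second acquisition,
e.g. at a different echo time) into a :class:`DesignMatrix`.

ppm axis convention: index ``i`` of an ``n``-point spectrum maps to
``ppm_high - i * (ppm_high - ppm_low) / (n - 1)``, endpoints inclusive,
so the axis is strictly descending — the orientation spectra are
conventionally plotted in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ClassOverlap,
    EmptyClass,
    EmptyRoi,
    MixedAxisLengths,
    NoCases,
)

CANONICAL_PPM_HIGH = 7.2
CANONICAL_PPM_LOW = -2.8
CANONICAL_POINTS = 512

HRMAS_PPM_HIGH = 4.5
HRMAS_PPM_LOW = 0.5


def ppm_axis(n_points: int, ppm_high: float, ppm_low: float) -> np.ndarray:
    """Descending, endpoint-inclusive linear chemical-shift axis."""
    if n_points < 2:
        raise ValueError("an axis needs at least 2 points")
    if ppm_high <= ppm_low:
        raise ValueError("ppm_high must exceed ppm_low")
    return np.linspace(ppm_high, ppm_low, n_points)


@dataclass
class Spectrum:
    """One frequency-domain trace.

    Parameters
    ----------
    intensities : array of float
        Point intensities, in axis order (high ppm first).
    ppm_axis : array of float
        Strictly descending chemical shifts, same length.
    map_position : (int, int), optional
        x-y position inside a multi-voxel grid.
    params : dict
        Opaque acquisition metadata, round-tripped verbatim.
    """

    intensities: np.ndarray
    ppm_axis: np.ndarray
    map_position: tuple[int, int] | None = None
    params: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        if self.intensities.ndim != 1 or self.ppm_axis.ndim != 1:
            raise ValueError("intensities and ppm_axis must be 1-D")
        if len(self.intensities) != len(self.ppm_axis):
            raise ValueError("intensities and ppm_axis lengths differ")
        if len(self.intensities) < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.ppm_axis) < 0):
            raise ValueError("ppm_axis must be strictly descending")

    def __len__(self) -> int:
        return len(self.intensities)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            np.array_equal(self.intensities, other.intensities)
            and np.array_equal(self.ppm_axis, other.ppm_axis)
            and self.map_position == other.map_position
            and self.params == other.params
        )


@dataclass
class Case:
    """One subject: identifier, tissue-type code and >=1 spectra."""

    id: str
    tissue_type: str
    spectra: list[Spectrum]

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError(f"case {self.id!r} has no spectra")


@dataclass
class MrsDataset:
    """An ordered collection of cases forming one study dataset.

    The training/testing role is always assigned explicitly by the
    caller, never inferred from content.
    """

    cases: list[Case] = field(default_factory=list)
    role: str = "training"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.cases]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate case ids: {dup}")

    def __len__(self) -> int:
        return len(self.cases)

    def case_by_id(self, case_id: str) -> Case:
        for c in self.cases:
            if c.id == case_id:
                return c
        raise KeyError(case_id)

    def tissue_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.cases:
            counts[c.tissue_type] = counts.get(c.tissue_type, 0) + 1
        return counts


@dataclass(frozen=True)
class ClassDefinition:
    """A classification class: a name plus the tissue types it pools.

    A super-class groups several tissue-type codes (e.g. glioblastoma +
    metastasis as one 'aggressive' class).
    """

    name: str
    member_types: frozenset[str]

    def __init__(self, name: str, member_types) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "member_types", frozenset(member_types))
        if not self.member_types:
            raise ValueError(f"class {name!r} has no member types")


@dataclass(frozen=True)
class RegionOfInterest:
    """Closed ppm interval [ppm_low, ppm_high] used for classification."""

    ppm_high: float
    ppm_low: float

    def __post_init__(self) -> None:
        if not self.ppm_high > self.ppm_low:
            raise ValueError("ppm_high must exceed ppm_low")


@dataclass
class DesignMatrix:
    """Cases x features matrix ready for selection and classification.

    ``feature_labels`` pairs each column with its source dataset tag
    ('DS1' or, for a concatenated second acquisition, 'DS2') and its
    chemical shift in ppm.
    """

    X: np.ndarray
    y: np.ndarray
    case_ids: list[str]
    feature_labels: list[tuple[str, float]]
    class_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != len(self.y) or self.X.shape[0] != len(self.case_ids):
            raise ValueError("row count mismatch between X, y and case_ids")
        if self.X.shape[1] != len(self.feature_labels):
            raise ValueError("column count mismatch with feature_labels")
        if len(self.y) and (self.y.min() < 0 or self.y.max() >= len(self.class_names)):
            raise ValueError("y refers to an undefined class")

    @property
    def n_cases(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def select_columns(self, idx) -> "DesignMatrix":
        """New design matrix restricted to the given feature columns."""
        idx = list(idx)
        return DesignMatrix(
            X=self.X[:, idx],
            y=self.y.copy(),
            case_ids=list(self.case_ids),
            feature_labels=[self.feature_labels[i] for i in idx],
            class_names=list(self.class_names),
        )


def extract_roi(
    spectrum: Spectrum, roi: RegionOfInterest
) -> tuple[np.ndarray, np.ndarray]:
    """Cut the intensities inside a closed ppm interval.

    Returns ``(intensities, ppm_labels)`` at every axis point ``p`` with
    ``ppm_low <= p <= ppm_high``, in descending-ppm order.
    """
    mask = (spectrum.ppm_axis >= roi.ppm_low) & (spectrum.ppm_axis <= roi.ppm_high)
    if not mask.any():
        raise EmptyRoi(
            f"no axis point in [{roi.ppm_low}; {roi.ppm_high}] ppm "
            f"(axis spans [{spectrum.ppm_axis[-1]}; {spectrum.ppm_axis[0]}])"
        )
    return spectrum.intensities[mask], spectrum.ppm_axis[mask]


def _check_disjoint(classes: list[ClassDefinition]) -> None:
    seen: dict[str, str] = {}
    for cd in classes:
        for t in cd.member_types:
            if t in seen:
                raise ClassOverlap(
                    f"tissue type {t!r} belongs to both {seen[t]!r} and {cd.name!r}"
                )
            seen[t] = cd.name


def _class_index(classes: list[ClassDefinition], tissue_type: str) -> int | None:
    for i, cd in enumerate(classes):
        if tissue_type in cd.member_types:
            return i
    return None


def build_design_matrix(
    train: MrsDataset,
    classes: list[ClassDefinition],
    roi: RegionOfInterest,
    second: MrsDataset | None = None,
) -> DesignMatrix:
    """Assemble the cases x features matrix for a set of class definitions.

    Single-dataset mode: one row per case holding the region of interest
    of its first spectrum (feature labels tagged ``DS1``). Two-dataset
    mode: cases are matched across the datasets by identifier, and each
    row is the ROI of the DS1 spectrum followed by the ROI of the
    matching DS2 spectrum; unmatched cases are dropped with a warning.
    Cases whose tissue type belongs to no class are excluded.
    """
    if not 2 <= len(classes) <= 4:
        raise ValueError("classifiers are defined for 2 to 4 classes")
    _check_disjoint(classes)

    if second is not None:
        second_by_id = {c.id: c for c in second.cases}
        kept = [c for c in train.cases if c.id in second_by_id]
        dropped = [c.id for c in train.cases if c.id not in second_by_id]
        dropped += [c.id for c in second.cases if train and c.id not in {k.id for k in kept}]
        if dropped:
            warnings.warn(
                f"{len(set(dropped))} case(s) present in only one dataset were "
                f"dropped: {sorted(set(dropped))[:10]}",
                stacklevel=2,
            )
    else:
        kept = list(train.cases)

    rows: list[np.ndarray] = []
    ys: list[int] = []
    ids: list[str] = []
    labels: list[tuple[str, float]] | None = None
    axis_len: tuple[int, ...] | None = None

    for case in kept:
        ci = _class_index(classes, case.tissue_type)
        if ci is None:
            continue
        spec1 = case.spectra[0]  # first spectrum in file order
        v1, p1 = extract_roi(spec1, roi)
        if second is not None:
            spec2 = second_by_id[case.id].spectra[0]
            v2, p2 = extract_roi(spec2, roi)
            lens = (len(spec1), len(spec2))
            row = np.concatenate([v1, v2])
            lab = [("DS1", p) for p in p1] + [("DS2", p) for p in p2]
        else:
            lens = (len(spec1),)
            row = v1
            lab = [("DS1", p) for p in p1]
        if axis_len is None:
            axis_len, labels = lens, lab
        elif lens != axis_len:
            raise MixedAxisLengths(
                f"case {case.id!r} has spectrum length {lens}, expected {axis_len}"
            )
        rows.append(row)
        ys.append(ci)
        ids.append(case.id)

    if not rows:
        raise NoCases("no case matches the class definitions")
    return DesignMatrix(
        X=np.vstack(rows),
        y=np.asarray(ys),
        case_ids=ids,
        feature_labels=labels,
        class_names=[cd.name for cd in classes],
    )


def class_profile(dm: DesignMatrix, class_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and sample standard deviation of one class.

    The sd uses the n-1 denominator, so a class needs at least two
    members.
    """
    rows = dm.X[dm.y == class_index]
    if rows.shape[0] == 0:
        raise EmptyClass(f"class index {class_index} has no members")
    if rows.shape[0] < 2:
        raise EmptyClass(
            f"class index {class_index} has a single member; sd undefined"
        )
    return rows.mean(axis=0), rows.std(axis=0, ddof=1)
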