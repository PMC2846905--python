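"""CLASSIFIER XML interchange format.

A trained classifier is exported as a CLASSIFIER root (attributes:
name, classification-method, creation-date, plus the common Gaussian
sigma) holding the node sequence Dataset, Classes, Boundaries,
Features, Weights and EvaluationResults:

* Dataset — path of the training dataset file;
* Classes — one Class per classification class, with its prior, its
  projected mean and the tumour types it pools;
* Boundaries — the IntersectionPoint and the outer Point of each
  pairwise class boundary in canonical space (2- and 3-class models);
* Features — the FS/FE method name and the selected features, each a
  dataset tag (DS1/DS2) plus a chemical shift in ppm;
* Weights — one Weight per feature carrying its canonical-variate
  coefficients;
* EvaluationResults — optional; a Bootstrapping node (overall mean and
  standard-deviation attributes plus one node per class) and per-class
  AUC nodes.

All numbers are written in the shortest decimal form that round-trips
the double exactly, so write -> read preserves every stored value
bit-for-bit. The creation-date attribute is ISO-8601 and is ignored on
equality comparison.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
import xml.etree.ElementTree as ET

import numpy as np

from ..errors import SchemaError
from ..lda import Boundaries, FisherLDAClassifier, compute_boundaries
from ..selection import FeatureSelectionResult
from ._num import fmt, parse_float


@dataclass
class EvaluationSummary:
    """Evaluation numbers embedded in the CLASSIFIER XML."""

    bootstrap_mean: float | None = None
    bootstrap_sd: float | None = None
    bootstrap_per_class: list[tuple[str, float, float]] = field(default_factory=list)
    aucs: list[tuple[str, float]] = field(default_factory=list)


def write_classifier_xml(
    model: FisherLDAClassifier,
    features: FeatureSelectionResult,
    evaluation: EvaluationSummary | None,
    path,
    name: str = "classifier",
    dataset_path: str = "",
    class_names: list[str] | None = None,
    class_types: list[list[str]] | None = None,
    boundaries: Boundaries | None = None,
) -> None:
    """Serialise a trained model (+ selection and evaluation results)."""
    C = len(model.classes_)
    if class_names is None:
        class_names = [str(c) for c in model.classes_]
    if class_types is None:
        class_types = [[] for _ in range(C)]

    root = ET.Element(
        "CLASSIFIER",
        name=name,
        attrib={
            "classification-method": "Fisher LDA",
            "creation-date": datetime.datetime.now().isoformat(timespec="seconds"),
            "sigma": fmt(model.sigma_),
        },
    )
    ET.SubElement(root, "Dataset", path=dataset_path)

    classes_el = ET.SubElement(root, "Classes")
    for c in range(C):
        class_el = ET.SubElement(
            classes_el, "Class", name=class_names[c], prior=fmt(model.priors_[c])
        )
        mean_el = ET.SubElement(class_el, "Mean")
        mean_el.text = " ".join(fmt(v) for v in np.atleast_1d(model.means_[c]))
        for t in class_types[c]:
            ET.SubElement(class_el, "Type").text = t

    if boundaries is None:
        boundaries = compute_boundaries(model)
    bounds_el = ET.SubElement(root, "Boundaries")
    if boundaries is not None:
        if boundaries.intersection_point is not None:
            ip = ET.SubElement(bounds_el, "IntersectionPoint")
            ip.text = " ".join(fmt(v) for v in boundaries.intersection_point)
        for (a, b), pt in zip(boundaries.pairs, boundaries.boundary_points):
            p = ET.SubElement(bounds_el, "Point", pair=f"{a}-{b}")
            p.text = " ".join(fmt(v) for v in pt)

    feats_el = ET.SubElement(root, "Features", Method=features.method)
    for tag, ppm in features.selected:
        ET.SubElement(feats_el, "Feature", dataset=tag, ppm=fmt(ppm))

    weights_el = ET.SubElement(root, "Weights")
    for i, (tag, ppm) in enumerate(features.selected):
        w = ET.SubElement(weights_el, "Weight", dataset=tag, ppm=fmt(ppm))
        w.text = " ".join(fmt(v) for v in np.atleast_1d(model.weights_[i]))

    if evaluation is not None:
        eval_el = ET.SubElement(root, "EvaluationResults")
        if evaluation.bootstrap_mean is not None:
            boot = ET.SubElement(
                eval_el,
                "Bootstrapping",
                mean=fmt(evaluation.bootstrap_mean),
                attrib={"standard-deviation": fmt(evaluation.bootstrap_sd)},
            )
            for cname, m, s in evaluation.bootstrap_per_class:
                ET.SubElement(
                    boot,
                    "Class",
                    name=cname,
                    mean=fmt(m),
                    attrib={"standard-deviation": fmt(s)},
                )
        if evaluation.aucs:
            auc_el = ET.SubElement(eval_el, "AUC")
            for cname, auc in evaluation.aucs:
                ET.SubElement(auc_el, "Class", name=cname, value=fmt(auc))

    tree = ET.ElementTree(root)
    ET.indent(tree, space="  ")
    tree.write(Path(path), encoding="utf-8", xml_declaration=True)


def _floats(text: str | None) -> np.ndarray:
    return np.array([parse_float(t) for t in (text or "").split()])


def read_classifier_xml(path):
    """Parse a CLASSIFIER XML file.

    Returns ``(model, features, evaluation, meta)`` where ``model`` is a
    usable :class:`FisherLDAClassifier`, ``features`` a
    :class:`FeatureSelectionResult`, ``evaluation`` an
    :class:`EvaluationSummary` or None, and ``meta`` a dict with the
    classifier name, method, creation date, class names, member tissue
    types, dataset path and boundary geometry.
    """
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise SchemaError(f"/: not well-formed XML ({exc})") from exc
    if root.tag != "CLASSIFIER":
        raise SchemaError(f"/: root element is {root.tag!r}, not CLASSIFIER")

    classes_el = root.find("Classes")
    if classes_el is None:
        raise SchemaError("/CLASSIFIER: missing Classes node")
    class_names, priors, means, class_types = [], [], [], []
    for ci, class_el in enumerate(classes_el, start=1):
        cpath = f"/CLASSIFIER/Classes/Class[{ci}]"
        if class_el.get("name") is None or class_el.get("prior") is None:
            raise SchemaError(f"{cpath}: missing name/prior attribute")
        class_names.append(class_el.get("name"))
        priors.append(parse_float(class_el.get("prior")))
        mean_el = class_el.find("Mean")
        if mean_el is None:
            raise SchemaError(f"{cpath}: missing Mean node")
        means.append(_floats(mean_el.text))
        class_types.append([t.text or "" for t in class_el.findall("Type")])

    feats_el = root.find("Features")
    if feats_el is None:
        raise SchemaError("/CLASSIFIER: missing Features node")
    selected = [
        (f.get("dataset", "DS1"), parse_float(f.get("ppm", "nan")))
        for f in feats_el.findall("Feature")
    ]
    features = FeatureSelectionResult(
        method=feats_el.get("Method", ""), selected=selected
    )

    weights_el = root.find("Weights")
    if weights_el is None:
        raise SchemaError("/CLASSIFIER: missing Weights node")
    weight_rows = [_floats(w.text) for w in weights_el.findall("Weight")]
    if len(weight_rows) != len(selected):
        raise SchemaError(
            "/CLASSIFIER/Weights: weight count differs from feature count"
        )

    sigma_attr = root.get("sigma")
    if sigma_attr is None:
        raise SchemaError("/CLASSIFIER: missing sigma attribute")

    model = FisherLDAClassifier()
    model.classes_ = np.arange(len(class_names))
    model.priors_ = np.array(priors)
    model.means_ = np.vstack(means)
    model.weights_ = (
        np.vstack(weight_rows) if weight_rows else np.empty((0, len(class_names) - 1))
    )
    model.sigma_ = parse_float(sigma_attr)
    model.eigenvalues_ = None
    model.n_features_in_ = model.weights_.shape[0]

    bounds_el = root.find("Boundaries")
    boundaries = None
    if bounds_el is not None and len(bounds_el):
        ip_el = bounds_el.find("IntersectionPoint")
        pts, pairs = [], []
        for p in bounds_el.findall("Point"):
            pts.append(_floats(p.text))
            a, b = p.get("pair", "0-1").split("-")
            pairs.append((int(a), int(b)))
        boundaries = Boundaries(
            intersection_point=_floats(ip_el.text) if ip_el is not None else None,
            boundary_points=pts,
            pairs=pairs,
        )

    evaluation = None
    eval_el = root.find("EvaluationResults")
    if eval_el is not None:
        evaluation = EvaluationSummary()
        boot = eval_el.find("Bootstrapping")
        if boot is not None:
            evaluation.bootstrap_mean = parse_float(boot.get("mean", "nan"))
            evaluation.bootstrap_sd = parse_float(
                boot.get("standard-deviation", "nan")
            )
            evaluation.bootstrap_per_class = [
                (
                    c.get("name", ""),
                    parse_float(c.get("mean", "nan")),
                    parse_float(c.get("standard-deviation", "nan")),
                )
                for c in boot.findall("Class")
            ]
        auc_el = eval_el.find("AUC")
        if auc_el is not None:
            evaluation.aucs = [
                (c.get("name", ""), parse_float(c.get("value", "nan")))
                for c in auc_el.findall("Class")
            ]

    meta = {
        "name": root.get("name", ""),
        "method": root.get("classification-method", ""),
        "creation_date": root.get("creation-date", ""),
        "class_names": class_names,
        "class_types": class_types,
        "dataset_path": root.find("Dataset").get("path", "")
        if root.find("Dataset") is not None
        else "",
        "boundaries": boundaries,
    }
    return model, features, evaluation, meta
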