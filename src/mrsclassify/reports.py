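"""Text reports and the classifier-history log.

Reports are tab-separated tables with '.' decimals and 6 significant
digits — full precision lives in the CLASSIFIER XML. The history is an
append-only line-delimited JSON log, one entry per completed run, used
to compare classifiers built with different parameters.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionMismatch
from .lda import FisherLDAClassifier
from .model import DesignMatrix


def _fmt6(x: float) -> str:
    return f"{x:.6g}"


def _check_compat(model: FisherLDAClassifier, dm: DesignMatrix) -> None:
    if model.weights_.shape[0] != dm.n_features:
        raise DimensionMismatch(
            f"model has {model.weights_.shape[0]} features, design matrix has "
            f"{dm.n_features}"
        )


def report_lda_results(
    model: FisherLDAClassifier, dm: DesignMatrix, tissue_types: list[str] | None = None
) -> str:
    """Per-case table: id, tissue type, actual and predicted class, and
    the canonical-space coordinates."""
    _check_compat(model, dm)
    Z = model.transform(dm.X)
    pred = model.predict(dm.X)
    d = Z.shape[1]
    coord_names = ["X", "Y", "Z"][:d] if d <= 3 else [f"c{i}" for i in range(d)]
    lines = ["\t".join(["case", "tissue", "actual", "predicted"] + coord_names)]
    for i, cid in enumerate(dm.case_ids):
        tissue = tissue_types[i] if tissue_types else ""
        row = [
            cid,
            tissue,
            dm.class_names[dm.y[i]],
            dm.class_names[int(pred[i])],
        ] + [_fmt6(v) for v in Z[i]]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def report_probabilities(
    model: FisherLDAClassifier,
    dm_train: DesignMatrix,
    dm_test: DesignMatrix | None = None,
) -> str:
    """Per-case class-membership probabilities (one column per class,
    rows sum to 1), for training and optionally testing cases."""
    _check_compat(model, dm_train)
    lines = ["\t".join(["case", "set"] + list(dm_train.class_names))]

    def add(dm: DesignMatrix, tag: str) -> None:
        post = model.predict_proba(dm.X)
        for i, cid in enumerate(dm.case_ids):
            lines.append(
                "\t".join([cid, tag] + [_fmt6(p) for p in post[i]])
            )

    add(dm_train, "training")
    if dm_test is not None:
        _check_compat(model, dm_test)
        add(dm_test, "testing")
    return "\n".join(lines) + "\n"


def report_weights(model: FisherLDAClassifier, feature_labels: list) -> str:
    """Weights matrix: rows are ppm-labelled features, columns are
    canonical variables."""
    if len(feature_labels) != model.weights_.shape[0]:
        raise DimensionMismatch("feature label count differs from weight rows")
    d = model.weights_.shape[1]
    lines = ["\t".join(["dataset", "ppm"] + [f"cv{j + 1}" for j in range(d)])]
    for (tag, ppm), row in zip(feature_labels, model.weights_):
        lines.append(
            "\t".join([tag, _fmt6(ppm)] + [_fmt6(v) for v in np.atleast_1d(row)])
        )
    return "\n".join(lines) + "\n"


@dataclass
class HistoryEntry:
    """One classifier run in the append-only history log."""

    classifier_name: str
    method: str
    classes: list[str]
    n_features: int
    bootstrap_mean: float | None = None
    bootstrap_sd: float | None = None
    aucs: dict[str, float] = field(default_factory=dict)
    config_hash: str = ""
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now().isoformat(timespec="seconds")
    )


def config_hash(config: dict) -> str:
    """Stable short hash of a run configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def append_history(entry: HistoryEntry, log_path) -> None:
    """Append one entry to the line-delimited history log."""
    log_path = Path(log_path)
    with log_path.open("a", encoding="utf-8") as fh:
        fh.write(json.dumps(asdict(entry), sort_keys=True) + "\n")


def read_history(log_path) -> list[HistoryEntry]:
    log_path = Path(log_path)
    if not log_path.exists():
        return []
    entries = []
    for ln in log_path.read_text(encoding="utf-8").splitlines():
        if ln.strip():
            entries.append(HistoryEntry(**json.loads(ln)))
    return entries


def format_history(entries: list[HistoryEntry]) -> str:
    """Comparison table over all runs in the history."""
    lines = [
        "\t".join(
            ["timestamp", "name", "method", "classes", "n_features",
             "bootstrap_mean", "bootstrap_sd", "config"]
        )
    ]
    for e in entries:
        lines.append(
            "\t".join(
                [
                    e.timestamp,
                    e.classifier_name,
                    e.method,
                    "+".join(e.classes),
                    str(e.n_features),
                    _fmt6(e.bootstrap_mean) if e.bootstrap_mean is not None else "-",
                    _fmt6(e.bootstrap_sd) if e.bootstrap_sd is not None else "-",
                    e.config_hash,
                ]
            )
        )
    return "\n".join(lines) + "\n"
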