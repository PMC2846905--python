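"""DATASET XML interchange format.

Layout::

    <DATASET>
      <Case ID="...">
        <Tissue Type="..."/>
        <Spectrum>
          <Parameters>            (omitted when empty)
            <Param key="..." value="..."/>
          </Parameters>
          <Points PpmHigh="..." PpmLow="...">v1 v2 ...</Points>
          <MapPosition X="..." Y="..."/>   (omitted for single-voxel)
        </Spectrum>
        ...
      </Case>
      ...
    </DATASET>

Node and attribute names follow the interchange schema (DATASET, Case
with ID, Tissue with Type, Spectrum with Parameters / Points /
MapPosition children; Parameters and MapPosition are optional). The
linear ppm axis is persisted as the PpmHigh/PpmLow attributes of the
Points node. Intensities are written in the shortest decimal form that
round-trips the double exactly, so write -> read -> write is
byte-identical.
"""

from __future__ import annotations

from pathlib import Path
import xml.etree.ElementTree as ET

import numpy as np

from ..errors import SchemaError
from ..model import Case, MrsDataset, Spectrum, ppm_axis
from ._num import fmt, parse_float


def write_dataset_xml(dataset: MrsDataset, path) -> None:
    """Serialise a dataset to the DATASET XML interchange format."""
    root = ET.Element("DATASET")
    for case in dataset.cases:
        case_el = ET.SubElement(root, "Case", ID=case.id)
        ET.SubElement(case_el, "Tissue", Type=case.tissue_type)
        for spec in case.spectra:
            spec_el = ET.SubElement(case_el, "Spectrum")
            if spec.params:
                params_el = ET.SubElement(spec_el, "Parameters")
                for k, v in spec.params.items():
                    ET.SubElement(params_el, "Param", key=str(k), value=str(v))
            points_el = ET.SubElement(
                spec_el,
                "Points",
                PpmHigh=fmt(spec.ppm_axis[0]),
                PpmLow=fmt(spec.ppm_axis[-1]),
            )
            points_el.text = " ".join(fmt(v) for v in spec.intensities)
            if spec.map_position is not None:
                ET.SubElement(
                    spec_el,
                    "MapPosition",
                    X=str(spec.map_position[0]),
                    Y=str(spec.map_position[1]),
                )
    tree = ET.ElementTree(root)
    ET.indent(tree, space="  ")
    tree.write(Path(path), encoding="utf-8", xml_declaration=True)


def _require(condition: bool, node_path: str, message: str) -> None:
    if not condition:
        raise SchemaError(f"{node_path}: {message}")


def read_dataset_xml(path) -> MrsDataset:
    """Parse a DATASET XML file back into the data model."""
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise SchemaError(f"/: not well-formed XML ({exc})") from exc
    _require(root.tag == "DATASET", "/", f"root element is {root.tag!r}, not DATASET")

    cases: list[Case] = []
    for ci, case_el in enumerate(root, start=1):
        cpath = f"/DATASET/Case[{ci}]"
        _require(case_el.tag == "Case", cpath, f"unexpected element {case_el.tag!r}")
        case_id = case_el.get("ID")
        _require(case_id is not None, cpath, "missing ID attribute")
        tissue_el = case_el.find("Tissue")
        _require(tissue_el is not None, cpath, "missing Tissue node")
        tissue = tissue_el.get("Type")
        _require(tissue is not None, f"{cpath}/Tissue", "missing Type attribute")
        spectra: list[Spectrum] = []
        for si, spec_el in enumerate(case_el.findall("Spectrum"), start=1):
            spath = f"{cpath}/Spectrum[{si}]"
            points_el = spec_el.find("Points")
            _require(points_el is not None, spath, "missing Points node")
            tokens = (points_el.text or "").split()
            _require(len(tokens) >= 2, f"{spath}/Points", "fewer than 2 points")
            values = np.array([parse_float(t, spath) for t in tokens])
            high = points_el.get("PpmHigh")
            low = points_el.get("PpmLow")
            _require(
                high is not None and low is not None,
                f"{spath}/Points",
                "missing PpmHigh/PpmLow attributes",
            )
            axis = ppm_axis(len(values), parse_float(high), parse_float(low))
            params: dict[str, str] = {}
            params_el = spec_el.find("Parameters")
            if params_el is not None:
                for p in params_el.findall("Param"):
                    params[p.get("key", "")] = p.get("value", "")
            pos = None
            pos_el = spec_el.find("MapPosition")
            if pos_el is not None:
                _require(
                    pos_el.get("X") is not None and pos_el.get("Y") is not None,
                    f"{spath}/MapPosition",
                    "missing X/Y attributes",
                )
                pos = (int(pos_el.get("X")), int(pos_el.get("Y")))
            spectra.append(Spectrum(values, axis, map_position=pos, params=params))
        _require(bool(spectra), cpath, "case has no Spectrum node")
        cases.append(Case(id=case_id, tissue_type=tissue, spectra=spectra))
    try:
        return MrsDataset(cases=cases, provenance=[str(path)])
    except ValueError as exc:
        raise SchemaError(f"/DATASET: {exc}") from exc
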