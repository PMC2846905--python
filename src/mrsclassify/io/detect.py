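"""Input-dialect detection.

The decision uses the file extension first (.art, .dat, .bsp are
unambiguous) and then content sniffing for the .txt dialects: an XML
root tag, the multi-voxel header line, a jMRUI header key, a single
all-numeric row (canonical single-voxel export) or a single numeric
column (high-resolution HRMAS export). Detection is deterministic and
an unmatched file raises :class:`UnknownFormat`, never a silent guess.
"""

from __future__ import annotations

import enum
from pathlib import Path

from ..errors import UnknownFormat
from ._num import is_float


class FormatDialect(str, enum.Enum):
    interpret_canonical = "interpret_canonical"
    interpret_dat = "interpret_dat"
    jmrui_txt = "jmrui_txt"
    dicsi_bsp = "dicsi_bsp"
    hrmas_txt = "hrmas_txt"
    dataset_xml = "dataset_xml"


def _xml_root(text: str) -> str | None:
    stripped = text.lstrip()
    if not stripped.startswith("<"):
        return None
    import xml.etree.ElementTree as ET

    try:
        return ET.fromstring(text).tag
    except ET.ParseError:
        return None


def detect_format(path) -> FormatDialect:
    """Identify which input dialect a file is written in."""
    path = Path(path)
    text = path.read_text(encoding="utf-8", errors="replace")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise UnknownFormat(f"{path}: empty file")

    ext = path.suffix.lower()
    if ext == ".art":
        return FormatDialect.interpret_canonical
    if ext == ".dat":
        return FormatDialect.interpret_dat
    if ext == ".bsp":
        return FormatDialect.dicsi_bsp

    root = _xml_root(text)
    if root is not None:
        if root == "DATASET":
            return FormatDialect.dataset_xml
        raise UnknownFormat(f"{path}: XML root {root!r} is not DATASET")

    if len(lines) >= 2 and lines[1].strip().startswith("Number of voxels:"):
        return FormatDialect.dicsi_bsp

    head = "\n".join(lines[:40])
    if "PointsInDataset" in head:
        return FormatDialect.jmrui_txt

    if len(lines) == 1 and all(is_float(t) for t in lines[0].split()):
        return FormatDialect.interpret_canonical

    if len(lines) >= 2 and all(
        len(ln.split()) == 1 and is_float(ln.strip()) for ln in lines
    ):
        return FormatDialect.hrmas_txt

    raise UnknownFormat(f"{path}: content matches no known dialect")
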