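"""Readers for the five pre-processed MRS text dialects.

All readers return :class:`~mrsclassify.model.Spectrum` objects (or an
:class:`~mrsclassify.model.MrsDataset` for the multi-case dialect) on
the descending-ppm axis convention. They read only the fields their
dialect documents; columns a dialect marks as unused (the imaginary
channel of multi-voxel exports, jMRUI columns 1, 2 and 4, the header
row of the .dat table) never influence the result.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np

from ..errors import DuplicateCaseId, ParseError
from ..model import (
    CANONICAL_PPM_HIGH,
    CANONICAL_PPM_LOW,
    CANONICAL_POINTS,
    HRMAS_PPM_HIGH,
    HRMAS_PPM_LOW,
    Case,
    MrsDataset,
    Spectrum,
    ppm_axis,
)
from ._num import is_float, parse_float

logger = logging.getLogger(__name__)


def read_interpret_canonical(
    path,
    ppm_high: float = CANONICAL_PPM_HIGH,
    ppm_low: float = CANONICAL_PPM_LOW,
) -> Spectrum:
    """Single-voxel canonical export: 512 points in one row,
    [7.2; -2.8] ppm."""
    path = Path(path)
    tokens = path.read_text(encoding="utf-8").split()
    if len(tokens) != CANONICAL_POINTS:
        raise ParseError(
            f"{path}: expected {CANONICAL_POINTS} values, found {len(tokens)}"
        )
    values = np.array([parse_float(t, str(path)) for t in tokens])
    return Spectrum(values, ppm_axis(CANONICAL_POINTS, ppm_high, ppm_low))


def read_interpret_dat(
    path,
    ppm_high: float = CANONICAL_PPM_HIGH,
    ppm_low: float = CANONICAL_PPM_LOW,
) -> MrsDataset:
    """SPSS-style table: a header row (ignored), then rows of 514
    tokens — class identifier, case identifier, 512 intensities."""
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    axis = ppm_axis(CANONICAL_POINTS, ppm_high, ppm_low)
    cases: list[Case] = []
    seen: set[str] = set()
    for ln_no, ln in enumerate(lines[1:], start=2):
        tokens = ln.split()
        if len(tokens) != CANONICAL_POINTS + 2:
            raise ParseError(
                f"{path}:{ln_no}: expected {CANONICAL_POINTS + 2} tokens, "
                f"found {len(tokens)}"
            )
        tissue, case_id = tokens[0], tokens[1]
        if case_id in seen:
            raise DuplicateCaseId(f"{path}: case id {case_id!r} appears twice")
        seen.add(case_id)
        values = np.array(
            [parse_float(t, f"{path}:{ln_no}") for t in tokens[2:]]
        )
        cases.append(Case(id=case_id, tissue_type=tissue, spectra=[Spectrum(values, axis)]))
    return MrsDataset(cases=cases, provenance=[str(path)])


_HEADER_RE = re.compile(r"^\s*([A-Za-z][\w ()]*?)\s*:\s*(.*)$")

_JMRUI_KEYS = ("PointsInDataset", "SamplingInterval", "TransmitterFrequency")


def read_jmrui_txt(path, reference_ppm: float = 4.7) -> Spectrum:
    """jMRUI text export: key/value header plus a >=4-column data block.

    Only the third data column (the real part of the spectrum) is read.
    The chemical-shift width is inferred from the header as
    ``(1000 / SamplingInterval_ms) / (TransmitterFrequency * 1e-6)``
    ppm, and the axis is centred on ``reference_ppm`` (default 4.7, the
    water resonance), descending.
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_rows: list[list[str]] = []
    for ln in path.read_text(encoding="utf-8").splitlines():
        if not ln.strip():
            continue
        tokens = ln.split()
        if len(tokens) >= 4 and all(is_float(t) for t in tokens):
            data_rows.append(tokens)
            continue
        m = _HEADER_RE.match(ln)
        if m and m.group(1) in _JMRUI_KEYS:
            try:
                header[m.group(1)] = parse_float(m.group(2).split()[0])
            except (ParseError, IndexError) as exc:
                raise ParseError(f"{path}: bad header value in {ln!r}") from exc
    missing = [k for k in _JMRUI_KEYS if k not in header]
    if missing:
        raise ParseError(f"{path}: missing mandatory header key(s) {missing}")
    if any(header[k] <= 0 for k in _JMRUI_KEYS):
        raise ParseError(f"{path}: header values must be positive: {header}")
    n = int(header["PointsInDataset"])
    if len(data_rows) != n:
        raise ParseError(
            f"{path}: PointsInDataset={n} but data block has {len(data_rows)} rows"
        )
    values = np.array([parse_float(row[2], str(path)) for row in data_rows])

    sw_hz = 1000.0 / header["SamplingInterval"]  # sampling interval in ms
    hz_per_ppm = header["TransmitterFrequency"] * 1e-6
    width_ppm = sw_hz / hz_per_ppm
    step = width_ppm / (n - 1)
    centre = (n - 1) / 2.0
    axis = reference_ppm + (centre - np.arange(n)) * step
    logger.info(
        "%s: inferred spectral width %.4f ppm (axis [%.4f; %.4f], reference "
        "%.2f ppm at the centre point)",
        path, width_ppm, axis[0], axis[-1], reference_ppm,
    )
    return Spectrum(values, axis)


_VOXEL_POS_RE = re.compile(r"\(\s*(-?\d+)\s*,\s*(-?\d+)\s*\)")


def read_3dicsi_bsp(
    path,
    ppm_high: float = CANONICAL_PPM_HIGH,
    ppm_low: float = CANONICAL_PPM_LOW,
) -> list[Spectrum]:
    """Multi-voxel ASCII export: header (set name, voxel and point
    counts, voxel index) then two columns of real/imaginary data.

    Only the real column is read. If the voxel-index block parses, the
    x-y grid position of each voxel is attached to its spectrum.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if len(lines) < 4:
        raise ParseError(f"{path}: truncated multi-voxel header")
    if not lines[1].strip().startswith("Number of voxels:"):
        raise ParseError(f"{path}: second line must start 'Number of voxels:'")
    if not lines[2].strip().startswith("Number of points per voxel:"):
        raise ParseError(
            f"{path}: third line must start 'Number of points per voxel:'"
        )
    try:
        n_voxels = int(lines[1].split(":", 1)[1])
        n_points = int(lines[2].split(":", 1)[1])
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer voxel/point count") from exc
    if not lines[3].strip().startswith("Voxel Index:"):
        raise ParseError(f"{path}: fourth line must start 'Voxel Index:'")

    positions: list[tuple[int, int]] = []
    data: list[float] = []
    idx_text = [lines[3].split(":", 1)[1]]
    for ln in lines[4:]:
        tokens = ln.split()
        if len(tokens) == 2 and all(is_float(t) for t in tokens):
            data.append(parse_float(tokens[0], str(path)))  # Real column only
        else:
            idx_text.append(ln)
    positions = [
        (int(x), int(y)) for x, y in _VOXEL_POS_RE.findall(" ".join(idx_text))
    ]

    if len(data) != n_voxels * n_points:
        raise ParseError(
            f"{path}: expected {n_voxels}x{n_points}={n_voxels * n_points} data "
            f"rows, found {len(data)}"
        )
    axis = ppm_axis(n_points, ppm_high, ppm_low)
    spectra = []
    for v in range(n_voxels):
        pos = positions[v] if len(positions) == n_voxels else None
        spectra.append(
            Spectrum(
                np.array(data[v * n_points : (v + 1) * n_points]),
                axis,
                map_position=pos,
            )
        )
    return spectra


def read_hrmas_txt(
    path,
    ppm_high: float = HRMAS_PPM_HIGH,
    ppm_low: float = HRMAS_PPM_LOW,
) -> Spectrum:
    """High-resolution (HRMAS) export: one intensity per line, default
    [4.5; 0.5] ppm axis."""
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ParseError(f"{path}: a spectrum needs at least 2 points")
    values = []
    for ln_no, ln in enumerate(lines, start=1):
        tokens = ln.split()
        if len(tokens) != 1:
            raise ParseError(f"{path}:{ln_no}: expected a single column")
        values.append(parse_float(tokens[0], f"{path}:{ln_no}"))
    return Spectrum(np.array(values), ppm_axis(len(values), ppm_high, ppm_low))
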