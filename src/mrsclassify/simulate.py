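"""Synthetic class-structured MRS spectra with known ground truth.

The generator emulates the peak structure the classifier assumes: each
class is a sum of Gaussian or Lorentzian resonance lines at fixed
chemical shifts, whose amplitudes vary from case to case (lognormal, so
they stay positive — mimicking metabolite-concentration variation
without chemical-shift drift), plus i.i.d. Gaussian point noise.
Datasets are written in every supported dialect so the whole pipeline
is testable without any acquisition.

One global seed drives a per-case seed sequence (class index, case
index), so enlarging a dataset never changes already-generated cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import zlib

import numpy as np

from .errors import OverlappingTypes, UnsupportedCombination
from .io._num import fmt
from .io.dataset_xml import write_dataset_xml
from .model import (
    CANONICAL_PPM_HIGH,
    CANONICAL_PPM_LOW,
    CANONICAL_POINTS,
    Case,
    MrsDataset,
    Spectrum,
    ppm_axis,
)


@dataclass(frozen=True)
class PeakSpec:
    """One resonance line.

    ``width_ppm`` is the full width at half maximum; the per-case
    amplitude is lognormal with the given mean and sd (sd 0 freezes
    it).
    """

    center_ppm: float
    width_ppm: float
    amplitude_mean: float
    amplitude_sd: float = 0.0
    lineshape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width_ppm <= 0:
            raise ValueError("width_ppm must be positive")
        if self.amplitude_sd < 0:
            raise ValueError("amplitude_sd must be non-negative")
        if self.lineshape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown lineshape {self.lineshape!r}")


@dataclass
class ClassSpec:
    """Generative recipe of one classification class."""

    name: str
    tissue_types: list[str]
    peaks: list[PeakSpec]
    n_cases: int
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _lineshape(peak: PeakSpec, axis: np.ndarray) -> np.ndarray:
    """Unit-amplitude profile of one peak on the given axis."""
    d = axis - peak.center_ppm
    if peak.lineshape == "gaussian":
        return np.exp(-4.0 * np.log(2.0) * d**2 / peak.width_ppm**2)
    half = peak.width_ppm / 2.0
    return half**2 / (d**2 + half**2)


def _draw_amplitude(peak: PeakSpec, rng: np.random.Generator) -> float:
    """Lognormal amplitude with exact mean and sd."""
    if peak.amplitude_sd == 0.0:
        return peak.amplitude_mean
    cv2 = (peak.amplitude_sd / peak.amplitude_mean) ** 2
    s2 = np.log1p(cv2)
    mu = np.log(peak.amplitude_mean) - s2 / 2.0
    return float(rng.lognormal(mean=mu, sigma=np.sqrt(s2)))


def generate_spectrum(
    peaks: list[PeakSpec],
    n_points: int,
    ppm_high: float,
    ppm_low: float,
    noise_sd: float,
    seed,
) -> Spectrum:
    """Sum of lineshapes on a descending ppm axis plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    axis = ppm_axis(n_points, ppm_high, ppm_low)
    values = np.zeros(n_points)
    for peak in peaks:
        values += _draw_amplitude(peak, rng) * _lineshape(peak, axis)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_points)
    return Spectrum(values, axis)


def generate_class_dataset(
    specs: list[ClassSpec],
    seed: int,
    n_points: int = CANONICAL_POINTS,
    ppm_high: float = CANONICAL_PPM_HIGH,
    ppm_low: float = CANONICAL_PPM_LOW,
    layout: str = "SV",
    grid: tuple[int, int] = (4, 4),
) -> MrsDataset:
    """Generate a labelled dataset from per-class recipes.

    Cases are named ``<type>_<k>`` with tissue types assigned
    round-robin over each class's type list; the generating class is
    recorded in the tissue type, so classification accuracy against
    ground truth is computable. ``layout='MV'`` gives every case a grid
    of spectra with distinct map positions.
    """
    seen: set[str] = set()
    for spec in specs:
        for t in spec.tissue_types:
            if t in seen:
                raise OverlappingTypes(f"tissue type {t!r} in two class specs")
            seen.add(t)
    if layout not in ("SV", "MV"):
        raise ValueError(f"unknown layout {layout!r}")

    cases: list[Case] = []
    for ci, spec in enumerate(specs):
        per_type: dict[str, int] = {}
        for k in range(spec.n_cases):
            tissue = spec.tissue_types[k % len(spec.tissue_types)]
            per_type[tissue] = per_type.get(tissue, 0) + 1
            case_id = f"{tissue}_{per_type[tissue]}"
            if layout == "SV":
                spectra = [
                    generate_spectrum(
                        spec.peaks, n_points, ppm_high, ppm_low, spec.noise_sd,
                        seed=[seed, ci, k],
                    )
                ]
            else:
                nx, ny = grid
                spectra = []
                for gx in range(nx):
                    for gy in range(ny):
                        s = generate_spectrum(
                            spec.peaks, n_points, ppm_high, ppm_low, spec.noise_sd,
                            seed=[seed, ci, k, gx, gy],
                        )
                        s.map_position = (gx, gy)
                        spectra.append(s)
            cases.append(Case(id=case_id, tissue_type=tissue, spectra=spectra))
    return MrsDataset(cases=cases)


# ---------------------------------------------------------------------------
# fixture writers

def _is_mv(dataset: MrsDataset) -> bool:
    return any(len(c.spectra) > 1 for c in dataset.cases)


def write_fixture_files(dataset: MrsDataset, dialect: str, directory) -> list[Path]:
    """Write a dataset in one of the supported dialects.

    Single-spectrum dialects get one file per case; the .dat table and
    the DATASET XML hold the whole dataset in one file. Multi-spectrum
    (multi-voxel) datasets are only expressible as .bsp or DATASET XML.
    Every file parses back through the format readers to the generating
    intensities exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if dialect not in (
        "interpret_canonical", "interpret_dat", "jmrui_txt",
        "dicsi_bsp", "hrmas_txt", "dataset_xml",
    ):
        raise UnsupportedCombination(f"unknown dialect {dialect!r}")
    if _is_mv(dataset) and dialect not in ("dicsi_bsp", "dataset_xml"):
        raise UnsupportedCombination(
            f"multi-voxel datasets cannot be written as {dialect}"
        )

    if dialect == "dataset_xml":
        out = directory / "dataset.xml"
        write_dataset_xml(dataset, out)
        return [out]

    if dialect == "interpret_dat":
        out = directory / "dataset.dat"
        with out.open("w", encoding="utf-8") as fh:
            header = ["class", "case"] + [f"p{i}" for i in range(CANONICAL_POINTS)]
            fh.write(" ".join(header) + "\n")
            for case in dataset.cases:
                spec = case.spectra[0]
                if len(spec) != CANONICAL_POINTS:
                    raise UnsupportedCombination(
                        f".dat rows need {CANONICAL_POINTS}-point spectra"
                    )
                row = [case.tissue_type, case.id] + [fmt(v) for v in spec.intensities]
                fh.write(" ".join(row) + "\n")
        return [out]

    for case in dataset.cases:
        if dialect == "interpret_canonical":
            if len(case.spectra[0]) != CANONICAL_POINTS:
                raise UnsupportedCombination(
                    f"canonical files need {CANONICAL_POINTS}-point spectra"
                )
            out = directory / f"{case.id}.txt"
            out.write_text(
                " ".join(fmt(v) for v in case.spectra[0].intensities) + "\n",
                encoding="utf-8",
            )
        elif dialect == "jmrui_txt":
            out = directory / f"{case.id}.txt"
            _write_jmrui(case.spectra[0], out)
        elif dialect == "hrmas_txt":
            out = directory / f"{case.id}.txt"
            out.write_text(
                "\n".join(fmt(v) for v in case.spectra[0].intensities) + "\n",
                encoding="utf-8",
            )
        else:  # dicsi_bsp: one acquisition (case) per file
            out = directory / f"{case.id}.bsp"
            _write_bsp(case, out)
        written.append(out)
    return written


_JMRUI_FREQ_HZ = 63.86e6  # 1.5 T proton frequency


def _write_jmrui(spec: Spectrum, path: Path) -> None:
    n = len(spec)
    width_ppm = float(spec.ppm_axis[0] - spec.ppm_axis[-1])
    sw_hz = width_ppm * _JMRUI_FREQ_HZ * 1e-6
    sampling_ms = 1000.0 / sw_hz
    rng = np.random.default_rng(zlib.crc32(path.name.encode()))
    with path.open("w", encoding="utf-8") as fh:
        fh.write("jMRUI Data Textfile\n\n")
        fh.write(f"PointsInDataset: {n}\n")
        fh.write("DatasetsInFile: 1\n")
        fh.write(f"SamplingInterval: {fmt(sampling_ms)}\n")
        fh.write("ZeroOrderPhase: 0\n")
        fh.write(f"TransmitterFrequency: {fmt(_JMRUI_FREQ_HZ)}\n")
        fh.write("MagneticField: 1.5\n")
        fh.write("\nSignal and FFT\n")
        fh.write("sig(real) sig(imag) fft(real) fft(imag)\n")
        for v in spec.intensities:
            # columns 1, 2 and 4 are never read; fill with unrelated values
            junk = rng.normal(size=3)
            fh.write(f"{fmt(junk[0])} {fmt(junk[1])} {fmt(v)} {fmt(junk[2])}\n")


def _write_bsp(case: Case, path: Path) -> None:
    n_vox = len(case.spectra)
    n_pts = len(case.spectra[0])
    if any(len(s) != n_pts for s in case.spectra):
        raise UnsupportedCombination("all voxels in a .bsp share one length")
    rng = np.random.default_rng(zlib.crc32(path.name.encode()))
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{case.id}\n")
        fh.write(f"Number of voxels: {n_vox}\n")
        fh.write(f"Number of points per voxel: {n_pts}\n")
        positions = " ".join(
            f"({s.map_position[0]},{s.map_position[1]})"
            if s.map_position is not None
            else f"({i},0)"
            for i, s in enumerate(case.spectra)
        )
        fh.write(f"Voxel Index: {positions}\n")
        for s in case.spectra:
            for v in s.intensities:
                # Imaginary column is never read; fill with unrelated values
                fh.write(f"{fmt(v)} {fmt(rng.normal())}\n")


# ---------------------------------------------------------------------------
# packaged default scenario

#: Chemical shifts (ppm) of the discriminative resonance of each
#: super-class in the default scenario.
DEFAULT_DISCRIMINATIVE_PPM = {
    "low-grade m": 1.47,   # alanine doublet region (meningioma marker)
    "aggressive": 1.29,    # mobile lipids (glioblastoma / metastasis)
    "low-grade g": 3.55,   # myo-inositol (low-grade glial marker)
}

DEFAULT_NOISE_SD = 1.0
DEFAULT_SEPARATION = 10.0  # discriminative amplitude gap, in noise-sd units


def default_scenario(n_cases_per_class: int = 20) -> list[ClassSpec]:
    """Three-super-class short-TE scenario at 512 points, [7.2; -2.8] ppm.

    Each super-class shares a common backbone (creatine 3.03, choline
    3.21, NAA 2.02) and carries one discriminative resonance whose mean
    amplitude exceeds the other classes' by ten noise standard
    deviations. Case-to-case amplitude variation is lognormal with sd
    1.0 (equal to the point-noise sd), a realistic concentration
    scatter that leaves the classes separable by construction.
    """
    hi = 2.0 + DEFAULT_SEPARATION * DEFAULT_NOISE_SD  # 12.0
    lo = 2.0
    width = 0.06
    amp_sd = 1.0

    def peaks(level_m, level_agg, level_g):
        return [
            PeakSpec(3.21, width, 8.0, amp_sd),   # choline
            PeakSpec(3.03, width, 7.0, amp_sd),   # creatine
            PeakSpec(2.02, width, 6.0, amp_sd),   # NAA
            PeakSpec(DEFAULT_DISCRIMINATIVE_PPM["low-grade m"], width, level_m, amp_sd),
            PeakSpec(DEFAULT_DISCRIMINATIVE_PPM["aggressive"], width, level_agg, amp_sd),
            PeakSpec(DEFAULT_DISCRIMINATIVE_PPM["low-grade g"], width, level_g, amp_sd),
        ]

    return [
        ClassSpec(
            name="low-grade m",
            tissue_types=["mm"],
            peaks=peaks(hi, lo, lo),
            n_cases=n_cases_per_class,
            noise_sd=DEFAULT_NOISE_SD,
        ),
        ClassSpec(
            name="aggressive",
            tissue_types=["gl", "me"],
            peaks=peaks(lo, hi, lo),
            n_cases=n_cases_per_class,
            noise_sd=DEFAULT_NOISE_SD,
        ),
        ClassSpec(
            name="low-grade g",
            tissue_types=["a2", "oa", "od"],
            peaks=peaks(lo, lo, hi),
            n_cases=n_cases_per_class,
            noise_sd=DEFAULT_NOISE_SD,
        ),
    ]


def oracle_accuracy(
    dataset: MrsDataset,
    specs: list[ClassSpec],
    n_points: int = CANONICAL_POINTS,
    ppm_high: float = CANONICAL_PPM_HIGH,
    ppm_low: float = CANONICAL_PPM_LOW,
) -> float:
    """Accuracy (percent) of the true-model template classifier.

    Scores each case against the noise-free mean template of every
    class under an independent Gaussian approximation per channel
    (variance = point-noise variance plus the amplitude variance
    propagated through each peak's profile). This is the constructed
    ceiling a trained classifier is compared against: a close
    approximation of the Bayes accuracy of the generative recipe
    (exact up to the lognormal-vs-Gaussian amplitude approximation).
    """
    axis = ppm_axis(n_points, ppm_high, ppm_low)
    type_to_class = {t: i for i, s in enumerate(specs) for t in s.tissue_types}
    templates, variances = [], []
    for spec in specs:
        mean = np.zeros(n_points)
        var = np.full(n_points, spec.noise_sd**2)
        for peak in spec.peaks:
            prof = _lineshape(peak, axis)
            mean += peak.amplitude_mean * prof
            var += (peak.amplitude_sd * prof) ** 2
        templates.append(mean)
        variances.append(var)
    correct = 0
    total = 0
    for case in dataset.cases:
        x = case.spectra[0].intensities
        ll = [
            -0.5 * float(np.sum((x - m) ** 2 / v + np.log(v)))
            for m, v in zip(templates, variances)
        ]
        if int(np.argmax(ll)) == type_to_class[case.tissue_type]:
            correct += 1
        total += 1
    return 100.0 * correct / total
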