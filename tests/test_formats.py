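"""Format readers, dialect detection and XML round trips."""

import numpy as np
import pytest

from mrsclassify import generate_class_dataset, write_fixture_files
from mrsclassify.errors import (
    DuplicateCaseId,
    ParseError,
    SchemaError,
    UnknownFormat,
    UnsupportedCombination,
)
from mrsclassify.io import (
    FormatDialect,
    detect_format,
    read_3dicsi_bsp,
    read_dataset_xml,
    read_hrmas_txt,
    read_interpret_canonical,
    read_interpret_dat,
    read_jmrui_txt,
    write_dataset_xml,
)
from mrsclassify.model import Case, MrsDataset, Spectrum, ppm_axis
from mrsclassify.simulate import ClassSpec, PeakSpec


def tiny_specs(n_points=None, n_cases=3):
    return [
        ClassSpec("A", ["mm"], [PeakSpec(3.0, 0.2, 8.0, 1.0)], n_cases, 0.5),
        ClassSpec("B", ["gl"], [PeakSpec(1.5, 0.2, 8.0, 1.0)], n_cases, 0.5),
    ]


@pytest.fixture
def sv_dataset():
    return generate_class_dataset(tiny_specs(), seed=5)  # 512-pt canonical


class TestDetect:
    def test_dataset_xml_root(self, sv_dataset, tmp_path):
        (f,) = write_fixture_files(sv_dataset, "dataset_xml", tmp_path)
        assert detect_format(f) == FormatDialect.dataset_xml

    def test_bsp_header_line(self, tmp_path):
        f = tmp_path / "x.txt"  # content sniffing, not extension
        f.write_text("some set\nNumber of voxels: 1\n"
                     "Number of points per voxel: 2\nVoxel Index: (0,0)\n"
                     "1.0 0.0\n2.0 0.0\n")
        assert detect_format(f) == FormatDialect.dicsi_bsp

    def test_empty_file_unknown(self, tmp_path):
        f = tmp_path / "empty.txt"
        f.write_text("")
        with pytest.raises(UnknownFormat):
            detect_format(f)

    def test_extensions(self, tmp_path):
        for ext, dialect in [
            (".art", FormatDialect.interpret_canonical),
            (".dat", FormatDialect.interpret_dat),
            (".bsp", FormatDialect.dicsi_bsp),
        ]:
            f = tmp_path / f"x{ext}"
            f.write_text("placeholder\n")
            assert detect_format(f) == dialect

    def test_single_row_canonical_vs_column_hrmas(self, tmp_path):
        row = tmp_path / "row.txt"
        row.write_text(" ".join("0.0" for _ in range(512)) + "\n")
        assert detect_format(row) == FormatDialect.interpret_canonical
        col = tmp_path / "col.txt"
        col.write_text("\n".join("0.0" for _ in range(100)) + "\n")
        assert detect_format(col) == FormatDialect.hrmas_txt

    def test_jmrui_header_sniffed(self, sv_dataset, tmp_path):
        files = write_fixture_files(sv_dataset, "jmrui_txt", tmp_path)
        assert detect_format(files[0]) == FormatDialect.jmrui_txt


class TestInterpretCanonical:
    def test_axis_and_length(self, tmp_path):
        f = tmp_path / "c.txt"
        f.write_text(" ".join("0.0" for _ in range(512)))
        spec = read_interpret_canonical(f)
        assert len(spec) == 512
        assert spec.ppm_axis[0] == 7.2 and spec.ppm_axis[-1] == -2.8

    def test_wrong_count(self, tmp_path):
        f = tmp_path / "c.txt"
        f.write_text(" ".join("0.0" for _ in range(511)))
        with pytest.raises(ParseError):
            read_interpret_canonical(f)

    def test_roundtrip_through_xml(self, tmp_path):
        f = tmp_path / "c.txt"
        values = np.arange(1.0, 513.0)
        f.write_text(" ".join(repr(float(v)) for v in values))
        spec = read_interpret_canonical(f)
        ds = MrsDataset(cases=[Case("c1", "mm", [spec])])
        out = tmp_path / "ds.xml"
        write_dataset_xml(ds, out)
        back = read_dataset_xml(out)
        np.testing.assert_array_equal(
            back.cases[0].spectra[0].intensities, values
        )


class TestInterpretDat:
    def _write(self, tmp_path, rows, header="h " * 514):
        f = tmp_path / "d.dat"
        f.write_text(header.strip() + "\n" + "\n".join(rows) + "\n")
        return f

    def test_three_cases(self, tmp_path):
        rows = [
            f"mm case{i} " + " ".join("1.5" for _ in range(512))
            for i in range(3)
        ]
        ds = read_interpret_dat(self._write(tmp_path, rows))
        assert len(ds) == 3
        assert all(len(c.spectra[0]) == 512 for c in ds.cases)
        assert ds.cases[0].tissue_type == "mm"

    def test_header_only_empty_dataset(self, tmp_path):
        ds = read_interpret_dat(self._write(tmp_path, []))
        assert len(ds) == 0

    def test_wrong_token_count(self, tmp_path):
        rows = ["mm c0 " + " ".join("1.0" for _ in range(511))]
        with pytest.raises(ParseError):
            read_interpret_dat(self._write(tmp_path, rows))

    def test_duplicate_case_id(self, tmp_path):
        row = "mm c0 " + " ".join("1.0" for _ in range(512))
        with pytest.raises(DuplicateCaseId):
            read_interpret_dat(self._write(tmp_path, [row, row]))

    def test_header_content_ignored(self, tmp_path):
        rows = ["mm c0 " + " ".join("2.5" for _ in range(512))]
        a = read_interpret_dat(self._write(tmp_path, rows))
        b = read_interpret_dat(
            self._write(tmp_path, rows, header="GARBAGE not even 514 tokens")
        )
        np.testing.assert_array_equal(
            a.cases[0].spectra[0].intensities, b.cases[0].spectra[0].intensities
        )


def write_jmrui(tmp_path, n=8, si="1", tf="63860000", col3=None, name="j.txt"):
    col3 = col3 if col3 is not None else [float(i) for i in range(n)]
    lines = [
        "jMRUI Data Textfile", "",
        f"PointsInDataset: {n}",
        f"SamplingInterval: {si}",
        f"TransmitterFrequency: {tf}",
        "", "Signal and FFT",
    ]
    rng = np.random.default_rng(0)
    for v in col3:
        a, b, c = rng.normal(size=3)
        lines.append(f"{a} {b} {v} {c}")
    f = tmp_path / name
    f.write_text("\n".join(lines) + "\n")
    return f


class TestJmrui:
    def test_spectral_width_inferred(self, tmp_path):
        # hand computation: 1000 Hz sweep / 63.86 Hz-per-ppm = 15.659 ppm
        f = write_jmrui(tmp_path, n=512)
        spec = read_jmrui_txt(f)
        width = spec.ppm_axis[0] - spec.ppm_axis[-1]
        assert width == pytest.approx(1000.0 / 63.86, rel=1e-9)

    def test_only_third_column_read(self, tmp_path):
        values = [10.0 * i for i in range(8)]
        spec = read_jmrui_txt(write_jmrui(tmp_path, n=8, col3=values))
        np.testing.assert_array_equal(spec.intensities, values)

    def test_missing_key_raises(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("PointsInDataset: 2\nSamplingInterval: 1\n1 2 3 4\n5 6 7 8\n")
        with pytest.raises(ParseError, match="TransmitterFrequency"):
            read_jmrui_txt(f)

    def test_row_count_mismatch(self, tmp_path):
        f = write_jmrui(tmp_path, n=8, col3=[1.0] * 7)
        # header says 8 but only 7 data rows written
        f.write_text(f.read_text().replace("PointsInDataset: 7", "PointsInDataset: 8"))
        with pytest.raises(ParseError):
            read_jmrui_txt(write_jmrui(tmp_path, n=9, col3=[1.0] * 8, name="k.txt"))

    def test_reference_centre(self, tmp_path):
        spec = read_jmrui_txt(write_jmrui(tmp_path, n=9), reference_ppm=4.7)
        assert spec.ppm_axis[4] == pytest.approx(4.7)


class TestBsp:
    def _write(self, tmp_path, n_vox=2, n_pts=4, data=None, index="(0,0) (0,1)"):
        lines = [
            "my set",
            f"Number of voxels: {n_vox}",
            f"Number of points per voxel: {n_pts}",
            f"Voxel Index: {index}",
        ]
        if data is None:
            data = [(float(i), -float(i)) for i in range(n_vox * n_pts)]
        lines += [f"{r} {im}" for r, im in data]
        f = tmp_path / "v.bsp"
        f.write_text("\n".join(lines) + "\n")
        return f

    def test_voxel_split(self, tmp_path):
        specs = read_3dicsi_bsp(self._write(tmp_path, n_vox=4, n_pts=256,
                                            index="(0,0) (0,1) (1,0) (1,1)"))
        assert len(specs) == 4 and all(len(s) == 256 for s in specs)
        assert specs[2].map_position == (1, 0)

    def test_real_column_only(self, tmp_path):
        data = [(float(i + 1), 99.0) for i in range(8)]
        (spec,) = read_3dicsi_bsp(self._write(tmp_path, n_vox=1, n_pts=8,
                                              data=data, index="(0,0)"))
        np.testing.assert_array_equal(spec.intensities, np.arange(1.0, 9.0))

    def test_imaginary_corruption_ignored(self, tmp_path):
        d1 = [(float(i), 0.0) for i in range(8)]
        d2 = [(float(i), 1e9) for i in range(8)]
        (a,) = read_3dicsi_bsp(self._write(tmp_path, 1, 8, d1, "(0,0)"))
        (b,) = read_3dicsi_bsp(self._write(tmp_path, 1, 8, d2, "(0,0)"))
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_row_count_mismatch(self, tmp_path):
        data = [(float(i), 0.0) for i in range(7)]
        with pytest.raises(ParseError):
            read_3dicsi_bsp(self._write(tmp_path, n_vox=1, n_pts=8, data=data))


class TestHrmas:
    def test_long_column(self, tmp_path):
        f = tmp_path / "h.txt"
        f.write_text("\n".join("0.5" for _ in range(1639)) + "\n")
        spec = read_hrmas_txt(f)
        assert len(spec) == 1639
        assert spec.ppm_axis[0] == 4.5 and spec.ppm_axis[-1] == 0.5

    def test_minimal_two_points(self, tmp_path):
        f = tmp_path / "h.txt"
        f.write_text("1.0\n2.0\n")
        assert len(read_hrmas_txt(f)) == 2

    def test_non_numeric(self, tmp_path):
        f = tmp_path / "h.txt"
        f.write_text("1.0\nabc\n3.0\n")
        with pytest.raises(ParseError):
            read_hrmas_txt(f)


class TestDatasetXml:
    def test_round_trip_identity(self, sv_dataset, tmp_path):
        out = tmp_path / "ds.xml"
        write_dataset_xml(sv_dataset, out)
        back = read_dataset_xml(out)
        assert len(back) == len(sv_dataset)
        for a, b in zip(sv_dataset.cases, back.cases):
            assert a.id == b.id and a.tissue_type == b.tissue_type
            assert a.spectra == b.spectra

    def test_rewrite_idempotent(self, sv_dataset, tmp_path):
        f1 = tmp_path / "a.xml"
        f2 = tmp_path / "b.xml"
        write_dataset_xml(sv_dataset, f1)
        write_dataset_xml(read_dataset_xml(f1), f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_missing_tissue_names_path(self, tmp_path):
        f = tmp_path / "bad.xml"
        f.write_text(
            "<DATASET><Case ID='c1'><Spectrum>"
            "<Points PpmHigh='1.0' PpmLow='0.0'>1 2</Points>"
            "</Spectrum></Case></DATASET>"
        )
        with pytest.raises(SchemaError, match=r"/DATASET/Case\[1\]"):
            read_dataset_xml(f)

    def test_multivoxel_map_positions(self, tmp_path):
        ds = generate_class_dataset(
            tiny_specs(n_cases=1), seed=3, layout="MV", grid=(2, 2), n_points=16
        )
        out = tmp_path / "mv.xml"
        write_dataset_xml(ds, out)
        back = read_dataset_xml(out)
        positions = {s.map_position for s in back.cases[0].spectra}
        assert positions == {(0, 0), (0, 1), (1, 0), (1, 1)}

    def test_params_round_trip_verbatim(self, tmp_path):
        spec = Spectrum(np.arange(4.0), ppm_axis(4, 2.0, 1.0),
                        params={"TE": "30ms", "field": "1.5T"})
        ds = MrsDataset(cases=[Case("c1", "mm", [spec])])
        out = tmp_path / "p.xml"
        write_dataset_xml(ds, out)
        assert read_dataset_xml(out).cases[0].spectra[0].params == spec.params


class TestFixtureRoundTrips:
    @pytest.mark.parametrize(
        "dialect", ["interpret_canonical", "interpret_dat", "jmrui_txt",
                    "dicsi_bsp", "hrmas_txt", "dataset_xml"]
    )
    def test_intensities_exact(self, sv_dataset, tmp_path, dialect):
        files = write_fixture_files(sv_dataset, dialect, tmp_path / dialect)
        readers = {
            "interpret_canonical": read_interpret_canonical,
            "jmrui_txt": read_jmrui_txt,
            "hrmas_txt": lambda f: read_hrmas_txt(f, 7.2, -2.8),
            "dicsi_bsp": lambda f: read_3dicsi_bsp(f)[0],
        }
        if dialect == "dataset_xml":
            back = read_dataset_xml(files[0])
            for a, b in zip(sv_dataset.cases, back.cases):
                np.testing.assert_array_equal(
                    a.spectra[0].intensities, b.spectra[0].intensities
                )
        elif dialect == "interpret_dat":
            back = read_interpret_dat(files[0])
            for a, b in zip(sv_dataset.cases, back.cases):
                assert a.id == b.id and a.tissue_type == b.tissue_type
                np.testing.assert_array_equal(
                    a.spectra[0].intensities, b.spectra[0].intensities
                )
        else:
            by_id = {c.id: c for c in sv_dataset.cases}
            for f in files:
                spec = readers[dialect](f)
                np.testing.assert_array_equal(
                    spec.intensities, by_id[f.stem].spectra[0].intensities
                )

    def test_mv_only_bsp_or_xml(self, tmp_path):
        mv = generate_class_dataset(
            tiny_specs(n_cases=1), seed=1, layout="MV", grid=(2, 2), n_points=16
        )
        with pytest.raises(UnsupportedCombination):
            write_fixture_files(mv, "interpret_canonical", tmp_path)
        write_fixture_files(mv, "dicsi_bsp", tmp_path / "b")
        write_fixture_files(mv, "dataset_xml", tmp_path / "x")

    def test_jmrui_ignored_columns_corruption(self, sv_dataset, tmp_path):
        files = write_fixture_files(sv_dataset, "jmrui_txt", tmp_path)
        f = files[0]
        original = read_jmrui_txt(f).intensities
        lines = f.read_text().splitlines()
        out = []
        for ln in lines:
            tokens = ln.split()
            if len(tokens) == 4 and all("." in t or "e" in t for t in tokens[:1]):
                tokens[0], tokens[1], tokens[3] = "777.0", "-777.0", "0.001"
                out.append(" ".join(tokens))
            else:
                out.append(ln)
        f.write_text("\n".join(out) + "\n")
        np.testing.assert_array_equal(read_jmrui_txt(f).intensities, original)

    def test_bsp_mv_round_trip_positions(self, tmp_path):
        mv = generate_class_dataset(
            tiny_specs(n_cases=1), seed=2, layout="MV", grid=(2, 2), n_points=16
        )
        files = write_fixture_files(mv, "dicsi_bsp", tmp_path)
        by_id = {c.id: c for c in mv.cases}
        for f in files:
            specs = read_3dicsi_bsp(f, 7.2, -2.8)
            case = by_id[f.stem]
            assert len(specs) == len(case.spectra)
            for a, b in zip(case.spectra, specs):
                np.testing.assert_array_equal(a.intensities, b.intensities)
                assert a.map_position == b.map_position
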