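import textwrap

import numpy as np
import pytest
from hypothesis import given, strategies as st

from scarspls.spectra_io import (
    WavenumberGrid,
    read_dataset_csv,
    read_jcamp,
    trim_region,
    write_dataset_csv,
)


def toy_csv(tmp_path, wavenumbers, name="toy.csv", n=3):
    rng = np.random.default_rng(0)
    header = "sample_id,batch,role,acetic_acid," + ",".join(str(w) for w in wavenumbers)
    lines = [header]
    for i in range(n):
        vals = ",".join(f"{v:.6f}" for v in rng.random(len(wavenumbers)))
        lines.append(f"s{i},B1,calibration,{0.5 + i},{vals}")
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


class TestWavenumberGrid:
    def test_default_grid_shape(self):
        g = WavenumberGrid.default()
        assert (g.count, g.first, g.last, g.step) == (949, 11536.0, 3952.0, 8.0)

    @given(
        first=st.integers(5000, 12000),
        step=st.sampled_from([2, 4, 8, 16]),
        count=st.integers(2, 500),
    )
    def test_grid_arithmetic(self, first, step, count):
        g = WavenumberGrid.from_range(first, first - step * (count - 1), step)
        assert g.count == (g.first - g.last) / g.step + 1 == count

    @pytest.mark.parametrize(
        "values", [[1, 2, 3], [3, 2, 2], [100.0]], ids=["ascending", "tie", "single"]
    )
    def test_invalid_grids_rejected(self, values):
        with pytest.raises(ValueError):
            WavenumberGrid(np.array(values, dtype=float))

    def test_irregular_spacing_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            WavenumberGrid(np.array([100.0, 92.0, 85.0]))


class TestDatasetCsv:
    def test_toy_read(self, tmp_path):
        path = toy_csv(tmp_path, [11536, 11528, 11520, 11512, 11504])
        ds = read_dataset_csv(path, analytes=["acetic_acid"])
        assert ds.grid.count == 5 and ds.grid.step == 8
        assert ds.n_samples == 3
        assert list(ds.references.columns) == ["acetic_acid"]

    def test_ascending_grid_rejected(self, tmp_path):
        path = toy_csv(tmp_path, [11504, 11512, 11520])
        with pytest.raises(ValueError, match="descending"):
            read_dataset_csv(path)

    def test_missing_analyte_named_in_error(self, tmp_path):
        path = toy_csv(tmp_path, [11536, 11528, 11520])
        with pytest.raises(ValueError, match="ethanol"):
            read_dataset_csv(path, analytes=["ethanol"])

    def test_non_numeric_cell_located(self, tmp_path):
        path = toy_csv(tmp_path, [11536, 11528, 11520])
        text = path.read_text().replace("\n", "\n", 1)
        lines = text.splitlines()
        cells = lines[2].split(",")
        cells[5] = "oops"
        lines[2] = ",".join(cells)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match=r"row 1.*11528"):
            read_dataset_csv(path)

    def test_roundtrip_identity(self, tmp_path, small_dataset):
        path = tmp_path / "ds.csv"
        write_dataset_csv(small_dataset, path)
        back = read_dataset_csv(path)
        np.testing.assert_allclose(back.absorbance, small_dataset.absorbance, atol=1e-12)
        np.testing.assert_allclose(
            back.references.to_numpy(), small_dataset.references.to_numpy(), atol=1e-12
        )
        assert back.grid == small_dataset.grid
        assert list(back.batch) == list(small_dataset.batch)
        assert list(back.role) == list(small_dataset.role)

    def test_roundtrip_paper_scale(self, tmp_path, paper_dataset):
        path = tmp_path / "paper.csv"
        write_dataset_csv(paper_dataset, path)
        back = read_dataset_csv(path)
        assert back.absorbance.shape == (192, 949)
        np.testing.assert_allclose(back.absorbance, paper_dataset.absorbance, atol=1e-12)

    def test_empty_dataset_roundtrip(self, tmp_path, small_dataset):
        empty = small_dataset.subset(np.zeros(small_dataset.n_samples, dtype=bool))
        path = tmp_path / "empty.csv"
        write_dataset_csv(empty, path)
        back = read_dataset_csv(path)
        assert back.n_samples == 0
        assert back.grid == small_dataset.grid

    def test_single_analyte_column_emitted(self, tmp_path, small_dataset):
        one = small_dataset.with_spectra(small_dataset.absorbance)
        one.references = one.references[["ethanol"]]
        path = tmp_path / "one.csv"
        write_dataset_csv(one, path)
        header = path.read_text().splitlines()[0].split(",")
        assert header[:4] == ["sample_id", "batch", "role", "ethanol"]
        assert read_dataset_csv(path).analytes == ["ethanol"]


def emit_jcamp_xydata(path, x, y):
    """Independent, minimal JCAMP-DX writer (AFFN, X++(Y..Y))."""
    step = x[1] - x[0]
    lines = [
        "##TITLE=synthetic spectrum",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##FIRSTX={x[0]}",
        f"##LASTX={x[-1]}",
        f"##NPOINTS={len(x)}",
        "##XYDATA=(X++(Y..Y))",
    ]
    for start in range(0, len(x), 4):
        chunk = y[start : start + 4]
        lines.append(f"{x[start]:.1f} " + " ".join(f"{v:.8f}" for v in chunk))
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")
    assert abs((x[-1] - x[0]) / (len(x) - 1) - step) < 1e-9


class TestJcamp:
    def test_xypoints_five_pairs(self, tmp_path):
        path = tmp_path / "p.jdx"
        path.write_text(
            textwrap.dedent(
                """\
                ##TITLE=five points
                ##XUNITS=1/CM
                ##YUNITS=ABSORBANCE
                ##XYPOINTS=(XY..XY)
                4000.0, 0.10; 4008.0, 0.20
                4016.0, 0.30; 4024.0, 0.40
                4032.0, 0.50
                ##END=
                """
            )
        )
        ds = read_jcamp(path)
        assert ds.grid.count == 5
        assert ds.grid.first == 4032.0  # descending canonical order
        np.testing.assert_allclose(ds.absorbance[0], [0.5, 0.4, 0.3, 0.2, 0.1])

    def test_xydata_roundtrip(self, tmp_path, small_dataset):
        spectrum = small_dataset.absorbance[0]
        x_ascending = small_dataset.grid.values[::-1]
        path = tmp_path / "s.jdx"
        emit_jcamp_xydata(path, x_ascending, spectrum[::-1])
        back = read_jcamp(path)
        assert back.grid == small_dataset.grid
        np.testing.assert_allclose(back.absorbance[0], spectrum, atol=1e-6)

    def test_missing_xunits(self, tmp_path):
        path = tmp_path / "nounits.jdx"
        path.write_text("##TITLE=x\n##XYPOINTS=(XY..XY)\n1 2; 3 4\n##END=\n")
        with pytest.raises(ValueError, match="units unknown"):
            read_jcamp(path)

    def test_compressed_ordinates_rejected(self, tmp_path):
        path = tmp_path / "sqz.jdx"
        path.write_text(
            "##TITLE=x\n##XUNITS=1/CM\n##FIRSTX=100\n##LASTX=104\n##NPOINTS=5\n"
            "##XYDATA=(X++(Y..Y))\n100 A123J45K2\n##END=\n"
        )
        with pytest.raises(ValueError, match="compression"):
            read_jcamp(path)


class TestTrimRegion:
    def test_default_grid_to_935(self, paper_dataset):
        trimmed = trim_region(paper_dataset, 11480, 4008)
        assert trimmed.grid.count == 935
        assert trimmed.grid.first == 11480.0 and trimmed.grid.last == 4008.0

    def test_full_span_identity(self, small_dataset):
        out = trim_region(small_dataset, small_dataset.grid.first, small_dataset.grid.last)
        np.testing.assert_array_equal(out.absorbance, small_dataset.absorbance)

    def test_three_point_window(self, small_dataset):
        g = small_dataset.grid
        out = trim_region(small_dataset, g.values[5], g.values[7])
        assert out.grid.count == 3
        np.testing.assert_array_equal(out.absorbance, small_dataset.absorbance[:, 5:8])

    def test_empty_window_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            trim_region(small_dataset, 3000, 2000)
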