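"""Spectral data model and I/O.

NIR spectra live on a wavenumber grid in cm^-1, stored in *descending*
order (the canonical direction for FT-NIR instruments scanning from the
short-wavelength end).  A :class:`SpectralDataset` bundles the absorbance
matrix with per-sample reference analyte values, batch labels, and a
calibration/prediction role flag.

The default grid spans 11,536 to 3,952 cm^-1 at 8 cm^-1 spacing
(949 points); trimming it to 11,480-4,008 cm^-1 leaves 935 points, the
variable count of a second-derivative-preprocessed spectrum.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberGrid",
    "SpectralDataset",
    "ROLE_CALIBRATION",
    "ROLE_PREDICTION",
    "read_dataset_csv",
    "write_dataset_csv",
    "read_jcamp",
    "trim_region",
]

ROLE_CALIBRATION = "calibration"
ROLE_PREDICTION = "prediction"

#: Metadata columns preceding the wavenumber columns in the CSV layout.
METADATA_COLUMNS = ("sample_id", "batch", "role")

_DEFAULT_FIRST = 11_536
_DEFAULT_LAST = 3_952
_DEFAULT_STEP = 8


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly descending, equally spaced wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("grid needs at least two wavenumber values")
        diffs = np.diff(values)
        if not np.all(diffs < 0):
            raise ValueError("grid must be descending")
        step = diffs[0]
        if not np.allclose(diffs, step, rtol=1e-9, atol=0.0):
            raise ValueError("grid spacing must be constant")
        object.__setattr__(self, "values", values)

    @property
    def step(self) -> float:
        """Spacing in cm^-1 (positive)."""
        return float(self.values[0] - self.values[1])

    @property
    def count(self) -> int:
        return int(self.values.size)

    @property
    def first(self) -> float:
        return float(self.values[0])

    @property
    def last(self) -> float:
        return float(self.values[-1])

    def mask(self, high: float, low: float) -> np.ndarray:
        """Boolean mask of points with ``high >= nu >= low``."""
        if high <= low:
            raise ValueError("high must exceed low")
        return (self.values <= high) & (self.values >= low)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.count

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return np.array_equal(self.values, other.values)

    @classmethod
    def default(cls) -> "WavenumberGrid":
        """The instrument grid: 11,536..3,952 cm^-1, step 8, 949 points."""
        return cls(np.arange(_DEFAULT_FIRST, _DEFAULT_LAST - 1, -_DEFAULT_STEP, dtype=float))

    @classmethod
    def from_range(cls, first: float, last: float, step: float) -> "WavenumberGrid":
        n = int(round((first - last) / step)) + 1
        return cls(first - step * np.arange(n, dtype=float))


@dataclass
class SpectralDataset:
    """Absorbance matrix plus per-sample reference values and labels.

    Parameters
    ----------
    grid
        Wavenumber axis; ``absorbance`` columns follow its order.
    absorbance
        ``(n_samples, grid.count)`` matrix of absorbance in AU.
    references
        One column per analyte of reference values (``%w/v``, ``%v/v``,
        ``°Brix`` or ``µg/mL`` depending on the analyte).  NaN marks a
        missing value; modelling an analyte requires it to be complete.
    batch, role
        Per-sample batch label and ``calibration``/``prediction`` flag.
    """

    grid: WavenumberGrid
    absorbance: np.ndarray
    references: pd.DataFrame
    batch: np.ndarray
    role: np.ndarray
    sample_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        n = self.absorbance.shape[0]
        if self.absorbance.shape[1] != self.grid.count:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but the "
                f"grid has {self.grid.count} points"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        if len(self.references) != n:
            raise ValueError("references row count does not match absorbance")
        for col in self.references.columns:
            vals = self.references[col].to_numpy(dtype=float)
            ok = np.isnan(vals) | (np.isfinite(vals) & (vals >= 0))
            if not ok.all():
                raise ValueError(f"reference values for {col!r} must be finite and >= 0")
        self.references = self.references.reset_index(drop=True)
        self.batch = np.asarray(self.batch, dtype=object)
        self.role = np.asarray(self.role, dtype=object)
        if self.batch.shape != (n,) or self.role.shape != (n,):
            raise ValueError("batch/role must have one entry per sample")
        bad = set(self.role) - {ROLE_CALIBRATION, ROLE_PREDICTION}
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")
        if self.sample_id is None:
            self.sample_id = np.array([f"s{i:04d}" for i in range(n)], dtype=object)
        else:
            self.sample_id = np.asarray(self.sample_id, dtype=object)
            if self.sample_id.shape != (n,):
                raise ValueError("sample_id must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def analytes(self) -> list[str]:
        return list(self.references.columns)

    def subset(self, mask: np.ndarray) -> "SpectralDataset":
        mask = np.asarray(mask)
        return SpectralDataset(
            grid=self.grid,
            absorbance=self.absorbance[mask],
            references=self.references.loc[mask].reset_index(drop=True),
            batch=self.batch[mask],
            role=self.role[mask],
            sample_id=self.sample_id[mask],
        )

    def calibration(self) -> "SpectralDataset":
        return self.subset(self.role == ROLE_CALIBRATION)

    def prediction(self) -> "SpectralDataset":
        return self.subset(self.role == ROLE_PREDICTION)

    def y(self, analyte: str) -> np.ndarray:
        """Reference values for ``analyte``; errors if absent or incomplete."""
        if analyte not in self.references.columns:
            raise KeyError(f"analyte {analyte!r} not present in the dataset")
        vals = self.references[analyte].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"analyte {analyte!r} has missing reference values")
        return vals

    def with_spectra(self, absorbance: np.ndarray, grid: WavenumberGrid | None = None) -> "SpectralDataset":
        """Copy with a replaced absorbance matrix (and optionally grid)."""
        return SpectralDataset(
            grid=self.grid if grid is None else grid,
            absorbance=absorbance,
            references=self.references.copy(),
            batch=self.batch.copy(),
            role=self.role.copy(),
            sample_id=self.sample_id.copy(),
        )


def _wavenumber_header(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(float(value))


def write_dataset_csv(dataset: SpectralDataset, path) -> str:
    """Write a dataset in the canonical CSV layout and return the path.

    Layout: ``sample_id,batch,role,<analyte...>,<wavenumber...>`` with
    wavenumber headers as cm^-1 numbers in grid (descending) order.
    """
    meta = pd.DataFrame(
        {
            "sample_id": dataset.sample_id,
            "batch": dataset.batch,
            "role": dataset.role,
        }
    )
    spec = pd.DataFrame(
        dataset.absorbance,
        columns=[_wavenumber_header(v) for v in dataset.grid.values],
    )
    out = pd.concat([meta, dataset.references.reset_index(drop=True), spec], axis=1)
    out.to_csv(path, index=False, float_format="%.17g")
    return str(path)


def read_dataset_csv(path, analytes: list[str] | None = None) -> SpectralDataset:
    """Read a dataset CSV written by :func:`write_dataset_csv`.

    ``analytes`` restricts (and checks) the reference columns; ``None``
    takes every non-wavenumber column after the metadata block.
    """
    frame = pd.read_csv(path, dtype={"sample_id": str, "batch": str, "role": str})
    wn_cols = [c for c in frame.columns if re.fullmatch(r"-?\d+(\.\d+)?", str(c).strip())]
    if len(wn_cols) < 2:
        raise ValueError("no wavenumber columns found in CSV header")
    wn = np.array([float(c) for c in wn_cols])
    if not np.all(np.diff(wn) < 0):
        raise ValueError("grid must be descending")
    grid = WavenumberGrid(wn)

    meta_missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if meta_missing:
        raise ValueError(f"missing metadata columns: {meta_missing}")
    other = [c for c in frame.columns if c not in wn_cols and c not in METADATA_COLUMNS]
    if analytes is None:
        analytes = other
    else:
        missing = [a for a in analytes if a not in frame.columns]
        if missing:
            raise ValueError(f"missing analyte column(s): {missing}")

    raw = frame[wn_cols]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~raw.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric absorbance value at row {int(r)}, column {wn_cols[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"missing absorbance value at row {int(r)}, column {wn_cols[c]!r}")

    refs = frame[list(analytes)].apply(pd.to_numeric, errors="raise") if analytes else pd.DataFrame(index=frame.index)
    return SpectralDataset(
        grid=grid,
        absorbance=numeric.to_numpy(dtype=float),
        references=refs,
        batch=frame["batch"].to_numpy(dtype=object),
        role=frame["role"].to_numpy(dtype=object),
        sample_id=frame["sample_id"].to_numpy(dtype=object),
    )


# SQZ/DIF/DUP ordinates use pseudo-digits @, %, and letters; plain AFFN
# numbers only ever contain e/E (exponents) among the alphabetics.
_JCAMP_COMPRESSED = re.compile(r"[@%A-DF-Za-df-z]")


def _jcamp_tokens(line: str) -> list[float]:
    return [float(tok) for tok in re.split(r"[,\s;]+", line.strip()) if tok]


def read_jcamp(path) -> SpectralDataset:
    """Read a single-spectrum JCAMP-DX file (AFFN encoding only).

    Supports ``##XYDATA=(X++(Y..Y))`` and ``##XYPOINTS=(XY..XY)``.  The
    SQZ/DIF/DUP compressed ordinate forms raise an explicit error.  The
    spectrum is returned on a descending grid regardless of file order.
    """
    text = open(path, "r", encoding="utf-8", errors="replace").read()
    lines = text.splitlines()
    headers: dict[str, str] = {}
    data_mode = None
    data_lines: list[str] = []
    for line in lines:
        line = line.split("$$")[0]  # strip comments
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key in ("XYDATA", "XYPOINTS"):
                data_mode = (key, value)
                data_lines = []
            elif key == "END":
                break
            else:
                headers[key] = value
        elif data_mode is not None and line.strip():
            data_lines.append(line)

    if data_mode is None:
        raise ValueError("no XYDATA or XYPOINTS block found")
    if "XUNITS" not in headers:
        raise ValueError("units unknown: missing ##XUNITS")
    xfactor = float(headers.get("XFACTOR", 1.0))
    yfactor = float(headers.get("YFACTOR", 1.0))

    mode, form = data_mode
    xs: list[float] = []
    ys: list[float] = []
    if mode == "XYDATA":
        if "(X++(Y..Y))" not in form.replace(" ", ""):
            raise ValueError(f"unsupported XYDATA form: {form!r}")
        for line in data_lines:
            if _JCAMP_COMPRESSED.search(line):
                raise ValueError("unsupported compression: SQZ/DIF/DUP ordinates are not supported")
            vals = _jcamp_tokens(line)
            if len(vals) < 2:
                raise ValueError("malformed XYDATA line")
            x0, yvals = vals[0], vals[1:]
            xs.extend([x0] * len(yvals))  # placeholder, fixed below
            ys.extend(yvals)
        # Reconstruct abscissae: each line starts at its X value; points are
        # equally spaced by (LASTX-FIRSTX)/(NPOINTS-1) when given, else by
        # consecutive line starts.
        npoints = int(float(headers.get("NPOINTS", len(ys))))
        if npoints != len(ys):
            raise ValueError("NPOINTS does not match the number of ordinates")
        firstx = float(headers.get("FIRSTX", xs[0] * xfactor)) if xs else 0.0
        lastx = float(headers.get("LASTX", xs[-1] * xfactor))
        if npoints > 1:
            step = (lastx - firstx) / (npoints - 1)
        else:
            step = 0.0
        xs = [firstx + step * i for i in range(npoints)]
        ys = [y * yfactor for y in ys]
    else:  # XYPOINTS
        for line in data_lines:
            if _JCAMP_COMPRESSED.search(line):
                raise ValueError("unsupported compression: SQZ/DIF/DUP ordinates are not supported")
            vals = _jcamp_tokens(line)
            if len(vals) % 2:
                raise ValueError("odd token count in XYPOINTS line")
            xs.extend(v * xfactor for v in vals[0::2])
            ys.extend(v * yfactor for v in vals[1::2])

    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    order = np.argsort(-x)
    grid = WavenumberGrid(x[order])
    title = headers.get("TITLE", "jcamp")
    return SpectralDataset(
        grid=grid,
        absorbance=y[order][None, :],
        references=pd.DataFrame(index=[0]),
        batch=np.array([title], dtype=object),
        role=np.array([ROLE_CALIBRATION], dtype=object),
        sample_id=np.array([title], dtype=object),
    )


def trim_region(dataset: SpectralDataset, high: float, low: float) -> SpectralDataset:
    """Restrict the dataset to wavenumbers with ``high >= nu >= low``."""
    mask = dataset.grid.mask(high, low)
    if not mask.any():
        raise ValueError(f"no grid points in {high}-{low} cm^-1")
    grid = WavenumberGrid(dataset.grid.values[mask])
    return dataset.with_spectra(dataset.absorbance[:, mask], grid=grid)
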