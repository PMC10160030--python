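"""imzML input/output and the in-memory raster data model.

An MSI acquisition is a rectangular raster of centroided mass spectra: one
full scan per pixel. Rows are stage steps (vertical), columns are positions
along the lateral scan direction; each row of the original acquisition was
one instrument file. Internally pixels are addressed 0-based ``(row, col)``,
row-major; imzML coordinates are 1-based with ``x = col + 1``,
``y = row + 1``.

Pixel geometry is physical: the pixel width (scan direction) is the product
of the stage's lateral speed and the scan cycle time, the pixel height is
the vertical step size. imzML stores pixel sizes but not stage kinematics,
so ``write_imzml`` additionally records the speed, cycle time and acquired
m/z range as userParams in the scanSettings block, and ``read_imzml`` reads
them back when present.

m/z arrays are stored as 64-bit floats (ppm-scale windows need double
precision); intensities as 32-bit floats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from lxml import etree

__all__ = [
    "PixelSpectrum",
    "RasterGeometry",
    "MSIDataset",
    "read_imzml",
    "write_imzml",
    "read_mzml_rows",
    "pixel_width_from_kinematics",
]

_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def pixel_width_from_kinematics(stage_speed_um_s: float, cycle_time_s: float) -> float:
    """Pixel width (um) from stage speed (um/s) and scan cycle time (s)."""
    if stage_speed_um_s <= 0:
        raise ValueError(f"stage speed must be positive, got {stage_speed_um_s}")
    if cycle_time_s <= 0:
        raise ValueError(f"cycle time must be positive, got {cycle_time_s}")
    return stage_speed_um_s * cycle_time_s


@dataclass(frozen=True)
class RasterGeometry:
    """Physical pixel geometry and acquired m/z range of a raster."""

    pixel_width_um: float
    pixel_height_um: float
    stage_speed_um_s: float
    cycle_time_s: float
    mz_range: tuple[float, float] = (50.0, 1000.0)

    def __post_init__(self) -> None:
        for name in ("pixel_width_um", "pixel_height_um",
                     "stage_speed_um_s", "cycle_time_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        expected = self.stage_speed_um_s * self.cycle_time_s
        if not np.isclose(self.pixel_width_um, expected, rtol=1e-6, atol=0.0):
            raise ValueError(
                f"pixel_width_um={self.pixel_width_um} inconsistent with "
                f"stage_speed*cycle_time={expected}"
            )
        low, high = self.mz_range
        if not low < high:
            raise ValueError(f"invalid m/z range {self.mz_range}")

    @classmethod
    def from_kinematics(
        cls,
        stage_speed_um_s: float,
        cycle_time_s: float,
        pixel_height_um: float,
        mz_range: tuple[float, float] = (50.0, 1000.0),
    ) -> "RasterGeometry":
        return cls(
            pixel_width_um=pixel_width_from_kinematics(stage_speed_um_s, cycle_time_s),
            pixel_height_um=pixel_height_um,
            stage_speed_um_s=stage_speed_um_s,
            cycle_time_s=cycle_time_s,
            mz_range=mz_range,
        )

    @classmethod
    def from_pixel_size(
        cls,
        pixel_width_um: float,
        pixel_height_um: float,
        mz_range: tuple[float, float] = (50.0, 1000.0),
    ) -> "RasterGeometry":
        """Geometry from pixel sizes alone (kinematics default to a 1 s cycle)."""
        return cls(
            pixel_width_um=pixel_width_um,
            pixel_height_um=pixel_height_um,
            stage_speed_um_s=pixel_width_um,
            cycle_time_s=1.0,
            mz_range=mz_range,
        )


@dataclass
class PixelSpectrum:
    """One centroided scan: strictly ascending m/z with non-negative intensities."""

    row_index: int
    col_index: int
    mz_values: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.mz_values = np.asarray(self.mz_values, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.mz_values.shape != self.intensities.shape:
            raise ValueError(
                f"pixel ({self.row_index},{self.col_index}): m/z and intensity "
                f"lengths differ ({self.mz_values.size} vs {self.intensities.size})"
            )
        if self.mz_values.size and np.any(np.diff(self.mz_values) <= 0):
            raise ValueError(
                f"pixel ({self.row_index},{self.col_index}): m/z values not "
                "strictly ascending"
            )
        if np.any(self.intensities < 0):
            raise ValueError(
                f"pixel ({self.row_index},{self.col_index}): negative intensity"
            )

    @property
    def tic(self) -> float:
        return float(self.intensities.sum()) if self.intensities.size else 0.0


@dataclass
class MSIDataset:
    """A dense rectangular raster of pixel spectra with shared geometry."""

    pixels: list[list[PixelSpectrum]]
    geometry: RasterGeometry
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pixels or not self.pixels[0]:
            raise ValueError("dataset must contain at least one pixel")
        n_cols = len(self.pixels[0])
        for r, row in enumerate(self.pixels):
            if len(row) != n_cols:
                raise ValueError(f"row {r} has {len(row)} pixels, expected {n_cols}")
            for c, spec in enumerate(row):
                if (spec.row_index, spec.col_index) != (r, c):
                    raise ValueError(
                        f"pixel at grid position ({r},{c}) carries indices "
                        f"({spec.row_index},{spec.col_index})"
                    )

    @property
    def n_rows(self) -> int:
        return len(self.pixels)

    @property
    def n_cols(self) -> int:
        return len(self.pixels[0])

    def spectrum(self, row: int, col: int) -> PixelSpectrum:
        return self.pixels[row][col]

    def iter_pixels(self) -> Iterator[PixelSpectrum]:
        for row in self.pixels:
            yield from row

    def total_ion_count(self) -> float:
        return float(sum(p.tic for p in self.iter_pixels()))

    @classmethod
    def from_spectra(
        cls,
        spectra: Sequence[PixelSpectrum],
        geometry: RasterGeometry,
        metadata: dict[str, str] | None = None,
    ) -> "MSIDataset":
        """Assemble a dataset from an unordered pixel list, checking rectangularity."""
        if not spectra:
            raise ValueError("no spectra supplied")
        n_rows = max(s.row_index for s in spectra) + 1
        n_cols = max(s.col_index for s in spectra) + 1
        grid: list[list[PixelSpectrum | None]] = [
            [None] * n_cols for _ in range(n_rows)
        ]
        for s in spectra:
            grid[s.row_index][s.col_index] = s
        missing = [
            (r, c)
            for r in range(n_rows)
            for c in range(n_cols)
            if grid[r][c] is None
        ]
        if missing:
            shown = ", ".join(f"({r + 1},{c + 1})" for r, c in missing[:10])
            more = "" if len(missing) <= 10 else f" and {len(missing) - 10} more"
            raise ValueError(
                f"non-rectangular raster: missing coordinate {shown}{more} "
                "(1-based x=col+1, y=row+1)"
            )
        return cls(pixels=grid, geometry=geometry, metadata=metadata or {})  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# imzML reading / writing
# ---------------------------------------------------------------------------

def _read_scan_settings(path: Path) -> dict[str, float]:
    """Pixel sizes and kinematic userParams from the imzML scanSettings block."""
    out: dict[str, float] = {}
    try:
        tree = etree.parse(str(path))
    except OSError:
        return out
    for cv in tree.iter(f"{_MZML_NS}cvParam"):
        acc = cv.get("accession")
        if acc == "IMS:1000046":
            out["pixel_width_um"] = float(cv.get("value"))
        elif acc == "IMS:1000047":
            out["pixel_height_um"] = float(cv.get("value"))
    for up in tree.iter(f"{_MZML_NS}userParam"):
        name = up.get("name")
        if name in {"stage_speed_um_s", "cycle_time_s", "mz_range_low", "mz_range_high"}:
            out[name] = float(up.get("value"))
    return out


def _make_deterministic(path: Path) -> None:
    """Replace the random ibd UUID with one derived from the binary payload.

    The ibd format opens with a 16-byte UUID that pyimzml draws at random,
    which would make byte-identical reruns impossible; deriving it from a
    SHA-256 of the payload keeps the write deterministic. The imzML's UUID
    and SHA-1 cvParams are updated to match.
    """
    import hashlib
    import uuid as _uuid

    ibd = path.with_suffix(".ibd")
    payload = ibd.read_bytes()[16:]
    digest = bytearray(hashlib.sha256(payload).digest()[:16])
    digest[6] = (digest[6] & 0x0F) | 0x40  # version 4 layout
    digest[8] = (digest[8] & 0x3F) | 0x80
    new_uuid = _uuid.UUID(bytes=bytes(digest))
    ibd.write_bytes(bytes(digest) + payload)
    sha1 = hashlib.sha1(bytes(digest) + payload).hexdigest()

    tree = etree.parse(str(path))
    for cv in tree.iter(f"{_MZML_NS}cvParam"):
        acc = cv.get("accession")
        if acc == "IMS:1000080":
            cv.set("value", ("{%s}" % new_uuid).upper())
        elif acc == "IMS:1000091":
            cv.set("value", sha1)
    # pyimzml embeds the full output path as the run id; keep only the stem
    # so identical data written in different directories stays identical
    for run in tree.iter(f"{_MZML_NS}run"):
        run.set("id", path.stem)
    tree.write(str(path), xml_declaration=True, encoding="ISO-8859-1")


def _inject_scan_settings(path: Path, geometry: RasterGeometry) -> None:
    """Write pixel sizes and kinematics into the imzML scanSettings element."""
    tree = etree.parse(str(path))
    settings_list = tree.find(f"{_MZML_NS}scanSettingsList")
    if settings_list is None:
        return
    settings = settings_list.find(f"{_MZML_NS}scanSettings")
    if settings is None:
        return
    for acc, name, value, unit in (
        ("IMS:1000046", "pixel size (x)", geometry.pixel_width_um, "micrometer"),
        ("IMS:1000047", "pixel size y", geometry.pixel_height_um, "micrometer"),
    ):
        el = etree.SubElement(settings, f"{_MZML_NS}cvParam")
        el.set("cvRef", "IMS")
        el.set("accession", acc)
        el.set("name", name)
        el.set("value", repr(value))
        el.set("unitCvRef", "UO")
        el.set("unitAccession", "UO:0000017")
        el.set("unitName", unit)
    for name, value in (
        ("stage_speed_um_s", geometry.stage_speed_um_s),
        ("cycle_time_s", geometry.cycle_time_s),
        ("mz_range_low", geometry.mz_range[0]),
        ("mz_range_high", geometry.mz_range[1]),
    ):
        el = etree.SubElement(settings, f"{_MZML_NS}userParam")
        el.set("name", name)
        el.set("value", repr(value))
    tree.write(str(path), xml_declaration=True, encoding="ISO-8859-1")


def read_imzml(
    path: str | Path,
    geometry: RasterGeometry | None = None,
) -> MSIDataset:
    """Read an imzML(+ibd) pair into an :class:`MSIDataset`.

    imzML 1-based (x, y) coordinates map to 0-based (row=y-1, col=x-1). The
    coordinate set must fill a full rectangle; missing coordinates raise with
    an explicit list. Geometry is taken from the file's pixel-size metadata
    when present, else from the ``geometry`` override.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    ibd = path.with_suffix(".ibd")
    if not path.exists():
        raise FileNotFoundError(f"imzML file not found: {path}")
    if not ibd.exists():
        raise FileNotFoundError(
            f"missing binary file: {ibd} (paired with {path})"
        )

    parser = ImzMLParser(str(path))
    coords = [(x, y) for (x, y, _z) in parser.coordinates]
    max_x = max(x for x, _ in coords)
    max_y = max(y for _, y in coords)
    have = set(coords)
    missing = [
        (x, y)
        for y in range(1, max_y + 1)
        for x in range(1, max_x + 1)
        if (x, y) not in have
    ]
    if missing:
        shown = ", ".join(f"({y},{x})" for x, y in missing[:10])
        more = "" if len(missing) <= 10 else f" and {len(missing) - 10} more"
        raise ValueError(f"non-rectangular raster: missing coordinate {shown}{more}")

    spectra = []
    mz_lo, mz_hi = np.inf, -np.inf
    for i, (x, y) in enumerate(coords):
        mzs, ints = parser.getspectrum(i)
        mzs = np.asarray(mzs, dtype=np.float64)
        ints = np.asarray(ints, dtype=np.float64)
        if mzs.size and np.any(np.diff(mzs) <= 0):
            raise ValueError(
                f"unsorted m/z array in pixel (row={y - 1}, col={x - 1})"
            )
        if mzs.size:
            mz_lo = min(mz_lo, float(mzs[0]))
            mz_hi = max(mz_hi, float(mzs[-1]))
        spectra.append(
            PixelSpectrum(row_index=y - 1, col_index=x - 1,
                          mz_values=mzs, intensities=ints)
        )

    meta = _read_scan_settings(path)
    if geometry is None:
        if "pixel_width_um" not in meta or "pixel_height_um" not in meta:
            raise ValueError(
                f"{path} carries no pixel-size metadata; supply a geometry override"
            )
        if np.isfinite(mz_lo):
            default_range = (min(mz_lo, mz_hi - 1e-9), mz_hi + 1e-9)
        else:
            default_range = (50.0, 1000.0)
        mz_range = (
            meta.get("mz_range_low", default_range[0]),
            meta.get("mz_range_high", default_range[1]),
        )
        if "stage_speed_um_s" in meta and "cycle_time_s" in meta:
            geometry = RasterGeometry(
                pixel_width_um=meta["pixel_width_um"],
                pixel_height_um=meta["pixel_height_um"],
                stage_speed_um_s=meta["stage_speed_um_s"],
                cycle_time_s=meta["cycle_time_s"],
                mz_range=mz_range,
            )
        else:
            geometry = RasterGeometry.from_pixel_size(
                meta["pixel_width_um"], meta["pixel_height_um"], mz_range
            )

    polarity = parser.polarity or ""
    metadata = {"source": str(path)}
    if polarity:
        metadata["polarity"] = polarity
    return MSIDataset.from_spectra(spectra, geometry, metadata)


def _add_spectrum(writer, mzs: np.ndarray, ints: np.ndarray, coords) -> None:
    """addSpectrum tolerant of empty (off-tissue, all-zero) pixels.

    pyimzml's public addSpectrum reduces over the arrays and fails on length
    zero, so empty spectra go through the encoder directly.
    """
    if mzs.size:
        writer.addSpectrum(mzs, ints, coords)
        return
    from pyimzml.ImzMLWriter import _Spectrum

    mz_data = writer._encode_and_write(mzs, writer.mz_dtype, writer.mz_compression)
    int_data = writer._encode_and_write(
        ints, writer.intensity_dtype, writer.intensity_compression
    )
    writer.spectra.append(
        _Spectrum(coords, mz_data[1], mz_data[0], mz_data[2],
                  int_data[1], int_data[0], int_data[2],
                  0.0, 0.0, 0.0, 0.0, 0.0, [])
    )


def write_imzml(
    dataset: MSIDataset,
    path: str | Path,
    mode: str = "processed",
) -> Path:
    """Write the dataset as an imzML+ibd pair (continuous or processed mode).

    Continuous mode requires all pixels to share one m/z axis. m/z is stored
    as 64-bit float, intensity as 32-bit float; read_imzml(write_imzml(d))
    is the identity on m/z and on intensities at 32-bit precision.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if mode not in {"continuous", "processed"}:
        raise ValueError(f"mode must be 'continuous' or 'processed', got {mode!r}")
    path = Path(path)
    if mode == "continuous":
        first = dataset.spectrum(0, 0).mz_values
        for spec in dataset.iter_pixels():
            if not np.array_equal(spec.mz_values, first):
                raise ValueError(
                    "continuous mode requires a shared m/z axis; pixel "
                    f"({spec.row_index},{spec.col_index}) differs"
                )

    polarity = dataset.metadata.get("polarity", "negative")
    with ImzMLWriter(str(path), mode=mode, polarity=polarity) as writer:
        for spec in dataset.iter_pixels():
            _add_spectrum(
                writer,
                spec.mz_values,
                spec.intensities.astype(np.float32),
                (spec.col_index + 1, spec.row_index + 1),
            )
    _make_deterministic(path)
    _inject_scan_settings(path, dataset.geometry)
    return path


def _read_mzml_spectra(path: Path) -> list[tuple[np.ndarray, np.ndarray]]:
    """Minimal mzML spectrum reader: uncompressed or zlib 32/64-bit arrays."""
    import base64
    import zlib

    scans = []
    for spectrum in etree.parse(str(path)).iter(f"{_MZML_NS}spectrum"):
        arrays: dict[str, np.ndarray] = {}
        for bda in spectrum.iter(f"{_MZML_NS}binaryDataArray"):
            dtype, compressed, kind = "<f8", False, None
            for cv in bda.iter(f"{_MZML_NS}cvParam"):
                acc = cv.get("accession")
                if acc == "MS:1000521":
                    dtype = "<f4"
                elif acc == "MS:1000523":
                    dtype = "<f8"
                elif acc == "MS:1000574":
                    compressed = True
                elif acc == "MS:1000514":
                    kind = "mz"
                elif acc == "MS:1000515":
                    kind = "intensity"
            binary = bda.find(f"{_MZML_NS}binary")
            raw = base64.b64decode(binary.text or "")
            if compressed:
                raw = zlib.decompress(raw)
            if kind is not None:
                arrays[kind] = np.frombuffer(raw, dtype=dtype).astype(np.float64)
        if "mz" in arrays and "intensity" in arrays:
            scans.append((arrays["mz"], arrays["intensity"]))
    return scans


def read_mzml_rows(
    manifest: str | Path,
    geometry: RasterGeometry,
) -> MSIDataset:
    """Assemble a raster from one mzML file per raster row.

    ``manifest`` is a text file listing one mzML path per line, top row
    first (mirroring one instrument file per stage row); the n-th spectrum
    of a file becomes column n of that row. Relative paths resolve against
    the manifest's directory. All rows must contain the same number of scans.
    """
    manifest = Path(manifest)
    row_paths = [
        line.strip()
        for line in manifest.read_text().splitlines()
        if line.strip() and not line.strip().startswith("#")
    ]
    if not row_paths:
        raise ValueError(f"empty manifest: {manifest}")

    spectra: list[PixelSpectrum] = []
    n_cols: int | None = None
    for r, raw in enumerate(row_paths):
        fp = Path(raw)
        if not fp.is_absolute():
            fp = manifest.parent / fp
        if not fp.exists():
            raise FileNotFoundError(f"row {r}: mzML file not found: {fp}")
        scans = _read_mzml_spectra(fp)
        if n_cols is None:
            n_cols = len(scans)
        elif len(scans) != n_cols:
            raise ValueError(
                f"row {r} has {len(scans)} scans, expected {n_cols}: "
                "non-rectangular raster"
            )
        for c, (mzs, ints) in enumerate(scans):
            order = np.argsort(mzs, kind="stable")
            spectra.append(
                PixelSpectrum(row_index=r, col_index=c,
                              mz_values=mzs[order], intensities=ints[order])
            )
    return MSIDataset.from_spectra(spectra, geometry, {"source": str(manifest)})
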