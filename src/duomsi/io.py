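"""Readers and writers for the pipeline's on-disk formats.

* imzML (XML + ``.ibd`` binary companion) for the spectral modality —
  processed and continuous modes, centroided spectra only, no or zlib
  compression. The reader rejects profile-mode data loudly instead of
  resampling it.
* Plain CSV grids (one per element, rows = y) plus a YAML sidecar for
  elemental stacks; a long-format CSV (x, y, element, value) is also
  accepted.
* TSV for landmark correspondences.
* CSV for ion-image rasters and lipid target lists; grayscale PNG export
  for display.

imzML coordinates are 1-based; they are shifted to this package's 0-based
convention on read and back on write.
"""

from __future__ import annotations

import csv
import hashlib
import logging
import struct
import uuid as uuid_mod
import zlib
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import yaml

from .datamodel import (
    COUNTS_PER_SECOND,
    MG_PER_KG,
    DimensionMismatchError,
    ElementalStack,
    ElementChannel,
    FormatError,
    LandmarkSet,
    LaserLineSeries,
    SpectralImage,
    UnsupportedModeError,
)

log = logging.getLogger("duomsi")

# imzML / mzML controlled-vocabulary accessions used here
_CV_PROCESSED = "IMS:1000031"
_CV_CONTINUOUS = "IMS:1000030"
_CV_CENTROID = "MS:1000127"
_CV_PROFILE = "MS:1000128"
_CV_UUID = "IMS:1000080"
_CV_SHA1 = "IMS:1000091"
_CV_POS_X = "IMS:1000050"
_CV_POS_Y = "IMS:1000051"
_CV_MAX_X = "IMS:1000042"
_CV_MAX_Y = "IMS:1000043"
_CV_PIXEL_X = "IMS:1000046"
_CV_EXT_OFFSET = "IMS:1000102"
_CV_EXT_LENGTH = "IMS:1000103"
_CV_EXT_ENCODED = "IMS:1000104"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INT_ARRAY = "MS:1000515"
_CV_ZLIB = "MS:1000574"
_CV_NOCOMP = "MS:1000576"
_DTYPES = {
    "MS:1000521": np.dtype("<f4"),  # 32-bit float
    "MS:1000523": np.dtype("<f8"),  # 64-bit float
    "MS:1000519": np.dtype("<i4"),  # 32-bit integer
    "MS:1000522": np.dtype("<i8"),  # 64-bit integer
}


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cvparams(elem: ET.Element) -> dict[str, str]:
    """accession -> value for all cvParam descendants of *elem*."""
    out = {}
    for cv in elem.iter():
        if _local(cv.tag) == "cvParam":
            out[cv.get("accession", "")] = cv.get("value", "")
    return out


def _own_cvparams(elem: ET.Element) -> dict[str, str]:
    return {
        cv.get("accession", ""): cv.get("value", "")
        for cv in elem
        if _local(cv.tag) == "cvParam"
    }


# ---------------------------------------------------------------------------
# imzML
# ---------------------------------------------------------------------------

def read_imzml(path: str | Path) -> SpectralImage:
    """Read a centroided imzML file into a :class:`SpectralImage`.

    The binary companion ``.ibd`` must sit next to the XML file. Pixels
    absent from the file come back as empty spectra; peaks stored with
    non-monotonic m/z are re-sorted with a warning.
    """
    path = Path(path)
    ibd_path = path.with_suffix(".ibd")
    if not ibd_path.exists():
        raise FormatError(f"missing binary companion {ibd_path} for {path}")
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise FormatError(f"malformed imzML XML in {path}: {exc}") from exc
    root = tree.getroot()

    file_cv = _cvparams(_find(root, "fileDescription"))
    if _CV_PROFILE in file_cv and _CV_CENTROID not in file_cv:
        raise UnsupportedModeError(
            f"{path}: profile-mode spectra are not supported; centroid the data first"
        )

    # referenceable param groups tell us dtype/compression per array kind
    groups: dict[str, dict[str, str]] = {}
    rpgl = root.find(".//{*}referenceableParamGroupList")
    if rpgl is not None:
        for g in rpgl:
            groups[g.get("id", "")] = _own_cvparams(g)

    scan_cv = _cvparams(root)  # includes scanSettings
    max_x = int(scan_cv.get(_CV_MAX_X, 0))
    max_y = int(scan_cv.get(_CV_MAX_Y, 0))
    pixel_size = float(scan_cv.get(_CV_PIXEL_X, 0.0)) or float("nan")

    spectra = []
    for spec in root.iter():
        if _local(spec.tag) != "spectrum":
            continue
        if _CV_PROFILE in _own_cvparams(spec):
            raise UnsupportedModeError(f"{path}: spectrum {spec.get('id')} is profile mode")
        params = _cvparams(spec)
        try:
            x = int(params[_CV_POS_X])
            y = int(params[_CV_POS_Y])
        except KeyError as exc:
            raise FormatError(f"{path}: spectrum {spec.get('id')} lacks a position") from exc
        arrays = {}
        for bda in spec.iter():
            if _local(bda.tag) != "binaryDataArray":
                continue
            cv = _own_cvparams(bda)
            ref = next(
                (b.get("ref", "") for b in bda if _local(b.tag) == "referenceableParamGroupRef"),
                "",
            )
            cv = {**groups.get(ref, {}), **cv}
            kind = "mz" if _CV_MZ_ARRAY in cv else ("int" if _CV_INT_ARRAY in cv else None)
            if kind is None:
                continue
            dtype = next((d for acc, d in _DTYPES.items() if acc in cv), np.dtype("<f8"))
            arrays[kind] = (
                int(cv[_CV_EXT_OFFSET]),
                int(cv[_CV_EXT_LENGTH]),
                int(cv[_CV_EXT_ENCODED]),
                dtype,
                _CV_ZLIB in cv,
            )
        if "mz" not in arrays or "int" not in arrays:
            raise FormatError(f"{path}: spectrum {spec.get('id')} lacks m/z or intensity array")
        spectra.append((x, y, arrays))
        max_x = max(max_x, x)
        max_y = max(max_y, y)

    width, height = max_x, max_y
    if width < 1 or height < 1:
        raise FormatError(f"{path}: no pixel positions found")

    mzs: list[np.ndarray] = [np.empty(0) for _ in range(width * height)]
    intensities: list[np.ndarray] = [np.empty(0) for _ in range(width * height)]
    with open(ibd_path, "rb") as ibd:
        for x, y, arrays in spectra:
            out = {}
            for kind, (offset, length, encoded, dtype, compressed) in arrays.items():
                ibd.seek(offset)
                raw = ibd.read(encoded)
                if compressed:
                    raw = zlib.decompress(raw)
                out[kind] = np.frombuffer(raw, dtype=dtype, count=length).astype(float)
            mz, inten = out["mz"], out["int"]
            if mz.size > 1 and np.any(np.diff(mz) <= 0):
                log.warning("non-monotonic m/z at pixel (x=%d, y=%d); re-sorting", x, y)
                order = np.argsort(mz, kind="stable")
                mz, inten = mz[order], inten[order]
                keep = np.concatenate([[True], np.diff(mz) > 0])
                mz, inten = mz[keep], inten[keep]
            idx = (y - 1) * width + (x - 1)  # imzML is 1-based
            mzs[idx], intensities[idx] = mz, inten

    nonempty = [m for m in mzs if m.size]
    if nonempty:
        mz_range = (min(float(m[0]) for m in nonempty), max(float(m[-1]) for m in nonempty))
    else:
        mz_range = (0.0, 0.0)
    meta_range = _cvparams(root)
    return SpectralImage(
        width=width,
        height=height,
        pixel_size=pixel_size,
        mzs=mzs,
        intensities=intensities,
        mz_range=mz_range,
        metadata={"source": str(path), "polarity": meta_range.get("MS:1000130", "")},
    )


def _find(root: ET.Element, tag: str) -> ET.Element:
    el = root.find(f".//{{*}}{tag}")
    if el is None:
        raise FormatError(f"imzML element <{tag}> missing")
    return el


def write_imzml(img: SpectralImage, path: str | Path, compress: bool = False) -> None:
    """Write a :class:`SpectralImage` as processed-mode centroided imzML.

    Produces ``path`` (XML) and the ``.ibd`` binary companion; m/z values
    are stored as 64-bit, intensities as 32-bit floats.
    """
    path = Path(path)
    ibd_path = path.with_suffix(".ibd")

    # serialize arrays first so the file UUID can be content-derived:
    # identical images then produce byte-identical files (reproducibility)
    chunks: list[tuple[bytes, int, bytes, int]] = []
    digest = hashlib.sha1()
    for mz, inten in zip(img.mzs, img.intensities):
        rec = []
        for arr, dtype in ((mz, "<f8"), (inten, "<f4")):
            raw = np.asarray(arr, dtype=dtype).tobytes()
            if compress:
                raw = zlib.compress(raw)
            digest.update(raw)
            rec.append((raw, len(arr)))
        chunks.append((rec[0][0], rec[0][1], rec[1][0], rec[1][1]))
    file_uuid = uuid_mod.UUID(bytes=digest.digest()[:16], version=4)

    offsets = []
    sha1 = hashlib.sha1()
    with open(ibd_path, "wb") as ibd:
        ibd.write(file_uuid.bytes)
        sha1.update(file_uuid.bytes)
        pos = 16
        for raw_mz, n_mz, raw_int, n_int in chunks:
            rec = {}
            for kind, raw, n in (("mz", raw_mz, n_mz), ("int", raw_int, n_int)):
                ibd.write(raw)
                sha1.update(raw)
                rec[kind] = (pos, n, len(raw))
                pos += len(raw)
            offsets.append(rec)

    comp_acc, comp_name = (
        (_CV_ZLIB, "zlib compression") if compress else (_CV_NOCOMP, "no compression")
    )

    def cv(accession: str, name: str, value: str = "") -> str:
        ref = accession.split(":")[0]
        return f'<cvParam cvRef="{ref}" accession="{accession}" name="{name}" value="{value}"/>'

    spectra_xml = []
    for row in range(img.height):
        for col in range(img.width):
            i = img.index(row, col)
            o = offsets[i]
            spectra_xml.append(
                f'<spectrum id="spectrum={i}" index="{i}" defaultArrayLength="{o["mz"][1]}">'
                + cv(_CV_CENTROID, "centroid spectrum")
                + "<scanList count=\"1\"><scan>"
                + cv(_CV_POS_X, "position x", str(col + 1))
                + cv(_CV_POS_Y, "position y", str(row + 1))
                + "</scan></scanList>"
                + '<binaryDataArrayList count="2">'
                + '<binaryDataArray encodedLength="0">'
                + '<referenceableParamGroupRef ref="mzArray"/>'
                + cv(_CV_EXT_OFFSET, "external offset", str(o["mz"][0]))
                + cv(_CV_EXT_LENGTH, "external array length", str(o["mz"][1]))
                + cv(_CV_EXT_ENCODED, "external encoded length", str(o["mz"][2]))
                + "<binary/></binaryDataArray>"
                + '<binaryDataArray encodedLength="0">'
                + '<referenceableParamGroupRef ref="intensityArray"/>'
                + cv(_CV_EXT_OFFSET, "external offset", str(o["int"][0]))
                + cv(_CV_EXT_LENGTH, "external array length", str(o["int"][1]))
                + cv(_CV_EXT_ENCODED, "external encoded length", str(o["int"][2]))
                + "<binary/></binaryDataArray>"
                + "</binaryDataArrayList></spectrum>"
            )

    xml = f"""<?xml version="1.0" encoding="UTF-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="IMS" fullName="Imaging MS Ontology" URI="https://raw.githubusercontent.com/imzML/imzML/master/imagingMS.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      {cv(_CV_PROCESSED, "processed")}
      {cv(_CV_CENTROID, "centroid spectrum")}
      {cv(_CV_UUID, "universally unique identifier", "{" + str(file_uuid) + "}")}
      {cv(_CV_SHA1, "ibd SHA-1", sha1.hexdigest())}
    </fileContent>
  </fileDescription>
  <referenceableParamGroupList count="2">
    <referenceableParamGroup id="mzArray">
      {cv(_CV_MZ_ARRAY, "m/z array")}
      {cv("MS:1000523", "64-bit float")}
      {cv(comp_acc, comp_name)}
      {cv("IMS:1000101", "external data", "true")}
    </referenceableParamGroup>
    <referenceableParamGroup id="intensityArray">
      {cv(_CV_INT_ARRAY, "intensity array")}
      {cv("MS:1000521", "32-bit float")}
      {cv(comp_acc, comp_name)}
      {cv("IMS:1000101", "external data", "true")}
    </referenceableParamGroup>
  </referenceableParamGroupList>
  <scanSettingsList count="1">
    <scanSettings id="scan1">
      {cv(_CV_MAX_X, "max count of pixels x", str(img.width))}
      {cv(_CV_MAX_Y, "max count of pixels y", str(img.height))}
      {cv(_CV_PIXEL_X, "pixel size (x)", repr(img.pixel_size))}
    </scanSettings>
  </scanSettingsList>
  <run id="run1">
    <spectrumList count="{img.n_pixels}" defaultDataProcessingRef="dp1">
      {"".join(spectra_xml)}
    </spectrumList>
  </run>
</mzML>
"""
    path.write_text(xml)


# ---------------------------------------------------------------------------
# Elemental CSV stacks
# ---------------------------------------------------------------------------

def _read_grid_csv(path: Path) -> np.ndarray:
    """Parse one CSV grid (rows = y); 'NA'/empty cells become NaN."""
    rows = []
    with path.open(newline="") as fh:
        for i, rec in enumerate(csv.reader(fh)):
            if not rec or (len(rec) == 1 and rec[0].strip() == ""):
                continue
            try:
                rows.append(
                    [float("nan") if c.strip() in ("", "NA", "NaN", "nan") else float(c) for c in rec]
                )
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric cell in row {i}: {exc}") from exc
            if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                raise FormatError(
                    f"{path}: ragged row {i} has {len(rows[-1])} cells, expected {len(rows[0])}"
                )
    if not rows:
        raise FormatError(f"{path}: empty grid")
    return np.asarray(rows, dtype=float)


def read_element_csv(
    source: str | Path | list,
    units: dict[str, str] | None = None,
    pixel_size: float = float("nan"),
    layout: str = "grid",
) -> ElementalStack:
    """Read an elemental stack from CSV files.

    ``source`` may be a directory (every ``*.csv`` inside, sorted, one
    channel each, labelled by file stem), an explicit list of CSV paths
    (channel order = list order), or a single long-format CSV with columns
    ``x, y, element, value`` when ``layout='long'``. A YAML sidecar named
    ``elements.yaml`` (directory case) or ``<file>.yaml`` may provide
    ``units: {label: unit}`` and ``pixel_size``; the default unit is
    counts per second.
    """
    units = dict(units or {})
    paths: list[Path]
    if isinstance(source, (list, tuple)):
        paths = [Path(p) for p in source]
        sidecar = paths[0].parent / "elements.yaml" if paths else None
    else:
        source = Path(source)
        if source.is_dir():
            paths = sorted(source.glob("*.csv"))
            sidecar = source / "elements.yaml"
        else:
            paths = [source]
            sidecar = source.with_suffix(".yaml")
    if sidecar is not None and sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        units = {**meta.get("units", {}), **units}
        pixel_size = float(meta.get("pixel_size", pixel_size))

    if layout == "long":
        if len(paths) != 1:
            raise FormatError("long layout takes a single CSV file")
        return _read_long_csv(paths[0], units, pixel_size)

    if not paths:
        raise FormatError(f"no element CSV files found in {source}")
    channels = []
    shape = None
    for p in paths:
        grid = _read_grid_csv(p)
        if shape is None:
            shape = grid.shape
        elif grid.shape != shape:
            raise DimensionMismatchError(
                f"{p}: grid shape {grid.shape} != {shape} of first channel"
            )
        label = p.stem
        channels.append(ElementChannel(label, units.get(label, COUNTS_PER_SECOND), grid))
    return ElementalStack(pixel_size=pixel_size, channels=channels)


def _read_long_csv(path: Path, units: dict[str, str], pixel_size: float) -> ElementalStack:
    import pandas as pd

    df = pd.read_csv(path)
    required = {"x", "y", "element", "value"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: long layout needs columns {sorted(required)}")
    width = int(df["x"].max()) + 1
    height = int(df["y"].max()) + 1
    channels = []
    for el, sub in df.groupby("element", sort=False):
        grid = np.full((height, width), np.nan)
        grid[sub["y"].astype(int), sub["x"].astype(int)] = sub["value"].astype(float)
        channels.append(ElementChannel(str(el), units.get(str(el), COUNTS_PER_SECOND), grid))
    return ElementalStack(pixel_size=pixel_size, channels=channels)


def write_element_csv(stack: ElementalStack, directory: str | Path) -> list[Path]:
    """Write one CSV grid per channel plus an ``elements.yaml`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for ch in stack.channels:
        p = directory / f"{ch.label}.csv"
        with p.open("w", newline="") as fh:
            w = csv.writer(fh)
            for row in ch.values:
                w.writerow(["NA" if not np.isfinite(v) else repr(float(v)) for v in row])
        written.append(p)
    sidecar = directory / "elements.yaml"
    sidecar.write_text(
        yaml.safe_dump(
            {
                "pixel_size": None if np.isnan(stack.pixel_size) else float(stack.pixel_size),
                "units": {ch.label: ch.unit for ch in stack.channels},
                "channel_order": stack.labels,
            },
            sort_keys=False,
        )
    )
    return written


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read landmark pairs from a TSV with header
    ``x_fixed  y_fixed  x_moving  y_moving`` (optional ``label`` column)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = ["x_fixed", "y_fixed", "x_moving", "y_moving"]
        if reader.fieldnames is None or not set(required).issubset(reader.fieldnames):
            raise FormatError(f"{path}: landmark TSV needs columns {required}")
        fixed, moving, labels = [], [], []
        for i, rec in enumerate(reader):
            try:
                fixed.append((float(rec["x_fixed"]), float(rec["y_fixed"])))
                moving.append((float(rec["x_moving"]), float(rec["y_moving"])))
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}: non-numeric landmark in row {i + 1}") from exc
            labels.append(rec.get("label") or f"L{i + 1}")
    if not fixed:
        raise FormatError(f"{path}: no landmarks")
    return LandmarkSet(fixed=np.asarray(fixed), moving=np.asarray(moving), labels=labels)


def write_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["x_fixed", "y_fixed", "x_moving", "y_moving", "label"])
        labels = lm.labels or [f"L{i + 1}" for i in range(len(lm))]
        for (xf, yf), (xm, ym), lab in zip(lm.fixed, lm.moving, labels):
            w.writerow([repr(float(xf)), repr(float(yf)), repr(float(xm)), repr(float(ym)), lab])


# ---------------------------------------------------------------------------
# Line scans (one CSV per line + YAML run sheet)
# ---------------------------------------------------------------------------

def read_line_scans(run_sheet: str | Path) -> list[LaserLineSeries]:
    """Read LA-ICP-MS line scans described by a YAML run sheet.

    The sheet holds ``scan_speed`` (µm/s), ``beam_diameter`` (µm) and a
    ``lines`` list of ``{file, y_offset}`` entries; each file is a CSV with
    a ``time_s`` column followed by one column per element.
    """
    run_sheet = Path(run_sheet)
    sheet = yaml.safe_load(run_sheet.read_text())
    lines = []
    for i, entry in enumerate(sheet["lines"]):
        p = run_sheet.parent / entry["file"]
        with p.open(newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if not header or header[0] != "time_s":
                raise FormatError(f"{p}: first column must be time_s")
            elements = header[1:]
            rows = [[float(c) for c in rec] for rec in reader if rec]
        arr = np.asarray(rows, dtype=float)
        lines.append(
            LaserLineSeries(
                line_index=i,
                y_offset=float(entry["y_offset"]),
                timestamps=arr[:, 0],
                counts={el: arr[:, j + 1] for j, el in enumerate(elements)},
                scan_speed=float(sheet["scan_speed"]),
                beam_diameter=float(sheet["beam_diameter"]),
            )
        )
    return lines


def write_line_scans(lines: list[LaserLineSeries], directory: str | Path) -> Path:
    """Write per-line CSVs plus the YAML run sheet; returns the sheet path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for line in lines:
        fname = f"line_{line.line_index:04d}.csv"
        with (directory / fname).open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_s"] + line.elements)
            for j, t in enumerate(line.timestamps):
                w.writerow([repr(float(t))] + [repr(float(line.counts[el][j])) for el in line.elements])
        entries.append({"file": fname, "y_offset": float(line.y_offset)})
    sheet = directory / "run_sheet.yaml"
    sheet.write_text(
        yaml.safe_dump(
            {
                "scan_speed": float(lines[0].scan_speed),
                "beam_diameter": float(lines[0].beam_diameter),
                "lines": entries,
            },
            sort_keys=False,
        )
    )
    return sheet


# ---------------------------------------------------------------------------
# Rasters, targets, reports
# ---------------------------------------------------------------------------

def write_raster_csv(values: np.ndarray, path: str | Path) -> None:
    """Write a single 2-D raster as a CSV grid (NaN → 'NA')."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        for row in np.atleast_2d(values):
            w.writerow(["NA" if not np.isfinite(v) else repr(float(v)) for v in row])


def read_raster_csv(path: str | Path) -> np.ndarray:
    return _read_grid_csv(Path(path))


def write_raster_png(values: np.ndarray, path: str | Path, bit_depth: int = 8) -> None:
    """Export a raster as a grayscale PNG, min–max scaled; NaN → 0."""
    from PIL import Image

    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    lo = float(v[finite].min()) if finite.any() else 0.0
    hi = float(v[finite].max()) if finite.any() else 1.0
    span = hi - lo if hi > lo else 1.0
    scaled = np.where(finite, (v - lo) / span, 0.0)
    if bit_depth == 16:
        img = Image.fromarray((scaled * 65535).astype(np.uint16), mode="I;16")
    elif bit_depth == 8:
        img = Image.fromarray((scaled * 255).astype(np.uint8), mode="L")
    else:
        raise ValueError("bit_depth must be 8 or 16")
    img.save(Path(path))


def write_rgb_png(rgb: np.ndarray, path: str | Path) -> None:
    """Write an (h, w, 3) float array in [0, 1] as an RGB PNG."""
    from PIL import Image

    arr = (np.clip(np.asarray(rgb, dtype=float), 0.0, 1.0) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(Path(path))


def read_targets_csv(path: str | Path) -> list[tuple[str, float]]:
    """Read a lipid target list CSV with columns ``label, mz``."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"label", "mz"}.issubset(reader.fieldnames):
            raise FormatError(f"{path}: target CSV needs columns label, mz")
        targets = [(rec["label"], float(rec["mz"])) for rec in reader]
    if not targets:
        raise FormatError(f"{path}: no targets")
    return targets


def write_targets_csv(targets: list[tuple[str, float]], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "mz"])
        for label, mz in targets:
            w.writerow([label, f"{mz:.4f}"])
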