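"""Readers and writers for spectra and manifests.

Formats:

* **wide CSV** — first column ``wavenumber``, one column per spectrum
  keyed ``<patientid>_<well>_<replicate>`` (underscores are forbidden
  inside patient ids so the key parses unambiguously; ``well`` is 1–3
  or ``background``).
* **JCAMP-DX 4.24 subset** — ``##XYDATA=(X++(Y..Y))`` with
  FIRSTX/LASTX/DELTAX/XFACTOR/YFACTOR; one spectrum per file.
* **manifest CSV** — the exact :data:`~spectriage.cohort.MANIFEST_COLUMNS`.

The canonical grid orientation is descending wavenumber; ascending
inputs are accepted and flipped on load.  Missing absorbance cells are
an error, never interpolated — quality control must see the raw record.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MANIFEST_COLUMNS, CohortManifest
from .errors import FormatError, SchemaError
from .spectra import (
    BACKGROUND_ROLE,
    BACKGROUND_WELL,
    SAMPLE_ROLE,
    SpectraCollection,
    Spectrum,
)

_COLUMN_KEY_RE = re.compile(r"^(?P<pid>[^_]+)_(?P<well>[123]|background)_(?P<rep>\d+)$")


def _parse_column_key(key: str, index: int) -> tuple[str, str, int]:
    m = _COLUMN_KEY_RE.match(key)
    if m is None:
        raise FormatError(
            f"column {index}: key {key!r} does not match 'patientid_well_replicate' "
            "(well ∈ 1..3 or 'background'; no underscores inside patient ids)"
        )
    return m.group("pid"), m.group("well"), int(m.group("rep"))


def write_wide_csv(collection: SpectraCollection, path: str | Path) -> None:
    """Write a collection as a wide CSV (wavenumber column + one column per spectrum)."""
    grid = collection.grid
    if grid is None:
        raise FormatError("cannot write an empty collection")
    columns: dict[str, np.ndarray] = {}
    for spectrum in collection:
        if "_" in spectrum.patient_id:
            raise FormatError(
                f"patient id {spectrum.patient_id!r} contains '_', which is reserved "
                "as the column-key separator"
            )
        key = spectrum.column_key
        if key in columns:
            raise FormatError(f"duplicate spectrum key {key!r}")
        columns[key] = spectrum.absorbance
    frame = pd.DataFrame({"wavenumber": grid, **columns})
    frame.to_csv(path, index=False, float_format="%.12g")


def read_wide_csv(path: str | Path) -> SpectraCollection:
    """Read a wide CSV back into a :class:`SpectraCollection`."""
    path = Path(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh), None)
    if not header or header[0] != "wavenumber":
        raise FormatError(
            f"{path.name}: first column must be 'wavenumber' "
            f"(got {header[0]!r})" if header else f"{path.name}: empty file"
        )
    seen: set[str] = set()
    for i, key in enumerate(header[1:], start=1):
        if key in seen:
            raise FormatError(f"{path.name}: duplicate column key {key!r}")
        seen.add(key)
        _parse_column_key(key, i)
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path.name}: ragged or malformed rows ({exc})") from exc
    if frame.isna().any().any():
        bad = frame.columns[frame.isna().any()][0]
        row = int(frame.index[frame[bad].isna()][0])
        raise FormatError(f"{path.name}: missing value at row {row}, column {bad!r}")
    grid = frame["wavenumber"].to_numpy(dtype=float)
    diffs = np.diff(grid)
    if diffs.size and not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise FormatError(f"{path.name}: wavenumber grid is not strictly monotone")
    flipped = bool(diffs.size and diffs[0] > 0)  # normalize to descending
    if flipped:
        frame = frame.iloc[::-1].reset_index(drop=True)
        grid = grid[::-1]
    collection = SpectraCollection()
    for i, key in enumerate(header[1:], start=1):
        pid, well, rep = _parse_column_key(key, i)
        role = BACKGROUND_ROLE if well == BACKGROUND_WELL else SAMPLE_ROLE
        collection.add(
            Spectrum(
                wavenumbers=grid,
                absorbance=frame[key].to_numpy(dtype=float),
                patient_id=pid,
                well=well,
                replicate=rep,
                role=role,
            )
        )
    return collection


# --- JCAMP-DX ---------------------------------------------------------------

_REQUIRED_LDRS = ("NPOINTS", "FIRSTX", "LASTX", "DELTAX", "YFACTOR", "XYDATA")


def write_jcampdx(
    spectrum: Spectrum, path: str | Path, yfactor: float = 1e-8
) -> None:
    """Write one spectrum as a JCAMP-DX 4.24 ``(X++(Y..Y))`` file.

    Absorbance is stored as integers scaled by ``yfactor``, so the
    round-trip error is bounded by ``yfactor / 2``.
    """
    wn, ab = spectrum.wavenumbers, spectrum.absorbance
    deltax = (wn[-1] - wn[0]) / (wn.size - 1) if wn.size > 1 else 0.0
    y_int = np.rint(ab / yfactor).astype(np.int64)
    lines = [
        f"##TITLE={spectrum.patient_id} well {spectrum.well} replicate {spectrum.replicate}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        f"##$PATIENTID={spectrum.patient_id}",
        f"##$WELL={spectrum.well}",
        f"##$REPLICATE={spectrum.replicate}",
        f"##$ROLE={spectrum.role}",
        f"##NPOINTS={wn.size}",
        f"##FIRSTX={wn[0]:.6f}",
        f"##LASTX={wn[-1]:.6f}",
        f"##DELTAX={deltax:.6f}",
        "##XFACTOR=1",
        f"##YFACTOR={yfactor:g}",
        f"##FIRSTY={ab[0]:.6g}",
        "##XYDATA=(X++(Y..Y))",
    ]
    for start in range(0, wn.size, 8):
        chunk = y_int[start : start + 8]
        lines.append(f"{wn[start]:.4f} " + " ".join(str(v) for v in chunk))
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_jcampdx(path: str | Path) -> Spectrum:
    """Read a JCAMP-DX ``(X++(Y..Y))`` file written by :func:`write_jcampdx`
    or any compliant producer of the same subset."""
    path = Path(path)
    ldrs: dict[str, str] = {}
    y_values: list[float] = []
    in_data = False
    yfactor = None
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = label.replace(" ", "").replace("-", "").upper()
            ldrs[label] = value.strip()
            if label == "XYDATA":
                in_data = True
                yfactor = float(ldrs.get("YFACTOR", "1"))
            elif label == "END":
                in_data = False
            continue
        if in_data:
            parts = line.split()
            # first token is the line's abscissa; the rest are scaled ordinates
            y_values.extend(float(tok) * yfactor for tok in parts[1:])
    missing = [l for l in _REQUIRED_LDRS if l not in ldrs]
    if missing:
        raise FormatError(f"{path.name}: missing required records: {missing}")
    npoints = int(ldrs["NPOINTS"])
    firstx, lastx = float(ldrs["FIRSTX"]), float(ldrs["LASTX"])
    deltax = float(ldrs["DELTAX"])
    if npoints > 1 and deltax * (lastx - firstx) <= 0:
        raise FormatError(
            f"{path.name}: DELTAX={deltax} inconsistent with FIRSTX={firstx}, LASTX={lastx}"
        )
    if len(y_values) != npoints:
        raise FormatError(
            f"{path.name}: NPOINTS={npoints} but {len(y_values)} ordinates found "
            "(truncated file?)"
        )
    grid = firstx + deltax * np.arange(npoints) if npoints > 1 else np.array([firstx])
    well = ldrs.get("$WELL", "1")
    return Spectrum(
        wavenumbers=grid,
        absorbance=np.asarray(y_values),
        patient_id=ldrs.get("$PATIENTID", "unknown"),
        well=well,
        replicate=int(ldrs.get("$REPLICATE", "1")),
        role=ldrs.get("$ROLE", BACKGROUND_ROLE if well == BACKGROUND_WELL else SAMPLE_ROLE),
    )


# --- manifests ---------------------------------------------------------------


def load_manifest(path: str | Path) -> CohortManifest:
    """Load a manifest CSV, validating the mandatory column set."""
    frame = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{Path(path).name}: missing mandatory columns: {missing}")
    return CohortManifest(frame[MANIFEST_COLUMNS].copy())


def save_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.frame.to_csv(path, index=False)
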