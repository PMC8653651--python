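"""Reading and writing the spectral and tabular formats the pipeline touches.

Two spectra dialects are supported:

* **wide tabular** text: first column the wavenumber in cm^-1, one column
  per sample, header row of sample ids;
* **JCAMP-DX** 4.24-compatible single-spectrum files with AFFN
  ``(X++(Y..Y))`` XYDATA, one file per sample.

A metadata table (columns ``id``, ``fraction_percent``, ``subset``)
carries the regression labels; samples without metadata come back with
``subset = "unassigned"`` and label 0.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .datatypes import SpectraSet, WavenumberAxis

__all__ = [
    "SpectraFileDialect",
    "read_spectra",
    "write_spectra",
    "read_metadata",
    "write_metadata",
    "write_report",
]


@dataclass(frozen=True)
class SpectraFileDialect:
    kind: Literal["wide_tabular", "jcamp_dx"] = "wide_tabular"
    delimiter: str = "\t"
    wavenumber_order: Literal["ascending", "descending"] = "descending"


# ---------------------------------------------------------------- metadata


def write_metadata(spectra: SpectraSet, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "id": spectra.ids,
            "fraction_percent": spectra.labels,
            "subset": spectra.subset,
        }
    ).to_csv(path, index=False)


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"id": str})
    required = {"id", "fraction_percent", "subset"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    if meta["id"].duplicated().any():
        dupes = meta.loc[meta["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dupes}")
    return meta


def _join_metadata(
    ids: np.ndarray, meta: pd.DataFrame | None
) -> tuple[np.ndarray, np.ndarray]:
    n = ids.size
    labels = np.zeros(n)
    subset = np.full(n, "unassigned", dtype=object)
    if meta is not None:
        lookup = meta.set_index("id")
        for i, sid in enumerate(ids):
            if sid in lookup.index:
                labels[i] = float(lookup.at[sid, "fraction_percent"])
                subset[i] = str(lookup.at[sid, "subset"])
    return labels, subset


# ------------------------------------------------------------ wide tabular


def _write_wide_tabular(spectra: SpectraSet, path: Path, dialect: SpectraFileDialect) -> None:
    axis = spectra.axis.values
    matrix = spectra.absorbance
    if dialect.wavenumber_order == "ascending":
        axis = axis[::-1]
        matrix = matrix[:, ::-1]
    frame = pd.DataFrame(matrix.T, columns=list(spectra.ids))
    frame.insert(0, "wavenumber", axis)
    frame.to_csv(path, sep=dialect.delimiter, index=False, float_format="%.10g")


def _read_wide_tabular(path: Path, dialect: SpectraFileDialect) -> tuple[WavenumberAxis, np.ndarray, np.ndarray]:
    try:
        frame = pd.read_csv(path, sep=dialect.delimiter)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"cannot parse spectra table {path}: {exc}") from None
    if frame.shape[1] < 2:
        raise ValueError(f"spectra table {path} needs a wavenumber column plus >=1 sample")
    with open(path) as fh:  # pandas mangles duplicate headers, so check the raw line
        raw_ids = fh.readline().rstrip("\n").split(dialect.delimiter)[1:]
    if len(set(raw_ids)) != len(raw_ids):
        raise ValueError(f"duplicate sample ids in {path}")
    ids = np.array([str(c) for c in raw_ids], dtype=object)
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.any(~np.isfinite(values)):
        raise ValueError(f"non-numeric or missing cells in {path}")
    axis = WavenumberAxis(values[:, 0])  # normalizes to descending
    matrix = values[:, 1:].T
    if frame.iloc[0, 0] < frame.iloc[-1, 0]:  # file was ascending: flip columns to match
        matrix = matrix[:, ::-1]
    return axis, matrix, ids


# ---------------------------------------------------------------- JCAMP-DX

_JCAMP_YFACTOR = 1e-8  # store absorbance as scaled integers-like AFFN with 8 decimals


def _write_jcamp(
    axis: WavenumberAxis, spectrum: np.ndarray, sample_id: str, path: Path
) -> None:
    x = axis.values
    deltax = (x[-1] - x[0]) / (x.size - 1)
    lines = [
        f"##TITLE={sample_id}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        "##XFACTOR=1.0",
        f"##YFACTOR={_JCAMP_YFACTOR:g}",
        f"##FIRSTX={x[0]:.6f}",
        f"##LASTX={x[-1]:.6f}",
        f"##DELTAX={deltax:.10f}",
        f"##NPOINTS={x.size}",
        f"##FIRSTY={spectrum[0]:.8f}",
        "##XYDATA=(X++(Y..Y))",
    ]
    yint = np.round(spectrum / _JCAMP_YFACTOR).astype(np.int64)
    per_line = 6
    for start in range(0, x.size, per_line):
        chunk = yint[start : start + per_line]
        lines.append(f"{x[start]:.4f} " + " ".join(str(v) for v in chunk))
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


def _read_jcamp(path: Path) -> tuple[str, np.ndarray, np.ndarray]:
    header: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            header[key] = value.strip()
            continue
        if in_data:
            fields = line.replace(",", " ").split()
            try:
                ys.extend(float(f) for f in fields[1:])  # first field is the X check value
            except ValueError:
                raise ValueError(f"non-numeric XYDATA in {path}: {line!r}") from None
    for req in ("FIRSTX", "DELTAX", "NPOINTS"):
        if req not in header:
            raise ValueError(f"JCAMP file {path} missing ##{req}=")
    npoints = int(header["NPOINTS"])
    if len(ys) != npoints:
        raise ValueError(f"{path}: NPOINTS={npoints} but {len(ys)} Y values found")
    firstx = float(header["FIRSTX"])
    deltax = float(header["DELTAX"])
    yfactor = float(header.get("YFACTOR", "1"))
    xfactor = float(header.get("XFACTOR", "1"))
    x = (firstx + deltax * np.arange(npoints)) * xfactor
    y = np.asarray(ys) * yfactor
    title = header.get("TITLE", path.stem)
    return title, x, y


def _read_jcamp_dir(directory: Path) -> tuple[WavenumberAxis, np.ndarray, np.ndarray]:
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".jdx", ".dx", ".jcm")
    )
    if not files:
        raise ValueError(f"no JCAMP-DX files (*.jdx, *.dx) found in {directory}")
    ids, rows = [], []
    ref_x: np.ndarray | None = None
    for f in files:
        title, x, y = _read_jcamp(f)
        if ref_x is None:
            ref_x = x
        elif x.shape != ref_x.shape or not np.allclose(x, ref_x, atol=1e-6):
            raise ValueError(f"axis mismatch: {f} does not share the axis of {files[0]}")
        ids.append(title)
        rows.append(y)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample ids (titles) among JCAMP files in {directory}")
    axis = WavenumberAxis(ref_x)
    matrix = np.vstack(rows)
    if ref_x[0] < ref_x[-1]:
        matrix = matrix[:, ::-1]
    return axis, matrix, np.array(ids, dtype=object)


# ------------------------------------------------------------- public API


def write_spectra(
    spectra: SpectraSet,
    path: str | os.PathLike,
    dialect: SpectraFileDialect = SpectraFileDialect(),
    metadata: bool = True,
) -> None:
    """Write a SpectraSet in the requested dialect.

    ``wide_tabular`` writes a single table at ``path``; ``jcamp_dx``
    treats ``path`` as a directory and writes one file per sample.  A
    metadata sidecar ``<path>.meta.csv`` (tabular) or
    ``<dir>/metadata.csv`` (JCAMP) carries labels and subset tags.
    """
    path = Path(path)
    if dialect.kind == "wide_tabular":
        _write_wide_tabular(spectra, path, dialect)
        if metadata:
            write_metadata(spectra, path.with_suffix(path.suffix + ".meta.csv"))
    elif dialect.kind == "jcamp_dx":
        path.mkdir(parents=True, exist_ok=True)
        for i in range(spectra.n_samples):
            _write_jcamp(spectra.axis, spectra.absorbance[i], str(spectra.ids[i]),
                         path / f"{spectra.ids[i]}.jdx")
        if metadata:
            write_metadata(spectra, path / "metadata.csv")
    else:
        raise ValueError(f"unknown dialect kind {dialect.kind!r}")


def read_spectra(
    path: str | os.PathLike,
    dialect: SpectraFileDialect = SpectraFileDialect(),
    metadata_path: str | os.PathLike | None = None,
) -> SpectraSet:
    """Read spectra (file or directory per dialect) into a SpectraSet.

    The returned axis is always descending.  Metadata is joined by exact
    sample id; samples missing from the metadata table get
    ``subset = "unassigned"``.
    """
    path = Path(path)
    if dialect.kind == "wide_tabular":
        axis, matrix, ids = _read_wide_tabular(path, dialect)
        default_meta = path.with_suffix(path.suffix + ".meta.csv")
    elif dialect.kind == "jcamp_dx":
        axis, matrix, ids = _read_jcamp_dir(path)
        default_meta = path / "metadata.csv"
    else:
        raise ValueError(f"unknown dialect kind {dialect.kind!r}")
    meta = None
    meta_path = Path(metadata_path) if metadata_path is not None else default_meta
    if meta_path.exists():
        meta = read_metadata(meta_path)
    labels, subset = _join_metadata(ids, meta)
    return SpectraSet(axis=axis, absorbance=matrix, labels=labels, subset=subset, ids=ids)


# ---------------------------------------------------------------- reports


def write_report(report, directory: str | os.PathLike) -> dict[str, Path]:
    """Serialize a study report to tabular text files in ``directory``.

    Emits the pretreatment-screening table, the selection-comparison
    table, predicted-vs-actual pairs for both sample sets, and a
    provenance block.  An entirely empty report is an error.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    pre = getattr(report, "preprocessing_table", None)
    sel = getattr(report, "selection_table", None)
    ev = getattr(report, "evaluation", None)
    if (pre is None or len(pre) == 0) and (sel is None or len(sel) == 0) and ev is None:
        raise ValueError("refusing to write an empty report")

    if pre is not None and len(pre):
        p = directory / "preprocessing_screen.csv"
        pd.DataFrame(pre).to_csv(p, index=False)
        written["preprocessing"] = p
    if sel is not None and len(sel):
        p = directory / "selection_comparison.csv"
        pd.DataFrame(sel).to_csv(p, index=False)
        written["selection"] = p
    if ev is not None:
        for tag in ("calibration", "test"):
            pairs = getattr(ev, f"pairs_{tag}", None)
            if pairs is not None:
                p = directory / f"predicted_vs_actual_{tag}.csv"
                pd.DataFrame(
                    {"actual_percent": pairs[0], "predicted_percent": pairs[1]}
                ).to_csv(p, index=False)
                written[f"pairs_{tag}"] = p
        p = directory / "evaluation.json"
        p.write_text(
            json.dumps(
                {
                    "rmsec_percent": ev.rmsec,
                    "rmsep_percent": ev.rmsep,
                    "r2_calibration": ev.r2_cal,
                    "r2_test": ev.r2_test,
                },
                indent=2,
            )
            + "\n"
        )
        written["evaluation"] = p
    prov = getattr(report, "provenance", None)
    if prov:
        p = directory / "provenance.json"
        p.write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")
        written["provenance"] = p
    return written
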