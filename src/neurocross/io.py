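"""Cohort and result I/O: NIfTI volumes, TSV tables, JSON run metadata.

Layout of a cohort directory::

    group_table.tsv            subject_id, group, timepoint + file references
    atlas_<NAME>.nii           one binary mask per network
    atlas.tsv                  ordered network names
    ts_<subject>.tsv           node time series, one column per node
    truth_<subject>.tsv        retained ground-truth courses (synthetic only)
    fmri_<subject>.nii         optional 4D volumes
    cbf_<subject>.nii          optional CBF maps

Tables are UTF-8 TSV with a single leading comment line carrying column
units. Every run writes a JSON metadata sidecar (settings, seeds, package
version) sufficient to reproduce its outputs.
"""

from __future__ import annotations

import json
import os
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import NodeTimeSeries, RSNAtlas, SubjectRecord
from .errors import LoaderError

__all__ = [
    "save_cohort",
    "load_cohort",
    "load_atlas",
    "write_table",
    "read_table",
    "write_metadata",
]


def _pkg_version() -> str:
    try:
        return version("neurocross")
    except PackageNotFoundError:
        return "unknown"


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def write_table(path: Path | str, df: pd.DataFrame, units: str | None = None) -> None:
    """Write a TSV with an optional leading ``#`` comment line of units."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w", encoding="utf-8", newline="") as fh:
        if units:
            fh.write(f"# {units}\n")
        df.to_csv(fh, sep="\t", index=False)
    os.replace(tmp, path)


def read_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_metadata(path: Path | str, config: dict) -> None:
    payload = {"package_version": _pkg_version(), **config}

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=default) + "\n",
        encoding="utf-8",
    )


def save_atlas(out_dir: Path | str, atlas: RSNAtlas) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(atlas.voxel_size_mm)
    for j, name in enumerate(atlas.names):
        img = nib.Nifti1Image(atlas.masks[j].astype(np.uint8), aff)
        nib.save(img, out_dir / f"atlas_{name}.nii")
    write_table(
        out_dir / "atlas.tsv",
        pd.DataFrame({"rsn": list(atlas.names)}),
        units="rsn: network label (mask in atlas_<rsn>.nii)",
    )


def load_atlas(path: Path | str) -> RSNAtlas:
    path = Path(path)
    tsv = path / "atlas.tsv"
    if not tsv.exists():
        raise LoaderError(f"missing atlas manifest {tsv}")
    names = tuple(read_table(tsv)["rsn"].astype(str))
    masks, vox = [], (1.0, 1.0, 1.0)
    for name in names:
        f = path / f"atlas_{name}.nii"
        if not f.exists():
            raise LoaderError(f"atlas mask file missing: {f}")
        img = nib.load(f)
        masks.append(np.asanyarray(img.dataobj).astype(bool))
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    return RSNAtlas(names=names, masks=np.stack(masks), voxel_size_mm=vox)


def save_cohort(
    out_dir: Path | str, cohort: list[SubjectRecord], atlas: RSNAtlas | None = None
) -> None:
    """Write a cohort directory (see module docstring for the layout)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if atlas is not None:
        save_atlas(out_dir, atlas)
    aff = _affine(atlas.voxel_size_mm) if atlas is not None else np.eye(4)
    rows = []
    for rec in cohort:
        row = {"subject_id": rec.subject_id, "group": rec.group, "timepoint": rec.timepoint}
        if rec.node_ts is not None:
            f = f"ts_{rec.subject_id}.tsv"
            df = pd.DataFrame(rec.node_ts.data, columns=list(rec.node_ts.node_names))
            write_table(out_dir / f, df, units="node time courses, arbitrary units")
            row["ts_file"] = f
        if rec.truth_ts is not None and rec.node_ts is not None:
            f = f"truth_{rec.subject_id}.tsv"
            df = pd.DataFrame(rec.truth_ts, columns=list(rec.node_ts.node_names))
            write_table(out_dir / f, df, units="ground-truth node courses (pre-noise)")
        if rec.fmri is not None:
            f = f"fmri_{rec.subject_id}.nii"
            nib.save(nib.Nifti1Image(np.asarray(rec.fmri, dtype=np.float32), aff), out_dir / f)
            row["fmri_file"] = f
        if rec.cbf is not None:
            f = f"cbf_{rec.subject_id}.nii"
            nib.save(nib.Nifti1Image(np.asarray(rec.cbf, dtype=np.float32), aff), out_dir / f)
            row["cbf_file"] = f
        rows.append(row)
    write_table(
        out_dir / "group_table.tsv",
        pd.DataFrame(rows),
        units="subject_id: label; group: label; timepoint: label; *_file: relative path",
    )


def load_cohort(path: Path | str) -> tuple[list[SubjectRecord], RSNAtlas | None]:
    """Read a cohort directory back; hard failure on any inconsistency."""
    path = Path(path)
    table = path / "group_table.tsv"
    if not table.exists():
        raise LoaderError(f"missing group table {table}")
    try:
        df = read_table(table)
    except Exception as exc:  # malformed TSV
        raise LoaderError(f"malformed group table {table}: {exc}") from exc
    for col in ("subject_id", "group", "timepoint"):
        if col not in df.columns:
            raise LoaderError(f"group table {table} lacks column {col!r}")
    atlas = load_atlas(path) if (path / "atlas.tsv").exists() else None

    cohort: list[SubjectRecord] = []
    grid = atlas.grid_shape if atlas is not None else None
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        node_ts = fmri = cbf = truth = None
        ts_file = row.get("ts_file")
        if isinstance(ts_file, str) and ts_file:
            f = path / ts_file
            if not f.exists():
                raise LoaderError(f"time-series file missing for {sid!r}: {f}")
            tdf = read_table(f)
            node_ts = NodeTimeSeries(sid, tdf.to_numpy(float), tuple(tdf.columns))
            tf = path / f"truth_{sid}.tsv"
            if tf.exists():
                truth = read_table(tf).to_numpy(float)
        for key, attr in (("fmri_file", "fmri"), ("cbf_file", "cbf")):
            fname = row.get(key)
            if isinstance(fname, str) and fname:
                f = path / fname
                if not f.exists():
                    raise LoaderError(f"{attr} file missing for {sid!r}: {f}")
                arr = np.asanyarray(nib.load(f).dataobj)
                if grid is not None and arr.shape[:3] != grid:
                    raise LoaderError(
                        f"{f} grid {arr.shape[:3]} does not match atlas grid {grid}"
                    )
                if attr == "fmri":
                    fmri = arr
                else:
                    cbf = arr
        if node_ts is None and fmri is None:
            raise LoaderError(f"subject {sid!r} has neither time series nor 4D data")
        cohort.append(
            SubjectRecord(
                subject_id=sid,
                group=str(row["group"]),
                timepoint=str(row["timepoint"]),
                fmri=fmri,
                node_ts=node_ts,
                cbf=cbf,
                truth_ts=truth,
            )
        )
    return cohort, atlas
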