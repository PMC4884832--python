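"""File I/O: NIfTI volumes, sensor CSVs, meshes and dipole tables.

NIfTI round-trips preserve data, spacing and origin bit-exactly for integer
label volumes; sensor CSVs carry ``label,x,y,z`` in mm.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import LabelVolume, SensorCloud, Volume


def write_volume(vol: Volume, path: str | os.PathLike) -> None:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vol.spacing
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asanyarray(vol.data), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, os.fspath(path))


def read_volume(path: str | os.PathLike, as_labels: bool = False) -> Volume:
    try:
        img = nib.load(os.fspath(path))
        data = np.asanyarray(img.dataobj)
        affine = img.affine
    except Exception as exc:  # malformed header / not a NIfTI
        raise IOError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    spacing = tuple(float(abs(affine[i, i])) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    cls = LabelVolume if as_labels else Volume
    return cls(data, spacing, origin)


def write_sensors(cloud: SensorCloud, path: str | os.PathLike) -> None:
    rows = [
        {"label": lb, "x": p[0], "y": p[1], "z": p[2]}
        for lb, p in zip(cloud.labels, cloud.points)
    ]
    for name, p in cloud.fiducials.items():
        rows.append({"label": f"FID:{name}", "x": p[0], "y": p[1], "z": p[2]})
    pd.DataFrame(rows).to_csv(os.fspath(path), index=False,
                              float_format="%.12g")


def read_sensors(path: str | os.PathLike) -> SensorCloud:
    try:
        df = pd.read_csv(os.fspath(path))
    except Exception as exc:
        raise IOError(f"cannot parse sensor file {path!r}: {exc}") from exc
    required = {"label", "x", "y", "z"}
    if df.empty or not required.issubset(df.columns):
        raise IOError(
            f"sensor file {path!r} must have non-empty columns label,x,y,z"
        )
    fid_rows = df["label"].astype(str).str.startswith("FID:")
    fiducials = {
        str(r["label"])[4:]: np.array([r["x"], r["y"], r["z"]], float)
        for _, r in df[fid_rows].iterrows()
    }
    body = df[~fid_rows]
    return SensorCloud(
        [str(v) for v in body["label"]],
        body[["x", "y", "z"]].to_numpy(float),
        fiducials,
    )


def write_mesh(mesh, path: str | os.PathLike) -> None:
    """Write a trimesh.Trimesh as OBJ (or any format trimesh infers)."""
    mesh.export(os.fspath(path))


def read_mesh(path: str | os.PathLike):
    import trimesh

    return trimesh.load_mesh(os.fspath(path))


def write_dipoles(dipoles, path: str | os.PathLike) -> None:
    """Dipole table CSV: patch_id, position, orientation, area, triple flag."""
    rows = []
    for d in dipoles:
        rows.append({
            "patch_id": d.patch_id,
            "x": d.position[0], "y": d.position[1], "z": d.position[2],
            "nx": d.orientation[0] if d.orientation is not None else np.nan,
            "ny": d.orientation[1] if d.orientation is not None else np.nan,
            "nz": d.orientation[2] if d.orientation is not None else np.nan,
            "area": d.area, "triple": int(d.triple),
        })
    pd.DataFrame(rows).to_csv(os.fspath(path), index=False,
                              float_format="%.12g")
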