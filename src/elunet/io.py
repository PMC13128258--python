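"""HDF5 container and NIfTI export for phantoms and inversion results.

Layout of the dataset container::

    /spacing                 (3,) voxel size
    /loadings/<i>/strain     (6, nx, ny, nz) tensor strain components
    /loadings/<i>/strain_noisy   optional
    /loadings/<i>/bc/<face>  group with attrs kind, normal_traction
    /orientation             (3, nx, ny, nz) Euler angles, optional
    /labels                  (nx, ny, nz) int region labels, optional
    /truth/<name>            ground-truth parameter volumes, optional
    attrs: provenance (JSON string)

Results re-use the same spacing/labels conventions under ``/result``.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .fields import BoundaryTractions, FACES, FaceCondition, orientation_field, strain_field
from .phantom import PhantomDataset

__all__ = ["save_datasets", "load_datasets", "save_result", "load_result",
           "export_nifti"]


def _write_bc(group: h5py.Group, bc: BoundaryTractions) -> None:
    for fname in FACES:
        g = group.create_group(fname)
        fc = bc.faces[fname]
        g.attrs["kind"] = fc.kind
        g.attrs["normal_traction"] = fc.normal_traction


def _read_bc(group: h5py.Group) -> BoundaryTractions:
    faces = {}
    for fname in FACES:
        g = group[fname]
        faces[fname] = FaceCondition(str(g.attrs["kind"]),
                                     float(g.attrs["normal_traction"]))
    return BoundaryTractions(faces)


def save_datasets(path, datasets: list[PhantomDataset]) -> None:
    """Write one or more loadings sharing truth/labels/orientation."""
    first = datasets[0]
    with h5py.File(path, "w") as f:
        f["spacing"] = np.asarray(first.spacing)
        for i, ds in enumerate(datasets):
            g = f.create_group(f"loadings/{i}")
            g.create_dataset("strain", data=ds.strain.values)
            if ds.strain_noisy is not None:
                g.create_dataset("strain_noisy", data=ds.strain_noisy.values)
            _write_bc(g.create_group("bc"), ds.bc)
        if first.orientation is not None:
            f["orientation"] = first.orientation.values
        if first.labels is not None:
            f["labels"] = first.labels
        for k, v in first.truth.items():
            f[f"truth/{k}"] = v
        f.attrs["provenance"] = json.dumps(
            [ds.provenance for ds in datasets], default=str)


def load_datasets(path) -> list[PhantomDataset]:
    with h5py.File(path, "r") as f:
        spacing = tuple(float(v) for v in f["spacing"][()])
        orientation = None
        if "orientation" in f:
            orientation = orientation_field(f["orientation"][()], spacing)
        labels = f["labels"][()] if "labels" in f else None
        truth = {k: f[f"truth/{k}"][()] for k in f.get("truth", {})}
        prov = json.loads(f.attrs.get("provenance", "[]"))
        out = []
        keys = sorted(f["loadings"], key=int)
        for i in keys:
            g = f[f"loadings/{i}"]
            noisy = None
            if "strain_noisy" in g:
                noisy = strain_field(g["strain_noisy"][()], spacing)
            out.append(PhantomDataset(
                strain=strain_field(g["strain"][()], spacing),
                bc=_read_bc(g["bc"]),
                truth=truth, labels=labels, orientation=orientation,
                strain_noisy=noisy,
                provenance=prov[int(i)] if int(i) < len(prov) else {},
            ))
    return out


def save_result(path, result) -> None:
    """Persist an :class:`~elunet.inversion.InversionResult`."""
    with h5py.File(path, "w") as f:
        for k, v in result.params.items():
            f[f"result/params/{k}"] = v
        for i, s in enumerate(result.stresses):
            f[f"result/stress/{i}"] = s
        for k, v in result.dimensionless.items():
            f[f"result/dimensionless/{k}"] = v
        f.attrs["sigma_star"] = result.scales.sigma_star
        f.attrs["eps_star"] = result.scales.eps_star
        f.attrs["config"] = json.dumps(
            {k: getattr(result.config, k) for k in
             ("mode", "epochs", "learning_rate", "widths", "seed")})
        f.attrs["config_hash"] = result.config.digest()
        hist = result.history
        if hist:
            cols = list(hist[0])
            f["history/columns"] = np.array(cols, dtype="S")
            f["history/values"] = np.array(
                [[row.get(c, np.nan) for c in cols] for row in hist])


def load_result(path) -> dict:
    """Load a saved result as plain dictionaries."""
    with h5py.File(path, "r") as f:
        out = {
            "params": {k: f[f"result/params/{k}"][()]
                       for k in f["result/params"]},
            "stresses": [f[f"result/stress/{i}"][()]
                         for i in sorted(f["result/stress"], key=int)],
            "dimensionless": {k: f[f"result/dimensionless/{k}"][()]
                              for k in f.get("result/dimensionless", {})},
            "scales": {"sigma_star": float(f.attrs["sigma_star"]),
                       "eps_star": float(f.attrs["eps_star"])},
            "config": json.loads(f.attrs["config"]),
        }
        if "history" in f:
            cols = [c.decode() for c in f["history/columns"][()]]
            vals = f["history/values"][()]
            out["history"] = [dict(zip(cols, row)) for row in vals]
    return out


def export_nifti(path, field_values: np.ndarray, spacing) -> None:
    """Write a (C, nx, ny, nz) field as a 4-D NIfTI volume with the
    voxel size in the affine (channels last, for viewer compatibility)."""
    import nibabel as nib

    vals = np.moveaxis(np.asarray(field_values), 0, -1)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(vals, affine), str(path))
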