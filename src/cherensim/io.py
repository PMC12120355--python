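"""File I/O: NIfTI voxel grids, HDF5 run results, CSV maps/spectra, PLY meshes.

A voxel grid is stored as two companion NIfTI volumes with identical
headers: ``<prefix>_labels.nii`` (integer tissue labels) and
``<prefix>_density.nii`` (float mass density).  The affine encodes voxel
spacing on its diagonal and the grid origin in its translation column, so a
round trip reproduces labels, densities, spacing and origin exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

import cherensim
from cherensim.optics import ExitRecords
from cherensim.phantom import SurfaceMesh, VoxelGrid


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing
    aff[:3, 3] = grid.origin
    return aff


def _geometry_extension(grid: VoxelGrid) -> nib.nifti1.Nifti1Extension:
    # the NIfTI header holds the affine in float32; carry the exact float64
    # geometry in a comment extension so round trips are bit exact
    payload = json.dumps({"spacing": list(grid.spacing), "origin": list(grid.origin)})
    return nib.nifti1.Nifti1Extension("comment", payload.encode())


def _read_geometry(img) -> tuple[tuple, tuple] | None:
    for ext in img.header.extensions:
        try:
            doc = json.loads(bytes(ext.get_content()).decode())
            return tuple(doc["spacing"]), tuple(doc["origin"])
        except (ValueError, KeyError, TypeError):
            continue
    return None


def save_voxel_grid(grid: VoxelGrid, prefix) -> tuple[Path, Path]:
    prefix = Path(prefix)
    labels_path = prefix.with_name(prefix.name + "_labels.nii")
    density_path = prefix.with_name(prefix.name + "_density.nii")
    aff = _affine(grid)
    for data, path in ((grid.tissue.astype(np.int16), labels_path),
                       (grid.density.astype(np.float64), density_path)):
        img = nib.Nifti1Image(data, aff)
        img.header.extensions.append(_geometry_extension(grid))
        nib.save(img, path)
    return labels_path, density_path


def load_voxel_grid(prefix) -> VoxelGrid:
    prefix = Path(prefix)
    labels_img = nib.load(prefix.with_name(prefix.name + "_labels.nii"))
    density_img = nib.load(prefix.with_name(prefix.name + "_density.nii"))
    geom = _read_geometry(labels_img)
    if geom is not None:
        spacing, origin = geom
    else:
        aff = labels_img.affine
        spacing = tuple(float(aff[i, i]) for i in range(3))
        origin = tuple(float(aff[i, 3]) for i in range(3))
    return VoxelGrid(
        tissue=np.asarray(labels_img.dataobj).astype(np.uint8),
        density=np.asarray(density_img.dataobj, dtype=np.float64),
        spacing=spacing,
        origin=origin,
    )


def save_exit_records(group: h5py.Group, exits: ExitRecords) -> None:
    group.create_dataset("element_id", data=exits.element_id)
    group.create_dataset("exit_position", data=exits.exit_position)
    group.create_dataset("exit_direction", data=exits.exit_direction)
    group.create_dataset("wavelength", data=exits.wavelength)
    group.create_dataset("birth_position", data=exits.birth_position)
    group.create_dataset("born_in_tumor", data=exits.born_in_tumor.astype(np.uint8))


def load_exit_records(group: h5py.Group) -> ExitRecords:
    return ExitRecords(
        element_id=group["element_id"][:],
        exit_position=group["exit_position"][:],
        exit_direction=group["exit_direction"][:],
        wavelength=group["wavelength"][:],
        birth_position=group["birth_position"][:],
        born_in_tumor=group["born_in_tumor"][:].astype(bool),
    )


def save_simulation_result(result, path, metadata: dict | None = None) -> None:
    """Persist a :class:`~cherensim.pipeline.SimulationResult` to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = cherensim.__version__
        f.attrs["seed"] = result.seed
        f.attrs["emission_fraction"] = result.emission_fraction
        f.attrs["modality"] = result.plan.modality
        for k, v in (metadata or {}).items():
            f.attrs[k] = v
        for i, b in enumerate(result.beams):
            g = f.create_group(f"beam_{i}")
            g.attrs["n_source_photons"] = b.n_source_photons
            g.attrs["mu_total"] = b.mu_total
            g.create_dataset("dose_energy_mev", data=b.transport.dose.energy_mev,
                             compression="gzip")
            g.create_dataset("emission_counts", data=b.transport.emission.counts,
                             compression="gzip")
            g.attrs["escaped_energy_mev"] = b.transport.escaped_energy_mev
            g.attrs["n_cherenkov_generated"] = b.transport.n_generated
            g.attrs["n_cherenkov_banked"] = b.transport.n_banked
            if "wavelength" in b.transport.photon_bank:
                g.create_dataset("emitted_wavelength_nm",
                                 data=b.transport.photon_bank["wavelength"].astype(np.float32),
                                 compression="gzip")
            if b.optics is not None:
                save_exit_records(g.create_group("exits"), b.optics.exits)
                g.create_dataset("photon_status", data=b.optics.status)


def load_run_arrays(path) -> dict:
    """Load a persisted simulation run: per-beam dose/emission arrays and exits.

    Returns a dict with keys ``beams`` (list of per-beam dicts with
    ``dose_energy_mev``, ``emission_counts``, ``exits``, ``mu_total``,
    ``n_source_photons``) and the file attributes under ``meta``.
    """
    out = {"beams": [], "meta": {}}
    with h5py.File(path) as f:
        out["meta"] = dict(f.attrs)
        i = 0
        while f"beam_{i}" in f:
            g = f[f"beam_{i}"]
            out["beams"].append(
                {
                    "dose_energy_mev": g["dose_energy_mev"][:],
                    "emission_counts": g["emission_counts"][:],
                    "mu_total": float(g.attrs["mu_total"]),
                    "n_source_photons": int(g.attrs["n_source_photons"]),
                    "exits": load_exit_records(g["exits"]) if "exits" in g else None,
                    "emitted_wavelength_nm": (g["emitted_wavelength_nm"][:]
                                              if "emitted_wavelength_nm" in g else None),
                }
            )
            i += 1
    return out


def concatenate_exits(banks: list[ExitRecords]) -> ExitRecords:
    banks = [b for b in banks if b is not None]
    return ExitRecords(
        element_id=np.concatenate([b.element_id for b in banks]),
        exit_position=np.concatenate([b.exit_position for b in banks]),
        exit_direction=np.concatenate([b.exit_direction for b in banks]),
        wavelength=np.concatenate([b.wavelength for b in banks]),
        birth_position=np.concatenate([b.birth_position for b in banks]),
        born_in_tumor=np.concatenate([b.born_in_tumor for b in banks]),
    )


def export_surface_map_csv(surface_map, path) -> None:
    import pandas as pd

    mesh = surface_map.mesh
    pd.DataFrame(
        {
            "element_id": np.arange(len(mesh)),
            "x_mm": mesh.centers[:, 0],
            "y_mm": mesh.centers[:, 1],
            "z_mm": mesh.centers[:, 2],
            "area_mm2": mesh.areas,
            "photons_per_mm2": surface_map.values,
        }
    ).to_csv(path, index=False)


def export_spectrum_csv(spectrum, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "lambda_nm": spectrum.bin_centers_nm,
            "intensity": spectrum.intensity,
        }
    ).to_csv(path, index=False)


def export_mesh_ply(mesh: SurfaceMesh, path) -> None:
    """Exposed-face mesh as PLY (visualization)."""
    mesh.to_trimesh().export(str(path))


def export_smoothed_mesh_ply(grid: VoxelGrid, path, level: float = 0.5) -> None:
    """Marching-cubes surface of the body for visualization only."""
    import trimesh
    from skimage import measure

    from cherensim.phantom import Tissue

    body = (grid.tissue != Tissue.AIR).astype(float)
    verts, faces, _, _ = measure.marching_cubes(body, level=level, spacing=grid.spacing)
    verts += np.asarray(grid.origin) - 0.5 * np.asarray(grid.spacing)
    trimesh.Trimesh(vertices=verts, faces=faces, process=False).export(str(path))
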