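"""File formats: NIfTI volumes, protocol/component TSV, solution containers.

Volumes travel as NIfTI-1 with a diagonal affine set by the voxel size;
parameter maps get one file per parameter plus a JSON sidecar recording the
evaluation frequencies, bin thresholds, and configuration hash.  Per-voxel
inversion ensembles are stored in a single compressed array container with
an index sidecar describing the layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .inversion import VoxelInversionResult
from .model import VoxelDistribution, PARAM_NAMES

__all__ = [
    "save_nifti", "load_nifti",
    "save_maps", "load_maps",
    "save_solutions", "load_solutions",
    "save_components_tsv", "load_components_tsv",
    "write_json", "read_json",
]


def save_nifti(volume: np.ndarray, path: str | Path,
               voxel_size_mm: float = 2.0,
               affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_maps(maps: dict[str, np.ndarray], out_dir: str | Path,
              voxel_size_mm: float = 2.0, sidecar: dict | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, vol in maps.items():
        save_nifti(vol, out / f"{name}.nii.gz", voxel_size_mm)
    if sidecar is not None:
        write_json(sidecar, out / "maps.json")


def load_maps(out_dir: str | Path) -> dict[str, np.ndarray]:
    out = Path(out_dir)
    maps = {}
    for f in sorted(out.glob("*.nii.gz")):
        maps[f.name.replace(".nii.gz", "")] = load_nifti(f)[0]
    return maps


def save_solutions(results: dict[int, VoxelInversionResult],
                   path: str | Path) -> None:
    """Store per-voxel bootstrap ensembles as one .npz + JSON index sidecar.

    Layout: ``params`` (total_components, 9), ``weights``
    (total_components,), ``voxel`` / ``bootstrap`` component ownership
    vectors, ``residuals`` flattened per (voxel, bootstrap).
    """
    path = Path(path)
    params, weights, voxel, boot, res_rows = [], [], [], [], []
    for vi in sorted(results):
        r = results[vi]
        for b, sol in enumerate(r.solutions):
            params.append(sol.params)
            weights.append(sol.weights)
            voxel.append(np.full(sol.n_components, vi))
            boot.append(np.full(sol.n_components, b))
        res_rows.append(np.column_stack(
            [np.full(r.n_bootstrap, vi), np.arange(r.n_bootstrap), r.residuals]))
    np.savez_compressed(
        path,
        params=np.vstack(params), weights=np.concatenate(weights),
        voxel=np.concatenate(voxel).astype(np.int64),
        bootstrap=np.concatenate(boot).astype(np.int64),
        residuals=np.vstack(res_rows))
    write_json({
        "format": "mdmri-solutions-v1",
        "param_names": list(PARAM_NAMES),
        "n_voxels": len(results),
        "arrays": ["params", "weights", "voxel", "bootstrap", "residuals"],
    }, path.with_suffix(".json"))


def load_solutions(path: str | Path) -> dict[int, VoxelInversionResult]:
    data = np.load(Path(path))
    params, weights = data["params"], data["weights"]
    voxel, boot = data["voxel"], data["bootstrap"]
    res = data["residuals"]
    out: dict[int, VoxelInversionResult] = {}
    for vi in np.unique(voxel):
        sols = []
        sel_v = voxel == vi
        n_boot = int(boot[sel_v].max()) + 1
        for b in range(n_boot):
            sel = sel_v & (boot == b)
            sols.append(VoxelDistribution(params[sel], weights[sel]))
        rres = res[res[:, 0] == vi]
        out[int(vi)] = VoxelInversionResult(
            sols, rres[np.argsort(rres[:, 1]), 2])
    return out


def save_components_tsv(v: VoxelDistribution, path: str | Path) -> None:
    df = pd.DataFrame(v.params, columns=list(PARAM_NAMES))
    df["weight"] = v.weights
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_components_tsv(path: str | Path) -> VoxelDistribution:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in (*PARAM_NAMES, "weight") if c not in df.columns]
    if missing:
        raise ValueError(f"component table {path} is missing columns {missing}")
    return VoxelDistribution(df[list(PARAM_NAMES)].to_numpy(),
                             df["weight"].to_numpy())


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
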