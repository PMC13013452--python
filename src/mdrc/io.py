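"""Readers and writers: NIfTI volumes, acquisition TSVs, ensemble
containers, parameter maps, and run configuration."""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version as _pkg_version

import nibabel as nib
import numpy as np
import yaml

from .acquisition import Protocol
from .inversion import VoxelEnsemble

try:
    __version__ = _pkg_version("mdrc")
except PackageNotFoundError:   # editable checkout without metadata
    __version__ = "0.0.0"


def read_dataset(nifti_path, tsv_path):
    """Load a 4D image and its acquisition table.

    Returns (volume (nx, ny, nz, n_rows), Protocol, affine).  The number of
    volumes must match the number of acquisition rows.
    """
    img = nib.load(str(nifti_path))
    vol = np.asarray(img.get_fdata(), dtype=float)
    if vol.ndim == 3:
        vol = vol[..., None]
    if vol.ndim != 4:
        raise ValueError(f"expected a 4D image, got shape {vol.shape}")
    protocol = Protocol.from_tsv(tsv_path)
    if vol.shape[3] != len(protocol):
        raise ValueError(
            f"volume count {vol.shape[3]} != acquisition rows "
            f"{len(protocol)}")
    return vol, protocol, img.affine


def write_dataset(volume, protocol, nifti_path, tsv_path, affine=None):
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine),
             str(nifti_path))
    protocol.to_tsv(tsv_path)


def write_maps(maps: dict, outdir, affine=None, omega_hz: float | None = None,
               prefix: str = "map", extra_meta: dict | None = None) -> dict:
    """Write one NIfTI per map plus a JSON index.

    ``maps`` maps a name (str or tuple joined by '_') to a 3D array; missing
    values are stored as NaN.  Returns the index dict.
    """
    import os
    os.makedirs(outdir, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    index = {"files": {}, "omega_hz": omega_hz, "version": __version__}
    if extra_meta:
        index.update(extra_meta)
    for key, arr in maps.items():
        name = "_".join(str(k) for k in key) if isinstance(key, tuple) \
            else str(key)
        fname = f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine),
                 os.path.join(outdir, fname))
        index["files"][name] = fname
    with open(os.path.join(outdir, f"{prefix}_index.json"), "w") as fh:
        json.dump(index, fh, indent=2)
    return index


# ------------------------------------------------------------- ensembles


def save_ensembles(path, ensembles: dict, meta: dict | None = None) -> None:
    """Serialize ``{(i, j, k): VoxelEnsemble}`` to one NPZ container.

    Per voxel the pooled parameter matrix, weights and bootstrap indices are
    stored; a ``meta`` dict (config, seed, ...) goes into a JSON sidecar
    next to the file.
    """
    arrays = {}
    indices = []
    for ix, ens in ensembles.items():
        params, weights, sol_idx = ens.pooled()
        tag = "v{}_{}_{}".format(*ix)
        arrays[f"{tag}_params"] = params
        arrays[f"{tag}_weights"] = weights
        arrays[f"{tag}_solidx"] = sol_idx
        arrays[f"{tag}_meta"] = np.array([ens.S0, len(ens.solutions)])
        indices.append(ix)
    arrays["indices"] = np.array(indices, dtype=int)
    np.savez_compressed(str(path), **arrays)
    sidecar = dict(meta or {})
    sidecar["version"] = __version__
    sidecar["n_voxels"] = len(indices)
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)


def load_ensembles(path) -> dict:
    data = np.load(str(path))
    out = {}
    for ix in data["indices"]:
        ix = tuple(int(v) for v in ix)
        tag = "v{}_{}_{}".format(*ix)
        params = data[f"{tag}_params"]
        weights = data[f"{tag}_weights"]
        sol_idx = data[f"{tag}_solidx"].astype(int)
        s0, n_sol = data[f"{tag}_meta"]
        solutions = []
        for s in range(int(n_sol)):
            sel = sol_idx == s
            solutions.append((params[sel], weights[sel]))
        out[ix] = VoxelEnsemble(solutions=solutions, S0=float(s0),
                                voxel_index=ix)
    return out


# ------------------------------------------------------------- config

_CONFIG_KEYS = {"seed", "output_dir", "verbosity", "protocol", "phantom",
                "limits", "inversion", "bins", "cluster", "histo"}


def load_config(path) -> dict:
    """Load and validate a YAML run configuration; unknown top-level keys
    are rejected so typos fail loudly."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg.setdefault("seed", 0)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config dict, embedded in outputs for
    provenance."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
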