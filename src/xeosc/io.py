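"""File formats: HDF5 k-space container, NIfTI volumes, YAML spectral models.

HDF5 layout of an acquisition container:

    /kspace          complex samples [spoke, echo, readout point]
    /trajectory      k-space coordinates [spoke, readout point, 3] (cycles/FOV)
    /timestamps      seconds per spoke
    /seq/*           SequenceParams as attributes
    /spectral/<c>    spectral model attributes per compartment (optional)
    /truth/*         phantom ground-truth maps (optional)
    /separated/<c>   per-compartment separated k-space (optional)
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import nibabel as nib
import numpy as np
import yaml

from .phantom import PhantomSpec
from .recon import Trajectory
from .sequence import SequenceParams
from .simulate import KSpaceAcquisition
from .spectral import COMPARTMENTS, Resonance, SpectralModel

__all__ = [
    "save_acquisition",
    "load_acquisition",
    "save_truth",
    "load_truth",
    "save_nifti",
    "save_separated",
    "spectral_to_yaml",
    "spectral_from_yaml",
]


def _write_spectral(grp, model: SpectralModel) -> None:
    for name, res in zip(COMPARTMENTS, model):
        sub = grp.create_group(name)
        for key, val in dataclasses.asdict(res).items():
            sub.attrs[key] = val


def _read_spectral(grp) -> SpectralModel:
    kw = {}
    for name in COMPARTMENTS:
        kw[name if name != "rbc" else "rbc"] = Resonance(**dict(grp[name].attrs))
    return SpectralModel(gas=kw["gas"], membrane=kw["membrane"], rbc=kw["rbc"])


def save_acquisition(path, acq: KSpaceAcquisition, phantom: PhantomSpec | None = None) -> None:
    """Write an acquisition (and optional ground truth) to one HDF5 file."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("kspace", data=acq.samples)
        fh.create_dataset("trajectory", data=acq.trajectory.coords)
        fh.create_dataset("timestamps", data=acq.timestamps)
        seq = fh.create_group("seq")
        for key, val in dataclasses.asdict(acq.seq).items():
            seq.attrs[key] = val
        if acq.spectral_truth is not None:
            _write_spectral(fh.create_group("spectral"), acq.spectral_truth)
        if phantom is not None:
            _save_truth_group(fh, phantom)


def load_acquisition(path) -> KSpaceAcquisition:
    with h5py.File(path, "r") as fh:
        seq_kw = dict(fh["seq"].attrs)
        seq_kw["echo_times"] = tuple(np.asarray(seq_kw["echo_times"], dtype=float))
        for key in ("n_spokes", "n_echoes", "n_samples_per_echo", "recon_matrix",
                    "nominal_matrix", "n_dummy"):
            seq_kw[key] = int(seq_kw[key])
        seq = SequenceParams(**seq_kw)
        coords = fh["trajectory"][...]
        dirs = coords[:, -1, :]
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        traj = Trajectory(coords=coords, spoke_dirs=dirs,
                          radii=np.linalg.norm(coords[0], axis=1))
        spectral = _read_spectral(fh["spectral"]) if "spectral" in fh else None
        return KSpaceAcquisition(samples=fh["kspace"][...], trajectory=traj,
                                 timestamps=fh["timestamps"][...], seq=seq,
                                 spectral_truth=spectral)


def _save_truth_group(fh, phantom: PhantomSpec) -> None:
    g = fh.create_group("truth") if "truth" not in fh else fh["truth"]
    g.attrs["grid"] = phantom.grid
    g.attrs["heart_rate"] = phantom.heart_rate
    g.attrs["waveform"] = phantom.waveform.name
    for name in ("rho_gas", "rho_m", "rho_rbc"):
        g.create_dataset(name.replace("rho_", "rho/"), data=getattr(phantom, name))
    g.create_dataset("alpha", data=phantom.alpha_map)
    g.create_dataset("phi", data=phantom.phi_map)


def save_truth(path, phantom: PhantomSpec) -> None:
    with h5py.File(path, "a") as fh:
        _save_truth_group(fh, phantom)


def load_truth(path) -> dict:
    """Ground-truth maps as a dict (alpha, phi, rho_*, heart_rate, grid)."""
    out = {}
    with h5py.File(path, "r") as fh:
        g = fh["truth"]
        out["grid"] = int(g.attrs["grid"])
        out["heart_rate"] = float(g.attrs["heart_rate"])
        out["alpha"] = g["alpha"][...]
        out["phi"] = g["phi"][...]
        for name in ("gas", "m", "rbc"):
            out[f"rho_{name}"] = g[f"rho/{name}"][...]
    return out


def save_separated(path, separated) -> None:
    with h5py.File(path, "a") as fh:
        if "separated" in fh:
            del fh["separated"]
        g = fh.create_group("separated")
        for name in COMPARTMENTS:
            g.create_dataset(name, data=separated[name])


def save_nifti(volume: np.ndarray, path, seq: SequenceParams | None = None) -> None:
    """Write a volume as NIfTI-1, RAS+, with the FOV-derived voxel size [mm]."""
    vol = np.asarray(volume)
    if np.iscomplexobj(vol):
        vol = np.abs(vol)
    voxel_mm = 1000.0 * seq.fov / seq.recon_matrix if seq is not None else 1.0
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.asarray(vol.shape) / 2.0)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))


def spectral_to_yaml(model: SpectralModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)


def spectral_from_yaml(path) -> SpectralModel:
    with open(path) as fh:
        return SpectralModel.from_dict(yaml.safe_load(fh))
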