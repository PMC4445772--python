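"""On-disk formats: the HDF5 spectral container, NIfTI tissue maps and the
covariate table.

Container layout (one file per subject, ``<subject_id>.h5``):

    /kspace            complex (kx, ky, t) phase-encode data
    /params            group attributes: every AcquisitionParams field
    /truth             optional group holding the phantom ground truth
        gm, wm, csf    high-resolution probability volumes
        mask           brain mask (uint8)
        b0_map         per-voxel frequency offsets (Hz)
        linewidth_map  per-voxel Gaussian FWHM (Hz)
        attrs: concentrations/relaxation (JSON), eddy terms, zero phase,
               noise SD, seed, subject effects

Tissue maps are additionally written as NIfTI-1 volumes (1 mm in-plane,
slab/3 slice thickness) so the overlay stage consumes the same format a
segmentation tool would produce.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .params import AcquisitionParams
from .phantom import MRSIAcquisition, PhantomSpec, make_covariates
from .presets import RelaxationParams

TISSUES = ("gm", "wm", "csf", "mask")


def _nifti_affine(params: AcquisitionParams, hr_res_mm: float) -> np.ndarray:
    aff = np.diag([hr_res_mm, hr_res_mm, params.slab_mm / 3.0, 1.0])
    return aff


def save_subject(path, acq: MRSIAcquisition) -> Path:
    """Write one subject's acquisition (and ground truth if present)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=acq.kspace)
        g = f.create_group("params")
        for field in dataclasses.fields(acq.params):
            g.attrs[field.name] = getattr(acq.params, field.name)
        spec = acq.truth
        if spec is not None:
            t = f.create_group("truth")
            t.create_dataset("gm", data=spec.gm.astype(np.float32))
            t.create_dataset("wm", data=spec.wm.astype(np.float32))
            t.create_dataset("csf", data=spec.csf.astype(np.float32))
            t.create_dataset("mask", data=spec.mask.astype(np.uint8))
            t.create_dataset("b0_map", data=spec.b0_map)
            t.create_dataset("linewidth_map", data=spec.linewidth_map)
            t.attrs["subject_id"] = spec.subject_id
            t.attrs["concentrations"] = json.dumps(
                {m: list(v) for m, v in spec.concentrations.items()}
            )
            t.attrs["relaxation"] = json.dumps(
                {m: [r.t1_ms, r.t2_ms, r.source] for m, r in spec.relaxation.items()}
            )
            t.attrs["eddy_terms"] = json.dumps([list(e) for e in spec.eddy_terms])
            t.attrs["zero_phase"] = spec.zero_phase
            t.attrs["water_residual_scale"] = spec.water_residual_scale
            t.attrs["water_amp0"] = spec.water_amp0
            t.attrs["noise_sd"] = spec.noise_sd
            t.attrs["seed"] = spec.seed
            t.attrs["hr_res_mm"] = spec.hr_res_mm
            t.attrs["subject_effects"] = json.dumps(spec.subject_effects)
    return path


def load_subject(path) -> MRSIAcquisition:
    """Read a subject container back into memory."""
    with h5py.File(path, "r") as f:
        pd_attrs = dict(f["params"].attrs)
        pd_attrs["press_box"] = tuple(int(v) for v in pd_attrs["press_box"])
        for k in ("n_phase_x", "n_phase_y", "n_points"):
            pd_attrs[k] = int(pd_attrs[k])
        params = AcquisitionParams(**pd_attrs)
        kspace = f["kspace"][()]
        truth = None
        if "truth" in f:
            t = f["truth"]
            relax = {
                m: RelaxationParams(v[0], v[1], str(v[2]))
                for m, v in json.loads(t.attrs["relaxation"]).items()
            }
            truth = PhantomSpec(
                subject_id=str(t.attrs["subject_id"]),
                gm=t["gm"][()].astype(float),
                wm=t["wm"][()].astype(float),
                csf=t["csf"][()].astype(float),
                mask=t["mask"][()].astype(bool),
                concentrations={
                    m: tuple(v)
                    for m, v in json.loads(t.attrs["concentrations"]).items()
                },
                relaxation=relax,
                b0_map=t["b0_map"][()],
                linewidth_map=t["linewidth_map"][()],
                eddy_terms=tuple(
                    tuple(e) for e in json.loads(t.attrs["eddy_terms"])
                ),
                zero_phase=float(t.attrs["zero_phase"]),
                water_residual_scale=float(t.attrs["water_residual_scale"]),
                water_amp0=float(t.attrs["water_amp0"]),
                noise_sd=float(t.attrs["noise_sd"]),
                seed=int(t.attrs["seed"]),
                subject_effects=json.loads(t.attrs["subject_effects"]),
                hr_res_mm=float(t.attrs["hr_res_mm"]),
            )
    return MRSIAcquisition(params=params, kspace=kspace, truth=truth)


def save_tissue_maps(
    out_dir, subject_id: str, spec: PhantomSpec, params: AcquisitionParams
) -> dict[str, Path]:
    """Write GM/WM/CSF probability maps and the brain mask as NIfTI-1."""
    out_dir = Path(out_dir)
    aff = _nifti_affine(params, spec.hr_res_mm)
    paths = {}
    vols = {"gm": spec.gm, "wm": spec.wm, "csf": spec.csf,
            "mask": spec.mask.astype(np.float32)}
    for name, vol in vols.items():
        p = out_dir / f"{subject_id}_{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), aff), p)
        paths[name] = p
    return paths


def load_tissue_maps(in_dir, subject_id: str) -> dict[str, np.ndarray]:
    in_dir = Path(in_dir)
    out = {}
    for name in TISSUES:
        img = nib.load(in_dir / f"{subject_id}_{name}.nii")
        out[name] = np.asarray(img.dataobj, dtype=float)
    return out


def write_cohort(
    specs: list[PhantomSpec],
    params: AcquisitionParams,
    out_dir,
    seed: int = 0,
    include_noise: bool = True,
) -> Path:
    """Simulate and write a full cohort: containers, NIfTI maps, covariates."""
    from .phantom import simulate_acquisition

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for spec in specs:
        acq = simulate_acquisition(spec, params, include_noise=include_noise)
        save_subject(out_dir / f"{spec.subject_id}.h5", acq)
        save_tissue_maps(out_dir, spec.subject_id, spec, params)
    cov = make_covariates(specs, seed)
    cov.to_csv(out_dir / "covariates.csv", index=False)
    return out_dir


def cohort_subject_ids(in_dir) -> list[str]:
    return sorted(p.stem for p in Path(in_dir).glob("*.h5"))
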