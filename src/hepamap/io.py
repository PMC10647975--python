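"""NIfTI / sidecar readers and writers and on-disk study layout.

Axis conventions: arrays are (x, y, z) or (x, y, z, volume), 0-based voxel
indices; NIfTI affines carry voxel geometry.  Diffusivities are stored on
disk in SI mm^2/s (header description tags the units); all human-facing
tables use x10^-3 mm^2/s and %.  b-value sidecars use the FSL dialect
(whitespace-separated values, one line).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .ivim import BValueScheme, DWISeries
from .hef import DCESeries

__all__ = [
    "read_volume",
    "write_volume",
    "read_bvals",
    "write_bvals",
    "read_times",
    "write_times",
    "read_aif",
    "write_aif",
    "load_dwi",
    "load_dce",
    "StudyLayout",
    "PipelineConfig",
    "write_study",
    "config_hash",
]


def write_volume(array, path, voxel_size=(1.0, 1.0, 1.0), description=""):
    """Write a 3D/4D array as NIfTI-1 (float32 for maps, native otherwise)."""
    array = np.asarray(array)
    if array.ndim not in (3, 4):
        raise ValueError("only 3D and 4D volumes are supported")
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(array.astype(np.float32), affine)
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))
    return Path(path)


def read_volume(path):
    """Read a NIfTI volume; returns (array, voxel_size, header)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected 3D or 4D, got {data.ndim}D")
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: volume contains non-finite values")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, voxel_size, img.header


def write_bvals(b_values, path):
    Path(path).write_text(" ".join(f"{b:g}" for b in b_values) + "\n")


def read_bvals(path):
    vals = [float(tok) for tok in Path(path).read_text().split()]
    return tuple(vals)


def write_times(times, path):
    Path(path).write_text("\n".join(f"{t:g}" for t in times) + "\n")


def read_times(path):
    return tuple(float(tok) for tok in Path(path).read_text().split())


def write_aif(times, aif, path):
    pd.DataFrame({"time_s": times, "aif": aif}).to_csv(path, index=False)


def read_aif(path):
    df = pd.read_csv(path)
    return np.asarray(df["time_s"], float), np.asarray(df["aif"], float)


def load_dwi(dwi_path, bvals_path, mask_path=None,
             averages=None) -> DWISeries:
    """Load a 4D DWI NIfTI + FSL bval sidecar (+ optional mask) as DWISeries."""
    data, voxel_size, _ = read_volume(dwi_path)
    bvals = read_bvals(bvals_path)
    if data.ndim != 4:
        raise ValueError("DWI volume must be 4D")
    if len(bvals) != data.shape[-1]:
        raise ValueError(
            f"bval sidecar has {len(bvals)} entries but the volume has "
            f"{data.shape[-1]} b-volumes")
    if averages is None:
        averages = (1,) * len(bvals)
    scheme = BValueScheme(b_values=bvals, averages=tuple(averages))
    mask = None
    if mask_path is not None:
        mask, _, _ = read_volume(mask_path)
        mask = mask > 0.5
    return DWISeries(data, scheme, voxel_size=voxel_size, mask=mask)


def load_dce(dce_path, times_path, aif_path, mask_path=None) -> DCESeries:
    """Load a 4D DCE NIfTI + times sidecar + AIF CSV as DCESeries."""
    data, _, _ = read_volume(dce_path)
    times = np.asarray(read_times(times_path), float)
    t_aif, aif = read_aif(aif_path)
    if not np.allclose(t_aif, times):
        raise ValueError("AIF time grid differs from the times sidecar")
    mask = None
    if mask_path is not None:
        mask, _, _ = read_volume(mask_path)
        mask = mask > 0.5
    return DCESeries(signal=data, times=times, aif=aif, mask=mask)


@dataclass
class StudyLayout:
    """Per-subject file map of an on-disk study."""

    root: Path
    manifest: pd.DataFrame  # columns: subject, cohort, seed

    def subject_dir(self, subject_id):
        return Path(self.root) / subject_id

    def paths(self, subject_id):
        d = self.subject_dir(subject_id)
        return {
            "dwi": d / "dwi.nii.gz", "bvals": d / "dwi.bval",
            "mask": d / "liver_mask.nii.gz",
            "spgr_pre_3": d / "spgr_pre_fa3.nii.gz",
            "spgr_pre_15": d / "spgr_pre_fa15.nii.gz",
            "spgr_post_3": d / "spgr_post_fa3.nii.gz",
            "spgr_post_15": d / "spgr_post_fa15.nii.gz",
            "b1": d / "b1_map.nii.gz",
            "dce": d / "dce.nii.gz", "times": d / "dce_times.txt",
            "aif": d / "aif.csv",
        }


_PIPELINE_FIELDS = {
    "ivim_method", "median_filter", "mcmc_iterations", "mcmc_burn_in",
    "b_threshold", "truncation_fraction", "split_time", "alpha",
    "bootstrap_samples", "bootstrap_level", "dice_floor", "seed",
    "voxel_fraction", "roi_slice", "spgr_tr", "flip_angles",
}


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (schema-validated)."""

    ivim_method: str = "bayes"
    median_filter: bool = True
    mcmc_iterations: int = 10000
    mcmc_burn_in: int = 5000
    b_threshold: float = 200.0
    truncation_fraction: float = 0.10
    split_time: float = 300.0
    alpha: float = 0.05
    bootstrap_samples: int = 1000
    bootstrap_level: float = 95.0
    dice_floor: float = 0.8
    seed: int = 0
    voxel_fraction: float = 1.0  # fraction of liver voxels fitted per subject
    roi_slice: int | None = None  # slice index for voxelwise correlation
    spgr_tr: float = 5.08
    flip_angles: tuple = (3.0, 15.0)

    def __post_init__(self):
        if self.ivim_method not in ("bayes", "lsq"):
            raise ValueError("ivim_method must be 'bayes' or 'lsq'")
        if not 0 < self.voxel_fraction <= 1:
            raise ValueError("voxel_fraction must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path):
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _PIPELINE_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "flip_angles" in raw:
            raw["flip_angles"] = tuple(raw["flip_angles"])
        return cls(**raw)

    def to_dict(self):
        d = dict(self.__dict__)
        d["flip_angles"] = list(self.flip_angles)
        return d


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_study(subjects, root, config=None) -> StudyLayout:
    """Write a simulated study bundle (from make_cohort) to disk.

    Per subject: NIfTI volumes (4D DWI/DCE, 3D SPGR/mask/B1), FSL bval
    sidecar, DCE time sidecar, AIF CSV; plus a study-level manifest and a
    truth table CSV (subject, cohort, region, parameter, value).
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows, truth_rows = [], []
    for subj in subjects:
        d = root / subj.subject_id
        d.mkdir(exist_ok=True)
        tag = f"hepamap simulate cohort={subj.cohort}"
        write_volume(subj.dwi.signal, d / "dwi.nii.gz", description=tag)
        write_bvals(subj.dwi.scheme.b_values, d / "dwi.bval")
        write_volume(subj.truth.liver_mask.astype(np.float32),
                     d / "liver_mask.nii.gz", description=tag)
        if subj.spgr_pre is not None:
            for a, vol in subj.spgr_pre.items():
                write_volume(vol, d / f"spgr_pre_fa{a:g}.nii.gz",
                             description=tag)
        if subj.spgr_post is not None:
            for a, vol in subj.spgr_post.items():
                write_volume(vol, d / f"spgr_post_fa{a:g}.nii.gz",
                             description=tag)
        if subj.b1_field is not None:
            write_volume(subj.b1_field, d / "b1_map.nii.gz", description=tag)
        if subj.dce is not None:
            write_volume(subj.dce.signal, d / "dce.nii.gz", description=tag)
            write_times(subj.dce.times, d / "dce_times.txt")
            write_aif(subj.dce.times, subj.dce.aif, d / "aif.csv")
        rows.append({"subject": subj.subject_id, "cohort": subj.cohort})
        lab = subj.truth.region_labels
        for name in ("d_slow", "d_fast", "f_p", "t1_pre", "t1_post", "hef"):
            f = getattr(subj.truth, name)
            for region in range(1, int(lab.max()) + 1):
                sel = lab == region
                if sel.any():
                    truth_rows.append({
                        "subject": subj.subject_id, "cohort": subj.cohort,
                        "region": region, "parameter": name,
                        "value": float(f[sel].mean())})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(root / "manifest.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(root / "truth.csv", index=False)
    return StudyLayout(root=root, manifest=manifest)
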