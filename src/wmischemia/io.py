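"""File I/O: NIfTI volumes, FSL-style gradient tables, AIF curves, cohort
bundles and the YAML pipeline configuration."""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import defaults as dflt
from .phantom import AcquisitionScheme, SubjectData, GroundTruth

log = logging.getLogger(__name__)

__all__ = ["read_nifti", "write_nifti", "read_gradients", "write_gradients",
           "read_aif", "write_aif", "load_config", "default_config",
           "write_cohort", "read_subject"]


# ---------------------------------------------------------------------------
# NIfTI

def read_nifti(path, ndim: int | None = None):
    """Load a NIfTI-1 volume -> (data array, voxel size in mm).

    ``ndim`` enforces the expected dimensionality (3 for scalar maps, 4 for
    series).  Both .nii and .nii.gz are accepted.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj)
    if ndim is not None and data.ndim != ndim:
        raise ValueError(f"{path}: expected a {ndim}-D volume, got {data.ndim}-D")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, voxel_size


def write_nifti(volume: np.ndarray, path,
                voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)):
    """Write an array as NIfTI-1 with the given voxel dimensions."""
    volume = np.asarray(volume)
    if volume.dtype == bool:
        volume = volume.astype(np.uint8)
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(volume, affine)
    img.header.set_zooms(voxel_size + (1.0,) * (volume.ndim - 3)
                         if volume.ndim > 3 else voxel_size)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# gradients (FSL dialect: bval one row, bvec three rows of N)

def read_gradients(bval_path, bvec_path, **scheme_kwargs) -> AcquisitionScheme:
    """Parse FSL-style bval/bvec text files into an AcquisitionScheme.

    Non-unit direction vectors are normalized (with a warning); b=0 rows are
    identified by a zero b-value.  Extra keyword arguments carry the DSC
    timing into the scheme.
    """
    bvals = np.loadtxt(bval_path).reshape(-1)
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape[0] != bvals.size:
        raise ValueError(
            f"gradient count mismatch: {bvals.size} b-values vs "
            f"{bvecs.shape[0]} direction vectors")
    b0 = bvals == 0
    dirs = bvecs[~b0]
    norms = np.linalg.norm(dirs, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero direction vector with nonzero b-value")
    if not np.allclose(norms, 1.0, atol=1e-8):
        log.warning("read_gradients: normalizing non-unit direction vectors")
        dirs = dirs / norms[:, None]
    nz = bvals[~b0]
    if nz.size and not np.allclose(nz, nz[0]):
        raise ValueError("multi-shell gradient tables are not supported")
    return AcquisitionScheme(directions=dirs,
                             b_value=float(nz[0]) if nz.size else 1000.0,
                             n_b0=max(int(b0.sum()), 1), **scheme_kwargs)


def write_gradients(scheme: AcquisitionScheme, bval_path, bvec_path):
    dirs, bvals = scheme.gradient_table()
    np.savetxt(bval_path, bvals[None, :], fmt="%.1f")
    np.savetxt(bvec_path, dirs.T, fmt="%.8f")


def read_aif(path) -> np.ndarray:
    """Single-column text file of arterial concentration per timepoint."""
    aif = np.loadtxt(path).reshape(-1)
    if aif.size < 10:
        raise ValueError("AIF curve has fewer than 10 samples")
    return aif


def write_aif(aif: np.ndarray, path):
    np.savetxt(path, np.asarray(aif).reshape(-1, 1), fmt="%.8f")


# ---------------------------------------------------------------------------
# configuration

def default_config() -> dict:
    return {
        "thresholds": dict(dflt.THRESHOLD_DEFAULTS),
        "deconvolution": {
            "threshold_frac": dflt.SVD_THRESHOLD_FRAC,
            "interpolate_tmax": False,
            "baseline_n": dflt.DSC_SIM_DEFAULTS["baseline_n"],
        },
        "segmentation": {"core_within_roi": False},
        "statistics": dict(dflt.STATS_DEFAULTS),
        "seed": 0,
    }


# (low, high, low_inclusive)
_RANGES = {
    ("thresholds", "fa_wm"): (0.0, 1.0, False),
    ("thresholds", "adc_core"): (0.0, np.inf, False),
    ("thresholds", "tmax_roi_k"): (0.0, np.inf, True),
    ("deconvolution", "threshold_frac"): (0.0, 1.0, False),
    ("deconvolution", "baseline_n"): (3, np.inf, True),
    ("statistics", "min_group_size"): (1, np.inf, True),
    ("statistics", "n_permutations"): (0, np.inf, True),
    ("statistics", "alpha"): (0.0, 1.0, False),
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load and validate the pipeline configuration.

    Starts from the defaults, deep-merges the YAML file (if given) and then
    ``overrides``.  Unknown keys and out-of-range values are rejected.
    """
    cfg = default_config()
    layers = []
    if path is not None:
        with open(path) as fh:
            layers.append(yaml.safe_load(fh) or {})
    if overrides:
        layers.append(overrides)
    for layer in layers:
        for section, value in layer.items():
            if section not in cfg:
                raise ValueError(f"unknown config section {section!r}")
            if isinstance(cfg[section], dict):
                for key, v in value.items():
                    if key not in cfg[section]:
                        raise ValueError(
                            f"unknown config key {section}.{key}")
                    cfg[section][key] = v
            else:
                cfg[section] = value
    for (section, key), (lo, hi, lo_inc) in _RANGES.items():
        v = cfg[section][key]
        ok = (lo <= v if lo_inc else lo < v) and v < hi
        if not ok:
            raise ValueError(f"config {section}.{key}={v} out of range")
    if cfg["statistics"]["split_unit"] not in ("person", "voxel"):
        raise ValueError("statistics.split_unit must be 'person' or 'voxel'")
    return cfg


# ---------------------------------------------------------------------------
# cohort bundles

def write_cohort(subjects: list[SubjectData], spec, out_dir):
    """Write per-subject NIfTI/text bundles plus cohort-level truth TSV."""
    from .phantom import region_truth_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vs = tuple(spec.voxel_size)
    for s in subjects:
        d = out / s.subject_id
        d.mkdir(exist_ok=True)
        write_nifti(s.dwi, d / "dwi.nii.gz", vs)
        write_nifti(s.dsc, d / "dsc.nii.gz", vs)
        write_nifti(s.truth.label_map.astype(np.int16), d / "labels.nii.gz", vs)
        write_nifti(s.truth.true_fa, d / "true_fa.nii.gz", vs)
        write_nifti(s.truth.true_adc, d / "true_adc.nii.gz", vs)
        write_nifti(s.truth.true_tmax, d / "true_tmax.nii.gz", vs)
        for name, m in s.masks.items():
            write_nifti(m, d / f"mask_{name}.nii.gz", vs)
        write_gradients(s.scheme, d / "dwi.bval", d / "dwi.bvec")
        write_aif(s.aif_curve, d / "aif.txt")
    region_truth_table(subjects).to_csv(out / "truth.tsv", sep="\t", index=False)
    meta = dict(n_subjects=spec.n_subjects, seed=spec.seed,
                grid_shape=list(spec.grid_shape),
                voxel_size=list(spec.voxel_size), snr_dwi=float(spec.snr_dwi),
                dsc_noise_sd=float(spec.dsc_noise_sd))
    with open(out / "cohort.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def read_subject(subject_dir, scheme: AcquisitionScheme | None = None) -> SubjectData:
    """Read one subject bundle written by :func:`write_cohort`."""
    d = Path(subject_dir)
    dwi, _ = read_nifti(d / "dwi.nii.gz", ndim=4)
    dsc, _ = read_nifti(d / "dsc.nii.gz", ndim=4)
    if scheme is None:
        scheme = read_gradients(d / "dwi.bval", d / "dwi.bvec")
    labels, _ = read_nifti(d / "labels.nii.gz", ndim=3)
    fa, _ = read_nifti(d / "true_fa.nii.gz", ndim=3)
    adc, _ = read_nifti(d / "true_adc.nii.gz", ndim=3)
    tmax, _ = read_nifti(d / "true_tmax.nii.gz", ndim=3)
    masks = {}
    for p in sorted(d.glob("mask_*.nii.gz")):
        m, _ = read_nifti(p, ndim=3)
        masks[p.name[len("mask_"):-len(".nii.gz")]] = m.astype(bool)
    truth = GroundTruth(labels.astype(np.int16), fa, adc, tmax,
                        region_values={}, principal_dirs={})
    return SubjectData(subject_id=d.name, truth=truth, dwi=dwi, dsc=dsc,
                       aif_curve=read_aif(d / "aif.txt"),
                       aif_voxels=np.empty((0, 3), dtype=int),
                       masks=masks, scheme=scheme)
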