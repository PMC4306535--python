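"""Threshold-based partition of white matter into infarct core, hypoperfused
and contralateral normal regions, plus per-voxel value extraction.

Rules (applied in physical units):
    WM mask          FA > 0.15 (strict; everything else counts as gray matter)
    infarct core     WM and ADC < 600e-6 mm^2/s
    hypoperfused     WM and ADC >= 600e-6 mm^2/s and inside the perfusion ROI
    normal contra    WM and inside the mirrored contralateral ROI

ADC exactly at the cut-off goes to the hypoperfused side so that the two
lesion classes partition the ROI.  The hand-drawn perfusion ROI of the
original workflow is replaced by either a user-supplied mask or the
reproducible ``auto_perfusion_roi`` surrogate (contralateral mean + k SD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import defaults as dflt
from .dti import ScalarMap

__all__ = ["Thresholds", "RegionMasks", "wm_mask", "segment",
           "auto_perfusion_roi", "extract_values"]

log = logging.getLogger(__name__)


@dataclass
class Thresholds:
    fa_wm: float = dflt.THRESHOLD_DEFAULTS["fa_wm"]
    adc_core: float = dflt.THRESHOLD_DEFAULTS["adc_core"]       # mm^2/s
    tmax_roi_k: float = dflt.THRESHOLD_DEFAULTS["tmax_roi_k"]   # SD multiplier

    def __post_init__(self) -> None:
        if not 0 < self.fa_wm < 1:
            raise ValueError("fa_wm must lie in (0, 1)")
        if self.adc_core <= 0:
            raise ValueError("adc_core must be positive")


@dataclass
class RegionMasks:
    """Boolean masks on a shared grid; invariants checked on construction."""

    wm: np.ndarray
    infarct_core: np.ndarray
    hypoperfused: np.ndarray
    normal_contra: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.infarct_core & self.hypoperfused):
            raise ValueError("infarct core and hypoperfused masks overlap")
        for name in ("infarct_core", "hypoperfused", "normal_contra"):
            m = getattr(self, name)
            if np.any(m & ~self.wm):
                raise ValueError(f"{name} extends outside the WM mask")
        if np.any(self.normal_contra & (self.infarct_core | self.hypoperfused)):
            raise ValueError("contralateral ROI overlaps the lesion masks")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"infarct_core": self.infarct_core,
                "hypoperfused": self.hypoperfused,
                "normal_contra": self.normal_contra}


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, ScalarMap) else np.asarray(m)


def wm_mask(fa_map, thresholds: Thresholds | None = None) -> np.ndarray:
    """White-matter mask: FA strictly above the gray-matter threshold.

    NaN FA (outside the brain or excluded voxels) is excluded.
    """
    thresholds = thresholds or Thresholds()
    fa = _values(fa_map)
    with np.errstate(invalid="ignore"):
        return np.isfinite(fa) & (fa > thresholds.fa_wm)


def segment(fa_map, adc_map, tmax_map=None, perfusion_roi=None,
            contra_roi=None, thresholds: Thresholds | None = None,
            core_within_roi: bool = False) -> RegionMasks:
    """Partition WM into infarct core / hypoperfused / contralateral normal.

    ``perfusion_roi`` (the region of visually increased Tmax in the original
    workflow) bounds the hypoperfused class; ``core_within_roi=True``
    additionally restricts the infarct core to the ROI.  ``tmax_map`` is
    accepted for grid checking only — the class rules use FA and ADC.
    """
    thresholds = thresholds or Thresholds()
    fa = _values(fa_map)
    adc = _values(adc_map)
    grids = [adc.shape]
    if tmax_map is not None:
        grids.append(_values(tmax_map).shape)
    if perfusion_roi is not None:
        grids.append(np.asarray(perfusion_roi).shape)
    if contra_roi is not None:
        grids.append(np.asarray(contra_roi).shape)
    if any(g != fa.shape for g in grids):
        raise ValueError("all maps and ROIs must share one voxel grid")

    wm = wm_mask(fa, thresholds)
    finite_adc = np.isfinite(adc)
    with np.errstate(invalid="ignore"):
        low_adc = finite_adc & (adc < thresholds.adc_core)
        high_adc = finite_adc & (adc >= thresholds.adc_core)

    roi = (np.ones_like(wm) if perfusion_roi is None
           else np.asarray(perfusion_roi, dtype=bool))
    core = wm & low_adc
    if core_within_roi:
        core &= roi
    hypo = wm & high_adc & roi
    contra = (np.zeros_like(wm) if contra_roi is None
              else wm & np.asarray(contra_roi, dtype=bool))
    contra &= ~(core | hypo)
    return RegionMasks(wm=wm, infarct_core=core, hypoperfused=hypo,
                       normal_contra=contra)


def auto_perfusion_roi(tmax_map, contra_roi, thresholds: Thresholds | None = None,
                       grid_step: float | None = None) -> np.ndarray:
    """Reproducible surrogate for the hand-drawn perfusion ROI.

    Includes voxels whose Tmax exceeds the contralateral mean by more than
    ``tmax_roi_k`` contralateral SDs.  With zero contralateral variance the
    rule degenerates, so it falls back to mean + one Tmax grid step
    (``grid_step``, default one TR of the standard acquisition).
    """
    thresholds = thresholds or Thresholds()
    tmax = _values(tmax_map)
    contra = np.asarray(contra_roi, dtype=bool)
    if tmax.shape != contra.shape:
        raise ValueError("Tmax map and contralateral ROI grids differ")
    ref = tmax[contra]
    ref = ref[np.isfinite(ref)]
    if ref.size == 0:
        raise ValueError("contralateral ROI is empty")
    mu, sd = float(ref.mean()), float(ref.std())
    if sd > 0:
        cut = mu + thresholds.tmax_roi_k * sd
    else:
        if grid_step is None:
            grid_step = dflt.DSC_DEFAULTS["tr"]
        cut = mu + grid_step
    with np.errstate(invalid="ignore"):
        return np.isfinite(tmax) & (tmax > cut)


def extract_values(masks: RegionMasks, fa_map, adc_map, tmax_map,
                   subject_id: str = "sub-01") -> pd.DataFrame:
    """One row per in-region voxel: (subject, region, voxel index, FA, ADC,
    Tmax).  Rows containing NaN are dropped (counted in the log)."""
    fa = _values(fa_map)
    adc = _values(adc_map)
    tmax = _values(tmax_map)
    frames = []
    for region, m in masks.as_dict().items():
        idx = np.flatnonzero(m.reshape(-1))
        frames.append(pd.DataFrame({
            "subject": subject_id,
            "region": region,
            "voxel": idx,
            "fa": fa.reshape(-1)[idx],
            "adc": adc.reshape(-1)[idx],
            "tmax": tmax.reshape(-1)[idx],
        }))
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["subject", "region", "voxel", "fa", "adc", "tmax"])
    n0 = len(table)
    table = table.dropna(subset=["fa", "adc", "tmax"]).reset_index(drop=True)
    if len(table) < n0:
        log.info("extract_values[%s]: dropped %d voxel rows with NaN values",
                 subject_id, n0 - len(table))
    return table
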