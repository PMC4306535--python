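"""Digital multi-subject DWI + DSC phantom with known FA / ADC / Tmax truth.

The phantom emulates the statistical structure of a hyperacute-stroke cohort:
each subject carries four tissue compartments (normal white matter, gray
matter, hypoperfused WM, infarct core) laid out as a lateralized lesion with a
mirror-image contralateral normal-WM region.  Per-subject region parameters
are drawn from truncated normal distributions around the configured
mean +/- SD targets; a small per-voxel truth jitter is added within regions.

DWI forward model
    S_i = s0 * exp(-b g_i^T D g_i) with an axially symmetric tensor
    (lambda2 = lambda3) built by ``solve_eigenvalues`` and a per-region
    principal direction, plus Rician noise at the configured baseline SNR.

DSC forward model
    The tissue concentration is the continuous convolution of a gamma-variate
    arterial input function (AIF) with an exponential residue exp(-t/MTT),
    evaluated on a fine (10 ms) grid and sampled at t - delay per voxel; the
    signal is S(t) = s0 * exp(-TE * C(t)) plus Gaussian noise.  The planted
    delay is chosen so that the *deconvolved* residue's peak sits at the
    voxel's true Tmax: the constant peak offset of the truncated-SVD
    deconvolution (a property of the AIF shape, MTT and threshold) is measured
    once by a noiseless round trip through :func:`wmischemia.dsc` and
    subtracted.  This makes recovered Tmax equal planted Tmax exactly on the
    TR grid for grid-aligned delays, and to ~0.05 s with sub-sample
    interpolation for arbitrary delays.

Everything is a pure function of (spec, scheme, seed).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from . import defaults as dflt
from . import dsc as dsc_mod

__all__ = [
    "RegionParams",
    "AcquisitionScheme",
    "PhantomSpec",
    "GroundTruth",
    "SubjectData",
    "REGION_CODES",
    "fibonacci_directions",
    "solve_eigenvalues",
    "build_geometry",
    "gamma_variate_aif",
    "calibrate_delay_offset",
    "draw_subject_truth",
    "simulate_dwi",
    "simulate_dsc",
    "simulate_subject",
    "generate_cohort",
    "default_spec",
]

REGION_CODES = {"normal_wm": 1, "gray_matter": 2,
                "hypoperfused_wm": 3, "infarct_core": 4}
_CODE_TO_REGION = {v: k for k, v in REGION_CODES.items()}


# ---------------------------------------------------------------------------
# domain types

@dataclass
class RegionParams:
    """Planted mean +/- SD targets for one tissue compartment."""

    label: str
    fa_mean: float
    fa_sd: float
    md_mean: float
    md_sd: float
    tmax_mean: float
    tmax_sd: float
    s0: float = 100.0

    def __post_init__(self) -> None:
        if self.label not in REGION_CODES:
            raise ValueError(f"unknown region label {self.label!r}")
        if not 0 <= self.fa_mean < 1:
            raise ValueError("fa_mean must lie in [0, 1)")
        if self.md_mean <= 0:
            raise ValueError("md_mean must be positive")
        if self.tmax_mean < 0:
            raise ValueError("tmax_mean must be nonnegative")
        if min(self.fa_sd, self.md_sd, self.tmax_sd) < 0:
            raise ValueError("SDs must be nonnegative")


def fibonacci_directions(n: int) -> np.ndarray:
    """n approximately uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + np.sqrt(5.0)) * i
    d = np.stack([np.sin(phi) * np.cos(theta),
                  np.sin(phi) * np.sin(theta),
                  np.cos(phi)], axis=1)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


@dataclass
class AcquisitionScheme:
    """DWI gradient scheme plus DSC timing."""

    directions: np.ndarray = field(
        default_factory=lambda: fibonacci_directions(
            dflt.DWI_DEFAULTS["n_directions"]))
    b_value: float = dflt.DWI_DEFAULTS["b_value"]
    n_b0: int = dflt.DWI_DEFAULTS["n_b0"]
    dsc_tr: float = dflt.DSC_DEFAULTS["tr"]
    dsc_te: float = dflt.DSC_DEFAULTS["te"]
    dsc_n_timepoints: int = dflt.DSC_DEFAULTS["n_timepoints"]

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("gradient directions must have unit norm")
        if self.b_value <= 0:
            raise ValueError("b_value must be positive")
        if self.n_b0 < 1:
            raise ValueError("need at least one b=0 volume")
        if self.dsc_n_timepoints < 10:
            raise ValueError("DSC series needs at least 10 timepoints")

    @property
    def n_volumes(self) -> int:
        return self.n_b0 + len(self.directions)

    def gradient_table(self):
        """(directions, bvals) for all volumes; b=0 rows lead with zero dirs."""
        dirs = np.vstack([np.zeros((self.n_b0, 3)), self.directions])
        bvals = np.concatenate([np.zeros(self.n_b0),
                                np.full(len(self.directions), self.b_value)])
        return dirs, bvals

    @property
    def dsc_times(self) -> np.ndarray:
        return np.arange(self.dsc_n_timepoints) * self.dsc_tr


def _default_regions() -> dict[str, RegionParams]:
    return {name: RegionParams(label=name, **params)
            for name, params in dflt.REGION_DEFAULTS.items()}


@dataclass
class PhantomSpec:
    """Full description of one synthetic cohort."""

    grid_shape: tuple[int, int, int] = dflt.PHANTOM_GRID
    voxel_size: tuple[float, float, float] = dflt.PHANTOM_VOXEL_SIZE
    regions: dict[str, RegionParams] = field(default_factory=_default_regions)
    snr_dwi: float = 30.0
    dsc_noise_sd: float = 1.0
    n_subjects: int = 21
    seed: int = 0
    voxel_sd: dict = field(default_factory=lambda: dict(dflt.VOXEL_SD))
    # DSC simulation physics
    aif: dict = field(default_factory=lambda: dict(dflt.AIF_DEFAULTS))
    mtt: float = dflt.DSC_SIM_DEFAULTS["mtt"]
    tissue_peak_conc: float = dflt.DSC_SIM_DEFAULTS["tissue_peak_conc"]
    threshold_frac: float = dflt.SVD_THRESHOLD_FRAC
    # optional step-FA mode for the split-search experiment
    changepoint: dict | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("cohort needs at least 2 subjects")
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be three positive integers")
        missing = set(REGION_CODES) - set(self.regions)
        if missing:
            raise ValueError(f"missing region parameters for {sorted(missing)}")


def default_spec(**overrides) -> PhantomSpec:
    """The default cohort: 21 subjects, 32x32x8 grid, SNR 30."""
    return replace(PhantomSpec(), **overrides) if overrides else PhantomSpec()


@dataclass
class GroundTruth:
    """Per-voxel planted truth for one subject."""

    label_map: np.ndarray   # region code per voxel, 0 = background
    true_fa: np.ndarray
    true_adc: np.ndarray
    true_tmax: np.ndarray
    region_values: dict     # region -> dict(fa, md, tmax) subject-level draw
    principal_dirs: dict    # region -> unit 3-vector


@dataclass
class SubjectData:
    """In-memory bundle for one simulated subject."""

    subject_id: str
    truth: GroundTruth
    dwi: np.ndarray
    dsc: np.ndarray
    aif_curve: np.ndarray
    aif_voxels: np.ndarray
    masks: dict
    scheme: AcquisitionScheme


# ---------------------------------------------------------------------------
# tensor construction

def solve_eigenvalues(fa: float, md: float):
    """Invert the FA definition for an axially symmetric (prolate) tensor.

    Returns (lambda1, lambda2, lambda3) with lambda2 = lambda3, mean md and
    fractional anisotropy fa.  Closed form: with d = lambda1 - lambda2,
    FA^2 (3 md^2 + 2 d^2 / 3) = d^2  =>  d = fa * md * sqrt(3) /
    sqrt(1 - 2 fa^2 / 3).
    """
    fa = float(fa)
    md = float(md)
    if not 0 <= fa < 1:
        raise ValueError("fa must lie in [0, 1)")
    if md <= 0:
        raise ValueError("md must be positive")
    d = fa * md * np.sqrt(3.0) / np.sqrt(1.0 - 2.0 * fa * fa / 3.0)
    l1 = md + 2.0 * d / 3.0
    l2 = md - d / 3.0
    if l2 < 0:
        raise ValueError(f"fa={fa}, md={md} gives negative lambda2")
    return l1, l2, l2


# ---------------------------------------------------------------------------
# geometry

def build_geometry(grid_shape: tuple[int, int, int]):
    """Region label map plus ROI masks on the given grid.

    Layout (x = left-right): a gray-matter slab along low y; the lesion — a
    hypoperfused block containing a smaller infarct-core block — sits in the
    high-x hemisphere; the contralateral normal-WM region of interest is its
    mirror image across the mid-sagittal plane.  Everything else inside the
    brain is normal WM.
    """
    nx, ny, nz = grid_shape
    label = np.full(grid_shape, REGION_CODES["normal_wm"], dtype=np.int16)

    gm_depth = max(2, ny // 8)
    label[:, :gm_depth, :] = REGION_CODES["gray_matter"]

    # lesion block in the high-x hemisphere
    def _span(center, half, lo, hi):
        return slice(max(lo, center - half), min(hi, center + half))

    cx, cy, cz = int(nx * 0.72), int(ny * 0.6), nz // 2
    hx, hy, hz = max(2, nx // 7), max(2, ny // 7), max(1, nz // 3)
    hypo = (_span(cx, hx, 0, nx), _span(cy, hy, 0, ny), _span(cz, hz, 0, nz))
    label[hypo] = REGION_CODES["hypoperfused_wm"]

    ix, iy, iz = max(1, hx // 2), max(1, hy // 2), max(1, hz // 2)
    core = (_span(cx, ix, 0, nx), _span(cy, iy, 0, ny), _span(cz, iz, 0, nz))
    label[core] = REGION_CODES["infarct_core"]

    lesion = ((label == REGION_CODES["hypoperfused_wm"])
              | (label == REGION_CODES["infarct_core"]))
    contra = lesion[::-1, :, :]
    if np.any(contra & lesion):
        raise ValueError("grid too small: lesion overlaps its mirror image")

    masks = {
        "brain": np.ones(grid_shape, dtype=bool),
        "perfusion_roi": lesion,
        "contra_roi": contra,
    }
    for name in REGION_CODES:
        if not np.any(label == REGION_CODES[name]):
            raise ValueError(f"grid too small: region {name} is empty")
    return label, masks


# ---------------------------------------------------------------------------
# subject-level truth

def _truncnorm_draw(rng, mean, sd, lo, hi, size=None):
    if sd == 0:
        return np.full(size, float(mean)) if size else float(mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                             random_state=rng)


def draw_subject_truth(spec: PhantomSpec, rng: np.random.Generator) -> GroundTruth:
    """One subject's ground-truth maps: region draws + per-voxel jitter."""
    label, _ = build_geometry(spec.grid_shape)
    fa = np.zeros(spec.grid_shape)
    adc = np.zeros(spec.grid_shape)
    tmax = np.zeros(spec.grid_shape)
    region_values: dict[str, dict] = {}
    principal_dirs: dict[str, np.ndarray] = {}
    vsd = spec.voxel_sd

    cp = spec.changepoint
    for name, code in REGION_CODES.items():
        p = spec.regions[name]
        r_tmax = _truncnorm_draw(rng, p.tmax_mean, p.tmax_sd, 0.0, np.inf)
        if cp is not None and name == "hypoperfused_wm":
            lo, hi = cp["tmax_range"]
            r_tmax = rng.uniform(lo, hi)
            level = cp["fa_above"] if r_tmax >= cp["tmax_split"] else cp["fa_below"]
            r_fa = _truncnorm_draw(rng, level, cp["fa_sd"], 0.0, 0.99)
        else:
            r_fa = _truncnorm_draw(rng, p.fa_mean, p.fa_sd, 0.0, 0.99)
        r_md = _truncnorm_draw(rng, p.md_mean, p.md_sd, 1e-6, np.inf)
        region_values[name] = dict(fa=float(r_fa), md=float(r_md),
                                   tmax=float(r_tmax), s0=p.s0)
        v = rng.normal(size=3)
        principal_dirs[name] = v / np.linalg.norm(v)

        sel = label == code
        n = int(sel.sum())
        fa[sel] = _truncnorm_draw(rng, r_fa, vsd["fa"], 0.0, 0.99, size=n)
        adc[sel] = _truncnorm_draw(rng, r_md, vsd["md"], 1e-6, np.inf, size=n)
        tmax[sel] = _truncnorm_draw(rng, r_tmax, vsd["tmax"], 0.0, np.inf, size=n)

    return GroundTruth(label, fa, adc, tmax, region_values, principal_dirs)


# ---------------------------------------------------------------------------
# DWI simulation

def simulate_dwi(spec: PhantomSpec, scheme: AcquisitionScheme,
                 truth: GroundTruth, seed: int):
    """4D DWI array plus the gradient table, Rician noise at spec.snr_dwi."""
    if truth.label_map.shape != tuple(spec.grid_shape):
        raise ValueError("truth grid does not match spec grid")
    rng = np.random.default_rng(seed)
    dirs, bvals = scheme.gradient_table()
    shape = truth.label_map.shape
    flat_lab = truth.label_map.reshape(-1)
    n_vox = flat_lab.size
    signal = np.zeros((n_vox, len(bvals)))

    for name, code in REGION_CODES.items():
        sel = flat_lab == code
        if not np.any(sel):
            continue
        fa_v = truth.true_fa.reshape(-1)[sel]
        md_v = truth.true_adc.reshape(-1)[sel]
        v = truth.principal_dirs[name]
        # axially symmetric tensor: D = l2 I + (l1 - l2) v v^T
        d = fa_v * md_v * np.sqrt(3.0) / np.sqrt(1.0 - 2.0 * fa_v ** 2 / 3.0)
        l1 = md_v + 2.0 * d / 3.0
        l2 = md_v - d / 3.0
        gv = dirs @ v                          # (n_vol,)
        quad = l2[:, None] + (l1 - l2)[:, None] * (gv ** 2)[None, :]
        s0 = spec.regions[name].s0
        signal[sel] = s0 * np.exp(-bvals[None, :] * quad)

    if np.isfinite(spec.snr_dwi):
        s0_mean = float(np.mean([p.s0 for p in spec.regions.values()]))
        sigma = s0_mean / spec.snr_dwi
        noise_r = rng.normal(0.0, sigma, signal.shape)
        noise_i = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + noise_r) ** 2 + noise_i ** 2)

    return signal.reshape(shape + (len(bvals),)), (dirs, bvals)


# ---------------------------------------------------------------------------
# DSC simulation

_FINE_DT = 0.01


def gamma_variate_aif(t: np.ndarray, t0: float, alpha: float, beta: float,
                      peak_conc: float = 1.0) -> np.ndarray:
    """Gamma-variate bolus (t-t0)^alpha exp(-(t-t0)/beta), peak-normalized."""
    t = np.asarray(t, dtype=float)
    x = np.clip(t - t0, 0.0, None)
    c = x ** alpha * np.exp(-x / beta)
    peak = (alpha * beta) ** alpha * np.exp(-alpha)  # analytic mode value
    return peak_conc * c / peak


def _tissue_curve_fine(spec: PhantomSpec, scheme: AcquisitionScheme):
    """(fine time grid, normalized AIF*residue convolution) on that grid."""
    t_end = (scheme.dsc_n_timepoints + 5) * scheme.dsc_tr
    tf = np.arange(0.0, t_end, _FINE_DT)
    a = gamma_variate_aif(tf, spec.aif["t0"], spec.aif["alpha"],
                          spec.aif["beta"])
    r = np.exp(-tf / spec.mtt)
    b = np.convolve(a, r)[: tf.size] * _FINE_DT
    b *= spec.tissue_peak_conc / b.max()
    return tf, b


@functools.lru_cache(maxsize=8)
def _calibrate_cached(key) -> float:
    (tr, te, ntp, t0, alpha, beta, mtt, peak, thr) = key
    scheme = AcquisitionScheme(dsc_tr=tr, dsc_te=te, dsc_n_timepoints=ntp)
    spec = PhantomSpec(aif=dict(t0=t0, alpha=alpha, beta=beta, peak_conc=48.0),
                       mtt=mtt, tissue_peak_conc=peak, threshold_frac=thr)
    tf, bfine = _tissue_curve_fine(spec, scheme)
    t = scheme.dsc_times
    aif = gamma_variate_aif(t, t0, alpha, beta, spec.aif.get("peak_conc", 48.0))
    # reference fractional delays in the middle of the window
    refs = [4.9, 5.6, 6.2]
    offs = []
    for d in refs:
        tissue = np.interp(t - d, tf, bfine, left=0.0)
        k = dsc_mod.deconvolve_osvd(tissue, aif, tr, thr)
        offs.append(dsc_mod.tmax_from_residue(k, tr, interpolate=True) - d)
    return float(np.mean(offs))


def calibrate_delay_offset(spec: PhantomSpec, scheme: AcquisitionScheme) -> float:
    """Constant peak offset of the deconvolved residue (s).

    Measured once per (AIF shape, MTT, TR, threshold) by planting reference
    delays, running the package's own deconvolver noiselessly and averaging
    recovered-minus-planted.  Subtracting it when planting delays makes the
    deconvolved peak land on the true Tmax.
    """
    key = (scheme.dsc_tr, scheme.dsc_te, scheme.dsc_n_timepoints,
           spec.aif["t0"], spec.aif["alpha"], spec.aif["beta"],
           spec.mtt, spec.tissue_peak_conc, spec.threshold_frac)
    return _calibrate_cached(key)


def simulate_dsc(spec: PhantomSpec, scheme: AcquisitionScheme,
                 truth: GroundTruth, seed: int):
    """4D DSC signal, the true AIF concentration curve, and AIF voxel indices.

    The AIF is embedded in a small corner block of voxels (outside the brain
    parenchyma labels) whose signal follows the arterial concentration.
    """
    if truth.label_map.shape != tuple(spec.grid_shape):
        raise ValueError("truth grid does not match spec grid")
    rng = np.random.default_rng(seed)
    t = scheme.dsc_times
    tau = calibrate_delay_offset(spec, scheme)
    delays = truth.true_tmax.reshape(-1) - tau
    max_delay = float(np.max(delays))
    if max_delay > t[-1] - spec.aif["t0"]:
        raise ValueError("planted delay exceeds the acquisition window")

    tf, bfine = _tissue_curve_fine(spec, scheme)
    sample_t = t[None, :] - delays[:, None]
    conc = np.interp(sample_t.ravel(), tf, bfine, left=0.0).reshape(sample_t.shape)

    flat_lab = truth.label_map.reshape(-1)
    s0 = np.full(flat_lab.shape, 100.0)
    for name, code in REGION_CODES.items():
        s0[flat_lab == code] = spec.regions[name].s0
    signal = s0[:, None] * np.exp(-scheme.dsc_te * conc)

    aif_curve = gamma_variate_aif(t, spec.aif["t0"], spec.aif["alpha"],
                                  spec.aif["beta"], spec.aif["peak_conc"])
    # embed arterial voxels in the (0, 0, 0) corner
    nx, ny, nz = spec.grid_shape
    aif_voxels = np.array([[0, 0, 0], [1, 0, 0]][: max(1, min(2, nx))])
    signal = signal.reshape(spec.grid_shape + (t.size,))
    for vx in aif_voxels:
        signal[tuple(vx)] = 100.0 * np.exp(-scheme.dsc_te * aif_curve)

    if spec.dsc_noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.dsc_noise_sd, signal.shape)
    return signal, aif_curve, aif_voxels


# ---------------------------------------------------------------------------
# cohort

def simulate_subject(spec: PhantomSpec, scheme: AcquisitionScheme,
                     subject_index: int) -> SubjectData:
    """Simulate one subject; deterministic in (spec.seed, subject_index)."""
    rng = np.random.default_rng([spec.seed, subject_index])
    truth = draw_subject_truth(spec, rng)
    dwi_seed = int(rng.integers(2 ** 31))
    dsc_seed = int(rng.integers(2 ** 31))
    dwi, _ = simulate_dwi(spec, scheme, truth, dwi_seed)
    dsc, aif_curve, aif_voxels = simulate_dsc(spec, scheme, truth, dsc_seed)
    _, masks = build_geometry(spec.grid_shape)
    masks = dict(masks)
    for vx in aif_voxels:  # arterial voxels are not parenchyma
        masks["brain"][tuple(vx)] = False
    return SubjectData(subject_id=f"sub-{subject_index + 1:02d}",
                       truth=truth, dwi=dwi, dsc=dsc, aif_curve=aif_curve,
                       aif_voxels=aif_voxels, masks=masks, scheme=scheme)


def generate_cohort(spec: PhantomSpec, scheme: AcquisitionScheme | None = None,
                    out_dir=None) -> list[SubjectData]:
    """Simulate all subjects of a cohort; optionally write bundles to disk.

    When ``out_dir`` is given, each subject's DWI / DSC / truth maps / masks
    are written as NIfTI with FSL-style bval/bvec text files, the AIF as a
    single-column text file, and the per-subject region truths as one
    cohort-level TSV (see :mod:`wmischemia.io`).
    """
    scheme = scheme or AcquisitionScheme()
    subjects = [simulate_subject(spec, scheme, i)
                for i in range(spec.n_subjects)]
    if out_dir is not None:
        from . import io as io_mod
        io_mod.write_cohort(subjects, spec, out_dir)
    return subjects


def _copula_param(rho_s: float, n: int | None) -> float:
    """Gaussian-copula Pearson parameter for a target Spearman value.

    With ``n`` given, the parameter is chosen so the *expected sample*
    Spearman coefficient of an n-pair draw equals ``rho_s``, using the exact
    bivariate-normal result E[r_s] = 6/(pi (n+1)) * ((n-2) asin(rho/2) +
    asin(rho)); the sample estimator is attenuated toward zero at small n, and
    published coefficients are themselves sample statistics.  With ``n=None``
    the large-n relation rho = 2 sin(pi rho_s / 6) is used.
    """
    if n is None:
        return 2.0 * np.sin(np.pi * rho_s / 6.0)
    from scipy.optimize import brentq

    def expected(r):
        return (6.0 / (np.pi * (n + 1))
                * ((n - 2) * np.arcsin(r / 2.0) + np.arcsin(r)))

    sign = 1.0 if rho_s >= 0 else -1.0
    return sign * brentq(lambda r: expected(r) - abs(rho_s), 0.0, 0.999999)


def simulate_correlated_pairs(rho_s: float, n: int,
                              rng: np.random.Generator,
                              marginals: tuple | None = None,
                              debias: bool = True):
    """Draw n bivariate (Tmax, FA) pairs from a Gaussian copula calibrated to
    Spearman rank correlation ``rho_s``.

    With ``debias=True`` (default) the copula parameter is set so the expected
    *sample* Spearman coefficient at size n equals ``rho_s`` (see
    :func:`_copula_param`).  ``marginals`` may give two callables mapping
    uniforms to values; by default the hypoperfused region's Tmax and FA
    normal marginals are used (any strictly monotone choice leaves the rank
    correlation untouched).
    """
    r = _copula_param(rho_s, n if debias else None)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    u = sps.norm.cdf(z)
    if marginals is None:
        p = dflt.REGION_DEFAULTS["hypoperfused_wm"]
        marginals = (
            lambda q: sps.norm.ppf(q, loc=p["tmax_mean"], scale=p["tmax_sd"]),
            lambda q: sps.norm.ppf(q, loc=p["fa_mean"], scale=p["fa_sd"]),
        )
    return marginals[0](u[:, 0]), marginals[1](u[:, 1])


def region_truth_table(subjects: list[SubjectData]):
    """Tidy DataFrame of per-subject, per-region planted values."""
    import pandas as pd

    rows = []
    for s in subjects:
        for region, vals in s.truth.region_values.items():
            rows.append(dict(subject=s.subject_id, region=region,
                             fa=vals["fa"], md=vals["md"], tmax=vals["tmax"]))
    return pd.DataFrame(rows)
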