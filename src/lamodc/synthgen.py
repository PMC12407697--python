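"""Synthetic cortical patches, ocular dominance maps and laminar fMRI runs.

The generator produces everything the downstream analysis consumes without
scanner data: a small cortical patch (two boundary surfaces plus intermediate
depth surfaces on a regular vertex grid), a columnar eye-preference map
confined to the V1-labelled region, and block-design time series whose
depth-dependent amplitude, spatial point spread and noise mimic GE-BOLD-,
SE-BOLD- and VASO-like acquisitions, including nulled/not-nulled volume
pairs for VASO.

Signal model for one run (baseline level fixed at 100 a.u.)::

    S(v, d, t) = 100 * (1 + a(d) * p_d(v) * (rL(t) - rR(t))
                          + b(d, v) * (rL(t) + rR(t))) + AR(1) noise

where ``a(d)`` is the contrast-specific depth amplitude profile, ``p_d`` the
columnar preference map smoothed by the depth-specific vascular point spread,
``rL/rR`` the HRF-convolved boxcars of left/right eye stimulation, and ``b``
an eye-symmetric, depth-scaled coarse venous bias.  LEFT stimulation drives
left-preferring vertices (preference > 0) positively and right-preferring
vertices negatively; RIGHT stimulation mirrors this.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .design import CONDITIONS, HrfSpec, RunDesign, condition_regressors

GE_BOLD = "GE_BOLD"
SE_BOLD = "SE_BOLD"
VASO = "VASO"
CONTRASTS = (GE_BOLD, SE_BOLD, VASO)

REGIONS = ("V1", "V2a", "V2b", "V3a", "V3b")
DEFAULT_LAYOUT = tuple((r, 0.2) for r in REGIONS)


class AliasingError(ValueError):
    """Columnar period not resolvable on the vertex grid."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CortexPatch:
    """Regular-grid cortical patch with boundary surfaces and region labels.

    Vertices are stored in row-major order (row ``iy``, column ``ix`` maps to
    index ``iy * n_x + ix``).  ``depth_fractions`` run from 0 (GM/WM) to 1
    (GM/CSF, pial).
    """

    n_x: int
    n_y: int
    spacing_mm: float
    region_label: np.ndarray
    inner_surface: np.ndarray
    outer_surface: np.ndarray
    depth_fractions: np.ndarray

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if self.inner_surface.shape != self.outer_surface.shape:
            raise ValueError("inner and outer surfaces must share vertex count")
        frac = np.asarray(self.depth_fractions)
        if frac[0] != 0.0 or frac[-1] != 1.0 or np.any(np.diff(frac) <= 0):
            raise ValueError("depth_fractions must strictly increase from 0 to 1")

    @property
    def n_vertices(self) -> int:
        return self.n_x * self.n_y

    @property
    def n_depths(self) -> int:
        return len(self.depth_fractions)

    def grid(self, values: np.ndarray) -> np.ndarray:
        """Fold a per-vertex array onto the (n_y, n_x) grid."""
        return np.asarray(values).reshape(self.n_y, self.n_x)


@dataclass(frozen=True)
class ColumnarMap:
    """Per-vertex ocular preference in [-1, 1]; zero outside V1."""

    preference: np.ndarray
    period_mm: float
    anisotropy: float
    sigmoid_gain: float
    seed: int


@dataclass(frozen=True)
class AcquisitionModel:
    """Contrast-specific depth behaviour of amplitude, point spread and noise.

    ``amplitude_base`` is the peak fractional signal change of the ocular
    response at depth 0.  BOLD-like contrasts gain linearly toward the pial
    surface (``pial_slope``); the VASO-like amplitude is a Gaussian bump at
    ``mid_peak_depth`` plus a small pial trend (reusing ``pial_slope`` as the
    trend coefficient).  Point-spread FWHM and temporal noise SD interpolate
    linearly between their deep (depth 0) and pial (depth 1) values.  Noise
    SDs are in the same arbitrary units as the 100 a.u. baseline.
    """

    contrast: str
    tr_s: float
    amplitude_base: float
    pial_slope: float
    mid_peak_depth: float = 0.5
    mid_peak_width: float = 0.25
    psf_fwhm_deep_mm: float = 0.4
    psf_fwhm_pial_mm: float = 0.5
    venous_bias_amp: float = 0.0
    noise_sigma_deep: float = 6.0
    noise_sigma_pial: float = 7.0
    ar1_coef: float = 0.3
    sign: int = 1

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}")
        for name in ("tr_s", "mid_peak_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # zero point spread / noise = idealized noiseless limits
        for name in ("psf_fwhm_deep_mm", "psf_fwhm_pial_mm",
                     "noise_sigma_deep", "noise_sigma_pial"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.contrast in (GE_BOLD, SE_BOLD) and self.psf_fwhm_pial_mm < self.psf_fwhm_deep_mm:
            raise ValueError("BOLD-like point spread must not shrink toward the pial surface")
        if (self.sign == -1) != (self.contrast == VASO):
            raise ValueError("sign must be -1 exactly for the VASO (nulled) contrast")

    @classmethod
    def ge_bold(cls, **kw) -> "AcquisitionModel":
        defaults = dict(contrast=GE_BOLD, tr_s=3.0, amplitude_base=0.006,
                        pial_slope=4.0, psf_fwhm_deep_mm=0.40, psf_fwhm_pial_mm=0.45,
                        venous_bias_amp=0.010, noise_sigma_deep=6.0,
                        noise_sigma_pial=7.0, ar1_coef=0.3, sign=1)
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def se_bold(cls, **kw) -> "AcquisitionModel":
        defaults = dict(contrast=SE_BOLD, tr_s=3.0, amplitude_base=0.004,
                        pial_slope=2.5, psf_fwhm_deep_mm=0.30, psf_fwhm_pial_mm=0.40,
                        venous_bias_amp=0.005, noise_sigma_deep=6.5,
                        noise_sigma_pial=7.5, ar1_coef=0.3, sign=1)
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def vaso(cls, **kw) -> "AcquisitionModel":
        defaults = dict(contrast=VASO, tr_s=5.0, amplitude_base=0.007,
                        pial_slope=0.2, mid_peak_depth=0.4, mid_peak_width=0.22,
                        psf_fwhm_deep_mm=0.30, psf_fwhm_pial_mm=0.35,
                        venous_bias_amp=0.002, noise_sigma_deep=8.0,
                        noise_sigma_pial=9.0, ar1_coef=0.3, sign=-1)
        defaults.update(kw)
        return cls(**defaults)


@dataclass(frozen=True)
class LaminarTimeSeries:
    """vertices x depths x time array with acquisition timestamps."""

    values: np.ndarray
    tr_s: float
    timestamps_s: np.ndarray
    depth_fractions: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps_s)
        if ts.size != self.values.shape[-1]:
            raise ValueError("timestamps must match the time dimension")
        if ts.size > 1 and np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[-1]

    def with_values(self, values: np.ndarray) -> "LaminarTimeSeries":
        return replace(self, values=values)


@dataclass(frozen=True)
class StudySpec:
    """Session/run replication structure of a multi-contrast ODC study."""

    n_participants: int = 1
    sessions_per_contrast: int = 2
    runs_per_session: int = 10
    contrasts: tuple[str, ...] = (GE_BOLD,)
    amplitude_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.sessions_per_contrast, self.runs_per_session) < 1:
            raise ValueError("participant/session/run counts must be >= 1")
        for c in self.contrasts:
            if c not in CONTRASTS:
                raise ValueError(f"unknown contrast {c!r}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def make_cortex_patch(n_x: int = 100, n_y: int = 100, spacing_mm: float = 0.3,
                      thickness_mm: float = 2.0, curvature_amp: float = 0.0,
                      region_layout=None, n_intermediate: int = 9) -> CortexPatch:
    """Build a synthetic cortical patch (flat or gently undulating slab).

    ``region_layout`` maps region labels to area fractions (ordered); columns
    of the grid are assigned left to right in layout order so that V2a is
    adjacent to V1 and V3a to V2b.  Unassigned columns are labelled "none".
    """
    if n_x < 8 or n_y < 8:
        raise ValueError("n_x and n_y must be at least 8")
    if thickness_mm <= 0 or spacing_mm <= 0:
        raise ValueError("thickness_mm and spacing_mm must be positive")
    layout = DEFAULT_LAYOUT if region_layout is None else tuple(
        region_layout.items() if isinstance(region_layout, dict) else region_layout)
    total = sum(f for _, f in layout)
    if total > 1.0 + 1e-9 or any(f < 0 for _, f in layout):
        raise ValueError("region fractions must be non-negative and sum to at most 1")

    ix = np.arange(n_x) * spacing_mm
    iy = np.arange(n_y) * spacing_mm
    X, Y = np.meshgrid(ix, iy)
    wavelength = max(n_x, n_y) * spacing_mm / 2.0
    z_inner = curvature_amp * np.sin(2 * np.pi * X / wavelength) * np.cos(2 * np.pi * Y / wavelength)
    inner = np.column_stack([X.ravel(), Y.ravel(), z_inner.ravel()])
    outer = inner + np.array([0.0, 0.0, thickness_mm])

    labels_cols = np.full(n_x, "none", dtype=object)
    cum = 0.0
    start = 0
    for name, frac in layout:
        cum += frac
        stop = int(round(cum * n_x))
        labels_cols[start:stop] = name
        start = stop
    region_label = np.tile(np.asarray(labels_cols, dtype="U4"), n_y)

    fractions = np.linspace(0.0, 1.0, n_intermediate + 2)
    return CortexPatch(n_x=n_x, n_y=n_y, spacing_mm=spacing_mm,
                       region_label=region_label, inner_surface=inner,
                       outer_surface=outer, depth_fractions=fractions)


def _bandpass_noise(n_y: int, n_x: int, spacing_mm: float, period_mm: float,
                    anisotropy: float, band_rel_width: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Band-pass-filtered Gaussian white noise on the vertex grid."""
    noise = rng.standard_normal((n_y, n_x))
    fx = np.fft.fftfreq(n_x, d=spacing_mm)
    fy = np.fft.fftfreq(n_y, d=spacing_mm)
    FX, FY = np.meshgrid(fx, fy)
    f = np.sqrt(FX ** 2 + (FY * anisotropy) ** 2)
    f0 = 1.0 / period_mm
    H = np.exp(-0.5 * ((f - f0) / (band_rel_width * f0)) ** 2)
    return np.real(np.fft.ifft2(np.fft.fft2(noise) * H))


def simulate_odc_pattern(patch: CortexPatch, period_mm: float = 1.0,
                         anisotropy: float = 1.0, sigmoid_gain: float = 3.0,
                         seed: int = 0, band_rel_width: float = 0.25) -> ColumnarMap:
    """Columnar eye-preference map: band-pass-filtered noise through a sigmoid.

    The map's radially averaged spatial amplitude spectrum peaks near
    ``1/period_mm`` cycles/mm; preference is identically zero outside V1.
    """
    if period_mm <= 2 * patch.spacing_mm:
        raise AliasingError(
            f"period_mm={period_mm} is not resolvable at spacing {patch.spacing_mm} mm")
    rng = np.random.default_rng(seed)
    filt = _bandpass_noise(patch.n_y, patch.n_x, patch.spacing_mm, period_mm,
                           anisotropy, band_rel_width, rng).ravel()
    in_v1 = patch.region_label == "V1"
    if not in_v1.any():
        raise ValueError("patch has no V1-labelled vertices")
    z = filt / filt[in_v1].std()
    pref = np.sign(z) if np.isinf(sigmoid_gain) else np.tanh(sigmoid_gain * z)
    pref = np.where(in_v1, pref, 0.0)
    return ColumnarMap(preference=pref, period_mm=period_mm, anisotropy=anisotropy,
                       sigmoid_gain=sigmoid_gain, seed=seed)


def depth_response(model: AcquisitionModel, depth_fraction) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(amplitude, psf_fwhm_mm, noise_sigma) at the given depth fraction(s).

    BOLD-like: amplitude_base * (1 + pial_slope * d), strictly increasing for
    positive slope.  VASO-like: Gaussian bump centred at ``mid_peak_depth``
    plus a small linear pial trend.  Point spread and noise interpolate
    linearly between their deep and pial values.
    """
    d = np.asarray(depth_fraction, dtype=float)
    if np.any(d < 0) or np.any(d > 1):
        raise ValueError("depth_fraction must lie in [0, 1]")
    if model.contrast == VASO:
        bump = np.exp(-0.5 * ((d - model.mid_peak_depth) / model.mid_peak_width) ** 2)
        amp = model.amplitude_base * (bump + model.pial_slope * d)
    else:
        amp = model.amplitude_base * (1.0 + model.pial_slope * d)
    fwhm = model.psf_fwhm_deep_mm + (model.psf_fwhm_pial_mm - model.psf_fwhm_deep_mm) * d
    sigma = model.noise_sigma_deep + (model.noise_sigma_pial - model.noise_sigma_deep) * d
    return amp, fwhm, sigma


def _smooth_grid(grid: np.ndarray, fwhm_mm: float, spacing_mm: float) -> np.ndarray:
    if fwhm_mm <= 0:
        return grid.copy()
    sigma_px = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / spacing_mm
    return ndimage.gaussian_filter(grid, sigma=sigma_px, mode="nearest")


def _depth_patterns(patch: CortexPatch, cmap: ColumnarMap, model: AcquisitionModel,
                    fractions: np.ndarray):
    """Per-depth smoothed preference pattern and coarse eye-symmetric bias."""
    pref_grid = patch.grid(cmap.preference)
    coarse = _smooth_grid(np.abs(pref_grid), 3.0, patch.spacing_mm)
    peak = coarse.max()
    if peak > 0:
        coarse = coarse / peak
    amps, fwhms, sigmas = depth_response(model, fractions)
    patterns = np.stack([
        _smooth_grid(pref_grid, fwhm, patch.spacing_mm).ravel() for fwhm in np.atleast_1d(fwhms)
    ], axis=1)  # (V, D)
    biases = model.venous_bias_amp * np.atleast_1d(fractions)[None, :] * coarse.ravel()[:, None]
    return np.atleast_1d(amps), patterns, biases, np.atleast_1d(sigmas)


def _ar1_noise(shape: tuple[int, ...], sigma_per_depth: np.ndarray, ar1: float,
               rng: np.random.Generator) -> np.ndarray:
    """AR(1) Gaussian noise with stationary SD ``sigma_per_depth`` (depth axis 1)."""
    eps = rng.standard_normal(shape) * sigma_per_depth[None, :, None]
    if ar1 == 0:
        return eps
    out = np.empty_like(eps)
    out[..., 0] = eps[..., 0]
    scale = np.sqrt(1.0 - ar1 ** 2)
    for t in range(1, shape[-1]):
        out[..., t] = ar1 * out[..., t - 1] + scale * eps[..., t]
    return out


BASELINE = 100.0


def simulate_run(patch: CortexPatch, cmap: ColumnarMap, design: RunDesign,
                 model: AcquisitionModel, depth_fractions=None, seed: int = 0,
                 hrf: HrfSpec | None = None, return_truth: bool = False):
    """Simulate one BOLD-like mapping run as a laminar time series.

    Returns a :class:`LaminarTimeSeries` of shape (n_vertices, n_depths,
    n_volumes); with ``return_truth`` also a dict holding the noiseless
    per-depth amplitudes and smoothed patterns the analysis should recover.
    """
    fractions = np.asarray(patch.depth_fractions if depth_fractions is None else depth_fractions,
                           dtype=float)
    if cmap.preference.shape[0] != patch.n_vertices:
        raise ValueError("columnar map does not match the patch vertex count")
    reg = condition_regressors(design, hrf=hrf)
    diff = reg["LEFT"] - reg["RIGHT"]
    total = reg["LEFT"] + reg["RIGHT"]
    amps, patterns, biases, sigmas = _depth_patterns(patch, cmap, model, fractions)

    modulation = (amps[None, :] * patterns)[:, :, None] * diff[None, None, :]
    modulation += biases[:, :, None] * total[None, None, :]
    values = BASELINE * (1.0 + modulation)
    rng = np.random.default_rng(seed)
    values = values + _ar1_noise(values.shape, sigmas, model.ar1_coef, rng)

    series = LaminarTimeSeries(values=values, tr_s=design.tr_s,
                               timestamps_s=design.volume_times(),
                               depth_fractions=fractions)
    if return_truth:
        truth = {"amplitudes": amps, "patterns": patterns, "biases": biases,
                 "regressors": reg}
        return series, truth
    return series


def simulate_vaso_pair(patch: CortexPatch, cmap: ColumnarMap, design: RunDesign,
                       model: AcquisitionModel, seed: int = 0,
                       bold_amp: float = 0.05, hrf: HrfSpec | None = None,
                       aligned_timestamps: bool = False,
                       return_truth: bool = False):
    """Simulate a VASO nulled/not-nulled volume pair for one run.

    ``not_nulled(t) = B * (1 + bold(t))`` and
    ``nulled(t) = B * (1 + bold(t)) * (1 - cbv(t))`` with independent noise,
    where ``cbv`` is the CBV-weighted columnar response (VASO depth profile)
    and ``bold`` a shared eye-unspecific BOLD contamination term growing
    toward the pial surface.  By default the not-nulled volumes are offset by
    half the pair TR; ``aligned_timestamps`` samples both at the same times.
    """
    if model.contrast != VASO:
        raise ValueError("simulate_vaso_pair requires a VASO acquisition model")
    fractions = np.asarray(patch.depth_fractions, dtype=float)
    pair_tr = model.tr_s
    n_pairs = int(round(design.run_duration_s / pair_tr))
    t_nulled = np.arange(n_pairs) * pair_tr
    t_nn = t_nulled if aligned_timestamps else t_nulled + pair_tr / 2.0

    amps, patterns, biases, sigmas = _depth_patterns(patch, cmap, model, fractions)
    rng = np.random.default_rng(seed)

    def cbv_at(times: np.ndarray) -> np.ndarray:
        reg = condition_regressors(design, hrf=hrf, times=times)
        diff = reg["LEFT"] - reg["RIGHT"]
        total = reg["LEFT"] + reg["RIGHT"]
        return ((amps[None, :] * patterns)[:, :, None] * diff[None, None, :]
                + biases[:, :, None] * total[None, None, :])

    def bold_at(times: np.ndarray) -> np.ndarray:
        reg = condition_regressors(design, hrf=hrf, times=times)
        total = (reg["LEFT"] + reg["RIGHT"]) / 2.0
        return bold_amp * (1.0 + 2.0 * fractions)[None, :, None] * total[None, None, :]

    cbv_n = cbv_at(t_nulled)
    nulled_vals = BASELINE * (1.0 + bold_at(t_nulled)) * (1.0 - cbv_n)
    nn_vals = np.broadcast_to(BASELINE * (1.0 + bold_at(t_nn)),
                              nulled_vals.shape).copy()
    nulled_vals = nulled_vals + _ar1_noise(nulled_vals.shape, sigmas, model.ar1_coef, rng)
    nn_vals = nn_vals + _ar1_noise(nn_vals.shape, sigmas, model.ar1_coef, rng)

    nulled = LaminarTimeSeries(values=nulled_vals, tr_s=pair_tr,
                               timestamps_s=t_nulled, depth_fractions=fractions)
    not_nulled = LaminarTimeSeries(values=nn_vals, tr_s=pair_tr,
                                   timestamps_s=t_nn, depth_fractions=fractions)
    if return_truth:
        truth = {"cbv_nulled_times": cbv_n, "amplitudes": amps, "patterns": patterns}
        return nulled, not_nulled, truth
    return nulled, not_nulled


# ---------------------------------------------------------------------------
# on-disk study generation
# ---------------------------------------------------------------------------

def _nifti_affine(patch: CortexPatch) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = patch.spacing_mm
    return aff


def series_to_volume(patch: CortexPatch, series: LaminarTimeSeries) -> np.ndarray:
    """Fold a (V, D, T) series into an (n_x, n_y, D, T) volume grid."""
    v = series.values
    return v.reshape(patch.n_y, patch.n_x, v.shape[1], v.shape[2]).transpose(1, 0, 2, 3)


def volume_to_series(patch: CortexPatch, volume: np.ndarray, tr_s: float,
                     timestamps_s=None) -> LaminarTimeSeries:
    """Inverse of :func:`series_to_volume`."""
    vals = volume.transpose(1, 0, 2, 3).reshape(patch.n_vertices, volume.shape[2],
                                                volume.shape[3])
    if timestamps_s is None:
        timestamps_s = np.arange(volume.shape[3]) * tr_s
    return LaminarTimeSeries(values=vals, tr_s=tr_s, timestamps_s=np.asarray(timestamps_s),
                             depth_fractions=patch.depth_fractions)


def write_surface_text(path: Path, coords: np.ndarray) -> None:
    """Plain-text surface format: one header line, then x y z per vertex."""
    with open(path, "w") as fh:
        fh.write(f"# vertices {coords.shape[0]}\n")
        np.savetxt(fh, coords, fmt="%.6f")


def simulate_study(spec: StudySpec, out_dir, patch: CortexPatch | None = None,
                   models: dict[str, AcquisitionModel] | None = None,
                   odc_kwargs: dict | None = None) -> dict:
    """Write a full synthetic study (NIfTI runs, surfaces, JSON manifest).

    Both sessions of a contrast reuse the participant's columnar map with
    independent noise, pseudorandomized block orders and a session-level
    multiplicative amplitude jitter.  Fully deterministic given ``spec.seed``.
    """
    import nibabel as nib

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as err:  # pragma: no cover - exercised only on bad paths
        raise IOError(f"cannot create study directory {out}: {err}") from err

    patch = patch or make_cortex_patch()
    models = models or {GE_BOLD: AcquisitionModel.ge_bold(),
                        SE_BOLD: AcquisitionModel.se_bold(),
                        VASO: AcquisitionModel.vaso()}
    odc_kwargs = odc_kwargs or {}
    root_ss = np.random.SeedSequence(spec.seed)
    aff = _nifti_affine(patch)

    surf_dir = out / "surfaces"
    surf_dir.mkdir(exist_ok=True)
    write_surface_text(surf_dir / "inner.txt", patch.inner_surface)
    write_surface_text(surf_dir / "outer.txt", patch.outer_surface)

    manifest: dict = {"seed": spec.seed, "patch": {"n_x": patch.n_x, "n_y": patch.n_y,
                      "spacing_mm": patch.spacing_mm},
                      "depth_fractions": patch.depth_fractions.tolist(),
                      "participants": []}
    rng = np.random.default_rng(root_ss)
    for p in range(spec.n_participants):
        map_seed = int(rng.integers(0, 2 ** 31 - 1))
        cmap = simulate_odc_pattern(patch, seed=map_seed, **odc_kwargs)
        p_entry = {"id": f"sub-{p + 1:02d}", "map_seed": map_seed, "sessions": []}
        for contrast in spec.contrasts:
            model = models[contrast]
            for s in range(spec.sessions_per_contrast):
                jitter = 1.0 + spec.amplitude_jitter_sd * float(rng.standard_normal())
                sess_model = replace(model, amplitude_base=model.amplitude_base * max(jitter, 0.0))
                sess = {"contrast": contrast, "session": s + 1,
                        "amplitude_scale": max(jitter, 0.0), "runs": []}
                for r in range(spec.runs_per_session):
                    run_seed = int(rng.integers(0, 2 ** 31 - 1))
                    design = RunDesign.pseudorandom(run_seed, tr_s=model.tr_s)
                    stem = f"{p_entry['id']}_{contrast}_ses-{s + 1}_run-{r + 1:02d}"
                    run_entry = {"seed": run_seed, "conditions": list(design.conditions)}
                    if contrast == VASO:
                        nulled, nn = simulate_vaso_pair(patch, cmap, design, sess_model,
                                                        seed=run_seed)
                        for tag, ser in (("nulled", nulled), ("notnulled", nn)):
                            img = nib.Nifti1Image(series_to_volume(patch, ser), aff)
                            fname = f"{stem}_{tag}.nii"
                            nib.save(img, out / fname)
                            run_entry[tag] = fname
                            run_entry[f"{tag}_timestamps_s"] = ser.timestamps_s.tolist()
                    else:
                        ser = simulate_run(patch, cmap, design, sess_model, seed=run_seed)
                        img = nib.Nifti1Image(series_to_volume(patch, ser), aff)
                        fname = f"{stem}.nii"
                        nib.save(img, out / fname)
                        run_entry["file"] = fname
                    sess["runs"].append(run_entry)
                p_entry["sessions"].append(sess)
        manifest["participants"].append(p_entry)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
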