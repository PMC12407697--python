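"""Temporal filtering, GLM contrast maps and phase-encoded retinotopy.

High-pass filtering regresses out a discrete-cosine drift basis (all DCT
components with period longer than the cutoff period, plus the constant) and
re-adds the temporal mean, so constants are preserved and the filter is an
exact projection (idempotent).

The GLM fits HRF-convolved left/right-eye boxcars plus per-run constants by
ordinary least squares; the left>right z-map and per-condition percent signal
changes feed the repeatability analysis and depth profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import CONDITIONS, HrfSpec, RunDesign, condition_regressors
from .synthgen import LaminarTimeSeries


@dataclass(frozen=True)
class ContrastMap:
    """Per-vertex, per-depth GLM results for the left > right eye contrast."""

    z: np.ndarray
    psc_left: np.ndarray
    psc_right: np.ndarray


def _dct_basis(n_vol: int, tr_s: float, cutoff_hz: float) -> np.ndarray:
    duration = n_vol * tr_s
    order = int(np.floor(2.0 * duration * cutoff_hz + 1e-9))
    n = np.arange(n_vol)
    cols = [np.cos(np.pi * (2 * n + 1) * k / (2.0 * n_vol)) for k in range(1, order + 1)]
    return np.column_stack(cols) if cols else np.empty((n_vol, 0))


def highpass_filter(series, cutoff_hz: float, tr_s: float | None = None):
    """Remove slow drifts below ``cutoff_hz`` by DCT-basis regression.

    Accepts a :class:`LaminarTimeSeries` or a plain array with time on the
    last axis (then ``tr_s`` is required).  The original temporal mean is
    re-added after projection.
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be positive")
    is_series = isinstance(series, LaminarTimeSeries)
    values = series.values if is_series else np.asarray(series, dtype=float)
    tr = series.tr_s if is_series else tr_s
    if tr is None:
        raise ValueError("tr_s is required for array input")
    n_vol = values.shape[-1]
    if 1.0 / cutoff_hz > n_vol * tr + 1e-9:
        raise ValueError("cutoff period exceeds the run duration")
    basis = _dct_basis(n_vol, tr, cutoff_hz)
    mean = values.mean(axis=-1, keepdims=True)
    resid = values - mean
    if basis.shape[1]:
        # orthonormalize and project out
        q, _ = np.linalg.qr(basis - basis.mean(axis=0))
        flat = resid.reshape(-1, n_vol)
        resid = (flat - (flat @ q) @ q.T).reshape(values.shape)
    out = resid + mean
    return series.with_values(out) if is_series else out


def select_time_points(design: RunDesign, n_discard_transient: int = 2):
    """Volume indices inside stimulation blocks, minus the first transients.

    Returns ``(retained_indices, labels)``: indices of volumes whose
    acquisition window lies inside a condition block, with the first
    ``n_discard_transient`` volumes of every block discarded, and per-volume
    eye labels.  Counts are balanced across conditions by construction.
    """
    per_block = design.block_s / design.tr_s
    if abs(per_block - round(per_block)) > 1e-9:
        raise ValueError("tr_s must divide block_s")
    per_block = int(round(per_block))
    if design.n_blocks and n_discard_transient >= per_block:
        raise ValueError("discarding all volumes of each block")
    indices: list[int] = []
    labels: list[str] = []
    for onset, cond in zip(design.block_onsets(), design.conditions):
        first = int(round(onset / design.tr_s))
        for k in range(first + n_discard_transient, first + per_block):
            indices.append(k)
            labels.append(cond)
    return np.asarray(indices, dtype=int), np.asarray(labels)


def glm_contrast(series, designs, hrf: HrfSpec | None = None) -> ContrastMap:
    """Fixed-effects OLS GLM of one or more runs with left/right regressors.

    ``series``/``designs`` may be single objects or lists (runs pooled into
    one model with shared condition betas and per-run constants).  z is the
    left-minus-right contrast divided by its standard error (Gaussian
    approximation); PSC_c = 100 * beta_c * max(regressor_c) / beta_constant.
    """
    if isinstance(series, LaminarTimeSeries):
        series = [series]
        designs = [designs]
    if len(series) != len(designs) or not series:
        raise ValueError("series and designs must be equal-length, non-empty lists")
    reg_blocks = []
    const_blocks = []
    reg_max = {c: 0.0 for c in CONDITIONS}
    for i, (ser, des) in enumerate(zip(series, designs)):
        reg = condition_regressors(des, hrf=hrf, times=np.asarray(ser.timestamps_s, dtype=float))
        reg_blocks.append(np.column_stack([reg[c] for c in CONDITIONS]))
        for c in CONDITIONS:
            reg_max[c] = max(reg_max[c], float(np.max(np.abs(reg[c]))))
        const = np.zeros((ser.n_volumes, len(series)))
        const[:, i] = 1.0
        const_blocks.append(const)
    X = np.column_stack([np.vstack(reg_blocks), np.vstack(const_blocks)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient GLM design matrix")
    Y = np.concatenate([s.values.reshape(-1, s.n_volumes).T for s in series], axis=0)

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = max(Y.shape[0] - X.shape[1], 1)
    sigma2 = (resid ** 2).sum(axis=0) / dof
    c = np.zeros(X.shape[1])
    c[0], c[1] = 1.0, -1.0
    var_c = float(c @ xtx_inv @ c)
    # residual variance at machine-precision level (e.g. noiseless data)
    # carries no inferential information: report z = 0 there
    degenerate = sigma2 <= 1e-20 * np.mean(Y ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(~degenerate & (sigma2 > 0),
                     (c @ beta) / np.sqrt(sigma2 * var_c), 0.0)

    shape = series[0].values.shape[:2]
    b0 = beta[2:].mean(axis=0)
    psc = {}
    for j, cond in enumerate(CONDITIONS):
        with np.errstate(divide="ignore", invalid="ignore"):
            psc[cond] = np.where(b0 != 0, 100.0 * beta[j] * reg_max[cond] / b0, 0.0)
    return ContrastMap(z=z.reshape(shape),
                       psc_left=psc["LEFT"].reshape(shape),
                       psc_right=psc["RIGHT"].reshape(shape))


def phase_encoded_analysis(runs, directions, stim_freq_hz: float, tr_s: float):
    """Phase and coherence maps from phase-encoded (traveling-wave) runs.

    Each run (array with time on the last axis) has its first quarter
    stimulus cycle discarded; the complex Fourier coefficient at the stimulus
    frequency is extracted, coefficients of reversed-direction runs
    (direction -1) are conjugated to cancel the hemodynamic lag, and the
    coefficients are averaged.  Returns ``(phase, coherence)`` where phase is
    in radians (a forward-run response ``cos(2*pi*f*t - phase)``) and
    coherence is the coefficient magnitude over the RMS amplitude across all
    non-DC frequencies.
    """
    runs = [np.asarray(r, dtype=float) for r in runs]
    directions = list(directions)
    if len(runs) != len(directions) or not runs:
        raise ValueError("need one direction per run")
    n_t = {r.shape[-1] for r in runs}
    if len(n_t) != 1:
        raise ValueError("runs must have identical length")
    n_drop = int(round((1.0 / stim_freq_hz) / 4.0 / tr_s))
    coefs = []
    rms_acc = []
    for run, direction in zip(runs, directions):
        data = run[..., n_drop:]
        n = data.shape[-1]
        spec = np.fft.rfft(data, axis=-1) / n
        freqs = np.fft.rfftfreq(n, d=tr_s)
        bin_ix = int(np.argmin(np.abs(freqs - stim_freq_hz)))
        if bin_ix == 0:
            raise ValueError("stimulus frequency not resolvable in the retained window")
        coef = spec[..., bin_ix]
        if direction < 0:
            coef = np.conj(coef)
        coefs.append(coef)
        rms_acc.append(np.sqrt(np.mean(np.abs(spec[..., 1:]) ** 2, axis=-1)))
    avg = np.mean(coefs, axis=0)
    rms = np.mean(rms_acc, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        coherence = np.where(rms > 0, np.abs(avg) / rms, 0.0)
    phase = -np.angle(avg)
    return phase, coherence
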