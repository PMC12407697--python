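"""BOLD correction of VASO nulled/not-nulled volume pairs.

The nulled time series carries both the CBV-weighted response of interest and
BOLD contamination; the not-nulled series is purely BOLD-weighted.  Both are
temporally upsampled onto a common grid and the nulled volumes are divided by
the not-nulled volumes, which removes multiplicative BOLD contamination
exactly.  The output keeps the raw ratio sign convention (the corrected
signal *decreases* when CBV increases); display code may invert it.
"""

from __future__ import annotations

import numpy as np

from .synthgen import LaminarTimeSeries


def _interp_time(values: np.ndarray, old_t: np.ndarray, new_t: np.ndarray) -> np.ndarray:
    """Linear interpolation along the last axis with edge-value hold."""
    t = np.clip(new_t, old_t[0], old_t[-1])
    idx = np.searchsorted(old_t, t, side="right") - 1
    idx = np.clip(idx, 0, old_t.size - 2)
    t0 = old_t[idx]
    t1 = old_t[idx + 1]
    w = np.where(t1 > t0, (t - t0) / (t1 - t0), 0.0)
    return values[..., idx] * (1.0 - w) + values[..., idx + 1] * w


def temporal_upsample(series: LaminarTimeSeries, target_tr_s: float) -> LaminarTimeSeries:
    """Resample onto the grid {0, tr, 2tr, ...} spanning the original run.

    Linear interpolation in time; the first/last acquired volumes are held
    constant outside the sampled range.  The run duration is taken as
    ``n_volumes * tr_s`` of the input, so a 54-volume series at a 5 s pair TR
    resampled to 3 s yields 90 volumes.
    """
    if target_tr_s <= 0:
        raise ValueError("target_tr_s must be positive")
    if series.n_volumes < 2:
        raise ValueError("cannot upsample a single-volume series")
    duration = series.n_volumes * series.tr_s
    n_new = int(round(duration / target_tr_s))
    new_t = np.arange(n_new) * target_tr_s
    vals = _interp_time(series.values, np.asarray(series.timestamps_s, dtype=float), new_t)
    return LaminarTimeSeries(values=vals, tr_s=target_tr_s, timestamps_s=new_t,
                             depth_fractions=series.depth_fractions)


def bold_correct(nulled: LaminarTimeSeries, not_nulled: LaminarTimeSeries,
                 target_tr_s: float, guard_eps: float = 1e-3):
    """Upsample both series to a common grid and divide nulled by not-nulled.

    Returns ``(corrected, valid_mask)`` where ``valid_mask`` is a per-voxel
    (vertex x depth) boolean; a voxel is flagged invalid (not clamped) if the
    denominator magnitude drops below ``guard_eps`` times that voxel's
    temporal mean at any time point.
    """
    if guard_eps <= 0:
        raise ValueError("guard_eps must be positive")
    t_n = np.asarray(nulled.timestamps_s, dtype=float)
    t_nn = np.asarray(not_nulled.timestamps_s, dtype=float)
    if t_n[-1] < t_nn[0] or t_nn[-1] < t_n[0]:
        raise ValueError("nulled and not-nulled series do not overlap in time")
    up_n = temporal_upsample(nulled, target_tr_s)
    up_nn = temporal_upsample(not_nulled, target_tr_s)
    n_t = min(up_n.n_volumes, up_nn.n_volumes)
    num = up_n.values[..., :n_t]
    den = up_nn.values[..., :n_t]
    mean_den = np.abs(den).mean(axis=-1, keepdims=True)
    bad = np.abs(den) < guard_eps * mean_den
    valid_mask = ~bad.any(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    corrected = LaminarTimeSeries(values=ratio, tr_s=target_tr_s,
                                  timestamps_s=up_n.timestamps_s[:n_t],
                                  depth_fractions=nulled.depth_fractions)
    return corrected, valid_mask
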