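"""Block-design run timing and hemodynamic response modelling.

A mapping run consists of a baseline period at the start and end of the run
and a sequence of monocular stimulation blocks (LEFT / RIGHT eye).  The
neural drive of a block is modelled as a boxcar which is convolved with a
canonical double-gamma hemodynamic response function (HRF) to obtain the
expected fMRI response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma

LEFT = "LEFT"
RIGHT = "RIGHT"
CONDITIONS = (LEFT, RIGHT)


@dataclass(frozen=True)
class HrfSpec:
    """Canonical double-gamma HRF.

    Parameters follow the widely used canonical form: a positive gamma
    response peaking at ``peak_delay_s`` minus a scaled undershoot gamma
    peaking at ``undershoot_delay_s``.  ``undershoot_ratio`` is the
    peak-to-undershoot amplitude ratio (6 means undershoot = 1/6 of peak).
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 6.0
    duration_s: float = 32.0
    dt_s: float = 0.1

    def __post_init__(self) -> None:
        if self.duration_s < 32.0:
            raise ValueError("HRF kernel must span at least 32 s")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")

    def kernel(self) -> np.ndarray:
        """Sampled kernel at ``dt_s`` resolution; integrates to a positive value."""
        t = np.arange(0.0, self.duration_s, self.dt_s)
        peak = _gamma.pdf(t, a=self.peak_delay_s / self.peak_dispersion_s,
                          scale=self.peak_dispersion_s)
        under = _gamma.pdf(t, a=self.undershoot_delay_s / self.undershoot_dispersion_s,
                           scale=self.undershoot_dispersion_s)
        h = peak - under / self.undershoot_ratio
        if h.sum() <= 0:
            raise ValueError("HRF kernel must integrate to a positive value")
        return h


#: Alternate kernel resembling a CBV response: faster time-to-peak, no
#: post-stimulus undershoot.  Off by default; exposed as a control.
CBV_HRF = HrfSpec(peak_delay_s=5.0, undershoot_ratio=1e12, duration_s=40.0)


@dataclass(frozen=True)
class RunDesign:
    """Timing of one ODC mapping run.

    Default timing: 270 s run, 15 s baseline at the start and end, eight
    30 s monocular blocks (four per eye), one volume every ``tr_s`` seconds.
    """

    run_duration_s: float = 270.0
    baseline_s: float = 15.0
    block_s: float = 30.0
    n_blocks: int = 8
    conditions: tuple[str, ...] = (LEFT, RIGHT, LEFT, RIGHT, LEFT, RIGHT, LEFT, RIGHT)
    tr_s: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if len(self.conditions) != self.n_blocks:
            raise ValueError("conditions must have length n_blocks")
        if abs(2 * self.baseline_s + self.n_blocks * self.block_s - self.run_duration_s) > 1e-9:
            raise ValueError(
                "timing inconsistency: 2*baseline_s + n_blocks*block_s must equal run_duration_s"
            )
        counts = {c: self.conditions.count(c) for c in set(self.conditions)}
        if set(counts) - set(CONDITIONS):
            raise ValueError(f"unknown condition labels: {set(counts) - set(CONDITIONS)}")
        if self.n_blocks and len(set(counts.values())) > 1:
            raise ValueError("each condition must appear equally often")
        n_vol = self.run_duration_s / self.tr_s
        if abs(n_vol - round(n_vol)) > 1e-9:
            raise ValueError("run_duration_s must be divisible by tr_s")

    @classmethod
    def pseudorandom(cls, seed: int, **kwargs) -> "RunDesign":
        """Balanced pseudorandom block order, deterministic given ``seed``."""
        proto = cls(**kwargs) if kwargs else cls()
        conds = np.array(proto.conditions)
        rng = np.random.default_rng(seed)
        rng.shuffle(conds)
        kwargs.setdefault("n_blocks", proto.n_blocks)
        return cls(conditions=tuple(conds.tolist()), seed=seed, **{
            k: v for k, v in kwargs.items() if k != "conditions"
        })

    @property
    def n_volumes(self) -> int:
        return int(round(self.run_duration_s / self.tr_s))

    def volume_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_s

    def block_onsets(self) -> np.ndarray:
        return self.baseline_s + np.arange(self.n_blocks) * self.block_s


def condition_regressors(design: RunDesign, hrf: HrfSpec | None = None,
                         times: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """HRF-convolved boxcar regressors, one per eye, jointly peak-normalized.

    The boxcars are built on a fine time grid (``hrf.dt_s``), convolved with
    the HRF kernel, normalized so the joint maximum is 1 (amplitudes are then
    peak fractional signal changes) and linearly interpolated at ``times``
    (volume acquisition times by default).  Normalizing on the fine grid makes
    the regressors independent of the requested sample times, so generator and
    GLM agree for arbitrary acquisition timestamps.
    """
    hrf = hrf or HrfSpec()
    dt = hrf.dt_s
    t_fine = np.arange(0.0, design.run_duration_s, dt)
    kern = hrf.kernel()
    onsets = design.block_onsets()
    fine: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        box = np.zeros_like(t_fine)
        for onset, c in zip(onsets, design.conditions):
            if c == cond:
                box[(t_fine >= onset) & (t_fine < onset + design.block_s)] = 1.0
        fine[cond] = np.convolve(box, kern)[: t_fine.size] * dt
    peak = max(np.max(np.abs(v)) if v.size else 0.0 for v in fine.values())
    if peak > 0:
        for cond in CONDITIONS:
            fine[cond] = fine[cond] / peak
    if times is None:
        times = design.volume_times()
    return {c: np.interp(times, t_fine, fine[c]) for c in CONDITIONS}
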