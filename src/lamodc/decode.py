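"""Depth-resolved eye-of-origin decoding.

The decoding pipeline mirrors standard laminar MVPA practice: per-volume
samples from inside the stimulation blocks (transients discarded), ANOVA
F-score feature selection on the training folds, per-feature standardization
with training statistics, a linear soft-margin SVM (fixed C), and
leave-one-run-out cross-validation producing one accuracy per cortical depth
and fold.  Feature selection modes:

- ``mean_depth`` (default): F computed on training samples averaged across
  depth; the same vertex set is used at every depth (preserves the columnar
  organization of the selected set).
- ``at_depth:<fraction>``: F computed at the depth nearest the fraction; one
  shared set.
- ``per_depth``: independent F and vertex set per depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC

from .preproc import select_time_points
from .synthgen import CortexPatch, LaminarTimeSeries

LABEL_OF = {"LEFT": 1, "RIGHT": -1}


@dataclass(frozen=True)
class DecoderConfig:
    """Decoder settings: number of features, SVM penalty, selection mode."""

    n_features: int = 200
    svm_c: float = 1.0
    selection_mode: str = "mean_depth"
    feature_count_grid: tuple[int, ...] | None = None
    solver_tol: float = 1e-4
    solver_max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")
        mode = self.selection_mode
        if mode not in ("mean_depth", "per_depth") and not mode.startswith("at_depth:"):
            raise ValueError(f"unknown selection_mode {mode!r}")


@dataclass
class SessionSamples:
    """Post-selection samples of one session.

    ``X`` has shape (n_samples, n_vertices, n_depths); ``y`` is +1 for LEFT
    and -1 for RIGHT; ``run_id`` indexes the source run per sample.
    ``vertex_index`` maps rows of the vertex axis back to patch vertex ids.
    """

    X: np.ndarray
    y: np.ndarray
    run_id: np.ndarray
    region_label: np.ndarray
    shared_fov_mask: np.ndarray
    depth_fractions: np.ndarray
    vertex_index: np.ndarray

    @property
    def n_depths(self) -> int:
        return self.X.shape[2]

    def eligible(self, region="V1") -> np.ndarray:
        names = (region,) if isinstance(region, str) else tuple(region)
        return np.flatnonzero(np.isin(self.region_label, names) & self.shared_fov_mask)


@dataclass(frozen=True)
class DecodingResult:
    """Per-fold, per-depth accuracies plus the selected features."""

    accuracy: np.ndarray
    depth_fractions: np.ndarray
    selected: tuple[np.ndarray, ...]
    config: DecoderConfig

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.accuracy.mean(axis=0)


def build_session_samples(runs, designs, patch: CortexPatch, regions=None,
                          n_discard_transient: int = 2) -> SessionSamples:
    """Stack block-interior volumes of all runs into a sample array.

    ``regions`` optionally restricts the vertex axis (memory saver); the
    shared field-of-view mask marks vertices finite in every retained volume
    of every run.
    """
    if len(runs) != len(designs) or not runs:
        raise ValueError("need one design per run")
    if regions is not None:
        names = (regions,) if isinstance(regions, str) else tuple(regions)
        keep = np.flatnonzero(np.isin(patch.region_label, names))
    else:
        keep = np.arange(patch.n_vertices)
    xs, ys, rids = [], [], []
    for rid, (ser, des) in enumerate(zip(runs, designs)):
        idx, labels = select_time_points(des, n_discard_transient)
        vals = ser.values[keep][:, :, idx]  # (V, D, S)
        xs.append(np.moveaxis(vals, -1, 0))  # (S, V, D)
        ys.append(np.array([LABEL_OF[l] for l in labels]))
        rids.append(np.full(idx.size, rid))
    X = np.concatenate(xs, axis=0)
    fov = np.isfinite(X).all(axis=(0, 2))
    return SessionSamples(X=X, y=np.concatenate(ys), run_id=np.concatenate(rids),
                          region_label=patch.region_label[keep],
                          shared_fov_mask=fov,
                          depth_fractions=np.asarray(runs[0].depth_fractions),
                          vertex_index=keep)


def f_statistic(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F per feature (between-group MS / within-group MS).

    Features with zero within-group variance get F = +inf if the group means
    differ (maximally paradigm-locked) and F = 0 otherwise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.unique(y)
    if groups.size < 2:
        raise ValueError("need at least two classes")
    n = X.shape[0]
    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for g in groups:
        sel = X[y == g]
        if sel.shape[0] < 2:
            raise ValueError("need at least two samples per class")
        gm = sel.mean(axis=0)
        ss_between += sel.shape[0] * (gm - grand) ** 2
        ss_within += ((sel - gm) ** 2).sum(axis=0)
    msb = ss_between / (groups.size - 1)
    msw = ss_within / (n - groups.size)
    out = np.zeros(X.shape[1])
    zero_w = msw <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out[~zero_w] = msb[~zero_w] / msw[~zero_w]
    out[zero_w & (msb > 0)] = np.inf
    return out


def _top_k(f: np.ndarray, candidates: np.ndarray, k: int) -> np.ndarray:
    """Top-k by F, ties (and +inf first) broken by ascending vertex index."""
    order = np.lexsort((candidates, -f))
    return candidates[order[:k]]


def _rank_features(samples: SessionSamples, cfg: DecoderConfig, train_mask: np.ndarray,
                   region) -> np.ndarray:
    """Full per-depth candidate ranking (n_depths x n_eligible)."""
    eligible = samples.eligible(region)
    if eligible.size < cfg.n_features:
        raise ValueError(
            f"only {eligible.size} eligible vertices for n_features={cfg.n_features}")
    Xtr = samples.X[train_mask][:, eligible, :]
    ytr = samples.y[train_mask]
    mode = cfg.selection_mode
    if mode == "mean_depth":
        f = f_statistic(Xtr.mean(axis=2), ytr)
        ranked = _top_k(f, eligible, eligible.size)
        return np.tile(ranked, (samples.n_depths, 1))
    if mode.startswith("at_depth:"):
        target = float(mode.split(":", 1)[1])
        d = int(np.argmin(np.abs(samples.depth_fractions - target)))
        f = f_statistic(Xtr[:, :, d], ytr)
        ranked = _top_k(f, eligible, eligible.size)
        return np.tile(ranked, (samples.n_depths, 1))
    rows = []
    for d in range(samples.n_depths):
        f = f_statistic(Xtr[:, :, d], ytr)
        rows.append(_top_k(f, eligible, eligible.size))
    return np.stack(rows)


def select_features(samples: SessionSamples, cfg: DecoderConfig, training_runs,
                    region="V1") -> np.ndarray:
    """Selected vertex rows per depth (n_depths x n_features), from training
    runs only."""
    train_mask = np.isin(samples.run_id, np.asarray(training_runs))
    if not train_mask.any():
        raise ValueError("training_runs select no samples")
    return _rank_features(samples, cfg, train_mask, region)[:, :cfg.n_features]


def standardize(train_X: np.ndarray, test_X: np.ndarray):
    """Per-feature z-scoring with training mean/SD, applied to both sets.

    Zero-SD features are dropped (with a warning) from both sets.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {np.count_nonzero(~keep)} zero-variance features")
    return ((train_X[:, keep] - mu[keep]) / sd[keep],
            (test_X[:, keep] - mu[keep]) / sd[keep])


def train_linear_classifier(train_Z: np.ndarray, y: np.ndarray, c_penalty: float = 1.0,
                            tol: float = 1e-4, max_iter: int = 1000) -> LinearSVC:
    """Soft-margin linear SVM: 0.5*||w||^2 + C * sum of hinge losses.

    Solved with liblinear's dual coordinate descent (hinge loss, fitted
    intercept via a weakly penalized augmented feature), which matches the
    libsvm solution to numerical precision at a fraction of the cost on
    near-chance data.  Deterministic for fixed tolerance/iteration settings.
    """
    if np.unique(y).size < 2:
        raise ValueError("need two classes to train")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*max_iter.*")
        warnings.filterwarnings("ignore", category=UserWarning)
        model = LinearSVC(loss="hinge", C=c_penalty, tol=tol, max_iter=max_iter,
                          intercept_scaling=10.0, random_state=0)
        model.fit(train_Z, y)
    return model


def leave_one_run_out(samples: SessionSamples, cfg: DecoderConfig,
                      region="V1") -> DecodingResult:
    """Leave-one-run-out cross-validated accuracy per depth.

    For each held-out run, features are selected and standardization
    statistics estimated on the remaining runs only (no test-set leakage).
    """
    runs = np.unique(samples.run_id)
    if runs.size < 2:
        raise ValueError("need at least two runs")
    acc = np.empty((runs.size, samples.n_depths))
    selected = []
    for i, r in enumerate(runs):
        train = samples.run_id != r
        test = ~train
        feats = select_features(samples, cfg, runs[runs != r], region=region)
        selected.append(feats)
        for d in range(samples.n_depths):
            Ztr, Zte = standardize(samples.X[train][:, feats[d], d],
                                   samples.X[test][:, feats[d], d])
            model = train_linear_classifier(Ztr, samples.y[train], cfg.svm_c,
                                            tol=cfg.solver_tol,
                                            max_iter=cfg.solver_max_iter)
            acc[i, d] = float(np.mean(model.predict(Zte) == samples.y[test]))
    return DecodingResult(accuracy=acc, depth_fractions=samples.depth_fractions,
                          selected=tuple(selected), config=cfg)


def feature_count_sweep(samples: SessionSamples, cfg: DecoderConfig, k_grid,
                        region="V1") -> np.ndarray:
    """Leave-one-run-out accuracy for each feature count in ``k_grid``.

    Per fold the F ranking is computed once and truncated per k (equivalent
    to re-selecting for a fixed ranking).  Returns (len(k_grid), n_depths).
    """
    k_grid = [int(k) for k in k_grid]
    runs = np.unique(samples.run_id)
    if runs.size < 2:
        raise ValueError("need at least two runs")
    eligible = samples.eligible(region)
    if max(k_grid) > eligible.size:
        raise ValueError("max(k_grid) exceeds the eligible vertex count")
    acc = np.zeros((len(k_grid), samples.n_depths))
    for r in runs:
        train = samples.run_id != r
        test = ~train
        ranking = _rank_features(samples, cfg, train, region)
        for d in range(samples.n_depths):
            for j, k in enumerate(k_grid):
                feats = ranking[d, :k]
                Ztr, Zte = standardize(samples.X[train][:, feats, d],
                                       samples.X[test][:, feats, d])
                model = train_linear_classifier(Ztr, samples.y[train], cfg.svm_c,
                                                tol=cfg.solver_tol,
                                                max_iter=cfg.solver_max_iter)
                acc[j, d] += float(np.mean(model.predict(Zte) == samples.y[test]))
    return acc / runs.size


def permuted_label_accuracy(samples: SessionSamples, cfg: DecoderConfig,
                            n_repeats: int = 20, seed: int = 0,
                            region="V1") -> np.ndarray:
    """Mean cross-validated accuracy (over depths) per within-run label
    permutation; the empirical chance distribution of the decoder."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_repeats)
    for i in range(n_repeats):
        y_perm = samples.y.copy()
        for r in np.unique(samples.run_id):
            sel = np.flatnonzero(samples.run_id == r)
            y_perm[sel] = y_perm[rng.permutation(sel)]
        shuffled = SessionSamples(X=samples.X, y=y_perm, run_id=samples.run_id,
                                  region_label=samples.region_label,
                                  shared_fov_mask=samples.shared_fov_mask,
                                  depth_fractions=samples.depth_fractions,
                                  vertex_index=samples.vertex_index)
        out[i] = float(leave_one_run_out(shuffled, cfg, region=region).mean_accuracy.mean())
    return out
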