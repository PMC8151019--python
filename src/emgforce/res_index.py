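"""RES cluster-separability index and the window-length sweep experiment.

The RES index is the ratio of the average Euclidean distance between
gesture-cluster means (over all unordered gesture pairs, first two feature
dimensions) to the average within-gesture standard deviation.  Higher
values mean better-separated, more compact gesture clusters.  It is
computed on 2-D scatter points obtained by reducing the 84-dimensional
feature space of *each force level separately* to c - 1 dimensions with
SRDA, sampling a fixed number of windows per gesture and force, and
min-max normalising the first two reduced dimensions over the pooled set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import invariant
from .reduce import fit_srda, normalize_first_two, transform
from .signal_io import FORCES, FilterSpec, Trial, preprocess_window, segment_windows

#: sweep lengths in ms (50 to 400 in steps of 50)
SWEEP_LENGTHS_MS = tuple(range(50, 401, 50))


def res(points: np.ndarray, labels: np.ndarray) -> float:
    """RES separability index of labelled 2-D (or wider) points.

    Cluster means use the first two dimensions; the dispersion term
    averages the per-dimension within-gesture sample standard deviations
    (ddof = 1) over all supplied dimensions and gestures.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    if P.shape[0] != labels.shape[0]:
        raise ValueError("points and labels must be aligned")
    classes = np.unique(labels)
    K = classes.size
    if K < 2:
        raise ValueError("need at least two gestures")
    means = []
    stds = []
    for cls in classes:
        pc = P[labels == cls]
        if pc.shape[0] < 2:
            raise ValueError(f"gesture {cls!r} needs at least 2 points")
        means.append(pc[:, :2].mean(axis=0))
        stds.append(pc.std(axis=0, ddof=1))
    ed = 0.0
    for p in range(K - 1):
        for q in range(p + 1, K):
            ed += float(np.linalg.norm(means[p] - means[q]))
    ed *= 2.0 / (K * (K - 1))
    sigma = float(np.mean(stds))
    if sigma == 0.0:
        raise ValueError("zero dispersion: every cluster is degenerate")
    return ed / sigma


def reduced_scatter(
    trials: list[Trial],
    window_ms: float = 150.0,
    step_ms: float = 100.0,
    samples_per_gesture: int = 25,
    seed: int = 0,
    reg: float = 0.01,
    log: bool = True,
    filter_spec: FilterSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalised 2-D scatter points for the RES / scatter-plot experiments.

    For each force level present, the feature vectors of that force's
    windows are reduced to c - 1 dimensions with an SRDA fitted on that
    force alone; ``samples_per_gesture`` windows per gesture and force are
    then drawn (deterministically for a given seed), pooled, and the first
    two reduced dimensions min-max normalised over the pooled set.

    Returns ``(points, gestures, forces)`` — for 3 forces, 6 gestures and
    25 samples each this is 450 points.
    """
    filter_spec = filter_spec or FilterSpec()
    by_force: dict[str, list] = {}
    for trial in trials:
        for w in segment_windows(trial, window_ms, step_ms=step_ms):
            vec = invariant.extract(preprocess_window(w, filter_spec), log=log)
            by_force.setdefault(trial.force, []).append((vec, trial.gesture))
    rng = np.random.default_rng(seed)
    blocks, gestures, forces = [], [], []
    for force in [f for f in FORCES if f in by_force]:
        X = np.array([v for v, _ in by_force[force]])
        y = np.array([g for _, g in by_force[force]])
        Z = transform(fit_srda(X, y, reg=reg), X)
        for g in np.unique(y):
            idx = np.flatnonzero(y == g)
            if idx.size < samples_per_gesture:
                raise ValueError(
                    f"only {idx.size} windows for gesture {g}, force {force!r}; "
                    f"need {samples_per_gesture}"
                )
            pick = np.sort(rng.choice(idx, size=samples_per_gesture, replace=False))
            blocks.append(Z[pick])
            gestures.extend([g] * samples_per_gesture)
            forces.extend([force] * samples_per_gesture)
    Z_all = np.vstack(blocks)
    return normalize_first_two(Z_all), np.asarray(gestures), np.asarray(forces)


def window_length_sweep(
    trials: list[Trial],
    lengths_ms: tuple[int, ...] = SWEEP_LENGTHS_MS,
    samples_per_gesture: int = 25,
    seed: int = 0,
    reg: float = 0.01,
    log: bool = True,
    step_ms: float = 100.0,
    filter_spec: FilterSpec | None = None,
) -> pd.DataFrame:
    """RES index as a function of window length.

    Windows advance by a fixed ``step_ms`` stride for every length so that
    short and long windows sample the trials at the same rate.  Returns one
    row per length: (window_ms, res_index, n_points, seed).
    """
    rows = []
    for length in lengths_ms:
        pts, gestures, _ = reduced_scatter(
            trials,
            window_ms=float(length),
            step_ms=step_ms,
            samples_per_gesture=samples_per_gesture,
            seed=seed,
            reg=reg,
            log=log,
            filter_spec=filter_spec,
        )
        rows.append(
            {
                "window_ms": length,
                "res_index": res(pts, gestures),
                "n_points": len(pts),
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
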