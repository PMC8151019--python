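"""Feature extraction: the force-invariant set and six classical baselines."""

from __future__ import annotations

import pandas as pd

from ..signal_io import FilterSpec, Trial, Window, preprocess_window, segment_windows
from . import baseline, invariant

LABEL_COLUMNS = ("subject", "gesture", "force", "trial", "window_start")


def extract_features(window: Window, method: str = "proposed", log: bool = True, **params):
    """Extract one feature vector from a preprocessed window."""
    if method.lower() == "proposed":
        return invariant.extract(window, log=log, **params)
    return baseline.extract_baseline(window, method, **params)


def feature_table(
    trials: list[Trial],
    method: str = "proposed",
    window_ms: float = 150.0,
    overlap_ms: float = 50.0,
    step_ms: float | None = None,
    filter_spec: FilterSpec | None = None,
    log: bool = True,
    **params,
) -> pd.DataFrame:
    """Window, preprocess and featurize a list of trials into a tidy table.

    One row per window: the label columns (subject, gesture, force, trial,
    window_start) followed by the named feature columns of ``method``.
    """
    filter_spec = filter_spec or FilterSpec()
    rows = []
    names: list[str] | None = None
    for trial in trials:
        for w in segment_windows(trial, window_ms, overlap_ms, step_ms=step_ms):
            vec = extract_features(preprocess_window(w, filter_spec), method, log=log, **params)
            if names is None:
                if method.lower() == "proposed":
                    names = invariant.feature_names(trial.n_channels, log=log)
                else:
                    names = baseline.feature_names(method, trial.n_channels)
            rows.append(
                {
                    "subject": w.subject_id,
                    "gesture": w.gesture,
                    "force": w.force,
                    "trial": w.trial_index,
                    "window_start": w.start_index,
                    **dict(zip(names, vec)),
                }
            )
    return pd.DataFrame(rows)
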