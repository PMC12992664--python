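"""Signal conditioning: percent signal change, confound regression, run
averaging.

Measured vertex series are standardized to percent signal change relative
to the run mean, 12 nuisance regressors (six motion parameters; white
matter, cerebrospinal fluid and global signal; three low-frequency cosine
drift terms) are removed by OLS, and conditioned runs are averaged
pointwise before tuning estimation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "to_percent_signal_change",
    "cosine_drift_basis",
    "regress_confounds",
    "average_runs",
    "condition_runs",
    "read_confounds_tsv",
    "DEFAULT_CONFOUND_COLUMNS",
]

DEFAULT_CONFOUND_COLUMNS = (
    "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
    "white_matter", "csf", "global_signal",
    "cosine00", "cosine01", "cosine02",
)


def to_percent_signal_change(values: np.ndarray) -> np.ndarray:
    """Map a run to percent signal change: v -> 100 (v / mean(v) - 1).

    A run whose mean is (numerically) zero has no meaningful baseline and
    is rejected as degenerate.
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=0)
    if np.any(np.abs(mean) < 1e-12):
        raise ValueError("zero-mean run is degenerate; cannot compute percent signal change")
    return 100.0 * (values / mean - 1.0)


def cosine_drift_basis(n_volumes: int, tr: float, n_terms: int = 3) -> np.ndarray:
    """Discrete-cosine (DCT-II) low-frequency drift basis.

    Returns the ``n_terms`` lowest-frequency non-constant cosines — the
    three-regressor drift model by default, where term k has period
    2 * run duration / k (609, 304.5 and 203 s for a 304.5 s run, all
    slower than a 128 s high-pass cutoff).
    """
    if not 1 <= n_terms < n_volumes:
        raise ValueError("n_terms must be in [1, n_volumes)")
    v = np.arange(n_volumes)
    cols = [np.cos(np.pi * k * (2 * v + 1) / (2 * n_volumes))
            for k in range(1, n_terms + 1)]
    return np.column_stack(cols)


def regress_confounds(values: np.ndarray, confounds) -> np.ndarray:
    """OLS residual of a run (or runs, columns) on [intercept | confounds].

    Raises on a rank-deficient design, naming the collinear columns.
    """
    values = np.asarray(values, dtype=float)
    if isinstance(confounds, pd.DataFrame):
        names = list(confounds.columns)
        X = confounds.to_numpy(dtype=float)
    else:
        X = np.asarray(confounds, dtype=float)
        names = [f"confound_{i}" for i in range(X.shape[1])]
    if X.shape[0] != values.shape[0]:
        raise ValueError("confound rows must match run length")
    design = np.column_stack([np.ones(X.shape[0]), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns not adding rank, for the diagnostic
        bad = []
        r = 1
        for j in range(1, design.shape[1]):
            new_r = np.linalg.matrix_rank(design[:, : j + 1])
            if new_r == r:
                bad.append(names[j - 1])
            r = new_r
        raise ValueError(f"confound design is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ beta


def average_runs(runs, subset=None) -> np.ndarray:
    """Pointwise mean over the selected runs.

    ``runs`` is a sequence of equal-length per-volume arrays, or a 2-D
    array with runs along axis 0; ``subset`` selects run indices.
    """
    runs = [np.asarray(r, dtype=float) for r in runs]
    lengths = {len(r) for r in runs}
    if len(lengths) != 1:
        raise ValueError("runs have unequal lengths")
    if subset is None:
        subset = range(len(runs))
    subset = list(subset)
    if not subset:
        raise ValueError("subset of runs must be non-empty")
    return np.mean([runs[i] for i in subset], axis=0)


def condition_runs(runs, confounds_per_run=None, psc: bool = True) -> list[np.ndarray]:
    """Apply the conditioning pipeline (PSC, then confound regression) per run."""
    out = []
    for i, run in enumerate(runs):
        r = np.asarray(run, dtype=float)
        if psc:
            r = to_percent_signal_change(r)
        if confounds_per_run is not None:
            r = regress_confounds(r, confounds_per_run[i])
        out.append(r)
    return out


def read_confounds_tsv(path, columns=DEFAULT_CONFOUND_COLUMNS) -> pd.DataFrame:
    """Read an fMRIPrep-style confound table, selecting the named columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"confound table lacks columns: {missing}")
    return df[list(columns)]
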