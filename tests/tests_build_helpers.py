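"""Shared builders for small synthetic PeakTables used across test modules."""

import numpy as np
import pandas as pd

from vocscreen.peak_model import PeakTable, VOCSpecies


def table_from_matrix(x_pos: np.ndarray, x_ctrl: np.ndarray) -> PeakTable:
    """Single-fragment PeakTable from per-class feature matrices
    (columns become species v0, v1, ...)."""
    n_pos, p = x_pos.shape
    n_ctrl = x_ctrl.shape[0]
    subjects = pd.DataFrame(
        {
            "subject_id": [f"p{i}" for i in range(n_pos)]
            + [f"c{i}" for i in range(n_ctrl)],
            "group": ["positive"] * n_pos + ["control"] * n_ctrl,
        }
    )
    species = [
        VOCSpecies(f"v{j}", f"v{j}", 5.0 + j, (60,), quantifier_mz=60)
        for j in range(p)
    ]
    rows = []
    full = np.vstack([x_pos, x_ctrl])
    for j in range(p):
        for sid, val in zip(subjects["subject_id"], full[:, j]):
            rows.append((sid, f"v{j}", 60, float(val), float(val)))
    meas = pd.DataFrame(
        rows, columns=["subject_id", "voc_id", "mz", "fragment_area", "tic_area"]
    )
    return PeakTable(species=species, subjects=subjects, measurements=meas)


def two_class_table(rng, n=12, p=2, shift=0.0) -> PeakTable:
    base = 100.0
    x_pos = base + rng.normal(shift, 1.0, size=(n, p))
    x_ctrl = base + rng.normal(0.0, 1.0, size=(n, p))
    return table_from_matrix(x_pos, x_ctrl)


def mirrored_table() -> PeakTable:
    rng = np.random.default_rng(0)
    x = 50.0 + rng.normal(size=(8, 2))
    return table_from_matrix(x, x.copy())
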