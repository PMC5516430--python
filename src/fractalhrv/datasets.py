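"""Bundled reference data.

``reference_cohort.csv`` holds the published per-astronaut 24-h session
means of five HRV indices — the power-law slope beta (dimensionless) and the
ULF, VLF, LF and HF band powers (ms^2) — for seven astronauts monitored five
times around a ~6-month stay on the International Space Station (Pre, F01,
F02, F03, Post).  These per-subject values are the input to replication
mode: the group statistics can be recomputed from them without access to the
raw ECG recordings, which are not publicly deposited.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

INDEX_UNITS = {"beta": "dimensionless", "ulf": "ms^2", "vlf": "ms^2", "lf": "ms^2", "hf": "ms^2"}


def load_reference_cohort() -> dict[str, pd.DataFrame]:
    """Per-index tables of per-subject stage values (rows: subjects, cols: stages)."""
    with resources.files("fractalhrv.data").joinpath("reference_cohort.csv").open() as fh:
        df = pd.read_csv(fh)
    out: dict[str, pd.DataFrame] = {}
    for name, grp in df.groupby("index", sort=False):
        out[name] = grp.set_index("subject")[["Pre", "F01", "F02", "F03", "Post"]].astype(float)
    return out
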