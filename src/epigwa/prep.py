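"""Standardization of seedling measurements into accession phenotypes.

Pipeline order: hypocotyl filter -> control-based set correction ->
within-set replicate residualization -> per-accession summary.  Each
step is idempotent, and the set correction leaves the global control
mean unchanged.
"""
from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def filter_seedlings(records: pd.DataFrame,
                     min_hypocotyl: float = 5.0
                     ) -> Tuple[pd.DataFrame, int]:
    """Remove seedlings whose hypocotyl is strictly below the threshold.

    Seedlings with a short hypocotyl most likely germinated late and
    would bias the day-7 root length downward.  Records without a
    hypocotyl measurement are kept.
    """
    hyp = records["hypocotyl_length"]
    drop = hyp.notna() & (hyp < min_hypocotyl)
    n_removed = int(drop.sum())
    if n_removed:
        logger.info("removed %d seedlings with hypocotyl < %g mm",
                    n_removed, min_hypocotyl)
    return records.loc[~drop].reset_index(drop=True), n_removed


def _control_mask(records: pd.DataFrame, control_id: Optional[str]):
    if control_id is not None:
        return records["accession_id"] == control_id
    return records["is_control"].astype(bool)


def correct_sets(records: pd.DataFrame,
                 control_id: Optional[str] = None,
                 by_replicate: bool = True) -> pd.DataFrame:
    """Remove between-set (and replicate) shifts via the shared control.

    Every value is corrected by the difference between the control
    accession's mean in its set x replicate cell and the control's
    global mean: value' = value - (control cell mean - control global
    mean).  With ``by_replicate=False`` the correction uses set-level
    control means only.
    """
    ctrl = _control_mask(records, control_id)
    if not ctrl.any():
        raise ValueError("no control rows found; pass control_id or flag "
                         "is_control")
    global_mean = records.loc[ctrl, "root_length"].mean()
    keys = ["set_id", "replicate_id"] if by_replicate else ["set_id"]

    cell_means = (records.loc[ctrl].groupby(keys)["root_length"].mean())
    out = records.copy()
    cells = records.groupby(keys).groups
    for cell, idx in cells.items():
        if cell not in cell_means.index:
            raise ValueError(
                f"no control rows in cell {dict(zip(keys, np.atleast_1d(cell)))}: "
                f"the control accession must be grown in every cell")
        out.loc[idx, "root_length"] = (records.loc[idx, "root_length"]
                                       - (cell_means[cell] - global_mean))
    return out


def residualize_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Remove residual replicate differences within each set.

    Within each set, values become residuals from a replicate-means
    model, re-centered on the set grand mean so the trait stays in mm:
    value' = value - replicate mean + set mean.  After the operation all
    replicate means within a set are equal.
    """
    out = records.copy()
    for set_id, sub in records.groupby("set_id"):
        set_mean = sub["root_length"].mean()
        rep_sizes = sub.groupby("replicate_id").size()
        singletons = rep_sizes[rep_sizes < 2]
        if len(singletons):
            logger.warning(
                "set %s: replicate(s) %s have a single row; their residual "
                "is 0", set_id, list(singletons.index))
        rep_means = sub.groupby("replicate_id")["root_length"].transform("mean")
        out.loc[sub.index, "root_length"] = (sub["root_length"] - rep_means
                                             + set_mean)
    return out


def summarize_accessions(records: pd.DataFrame) -> pd.DataFrame:
    """Per-accession mean, unbiased variance and seedling count.

    The variance of a single-seedling accession is undefined (NaN).
    """
    g = records.groupby("accession_id")["root_length"]
    out = pd.DataFrame({
        "accession_id": list(g.groups),
        "mean": g.mean().to_numpy(),
        "variance": g.var(ddof=1).to_numpy(),
        "n_seedlings": g.count().to_numpy(),
    })
    return out.sort_values("accession_id", ignore_index=True)


def standardize(records: pd.DataFrame, control_id: Optional[str] = None,
                min_hypocotyl: float = 5.0,
                by_replicate: bool = True
                ) -> Tuple[pd.DataFrame, dict]:
    """Full prep pipeline: filter -> correct_sets -> residualize ->
    summarize.  Returns the accession table and a step log."""
    filtered, n_removed = filter_seedlings(records, min_hypocotyl)
    corrected = correct_sets(filtered, control_id, by_replicate)
    resid = residualize_replicates(corrected)
    table = summarize_accessions(resid)
    info = {"n_input": int(len(records)),
            "n_removed_hypocotyl": n_removed,
            "n_used": int(len(resid)),
            "n_accessions": int(table.shape[0])}
    return table, info
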