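"""Rarefaction and relative-abundance transforms for clade count tables.

Rarefaction equalises sequencing effort by drawing, once per sample, a
uniform subsample without replacement (multivariate hypergeometric) of a
fixed depth; samples below the depth are dropped and reported, never an
error. Each sample uses its own seed substream keyed by sample id, so the
result is independent of row order and stable when samples are added.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .labels import MAIN_CLADES
from .simulate import rng_for

ROW_SUM_TOL = 1e-9


def rarefy(
    table: pd.DataFrame, depth: int = 50, seed: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subsample every sample's counts to exactly ``depth`` reads.

    Returns ``(rarefied, drop_report)``. ``drop_report`` lists samples whose
    total was below the depth (removed for low sequence coverage). A sample
    whose total equals the depth is returned unchanged.
    """
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    counts = table.to_numpy()
    if (counts < 0).any():
        raise ValueError("count table has negative cells")
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = pd.DataFrame(
        {
            "sample_id": table.index[~keep],
            "total": totals[~keep].astype(int),
            "reason": "low sequence coverage",
        }
    ).set_index("sample_id")
    rows = {}
    for sample_id, row in table.loc[keep].iterrows():
        vec = row.to_numpy().astype(np.int64)
        if vec.sum() == depth:
            rows[sample_id] = vec
        else:
            rng = rng_for(seed, "rarefy", str(sample_id))
            rows[sample_id] = rng.multivariate_hypergeometric(vec, depth)
    rarefied = pd.DataFrame.from_dict(rows, orient="index", columns=table.columns)
    rarefied = rarefied.loc[table.index[keep]].astype(int)
    rarefied.index.name = table.index.name
    return rarefied, dropped


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample's counts by its total; rows then sum to 1."""
    totals = table.sum(axis=1)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {', '.join(map(str, zero[:5]))}")
    return table.div(totals, axis=0)


def restrict_to_main_clades(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop pseudo-clade columns and renormalise rows over the 12 main clades.

    Samples whose mass lies entirely in pseudo clades cannot be renormalised
    and are dropped with a report.
    """
    main = [c for c in table.columns if c in MAIN_CLADES]
    if not main:
        raise ValueError("table contains no main-clade columns")
    sub = table[main]
    totals = sub.sum(axis=1)
    keep = totals > 0
    dropped = pd.DataFrame(
        {
            "sample_id": table.index[~keep],
            "total": totals[~keep],
            "reason": "no main-clade mass",
        }
    ).set_index("sample_id")
    out = sub.loc[keep].div(totals[keep], axis=0)
    return out, dropped


def assert_abundance_table(table: pd.DataFrame, tol: float = ROW_SUM_TOL) -> None:
    """Validate the proportions contract: cells in [0,1], rows sum to 1."""
    values = table.to_numpy(dtype=float)
    if (values < -tol).any() or (values > 1 + tol).any():
        raise ValueError("abundance cells must lie in [0, 1]")
    bad = np.abs(values.sum(axis=1) - 1.0) > tol
    if bad.any():
        names = ", ".join(map(str, table.index[bad][:5]))
        raise ValueError(f"abundance rows must sum to 1: {names}")
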