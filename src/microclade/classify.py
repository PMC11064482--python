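"""Clade and pseudo-clade assignment from protein-alignment hit tables.

A metagenomic read aligned against the marker reference database yields a set
of hits. After filtering (identity >= 98%, E-value < 1e-20, background entries
removed) the read is assigned to the single clade whose hits reach the
globally highest percent identity; if two or more clades tie at that top
identity, the read goes to the pseudo clade named by the sorted tie set
(e.g. "1-2"). Pseudo clades with fewer than 10 reads pooled across the whole
dataset are collapsed into the broad pseudo clade.

Identity comparisons use the values exactly as printed in the hit file — ties
in the tabular alignment format are exact at its printed precision, so no
epsilon is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .labels import BACKGROUND, BROAD_PSEUDO, MAIN_CLADES, is_pseudo, pseudo_label, sort_labels
from .simulate import HIT_COLUMNS

DISCARDED = "discarded"

_NUMERIC = {
    "pct_identity": float,
    "aln_length": int,
    "mismatches": int,
    "gap_opens": int,
    "q_start": int,
    "q_end": int,
    "s_start": int,
    "s_end": int,
    "evalue": float,
    "bit_score": float,
}


class HitTableError(ValueError):
    """Malformed hit table: carries the offending line numbers."""


@dataclass(frozen=True)
class CladeAssignment:
    query_id: str
    label: str  # "1".."12", "1-2", ... or "discarded"
    top_identity: float
    n_hits_used: int


def _load_annotations(annotations) -> pd.Series:
    """entry_id -> clade mapping from a frame, path or MarkerDatabase."""
    if hasattr(annotations, "to_frame") and not isinstance(annotations, (pd.Series, pd.DataFrame)):
        annotations = annotations.to_frame()  # MarkerDatabase
    if isinstance(annotations, (str, Path)):
        annotations = pd.read_csv(annotations, sep="\t", dtype=str).set_index("entry_id")
    if isinstance(annotations, pd.DataFrame):
        return annotations["clade"].astype(str)
    return annotations.astype(str)


def parse_hit_table(path, annotations) -> pd.DataFrame:
    """Read a 12-column tabular alignment file and join clade annotations.

    Malformed lines (wrong field count, identity outside [0, 100], negative
    E-value) are reported together with their 1-based line numbers; a subject
    absent from the annotation table is an error naming it. An empty file
    yields an empty table.
    """
    clade_of = _load_annotations(annotations)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=list(HIT_COLUMNS), dtype=str, comment="#"
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=list(HIT_COLUMNS))
    bad: list[tuple[int, str]] = []
    for col, typ in _NUMERIC.items():
        converted = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[converted.isna() & df[col].notna()]:
            bad.append((i + 1, f"field {col!r} is not numeric: {df.at[i, col]!r}"))
        df[col] = converted
    ident = df["pct_identity"]
    for i in df.index[(ident < 0) | (ident > 100)]:
        bad.append((i + 1, f"pct_identity out of [0, 100]: {ident[i]}"))
    for i in df.index[df["evalue"] < 0]:
        bad.append((i + 1, f"negative evalue: {df.at[i, 'evalue']}"))
    for i in df.index[df[list(HIT_COLUMNS)].isna().any(axis=1)]:
        if not any(line == i + 1 for line, _ in bad):
            bad.append((i + 1, "wrong field count or empty field"))
    if bad:
        detail = "; ".join(f"line {line}: {msg}" for line, msg in sorted(bad))
        raise HitTableError(f"malformed hit table {path}: {detail}")
    unknown = set(df["subject_id"]) - set(clade_of.index)
    if unknown:
        names = ", ".join(sorted(unknown)[:5])
        raise KeyError(f"subject ids absent from the annotation table: {names}")
    df["clade"] = df["subject_id"].map(clade_of)
    return df


def filter_hits(
    records: pd.DataFrame,
    min_identity: float = 98.0,
    max_evalue: float = 1e-20,
    drop_background: bool = True,
) -> pd.DataFrame:
    """Keep hits with identity >= min_identity and E-value strictly < max_evalue.

    Background (non-target) reference entries are dropped here: they act as
    competitive decoys during alignment but never contribute to clade calls.
    """
    if not (np.isfinite(min_identity) and np.isfinite(max_evalue)):
        raise ValueError("filter thresholds must be finite")
    keep = (records["pct_identity"] >= min_identity) & (records["evalue"] < max_evalue)
    if drop_background and "clade" in records:
        keep &= records["clade"] != BACKGROUND
    return records.loc[keep]


def assign_query(records: pd.DataFrame) -> CladeAssignment:
    """Assign one read from its filtered hits.

    The tie set T is the set of clades whose best hit attains the global
    maximum identity M over all of the read's hits; |T| = 1 assigns that
    clade ("one clade consistently highest"), |T| >= 2 assigns the pseudo
    clade of sorted T. No hits -> discarded.
    """
    if len(records) == 0:
        return CladeAssignment("", DISCARDED, float("nan"), 0)
    qids = records["query_id"].unique()
    if len(qids) > 1:
        raise ValueError(f"records mix query ids: {sorted(qids)[:3]}")
    per_clade_max = records.groupby("clade")["pct_identity"].max()
    top = per_clade_max.max()
    tie = per_clade_max.index[per_clade_max == top]
    n_used = int((records["pct_identity"] == top).sum())
    label = tie[0] if len(tie) == 1 else pseudo_label(tie)
    return CladeAssignment(qids[0], label, float(top), n_used)


def classify_sample(records: pd.DataFrame) -> tuple[dict[str, int], dict]:
    """Tally clade/pseudo-clade labels over one sample's filtered hits.

    Returns ``(counts, diagnostics)``; discarded reads (no surviving hits)
    are counted in diagnostics only, so the count total equals the number of
    assigned reads.
    """
    counts: dict[str, int] = {}
    diagnostics = {"n_queries": 0, "n_assigned": 0, "n_discarded": 0}
    if len(records) == 0:
        return counts, diagnostics
    # per (query, clade) max identity, then the argmax clade set per query
    per = records.groupby(["query_id", "clade"], sort=False)["pct_identity"].max()
    for qid, sub in per.groupby(level=0, sort=False):
        clades = sub.droplevel(0)
        top = clades.max()
        tie = clades.index[clades == top]
        label = tie[0] if len(tie) == 1 else pseudo_label(tie)
        counts[label] = counts.get(label, 0) + 1
        diagnostics["n_assigned"] += 1
    diagnostics["n_queries"] = diagnostics["n_assigned"]
    return counts, diagnostics


def classify_samples(
    tables: dict[str, pd.DataFrame],
    annotations=None,
    min_identity: float = 98.0,
    max_evalue: float = 1e-20,
    discard_background_topped: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter + classify every sample's hit table into a clade count table.

    ``tables`` maps sample id to a raw hit table (with clade column joined, or
    joinable via ``annotations``). ``discard_background_topped=True`` applies
    the stricter rule that a read whose single best overall hit is a
    background entry is discarded outright instead of being assigned from its
    remaining marker hits.

    Returns ``(CladeCountTable, diagnostics)`` where the count table is
    samples x labels (main clades first, then pseudo clades) and diagnostics
    has per-sample query bookkeeping.
    """
    counts_by_sample: dict[str, dict[str, int]] = {}
    diag_rows = []
    for sample_id, raw in tables.items():
        if "clade" not in raw.columns:
            if annotations is None:
                raise ValueError("hit tables lack clade annotations and none were given")
            raw = raw.assign(clade=raw["subject_id"].map(_load_annotations(annotations)))
        n_queries = raw["query_id"].nunique()
        kept = filter_hits(raw, min_identity=min_identity, max_evalue=max_evalue)
        n_bg_topped = 0
        if discard_background_topped and len(kept):
            best_all = raw.loc[
                (raw["pct_identity"] >= min_identity) & (raw["evalue"] < max_evalue)
            ].groupby("query_id")["pct_identity"].max()
            best_marker = kept.groupby("query_id")["pct_identity"].max()
            bg_topped = best_marker.index[
                best_marker < best_all.reindex(best_marker.index)
            ]
            n_bg_topped = len(bg_topped)
            kept = kept.loc[~kept["query_id"].isin(bg_topped)]
        counts, diag = classify_sample(kept)
        counts_by_sample[sample_id] = counts
        diag_rows.append(
            {
                "sample_id": sample_id,
                "n_queries": n_queries,
                "n_assigned": diag["n_assigned"],
                "n_discarded": n_queries - diag["n_assigned"],
                "n_background_topped": n_bg_topped,
            }
        )
    table = pd.DataFrame.from_dict(counts_by_sample, orient="index").fillna(0).astype(int)
    labels = sort_labels(set(table.columns) | set(MAIN_CLADES))
    # samples whose reads were all discarded still get an (all-zero) row
    table = table.reindex(index=list(tables), columns=labels, fill_value=0).fillna(0).astype(int)
    table.index.name = "sample_id"
    return table, pd.DataFrame(diag_rows).set_index("sample_id")


def collapse_rare_pseudo_clades(table: pd.DataFrame, min_hits: int = 10) -> pd.DataFrame:
    """Merge pseudo clades with < min_hits reads dataset-wide into broad_pseudo.

    Totals are pooled across all samples (no per-sample threshold) so every
    sample keeps an identical column set; main-clade columns are untouched and
    the grand total is conserved.
    """
    table = table.copy()
    pseudo_cols = [c for c in table.columns if is_pseudo(c)]
    rare = [c for c in pseudo_cols if table[c].sum() < min_hits]
    if BROAD_PSEUDO not in table.columns:
        table[BROAD_PSEUDO] = 0
    if rare:
        table[BROAD_PSEUDO] = table[BROAD_PSEUDO] + table[rare].sum(axis=1)
        table = table.drop(columns=rare)
    return table.reindex(columns=sort_labels(table.columns))
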