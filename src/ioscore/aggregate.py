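"""Total IO-scores over common orthologs and differential-expression calls.

Per-species IO-scores of a common ortholog's members are summed into a total
IO-score anchored on the hub protein id.  The calling threshold is derived
from the total number of curated sample pairs: the smallest integer at least
``fraction`` (default 20%) of the attainable maximum, i.e. ``ceil(0.2 * 31)
= 7`` for a 31-pair study, applied symmetrically as +-threshold.  Totals at
or beyond the threshold are called up/down; the boundary is inclusive.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .scoring import SpeciesScoreTable

logger = logging.getLogger(__name__)

CALL_UP = "up"
CALL_DOWN = "down"
CALL_UNCHANGED = "unchanged"


def total_io_score(
    groups: pd.DataFrame,
    species_tables: Mapping[str, SpeciesScoreTable | pd.Series],
    strict: bool = False,
) -> pd.DataFrame:
    """Sum per-species IO-scores over the common ortholog groups.

    Parameters
    ----------
    groups
        Consolidated ortholog groups (:func:`ioscore.orthology.consolidate`):
        indexed by hub_id, one member-id column per species plus
        ``is_common``.  Only common groups are scored — the candidate
        universe, as only they are measurable in every species.
    species_tables
        Per-species score tables (or plain ``transcript_id -> io_score``
        Series).  The hub's own table must be present; a hub protein with no
        row in it (no transcript in the expression data) drops its group with
        a logged count.  A non-hub member with no row contributes 0 and the
        group is flagged in ``n_missing``.
    strict
        If true, any unresolvable member raises instead.

    Returns
    -------
    DataFrame indexed by hub_id with one integer contribution column per
    species, ``total``, ``single_species`` (exactly one nonzero
    contribution) and ``n_missing``.
    """
    species = [c for c in groups.columns if c != "is_common"]
    scores: dict[str, pd.Series] = {}
    for sp, tab in species_tables.items():
        scores[sp] = tab.io_score() if isinstance(tab, SpeciesScoreTable) else tab
    missing_sp = set(species) - set(scores)
    if missing_sp:
        raise DataError(f"no score table for species {sorted(missing_sp)}")

    common = groups[groups["is_common"]]

    # hub members without expression: drop the whole group
    hub_species = [sp for sp in scores if sp not in species]
    if len(hub_species) != 1:
        raise DataError(
            "species_tables must contain exactly the hub plus the groups' species"
        )
    hub = hub_species[0]
    hub_ok = common.index.isin(scores[hub].index)
    n_dropped = int((~hub_ok).sum())
    if n_dropped:
        if strict:
            bad = common.index[~hub_ok][0]
            raise DataError(f"hub protein {bad!r} has no expression score")
        logger.info(
            "dropping %d common group(s) whose hub protein has no expression data",
            n_dropped,
        )
    common = common[hub_ok]

    out = pd.DataFrame(index=common.index)
    n_missing = np.zeros(len(common), dtype=int)
    out[hub] = scores[hub].reindex(common.index).astype(int)
    for sp in species:
        members = common[sp]
        contrib = scores[sp].reindex(members.to_numpy())
        unresolved = contrib.isna().to_numpy()
        if unresolved.any():
            if strict:
                raise DataError(
                    f"{sp}: member {members.to_numpy()[unresolved][0]!r} absent "
                    "from its species score table"
                )
            n_missing += unresolved.astype(int)
        out[sp] = np.nan_to_num(contrib.to_numpy()).astype(int)
    n_flagged = int((n_missing > 0).sum())
    if n_flagged:
        logger.info(
            "%d group(s) have members without expression data (contribution 0)",
            n_flagged,
        )

    contrib_cols = [hub] + species
    out["total"] = out[contrib_cols].sum(axis=1).astype(int)
    out["single_species"] = (out[contrib_cols] != 0).sum(axis=1) == 1
    out["n_missing"] = n_missing
    out.index.name = "hub_id"
    return out


def derive_total_threshold(n_pairs_total: int, fraction: float = 0.2) -> int:
    """Calling threshold: smallest integer >= fraction * n_pairs_total.

    The attainable maximum total equals the total pair count, so with 31
    pairs and the default 20% rule the threshold is ceil(6.2) = 7; the down
    threshold is its negation.
    """
    if n_pairs_total < 1:
        raise ValidationError("n_pairs_total must be >= 1")
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must lie in (0, 1], got {fraction}")
    # round() guards float artifacts such as 0.2 * 10 -> 2.0000000000000004
    return max(1, math.ceil(round(fraction * n_pairs_total, 9)))


def call_degs(
    records: pd.DataFrame, threshold: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition records into (up, down, unchanged) at +-threshold, inclusive.

    Each returned frame carries a ``call`` column and is sorted by descending
    absolute total, ties broken by hub_id.
    """
    if threshold < 1:
        raise ValidationError("threshold must be >= 1")
    rec = records.copy()
    rec["call"] = np.where(
        rec["total"] >= threshold, CALL_UP,
        np.where(rec["total"] <= -threshold, CALL_DOWN, CALL_UNCHANGED),
    )
    rec = rec.iloc[
        np.lexsort((rec.index.to_numpy(), -rec["total"].abs().to_numpy()))
    ]
    up = rec[rec["call"] == CALL_UP]
    down = rec[rec["call"] == CALL_DOWN]
    unchanged = rec[rec["call"] == CALL_UNCHANGED]
    return up, down, unchanged


def rank_records(records: pd.DataFrame) -> pd.DataFrame:
    """Add a 1-based ``rank`` by descending total (ties by hub_id)."""
    rec = records.iloc[
        np.lexsort((records.index.to_numpy(), -records["total"].to_numpy()))
    ].copy()
    rec["rank"] = np.arange(1, len(rec) + 1)
    return rec


def composition_table(records: pd.DataFrame) -> pd.DataFrame:
    """Long-format signed per-species contribution breakdown.

    One row per (hub_id, species) suitable for stacked-bar rendering;
    ``single_species`` marks genes whose entire total comes from one species
    (the asterisk convention in composition plots).  Rows for one hub_id sum
    exactly to its total.
    """
    species = [
        c for c in records.columns
        if c not in ("total", "single_species", "n_missing", "call", "rank",
                     "reference_id")
    ]
    long = records[species].stack().rename("contribution").reset_index()
    long.columns = ["hub_id", "species", "contribution"]
    long["contribution"] = long["contribution"].astype(int)
    flags = records["single_species"]
    long["single_species"] = long["hub_id"].map(flags).astype(bool)
    return long


def annotate(
    records: pd.DataFrame, best_hit_table: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Join reference-annotation symbols onto records by best alignment score.

    ``best_hit_table`` has columns ``hub_id, reference_id, score``; per hub
    id the max-score reference is kept, score ties broken by the
    lexicographically smallest reference id (logged).  Returns the annotated
    records (new ``reference_id`` column, empty string where unmapped) and
    the unmapped count.
    """
    need = {"hub_id", "reference_id", "score"} - set(best_hit_table.columns)
    if need:
        raise DataError(f"best-hit table missing column(s) {sorted(need)}")
    tab = best_hit_table.copy()
    # duplicate (hub, reference) rows: keep the max score
    tab = (
        tab.sort_values(["hub_id", "reference_id", "score"],
                        ascending=[True, True, False], kind="mergesort")
        .drop_duplicates(["hub_id", "reference_id"], keep="first")
    )
    best = (
        tab.sort_values(["hub_id", "score", "reference_id"],
                        ascending=[True, False, True], kind="mergesort")
        .drop_duplicates("hub_id", keep="first")
    )
    n_ties = 0
    if len(tab):
        merged = tab.merge(
            best[["hub_id", "score"]], on="hub_id", suffixes=("", "_best")
        )
        at_best = (merged["score"] == merged["score_best"]).groupby(
            merged["hub_id"]
        ).sum()
        n_ties = int((at_best > 1).sum())
    if n_ties:
        logger.info("%d hub id(s) had tied annotation scores; smallest id kept", n_ties)
    mapping = best.set_index("hub_id")["reference_id"]
    out = records.copy()
    out["reference_id"] = out.index.map(mapping).fillna("")
    unmapped = int((out["reference_id"] == "").sum())
    return out, unmapped
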