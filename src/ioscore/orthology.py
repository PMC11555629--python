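"""Reciprocal-best-hit (RBH) orthology against a hub proteome.

Pairwise homology-search results (12-column tabular format, the BLAST/Diamond
``outfmt 6`` dialect) are reduced per query to a single best hit by bitscore;
a hub protein and a species protein form an ortholog pair when each is the
other's best hit.  Per-species RBH maps are then consolidated onto the hub
protein ids, and groups with a member in every species form the common
ortholog set — the candidate universe for cross-species scoring.

Only 1:1 orthology is inferred; many-to-many paralogy and tree-based
orthology are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

#: Column names of the 12-column tabular hit format (outfmt-6 dialect).
HIT_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)

_NUMERIC = {
    "pident": float,
    "length": int,
    "mismatch": int,
    "gapopen": int,
    "qstart": int,
    "qend": int,
    "sstart": int,
    "send": int,
    "evalue": float,
    "bitscore": float,
}

#: Default e-value cutoff, applied at parse time so both search directions
#: see the same filtered universe (mirrors passing ``-e 1e-3`` to the search).
DEFAULT_EVALUE_CUTOFF = 1e-3


def parse_hits(path: Path | str, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF) -> pd.DataFrame:
    """Parse a headerless 12-column hit table, dropping hits above the cutoff."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty hit table", path)
        return pd.DataFrame(
            {c: pd.Series(dtype=t) for c, t in
             [("qseqid", object), ("sseqid", object)] + list(_NUMERIC.items())}
        )
    if df.shape[1] != len(HIT_COLUMNS):
        raise DataError(
            f"{path}: expected 12 tab-separated columns per line, found {df.shape[1]}"
        )
    df.columns = list(HIT_COLUMNS)
    try:
        df = df.astype(_NUMERIC)
    except (ValueError, TypeError) as exc:
        raise DataError(f"{path}: unparseable numeric field ({exc})") from exc
    if (df["evalue"] < 0).any():
        raise DataError(f"{path}: negative e-value")
    kept = df[df["evalue"] <= evalue_cutoff].reset_index(drop=True)
    if kept.empty and len(df):
        logger.warning("%s: no hits pass e-value cutoff %g", path, evalue_cutoff)
    return kept


def best_hit(hits: pd.DataFrame, exclude_self: bool = True) -> pd.Series:
    """Best subject per query: max bitscore, ties by lower e-value, then
    longer alignment, then lexicographically smallest subject id.

    Multiple HSPs for the same (query, subject) are first collapsed to the
    max-bitscore one.  Returns a Series mapping ``qseqid -> sseqid``.
    """
    if hits.empty:
        return pd.Series(dtype=object, name="sseqid")
    df = hits
    if exclude_self:
        df = df[df["qseqid"] != df["sseqid"]]
    ordered = df.sort_values(
        by=["bitscore", "evalue", "length", "sseqid"],
        ascending=[False, True, False, True],
        kind="mergesort",
    )
    # collapse HSPs, then take the top row per query under the same ordering
    collapsed = ordered.drop_duplicates(subset=["qseqid", "sseqid"], keep="first")
    top = collapsed.drop_duplicates(subset=["qseqid"], keep="first")
    return top.set_index("qseqid")["sseqid"]


@dataclass
class RBHMap:
    """1:1 ortholog pairs between the hub proteome and one species."""

    species: str
    pairs: pd.DataFrame  # columns: hub_id, member_id

    def __post_init__(self) -> None:
        for col in ("hub_id", "member_id"):
            if self.pairs[col].duplicated().any():
                dup = self.pairs[col][self.pairs[col].duplicated()].iloc[0]
                raise DataError(
                    f"{self.species}: id {dup!r} appears twice in RBH map "
                    f"(column {col}); RBH must be 1:1"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def as_series(self) -> pd.Series:
        return self.pairs.set_index("hub_id")["member_id"]


def reciprocal_best_hits(
    hits_hub_to_sp: pd.DataFrame, hits_sp_to_hub: pd.DataFrame, species: str = ""
) -> RBHMap:
    """Pairs (h, s) where s is h's best hit and h is s's best hit."""
    fwd = best_hit(hits_hub_to_sp)  # hub query -> species subject
    rev = best_hit(hits_sp_to_hub)  # species query -> hub subject
    if fwd.empty or rev.empty:
        pairs = pd.DataFrame({"hub_id": pd.Series(dtype=object), "member_id": pd.Series(dtype=object)})
        return RBHMap(species=species, pairs=pairs)
    back = fwd.map(rev)  # hub query -> best hit of its best hit
    keep = back == back.index.to_series()
    pairs = (
        pd.DataFrame({"hub_id": fwd.index[keep], "member_id": fwd[keep].to_numpy()})
        .sort_values("hub_id", kind="mergesort")
        .reset_index(drop=True)
    )
    return RBHMap(species=species, pairs=pairs)


def consolidate(
    rbh_maps: Mapping[str, RBHMap], hub_ids: Iterable[str]
) -> pd.DataFrame:
    """Consolidate per-species RBH maps onto hub protein ids.

    Returns a frame indexed by ``hub_id`` with one member-id column per
    species (NaN where absent) and a boolean ``is_common`` column set iff a
    member exists for every species in ``rbh_maps``.  Hub ids never seen in
    any map but listed in ``hub_ids`` get all-absent rows.
    """
    hub_index = pd.Index(pd.unique(pd.Series(list(hub_ids), dtype=object)), name="hub_id")
    members = {}
    for species, rbh in rbh_maps.items():
        series = rbh.as_series()
        if series.index.has_duplicates or series.duplicated().any():
            raise DataError(f"{species}: RBH map is not 1:1")
        members[species] = series
    groups = pd.DataFrame(members)
    groups = groups.reindex(hub_index.union(groups.index, sort=False).rename("hub_id"))
    groups = groups.sort_index(kind="mergesort")
    if rbh_maps:
        groups["is_common"] = groups[list(rbh_maps)].notna().all(axis=1)
    else:
        groups["is_common"] = False
    return groups


def rbh_counts(rbh_maps: Mapping[str, RBHMap]) -> dict[str, int]:
    """Per-species reciprocal-best-hit counts (summary-table bookkeeping)."""
    return {species: len(rbh) for species, rbh in rbh_maps.items()}
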