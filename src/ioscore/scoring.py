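"""Paired intersexual/ovary expression scoring.

The unit of analysis is a curated sample pair: one intersexual (transitional)
gonad library and one ovary library from the same species.  For each
transcript and pair the IO-ratio is

    io_ratio = log2(TPM_intersexual + c) - log2(TPM_ovary + c)

with pseudocount ``c`` (default 0.01 TPM) keeping the logarithm finite at
zero expression.  A pair is labelled ``upregulated`` when the ratio strictly
exceeds ``log2(fold_threshold)`` (default 5-fold), ``downregulated`` when it
is strictly below the negation, and ``unchanged`` otherwise; ratios exactly
at the boundary are unchanged.  The per-species IO-score of a transcript is
the count of upregulated pairs minus the count of downregulated pairs.

Ratios are computed pair by pair, never on averaged replicates, which is
what makes the score robust to study-to-study batch differences: each pair
is compared only with itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

logger = logging.getLogger(__name__)

LABEL_UP = "upregulated"
LABEL_DOWN = "downregulated"
LABEL_UNCHANGED = "unchanged"
LABELS = (LABEL_UP, LABEL_DOWN, LABEL_UNCHANGED)

#: Header of the Salmon ``quant.sf`` dialect.  Only Name and TPM are consumed.
QUANT_SF_COLUMNS = ("Name", "Length", "EffectiveLength", "TPM", "NumReads")

MANIFEST_COLUMNS = ("species", "pair_id", "intersexual_sample", "ovary_sample")


@dataclass(frozen=True)
class ScoringParams:
    """Pseudocount (TPM units) and fold-change cutoff for pair labelling."""

    pseudocount: float = 0.01
    fold_threshold: float = 5.0

    def __post_init__(self) -> None:
        if not self.pseudocount > 0:
            raise ValidationError(f"pseudocount must be > 0, got {self.pseudocount}")
        if not self.fold_threshold > 1:
            raise ValidationError(
                f"fold_threshold must be > 1, got {self.fold_threshold}"
            )

    @property
    def log2_cutoff(self) -> float:
        return math.log2(self.fold_threshold)


@dataclass
class ExpressionMatrix:
    """Transcript x sample TPM table for one species.

    ``data`` is indexed by transcript id with one column per sample id.
    """

    species: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DataError(f"{self.species}: duplicate transcript id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise DataError(f"{self.species}: duplicate sample id {dup!r}")
        values = self.data.to_numpy()
        if np.isnan(values).any():
            raise DataError(f"{self.species}: expression matrix contains missing TPMs")
        if (values < 0).any():
            raise DataError(f"{self.species}: negative TPM values present")

    @property
    def transcript_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns


@dataclass
class SpeciesScoreTable:
    """Per-pair IO-ratios/labels and per-transcript IO-scores for one species.

    Attributes
    ----------
    ratios : long table ``transcript_id, pair_id, io_ratio, label``.
    scores : table ``transcript_id, io_score, n_up, n_down, n_unchanged``
        indexed by transcript id.
    """

    species: str
    ratios: pd.DataFrame
    scores: pd.DataFrame
    n_pairs: int

    def io_score(self) -> pd.Series:
        return self.scores["io_score"]


def _read_quant_sf(path: Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    missing = set(("Name", "TPM")) - set(df.columns)
    if missing:
        raise DataError(
            f"{path}: malformed quant.sf header, missing column(s) {sorted(missing)}"
        )
    return df.set_index("Name")["TPM"]


def _read_tsv(path: Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    missing = set(("transcript_id", "tpm")) - set(df.columns)
    if missing:
        raise DataError(f"{path}: expected header with columns transcript_id, tpm")
    return df.set_index("transcript_id")["tpm"]


def read_expression(
    files: Mapping[str, Path | str] | Sequence[Path | str],
    species: str,
    format: str = "quant_sf",
    missing: str = "error",
) -> ExpressionMatrix:
    """Read per-sample abundance files into one expression matrix.

    Parameters
    ----------
    files
        Either a mapping ``sample_id -> path`` or a sequence of paths, in
        which case the sample id is the file stem (with a trailing
        ``.quant`` stripped).
    format
        ``"quant_sf"`` (tab-separated Salmon dialect, Name/TPM consumed) or
        ``"tsv"`` (two columns ``transcript_id``, ``tpm``, header required).
    missing
        Policy for transcripts present in some samples but not all:
        ``"error"`` (default) raises naming the transcript; ``"zero"``
        imputes TPM 0 with a logged warning (the pseudocount keeps the
        ratio finite).
    """
    if format not in ("quant_sf", "tsv"):
        raise ValidationError(f"unknown expression format {format!r}")
    if missing not in ("error", "zero"):
        raise ValidationError(f"unknown missing-transcript policy {missing!r}")
    reader = _read_quant_sf if format == "quant_sf" else _read_tsv

    if isinstance(files, Mapping):
        items = [(sid, Path(p)) for sid, p in files.items()]
    else:
        items = []
        for p in files:
            p = Path(p)
            stem = p.stem
            if stem.endswith(".quant"):
                stem = stem[: -len(".quant")]
            items.append((stem, p))
    if not items:
        raise DataError(f"{species}: no expression files given")

    columns: dict[str, pd.Series] = {}
    for sample_id, path in items:
        if not path.exists():
            raise DataError(
                f"{species}: no abundance file for sample {sample_id!r} ({path})"
            )
        series = reader(path)
        if series.index.has_duplicates:
            dup = series.index[series.index.duplicated()][0]
            raise DataError(f"{path}: duplicate transcript id {dup!r}")
        if (series < 0).any():
            tid = series.index[series < 0][0]
            raise DataError(f"{path}: negative TPM for transcript {tid!r}")
        columns[sample_id] = series

    matrix = pd.DataFrame(columns)  # outer join on transcript ids
    if matrix.isna().any().any():
        if missing == "error":
            bad = matrix.index[matrix.isna().any(axis=1)]
            raise DataError(
                f"{species}: transcript {bad[0]!r} missing from at least one "
                f"sample ({len(bad)} transcripts affected); use missing='zero' "
                "to impute zeros"
            )
        n = int(matrix.isna().to_numpy().sum())
        logger.warning("%s: imputed %d missing TPM entries as 0", species, n)
        matrix = matrix.fillna(0.0)
    return ExpressionMatrix(species=species, data=matrix.astype(float))


def read_manifest(path: Path | str) -> pd.DataFrame:
    """Read and validate a curated sample-pair manifest (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_manifest(df)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise DataError(f"manifest missing column(s) {sorted(missing)}")
    dup = manifest.duplicated(subset=["species", "pair_id"])
    if dup.any():
        row = manifest[dup].iloc[0]
        raise DataError(
            f"duplicate pair_id {row.pair_id!r} within species {row.species!r}"
        )
    same = manifest["intersexual_sample"] == manifest["ovary_sample"]
    if same.any():
        row = manifest[same].iloc[0]
        raise DataError(
            f"pair {row.pair_id!r} ({row.species}) uses the same sample twice"
        )
    return manifest.loc[:, list(MANIFEST_COLUMNS)].reset_index(drop=True)


def compute_io_ratio(tpm_intersexual, tpm_ovary, params: ScoringParams | None = None):
    """log2 ratio of pseudocount-adjusted TPMs (intersexual over ovary).

    Accepts scalars or arrays; negative TPMs raise :class:`DataError`.
    Antisymmetric in its arguments and strictly monotone in each.
    """
    params = params or ScoringParams()
    a = np.asarray(tpm_intersexual, dtype=float)
    b = np.asarray(tpm_ovary, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise DataError("TPM values must be non-negative")
    ratio = np.log2(a + params.pseudocount) - np.log2(b + params.pseudocount)
    if ratio.ndim == 0:
        return float(ratio)
    return ratio


def classify_ratio(io_ratio, params: ScoringParams | None = None):
    """Label ratios against the fold cutoff; boundary values are unchanged.

    The inequalities are strict: ``up`` iff ratio > log2(fold_threshold),
    ``down`` iff ratio < -log2(fold_threshold).
    """
    params = params or ScoringParams()
    cutoff = params.log2_cutoff
    r = np.asarray(io_ratio, dtype=float)
    out = np.where(r > cutoff, LABEL_UP, np.where(r < -cutoff, LABEL_DOWN, LABEL_UNCHANGED))
    if out.ndim == 0:
        return str(out)
    return out


def species_io_score(labels: pd.DataFrame) -> pd.Series:
    """IO-score per transcript: count(up) - count(down) across pairs.

    ``labels`` is a long table with columns ``transcript_id, pair_id, label``;
    every (transcript, pair) must carry a label.
    """
    if labels["label"].isna().any():
        row = labels[labels["label"].isna()].iloc[0]
        raise DataError(
            f"missing label for transcript {row.transcript_id!r}, pair {row.pair_id!r}"
        )
    bad = set(labels["label"]) - set(LABELS)
    if bad:
        raise DataError(f"unknown label(s) {sorted(bad)}")
    signed = labels["label"].map({LABEL_UP: 1, LABEL_DOWN: -1, LABEL_UNCHANGED: 0})
    return (
        signed.groupby(labels["transcript_id"]).sum().astype(int).rename("io_score")
    )


def score_species(
    expr: ExpressionMatrix,
    manifest: pd.DataFrame,
    params: ScoringParams | None = None,
) -> SpeciesScoreTable:
    """Compute IO-ratios, labels and IO-scores for one species.

    Every pair in the manifest rows for ``expr.species`` must reference
    samples present in the matrix.
    """
    params = params or ScoringParams()
    sub = manifest[manifest["species"] == expr.species]
    if sub.empty:
        raise DataError(f"manifest has no pairs for species {expr.species!r}")
    for col in ("intersexual_sample", "ovary_sample"):
        unknown = set(sub[col]) - set(expr.sample_ids)
        if unknown:
            raise DataError(
                f"{expr.species}: manifest sample {sorted(unknown)[0]!r} not in "
                "expression matrix"
            )

    tpm_i = expr.data[list(sub["intersexual_sample"])].to_numpy()
    tpm_o = expr.data[list(sub["ovary_sample"])].to_numpy()
    ratios = np.log2(tpm_i + params.pseudocount) - np.log2(tpm_o + params.pseudocount)
    cutoff = params.log2_cutoff
    up = ratios > cutoff
    down = ratios < -cutoff

    n_t, n_p = ratios.shape
    long = pd.DataFrame(
        {
            "transcript_id": np.repeat(expr.transcript_ids.to_numpy(), n_p),
            "pair_id": np.tile(sub["pair_id"].to_numpy(), n_t),
            "io_ratio": ratios.ravel(),
            "label": np.where(
                up.ravel(), LABEL_UP, np.where(down.ravel(), LABEL_DOWN, LABEL_UNCHANGED)
            ),
        }
    )
    scores = pd.DataFrame(
        {
            "io_score": (up.sum(axis=1) - down.sum(axis=1)).astype(int),
            "n_up": up.sum(axis=1).astype(int),
            "n_down": down.sum(axis=1).astype(int),
            "n_unchanged": (n_p - up.sum(axis=1) - down.sum(axis=1)).astype(int),
        },
        index=expr.transcript_ids.rename("transcript_id"),
    )
    return SpeciesScoreTable(
        species=expr.species, ratios=long, scores=scores, n_pairs=n_p
    )


@dataclass(frozen=True)
class RatioSD:
    """Pooled IO-ratio dispersion for one species.

    ``fold_at_2sd = 2**(2*sd)`` is the fold change sitting at the +2 SD edge
    of the pooled ratio distribution, directly comparable with the 5-fold
    calling cutoff.
    """

    species: str
    mean: float
    sd: float
    fold_at_2sd: float
    n: int


def ratio_sd_diagnostic(
    table: SpeciesScoreTable, min_tpm_ratio_count: int = 0
) -> RatioSD:
    """Mean/SD of all pooled IO-ratios and the fold change at +-2 SD.

    All transcripts and pairs are pooled into one distribution per species.
    ``min_tpm_ratio_count`` optionally drops transcripts whose ratio is 0 in
    every pair (typically all-zero expression) when set to 1; the default
    pools everything.
    """
    ratios = table.ratios
    if min_tpm_ratio_count:
        nonzero = ratios.groupby("transcript_id")["io_ratio"].transform(
            lambda s: (s != 0).sum()
        )
        ratios = ratios[nonzero >= min_tpm_ratio_count]
    values = ratios["io_ratio"].to_numpy()
    if values.size < 2:
        raise DataError("ratio SD diagnostic needs at least 2 ratios")
    sd = float(np.std(values, ddof=1))
    return RatioSD(
        species=table.species,
        mean=float(np.mean(values)),
        sd=sd,
        fold_at_2sd=float(2.0 ** (2.0 * sd)),
        n=values.size,
    )
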