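"""End-to-end orchestration: expression -> per-species scores -> RBH ->
common orthologs -> total IO-scores -> DEG calls -> reports.

The pipeline is deterministic: identical inputs and configuration produce
byte-identical output tables.  Every stage logs its record counts so that
records in = records out + dropped holds across the run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .aggregate import (
    annotate,
    call_degs,
    composition_table,
    derive_total_threshold,
    rank_records,
    total_io_score,
)
from .errors import DataError, ValidationError
from .orthology import consolidate, parse_hits, rbh_counts, reciprocal_best_hits
from .scoring import (
    ExpressionMatrix,
    ScoringParams,
    SpeciesScoreTable,
    ratio_sd_diagnostic,
    read_expression,
    read_manifest,
    score_species,
)
from .simulate import SimBundle, read_fixture_bundle

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    ``expression`` maps species -> {"format": ..., "files": [...]} (or a
    directory with ``glob``).  Hit tables live in ``hits_dir`` as
    ``hub__to__<sp>.tsv`` / ``<sp>__to__hub.tsv`` unless declared per
    species under ``hits``.
    """

    manifest: Path
    expression: dict
    hub: str
    out_dir: Path
    hits_dir: Path | None = None
    hits: dict | None = None
    annotation: Path | None = None
    pseudocount: float = 0.01
    fold_threshold: float = 5.0
    threshold_fraction: float = 0.2
    evalue_cutoff: float = 1e-3
    missing_policy: str = "error"
    strict: bool = True

    def __post_init__(self) -> None:
        self.manifest = Path(self.manifest)
        self.out_dir = Path(self.out_dir)
        if self.hits_dir is not None:
            self.hits_dir = Path(self.hits_dir)
        if self.annotation is not None:
            self.annotation = Path(self.annotation)
        if not 0 < self.threshold_fraction <= 1:
            raise ValidationError(
                f"threshold_fraction must lie in (0, 1], got {self.threshold_fraction}"
            )
        if self.missing_policy not in ("error", "zero"):
            raise ValidationError(f"unknown missing policy {self.missing_policy!r}")

    @property
    def params(self) -> ScoringParams:
        return ScoringParams(
            pseudocount=self.pseudocount, fold_threshold=self.fold_threshold
        )

    @classmethod
    def from_yaml(cls, path: Path | str, **overrides) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        d.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**d)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}


@dataclass
class PipelineResult:
    """In-memory results of one pipeline run."""

    species_tables: dict[str, SpeciesScoreTable]
    diagnostics: pd.DataFrame
    rbh_maps: dict
    groups: pd.DataFrame
    records: pd.DataFrame  # ranked total-score records with calls
    threshold: int
    up: pd.DataFrame
    down: pd.DataFrame
    unchanged: pd.DataFrame
    composition: pd.DataFrame
    summary: dict


def run_scoring(
    matrices: Mapping[str, ExpressionMatrix],
    manifest: pd.DataFrame,
    params: ScoringParams,
) -> tuple[dict[str, SpeciesScoreTable], pd.DataFrame]:
    """Score every species and collect the ratio-SD diagnostics table."""
    tables: dict[str, SpeciesScoreTable] = {}
    diag_rows = []
    for sp in sorted(matrices):
        table = score_species(matrices[sp], manifest, params)
        tables[sp] = table
        d = ratio_sd_diagnostic(table)
        diag_rows.append(
            (sp, table.n_pairs, d.mean, d.sd, d.fold_at_2sd, d.n)
        )
        logger.info(
            "%s: %d transcripts x %d pairs scored (ratio SD %.3f, fold at 2SD %.2f)",
            sp, len(table.scores), table.n_pairs, d.sd, d.fold_at_2sd,
        )
    diagnostics = pd.DataFrame(
        diag_rows, columns=["species", "n_pairs", "ratio_mean", "ratio_sd",
                            "fold_at_2sd", "n_ratios"]
    )
    return tables, diagnostics


def run_pipeline(
    matrices: Mapping[str, ExpressionMatrix],
    manifest: pd.DataFrame,
    hit_tables: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
    hub: str,
    hub_ids: Sequence[str] | None = None,
    params: ScoringParams | None = None,
    threshold_fraction: float = 0.2,
    annotation: pd.DataFrame | None = None,
    strict: bool = False,
) -> PipelineResult:
    """Run scoring, orthology and aggregation on in-memory inputs.

    ``hit_tables`` maps each non-hub species to its (hub_to_sp, sp_to_hub)
    parsed hit tables.  ``hub_ids`` defaults to the hub species' transcript
    ids (protein and transcript ids coincide, one ORF per transcript).
    """
    params = params or ScoringParams()
    if hub not in matrices:
        raise DataError(f"hub species {hub!r} has no expression matrix")
    tables, diagnostics = run_scoring(matrices, manifest, params)

    rbh_maps = {}
    for sp in sorted(hit_tables):
        fwd, rev = hit_tables[sp]
        rbh_maps[sp] = reciprocal_best_hits(fwd, rev, species=sp)
    if hub_ids is None:
        hub_ids = list(matrices[hub].transcript_ids)
    groups = consolidate(rbh_maps, hub_ids)
    n_common = int(groups["is_common"].sum())
    logger.info(
        "consolidated %d hub proteins into %d groups, %d common to all species",
        len(hub_ids), len(groups), n_common,
    )

    records = total_io_score(groups, {**tables, hub: tables[hub]}, strict=strict)
    n_pairs_total = int(sum(t.n_pairs for t in tables.values()))
    threshold = derive_total_threshold(n_pairs_total, threshold_fraction)
    up, down, unchanged = call_degs(records, threshold)
    records = rank_records(
        pd.concat([up, down, unchanged]) if len(records) else records.assign(call=[], rank=[])
    )

    unmapped = None
    if annotation is not None:
        records, unmapped = annotate(records, annotation)
        logger.info(
            "annotation: %d of %d records mapped to a reference gene",
            len(records) - unmapped, len(records),
        )

    composition = composition_table(pd.concat([up, down])) if len(up) + len(down) else (
        pd.DataFrame(columns=["hub_id", "species", "contribution", "single_species"])
    )

    summary = {
        "tool_version": __version__,
        "n_species": len(tables),
        "pairs_per_species": {sp: t.n_pairs for sp, t in tables.items()},
        "n_pairs_total": n_pairs_total,
        "threshold_fraction": threshold_fraction,
        "threshold": threshold,
        "rbh_counts": rbh_counts(rbh_maps),
        "n_groups": len(groups),
        "n_common_orthologs": n_common,
        "n_scored": len(records),
        "n_up": len(up),
        "n_down": len(down),
        "n_unchanged": len(unchanged),
        "n_single_species": int(records["single_species"].sum()) if len(records) else 0,
    }
    if unmapped is not None:
        summary["n_unmapped_annotation"] = unmapped
    return PipelineResult(
        species_tables=tables, diagnostics=diagnostics, rbh_maps=rbh_maps,
        groups=groups, records=records, threshold=threshold,
        up=up, down=down, unchanged=unchanged,
        composition=composition, summary=summary,
    )


def run_on_bundle(
    bundle: SimBundle,
    params: ScoringParams | None = None,
    threshold_fraction: float = 0.2,
) -> PipelineResult:
    """Convenience: run the full pipeline on a simulated fixture bundle."""
    return run_pipeline(
        matrices=bundle.matrices,
        manifest=bundle.manifest,
        hit_tables={sp: (p.hub_to_sp, p.sp_to_hub) for sp, p in bundle.hit_tables.items()},
        hub=bundle.config.hub,
        hub_ids=list(bundle.truth.hub_universe()),
        params=params,
        threshold_fraction=threshold_fraction,
    )


def _float_fmt(x) -> str:
    return f"{x:.6f}"


def write_outputs(result: PipelineResult, out_dir: Path | str) -> Path:
    """Write all report tables of a run.

    Emits per-species score and ratio tables, the RBH map, the common
    ortholog list, ``total_scores.tsv``, ``composition.tsv``,
    ``sd_diagnostic.tsv`` and ``summary.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sp, table in result.species_tables.items():
        table.scores.to_csv(out / f"scores_{sp}.tsv", sep="\t")
        table.ratios.to_csv(
            out / f"ratios_{sp}.tsv", sep="\t", index=False, float_format="%.6f"
        )
    rbh_rows = []
    for sp, rbh in result.rbh_maps.items():
        for _, row in rbh.pairs.iterrows():
            rbh_rows.append((row.hub_id, sp, row.member_id))
    pd.DataFrame(rbh_rows, columns=["hub_id", "species", "member_id"]).to_csv(
        out / "rbh.tsv", sep="\t", index=False
    )
    common = result.groups.index[result.groups["is_common"]]
    pd.Series(common, name="hub_id").to_csv(out / "common_orthologs.tsv",
                                            sep="\t", index=False)
    result.records.to_csv(out / "total_scores.tsv", sep="\t")
    result.composition.to_csv(out / "composition.tsv", sep="\t", index=False)
    result.diagnostics.to_csv(
        out / "sd_diagnostic.tsv", sep="\t", index=False, float_format="%.6f"
    )
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2) + "\n")
    return out


def run_from_config(config: RunConfig) -> PipelineResult:
    """Disk-to-disk pipeline run driven by a :class:`RunConfig`."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(config.out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("ioscore")
    root.addHandler(handler)
    try:
        logger.info("ioscore %s starting run", __version__)
        manifest = read_manifest(config.manifest)
        matrices = {}
        for sp, decl in config.expression.items():
            files = decl.get("files")
            if files is None:
                pattern = decl.get("glob", "*.quant.sf")
                files = sorted(Path(decl["dir"]).glob(pattern))
            matrices[sp] = read_expression(
                files, species=sp,
                format=decl.get("format", "quant_sf"),
                missing=config.missing_policy,
            )
        # validate manifest samples before heavier stages
        for sp, sub in manifest.groupby("species"):
            if sp not in matrices:
                raise DataError(f"manifest species {sp!r} has no expression files")
            known = set(matrices[sp].sample_ids)
            for col in ("intersexual_sample", "ovary_sample"):
                missing = set(sub[col]) - known
                if missing:
                    raise DataError(
                        f"manifest references missing sample {sorted(missing)[0]!r} "
                        f"for species {sp!r}"
                    )
        hit_tables = {}
        for sp in matrices:
            if sp == config.hub:
                continue
            if config.hits and sp in config.hits:
                fwd_path = Path(config.hits[sp]["hub_to_sp"])
                rev_path = Path(config.hits[sp]["sp_to_hub"])
            elif config.hits_dir is not None:
                fwd_path = config.hits_dir / f"hub__to__{sp}.tsv"
                rev_path = config.hits_dir / f"{sp}__to__hub.tsv"
            else:
                raise ValidationError("neither hits_dir nor per-species hits declared")
            hit_tables[sp] = (
                parse_hits(fwd_path, config.evalue_cutoff),
                parse_hits(rev_path, config.evalue_cutoff),
            )
        annotation = None
        if config.annotation is not None:
            annotation = pd.read_csv(config.annotation, sep="\t")
        result = run_pipeline(
            matrices=matrices, manifest=manifest, hit_tables=hit_tables,
            hub=config.hub, params=config.params,
            threshold_fraction=config.threshold_fraction,
            annotation=annotation, strict=config.strict,
        )
        write_outputs(result, config.out_dir)
        (config.out_dir / "config_echo.yaml").write_text(
            yaml.safe_dump(config.echo(), sort_keys=True)
        )
        return result
    finally:
        root.removeHandler(handler)
        handler.close()


def run_bundle_dir(
    bundle_dir: Path | str,
    out_dir: Path | str,
    params: ScoringParams | None = None,
    threshold_fraction: float = 0.2,
) -> PipelineResult:
    """Run the pipeline on a fixture bundle directory and write reports."""
    bundle = read_fixture_bundle(bundle_dir)
    result = run_on_bundle(bundle, params=params, threshold_fraction=threshold_fraction)
    write_outputs(result, out_dir)
    return result


def write_report(out_dir: Path | str, plot: bool = False) -> Path:
    """Derive plot-ready report tables from a completed run directory.

    Writes ``report/rank_table.tsv`` (rank, total, call per hub id) next to
    the existing composition and SD-diagnostic tables; with ``plot=True`` and
    matplotlib available, renders the descending total-score scatter.
    """
    out = Path(out_dir)
    scores_path = out / "total_scores.tsv"
    if not scores_path.exists():
        raise DataError(f"{out}: no completed run found (total_scores.tsv missing)")
    records = pd.read_csv(scores_path, sep="\t", index_col="hub_id")
    report = out / "report"
    report.mkdir(exist_ok=True)
    rank_table = records.sort_values("rank")[["rank", "total", "call"]]
    rank_table.to_csv(report / "rank_table.tsv", sep="\t")
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        colors = rank_table["call"].map(
            {"up": "tab:red", "down": "tab:blue", "unchanged": "0.6"}
        )
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.scatter(rank_table["rank"], rank_table["total"], s=4, c=colors)
        ax.set_xlabel("gene rank (descending total IO-score)")
        ax.set_ylabel("total IO-score")
        fig.tight_layout()
        fig.savefig(report / "rank_scatter.png", dpi=150)
        plt.close(fig)
    return report
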