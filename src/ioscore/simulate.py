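"""Synthetic cross-species fixture bundles.

Emulates the shape of a multi-species gonadal RNA-seq meta-analysis dataset:
an ortholog universe over ``n_species`` species anchored on a designated hub
proteome, species-specific ortholog absence, paralog decoys in the homology
hit tables, and paired intersexual/ovary TPM tables with planted fold
effects.  The defaults reproduce the study design the scoring method was
built for: 7 species with (4, 2, 2, 6, 2, 12, 3) sample pairs (31 in total),
a 25-fold planted effect in 1% of orthologs per direction, log-normal
baselines, 0.25 log2 noise on the intersexual member of each pair, and 2%
zero-dropout.

Generative model, per (transcript, pair):

    ovary log2-TPM       ~  Normal(baseline_log2_mean, baseline_log2_sd)
    intersexual log2-TPM =  ovary + s * log2(effect_fold) + Normal(0, noise_sd)

with s = +1 for planted-up orthologs, -1 for planted-down, 0 otherwise, so a
pair's IO-ratio is Normal(s * log2(effect_fold), noise_sd) before dropout.
Dropout zeroes individual TPM entries independently.  TPMs are deliberately
NOT renormalised to sum to 1e6 per sample: the scoring consumes ratios only,
and renormalisation would couple transcripts.

One master seed drives everything; per-species and per-stage substreams are
derived from it deterministically, so an identical config yields a
byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, ValidationError
from .orthology import HIT_COLUMNS
from .scoring import ExpressionMatrix, MANIFEST_COLUMNS, QUANT_SF_COLUMNS, read_expression, read_manifest

logger = logging.getLogger(__name__)

TRUTH_COLUMNS = ("ortholog_id", "planted_class", "species", "member_id", "present")

CLASS_UP = "up"
CLASS_DOWN = "down"
CLASS_NULL = "null"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    ``presence_prob`` may be a single probability applied to every non-hub
    species or a per-species sequence (the hub always retains everything).
    ``break_reciprocity_frac`` is the fraction of decoy paralogs made the
    best hit in one search direction only; such decoys never displace a true
    ortholog pair.
    """

    n_species: int = 7
    hub_index: int = 0
    n_orthologs: int = 5000
    presence_prob: float | tuple[float, ...] = 0.9
    pairs_per_species: tuple[int, ...] = (4, 2, 2, 6, 2, 12, 3)
    frac_up: float = 0.01
    frac_down: float = 0.01
    effect_fold: float = 25.0
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    noise_sd: float = 0.25
    dropout_prob: float = 0.02
    n_paralogs: int = 100
    break_reciprocity_frac: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValidationError("n_species must be >= 2")
        if not 0 <= self.hub_index < self.n_species:
            raise ValidationError("hub_index out of range")
        if self.n_orthologs < 1:
            raise ValidationError("empty universe: n_orthologs must be >= 1")
        object.__setattr__(self, "pairs_per_species", tuple(int(p) for p in self.pairs_per_species))
        if any(p < 1 for p in self.pairs_per_species):
            raise ValidationError("every species needs at least one sample pair")
        if len(self.pairs_per_species) != self.n_species:
            raise ValidationError(
                "pairs_per_species must have exactly one entry per species"
            )
        probs = self.presence_probs()
        if ((probs < 0) | (probs > 1)).any():
            raise ValidationError("presence_prob values must lie in [0, 1]")
        for name in ("frac_up", "frac_down", "dropout_prob", "break_reciprocity_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_up + self.frac_down > 1:
            raise ValidationError("frac_up + frac_down must be <= 1")
        if not self.effect_fold > 1:
            raise ValidationError("effect_fold must be > 1")
        if self.noise_sd < 0 or self.baseline_log2_sd < 0:
            raise ValidationError("standard deviations must be non-negative")
        if self.n_paralogs < 0:
            raise ValidationError("n_paralogs must be >= 0")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(f"sp{i + 1}" for i in range(self.n_species))

    @property
    def hub(self) -> str:
        return self.species[self.hub_index]

    def presence_probs(self) -> np.ndarray:
        """Per-species retention probability; the hub entry is forced to 1."""
        if isinstance(self.presence_prob, (int, float)):
            probs = np.full(self.n_species, float(self.presence_prob))
        else:
            probs = np.asarray(self.presence_prob, dtype=float)
            if probs.shape != (self.n_species,):
                raise ValidationError(
                    "presence_prob sequence must have one entry per species"
                )
        probs = probs.copy()
        probs[self.hub_index] = 1.0
        return probs

    def to_yaml(self, path: Path) -> None:
        d = dataclasses.asdict(self)
        d["pairs_per_species"] = list(self.pairs_per_species)
        if isinstance(d["presence_prob"], tuple):
            d["presence_prob"] = list(d["presence_prob"])
        path.write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if isinstance(d.get("presence_prob"), list):
            d["presence_prob"] = tuple(d["presence_prob"])
        d["pairs_per_species"] = tuple(d["pairs_per_species"])
        return cls(**d)


class HitTablePair(NamedTuple):
    """The two search directions between the hub and one species."""

    hub_to_sp: pd.DataFrame
    sp_to_hub: pd.DataFrame


@dataclass
class TruthTable:
    """Planted ortholog universe: long table over (ortholog, species).

    Columns: ``ortholog_id, planted_class, species, member_id, present``.
    The hub row of every ortholog is always present; ``planted_class`` is
    identical across a group's rows (shared regulation across species).
    ``hub_decoys`` lists extra hub protein ids that belong to no group.
    """

    species: tuple[str, ...]
    hub: str
    table: pd.DataFrame
    hub_decoys: tuple[str, ...] = ()

    def presence(self) -> pd.DataFrame:
        return (
            self.table.pivot(index="ortholog_id", columns="species", values="present")
            .astype(bool)
            .loc[:, list(self.species)]
        )

    def members(self) -> pd.DataFrame:
        return self.table.pivot(
            index="ortholog_id", columns="species", values="member_id"
        ).loc[:, list(self.species)]

    def planted_class(self) -> pd.Series:
        return self.table.groupby("ortholog_id")["planted_class"].first()

    def hub_member(self) -> pd.Series:
        """ortholog_id -> hub protein/transcript id."""
        hub_rows = self.table[self.table["species"] == self.hub]
        return hub_rows.set_index("ortholog_id")["member_id"]

    def common_ids(self) -> pd.Index:
        """Ortholog ids present in every species."""
        return self.presence().all(axis=1).pipe(lambda m: m.index[m])

    def common_hub_ids(self) -> pd.Index:
        return pd.Index(self.hub_member().loc[self.common_ids()].to_numpy(), name="hub_id")

    def hub_universe(self) -> pd.Index:
        """All hub protein ids: one per ortholog plus decoys."""
        return pd.Index(
            list(self.hub_member().to_numpy()) + list(self.hub_decoys), name="hub_id"
        )


@dataclass
class SimBundle:
    """Everything one simulated study comprises, in memory."""

    config: SimConfig
    truth: TruthTable
    matrices: dict[str, ExpressionMatrix]
    manifest: pd.DataFrame
    hit_tables: dict[str, HitTablePair]


def _member_id(species: str, og_index: int) -> str:
    return f"{species}_g{og_index + 1:05d}"


def _format_hits(rows: list[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=list(HIT_COLUMNS))
    return df.astype(
        {
            "pident": float, "length": int, "mismatch": int, "gapopen": int,
            "qstart": int, "qend": int, "sstart": int, "send": int,
            "evalue": float, "bitscore": float,
        }
    )


def _hit_row(rng, q: str, s: str, bitscore: float, evalue: float) -> tuple:
    pident = round(float(rng.uniform(40.0, 99.0)), 1)
    length = int(rng.integers(100, 600))
    mismatch = int(round(length * (1.0 - pident / 100.0)))
    gapopen = int(rng.integers(0, 5))
    return (q, s, pident, length, mismatch, gapopen, 1, length, 1, length,
            evalue, round(float(bitscore), 1))


def simulate_universe(config: SimConfig) -> tuple[TruthTable, dict[str, HitTablePair]]:
    """Plant an ortholog universe and emit consistent reciprocal hit tables.

    For every retained ortholog the hub<->species hits are each other's
    highest-bitscore hits in both directions; paralog decoys receive strictly
    lower bitscores (below 0.9x the true pair) unless they are
    reciprocity-breakers, which become the best hit of a hub protein that has
    no retained partner in that species (so they never displace truth).
    """
    if config.n_orthologs < 1:
        raise ValidationError("empty universe: n_orthologs must be >= 1")
    species = config.species
    hub = config.hub
    n = config.n_orthologs

    ss = np.random.SeedSequence([config.seed, 0])
    rng = np.random.default_rng(ss)

    # planted classes
    n_up = int(round(config.frac_up * n))
    n_down = int(round(config.frac_down * n))
    classes = np.array([CLASS_NULL] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_up]] = CLASS_UP
    classes[order[n_up:n_up + n_down]] = CLASS_DOWN

    # per-species retention
    probs = config.presence_probs()
    presence = rng.random((config.n_species, n)) < probs[:, None]
    presence[config.hub_index, :] = True

    og_ids = [f"og{i + 1:05d}" for i in range(n)]
    rows = []
    for si, sp in enumerate(species):
        for gi in range(n):
            present = bool(presence[si, gi])
            rows.append(
                (og_ids[gi], classes[gi], sp, _member_id(sp, gi) if present else "", present)
            )
    hub_decoys = tuple(f"{hub}_d{k + 1:04d}" for k in range(config.n_paralogs))
    truth = TruthTable(
        species=species,
        hub=hub,
        table=pd.DataFrame(rows, columns=list(TRUTH_COLUMNS)),
        hub_decoys=hub_decoys,
    )

    hub_ids = np.array([_member_id(hub, gi) for gi in range(n)], dtype=object)
    hit_tables: dict[str, HitTablePair] = {}
    for si, sp in enumerate(species):
        if si == config.hub_index:
            continue
        sp_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0, si]))
        retained = np.flatnonzero(presence[si])
        true_bits = np.round(sp_rng.uniform(250.0, 500.0, size=n), 1)

        fwd_rows, rev_rows = [], []
        for gi in retained:
            ev = 10.0 ** (-float(sp_rng.uniform(20.0, 170.0)))
            sp_id = _member_id(sp, gi)
            fwd_rows.append(_hit_row(sp_rng, hub_ids[gi], sp_id, true_bits[gi], ev))
            rev_rows.append(_hit_row(sp_rng, sp_id, hub_ids[gi], true_bits[gi], ev))

        n_break = int(round(config.break_reciprocity_frac * config.n_paralogs))
        # hub proteins with no retained partner here: decoy hub ids + dropped orthologs
        absent = np.flatnonzero(~presence[si])
        free_targets = list(hub_decoys) + [hub_ids[gi] for gi in absent]
        for k in range(config.n_paralogs):
            decoy = f"{sp}_d{k + 1:04d}"
            ev = 10.0 ** (-float(sp_rng.uniform(4.0, 20.0)))
            if k < n_break and free_targets:
                target = free_targets[int(sp_rng.integers(len(free_targets)))]
                # best (only) hit of `target` in hub->sp, but the decoy's own
                # best hit points elsewhere: reciprocity fails by design
                fwd_rows.append(_hit_row(sp_rng, target, decoy,
                                         float(sp_rng.uniform(250.0, 500.0)), ev))
                if len(retained):
                    gj = retained[int(sp_rng.integers(len(retained)))]
                    rev_rows.append(_hit_row(sp_rng, decoy, hub_ids[gj],
                                             0.8 * true_bits[gj], ev))
            elif len(retained):
                gj = retained[int(sp_rng.integers(len(retained)))]
                frac = float(sp_rng.uniform(0.3, 0.85))
                fwd_rows.append(_hit_row(sp_rng, hub_ids[gj], decoy,
                                         frac * true_bits[gj], ev))
                rev_rows.append(_hit_row(sp_rng, decoy, hub_ids[gj],
                                         frac * true_bits[gj], ev))
            else:
                # no retained orthologs: one-direction noise hit only
                rev_rows.append(_hit_row(sp_rng, decoy, hub_ids[int(sp_rng.integers(n))],
                                         float(sp_rng.uniform(100.0, 200.0)), ev))
        hit_tables[sp] = HitTablePair(
            hub_to_sp=_format_hits(fwd_rows), sp_to_hub=_format_hits(rev_rows)
        )
    return truth, hit_tables


def simulate_expression(
    config: SimConfig, truth: TruthTable
) -> tuple[dict[str, ExpressionMatrix], pd.DataFrame]:
    """Paired TPM tables per species plus the curated pair manifest."""
    if len(config.pairs_per_species) != config.n_species:
        raise ValidationError(
            "pairs_per_species must have exactly one entry per species"
        )
    presence = truth.presence()
    members = truth.members()
    classes = truth.planted_class()
    sign = classes.map({CLASS_UP: 1.0, CLASS_DOWN: -1.0, CLASS_NULL: 0.0})
    shift = math.log2(config.effect_fold)

    matrices: dict[str, ExpressionMatrix] = {}
    manifest_rows = []
    for si, sp in enumerate(config.species):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, si]))
        mask = presence[sp].to_numpy()
        tids = members[sp].to_numpy()[mask]
        s = sign.loc[presence.index].to_numpy()[mask]
        n_t = mask.sum()
        n_p = config.pairs_per_species[si]

        ov_log2 = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, (n_t, n_p))
        noise = rng.normal(0.0, config.noise_sd, (n_t, n_p))
        in_log2 = ov_log2 + s[:, None] * shift + noise
        ov = 2.0 ** ov_log2
        iv = 2.0 ** in_log2
        if config.dropout_prob > 0:
            iv[rng.random((n_t, n_p)) < config.dropout_prob] = 0.0
            ov[rng.random((n_t, n_p)) < config.dropout_prob] = 0.0

        i_samples = [f"{sp}_I{p + 1:02d}" for p in range(n_p)]
        o_samples = [f"{sp}_O{p + 1:02d}" for p in range(n_p)]
        data = pd.DataFrame(
            np.hstack([iv, ov]),
            index=pd.Index(tids, name="transcript_id"),
            columns=i_samples + o_samples,
        )
        matrices[sp] = ExpressionMatrix(species=sp, data=data)
        for p in range(n_p):
            manifest_rows.append((sp, f"{sp}_pair{p + 1:02d}", i_samples[p], o_samples[p]))

    manifest = pd.DataFrame(manifest_rows, columns=list(MANIFEST_COLUMNS))
    return matrices, manifest


def simulate_bundle(config: SimConfig) -> SimBundle:
    """Full in-memory fixture: universe, hit tables, expression, manifest."""
    truth, hit_tables = simulate_universe(config)
    matrices, manifest = simulate_expression(config, truth)
    return SimBundle(
        config=config, truth=truth, matrices=matrices,
        manifest=manifest, hit_tables=hit_tables,
    )


def _write_quant_sf(path: Path, tpm: pd.Series) -> None:
    # Length/EffectiveLength/NumReads are plausible deterministic placeholders;
    # downstream code reads only Name and TPM.
    with open(path, "w") as fh:
        fh.write("\t".join(QUANT_SF_COLUMNS) + "\n")
        for i, (tid, v) in enumerate(tpm.items()):
            length = 500 + (i * 37) % 2500
            eff = length - 199
            fh.write(f"{tid}\t{length}\t{eff:.3f}\t{v:.6f}\t{v * eff / 100.0:.3f}\n")


def _hits_to_tsv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    out["pident"] = out["pident"].map(lambda v: f"{v:.1f}")
    out["evalue"] = out["evalue"].map(lambda v: f"{v:.2e}")
    out["bitscore"] = out["bitscore"].map(lambda v: f"{v:.1f}")
    out.to_csv(path, sep="\t", header=False, index=False)


def write_fixture_bundle(bundle: SimBundle, out_dir: Path | str) -> Path:
    """Write a self-describing, re-loadable fixture bundle.

    Layout::

        out_dir/
          config.yaml                 generating parameters
          truth.tsv                   planted ortholog universe
          hub_decoys.txt              extra hub protein ids (one per line)
          manifest.tsv                curated sample pairs
          quants/<sample>.quant.sf    one abundance table per sample
          hits/hub__to__<sp>.tsv      12-column hit tables, both directions
          hits/<sp>__to__hub.tsv
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "quants").mkdir(exist_ok=True)
        (out / "hits").mkdir(exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create bundle directory {out}: {exc}") from exc

    bundle.config.to_yaml(out / "config.yaml")
    bundle.truth.table.to_csv(out / "truth.tsv", sep="\t", index=False)
    (out / "hub_decoys.txt").write_text(
        "".join(f"{d}\n" for d in bundle.truth.hub_decoys)
    )
    bundle.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    for sp, matrix in bundle.matrices.items():
        for sample in matrix.sample_ids:
            _write_quant_sf(out / "quants" / f"{sample}.quant.sf", matrix.data[sample])
    for sp, pair in bundle.hit_tables.items():
        _hits_to_tsv(pair.hub_to_sp, out / "hits" / f"hub__to__{sp}.tsv")
        _hits_to_tsv(pair.sp_to_hub, out / "hits" / f"{sp}__to__hub.tsv")
    return out


def read_fixture_bundle(bundle_dir: Path | str) -> SimBundle:
    """Load a bundle written by :func:`write_fixture_bundle`."""
    from .orthology import parse_hits

    d = Path(bundle_dir)
    if not (d / "config.yaml").exists():
        raise DataError(f"{d}: not a fixture bundle (config.yaml missing)")
    config = SimConfig.from_yaml(d / "config.yaml")
    table = pd.read_csv(d / "truth.tsv", sep="\t", dtype=str, keep_default_na=False)
    table["present"] = table["present"].map({"True": True, "False": False})
    decoys = tuple(
        line for line in (d / "hub_decoys.txt").read_text().splitlines() if line
    )
    truth = TruthTable(
        species=config.species, hub=config.hub, table=table, hub_decoys=decoys
    )
    manifest = read_manifest(d / "manifest.tsv")
    matrices = {}
    for sp, sub in manifest.groupby("species"):
        samples = sorted(set(sub["intersexual_sample"]) | set(sub["ovary_sample"]))
        files = {s: d / "quants" / f"{s}.quant.sf" for s in samples}
        matrices[sp] = read_expression(files, species=sp, format="quant_sf")
    hit_tables = {}
    for sp in config.species:
        if sp == config.hub:
            continue
        hit_tables[sp] = HitTablePair(
            hub_to_sp=parse_hits(d / "hits" / f"hub__to__{sp}.tsv"),
            sp_to_hub=parse_hits(d / "hits" / f"{sp}__to__hub.tsv"),
        )
    return SimBundle(
        config=config, truth=truth, matrices=matrices,
        manifest=manifest, hit_tables=hit_tables,
    )
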