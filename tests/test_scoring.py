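"""Unit and property tests for paired IO-ratio/IO-score computation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ioscore as io
from ioscore.errors import DataError
from ioscore.scoring import LABEL_DOWN, LABEL_UNCHANGED, LABEL_UP

from conftest import make_manifest

TPM = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)


class TestComputeIORatio:
    @pytest.mark.parametrize(
        "tpm_i,tpm_o,expected",
        [
            (0.0, 0.0, 0.0),                      # symmetric zero case
            (0.99, 0.19, math.log2(5)),           # (1.00)/(0.20) = 5
            (0.01, 0.03, -1.0),                   # (0.02)/(0.04) = 0.5
        ],
    )
    def test_exact_values(self, tpm_i, tpm_o, expected):
        assert io.compute_io_ratio(tpm_i, tpm_o) == pytest.approx(expected, abs=1e-12)

    def test_negative_tpm_rejected(self):
        with pytest.raises(DataError):
            io.compute_io_ratio(-0.1, 1.0)
        with pytest.raises(DataError):
            io.compute_io_ratio(1.0, -0.1)

    def test_vectorized(self):
        out = io.compute_io_ratio(np.array([0.99, 0.01]), np.array([0.19, 0.03]))
        assert np.allclose(out, [math.log2(5), -1.0])

    @given(a=TPM, b=TPM)
    def test_antisymmetry(self, a, b):
        assert io.compute_io_ratio(a, b) == pytest.approx(
            -io.compute_io_ratio(b, a), abs=1e-9
        )

    @given(a=TPM, b=TPM, delta=st.floats(min_value=1e-3, max_value=1e3))
    def test_strict_monotonicity(self, a, b, delta):
        base = io.compute_io_ratio(a, b)
        assert io.compute_io_ratio(a + delta, b) > base
        assert io.compute_io_ratio(a, b + delta) < base

    @given(a=st.floats(min_value=1e-3, max_value=1e5),
           b=st.floats(min_value=1e-3, max_value=1e5))
    def test_pseudocount_limit(self, a, b):
        """As the pseudocount vanishes the ratio approaches log2(a/b)."""
        tiny = io.ScoringParams(pseudocount=1e-12)
        assert io.compute_io_ratio(a, b, tiny) == pytest.approx(
            math.log2(a / b), abs=1e-6
        )


class TestClassifyRatio:
    def test_boundary_is_unchanged(self):
        cutoff = math.log2(5)
        assert io.classify_ratio(cutoff) == LABEL_UNCHANGED
        assert io.classify_ratio(-cutoff) == LABEL_UNCHANGED

    @pytest.mark.parametrize(
        "ratio,label",
        [(2.40, LABEL_UP), (-2.322, LABEL_DOWN), (0.0, LABEL_UNCHANGED),
         (2.32, LABEL_UNCHANGED)],
    )
    def test_examples(self, ratio, label):
        assert io.classify_ratio(ratio) == label

    def test_custom_fold_threshold(self):
        params = io.ScoringParams(fold_threshold=2.0)
        assert io.classify_ratio(1.5, params) == LABEL_UP
        assert io.classify_ratio(1.0, params) == LABEL_UNCHANGED


class TestSpeciesIOScore:
    def _labels(self, labels, tid="t1"):
        return pd.DataFrame(
            {"transcript_id": tid, "pair_id": [f"p{i}" for i in range(len(labels))],
             "label": labels}
        )

    @pytest.mark.parametrize(
        "labels,expected",
        [
            ([LABEL_UP, LABEL_UP, LABEL_DOWN, LABEL_UNCHANGED], 1),
            ([LABEL_UNCHANGED] * 5, 0),
            ([LABEL_UP] * 12, 12),
            ([LABEL_DOWN] * 3, -3),
        ],
    )
    def test_counts(self, labels, expected):
        assert io.species_io_score(self._labels(labels))["t1"] == expected

    def test_missing_label_rejected(self):
        df = self._labels([LABEL_UP, None])
        with pytest.raises(DataError, match="missing label"):
            io.species_io_score(df)

    @given(st.data())
    def test_matches_brute_force_recount(self, data):
        """Score conservation: vectorised score equals a per-transcript recount."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        n_t, n_p = int(rng.integers(1, 20)), int(rng.integers(1, 10))
        labels = rng.choice([LABEL_UP, LABEL_DOWN, LABEL_UNCHANGED], size=(n_t, n_p))
        long = pd.DataFrame(
            {"transcript_id": np.repeat([f"t{i}" for i in range(n_t)], n_p),
             "pair_id": np.tile([f"p{j}" for j in range(n_p)], n_t),
             "label": labels.ravel()}
        )
        scores = io.species_io_score(long)
        for i in range(n_t):
            row = labels[i]
            expect = sum(1 for x in row if x == LABEL_UP) - sum(
                1 for x in row if x == LABEL_DOWN
            )
            assert scores[f"t{i}"] == expect


class TestScoreSpecies:
    def _tiny(self):
        expr = io.ExpressionMatrix(
            "spA",
            pd.DataFrame(
                {"i1": [50.0, 0.2, 1.0], "o1": [1.0, 5.0, 1.0],
                 "i2": [60.0, 1.0, 2.0], "o2": [1.0, 1.0, 2.0]},
                index=pd.Index(["tA", "tB", "tC"], name="transcript_id"),
            ),
        )
        manifest = make_manifest(
            [("spA", "p1", "i1", "o1"), ("spA", "p2", "i2", "o2")]
        )
        return expr, manifest

    def test_scores_and_bound(self):
        expr, manifest = self._tiny()
        table = io.score_species(expr, manifest)
        assert table.n_pairs == 2
        assert table.scores.loc["tA", "io_score"] == 2      # 50x and 60x up
        assert table.scores.loc["tB", "io_score"] == -1     # 25x down then flat
        assert table.scores.loc["tC", "io_score"] == 0
        assert (table.scores["io_score"].abs() <= table.n_pairs).all()
        # per-pair counts are conserved
        assert (
            table.scores[["n_up", "n_down", "n_unchanged"]].sum(axis=1)
            == table.n_pairs
        ).all()

    def test_unknown_sample_rejected(self):
        expr, manifest = self._tiny()
        manifest.loc[0, "ovary_sample"] = "nope"
        with pytest.raises(DataError, match="nope"):
            io.score_species(expr, manifest)

    def test_pairwise_not_averaged(self):
        """Each pair is ratioed on its own samples, never pooled replicates."""
        expr, manifest = self._tiny()
        table = io.score_species(expr, manifest)
        r = table.ratios.set_index(["transcript_id", "pair_id"])["io_ratio"]
        assert r[("tA", "p1")] == pytest.approx(io.compute_io_ratio(50.0, 1.0))
        assert r[("tA", "p2")] == pytest.approx(io.compute_io_ratio(60.0, 1.0))


class TestRatioSDDiagnostic:
    def _table_from_ratios(self, values):
        ratios = pd.DataFrame(
            {"transcript_id": [f"t{i}" for i in range(len(values))],
             "pair_id": "p1", "io_ratio": values,
             "label": LABEL_UNCHANGED}
        )
        scores = pd.DataFrame(index=pd.Index([], name="transcript_id"))
        return io.SpeciesScoreTable("spA", ratios, scores, n_pairs=1)

    def test_constant_ratios(self):
        d = io.ratio_sd_diagnostic(self._table_from_ratios([1.5] * 10))
        assert d.sd == 0.0
        assert d.fold_at_2sd == 1.0

    def test_standard_normal_monte_carlo(self):
        rng = np.random.default_rng(0)
        d = io.ratio_sd_diagnostic(self._table_from_ratios(rng.normal(0, 1, 100_000)))
        assert d.sd == pytest.approx(1.0, rel=0.02)
        assert d.fold_at_2sd == pytest.approx(4.0, rel=0.02)

    def test_null_bundle_noise_sd_for_fivefold(self):
        """At ratio SD log2(5)/2 = 1.161 the 2-SD fold equals the 5x cutoff."""
        cfg = io.SimConfig(
            n_species=2, n_orthologs=2000, presence_prob=1.0,
            pairs_per_species=(4, 4), frac_up=0.0, frac_down=0.0,
            noise_sd=1.161, dropout_prob=0.0, n_paralogs=0, seed=5,
        )
        bundle = io.simulate_bundle(cfg)
        table = io.score_species(bundle.matrices["sp1"], bundle.manifest)
        d = io.ratio_sd_diagnostic(table)
        assert d.fold_at_2sd == pytest.approx(5.0, rel=0.02)

    def test_too_few_values(self):
        with pytest.raises(DataError):
            io.ratio_sd_diagnostic(self._table_from_ratios([0.1]))


class TestReadExpression:
    def _write_quant(self, path, rows):
        lines = ["Name\tLength\tEffectiveLength\tTPM\tNumReads"]
        lines += [f"{n}\t500\t301.0\t{t}\t{t * 3}" for n, t in rows]
        path.write_text("\n".join(lines) + "\n")

    def test_quant_sf_preserves_tpm(self, tmp_path):
        self._write_quant(tmp_path / "s1.quant.sf",
                          [("t1", 0.123456), ("t2", 1234.5), ("t3", 0.0)])
        expr = io.read_expression({"s1": tmp_path / "s1.quant.sf"}, species="spA")
        assert list(expr.transcript_ids) == ["t1", "t2", "t3"]
        assert expr.data.loc["t1", "s1"] == 0.123456

    def test_missing_transcript_policies(self, tmp_path):
        self._write_quant(tmp_path / "a.quant.sf", [("t1", 1.0), ("t2", 2.0)])
        self._write_quant(tmp_path / "b.quant.sf", [("t1", 1.0)])
        files = {"a": tmp_path / "a.quant.sf", "b": tmp_path / "b.quant.sf"}
        with pytest.raises(DataError, match="t2"):
            io.read_expression(files, species="spA", missing="error")
        expr = io.read_expression(files, species="spA", missing="zero")
        assert expr.data.loc["t2", "b"] == 0.0

    def test_duplicate_transcript_rejected(self, tmp_path):
        self._write_quant(tmp_path / "a.quant.sf", [("t1", 1.0), ("t1", 2.0)])
        with pytest.raises(DataError, match="duplicate"):
            io.read_expression({"a": tmp_path / "a.quant.sf"}, species="spA")

    def test_malformed_header_rejected(self, tmp_path):
        (tmp_path / "a.quant.sf").write_text("foo\tbar\n1\t2\n")
        with pytest.raises(DataError, match="quant.sf"):
            io.read_expression({"a": tmp_path / "a.quant.sf"}, species="spA")

    def test_negative_tpm_rejected(self, tmp_path):
        self._write_quant(tmp_path / "a.quant.sf", [("t1", -1.0)])
        with pytest.raises(DataError, match="negative"):
            io.read_expression({"a": tmp_path / "a.quant.sf"}, species="spA")

    def test_generic_tsv_dialect(self, tmp_path):
        (tmp_path / "a.tsv").write_text("transcript_id\ttpm\nt1\t3.5\n")
        expr = io.read_expression({"a": tmp_path / "a.tsv"}, species="spA", format="tsv")
        assert expr.data.loc["t1", "a"] == 3.5
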