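"""Contrast tables, the composition identity, and fold-change screens."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from beadpool import (
    FTestConfig,
    NormalizedMatrix,
    ScreenConfig,
    ValidationError,
    build_contrasts,
    opposite_fc_screen,
    threshold_screen,
    top_gene_table,
)
from beadpool.contrasts import DEFAULT_PAIRS
from beadpool.datasets import crystallin_contrasts
from beadpool.ftest import FTestResult

GROUPS = ["NCD", "HFD", "NCD+BB", "HFD+BB"]


def nm(values, probe_ids=None):
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"p{i}" for i in range(values.shape[0])]
    return NormalizedMatrix(pd.DataFrame(values, index=probe_ids, columns=GROUPS))


def fake_gate(probe_ids, p):
    """An FTestResult shell with prescribed p-values for screen gating."""
    p = np.asarray(p, dtype=float)
    tab = pd.DataFrame(
        {
            "between_variance": 1.0,
            "within_variance": 1.0,
            "F": 1.0,
            "df1": 3.0,
            "df2": 30.0,
            "p": p,
            "p_bonf": np.minimum(1.0, p * len(p)),
            "degenerate": False,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return FTestResult(tab, FTestConfig())


class TestBuildContrasts:
    def test_identical_columns_all_zero(self):
        m = nm(np.tile([[5.0]], (3, 4)))
        ct = build_contrasts(m)
        assert (ct.log_ratios.to_numpy() == 0).all()

    def test_column_difference(self):
        m = nm([[1.0, 4.0, 2.0, 3.0]])
        ct = build_contrasts(m, [("HFD", "NCD")])
        assert ct.log_ratios.at["p0", "HFD/NCD"] == pytest.approx(3.0)

    def test_degenerate_pair_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            build_contrasts(nm([[1, 2, 3, 4]]), [("NCD", "NCD")])

    def test_reversed_contrast_negates_column(self):
        rng = np.random.default_rng(0)
        m = nm(rng.normal(8, 1, (20, 4)))
        ct = build_contrasts(m, [("HFD", "NCD"), ("NCD", "HFD")])
        np.testing.assert_allclose(
            ct.log_ratios["HFD/NCD"], -ct.log_ratios["NCD/HFD"], atol=1e-12
        )

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        arrays(np.float64, (6, 4),
               elements=st.floats(0, 16, allow_nan=False, width=32))
    )
    def test_composition_identity_every_triple(self, x):
        # lr(C/B) == lr(C/A) - lr(B/A) for every probe and group triple
        m = nm(x)
        pairs = [(a, b) for a in GROUPS for b in GROUPS if a != b]
        ct = build_contrasts(m, pairs)
        for a in GROUPS:
            for b in GROUPS:
                for c in GROUPS:
                    if len({a, b, c}) < 3:
                        continue
                    lhs = ct.log_ratios[f"{c}/{b}"]
                    rhs = ct.log_ratios[f"{c}/{a}"] - ct.log_ratios[f"{b}/{a}"]
                    np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestDerivedContrast:
    def test_crystallin_pattern_derived_column(self):
        """Composing the diet and combined-arm contrasts reproduces the
        printed supplement-on-high-fat column to printed precision."""
        cry = crystallin_contrasts()
        # embed the printed ratios as log2 values relative to NCD = 0
        values = pd.DataFrame(
            {
                "NCD": 0.0,
                "HFD": cry["HFD/NCD"],
                "NCD+BB": cry["NCD+BB/NCD"],
                "HFD+BB": cry["HFD+BB/NCD"],
            }
        )
        m = NormalizedMatrix(values[GROUPS])
        ct = build_contrasts(m, DEFAULT_PAIRS)
        derived = ct.log_ratios["HFD+BB/HFD"]
        # each printed column is independently rounded to 2 decimals, so the
        # composition of two rounded columns can differ from the printed
        # derived column by up to ~0.015
        np.testing.assert_allclose(
            derived, cry["HFD+BB/HFD"], atol=0.015 + 1e-12
        )

    def test_derive_requires_shared_denominator(self):
        m = nm(np.random.default_rng(1).normal(8, 1, (5, 4)))
        ct = build_contrasts(m, [("HFD", "NCD"), ("HFD+BB", "HFD")])
        with pytest.raises(ValidationError, match="denominator"):
            ct.derive("HFD/NCD", "HFD+BB/HFD")

    def test_derive_composes(self):
        m = nm(np.random.default_rng(2).normal(8, 1, (5, 4)))
        ct = build_contrasts(m, [("HFD+BB", "NCD"), ("HFD", "NCD")])
        got = ct.derive("HFD+BB/NCD", "HFD/NCD")
        want = m.values["HFD+BB"] - m.values["HFD"]
        np.testing.assert_allclose(got, want, atol=1e-12)


class TestThresholdScreen:
    def ct_from_lr(self, lr):
        """Contrast table with a single HFD/NCD column equal to lr."""
        lr = np.asarray(lr, dtype=float)
        values = np.zeros((len(lr), 4))
        values[:, 1] = lr  # HFD column; NCD stays 0
        return build_contrasts(nm(values), [("HFD", "NCD")])

    def test_all_below_cutoff_empty(self):
        ct = self.ct_from_lr([0.1, -0.2, 0.3])
        gate = fake_gate(ct.probe_ids, [0.001] * 3)
        res = threshold_screen(ct, "HFD/NCD", "up", ScreenConfig(), gate)
        assert res.n_probes == 0

    def test_zero_cutoff_returns_every_gated_signed_probe(self):
        ct = self.ct_from_lr([0.1, -0.2, 0.3, 0.0])
        gate = fake_gate(ct.probe_ids, [0.001] * 4)
        cfg = ScreenConfig(log_ratio_cutoff=0.0)
        up = threshold_screen(ct, "HFD/NCD", "up", cfg, gate)
        down = threshold_screen(ct, "HFD/NCD", "down", cfg, gate)
        assert set(up.probes) == {"p0", "p2"}
        assert set(down.probes) == {"p1"}  # lr == 0 is excluded

    def test_planted_counts(self):
        # 5 planted up (lr=+1), 3 planted down (lr=-1), 4 null
        lr = [1.0] * 5 + [-1.0] * 3 + [0.0] * 4
        ct = self.ct_from_lr(lr)
        gate = fake_gate(ct.probe_ids, [0.001] * 12)
        cfg = ScreenConfig(log_ratio_cutoff=0.4)
        up = threshold_screen(ct, "HFD/NCD", "up", cfg, gate)
        down = threshold_screen(ct, "HFD/NCD", "down", cfg, gate)
        assert (up.n_probes, down.n_probes) == (5, 3)
        assert not set(up.probes) & set(down.probes)

    def test_p_gate_excludes_non_significant(self):
        ct = self.ct_from_lr([1.0, 1.0])
        gate = fake_gate(ct.probe_ids, [0.001, 0.5])
        res = threshold_screen(ct, "HFD/NCD", "up", ScreenConfig(), gate)
        assert res.probes == ["p0"]

    def test_gene_collapse_counts_unique_symbols(self, toy_annotation):
        ct = self.ct_from_lr([1.0, 1.0, 1.0, 1.0])
        # p3 has no annotation entry -> counted as unknown
        gate = fake_gate(ct.probe_ids, [0.001] * 4)
        res = threshold_screen(
            ct, "HFD/NCD", "up", ScreenConfig(), gate, annotation=toy_annotation
        )
        assert res.n_probes == 4
        assert res.genes == ["GeneA", "GeneB"]  # p0,p2 share GeneA
        assert res.n_unknown == 1
        assert res.n_genes <= res.n_probes

    def test_unknown_contrast_rejected(self):
        ct = self.ct_from_lr([1.0])
        gate = fake_gate(ct.probe_ids, [0.001])
        with pytest.raises(ValidationError, match="unknown contrast"):
            threshold_screen(ct, "nope", "up", ScreenConfig(), gate)


class TestOppositeScreen:
    def build(self, base_lr, comp_lr):
        values = np.zeros((len(base_lr), 4))
        values[:, 1] = base_lr        # HFD vs NCD
        values[:, 3] = np.asarray(base_lr) + np.asarray(comp_lr)  # HFD+BB
        m = nm(values)
        return build_contrasts(m, [("HFD", "NCD"), ("HFD+BB", "HFD")])

    def test_same_signed_comparison_empty(self):
        ct = self.build([1.0, 1.0], [0.5, 0.8])
        gate = fake_gate(ct.probe_ids, [0.001] * 2)
        base = threshold_screen(ct, "HFD/NCD", "up", ScreenConfig(), gate)
        res = opposite_fc_screen(base, ct, "HFD+BB/HFD", ScreenConfig())
        assert res.n_probes == 0

    def test_hand_enumeration_and_zero_cutoff(self):
        # base {A,B,C} up; comparison lr A=-0.5, B=-0.1, C=+0.2
        ct = self.build([1.0, 1.0, 1.0], [-0.5, -0.1, 0.2])
        gate = fake_gate(ct.probe_ids, [0.001] * 3)
        cfg = ScreenConfig(log_ratio_cutoff=0.4)
        base = threshold_screen(ct, "HFD/NCD", "up", cfg, gate)
        strict = opposite_fc_screen(base, ct, "HFD+BB/HFD", cfg)
        loose = opposite_fc_screen(base, ct, "HFD+BB/HFD", cfg, cutoff=0.0)
        assert strict.probes == ["p0"]
        assert set(loose.probes) == {"p0", "p1"}

    def test_antitone_in_cutoff(self):
        rng = np.random.default_rng(9)
        n = 100
        ct = self.build(rng.normal(0.8, 0.3, n), rng.normal(-0.3, 0.4, n))
        gate = fake_gate(ct.probe_ids, [0.001] * n)
        cfg = ScreenConfig(log_ratio_cutoff=0.4)
        base = threshold_screen(ct, "HFD/NCD", "up", cfg, gate)
        at_04 = set(opposite_fc_screen(base, ct, "HFD+BB/HFD", cfg).probes)
        at_0 = set(opposite_fc_screen(base, ct, "HFD+BB/HFD", cfg, cutoff=0.0).probes)
        at_08 = set(opposite_fc_screen(base, ct, "HFD+BB/HFD", cfg, cutoff=0.8).probes)
        assert at_08 <= at_04 <= at_0


class TestTopGeneTable:
    def test_empty_when_nothing_passes(self):
        values = np.random.default_rng(3).normal(8, 0.01, (5, 4))
        ct = build_contrasts(nm(values), DEFAULT_PAIRS)
        gate = fake_gate(ct.probe_ids, [0.9] * 5)
        top = top_gene_table(gate, ct, p_level=0.01)
        assert len(top) == 0

    def test_ranked_by_p_with_annotation(self, toy_annotation):
        values = np.zeros((3, 4))
        ct = build_contrasts(nm(values), DEFAULT_PAIRS)
        gate = fake_gate(ct.probe_ids, [0.005, 0.0001, 0.002])
        top = top_gene_table(gate, ct, annotation=toy_annotation, p_level=0.01)
        assert list(top["probe_id"]) == ["p1", "p2", "p0"]
        assert list(top["rank"]) == [1, 2, 3]
        assert list(top["gene_symbol"]) == ["GeneB", "GeneA", "GeneA"]
        for name in ct.log_ratios.columns:
            assert name in top.columns
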