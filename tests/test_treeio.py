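import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from l1dynamics import (
    UNKNOWN,
    PhyloTree,
    SimConfig,
    TipStates,
    TreeSample,
    UnitConversion,
    binarize_activity,
    check_ultrametric,
    generations_to_substitutions,
    read_tip_states,
    read_tree_sample,
    simulate_bisse,
    write_tip_states,
    write_tree_sample,
)
from l1dynamics.treeio import TreeFormatError, TreeValidationError


class TestParsing:
    def test_basic_newick(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,C:2);")
        assert t.n_tips == 3
        assert set(t.tip_labels) == {"A", "B", "C"}
        assert t.depth == pytest.approx(2.0)

    def test_quoted_and_underscore_labels(self):
        t = PhyloTree.from_newick("(('taxon one':1,tax_2:1):1,C:2);")
        assert "taxon one" in t.tip_labels
        assert "tax_2" in t.tip_labels

    def test_support_labels_tolerated(self):
        t = PhyloTree.from_newick("((A:1,B:1)0.95:1,C:2);")
        assert t.n_tips == 3

    def test_parse_failure_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.nwk"
        bad.write_text("((A:1,B:1):1,C:2;\n")
        with pytest.raises(TreeFormatError):
            read_tree_sample(str(bad))

    def test_polytomy_rejected(self):
        with pytest.raises(TreeValidationError):
            PhyloTree.from_newick("(A:1,B:1,C:1,D:1);")

    def test_tree_sample_consistent_tips(self, tmp_path):
        f = tmp_path / "trees.nwk"
        f.write_text("((A:1,B:1):1,C:2);\n((A:2,C:2):1,B:3);\n")
        sample = read_tree_sample(str(f))
        assert len(sample) == 2

    def test_tree_sample_mismatched_tips_error(self, tmp_path):
        f = tmp_path / "trees.nwk"
        f.write_text("((A:1,B:1):1,C:2);\n((A:1,D:1):1,C:2);\n")
        with pytest.raises(TreeValidationError, match="tip set"):
            read_tree_sample(str(f))

    def test_round_trip_preserves_lengths(self, tmp_path, large_sim):
        sample = TreeSample([large_sim.tree])
        path = tmp_path / "rt.nwk"
        write_tree_sample(sample, str(path))
        back = read_tree_sample(str(path))
        a = sorted(large_sim.tree.branch_length)
        b = sorted(back[0].branch_length)
        np.testing.assert_allclose(a, b, rtol=1e-9)
        assert set(back[0].tip_labels) == set(large_sim.tree.tip_labels)


class TestUltrametric:
    def test_exact_ultrametric(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,C:2);")
        rep = check_ultrametric(t)
        assert rep.is_ultrametric and rep.max_deviation == 0.0

    def test_deviation_reported(self):
        t = PhyloTree.from_newick("((A:1,B:1.5):1,C:2);")
        rep = check_ultrametric(t)
        assert not rep.is_ultrametric
        assert rep.max_deviation == pytest.approx(0.5)

    def test_tolerance_contract(self):
        t = PhyloTree.from_newick("((A:1,B:1.001):1,C:2.0005);")
        assert check_ultrametric(t, rel_tol=0.01).is_ultrametric
        assert not check_ultrametric(t, rel_tol=1e-6).is_ultrametric


class TestUnitConversion:
    def test_change_point_boundaries(self):
        conv = UnitConversion()
        assert generations_to_substitutions(140, conv) == pytest.approx(3.5e-6)
        assert generations_to_substitutions(4720, conv) == pytest.approx(1.18e-4)
        assert generations_to_substitutions(0, conv) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            UnitConversion().generations_to_substitutions(-1)
        with pytest.raises(ValueError):
            UnitConversion(subst_rate=0.0)

    @given(
        a=st.floats(0, 1e6, allow_nan=False),
        b=st.floats(0, 1e6, allow_nan=False),
    )
    @settings(deadline=None, max_examples=50)
    def test_linearity(self, a, b):
        conv = UnitConversion()
        f = conv.generations_to_substitutions
        assert f(a + b) == pytest.approx(f(a) + f(b), rel=1e-12, abs=1e-300)


class TestBinarize:
    def test_basic_threshold(self):
        ts = TipStates.from_activity({"A": 100.0, "B": 3.0})
        out = binarize_activity(ts, threshold=25)
        assert out.states == {"A": 1, "B": 0}

    def test_tie_is_high(self):
        out = binarize_activity(TipStates.from_activity({"A": 25.0}), threshold=25)
        assert out.states["A"] == 1

    def test_missing_becomes_unknown(self):
        ts = TipStates({"A": UNKNOWN, "B": UNKNOWN}, {"A": 30.0})
        out = binarize_activity(ts)
        assert out.states == {"A": 1, "B": UNKNOWN}

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            TipStates.from_activity({"A": -1.0})

    @given(
        acts=st.dictionaries(
            st.text(alphabet="abcde", min_size=1, max_size=3),
            st.floats(0, 200, allow_nan=False),
            min_size=1,
            max_size=12,
        ),
        thr_lo=st.floats(5, 50),
        thr_hi=st.floats(5, 50),
    )
    @settings(deadline=None, max_examples=60)
    def test_idempotent_and_monotone(self, acts, thr_lo, thr_hi):
        lo, hi = sorted((thr_lo, thr_hi))
        ts = TipStates.from_activity(acts)
        out_lo = binarize_activity(ts, threshold=lo)
        out_hi = binarize_activity(ts, threshold=hi)
        # idempotent: re-binarizing at the same threshold changes nothing
        assert binarize_activity(out_lo, threshold=lo).states == out_lo.states
        # monotone: raising the threshold never converts a low to a high
        for k in acts:
            assert out_hi.states[k] <= out_lo.states[k]

    def test_state_array_requires_every_tip(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(KeyError, match="C"):
            TipStates({"A": 0, "B": 1}).state_array(t)


class TestTipStatesIO:
    def test_tsv_round_trip(self, tmp_path):
        ts = TipStates({"A": 1, "B": 0, "C": UNKNOWN}, {"A": 80.0, "B": 2.5})
        path = tmp_path / "states.tsv"
        write_tip_states(ts, str(path))
        back = read_tip_states(str(path))
        assert back.states == ts.states
        assert back.activity["A"] == pytest.approx(80.0)


class TestAnalysisConfig:
    def test_read_full_config(self, tmp_path):
        from l1dynamics import read_config

        cfg_text = """
subst_rate: 2.5e-8
constraints: [unconstrained, mu0=mu1=0, yule]
custom_constraints:
  - id: yule
    groups: {lambda0: lambda, lambda1: lambda, mu0: null, mu1: null,
             q01: null, q10: null}
change_points:
  - [140]
  - [140, 4720]
"""
        path = tmp_path / "config.yaml"
        path.write_text(cfg_text)
        cfg = read_config(str(path))
        assert [c.id for c in cfg.constraints] == ["unconstrained", "mu0=mu1=0", "yule"]
        assert cfg.constraints[2].df == 1
        assert cfg.change_points == ((140.0,), (140.0, 4720.0))
        assert cfg.conv.subst_rate == 2.5e-8

    def test_unknown_constraint_rejected(self, tmp_path):
        from l1dynamics import read_config

        path = tmp_path / "config.yaml"
        path.write_text("constraints: [nonexistent]\n")
        with pytest.raises(ValueError, match="nonexistent"):
            read_config(str(path))
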