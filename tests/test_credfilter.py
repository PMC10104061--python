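"""Credible-set QC, connected components, and summary-statistic filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from qtlcanvas.credfilter import (
    CredFilterError,
    CredibleSet,
    build_components,
    filter_summary_stats,
    qc_credible_sets,
    run_filter_pipeline,
    select_representative_traits,
)
from qtlcanvas.synthfix import SimConfig, credible_sets_from_frame, sim_credible_sets


def cs(cs_id, variants, trait="T1", group="G1", zmax=5.0, pip_peak=0.5):
    variants = list(variants)
    return CredibleSet(
        cs_id=cs_id, trait_id=trait, group_id=group, signal_index=1,
        variant_ids=frozenset(variants),
        pips={v: (pip_peak if i == 0 else 0.01) for i, v in enumerate(variants)},
        zscores={v: (zmax if i == 0 else 0.5) for i, v in enumerate(variants)},
    )


class TestQC:
    def test_low_z_dropped(self):
        kept, rep = qc_credible_sets([cs("a", ["v1"], zmax=2.9)])
        assert kept == [] and rep.dropped[0][0] == "a"

    def test_oversized_dropped_even_with_strong_z(self):
        big = cs("b", [f"v{i}" for i in range(201)], zmax=8.0)
        kept, rep = qc_credible_sets([big])
        assert kept == [] and "size=201" in rep.dropped[0][1]

    def test_boundaries_kept(self):
        """max|z| exactly 3 and size exactly 200 survive (strict inequalities)."""
        edge = cs("c", [f"v{i}" for i in range(200)], zmax=3.0)
        kept, rep = qc_credible_sets([edge])
        assert len(kept) == 1 and rep.n_dropped == 0

    def test_negative_z_uses_absolute_value(self):
        kept, _ = qc_credible_sets([cs("d", ["v1"], zmax=-4.0)])
        assert len(kept) == 1

    def test_missing_zscores_error(self):
        broken = CredibleSet("e", "T", "G", 1, frozenset(["v1", "v2"]),
                             {"v1": 0.5}, {"v1": 4.0})
        with pytest.raises(CredFilterError, match="e"):
            qc_credible_sets([broken])


def brute_force_components(sets):
    """O(n^2) pairwise overlap + transitive closure via repeated merging."""
    comps = [{s.cs_id} for s in sets]
    by_id = {s.cs_id: s for s in sets}

    def linked(a, b):
        return a.group_id == b.group_id and bool(a.variant_ids & b.variant_ids)

    changed = True
    while changed:
        changed = False
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                if any(
                    linked(by_id[x], by_id[y])
                    for x in comps[i] for y in comps[j]
                ):
                    comps[i] |= comps[j]
                    del comps[j]
                    changed = True
                    break
            if changed:
                break
    return {frozenset(c) for c in comps}


class TestComponents:
    def test_simple_overlap(self):
        sets = [cs("A", ["v1", "v2"]), cs("B", ["v2", "v3"]), cs("C", ["v4"])]
        comps = build_components(sets)
        parts = {frozenset(s.cs_id for s in c) for c in comps}
        assert parts == {frozenset({"A", "B"}), frozenset({"C"})}

    def test_transitive_chain(self):
        sets = [cs("A", ["v1", "v2"]), cs("B", ["v2", "v3"]), cs("C", ["v3", "v4"])]
        comps = build_components(sets)
        assert len(comps) == 1 and len(comps[0]) == 3

    def test_groups_separate_identical_variant_sets(self):
        sets = [cs("A", ["v1"], group="G1"), cs("B", ["v1"], group="G2")]
        assert len(build_components(sets)) == 2

    @settings(max_examples=150, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 21))
        sets = []
        for i in range(n):
            nv = int(rng.integers(1, 6))
            variants = [f"v{int(v)}" for v in rng.integers(0, 15, nv)]
            sets.append(cs(f"cs{i}", dict.fromkeys(variants),
                           group=f"G{int(rng.integers(0, 3))}"))
        ours = {frozenset(s.cs_id for s in c) for c in build_components(sets)}
        assert ours == brute_force_components(sets)


class TestSelection:
    def test_highest_pip_wins(self):
        comps = [[cs("A", ["v1"], trait="T1", pip_peak=0.9),
                  cs("B", ["v1"], trait="T2", pip_peak=0.7)]]
        sel = select_representative_traits(comps)[0]
        assert sel.selected_trait_id == "T1"
        assert sel.selected_pip == pytest.approx(0.9)

    def test_single_set_component(self):
        sel = select_representative_traits([[cs("A", ["v1"], trait="T9")]])[0]
        assert sel.selected_trait_id == "T9"

    def test_tie_breaks_lexicographically(self):
        comps = [[cs("A", ["v1"], trait="ENST0002", pip_peak=0.5),
                  cs("B", ["v1"], trait="ENST0001", pip_peak=0.5)]]
        assert select_representative_traits(comps)[0].selected_trait_id == "ENST0001"

    def test_sum_rule_can_differ_from_max(self):
        comps = [[
            CredibleSet("A", "T1", "G", 1, frozenset(["v1", "v2"]),
                        {"v1": 0.4, "v2": 0.4}, {"v1": 5, "v2": 5}),
            CredibleSet("B", "T2", "G", 1, frozenset(["v1"]),
                        {"v1": 0.5}, {"v1": 5}),
        ]]
        assert select_representative_traits(comps, "max")[0].selected_trait_id == "T2"
        assert select_representative_traits(comps, "sum")[0].selected_trait_id == "T1"


class TestFilterStats:
    def _stats(self):
        rows = [("G1", f"T{t}", i) for t in range(20) for i in range(3)]
        return pd.DataFrame(rows, columns=["group_id", "trait_id", "pos"])

    def test_reduction_arithmetic(self):
        sels = select_representative_traits([[cs("A", ["v1"], trait="T0")]])
        out, rep = filter_summary_stats(self._stats(), sels)
        assert rep.reduction_fraction == pytest.approx(0.95)
        assert set(out["trait_id"]) == {"T0"}

    def test_all_selected_no_reduction(self):
        comps = [[cs(f"c{t}", [f"u{t}"], trait=f"T{t}")] for t in range(20)]
        sels = select_representative_traits(comps)
        _, rep = filter_summary_stats(self._stats(), sels)
        assert rep.reduction_fraction == 0.0

    def test_idempotent(self):
        sels = select_representative_traits([[cs("A", ["v1"], trait="T0")]])
        once, _ = filter_summary_stats(self._stats(), sels)
        twice, rep = filter_summary_stats(once, sels)
        assert twice.equals(once) and rep.reduction_fraction == 0.0


class TestEndToEnd:
    def test_planted_truth_recovered(self, sim_cfg):
        cs_df, stats_df, truth = sim_credible_sets(sim_cfg)
        cs_list = credible_sets_from_frame(cs_df)
        filtered, selections, drops, reduction = run_filter_pipeline(cs_list, stats_df)
        assert drops.n_dropped == truth.n_qc_violating
        # every component corresponds to one planted signal
        expected = set(truth.expected_selected.values())
        assert {s.selected_trait_id for s in selections} == expected
        by_signal = {}
        for s in selections:
            member = s.member_cs_ids[0]
            sig = cs_df.loc[cs_df.cs_id == member, "signal_index"].iloc[0]
            by_signal[f"{s.group_id}:s{sig - 1}"] = s.selected_trait_id
        assert by_signal == truth.expected_selected
        assert reduction.reduction_fraction > 0.5
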