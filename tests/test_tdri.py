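"""Stress ratios, the 17-term TDRI, banding, ranking and trait grouping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenodrought import (
    IncompleteRatioError,
    SBIR_PANEL_ROLES,
    SBIR_PANEL_TDRI,
    StressRatioVector,
    TDRI_TRAITS,
    aggregate_means,
    classify_tdri,
    compute_tdri,
    group_traits,
    rank_lines,
    stress_ratios,
    tdri_table,
)
from phenodrought.core import OBS_COLUMNS


def _matrix_from_means(ww, ws):
    """Build a mean matrix from per-trait WW/WS dicts for a single line."""
    rows = []
    for trait in TDRI_TRAITS:
        rows.append(("L1", "WW", 1, trait, ww[trait], None))
        rows.append(("L1", "WS", 1, trait, ws[trait], None))
    return aggregate_means(pd.DataFrame(rows, columns=list(OBS_COLUMNS)))


def _vector(value=1.0):
    return StressRatioVector(
        "L1", {t: value for t in TDRI_TRAITS}, {t: "ok" for t in TDRI_TRAITS})


class TestStressRatios:
    def test_identical_treatments_give_unit_ratios(self):
        means = {t: float(i + 1) for i, t in enumerate(TDRI_TRAITS)}
        means["LOP"] = -1.31
        vec = stress_ratios(_matrix_from_means(means, means), "L1")
        assert vec.complete
        assert all(r == pytest.approx(1.0) for r in vec.ratios.values())

    def test_osmotic_potential_ratio_positive(self):
        ww = {t: 1.0 for t in TDRI_TRAITS}
        ws = {t: 1.0 for t in TDRI_TRAITS}
        ww["LOP"], ws["LOP"] = -1.31, -2.62
        vec = stress_ratios(_matrix_from_means(ww, ws), "L1")
        assert vec.ratios["LOP"] == pytest.approx(2.0)

    def test_zero_control_mean_flagged(self):
        ww = {t: 1.0 for t in TDRI_TRAITS}
        ws = {t: 1.0 for t in TDRI_TRAITS}
        ww["LOP"] = -1.0
        ws["LOP"] = -1.0
        ww["TN"] = 0.0
        vec = stress_ratios(_matrix_from_means(ww, ws), "L1")
        assert vec.flags["TN"] == "nonpositive_denominator"
        assert not vec.complete


class TestComputeTDRI:
    def test_all_ones_sums_to_seventeen(self):
        assert compute_tdri(_vector(1.0)) == 17.0

    def test_uniform_ratio(self):
        assert compute_tdri(_vector(1.1)) == pytest.approx(18.7)

    def test_missing_trait_error_names_it(self):
        vec = _vector()
        vec.flags["RAD"] = "missing"
        del vec.ratios["RAD"]
        with pytest.raises(IncompleteRatioError, match="RAD"):
            compute_tdri(vec)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(delta=st.floats(-5, 5),
           idx=st.integers(0, len(TDRI_TRAITS) - 1))
    def test_additivity_in_any_single_ratio(self, delta, idx):
        base = _vector(1.0)
        bumped = _vector(1.0)
        bumped.ratios[TDRI_TRAITS[idx]] += delta
        assert compute_tdri(bumped) - compute_tdri(base) == pytest.approx(
            delta, rel=1e-12, abs=1e-12)


class TestClassify:
    @pytest.mark.parametrize("value,band", [
        (18.73186, "tolerant"), (16.82162, "moderate"),
        (14.08513, "low"), (12.52044, "low"),
        (15.05, "low"), (15.050001, "moderate"),
        (17.05, "moderate"), (17.050001, "tolerant"),
    ])
    def test_band_boundaries(self, value, band):
        assert classify_tdri(value) == band

    def test_monotone_in_tdri(self):
        order = {"low": 0, "moderate": 1, "tolerant": 2}
        grid = np.linspace(10, 20, 401)
        bands = [order[classify_tdri(x)] for x in grid]
        assert bands == sorted(bands)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_tdri(float("nan"))

    def test_published_panel_reclassified_exactly(self):
        results = {line: classify_tdri(v) for line, v in SBIR_PANEL_TDRI.items()}
        sbirs = [l for l in SBIR_PANEL_TDRI if l not in SBIR_PANEL_ROLES]
        counts = pd.Series([results[l] for l in sbirs]).value_counts()
        assert counts["low"] == 6 and counts["moderate"] == 3 \
            and counts["tolerant"] == 6
        assert results["IR-554190"] == "moderate"
        assert results["Super Basmati"] == "low"
        assert results["Azucena"] == "tolerant"


class TestRanking:
    def test_published_panel_top_two(self):
        sbirs = {l: v for l, v in SBIR_PANEL_TDRI.items()
                 if l not in SBIR_PANEL_ROLES}
        ranked = rank_lines(sbirs)
        assert ranked[0].line_id == "SBIR-153-146-13"
        assert ranked[1].line_id == "SBIR-127-105-12"
        assert [r.rank for r in ranked] == list(range(1, 16))

    def test_ties_break_lexicographically(self):
        ranked = rank_lines({"B": 16.0, "A": 16.0, "C": 17.5})
        assert [r.line_id for r in ranked] == ["C", "A", "B"]

    def test_single_line(self):
        assert rank_lines({"only": 14.0})[0].rank == 1

    def test_idempotent_permutation(self):
        vals = {f"L{i}": 13.0 + 0.37 * i for i in range(8)}
        once = rank_lines(vals)
        twice = rank_lines({r.line_id: r.tdri for r in once})
        assert once == twice


class TestGrouping:
    def _vectors(self, values):
        return {
            lid: StressRatioVector(
                lid,
                {t: (v if t == "TN" else 1.0) for t in TDRI_TRAITS},
                {t: "ok" for t in TDRI_TRAITS},
            )
            for lid, v in values.items()
        }

    def test_three_line_tertiles(self):
        vecs = self._vectors({"A": 0.5, "B": 1.0, "C": 1.5})
        assert group_traits(vecs, "C").groups["TN"] == "high"
        assert group_traits(vecs, "B").groups["TN"] == "medium"
        assert group_traits(vecs, "A").groups["TN"] == "low"

    def test_degenerate_distribution_all_medium(self):
        vecs = self._vectors({"A": 1.0, "B": 1.0, "C": 1.0})
        for lid in vecs:
            assert group_traits(vecs, lid).groups["TN"] == "medium"

    def test_fifteen_line_known_membership(self):
        # brute-force oracle: values 1..15 scaled; membership by rank
        values = {f"L{i:02d}": 0.1 * i for i in range(1, 16)}
        vecs = self._vectors(values)
        vals = np.array(sorted(values.values()))
        q1, q2 = np.quantile(vals, [1 / 3, 2 / 3])
        for lid, v in values.items():
            expect = "high" if v > q2 else ("low" if v < q1 else "medium")
            assert group_traits(vecs, lid).groups["TN"] == expect

    def test_cost_trait_reversed(self):
        vecs = self._vectors({"A": 1.0, "B": 1.0, "C": 1.0})
        extra = {"PR_SDW": {"A": 10.0, "B": 40.0, "C": 70.0}}
        rep = group_traits(vecs, "A", extra_values=extra)
        assert rep.groups["PR_SDW"] == "high"  # smallest reduction = best

    def test_fewer_than_three_lines_rejected(self):
        vecs = self._vectors({"A": 1.0, "B": 2.0})
        with pytest.raises(ValueError, match="3 lines"):
            group_traits(vecs, "A")


class TestTdriTable:
    def test_noiseless_trial_recovers_generating_bands(self, noiseless_trial):
        obs, truth = noiseless_trial
        table = tdri_table(aggregate_means(obs))
        merged = table.merge(truth, on="line_id", suffixes=("", "_true"))
        assert (merged["band"] == merged["band_true"]).all()
        np.testing.assert_allclose(
            merged["tdri"], merged["expected_tdri"], rtol=0, atol=1e-12)
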