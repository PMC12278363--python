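"""ROR, chi-square, Bonferroni and the four-gate signal screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pvsignal.disproportionality import (ContingencyTable, ScreenThresholds,
                                         analyze, bonferroni_adjust,
                                         build_contingency, chi_square,
                                         chi_square_arrays, compute_ror,
                                         ror_stats_arrays, screen_signals,
                                         tabulate_exposure_event,
                                         volcano_table)
from pvsignal.errors import DegenerateTableError, ZeroCellError

cells = st.integers(min_value=1, max_value=2000)


class TestBuildContingency:
    def test_one_case_per_cell(self):
        t = build_contingency([True, True, False, False],
                              [True, False, True, False])
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_all_unexposed(self):
        t = build_contingency([False] * 4, [True, False, True, False])
        assert t.a == 0 and t.b == 0 and t.c == 2 and t.d == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_contingency([], [])

    def test_matches_brute_force_tally_on_fixture(self, small_quarter):
        _, tables, _ = small_quarter
        truth = tables.truth_cases
        exposed = truth["exposed_drugA"].astype(bool).to_numpy()
        event = truth["event"].astype(bool).to_numpy()
        t = build_contingency(exposed, event)
        assert t.a == int(np.sum(exposed & event))
        assert t.d == int(np.sum(~exposed & ~event))
        assert t.total == len(truth)


class TestComputeRor:
    def test_hand_evaluated_fixture(self):
        # ad/bc = 10*9900/(90*100) = 11; CI = exp(ln 11 -+ 1.96*0.348155)
        ror, lo, hi = compute_ror(ContingencyTable(10, 90, 100, 9900))
        assert ror == pytest.approx(11.0, abs=1e-12)
        assert lo == pytest.approx(5.559585, abs=1e-5)
        assert hi == pytest.approx(21.764216, abs=1e-5)

    def test_balanced_table_symmetric_about_one(self):
        ror, lo, hi = compute_ror(ContingencyTable(10, 10, 10, 10))
        assert ror == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=100, deadline=None)
    def test_reciprocal_symmetry(self, a, b, c, d):
        """Relabelling event <-> non-event maps ROR to 1/ROR and leaves the
        chi-square statistic unchanged."""
        r1, lo1, hi1 = compute_ror(ContingencyTable(a, b, c, d))
        r2, lo2, hi2 = compute_ror(ContingencyTable(b, a, d, c))
        assert r2 == pytest.approx(1.0 / r1, rel=1e-9)
        assert lo2 == pytest.approx(1.0 / hi1, rel=1e-9)
        chi1, _ = chi_square(ContingencyTable(a, b, c, d))
        chi2_, _ = chi_square(ContingencyTable(b, a, d, c))
        assert chi2_ == pytest.approx(chi1, rel=1e-9, abs=1e-9)

    def test_zero_cell_raises_naming_cell(self):
        with pytest.raises(ZeroCellError, match="cell b"):
            compute_ror(ContingencyTable(5, 0, 3, 10))

    def test_haldane_correction_handles_zero_cells(self):
        ror, lo, hi = compute_ror(ContingencyTable(5, 0, 3, 10), haldane=True)
        assert ror == pytest.approx((5.5 * 10.5) / (0.5 * 3.5))
        assert lo < ror < hi


class TestChiSquare:
    def test_independent_table_is_zero(self):
        chi2, p = chi_square(ContingencyTable(25, 25, 25, 25))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_expected_count_oracle(self):
        t = ContingencyTable(10, 90, 100, 9900)
        obs = np.array([[10, 90], [100, 9900]], float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        oracle = ((obs - expected) ** 2 / expected).sum()
        chi2, _ = chi_square(t)
        assert chi2 == pytest.approx(oracle, rel=1e-12)
        assert chi2 == pytest.approx(74.447174, abs=1e-5)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=50, deadline=None)
    def test_doubling_cells_doubles_statistic(self, a, b, c, d):
        chi1, _ = chi_square(ContingencyTable(a, b, c, d))
        chi2_, _ = chi_square(ContingencyTable(2 * a, 2 * b, 2 * c, 2 * d))
        assert chi2_ == pytest.approx(2 * chi1, rel=1e-9, abs=1e-9)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi_square(ContingencyTable(0, 0, 5, 5))

    def test_yates_never_exceeds_plain(self):
        t = ContingencyTable(12, 88, 100, 9800)
        plain, _ = chi_square(t)
        corrected, _ = chi_square(t, yates=True)
        assert corrected <= plain


class TestBonferroni:
    def test_direct_product(self):
        assert bonferroni_adjust([0.004], m=2)[0] == pytest.approx(0.008)

    def test_clamped_at_one(self):
        assert bonferroni_adjust([0.9], m=50)[0] == 1.0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_order_preserving(self, ps):
        adj = bonferroni_adjust(sorted(ps), m=len(ps) + 5)
        assert list(adj) == sorted(adj)

    def test_invalid_family_sizes(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.5], m=0)
        with pytest.raises(ValueError):
            bonferroni_adjust([0.5, 0.6], m=1)


class TestVectorisedKernels:
    """The array kernels must agree exactly with the scalar contracts."""

    def test_agree_with_scalar_functions(self):
        rng = np.random.default_rng(4)
        a, b, c, d = (rng.integers(1, 500, 200) for _ in range(4))
        ror, lo, hi = ror_stats_arrays(a, b, c, d)
        chi2, p = chi_square_arrays(a, b, c, d)
        for i in range(200):
            t = ContingencyTable(int(a[i]), int(b[i]), int(c[i]), int(d[i]))
            r, l, h = compute_ror(t)
            x2, pp = chi_square(t)
            assert ror[i] == pytest.approx(r, rel=1e-12)
            assert lo[i] == pytest.approx(l, rel=1e-12)
            assert hi[i] == pytest.approx(h, rel=1e-12)
            assert chi2[i] == pytest.approx(x2, rel=1e-10)
            assert p[i] == pytest.approx(pp, rel=1e-9, abs=1e-300)

    def test_tabulate_matches_build_contingency(self):
        rng = np.random.default_rng(8)
        expo = rng.random((500, 4)) < 0.3
        event = rng.random(500) < 0.4
        a, b, c, d = tabulate_exposure_event(expo, event)
        for j in range(4):
            t = build_contingency(expo[:, j], event)
            assert (a[j], b[j], c[j], d[j]) == (t.a, t.b, t.c, t.d)


class TestScreen:
    def _row(self, **kw):
        base = dict(drug="x", a=150, b=100, c=500, d=10_000, ror=3.0,
                    ror_lower=1.2, ror_upper=4.0, chi2=50.0, p_raw=1e-6,
                    p_adjust=0.005, n_reports=150, zero_cell=False,
                    is_signal=False)
        base.update(kw)
        return base

    def test_all_gates_pass(self):
        df = pd.DataFrame([self._row()])
        assert len(screen_signals(df)) == 1

    @pytest.mark.parametrize("kw", [
        dict(a=99, n_reports=99, p_adjust=1e-10, ror_lower=5.0),  # count gate
        dict(a=100, n_reports=100),                  # strictly more than 100
        dict(ror_lower=0.99),                        # CI gate
        dict(ror_lower=1.0),                         # strict inequality
        dict(p_adjust=0.01),                         # strict inequality
        dict(a=2, n_reports=2),                      # min_a gate
    ])
    def test_single_gate_failure_blocks_signal(self, kw):
        df = pd.DataFrame([self._row(**kw)])
        assert len(screen_signals(df)) == 0

    def test_count_boundary_101_vs_99(self):
        df = pd.DataFrame([self._row(drug="hi", a=101),
                           self._row(drug="lo", a=99)])
        out = screen_signals(df)
        assert list(out["drug"]) == ["hi"]

    def test_relaxed_count_rule(self):
        df = pd.DataFrame([self._row(a=100)])
        th = ScreenThresholds(count_rule="ge")
        assert len(screen_signals(df, th)) == 1

    def test_sorted_by_descending_ror_ties_alphabetical(self):
        df = pd.DataFrame([self._row(drug="b", ror=2.0),
                           self._row(drug="a", ror=2.0),
                           self._row(drug="c", ror=9.0)])
        out = screen_signals(df)
        assert list(out["drug"]) == ["c", "a", "b"]


class TestAnalyze:
    def test_cells_match_brute_force_on_fixture(self, small_quarter, event_def):
        from pvsignal.io import (deduplicate, normalize_drug_names,
                                 read_quarter, suspect_pairs,
                                 flag_event_cases)
        outdir, tables, _ = small_quarter
        rs = normalize_drug_names(deduplicate(read_quarter(outdir)))
        flags = flag_event_cases(rs, event_def)
        res = analyze(flags, suspect_pairs(rs)).set_index("drug")
        truth = tables.truth_cases
        event = truth["event"].astype(bool).to_numpy()
        for drug in ("druga", "drugb"):
            exposed = truth[f"exposed_drug{drug[-1].upper()}"] \
                .astype(bool).to_numpy()
            assert res.loc[drug, "a"] == int(np.sum(exposed & event))
            assert res.loc[drug, "b"] == int(np.sum(exposed & ~event))
            assert res.loc[drug, "c"] == int(np.sum(~exposed & event))
            assert res.loc[drug, "d"] == int(np.sum(~exposed & ~event))

    def test_family_size_is_tested_drug_count(self, small_quarter, event_def):
        from pvsignal.io import (deduplicate, normalize_drug_names,
                                 read_quarter, suspect_pairs,
                                 flag_event_cases)
        outdir, _, _ = small_quarter
        rs = normalize_drug_names(deduplicate(read_quarter(outdir)))
        flags = flag_event_cases(rs, event_def)
        res = analyze(flags, suspect_pairs(rs))
        assert res.attrs["family_size"] == len(res)
        assert (res["p_adjust"] >= res["p_raw"]).all()


class TestVolcano:
    def test_log_identities_and_completeness(self):
        df = pd.DataFrame({
            "drug": ["a", "b", "c"],
            "ror": [1.0, 2.0, 3.0],
            "p_adjust": [1.0, 0.01, 1e-320],
            "is_signal": [False, True, True],
        })
        out = volcano_table(df)
        assert len(out) == 3
        assert out["neg_log10_p_adjust"].iloc[0] == pytest.approx(0.0)
        assert out["neg_log10_p_adjust"].iloc[1] == pytest.approx(2.0)
        assert np.isfinite(out["neg_log10_p_adjust"]).all()
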