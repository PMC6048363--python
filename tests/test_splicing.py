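"""PSI estimation, delta-PSI Fisher tests, classification and shortlisting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from saspkit import splicing
from saspkit.exceptions import (
    CoverageError,
    DegenerateInputError,
    FormatError,
    SampleSizeError,
)


class TestPsiEstimators:
    @pytest.mark.parametrize("inc1,inc2,skip,expected", [
        (10, 10, 10, 0.5),
        (30, 10, 20, 0.5),   # I = (30+10)/2 = 20
        (5, 5, 0, 1.0),
        (0, 0, 7, 0.0),
    ])
    def test_junction_psi(self, inc1, inc2, skip, expected):
        est = splicing.psi_from_junctions(inc1, inc2, skip)
        assert est.psi == pytest.approx(expected)

    def test_all_zero_counts_flagged(self):
        with pytest.raises(DegenerateInputError):
            splicing.psi_from_junctions(0, 0, 0)

    @pytest.mark.parametrize("c_long,c_short,expected", [
        (2.0, 2.0, 0.5), (0.0, 3.0, 0.0), (9.0, 1.0, 0.9),
    ])
    def test_concentration_psi(self, c_long, c_short, expected):
        assert splicing.psi_from_concentrations(c_long, c_short).psi == pytest.approx(expected)

    def test_zero_concentrations_flagged(self):
        with pytest.raises(DegenerateInputError):
            splicing.psi_from_concentrations(0.0, 0.0)


def fisher_oracle(table):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    n1, n2, k = a + b, c + d, a + c
    lo, hi = max(0, k - n2), min(k, n1)
    probs = {
        x: stats.hypergeom.pmf(x, n1 + n2, k, n1) for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestDeltaPsiTest:
    def test_identical_counts_null(self):
        r = splicing.delta_psi_test((10, 10, 10), (10, 10, 10))
        assert r.delta_psi == 0.0 and r.p == 1.0

    def test_p_matches_hypergeometric_oracle(self):
        r = splicing.delta_psi_test((10, 10, 10), (18, 18, 2))
        assert r.p == pytest.approx(fisher_oracle([[10, 10], [18, 2]]), abs=1e-12)

    def test_swap_negates_delta_keeps_p(self):
        a, b = (12, 8, 30), (40, 36, 9)
        r1 = splicing.delta_psi_test(a, b)
        r2 = splicing.delta_psi_test(b, a)
        assert r1.delta_psi == pytest.approx(-r2.delta_psi)
        assert r1.p == pytest.approx(r2.p)

    def test_zero_margin_is_degenerate(self):
        r = splicing.delta_psi_test((0, 0, 10), (0, 0, 20))
        assert r.degenerate and r.p == 1.0

    def test_inclusion_rounding_half_up(self):
        # I_A = (3+2)/2 = 2.5 -> 3
        r = splicing.delta_psi_test((3, 2, 10), (10, 10, 10))
        assert not r.degenerate
        _, p = stats.fisher_exact([[3, 10], [10, 10]])
        assert r.p == pytest.approx(p)


class TestDeltaPsiTable:
    def test_pools_replicates_by_summing(self):
        junctions = pd.DataFrame([
            dict(event_id="E1", sample_id="c1", condition="ctl", inc1=5, inc2=5, skip=5),
            dict(event_id="E1", sample_id="c2", condition="ctl", inc1=5, inc2=5, skip=5),
            dict(event_id="E1", sample_id="k1", condition="kd", inc1=18, inc2=18, skip=2),
        ])
        out = splicing.delta_psi_table(junctions, "ctl", "kd")
        ref = splicing.delta_psi_test((10, 10, 10), (18, 18, 2))
        assert out.loc[0, "p"] == pytest.approx(ref.p)

    def test_missing_condition_raises(self):
        junctions = pd.DataFrame([
            dict(event_id="E1", sample_id="c1", condition="ctl", inc1=5, inc2=5, skip=5),
        ])
        with pytest.raises(CoverageError, match="E1"):
            splicing.delta_psi_table(junctions, "ctl", "kd")


class TestClassifyAndShortlist:
    @pytest.mark.parametrize("delta,fdr,expected", [
        (0.25, 0.01, "repressed"),
        (0.25, 0.20, "unchanged"),
        (-0.5, 1e-6, "enhanced"),
        (0.1, 0.001, "unchanged"),
    ])
    def test_classification_rules(self, delta, fdr, expected):
        rec = pd.DataFrame([dict(event_id="E", delta_psi=delta, fdr=fdr)])
        out = splicing.classify_regulation(rec)
        assert out.loc[0, "regulation_class"] == expected

    def _records(self, rows):
        return pd.DataFrame(
            [dict(event_id=e, delta_psi=d, regulation_class=c) for e, d, c in rows]
        )

    def test_two_tier_rules(self):
        test = self._records([
            ("E1", 0.25, "repressed"),   # also changed in reference -> tier1
            ("E2", 0.25, "repressed"),   # unchanged in reference, < strict -> dropped
            ("E3", 0.35, "repressed"),   # unchanged in reference, >= strict -> tier2
            ("E4", 0.05, "unchanged"),
        ])
        ref = self._records([
            ("E1", 0.30, "repressed"),
            ("E2", 0.00, "unchanged"),
            ("E3", 0.00, "unchanged"),
            ("E4", 0.00, "unchanged"),
        ])
        out = splicing.shortlist_events(test, ref)
        assert dict(zip(out["event_id"], out["tier"])) == {"E1": "tier1", "E3": "tier2"}
        # sorted by |delta| descending
        assert list(out["event_id"]) == ["E3", "E1"]

    def test_mismatched_universe_rejected(self):
        test = self._records([("E1", 0.25, "repressed")])
        ref = self._records([("E2", 0.0, "unchanged")])
        with pytest.raises(CoverageError):
            splicing.shortlist_events(test, ref)


class TestProportionTest:
    def test_balanced_gives_half(self):
        chi2, p = splicing.inclusion_proportion_test(50, 100)
        assert chi2 == 0.0 and p == pytest.approx(0.5)

    def test_seventy_of_hundred(self):
        chi2, p = splicing.inclusion_proportion_test(70, 100)
        assert chi2 == pytest.approx(16.0)
        # one-sided tail: chi2(1) sf halved equals the normal tail at z=4
        assert p == pytest.approx(stats.norm.sf(4.0), rel=1e-8)

    def test_opposite_direction_near_one(self):
        _, p = splicing.inclusion_proportion_test(0, 10)
        assert p > 0.99

    def test_empty_total_rejected(self):
        with pytest.raises(SampleSizeError):
            splicing.inclusion_proportion_test(0, 0)


class TestEventTypeSummary:
    def test_counts_and_fractions(self):
        events = pd.DataFrame({"event_type": ["SE"] * 3 + ["RI"]})
        out = splicing.summarize_event_types(events).set_index("event_type")
        assert out.loc["SE", "count"] == 3 and out.loc["RI", "count"] == 1
        assert out.loc["MXE", "count"] == 0
        assert out["fraction"].sum() == pytest.approx(1.0)

    def test_empty_table_all_zero(self):
        out = splicing.summarize_event_types(pd.DataFrame({"event_type": []}))
        assert (out["count"] == 0).all()

    def test_unknown_type_rejected(self):
        with pytest.raises(FormatError):
            splicing.summarize_event_types(pd.DataFrame({"event_type": ["??"]}))
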