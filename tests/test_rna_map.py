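"""PWM scanning with exact p-values, splice-site anchoring and RNA maps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from saspkit import rna_map
from saspkit.exceptions import CoverageError, ParameterError


def enumeration_pvalue(pwm, score):
    """Brute-force tail probability over all 4^w words."""
    lods, bg = pwm.log_odds, pwm.background
    total = 0.0
    for word in itertools.product(range(4), repeat=pwm.width):
        s = sum(lods[a, j] for j, a in enumerate(word))
        if s >= score - 1e-9:
            total += np.prod([bg[a] for a in word])
    return total


def random_pwm(width, seed, uniform_bg=True):
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.ones(4) * 0.8, size=width).T
    bg = np.full(4, 0.25) if uniform_bg else rng.dirichlet(np.ones(4) * 5)
    return rna_map.Pwm(probs, background=bg)


class TestPwmScan:
    def test_degenerate_matrix_finds_substring_matches(self):
        probs = np.zeros((4, 4))
        for j, base in enumerate("TCTT"):
            probs["ACGT".index(base), j] = 1.0
        pwm = rna_map.Pwm(probs, pseudocount=1e-6)
        seq = "AATCTTGGTCTTAA"
        occ = rna_map.pwm_scan(seq, pwm, p_threshold=1e-2)
        assert list(occ["start"]) == [2, 8]
        assert (occ["end"] - occ["start"] == 4).all()

    @pytest.mark.parametrize("width", [3, 4])
    @pytest.mark.parametrize("uniform_bg", [True, False])
    def test_pvalues_match_enumeration(self, width, uniform_bg):
        pwm = random_pwm(width, seed=width, uniform_bg=uniform_bg)
        rng = np.random.default_rng(0)
        # probe at every achievable word score of a few random words plus extremes
        words = rng.integers(0, 4, size=(20, width))
        scores = [pwm.log_odds[w, range(width)].sum() for w in words]
        scores += [pwm.log_odds.max(axis=0).sum(), pwm.log_odds.min(axis=0).sum()]
        for s in scores:
            assert pwm.score_pvalue(s) == pytest.approx(
                enumeration_pvalue(pwm, s), abs=1e-6
            )

    def test_p_monotone_in_score(self):
        pwm = random_pwm(5, seed=3)
        s = np.linspace(-10, 10, 50)
        p = pwm.score_pvalue(s)
        assert (np.diff(p) <= 1e-12).all()

    def test_short_and_empty_sequences(self):
        pwm = rna_map.cu_rich_example_pwm()
        assert rna_map.pwm_scan("", pwm).empty
        assert rna_map.pwm_scan("ACG", pwm).empty

    def test_n_positions_skipped(self):
        pwm = rna_map.cu_rich_example_pwm()
        occ = rna_map.pwm_scan("TCTTTCTT".replace("C", "N"), pwm, p_threshold=1.0)
        assert occ.empty

    def test_invalid_pwm_rejected(self):
        with pytest.raises(ParameterError):
            rna_map.Pwm(np.full((4, 3), 0.3))  # columns don't sum to 1


def _event(strand, alt_start=1000, alt_end=1120):
    return pd.Series(dict(event_id="EV1", strand=strand, chrom="chr1",
                          alt_start=alt_start, alt_end=alt_end))


class TestAnchoring:
    def test_plus_strand_acceptor_offsets(self):
        occ = pd.DataFrame([dict(start=960, end=966, score=1.0, p=0.001)])
        anc, dropped = rna_map.anchor_occurrences(_event("+"), occ)
        assert dropped == 0
        row = anc.iloc[0]
        assert (row["anchor"], row["offset_start"], row["offset_end"]) == (
            "acceptor", -40, -34)

    def test_minus_strand_mirror_gives_same_offsets(self):
        # the mirror of [960, 966) before a + acceptor at 1000 is
        # [1154, 1160) after a - acceptor at alt_end=1120
        occ = pd.DataFrame([dict(start=1154, end=1160, score=1.0, p=0.001)])
        anc, _ = rna_map.anchor_occurrences(_event("-"), occ)
        row = anc.iloc[0]
        assert (row["anchor"], row["offset_start"], row["offset_end"]) == (
            "acceptor", -40, -34)

    def test_out_of_region_occurrence_dropped(self):
        occ = pd.DataFrame([dict(start=400, end=406, score=1.0, p=0.001)])
        anc, dropped = rna_map.anchor_occurrences(
            _event("+"), occ, rna_map.RegionSpec(upstream_flank=300)
        )
        assert anc.empty and dropped == 1

    def test_local_to_genomic_roundtrip_both_strands(self):
        spec = rna_map.RegionSpec()
        for strand in "+-":
            ev = _event(strand)
            g = rna_map.local_to_genomic(ev, "upstream_intron", 260, 266, 300)
            occ = pd.DataFrame([dict(start=g[0], end=g[1], score=0.0, p=0.5)])
            anc, _ = rna_map.anchor_occurrences(ev, occ, spec)
            # local 260 with flank 300 is 40 nt before the 3' splice site
            assert anc.iloc[0]["offset_start"] == -40
            assert anc.iloc[0]["offset_end"] == -34


def _anchored(rows):
    return pd.DataFrame(
        [dict(event_id=e, anchor="acceptor", offset_start=s, offset_end=s + 8,
              score=0.0, p=0.001) for e, s in rows]
    )


class TestRnaMap:
    def test_worked_fisher_window(self):
        """8/10 motif-positive repressed vs 2/10 unchanged in one window."""
        groups = {f"R{i}": "repressed" for i in range(10)}
        groups.update({f"U{i}": "unchanged" for i in range(10)})
        rows = [(f"R{i}", -40) for i in range(8)] + [(f"U{i}", -40) for i in range(2)]
        res = rna_map.build_rna_map(groups, _anchored(rows), window=31)
        win = res.windows[(res.windows["center"] == -36)
                          & (res.windows["group"] == "repressed")]
        assert win["p"].iloc[0] == pytest.approx(2126 / 184756, rel=1e-12)
        assert win["n_test_pos"].iloc[0] == 8 and win["n_ref_pos"].iloc[0] == 2

    def test_density_counts_fraction_of_exons(self):
        groups = {"R0": "repressed", "R1": "repressed", "U0": "unchanged"}
        res = rna_map.build_rna_map(groups, _anchored([("R0", -40)]), window=31)
        dens = res.densities["repressed"]
        offsets = res.offsets
        inside = (offsets >= -40) & (offsets < -32)
        assert np.allclose(dens[inside], 0.5)
        assert np.allclose(dens[~inside], 0.0)
        assert np.allclose(res.densities["unchanged"], 0.0)

    def test_empty_reference_group_rejected(self):
        with pytest.raises(CoverageError):
            rna_map.build_rna_map({"R0": "repressed"}, _anchored([]), window=31)

    def test_event_order_invariance(self):
        groups = {f"E{i}": ("repressed" if i % 3 else "unchanged") for i in range(12)}
        rows = [(f"E{i}", -60 + i) for i in range(12)]
        a = rna_map.build_rna_map(groups, _anchored(rows))
        b = rna_map.build_rna_map(dict(reversed(list(groups.items()))),
                                  _anchored(list(reversed(rows))))
        pd.testing.assert_frame_equal(
            a.windows.sort_values(["center", "group"]).reset_index(drop=True),
            b.windows.sort_values(["center", "group"]).reset_index(drop=True),
        )

    def test_window_significance_bh_monotone(self):
        groups = {f"R{i}": "repressed" for i in range(6)}
        groups.update({f"U{i}": "unchanged" for i in range(6)})
        rows = [(f"R{i}", -50 + 4 * i) for i in range(6)]
        res = rna_map.build_rna_map(groups, _anchored(rows))
        ann = rna_map.window_significance(res.windows, adjust=True)
        sub = ann.sort_values("p")
        assert (np.diff(sub["p_adj"].to_numpy()) >= -1e-12).all()
        # raw p untouched by default
        assert "p_adj" not in rna_map.window_significance(res.windows).columns
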