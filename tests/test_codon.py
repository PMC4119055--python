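"""NG86 counting, Jukes-Cantor correction and the derived gene-level stats."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import random_sense_codons
from oracles import naive_pair_totals, naive_path_diffs, naive_site_counts

from mtevol.codon import (
    _CODONS,
    _codon_table,
    aggregate_gene_stats,
    codon_path_diffs,
    codon_site_counts,
    cumulative_site_profile,
    dnds_regression,
    jukes_cantor_correct,
    pairwise_ng86,
)

STOPS = set(_codon_table(1).stop_codons)
SENSE = [c for c in _CODONS if c not in STOPS]


class TestSiteCounts:
    @pytest.mark.parametrize(
        "codon,s,n",
        [
            ("GGG", 1.0, 2.0),  # third position wholly synonymous for Gly
            ("ATG", 0.0, 3.0),  # Met has no synonymous single change
            ("TTT", 1 / 3, 8 / 3),  # only TTT->TTC synonymous
        ],
    )
    def test_hand_enumerated_codons(self, codon, s, n):
        got_s, got_n = codon_site_counts(codon)
        assert got_s == pytest.approx(s, abs=1e-12)
        assert got_n == pytest.approx(n, abs=1e-12)

    def test_all_sense_codons_match_naive_enumeration(self):
        for codon in SENSE:
            s, n = codon_site_counts(codon)
            es, en = naive_site_counts(codon)
            assert s == pytest.approx(es, abs=1e-12), codon
            assert n == pytest.approx(en, abs=1e-12), codon
            assert s + n == pytest.approx(3.0, abs=1e-12)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            codon_site_counts("TAA")

    def test_ambiguous_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_site_counts("ANT")


class TestPathDiffs:
    @pytest.mark.parametrize(
        "a,b,sd,nd",
        [
            ("TTT", "TTC", 1.0, 0.0),  # single synonymous change
            ("TTT", "TTA", 0.0, 1.0),  # Phe -> Leu
            ("TTT", "GTA", 0.5, 1.5),  # two pathways averaged
        ],
    )
    def test_hand_enumerated_pairs(self, a, b, sd, nd):
        got_sd, got_nd, _, _ = codon_path_diffs(a, b)
        assert got_sd == pytest.approx(sd)
        assert got_nd == pytest.approx(nd)

    def test_transition_transversion_classification(self):
        _, _, ts, tv = codon_path_diffs("TTT", "TTC")
        assert (ts, tv) == (1, 0)
        _, _, ts, tv = codon_path_diffs("TTT", "GTA")
        assert (ts, tv) == (0, 2)

    def test_all_sense_pairs_match_naive_enumeration(self):
        for a in SENSE:
            for b in SENSE:
                sd, nd, ts, tv = codon_path_diffs(a, b)
                esd, end_ = naive_path_diffs(a, b)
                assert sd == pytest.approx(esd, abs=1e-12), (a, b)
                assert nd == pytest.approx(end_, abs=1e-12), (a, b)
                ndiff = sum(x != y for x, y in zip(a, b))
                assert sd + nd == pytest.approx(ndiff, abs=1e-12)
                assert ts + tv == ndiff

    def test_symmetry(self, rng):
        for _ in range(200):
            a, b = (SENSE[i] for i in rng.integers(0, len(SENSE), 2))
            assert codon_path_diffs(a, b)[:2] == codon_path_diffs(b, a)[:2]


class TestJukesCantor:
    def test_zero_and_closed_form(self):
        assert jukes_cantor_correct(0.0) == 0.0
        expected = -0.75 * math.log(1 - 0.05 * 4 / 3)
        assert jukes_cantor_correct(0.05) == pytest.approx(expected, rel=1e-12)
        assert jukes_cantor_correct(0.05) == pytest.approx(0.0517447, abs=1e-6)

    def test_saturation(self):
        assert math.isnan(jukes_cantor_correct(0.75))
        assert math.isnan(jukes_cantor_correct(0.9))
        # approaching saturation the distance is capped, flagged by value
        assert jukes_cantor_correct(0.7499999) <= 10.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            jukes_cantor_correct(-0.01)


class TestPairwiseNG86:
    def test_identical_sequences(self):
        st = pairwise_ng86("GGGTTTATG", "GGGTTTATG")
        assert st.Sd == st.Nd == 0.0
        assert st.dS == st.dN == 0.0
        assert math.isnan(st.omega)

    def test_three_codon_hand_case(self):
        st = pairwise_ng86("GGGTTTATG", "GGATTTATG")
        assert st.Sd == 1.0 and st.Nd == 0.0
        assert st.S_sites == pytest.approx(4 / 3)
        assert st.ps == pytest.approx(0.75)
        assert st.saturated_s  # ps hits the JC singularity

    def test_site_sum_invariant(self, rng):
        a = random_sense_codons(rng, 25)
        b = random_sense_codons(rng, 25)
        st = pairwise_ng86(a, b)
        assert st.S_sites + st.N_sites == pytest.approx(3 * st.n_codons, abs=1e-9)

    def test_random_pairs_match_naive_oracle(self, rng):
        for _ in range(100):
            a = random_sense_codons(rng, 30)
            b = random_sense_codons(rng, 30)
            st = pairwise_ng86(a, b)
            Sd, Nd, Ss, Ns, n = naive_pair_totals(a, b)
            assert st.Sd == pytest.approx(Sd, abs=1e-9)
            assert st.Nd == pytest.approx(Nd, abs=1e-9)
            assert st.S_sites == pytest.approx(Ss, abs=1e-9)
            assert st.N_sites == pytest.approx(Ns, abs=1e-9)
            assert st.n_codons == n

    def test_gapped_codons_skipped(self):
        st = pairwise_ng86("GGG---TTT", "GGGAAATTC")
        assert st.n_codons == 2
        assert st.Sd == 1.0  # TTT vs TTC

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            pairwise_ng86("GGGTTT", "GGG")

    def test_biopython_cross_check(self, rng):
        """Low-divergence pairs agree with Bio.codonalign's NG86 to within
        its slightly different stop-codon site convention."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        from mtevol.synthetic_data import CodonSimConfig, simulate_codon_msa

        seqs, _ = simulate_codon_msa(
            CodonSimConfig(6, 80, [(1, 80, 0.5)], seed=3, branch_length=0.08)
        )
        checked = 0
        for i in range(3):
            a, b = seqs[i][1], seqs[i + 1][1]
            st = pairwise_ng86(a, b)
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            if ds <= 0 or st.saturated or st.dS == 0:
                continue
            assert st.dN == pytest.approx(dn, rel=0.12, abs=5e-3)
            assert st.dS == pytest.approx(ds, rel=0.12, abs=5e-3)
            checked += 1
        assert checked >= 1


class TestCumulativeProfile:
    def test_identical_sequences_flat_zero(self):
        prof = cumulative_site_profile(["GGGTTTATG", "GGGTTTATG"])
        assert (prof.cum_syn == 0).all() and (prof.cum_nonsyn == 0).all()

    def test_single_difference_steps_once(self):
        prof = cumulative_site_profile(["GGGTTTATG", "GGGTTCATG"])
        np.testing.assert_allclose(prof.cum_syn, [0, 1, 1])
        np.testing.assert_allclose(prof.cum_nonsyn, [0, 0, 0])

    def test_monotone_and_totals_match_pairwise(self, rng):
        seqs = [random_sense_codons(rng, 20) for _ in range(4)]
        prof = cumulative_site_profile(seqs)
        assert (np.diff(prof.cum_syn) >= -1e-12).all()
        assert (np.diff(prof.cum_nonsyn) >= -1e-12).all()
        tot_s = tot_n = 0.0
        n_pairs = 0
        for i in range(4):
            for j in range(i + 1, 4):
                st = pairwise_ng86(seqs[i], seqs[j])
                tot_s += st.Sd
                tot_n += st.Nd
                n_pairs += 1
        assert prof.cum_syn[-1] == pytest.approx(tot_s / n_pairs, abs=1e-9)
        assert prof.cum_nonsyn[-1] == pytest.approx(tot_n / n_pairs, abs=1e-9)

    def test_hotspot_share(self):
        prof = cumulative_site_profile(
            ["GGGTTTATG", "GGGTTAATG"], hotspots=[(2, 2, "site2")]
        )
        assert prof.window_nonsyn_share["site2"] == pytest.approx(1.0)

    def test_bad_hotspot_rejected(self):
        with pytest.raises(ValueError, match="hotspot"):
            cumulative_site_profile(
                ["GGGTTTATG", "GGGTTAATG"], hotspots=[(1, 99, "w")]
            )


class TestAggregates:
    # 20 codons differing by one synonymous (AAA->AAG) and one
    # non-synonymous (GGG->AGG) change: far from JC saturation
    _A = "AAA" * 10 + "GGG" * 10
    _B = "AAG" + "AAA" * 9 + "AGG" + "GGG" * 9

    def test_single_pair_passthrough(self):
        st = pairwise_ng86(self._A, self._B)
        assert not st.saturated
        agg = aggregate_gene_stats([st], "g")
        assert agg["mean_dS"] == pytest.approx(st.dS)
        assert agg["mean_dN"] == pytest.approx(st.dN)

    def test_mean_of_ratios_convention(self):
        from mtevol.codon import CodonPairStats

        def mk(dn, ds):
            return CodonPairStats(
                n_codons=10, S_sites=10, N_sites=20, Sd=1, Nd=1,
                ps=0.1, pn=0.05, dS=ds, dN=dn, omega=dn / ds, ts_fraction=0.5,
            )

        agg = aggregate_gene_stats([mk(0.2, 0.4), mk(0.1, 0.2)], "g")
        # omega is averaged per pair (mean of ratios), not ratio of means
        assert agg["mean_omega"] == pytest.approx(0.5)

    def test_saturated_pairs_excluded_and_counted(self):
        ok = pairwise_ng86(self._A, self._B)
        sat = pairwise_ng86("GGGTTTATG", "GGATTTATG")  # ps = 0.75
        agg = aggregate_gene_stats([ok, sat], "g")
        assert agg["n_saturated"] == 1
        assert agg["mean_dS"] == pytest.approx(ok.dS)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_gene_stats([], "g")


class TestRegression:
    def test_points_on_neutrality_line(self):
        table = pd.DataFrame(
            {
                "gene": list("abcd"),
                "group": ["g"] * 4,
                "mean_dS": [0.1, 0.2, 0.4, 0.8],
                "mean_dN": [0.1, 0.2, 0.4, 0.8],
            }
        )
        res = dnds_regression(table).iloc[0]
        assert res["slope"] == pytest.approx(1.0)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert res["r"] == pytest.approx(1.0)

    def test_constant_quarter_ratio(self):
        table = pd.DataFrame(
            {
                "gene": list("abcd"),
                "group": ["g"] * 4,
                "mean_dS": [0.1, 0.2, 0.4, 0.8],
                "mean_dN": [x / 4 for x in (0.1, 0.2, 0.4, 0.8)],
            }
        )
        res = dnds_regression(table).iloc[0]
        assert res["slope"] == pytest.approx(1.0)
        assert res["intercept"] == pytest.approx(-2.0)

    def test_small_groups_skipped_and_zeros_excluded(self):
        table = pd.DataFrame(
            {
                "gene": list("abc"),
                "group": ["g"] * 3,
                "mean_dS": [0.1, 0.2, 0.0],
                "mean_dN": [0.1, 0.2, 0.1],
            }
        )
        res = dnds_regression(table).iloc[0]
        assert bool(res["skipped"])
        assert res["n_excluded"] == 1
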