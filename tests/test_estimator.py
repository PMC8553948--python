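"""Queller–Goodnight estimator, classification and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinpile import (NoOverlapError, PairwiseResult, classify, compare_pair,
                     confidence_tier, gen_cohort, gen_freq_panel,
                     normalize_unrelated, pair_loci, pairwise_hrc, rxy_locus)
from kinpile.estimator import (CLASS_FIRST, CLASS_SECOND,
                               CLASS_SECOND_OR_THIRD, CLASS_UNRELATED,
                               results_to_frame)


class TestRxyLocus:
    def test_identical_homozygotes_give_one_any_frequency(self):
        for p in (0.1, 0.3, 0.5, 0.9):
            assert rxy_locus("A", "A", "A", "A", {"A": p}) == pytest.approx(1.0)

    def test_full_mismatch_at_half(self):
        p = {"A": 0.5, "G": 0.5}
        assert rxy_locus("A", "A", "G", "G", p) == pytest.approx(-1.0)

    def test_hand_worked_diploid_example_both_directions(self):
        """Heterozygous x (A,G) vs homozygous y (A,A), pA=0.3, pG=0.2."""
        p = {"A": 0.3, "G": 0.2}
        assert rxy_locus("A", "G", "A", "A", p) == pytest.approx(1.0, abs=1e-12)
        assert rxy_locus("A", "A", "A", "G", p) == pytest.approx(0.4 / 1.4, abs=1e-12)

    def test_frequency_bounds_enforced(self):
        with pytest.raises(Exception, match="frequency"):
            rxy_locus("A", "A", "G", "G", {"A": 1.0, "G": 0.0})

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(freq=st.floats(0.01, 0.99),
           ax=st.sampled_from("AG"), ay=st.sampled_from("AG"))
    def test_pseudo_haploid_reduction_matches_general_form(self, freq, ax, ay):
        """(I-p)/(1-p) fast path equals the four-allele formula."""
        p = {"A": freq, "G": 1.0 - freq}
        general = rxy_locus(ax, ax, ay, ay, p)
        reduced = (float(ax == ay) - p[ax]) / (1.0 - p[ax])
        assert general == pytest.approx(reduced, abs=1e-12)


@pytest.fixture(scope="module")
def cohort(panel_uniform_2k):
    tables, _ = gen_cohort(panel_uniform_2k, [("x", "y", 0.125)], seed=31,
                           singles=("z",))
    return tables


class TestPairwiseHrc:
    def test_self_identity_is_exactly_one(self, panel_uniform_2k, cohort):
        clone = cohort["x"]
        pair = pair_loci(clone, PseudoHaploidClone("x2", clone), panel_uniform_2k)
        for mode in ("mean_of_ratios", "ratio_of_sums"):
            assert pairwise_hrc(pair, mode=mode).hrc == pytest.approx(1.0, abs=1e-15)

    def test_three_locus_hand_example(self):
        """pA=pG=0.5 everywhere, x=(A,A,A), y=(A,G,A): per-locus (1,-1,1)."""
        panel = _half_panel()
        tx = _table("x", panel, "AAA")
        ty = _table("y", panel, "AGA")
        res = pairwise_hrc(pair_loci(tx, ty, panel))
        assert res.hrc == pytest.approx(1 / 3)
        assert res.n_snps == 3

    def test_symmetry(self, panel_uniform_2k, cohort):
        for mode in ("mean_of_ratios", "ratio_of_sums"):
            fwd = pairwise_hrc(pair_loci(cohort["x"], cohort["y"], panel_uniform_2k), mode)
            rev = pairwise_hrc(pair_loci(cohort["y"], cohort["x"], panel_uniform_2k), mode)
            assert fwd.hrc == pytest.approx(rev.hrc, abs=1e-12)

    def test_allele_relabeling_invariance(self, panel_uniform_2k, cohort):
        """Swapping allele1<->allele2 with freq1 -> 1-freq1 leaves HRC unchanged."""
        panel = panel_uniform_2k
        flipped = panel.loci.copy()
        flipped[["allele1", "allele2"]] = flipped[["allele2", "allele1"]].to_numpy()
        flipped["freq1"] = 1.0 - flipped["freq1"]
        from kinpile import FrequencyPanel
        panel_flipped = FrequencyPanel(flipped)
        a = pairwise_hrc(pair_loci(cohort["x"], cohort["y"], panel))
        b = pairwise_hrc(pair_loci(cohort["x"], cohort["y"], panel_flipped))
        assert a.hrc == pytest.approx(b.hrc, abs=1e-12)

    def test_modes_agree_at_constant_frequency(self):
        """At p = 0.5 every carried allele has the same frequency, so the
        per-locus denominators are constant and the two multilocus
        combinations coincide exactly."""
        panel = _half_panel(n=20, freq=0.5)
        rng = np.random.default_rng(8)
        tx = _table("x", panel, "".join(rng.choice(list("AG"), 20)))
        ty = _table("y", panel, "".join(rng.choice(list("AG"), 20)))
        pair = pair_loci(tx, ty, panel)
        assert pairwise_hrc(pair, "mean_of_ratios").hrc == pytest.approx(
            pairwise_hrc(pair, "ratio_of_sums").hrc, abs=1e-12)

    def test_matches_brute_force_oracle(self, panel_uniform_2k, cohort):
        """Vectorized estimator equals per-locus four-allele evaluation."""
        pair = pair_loci(cohort["x"], cohort["y"], panel_uniform_2k)
        expected = np.mean([
            0.5 * (rxy_locus(a, a, c, c, {a: fa} | {c: fc if c != a else fa})
                   + rxy_locus(c, c, a, a, {c: fc} | {a: fa if a != c else fc}))
            for a, c, fa, fc in zip(pair.allele_x[:200], pair.allele_y[:200],
                                    pair.freq_x[:200], pair.freq_y[:200])])
        sub = pair_loci(cohort["x"], cohort["y"], panel_uniform_2k)
        sub.locus_ids = sub.locus_ids[:200]
        sub.allele_x, sub.allele_y = sub.allele_x[:200], sub.allele_y[:200]
        sub.freq_x, sub.freq_y = sub.freq_x[:200], sub.freq_y[:200]
        assert pairwise_hrc(sub).hrc == pytest.approx(float(expected), abs=1e-12)

    def test_empty_intersection_raises(self, panel_uniform_2k):
        tx = _table_ids("x", panel_uniform_2k, [0, 1])
        ty = _table_ids("y", panel_uniform_2k, [2, 3])
        with pytest.raises(NoOverlapError, match="no overlapping SNPs"):
            pairwise_hrc(pair_loci(tx, ty, panel_uniform_2k))

    def test_unrelated_expectation_near_zero(self, panel_uniform_2k):
        """Mean HRC over simulated unrelated pairs is 0 within 3 SE."""
        from kinpile.simulate import hrc_of_vectors, simulate_pair
        f = panel_uniform_2k.loci["freq1"].to_numpy()
        rng = np.random.default_rng(99)
        vals = np.array([hrc_of_vectors(*simulate_pair(f, 0.0, rng), f)
                         for _ in range(300)])
        assert abs(vals.mean()) < 3 * vals.std(ddof=1) / np.sqrt(len(vals))


class TestClassify:
    @pytest.mark.parametrize("hrc,label", [
        (0.2595, CLASS_FIRST),            # published 1st-degree estimate
        (0.0962, CLASS_SECOND),           # published 2nd-degree estimate
        (-0.01, CLASS_UNRELATED),
        (0.07, CLASS_SECOND_OR_THIRD),
        # boundaries assign upward
        (0.1875, CLASS_FIRST),
        (0.090, CLASS_SECOND),
        (0.0625, CLASS_SECOND_OR_THIRD),
    ])
    def test_labels(self, hrc, label):
        assert classify(hrc) == label

    def test_monotone_in_hrc(self):
        rank = {CLASS_UNRELATED: 0, CLASS_SECOND_OR_THIRD: 1,
                CLASS_SECOND: 2, CLASS_FIRST: 3}
        grid = np.linspace(-0.2, 0.5, 141)
        ranks = [rank[classify(h)] for h in grid]
        assert ranks == sorted(ranks)

    def test_non_finite_rejected(self):
        with pytest.raises(Exception):
            classify(float("nan"))


class TestConfidenceTier:
    @pytest.mark.parametrize("n,tier", [
        (18_364, "high"), (18_000, "high"), (17_999, "medium"),
        (11_000, "medium"), (10_999, "low"), (4_059, "low"),
        (4_000, "low"), (3_999, "below_threshold"), (1, "below_threshold"),
    ])
    def test_tiers(self, n, tier):
        assert confidence_tier(n) == tier


class TestNormalization:
    def _results(self, hrcs):
        return [PairwiseResult(f"a{i}", f"b{i}", h, 20_000, classify(h), "high")
                for i, h in enumerate(hrcs)]

    def test_zero_mean_is_identity(self):
        res = self._results([0.0, 0.2])
        # artificial unrelated pair with hrc exactly 0
        out = normalize_unrelated(res, [("a0", "b0")])
        assert out[1].hrc == pytest.approx(0.2)

    def test_published_correction_example(self):
        """Mismatched-panel case: 0.3131 corrected by unrelated mean 0.1149."""
        res = self._results([0.1149, 0.3131])
        out = normalize_unrelated(res, [("a0", "b0")])
        assert out[1].hrc == pytest.approx(0.1982)
        assert out[1].class_label == CLASS_FIRST
        assert out[1].hrc_raw == pytest.approx(0.3131)

    def test_centering_property(self):
        res = self._results([0.10, 0.13, 0.30])
        out = normalize_unrelated(res, [("a0", "b0"), ("a1", "b1")])
        corrected_unrel = [r.hrc for r in out[:2]]
        assert np.mean(corrected_unrel) == pytest.approx(0.0, abs=1e-15)

    def test_empty_and_unknown_pairs_rejected(self):
        res = self._results([0.1])
        with pytest.raises(ValueError):
            normalize_unrelated(res, [])
        with pytest.raises(KeyError):
            normalize_unrelated(res, [("nope", "nah")])


def test_results_frame_columns():
    res = [PairwiseResult("a", "b", 0.2, 15_000, classify(0.2), "medium")]
    frame = results_to_frame(res)
    assert frame.loc[0, "hrc"] == 0.2
    assert np.isnan(frame.loc[0, "hrc_normalized"])


# --- helpers -------------------------------------------------------------

from kinpile import FrequencyPanel, PseudoHaploidTable  # noqa: E402


def PseudoHaploidClone(new_id, table):
    return PseudoHaploidTable(new_id, table.calls.copy())


def _half_panel(n=3, freq=0.5):
    pos = np.arange(1, n + 1) * 10
    df = pd.DataFrame({"chrom": "1", "pos": pos,
                       "id": [f"1_{p}" for p in pos],
                       "allele1": "A", "allele2": "G",
                       "freq1": freq}).set_index("id")
    return FrequencyPanel(df)


def _table(iid, panel, alleles):
    return PseudoHaploidTable(iid, pd.Series(list(alleles), index=panel.ids,
                                             dtype=object))


def _table_ids(iid, panel, idx):
    ids = panel.ids[idx]
    alleles = panel.loci.loc[ids, "allele1"]
    return PseudoHaploidTable(iid, pd.Series(alleles.to_numpy(), index=ids,
                                             dtype=object))
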