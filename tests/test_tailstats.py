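"""Aggregate statistics: length histogram, modification classes, positional
and pooled non-A composition, clone statistics and Tukey HSD."""

import math

import numpy as np
import pytest

from tailscope import simulate, tailstats
from tailscope.tailcall import EMPTY_SPAN, TailCall, classify_mod


def mk_call(polyA_len, mod_seq="", read_id="r", quals=None, tail_seq=None):
    """TailCall with a pure-A poly(A) region plus an optional modification."""
    if tail_seq is None:
        tail_seq = "A" * polyA_len + mod_seq
    n = len(tail_seq)
    if polyA_len == 0:
        return TailCall(read_id=read_id)
    return TailCall(
        read_id=read_id,
        polyA_span=(0, polyA_len),
        mod_span=(polyA_len, n) if n > polyA_len else EMPTY_SPAN,
        polyA_score=1,
        mod_class=classify_mod(tail_seq[polyA_len:]),
        tail_seq=tail_seq,
        tail_quals=tuple(quals) if quals is not None else tuple([38] * n),
    )


class TestLengthDistribution:
    def test_cap_pooling(self):
        calls = [mk_call(12) for _ in range(5)] + [mk_call(45) for _ in range(3)]
        hist = tailstats.length_distribution(calls)
        assert hist[12] == pytest.approx(62.5)
        assert hist[tailstats.GE_CAP_LABEL] == pytest.approx(37.5)

    def test_no_polyA_reads_excluded(self):
        assert tailstats.length_distribution([mk_call(0), mk_call(0)]) == {}

    def test_length_40_is_in_cap_bin(self):
        hist = tailstats.length_distribution([mk_call(40)])
        assert hist[tailstats.GE_CAP_LABEL] == pytest.approx(100.0)

    def test_normalization(self):
        rng = np.random.default_rng(3)
        calls = [mk_call(int(rng.integers(1, 80))) for _ in range(500)]
        hist = tailstats.length_distribution(calls)
        assert sum(hist.values()) == pytest.approx(100.0, abs=1e-6)


class TestModClassFrequencies:
    def test_short_class_frequencies(self):
        calls = [mk_call(10, "TT"), mk_call(12, "TTT"), mk_call(15),
                 mk_call(20, "GG")]
        freqs = tailstats.mod_class_frequencies(calls)
        short = freqs[tailstats.LENCLASS_SHORT]
        assert short == {"U": pytest.approx(50.0), "none": pytest.approx(25.0),
                         "G": pytest.approx(25.0)}
        assert tailstats.LENCLASS_LONG not in freqs  # empty class absent

    def test_all_none(self):
        freqs = tailstats.mod_class_frequencies([mk_call(50), mk_call(60)])
        assert freqs[tailstats.LENCLASS_LONG] == {"none": pytest.approx(100.0)}

    def test_uridylation_frequency_recovery(self, reference, adapter):
        # short tails uridylated at 60%: the U-class frequency in the
        # <=40 nt class must recover within 3 binomial SD over n=5,000
        cfg = simulate.StageConfig(p_long=0.0, p_uridylated=0.6)
        rng = np.random.default_rng(31)
        truths = [simulate.gen_tail(cfg, rng, f"r{i}") for i in range(5_000)]
        calls = simulate.calls_from_truth(truths)
        freqs = tailstats.mod_class_frequencies(calls)
        u_pct = freqs[tailstats.LENCLASS_SHORT]["U"]
        sd = 100 * math.sqrt(0.6 * 0.4 / 5_000)
        assert abs(u_pct - 60.0) <= 3 * sd


class TestPositionalNonA:
    def test_all_A_tails(self):
        df = tailstats.positional_nonA([mk_call(4), mk_call(4)], "5to3")
        assert (df["pct_nonA"] == 0.0).all()

    def test_5to3_example(self):
        calls = [mk_call(4, tail_seq="TAAA"),
                 mk_call(4, tail_seq="AAAA")]
        df = tailstats.positional_nonA(calls, "5to3")
        assert df["pct_nonA"].tolist() == [50.0, 0.0, 0.0, 0.0]

    def test_3to5_mirror(self):
        calls = [mk_call(4, tail_seq="AAAT"),
                 mk_call(4, tail_seq="AAAA")]
        df = tailstats.positional_nonA(calls, "3to5")
        assert df["pct_nonA"].iloc[0] == pytest.approx(50.0)

    def test_masked_bases_leave_both_counts(self):
        calls = [mk_call(4, tail_seq="TAAA", quals=[5, 38, 38, 38]),
                 mk_call(4, tail_seq="AAAA")]
        df = tailstats.positional_nonA(calls, "5to3")
        assert df["n_reads"].tolist() == [1, 2, 2, 2]
        assert df["pct_nonA"].iloc[0] == 0.0  # the masked T never counts

    def test_both_directions_see_the_same_bases(self):
        rng = np.random.default_rng(4)
        calls = []
        for i in range(200):
            n = int(rng.integers(1, 30))
            tail = "".join(rng.choice(list("ACGT"), size=n))
            # force a leading A so it is a plausible called tail
            calls.append(mk_call(n, tail_seq="A" + tail[1:]))
        fwd = tailstats.positional_nonA(calls, "5to3")
        rev = tailstats.positional_nonA(calls, "3to5")
        fwd_nonA = (fwd["pct_nonA"].fillna(0) / 100 * fwd["n_reads"]).sum()
        rev_nonA = (rev["pct_nonA"].fillna(0) / 100 * rev["n_reads"]).sum()
        assert fwd_nonA == pytest.approx(rev_nonA)

    def test_linear_schedule_recovery(self):
        # non-canonical stage: the 5'->3' positional profile must track
        # the generator's interpolated schedule at well-supported positions
        cfg = simulate.StageConfig(p_long=0.5, p_uridylated=0.0,
                                   noncanonical=True,
                                   nonA_5prime=0.30, nonA_3prime=0.05)
        rng = np.random.default_rng(41)
        truths = [simulate.gen_tail(cfg, rng, f"r{i}") for i in range(5_000)]
        calls = simulate.calls_from_truth(truths)
        df = tailstats.positional_nonA(calls, "5to3")
        lens = np.array([t.polyA_len for t in truths])
        for _, row in df.iterrows():
            if row["n_reads"] < 200:
                continue
            i = int(row["position"])
            contributing = lens[lens >= i]
            expected = np.mean([
                cfg.nonA_5prime + (i - 1) / (L - 1) * (cfg.nonA_3prime - cfg.nonA_5prime)
                if L > 1 else cfg.nonA_5prime
                for L in contributing])
            sd = math.sqrt(expected * (1 - expected) / len(contributing))
            assert abs(row["pct_nonA"] / 100 - expected) <= 3 * sd + 1e-12


class TestCompositionNonA:
    def test_single_T(self):
        calls = [mk_call(4, tail_seq="AATA"),
                 mk_call(4, tail_seq="AAAA")]
        comp = tailstats.composition_nonA(calls)
        assert comp == {"U": pytest.approx(12.5), "G": 0.0, "C": 0.0}

    def test_equal_three_way(self):
        comp = tailstats.composition_nonA([mk_call(3, tail_seq="TGC")])
        assert comp["U"] == comp["G"] == comp["C"] == pytest.approx(100 / 3)

    def test_sums_to_total_nonA_fraction(self):
        rng = np.random.default_rng(5)
        calls = [mk_call(20, tail_seq="A" + "".join(rng.choice(list("ACGT"), size=19))) for _ in range(100)]
        comp = tailstats.composition_nonA(calls)
        non_a = sum(b != "A" for c in calls for b in c.tail_seq)
        total = sum(len(c.tail_seq) for c in calls)
        assert sum(comp.values()) == pytest.approx(100 * non_a / total)

    def test_empty_input_flagged_empty(self):
        assert tailstats.composition_nonA([]) == {}


class TestTerminalUridine:
    def test_all_A_clones(self):
        st = tailstats.terminal_uridine_stats(["AAAAA", "AAAAA"])
        assert (st.mean, st.se) == (0.0, 0.0)

    def test_mean_and_se_hand_arithmetic(self):
        st = tailstats.terminal_uridine_stats(["AATTT", "AAAAA"])
        assert st.mean == pytest.approx(1.5)
        assert st.se == pytest.approx(1.5)  # SD(3, 0)/sqrt(2)

    def test_single_clone_flags_degenerate_se(self):
        st = tailstats.terminal_uridine_stats(["TTTTT"])
        assert st.mean == 5.0 and st.se == 0.0
        assert any("n=1" in flag for flag in st.flags)

    def test_short_clone_used_in_full_and_flagged(self):
        st = tailstats.terminal_uridine_stats(["TTT", "AAAAA"], k=5)
        assert st.counts == (3, 0)
        assert any("shorter" in flag for flag in st.flags)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            tailstats.terminal_uridine_stats([])


class TestTukeyHSD:
    def test_identical_groups_not_significant(self):
        table = tailstats.tukey_hsd({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert not table["significant"].any()

    def test_separated_group_flagged_lower(self):
        table = tailstats.tukey_hsd({
            "low": [0, 0, 0, 0], "b": [3, 3, 3, 3], "c": [3, 3, 3, 3]})
        by_pair = {frozenset((r.group1, r.group2)): r for r in table.itertuples()}
        assert by_pair[frozenset(("low", "b"))].significant
        assert by_pair[frozenset(("low", "b"))].mean_diff < 0
        assert by_pair[frozenset(("low", "c"))].significant
        assert not by_pair[frozenset(("b", "c"))].significant

    def test_invariant_to_group_order(self):
        groups = {"a": [0, 1, 0, 1], "b": [4, 5, 4, 5], "c": [4, 4, 5, 5]}
        fwd = tailstats.tukey_hsd(groups)
        rev = tailstats.tukey_hsd(dict(reversed(groups.items())))
        fwd_map = {frozenset((r.group1, r.group2)): r.p_adj for r in fwd.itertuples()}
        rev_map = {frozenset((r.group1, r.group2)): r.p_adj for r in rev.itertuples()}
        assert fwd_map == pytest.approx(rev_map)

    def test_agrees_with_statsmodels(self):
        # independent oracle: statsmodels' pairwise Tukey HSD
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = {"a": [0.0, 1.0, 0.5, 1.5], "b": [3.0, 3.5, 4.0, 2.5],
                  "c": [3.2, 2.8, 3.9, 3.1]}
        ours = tailstats.tukey_hsd(groups)
        data = [v for vals in groups.values() for v in vals]
        labels = [k for k, vals in groups.items() for _ in vals]
        theirs = pairwise_tukeyhsd(np.array(data), np.array(labels))
        theirs_p = {}
        for row, p in zip(theirs._results_table.data[1:], theirs.pvalues):
            theirs_p[frozenset((row[0], row[1]))] = p
        for r in ours.itertuples():
            assert r.p_adj == pytest.approx(
                theirs_p[frozenset((r.group1, r.group2))], abs=1e-6)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            tailstats.tukey_hsd({"a": [1], "b": [1, 2]})


class TestProfileBundle:
    def test_normalization_invariants(self, reference, adapter):
        pairs, _ = simulate.simulate_batch(
            reference, simulate.STAGE_PRESETS["GV"], adapter, 300, seed=6,
            err=simulate.ErrorModel(sub_rate=0.003, q_mean=30, q_sd=8))
        from tailscope import extract
        from tailscope import tailcall as tc
        kept, _ = extract.extract_pairs(pairs, adapter, reference)
        calls = tc.call_batch((p.read3 for p in kept), adapter, reference)
        prof = tailstats.profile(calls)
        assert sum(prof.length_hist.values()) == pytest.approx(100.0, abs=1e-6)
        for freqs in prof.mod_class_freq_by_lenclass.values():
            assert sum(freqs.values()) == pytest.approx(100.0, abs=1e-6)
        assert ((prof.positional_nonA_5to3["pct_nonA"].dropna() >= 0).all()
                and (prof.positional_nonA_5to3["pct_nonA"].dropna() <= 100).all())
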