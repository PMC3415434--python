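import numpy as np
import pytest

from sinetrace.construct import default_construct, render_tail
from sinetrace.tails import segment_tail
from sinetrace.tprt import (
    NoTargetSiteError,
    SlippageParams,
    eligible_priming_positions,
    en_site_scores,
    integrate,
    make_atypical,
    replay_slips,
    reverse_transcribe_tail,
    revcomp,
    scan_consensus_sites,
    select_target_site,
)


class TestTargetSite:
    def test_single_perfect_site_always_chosen(self):
        seq = "G" * 50 + "TTAAAA" + "G" * 50  # bottom strand TTTT/AA
        sites = scan_consensus_sites(seq, min_score=6)
        assert sites == [(52, "+", 6)]  # cut after the TT
        for i in range(5):
            assert select_target_site(seq, rng=i, min_score=6) == ("chr", 52, "+", 6)

    def test_minus_orientation_site(self):
        seq = "G" * 50 + "TTTTAA" + "G" * 50
        assert scan_consensus_sites(seq, min_score=6) == [(54, "-", 6)]

    def test_two_sites_drawn_evenly(self):
        seq = "G" * 50 + "TTAAAA" + "G" * 200 + "TTAAAA" + "G" * 50
        rng = np.random.default_rng(0)
        first = sum(select_target_site(seq, rng)[1] == 52 for _ in range(2000))
        assert 0.45 < first / 2000 < 0.55  # 99% binomial CI around 0.5

    def test_no_site_raises(self):
        with pytest.raises(NoTargetSiteError):
            select_target_site("G" * 300, rng=0)

    def test_en_score_arrays_match_hand_counts(self):
        seq = "GGTTACAAGG"  # imperfect both ways
        plus, minus = en_site_scores(seq)
        # cut at 4: top window seq[2:8]="TTACAA" vs TTAAAA -> 5 matches
        assert plus[4] == 5


class TestReverseTranscription:
    def test_no_slippage_end_priming_identity(self, a70):
        rendered = render_tail(a70)
        tail, q, events, copied = reverse_transcribe_tail(
            a70, SlippageParams(p_dissoc0=0.0), rng=0, primed_position=82
        )
        assert tail == rendered
        assert q == 82 and not events
        assert copied == list(range(81, -1, -1))

    def test_no_slippage_internal_priming_prefix(self, a70):
        rendered = render_tail(a70)
        for q in (25, 40, 59):
            tail, _, _, _ = reverse_transcribe_tail(
                a70, SlippageParams(p_dissoc0=0.0), rng=0, primed_position=q
            )
            assert tail == rendered[:q]

    def test_priming_respects_min_offset_and_segments(self, a70):
        eligible = eligible_priming_positions(a70, 20)
        assert min(eligible) >= 20
        rendered = render_tail(a70)
        spans = a70.segment_spans()
        for q in eligible:
            assert any(s <= q - 1 < e for s, e in spans)
        # segment 1 (first 17 nt) is never a priming target at offset 20
        assert all(q > 17 for q in eligible)

    def test_slip_replay_conservation(self, a70):
        rng = np.random.default_rng(11)
        for _ in range(300):
            tail, q, events, _ = reverse_transcribe_tail(a70, SlippageParams(), rng)
            assert replay_slips(a70, q, events) == tail

    def test_mean_length_monotone_in_p_duplicate(self, a70):
        means = []
        for p_dup in (0.1, 0.5, 0.9):
            rng = np.random.default_rng(21)
            params = SlippageParams(p_duplicate=p_dup)
            means.append(
                np.mean(
                    [len(reverse_transcribe_tail(a70, params, rng)[0]) for _ in range(400)]
                )
            )
        assert means[0] < means[1] < means[2]

    def test_forced_duplication_across_disruption(self, a70):
        """With guaranteed crossing, a duplicated disruption string shows up
        in the realized tail."""
        params = SlippageParams(
            p_dissoc0=0.9, p_duplicate=1.0, p_cross_disruption=1.0, slip_span_mean=8.0
        )
        rng = np.random.default_rng(3)
        seen = 0
        for _ in range(100):
            tail, _, _, _ = reverse_transcribe_tail(a70, params, rng)
            p = segment_tail(tail, a70, max_disruption_mismatch=0)
            seen += bool(p.duplication_events)
        assert seen > 10

    def test_terminal_expansion_exceeds_internal(self, a70):
        """The depth-decaying dissociation model concentrates expansion at
        the 3' (terminal) end, as in the observed inserts."""
        rng = np.random.default_rng(5)
        term, internal = [], []
        for _ in range(1000):
            tail, _, _, _ = reverse_transcribe_tail(a70, SlippageParams(), rng)
            p = segment_tail(tail, a70)
            idx = p.priming_segment_index
            for i, n in p.segment_lengths.items():
                (term if i == idx else internal).append(n - a70.segments[i - 1])
        assert np.median(term) > np.median(internal)


class TestIntegration:
    def _window(self):
        rng = np.random.default_rng(8)
        left = "".join(rng.choice(list("ACGT"), 200))
        right = "".join(rng.choice(list("CGT"), 200))  # no A's: junction run = 4
        return left + "TTAAAA" + right, 202  # cut after TT

    def test_tsd_duplicated_at_both_junctions(self, construct):
        pre, cut = self._window()
        post, tsd_seq, dup_total, obs_tail, k = integrate(
            pre, cut, "+", construct.body, "A" * 40, tsd_len=14
        )
        assert k == 4 and dup_total == 18
        assert len(tsd_seq) == 14 and not tsd_seq.startswith("A")
        dup_region = pre[cut : cut + dup_total]
        ins = construct.body + "A" * 40
        assert post == pre[: cut + dup_total] + ins + pre[cut:]
        assert post.count(dup_region) >= 2
        assert obs_tail == "A" * 44

    def test_minus_strand_mirrors_plus(self, construct):
        pre, cut = self._window()
        pre_rc = revcomp(pre)
        cut_rc = len(pre) - cut
        plus, tsd_p, dup_p, obs_p, _ = integrate(pre, cut, "+", construct.body, "A" * 30, 10)
        minus, tsd_m, dup_m, obs_m, _ = integrate(
            pre_rc, cut_rc, "-", construct.body, "A" * 30, 10
        )
        assert revcomp(minus) == plus
        assert (tsd_m, dup_m, obs_m) == (tsd_p, dup_p, obs_p)

    def test_full_body_present_without_truncation(self, construct):
        pre, cut = self._window()
        post, *_ = integrate(pre, cut, "+", construct.body, "A" * 30, 12)
        assert construct.body in post


class TestAtypical:
    def test_chimeric_requires_donor(self, construct):
        with pytest.raises(ValueError):
            make_atypical("ACGT" * 100, 200, "chimeric", construct, "A" * 20,
                          np.random.default_rng(0))

    def test_chimeric_has_no_junction_duplication(self, construct, genome, cohort):
        _, truth = cohort
        from sinetrace.characterize import characterize_insert

        recs, _ = cohort
        chims = truth[truth["class"] == "chimeric_recombination"]["id"]
        assert len(chims) > 0
        by_id = {r.id: r for r in recs}
        for rid in chims:
            res = characterize_insert(by_id[rid], construct)
            assert res.tsd_len < 5

    def test_unknown_mode_rejected(self, construct):
        with pytest.raises(ValueError):
            make_atypical("ACGT" * 100, 200, "nonsense", construct, "A" * 20,
                          np.random.default_rng(0))
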