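import numpy as np
import pandas as pd
import pytest

from sinetrace.characterize import (
    InsertRecord,
    anchor_insert,
    build_target_pfm,
    characterize_cohort,
    characterize_insert,
    classify_genic_context,
    classify_insertion,
    detect_truncation,
    find_tsd,
    pfm_consensus,
    score_en_site,
    strand_bias_test,
)
from sinetrace.tprt import revcomp


def oracle_tsd(pre, post, body, max_len=50):
    """Brute-force junction-anchored longest-common-substring oracle,
    written independently of the anchoring code."""
    if body[-20:] not in post:
        pre, post = revcomp(pre), revcomp(post)
        assert body[-20:] in post
    # insert start: longest suffix of the body present in post
    for t in range(len(body)):
        if body[t:] in post:
            s = post.index(body[t:])
            break
    best = 0
    for L in range(min(max_len, s), 0, -1):
        left = post[s - L : s]
        if left != pre[s - L : s]:
            continue
        r = len(post) - (len(pre) - (s - L))
        if r < s or r + L > len(post):
            continue
        if post[r : r + L] == left and post[r + L :] == pre[s:]:
            best = L
            break
    while best > 0 and pre[s - best] == "A":
        best -= 1
    return best


class TestFindTSD:
    def test_recovers_drawn_tsd_and_matches_oracle(self, construct, cohort):
        records, truth = cohort
        typical = truth[truth["class"] == "TPRT_typical"].set_index("id")
        by_id = {r.id: r for r in records}
        drawn, recovered = [], []
        for rid, row in typical.iterrows():
            rec = by_id[rid]
            tsd_seq, junctions = find_tsd(rec.pre_locus, rec.post_locus, construct)
            assert len(tsd_seq) == row.tsd_len
            assert tsd_seq == row.tsd_seq
            assert len(tsd_seq) == oracle_tsd(rec.pre_locus, rec.post_locus, construct.body)
            drawn.append(row.tsd_len)
            recovered.append(len(tsd_seq))
        assert np.mean(recovered) == pytest.approx(np.mean(drawn))

    def test_chimeric_records_have_no_tsd(self, construct, cohort):
        records, truth = cohort
        by_id = {r.id: r for r in records}
        for rid in truth.loc[truth["class"] == "chimeric_recombination", "id"]:
            tsd_seq, _ = find_tsd(by_id[rid].pre_locus, by_id[rid].post_locus, construct)
            assert len(tsd_seq) < 5

    def test_unresolvable_without_body(self, construct):
        tsd, junctions = find_tsd("ACGT" * 100, "ACGT" * 100, construct)
        assert tsd == "" and junctions is None

    def test_tsd_first_convention_keeps_junction_as(self, construct, cohort):
        records, truth = cohort
        row = truth[truth["class"] == "TPRT_typical"].iloc[0]
        rec = {r.id: r for r in records}[row.id]
        a_tail = anchor_insert(rec.pre_locus, rec.post_locus, construct, a_assignment="tail")
        a_tsd = anchor_insert(rec.pre_locus, rec.post_locus, construct, a_assignment="tsd")
        assert a_tsd.tsd_len == row.dup_total_len
        assert a_tail.tsd_len == row.tsd_len <= a_tsd.tsd_len


class TestENSite:
    def test_perfect_site_scores_six(self):
        #              0123456789
        pre = "GGGGGGGGTTAAAAGGGGGGGG"  # cut at 10 (after the TT)
        score, orient, window, clipped = score_en_site(pre, 10)
        assert (score, orient, window, clipped) == (6, "+", "TTTTAA", False)

    def test_all_g_scores_zero(self):
        score, _, _, clipped = score_en_site("G" * 30, 15)
        assert score == 0 and not clipped

    def test_single_mismatch_scores_five(self):
        # bottom strand TTTCAA: top = revcomp = TTGAAA
        pre = "G" * 10 + "TTGAAA" + "G" * 10
        score, orient, window, _ = score_en_site(pre, 12)
        assert window == "TTTCAA" and score == 5 and orient == "+"

    def test_clipped_near_sequence_end(self):
        score, _, _, clipped = score_en_site("GGG", 1)
        assert clipped


class TestPFM:
    def test_identical_windows_one_hot(self):
        pfm = build_target_pfm(["TTTTAA"] * 10)
        assert pfm.loc["T", 0] == 1.0 and pfm.loc["A", 4] == 1.0
        assert np.allclose(pfm.sum(axis=0), 1.0, atol=1e-12)
        assert pfm_consensus(pfm) == "TTTTAA"

    def test_mixed_position_frequencies(self):
        pfm = build_target_pfm(["TTTTAA"] * 5 + ["CTTTAA"] * 5)
        assert pfm.loc["T", 0] == pytest.approx(0.5)
        assert pfm.loc["C", 0] == pytest.approx(0.5)

    def test_cohort_consensus_is_en_site(self, construct, cohort):
        records, _ = cohort
        _, summary = characterize_cohort(records, construct)
        assert summary["en_consensus"] == "TTTTAA"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_target_pfm([])


class TestTruncationAndClass:
    def test_truncation_recovered(self, construct, cohort):
        records, truth = cohort
        by_id = {r.id: r for r in records}
        typ = truth[truth["class"] == "TPRT_typical"]
        for row in typ.itertuples():
            assert detect_truncation(
                by_id[row.id].pre_locus, by_id[row.id].post_locus, construct
            ) == row.truncation_5p

    def test_truncated_fraction_near_rate(self, genome, construct):
        from sinetrace.synthetic import generate_cohort

        _, truth = generate_cohort(genome, construct, n=226, seed=9)
        typ = truth[truth["class"] == "TPRT_typical"]
        truncated = int((typ["truncation_5p"] > 0).sum())
        assert 1 <= truncated <= 20  # wide CI around binomial(226, 0.035) ~ 8

    def test_classification_rules(self):
        assert classify_insertion(14, 6, None)[0] == "TPRT_typical"
        assert classify_insertion(0, 6, None)[0] == "ambiguous"
        assert classify_insertion(0, 2, {"alu_identity": 0.95})[0] == "chimeric_recombination"
        assert classify_insertion(0, 2, None)[0] == "endonuclease_independent"
        label, reasons = classify_insertion(10, 1, None)
        assert label == "ambiguous" and reasons

    def test_cohort_class_mix_recovered(self, construct, cohort):
        records, truth = cohort
        df, summary = characterize_cohort(records, construct)
        got = df.set_index("id")["insertion_class"]
        want = truth.set_index("id")["class"]
        assert (got == want).all()


class TestBodyMismatches:
    def test_error_free_cohort_scans_clean(self, construct, cohort):
        records, _ = cohort
        df, summary = characterize_cohort(records, construct)
        assert summary["body_mismatch_total"] == 0
        assert summary["analyzed_bp_total"] > 0

    def test_planted_substitutions_are_counted(self, construct, cohort):
        """Substitutions planted mid-body (outside the masked A-rich middle)
        are recovered exactly, and the rate uses the analyzed bases."""
        records, truth = cohort
        mask = construct.a_rich_middle
        positions = [40, 100, 200]  # interior, well clear of the masked middle
        assert all(not mask[0] <= p < mask[1] for p in positions)
        n_checked = 0
        for rec, row in zip(records, truth.itertuples()):
            if row._2 != "TPRT_typical" or row.truncation_5p:
                continue
            post = rec.post_locus
            if row.strand == "-":
                post = revcomp(post)
            s = post.find(construct.body)
            assert s >= 0
            mutated = list(post)
            for p in positions:
                mutated[s + p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[s + p]]
            post_mut = "".join(mutated)
            if row.strand == "-":
                post_mut = revcomp(post_mut)
            res = characterize_insert(
                InsertRecord(rec.id, rec.pre_locus, post_mut), construct
            )
            assert res.body_mismatch_count == len(positions)
            assert sorted(res.body_mismatch_positions) == positions
            n_checked += 1
            if n_checked >= 40:
                break
        assert n_checked == 40

    def test_rate_is_count_over_analyzed_bp(self):
        # 6 substitutions over 52,039 analyzed bases is a ~0.01% rate
        assert 6 / 52039 == pytest.approx(1.15e-4, rel=0.01)


class TestGenicContext:
    @pytest.fixture()
    def genes(self):
        rows = [
            ("chr1", 1000, 9000, "-", "g1", "gene"),
            ("chr1", 1000, 1400, "-", "g1", "three_prime_UTR"),
            ("chr1", 1400, 4000, "-", "g1", "intron"),
            ("chr1", 4000, 4300, "-", "g1", "CDS"),
            ("chr1", 4300, 8700, "-", "g1", "intron"),
            ("chr1", 8700, 9000, "-", "g1", "five_prime_UTR"),
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "strand", "gene_id", "feature"]
        )

    def test_intron_antisense(self, genes):
        assert classify_genic_context("chr1", 2000, "+", genes) == ("intron", "antisense")

    def test_cds_sense(self, genes):
        assert classify_genic_context("chr1", 4100, "-", genes) == ("CDS", "sense")

    def test_utr(self, genes):
        assert classify_genic_context("chr1", 1100, "-", genes) == ("UTR", "sense")

    def test_intergenic(self, genes):
        assert classify_genic_context("chr1", 20_000, "+", genes) == ("intergenic", None)

    def test_strand_bias_matches_reported_p(self):
        """47 sense / 83 antisense genic inserts against a 0.5 null gives the
        two-sided binomial p of about 0.002."""
        assert strand_bias_test(47, 83) == pytest.approx(0.002, abs=5e-4)
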