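"""Splice-correction, ES-VE and ES-RF assessors against brute-force oracles."""

import numpy as np
import pytest

from aontriage.variant_annotation import AnnotatedVariant
from aontriage.variant_strategies import (
    assess_splice_correction,
    plan_es_rf,
    plan_es_ve,
    recurrent_subset,
)

from .conftest import make_transcript, random_transcript
from . import oracles


def _variant(klass, start, end, vid="v1", subs=1):
    return AnnotatedVariant(
        variant_id=vid, gene="GENE", chromosome="chr1", start=start, end=end,
        length_bp=end - start, raw_consequences=[klass], resolved_class=klass,
        submission_count=subs,
    )


class TestSpliceCorrection:
    def test_deep_intronic_1050_targetable(self):
        t = make_transcript([120, 120, 120], intron=4000)
        pos = t.exons[0][1] + 1049
        out = assess_splice_correction(_variant("intron_variant", pos, pos + 1), t)
        assert out == {"targetable": True, "distance": 1050}

    def test_distance_49_fails_boundary(self):
        t = make_transcript([120, 120], intron=500)
        pos = t.exons[0][1] + 48
        out = assess_splice_correction(_variant("intron_variant", pos, pos + 1), t)
        assert not out["targetable"] and out["distance"] == 49

    def test_distance_50_passes_boundary(self):
        t = make_transcript([120, 120], intron=500)
        pos = t.exons[0][1] + 49
        assert assess_splice_correction(
            _variant("intron_variant", pos, pos + 1), t)["targetable"]

    def test_wrong_class_not_targetable(self):
        t = make_transcript([120, 120], intron=500)
        pos = t.exons[0][1] + 100
        out = assess_splice_correction(
            _variant("splice_donor_variant", pos, pos + 1), t)
        assert not out["targetable"]


class TestRecurrentSubset:
    def test_three_or_more_submissions(self):
        vs = [_variant("intron_variant", 0, 1, vid=f"v{i}", subs=c)
              for i, c in enumerate([1, 2, 3, 7])]
        kept = recurrent_subset(vs)
        assert [v.submission_count for v in kept] == [3, 7]

    def test_all_singletons_empty(self):
        vs = [_variant("intron_variant", 0, 1, subs=1)]
        assert recurrent_subset(vs) == []


class TestEsVe:
    def test_accepted_internal_in_frame_exon(self):
        t = make_transcript([90, 120, 2790])  # CDS 3000, exon2 loss 0.04
        pos = t.exons[1][0] + 10
        plan = plan_es_ve(_variant("stop_gained", pos, pos + 1), t)
        assert plan.accepted
        assert plan.exons_to_skip == frozenset({2})
        assert plan.cds_loss == pytest.approx(0.04)

    def test_out_of_frame_exon_rejected(self):
        t = make_transcript([90, 121, 2789])
        pos = t.exons[1][0] + 10
        plan = plan_es_ve(_variant("stop_gained", pos, pos + 1), t)
        assert not plan.accepted and plan.rejection_reason == "wrong_exon_frame"

    def test_last_exon_rejected(self):
        t = make_transcript([90, 120, 2790])
        pos = t.exons[2][0] + 10
        plan = plan_es_ve(_variant("frameshift_variant", pos, pos + 1), t)
        assert plan.rejection_reason == "first_or_last_exon"

    def test_loss_over_ten_percent_rejected(self):
        t = make_transcript([90, 402, 2508])  # 402/3000 = 0.134
        pos = t.exons[1][0] + 10
        plan = plan_es_ve(_variant("stop_gained", pos, pos + 1), t)
        assert plan.rejection_reason == "loss_gt_10pct"

    def test_loss_boundary_one_nt(self):
        # 300/3000 = exactly 10% accepted; 300/2999 just above rejected
        t_ok = make_transcript([90, 300, 2610])
        pos = t_ok.exons[1][0] + 10
        assert plan_es_ve(_variant("stop_gained", pos, pos + 1), t_ok).accepted
        t_no = make_transcript([90, 300, 2609])
        pos = t_no.exons[1][0] + 10
        plan = plan_es_ve(_variant("stop_gained", pos, pos + 1), t_no)
        assert plan.rejection_reason == "loss_gt_10pct"

    def test_missense_rejected_by_class(self):
        t = make_transcript([90, 120, 2790])
        pos = t.exons[1][0] + 10
        plan = plan_es_ve(_variant("missense_variant", pos, pos + 1), t)
        assert plan.rejection_reason == "wrong_variant_class"


class TestEsRf:
    def test_deleted_100_neighbor_233_restores_frame(self):
        # the exon 50/51 pattern: 100 + 233 = 333, a multiple of three
        t = make_transcript([90, 600, 100, 233, 2310], intron=500)
        s = t.exons[2][0] - 50
        e = t.exons[2][1] + 50
        plans = plan_es_rf(_variant("sv", s, e), t)
        accepted = [p for p in plans if p.accepted]
        assert len(accepted) == 1
        assert accepted[0].exons_to_skip == frozenset({4})
        assert accepted[0].frame_sum_mod3 == 0
        assert accepted[0].deleted_exons == frozenset({3})

    def test_in_frame_deletion_ineligible(self):
        t = make_transcript([90, 600, 102, 233, 2310], intron=500)
        s = t.exons[2][0] - 50
        e = t.exons[2][1] + 50
        plans = plan_es_rf(_variant("sv", s, e), t)
        assert not any(p.accepted for p in plans)
        assert plans[0].rejection_reason == "wrong_exon_frame"

    def test_partial_exon_sv_rejected(self):
        t = make_transcript([90, 600, 100, 233, 2310], intron=500)
        s = t.exons[2][0] + 10
        e = t.exons[2][1] + 50
        plans = plan_es_rf(_variant("sv", s, e), t)
        assert plans[0].rejection_reason == "not_whole_exon"

    def test_canonical_donor_obligates_upstream_exon(self):
        # donor +2 of out-of-frame exon 3; neighbor 4 restores; loss under 10%
        t = make_transcript([90, 600, 100, 233, 2310], intron=500)
        pos = t.exons[2][1] + 1  # distance 2
        plans = plan_es_rf(_variant("splice_donor_variant", pos, pos + 1), t)
        accepted = [p for p in plans if p.accepted]
        assert len(accepted) == 1
        assert accepted[0].exons_to_skip == frozenset({3, 4})
        assert accepted[0].deleted_exons == frozenset()

    def test_acceptor_obligates_downstream_exon(self):
        t = make_transcript([90, 600, 100, 233, 2310], intron=500)
        pos = t.exons[3][0] - 1  # distance 1 before exon 4 (mod 2)
        plans = plan_es_rf(_variant("splice_acceptor_variant", pos, pos + 1), t)
        accepted = [p for p in plans if p.accepted]
        assert len(accepted) == 1
        assert accepted[0].exons_to_skip == frozenset({3, 4})

    def test_splice_variant_on_in_frame_exon_ineligible(self):
        t = make_transcript([90, 600, 102, 233, 2310], intron=500)
        pos = t.exons[2][1]  # donor distance 1 of in-frame exon 3
        plans = plan_es_rf(_variant("splice_donor_variant", pos, pos + 1), t)
        assert plans[0].rejection_reason == "wrong_exon_frame"

    def test_both_neighbors_can_restore(self):
        # deleted exon 3 (mod 1); neighbors 2 and 4 both mod 2
        t = make_transcript([90, 233, 100, 233, 3000], intron=500)
        s = t.exons[2][0] - 50
        e = t.exons[2][1] + 50
        plans = plan_es_rf(_variant("sv", s, e), t)
        accepted = {frozenset(p.exons_to_skip) for p in plans if p.accepted}
        assert accepted == {frozenset({2}), frozenset({4})}

    def test_first_exon_deletion_rejected(self):
        t = make_transcript([91, 233, 100, 2310], intron=500)
        s = t.exons[0][0] - 20
        e = t.exons[0][1] + 50
        plans = plan_es_rf(_variant("sv", s, e), t)
        assert plans[0].rejection_reason == "first_or_last_exon"


class TestOracleBattery:
    """Randomized agreement with brute-force enumeration from raw intervals."""

    @pytest.mark.parametrize("seed", range(8))
    def test_es_rf_whole_exon_deletions_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            t = random_transcript(rng)
            n = len(t.exons)
            width = int(rng.integers(1, min(3, n) + 1))
            lo = int(rng.integers(1, n - width + 2))
            block = list(range(lo, lo + width))
            s = t.exons[block[0] - 1][0] - 10
            e = t.exons[block[-1] - 1][1] + 10
            plans = plan_es_rf(_variant("sv", s, e), t)
            got = {
                next(iter(p.exons_to_skip))
                for p in plans if p.accepted
            }
            assert got == oracles.brute_force_es_rf(t, block)
            for p in plans:
                if p.accepted:
                    removed = p.deleted_exons | p.exons_to_skip
                    assert sum(
                        oracles.coding_length_raw(t, i) for i in removed
                    ) % 3 == 0
                    assert p.cds_loss <= 0.10
                    assert 1 not in removed and n not in removed
                else:
                    assert p.rejection_reason is not None

    @pytest.mark.parametrize("seed", range(8))
    def test_es_ve_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            t = random_transcript(rng)
            exon = int(rng.integers(1, len(t.exons) + 1))
            s, e = t.exons[exon - 1]
            pos = int(rng.integers(s, e))
            plan = plan_es_ve(_variant("stop_gained", pos, pos + 1), t)
            assert plan.accepted == oracles.brute_force_es_ve(t, exon)
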