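"""Variant-level AON strategy assessors.

Three assessors act on annotated variants against the MANE transcript:

* splice correction — deep-intronic ``intron_variant`` calls at least 50 nt
  from the nearest exon-intron boundary (plus a recurrence filter at >= 3
  ClinVar submissions);
* exon skipping for variant exclusion (ES-VE) — a truncating variant in a
  single internal in-frame exon whose removal costs at most 10% of the CDS;
* exon skipping for reading-frame restoration (ES-RF) — a whole-exon
  frameshifting deletion (or a canonical +/-2 splice variant bordering an
  out-of-frame exon, an obligate skip of that exon) combined with skipping
  an immediately neighboring exon so the total removed coding length is a
  multiple of three, again capped at 10% CDS loss and sparing the first and
  last exons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

from . import config
from .gene_model import (
    TranscriptModel,
    adjacent_exon,
    cds_loss_fraction,
    exon_facts,
    locate_variant,
)
from .variant_annotation import AnnotatedVariant

REJECTION_REASONS = (
    "first_or_last_exon",
    "loss_gt_10pct",
    "no_frame_restoring_neighbor",
    "wrong_exon_frame",
    "not_whole_exon",
    "wrong_variant_class",
)


@dataclass(frozen=True)
class SkipPlan:
    """A concrete exon-skipping proposal for one variant."""

    strategy: str  # ES_RF | ES_VE
    variant_id: str
    exons_to_skip: frozenset  # exon indices an AON would skip
    deleted_exons: frozenset  # exons already removed by the variant (ES-RF SV)
    frame_sum_mod3: int  # (sum of removed coding lengths) mod 3
    cds_loss: float
    accepted: bool
    rejection_reason: Optional[str] = None

    def __post_init__(self):
        if self.accepted:
            assert self.rejection_reason is None
            assert self.cds_loss <= config.MAX_CDS_LOSS + 1e-12
        elif self.rejection_reason is not None:
            assert self.rejection_reason in REJECTION_REASONS


def assess_splice_correction(
    v: AnnotatedVariant, t: TranscriptModel
) -> dict:
    """Deep-intronic rule: targetable iff the resolved class is
    ``intron_variant`` and the variant sits >= 50 nt from the nearest
    exon-intron boundary (the base adjacent to an exon has distance 1)."""
    if v.resolved_class != "intron_variant":
        return {"targetable": False, "distance": None}
    loc = locate_variant(t, v.interval)
    if loc.kind != "intronic":
        return {"targetable": False, "distance": None}
    return {
        "targetable": loc.distance >= config.DEEP_INTRONIC_MIN_DISTANCE,
        "distance": loc.distance,
    }


def recurrent_subset(variants: List[AnnotatedVariant]) -> List[AnnotatedVariant]:
    """Variants with >= 3 ClinVar submissions (recurrence proxy)."""
    return [
        v for v in variants
        if v.submission_count >= config.RECURRENT_MIN_SUBMISSIONS
    ]


def plan_es_ve(v: AnnotatedVariant, t: TranscriptModel) -> SkipPlan:
    """Exon skipping for variant exclusion.

    Accepted iff the variant is stop_gained/frameshift, lies wholly within
    one exon, that exon is in-frame (coding length a multiple of three) and
    internal, and skipping it loses at most 10% of the CDS.  Missense
    variants are rejected by class: a pathogenic missense typically marks
    an exon whose sequence cannot be spared.
    """

    def reject(reason: str, exon: Optional[int] = None, loss: float = 0.0) -> SkipPlan:
        return SkipPlan(
            strategy="ES_VE",
            variant_id=v.variant_id,
            exons_to_skip=frozenset() if exon is None else frozenset([exon]),
            deleted_exons=frozenset(),
            frame_sum_mod3=-1 if exon is None else t.exon_coding_length(exon) % 3,
            cds_loss=loss,
            accepted=False,
            rejection_reason=reason,
        )

    if v.resolved_class not in {"stop_gained", "frameshift_variant"}:
        return reject("wrong_variant_class")
    loc = locate_variant(t, v.interval)
    if loc.kind != "exonic":
        return reject("not_whole_exon")
    exon = loc.exon_index
    facts = exon_facts(t)[exon - 1]
    if facts.is_first or facts.is_last:
        return reject("first_or_last_exon", exon)
    if facts.frame_class != "in_frame":
        return reject("wrong_exon_frame", exon)
    loss = cds_loss_fraction(t, [exon])
    if loss > config.MAX_CDS_LOSS:
        return reject("loss_gt_10pct", exon, loss)
    return SkipPlan(
        strategy="ES_VE",
        variant_id=v.variant_id,
        exons_to_skip=frozenset([exon]),
        deleted_exons=frozenset(),
        frame_sum_mod3=facts.coding_length % 3,
        cds_loss=loss,
        accepted=True,
    )


def _es_rf_block(v: AnnotatedVariant, t: TranscriptModel):
    """The obligate removed block for ES-RF, or (None, reason).

    Case (a): an SV deleting one or more whole exons — the deleted block.
    Case (b): a canonical (+/-2 nt) splice donor/acceptor variant — an
    obligate skip of the adjacent out-of-frame exon (the donor borders its
    upstream exon, the acceptor its downstream exon, in transcript
    orientation).
    """
    facts = exon_facts(t)
    if v.resolved_class == "sv":
        loc = locate_variant(t, v.interval)
        if loc.kind != "whole_exon_deletion":
            return None, "not_whole_exon"
        block = sorted(loc.deleted_exons)
        return block, None
    if v.resolved_class in {"splice_donor_variant", "splice_acceptor_variant"}:
        loc = locate_variant(t, v.interval)
        if loc.kind != "intronic" or loc.distance > config.CANONICAL_SPLICE_WINDOW:
            return None, "wrong_variant_class"
        exon = adjacent_exon(t, v.interval)
        if facts[exon - 1].frame_class != "out_of_frame":
            return None, "wrong_exon_frame"
        return [exon], None
    return None, "wrong_variant_class"


def plan_es_rf(v: AnnotatedVariant, t: TranscriptModel) -> List[SkipPlan]:
    """Exon skipping for reading-frame restoration.

    For an eligible obligate block (see ``_es_rf_block``) each immediately
    neighboring exon N yields a candidate plan, accepted iff N's coding
    length is not a multiple of three, block + N together are a multiple of
    three, N is internal, and the combined CDS loss is at most 10%.  Both
    neighbors may yield accepted plans.  Non-accepted evaluations carry a
    rejection reason; there are no silent drops.
    """

    def plan(block, skip, mod3, loss, accepted, reason=None) -> SkipPlan:
        deleted = frozenset(block) if v.resolved_class == "sv" else frozenset()
        obligate = frozenset() if v.resolved_class == "sv" else frozenset(block)
        return SkipPlan(
            strategy="ES_RF",
            variant_id=v.variant_id,
            exons_to_skip=frozenset(skip) | obligate,
            deleted_exons=deleted,
            frame_sum_mod3=mod3,
            cds_loss=loss,
            accepted=accepted,
            rejection_reason=reason,
        )

    block, reason = _es_rf_block(v, t)
    if block is None:
        return [plan([], [], -1, 0.0, False, reason)]

    facts = exon_facts(t)
    block_sum = sum(facts[i - 1].coding_length for i in block)
    if block_sum % 3 == 0:
        # frame already intact (or block is noncoding): nothing to restore
        return [plan(block, [], 0, 0.0, False, "wrong_exon_frame")]
    if any(facts[i - 1].is_first or facts[i - 1].is_last for i in block):
        return [plan(block, [], block_sum % 3, 0.0, False, "first_or_last_exon")]

    plans: List[SkipPlan] = []
    for neighbor in (min(block) - 1, max(block) + 1):
        if not (1 <= neighbor <= t.n_exons):
            continue
        nf = facts[neighbor - 1]
        total_mod = (block_sum + nf.coding_length) % 3
        if nf.is_first or nf.is_last:
            plans.append(plan(block, [neighbor], total_mod, 0.0, False,
                              "first_or_last_exon"))
            continue
        if nf.coding_length % 3 == 0 or total_mod != 0:
            plans.append(plan(block, [neighbor], total_mod, 0.0, False,
                              "no_frame_restoring_neighbor"))
            continue
        loss = cds_loss_fraction(t, set(block) | {neighbor})
        if loss > config.MAX_CDS_LOSS:
            plans.append(plan(block, [neighbor], total_mod, loss, False,
                              "loss_gt_10pct"))
            continue
        plans.append(plan(block, [neighbor], total_mod, loss, True))
    if not plans:
        # block flanked only by out-of-range positions (cannot happen for
        # internal blocks, defensive)
        plans.append(plan(block, [], block_sum % 3, 0.0, False,
                          "no_frame_restoring_neighbor"))
    return plans
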