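"""Resolve each variant to a single consequence class.

The resolution rules, in order: (1) variants spanning 50 bp or more are
structural variants (SVs) regardless of any predicted consequence; (2) an
ambiguous consequence list that includes a splice-region call becomes
``splice_region_variant`` when the maximum SpliceAI delta exceeds 0.2;
(3) any other ambiguous list resolves to its most severe member under a
frozen severity ranking; (4) an unambiguous list resolves to its only
member.

External annotations (precomputed VEP/SpliceAI columns) always take
precedence.  Absent those, a simplified internal annotator derives the raw
consequences from the variant's position relative to the exon/CDS
structure (and the CDS sequence, when available).  The internal annotator
is only trusted for synthetic cohorts; real-data runs require precomputed
annotation columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd

from . import config
from .gene_model import (
    STOP_CODONS,
    TranscriptModel,
    locate_variant,
    predict_nmd_escape,
    ptc_context,
)

logger = logging.getLogger(__name__)

# Severity ranking (most severe first), frozen from the Ensembl consequence
# order so resolution is reproducible without Ensembl at runtime.
SEVERITY_ORDER = (
    "sv",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "missense_variant",
    "splice_region_variant",
    "synonymous_variant",
    "utr_variant",
    "intron_variant",
    "other",
)
_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

CONSEQUENCE_CLASSES = frozenset(SEVERITY_ORDER)

# consequences that sit in the splice region for the SpliceAI disambiguation
_SPLICE_REGION_SET = {"splice_region_variant"}


def severity_rank(consequence: str) -> int:
    """Rank in the frozen severity order (lower = more severe); unknown
    strings map to ``other`` with a warning."""
    if consequence not in _SEVERITY_RANK:
        logger.warning("unknown consequence %r mapped to 'other'", consequence)
        return _SEVERITY_RANK["other"]
    return _SEVERITY_RANK[consequence]


def resolve_consequence(
    raw: List[str],
    spliceai_max: Optional[float],
    length_bp: int,
) -> str:
    """Resolve a raw consequence list to a single class (see module rules)."""
    if not raw:
        raise ValueError("raw consequence list must be non-empty")
    raw = [c if c in CONSEQUENCE_CLASSES else "other" for c in raw]
    if length_bp >= config.SV_MIN_LENGTH:
        return "sv"
    if len(raw) > 1:
        if (
            any(c in _SPLICE_REGION_SET for c in raw)
            and spliceai_max is not None
            and spliceai_max > config.SPLICEAI_THRESHOLD
        ):
            return "splice_region_variant"
        return min(raw, key=severity_rank)
    return raw[0]


@dataclass
class AnnotatedVariant:
    """A ClinVar-style record with its resolved consequence class."""

    variant_id: str
    gene: str
    chromosome: str
    start: int  # 0-based half-open
    end: int
    length_bp: int
    raw_consequences: List[str]
    resolved_class: str
    spliceai_max: Optional[float] = None
    nmd_escape: Optional[bool] = None
    submission_count: int = 1
    ref: str = ""
    alt: str = ""
    omim_counts: Dict[str, int] = field(default_factory=dict)

    @property
    def interval(self) -> tuple:
        return (self.start, self.end)


class UnannotatableError(ValueError):
    """The variant cannot be assigned a consequence (e.g. no MANE model)."""


def _internal_raw_consequences(
    row: dict, t: TranscriptModel
) -> List[str]:
    """Positional consequence call for synthetic cohorts.

    Point/short variants: intronic positions within 2 nt of an exon edge are
    canonical splice-site hits, positions 3-8 nt away are splice-region,
    deeper ones intron variants.  Exonic substitutions are classified with
    the CDS sequence (stop vs missense vs synonymous); exonic indels whose
    net length is not a multiple of three are frameshifts.
    """
    interval = (row["start"], row["end"])
    loc = locate_variant(t, interval)
    ref, alt = row.get("ref", "") or "", row.get("alt", "") or ""
    if loc.kind == "outside":
        return ["other"]
    if loc.kind == "intronic":
        if loc.distance <= config.CANONICAL_SPLICE_WINDOW:
            return [f"splice_{loc.side}_variant"]
        if loc.distance <= 8:
            return ["splice_region_variant"]
        return ["intron_variant"]
    if loc.kind in {"whole_exon_deletion", "partial"}:
        # multi-base deletion under 50 bp crossing exon boundaries
        net = abs(len(ref) - len(alt)) or (row["end"] - row["start"])
        return ["frameshift_variant" if net % 3 else "other"]
    # exonic
    pos5 = t.five_prime_end(interval)
    cds_pos = t.genomic_to_cds(pos5)
    if cds_pos is None:
        return ["utr_variant"]
    if len(ref) != len(alt):
        net = abs(len(ref) - len(alt))
        return ["frameshift_variant" if net % 3 else "other"]
    if t.cds_sequence is None or len(ref) != 1:
        return ["missense_variant"]  # substitution of unknown effect
    seq = t.cds_sequence.upper()
    i = cds_pos - 1
    codon_start = i - i % 3
    codon = list(seq[codon_start:codon_start + 3])
    if len(codon) < 3:
        return ["other"]
    codon[i - codon_start] = alt.upper()
    new_codon = "".join(codon)
    old_codon = seq[codon_start:codon_start + 3]
    if new_codon in STOP_CODONS and old_codon not in STOP_CODONS:
        return ["stop_gained"]
    from Bio.Seq import Seq

    if str(Seq(new_codon).translate()) == str(Seq(old_codon).translate()):
        return ["synonymous_variant"]
    return ["missense_variant"]


def annotate_variant(
    row: dict,
    t: Optional[TranscriptModel],
    external: Optional[dict] = None,
) -> AnnotatedVariant:
    """Build an AnnotatedVariant from a ClinVar-dialect row.

    ``external`` may carry precomputed annotation columns (``consequences``
    list, ``spliceai_max``, ``nmd_escape``) which take precedence over the
    internal annotator.  A gene without a MANE model raises
    UnannotatableError (such variants are excluded with a reason).
    """
    if t is None:
        raise UnannotatableError(
            f"variant {row['variant_id']}: no MANE transcript for gene "
            f"{row.get('gene')}"
        )
    spliceai_max = None
    nmd_flag = None
    if external is not None:
        raw = list(external.get("consequences") or [])
        spliceai_max = external.get("spliceai_max")
        nmd_flag = external.get("nmd_escape")
        if not raw:
            raw = _internal_raw_consequences(row, t)
    else:
        raw = _internal_raw_consequences(row, t)

    length_bp = row["end"] - row["start"]
    resolved = resolve_consequence(raw, spliceai_max, length_bp)
    v = AnnotatedVariant(
        variant_id=str(row["variant_id"]),
        gene=row["gene"],
        chromosome=row.get("chromosome", t.chromosome),
        start=int(row["start"]),
        end=int(row["end"]),
        length_bp=length_bp,
        raw_consequences=raw,
        resolved_class=resolved,
        spliceai_max=spliceai_max,
        submission_count=int(row.get("submission_count", 1)),
        ref=row.get("ref", "") or "",
        alt=row.get("alt", "") or "",
        omim_counts=row.get("omim_counts", {}) or {},
    )
    if resolved in {"stop_gained", "frameshift_variant"}:
        if nmd_flag is not None:
            v.nmd_escape = bool(nmd_flag)
        else:
            try:
                ctx = ptc_context(
                    t, v.interval, resolved, ref=v.ref, alt=v.alt,
                    surrogate=t.cds_sequence is None,
                )
                v.nmd_escape = predict_nmd_escape(t, ctx)
            except ValueError:
                v.nmd_escape = None
    return v


def is_lof(v: AnnotatedVariant) -> bool:
    """Loss-of-function: stop-gained, frameshift or canonical splice
    donor/acceptor consequence, excluding predicted NMD-escapers."""
    if v.resolved_class not in {
        "stop_gained",
        "frameshift_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
    }:
        return False
    return v.nmd_escape is not True


def read_annotation_table(path) -> Dict[str, dict]:
    """Read an optional precomputed annotation TSV (variant_id,
    consequences comma-joined, DS_AG, DS_AL, DS_DG, DS_DL, nmd_escape).

    The SpliceAI maximum is the max of the four delta scores.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    out: Dict[str, dict] = {}
    ds_cols = [c for c in ("DS_AG", "DS_AL", "DS_DG", "DS_DL") if c in df.columns]
    for row in df.to_dict("records"):
        entry: dict = {}
        cons = row.get("consequences")
        if isinstance(cons, str) and cons:
            entry["consequences"] = cons.split(",")
        scores = [row[c] for c in ds_cols if pd.notna(row[c])]
        entry["spliceai_max"] = max(scores) if scores else None
        if "nmd_escape" in row and pd.notna(row["nmd_escape"]):
            entry["nmd_escape"] = bool(row["nmd_escape"])
        out[str(row["variant_id"])] = entry
    return out
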