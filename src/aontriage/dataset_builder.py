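"""Build the analysis dataset of disease-gene associations.

Associations from sysNDD-, DDG2P-, HPO- and panel-style sources are merged
on (gene, OMIM disease id, inheritance), scored for clinical validity by a
cumulative per-source point table, and retained when the score reaches 3
and an OMIM disease id is present.  (Likely) pathogenic ClinVar variants
are then attached to associations via each variant's most-reported OMIM
disease id(s).

Rows whose inheritance cannot be reconciled computationally are emitted to
a manual-curation queue rather than guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .formats_io import ClinVarTable, SourceTable

logger = logging.getLogger(__name__)

# cumulative clinical-validity points per (source, confidence category)
SCORE_TABLE = {
    ("sysndd", "limited"): 1,
    ("sysndd", "moderate"): 1,
    ("sysndd", "definitive"): 2,
    ("ddg2p", "limited"): 1,
    ("ddg2p", "moderate"): 1,
    ("ddg2p", "strong"): 1,
    ("ddg2p", "both rd and if"): 1,
    ("ddg2p", "definitive"): 2,
}
HPO_POINTS = 1  # every HPO entry
PANEL_POINTS = 2  # every diagnostic-panel entry


def score_evidence(evidence: List[Tuple[str, Optional[str]]]) -> int:
    """Sum clinical-validity points over (source, category) evidence.

    Unknown categories contribute 0 points and are logged; the order of
    evidence entries never matters.
    """
    total = 0
    for source, category in evidence:
        if source == "hpo":
            total += HPO_POINTS
        elif source == "panel":
            total += PANEL_POINTS
        else:
            key = (source, (category or "").strip().lower())
            pts = SCORE_TABLE.get(key)
            if pts is None:
                logger.warning(
                    "unknown confidence category %r for source %r scores 0",
                    category, source,
                )
                pts = 0
            total += pts
    return total


@dataclass
class DiseaseGeneAssociation:
    """One (gene, OMIM disease, inheritance) triple with its evidence."""

    gene: str
    omim_disease_id: Optional[str]
    inheritance: str
    evidence: List[Tuple[str, Optional[str]]] = field(default_factory=list)
    source_score: int = 0
    retained: bool = False
    exclusion_reason: Optional[str] = None  # low_score | no_omim

    @property
    def key(self) -> Tuple[str, Optional[str], str]:
        return (self.gene, self.omim_disease_id, self.inheritance)


def merge_associations(
    tables: List[SourceTable],
) -> Tuple[List[DiseaseGeneAssociation], List[dict]]:
    """Merge and deduplicate source tables into scored associations.

    Rows are keyed on (gene, OMIM id, inheritance); rows without an OMIM id
    merge on (gene, inheritance) and stay OMIM-less.  A row with unknown
    inheritance joins the unique existing inheritance for its (gene, OMIM)
    pair when exactly one exists; with several candidates it is sent to the
    manual-curation queue instead of guessed.  Returns (associations,
    curation_queue).
    """
    raw_rows = []
    for table in tables:
        for row in table.rows.itertuples(index=False):
            gene = row.gene if isinstance(row.gene, str) else row.hgnc_id
            raw_rows.append(
                {
                    "gene": gene,
                    "omim": row.omim_disease_id
                    if isinstance(row.omim_disease_id, str)
                    else None,
                    "inheritance": row.inheritance,
                    "source": table.source_name,
                    "category": row.category
                    if isinstance(row.category, str)
                    else None,
                }
            )

    # inheritance vocabularies observed per (gene, omim) among resolved rows
    known_inh: Dict[Tuple[str, Optional[str]], set] = {}
    for r in raw_rows:
        if r["inheritance"] != "unknown":
            known_inh.setdefault((r["gene"], r["omim"]), set()).add(r["inheritance"])

    merged: Dict[Tuple[str, Optional[str], str], DiseaseGeneAssociation] = {}
    curation_queue: List[dict] = []
    for r in raw_rows:
        inh = r["inheritance"]
        if inh == "unknown":
            candidates = known_inh.get((r["gene"], r["omim"]), set())
            if len(candidates) == 1:
                inh = next(iter(candidates))
            elif len(candidates) > 1:
                curation_queue.append(
                    {**r, "reason": "ambiguous_inheritance",
                     "candidates": sorted(candidates)}
                )
                continue
        key = (r["gene"], r["omim"], inh)
        assoc = merged.get(key)
        if assoc is None:
            assoc = DiseaseGeneAssociation(
                gene=r["gene"], omim_disease_id=r["omim"], inheritance=inh
            )
            merged[key] = assoc
        assoc.evidence.append((r["source"], r["category"]))

    associations = list(merged.values())
    for a in associations:
        a.source_score = score_evidence(a.evidence)
    return associations, curation_queue


def apply_retention(
    associations: List[DiseaseGeneAssociation],
    min_score: int = 3,
) -> Tuple[List[DiseaseGeneAssociation], List[DiseaseGeneAssociation]]:
    """Partition associations into (retained, excluded).

    Retained iff source score >= ``min_score`` AND an OMIM disease id is
    present; exclusions carry a reason (``no_omim`` takes precedence, since
    without an OMIM id no variant or phenotype annotation is possible).
    """
    retained, excluded = [], []
    for a in associations:
        if a.omim_disease_id is None:
            a.retained, a.exclusion_reason = False, "no_omim"
            excluded.append(a)
        elif a.source_score < min_score:
            a.retained, a.exclusion_reason = False, "low_score"
            excluded.append(a)
        else:
            a.retained, a.exclusion_reason = True, None
            retained.append(a)
    return retained, excluded


def most_reported_omim(omim_counts: Dict[str, int]) -> set:
    """The OMIM id(s) with the maximal report count (ties keep all)."""
    if not omim_counts:
        return set()
    top = max(omim_counts.values())
    return {k for k, v in omim_counts.items() if v == top}


def attach_variants(
    associations: List[DiseaseGeneAssociation],
    clinvar: ClinVarTable,
) -> Tuple[Dict[Tuple[str, Optional[str], str], List[dict]], List[str]]:
    """Attach ClinVar variants to retained associations.

    A variant attaches to an association when the association's OMIM id is
    among the variant's most-reported OMIM ids and the gene matches.  Ties
    attach to all tied associations (logged).  Returns (links keyed by
    association key, list of unattached variant ids).
    """
    by_gene_omim: Dict[Tuple[str, str], List[DiseaseGeneAssociation]] = {}
    for a in associations:
        if a.retained and a.omim_disease_id is not None:
            by_gene_omim.setdefault((a.gene, a.omim_disease_id), []).append(a)

    links: Dict[Tuple[str, Optional[str], str], List[dict]] = {
        a.key: [] for a in associations if a.retained
    }
    unattached: List[str] = []
    for row in clinvar.rows.to_dict("records"):
        top_ids = most_reported_omim(row["omim_counts"])
        if len(top_ids) > 1:
            logger.info(
                "variant %s: tie among most-reported OMIM ids %s; "
                "attached to all", row["variant_id"], sorted(top_ids),
            )
        hit = False
        for omim in top_ids:
            for a in by_gene_omim.get((row["gene"], omim), []):
                links[a.key].append(row)
                hit = True
        if not hit:
            unattached.append(row["variant_id"])
    return links, unattached
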