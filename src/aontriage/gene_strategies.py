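"""Gene-level assessors for wildtype-allele upregulation strategies.

Upregulation of the intact allele (TANGO, uAUG interference, ARE blocking,
lncRNA degradation) only helps when disease arises from haploinsufficiency,
so every such strategy is gated on: autosomal dominant inheritance, pLI
strictly above 0.9, and strictly more than 20% of the gene's causative
variants being loss-of-function.  TANGO/uAUG/ARE amenability is then simple
membership in the published catalogs; lncRNA amenability requires a lncRNA
in the gene's TAD that is significantly co-expressed with it across brain
tissues (Pearson correlation, Benjamini-Hochberg corrected across all
pairs evaluated in the run).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import config
from .dataset_builder import DiseaseGeneAssociation
from .formats_io import ExpressionMatrix, TADSet
from .variant_annotation import AnnotatedVariant, is_lof

logger = logging.getLogger(__name__)


def lof_ratio(variants: List[AnnotatedVariant]) -> float:
    """Fraction of attached pathogenic variants that are loss-of-function.

    An empty list has no defined ratio; callers treat it as failing the
    >20% gate (returned as 0.0 with a log message).
    """
    if not variants:
        logger.info("lof_ratio undefined on empty variant list; gate fails")
        return 0.0
    return sum(is_lof(v) for v in variants) / len(variants)


@dataclass
class LncRNAPartner:
    lncrna_id: str
    r: float
    p_raw: float
    p_adjusted: float


@dataclass
class GeneDossier:
    """Per-gene evidence consumed by the upregulation strategies."""

    gene: str
    pli: Optional[float]
    lof_ratio: float
    in_tango_list: bool = False
    in_uaug_list: bool = False
    in_are_list: bool = False
    lncrna_partners: List[LncRNAPartner] = field(default_factory=list)
    missing_expression: bool = False


@dataclass
class UpregulationGate:
    """Haploinsufficiency eligibility of one association."""

    association: DiseaseGeneAssociation
    eligible: bool
    reasons: Set[str] = field(default_factory=set)
    missing_pli: bool = False


def upregulation_gate(
    a: DiseaseGeneAssociation, d: GeneDossier
) -> UpregulationGate:
    """Eligible iff AD inheritance, pLI > 0.9 and LoF ratio > 0.2.

    All three criteria are evaluated (not short-circuited) so the reasons
    set names every failed gate.  A missing pLI fails the pLI gate and is
    flagged as missing data.
    """
    reasons: Set[str] = set()
    if a.inheritance != "AD":
        reasons.add("not_AD")
    missing_pli = d.pli is None
    if missing_pli or d.pli <= config.PLI_THRESHOLD:
        reasons.add("pLI_le_0.9")
    if d.lof_ratio <= config.LOF_RATIO_THRESHOLD:
        reasons.add("lof_ratio_le_20pct")
    return UpregulationGate(
        association=a,
        eligible=not reasons,
        reasons=reasons,
        missing_pli=missing_pli,
    )


def list_based_checks(
    gene: str, lists: Dict[str, Set[str]]
) -> Tuple[bool, bool, bool]:
    """(tango, uaug, are) catalog membership for one gene."""
    return (
        gene in lists.get("tango", set()),
        gene in lists.get("uaug", set()),
        gene in lists.get("are", set()),
    )


def brain_tissues(expr: ExpressionMatrix,
                  prefix: str = config.BRAIN_TISSUE_PREFIX) -> List[str]:
    return [t for t in expr.tissues if t.startswith(prefix)]


def lncrna_partners(
    genes: Iterable[str],
    gene_intervals: Dict[str, Tuple[str, int, int]],
    lncrna_catalog: pd.DataFrame,
    tads: TADSet,
    expr: ExpressionMatrix,
    alpha: float = config.COEXPRESSION_ALPHA,
    brain_prefix: str = config.BRAIN_TISSUE_PREFIX,
) -> Tuple[Dict[str, List[LncRNAPartner]], pd.DataFrame]:
    """TAD-constrained lncRNA co-expression search for many genes at once.

    For each gene, candidate lncRNAs share at least one TAD with the gene's
    genomic span and have TPM > 0 in at least one brain tissue.  Pearson
    correlations are computed across the brain tissues, p-values are
    BH-adjusted across *all* pairs evaluated in the run (the family size is
    recorded in the returned pair table), and partners are the candidates
    with adjusted p <= alpha.  Zero-variance expression vectors are skipped
    with a flag (r undefined); genes absent from the matrix yield an empty
    partner list.

    Returns (partners per gene, per-pair table).
    """
    tissues = [t for t in expr.tissues if t.startswith(brain_prefix)]
    if len(tissues) < 3:
        raise ValueError(
            f"need at least 3 brain tissues for correlation; found {len(tissues)}"
        )
    mat = expr.tpm[tissues]

    pairs: List[dict] = []
    missing: Set[str] = set()
    for gene in genes:
        if gene not in gene_intervals:
            continue
        if gene not in mat.index:
            missing.add(gene)
            continue
        gvec = mat.loc[gene].to_numpy(dtype=float)
        span = gene_intervals[gene]
        for row in lncrna_catalog.itertuples(index=False):
            lnc_span = (str(row.chrom), int(row.start), int(row.end))
            if not tads.share_tad(span, lnc_span):
                continue
            if row.lncrna_id not in mat.index:
                continue
            lvec = mat.loc[row.lncrna_id].to_numpy(dtype=float)
            if not (lvec > 0).any():
                continue  # expression gate: >=1 tissue with TPM > 0
            if np.ptp(gvec) == 0 or np.ptp(lvec) == 0:
                pairs.append(
                    {"gene": gene, "lncrna_id": row.lncrna_id, "r": np.nan,
                     "p_raw": np.nan, "skipped": "zero_variance"}
                )
                continue
            r, p = stats.pearsonr(gvec, lvec)
            pairs.append(
                {"gene": gene, "lncrna_id": row.lncrna_id, "r": float(r),
                 "p_raw": float(p), "skipped": None}
            )

    table = pd.DataFrame(
        pairs, columns=["gene", "lncrna_id", "r", "p_raw", "skipped"]
    )
    tested = table["skipped"].isna() & table["p_raw"].notna()
    table["p_adjusted"] = np.nan
    if tested.any():
        table.loc[tested, "p_adjusted"] = multipletests(
            table.loc[tested, "p_raw"].to_numpy(), method="fdr_bh"
        )[1]
    table.attrs["bh_family_size"] = int(tested.sum())

    partners: Dict[str, List[LncRNAPartner]] = {g: [] for g in genes}
    for row in table[tested].itertuples(index=False):
        if row.p_adjusted <= alpha:
            partners.setdefault(row.gene, []).append(
                LncRNAPartner(
                    lncrna_id=row.lncrna_id,
                    r=row.r,
                    p_raw=row.p_raw,
                    p_adjusted=row.p_adjusted,
                )
            )
    for gene in missing:
        logger.info("gene %s absent from expression matrix; no partners", gene)
    return partners, table


def build_dossiers(
    associations: List[DiseaseGeneAssociation],
    variants_by_gene: Dict[str, List[AnnotatedVariant]],
    pli: Dict[str, float],
    lists: Dict[str, Set[str]],
    partners: Dict[str, List[LncRNAPartner]],
    missing_expression: Set[str] = frozenset(),
) -> Dict[str, GeneDossier]:
    """Assemble one GeneDossier per gene appearing in the associations."""
    dossiers: Dict[str, GeneDossier] = {}
    for a in associations:
        if a.gene in dossiers:
            continue
        gene_variants = variants_by_gene.get(a.gene, [])
        tango, uaug, are = list_based_checks(a.gene, lists)
        dossiers[a.gene] = GeneDossier(
            gene=a.gene,
            pli=pli.get(a.gene),
            lof_ratio=lof_ratio(gene_variants),
            in_tango_list=tango,
            in_uaug_list=uaug,
            in_are_list=are,
            lncrna_partners=partners.get(a.gene, []),
            missing_expression=a.gene in missing_expression,
        )
    return dossiers
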