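"""End-to-end driver: from an input bundle to strategy profiles.

Wires every stage together over a bundle directory laid out with the
standard file names (see ``docs/formats.md``): dataset building, variant
annotation, phenotype calls, variant- and gene-level strategy assessment,
profile integration and the per-strategy AON economics.  Identical inputs
produce byte-identical output tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Set, Tuple

import pandas as pd

from . import config, formats_io
from .dataset_builder import (
    DiseaseGeneAssociation,
    apply_retention,
    attach_variants,
    merge_associations,
)
from .gene_strategies import (
    GeneDossier,
    UpregulationGate,
    build_dossiers,
    lncrna_partners,
    upregulation_gate,
)
from .integration import (
    StrategyProfile,
    VariantAssessment,
    aon_economics,
    profile_ndd,
    profile_submissions,
    profiles_frame,
    upset_table,
)
from .phenotype import PhenotypeCall, call_phenotypes
from .variant_annotation import (
    UnannotatableError,
    annotate_variant,
    read_annotation_table,
)
from .variant_strategies import assess_splice_correction, plan_es_rf, plan_es_ve

logger = logging.getLogger(__name__)

BUNDLE_FILES = {
    "transcripts": "transcripts.gtf",
    "cds_fasta": "cds.fa",
    "sysndd": "sysndd.tsv",
    "ddg2p": "ddg2p.tsv",
    "hpo": "hpo_source.tsv",
    "panel": "panel.tsv",
    "clinvar": "clinvar.tsv",
    "annotations": "annotations.tsv",
    "ontology": "hp.obo",
    "disease_phenotypes": "phenotype_to_genes.tsv",
    "pli": "pli.tsv",
    "tads": "tads.bed",
    "expression": "expression.gct",
    "lncrna": "lncrna.tsv",
    "gene_lists": ("tango.tsv", "uaug.tsv", "are.tsv"),
}


@dataclass
class PipelineResult:
    associations: List[DiseaseGeneAssociation]
    retained: List[DiseaseGeneAssociation]
    excluded: List[DiseaseGeneAssociation]
    curation_queue: List[dict]
    unattached_variants: List[str]
    unannotatable_variants: List[str]
    assessments: Dict[str, VariantAssessment]
    links: Dict[Tuple, List[VariantAssessment]]
    phenotypes: Dict[Tuple, PhenotypeCall]
    gates: Dict[Tuple, UpregulationGate]
    dossiers: Dict[str, GeneDossier]
    ndd_profiles: List[StrategyProfile]
    variant_profiles: List[StrategyProfile]
    pair_table: pd.DataFrame
    run_summary: dict

    def ndd_frame(self) -> pd.DataFrame:
        return profiles_frame(self.ndd_profiles)

    def variant_frame(self) -> pd.DataFrame:
        return profiles_frame(self.variant_profiles)

    def economics(self) -> pd.DataFrame:
        rows = []
        for strategy in config.STRATEGIES:
            rows.append(aon_economics(
                self.variant_profiles, self.assessments, strategy))
            if strategy == "splice_correction":
                rows.append(aon_economics(
                    self.variant_profiles, self.assessments, strategy,
                    recurrent_only=True))
        return pd.DataFrame(rows)


def run_pipeline(bundle_dir, out_dir=None, alpha: float = config.COEXPRESSION_ALPHA) -> PipelineResult:
    """Run the full triage over a bundle directory.

    When ``out_dir`` is given, writes retained/excluded association tables,
    the curation queue, variant links, NDD and variant profiles, UpSet
    combination tables, the economics table and a run summary JSON.
    """
    bundle = Path(bundle_dir)

    def p(key) -> Path:
        return bundle / BUNDLE_FILES[key]

    # --- dataset ------------------------------------------------------------
    tables = [
        formats_io.read_association_source(p(k), k)
        for k in ("sysndd", "ddg2p", "hpo", "panel")
        if p(k).exists()
    ]
    associations, curation_queue = merge_associations(tables)
    retained, excluded = apply_retention(associations)
    clinvar = formats_io.read_clinvar_summary(p("clinvar"))
    raw_links, unattached = attach_variants(retained, clinvar)

    # --- annotation ---------------------------------------------------------
    transcripts = formats_io.read_transcripts(
        p("transcripts"),
        cds_fasta=p("cds_fasta") if p("cds_fasta").exists() else None,
    )
    external = (
        read_annotation_table(p("annotations"))
        if p("annotations").exists() else {}
    )
    assessments: Dict[str, VariantAssessment] = {}
    unannotatable: List[str] = []
    links: Dict[Tuple, List[VariantAssessment]] = {}
    for key, rows in raw_links.items():
        gene = key[0]
        t = transcripts.get(gene)
        key_assessments = []
        for row in rows:
            vid = str(row["variant_id"])
            va = assessments.get(vid)
            if va is None:
                try:
                    v = annotate_variant(row, t, external.get(vid))
                except UnannotatableError:
                    unannotatable.append(vid)
                    continue
                va = VariantAssessment(variant=v)
                sc = assess_splice_correction(v, t)
                va.splice_targetable = sc["targetable"]
                va.splice_distance = sc["distance"]
                va.es_ve_plan = plan_es_ve(v, t)
                va.es_rf_plans = plan_es_rf(v, t)
                assessments[vid] = va
            key_assessments.append(va)
        links[key] = key_assessments

    # --- phenotype ----------------------------------------------------------
    ontology = formats_io.read_ontology(p("ontology"))
    disease_terms = formats_io.read_disease_phenotypes(p("disease_phenotypes"))
    calls_by_omim = call_phenotypes(
        disease_terms, ontology,
        {a.omim_disease_id for a in retained},
    )
    phenotypes = {a.key: calls_by_omim[a.omim_disease_id] for a in retained}

    # --- gene level ---------------------------------------------------------
    pli = formats_io.read_pli(p("pli"))
    lists = formats_io.read_gene_lists(bundle / f for f in BUNDLE_FILES["gene_lists"])
    tads = formats_io.read_tads(p("tads"))
    expr = formats_io.read_expression(p("expression"))
    catalog = formats_io.read_lncrna_catalog(p("lncrna"))
    gene_intervals = {
        g: (t.chromosome, *t.span) for g, t in transcripts.items()
    }
    retained_genes = sorted({a.gene for a in retained})
    partners, pair_table = lncrna_partners(
        retained_genes, gene_intervals, catalog, tads, expr, alpha=alpha)

    variants_by_gene: Dict[str, List] = {}
    for key, vas in links.items():
        seen: Set[str] = {
            v.variant.variant_id for v in variants_by_gene.get(key[0], [])
        }
        for va in vas:
            if va.variant.variant_id not in seen:
                variants_by_gene.setdefault(key[0], []).append(va.variant)
                seen.add(va.variant.variant_id)
    dossiers = build_dossiers(
        retained, variants_by_gene, pli, lists, partners,
        missing_expression={g for g in retained_genes if g not in expr.tpm.index},
    )
    gates = {
        a.key: upregulation_gate(a, dossiers[a.gene]) for a in retained
    }

    # --- integration --------------------------------------------------------
    ndd_profiles = [
        profile_ndd(a, links[a.key], phenotypes[a.key], gates[a.key],
                    dossiers[a.gene])
        for a in retained
    ]
    variant_profiles = profile_submissions(links, phenotypes, gates, dossiers)

    run_summary = {
        "n_associations_merged": len(associations),
        "n_retained": len(retained),
        "n_excluded": len(excluded),
        "n_curation_queue": len(curation_queue),
        "n_variants_input": int(len(clinvar.rows)),
        "clinvar_dropped": clinvar.dropped,
        "n_variants_attached": len(assessments),
        "n_variants_unattached": len(unattached),
        "n_variants_unannotatable": len(unannotatable),
        "n_submissions_total": int(
            sum(p_.submission_count for p_ in variant_profiles)),
        "n_ndds_targetable": int(
            sum(p_.any_strategy for p_ in ndd_profiles)),
        "n_submissions_targetable": int(sum(
            p_.submission_count for p_ in variant_profiles if p_.any_strategy)),
        "bh_family_size": int(pair_table.attrs.get("bh_family_size", 0)),
        "alpha": alpha,
    }

    result = PipelineResult(
        associations=associations, retained=retained, excluded=excluded,
        curation_queue=curation_queue, unattached_variants=unattached,
        unannotatable_variants=unannotatable, assessments=assessments,
        links=links, phenotypes=phenotypes, gates=gates, dossiers=dossiers,
        ndd_profiles=ndd_profiles, variant_profiles=variant_profiles,
        pair_table=pair_table, run_summary=run_summary,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def _assoc_frame(assocs: List[DiseaseGeneAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": a.gene,
                "omim_disease_id": a.omim_disease_id or "",
                "inheritance": a.inheritance,
                "source_score": a.source_score,
                "evidence": ";".join(
                    f"{s}:{c or ''}" for s, c in sorted(a.evidence)),
                "retained": a.retained,
                "exclusion_reason": a.exclusion_reason or "",
            }
            for a in assocs
        ]
    )


def write_outputs(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _assoc_frame(result.retained).to_csv(out / "retained.tsv", sep="\t", index=False)
    _assoc_frame(result.excluded).to_csv(out / "excluded.tsv", sep="\t", index=False)
    pd.DataFrame(result.curation_queue).to_csv(
        out / "curation_queue.tsv", sep="\t", index=False)
    link_rows = [
        {"gene": key[0], "omim_disease_id": key[1] or "",
         "inheritance": key[2], "variant_id": va.variant.variant_id}
        for key, vas in sorted(result.links.items(),
                               key=lambda kv: (kv[0][0], str(kv[0][1])))
        for va in vas
    ]
    pd.DataFrame(link_rows, columns=["gene", "omim_disease_id", "inheritance",
                                     "variant_id"]).to_csv(
        out / "variant_links.tsv", sep="\t", index=False)
    formats_io.write_profile_table(result.ndd_frame(), out / "ndd_profiles.tsv")
    formats_io.write_profile_table(result.variant_frame(),
                                   out / "variant_profiles.tsv")
    upset_table(result.ndd_profiles, mode="intersect").to_csv(
        out / "upset_disease.tsv", sep="\t", index=False)
    upset_table(result.variant_profiles, mode="intersect", weighted=True).to_csv(
        out / "upset_individuals.tsv", sep="\t", index=False)
    result.economics().to_csv(out / "economics.tsv", sep="\t", index=False)
    (out / "run_summary.json").write_text(
        json.dumps(result.run_summary, indent=1, sort_keys=True))
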