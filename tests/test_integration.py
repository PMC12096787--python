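"""Profile roll-up, UpSet tables and AON economics."""

from aontriage import config
from aontriage.dataset_builder import DiseaseGeneAssociation
from aontriage.gene_strategies import GeneDossier, LncRNAPartner, UpregulationGate
from aontriage.integration import (
    StrategyProfile,
    VariantAssessment,
    aon_economics,
    profile_ndd,
    profile_submissions,
    upset_table,
)
from aontriage.phenotype import PhenotypeCall
from aontriage.variant_annotation import AnnotatedVariant
from aontriage.variant_strategies import SkipPlan


def _variant(vid, klass="stop_gained", subs=1, escape=False):
    return AnnotatedVariant(
        variant_id=vid, gene="G", chromosome="chr1", start=0, end=1,
        length_bp=1, raw_consequences=[klass], resolved_class=klass,
        nmd_escape=escape if klass in {"stop_gained", "frameshift_variant"} else None,
        submission_count=subs,
    )


def _phenotype(targetable=True):
    return PhenotypeCall(
        omim_disease_id="OMIM:1",
        matched_terms=frozenset({"HP:0001250"}) if targetable else frozenset(),
        neonatal_lethal=False, targetable=targetable,
    )


def _assoc(inh="AD"):
    return DiseaseGeneAssociation(
        gene="G", omim_disease_id="OMIM:1", inheritance=inh,
        source_score=3, retained=True,
    )


def _gate(eligible=True):
    return UpregulationGate(association=_assoc(), eligible=eligible,
                            reasons=set() if eligible else {"not_AD"})


def _dossier(tango=False, lnc=False):
    partners = [LncRNAPartner("L1", 0.95, 1e-8, 1e-6)] if lnc else []
    return GeneDossier(gene="G", pli=0.95, lof_ratio=0.4,
                       in_tango_list=tango, lncrna_partners=partners)


def _es_ve_plan(vid, accepted=True, exon=5):
    return SkipPlan(strategy="ES_VE", variant_id=vid,
                    exons_to_skip=frozenset({exon}), deleted_exons=frozenset(),
                    frame_sum_mod3=0, cds_loss=0.04, accepted=accepted,
                    rejection_reason=None if accepted else "wrong_exon_frame")


class TestProfileNdd:
    def test_phenotype_gates_all_seven_flags(self):
        va = VariantAssessment(variant=_variant("v1"), splice_targetable=True,
                               es_ve_plan=_es_ve_plan("v1"))
        profile = profile_ndd(_assoc(), [va], _phenotype(False), _gate(True),
                              _dossier(tango=True, lnc=True))
        assert not any(profile.flags.values())

    def test_single_deep_intronic_flag(self):
        va = VariantAssessment(
            variant=_variant("v1", klass="intron_variant"),
            splice_targetable=True, splice_distance=1050)
        profile = profile_ndd(_assoc(), [va], _phenotype(), _gate(False),
                              _dossier())
        assert profile.flags["splice_correction"]
        assert sum(profile.flags.values()) == 1

    def test_tango_conjunction(self):
        va = VariantAssessment(variant=_variant("v1"))  # LoF stop
        profile = profile_ndd(_assoc(), [va], _phenotype(), _gate(True),
                              _dossier(tango=True))
        assert profile.flags["tango"] and not profile.flags["lncrna"]

    def test_gene_flags_need_a_lof_variant(self):
        va = VariantAssessment(variant=_variant("v1", klass="missense_variant"))
        profile = profile_ndd(_assoc(), [va], _phenotype(), _gate(True),
                              _dossier(tango=True, lnc=True))
        assert not profile.flags["tango"] and not profile.flags["lncrna"]

    def test_lncrna_needs_partner(self):
        va = VariantAssessment(variant=_variant("v1"))
        with_partner = profile_ndd(_assoc(), [va], _phenotype(), _gate(True),
                                   _dossier(lnc=True))
        without = profile_ndd(_assoc(), [va], _phenotype(), _gate(True),
                              _dossier(lnc=False))
        assert with_partner.flags["lncrna"] and not without.flags["lncrna"]


class TestProfileSubmissions:
    def _links(self, vas):
        return {("G", "OMIM:1", "AD"): vas}

    def test_submission_weighting(self):
        va = VariantAssessment(variant=_variant("v1", subs=4),
                               es_ve_plan=_es_ve_plan("v1"))
        profiles = profile_submissions(
            self._links([va]),
            {("G", "OMIM:1", "AD"): _phenotype()},
            {("G", "OMIM:1", "AD"): _gate(False)},
            {"G": _dossier()},
        )
        (p,) = profiles
        assert p.flags["es_ve"] and p.submission_count == 4

    def test_missense_in_tango_gene_contributes_nothing(self):
        va = VariantAssessment(variant=_variant("v1", klass="missense_variant",
                                                subs=9))
        (p,) = profile_submissions(
            self._links([va]),
            {("G", "OMIM:1", "AD"): _phenotype()},
            {("G", "OMIM:1", "AD"): _gate(True)},
            {"G": _dossier(tango=True)},
        )
        assert not p.any_strategy

    def test_variant_in_two_associations_counted_once(self):
        va = VariantAssessment(variant=_variant("v1", subs=3),
                               es_ve_plan=_es_ve_plan("v1"))
        links = {("G", "OMIM:1", "AD"): [va], ("G", "OMIM:2", "AD"): [va]}
        pheno = {k: _phenotype() for k in links}
        gates = {k: _gate(False) for k in links}
        profiles = profile_submissions(links, pheno, gates, {"G": _dossier()})
        assert len(profiles) == 1
        assert profiles[0].submission_count == 3


def _profile(vid, flags, subs=1, gene="G"):
    f = {s: False for s in config.STRATEGIES}
    f.update(flags)
    return StrategyProfile(subject_type="variant", subject_id=vid, gene=gene,
                           flags=f, submission_count=subs)


class TestUpsetTable:
    def test_intersect_mode_counts_overlap(self):
        profiles = [
            _profile("a", {"es_ve": True}),
            _profile("b", {"es_ve": True, "tango": True}),
        ]
        table = upset_table(profiles, mode="intersect")
        counts = dict(zip(table["combination"], table["count"]))
        assert counts["es_ve"] == 2
        assert counts["union"] == 2

    def test_distinct_mode_partitions(self):
        profiles = [
            _profile("a", {"es_ve": True}),
            _profile("b", {"es_ve": True}),
            _profile("c", {"es_ve": True, "tango": True}),
            _profile("d", {}),
        ]
        table = upset_table(profiles, mode="distinct")
        body = table[table["combination"] != "union"]
        assert body["count"].sum() == 3  # = number of flagged subjects

    def test_empty_profiles(self):
        table = upset_table([], mode="distinct")
        assert list(table["combination"]) == ["union"]
        assert table["count"].iloc[0] == 0

    def test_union_bounded_by_sum_of_strategies(self):
        profiles = [
            _profile("a", {"es_ve": True, "tango": True}, subs=2),
            _profile("b", {"tango": True}, subs=5),
        ]
        table = upset_table(profiles, mode="intersect", weighted=True)
        counts = dict(zip(table["combination"], table["count"]))
        per_strategy = sum(
            v for k, v in counts.items() if k in config.STRATEGIES)
        assert counts["union"] <= per_strategy


class TestEconomics:
    def test_splice_correction_individuals_per_aon(self):
        profiles = [
            _profile(f"v{i}", {"splice_correction": True}, subs=s)
            for i, s in enumerate([4, 3, 2, 1])
        ]
        out = aon_economics(profiles, {}, "splice_correction")
        assert out["amenable_individuals"] == 10
        assert out["aons_needed"] == 4
        assert out["individuals_per_aon"] == 2.5

    def test_recurrent_only_restriction(self):
        profiles = [
            _profile(f"v{i}", {"splice_correction": True}, subs=s)
            for i, s in enumerate([4, 3, 2, 1])
        ]
        out = aon_economics(profiles, {}, "splice_correction",
                            recurrent_only=True)
        assert out["amenable_individuals"] == 7
        assert out["aons_needed"] == 2

    def test_es_ve_unique_gene_exon_pairs(self):
        profiles = [
            _profile("v1", {"es_ve": True}), _profile("v2", {"es_ve": True}),
            _profile("v3", {"es_ve": True}),
        ]
        assessments = {
            "v1": VariantAssessment(variant=_variant("v1"),
                                    es_ve_plan=_es_ve_plan("v1", exon=5)),
            "v2": VariantAssessment(variant=_variant("v2"),
                                    es_ve_plan=_es_ve_plan("v2", exon=5)),
            "v3": VariantAssessment(variant=_variant("v3"),
                                    es_ve_plan=_es_ve_plan("v3", exon=7)),
        }
        out = aon_economics(profiles, assessments, "es_ve")
        assert out["aons_needed"] == 2  # exons {5, 7} of one gene

    def test_gene_based_strategy_counts_genes(self):
        profiles = [
            _profile("v1", {"tango": True}, gene="G1"),
            _profile("v2", {"tango": True}, gene="G2"),
            _profile("v3", {"tango": True}, gene="G3"),
            _profile("v4", {"tango": True}, gene="G3"),
        ]
        out = aon_economics(profiles, {}, "tango")
        assert out["aons_needed"] == 3

    def test_no_amenable_variants_reports_not_applicable(self):
        out = aon_economics([], {}, "uaug")
        assert out["aons_needed"] == 0
        assert out["individuals_per_aon"] is None
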