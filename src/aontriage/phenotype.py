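"""Phenotype targetability calls from HPO annotations.

A disorder's phenotype is presumed rescuable when at least one of its HPO
terms falls under one of six included roots (developmental, mental or
ambulation deterioration; neurodegeneration; seizures; abnormality of
movement) and none falls under neonatal lethality.  Matching is by
descendant closure: a disease annotated with any term at or below an
included root matches that root.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Set

import pandas as pd

from . import config
from .formats_io import Ontology


def descendants(o: Ontology, term: str) -> Set[str]:
    """Reflexive-transitive closure of the child relation below ``term``."""
    if term not in o.terms:
        raise KeyError(f"unknown ontology term {term!r}")
    children = o.children_map()
    seen = {term}
    frontier = [term]
    while frontier:
        node = frontier.pop()
        for child in children.get(node, ()):
            if child not in seen:
                seen.add(child)
                frontier.append(child)
    return seen


@dataclass
class PhenotypeCall:
    """Per-disease targetability of the phenotype."""

    omim_disease_id: str
    matched_terms: FrozenSet[str]  # included roots hit (root-level ids)
    neonatal_lethal: bool
    targetable: bool
    no_annotation: bool = False


def call_phenotype(
    omim_disease_id: str,
    disease_terms: Set[str],
    o: Ontology,
    include_roots: Iterable[str] = config.PHENOTYPE_INCLUDE_ROOTS,
    exclude_root: str = config.PHENOTYPE_EXCLUDE_ROOT,
) -> PhenotypeCall:
    """Call one disease: targetable iff any included root's descendant
    closure intersects the disease terms and no term falls under the
    neonatal-lethality root.  A disease with no HPO terms at all is not
    targetable and flagged ``no_annotation``."""
    if not disease_terms:
        return PhenotypeCall(
            omim_disease_id=omim_disease_id,
            matched_terms=frozenset(),
            neonatal_lethal=False,
            targetable=False,
            no_annotation=True,
        )
    matched = frozenset(
        root
        for root in include_roots
        if root in o.terms and descendants(o, root) & disease_terms
    )
    lethal = (
        exclude_root in o.terms
        and bool(descendants(o, exclude_root) & disease_terms)
    )
    return PhenotypeCall(
        omim_disease_id=omim_disease_id,
        matched_terms=matched,
        neonatal_lethal=lethal,
        targetable=bool(matched) and not lethal,
    )


def call_phenotypes(
    disease_terms: Dict[str, Set[str]],
    o: Ontology,
    omim_ids: Iterable[str],
    **kwargs,
) -> Dict[str, PhenotypeCall]:
    """Call every OMIM id in ``omim_ids`` (ids without annotation get a
    ``no_annotation`` call)."""
    return {
        omim: call_phenotype(omim, disease_terms.get(omim, set()), o, **kwargs)
        for omim in omim_ids
    }


def phenotype_upset(calls: Iterable[PhenotypeCall]) -> pd.DataFrame:
    """Distinct-mode combination table over the included roots.

    Each targetable disease is counted in exactly one row (its exact set of
    matched roots), so the counts sum to the number of targetable diseases.
    """
    combos: Dict[FrozenSet[str], int] = {}
    for call in calls:
        if call.targetable:
            combos[call.matched_terms] = combos.get(call.matched_terms, 0) + 1
    rows = [
        {"combination": "|".join(sorted(terms)), "count": count}
        for terms, count in combos.items()
    ]
    rows.sort(key=lambda r: (-r["count"], r["combination"]))
    return pd.DataFrame(rows, columns=["combination", "count"])
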