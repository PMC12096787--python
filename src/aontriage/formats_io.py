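"""Readers and writers for every external format the pipeline touches.

Real database exports and synthetic fixtures flow through the same code
paths.  The TSV dialects are documented in ``docs/formats.md``; genomic
coordinates are converted to the internal 0-based half-open convention at
this boundary (GTF and ClinVar files are 1-based inclusive on disk).

Readers never silently drop rows except where a triage rule says so
(ClinSigSimple, DDG2P organ system); dropped-row counts are kept on the
returned objects.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from intervaltree import IntervalTree

from . import config
from .gene_model import TranscriptModel

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A file does not conform to its documented dialect."""


SOURCE_NAMES = ("sysndd", "ddg2p", "hpo", "panel")

# canonical inheritance vocabulary; anything unmapped becomes "unknown"
_INHERITANCE_MAP = {
    "ad": "AD", "autosomal dominant": "AD", "monoallelic_autosomal": "AD",
    "ar": "AR", "autosomal recessive": "AR", "biallelic_autosomal": "AR",
    "xl": "XL", "x-linked": "XL", "monoallelic_x": "XL",
    "xld": "XLD", "x-linked dominant": "XLD",
    "xlr": "XLR", "x-linked recessive": "XLR",
}


def normalize_inheritance(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "unknown"
    value = str(value).strip()
    if not value:
        return "unknown"
    return _INHERITANCE_MAP.get(value.lower(), value.upper() if value.upper() in
                                {"AD", "AR", "XL", "XLD", "XLR"} else "unknown")


@dataclass
class SourceTable:
    """Parsed rows of one disease-gene association source.

    ``rows`` columns: gene, hgnc_id, omim_disease_id (nullable string),
    inheritance (canonical vocabulary or "unknown"), category (confidence
    string preserved verbatim; the scorer decides what it is worth).
    """

    source_name: str
    rows: pd.DataFrame
    dropped: Dict[str, int] = field(default_factory=dict)


# per-dialect column names: (gene symbol, hgnc id, omim, inheritance, category)
_SOURCE_COLUMNS = {
    "sysndd": ("gene_symbol", "hgnc_id", "omim_id", "inheritance", "category"),
    "ddg2p": ("gene_symbol", "hgnc_id", "disease_mim", "allelic_requirement",
              "confidence_category"),
    "hpo": ("gene_symbol", "hgnc_id", "disease_id", "inheritance", None),
    "panel": ("gene_symbol", "hgnc_id", "omim_id", "inheritance", "panel"),
}


def _extract_omim(value) -> Optional[str]:
    """Normalize 'OMIM:600001' / '600001' / NaN to 'OMIM:600001' or None."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in {"nan", "na", ""}:
        return None
    m = re.search(r"(?:OMIM:)?(\d{6})", s)
    return f"OMIM:{m.group(1)}" if m else None


def read_association_source(path, source_name: str) -> SourceTable:
    """Read one association source TSV in its documented dialect.

    DDG2P rows are restricted to the Brain/Cognition organ system; other
    sources keep every row that names a gene.
    """
    if source_name not in SOURCE_NAMES:
        raise ParseError(f"unknown source {source_name!r}; expected one of {SOURCE_NAMES}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    sym_col, hgnc_col, omim_col, inh_col, cat_col = _SOURCE_COLUMNS[source_name]
    if sym_col not in df.columns and hgnc_col not in df.columns:
        raise ParseError(
            f"{path}: {source_name} dialect requires a gene column "
            f"({sym_col!r} or {hgnc_col!r}); found {list(df.columns)}"
        )
    dropped: Dict[str, int] = {}
    if source_name == "ddg2p" and "organ_specificity_list" in df.columns:
        keep = df["organ_specificity_list"].fillna("").str.contains(
            "Brain/Cognition", regex=False
        )
        dropped["organ_system"] = int((~keep).sum())
        df = df[keep]
    out = pd.DataFrame(
        {
            "gene": df[sym_col] if sym_col in df.columns else pd.Series(dtype=str),
            "hgnc_id": df[hgnc_col] if hgnc_col in df.columns else None,
            "omim_disease_id": (
                df[omim_col].map(_extract_omim) if omim_col in df.columns else None
            ),
            "inheritance": (
                df[inh_col].map(normalize_inheritance)
                if inh_col and inh_col in df.columns
                else "unknown"
            ),
            "category": (
                df[cat_col] if cat_col and cat_col in df.columns else None
            ),
        }
    )
    no_gene = out["gene"].isna() & out["hgnc_id"].isna()
    if no_gene.any():
        dropped["no_gene_id"] = int(no_gene.sum())
        logger.warning("%s: rejected %d rows without a gene id", path, no_gene.sum())
        out = out[~no_gene]
    out = out.reset_index(drop=True)
    return SourceTable(source_name=source_name, rows=out, dropped=dropped)


@dataclass
class ClinVarTable:
    """(Likely) pathogenic variants in the ClinVar variant_summary dialect.

    ``rows`` columns: variant_id, gene, name, chromosome, start, end
    (0-based half-open), ref, alt, length_bp, omim_counts (dict id→reports),
    submission_count.  Only ClinSigSimple == 1 rows are retained.
    """

    rows: pd.DataFrame
    dropped: Dict[str, int] = field(default_factory=dict)


def _parse_phenotype_ids(value) -> Dict[str, int]:
    """Count OMIM ids across the '|'-separated per-submission groups of a
    PhenotypeIDS field; repeats measure how often a disease is reported."""
    counts: Dict[str, int] = {}
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return counts
    for group in str(value).split("|"):
        for token in re.split(r"[,;]", group):
            m = re.match(r"\s*OMIM:(\d+)", token)
            if m:
                key = f"OMIM:{m.group(1)}"
                counts[key] = counts.get(key, 0) + 1
    return counts


def read_clinvar_summary(path, expected_assembly: str = config.EXPECTED_ASSEMBLY) -> ClinVarTable:
    """Read a ClinVar variant_summary-dialect TSV.

    Leading '#'-comment lines may declare the assembly ('#Assembly: GRCh38');
    a mismatch with ``expected_assembly`` is a hard error.  Submission count
    prefers a 'Submissions' column, falls back to 'NumberSubmitters', and
    finally defaults to 1 with a warning.
    """
    path = Path(path)
    comments: List[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                comments.append(line)
            else:
                break
    for line in comments:
        m = re.match(r"#\s*Assembly\s*[:=]\s*(\S+)", line)
        if m and m.group(1) != expected_assembly:
            raise ParseError(
                f"{path}: assembly {m.group(1)} does not match expected "
                f"{expected_assembly}"
            )
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"Name", "GeneSymbol", "ClinSigSimple", "Chromosome", "Start", "Stop"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing ClinVar columns {sorted(missing)}")
    dropped: Dict[str, int] = {}
    sig = pd.to_numeric(df["ClinSigSimple"], errors="coerce")
    keep = sig == 1
    dropped["clinsig_not_1"] = int((~keep).sum())
    df = df[keep].reset_index(drop=True)

    if "Submissions" in df.columns:
        subs = pd.to_numeric(df["Submissions"], errors="coerce")
    elif "NumberSubmitters" in df.columns:
        subs = pd.to_numeric(df["NumberSubmitters"], errors="coerce")
    else:
        subs = pd.Series(np.nan, index=df.index)
    n_default = int(subs.isna().sum())
    if n_default:
        logger.warning(
            "%s: %d rows lack a submission count; defaulting to 1", path, n_default
        )
    subs = subs.fillna(1).astype(int).clip(lower=1)

    if "VariationID" in df.columns:
        vid = df["VariationID"]
    else:
        vid = pd.Series([f"var{i}" for i in range(len(df))], index=df.index)

    start = pd.to_numeric(df["Start"]).astype(int)
    stop = pd.to_numeric(df["Stop"]).astype(int)
    if (start > stop).any():
        raise ParseError(f"{path}: Start > Stop on some rows")
    ref = df.get("ReferenceAlleleVCF", pd.Series("", index=df.index)).fillna("")
    alt = df.get("AlternateAlleleVCF", pd.Series("", index=df.index)).fillna("")
    rows = pd.DataFrame(
        {
            "variant_id": vid.astype(str),
            "gene": df["GeneSymbol"].astype(str),
            "name": df["Name"].astype(str),
            "chromosome": df["Chromosome"].astype(str),
            "start": start - 1,  # -> 0-based half-open
            "end": stop,
            "ref": ref.astype(str),
            "alt": alt.astype(str),
            "omim_counts": df.get(
                "PhenotypeIDS", pd.Series(np.nan, index=df.index)
            ).map(_parse_phenotype_ids),
            "submission_count": subs,
        }
    )
    rows["length_bp"] = rows["end"] - rows["start"]
    return ClinVarTable(rows=rows.reset_index(drop=True), dropped=dropped)


# --- transcripts (GTF) ------------------------------------------------------


def read_transcripts(path, cds_fasta=None) -> Dict[str, TranscriptModel]:
    """Read MANE-tagged transcripts from a GTF with exon and CDS features.

    Returns a mapping gene → TranscriptModel (one MANE model per gene).
    Exons are ordered 5'→3' in transcript orientation; a transcript whose
    CDS falls outside its exon union fails validation.  ``cds_fasta`` may
    supply spliced CDS sequences keyed by transcript id (used for
    frameshift PTC scanning).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: Dict[str, list] = {}
    cds: Dict[str, list] = {}
    meta: Dict[str, tuple] = {}
    mane: Set[str] = set()
    for feat in db.all_features():
        if feat.featuretype not in {"exon", "CDS", "transcript"}:
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise ParseError(f"{path}: feature without transcript_id")
        gene = feat.attributes.get("gene_id", [tid])[0]
        meta[tid] = (gene, feat.seqid, feat.strand)
        if any("MANE" in tag for tag in feat.attributes.get("tag", [])):
            mane.add(tid)
        iv = (feat.start - 1, feat.end)  # GFF 1-based inclusive -> half-open
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(iv)
        elif feat.featuretype == "CDS":
            cds.setdefault(tid, []).append(iv)

    models: Dict[str, TranscriptModel] = {}
    sequences = {}
    if cds_fasta is not None:
        from Bio import SeqIO

        sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(cds_fasta), "fasta")}
    for tid in sorted(mane):
        if tid not in exons:
            if tid in cds:
                raise ParseError(f"{path}: transcript {tid} has CDS but no exons")
            continue
        if tid not in cds:
            continue  # noncoding models are not a substrate for triage
        gene, chrom, strand = meta[tid]
        ex = sorted(exons[tid])
        if strand == "-":
            ex = ex[::-1]
        cds_lo = min(s for s, _ in cds[tid])
        cds_hi = max(e for _, e in cds[tid])
        try:
            model = TranscriptModel(
                transcript_id=tid,
                gene=gene,
                chromosome=chrom,
                strand=strand,
                exons=tuple(ex),
                cds_start=cds_lo,
                cds_end=cds_hi,
                mane=True,
                cds_sequence=sequences.get(tid),
            )
        except ValueError as err:
            raise ParseError(f"{path}: invalid transcript {tid}: {err}") from err
        models[gene] = model
    return models


# --- ontology ---------------------------------------------------------------


@dataclass
class Ontology:
    """A parsed is_a ontology (HPO subset).

    ``parents`` maps each term to its direct is_a parents; the graph is
    guaranteed acyclic at parse time.
    """

    terms: Set[str]
    parents: Dict[str, Set[str]]
    labels: Dict[str, str]

    def children_map(self) -> Dict[str, Set[str]]:
        children: Dict[str, Set[str]] = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                children.setdefault(p, set()).add(child)
        return children


def read_ontology(path) -> Ontology:
    """Read an OBO file (id/name/is_a stanzas) into an Ontology."""
    graph = obonet.read_obo(str(path))
    if not nx.is_directed_acyclic_graph(graph):
        raise ParseError(f"{path}: cyclic is_a graph")
    terms = set(graph.nodes)
    parents: Dict[str, Set[str]] = {}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents.setdefault(child, set()).add(parent)
    for ps in parents.values():
        unknown = ps - terms
        if unknown:
            raise ParseError(f"{path}: is_a references unknown terms {unknown}")
    labels = {n: data.get("name", n) for n, data in graph.nodes(data=True)}
    return Ontology(terms=terms, parents=parents, labels=labels)


def read_disease_phenotypes(path) -> Dict[str, Set[str]]:
    """Read a phenotype_to_genes-format TSV into OMIM id → HPO term ids."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "hpo_id" not in df.columns or "disease_id" not in df.columns:
        raise ParseError(
            f"{path}: phenotype table requires 'hpo_id' and 'disease_id' columns"
        )
    out: Dict[str, Set[str]] = {}
    for disease, hpo in zip(df["disease_id"], df["hpo_id"]):
        omim = _extract_omim(disease)
        if omim is None:
            continue
        out.setdefault(omim, set()).add(hpo)
    return out


# --- expression, TADs, gene lists ------------------------------------------


@dataclass
class ExpressionMatrix:
    """Median-TPM matrix (genes × tissues), GCT-like on disk."""

    tpm: pd.DataFrame  # index: gene ids; columns: tissue names

    @property
    def genes(self) -> List[str]:
        return list(self.tpm.index)

    @property
    def tissues(self) -> List[str]:
        return list(self.tpm.columns)


def read_expression(path) -> ExpressionMatrix:
    """Read a GCT-like expression matrix (version line '#1.2', dimension
    line, then Name [Description] + tissue columns)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    skip = 2 if first.startswith("#1.") else 0
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    name_col = df.columns[0]
    if df[name_col].duplicated().any():
        dupes = df[name_col][df[name_col].duplicated()].unique()
        raise ParseError(f"{path}: duplicate gene ids in expression matrix: {dupes[:5]}")
    df = df.set_index(name_col)
    if "Description" in df.columns:
        df = df.drop(columns=["Description"])
    tpm = df.astype(float)
    if (tpm.values < 0).any():
        raise ParseError(f"{path}: negative TPM values")
    return ExpressionMatrix(tpm=tpm)


@dataclass
class TADSet:
    """Topologically associating domains as half-open genomic intervals."""

    intervals: List[Tuple[str, int, int]]

    def __post_init__(self):
        self._trees: Dict[str, IntervalTree] = {}
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ParseError(f"TAD with start >= end: {chrom}:{start}-{end}")
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def overlapping(self, chrom: str, start: int, end: int) -> List[Tuple[str, int, int]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((chrom, iv.begin, iv.end) for iv in tree.overlap(start, end))

    def share_tad(self, a: Tuple[str, int, int], b: Tuple[str, int, int]) -> bool:
        """True when the two genomic spans overlap at least one common TAD."""
        tads_a = set(self.overlapping(*a))
        return any(t in tads_a for t in self.overlapping(*b))


def read_tads(path) -> TADSet:
    """Read TAD intervals from a BED3 file (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end"], usecols=[0, 1, 2], dtype={0: str},
    )
    return TADSet(
        intervals=[(str(c), int(s), int(e)) for c, s, e in df.itertuples(index=False)]
    )


def read_gene_list(path) -> Tuple[str, Set[str]]:
    """Read a one-column gene list whose header names the list."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 1:
        raise ParseError(f"{path}: gene list must have exactly one column")
    name = df.columns[0].strip().lower()
    return name, set(df.iloc[:, 0].dropna())


def read_gene_lists(paths) -> Dict[str, Set[str]]:
    lists: Dict[str, Set[str]] = {}
    for p in paths:
        name, genes = read_gene_list(p)
        lists[name] = genes
    return lists


def read_pli(path) -> Dict[str, float]:
    """Read a two-column gene → pLI table."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ParseError(f"{path}: pLI table requires gene and pLI columns")
    gcol, pcol = df.columns[:2]
    return dict(zip(df[gcol], df[pcol].astype(float)))


def read_lncrna_catalog(path) -> pd.DataFrame:
    """Read a BED-like lncRNA catalog (chrom, start, end, id, biotype);
    only rows with biotype 'lncRNA' are kept."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "lncrna_id", "biotype"],
        dtype={"chrom": str},
    )
    return df[df["biotype"] == "lncRNA"].reset_index(drop=True)


# --- profile output ---------------------------------------------------------

_PROFILE_BOOL_COLUMNS = list(config.STRATEGIES) + ["any_strategy"]


def write_profile_table(profiles: pd.DataFrame, path) -> None:
    """Write a strategy-profile table (one row per NDD or variant, seven
    boolean strategy columns, evidence serialized as JSON)."""
    out = profiles.copy()
    for col in _PROFILE_BOOL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype(bool)
    if "evidence" in out.columns:
        out["evidence"] = out["evidence"].map(
            lambda e: json.dumps(e, sort_keys=True) if not isinstance(e, str) else e
        )
    out.to_csv(path, sep="\t", index=False)


def read_profile_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in _PROFILE_BOOL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(bool)
    if "evidence" in df.columns:
        df["evidence"] = df["evidence"].map(json.loads)
    return df
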