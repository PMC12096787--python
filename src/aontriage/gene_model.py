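"""Transcript arithmetic on MANE transcript models.

All reading-frame, distance and coding-loss rules of the pipeline reduce to
arithmetic over one transcript model per gene: exon coding lengths and their
mod-3 frame classes, variant-to-exon mapping, intron distances, premature
termination codon (PTC) placement and the NMD-escape rule set.

Coordinates are 0-based half-open genomic intervals.  Exons are stored in
transcript orientation (5'→3'), so exon index 1 is the most 5' exon of the
mRNA regardless of strand.  All results are strand-symmetric: mirroring a
transcript to the opposite strand leaves every derived quantity unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from . import config

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one (MANE) transcript.

    Parameters
    ----------
    transcript_id, gene : str
        Identifiers; ``gene`` is the key used to join variants and dossiers.
    chromosome : str
    strand : str
        ``"+"`` or ``"-"``.
    exons : tuple of (int, int)
        Genomic half-open intervals in transcript orientation.  For a
        minus-strand transcript the first tuple element is therefore the
        exon with the *largest* genomic coordinates.
    cds_start, cds_end : int
        Genomic half-open span of the CDS (``cds_start < cds_end``
        regardless of strand).
    mane : bool
        Whether this is the MANE-designated model for the gene.
    cds_sequence : str, optional
        Spliced CDS sequence 5'→3' (starts with ATG, ends with a stop);
        required only for frameshift PTC scanning.
    """

    transcript_id: str
    gene: str
    chromosome: str
    strand: str
    exons: tuple
    cds_start: int
    cds_end: int
    mane: bool = True
    cds_sequence: Optional[str] = None

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        for s, e in exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon [{s}, {e})")
        genomic = sorted(exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        # transcript orientation check: + ascending, - descending
        expected = genomic if self.strand == "+" else genomic[::-1]
        if exons != tuple(expected):
            raise ValueError(
                f"{self.transcript_id}: exons not in transcript orientation"
            )
        if self.cds_start >= self.cds_end:
            raise ValueError(f"{self.transcript_id}: empty CDS span")
        # CDS endpoints must fall inside the exon union
        for pos in (self.cds_start, self.cds_end - 1):
            if not any(s <= pos < e for s, e in exons):
                raise ValueError(
                    f"{self.transcript_id}: CDS outside exon union"
                )
        if self.coding_length == 0:
            raise ValueError(f"{self.transcript_id}: zero coding length")
        if self.cds_sequence is not None and len(self.cds_sequence) != self.coding_length:
            raise ValueError(
                f"{self.transcript_id}: cds_sequence length "
                f"{len(self.cds_sequence)} != coding length {self.coding_length}"
            )

    # -- basic geometry ----------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple:
        """Genomic half-open span from first to last exon."""
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    def exon_coding_length(self, index: int) -> int:
        """Coding (CDS-overlapping) length of the 1-based exon ``index``."""
        s, e = self.exons[index - 1]
        return max(0, min(e, self.cds_end) - max(s, self.cds_start))

    @property
    def coding_length(self) -> int:
        return sum(
            max(0, min(e, self.cds_end) - max(s, self.cds_start))
            for s, e in self.exons
        )

    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """0-based spliced-transcript coordinate of genomic ``pos``.

        Returns None for intronic or out-of-span positions.
        """
        offset = 0
        for s, e in self.exons:
            if s <= pos < e:
                if self.strand == "+":
                    return offset + (pos - s)
                return offset + (e - 1 - pos)
            offset += e - s
        return None

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """1-based CDS coordinate of genomic ``pos`` (None if outside CDS)."""
        if not (self.cds_start <= pos < self.cds_end):
            return None
        tpos = self.genomic_to_transcript(pos)
        if tpos is None:
            return None
        cds_first = self.cds_start if self.strand == "+" else self.cds_end - 1
        t0 = self.genomic_to_transcript(cds_first)
        cds_pos = tpos - t0 + 1
        if cds_pos < 1 or cds_pos > self.coding_length:
            return None
        return cds_pos

    def five_prime_end(self, interval: tuple) -> int:
        """Genomic position of the transcript-most-5' base of ``interval``."""
        s, e = interval
        return s if self.strand == "+" else e - 1


@dataclass(frozen=True)
class ExonFacts:
    """Frame bookkeeping for one exon.

    frame_class is ``in_frame`` iff the exon overlaps the CDS and its coding
    length is a multiple of three; UTR-only exons are ``noncoding`` and
    frame-neutral.
    """

    index: int  # 1-based, transcript orientation
    coding_length: int
    frame_class: str  # in_frame | out_of_frame | noncoding
    is_first: bool
    is_last: bool


def exon_facts(t: TranscriptModel) -> list:
    """One ExonFacts per exon; sum of coding lengths equals the CDS length."""
    facts = []
    for i in range(1, t.n_exons + 1):
        clen = t.exon_coding_length(i)
        if clen == 0:
            fc = "noncoding"
        elif clen % 3 == 0:
            fc = "in_frame"
        else:
            fc = "out_of_frame"
        facts.append(
            ExonFacts(
                index=i,
                coding_length=clen,
                frame_class=fc,
                is_first=(i == 1),
                is_last=(i == t.n_exons),
            )
        )
    return facts


@dataclass(frozen=True)
class VariantLocation:
    """Where a genomic interval falls on a transcript.

    kind:
      ``exonic``             wholly inside one exon (``exon_index`` set)
      ``intronic``           wholly inside one intron (``distance``/``side``)
      ``whole_exon_deletion``covers >=1 full exon, breakpoints intronic
                             (``deleted_exons`` set, transcript indices)
      ``partial``            overlaps an exon partially
      ``outside``            no overlap with the transcript span
    Distances follow the HPO/HGVS intron-offset convention: the intronic
    base immediately adjacent to an exon has distance 1.
    """

    kind: str
    exon_index: Optional[int] = None
    deleted_exons: frozenset = frozenset()
    distance: Optional[int] = None
    side: Optional[str] = None  # donor | acceptor (transcript orientation)


def locate_variant(t: TranscriptModel, interval: tuple) -> VariantLocation:
    """Map a genomic half-open interval onto the transcript structure."""
    s, e = int(interval[0]), int(interval[1])
    if s >= e:
        raise ValueError(f"empty variant interval [{s}, {e})")
    span_s, span_e = t.span
    if e <= span_s or s >= span_e:
        return VariantLocation(kind="outside")

    genomic_order = sorted(range(t.n_exons), key=lambda i: t.exons[i][0])
    contained, partial = [], []
    for i in genomic_order:
        xs, xe = t.exons[i]
        if s <= xs and xe <= e:
            contained.append(i)
        elif s < xe and xs < e:  # some overlap
            if xs <= s and e <= xe:
                return VariantLocation(kind="exonic", exon_index=i + 1)
            partial.append(i)
    if contained and not partial:
        return VariantLocation(
            kind="whole_exon_deletion",
            deleted_exons=frozenset(i + 1 for i in contained),
        )
    if contained or partial:
        return VariantLocation(kind="partial")

    # wholly intronic: find the flanking exons in genomic order
    up_end = down_start = None
    for i in genomic_order:
        xs, xe = t.exons[i]
        if xe <= s:
            up_end = xe
        if xs >= e and down_start is None:
            down_start = xs
    if up_end is None or down_start is None:
        # inside span but outside exon hull can't happen; defensive
        return VariantLocation(kind="outside")
    dist_up = s - up_end + 1  # closest variant base to upstream (genomic) exon
    dist_down = down_start - (e - 1)
    distance = min(dist_up, dist_down)
    # side in transcript orientation: the genomically-upstream exon end is a
    # donor site on '+', an acceptor site on '-'
    if dist_up <= dist_down:
        side = "donor" if t.strand == "+" else "acceptor"
    else:
        side = "acceptor" if t.strand == "+" else "donor"
    return VariantLocation(kind="intronic", distance=distance, side=side)


def adjacent_exon(t: TranscriptModel, interval: tuple) -> Optional[int]:
    """Transcript index of the exon bordering the splice site nearest to an
    intronic ``interval`` (the obligate-skip exon of a canonical splice
    variant), or None if the variant is not intronic."""
    loc = locate_variant(t, interval)
    if loc.kind != "intronic":
        return None
    s, e = interval
    genomic_order = sorted(range(t.n_exons), key=lambda i: t.exons[i][0])
    up = down = None
    for i in genomic_order:
        xs, xe = t.exons[i]
        if xe <= s:
            up = i
        if xs >= e and down is None:
            down = i
    dist_up = s - t.exons[up][1] + 1
    dist_down = t.exons[down][0] - (e - 1)
    nearest = up if dist_up <= dist_down else down
    return nearest + 1


@dataclass(frozen=True)
class PTCContext:
    """Placement of a premature termination codon within the spliced mRNA.

    ptc_cds_pos is the 1-based nt index of the PTC's first base within the
    CDS; distance_to_last_junction is measured in spliced-transcript nt and
    is negative when the PTC lies downstream of (3' of) the last exon-exon
    junction, i.e. in the last exon.
    """

    ptc_cds_pos: int
    containing_exon: int
    distance_to_last_junction: int


def _cds_pos_to_context(t: TranscriptModel, cds_pos: int) -> PTCContext:
    if not (1 <= cds_pos <= t.coding_length):
        raise ValueError(
            f"CDS position {cds_pos} outside [1, {t.coding_length}]"
        )
    # transcript coordinate of CDS base 1
    cds_first = t.cds_start if t.strand == "+" else t.cds_end - 1
    t0 = t.genomic_to_transcript(cds_first)
    tpos = t0 + cds_pos - 1  # 0-based transcript coordinate of the PTC base
    # containing exon: walk cumulative exon lengths
    offset = 0
    containing = t.n_exons
    for i, (s, e) in enumerate(t.exons, start=1):
        if tpos < offset + (e - s):
            containing = i
            break
        offset += e - s
    junction = sum(e - s for s, e in t.exons[:-1])  # transcript pos of last junction
    return PTCContext(
        ptc_cds_pos=cds_pos,
        containing_exon=containing,
        distance_to_last_junction=junction - tpos,
    )


def ptc_context(
    t: TranscriptModel,
    interval: tuple,
    resolved_class: str,
    ref: str = "",
    alt: str = "",
    surrogate: bool = False,
) -> PTCContext:
    """PTC placement for a stop_gained or frameshift variant.

    stop_gained: the PTC is the variant codon.  frameshift: with a CDS
    sequence on the transcript the shifted frame is scanned for the first
    stop codon; without one (or with ``surrogate=True``) the PTC is assumed
    at the variant position — a documented approximation that is exact
    whenever the first shifted-frame stop is nearby.
    """
    if resolved_class not in {"stop_gained", "frameshift_variant"}:
        raise ValueError(f"no PTC context for class {resolved_class!r}")
    pos5 = t.five_prime_end(interval)
    cds_pos = t.genomic_to_cds(pos5)
    if cds_pos is None:
        raise ValueError(
            f"{resolved_class} variant at {interval} is outside the CDS"
        )
    if resolved_class == "stop_gained" or surrogate or t.cds_sequence is None:
        # PTC at the variant codon (codon start of the affected base)
        codon_start = cds_pos - (cds_pos - 1) % 3
        return _cds_pos_to_context(t, codon_start)

    # frameshift with sequence: splice the indel into the CDS and scan
    seq = t.cds_sequence.upper()
    i = cds_pos - 1
    mutated = seq[:i] + alt.upper() + seq[i + len(ref):]
    shift = len(alt) - len(ref)
    if shift % 3 == 0:
        raise ValueError("in-frame indel passed as frameshift_variant")
    codon_start = i - i % 3
    ptc_mut = None
    for j in range(codon_start, len(mutated) - 2, 3):
        if mutated[j:j + 3] in STOP_CODONS:
            ptc_mut = j  # 0-based in mutated CDS
            break
    if ptc_mut is None:
        # stop-loss readthrough: place the PTC at the end of the CDS
        ptc_mut = len(mutated) - len(mutated) % 3 - 3
    # map back to original coordinates for junction arithmetic
    ptc_orig = ptc_mut - shift if ptc_mut > i else ptc_mut
    ptc_orig = max(1, min(t.coding_length, ptc_orig + 1))
    return _cds_pos_to_context(t, ptc_orig)


def predict_nmd_escape(t: TranscriptModel, p: PTCContext) -> bool:
    """VEP NMD-plugin rule set: a PTC escapes NMD iff it is in the last
    exon, within 50 nt upstream of the last exon-exon junction, within
    100 nt of the start codon, or the transcript is intronless."""
    if t.n_exons == 1:
        return True
    if p.containing_exon == t.n_exons:
        return True
    if p.distance_to_last_junction <= config.NMD_LAST_JUNCTION_WINDOW:
        return True
    if p.ptc_cds_pos <= config.NMD_START_PROXIMAL_WINDOW:
        return True
    return False


def cds_loss_fraction(
    t: TranscriptModel,
    removed: Sequence[int],
    extra_deleted_coding_nt: int = 0,
) -> float:
    """Fraction of the CDS lost when the 1-based exons in ``removed`` are
    skipped/deleted, plus ``extra_deleted_coding_nt`` from the variant."""
    if extra_deleted_coding_nt < 0:
        raise ValueError("extra_deleted_coding_nt must be non-negative")
    removed = set(removed)
    for i in removed:
        if not (1 <= i <= t.n_exons):
            raise ValueError(f"exon index {i} out of range 1..{t.n_exons}")
    lost = sum(t.exon_coding_length(i) for i in removed) + extra_deleted_coding_nt
    return lost / t.coding_length
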