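import numpy as np
import pytest

from aontriage.gene_model import TranscriptModel


def make_transcript(
    coding,
    utr5=90,
    utr3=60,
    intron=500,
    offset=10_000,
    chrom="chr1",
    strand="+",
    gene="GENE",
    with_sequence=False,
    rng=None,
):
    """Build a forward-strand transcript from per-exon coding lengths.

    Zeros are allowed only for the first/last exon (pure-UTR exons).  The
    5'UTR sits in the first exon and the 3'UTR in the last.  ``intron`` may
    be an int (uniform) or a list of per-intron lengths.  With
    ``with_sequence=True`` a valid CDS sequence (ATG ... TAA) is attached.
    """
    n = len(coding)
    introns = [intron] * (n - 1) if isinstance(intron, int) else list(intron)
    exon_lens = []
    for i, c in enumerate(coding):
        L = c
        if i == 0:
            L += utr5
        if i == n - 1:
            L += utr3
        exon_lens.append(L if L > 0 else 50)
    exons, cur = [], offset
    for i, L in enumerate(exon_lens):
        exons.append((cur, cur + L))
        cur += L + (introns[i] if i < n - 1 else 0)
    first_coding = next(i for i, c in enumerate(coding) if c > 0)
    last_coding = max(i for i, c in enumerate(coding) if c > 0)
    cds_start = exons[first_coding][0] + (utr5 if first_coding == 0 else 0)
    cds_end = exons[last_coding][1] - (utr3 if last_coding == n - 1 else 0)
    seq = None
    if with_sequence:
        total = sum(coding)
        assert total % 3 == 0, "sequence requires a whole number of codons"
        rng = rng or np.random.default_rng(0)
        sense = [
            a + b + c
            for a in "ACGT" for b in "ACGT" for c in "ACGT"
            if a + b + c not in {"TAA", "TAG", "TGA"}
        ]
        seq = "ATG" + "".join(
            sense[int(k)] for k in rng.integers(0, len(sense), total // 3 - 2)
        ) + "TAA"
    if strand == "-":
        from aontriage.synthetic import mirror_transcript

        fwd = TranscriptModel(
            transcript_id="TX1", gene=gene, chromosome=chrom, strand="+",
            exons=tuple(exons), cds_start=cds_start, cds_end=cds_end,
            cds_sequence=seq,
        )
        return mirror_transcript(fwd, 2 * offset + (exons[-1][1] - exons[0][0]))
    return TranscriptModel(
        transcript_id="TX1", gene=gene, chromosome=chrom, strand="+",
        exons=tuple(exons), cds_start=cds_start, cds_end=cds_end,
        cds_sequence=seq,
    )


def random_transcript(rng, max_exons=8, min_exons=3):
    """A random multi-exon transcript for oracle batteries."""
    n = int(rng.integers(min_exons, max_exons + 1))
    coding = [int(rng.integers(30, 400)) for _ in range(n)]
    introns = [int(rng.integers(100, 2000)) for _ in range(n - 1)]
    return make_transcript(coding, intron=introns,
                           offset=int(rng.integers(1000, 50_000)))


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """One default synthetic bundle shared across read-only tests."""
    from aontriage.synthetic import CohortConfig, generate_cohort

    out = tmp_path_factory.mktemp("bundle")
    truth = generate_cohort(CohortConfig(seed=11), out)
    return out, truth


@pytest.fixture(scope="session")
def small_result(small_bundle):
    from aontriage.pipeline import run_pipeline

    out, truth = small_bundle
    return run_pipeline(out), truth
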