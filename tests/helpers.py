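"""Shared toy-model builders for the test suite."""
from __future__ import annotations

from kinefuse.annotation import GeneModel, Transcript
from kinefuse.evidence import ChimericEvidence, Locus


def make_gene(gene_id: str, chrom: str = "chrT", strand: str = "+",
              exons=((100, 200), (300, 400)), cds=None, symbol=None,
              kinase_domain=None) -> GeneModel:
    """Build a single-transcript gene from genomically sorted exon intervals."""
    exons = tuple(sorted(exons, reverse=strand == "-"))
    cds = tuple(sorted(cds, reverse=strand == "-")) if cds else ()
    tx = Transcript(tx_id=f"{gene_id}.t1", strand=strand, exons=exons, cds=cds)
    start = min(s for s, _ in exons)
    end = max(e for _, e in exons)
    return GeneModel(gene_id=gene_id, symbol=symbol or gene_id, chrom=chrom,
                     strand=strand, start=start, end=end, transcripts=(tx,),
                     is_kinase=kinase_domain is not None,
                     kinase_domain=kinase_domain)


def locus(chrom: str, start: int, strand: str = "+", span: int = 30) -> Locus:
    return Locus(chrom=chrom, start=start, strand=strand, span=span)


def pair_ev(sample: str, read_id: str, locus_a: Locus, locus_b: Locus
            ) -> ChimericEvidence:
    return ChimericEvidence(sample, read_id, "pair", locus_a, locus_b)


def split_ev(sample: str, read_id: str, locus_a: Locus, locus_b: Locus,
             donor: int, acceptor: int, oh_a: int = 20, oh_b: int = 20
             ) -> ChimericEvidence:
    return ChimericEvidence(sample, read_id, "split", locus_a, locus_b,
                            donor, acceptor, oh_a, oh_b)
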