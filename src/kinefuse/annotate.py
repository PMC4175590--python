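"""Functional annotation of fusion candidates.

Implements the manual-review rules for calling a fusion a candidate driver:
an intergenic junction between exons (or an exon and a cryptic exon), an
in-frame predicted coding sequence (or a promoter fusion that leaves the
downstream coding sequence intact), full conservation of the kinase
catalytic domain, dimerization-motif detection on the partner moiety, and
artifact flags for partner homology and trans-splicing chimeras.
"""
from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from Bio.Seq import Seq

from .annotation import ExpressionMatrix, GeneModel, Transcript
from .coils import CoilsParameters, coils_scan
from .config import FilterConfig
from .detect import FusionCandidate

JUNCTION_EXON_EXON = "exon_exon"
JUNCTION_EXON_CRYPTIC = "exon_cryptic"
JUNCTION_UNRESOLVED = "unresolved"

FRAME_IN = "in_frame"
FRAME_OUT = "out_of_frame"
FRAME_PROMOTER = "promoter_fusion"
FRAME_NO_CDS = "no_cds"

DOMAIN_COMPLETE = "complete"
DOMAIN_TRUNCATED = "truncated"
DOMAIN_ABSENT = "absent"

ARTIFACT_HOMOLOGOUS = "homologous_repeat"
ARTIFACT_TRANS_SPLICE = "trans_splice_suspect"

VERDICT_DRIVER = "candidate_driver"
VERDICT_PASSENGER = "passenger"
VERDICT_ARTIFACT = "artifact"


class BreakpointOutsideExon(ValueError):
    """A split-read breakpoint falls outside the canonical transcript's exons."""


# ---------------------------------------------------------------------------
# junction classification
# ---------------------------------------------------------------------------

def _donor_boundaries(gene: GeneModel) -> set[int]:
    """Genomic bases that are the transcription-orientation 3' end of an exon."""
    out = set()
    for tx in gene.transcripts:
        for s, e in tx.exons:
            out.add(e - 1 if gene.strand == "+" else s)
    return out


def _acceptor_boundaries(gene: GeneModel) -> set[int]:
    """Genomic bases that are the transcription-orientation 5' start of an exon."""
    out = set()
    for tx in gene.transcripts:
        for s, e in tx.exons:
            out.add(s if gene.strand == "+" else e - 1)
    return out


def classify_junction(candidate: FusionCandidate) -> str:
    """exon_exon when both breakpoints sit on annotated exon boundaries in
    transcription orientation, exon_cryptic when exactly one does,
    unresolved otherwise or without split-read support."""
    if candidate.n_split == 0 or candidate.breakpoint5 is None:
        return JUNCTION_UNRESOLVED
    donor_ok = candidate.breakpoint5 in _donor_boundaries(candidate.gene5)
    acceptor_ok = candidate.breakpoint3 in _acceptor_boundaries(candidate.gene3)
    if donor_ok and acceptor_ok:
        return JUNCTION_EXON_EXON
    if donor_ok or acceptor_ok:
        return JUNCTION_EXON_CRYPTIC
    return JUNCTION_UNRESOLVED


# ---------------------------------------------------------------------------
# fusion transcript construction
# ---------------------------------------------------------------------------

@dataclass
class FusionTranscript:
    """Chimeric transcript model built from the two canonical transcripts.

    ``seq`` is the predicted fusion mRNA; the bookkeeping fields record how
    much of each partner's CDS/UTR is retained, all in nucleotides of
    transcript coordinates.
    """

    candidate: FusionCandidate
    tx5: Transcript
    tx3: Transcript
    seq: str
    five_len: int                 # nt contributed by the 5' partner
    five_cds_nt: int              # coding nt retained from the 5' partner
    cds5_tstart: Optional[int]    # 5' CDS start within the fusion (== tx5 CDS start)
    three_cds_skipped_nt: int     # nt of the 3' CDS lost upstream of the junction
    three_cds_retained_nt: int
    three_cds_start_in_fusion: Optional[int]

    @property
    def three_cds_complete(self) -> bool:
        return self.three_cds_skipped_nt == 0 and self.three_cds_retained_nt > 0

    @property
    def three_cds_total_nt(self) -> int:
        return self.three_cds_skipped_nt + self.three_cds_retained_nt

    def partner_peptide(self) -> str:
        """Amino acids contributed by the 5' (partner) moiety."""
        if self.cds5_tstart is None or self.five_cds_nt < 3:
            return ""
        n = 3 * (self.five_cds_nt // 3)
        return str(Seq(self.seq[self.cds5_tstart:self.cds5_tstart + n]).translate())


def build_fusion_transcript(candidate: FusionCandidate,
                            genome: Mapping[str, str]) -> FusionTranscript:
    """Concatenate the 5' partner's exonic sequence through its breakpoint
    with the 3' partner's from its breakpoint on, in transcription
    orientation, tracking retained CDS/UTR on both sides.

    Raises :class:`BreakpointOutsideExon` when a breakpoint is not exonic in
    the canonical transcript.
    """
    if candidate.breakpoint5 is None or candidate.breakpoint3 is None:
        raise BreakpointOutsideExon("candidate has no split-read breakpoints")
    tx5, tx3 = candidate.gene5.canonical, candidate.gene3.canonical
    t_donor = tx5.to_tpos(candidate.breakpoint5)
    t_acc = tx3.to_tpos(candidate.breakpoint3)
    if t_donor is None:
        raise BreakpointOutsideExon(
            f"5' breakpoint {candidate.breakpoint5} outside exons of {tx5.tx_id}")
    if t_acc is None:
        raise BreakpointOutsideExon(
            f"3' breakpoint {candidate.breakpoint3} outside exons of {tx3.tx_id}")

    seq5 = tx5.spliced(genome, candidate.gene5.chrom)
    seq3 = tx3.spliced(genome, candidate.gene3.chrom)
    five_piece = seq5[:t_donor + 1]
    three_piece = seq3[t_acc:]
    five_len = len(five_piece)

    cds5 = tx5.cds_tspan
    if cds5 is None:
        five_cds_nt, cds5_tstart = 0, None
    else:
        five_cds_nt = max(0, min(t_donor + 1, cds5[1]) - cds5[0])
        cds5_tstart = cds5[0] if five_cds_nt > 0 else None

    cds3 = tx3.cds_tspan
    if cds3 is None:
        skipped = retained = 0
        start_in_fusion = None
    else:
        skipped = min(max(0, t_acc - cds3[0]), cds3[1] - cds3[0])
        retained = max(0, cds3[1] - max(t_acc, cds3[0]))
        start_in_fusion = (five_len + max(0, cds3[0] - t_acc)) if retained else None

    return FusionTranscript(candidate=candidate, tx5=tx5, tx3=tx3,
                            seq=five_piece + three_piece, five_len=five_len,
                            five_cds_nt=five_cds_nt, cds5_tstart=cds5_tstart,
                            three_cds_skipped_nt=skipped,
                            three_cds_retained_nt=retained,
                            three_cds_start_in_fusion=start_in_fusion)


# ---------------------------------------------------------------------------
# reading frame
# ---------------------------------------------------------------------------

def predict_frame(ft: FusionTranscript) -> tuple[str, int]:
    """Frame status of the fusion transcript plus the number of amino acids
    contributed by the 5' partner.

    promoter_fusion: the 5' partner contributes only untranslated sequence
    and the complete downstream CDS is retained.  in_frame: the retained 5'
    coding sequence joins the 3' CDS in its annotated codon phase with no
    intervening stop.  no_cds: neither side contributes coding sequence.
    """
    contrib_aa = ft.five_cds_nt // 3
    if ft.five_cds_nt == 0 and ft.three_cds_retained_nt == 0:
        return FRAME_NO_CDS, 0
    if ft.five_cds_nt == 0:
        if ft.three_cds_complete:
            return FRAME_PROMOTER, 0
        return FRAME_OUT, 0
    if ft.three_cds_retained_nt == 0:
        return FRAME_OUT, contrib_aa

    start3 = ft.three_cds_start_in_fusion
    assert start3 is not None and ft.cds5_tstart is not None
    # codon phase of the first retained 3' CDS base must match its position
    # in the fused open reading frame
    if (start3 - ft.cds5_tstart - ft.three_cds_skipped_nt) % 3 != 0:
        return FRAME_OUT, contrib_aa
    end3 = start3 + ft.three_cds_retained_nt
    coding = ft.seq[ft.cds5_tstart:end3]
    coding = coding[:3 * (len(coding) // 3)]
    protein = str(Seq(coding).translate())
    internal_stop = "*" in protein[:-1]
    if internal_stop:
        return FRAME_OUT, contrib_aa
    return FRAME_IN, contrib_aa


# ---------------------------------------------------------------------------
# kinase-domain conservation
# ---------------------------------------------------------------------------

def check_kinase_domain(ft: FusionTranscript, kinase: GeneModel) -> str:
    """complete / truncated / absent depending on how much of the kinase's
    catalytic-domain interval survives in the fusion protein.

    Only fully retained codons count as retained residues.
    """
    if kinase.kinase_domain is None:
        warnings.warn(f"{kinase.symbol}: no kinase-domain interval in registry; "
                      f"status computed as absent")
        return DOMAIN_ABSENT
    dom_start, dom_end = kinase.kinase_domain
    plen = kinase.protein_length()
    if plen is None:
        return DOMAIN_ABSENT

    if kinase.gene_id == ft.candidate.gene3.gene_id:
        if ft.three_cds_retained_nt == 0:
            return DOMAIN_ABSENT
        k = ft.three_cds_skipped_nt
        first_aa = k // 3 + 1 if k % 3 == 0 else k // 3 + 2
        retained = (first_aa, plen)
    elif kinase.gene_id == ft.candidate.gene5.gene_id:
        last_aa = ft.five_cds_nt // 3
        if last_aa == 0:
            return DOMAIN_ABSENT
        retained = (1, last_aa)
    else:
        raise ValueError(f"{kinase.symbol} is not a partner of this fusion")

    lo = max(retained[0], dom_start)
    hi = min(retained[1], dom_end)
    if lo > hi:
        return DOMAIN_ABSENT
    if retained[0] <= dom_start and dom_end <= retained[1]:
        return DOMAIN_COMPLETE
    return DOMAIN_TRUNCATED


# ---------------------------------------------------------------------------
# expression support and artifact flags
# ---------------------------------------------------------------------------

def expression_zscore(matrix: ExpressionMatrix, gene: str, sample: str) -> float:
    """Within-cohort z-score of a gene's expression (unbiased sd)."""
    return matrix.zscore(gene, sample)


def flag_artifacts(candidate: FusionCandidate, junction_class: str,
                   expression: Optional[ExpressionMatrix],
                   homologous: bool, config: FilterConfig) -> frozenset[str]:
    """homologous_repeat when the partners share homologous sequence;
    trans_splice_suspect when a partner is extremely highly expressed in the
    sample and the call has neither split support nor a resolvable junction."""
    flags: set[str] = set()
    if homologous:
        flags.add(ARTIFACT_HOMOLOGOUS)
    if candidate.n_split == 0 and junction_class == JUNCTION_UNRESOLVED \
            and expression is not None:
        for gene in (candidate.gene5, candidate.gene3):
            try:
                z = expression.zscore(gene.symbol, candidate.sample_id)
            except KeyError:
                warnings.warn(f"{gene.symbol} absent from expression matrix; "
                              f"trans-splice test skipped")
                continue
            if z >= config.trans_splice_z:
                flags.add(ARTIFACT_TRANS_SPLICE)
                break
    return frozenset(flags)


# ---------------------------------------------------------------------------
# verdict
# ---------------------------------------------------------------------------

@dataclass
class FusionAnnotation:
    """Functional annotation of one fusion occurrence."""

    candidate: FusionCandidate
    junction_class: str
    frame_status: Optional[str]
    kinase_gene: Optional[str]
    kinase_domain_status: Optional[str]
    partner_contrib_aa: int
    motif_calls: list[tuple[str, tuple[int, int], float]] = field(default_factory=list)
    artifact_flags: frozenset[str] = frozenset()
    verdict: str = VERDICT_PASSENGER
    zscores: dict[str, float] = field(default_factory=dict)
    expression_rank3: Optional[int] = None
    junction_dinucleotides: Optional[tuple[str, str]] = None
    notes: tuple[str, ...] = ()

    def validate(self) -> "FusionAnnotation":
        if self.verdict == VERDICT_DRIVER:
            ok = (self.junction_class != JUNCTION_UNRESOLVED
                  and self.frame_status in (FRAME_IN, FRAME_PROMOTER)
                  and self.kinase_domain_status == DOMAIN_COMPLETE
                  and not self.artifact_flags)
            if not ok:
                raise ValueError("candidate_driver verdict violates its invariant")
        return self

    def to_dict(self) -> dict:
        c = self.candidate
        return {
            "sample_id": c.sample_id,
            "cohort": c.cohort,
            "gene5": c.gene5.gene_id, "symbol5": c.gene5.symbol,
            "gene3": c.gene3.gene_id, "symbol3": c.gene3.symbol,
            "n_chimeric": c.n_chimeric, "n_split": c.n_split,
            "breakpoint5": None if c.breakpoint5 is None else c.breakpoint5 + 1,
            "breakpoint3": None if c.breakpoint3 is None else c.breakpoint3 + 1,
            "junction_class": self.junction_class,
            "frame_status": self.frame_status,
            "kinase_gene": self.kinase_gene,
            "kinase_domain_status": self.kinase_domain_status,
            "partner_contrib_aa": self.partner_contrib_aa,
            "motif_calls": [{"motif": m, "aa_start": s, "aa_end": e, "score": round(p, 4)}
                            for m, (s, e), p in self.motif_calls],
            "artifact_flags": sorted(self.artifact_flags),
            "verdict": self.verdict,
            "expression_zscores": {g: round(z, 4) for g, z in sorted(self.zscores.items())},
            "expression_rank3": self.expression_rank3,
            "junction_dinucleotides": list(self.junction_dinucleotides)
            if self.junction_dinucleotides else None,
            "notes": list(self.notes),
        }


def classify_verdict(annotation: FusionAnnotation, recurrent: bool) -> str:
    """artifact when any artifact flag is set; candidate_driver when the
    fusion is recurrent with a resolvable junction, an in-frame (or
    promoter) coding sequence and a complete kinase domain; else passenger."""
    if annotation.artifact_flags:
        return VERDICT_ARTIFACT
    if (recurrent
            and annotation.junction_class in (JUNCTION_EXON_EXON, JUNCTION_EXON_CRYPTIC)
            and annotation.frame_status in (FRAME_IN, FRAME_PROMOTER)
            and annotation.kinase_domain_status == DOMAIN_COMPLETE):
        return VERDICT_DRIVER
    return VERDICT_PASSENGER


# ---------------------------------------------------------------------------
# motif table + end-to-end annotation
# ---------------------------------------------------------------------------

def load_motif_table(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """User-extensible dimerization-motif intervals: gene, motif_name,
    aa_start, aa_end (1-based inclusive)."""
    out: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.setdefault(row["gene"], []).append(
                (row["motif_name"], int(row["aa_start"]), int(row["aa_end"])))
    return out


def _junction_dinucleotides(candidate: FusionCandidate,
                            genome: Mapping[str, str]) -> Optional[tuple[str, str]]:
    """The two genomic bases just downstream of the donor and just upstream
    of the acceptor, in transcription orientation (reviewer aid for cryptic
    junctions; normally the GT/AG of the spliced-out intron)."""
    if candidate.breakpoint5 is None:
        return None
    try:
        g5, g3 = candidate.gene5, candidate.gene3
        chrom5, chrom3 = genome[g5.chrom], genome[g3.chrom]
        d, a = candidate.breakpoint5, candidate.breakpoint3
        if g5.strand == "+":
            donor_di = chrom5[d + 1:d + 3]
        else:
            donor_di = str(Seq(chrom5[d - 2:d]).reverse_complement())
        if g3.strand == "+":
            acc_di = chrom3[a - 2:a]
        else:
            acc_di = str(Seq(chrom3[a + 1:a + 3]).reverse_complement())
        return donor_di, acc_di
    except (KeyError, IndexError):
        return None


def annotate_candidate(candidate: FusionCandidate,
                       genome: Optional[Mapping[str, str]],
                       expression: Optional[ExpressionMatrix],
                       config: FilterConfig, *,
                       recurrent: bool = True,
                       homologous: bool = False,
                       coils_params: Optional[CoilsParameters] = None,
                       motif_table: Optional[Mapping[str, list]] = None
                       ) -> FusionAnnotation:
    """Run the full annotation rule set on one candidate occurrence."""
    junction = classify_junction(candidate)
    notes: list[str] = []
    ft: Optional[FusionTranscript] = None
    if junction != JUNCTION_UNRESOLVED and genome is not None:
        try:
            ft = build_fusion_transcript(candidate, genome)
        except BreakpointOutsideExon as exc:
            junction = JUNCTION_UNRESOLVED
            notes.append(f"breakpoint_outside_canonical_transcript: {exc}")

    frame_status: Optional[str] = None
    contrib_aa = 0
    if ft is not None:
        frame_status, contrib_aa = predict_frame(ft)

    kinase = candidate.gene3 if candidate.gene3.is_kinase else (
        candidate.gene5 if candidate.gene5.is_kinase else None)
    domain_status: Optional[str] = None
    if ft is not None and kinase is not None:
        domain_status = check_kinase_domain(ft, kinase)

    motifs: list[tuple[str, tuple[int, int], float]] = []
    if ft is not None and contrib_aa > 0:
        peptide = ft.partner_peptide()
        params = coils_params or CoilsParameters.default()
        if len(peptide) >= params.window:
            res = coils_scan(peptide, params)
            for s, e in res.intervals:
                motifs.append(("coiled_coil", (s + 1, e),
                               float(res.probabilities[s:e].max())))
        if motif_table:
            for name, s, e in motif_table.get(candidate.gene5.symbol, []):
                if e <= contrib_aa:
                    motifs.append((name, (s, e), 1.0))

    zscores: dict[str, float] = {}
    if expression is not None:
        for g in (candidate.gene5, candidate.gene3):
            try:
                zscores[g.symbol] = expression.zscore(g.symbol, candidate.sample_id)
            except KeyError:
                pass
    rank3 = None
    if expression is not None and candidate.gene3.symbol in expression.values.index:
        rank3 = expression.rank_in_cohort(candidate.gene3.symbol, candidate.sample_id)

    artifact_flags = flag_artifacts(candidate, junction, expression,
                                    homologous, config)

    ann = FusionAnnotation(
        candidate=candidate, junction_class=junction, frame_status=frame_status,
        kinase_gene=None if kinase is None else kinase.symbol,
        kinase_domain_status=domain_status, partner_contrib_aa=contrib_aa,
        motif_calls=motifs, artifact_flags=artifact_flags,
        zscores=zscores, expression_rank3=rank3,
        junction_dinucleotides=None if genome is None
        else _junction_dinucleotides(candidate, genome),
        notes=tuple(notes))
    ann.verdict = classify_verdict(ann, recurrent)
    return ann.validate()
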