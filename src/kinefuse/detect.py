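"""Per-sample fusion candidate calling.

Evidence records are assigned to genes by exonic overlap, oriented into a
5'->3' gene order by strand concordance, deduplicated per fragment, screened
against partner homology, and finally retained or dropped by tiered
read-support thresholds (chimeric-pair requirements that relax as split-read
support increases).
"""
from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio.Seq import Seq

from .annotation import GeneIndex, GeneModel, interval_overlap
from .config import FilterConfig
from .evidence import ChimericEvidence, Locus

logger = logging.getLogger(__name__)

FLAG_HOMOLOGOUS = "homologous_partners"
FLAG_OVERLAPPING = "overlapping_homologs"
FLAG_BELOW_SUPPORT = "below_support"
FLAG_IMPROBABLE = "improbable_frequency"
FLAG_PROMISCUOUS = "promiscuous_partners"


@dataclass(eq=False)
class FusionCandidate:
    """An ordered 5'/3' gene pair with read support and breakpoints.

    Breakpoints are 0-based genomic coordinates of the junction bases (the
    last transcribed base of the 5' partner, the first of the 3' partner);
    they are present iff at least one admissible split read was seen.
    """

    sample_id: str
    gene5: GeneModel
    gene3: GeneModel
    n_chimeric: int
    n_split: int
    breakpoint5: Optional[int] = None
    breakpoint3: Optional[int] = None
    flags: frozenset[str] = frozenset()
    cohort: Optional[str] = None

    def __post_init__(self) -> None:
        if self.gene5 is self.gene3 or self.gene5.gene_id == self.gene3.gene_id:
            raise ValueError("gene5 and gene3 must differ")
        if self.n_chimeric < 0 or self.n_split < 0:
            raise ValueError("support counts must be >= 0")
        if (self.breakpoint5 is not None) != (self.n_split >= 1):
            raise ValueError("breakpoints present iff split support present")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene5.gene_id, self.gene3.gene_id)

    @property
    def retained(self) -> bool:
        return not self.flags

    def with_flags(self, *extra: str) -> "FusionCandidate":
        return replace(self, flags=self.flags | frozenset(extra))


@dataclass
class DetectionStats:
    n_evidence: int = 0
    n_unassigned: int = 0
    n_ambiguous: int = 0
    n_same_gene: int = 0
    n_strand_discordant: int = 0
    n_split_inadmissible: int = 0


# ---------------------------------------------------------------------------
# locus -> gene assignment
# ---------------------------------------------------------------------------

def _assign(locus: Locus, index: GeneIndex) -> tuple[Optional[GeneModel], str]:
    best: Optional[GeneModel] = None
    best_ov = 0
    tie = False
    for g in index.overlapping(locus.chrom, locus.start, locus.end):
        ov = g.exonic_overlap(locus.start, locus.end)
        if ov == 0:
            continue
        if ov > best_ov:
            best, best_ov, tie = g, ov, False
        elif ov == best_ov:
            tie = True
    if best is None:
        return None, "none"
    if tie:
        return None, "tie"
    return best, "ok"


def assign_locus_to_gene(locus: Locus, index: GeneIndex) -> Optional[GeneModel]:
    """Gene whose exon union overlaps the aligned span most, in nt.

    Returns None for intergenic spans and for exact overlap ties (the latter
    are discarded to avoid double counting).
    """
    gene, _ = _assign(locus, index)
    return gene


# ---------------------------------------------------------------------------
# strand concordance / 5'->3' orientation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientedEvidence:
    gene5: GeneModel
    gene3: GeneModel
    donor: Optional[int]       # junction base on the 5' side
    acceptor: Optional[int]    # junction base on the 3' side
    overhang5: Optional[int]
    overhang3: Optional[int]


def orient_pair(ev: ChimericEvidence, gene_a: GeneModel,
                gene_b: GeneModel) -> Optional[OrientedEvidence]:
    """Order two assigned genes into a 5'->3' fusion, or reject.

    Locus A is the upstream side of the fragment as sequenced.  If the
    fragment represents the sense of the fusion transcript, both aligned
    strands match their gene strands and A is the 5' partner; if it is the
    antisense representation, both mismatch and B is the 5' partner.  Mixed
    configurations (and the degenerate case where both orderings would be
    consistent) are rejected.
    """
    fwd = ev.locus_a.strand == gene_a.strand and ev.locus_b.strand == gene_b.strand
    rev = ev.locus_a.strand != gene_a.strand and ev.locus_b.strand != gene_b.strand
    if fwd == rev:  # neither ordering, or (defensively) both
        return None
    if fwd:
        return OrientedEvidence(gene_a, gene_b, ev.donor_pos, ev.acceptor_pos,
                                ev.overhang_a, ev.overhang_b)
    return OrientedEvidence(gene_b, gene_a, ev.acceptor_pos, ev.donor_pos,
                            ev.overhang_b, ev.overhang_a)


# ---------------------------------------------------------------------------
# partner homology
# ---------------------------------------------------------------------------

def _gene_sequence(gene: GeneModel, genome: Mapping[str, str]) -> Optional[str]:
    if gene.chrom not in genome:
        return None
    chunks = [genome[gene.chrom][s:e] for s, e in gene.exon_union]
    seq = "".join(chunks)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _kmers(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


class HomologyIndex:
    """Cached partner-homology decisions over a gene set.

    Two genes are homologous when the fraction of one gene's distinct k-mers
    found in the other (max over both directions) reaches the configured
    share, or when the unordered symbol pair appears in a user-supplied
    paralog table.
    """

    def __init__(self, genome: Optional[Mapping[str, str]], config: FilterConfig,
                 paralog_pairs: Iterable[tuple[str, str]] = ()):
        self._genome = genome
        self._config = config
        self._paralogs = {frozenset(p) for p in paralog_pairs}
        self._kmer_cache: dict[str, Optional[frozenset[str]]] = {}
        self._pair_cache: dict[frozenset[str], bool] = {}

    def _gene_kmers(self, gene: GeneModel) -> Optional[frozenset[str]]:
        cached = self._kmer_cache.get(gene.gene_id, "missing")
        if cached != "missing":
            return cached
        kmers: Optional[frozenset[str]] = None
        if self._genome is not None:
            seq = _gene_sequence(gene, self._genome)
            if seq is not None and len(seq) >= self._config.homology_kmer:
                kmers = _kmers(seq, self._config.homology_kmer)
        self._kmer_cache[gene.gene_id] = kmers
        return kmers

    def is_homologous(self, gene_a: GeneModel, gene_b: GeneModel) -> bool:
        if frozenset((gene_a.symbol, gene_b.symbol)) in self._paralogs:
            return True
        key = frozenset((gene_a.gene_id, gene_b.gene_id))
        if key in self._pair_cache:
            return self._pair_cache[key]
        ka, kb = self._gene_kmers(gene_a), self._gene_kmers(gene_b)
        if ka is None or kb is None or not ka or not kb:
            warnings.warn(f"no sequence for homology test of "
                          f"{gene_a.symbol}/{gene_b.symbol}; treated as non-homologous")
            result = False
        else:
            shared = len(ka & kb)
            result = max(shared / len(ka), shared / len(kb)) >= self._config.homology_share_frac
        self._pair_cache[key] = result
        return result


def mark_homologous(gene_a: GeneModel, gene_b: GeneModel,
                    sequences: Optional[Mapping[str, str]], config: FilterConfig,
                    paralog_pairs: Iterable[tuple[str, str]] = ()) -> bool:
    """One-shot homology decision (see :class:`HomologyIndex`)."""
    return HomologyIndex(sequences, config, paralog_pairs).is_homologous(gene_a, gene_b)


def load_paralog_table(path: str | Path) -> frozenset[frozenset[str]]:
    pairs = set()
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if len(parts) >= 2 and not line.startswith("#"):
                pairs.add(frozenset(parts[:2]))
    return frozenset(pairs)


# ---------------------------------------------------------------------------
# per-sample detection
# ---------------------------------------------------------------------------

def support_retained(n_split: int, n_chimeric: int, config: FilterConfig) -> bool:
    """Tiered read-support rule: the chimeric-pair requirement relaxes with
    increasing split-read support (>=2 splits, 1 split, 0 splits)."""
    if n_split >= 2:
        return n_chimeric >= config.min_chimeric_2split
    if n_split == 1:
        return n_chimeric >= config.min_chimeric_1split
    return n_chimeric >= config.min_chimeric_0split


def _modal_junction(splits: list[OrientedEvidence]) -> tuple[int, int]:
    counts: Counter[tuple[int, int]] = Counter()
    overhang_total: Counter[tuple[int, int]] = Counter()
    for o in splits:
        j = (o.donor, o.acceptor)
        counts[j] += 1
        overhang_total[j] += (o.overhang5 or 0) + (o.overhang3 or 0)
    best = max(counts.values())
    top = [j for j, c in counts.items() if c == best]
    best_oh = max(overhang_total[j] for j in top)
    top = [j for j in top if overhang_total[j] == best_oh]
    return min(top)  # smallest genomic coordinate pair


def detect_sample(evidence: Iterable[ChimericEvidence], index: GeneIndex,
                  config: FilterConfig,
                  homology: Optional[HomologyIndex] = None, *,
                  include_filtered: bool = False,
                  stats: Optional[DetectionStats] = None) -> list[FusionCandidate]:
    """Call fusion candidates from one sample's chimeric evidence.

    A split read counts toward split support only when both overhangs reach
    ``config.min_overhang``.  Each ``read_id`` contributes at most once per
    ordered gene pair, with the split representation outranking the pair
    representation.  Pairs of homologous (or genomically overlapping
    homologous) genes are flagged and excluded from the retained set, as are
    pairs below the tiered support thresholds.

    With ``include_filtered=True`` the flagged candidates are returned too.
    """
    config.validate()
    stats = stats if stats is not None else DetectionStats()
    sample_id: Optional[str] = None
    per_pair: dict[tuple[str, str], dict[str, tuple[str, OrientedEvidence]]] = {}
    gene_by_id: dict[str, GeneModel] = {}

    for ev in evidence:
        stats.n_evidence += 1
        if sample_id is None:
            sample_id = ev.sample_id
        elif ev.sample_id != sample_id:
            raise ValueError(f"evidence from mixed samples: {sample_id!r} "
                             f"and {ev.sample_id!r}")
        ga, ra = _assign(ev.locus_a, index)
        gb, rb = _assign(ev.locus_b, index)
        if ra == "tie" or rb == "tie":
            stats.n_ambiguous += 1
            continue
        if ga is None or gb is None:
            stats.n_unassigned += 1
            continue
        if ga.gene_id == gb.gene_id:
            stats.n_same_gene += 1
            continue
        oriented = orient_pair(ev, ga, gb)
        if oriented is None:
            stats.n_strand_discordant += 1
            continue
        key = (oriented.gene5.gene_id, oriented.gene3.gene_id)
        gene_by_id[key[0]] = oriented.gene5
        gene_by_id[key[1]] = oriented.gene3
        reads = per_pair.setdefault(key, {})
        # split outranks pair for the same fragment
        if ev.kind == "split" or ev.read_id not in reads:
            reads[ev.read_id] = (ev.kind, oriented)

    candidates: list[FusionCandidate] = []
    for key in sorted(per_pair):
        reads = per_pair[key]
        splits = [o for kind, o in reads.values() if kind == "split"]
        admissible = [o for o in splits
                      if (o.overhang5 or 0) >= config.min_overhang
                      and (o.overhang3 or 0) >= config.min_overhang]
        stats.n_split_inadmissible += len(splits) - len(admissible)
        n_split = len(admissible)
        n_chimeric = sum(1 for kind, _ in reads.values() if kind == "pair")
        gene5, gene3 = gene_by_id[key[0]], gene_by_id[key[1]]

        flags: set[str] = set()
        if homology is not None and homology.is_homologous(gene5, gene3):
            flags.add(FLAG_HOMOLOGOUS)
            if (gene5.chrom == gene3.chrom
                    and interval_overlap((gene5.start, gene5.end),
                                         (gene3.start, gene3.end)) > 0):
                flags.add(FLAG_OVERLAPPING)
        if not support_retained(n_split, n_chimeric, config):
            flags.add(FLAG_BELOW_SUPPORT)

        bp5 = bp3 = None
        if n_split:
            bp5, bp3 = _modal_junction(admissible)
        cand = FusionCandidate(sample_id=sample_id or "", gene5=gene5,
                               gene3=gene3, n_chimeric=n_chimeric,
                               n_split=n_split, breakpoint5=bp5,
                               breakpoint3=bp3, flags=frozenset(flags))
        if cand.retained or include_filtered:
            candidates.append(cand)
    return candidates


# ---------------------------------------------------------------------------
# candidate I/O (TSV + BEDPE)
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = ("sample_id", "gene5", "gene3", "symbol5", "symbol3",
                     "n_chimeric", "n_split", "breakpoint5", "breakpoint3",
                     "flags")


def write_candidates_tsv(path: str | Path,
                         candidates: Iterable[FusionCandidate]) -> None:
    """Write candidates as TSV (breakpoints 1-based, '.' when absent)."""
    with open(path, "w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for c in sorted(candidates, key=lambda c: (c.sample_id, c.pair)):
            fh.write("\t".join([
                c.sample_id, c.gene5.gene_id, c.gene3.gene_id,
                c.gene5.symbol, c.gene3.symbol,
                str(c.n_chimeric), str(c.n_split),
                "." if c.breakpoint5 is None else str(c.breakpoint5 + 1),
                "." if c.breakpoint3 is None else str(c.breakpoint3 + 1),
                ",".join(sorted(c.flags)) or ".",
            ]) + "\n")


def read_candidates_tsv(path: str | Path, index: GeneIndex) -> list[FusionCandidate]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != CANDIDATE_COLUMNS:
            bad = next((c for c in header if c not in CANDIDATE_COLUMNS), "?")
            raise ValueError(f"{path}: unexpected candidate column {bad!r}")
        for line in fh:
            p = line.rstrip("\n").split("\t")
            if len(p) != len(CANDIDATE_COLUMNS):
                raise ValueError(f"{path}: malformed candidate row")
            out.append(FusionCandidate(
                sample_id=p[0], gene5=index.get(p[1]), gene3=index.get(p[2]),
                n_chimeric=int(p[5]), n_split=int(p[6]),
                breakpoint5=None if p[7] == "." else int(p[7]) - 1,
                breakpoint3=None if p[8] == "." else int(p[8]) - 1,
                flags=frozenset() if p[9] == "." else frozenset(p[9].split(","))))
    return out


def write_bedpe(path: str | Path, candidates: Iterable[FusionCandidate]) -> None:
    """Write split-supported breakpoints as BEDPE (0-based half-open)."""
    with open(path, "w") as fh:
        for c in sorted(candidates, key=lambda c: (c.sample_id, c.pair)):
            if c.breakpoint5 is None:
                continue
            fh.write("\t".join([
                c.gene5.chrom, str(c.breakpoint5), str(c.breakpoint5 + 1),
                c.gene3.chrom, str(c.breakpoint3), str(c.breakpoint3 + 1),
                f"{c.gene5.symbol}--{c.gene3.symbol}", str(c.n_split),
                c.gene5.strand, c.gene3.strand,
            ]) + "\n")
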