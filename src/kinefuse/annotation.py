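"""Gene annotation, sequences, kinase registry and expression input.

Coordinates are 0-based half-open internally; GTF I/O uses the format's
native 1-based inclusive convention.  Exons of a transcript are kept in
transcription order (genomically descending for minus-strand genes) so that
transcript coordinates always run 5'->3'.
"""
from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Gene annotation violates a structural invariant."""


class GTFParseError(AnnotationError):
    """A GTF line could not be parsed."""


def merge_intervals(ivs: Iterable[Interval]) -> tuple[Interval, ...]:
    """Merge possibly overlapping intervals into a sorted disjoint set."""
    ivs = sorted(ivs)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return tuple((s, e) for s, e in out)


def interval_overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


@dataclass(frozen=True)
class Transcript:
    """One transcript: exons (and optional CDS) in transcription order."""

    tx_id: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.tx_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.tx_id}: transcript has no exons")
        ordered = sorted(self.exons, reverse=self.strand == "-")
        if tuple(ordered) != self.exons:
            raise AnnotationError(f"{self.tx_id}: exons not in transcription order")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise AnnotationError(f"{self.tx_id}: overlapping exons")
        union = merge_intervals(self.exons)
        for c in self.cds:
            if not any(s <= c[0] and c[1] <= e for s, e in union):
                raise AnnotationError(f"{self.tx_id}: CDS segment {c} outside exons")

    # -- lengths -----------------------------------------------------------
    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    # -- coordinate maps ---------------------------------------------------
    def to_tpos(self, gpos: int) -> Optional[int]:
        """Transcript coordinate (0-based, 5'->3') of a genomic base.

        Returns None when the base is not exonic in this transcript.
        """
        off = 0
        for s, e in self.exons:
            if s <= gpos < e:
                return off + (gpos - s if self.strand == "+" else e - 1 - gpos)
            off += e - s
        return None

    def tpos_to_genomic(self, tpos: int) -> int:
        if tpos < 0:
            raise IndexError(tpos)
        off = 0
        for s, e in self.exons:
            n = e - s
            if tpos < off + n:
                d = tpos - off
                return s + d if self.strand == "+" else e - 1 - d
            off += n
        raise IndexError(f"{self.tx_id}: transcript position {tpos} out of range")

    @cached_property
    def cds_tspan(self) -> Optional[tuple[int, int]]:
        """CDS as a half-open interval in transcript coordinates."""
        if not self.cds:
            return None
        first = self.cds[0][0] if self.strand == "+" else self.cds[0][1] - 1
        last = self.cds[-1][1] - 1 if self.strand == "+" else self.cds[-1][0]
        t0, t1 = self.to_tpos(first), self.to_tpos(last)
        assert t0 is not None and t1 is not None
        return t0, t1 + 1

    # -- derived UTRs ------------------------------------------------------
    def _utr(self, five: bool) -> tuple[Interval, ...]:
        span = self.cds_tspan
        if span is None:
            return ()
        lo, hi = (0, span[0]) if five else (span[1], self.exonic_length)
        if lo >= hi:
            return ()
        pieces = []
        off = 0
        for s, e in self.exons:
            n = e - s
            a, b = max(lo, off), min(hi, off + n)
            if a < b:
                if self.strand == "+":
                    pieces.append((s + (a - off), s + (b - off)))
                else:
                    pieces.append((e - (b - off), e - (a - off)))
            off += n
        return tuple(sorted(pieces))

    @property
    def utr5(self) -> tuple[Interval, ...]:
        return self._utr(True)

    @property
    def utr3(self) -> tuple[Interval, ...]:
        return self._utr(False)

    def spliced(self, genome: Mapping[str, str], chrom: str) -> str:
        """mRNA-sense spliced sequence of this transcript."""
        chunks = []
        for s, e in self.exons:
            seg = genome[chrom][s:e]
            chunks.append(seg if self.strand == "+" else str(Seq(seg).reverse_complement()))
        return "".join(chunks)


@dataclass(eq=False)
class GeneModel:
    """A gene with its transcripts and optional kinase-domain annotation.

    ``kinase_domain`` is a 1-based inclusive amino-acid interval on the
    protein of the canonical transcript.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: tuple[Transcript, ...] = ()
    is_kinase: bool = False
    kinase_domain: Optional[tuple[int, int]] = None
    kinase_domain_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        for tx in self.transcripts:
            for s, e in tx.exons:
                if s < self.start or e > self.end:
                    raise AnnotationError(
                        f"{self.gene_id}: exon ({s}, {e}) of {tx.tx_id} "
                        f"outside gene span ({self.start}, {self.end})")
            if tx.strand != self.strand:
                raise AnnotationError(f"{self.gene_id}: strand mismatch for {tx.tx_id}")

    @cached_property
    def exon_union(self) -> tuple[Interval, ...]:
        return merge_intervals(iv for tx in self.transcripts for iv in tx.exons)

    @cached_property
    def canonical(self) -> Transcript:
        """Canonical transcript: longest CDS, ties broken by tx_id."""
        if not self.transcripts:
            raise AnnotationError(f"{self.gene_id}: no transcripts")
        return min(self.transcripts,
                   key=lambda t: (-t.cds_length, -t.exonic_length, t.tx_id))

    def exonic_overlap(self, start: int, end: int) -> int:
        return sum(interval_overlap((start, end), iv) for iv in self.exon_union)

    def protein_length(self) -> Optional[int]:
        """Length in aa of the canonical protein (terminal stop excluded)."""
        tx = self.canonical
        if not tx.cds:
            return None
        n = tx.cds_length // 3
        return n - 1 if tx.cds_length % 3 == 0 else n

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GeneModel({self.symbol}:{self.chrom}:{self.start}-{self.end}{self.strand})"


class GeneIndex:
    """Indexed gene set supporting point and interval queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes = sorted(genes, key=lambda g: g.gene_id)
        self._by_id = {}
        self._by_symbol: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in self._genes:
            if g.gene_id in self._by_id:
                raise AnnotationError(f"duplicate gene_id {g.gene_id}")
            self._by_id[g.gene_id] = g
            self._by_symbol.setdefault(g.symbol, g)
            if g.end > g.start:
                self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes)

    def __len__(self) -> int:
        return len(self._genes)

    @property
    def genes(self) -> list[GeneModel]:
        return list(self._genes)

    def get(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def get_symbol(self, symbol: str) -> Optional[GeneModel]:
        return self._by_symbol.get(symbol)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda g: g.gene_id)

    def at(self, chrom: str, pos: int) -> list[GeneModel]:
        return self.overlapping(chrom, pos, pos + 1)


# ---------------------------------------------------------------------------
# GTF + registry loading
# ---------------------------------------------------------------------------

def _prevalidate_gtf(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise GTFParseError(f"{path}: line {lineno}: expected 9 tab-separated "
                                    f"fields, found {len(parts)}")
            try:
                s, e = int(parts[3]), int(parts[4])
            except ValueError:
                raise GTFParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            if s < 1 or e < s:
                raise GTFParseError(f"{path}: line {lineno}: bad coordinate range {s}-{e}")
            if parts[6] not in "+-":
                raise GTFParseError(f"{path}: line {lineno}: bad strand {parts[6]!r}")


def load_annotation(path: str | Path,
                    kinase_registry: str | Path | None = None) -> GeneIndex:
    """Load a Gencode-style GTF (and optional kinase registry) into a GeneIndex.

    The registry is a TSV with columns ``symbol``, ``domain_start_aa``,
    ``domain_end_aa``, ``domain_name``; listed genes are marked as kinases.
    Registry genes absent from the GTF are skipped with a warning.
    """
    path = Path(path)
    _prevalidate_gtf(path)
    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            disable_infer_genes=True, disable_infer_transcripts=True)

    tx_gene: dict[str, str] = {}
    tx_strand: dict[str, str] = {}
    for f in db.features_of_type("transcript"):
        tx_id = f.attributes["transcript_id"][0]
        tx_gene[tx_id] = f.attributes["gene_id"][0]
        tx_strand[tx_id] = f.strand

    exons_by_tx: dict[str, list[Interval]] = {}
    cds_by_tx: dict[str, list[Interval]] = {}
    for ftype, store in (("exon", exons_by_tx), ("CDS", cds_by_tx)):
        for f in db.features_of_type(ftype):
            tx_id = f.attributes["transcript_id"][0]
            store.setdefault(tx_id, []).append((f.start - 1, f.end))

    genes: list[GeneModel] = []
    for f in db.features_of_type("gene"):
        gid = f.attributes["gene_id"][0]
        symbol = f.attributes.get("gene_name", [gid])[0]
        txs = []
        for tx_id, g in tx_gene.items():
            if g != gid:
                continue
            rev = tx_strand[tx_id] == "-"
            exons = tuple(sorted(exons_by_tx.get(tx_id, []), reverse=rev))
            cds = tuple(sorted(cds_by_tx.get(tx_id, []), reverse=rev))
            txs.append(Transcript(tx_id=tx_id, strand=tx_strand[tx_id],
                                  exons=exons, cds=cds))
        txs.sort(key=lambda t: t.tx_id)
        genes.append(GeneModel(gene_id=gid, symbol=symbol, chrom=f.seqid,
                               strand=f.strand, start=f.start - 1, end=f.end,
                               transcripts=tuple(txs)))
    index = GeneIndex(genes)
    if kinase_registry is not None:
        _apply_registry(index, Path(kinase_registry))
    return index


def _apply_registry(index: GeneIndex, path: Path) -> None:
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"symbol", "domain_start_aa", "domain_end_aa"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise AnnotationError(
                f"{path}: kinase registry must have columns {sorted(required)}")
        for row in reader:
            gene = index.get_symbol(row["symbol"])
            if gene is None:
                warnings.warn(f"kinase registry gene {row['symbol']!r} absent "
                              f"from annotation; skipped")
                continue
            s, e = int(row["domain_start_aa"]), int(row["domain_end_aa"])
            if s < 1 or e < s:
                raise AnnotationError(f"{path}: bad domain interval {s}-{e} "
                                      f"for {row['symbol']}")
            gene.is_kinase = True
            gene.kinase_domain = (s, e)
            gene.kinase_domain_name = row.get("domain_name") or None


def load_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA of chromosome (or contig) sequences as plain strings."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of FPKM-like values with per-sample cohort labels."""

    values: pd.DataFrame
    cohorts: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression matrix contains negative values")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicated gene id in expression matrix: {dup!r}")
        missing = [s for s in self.values.columns if s not in self.cohorts.index]
        if missing:
            raise ValueError(f"samples without a cohort label: {missing}")
        self.cohorts = self.cohorts.loc[list(self.values.columns)]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def cohort_samples(self, cohort: str) -> list[str]:
        return [s for s in self.values.columns if self.cohorts[s] == cohort]

    def zscore(self, gene: str, sample: str) -> float:
        """Within-cohort z-score, unbiased (n-1) standard deviation."""
        if gene not in self.values.index:
            raise KeyError(gene)
        cohort = self.cohorts[sample]
        samples = self.cohort_samples(cohort)
        if len(samples) < 3:
            raise ValueError(f"cohort {cohort!r} has fewer than 3 samples")
        vals = self.values.loc[gene, samples].astype(float)
        sd = float(vals.std(ddof=1))
        if sd == 0.0:
            warnings.warn(f"zero variance for {gene} in cohort {cohort}; z set to 0")
            return 0.0
        return float((vals[sample] - vals.mean()) / sd)

    def rank_in_cohort(self, gene: str, sample: str) -> int:
        """Rank (1 = highest) of the sample's value among its cohort."""
        samples = self.cohort_samples(self.cohorts[sample])
        vals = self.values.loc[gene, samples].astype(float)
        return int((vals > vals[sample]).sum()) + 1

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


def load_expression(path: str | Path, sample_sheet: str | Path) -> ExpressionMatrix:
    """Load an expression TSV (gene rows x sample columns) plus sample sheet.

    The sample sheet is a TSV with at least ``sample_id`` and ``cohort``
    columns; extra columns are ignored here.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet, sep="\t", dtype=str)
    if not {"sample_id", "cohort"} <= set(sheet.columns):
        raise ValueError(f"{sample_sheet}: sample sheet needs sample_id and cohort columns")
    cohorts = sheet.set_index("sample_id")["cohort"]
    if cohorts.isna().any():
        raise ValueError(f"{sample_sheet}: every sample needs a cohort label")
    return ExpressionMatrix(values=values.astype(float), cohorts=cohorts)
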