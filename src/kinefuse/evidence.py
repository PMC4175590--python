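"""Ingest of per-sample chimeric-evidence files.

The evidence dialect is a plain TSV that models the chimeric output of a
spliced aligner at the fragment level.  Each record links two genomic loci
and is either a chimeric read pair (``pair``: the two sequencing ends map to
different loci) or a split read (``split``: one read spans the fusion
junction, with an alignment overhang on each side).

Column order (positions are 1-based in the file, 0-based in memory)::

    sample_id read_id kind chromA posA strandA spanA chromB posB strandB
    spanB donor_pos acceptor_pos overhangA overhangB

The last four columns are empty for ``pair`` records.  Locus A is the
upstream side of the fragment as sequenced; a fragment representing the
antisense of the fusion transcript simply carries flipped strands.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

EVIDENCE_COLUMNS = (
    "sample_id", "read_id", "kind", "chromA", "posA", "strandA", "spanA",
    "chromB", "posB", "strandB", "spanB",
    "donor_pos", "acceptor_pos", "overhangA", "overhangB",
)


class EvidenceParseError(ValueError):
    """The evidence file does not match the documented dialect."""


@dataclass(frozen=True)
class Locus:
    """One aligned segment: half-open interval [start, start+span) on chrom."""

    chrom: str
    start: int
    strand: str
    span: int

    @property
    def end(self) -> int:
        return self.start + self.span


@dataclass(frozen=True)
class ChimericEvidence:
    """A single read-level observation linking two genomic loci."""

    sample_id: str
    read_id: str
    kind: str  # "pair" | "split"
    locus_a: Locus
    locus_b: Locus
    donor_pos: Optional[int] = None      # junction base on the A side (0-based)
    acceptor_pos: Optional[int] = None   # junction base on the B side (0-based)
    overhang_a: Optional[int] = None
    overhang_b: Optional[int] = None


@dataclass
class IngestStats:
    n_lines: int = 0
    n_emitted: int = 0
    n_rejected: int = 0


def _parse_line(parts: list[str], sample_id: Optional[str]) -> ChimericEvidence:
    if len(parts) != len(EVIDENCE_COLUMNS):
        raise EvidenceParseError(
            f"expected {len(EVIDENCE_COLUMNS)} columns, found {len(parts)}")
    rec_sample, read_id, kind = parts[0], parts[1], parts[2]
    if kind not in ("pair", "split"):
        raise EvidenceParseError(f"unknown kind token {kind!r}")
    if sample_id is not None and rec_sample != sample_id:
        raise EvidenceParseError(
            f"record sample_id {rec_sample!r} does not match expected {sample_id!r}")
    locus_a = Locus(parts[3], int(parts[4]) - 1, parts[5], int(parts[6]))
    locus_b = Locus(parts[7], int(parts[8]) - 1, parts[9], int(parts[10]))
    for loc in (locus_a, locus_b):
        if loc.strand not in "+-" or loc.span < 1 or loc.start < 0:
            raise ValueError("bad locus")
    donor = acceptor = oh_a = oh_b = None
    if kind == "split":
        if any(p == "" for p in parts[11:15]):
            raise ValueError("split record missing junction fields")
        donor, acceptor = int(parts[11]) - 1, int(parts[12]) - 1
        oh_a, oh_b = int(parts[13]), int(parts[14])
        if oh_a < 1 or oh_b < 1:
            raise ValueError("split overhangs must be >= 1")
    # the two loci must be distinguishable observations
    if (locus_a.chrom == locus_b.chrom and locus_a.strand == locus_b.strand
            and locus_a.start == locus_b.start):
        raise ValueError("identical loci")
    return ChimericEvidence(rec_sample, read_id, kind, locus_a, locus_b,
                            donor, acceptor, oh_a, oh_b)


def read_evidence(path: str | Path, sample_id: Optional[str] = None,
                  stats: Optional[IngestStats] = None) -> list[ChimericEvidence]:
    """Parse an evidence TSV into ChimericEvidence records.

    Records failing structural invariants (missing junction fields, zero
    overhangs, identical loci) are dropped and counted in ``stats``; an
    unknown ``kind`` token or a schema mismatch raises
    :class:`EvidenceParseError`.
    """
    stats = stats if stats is not None else IngestStats()
    out: list[ChimericEvidence] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header:
            cols = tuple(header.split("\t"))
            if cols != EVIDENCE_COLUMNS:
                bad = next((c for c, e in zip(cols, EVIDENCE_COLUMNS) if c != e),
                           cols[len(EVIDENCE_COLUMNS):][0] if len(cols) > len(EVIDENCE_COLUMNS) else "?")
                raise EvidenceParseError(
                    f"{path}: unexpected evidence column {bad!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            stats.n_lines += 1
            try:
                out.append(_parse_line(line.split("\t"), sample_id))
                stats.n_emitted += 1
            except EvidenceParseError:
                raise
            except ValueError:
                stats.n_rejected += 1
    if stats.n_rejected:
        logger.info("%s: rejected %d of %d evidence records",
                    path, stats.n_rejected, stats.n_lines)
    return out


def write_evidence(path: str | Path, records: Iterable[ChimericEvidence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EVIDENCE_COLUMNS) + "\n")
        for r in records:
            row = [
                r.sample_id, r.read_id, r.kind,
                r.locus_a.chrom, str(r.locus_a.start + 1), r.locus_a.strand,
                str(r.locus_a.span),
                r.locus_b.chrom, str(r.locus_b.start + 1), r.locus_b.strand,
                str(r.locus_b.span),
                "" if r.donor_pos is None else str(r.donor_pos + 1),
                "" if r.acceptor_pos is None else str(r.acceptor_pos + 1),
                "" if r.overhang_a is None else str(r.overhang_a),
                "" if r.overhang_b is None else str(r.overhang_b),
            ]
            fh.write("\t".join(row) + "\n")
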