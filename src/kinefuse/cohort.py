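"""Cohort-level false-positive removal and recurrence selection.

Three successive screens operate across samples: the improbable-frequency
flags (a pair called in almost every sample of a cancer type, or a pair of
mutually promiscuous partners), removal of pairs seen in a panel of normal
samples, and finally selection of kinase fusions that recur in at least
``recurrence_min`` tumour samples pooled over all cancer types.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .annotation import GeneIndex
from .config import FilterConfig
from .detect import (FLAG_IMPROBABLE, FLAG_PROMISCUOUS, FusionCandidate,
                     HomologyIndex, detect_sample)
from .evidence import read_evidence

logger = logging.getLogger(__name__)

PairKey = tuple[str, str]


@dataclass
class CohortCallSet:
    """Fusion candidates of one tumour-type cohort across its samples."""

    cohort_id: str
    n_samples: int
    candidates: list[FusionCandidate]

    def __post_init__(self) -> None:
        if self.n_samples < len({c.sample_id for c in self.candidates}):
            raise ValueError(f"{self.cohort_id}: n_samples smaller than number "
                             f"of distinct sample ids in call set")


def _pair_samples(candidates: Iterable[FusionCandidate]) -> dict[PairKey, set[str]]:
    out: dict[PairKey, set[str]] = defaultdict(set)
    for c in candidates:
        out[c.pair].add(c.sample_id)
    return out


def flag_improbable(callset: CohortCallSet, config: FilterConfig) -> CohortCallSet:
    """Flag pairs at improbable within-cohort frequencies.

    A pair present in strictly more than ``improbable_prevalence`` of the
    cohort's samples is flagged; a pair in which *each* partner participates
    in >=2 distinct fusion pairs and is itself fused in strictly more than
    ``promiscuity_prevalence`` of samples is flagged as promiscuous.
    Multiple breakpoints of the same pair within a sample count once.
    """
    n = callset.n_samples
    if n == 0 or not callset.candidates:
        return callset
    pair_samples = _pair_samples(callset.candidates)
    gene_pairs: dict[str, set[PairKey]] = defaultdict(set)
    gene_samples: dict[str, set[str]] = defaultdict(set)
    for c in callset.candidates:
        for gid in c.pair:
            gene_pairs[gid].add(c.pair)
            gene_samples[gid].add(c.sample_id)

    def promiscuous(gid: str) -> bool:
        return (len(gene_pairs[gid]) >= 2
                and len(gene_samples[gid]) > config.promiscuity_prevalence * n)

    flagged: list[FusionCandidate] = []
    for c in callset.candidates:
        extra = []
        if len(pair_samples[c.pair]) > config.improbable_prevalence * n:
            extra.append(FLAG_IMPROBABLE)
        if promiscuous(c.pair[0]) and promiscuous(c.pair[1]):
            extra.append(FLAG_PROMISCUOUS)
        flagged.append(c.with_flags(*extra) if extra else c)
    return CohortCallSet(callset.cohort_id, n, flagged)


# ---------------------------------------------------------------------------
# panel of normals
# ---------------------------------------------------------------------------

@dataclass
class NormalsPanel:
    """Per-gene-pair count of distinct normal samples carrying the fusion."""

    counts: dict[PairKey, int]

    def __post_init__(self) -> None:
        bad = [k for k, v in self.counts.items() if v < 1]
        if bad:
            raise ValueError(f"panel counts must be >= 1, offending keys: {bad[:3]}")

    def count(self, pair: PairKey) -> int:
        return self.counts.get(pair, 0)

    @classmethod
    def from_evidence_files(cls, paths: Sequence[str | Path], index: GeneIndex,
                            config: FilterConfig,
                            homology: Optional[HomologyIndex] = None) -> "NormalsPanel":
        """Build a panel by running the identical detection procedure on each
        normal sample's evidence file."""
        counts: dict[PairKey, int] = defaultdict(int)
        for path in sorted(str(p) for p in paths):
            records = read_evidence(path)
            pairs = {c.pair for c in detect_sample(records, index, config, homology)}
            for pair in pairs:
                counts[pair] += 1
        return cls(dict(counts))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NormalsPanel":
        counts: dict[PairKey, int] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["gene5", "gene3", "n_normal_samples"]:
                raise ValueError(f"{path}: expected columns gene5, gene3, "
                                 f"n_normal_samples")
            for line in fh:
                g5, g3, n = line.rstrip("\n").split("\t")
                counts[(g5, g3)] = int(n)
        return cls(counts)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene5\tgene3\tn_normal_samples\n")
            for (g5, g3), n in sorted(self.counts.items()):
                fh.write(f"{g5}\t{g3}\t{n}\n")


def apply_normals_panel(callset: CohortCallSet, panel: NormalsPanel,
                        config: FilterConfig) -> CohortCallSet:
    """Remove candidates whose gene pair was detected in at least
    ``normals_min_samples`` normal samples."""
    kept = [c for c in callset.candidates
            if panel.count(c.pair) < config.normals_min_samples]
    n_removed = len(callset.candidates) - len(kept)
    if n_removed:
        logger.info("%s: removed %d candidates via panel of normals",
                    callset.cohort_id, n_removed)
    return CohortCallSet(callset.cohort_id, callset.n_samples, kept)


# ---------------------------------------------------------------------------
# recurrence across cohorts
# ---------------------------------------------------------------------------

def select_recurrent_kinase(callsets: Sequence[CohortCallSet],
                            config: FilterConfig,
                            mode: str = "kinase") -> list[FusionCandidate]:
    """Keep kinase fusions recurring in >= ``recurrence_min`` tumour samples
    pooled across all cohorts.

    ``mode='kinase'`` (default) counts distinct samples per kinase gene
    across all of its partners; ``mode='pair'`` counts per ordered gene pair.
    Flagged candidates are excluded from both counting and output.
    """
    if mode not in ("kinase", "pair"):
        raise ValueError(f"unknown recurrence mode {mode!r}")
    eligible: list[tuple[str, FusionCandidate]] = [
        (cs.cohort_id, c) for cs in callsets for c in cs.candidates
        if c.retained and (c.gene5.is_kinase or c.gene3.is_kinase)]

    samples_by_key: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for cohort, c in eligible:
        occurrence = (cohort, c.sample_id)
        if mode == "pair":
            samples_by_key["|".join(c.pair)].add(occurrence)
        else:
            for g in (c.gene5, c.gene3):
                if g.is_kinase:
                    samples_by_key[g.gene_id].add(occurrence)

    out: list[FusionCandidate] = []
    for cohort, c in eligible:
        if mode == "pair":
            n = len(samples_by_key["|".join(c.pair)])
            recurrent = n >= config.recurrence_min
        else:
            recurrent = any(len(samples_by_key[g.gene_id]) >= config.recurrence_min
                            for g in (c.gene5, c.gene3) if g.is_kinase)
        if recurrent:
            out.append(replace(c, cohort=cohort))
    out.sort(key=lambda c: (c.cohort or "", c.sample_id, c.pair))
    return out


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def cohort_summary(callsets: Sequence[CohortCallSet],
                   recurrent: Optional[Sequence[FusionCandidate]] = None,
                   categories: Optional[dict[PairKey, str]] = None) -> pd.DataFrame:
    """Per-cohort statistics: kinase fusions per sample, percentage of samples
    with a recurrent kinase fusion, and optional novelty-category counts."""
    rows = []
    recurrent = recurrent or []
    for cs in sorted(callsets, key=lambda c: c.cohort_id):
        retained = [c for c in cs.candidates if c.retained]
        kinase = [c for c in retained if c.gene5.is_kinase or c.gene3.is_kinase]
        rec_samples = {c.sample_id for c in recurrent if c.cohort == cs.cohort_id}
        n = cs.n_samples
        row = {
            "cohort": cs.cohort_id,
            "n_samples": n,
            "n_fusions": len(retained),
            "n_kinase_fusions": len(kinase),
            "fusions_per_sample": len(retained) / n if n else 0.0,
            "kinase_fusions_per_sample": len(kinase) / n if n else 0.0,
            "pct_samples_recurrent_kinase": 100.0 * len(rec_samples) / n if n else 0.0,
        }
        if categories is not None:
            cat_counts: dict[str, int] = defaultdict(int)
            for c in retained:
                cat_counts[categories.get(c.pair, "uncategorized")] += 1
            for cat in sorted(cat_counts):
                row[f"n_{cat}"] = cat_counts[cat]
        rows.append(row)
    return pd.DataFrame(rows)
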