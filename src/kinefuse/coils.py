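"""Sliding-window coiled-coil prediction.

A window of ``window`` residues is scored at each of the seven possible
heptad registers; the window score is the geometric mean of the per-position
propensities at the best register.  Each residue inherits the maximum score
over the windows covering it, and the score is turned into a coiled-coil
probability through the ratio of two Gaussian densities fitted to the score
distributions of coiled-coil and globular sequences, weighted by a prior
odds of globular over coiled-coil residues.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

HEPTAD = "abcdefg"


@dataclass
class CoilsParameters:
    """Window size, propensity table and score statistics for the scanner.

    ``score_stats`` holds ``(mean, sd)`` for the coiled-coil and globular
    score distributions; ``prior_ratio`` is the assumed excess of globular
    over coiled-coil residues entering the probability ratio.
    """

    window: int = 28
    propensity_table: dict[str, tuple[float, ...]] = field(default_factory=dict)
    score_stats: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "coiled_coil": (1.63, 0.24),
        "globular": (0.77, 0.20),
    })
    prior_ratio: float = 30.0

    def __post_init__(self) -> None:
        if self.window < 7:
            raise ValueError("window must be at least one heptad")
        for res, row in self.propensity_table.items():
            if len(row) != 7:
                raise ValueError(f"propensities for {res!r} must have 7 positions")
            if any(p <= 0 for p in row):
                raise ValueError(f"propensities must be > 0 ({res!r})")

    @classmethod
    def default(cls, window: int = 28) -> "CoilsParameters":
        return cls(window=window, propensity_table=load_propensity_table())


def load_propensity_table(path: str | Path | None = None) -> dict[str, tuple[float, ...]]:
    """Load a residue -> per-heptad-position propensity table from TSV."""
    if path is None:
        source = resources.files("kinefuse.data").joinpath("coils_mtk.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, tuple[float, ...]] = {}
    rows = [r for r in text.splitlines() if r and not r.startswith("#")]
    reader = csv.reader(rows, delimiter="\t")
    header = next(reader)
    if header[:1] != ["residue"]:
        raise ValueError("propensity table must start with a 'residue' column")
    for row in reader:
        table[row[0]] = tuple(float(x) for x in row[1:8])
    return table


@dataclass
class CoilsResult:
    scores: np.ndarray         # per-residue best window score
    probabilities: np.ndarray  # per-residue coiled-coil probability
    intervals: list[tuple[int, int]]  # maximal runs with p >= 0.5, 0-based half-open

    @property
    def max_probability(self) -> float:
        return float(self.probabilities.max()) if len(self.probabilities) else 0.0


def _gauss(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mean) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))


def coils_scan(sequence: str, params: Optional[CoilsParameters] = None) -> CoilsResult:
    """Scan a protein sequence for coiled-coil segments.

    Sequences shorter than the window yield all-zero probabilities.  Unknown
    residues score a neutral propensity of 1.
    """
    params = params or CoilsParameters.default()
    n = len(sequence)
    table = params.propensity_table
    if n < params.window:
        empty = np.zeros(n)
        return CoilsResult(scores=empty, probabilities=empty, intervals=[])

    # log-propensity matrix: residue i x heptad position
    logp = np.zeros((n, 7))
    for i, res in enumerate(sequence):
        row = table.get(res.upper())
        logp[i] = np.log(row) if row is not None else 0.0

    w = params.window
    scores = np.zeros(n)
    for start in range(n - w + 1):
        best = -math.inf
        for register in range(7):
            idx = (np.arange(start, start + w) + register) % 7
            s = logp[np.arange(start, start + w), idx].mean()
            if s > best:
                best = s
        wscore = math.exp(best)
        seg = scores[start:start + w]
        np.maximum(seg, wscore, out=seg)

    ccm, ccs = params.score_stats["coiled_coil"]
    gm, gs = params.score_stats["globular"]
    gcc = _gauss(scores, ccm, ccs)
    gg = _gauss(scores, gm, gs)
    probs = gcc / (gcc + params.prior_ratio * gg)

    intervals: list[tuple[int, int]] = []
    run_start: Optional[int] = None
    for i, p in enumerate(probs):
        if p >= 0.5 and run_start is None:
            run_start = i
        elif p < 0.5 and run_start is not None:
            intervals.append((run_start, i))
            run_start = None
    if run_start is not None:
        intervals.append((run_start, n))
    return CoilsResult(scores=scores, probabilities=probs, intervals=intervals)
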