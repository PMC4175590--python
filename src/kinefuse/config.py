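"""Filtering thresholds for the fusion-calling pipeline.

All numeric knobs used by detection, cohort filtering and artifact flagging
live in a single :class:`FilterConfig` so that every run can be audited
against the thresholds it actually used.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """A configuration value violates its invariant."""


@dataclass
class FilterConfig:
    """Thresholds applied during fusion detection and cohort filtering.

    Attributes
    ----------
    min_chimeric_2split:
        Minimum chimeric read pairs required when two or more split reads
        support the junction.
    min_chimeric_1split:
        Minimum chimeric pairs required when exactly one split read is present.
    min_chimeric_0split:
        Minimum chimeric pairs required when no split read is present.
    min_overhang:
        Minimum alignment overhang (nt) on *each* side of a split read for it
        to count as split support.
    improbable_prevalence:
        A gene pair seen in more than this fraction of a cohort's samples is
        flagged as an improbable-frequency false positive (strict ``>``).
    promiscuity_prevalence:
        Fraction-of-samples threshold for the dual-partner promiscuity clause
        (each partner in >1 distinct fusions in more than this fraction of
        samples; strict ``>``).
    normals_min_samples:
        A gene pair detected in at least this many normal samples (panel of
        normals) is excluded.
    recurrence_min:
        Minimum number of tumour samples, pooled across all cohorts, for a
        kinase fusion to be called recurrent.
    homology_kmer:
        k-mer length (nt) used by the partner-homology filter.
    homology_share_frac:
        Minimum shared distinct k-mer fraction (max over both directions) for
        two genes to be treated as homologous.
    trans_splice_z:
        Expression z-score at or above which a partner counts as highly
        expressed for the trans-splicing artifact flag.
    """

    min_chimeric_2split: int = 5
    min_chimeric_1split: int = 10
    min_chimeric_0split: int = 20
    min_overhang: int = 15
    improbable_prevalence: float = 0.95
    promiscuity_prevalence: float = 0.25
    normals_min_samples: int = 5
    recurrence_min: int = 2
    homology_kmer: int = 24
    homology_share_frac: float = 0.05
    trans_splice_z: float = 3.0

    _COUNT_FIELDS = (
        "min_chimeric_2split",
        "min_chimeric_1split",
        "min_chimeric_0split",
        "min_overhang",
        "normals_min_samples",
        "recurrence_min",
        "homology_kmer",
    )
    _FRACTION_FIELDS = ("improbable_prevalence", "promiscuity_prevalence",
                        "homology_share_frac")

    def validate(self) -> "FilterConfig":
        for name in self._COUNT_FIELDS:
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {v!r}")
        for name in self._FRACTION_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= float(v) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if float(self.trans_splice_z) < 0:
            raise ConfigError(f"trans_splice_z must be >= 0, got {self.trans_splice_z!r}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
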