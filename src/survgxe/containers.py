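"""Core data containers shared across the pipeline.

A :class:`GenotypeMatrix` holds sample-by-variant allele dosages in [0, 2]
(``NaN`` marks a missing call) together with per-variant metadata, and is the
in-memory genotype representation used by QC, GWAS, and LD operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["VariantRecord", "GenotypeMatrix"]


@dataclass
class VariantRecord:
    """Metadata for one biallelic variant.

    ``maf`` is the minor allele frequency, ``info`` the imputation quality
    score in [0, 1], ``call_rate`` the fraction of non-missing calls and
    ``hwe_p`` the Hardy-Weinberg exact-test p-value on hard calls.
    """

    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alt: str
    maf: float = np.nan
    info: float = 1.0
    call_rate: float = 1.0
    hwe_p: float = 1.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"positions are 1-based; got {self.pos}")
        for name in ("call_rate", "info"):
            v = getattr(self, name)
            if np.isfinite(v) and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1]; got {v}")
        if np.isfinite(self.maf) and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"maf must be in [0, 0.5]; got {self.maf}")

    @property
    def is_biallelic(self) -> bool:
        return ("," not in self.alt) and bool(self.alt) and bool(self.ref)


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with missingness encoded as NaN."""

    dosages: np.ndarray  # float, shape (n_samples, n_variants)
    variants: list[VariantRecord]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"{self.dosages.shape[1]} dosage columns for "
                f"{len(self.variants)} variant records"
            )
        if not self.sample_ids:
            self.sample_ids = [f"S{i:06d}" for i in range(self.dosages.shape[0])]
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ValueError("sample_ids length does not match dosage rows")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ValueError("non-missing dosages must lie in [0, 2]")
        keys = [(v.chrom, v.pos) for v in self.variants]
        if keys != sorted(keys):
            raise ValueError("variants must be sorted by (chromosome, position)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self) -> dict[str, int]:
        return {v.id: j for j, v in enumerate(self.variants)}

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=1)

    def hard_calls(self) -> np.ndarray:
        """Round dosages to genotype classes {0,1,2}.

        Uses round-half-to-even (so a dosage of exactly 0.5 becomes 0 and
        1.5 becomes 2), keeping the rounding rule deterministic at class
        boundaries. Missing stays NaN.
        """
        return np.rint(self.dosages)

    def mean_imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-variant mean."""
        out = self.dosages.copy()
        if np.isnan(out).any():
            col_mean = np.nanmean(out, axis=0)
            idx = np.where(np.isnan(out))
            out[idx] = col_mean[idx[1]]
        return out

    def take_variants(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            variants=[replace(self.variants[j]) for j in index],
            sample_ids=list(self.sample_ids),
        )

    def take_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            variants=[replace(v) for v in self.variants],
            sample_ids=[self.sample_ids[i] for i in index],
        )
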