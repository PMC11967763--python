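"""Organoid-tumor genomic concordance statistics.

Quantifies how faithfully a patient-derived organoid (PDO) recapitulates the
genome of its parental tumor, using two complementary views:

* an allele-specific copy-number similarity score: the per-gene Euclidean
  distance between (cnA, cnB) pairs of tumor and organoid, min-max normalized
  within the pair and inverted (``s = 1 - d'``), summarised over genes;
* a shared/private partition of somatic SNVs with purity-corrected allelic
  fractions, and a two-sided rank-sum comparison of shared versus private
  corrected allelic fractions (shared variants are expected to be clonal and
  therefore sit at higher corrected fractions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GeneCopyState",
    "CopyProfilePair",
    "SomaticVariant",
    "VariantPartition",
    "SimilarityResult",
    "gene_distance",
    "cnv_similarity",
    "filter_confident_variants",
    "partition_variants",
    "correct_allelic_fraction",
    "compare_af",
    "PairingError",
    "InsufficientDataError",
]


class PairingError(ValueError):
    """Tumor/organoid inputs do not describe the same loci or genes."""


class InsufficientDataError(ValueError):
    """Not enough observations for the requested statistic."""


@dataclass(frozen=True)
class GeneCopyState:
    """Allele-specific copy number of one gene: cnA major, cnB minor allele."""

    gene: str
    cnA: float
    cnB: float

    def __post_init__(self) -> None:
        if not (self.cnA >= self.cnB >= 0):
            raise ValueError(
                f"{self.gene}: require cnA >= cnB >= 0, got ({self.cnA}, {self.cnB})"
            )


@dataclass(frozen=True)
class CopyProfilePair:
    """Aligned per-gene copy states for a matched tumor-organoid pair."""

    sample_id: str
    tumor: tuple[GeneCopyState, ...]
    organoid: tuple[GeneCopyState, ...]

    def __post_init__(self) -> None:
        if len(self.tumor) == 0 or len(self.organoid) == 0:
            raise InsufficientDataError("copy profiles must be non-empty")
        if len(self.tumor) != len(self.organoid):
            raise PairingError("tumor and organoid profiles differ in length")
        for t, o in zip(self.tumor, self.organoid):
            if t.gene != o.gene:
                raise PairingError(f"misaligned genes: {t.gene!r} vs {o.gene!r}")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g.gene for g in self.tumor)


@dataclass
class SomaticVariant:
    """A somatic SNV keyed by (chrom, pos, ref, alt), positions 1-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    deleterious: bool = False
    corrected_af: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf must be in [0,1], got {self.vaf}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class VariantPartition:
    """Shared / tumor-private / organoid-private split of two variant sets."""

    shared: tuple[SomaticVariant, ...]
    tumor_private: tuple[SomaticVariant, ...]
    organoid_private: tuple[SomaticVariant, ...]

    @property
    def proportions(self) -> tuple[float, float, float]:
        n = len(self.shared) + len(self.tumor_private) + len(self.organoid_private)
        if n == 0:
            return (0.0, 0.0, 0.0)
        return (
            len(self.shared) / n,
            len(self.tumor_private) / n,
            len(self.organoid_private) / n,
        )


@dataclass(frozen=True)
class SimilarityResult:
    """Per-gene distances/similarities and the pair-level summary score."""

    sample_id: str
    genes: tuple[str, ...]
    per_gene_d: np.ndarray
    per_gene_s: np.ndarray
    summary_s: float
    degenerate: bool = field(default=False)  # max(d) == min(d) convention used


def gene_distance(t: GeneCopyState, o: GeneCopyState) -> float:
    """Euclidean distance between tumor and organoid (cnA, cnB) for one gene."""
    if t.gene != o.gene:
        raise PairingError(f"gene mismatch: {t.gene!r} vs {o.gene!r}")
    return float(np.hypot(t.cnA - o.cnA, t.cnB - o.cnB))


def cnv_similarity(
    pair: CopyProfilePair,
    summary: Literal["mean", "median"] = "mean",
) -> SimilarityResult:
    """Allele-specific copy-number similarity for a matched pair.

    Per gene, d is the Euclidean distance between (cnA, cnB) vectors; d is
    min-max normalized across the pair's genes (d' = (d - min d)/(max d - min d))
    and inverted, s = 1 - d'.  The summary is the mean (default) or median of
    per-gene s.  When every gene is equidistant (including identical profiles)
    the normalization is undefined; by convention all s = 1 then, since under a
    within-pair normalization a uniformly-offset profile carries no internal
    dissimilarity signal.
    """
    d = np.array(
        [gene_distance(t, o) for t, o in zip(pair.tumor, pair.organoid)],
        dtype=float,
    )
    dmin, dmax = float(d.min()), float(d.max())
    degenerate = dmax == dmin
    if degenerate:
        s = np.ones_like(d)
    else:
        s = 1.0 - (d - dmin) / (dmax - dmin)
    if summary == "mean":
        summary_s = float(s.mean())
    elif summary == "median":
        summary_s = float(np.median(s))
    else:
        raise ValueError(f"unknown summary {summary!r}")
    return SimilarityResult(
        sample_id=pair.sample_id,
        genes=pair.genes,
        per_gene_d=d,
        per_gene_s=s,
        summary_s=summary_s,
        degenerate=degenerate,
    )


def filter_confident_variants(
    variants: Sequence[SomaticVariant], vaf_min: float = 0.05
) -> list[SomaticVariant]:
    """Keep variants with VAF strictly greater than ``vaf_min`` (default 0.05).

    Order is preserved. Upstream panel-of-normals / population-database
    filtering is assumed done before these tables are produced.
    """
    if not (0.0 <= vaf_min < 1.0):
        raise ValueError(f"vaf_min must be in [0,1), got {vaf_min}")
    return [v for v in variants if v.vaf > vaf_min]


def _check_unique(variants: Sequence[SomaticVariant], label: str) -> dict:
    out = {}
    for v in variants:
        if v.key in out:
            raise ValueError(f"duplicate variant key {v.key} in {label} sample")
        out[v.key] = v
    return out


def partition_variants(
    tumor: Sequence[SomaticVariant],
    organoid: Sequence[SomaticVariant],
    deleterious_only: bool = False,
) -> VariantPartition:
    """Partition two samples' variants into shared and private sets.

    Identity is (chrom, pos, ref, alt). Proportions are over the union of
    keys and sum to 1. With ``deleterious_only`` both inputs are pre-filtered
    to deleterious variants, reproducing the deleterious-SNV partition.
    """
    if deleterious_only:
        tumor = [v for v in tumor if v.deleterious]
        organoid = [v for v in organoid if v.deleterious]
    tmap = _check_unique(tumor, "tumor")
    omap = _check_unique(organoid, "organoid")
    shared_keys = [k for k in tmap if k in omap]  # tumor order
    shared = tuple(tmap[k] for k in shared_keys)
    tumor_private = tuple(v for v in tumor if v.key not in omap)
    organoid_private = tuple(v for v in organoid if v.key not in tmap)
    return VariantPartition(shared, tumor_private, organoid_private)


def correct_allelic_fraction(v: SomaticVariant, purity: float) -> float:
    """Purity-corrected allelic fraction, capped at 1.

    Dilution-by-normal-cells convention: corrected = min(1, vaf / purity).
    A fuller correction would also use local copy number; only purity is
    applied here, and downstream comparisons are labelled accordingly.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0,1], got {purity}")
    corrected = min(1.0, v.vaf / purity)
    v.corrected_af = corrected
    return corrected


def compare_af(
    shared_afs: Sequence[float], private_afs: Sequence[float]
) -> tuple[float, float]:
    """Two-sided rank-sum (Mann-Whitney U) test of shared vs private AFs.

    Exact null distribution for combined n <= 12 without ties; normal
    approximation with tie correction otherwise. Returns (U, p).
    """
    shared_afs = np.asarray(shared_afs, dtype=float)
    private_afs = np.asarray(private_afs, dtype=float)
    if shared_afs.size == 0 or private_afs.size == 0:
        raise InsufficientDataError("both AF groups must be non-empty")
    combined = np.concatenate([shared_afs, private_afs])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        shared_afs, private_afs, alternative="two-sided", method=method
    )
    return float(res.statistic), float(min(1.0, res.pvalue))
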