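"""Mosaic aneuploidy calling from binned low-pass read counts.

Per-bin counts are normalized to copy ratios against the genome-wide
median (diploid baseline r = 1), averaged per chromosome, and
inverted to a mosaic fraction through the linear mixture model: a
biopsy in which a fraction m of cells carries a third chromosome copy
has mean copy number 2 + m, hence ratio r = (2 + m)/2, so
m = 2(r - 1) for gains and 2(1 - r) for losses. Whole-chromosome
resolution only; no segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CnvThresholds:
    """Class bounds on the mosaic fraction (PGT-A reporting convention)."""

    euploid_max_m: float = 0.2
    full_min_m: float = 0.8
    # |r - 1| below this is treated as noise: direction 'none'
    noise_floor: float = 0.05


@dataclass
class CnvCall:
    chrom: str
    mean_ratio: float
    mosaic_fraction: float
    direction: str            # gain / loss / none
    cnv_class: str            # euploid / mosaic / full_aneuploid
    n_bins: int
    masked_fraction: float


def normalize_counts(cov: pd.DataFrame) -> pd.DataFrame:
    """Add a ``ratio`` column: count / genome-wide median bin count.

    The median runs over autosomal bins with positive counts;
    zero-count bins are masked (ratio NaN).
    """
    cov = cov.copy()
    counts = cov["count"].to_numpy(dtype=float)
    positive = counts > 0
    if not positive.any():
        raise ValueError("all bin counts are zero")
    baseline = float(np.median(counts[positive]))
    ratio = counts / baseline
    ratio[~positive] = np.nan
    cov["ratio"] = ratio
    return cov


def estimate_mosaic_fraction(mean_ratio: float,
                             noise_floor: float = 0.05) -> tuple[float, str]:
    """Invert a per-chromosome mean copy ratio to (m, direction)."""
    if mean_ratio <= 0:
        raise ValueError("mean ratio must be positive")
    dev = mean_ratio - 1.0
    if abs(dev) < noise_floor:
        return 0.0, "none"
    direction = "gain" if dev > 0 else "loss"
    m = float(np.clip(2.0 * abs(dev), 0.0, 1.0))
    return m, direction


def _classify_m(m: float, thresholds: CnvThresholds) -> str:
    if m < thresholds.euploid_max_m:
        return "euploid"
    if m > thresholds.full_min_m:
        return "full_aneuploid"
    return "mosaic"


def call_chromosomes(cov: pd.DataFrame,
                     thresholds: CnvThresholds | None = None) -> list[CnvCall]:
    """Call every chromosome present in the coverage table.

    The diploid baseline for each chromosome is the median count of
    all OTHER chromosomes' non-zero bins (leave-one-out), so an
    aneuploid chromosome cannot inflate its own reference and bias its
    estimate toward diploidy; with a single-chromosome table the
    chromosome's own median is the only available baseline.
    """
    thresholds = thresholds or CnvThresholds()
    counts = cov["count"].to_numpy(dtype=float)
    if not (counts > 0).any():
        raise ValueError("all bin counts are zero")
    calls = []
    for chrom, grp in cov.groupby("chrom", sort=False):
        others = counts[(cov["chrom"] != chrom).to_numpy() & (counts > 0)]
        own = grp["count"].to_numpy(dtype=float)
        own_pos = own[own > 0]
        masked = float((own == 0).mean())
        if len(own_pos) == 0:
            warnings.warn(f"chromosome {chrom} fully masked; no CNV call")
            continue
        baseline = float(np.median(others if len(others) else own_pos))
        r = float(np.mean(own_pos / baseline))
        m, direction = estimate_mosaic_fraction(r, thresholds.noise_floor)
        calls.append(CnvCall(chrom=str(chrom), mean_ratio=r, mosaic_fraction=m,
                             direction=direction,
                             cnv_class=_classify_m(m, thresholds),
                             n_bins=int(len(grp)), masked_fraction=masked))
    return calls


@dataclass
class EmbryoCnvSummary:
    calls: list[CnvCall]
    normal_karyotype: bool
    abnormal_chroms: list[str]

    @property
    def multiple_abnormalities(self) -> bool:
        return len(self.abnormal_chroms) > 1


def classify_embryo_cnv(cov: pd.DataFrame,
                        thresholds: CnvThresholds | None = None,
                        ) -> EmbryoCnvSummary:
    """Per-chromosome classes plus an embryo-level karyotype summary.

    An embryo has a normal karyotype iff every called chromosome is
    euploid (m below the euploid bound).
    """
    calls = call_chromosomes(cov, thresholds)
    abnormal = [c.chrom for c in calls if c.cnv_class != "euploid"]
    return EmbryoCnvSummary(calls=calls, normal_karyotype=not abnormal,
                            abnormal_chroms=abnormal)


def calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])


def write_cnv_calls(calls: list[CnvCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)
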