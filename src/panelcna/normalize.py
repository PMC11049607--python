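"""GC-corrected, zero-centered log2 coverage profiles with per-SNP BAFs.

A test sample's per-bin counts are library-size normalized against the
control reference, converted to log2 ratios against the expected reads,
flattened against GC content with a decile-median curve, and median-
centered so that 0 denotes no copy-number change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .reference import ReferenceProfile, aggregate_to_bins

logger = logging.getLogger(__name__)

__all__ = ["GCModel", "Log2Profile", "raw_log2", "correct_gc", "center",
           "compute_baf", "normalize_sample", "Log2Normalizer"]


@dataclass
class GCModel:
    """Piecewise-linear GC correction curve (GC fraction -> log2 offset)."""

    gc_knots: np.ndarray
    offsets: np.ndarray

    def correction(self, gc: np.ndarray) -> np.ndarray:
        return np.interp(gc, self.gc_knots, self.offsets)


@dataclass
class Log2Profile:
    """Per-bin log2 coverage ratios plus per-SNP BAFs for one sample.

    ``values`` is aligned to the reference's retained bins. After
    centering the median of ``values`` is 0 (to within numerical noise).
    """

    sample_id: str
    bins: pd.DataFrame  # retained reference bins (bin_id, chrom, start, end, gc)
    values: np.ndarray
    baf: pd.DataFrame  # chrom, pos, baf, depth
    center_offset: float = 0.0
    gc_model: GCModel | None = None
    meta: dict = field(default_factory=dict)


def raw_log2(
    sample_counts: np.ndarray,
    expected_reads: np.ndarray,
    pseudo_count: float = 0.5,
) -> np.ndarray:
    """log2((normalized + eps) / (expected + eps)), aligned bin by bin.

    ``sample_counts`` must already be library-size normalized onto the
    reference scale. The pseudo-count is applied symmetrically so a
    sample exactly matching its expectation maps to exactly zero.
    """
    sample_counts = np.asarray(sample_counts, dtype=float)
    expected_reads = np.asarray(expected_reads, dtype=float)
    if sample_counts.shape != expected_reads.shape:
        raise ValueError("sample counts not aligned to reference bins")
    return np.log2(
        (sample_counts + pseudo_count) / (expected_reads + pseudo_count)
    )


def correct_gc(
    values: np.ndarray,
    gc: np.ndarray,
    n_deciles: int = 10,
    min_bins_per_decile: int = 5,
) -> tuple[np.ndarray, GCModel]:
    """Remove the GC trend with a decile-median curve.

    Bins are grouped into GC deciles; deciles holding fewer than
    ``min_bins_per_decile`` bins are merged with their neighbor (logged).
    The median log2 value of each group, interpolated linearly in GC,
    is subtracted, leaving a GC-flat profile.
    """
    values = np.asarray(values, dtype=float)
    gc = np.asarray(gc, dtype=float)
    edges = np.unique(np.quantile(gc, np.linspace(0, 1, n_deciles + 1)))
    groups = np.clip(np.searchsorted(edges, gc, side="right") - 1,
                     0, len(edges) - 2)

    # merge undersized groups rightward (last one leftward)
    ids = np.unique(groups)
    sizes = {g: int((groups == g).sum()) for g in ids}
    merged = False
    for g in list(ids):
        if sizes.get(g, 0) and sizes[g] < min_bins_per_decile:
            neighbors = [h for h in sorted(sizes) if h != g and sizes[h] > 0]
            if not neighbors:
                break
            tgt = min(neighbors, key=lambda h: abs(h - g))
            groups[groups == g] = tgt
            sizes[tgt] += sizes[g]
            sizes[g] = 0
            merged = True
    if merged:
        logger.warning("merged undersized GC deciles with neighbors")

    knots, meds = [], []
    for g in np.unique(groups):
        mask = groups == g
        knots.append(np.median(gc[mask]))
        meds.append(np.median(values[mask]))
    order = np.argsort(knots)
    model = GCModel(np.asarray(knots)[order], np.asarray(meds)[order])
    return values - model.correction(gc), model


def center(
    values: np.ndarray, neutral_mask: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Subtract the median so copy-neutral bins sit at zero.

    ``neutral_mask`` restricts the centering statistic to bins believed
    neutral; an empty mask falls back to the global median (logged).
    """
    values = np.asarray(values, dtype=float)
    if neutral_mask is not None and np.any(neutral_mask):
        offset = float(np.median(values[neutral_mask]))
    else:
        if neutral_mask is not None:
            logger.warning("empty neutral mask; centering on global median")
        offset = float(np.median(values))
    return values - offset, offset


def compute_baf(
    allele_depths: pd.DataFrame, min_depth: int = 20
) -> pd.DataFrame:
    """B-allele fractions for SNPs with total depth >= ``min_depth``.

    ``allele_depths`` needs columns chrom, pos, ref_depth, alt_depth.
    Shallow SNPs are dropped (count logged).
    """
    ref_d = allele_depths["ref_depth"].to_numpy()
    alt_d = allele_depths["alt_depth"].to_numpy()
    if np.any(ref_d < 0) or np.any(alt_d < 0):
        raise ValueError("negative allele depths")
    depth = ref_d + alt_d
    keep = depth >= min_depth
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d SNPs below depth %d", n_dropped, min_depth)
    kept = allele_depths.loc[keep].reset_index(drop=True)
    out = kept[["chrom", "pos"]].copy()
    out["baf"] = kept["alt_depth"] / depth[keep]
    out["depth"] = depth[keep]
    return out


def normalize_sample(
    sample_id: str,
    window_counts: np.ndarray,
    ref: ReferenceProfile,
    window_bin: np.ndarray,
    allele_depths: pd.DataFrame | None = None,
    pseudo_count: float = 0.5,
    min_baf_depth: int = 20,
) -> Log2Profile:
    """Window counts -> binned, normalized, GC-corrected, centered profile."""
    binned = aggregate_to_bins(
        np.asarray(window_counts, dtype=float), window_bin, ref.n_bins
    )
    retained = ref.retained()
    keep = ref.bins["reliable"].to_numpy()
    sample = binned[keep]
    expected = retained["expected_reads"].to_numpy()

    total = sample.sum()
    if total <= 0:
        raise ValueError(f"{sample_id}: no reads on retained bins")
    sample = sample * (expected.sum() / total)  # library-size normalization

    values = raw_log2(sample, expected, pseudo_count)
    values, gc_model = correct_gc(values, retained["gc"].to_numpy())
    values, offset = center(values)

    if allele_depths is not None and len(allele_depths):
        baf = compute_baf(allele_depths, min_depth=min_baf_depth)
    else:
        baf = pd.DataFrame(columns=["chrom", "pos", "baf", "depth"])

    return Log2Profile(
        sample_id=sample_id,
        bins=retained,
        values=values,
        baf=baf,
        center_offset=offset,
        gc_model=gc_model,
        meta={"pseudo_count": pseudo_count, "min_baf_depth": min_baf_depth},
    )


class Log2Normalizer(BaseEstimator):
    """Estimator facade over the normalization chain.

    ``fit`` binds a reference profile (and the window->bin map);
    ``transform_sample`` turns one sample's window counts (plus optional
    allele depths) into a :class:`Log2Profile`.
    """

    def __init__(self, pseudo_count: float = 0.5, min_baf_depth: int = 20):
        self.pseudo_count = pseudo_count
        self.min_baf_depth = min_baf_depth

    def fit(self, ref: ReferenceProfile, window_bin: np.ndarray) -> "Log2Normalizer":
        self.ref_ = ref
        self.window_bin_ = np.asarray(window_bin)
        return self

    def transform_sample(
        self,
        sample_id: str,
        window_counts: np.ndarray,
        allele_depths: pd.DataFrame | None = None,
    ) -> Log2Profile:
        return normalize_sample(
            sample_id,
            window_counts,
            self.ref_,
            self.window_bin_,
            allele_depths,
            pseudo_count=self.pseudo_count,
            min_baf_depth=self.min_baf_depth,
        )
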