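"""Control-cohort reference with dynamic, equal-read bins.

The reference stage pools a healthy-control cohort into an expected-
coverage profile. Bins are sized dynamically so that each holds a
consistent number of reads (default target 1000 on the library-normalized
cohort-mean scale): greedy left-to-right accumulation per chromosome,
closing a bin as soon as the running read total reaches the target. Bins
never span chromosome boundaries or gaps in the panel footprint, so the
bins of each chromosome exactly tile its covered intervals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceProfile",
    "build_dynamic_bins",
    "build_reference",
    "build_reference_profile",
    "normalize_library_size",
    "aggregate_to_bins",
    "assign_windows",
    "ReferenceBuilder",
    "read_reference",
    "write_reference",
]

BIN_COLUMNS = ["bin_id", "chrom", "start", "end", "gc",
               "expected_reads", "dispersion", "reliable"]


@dataclass
class ReferenceProfile:
    """Dynamic bins with expected read counts and control variability.

    ``bins`` carries one row per bin: bin_id, chrom, start, end, gc,
    expected_reads (cohort mean of library-normalized counts),
    dispersion (cohort standard deviation, floored at the Poisson level
    sqrt(expected)), and a ``reliable`` flag — bins whose expected count
    falls below ``min_expected`` are excluded from downstream emission
    likelihoods.
    """

    bins: pd.DataFrame
    n_controls: int
    target_reads_per_bin: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def retained(self) -> pd.DataFrame:
        """Bins that passed the reliability floor."""
        return self.bins[self.bins["reliable"]].reset_index(drop=True)


def build_dynamic_bins(
    track: pd.DataFrame, target_reads_per_bin: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Greedy equal-read binning of a coverage track.

    Parameters
    ----------
    track
        One row per fine window: chrom, start, end, reads, and optionally
        gc. Windows must be sorted by (chrom, start) within chromosome.
    target_reads_per_bin
        Close the running bin once its pooled reads reach this value
        (must be >= 50).

    Returns
    -------
    bins, window_bin
        ``bins`` with columns bin_id, chrom, start, end, gc, reads;
        ``window_bin`` maps each track row to its bin index. Bins never
        cross chromosomes or footprint gaps; a trailing remainder of less
        than half the target is absorbed into the previous bin of the
        same contiguous block. A chromosome whose total reads fall short
        of the target yields a single bin per contiguous block and logs a
        warning.
    """
    if target_reads_per_bin < 50:
        raise ValueError("target_reads_per_bin must be >= 50")
    required = {"chrom", "start", "end", "reads"}
    if not required.issubset(track.columns):
        raise ValueError(f"track must have columns {sorted(required)}")
    has_gc = "gc" in track.columns

    window_bin = np.empty(len(track), dtype=np.int64)
    records: list[dict] = []

    for chrom, group in track.groupby("chrom", sort=False):
        idx = group.index.to_numpy()
        starts = group["start"].to_numpy()
        ends = group["end"].to_numpy()
        reads = group["reads"].to_numpy(dtype=float)
        gcs = group["gc"].to_numpy() if has_gc else np.full(len(group), np.nan)

        if reads.sum() < target_reads_per_bin:
            logger.warning(
                "chromosome %s has %.0f pooled reads < target %d; "
                "emitting whole-block bins",
                chrom, reads.sum(), target_reads_per_bin,
            )

        # contiguous blocks of the footprint
        breaks = np.nonzero(starts[1:] != ends[:-1])[0] + 1
        for block in np.split(np.arange(len(group)), breaks):
            _bin_block(
                chrom, block, idx, starts, ends, reads, gcs,
                target_reads_per_bin, records, window_bin,
            )

    bins = pd.DataFrame.from_records(
        records, columns=["chrom", "start", "end", "gc", "reads", "length"]
    )
    bins.insert(0, "bin_id", np.arange(len(bins)))
    return bins.drop(columns="length"), window_bin


def _bin_block(
    chrom, block, idx, starts, ends, reads, gcs, target, records, window_bin
) -> None:
    """Greedy accumulation within one contiguous footprint block."""
    first_bin_of_block = len(records)
    acc: list[int] = []
    acc_reads = 0.0
    for j in block:
        acc.append(j)
        acc_reads += reads[j]
        if acc_reads >= target:
            _close_bin(chrom, acc, idx, starts, ends, reads, gcs,
                       records, window_bin)
            acc, acc_reads = [], 0.0
    if acc:
        if acc_reads < target / 2 and len(records) > first_bin_of_block:
            # absorb the small remainder into the previous bin
            prev = records[-1]
            members = acc
            w = ends[members] - starts[members]
            tot_len = prev["length"] + w.sum()
            prev["gc"] = (
                prev["gc"] * prev["length"] + float((gcs[members] * w).sum())
            ) / tot_len
            prev["length"] = tot_len
            prev["end"] = int(ends[members[-1]])
            prev["reads"] += float(reads[members].sum())
            window_bin[idx[members]] = len(records) - 1
        else:
            _close_bin(chrom, acc, idx, starts, ends, reads, gcs,
                       records, window_bin)


def _close_bin(chrom, members, idx, starts, ends, reads, gcs,
               records, window_bin) -> None:
    members = np.asarray(members)
    w = (ends[members] - starts[members]).astype(float)
    records.append(
        {
            "chrom": chrom,
            "start": int(starts[members[0]]),
            "end": int(ends[members[-1]]),
            "gc": float((gcs[members] * w).sum() / w.sum()),
            "reads": float(reads[members].sum()),
            "length": float(w.sum()),
        }
    )
    window_bin[idx[members]] = len(records) - 1


def normalize_library_size(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale each sample's counts to the cohort-median total.

    Returns the scaled (float) matrix and the per-sample scale factors.
    Median rescaling keeps the normalized counts on a read-like scale
    without letting deep samples dominate.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("every sample must have positive total reads")
    factors = np.median(totals) / totals
    return counts * factors[:, None], factors


def aggregate_to_bins(
    counts: np.ndarray, window_bin: np.ndarray, n_bins: int
) -> np.ndarray:
    """Sum window-level counts into bins. ``counts`` is 1-D or 2-D."""
    counts = np.atleast_2d(counts)
    out = np.empty((counts.shape[0], n_bins))
    for i in range(counts.shape[0]):
        out[i] = np.bincount(window_bin, weights=counts[i], minlength=n_bins)
    return out if out.shape[0] > 1 else out[0]


def assign_windows(bins: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Map window midpoints onto bin indices (for counts saved on disk).

    Windows falling outside every bin get -1.
    """
    out = np.full(len(windows), -1, dtype=np.int64)
    mid = ((windows["start"] + windows["end"]) // 2).to_numpy()
    wchrom = windows["chrom"].to_numpy()
    for chrom, group in bins.groupby("chrom", sort=False):
        mask = wchrom == chrom
        starts = group["start"].to_numpy()
        ends = group["end"].to_numpy()
        pos = np.searchsorted(starts, mid[mask], side="right") - 1
        ok = (pos >= 0) & (mid[mask] < ends[np.clip(pos, 0, None)])
        res = np.where(ok, group["bin_id"].to_numpy()[np.clip(pos, 0, None)], -1)
        out[mask] = res
    return out


def build_reference(
    control_counts_binned: np.ndarray,
    bins: pd.DataFrame,
    target_reads_per_bin: int,
    min_expected: float | None = None,
    metadata: dict | None = None,
) -> ReferenceProfile:
    """Expected counts and variability per bin from >= 2 controls.

    ``control_counts_binned`` holds library-normalized counts, one row per
    control, aligned to ``bins``. The dispersion is the per-bin standard
    deviation floored at sqrt(expected) (a cohort of identical controls
    therefore sits exactly at the floor).
    """
    counts = np.atleast_2d(np.asarray(control_counts_binned, dtype=float))
    if counts.shape[0] < 2:
        raise ValueError("refusing to build a reference from < 2 controls "
                         "(no variance estimate)")
    if counts.shape[1] != len(bins):
        raise ValueError("control counts not aligned to bins")
    if min_expected is None:
        min_expected = 0.1 * target_reads_per_bin

    expected = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1)
    dispersion = np.maximum(sd, np.sqrt(np.maximum(expected, 0.0)))
    reliable = expected >= min_expected
    n_dropped = int((~reliable).sum())
    if n_dropped:
        logger.warning("%d bins below expected-read floor %.1f flagged "
                       "unreliable", n_dropped, min_expected)

    out = bins[["bin_id", "chrom", "start", "end", "gc"]].copy()
    out["expected_reads"] = expected
    out["dispersion"] = dispersion
    out["reliable"] = reliable
    return ReferenceProfile(
        bins=out,
        n_controls=counts.shape[0],
        target_reads_per_bin=target_reads_per_bin,
        metadata=dict(metadata or {}),
    )


def build_reference_profile(
    windows: pd.DataFrame,
    control_counts: np.ndarray,
    target_reads_per_bin: int = 1000,
    min_expected: float | None = None,
    metadata: dict | None = None,
) -> tuple[ReferenceProfile, np.ndarray]:
    """Window-level control counts -> dynamic bins -> reference profile.

    The binning track is the cohort mean of library-normalized window
    counts, so ``expected_reads`` of the resulting bins lands near the
    target. Returns the profile and the window->bin assignment.
    """
    normalized, _ = normalize_library_size(control_counts)
    track = windows[["chrom", "start", "end"]].copy()
    if "gc" in windows.columns:
        track["gc"] = windows["gc"].to_numpy()
    track["reads"] = normalized.mean(axis=0)
    bins, window_bin = build_dynamic_bins(track, target_reads_per_bin)
    binned = aggregate_to_bins(normalized, window_bin, len(bins))
    profile = build_reference(
        binned, bins, target_reads_per_bin, min_expected, metadata
    )
    return profile, window_bin


class ReferenceBuilder(BaseEstimator):
    """Estimator facade: fit a control cohort, keep the reference.

    Parameters
    ----------
    target_reads_per_bin : int, default 1000
        Dynamic-bin read target on the cohort-mean normalized scale.
    min_expected : float or None
        Reliability floor for expected reads; default 10% of the target.

    Attributes
    ----------
    profile_ : ReferenceProfile
    window_bin_ : ndarray mapping fit-time windows to bins.
    """

    def __init__(self, target_reads_per_bin: int = 1000,
                 min_expected: float | None = None):
        self.target_reads_per_bin = target_reads_per_bin
        self.min_expected = min_expected

    def fit(self, X: np.ndarray, windows: pd.DataFrame) -> "ReferenceBuilder":
        """X: (n_controls, n_windows) raw read counts."""
        self.profile_, self.window_bin_ = build_reference_profile(
            windows, X, self.target_reads_per_bin, self.min_expected
        )
        return self


def write_reference(profile: ReferenceProfile, path: str | Path) -> None:
    """Serialize bins as TSV plus a JSON sidecar of build metadata."""
    path = Path(path)
    profile.bins[BIN_COLUMNS].to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {
        "n_controls": profile.n_controls,
        "target_reads_per_bin": profile.target_reads_per_bin,
        **profile.metadata,
    }
    sidecar.write_text(json.dumps(meta, indent=2, default=str))


def read_reference(path: str | Path) -> ReferenceProfile:
    path = Path(path)
    bins = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ReferenceProfile(
        bins=bins,
        n_controls=int(meta.pop("n_controls", 0)),
        target_reads_per_bin=int(meta.pop("target_reads_per_bin", 0)),
        metadata=meta,
    )
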