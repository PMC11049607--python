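"""Gene-level CNA calls from segments, and cohort frequency tables.

Copy-number classes follow the clinical definitions: a gain is one extra
copy (three total), an amplification two or more extra copies (four or
more total), and a loss one or both copies missing. Calls supported by a
segment longer than ``max_event_span`` (default 5 Mb) are suppressed —
reported neutral with the raw class kept in provenance — so that very
large, less gene-specific events do not enter the gene-level call set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import Segment
from .panel import PanelRegion

logger = logging.getLogger(__name__)

__all__ = [
    "CALL_CLASSES",
    "classify_cn",
    "call_genes",
    "frequency_table",
    "FrequencyTables",
    "calls_from_truth",
]

CALL_CLASSES = ("loss", "neutral", "gain", "amplification")

DEFAULT_MAX_EVENT_SPAN = 5_000_000

CALL_COLUMNS = ["sample_id", "gene", "cn_total", "call_class", "raw_class",
                "filtered", "segment_span"]


def classify_cn(cn_total: int) -> str:
    """Map a total copy number to its clinical call class.

    <=1 -> loss, 2 -> neutral, 3 -> gain, >=4 -> amplification.
    """
    cn = int(cn_total)
    if cn < 0:
        raise ValueError("copy number must be non-negative")
    if cn <= 1:
        return "loss"
    if cn == 2:
        return "neutral"
    if cn == 3:
        return "gain"
    return "amplification"


def _pick_segment(
    region: PanelRegion, segments: list[Segment]
) -> Segment | None:
    """Largest-reciprocal-overlap segment; midpoint coverage breaks ties."""
    best, best_score = None, -1.0
    mid = region.midpoint
    for seg in segments:
        if seg.chrom != region.chrom:
            continue
        ov = min(seg.end, region.end) - max(seg.start, region.start)
        if ov <= 0:
            continue
        score = min(ov / region.length, ov / max(seg.span, 1))
        covers_mid = seg.start <= mid < seg.end
        if score > best_score + 1e-12:
            best, best_score = seg, score
        elif abs(score - best_score) <= 1e-12 and covers_mid:
            best = seg
    return best


def call_genes(
    segments: list[Segment],
    panel: list[PanelRegion],
    sample_id: str,
    max_event_span: int = DEFAULT_MAX_EVENT_SPAN,
) -> pd.DataFrame:
    """One call per panel gene for one sample, always.

    For each gene the supporting segment is the one with the largest
    reciprocal overlap with the gene interval (ties go to the segment
    covering the gene's midpoint). A non-neutral supporting segment whose
    span exceeds ``max_event_span`` marks the call filtered and reports
    it neutral. A gene with no overlapping segment yields a neutral call
    and a logged warning (panel/reference mismatch).
    """
    rows = []
    for region in panel:
        seg = _pick_segment(region, segments)
        if seg is None:
            logger.warning(
                "%s: no segment overlaps %s; emitting neutral call",
                sample_id, region.gene,
            )
            rows.append((sample_id, region.gene, 2, "neutral", "neutral",
                         False, 0))
            continue
        raw = classify_cn(seg.cn_total)
        filtered = raw != "neutral" and seg.span > max_event_span
        reported = "neutral" if filtered else raw
        rows.append((sample_id, region.gene, seg.cn_total, reported, raw,
                     filtered, seg.span))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


@dataclass
class FrequencyTables:
    """Per-type, overall and class-mix summaries of a cohort call set."""

    per_type: pd.DataFrame  # tumor_type, gene, n_events, n_samples, frequency
    overall: pd.DataFrame  # gene, n_events, n_samples, frequency
    class_mix: pd.DataFrame  # call_class, n_events, proportion


def frequency_table(
    calls: pd.DataFrame, sample_types: dict[str, str]
) -> FrequencyTables:
    """Aggregate gene calls into per-tumor-type frequency tables.

    The numerator for a (tumor type, gene) cell is the number of samples
    of that type carrying a non-neutral, unfiltered call on that gene;
    the denominator is the number of samples of that type. ``class_mix``
    gives the gain/loss/amplification shares of all events.
    """
    missing = set(calls["sample_id"]) - set(sample_types)
    if missing:
        raise ValueError(f"samples without a tumor type: {sorted(missing)}")

    calls = calls.copy()
    calls["tumor_type"] = calls["sample_id"].map(sample_types)
    calls["is_event"] = (calls["call_class"] != "neutral") & ~calls["filtered"]

    type_sizes = pd.Series(sample_types).value_counts().sort_index()
    type_sizes.index.name = "tumor_type"
    genes = sorted(calls["gene"].unique())

    per_type = (
        calls.groupby(["tumor_type", "gene"])["is_event"].sum().rename("n_events")
        .reindex(
            pd.MultiIndex.from_product(
                [type_sizes.index, genes], names=["tumor_type", "gene"]
            ),
            fill_value=0,
        )
        .reset_index()
    )
    per_type["n_samples"] = per_type["tumor_type"].map(type_sizes)
    per_type["frequency"] = per_type["n_events"] / per_type["n_samples"]

    n_total = len(set(sample_types))
    overall = (
        calls.groupby("gene")["is_event"].sum().rename("n_events")
        .reindex(genes, fill_value=0).rename_axis("gene").reset_index()
    )
    overall["n_samples"] = n_total
    overall["frequency"] = overall["n_events"] / n_total

    events = calls[calls["is_event"]]
    mix_counts = events["call_class"].value_counts()
    mix = pd.DataFrame(
        {
            "call_class": ["gain", "loss", "amplification"],
        }
    )
    mix["n_events"] = mix["call_class"].map(mix_counts).fillna(0).astype(int)
    total_events = int(mix["n_events"].sum())
    mix["proportion"] = (
        mix["n_events"] / total_events if total_events else 0.0
    )
    return FrequencyTables(per_type=per_type, overall=overall, class_mix=mix)


def calls_from_truth(
    events, sample_ids: list[str], panel: list[PanelRegion]
) -> pd.DataFrame:
    """Expand planted events into a complete (sample x gene) call matrix.

    This is the truth channel for concordance: every pair absent from the
    event list is neutral.
    """
    by_pair = {(e.sample_id, e.gene): e.total_copies for e in events}
    rows = []
    for sid in sample_ids:
        for region in panel:
            cn = by_pair.get((sid, region.gene), 2)
            rows.append((sid, region.gene, cn, classify_cn(cn),
                         classify_cn(cn), False, region.length))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)
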