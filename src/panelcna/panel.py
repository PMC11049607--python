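"""The 24-gene clinically relevant region panel.

Coordinates are hg19-like gene loci padded to round region boundaries;
intervals are 0-based half-open (BED convention) and non-overlapping
within a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["PanelRegion", "default_panel", "panel_to_frame", "read_panel_bed",
           "write_panel_bed"]


@dataclass(frozen=True)
class PanelRegion:
    """One clinically relevant gene interval on the genome."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene}: start must be < end")
        if self.start < 0:
            raise ValueError(f"{self.gene}: negative start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


# gene -> (chrom, start, end); loci padded to give each region a usable
# multi-bin footprint for read-depth analysis.
_DEFAULT_REGIONS: list[tuple[str, str, int, int]] = [
    ("ALK",    "chr2",   29_300_000,  29_700_000),
    ("RAF1",   "chr3",   12_500_000,  12_800_000),
    ("PIK3CA", "chr3",  178_700_000, 179_000_000),
    ("PDGFRA", "chr4",   54_900_000,  55_300_000),
    ("RICTOR", "chr5",   38_800_000,  39_200_000),
    ("EGFR",   "chr7",   55_000_000,  55_400_000),
    ("CDK6",   "chr7",   92_100_000,  92_500_000),
    ("MET",    "chr7",  116_200_000, 116_500_000),
    ("BRAF",   "chr7",  140_300_000, 140_700_000),
    ("FGFR1",  "chr8",   38_100_000,  38_400_000),
    ("MYC",    "chr8",  128_600_000, 128_900_000),
    ("CDKN2A", "chr9",   21_800_000,  22_100_000),
    ("FANCC",  "chr9",   97_800_000,  98_100_000),
    ("PTEN",   "chr10",  89_500_000,  89_800_000),
    ("FGFR2",  "chr10", 123_100_000, 123_400_000),
    ("CCND1",  "chr11",  69_300_000,  69_600_000),
    ("KRAS",   "chr12",  25_200_000,  25_500_000),
    ("CDK4",   "chr12",  58_000_000,  58_300_000),
    ("MDM2",   "chr12",  69_100_000,  69_400_000),
    ("RB1",    "chr13",  48_800_000,  49_100_000),
    ("TP53",   "chr17",   7_400_000,   7_700_000),
    ("ERBB2",  "chr17",  37_700_000,  38_000_000),
    ("CCNE1",  "chr19",  30_200_000,  30_500_000),
    ("AR",     "chrX",   66_600_000,  67_000_000),
]


def default_panel() -> list[PanelRegion]:
    """Return the default 24-gene panel, sorted by chromosome then start."""
    return [PanelRegion(g, c, s, e) for g, c, s, e in _DEFAULT_REGIONS]


def panel_to_frame(panel: list[PanelRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in panel],
            "chrom": [r.chrom for r in panel],
            "start": [r.start for r in panel],
            "end": [r.end for r in panel],
        }
    )


def write_panel_bed(panel: list[PanelRegion], path: str | Path) -> None:
    """Write the panel as 4-column BED (chrom, start, end, gene)."""
    df = panel_to_frame(panel)
    df[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_panel_bed(path: str | Path) -> list[PanelRegion]:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene"]
    )
    return [
        PanelRegion(row.gene, row.chrom, int(row.start), int(row.end))
        for row in df.itertuples()
    ]
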