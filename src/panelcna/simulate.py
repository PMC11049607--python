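"""Synthetic FFPE-like targeted-panel data generator.

Emulates the study cohort the caller is validated on: a control cohort of
10 male + 10 female individuals sequenced at 5-10x, and 50 FFPE tumor
samples across five tumor types (breast 10, ovary 8, pancreas 8,
melanoma 4, prostate 20) with tumor cellularity 20-100% and 54 planted
copy-number events (34 gains, 12 amplifications, 8 losses).

The generative model works at fine-window resolution (default 500 bp):

* window read counts are negative-binomial with mean proportional to
  window length x mean coverage x a smooth multiplicative GC-bias factor
  (per-sample bias amplitude, so test samples and the control reference
  disagree and the GC-correction stage has real work to do);
* inside a planted event's span the tumor mean is scaled by the effective
  copy ratio r = (p*CN + (1-p)*2) / 2, where p is tumor purity and CN the
  event's total copy number;
* heterozygous-SNP alt depths are binomial with success probability equal
  to the expected B-allele frequency under (CN, p); the amplified allele
  is picked at random per SNP, so BAF shifts appear on both sides of 0.5.

Identical seeds reproduce identical datasets bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import PanelRegion, default_panel, panel_to_frame, write_panel_bed

__all__ = [
    "SimulationConfig",
    "PlantedEvent",
    "SyntheticDataset",
    "simulate_dataset",
    "study_event_mix",
    "default_config",
    "cohort_samples",
    "write_dataset",
]

# tumor-type prefixes used to mint sample identifiers
_TYPE_PREFIX = {
    "breast": "BR",
    "ovary": "OV",
    "pancreas": "PN",
    "melanoma": "ML",
    "prostate": "PR",
}

#: study-cohort tumor-type composition
DEFAULT_TUMOR_MIX = {
    "breast": 10,
    "ovary": 8,
    "pancreas": 8,
    "melanoma": 4,
    "prostate": 20,
}

_GC_CENTER = 0.45
_GC_SCALE = 0.15


@dataclass(frozen=True)
class PlantedEvent:
    """A ground-truth copy-number event planted in one tumor sample.

    ``total_copies`` follows the clinical convention: 0 or 1 = loss,
    3 = gain, >= 4 = amplification; 2 is neutral and therefore not an
    event. ``span`` may exceed the gene region (used to exercise the
    large-CNV size filter downstream).
    """

    sample_id: str
    gene: str
    total_copies: int
    chrom: str
    span_start: int
    span_end: int

    def __post_init__(self) -> None:
        if self.total_copies == 2:
            raise ValueError("total_copies == 2 is neutral, not an event")
        if self.total_copies < 0:
            raise ValueError("total_copies must be non-negative")
        if self.span_start >= self.span_end:
            raise ValueError("event span must be a non-empty interval")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 10+10 controls at 5-10x,
    50 tumors in the published tumor-type mix, purity uniform on
    [0.20, 1.00], and a dynamic-bin target of 1000 reads per bin.
    Tumor coverage defaults to 300-500x, a typical deduplicated depth for
    hybrid-capture tumor panels; the negative-binomial dispersion
    ``overdispersion`` (k = 300) puts per-bin log2 noise near 0.09 sd,
    in line with good-quality FFPE panel profiles.
    """

    seed: int = 0
    n_controls_male: int = 10
    n_controls_female: int = 10
    tumor_type_mix: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TUMOR_MIX)
    )
    purity_range: tuple[float, float] = (0.20, 1.00)
    mean_coverage_range: tuple[float, float] = (5.0, 10.0)
    tumor_coverage_range: tuple[float, float] = (300.0, 500.0)
    reads_per_bin_target: int = 1000
    overdispersion: float = 300.0
    gc_bias_amplitude: float = 0.3
    event_table: list[PlantedEvent] = field(default_factory=list)
    window_size: int = 500
    read_length: int = 100
    snps_per_region: int = 10

    @property
    def n_controls(self) -> int:
        return self.n_controls_male + self.n_controls_female

    @property
    def n_tumors(self) -> int:
        return sum(self.tumor_type_mix.values())

    def validate(self) -> None:
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("purity_range must lie within (0, 1]")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be > 0")
        if self.n_controls < 2:
            raise ValueError("need at least 2 controls")
        if any(n < 0 for n in self.tumor_type_mix.values()):
            raise ValueError("tumor_type_mix counts must be non-negative")
        if self.window_size <= 0 or self.read_length <= 0:
            raise ValueError("window_size and read_length must be positive")


@dataclass
class SyntheticDataset:
    """Everything one end-to-end run of the pipeline consumes."""

    panel: list[PanelRegion]
    windows: pd.DataFrame  # chrom, start, end, gc — fine coverage windows
    control_ids: list[str]
    control_counts: np.ndarray  # (n_controls, n_windows) int
    tumor_ids: list[str]
    tumor_counts: np.ndarray  # (n_tumors, n_windows) int
    snp_allele_depths: pd.DataFrame  # sample_id, chrom, pos, ref_depth, alt_depth
    truth: list[PlantedEvent]
    purities: dict[str, float]
    tumor_types: dict[str, str]
    config: SimulationConfig

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [e.sample_id for e in self.truth],
                "gene": [e.gene for e in self.truth],
                "total_copies": [e.total_copies for e in self.truth],
                "chrom": [e.chrom for e in self.truth],
                "span_start": [e.span_start for e in self.truth],
                "span_end": [e.span_end for e in self.truth],
            }
        )


def cohort_samples(
    mix: dict[str, int] | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Sample identifiers and tumor types for a cohort composition.

    Defaults to the 50-sample study mix. Useful for building truth call
    matrices without generating count data.
    """
    return _sample_ids(dict(DEFAULT_TUMOR_MIX) if mix is None else mix)


def _sample_ids(mix: dict[str, int]) -> tuple[list[str], dict[str, str]]:
    ids: list[str] = []
    types: dict[str, str] = {}
    for ttype in sorted(mix):
        prefix = _TYPE_PREFIX.get(ttype, ttype[:2].upper())
        for i in range(mix[ttype]):
            sid = f"{prefix}{i + 1:02d}"
            ids.append(sid)
            types[sid] = ttype
    return ids, types


def _make_windows(
    panel: list[PanelRegion], window_size: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Tile each panel region with fine windows carrying a smooth GC track."""
    rows = []
    # deterministic per-chromosome phase for the GC field
    chroms = sorted({r.chrom for r in panel})
    phase = {c: rng.uniform(0, 2 * np.pi) for c in chroms}
    for region in sorted(panel, key=lambda r: (r.chrom, r.start)):
        starts = np.arange(region.start, region.end, window_size)
        ends = np.minimum(starts + window_size, region.end)
        mid = (starts + ends) / 2.0
        gc = (
            _GC_CENTER
            + 0.13 * np.sin(2 * np.pi * mid / 150_000.0 + phase[region.chrom])
            + rng.normal(0.0, 0.02, size=len(starts))
        )
        gc = np.clip(gc, 0.28, 0.68)
        rows.append(
            pd.DataFrame(
                {"chrom": region.chrom, "start": starts, "end": ends,
                 "gc": gc, "gene": region.gene}
            )
        )
    windows = pd.concat(rows, ignore_index=True)
    return windows


def _gc_factor(gc: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth unimodal multiplicative coverage bias as a function of GC.

    Peak at GC = 0.45; ``amplitude`` is the log2 depression one GC-scale
    unit (0.15) away from the peak.
    """
    z = (gc - _GC_CENTER) / _GC_SCALE
    return np.exp2(-amplitude * z * z)


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, k: float
) -> np.ndarray:
    """Negative-binomial counts with mean ``mean`` and dispersion size k."""
    mean = np.maximum(mean, 1e-9)
    p = k / (k + mean)
    return rng.negative_binomial(k, p)


def _copy_ratio(total_copies: int, purity: float) -> float:
    return (purity * total_copies + (1.0 - purity) * 2.0) / 2.0


def simulate_dataset(
    cfg: SimulationConfig, panel: list[PanelRegion] | None = None
) -> SyntheticDataset:
    """Draw a complete synthetic cohort under ``cfg``.

    ``panel`` defaults to the 24-gene study panel; a smaller panel makes
    cheap test cohorts.

    Raises
    ------
    ValueError
        for invalid configs, event spans off the panel's chromosomes, or
        event spans that do not contain their gene region.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    panel = default_panel() if panel is None else panel
    regions = {r.gene: r for r in panel}
    chroms = {r.chrom for r in panel}

    for ev in cfg.event_table:
        if ev.chrom not in chroms:
            raise ValueError(f"event on {ev.chrom}: not a panel chromosome")
        region = regions.get(ev.gene)
        if region is None:
            raise ValueError(f"event gene {ev.gene} not on the panel")
        if not (ev.span_start <= region.start and ev.span_end >= region.end):
            raise ValueError(
                f"event span on {ev.gene} must contain the gene region"
            )

    windows = _make_windows(panel, cfg.window_size, rng)
    n_windows = len(windows)
    base_mean = (windows["end"] - windows["start"]).to_numpy() / cfg.read_length
    gc = windows["gc"].to_numpy()
    w_chrom = windows["chrom"].to_numpy()
    w_mid = ((windows["start"] + windows["end"]) / 2.0).to_numpy()

    def sample_bias() -> np.ndarray:
        amp = max(rng.normal(cfg.gc_bias_amplitude, cfg.gc_bias_amplitude / 3), 0.0)
        return _gc_factor(gc, amp)

    # --- controls ---
    control_ids = [f"CM{i + 1:02d}" for i in range(cfg.n_controls_male)] + [
        f"CF{i + 1:02d}" for i in range(cfg.n_controls_female)
    ]
    control_counts = np.empty((cfg.n_controls, n_windows), dtype=np.int64)
    for i in range(cfg.n_controls):
        cov = rng.uniform(*cfg.mean_coverage_range)
        mean = cov * base_mean * sample_bias()
        control_counts[i] = _nb_draw(rng, mean, cfg.overdispersion)

    # --- tumors ---
    tumor_ids, tumor_types = _sample_ids(cfg.tumor_type_mix)
    lo, hi = cfg.purity_range
    purities = {sid: float(rng.uniform(lo, hi)) for sid in tumor_ids}
    for ev in cfg.event_table:
        if ev.sample_id not in purities:
            raise ValueError(f"event sample {ev.sample_id} not in the cohort")

    events_by_sample: dict[str, list[PlantedEvent]] = {s: [] for s in tumor_ids}
    for ev in cfg.event_table:
        events_by_sample[ev.sample_id].append(ev)

    tumor_counts = np.empty((len(tumor_ids), n_windows), dtype=np.int64)
    tumor_cov = {}
    for i, sid in enumerate(tumor_ids):
        cov = rng.uniform(*cfg.tumor_coverage_range)
        tumor_cov[sid] = cov
        ratio = np.ones(n_windows)
        for ev in events_by_sample[sid]:
            inside = (
                (w_chrom == ev.chrom)
                & (w_mid >= ev.span_start)
                & (w_mid < ev.span_end)
            )
            ratio[inside] = _copy_ratio(ev.total_copies, purities[sid])
        mean = cov * base_mean * sample_bias() * ratio
        tumor_counts[i] = _nb_draw(rng, mean, cfg.overdispersion)

    # --- heterozygous SNPs ---
    snp_rows = _simulate_snps(
        rng, panel, tumor_ids, purities, events_by_sample, tumor_cov, cfg
    )

    return SyntheticDataset(
        panel=panel,
        windows=windows,
        control_ids=control_ids,
        control_counts=control_counts,
        tumor_ids=tumor_ids,
        tumor_counts=tumor_counts,
        snp_allele_depths=snp_rows,
        truth=list(cfg.event_table),
        purities=purities,
        tumor_types=tumor_types,
        config=cfg,
    )


def _expected_baf(total_copies: int, b_copies: int, purity: float) -> float:
    """Expected alt-allele fraction of a germline-het SNP under (CN, p)."""
    tumor_total = purity * total_copies + (1.0 - purity) * 2.0
    if tumor_total <= 0:
        return 0.5
    return (purity * b_copies + (1.0 - purity) * 1.0) / tumor_total


def _simulate_snps(
    rng: np.random.Generator,
    panel: list[PanelRegion],
    tumor_ids: list[str],
    purities: dict[str, float],
    events_by_sample: dict[str, list[PlantedEvent]],
    tumor_cov: dict[str, float],
    cfg: SimulationConfig,
) -> pd.DataFrame:
    positions: list[tuple[str, int]] = []
    for region in sorted(panel, key=lambda r: (r.chrom, r.start)):
        pos = np.sort(
            rng.integers(region.start, region.end, size=cfg.snps_per_region)
        )
        positions.extend((region.chrom, int(p)) for p in pos)

    rows: list[tuple[str, str, int, int, int]] = []
    for sid in tumor_ids:
        p = purities[sid]
        for chrom, pos in positions:
            cn, baf = 2, 0.5
            for ev in events_by_sample[sid]:
                if ev.chrom == chrom and ev.span_start <= pos < ev.span_end:
                    cn = ev.total_copies
                    if cn == 0:
                        baf = 0.5  # residual normal reads only
                    else:
                        # one allele carries the dosage change
                        b = int(rng.choice([min(1, cn), max(cn - 1, 0)]))
                        baf = _expected_baf(cn, b, p)
                    break
            depth_mean = tumor_cov[sid] * _copy_ratio(cn, p)
            depth = int(_nb_draw(rng, np.asarray(depth_mean), cfg.overdispersion))
            alt = int(rng.binomial(depth, baf)) if depth > 0 else 0
            rows.append((sid, chrom, pos, depth - alt, alt))

    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "pos", "ref_depth", "alt_depth"]
    )


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-condition config: full cohort with the published 54-event mix."""
    cfg = SimulationConfig(seed=seed, event_table=study_event_mix(), **overrides)
    return cfg


# ---------------------------------------------------------------------------
# published event mix
# ---------------------------------------------------------------------------

# (sample_id, gene, class) for the 54 events: per-gene and per-tumor-type
# counts follow the published per-type frequencies (MYC 9/50 overall with
# 4/8 in ovary, TP53 6/50, BRAF 4/50, ...); class totals are 34 gains,
# 12 amplifications, 8 losses; melanoma carries no amplification and
# pancreas no loss. Events in CDKN2A/PTEN/RB1/FGFR2 fill the gap between
# the per-gene enumeration and the stated 54-event total, placed only in
# samples that already carry events.
_EVENT_CLASSES = {"gain": 3, "amp": 4, "loss": 1}

_STUDY_EVENTS: list[tuple[str, str, str]] = [
    # breast: 5/10 positive, 4 with >= 2 events
    ("BR01", "MYC", "amp"),
    ("BR01", "CCND1", "gain"),
    ("BR01", "PIK3CA", "gain"),
    ("BR01", "AR", "gain"),
    ("BR01", "ERBB2", "amp"),
    ("BR01", "FGFR2", "amp"),
    ("BR02", "MYC", "gain"),
    ("BR02", "MDM2", "amp"),
    ("BR02", "BRAF", "gain"),
    ("BR02", "KRAS", "gain"),
    ("BR03", "CCND1", "gain"),
    ("BR03", "ERBB2", "amp"),
    ("BR03", "EGFR", "gain"),
    ("BR03", "TP53", "loss"),
    ("BR04", "MDM2", "gain"),
    ("BR04", "TP53", "loss"),
    ("BR04", "FGFR1", "gain"),
    ("BR05", "CCNE1", "amp"),
    # melanoma: 2/4 positive, no amplification
    ("ML01", "BRAF", "gain"),
    ("ML01", "RAF1", "gain"),
    ("ML01", "CDK4", "gain"),
    ("ML01", "CDKN2A", "loss"),
    ("ML02", "MDM2", "gain"),
    ("ML02", "RICTOR", "gain"),
    ("ML02", "MET", "gain"),
    # ovary: 5/8 positive, 4 with >= 2 events, MYC in 4/8
    ("OV01", "MYC", "amp"),
    ("OV01", "TP53", "loss"),
    ("OV01", "PIK3CA", "gain"),
    ("OV01", "CDK6", "gain"),
    ("OV01", "RB1", "loss"),
    ("OV02", "MYC", "amp"),
    ("OV02", "BRAF", "gain"),
    ("OV02", "FANCC", "gain"),
    ("OV02", "FGFR2", "amp"),
    ("OV03", "MYC", "gain"),
    ("OV03", "TP53", "loss"),
    ("OV03", "EGFR", "gain"),
    ("OV03", "ALK", "gain"),
    ("OV04", "MYC", "gain"),
    ("OV04", "PDGFRA", "gain"),
    ("OV04", "FGFR1", "gain"),
    ("OV05", "RICTOR", "gain"),
    # pancreas: 2/8 positive, no loss
    ("PN01", "TP53", "gain"),
    ("PN01", "MYC", "amp"),
    ("PN02", "FGFR1", "gain"),
    ("PN02", "ERBB2", "amp"),
    ("PN02", "RB1", "gain"),
    # prostate: 3/20 positive, MYC in 2/20
    ("PR01", "MYC", "amp"),
    ("PR01", "TP53", "loss"),
    ("PR01", "PTEN", "loss"),
    ("PR02", "MYC", "gain"),
    ("PR02", "BRAF", "gain"),
    ("PR02", "FGFR2", "gain"),
    ("PR03", "PIK3CA", "gain"),
]


def study_event_mix() -> list[PlantedEvent]:
    """The 54-event truth set matching the published class and gene mix.

    34 gains (CN=3), 12 amplifications (CN=4) and 8 losses (CN=1) over the
    50-sample cohort; each event spans exactly its gene's panel region.
    """
    regions = {r.gene: r for r in default_panel()}
    events = []
    for sid, gene, cls in _STUDY_EVENTS:
        r = regions[gene]
        events.append(
            PlantedEvent(
                sample_id=sid,
                gene=gene,
                total_copies=_EVENT_CLASSES[cls],
                chrom=r.chrom,
                span_start=r.start,
                span_end=r.end,
            )
        )
    return events


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def _counts_long(
    windows: pd.DataFrame, ids: list[str], counts: np.ndarray
) -> pd.DataFrame:
    n = len(windows)
    return pd.DataFrame(
        {
            "sample_id": np.repeat(ids, n),
            "bin_id": np.tile(np.arange(n), len(ids)),
            "chrom": np.tile(windows["chrom"].to_numpy(), len(ids)),
            "start": np.tile(windows["start"].to_numpy(), len(ids)),
            "end": np.tile(windows["end"].to_numpy(), len(ids)),
            "gc": np.tile(windows["gc"].to_numpy(), len(ids)),
            "reads": counts.ravel(),
        }
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write panel BED, count TSVs, allele-depth TSV and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_panel_bed(ds.panel, outdir / "panel.bed")
    _counts_long(ds.windows, ds.control_ids, ds.control_counts).to_csv(
        outdir / "control_counts.tsv", sep="\t", index=False
    )
    _counts_long(ds.windows, ds.tumor_ids, ds.tumor_counts).to_csv(
        outdir / "tumor_counts.tsv", sep="\t", index=False
    )
    ds.snp_allele_depths.to_csv(
        outdir / "allele_depths.tsv", sep="\t", index=False
    )
    ds.truth_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    meta = pd.DataFrame(
        {
            "sample_id": ds.tumor_ids,
            "tumor_type": [ds.tumor_types[s] for s in ds.tumor_ids],
            "purity": [ds.purities[s] for s in ds.tumor_ids],
        }
    )
    meta.to_csv(outdir / "samples.tsv", sep="\t", index=False)
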