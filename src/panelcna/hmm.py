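"""Copy-number segmentation with a log2 + BAF hidden Markov model.

Hidden states are total copy numbers 0..max_cn. Each state predicts

* a log2 coverage ratio  log2((p*CN + (1-p)*2) / 2)  at tumor purity p,
  observed with Gaussian noise, and
* a set of B-allele frequencies for germline-heterozygous SNPs,
  {(p*b + (1-p)) / (p*CN + (1-p)*2) : b = 0..CN}, observed through an
  equal-weight Beta mixture.

Decoding is exact maximum-a-posteriori Viterbi in log space, run per
chromosome over the dynamic bins (per-bin transition steps: the dynamic
bins equalize information content, so bin index is the natural clock).
Consecutive same-state bins merge into segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist
from sklearn.base import BaseEstimator

from .normalize import Log2Profile

logger = logging.getLogger(__name__)

__all__ = [
    "CopyNumberState",
    "HmmSpec",
    "Segment",
    "emission_loglik",
    "viterbi_path",
    "viterbi_segment",
    "estimate_purity",
    "estimate_log2_sd",
    "HMMSegmenter",
    "segments_to_frame",
]

# expected copy ratio is floored here so homozygous loss at purity 1 keeps
# a finite log2 expectation
_MIN_RATIO = 2.0 ** -5
_BAF_EPS = 1e-4
_MEAN_CLAMP = 0.005

DEFAULT_PURITY_GRID = tuple(np.round(np.arange(0.2, 1.01, 0.1), 2))


@dataclass(frozen=True)
class CopyNumberState:
    """One hidden state: a total copy number."""

    cn_total: int

    def __post_init__(self) -> None:
        if self.cn_total < 0:
            raise ValueError("copy number must be non-negative")

    def expected_log2(self, purity: float) -> float:
        """log2 of the purity-diluted copy ratio; exactly 0 at CN=2."""
        r = (purity * self.cn_total + (1.0 - purity) * 2.0) / 2.0
        return float(np.log2(max(r, _MIN_RATIO)))

    def expected_bafs(self, purity: float) -> np.ndarray:
        """Possible het-SNP alt fractions for b = 0..CN B-allele copies."""
        denom = purity * self.cn_total + (1.0 - purity) * 2.0
        if denom <= 0:
            return np.array([0.5])
        b = np.arange(self.cn_total + 1, dtype=float)
        return (purity * b + (1.0 - purity)) / denom


@dataclass
class HmmSpec:
    """State space and emission/transition parameters of the copy-number HMM."""

    states: list[CopyNumberState] = field(
        default_factory=lambda: [CopyNumberState(c) for c in range(7)]
    )
    purity: float = 1.0
    self_transition: float = 1.0 - 1e-4
    log2_sd: float = 0.1
    baf_concentration: float = 80.0

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must lie in (0, 1]")
        if not (0.5 < self.self_transition < 1.0):
            raise ValueError("self_transition must lie in (0.5, 1)")
        if self.log2_sd <= 0 or self.baf_concentration <= 0:
            raise ValueError("emission spreads must be positive")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def log_transition(self) -> np.ndarray:
        """Uniform switching mass over non-self states; rows sum to one."""
        k = self.n_states
        t = np.full((k, k), (1.0 - self.self_transition) / (k - 1))
        np.fill_diagonal(t, self.self_transition)
        return np.log(t)

    def log_initial(self) -> np.ndarray:
        return np.full(self.n_states, -np.log(self.n_states))


@dataclass
class Segment:
    """A constant-copy-number run of bins."""

    chrom: str
    start: int
    end: int
    cn_total: int
    mean_log2: float
    n_bins: int
    n_snps: int = 0

    @property
    def span(self) -> int:
        return self.end - self.start


def _gauss_loglik(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)


def _baf_mixture_loglik(
    bafs: np.ndarray, state: CopyNumberState, spec: HmmSpec
) -> np.ndarray:
    """Per-SNP log density under the state's equal-weight Beta mixture."""
    if len(bafs) == 0:
        return np.zeros(0)
    means = np.clip(state.expected_bafs(spec.purity), _MEAN_CLAMP, 1 - _MEAN_CLAMP)
    kappa = spec.baf_concentration
    x = np.clip(np.asarray(bafs, dtype=float), _BAF_EPS, 1 - _BAF_EPS)
    # (n_snps, n_components)
    comp = beta_dist.logpdf(
        x[:, None], means[None, :] * kappa, (1.0 - means[None, :]) * kappa
    )
    return logsumexp(comp, axis=1) - np.log(len(means))


def emission_loglik(
    bin_value: float,
    snp_bafs: list[float] | np.ndarray,
    state: CopyNumberState,
    spec: HmmSpec,
) -> float:
    """Joint log-likelihood of one bin's log2 value and its SNP BAFs.

    Always finite: observations are clamped away from the open-interval
    boundaries before the Beta densities are evaluated.
    """
    ll = float(
        _gauss_loglik(np.asarray(bin_value, dtype=float),
                      state.expected_log2(spec.purity), spec.log2_sd)
    )
    ll += float(_baf_mixture_loglik(np.asarray(snp_bafs, dtype=float),
                                    state, spec).sum())
    return ll


def _snp_bin_index(bins: pd.DataFrame, baf: pd.DataFrame) -> np.ndarray:
    """Row index of the bin containing each SNP (-1 if none)."""
    out = np.full(len(baf), -1, dtype=np.int64)
    if len(baf) == 0:
        return out
    pos = baf["pos"].to_numpy()
    bchrom = baf["chrom"].to_numpy()
    for chrom, group in bins.groupby("chrom", sort=False):
        mask = bchrom == chrom
        if not mask.any():
            continue
        starts = group["start"].to_numpy()
        ends = group["end"].to_numpy()
        rows = group.index.to_numpy()
        j = np.searchsorted(starts, pos[mask], side="right") - 1
        ok = (j >= 0) & (pos[mask] < ends[np.clip(j, 0, None)])
        out[mask] = np.where(ok, rows[np.clip(j, 0, None)], -1)
    return out


def emission_matrix(profile: Log2Profile, spec: HmmSpec) -> np.ndarray:
    """(n_bins, n_states) emission log-likelihoods for a whole profile."""
    values = profile.values
    n = len(values)
    em = np.empty((n, spec.n_states))
    snp_bin = _snp_bin_index(profile.bins, profile.baf)
    in_bin = snp_bin >= 0
    bafs = profile.baf["baf"].to_numpy()[in_bin] if len(profile.baf) else np.zeros(0)
    snp_bin = snp_bin[in_bin]
    for s, state in enumerate(spec.states):
        em[:, s] = _gauss_loglik(
            values, state.expected_log2(spec.purity), spec.log2_sd
        )
        if len(bafs):
            snp_ll = _baf_mixture_loglik(bafs, state, spec)
            em[:, s] += np.bincount(snp_bin, weights=snp_ll, minlength=n)
    return em


def viterbi_path(
    emissions: np.ndarray,
    log_transition: np.ndarray,
    log_initial: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Exact MAP state path through a chain; returns (path, path log-lik)."""
    n, k = emissions.shape
    if n == 0:
        return np.zeros(0, dtype=np.int64), 0.0
    psi = np.zeros((n, k), dtype=np.int64)
    delta = log_initial + emissions[0]
    for t in range(1, n):
        scores = delta[:, None] + log_transition
        psi[t] = np.argmax(scores, axis=0)
        delta = scores[psi[t], np.arange(k)] + emissions[t]
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path, float(delta[path[-1]])


def viterbi_segment(
    profile: Log2Profile, spec: HmmSpec
) -> tuple[list[Segment], float]:
    """Segment a profile chromosome by chromosome.

    Chromosomes are decoded independently, and within a chromosome each
    contiguous block of the binned footprint is decoded as its own chain:
    a segment never spans an unobserved gap between panel regions, so a
    reported segment span is always backed by data. Returns the merged
    segments and the total Viterbi path log-likelihood. Deterministic
    given its inputs; an empty chromosome contributes nothing (logged).
    """
    bins = profile.bins
    em = emission_matrix(profile, spec)
    snp_bin = _snp_bin_index(bins, profile.baf)
    snps_per_bin = np.bincount(snp_bin[snp_bin >= 0], minlength=len(bins))
    log_t = spec.log_transition()
    log_i = spec.log_initial()

    segments: list[Segment] = []
    total_ll = 0.0
    for chrom in bins["chrom"].unique():
        rows = np.nonzero((bins["chrom"] == chrom).to_numpy())[0]
        if len(rows) == 0:
            logger.warning("chromosome %s has no retained bins", chrom)
            continue
        starts = bins["start"].to_numpy()[rows]
        ends = bins["end"].to_numpy()[rows]
        breaks = np.nonzero(starts[1:] != ends[:-1])[0] + 1
        for block in np.split(np.arange(len(rows)), breaks):
            sub = rows[block]
            path, ll = viterbi_path(em[sub], log_t, log_i)
            total_ll += ll
            segments.extend(
                _merge_path(bins.iloc[sub], profile.values[sub],
                            snps_per_bin[sub], path, spec)
            )
    return segments, total_ll


def _merge_path(bins, values, snps, path, spec) -> list[Segment]:
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    chrom = bins["chrom"].iloc[0]
    segs = []
    boundaries = np.nonzero(np.diff(path))[0] + 1
    for run in np.split(np.arange(len(path)), boundaries):
        segs.append(
            Segment(
                chrom=chrom,
                start=int(starts[run[0]]),
                end=int(ends[run[-1]]),
                cn_total=spec.states[path[run[0]]].cn_total,
                mean_log2=float(values[run].mean()),
                n_bins=len(run),
                n_snps=int(snps[run].sum()),
            )
        )
    return segs


def estimate_log2_sd(values: np.ndarray, floor: float = 0.02) -> float:
    """Robust emission-noise estimate: 1.4826 x MAD, floored."""
    values = np.asarray(values, dtype=float)
    mad = np.median(np.abs(values - np.median(values)))
    return float(max(1.4826 * mad, floor))


def _spec_at_purity(purity: float, template: HmmSpec) -> HmmSpec:
    return HmmSpec(
        states=template.states,
        purity=purity,
        self_transition=template.self_transition,
        log2_sd=template.log2_sd,
        baf_concentration=template.baf_concentration,
    )


def estimate_purity(
    profile: Log2Profile,
    spec_template: HmmSpec,
    grid: tuple[float, ...] = DEFAULT_PURITY_GRID,
) -> float:
    """Grid-search tumor purity by total Viterbi path log-likelihood.

    Ties break toward larger purity. A profile whose best path carries no
    copy-number event is purity-uninformative; the grid maximum is
    returned with a warning.
    """
    if not grid:
        raise ValueError("purity grid must be non-empty")
    # forgive float accumulation (e.g. arange landing on 1 + 1e-16)
    grid = sorted(1.0 if 1.0 < p < 1.0 + 1e-9 else float(p) for p in grid)
    best_p, best_ll, best_segments = grid[0], -np.inf, None
    for p in grid:
        segments, ll = viterbi_segment(profile, _spec_at_purity(p, spec_template))
        if ll >= best_ll:
            best_p, best_ll, best_segments = p, ll, segments
    if all(s.cn_total == 2 for s in best_segments):
        logger.warning(
            "%s: no candidate events; purity is uninformative, returning "
            "grid maximum", profile.sample_id,
        )
        return float(grid[-1])
    return float(best_p)


def segments_to_frame(sample_id: str, segments: list[Segment]) -> pd.DataFrame:
    """SEG-style table: sample, chrom, start, end, n_bins, cn_total, mean_log2."""
    return pd.DataFrame(
        {
            "sample": sample_id,
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "n_bins": [s.n_bins for s in segments],
            "n_snps": [s.n_snps for s in segments],
            "cn_total": [s.cn_total for s in segments],
            "mean_log2": [s.mean_log2 for s in segments],
        }
    )


class HMMSegmenter(BaseEstimator):
    """Estimator facade over the copy-number HMM.

    Parameters
    ----------
    max_cn : int, default 6
        Highest copy-number state; stronger amplifications collapse into it.
    self_transition : float
        Per-bin probability of staying in the current state.
    purity : "auto" or float in (0, 1]
        Tumor purity; "auto" grid-searches ``purity_grid``.
    log2_sd : float or None
        Gaussian emission sd; None estimates it per profile from the MAD.
    baf_concentration : float
        Beta-mixture concentration for BAF emissions.
    """

    def __init__(
        self,
        max_cn: int = 6,
        self_transition: float = 1.0 - 1e-4,
        purity: float | str = "auto",
        purity_grid: tuple[float, ...] = DEFAULT_PURITY_GRID,
        log2_sd: float | None = None,
        baf_concentration: float = 80.0,
    ):
        self.max_cn = max_cn
        self.self_transition = self_transition
        self.purity = purity
        self.purity_grid = purity_grid
        self.log2_sd = log2_sd
        self.baf_concentration = baf_concentration

    def fit(self, X=None, y=None) -> "HMMSegmenter":  # stateless
        return self

    def _spec(self, profile: Log2Profile, purity: float) -> HmmSpec:
        sd = self.log2_sd or estimate_log2_sd(profile.values)
        return HmmSpec(
            states=[CopyNumberState(c) for c in range(self.max_cn + 1)],
            purity=purity,
            self_transition=self.self_transition,
            log2_sd=sd,
            baf_concentration=self.baf_concentration,
        )

    def predict(
        self, profile: Log2Profile, purity: float | None = None
    ) -> list[Segment]:
        """MAP segments for one profile.

        ``purity`` overrides the constructor setting (e.g. a pathologist's
        cellularity estimate for this sample).
        """
        p = purity if purity is not None else self.purity
        if p == "auto":
            template = self._spec(profile, 1.0)
            p = estimate_purity(profile, template, self.purity_grid)
            logger.info("%s: estimated purity %.2f", profile.sample_id, p)
        segments, _ = viterbi_segment(profile, self._spec(profile, float(p)))
        return segments
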