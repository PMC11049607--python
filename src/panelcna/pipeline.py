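"""End-to-end cohort pipeline: controls -> reference -> per-sample calls.

``PanelCNAPipeline`` is the top-level estimator: ``fit`` consumes the
control cohort's window-level read counts and builds the dynamic-bin
reference; ``predict`` turns tumor window counts (plus optional SNP
allele depths and per-sample purities) into one gene-level call per
(sample, gene).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .calls import DEFAULT_MAX_EVENT_SPAN, call_genes
from .hmm import DEFAULT_PURITY_GRID, HMMSegmenter, Segment, segments_to_frame
from .normalize import Log2Normalizer
from .panel import PanelRegion, default_panel
from .reference import ReferenceBuilder

logger = logging.getLogger(__name__)

__all__ = ["PanelCNAPipeline", "run_cohort"]


class PanelCNAPipeline(BaseEstimator):
    """Targeted-panel CNA caller, from raw bin counts to gene calls.

    Parameters mirror the stage estimators; see
    :class:`~panelcna.reference.ReferenceBuilder`,
    :class:`~panelcna.normalize.Log2Normalizer`,
    :class:`~panelcna.hmm.HMMSegmenter` and
    :func:`~panelcna.calls.call_genes`.

    Attributes
    ----------
    reference_ : ReferenceProfile (after fit)
    segments_ : dict sample_id -> list[Segment] (after predict)
    profiles_ : dict sample_id -> Log2Profile (after predict)
    """

    def __init__(
        self,
        panel: list[PanelRegion] | None = None,
        target_reads_per_bin: int = 1000,
        pseudo_count: float = 0.5,
        min_baf_depth: int = 20,
        max_cn: int = 6,
        self_transition: float = 1.0 - 1e-4,
        purity: float | str = "auto",
        purity_grid: tuple[float, ...] = DEFAULT_PURITY_GRID,
        log2_sd: float | None = None,
        baf_concentration: float = 80.0,
        max_event_span: int = DEFAULT_MAX_EVENT_SPAN,
    ):
        self.panel = panel
        self.target_reads_per_bin = target_reads_per_bin
        self.pseudo_count = pseudo_count
        self.min_baf_depth = min_baf_depth
        self.max_cn = max_cn
        self.self_transition = self_transition
        self.purity = purity
        self.purity_grid = purity_grid
        self.log2_sd = log2_sd
        self.baf_concentration = baf_concentration
        self.max_event_span = max_event_span

    def fit(
        self, X: np.ndarray, windows: pd.DataFrame
    ) -> "PanelCNAPipeline":
        """Build the control reference from (n_controls, n_windows) counts."""
        builder = ReferenceBuilder(self.target_reads_per_bin)
        builder.fit(X, windows)
        self.reference_ = builder.profile_
        self.window_bin_ = builder.window_bin_
        self._normalizer = Log2Normalizer(
            self.pseudo_count, self.min_baf_depth
        ).fit(self.reference_, self.window_bin_)
        self._segmenter = HMMSegmenter(
            max_cn=self.max_cn,
            self_transition=self.self_transition,
            purity=self.purity,
            purity_grid=self.purity_grid,
            log2_sd=self.log2_sd,
            baf_concentration=self.baf_concentration,
        )
        return self

    def predict(
        self,
        X: np.ndarray,
        sample_ids: list[str],
        allele_depths: pd.DataFrame | None = None,
        purities: dict[str, float] | None = None,
    ) -> pd.DataFrame:
        """Gene-level calls for tumor samples.

        ``X`` is (n_samples, n_windows) on the fit-time window grid.
        ``purities`` supplies known cellularities per sample; samples
        missing from it fall back to the pipeline's purity policy.
        """
        if not hasattr(self, "reference_"):
            raise RuntimeError("pipeline is not fitted")
        X = np.atleast_2d(np.asarray(X))
        if X.shape[0] != len(sample_ids):
            raise ValueError("sample_ids must match the count matrix rows")
        panel = self.panel if self.panel is not None else default_panel()

        self.segments_: dict[str, list[Segment]] = {}
        self.profiles_ = {}
        all_calls = []
        for i, sid in enumerate(sample_ids):
            snp = None
            if allele_depths is not None and len(allele_depths):
                snp = allele_depths[allele_depths["sample_id"] == sid]
            profile = self._normalizer.transform_sample(sid, X[i], snp)
            purity = (purities or {}).get(sid)
            segments = self._segmenter.predict(profile, purity=purity)
            self.profiles_[sid] = profile
            self.segments_[sid] = segments
            all_calls.append(
                call_genes(segments, panel, sid, self.max_event_span)
            )
        return pd.concat(all_calls, ignore_index=True)

    def segments_frame(self) -> pd.DataFrame:
        """SEG-format table of the last predict call."""
        frames = [
            segments_to_frame(sid, segs) for sid, segs in self.segments_.items()
        ]
        return pd.concat(frames, ignore_index=True)


def run_cohort(dataset, use_known_purity: bool = True, **pipeline_kwargs):
    """Fit + predict a synthetic dataset; returns (pipeline, calls).

    With ``use_known_purity`` the simulator's per-sample purities stand in
    for the pathologist's cellularity estimate; otherwise purity is
    grid-estimated per sample.
    """
    pipe = PanelCNAPipeline(panel=dataset.panel, **pipeline_kwargs)
    pipe.fit(dataset.control_counts, dataset.windows)
    purities = dataset.purities if use_known_purity else None
    calls = pipe.predict(
        dataset.tumor_counts,
        dataset.tumor_ids,
        allele_depths=dataset.snp_allele_depths,
        purities=purities,
    )
    return pipe, calls
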