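"""Top-level calling workflow: signals in, CN segmentation out.

Chains smoothing, histogram peak finding, genotype-rule anchoring, the E1
grid fit of (alpha, beta), and HMM refinement, honoring the analysis mode
(normal / cell_line / tumor / agilent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .calibration import MAX_CN, SampleModel, SignalCalibration
from .sample_model import (
    AlphaBetaGrid,
    PeakSet,
    anchor_peaks,
    build_histogram_and_find_peaks,
    fit_alpha_beta,
    smooth_signal,
)
from .segmentation import CnSegmentation, HmmConfig, refine

__all__ = ["RunConfig", "PipelineResult", "run_call_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables of the calling workflow, with field-standard defaults."""

    mode: str = "tumor"
    calibration: SignalCalibration = field(default_factory=SignalCalibration)
    grid: AlphaBetaGrid = field(default_factory=AlphaBetaGrid)
    break_penalty: float = 54.0
    max_cn: int = MAX_CN
    window: int = 101
    bin_size: float = 0.1
    call_rate_threshold: float = 60.0
    het_threshold: float = 3.0
    height_ratio: float = 2.0
    max_iter: int = 20
    no_contamination_adjust: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("break_penalty", "window", "bin_size", "call_rate_threshold",
                     "het_threshold", "height_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineResult:
    segmentation: CnSegmentation
    peaks: PeakSet
    alpha0: float
    beta0: float
    e1: float

    def report(self) -> dict:
        rep = self.segmentation.report()
        rep.update(
            {
                "alpha0": self.alpha0,
                "beta0": self.beta0,
                "e1": self.e1,
                "peaks": [p.to_dict() for p in self.peaks],
            }
        )
        return rep


def run_call_pipeline(signals: pd.DataFrame, config: RunConfig | None = None) -> PipelineResult:
    """Run the full CN-calling chain on a per-probe signal table.

    ``signals`` must hold (snp_id, chrom, pos, signal) and may hold a
    per-probe ``genotype`` column (AA/AB/BB/NC) used for peak anchoring;
    without it the genotype rules are unavailable, as for oligo-CGH
    arrays.  Deterministic given inputs and config.
    """
    config = config or RunConfig()
    df = signals.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("empty signal table")

    mode = config.mode
    if config.no_contamination_adjust and mode in ("tumor", "agilent"):
        mode = "cell_line"  # alpha pinned to 0, beta still fitted

    track = smooth_signal(df[["chrom", "pos", "signal"]], window=config.window)
    genotypes = df["genotype"] if ("genotype" in df.columns and mode != "agilent") else None
    peaks = build_histogram_and_find_peaks(
        track, bin_size=config.bin_size, genotypes=genotypes
    )
    if len(peaks) == 0:
        raise RuntimeError("peak detection found no peaks; signal track degenerate")
    peaks = anchor_peaks(
        peaks,
        mode,
        call_rate_threshold=config.call_rate_threshold,
        het_threshold=config.het_threshold,
        height_ratio=config.height_ratio,
    )
    alpha0, beta0, e1, _ = fit_alpha_beta(
        peaks, config.calibration, mode, config.grid, config.max_cn
    )
    logger.info("initial fit: alpha=%.2f beta=%.3f E1=%.4g", alpha0, beta0, e1)

    initial = SampleModel(alpha=alpha0, beta=beta0, sigma2=1.0, mode=mode)
    initial.sigma2 = None  # force data-driven initialization in refine
    seg = refine(
        df,
        initial,
        config.calibration,
        HmmConfig(config.max_cn, config.break_penalty, None, config.max_iter),
        config.grid,
        smoothing_window=config.window,
    )
    return PipelineResult(segmentation=seg, peaks=peaks, alpha0=alpha0, beta0=beta0, e1=e1)
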