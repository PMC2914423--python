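"""Estimate contamination (alpha) and genome-size factor (beta) per sample.

The per-SNP signals are smoothed with a 101-probe geometric-mean window per
chromosome; a 0.1-wide histogram of the smoothed track shows one local
maximum per copy-number level present in the sample.  A small set of
genotype-based rules anchors some peaks to integer CN (a peak of SNPs with
genotyping call rate < 60% must be CN=0; heterozygosity < 3% indicates
CN=1; a dominant peak is CN=2), and the remaining assignment together with
(alpha, beta) is found by brute-force grid minimization of

    E1(alpha, beta) = sum_k H(T_k) * (log T_k - log S(c_k))^2,

where S(c) is the adjusted expected signal and, for unanchored peaks, c_k
is the best-matching CN at each grid point.  The result seeds the HMM
refinement in :mod:`cnarray.segmentation`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import MAX_CN, SampleModel, SignalCalibration

__all__ = [
    "SIGNAL_FLOOR",
    "SmoothedTrack",
    "Peak",
    "PeakSet",
    "AlphaBetaGrid",
    "smooth_signal",
    "build_histogram_and_find_peaks",
    "anchor_peaks",
    "fit_alpha_beta",
]

#: Signals are clamped to this floor before any logarithm.
SIGNAL_FLOOR = 0.01

DEFAULT_WINDOW = 101
DEFAULT_BIN = 0.1
#: Peaks holding less than this fraction of SNPs are flagged (not dropped).
MIN_PEAK_HEIGHT_FRAC = 0.0002

CALL_RATE_THRESHOLD = 60.0   # percent, below => CN=0 region
HET_THRESHOLD = 3.0          # percent, below => CN=1 region
HEIGHT_RATIO = 2.0           # dominant-peak rule


@dataclass
class SmoothedTrack:
    """Per-SNP smoothed signals T_i aligned with the input table."""

    frame: pd.DataFrame  # snp_id, chrom, pos, signal, smoothed
    window: int = DEFAULT_WINDOW

    @property
    def smoothed(self) -> np.ndarray:
        return self.frame["smoothed"].to_numpy(float)


@dataclass
class Peak:
    position: float              # bin-center of the mode, signal units
    height: float                # percent of SNPs in the mode bin
    call_rate: float | None = None       # percent, over mode bin +/- 1
    heterozygosity: float | None = None  # percent AB among called
    anchored_cn: int | None = None
    assigned_cn: int | None = None
    flagged: bool = False
    bin_range: tuple[int, int] = (0, 0)  # inclusive bin-index range of the mode

    def to_dict(self) -> dict:
        return {
            "position": self.position,
            "height_pct": self.height,
            "call_rate_pct": self.call_rate,
            "heterozygosity_pct": self.heterozygosity,
            "anchored_cn": self.anchored_cn,
            "assigned_cn": self.assigned_cn,
            "flagged": self.flagged,
        }


@dataclass
class PeakSet:
    peaks: list[Peak]
    bin_size: float = DEFAULT_BIN
    n_snps: int = 0

    def __post_init__(self) -> None:
        pos = [p.position for p in self.peaks]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("peak positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def _window_mean(x: np.ndarray, half: int) -> np.ndarray:
    """Centered moving mean with windows truncated at the array ends."""
    n = x.size
    cs = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half, n - 1)
    return (cs[hi + 1] - cs[lo]) / (hi - lo + 1)


def smooth_signal(
    signals: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    floor: float = SIGNAL_FLOOR,
) -> SmoothedTrack:
    """Geometric-mean smoothing: log T_i = mean of log S_j over the window.

    ``signals`` must hold columns (chrom, pos, signal) sorted by position
    within chromosome; windows are truncated (never wrapped) at chromosome
    ends and never span chromosomes.  Natural logs; signals clamped at
    ``floor`` first.  A chromosome with fewer than 2 probes is copied
    through unsmoothed.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    df = signals.copy()
    out = np.empty(len(df), dtype=float)
    logs = np.log(np.maximum(df["signal"].to_numpy(float), floor))
    start = 0
    for chrom, sub in df.groupby("chrom", sort=False):
        n = len(sub)
        seg = logs[start : start + n]
        if n < 2:
            warnings.warn(f"chromosome {chrom}: <2 probes, copied through unsmoothed")
            out[start : start + n] = np.exp(seg)
        else:
            out[start : start + n] = np.exp(_window_mean(seg, half))
        start += n
    df["smoothed"] = out
    return SmoothedTrack(frame=df, window=window)


def _mode_runs(counts: np.ndarray) -> list[tuple[int, int]]:
    """Local maxima of a histogram after merging equal-height plateaus.

    Returns inclusive (start, end) bin-index ranges of runs strictly higher
    than both neighboring runs (array ends padded with zero counts).
    """
    # run-length encode
    runs = []
    s = 0
    for i in range(1, len(counts) + 1):
        if i == len(counts) or counts[i] != counts[s]:
            runs.append((s, i - 1, counts[s]))
            s = i
    out = []
    for j, (a, b, h) in enumerate(runs):
        if h <= 0:
            continue
        left = runs[j - 1][2] if j > 0 else 0
        right = runs[j + 1][2] if j + 1 < len(runs) else 0
        if h > left and h > right:
            out.append((a, b))
    return out


def build_histogram_and_find_peaks(
    track: SmoothedTrack,
    bin_size: float = DEFAULT_BIN,
    min_height_frac: float = MIN_PEAK_HEIGHT_FRAC,
    genotypes: pd.Series | None = None,
) -> PeakSet:
    """Histogram the smoothed track and locate its modes.

    Bins are ``[k*bin, (k+1)*bin)`` on the raw signal scale.  A peak is a
    bin strictly higher than both neighbors, after merging adjacent
    equal-height bins into a plateau whose center bin is reported.  Peaks
    below ``min_height_frac`` of SNPs are retained but flagged.

    ``genotypes``, if given, is a per-SNP Series aligned with the track
    frame with values in {AA, AB, BB, NC}; per-peak genotyping call rate
    (percent non-NC) and heterozygosity (percent AB among called) are
    computed over SNPs whose T falls within the mode's bins +/- 1 bin.
    """
    t = track.smoothed
    if t.size == 0:
        raise ValueError("empty smoothed track")
    k = np.floor(t / bin_size).astype(int)
    kmax = int(k.max())
    counts = np.bincount(np.clip(k, 0, None), minlength=kmax + 1)
    modes = _mode_runs(counts)

    peaks = []
    for a, b in modes:
        center_bin = (a + b) // 2
        height_frac = counts[center_bin] / t.size
        # position refined to the mass centroid over the mode +/- 1 bin:
        # bin centers quantize T_k by up to bin/2, which is enough to blur
        # the low-CN nonlinearity the (alpha, beta) fit keys on
        sel = (k >= a - 1) & (k <= b + 1)
        peak = Peak(
            position=float(t[sel].mean()) if sel.any() else float((center_bin + 0.5) * bin_size),
            height=100.0 * height_frac,
            flagged=height_frac < min_height_frac,
            bin_range=(a, b),
        )
        if genotypes is not None:
            sel = (k >= a - 1) & (k <= b + 1)
            g = np.asarray(genotypes)[sel]
            n = g.size
            if n:
                called = g != "NC"
                peak.call_rate = 100.0 * called.mean()
                n_called = int(called.sum())
                peak.heterozygosity = (
                    100.0 * (g[called] == "AB").mean() if n_called else 0.0
                )
        peaks.append(peak)
    return PeakSet(peaks=peaks, bin_size=bin_size, n_snps=int(t.size))


def anchor_peaks(
    peaks: PeakSet,
    mode: str,
    call_rate_threshold: float = CALL_RATE_THRESHOLD,
    het_threshold: float = HET_THRESHOLD,
    height_ratio: float = HEIGHT_RATIO,
) -> PeakSet:
    """Pin integer CN to peaks the genotype statistics identify.

    Rules, applied in order (an earlier anchor wins a conflict, with a
    warning):

    1. a single maximum is the diploid peak: c_1 = 2;
    2. n > 1 and the first peak's call rate < 60%  => c_1 = 0;
    3. n > 1 and the first peak's heterozygosity < 3%  => c_1 = 1;
    4. n > 2, c_1 = 0 and the second peak's heterozygosity < 3% => c_2 = 1;
    5. n > 1 and the highest peak at least twice the second highest => CN=2.

    In ``agilent`` mode rules 2-4 are unavailable (no per-probe genotypes).
    Anchors constrain the grid fit; they are not final calls.  The
    operation is idempotent.
    """
    ps = [replace(p) for p in peaks.peaks]
    out = PeakSet(peaks=ps, bin_size=peaks.bin_size, n_snps=peaks.n_snps)
    n = len(ps)
    genotype_rules = mode != "agilent"

    def _set(peak: Peak, cn: int, rule: str) -> None:
        if peak.anchored_cn is not None and peak.anchored_cn != cn:
            warnings.warn(
                f"anchor conflict at peak {peak.position}: rule {rule} wants CN={cn}, "
                f"keeping CN={peak.anchored_cn}"
            )
            return
        peak.anchored_cn = cn

    if n == 1:
        _set(ps[0], 2, "1")
        return out
    if genotype_rules and n > 1:
        p1 = ps[0]
        if p1.call_rate is not None and p1.call_rate < call_rate_threshold:
            _set(p1, 0, "2")
        if p1.heterozygosity is not None and p1.heterozygosity < het_threshold:
            _set(p1, 1, "3")
        if n > 2 and p1.anchored_cn == 0:
            p2 = ps[1]
            if p2.heterozygosity is not None and p2.heterozygosity < het_threshold:
                _set(p2, 1, "4")
    if n > 1:
        order = sorted(range(n), key=lambda i: -ps[i].height)
        if ps[order[0]].height >= height_ratio * ps[order[1]].height:
            _set(ps[order[0]], 2, "5")
    return out


@dataclass
class AlphaBetaGrid:
    """Enumeration grid for (alpha, beta)."""

    alpha_min: float = 0.0
    alpha_max: float = 0.99
    alpha_step: float = 0.01
    beta_min: float = 0.5
    beta_max: float = 2.0
    beta_step: float = 0.005

    def alphas(self) -> np.ndarray:
        n = int(round((self.alpha_max - self.alpha_min) / self.alpha_step)) + 1
        return self.alpha_min + self.alpha_step * np.arange(n)

    def betas(self) -> np.ndarray:
        n = int(round((self.beta_max - self.beta_min) / self.beta_step)) + 1
        return self.beta_min + self.beta_step * np.arange(n)


def _log_signal_grid(
    alphas: np.ndarray, betas: np.ndarray, cal: SignalCalibration, max_cn: int
) -> np.ndarray:
    """log S(c; alpha, beta) on the grid, shape (n_alpha, n_beta, max_cn+1)."""
    s0 = cal.s0_vector(max_cn)[None, None, :]
    a = alphas[:, None, None]
    b = betas[None, :, None]
    s = b * (2.0 * a + (1.0 - a) * s0)
    return np.log(np.maximum(s, SIGNAL_FLOOR))


def fit_alpha_beta(
    peaks: PeakSet,
    cal: SignalCalibration | None = None,
    mode: str = "tumor",
    grid: AlphaBetaGrid | None = None,
    max_cn: int = MAX_CN,
    near_tie_margin: float = 0.05,
) -> tuple[float, float, float, list[int]]:
    """Grid-minimize E1 over (alpha, beta); returns (alpha0, beta0, E1, c_k).

    Anchored peaks keep their CN; every other peak takes, at each grid
    point, the CN in 0..max_cn minimizing |log T_k - log S(c)| (ties to the
    smaller CN).  ``normal`` mode returns (0, 1) directly; ``cell_line``
    mode fixes alpha = 0.

    The integer-CN ladder admits a family of near-equivalent explanations
    of the same peak set — most prominently the alias at
    alpha' = (1 + alpha)/2 that maps copy numbers 1,2,3,4 onto 0,2,4,6 —
    whose E1 values differ from the correct solution's only by histogram
    noise whenever no peak beyond the diploid one is anchored.  Since
    every alias sits at higher contamination than the solution it shadows
    (a lower-alpha alias would need half-integer states), near-ties
    resolve toward the smallest contamination: grid points with
    E1 <= min(E1) + ``near_tie_margin`` (an absolute slack in the
    height-weighted squared-log units of E1, generous against
    transition-artifact peaks yet far below the misfit of a genuinely
    wrong solution) are grouped into connected basins, and the basin
    whose own optimum has the smallest alpha wins; its optimum is
    returned, so the estimate is not biased across the basin's width.
    """
    cal = cal or SignalCalibration()
    grid = grid or AlphaBetaGrid()
    if len(peaks) == 0:
        raise ValueError("no peaks to fit")
    if mode == "normal":
        alphas = np.array([0.0])
        betas = np.array([1.0])
    elif mode == "cell_line":
        alphas = np.array([0.0])
        betas = grid.betas()
    else:
        alphas = grid.alphas()
        betas = grid.betas()

    logs_grid = _log_signal_grid(alphas, betas, cal, max_cn)  # (na, nb, C)
    e1 = np.zeros(logs_grid.shape[:2])
    for p in peaks:
        log_t = np.log(max(p.position, SIGNAL_FLOOR))
        d2 = (log_t - logs_grid) ** 2
        if p.anchored_cn is not None:
            contrib = d2[:, :, p.anchored_cn]
        else:
            contrib = d2.min(axis=2)
        e1 += p.height * contrib

    from scipy import ndimage

    near = e1 <= float(e1.min()) + near_tie_margin + 1e-12
    labels, n_basins = ndimage.label(near)
    best = None  # ((alpha_of_optimum, e1_of_optimum), basin_label)
    for lab in range(1, n_basins + 1):
        masked = np.where(labels == lab, e1, np.inf)
        ia, ib = np.unravel_index(int(np.argmin(masked)), e1.shape)
        key = (float(alphas[ia]), float(masked[ia, ib]))
        if best is None or key < best[0]:
            best = (key, lab)
    # within the winning basin the landscape can be nearly flat (at strong
    # contamination the compressed ladder merges the basins); take the
    # smallest alpha whose E1 ties the basin optimum within a tight slack
    masked = np.where(labels == best[1], e1, np.inf)
    tie = masked <= masked.min() + 0.04 * near_tie_margin + 1e-12
    ia = int(np.flatnonzero(tie.any(axis=1))[0])
    ib = int(np.argmin(np.where(tie[ia], masked[ia], np.inf)))
    alpha0, beta0 = float(alphas[ia]), float(betas[ib])

    # final CN assignment at the optimum
    log_s = _log_signal_grid(np.array([alpha0]), np.array([beta0]), cal, max_cn)[0, 0]
    assigned = []
    for p in peaks:
        if p.anchored_cn is not None:
            c = p.anchored_cn
        else:
            c = int(np.argmin(np.abs(np.log(max(p.position, SIGNAL_FLOOR)) - log_s)))
        p.assigned_cn = c
        assigned.append(c)
    return alpha0, beta0, float(e1[ia, ib]), assigned
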