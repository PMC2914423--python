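"""Integer copy-number segmentation by dynamic programming.

States are integer copy numbers 0..70.  The log-likelihood of a CN path
{c_i} over one chromosome is, up to constants,

    -sum_i (log S_i - log S(c_i))^2 / (2 sigma^2)  -  lambda * #breaks,

with lambda = -ln(gamma) the cost of a CN change between adjacent probes
(gamma being the a-priori probability that neighbors differ).  The uniform
break penalty admits an O(n * n_states) Viterbi-style recursion: at each
probe the best predecessor is either the same state or the globally
cheapest state plus lambda.  Chromosomes are independent and decoded
separately.

``refine`` alternates decoding with re-estimation of (alpha, beta) by
grid-minimizing the mean squared log-residual E2 (whose optimum value also
re-estimates sigma^2), until both parameters stabilize.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import MAX_CN, SampleModel, SignalCalibration, expected_signal
from .sample_model import SIGNAL_FLOOR, AlphaBetaGrid, _log_signal_grid, smooth_signal

__all__ = [
    "HmmConfig",
    "CnSegmentation",
    "decode_path",
    "estimate_e2",
    "minimize_e2",
    "refine",
    "segments_from_path",
]

SIGMA2_FLOOR = 1e-4


@dataclass
class HmmConfig:
    """Decoder settings.

    ``break_penalty`` is -ln(gamma); the decoded path depends on
    sigma^2 * break_penalty, so the default 54 is calibrated jointly with
    the typical per-probe log-signal variance (~0.04).
    """

    max_cn: int = MAX_CN
    break_penalty: float = 54.0
    sigma2: float | None = None
    max_iter: int = 20

    def __post_init__(self) -> None:
        if self.max_cn < 2:
            raise ValueError("max_cn must be >= 2")
        if self.break_penalty <= 0:
            raise ValueError("break_penalty must be positive")


@dataclass
class CnSegmentation:
    """Decoded per-probe CN path plus derived segments and the final model."""

    probes: pd.DataFrame      # snp_id, chrom, pos, signal, cn
    segments: pd.DataFrame    # chrom, start, end, cn, n_probes, mean_signal
    sample_model: SampleModel
    iterations: int = 0
    converged: bool = True
    e2: float = float("nan")

    def report(self) -> dict:
        return {
            "alpha": self.sample_model.alpha,
            "beta": self.sample_model.beta,
            "sigma2": self.sample_model.sigma2,
            "mode": self.sample_model.mode,
            "iterations": self.iterations,
            "converged": self.converged,
            "e2": self.e2,
            "n_segments": int(len(self.segments)),
        }


def decode_path(
    signals: np.ndarray,
    model: SampleModel,
    cal: SignalCalibration | None = None,
    config: HmmConfig | None = None,
) -> np.ndarray:
    """Most likely integer-CN path for one chromosome's ordered signals.

    Emission cost for probe i in state c is
    ``(log S_i - log S(c))^2 / (2 sigma^2)``; a state change between
    adjacent probes costs ``break_penalty``.  Ties resolve to the smaller
    CN in the backtrace.  Deterministic.
    """
    cal = cal or SignalCalibration()
    config = config or HmmConfig()
    sigma2 = config.sigma2 if config.sigma2 is not None else model.sigma2
    if sigma2 is None or sigma2 <= 0:
        raise ValueError("sigma2 must be positive for decoding")
    x = np.asarray(signals, dtype=float)
    n = x.size
    if n == 0:
        return np.empty(0, dtype=int)

    n_states = config.max_cn + 1
    log_s = np.log(
        np.maximum(expected_signal(np.arange(n_states), model, cal), SIGNAL_FLOOR)
    )
    log_x = np.log(np.maximum(x, SIGNAL_FLOOR))
    emis = (log_x[:, None] - log_s[None, :]) ** 2 / (2.0 * sigma2)  # (n, C)

    lam = config.break_penalty
    ptr = np.empty((n, n_states), dtype=np.int16)
    cost = emis[0].copy()
    states = np.arange(n_states, dtype=np.int16)
    for i in range(1, n):
        j = int(np.argmin(cost))          # first occurrence = smallest CN
        base = cost[j] + lam
        stay = cost <= base               # ties prefer no break
        ptr[i] = np.where(stay, states, j)
        cost = emis[i] + np.where(stay, cost, base)

    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmin(cost))       # ties -> smaller CN
    for i in range(n - 1, 0, -1):
        path[i - 1] = ptr[i][path[i]]
    return path


def estimate_e2(
    signals: np.ndarray,
    path: np.ndarray,
    alpha: float,
    beta: float,
    cal: SignalCalibration | None = None,
) -> float:
    """Mean squared log-residual of signals about S(c_i); doubles as the
    sigma^2 estimate."""
    cal = cal or SignalCalibration()
    x = np.log(np.maximum(np.asarray(signals, dtype=float), SIGNAL_FLOOR))
    s0 = cal.s0_vector()[np.asarray(path, dtype=int)]
    mu = np.log(np.maximum(beta * (2.0 * alpha + (1.0 - alpha) * s0), SIGNAL_FLOOR))
    return float(np.mean((x - mu) ** 2))


def minimize_e2(
    signals: np.ndarray,
    path: np.ndarray,
    cal: SignalCalibration,
    mode: str,
    grid: AlphaBetaGrid,
    max_cn: int = MAX_CN,
) -> tuple[float, float, float]:
    """Grid-minimize E2(alpha, beta) with the CN path held fixed.

    Uses per-state sufficient statistics so the whole grid is one
    broadcast.  Ties resolve to smaller alpha, then smaller beta.
    """
    if mode == "normal":
        return 0.0, 1.0, estimate_e2(signals, path, 0.0, 1.0, cal)
    alphas = np.array([0.0]) if mode == "cell_line" else grid.alphas()
    betas = grid.betas()

    log_x = np.log(np.maximum(np.asarray(signals, dtype=float), SIGNAL_FLOOR))
    c = np.asarray(path, dtype=int)
    n = c.size
    n_c = np.bincount(c, minlength=max_cn + 1).astype(float)
    sum_c = np.bincount(c, weights=log_x, minlength=max_cn + 1)
    ss_c = np.bincount(c, weights=log_x ** 2, minlength=max_cn + 1)

    mu = _log_signal_grid(alphas, betas, cal, max_cn)  # (na, nb, C)
    e2 = (ss_c.sum() - 2.0 * np.tensordot(mu, sum_c, axes=([2], [0]))
          + np.tensordot(mu ** 2, n_c, axes=([2], [0]))) / n
    flat = int(np.argmin(e2))
    ia, ib = np.unravel_index(flat, e2.shape)
    return float(alphas[ia]), float(betas[ib]), float(e2[ia, ib])


def segments_from_path(probes: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-probe CN path into maximal constant-CN segments.

    Coordinates are BED-like 0-based half-open: start = first probe's
    (1-based) position - 1, end = last probe's position.
    """
    rows = []
    for chrom, sub in probes.groupby("chrom", sort=False):
        cn = sub["cn"].to_numpy(int)
        pos = sub["pos"].to_numpy(int)
        sig = sub["signal"].to_numpy(float)
        brk = np.flatnonzero(np.diff(cn) != 0) + 1
        starts = np.concatenate([[0], brk])
        ends = np.concatenate([brk, [cn.size]])
        for a, b in zip(starts, ends):
            rows.append(
                (chrom, int(pos[a]) - 1, int(pos[b - 1]), int(cn[a]), int(b - a),
                 float(np.mean(sig[a:b])))
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "cn", "n_probes", "mean_signal"]
    )


def _decode_all(
    frame: pd.DataFrame,
    model: SampleModel,
    cal: SignalCalibration,
    config: HmmConfig,
) -> np.ndarray:
    path = np.empty(len(frame), dtype=int)
    start = 0
    for _, sub in frame.groupby("chrom", sort=False):
        n = len(sub)
        path[start : start + n] = decode_path(
            sub["signal"].to_numpy(float), model, cal, config
        )
        start += n
    return path


def _init_sigma2(
    frame: pd.DataFrame,
    model: SampleModel,
    cal: SignalCalibration,
    max_cn: int,
    window: int,
) -> float:
    """Starting sigma^2: residuals about the CN levels nearest the smoothed
    track (no decoding needed yet)."""
    track = smooth_signal(frame[["chrom", "pos", "signal"]], window=window)
    log_t = np.log(np.maximum(track.smoothed, SIGNAL_FLOOR))
    mu = np.log(
        np.maximum(expected_signal(np.arange(max_cn + 1), model, cal), SIGNAL_FLOOR)
    )
    c = np.argmin(np.abs(log_t[:, None] - mu[None, :]), axis=1)
    e2 = estimate_e2(frame["signal"].to_numpy(float), c, model.alpha, model.beta, cal)
    return max(e2, SIGMA2_FLOOR)


def refine(
    signals: pd.DataFrame,
    initial: SampleModel,
    cal: SignalCalibration | None = None,
    config: HmmConfig | None = None,
    grid: AlphaBetaGrid | None = None,
    alpha_tol: float = 0.03,
    beta_rel_tol: float = 0.001,
    smoothing_window: int = 101,
) -> CnSegmentation:
    """Iteratively decode and re-estimate (alpha, beta, sigma^2).

    Each round decodes all chromosomes under the current model, then
    grid-minimizes E2 with the path fixed and sets sigma^2 = E2.
    Convergence: |delta alpha| < ``alpha_tol`` (absolute) and
    |delta beta| / beta < ``beta_rel_tol``.  ``normal`` mode performs a
    single decode.  If the parameter sequence revisits a state
    (oscillation), the best-E2 iterate is returned with converged=False.
    """
    cal = cal or SignalCalibration()
    config = config or HmmConfig()
    grid = grid or AlphaBetaGrid()
    frame = signals.copy().reset_index(drop=True)

    alpha, beta = initial.alpha, initial.beta
    sigma2 = initial.sigma2 if initial.sigma2 and initial.sigma2 > 0 else None
    mode = initial.mode
    if sigma2 is None:
        probe_model = SampleModel(alpha=alpha, beta=beta, sigma2=1.0, mode=mode)
        sigma2 = _init_sigma2(frame, probe_model, cal, config.max_cn, smoothing_window)

    if mode == "normal":
        model = SampleModel(alpha=0.0, beta=1.0, sigma2=sigma2, mode=mode)
        path = _decode_all(frame, model, cal, config)
        e2 = estimate_e2(frame["signal"].to_numpy(float), path, 0.0, 1.0, cal)
        frame["cn"] = path
        return CnSegmentation(
            probes=frame,
            segments=segments_from_path(frame),
            sample_model=SampleModel(0.0, 1.0, max(e2, SIGMA2_FLOOR), mode),
            iterations=1,
            converged=True,
            e2=e2,
        )

    seen: set[tuple[float, float]] = set()
    best = None  # (e2, path, alpha, beta, sigma2, iteration)
    converged = False
    it = 0
    path = None
    for it in range(1, config.max_iter + 1):
        model = SampleModel(alpha=alpha, beta=beta, sigma2=sigma2, mode=mode)
        cfg = HmmConfig(config.max_cn, config.break_penalty, sigma2, config.max_iter)
        path = _decode_all(frame, model, cal, cfg)
        new_alpha, new_beta, e2 = minimize_e2(
            frame["signal"].to_numpy(float), path, cal, mode, grid, config.max_cn
        )
        if best is None or e2 < best[0]:
            best = (e2, path.copy(), new_alpha, new_beta, max(e2, SIGMA2_FLOOR), it)
        if abs(new_alpha - alpha) < alpha_tol and abs(new_beta - beta) / max(beta, 1e-9) < beta_rel_tol:
            alpha, beta, sigma2 = new_alpha, new_beta, max(e2, SIGMA2_FLOOR)
            converged = True
            break
        key = (round(new_alpha, 6), round(new_beta, 6))
        if key in seen:
            e2, path, alpha, beta, sigma2, it = best
            converged = False
            break
        seen.add(key)
        alpha, beta, sigma2 = new_alpha, new_beta, max(e2, SIGMA2_FLOOR)
    final_model = SampleModel(alpha=alpha, beta=beta, sigma2=sigma2, mode=mode)
    # re-decode so the reported path matches the final parameters
    path = _decode_all(
        frame, final_model, cal, HmmConfig(config.max_cn, config.break_penalty, sigma2)
    )
    e2 = estimate_e2(frame["signal"].to_numpy(float), path, alpha, beta, cal)
    frame["cn"] = path
    return CnSegmentation(
        probes=frame,
        segments=segments_from_path(frame),
        sample_model=final_model,
        iterations=it,
        converged=converged,
        e2=e2,
    )
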