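"""Independent brute-force oracles used by multiple test modules."""

import numpy as np

from cnarray.calibration import expected_signal


def all_paths(n_states: int, n_probes: int) -> np.ndarray:
    """Every state sequence of length n_probes over n_states states,
    shape (n_states**n_probes, n_probes)."""
    grids = np.meshgrid(*([np.arange(n_states)] * n_probes), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def enumerate_best_path(signals, model, cal, config):
    """Exhaustive minimum-cost CN path (emission + break costs), as an
    independent check of the dynamic-programming decoder."""
    n_states = config.max_cn + 1
    log_s = np.log(np.maximum(
        expected_signal(np.arange(n_states), model, cal), 0.01))
    log_x = np.log(np.maximum(np.asarray(signals, float), 0.01))
    emis = (log_x[:, None] - log_s[None, :]) ** 2 / (2.0 * config.sigma2)
    paths = all_paths(n_states, len(signals))
    cost = emis[np.arange(len(signals))[None, :], paths].sum(axis=1)
    if paths.shape[1] > 1:
        cost = cost + config.break_penalty * (np.diff(paths, axis=1) != 0).sum(axis=1)
    best = int(np.argmin(cost))
    return paths[best], float(cost[best])


def path_cost(path, signals, model, cal, config):
    log_s = np.log(np.maximum(
        expected_signal(np.arange(config.max_cn + 1), model, cal), 0.01))
    log_x = np.log(np.maximum(np.asarray(signals, float), 0.01))
    c = np.asarray(path)
    return float(
        (((log_x - log_s[c]) ** 2) / (2 * config.sigma2)).sum()
        + config.break_penalty * (np.diff(c) != 0).sum()
    )
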