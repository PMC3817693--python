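"""Model-vs-reference density correlation and ensemble statistics.

The quality measure throughout is the global Pearson correlation between
density simulated from a model and a reference map, after both are low-pass
filtered by hard Fourier truncation at a stated resolution limit (default
3 A).  Ensemble statistics summarise a set of sampled models the way a
rebuilding benchmark is scored: the average model CC, the best sampled CC,
and the CC of the best of ``select_k`` models chosen by an *independent*
selector score (a stand-in for ranking against unphased data — here a
density score on a held-out selection map, never the evaluation map).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import fft as sp_fft

from .density import DensityMap, simulate_on_grid
from .model import BackboneModel

DEFAULT_RESOLUTION_LIMIT = 3.0


def lowpass(values: np.ndarray, spacing: np.ndarray,
            resolution_limit: float) -> np.ndarray:
    """Hard Fourier truncation at spatial frequency 1/resolution_limit."""
    spec = sp_fft.fftn(values)
    freqs = [sp_fft.fftfreq(n, d=float(h))
             for n, h in zip(values.shape, spacing)]
    k2 = (freqs[0][:, None, None] ** 2 + freqs[1][None, :, None] ** 2
          + freqs[2][None, None, :] ** 2)
    spec[k2 > 1.0 / resolution_limit**2] = 0.0
    return sp_fft.ifftn(spec).real


def model_map_cc(model: BackboneModel, reference_map: DensityMap,
                 resolution_limit: float = DEFAULT_RESOLUTION_LIMIT) -> float:
    """Pearson correlation of model-simulated vs reference density, both
    low-pass filtered to ``resolution_limit``."""
    calc = simulate_on_grid(model, reference_map)
    a = lowpass(calc.values, reference_map.spacing, resolution_limit)
    b = lowpass(reference_map.values, reference_map.spacing, resolution_limit)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance map after low-pass filtering")
    return float(np.corrcoef(a.ravel(), b.ravel())[0, 1])


def ensemble_stats(models: list[BackboneModel], reference_map: DensityMap,
                   select_k: int, selector_score,
                   resolution_limit: float = DEFAULT_RESOLUTION_LIMIT):
    """(avg_cc, best_cc, sel_cc) over an ensemble.

    ``selector_score`` is a callable model -> float with *lower is better*
    semantics (like the density score); ``sel_cc`` is the best CC among the
    ``select_k`` models it ranks best.
    """
    if select_k <= 0:
        raise ValueError("select_k must be positive")
    if len(models) < select_k:
        raise ValueError("fewer models than select_k")
    ccs = np.array([model_map_cc(m, reference_map, resolution_limit)
                    for m in models])
    scores = np.array([selector_score(m) for m in models])
    order = np.argsort(scores, kind="stable")
    sel_cc = float(ccs[order[:select_k]].max())
    return float(ccs.mean()), float(ccs.max()), sel_cc


def cc_vs_samples(models: list[BackboneModel], reference_map: DensityMap,
                  selector_score, n_max: int | None = None,
                  n_permutations: int = 100, rng=None, method: str = "permute",
                  resolution_limit: float = DEFAULT_RESOLUTION_LIMIT):
    """Expected selected-model CC as a function of the number of models
    generated.

    For each N, the first N models of a random generation order are scored
    and the selector's top pick evaluated; averaging over orderings gives
    the expected curve.  ``method="exact"`` computes the same expectation in
    closed form (the first N of a random permutation is a uniform random
    N-subset, so the selector's pick is the subset's selector-best model).

    Returns (N values 1..n_max, expected sel-CC array).
    """
    n = len(models)
    n_max = n if n_max is None else min(n_max, n)
    ccs = np.array([model_map_cc(m, reference_map, resolution_limit)
                    for m in models])
    scores = np.array([selector_score(m) for m in models])
    order = np.argsort(scores, kind="stable")  # best selector first
    cc_by_rank = ccs[order]
    ns = np.arange(1, n_max + 1)
    if method == "exact":
        curve = np.empty(n_max)
        for idx, n_sub in enumerate(ns):
            # P(subset's selector-best has rank r) = C(n-r, k-1) / C(n, k)
            logc_n = math.lgamma(n + 1) - math.lgamma(n_sub + 1) \
                - math.lgamma(n - n_sub + 1)
            exp_cc = 0.0
            for r in range(1, n - n_sub + 2):
                rest = n - r
                logc = math.lgamma(rest + 1) - math.lgamma(n_sub) \
                    - math.lgamma(rest - n_sub + 2)
                exp_cc += cc_by_rank[r - 1] * math.exp(logc - logc_n)
            curve[idx] = exp_cc
        return ns, curve
    if method != "permute":
        raise ValueError("method must be 'permute' or 'exact'")
    rng = np.random.default_rng(rng)
    rank_of = np.empty(n, dtype=int)
    rank_of[order] = np.arange(n)
    acc = np.zeros(n_max)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        best_rank = np.minimum.accumulate(rank_of[perm])[:n_max]
        acc += cc_by_rank[best_rank]
    return ns, acc / n_permutations


def plateau_n(ns: np.ndarray, curve: np.ndarray, tol: float = 0.02) -> int:
    """Smallest N whose expected selected CC is within ``tol`` of the
    curve's final value."""
    final = curve[-1]
    ok = np.nonzero(curve >= final - tol)[0]
    return int(ns[ok[0]])
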