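"""Benchmark experiments: multi-seed protocol comparisons on the synthetic
cases.

These drive the qualitative reproductions of the old-vs-new protocol
comparison: strand-pairing preservation on the register-shift case,
displaced-loop recovery, and the sampling-efficiency (selected-CC vs number
of models) curves.  Cycle counts are reduced relative to the production
defaults so a two-protocol, ten-seed comparison runs in minutes on one CPU;
see docs/methods.md for the reasoning.
"""

from __future__ import annotations

from .density import build_spline_field, fast_density_score, simulate_map
from .energy import EnergyModel
from .evaluate import cc_vs_samples, model_map_cc, plateau_n
from .rebuild import LoopRebuilder, RebuildConfig
from .synthetic import BenchmarkCase

# both protocols get the same per-segment proposal budget, as in a
# like-for-like benchmark run
COMPARISON_CYCLES = {"2011": 12, "2013": 12}


def comparison_config(protocol: str, **overrides) -> RebuildConfig:
    kw = dict(n_cycles=COMPARISON_CYCLES[protocol], heal_evals=250,
              final_min_evals=400)
    kw.update(overrides)
    return RebuildConfig(protocol=protocol, **kw)


def protocol_ensemble(case: BenchmarkCase, protocol: str, seeds,
                      **overrides) -> list:
    """One rebuilt model per seed for the given protocol."""
    rebuilder = LoopRebuilder(case.template, case.alignment, case.observed,
                              case.library,
                              config=comparison_config(protocol, **overrides))
    return [rebuilder.fit(seed=int(s)).model for s in seeds]


def truth_map(case: BenchmarkCase, spacing: float = 1.0,
              resolution: float = 3.0):
    return simulate_map(case.truth, spacing, resolution)


def hbond_counts(models) -> list[int]:
    em = EnergyModel({"density": 0})
    return [em.count_hbonds(m) for m in models]


def model_ccs(models, reference) -> list[float]:
    return [model_map_cc(m, reference) for m in models]


def selection_selector(case: BenchmarkCase):
    """Selector score on the held-out selection map (lower is better)."""
    field = build_spline_field(case.selection_map.standardized())

    def score(m):
        s, _ = fast_density_score(m, field)
        return s
    return score


def sampling_curve(models, case: BenchmarkCase, reference,
                   tol: float = 0.02):
    """Exact expected selected-CC curve and its plateau N."""
    ns, curve = cc_vs_samples(models, reference, selection_selector(case),
                              method="exact")
    return ns, curve, plateau_n(ns, curve, tol=tol)
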