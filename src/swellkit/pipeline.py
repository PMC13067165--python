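"""End-to-end study analysis: fit every replicate, call mechanisms, compare samples.

This is the library-level composition the CLI ``fit`` command exposes:
each replicate curve is fitted independently by every requested model;
sample-level mechanism calls use the replicate-mean amplitudes; samples
with replicate structure are compared by ANOVA + Tukey on k (and on the
power-law exponent when fitted).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .data import SwellingCurve
from .estimators import FitResult
from .fitting import MODEL_REGISTRY
from .io import RunConfig
from .mechanism import MechanismCall, classify_from_ratio
from .parameters import SwellingEqParams
from .stats import GroupComparison, compare_groups

__all__ = ["analyze_study"]


def _reference_time(cfg: RunConfig, window: tuple[float, float]) -> float:
    if cfg.reference_time == "window_midpoint":
        return 0.5 * (window[0] + window[1])
    return float(cfg.reference_time)


def analyze_study(
    curves: Sequence[SwellingCurve], cfg: RunConfig | None = None
) -> tuple[list[FitResult], dict[str, MechanismCall], list[GroupComparison]]:
    cfg = cfg or RunConfig()
    fits: list[FitResult] = []
    for curve in curves:
        for model in cfg.models:
            if model not in MODEL_REGISTRY:
                raise ValueError(f"unknown model {model!r}; have {sorted(MODEL_REGISTRY)}")
            kwargs = {}
            if model == "swelling_eq":
                kwargs = {"n_starts": cfg.n_starts, "seed": cfg.seed,
                          "tail_fraction": cfg.tail_fraction}
            elif model in ("power_law", "peppas_sahlin"):
                kwargs = {"window_fraction": cfg.window_fraction,
                          "tail_fraction": cfg.tail_fraction}
            fits.append(MODEL_REGISTRY[model](curve, **kwargs))

    calls: dict[str, MechanismCall] = {}
    se_fits = [f for f in fits if f.model_id == "swelling_eq"]
    samples = sorted({f.sample_id for f in se_fits})
    for sample in samples:
        sf = [f for f in se_fits if f.sample_id == sample]
        k = float(np.mean([f.params.k for f in sf]))
        a = float(np.mean([f.params.a_star for f in sf]))
        b = float(np.mean([f.params.b_star for f in sf]))
        window = sf[0].window
        calls[sample] = classify_from_ratio(
            SwellingEqParams(k=k, a_star=a if a or b else 1.0, b_star=b),
            thresholds=(cfg.threshold_lower, cfg.threshold_upper),
            reference_time=_reference_time(cfg, window),
        )

    comparisons: list[GroupComparison] = []
    by_sample_se = {s: [f for f in se_fits if f.sample_id == s] for s in samples}
    enough = len(samples) >= 2 and all(len(v) >= 2 for v in by_sample_se.values())
    if enough and se_fits:
        comparisons.append(compare_groups(by_sample_se, "k", alpha=cfg.alpha))
    pl_fits = [f for f in fits if f.model_id == "power_law"]
    if pl_fits:
        by_sample_pl = {
            s: [f for f in pl_fits if f.sample_id == s]
            for s in sorted({f.sample_id for f in pl_fits})
        }
        if len(by_sample_pl) >= 2 and all(len(v) >= 2 for v in by_sample_pl.values()):
            comparisons.append(compare_groups(by_sample_pl, "n", alpha=cfg.alpha))
    return fits, calls, comparisons
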