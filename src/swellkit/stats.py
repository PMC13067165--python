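"""Replicate statistics: one-way ANOVA, Tukey HSD, compact letter display.

Samples are fitted per replicate; sample-level parameters are compared by
one-way ANOVA followed by all-pairs Tukey HSD at a 1 - alpha confidence
level.  The compact letter display assigns letters so that two samples
share a letter if and only if their means are not significantly
different — computed from the maximal cliques of the non-significance
graph, which guarantees that equivalence exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .estimators import FitResult

__all__ = ["GroupComparison", "compare_groups", "compare_value_groups"]


@dataclass(frozen=True)
class GroupComparison:
    """Per-sample means +/- sd with ANOVA p-value and Tukey letters."""

    parameter: str
    alpha: float
    means: Mapping[str, float]
    sds: Mapping[str, float]
    n: Mapping[str, int]
    anova_p: float
    letters: Mapping[str, str]
    tukey_p: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "alpha": self.alpha,
            "groups": {
                g: {"mean": self.means[g], "sd": self.sds[g], "n": self.n[g],
                    "letters": self.letters[g]}
                for g in sorted(self.means)
            },
            "anova_p": self.anova_p,
            "tukey_p": {f"{a}|{b}": p for (a, b), p in sorted(self.tukey_p.items())},
        }


def _compact_letters(groups: Sequence[str], means: Mapping[str, float],
                     nonsig: set[frozenset]) -> dict[str, str]:
    """Letters from maximal cliques of the non-significance graph.

    Two groups share a letter iff they lie in a common maximal clique,
    i.e. iff their pair is non-significant.  Cliques are lettered in
    order of their best (largest-mean) member so the display is invariant
    under relabeling of the groups.
    """
    idx = {g: i for i, g in enumerate(groups)}
    adj = {g: set() for g in groups}
    for pair in nonsig:
        a, b = tuple(pair)
        adj[a].add(b)
        adj[b].add(a)

    cliques: list[frozenset] = []

    def bron_kerbosch(R: set, P: set, X: set) -> None:
        if not P and not X:
            cliques.append(frozenset(R))
            return
        for v in sorted(P, key=lambda g: idx[g]):
            bron_kerbosch(R | {v}, P & adj[v], X & adj[v])
            P = P - {v}
            X = X | {v}

    bron_kerbosch(set(), set(groups), set())
    # order cliques by their most-swollen member's mean (desc), then size
    cliques.sort(key=lambda c: (-max(means[g] for g in c), -len(c),
                                sorted(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, c in enumerate(cliques):
        ch = alphabet[i % len(alphabet)] * (i // len(alphabet) + 1)
        for g in sorted(c, key=lambda g: idx[g]):
            letters[g] += ch
    return {g: "".join(sorted(letters[g])) for g in groups}


def compare_value_groups(
    values_by_group: Mapping[str, Sequence[float]],
    parameter: str = "value",
    alpha: float = 0.05,
) -> GroupComparison:
    """ANOVA + Tukey HSD + compact letters on raw per-replicate values."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    groups = sorted(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    arrays = []
    for g in groups:
        v = np.asarray(values_by_group[g], dtype=float)
        if len(v) < 2:
            raise ValueError(f"group {g!r} has {len(v)} replicate(s); need >= 2")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {g!r} contains non-finite values")
        arrays.append(v)
    anova_p = float(sps.f_oneway(*arrays).pvalue)
    hsd = sps.tukey_hsd(*arrays)
    means = {g: float(a.mean()) for g, a in zip(groups, arrays)}
    sds = {g: float(a.std(ddof=1)) for g, a in zip(groups, arrays)}
    n = {g: int(len(a)) for g, a in zip(groups, arrays)}
    nonsig: set[frozenset] = set()
    tukey_p: dict[tuple[str, str], float] = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p = float(hsd.pvalue[i, j])
            tukey_p[(groups[i], groups[j])] = p
            if p > alpha:
                nonsig.add(frozenset({groups[i], groups[j]}))
    letters = _compact_letters(groups, means, nonsig)
    return GroupComparison(parameter, alpha, means, sds, n, anova_p, letters, tukey_p)


def compare_groups(
    fits_by_sample: Mapping[str, Sequence[FitResult]],
    parameter: str,
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare one fitted parameter across samples (replicate fits as input).

    ``parameter`` names a field of the fits' parameter records (e.g.
    ``"k"``, ``"a_star"``, ``"n"``, ``"beta"``) or a derived quantity
    (``"ratio"`` for a*/b*).
    """
    values: dict[str, list[float]] = {}
    for sample, fits in fits_by_sample.items():
        vals = []
        for fr in fits:
            if parameter == "ratio":
                vals.append(float(fr.params.ratio))
            else:
                d = fr.param_dict()
                if parameter not in d:
                    raise KeyError(
                        f"parameter {parameter!r} not in {fr.model_id} fit "
                        f"(has {sorted(d)})"
                    )
                vals.append(float(d[parameter]))
        values[sample] = vals
    return compare_value_groups(values, parameter=parameter, alpha=alpha)
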