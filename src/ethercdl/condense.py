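"""Cardiolipin condensation calculus: predicting CDL ether-class
distributions from PE/PG compositions.

Bacterial cardiolipin synthases (Cls) build a CDL by condensing two parent
phospholipids — two PGs (ClsA-like) or one PE with one PG (ClsC-like).  If
ester bonds in the cores are not modified after condensation, the number of
ether bonds in a CDL is simply the sum of the ether bonds contributed by
its two parents.  The predicted CDL ether-class distribution over {0..4}
is therefore the discrete convolution of the two parents' per-core
ether-count distributions over {0,1,2} (DAG→0, AEG→1, DEG→2), assuming the
synthase draws parents independently of their core structure.

Lyso cores (MEG/MAG) are excluded by default — only intact two-chain cores
can yield a four-chain CDL — and the remaining intact-core percentages are
renormalized.  A mixed scenario averages the PE+PG and PG+PG predictions
with configurable weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParentDistribution",
    "ScenarioResult",
    "parent_distribution",
    "condense",
    "run_scenario",
    "compare",
    "CORE_ETHER_COUNT",
]

# ether bonds contributed by each core class
CORE_ETHER_COUNT: dict[str, int] = {"DAG": 0, "AEG": 1, "DEG": 2, "MAG": 0, "MEG": 1}
_INTACT = ("DAG", "AEG", "DEG")


@dataclass(frozen=True)
class ParentDistribution:
    """Per-parent probability distribution over ether count {0,1,2}."""

    head_group: str
    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.shape != (3,):
            raise ValueError("parent distribution is over ether counts {0,1,2}")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class ScenarioResult:
    """Predicted CDL ether-class distribution over {0..4} for one scenario."""

    scenario: str
    q: np.ndarray
    mix_weights: Optional[tuple[float, float]] = None

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if q.shape != (5,):
            raise ValueError("CDL distribution is over ether counts {0..4}")
        if (q < 0).any() or abs(q.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "q", q)

    def as_series(self) -> pd.Series:
        return pd.Series(self.q, index=range(5), name=self.scenario)


def parent_distribution(
    composition: pd.DataFrame | Mapping[str, float],
    head_group: str = "",
    include_lyso: bool = False,
) -> ParentDistribution:
    """Per-parent ether-count distribution from a core-class composition.

    ``composition`` is either a mapping core class → percent (of total for
    that head group) or a table with columns ``head_group``, ``core_class``
    and ``percent``.  Lyso classes (MEG/MAG) are dropped by default and the
    intact-core percentages renormalized; with ``include_lyso=True`` they
    contribute their own ether counts (MEG→1, MAG→0).
    """
    if isinstance(composition, pd.DataFrame):
        sub = composition[composition["head_group"] == head_group]
        if sub.empty:
            raise ValueError(f"no rows for head group {head_group!r}")
        comp = dict(zip(sub["core_class"], sub["percent"]))
    else:
        comp = dict(composition)
    p = np.zeros(3)
    for cls, pct in comp.items():
        if cls not in CORE_ETHER_COUNT:
            raise ValueError(f"unknown core class {cls!r}")
        if pct < 0:
            raise ValueError(f"negative percentage for {cls}")
        if not include_lyso and cls not in _INTACT:
            continue
        p[CORE_ETHER_COUNT[cls]] += pct
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero composition")
    return ParentDistribution(head_group or "?", p / total)


def condense(a: ParentDistribution, b: ParentDistribution) -> np.ndarray:
    """Ether-count distribution of CDLs formed from parents ``a`` and ``b``:
    the discrete convolution q[E] = Σ_{e1+e2=E} a[e1]·b[e2] over {0..4}."""
    return np.convolve(a.p, b.p)


def run_scenario(
    composition: pd.DataFrame | Mapping[str, Mapping[str, float]],
    scenario: str,
    mix_weights: tuple[float, float] = (0.5, 0.5),
    include_lyso: bool = False,
) -> ScenarioResult:
    """Predict the CDL ether-class distribution under one synthase scenario.

    Scenarios: ``"PE+PE"``, ``"PE+PG"``, ``"PG+PG"``, or ``"mix"`` — the
    ``mix_weights``-weighted average of PE+PG and PG+PG (default 50–50,
    i.e. both condensation pathways equally active).
    """
    def parent(hg: str) -> ParentDistribution:
        if isinstance(composition, pd.DataFrame):
            return parent_distribution(composition, hg, include_lyso)
        if hg not in composition:
            raise ValueError(f"composition lacks head group {hg!r}")
        return parent_distribution(composition[hg], hg, include_lyso)

    if scenario == "PE+PE":
        q = condense(parent("PE"), parent("PE"))
    elif scenario == "PE+PG":
        q = condense(parent("PE"), parent("PG"))
    elif scenario == "PG+PG":
        q = condense(parent("PG"), parent("PG"))
    elif scenario == "mix":
        w1, w2 = mix_weights
        if w1 < 0 or w2 < 0 or abs(w1 + w2 - 1.0) > 1e-9:
            raise ValueError("mix weights must be non-negative and sum to 1")
        q = (
            w1 * condense(parent("PE"), parent("PG"))
            + w2 * condense(parent("PG"), parent("PG"))
        )
        return ScenarioResult("mix", q, mix_weights=(w1, w2))
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return ScenarioResult(scenario, q)


def compare(
    predicted: ScenarioResult | np.ndarray | Sequence[float],
    measured: np.ndarray | Sequence[float],
) -> dict:
    """L1 distance and per-class differences between predicted and
    measured CDL ether-class distributions (both normalized over {0..4})."""
    q = predicted.q if isinstance(predicted, ScenarioResult) else np.asarray(predicted, float)
    m = np.asarray(measured, dtype=float)
    if q.shape != m.shape:
        raise ValueError("distribution length mismatch")
    for v, name in ((q, "predicted"), (m, "measured")):
        if (v < 0).any() or abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} distribution is not normalized")
    diff = q - m
    return {
        "l1": float(np.abs(diff).sum()),
        "per_class": {e: float(d) for e, d in enumerate(diff)},
    }
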