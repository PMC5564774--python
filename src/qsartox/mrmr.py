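"""Minimum-redundancy maximum-relevance (mRMR) descriptor ranking.

Continuous descriptors and the continuous target are discretized into three
states at mean +/- k*sigma (k = 1 by default, the binning the mRMR authors
use for expression data), mutual information is estimated by the plug-in
formula on the joint contingency table (natural log, nats), and features are
ranked greedily: the first feature maximizes relevance I(f; y); each later
pick maximizes

    MID (difference):  I(f; y) - mean_{s in S} I(f; s)
    MIQ (quotient):    I(f; y) / mean_{s in S} I(f; s)

over the not-yet-selected features, S being the current selection.  Ties
break toward the earlier column, making the ranking deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .table import DescriptorTable


class DiscretizationError(ValueError):
    """Feature cannot be binned (constant vector)."""


@dataclass(frozen=True)
class MrmrConfig:
    """mRMR stage configuration.

    n_keep
        how many features to pass on to the wrapper stage.
    criterion
        'MID' (relevance minus redundancy) or 'MIQ' (relevance over
        redundancy).
    k_sigma
        half-width multiplier of the middle bin, mean +/- k*sigma.
    """

    n_keep: int = 30
    criterion: str = "MID"
    k_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.criterion not in ("MID", "MIQ"):
            raise ValueError(f"unknown mRMR criterion {self.criterion!r}")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if self.n_keep < 1:
            raise ValueError("n_keep must be >= 1")


@dataclass
class SelectionResult:
    """Outcome of a selection stage (mRMR ranking or GA mask)."""

    stage: str
    features: list[str]  # ordered for mRMR; best mask contents for GA
    scores: list[float] = field(default_factory=list)
    fitness_trace: list[float] = field(default_factory=list)
    final_fitness: float | None = None
    seed: int | None = None
    config: dict = field(default_factory=dict)


def discretize(x, k_sigma: float = 1.0) -> np.ndarray:
    """Bin a continuous vector into states {0, 1, 2} at mean +/- k*sigma.

    State 1 is the middle band; affine transforms of ``x`` leave the state
    vector unchanged because the cut points move with mean and sigma.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise DiscretizationError("need a 1-D vector of length >= 2")
    sd = float(np.std(x))
    if sd == 0.0:
        raise DiscretizationError("constant vector cannot be discretized")
    mu = float(np.mean(x))
    lo, hi = mu - k_sigma * sd, mu + k_sigma * sd
    # boundaries are inclusive on the outer bands so that a two-point vector
    # (whose extremes sit exactly on the cut points) still separates
    return np.where(x <= lo, 0, np.where(x >= hi, 2, 1)).astype(np.int64)


def mutual_information(a, b) -> float:
    """Plug-in mutual information (nats) of two discrete vectors.

    Estimated from the joint contingency table; MI(a, a) equals the entropy
    of a, and independent variables give values near zero (exactly zero for
    product-form tables).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = len(a)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    pij = joint / n
    pi = pij.sum(axis=1, keepdims=True)
    pj = pij.sum(axis=0, keepdims=True)
    mask = pij > 0
    return float(np.sum(pij[mask] * np.log(pij[mask] / (pi @ pj)[mask])))


def mrmr_rank(table: DescriptorTable, config: MrmrConfig | None = None) -> SelectionResult:
    """Greedy mRMR ranking of the table's descriptors against its target.

    Returns the ordered top ``n_keep`` features with their greedy criterion
    scores.  Constant descriptors cannot be discretized and raise; drop them
    first.
    """
    config = config or MrmrConfig()
    names = table.descriptor_names
    if len(names) < 2:
        raise ValueError("mRMR needs at least two candidate descriptors")
    y_disc = discretize(table.target(), config.k_sigma)
    disc = {
        name: discretize(table.X[name].to_numpy(dtype=float), config.k_sigma)
        for name in names
    }
    relevance = {name: mutual_information(disc[name], y_disc) for name in names}

    selected: list[str] = []
    scores: list[float] = []
    remaining = list(names)
    n_keep = min(config.n_keep, len(names))
    # pairwise MI cache grows as features are selected
    redundancy_sum = {name: 0.0 for name in names}
    while len(selected) < n_keep:
        best_name, best_score = None, -np.inf
        for name in remaining:
            if not selected:
                score = relevance[name]
            else:
                red = redundancy_sum[name] / len(selected)
                if config.criterion == "MID":
                    score = relevance[name] - red
                else:
                    score = relevance[name] / max(red, 1e-12)
            if score > best_score:
                best_name, best_score = name, score
        selected.append(best_name)
        scores.append(best_score)
        remaining.remove(best_name)
        for name in remaining:
            redundancy_sum[name] += mutual_information(disc[name], disc[best_name])

    return SelectionResult(
        stage="mrmr",
        features=selected,
        scores=scores,
        config={
            "n_keep": config.n_keep,
            "criterion": config.criterion,
            "k_sigma": config.k_sigma,
        },
    )
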