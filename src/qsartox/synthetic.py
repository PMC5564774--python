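"""Synthetic descriptor tables with known ground truth.

Generates tables shaped like the real 581-compound, 68-descriptor toxicity
dataset: a few informative descriptors drive a linear (optionally monotone
nonlinear) target, some descriptors are noisy copies of informative ones
(redundant), and the rest are independent noise.  The default target-noise
level is calibrated so the best attainable training R^2 sits near 0.84,
the regime of the real data.

Everything is deterministic per seed, and the generator returns the true
informative mask so selection methods can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import DescriptorTable

#: coefficients used when a spec does not state its own
DEFAULT_COEFFICIENTS = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)


class SyntheticSpecError(ValueError):
    """Impossible generator specification."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic descriptor table.

    n
        number of compounds (default 581, the real benchmark size).
    n_informative / n_redundant / n_noise
        counts of target-driving, duplicated-with-jitter, and independent
        descriptors (defaults 6 / 6 / 56, totalling 68 columns).
    coefficients
        linear weights of the informative descriptors; defaults to a
        decreasing ladder 1.0 .. 0.5.
    redundancy_map
        source informative index for each redundant feature; defaults to
        cycling through the informative features.
    sigma_redundant
        sd of the jitter added to redundant copies.
    sigma
        target noise sd; ``None`` calibrates it so the population R^2 of
        the true model is ``target_r2``.
    nonlinearity
        per-informative-feature tags: 'linear', 'tanh' or 'cubic'
        (monotone transforms applied before the linear combination).
    """

    n: int = 581
    n_informative: int = 6
    n_redundant: int = 6
    n_noise: int = 56
    coefficients: tuple[float, ...] | None = None
    redundancy_map: tuple[int, ...] | None = None
    sigma_redundant: float = 0.1
    sigma: float | None = None
    target_r2: float = 0.84
    nonlinearity: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise SyntheticSpecError("need at least two compounds")
        if min(self.n_informative, self.n_redundant, self.n_noise) < 0:
            raise SyntheticSpecError("feature counts must be >= 0")
        if self.n_informative + self.n_redundant + self.n_noise < 1:
            raise SyntheticSpecError("at least one descriptor required")
        if self.n_informative == 0 and self.n_redundant > 0:
            raise SyntheticSpecError("redundant features need informative sources")
        if self.sigma is not None and self.sigma < 0:
            raise SyntheticSpecError("sigma must be >= 0")
        if self.sigma_redundant < 0:
            raise SyntheticSpecError("sigma_redundant must be >= 0")
        if self.coefficients is not None and len(self.coefficients) != self.n_informative:
            raise SyntheticSpecError("one coefficient per informative feature")
        if self.redundancy_map is not None:
            if len(self.redundancy_map) != self.n_redundant:
                raise SyntheticSpecError("one source per redundant feature")
            if any(not 0 <= s < self.n_informative for s in self.redundancy_map):
                raise SyntheticSpecError("redundancy source out of range")
        if self.nonlinearity is not None:
            if len(self.nonlinearity) != self.n_informative:
                raise SyntheticSpecError("one nonlinearity tag per informative feature")
            bad = set(self.nonlinearity) - {"linear", "tanh", "cubic"}
            if bad:
                raise SyntheticSpecError(f"unknown nonlinearity tags {sorted(bad)}")

    def resolved_coefficients(self) -> np.ndarray:
        if self.coefficients is not None:
            return np.asarray(self.coefficients, dtype=float)
        base = np.array(DEFAULT_COEFFICIENTS)
        if self.n_informative <= len(base):
            return base[: self.n_informative].copy()
        reps = int(np.ceil(self.n_informative / len(base)))
        return np.tile(base, reps)[: self.n_informative]

    def resolved_sigma(self, signal_var: float) -> float:
        if self.sigma is not None:
            return self.sigma
        # choose sigma so signal_var / (signal_var + sigma^2) = target_r2
        return float(np.sqrt(signal_var * (1 - self.target_r2) / self.target_r2))


@dataclass
class GroundTruth:
    """What the generator actually did, for scoring selections."""

    informative: list[str]
    redundant: list[str]
    noise: list[str]
    coefficients: dict[str, float]
    redundancy_map: dict[str, str]
    sigma: float
    seed: int

    def as_dict(self) -> dict:
        return {
            "informative": self.informative,
            "redundant": self.redundant,
            "noise": self.noise,
            "coefficients": self.coefficients,
            "redundancy_map": self.redundancy_map,
            "sigma": self.sigma,
            "seed": self.seed,
        }


_TRANSFORMS = {
    "linear": lambda x: x,
    "tanh": np.tanh,
    "cubic": lambda x: x**3,
}


def generate_table(spec: SyntheticSpec) -> tuple[DescriptorTable, GroundTruth]:
    """Draw one table per the spec; returns the table and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    ni, nr, nn = spec.n_informative, spec.n_redundant, spec.n_noise

    info = rng.standard_normal((spec.n, ni))
    coef = spec.resolved_coefficients()
    tags = spec.nonlinearity or ("linear",) * ni
    contrib = np.column_stack(
        [_TRANSFORMS[t](info[:, j]) for j, t in enumerate(tags)]
    ) if ni else np.zeros((spec.n, 0))
    signal = contrib @ coef if ni else np.zeros(spec.n)
    signal_var = float(np.sum(coef**2)) if ni else 1.0
    sigma = spec.resolved_sigma(signal_var)
    y = signal + sigma * rng.standard_normal(spec.n)

    rmap = (
        list(spec.redundancy_map)
        if spec.redundancy_map is not None
        else [j % ni for j in range(nr)]
    )
    red = np.column_stack(
        [info[:, s] + spec.sigma_redundant * rng.standard_normal(spec.n) for s in rmap]
    ) if nr else np.zeros((spec.n, 0))
    noise = rng.standard_normal((spec.n, nn))

    info_names = [f"inf{j + 1}" for j in range(ni)]
    red_names = [f"red{j + 1}" for j in range(nr)]
    noise_names = [f"noise{j + 1}" for j in range(nn)]
    X = pd.DataFrame(
        np.hstack([info, red, noise]),
        columns=info_names + red_names + noise_names,
    )
    ids = [f"cpd{i + 1}" for i in range(spec.n)]
    table = DescriptorTable(ids=ids, X=X, y=pd.Series(y, name="logIGC50inv"))
    truth = GroundTruth(
        informative=info_names,
        redundant=red_names,
        noise=noise_names,
        coefficients=dict(zip(info_names, coef.tolist())),
        redundancy_map={r: info_names[s] for r, s in zip(red_names, rmap)},
        sigma=sigma,
        seed=spec.seed,
    )
    return table, truth


def generate_split(
    table: DescriptorTable,
    train_fraction: float = 500 / 581,
    seed: int = 0,
) -> tuple[DescriptorTable, DescriptorTable]:
    """Seeded random train/test split; default fraction mirrors the real
    500/81 partition of the benchmark dataset."""
    if not 0 < train_fraction < 1:
        raise SyntheticSpecError("train fraction must lie strictly in (0, 1)")
    n_train = int(round(table.n * train_fraction))
    if n_train < 1 or n_train >= table.n:
        raise SyntheticSpecError(
            f"degenerate split: {n_train}/{table.n - n_train} from n={table.n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(table.n)
    return table.subset_rows(np.sort(perm[:n_train])), table.subset_rows(
        np.sort(perm[n_train:])
    )
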