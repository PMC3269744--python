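"""Seeded synthetic descriptor matrices with planted ground truth.

Real high-dimensional descriptor tables (thousands of computed
molecular descriptors for a few dozen compounds) mix a handful of
activity-driving features with many irrelevant ones, near-duplicate
correlated descriptors, and constant columns. The generator emulates
exactly that structure so selection, evaluation and interpretability
can be tested against a known answer:

* ``k`` informative descriptors, standard normal, with recorded
  positive coefficients beta_j ~ Uniform(0.5, 1.5);
* ``r`` redundant copies of each informative descriptor at correlation
  rho (copy = rho * source + sqrt(1 - rho^2) * fresh noise);
* irrelevant standard-normal descriptors filling up to ``D`` columns;
* ``n_constant`` constant columns;
* response y = f(informative) + Normal(0, sigma^2), where f is linear,
  linear plus an x1*x2 interaction, or linear plus sin(pi * x1);
* an 80/20 train/test split by seeded shuffle.

Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ActivityTable, DescriptorMatrix

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "DEFAULT_BENCHMARK"]

EFFECT_FORMS = ("linear", "linear+interaction", "linear+sine")


@dataclass(frozen=True)
class SyntheticSpec:
    n: int = 40                # compounds
    D: int = 300               # total descriptors
    k: int = 5                 # informative descriptors
    r: int = 2                 # correlated copies per informative descriptor
    rho: float = 0.9           # copy correlation
    n_constant: int = 5        # constant columns
    noise_sd: float = 0.3      # response noise sigma
    effect: str = "linear+interaction"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k + self.k * self.r + self.n_constant > self.D:
            raise ValueError("k + k*r + n_constant must not exceed D")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.effect not in EFFECT_FORMS:
            raise ValueError(f"effect must be one of {EFFECT_FORMS}")
        if self.n < 5:
            raise ValueError("need at least 5 compounds for an 80/20 split")


#: the benchmark conditions used throughout the test suite
DEFAULT_BENCHMARK = SyntheticSpec()


@dataclass
class GroundTruth:
    informative: list[str]
    betas: dict[str, float]
    beta_interaction: float | None = None
    redundant: dict[str, str] = field(default_factory=dict)  # copy -> source
    constant: list[str] = field(default_factory=list)
    irrelevant: list[str] = field(default_factory=list)
    effect: str = "linear"

    def to_dict(self) -> dict:
        return {"informative": self.informative, "betas": self.betas,
                "beta_interaction": self.beta_interaction,
                "redundant": self.redundant, "constant": self.constant,
                "irrelevant": self.irrelevant, "effect": self.effect}


def generate(spec: SyntheticSpec) -> tuple[DescriptorMatrix, ActivityTable, GroundTruth]:
    """Generate one seeded dataset; identical spec => identical output."""
    rng = np.random.default_rng(spec.seed)
    n, D, k, r = spec.n, spec.D, spec.k, spec.r
    n_irrelevant = D - k - k * r - spec.n_constant

    informative = [f"inf{i + 1}" for i in range(k)]
    X_inf = rng.standard_normal((n, k))

    redundant: dict[str, str] = {}
    cols_red = []
    for i, src in enumerate(informative):
        for j in range(r):
            name = f"{src}_cor{j + 1}"
            redundant[name] = src
            noise = rng.standard_normal(n)
            cols_red.append(spec.rho * X_inf[:, i] + np.sqrt(1 - spec.rho**2) * noise)
    X_red = np.column_stack(cols_red) if cols_red else np.empty((n, 0))

    irrelevant = [f"irr{i + 1}" for i in range(n_irrelevant)]
    X_irr = rng.standard_normal((n, n_irrelevant))

    constant = [f"const{i + 1}" for i in range(spec.n_constant)]
    const_values = rng.uniform(-2, 2, size=spec.n_constant)
    X_const = np.tile(const_values, (n, 1))

    betas = {name: float(b) for name, b in zip(informative, rng.uniform(0.5, 1.5, size=k))}
    signal = X_inf @ np.array([betas[nm] for nm in informative])
    beta_int = None
    if spec.effect == "linear+interaction" and k >= 2:
        beta_int = float(rng.uniform(0.5, 1.5))
        signal = signal + beta_int * X_inf[:, 0] * X_inf[:, 1]
    elif spec.effect == "linear+sine":
        signal = signal + np.sin(np.pi * X_inf[:, 0])
    y = signal + spec.noise_sd * rng.standard_normal(n)

    names = informative + list(redundant) + irrelevant + constant
    values = np.hstack([X_inf, X_red, X_irr, X_const])
    ids = [f"c{i + 1:03d}" for i in range(n)]
    matrix = DescriptorMatrix(pd.DataFrame(values, index=ids, columns=names))

    n_test = max(1, round(0.2 * n))
    test_ids = set(np.array(ids)[rng.permutation(n)[:n_test]])
    split = ["test" if cid in test_ids else "train" for cid in ids]
    activities = ActivityTable(pd.DataFrame(
        {"pIC50": y, "split": split}, index=pd.Index(ids, name="compound")))

    truth = GroundTruth(informative=informative, betas=betas,
                        beta_interaction=beta_int, redundant=redundant,
                        constant=constant, irrelevant=irrelevant, effect=spec.effect)
    return matrix, activities, truth
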