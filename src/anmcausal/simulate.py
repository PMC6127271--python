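"""Synthetic-data generators and simulation drivers.

Generator families
------------------
``model1`` .. ``model6``
    Y = X + b*g(X) + eps with X ~ N(0,1); g is X^2 (models 1-2),
    log|X| (models 3-4) or e^X (models 5-6); eps is N(0,1) for the
    odd-numbered models and Student t with 5 df for the even ones.
    The coefficient b controls departure from linearity: at b = 0 every
    family collapses to the linear-Gaussian case, where the causal
    direction is unidentifiable and the direction rule is a coin flip.
``null-independent``
    X, Y independent standard normal (no association, no causation).
``null-associated``
    A common confounder Z drives both variables (association without
    causation): X = (Z + eps1)/sqrt(3), Y = (Z + eps2)/sqrt(3) with
    Z ~ N(0,2), eps1, eps2 ~ N(0,1); the 1/sqrt(3) standardization
    gives both marginals unit variance.
``power-bump``
    Y = sum_j w_j exp(-gamma (x - x_j)^2) + N with three Gaussian
    bumps: w_j ~ U(0,1), x_j ~ N(0,1), gamma ~ N(0,1) redrawn until
    positive, N ~ N(0, 0.01).  A smooth nonlinear signal with small
    noise, used for power studies.
``example-b-quadratic``
    Y = 5 X^2 + eps, X ~ U(-2,2), eps ~ U(-1,1): causation without
    linear correlation (E[X * X^2] = 0 by symmetry).
``example-c-confounder``
    The raw (unstandardized) confounder model above: correlation 2/3
    without causation.
``cubic-uniform``
    Y = X^3 + eps, X ~ U(-1.5, 1.5), eps ~ U(-1,1): a strongly
    identifiable nonlinear ANM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import PairedSample, SplitSpec, permutation_test, score_directions
from .hsic import HSICConfig

__all__ = [
    "SimModelSpec",
    "ExperimentRow",
    "generate",
    "false_decision_rate",
    "rejection_rate",
    "confounder_moments",
    "example_b_report",
    "generate_planted_network",
]

_B_FAMILIES = {"model1", "model2", "model3", "model4", "model5", "model6"}
FAMILIES = _B_FAMILIES | {
    "null-independent",
    "null-associated",
    "power-bump",
    "example-b-quadratic",
    "example-c-confounder",
    "cubic-uniform",
}


@dataclass(frozen=True)
class SimModelSpec:
    family: str
    n: int
    seed: int = 0
    b: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if (self.family in _B_FAMILIES) != (self.b is not None):
            raise ValueError("coefficient b is required exactly for families model1..model6")
        if self.n < 20:
            raise ValueError("n must be >= 20")


@dataclass(frozen=True)
class ExperimentRow:
    """One estimated proportion with its binomial standard error."""

    condition: str
    b: float | None
    n: int
    reps: int
    rate: float
    se: float
    alpha: float | None = None


def _noise(rng: np.random.Generator, family: str, n: int) -> np.ndarray:
    if family in ("model2", "model4", "model6"):
        return rng.standard_t(5, size=n)
    return rng.standard_normal(n)


def generate(spec: SimModelSpec) -> PairedSample:
    """Draw one reproducible paired sample from the named family."""
    rng = np.random.default_rng(spec.seed)
    n, fam = spec.n, spec.family

    if fam in _B_FAMILIES:
        x = rng.standard_normal(n)
        if fam in ("model3", "model4"):
            # log|x| is undefined at 0; redraw the (measure-zero) offenders
            bad = np.abs(x) < 1e-12
            while bad.any():
                x[bad] = rng.standard_normal(bad.sum())
                bad = np.abs(x) < 1e-12
            g = np.log(np.abs(x))
        elif fam in ("model1", "model2"):
            g = x * x
        else:
            g = np.exp(x)
        y = x + spec.b * g + _noise(rng, fam, n)
        return PairedSample(x, y)

    if fam == "null-independent":
        return PairedSample(rng.standard_normal(n), rng.standard_normal(n))

    if fam in ("null-associated", "example-c-confounder"):
        z = rng.normal(0.0, np.sqrt(2.0), size=n)
        x = z + rng.standard_normal(n)
        y = z + rng.standard_normal(n)
        if fam == "null-associated":
            x = x / np.sqrt(3.0)
            y = y / np.sqrt(3.0)
        return PairedSample(x, y)

    if fam == "power-bump":
        gamma = rng.standard_normal()
        while gamma <= 0:
            gamma = rng.standard_normal()
        centers = rng.standard_normal(3)
        weights = rng.uniform(0.0, 1.0, size=3)
        x = rng.standard_normal(n)
        f = np.zeros(n)
        for w_j, c_j in zip(weights, centers):
            f += w_j * np.exp(-gamma * (x - c_j) ** 2)
        y = f + rng.normal(0.0, 0.1, size=n)
        return PairedSample(x, y)

    if fam == "example-b-quadratic":
        x = rng.uniform(-2.0, 2.0, size=n)
        y = 5.0 * x * x + rng.uniform(-1.0, 1.0, size=n)
        return PairedSample(x, y)

    if fam == "cubic-uniform":
        x = rng.uniform(-1.5, 1.5, size=n)
        y = x**3 + rng.uniform(-1.0, 1.0, size=n)
        return PairedSample(x, y)

    raise AssertionError(fam)


def _child_seeds(seed: int, reps: int) -> np.ndarray:
    # one independent 31-bit stream per replicate, reproducible from seed
    return np.random.SeedSequence(seed).generate_state(reps, dtype=np.uint64) % (2**31)


def false_decision_rate(
    family: str,
    b: float | None,
    n: int,
    reps: int,
    seed: int = 0,
    reg_method: str = "spline",
    hsic_config: HSICConfig | None = None,
) -> ExperimentRow:
    """Proportion of replicates where the backward model is (wrongly) chosen.

    The forward model X -> Y is the truth for every generator family, so
    a backward decision is an error.  Undecided outcomes count 0.5.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    seeds = _child_seeds(seed, reps)
    wrong = 0.0
    for s in seeds:
        spec = SimModelSpec(family=family, n=n, seed=int(s), b=b)
        scores = score_directions(
            generate(spec), SplitSpec(seed=int(s)), reg_method, hsic_config
        )
        if scores.decision == "backward":
            wrong += 1.0
        elif scores.decision == "undecided":
            wrong += 0.5
    rate = wrong / reps
    return ExperimentRow(
        condition=family,
        b=b,
        n=n,
        reps=reps,
        rate=rate,
        se=float(np.sqrt(rate * (1.0 - rate) / reps)),
    )


def rejection_rate(
    family: str,
    n: int,
    reps: int,
    n_permutations: int,
    alphas: tuple[float, ...] = (0.05,),
    seed: int = 0,
    b: float | None = None,
    reg_method: str = "spline",
    hsic_config: HSICConfig | None = None,
) -> list[ExperimentRow]:
    """Rejection proportion of the permutation causation test at each alpha.

    For the null families this estimates the type-I error; for causal
    families it estimates power.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if n_permutations < 19:
        raise ValueError("n_permutations must be >= 19 to resolve alpha = 0.05")
    seeds = _child_seeds(seed, reps)
    p_values = np.empty(reps)
    for i, s in enumerate(seeds):
        spec = SimModelSpec(family=family, n=n, seed=int(s), b=b)
        result = permutation_test(
            generate(spec),
            n_permutations=n_permutations,
            split=SplitSpec(seed=int(s)),
            reg_method=reg_method,
            hsic_config=hsic_config,
        )
        p_values[i] = result.p_value
    rows = []
    for alpha in alphas:
        rate = float(np.mean(p_values <= alpha))
        rows.append(
            ExperimentRow(
                condition=family,
                b=b,
                n=n,
                reps=reps,
                rate=rate,
                se=float(np.sqrt(rate * (1.0 - rate) / reps)),
                alpha=alpha,
            )
        )
    return rows


def confounder_moments(mc_n: int = 10**6, seed: int = 0) -> dict[str, dict[str, float]]:
    """Closed-form moments of the confounder model, plus Monte-Carlo checks.

    The model X = Z + eps1, Y = Z + eps2 with Z ~ N(0,2) and unit-variance
    independent noises has cov(X,Y) = Var(Z) = 2, Var(X) = Var(Y) = 3,
    Pearson rho = 2/3, and cov(X, eps2 - eps1) = -Var(eps1) = -1 — so X
    and the effective noise of the implied regression Y = X + (eps2 - eps1)
    are dependent, ruling out an ANM in either direction despite the
    strong linear correlation.  Exact values are derived symbolically.
    """
    import sympy
    from sympy.stats import Normal, covariance, variance

    z = Normal("Z", 0, sympy.sqrt(2))
    e1 = Normal("eps1", 0, 1)
    e2 = Normal("eps2", 0, 1)
    x = z + e1
    y = z + e2
    cov_xy = sympy.simplify(covariance(x, y))
    var_x = sympy.simplify(variance(x))
    var_y = sympy.simplify(variance(y))
    rho = sympy.simplify(cov_xy / sympy.sqrt(var_x * var_y))
    cov_x_nd = sympy.simplify(covariance(x, e2 - e1))
    exact = {
        "cov_xy": float(cov_xy),
        "var_x": float(var_x),
        "var_y": float(var_y),
        "pearson_rho": float(rho),
        "cov_x_noisediff": float(cov_x_nd),
    }

    rng = np.random.default_rng(seed)
    zs = rng.normal(0.0, np.sqrt(2.0), size=mc_n)
    e1s = rng.standard_normal(mc_n)
    e2s = rng.standard_normal(mc_n)
    xs, ys = zs + e1s, zs + e2s
    mc = {
        "cov_xy": float(np.cov(xs, ys)[0, 1]),
        "var_x": float(np.var(xs, ddof=1)),
        "var_y": float(np.var(ys, ddof=1)),
        "pearson_rho": float(np.corrcoef(xs, ys)[0, 1]),
        "cov_x_noisediff": float(np.cov(xs, e2s - e1s)[0, 1]),
    }
    return {"exact": exact, "monte_carlo": mc}


def example_b_report(
    n: int = 2000, seed: int = 0, n_permutations: int = 500
) -> tuple[float, float]:
    """Sample Pearson correlation and causation p-value for Y = 5X^2 + eps.

    The population correlation is exactly zero (E[X * X^2] = 0 for the
    symmetric uniform X) while the causation X -> Y is strong, so this
    exemplifies causation without linear correlation.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    data = generate(SimModelSpec(family="example-b-quadratic", n=n, seed=seed))
    corr = float(np.corrcoef(data.x, data.y)[0, 1])
    result = permutation_test(
        data, n_permutations=n_permutations, split=SplitSpec(seed=seed)
    )
    return corr, result.p_value


def generate_planted_network(
    n_genes: int = 10,
    n_edges: int = 8,
    n_samples: int = 500,
    seed: int = 0,
):
    """Synthetic expression matrix with planted nonlinear regulatory edges.

    The genes are split at random into a regulator layer and a target
    layer and ``n_edges`` directed regulator -> target edges are
    planted (round-robin, so fan-out and fan-in stay balanced).  The
    depth-1 layout is deliberate: deeper cascades make ancestor pairs
    genuinely causal (they would be scored as false against the direct
    edge set), and heavy fan-out hubs flood the ranking with
    confounded sibling pairs, so neither makes a clean orientation
    benchmark.  Each edge contributes a mechanism z + c*z^2 or
    z + c*z^3 (alternating, c a random sign) of the standardized
    regulator; targets add independent Gaussian noise at sd 0.5 and
    unregulated genes are independent standard normal.  Returns
    (expression DataFrame of shape genes x samples, set of true
    directed (source, target) edges).
    """
    import pandas as pd

    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    n_src = n_genes // 2
    n_tgt = n_genes - n_src
    max_edges = n_src * n_tgt
    if not 1 <= n_edges <= max_edges:
        raise ValueError(f"n_edges must be in [1, {max_edges}]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_genes)
    sources, targets = order[:n_src], order[n_src:]
    balanced = [
        (int(sources[i]), int(targets[(i + offset) % n_tgt]))
        for offset in range(n_tgt)
        for i in range(n_src)
    ]
    chosen = balanced[:n_edges]

    values = np.zeros((n_genes, n_samples))
    for g in sources:
        values[g] = rng.standard_normal(n_samples)
    parents: dict[int, list[int]] = {}
    for j, (src, tgt) in enumerate(chosen):
        parents.setdefault(tgt, []).append(j)
    for g in targets:
        if g not in parents:
            values[g] = rng.standard_normal(n_samples)
            continue
        signal = np.zeros(n_samples)
        for j in parents[g]:
            parent = values[chosen[j][0]]
            z = (parent - parent.mean()) / parent.std()
            c = 1.0 if rng.random() < 0.5 else -1.0
            signal += z + c * (z * z if j % 2 == 0 else z**3)
        values[g] = signal + rng.normal(0.0, 0.5, size=n_samples)

    genes = [f"g{i + 1}" for i in range(n_genes)]
    samples = [f"s{i + 1}" for i in range(n_samples)]
    expr = pd.DataFrame(values, index=genes, columns=samples)
    truth = {(genes[src], genes[tgt]) for src, tgt in chosen}
    return expr, truth
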