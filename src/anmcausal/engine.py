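"""Bivariate ANM causal-discovery engine.

The procedure:

1. split the sample into a training half and a test half;
2. regress Y on X and X on Y nonparametrically on the training half;
3. predict out-of-sample residuals E_Y and E_X on the test half;
4. compute HSIC2(E_Y, X) and HSIC2(E_X, Y) on the test half;
5. infer X -> Y if HSIC2(E_Y, X) < HSIC2(E_X, Y), Y -> X if greater,
   undecided on exact equality.

Causation in either direction is tested by permuting the test-half y
values (x fixed), pushing them through the fixed fitted curves to get
permuted residuals, and comparing permuted values of the asymmetry
statistic T_C = |HSIC2(E_Y,X) - HSIC2(E_X,Y)| with the observed one.
When x and y are independent the permuted datasets are exchangeable
with the observed one, so the test is exactly valid; a variant that
permutes y over the whole sample and refits both ANMs per permutation
is available via ``refit=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hsic import HSICConfig, hsic_squared
from .regress import fit_nonparametric, residuals

__all__ = [
    "PairedSample",
    "SplitSpec",
    "DirectionScores",
    "CausalTestResult",
    "split_train_test",
    "score_directions",
    "permutation_test",
]


@dataclass(frozen=True)
class PairedSample:
    """Paired observations of a candidate cause x and effect y."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, str] = ("x", "y")

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float).ravel()
        y = np.asarray(self.y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("x and y must have equal length")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("paired sample contains missing or non-finite values")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.x.size

    def swapped(self) -> "PairedSample":
        return PairedSample(self.y, self.x, (self.labels[1], self.labels[0]))


@dataclass(frozen=True)
class SplitSpec:
    """Seeded random train/test partition. Both halves must have >= 10 points."""

    train_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class DirectionScores:
    hsic_forward: float   # HSIC2(E_Y, X): small if X -> Y admits an ANM
    hsic_backward: float  # HSIC2(E_X, Y)
    decision: str = field(init=False)

    def __post_init__(self) -> None:
        if self.hsic_forward < self.hsic_backward:
            d = "forward"
        elif self.hsic_forward > self.hsic_backward:
            d = "backward"
        else:
            d = "undecided"
        object.__setattr__(self, "decision", d)

    @property
    def t_c(self) -> float:
        return abs(self.hsic_forward - self.hsic_backward)


@dataclass(frozen=True)
class CausalTestResult:
    t_c: float
    n_permutations: int
    p_value: float
    decision: str
    seed: int
    scores: DirectionScores

    def p_value_display(self) -> str:
        if self.p_value == 0.0:
            return f"< {1.0 / self.n_permutations:g}"
        return f"{self.p_value:g}"


def _split_indices(n: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    n_train = int(round(n * spec.train_fraction))
    n_test = n - n_train
    if n_train < 10 or n_test < 10:
        raise ValueError(
            f"split of {n} at fraction {spec.train_fraction} leaves "
            f"train={n_train}, test={n_test}; both must be >= 10"
        )
    perm = np.random.default_rng(spec.seed).permutation(n)
    return perm[:n_train], perm[n_train:]


def split_train_test(
    data: PairedSample, spec: SplitSpec | None = None
) -> tuple[PairedSample, PairedSample]:
    """Disjoint seeded random partition; the union equals the input."""
    spec = spec or SplitSpec()
    if len(data) < 20:
        raise ValueError("need at least 20 observations to split")
    tr, te = _split_indices(len(data), spec)
    return (
        PairedSample(data.x[tr], data.y[tr], data.labels),
        PairedSample(data.x[te], data.y[te], data.labels),
    )


def _scores_for_split(
    x: np.ndarray,
    y: np.ndarray,
    tr: np.ndarray,
    te: np.ndarray,
    reg_method: str,
    hsic_config: HSICConfig,
) -> DirectionScores:
    fit_fwd = fit_nonparametric(x[tr], y[tr], reg_method)
    fit_bwd = fit_nonparametric(y[tr], x[tr], reg_method)
    e_y = residuals(fit_fwd, x[te], y[te])
    e_x = residuals(fit_bwd, y[te], x[te])
    return DirectionScores(
        hsic_forward=hsic_squared(e_y, x[te], hsic_config),
        hsic_backward=hsic_squared(e_x, y[te], hsic_config),
    )


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def score_directions(
    data: PairedSample,
    split: SplitSpec | None = None,
    reg_method: str = "spline",
    hsic_config: HSICConfig | None = None,
) -> DirectionScores:
    """Run the 5-step direction procedure on one paired sample.

    Both variables are standardized over the full sample first, so the
    decision is invariant to affine rescaling of either axis.
    """
    split = split or SplitSpec()
    hsic_config = hsic_config or HSICConfig()
    if len(data) < 20:
        raise ValueError("need at least 20 observations")
    tr, te = _split_indices(len(data), split)
    x = _standardize(data.x)
    y = _standardize(data.y)
    return _scores_for_split(x, y, tr, te, reg_method, hsic_config)


def permutation_test(
    data: PairedSample,
    n_permutations: int = 500,
    split: SplitSpec | None = None,
    reg_method: str = "spline",
    hsic_config: HSICConfig | None = None,
    refit: bool = False,
    reshuffle_split: bool = False,
) -> CausalTestResult:
    """Permutation test of H0: no causation X -> Y and no causation Y -> X.

    Default scheme: the regressions are fitted once on the training
    half; for each permutation the test-half y values are shuffled
    (x fixed), residuals are recomputed through the fixed fitted
    curves, and T_C is recomputed.  Because the residual maps are
    fixed functions estimated on an independent training half, the
    observed and permuted statistics are exchangeable whenever x and
    y are independent, making the test exactly valid there; under
    dependence without causation it is conservative.

    ``refit=True`` instead permutes y over the whole sample and
    refits both ANMs (bandwidths recomputed) on each permuted
    dataset.  The p-value is the plain proportion of permuted T_C
    values >= the observed one, so its resolution is 1/n_permutations.
    The train/test partition is reused across permutations unless
    ``reshuffle_split`` is set (refit mode only), so permutation
    variability reflects the statistic rather than the split.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    split = split or SplitSpec()
    hsic_config = hsic_config or HSICConfig()
    if len(data) < 20:
        raise ValueError("need at least 20 observations")

    n = len(data)
    tr, te = _split_indices(n, split)
    x = _standardize(data.x)
    y = _standardize(data.y)

    rng = np.random.default_rng(np.random.SeedSequence([split.seed, 0x9E3779B9]))
    n_ge = 0

    if refit:
        observed = _scores_for_split(x, y, tr, te, reg_method, hsic_config)
        t_obs = observed.t_c
        for _ in range(n_permutations):
            y_perm = y[rng.permutation(n)]
            if reshuffle_split:
                perm = rng.permutation(n)
                tr_i, te_i = perm[: tr.size], perm[tr.size :]
            else:
                tr_i, te_i = tr, te
            scores = _scores_for_split(x, y_perm, tr_i, te_i, reg_method, hsic_config)
            if scores.t_c >= t_obs:
                n_ge += 1
    else:
        fit_fwd = fit_nonparametric(x[tr], y[tr], reg_method)
        fit_bwd = fit_nonparametric(y[tr], x[tr], reg_method)
        x_te, y_te = x[te], y[te]

        def t_c_of(y_vals: np.ndarray) -> DirectionScores:
            e_y = residuals(fit_fwd, x_te, y_vals)
            e_x = residuals(fit_bwd, y_vals, x_te)
            return DirectionScores(
                hsic_forward=hsic_squared(e_y, x_te, hsic_config),
                hsic_backward=hsic_squared(e_x, y_vals, hsic_config),
            )

        observed = t_c_of(y_te)
        t_obs = observed.t_c
        m = y_te.size
        for _ in range(n_permutations):
            if t_c_of(y_te[rng.permutation(m)]).t_c >= t_obs:
                n_ge += 1

    return CausalTestResult(
        t_c=t_obs,
        n_permutations=n_permutations,
        p_value=n_ge / n_permutations,
        decision=observed.decision,
        seed=split.seed,
        scores=observed,
    )
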