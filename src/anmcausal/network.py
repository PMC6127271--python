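"""Pairwise ANM orientation of gene-expression networks.

Every unordered gene pair is run through the bivariate direction
procedure; the pair is emitted as one directed edge in the inferred
direction carrying the asymmetry statistic T_C, and edges are ranked
by T_C descending.  Against a reference directed network (e.g. a KEGG
pathway) the top-k edges are scored by detection accuracy: the
fraction of reported edges present in the reference, requiring the
direction to match ("directed") or not ("undirected").
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .engine import PairedSample, SplitSpec, permutation_test, score_directions
from .hsic import HSICConfig

__all__ = ["pairwise_anm", "detection_accuracy"]

EDGE_COLUMNS = ["rank", "source", "target", "statistic", "p_value"]


def _validate_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if expr.shape[1] < 40:
        raise ValueError(
            f"need at least 40 samples (20 per split half), got {expr.shape[1]}"
        )
    if not expr.index.is_unique:
        raise ValueError("gene identifiers must be unique")
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains missing or non-finite values")
    return expr


def pairwise_anm(
    expr: pd.DataFrame,
    seed: int = 0,
    reg_method: str = "spline",
    hsic_config: HSICConfig | None = None,
    n_permutations: int = 0,
) -> pd.DataFrame:
    """All-pairs bivariate ANM over a genes x samples matrix.

    Returns a DataFrame with columns (rank, source, target, statistic,
    p_value); p_value is NaN unless ``n_permutations`` > 0.  Undecided
    pairs (exactly tied HSIC values) are omitted.  Expression is
    standardized per gene before analysis.
    """
    expr = _validate_matrix(expr)
    genes = list(expr.index)
    records = []
    for ga, gb in combinations(genes, 2):
        data = PairedSample(
            expr.loc[ga].to_numpy(dtype=float),
            expr.loc[gb].to_numpy(dtype=float),
            labels=(str(ga), str(gb)),
        )
        split = SplitSpec(seed=seed)
        scores = score_directions(data, split, reg_method, hsic_config)
        if scores.decision == "undecided":
            continue
        if scores.decision == "forward":
            src, tgt = ga, gb
        else:
            src, tgt = gb, ga
        p_value = np.nan
        if n_permutations > 0:
            p_value = permutation_test(
                data, n_permutations, split, reg_method, hsic_config
            ).p_value
        records.append((str(src), str(tgt), scores.t_c, p_value))

    out = pd.DataFrame(records, columns=["source", "target", "statistic", "p_value"])
    out = out.sort_values(
        ["statistic", "source", "target"], ascending=[False, True, True]
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def detection_accuracy(
    edges: pd.DataFrame,
    truth: set[tuple[str, str]],
    mode: str = "directed",
    top_k: int | None = None,
) -> float:
    """Fraction of reported edges present in the reference network.

    ``mode='directed'`` counts (source, target) matches only;
    ``mode='undirected'`` also counts the reversed pair.  With
    ``top_k`` the first k rows by rank are scored.
    """
    if mode not in ("directed", "undirected"):
        raise ValueError(f"mode must be 'directed' or 'undirected', got {mode!r}")
    if len(edges) == 0:
        raise ValueError("edge list is empty")
    subset = edges.sort_values("rank") if "rank" in edges.columns else edges
    if top_k is not None:
        if top_k < 1:
            raise ValueError("top_k must be >= 1")
        subset = subset.head(top_k)
    matches = 0
    for src, tgt in zip(subset["source"], subset["target"]):
        pair = (str(src), str(tgt))
        if pair in truth or (mode == "undirected" and pair[::-1] in truth):
            matches += 1
    return matches / len(subset)
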