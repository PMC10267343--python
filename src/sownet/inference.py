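"""Subgroup comparisons of degree measures.

Each animal contributes a single degree value (e.g. presence-adjusted
in-degree), grouped by its k-core subgroup. With one observation per
animal a per-animal random effect is degenerate, so the comparison rests
on two complementary procedures:

* a permutation omnibus test — statistic = size-weighted between-group
  variance of group means, null built by shuffling group labels; and
* a fixed-effects negative-binomial regression of (rounded) counts on
  subgroup indicators, delegated to statsmodels, reference level = the
  group with the smallest mean. Coefficients are on the log scale, so a
  coefficient c means the group mean is e^c times the reference mean.

The substitution of the fixed-effects model for a mixed model is recorded
in the output metadata of every report that carries these results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubgroupComparison",
    "subgroup_stats",
    "permutation_group_test",
    "negbin_fit",
    "compare_subgroups",
]

INFERENCE_NOTE = (
    "Fixed-effects negative-binomial GLM plus a label-permutation omnibus test; "
    "a per-animal random effect is degenerate with one degree value per animal."
)


@dataclass
class SubgroupComparison:
    measure: str
    group_stats: pd.DataFrame
    statistic: float
    p_permutation: float
    n_permutations: int
    seed: int
    negbin: pd.DataFrame | None
    negbin_converged: bool
    top_group: object
    note: str = INFERENCE_NOTE

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "group_stats": self.group_stats.reset_index().to_dict(orient="records"),
            "statistic": self.statistic,
            "p_permutation": self.p_permutation,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "negbin": None
            if self.negbin is None
            else self.negbin.reset_index().to_dict(orient="records"),
            "negbin_converged": self.negbin_converged,
            "top_group": self.top_group,
            "note": self.note,
        }


def subgroup_stats(values: Sequence[float], groups: Sequence) -> pd.DataFrame:
    """Per-group n, mean and sample SD (SD is 0 for singleton groups)."""
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    out = df.groupby("group")["value"].agg(n="size", mean="mean", sd="std")
    out["sd"] = out["sd"].fillna(0.0)
    out.index.name = "group"
    return out


def _between_group_stat(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Size-weighted between-group variance of group means."""
    sums = np.bincount(codes, weights=values, minlength=n_groups)
    ns = np.bincount(codes, minlength=n_groups)
    means = sums / ns
    grand = values.mean()
    return float(np.dot(ns, (means - grand) ** 2))


def permutation_group_test(
    values: Sequence[float],
    groups: Sequence,
    n_perm: int = 5000,
    seed: int = 0,
) -> tuple[float, float]:
    """(statistic, p) for the permutation omnibus test of group differences.

    p is the add-one Monte-Carlo proportion of label permutations whose
    statistic is at least the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.asarray(values, dtype=float)
    labels = pd.factorize(np.asarray(groups))[0]
    if labels.max() < 1:
        raise ValueError("need at least 2 non-empty groups")
    n_groups = labels.max() + 1
    obs = _between_group_stat(values, labels, n_groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _between_group_stat(values, perm, n_groups) >= obs - 1e-12:
            count += 1
    return obs, (1 + count) / (1 + n_perm)


def negbin_fit(values: Sequence[float], groups: Sequence) -> tuple[pd.DataFrame, bool]:
    """Negative-binomial regression of counts on subgroup indicators.

    Returns (table, converged). The table has one row per non-reference
    group with log-scale coefficient, z and p; the reference level is the
    group with the smallest mean. Values are rounded to integers for the
    count likelihood. Non-convergence (or a degenerate fit) is flagged and
    returns whatever estimates were reached.
    """
    import statsmodels.api as sm

    y = np.asarray(np.round(values), dtype=float)
    if (y < 0).any():
        raise ValueError("negative counts")
    g = pd.Series(list(groups), name="group")
    order = subgroup_stats(y, g)["mean"].sort_values().index
    cat = pd.Categorical(g, categories=list(order))
    dummies = pd.get_dummies(cat, drop_first=True, dtype=float)
    X = sm.add_constant(dummies)
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.NegativeBinomial(y, X)
            res = model.fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False)) and np.isfinite(
            res.params
        ).all()
        table = pd.DataFrame(
            {
                "coef": res.params,
                "std_err": res.bse,
                "z": res.tvalues,
                "p": res.pvalues,
            }
        )
    except Exception:
        converged = False
        table = pd.DataFrame(columns=["coef", "std_err", "z", "p"])
    table.index.name = "term"
    return table, converged


def compare_subgroups(
    degrees: pd.DataFrame,
    coreness: Mapping[str, int],
    measure: str = "in",
    use_adjusted: bool = True,
    n_perm: int = 5000,
    seed: int = 0,
) -> SubgroupComparison:
    """Compare a degree measure across k-core subgroups.

    ``degrees`` is the table from :func:`sownet.build.adjusted_degrees`;
    ``measure`` selects in- or out-degree; ``use_adjusted`` picks the
    presence-adjusted counts (default) or the raw ones.
    """
    if measure not in ("in", "out"):
        raise ValueError("measure must be 'in' or 'out'")
    col = f"{measure}_{'adjusted' if use_adjusted else 'degree_raw'}"
    animals = [a for a in degrees.index if a in coreness]
    vals = degrees.loc[animals, col].to_numpy(dtype=float)
    grp = [coreness[a] for a in animals]
    stats = subgroup_stats(vals, grp)
    statistic, p_perm = permutation_group_test(vals, grp, n_perm=n_perm, seed=seed)
    nb, converged = negbin_fit(vals, grp)
    top_group = stats["mean"].idxmax()
    return SubgroupComparison(
        measure=col,
        group_stats=stats,
        statistic=statistic,
        p_permutation=p_perm,
        n_permutations=n_perm,
        seed=seed,
        negbin=nb,
        negbin_converged=converged,
        top_group=top_group,
    )
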