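"""E-I index of assortment by attribute, with a permutation null.

The E-I index contrasts External ties (endpoints in different attribute
classes) with Internal ties (same class): ``(E - I) / (E + I)``, ranging
from -1 (perfect homophily, all ties internal) to +1 (perfect heterophily,
all ties external). Each directed arc is counted once, binary by default.

Significance is assessed by permuting the attribute labels over nodes
(class sizes preserved, graph fixed) and comparing the observed index to
the permutation distribution. The reported p-value is two-tailed by
default — the proportion of permuted indices at least as far from the
permutation mean as the observed one — with a one-tailed homophily
alternative available. The identity permutation is included via the
standard add-one Monte-Carlo correction, so p is never exactly 0.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np

from .data import PrefNetwork

__all__ = ["EIResult", "ei_index", "ei_permutation_test"]


@dataclass(frozen=True)
class EIResult:
    attribute: str
    E: int
    I: int
    ei_observed: float
    ei_expected: float
    ei_sd: float
    p_value: float
    n_permutations: int
    seed: int
    alternative: str

    def to_dict(self) -> dict:
        return asdict(self)


def _arc_arrays(net: PrefNetwork, labels: Mapping[str, object], weighted: bool):
    node_index = {a: i for i, a in enumerate(net.nodes)}
    unlabeled = sorted(
        {a for pair in net.arcs for a in pair if labels.get(a) is None}
    )
    if unlabeled:
        raise ValueError(f"non-isolate node(s) without attribute label: {unlabeled}")
    src = np.fromiter((node_index[u] for (u, _) in net.arcs), dtype=np.intp, count=net.n_arcs)
    dst = np.fromiter((node_index[v] for (_, v) in net.arcs), dtype=np.intp, count=net.n_arcs)
    if weighted:
        w = np.fromiter(net.arcs.values(), dtype=float, count=net.n_arcs)
    else:
        w = np.ones(net.n_arcs)
    # Unlabeled isolates get a private sentinel; they touch no arc.
    lab_list = [labels.get(a, ("__unlabeled__", i)) for i, a in enumerate(net.nodes)]
    codes = {l: c for c, l in enumerate(dict.fromkeys(lab_list))}
    lab = np.array([codes[l] for l in lab_list], dtype=np.intp)
    return src, dst, w, lab


def _ei(lab: np.ndarray, src: np.ndarray, dst: np.ndarray, w: np.ndarray):
    external = lab[src] != lab[dst]
    E = float(w[external].sum())
    I = float(w[~external].sum())
    return E, I, (E - I) / (E + I)


def ei_index(
    net: PrefNetwork, labels: Mapping[str, object], weighted: bool = False
) -> tuple[float, float, float]:
    """(E, I, ei) for one attribute; raises if the network has no arcs."""
    if net.n_arcs == 0:
        raise ValueError("E-I index undefined on a network with no arcs")
    src, dst, w, lab = _arc_arrays(net, labels, weighted)
    return _ei(lab, src, dst, w)


def ei_permutation_test(
    net: PrefNetwork,
    labels: Mapping[str, object],
    n_perm: int = 10_000,
    seed: int = 0,
    attribute: str = "attribute",
    weighted: bool = False,
    alternative: str = "two-sided",
) -> EIResult:
    """Node-label permutation test of the E-I index.

    ``alternative`` is ``"two-sided"`` (deviation from the permutation mean
    in either direction) or ``"homophily"`` (one-tailed toward negative
    E-I). With a degenerate partition (one class) every permutation gives
    the same index, sd is 0 and p is 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("two-sided", "homophily"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if net.n_arcs == 0:
        raise ValueError("E-I index undefined on a network with no arcs")
    src, dst, w, lab = _arc_arrays(net, labels, weighted)
    E, I, obs = _ei(lab, src, dst, w)
    rng = np.random.default_rng(seed)
    perm_ei = np.empty(n_perm)
    for b in range(n_perm):
        p = rng.permutation(lab)
        _, _, perm_ei[b] = _ei(p, src, dst, w)
    expected = float(perm_ei.mean())
    sd = float(perm_ei.std(ddof=0))
    if sd == 0.0:
        p_value = 1.0
    elif alternative == "two-sided":
        extreme = np.abs(perm_ei - expected) >= abs(obs - expected) - 1e-12
        p_value = (1 + int(extreme.sum())) / (1 + n_perm)
    else:  # homophily: permuted index as low or lower than observed
        p_value = (1 + int((perm_ei <= obs + 1e-12).sum())) / (1 + n_perm)
    return EIResult(
        attribute=attribute,
        E=int(round(E)),
        I=int(round(I)),
        ei_observed=obs,
        ei_expected=expected,
        ei_sd=sd,
        p_value=float(min(p_value, 1.0)),
        n_permutations=n_perm,
        seed=seed,
        alternative=alternative,
    )
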