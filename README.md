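# sownet

Directed social-network analysis for dynamic livestock herds, built around
preferential associations in group-housed sows. In a dynamic production
system animals are added to and removed from the herd every few weeks, so
the social network is unstable by design; the question the toolkit
addresses is whether animals nevertheless discriminate socially — who
approaches whom to rest, whether those ties are reciprocated, whether they
assort by parity, familiarity or connectedness, and which animals broker
contact within and between subgroups. The intended users are researchers in
applied ethology and animal-welfare science working with dyadic
observation data.

## What it computes

An approach qualifies as a preferential association when the approaching
animal's proximity is *tolerated for more than 60 s*. Qualifying events are
counted per ordered dyad into a directed weighted network, filtered at
minimum dyad counts 1, 2 and 3 (the original, mean and 1.5×-mean
networks). On those networks the package computes:

- **Presence-adjusted degrees.** Animals present only `x` of the `H` total
  observation hours get the per-hour rate `y = n/x` (where `n` is the
  weighted in- or out-degree) and the adjusted degree `y·H`, under a
  constant-rate assumption.
- **Cohesion metrics.** Density `arcs / n(n−1)`; arc reciprocity (fraction
  of arcs whose reverse exists); Freeman degree centralization
  `Σ_v (c_max − c_v) / max`; unnormalized directed betweenness; the overall
  clustering coefficient `Σ_v cc_v·p_v / Σ_v p_v` with `p_v` the neighbour-
  pair count on the symmetrized graph; weak components and isolates.
- **E-I assortment.** `(E − I)/(E + I)` per attribute (−1 perfect
  homophily, +1 perfect heterophily) with a seeded node-label permutation
  test.
- **k-cores.** Coreness by iterative pruning of the symmetrized graph;
  shells define the connectedness subgroups.
- **Gould–Fernandez brokerage.** For every open directed two-path
  `i → j → k` (no direct `i → k` arc) the broker `j` is a coordinator,
  gatekeeper, representative, consultant or liaison depending on the three
  nodes' subgroup labels; raw counts are normalized by their label-
  permutation expectation and the per-subgroup census is tabulated.
- **Subgroup comparisons.** Per-core mean ± SD of adjusted degrees, a
  permutation omnibus test, and a fixed-effects negative-binomial
  regression (log-scale coefficients, least-connected core as reference).

A synthetic dynamic-herd generator (gamma-distributed sociality,
popularity correlated with sociality, staggered presence, capped dyad
counts, optional planted homophily) provides realistic inputs so the whole
pipeline is testable without farm data.

## Worked example

The numbered drivers under `analysis/` run the full study on a synthetic
78-sow herd (seed 1) and write their tables under `results/`:

```bash
python analysis/01_simulate_herd.py      # 1365 approach records, 14 sows < 21 h
python analysis/02_build_networks.py     # 840 / 120 / 21 arcs at thresholds 1/2/3
python analysis/03_cohesion_metrics.py
python analysis/04_assortment_ei.py
python analysis/05_brokerage_roles.py
python analysis/06_subgroup_degrees.py
```

Step 03 prints the threshold comparison — density falls 0.140 → 0.020 →
0.003 while isolates rise 2 → 17 → 55, the signature of few sustained
associations. Step 04 prints, for the mean network:

```
parity         E-I = +0.683 (expected +0.684 +- 0.068), p = 1.0000
breeding_group E-I = +0.800 (expected +0.737 +- 0.063), p = 0.3579
kcore          E-I = -0.217 (expected +0.515 +- 0.081), p = 0.0001
```

i.e. ties do not assort by parity or breeding group, but sows of similar
connectedness associate far more than chance expects. Step 05 finds the
densest core dominated by coordinators (brokering within the own
subgroup), and step 06 shows the top core both receives (8.0 ± 5.8 vs ≤
3.2 elsewhere) and initiates (9.8 ± 7.2 vs ≤ 2.2) the most approaches
(permutation p = 0.0002).

The same pipeline runs in one shot on real or simulated data via the CLI:

```bash
sownet run-all --simulate --seed 1 --out-dir results/run1
```

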