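# Methods

## Data model

An observation is one approach event: day within the 21-day cycle,
session (morning / afternoon / evening one-hour blocks), initiator,
recipient, toleration duration in seconds, and outcome (tolerated /
displaced / withdrawn). The registry carries per-animal parity (1–6),
breeding group (1–7) and hours present in `(0, 21]`. Identifiers are
opaque strings. Networks carry their node set independently of their arc
list so that animals without qualifying ties remain representable as
isolates after filtering.

## Network construction

An event qualifies when the outcome is *tolerated* and the duration is
**strictly** greater than 60 s — a 60.0 s event does not qualify. Arc
weight for the ordered dyad (initiator, recipient) is the count of
qualifying events over the whole window; direction is always
initiator → recipient. Thresholding keeps arcs with weight ≥ level
(1 = original, 2 = mean, 3 = 1.5×-mean). Thresholds are lower bounds only:
the "up to 5 interactions" seen in observed data is an empirical maximum,
not a cap in the filter. Nodes are retained as isolates by default, since
isolate counts inside filtered networks are themselves a result; a
`drop_isolates` flag reproduces the alternative convention in which the
filtered network shrinks to its connected animals. Both conventions are
supported because published tables are often ambiguous about which was
used.

## Presence adjustment

Dynamic herds mean unequal observation exposure. For an animal observed
`x` hours with weighted degree `n`, the per-hour rate is `y = n/x` and the
adjusted degree is `y · H` with `H` the full window (21 h). This assumes
the animal's interaction rate is constant across hours — reasonable when
the analysis does not address temporal change, but it linearly
extrapolates and can overstate the degrees of briefly-present animals
with a lucky hour. Raw, rate and adjusted values are all emitted, as are
binary-degree variants (distinct partners rather than event counts).

## Metric conventions

- **Density, reciprocity, centralization, betweenness, components,
  k-cores** are computed on the binarized directed graph; weights enter
  only through weighted degrees and symmetrization.
- **Centralization** is Freeman's index `Σ_v (c_max − c_v)` divided by the
  maximum attainable for a directed graph of the same size: `(n−1)²` for
  in- or out-degree (one-way star), `2(n−1)(n−2)` for total degree (hub
  tied both ways to everyone). A directed cycle scores 0; a perfect star
  scores 1.
- **Betweenness** is unnormalized shortest-path betweenness on the
  directed binary graph (a normalized variant is a flag); published group
  means in this literature are clearly unnormalized.
- **Clustering** is the overall graph clustering coefficient on the
  symmetrized graph: each node's local coefficient (fraction of its
  neighbour pairs that are connected) weighted by its number of neighbour
  pairs. This equals the closed-triple / connected-triple ratio
  (transitivity). The weighting is over opportunity counts; edge weights
  themselves do not enter the coefficient, only the symmetrization that
  defines adjacency. Undefined (NaN) when no node has two neighbours.
- **k-cores** are computed on the symmetrized binary graph (an undirected
  edge exists if an arc exists in either direction; its weight, where
  needed, is the sum of the two arc weights); a node's coreness is the
  largest k at which it survives iterative pruning.
- **Mean degree** is emitted both binary (arcs/n) and weighted (total
  weight/n); neither is privileged because published tables rarely state
  the convention.

## E-I index and permutation null

`ei = (E − I)/(E + I)` over binary arcs (each directed arc counted once;
a weighted option exists). The null permutes the attribute labels over
nodes with class sizes preserved and the graph fixed — node-label
permutation is the standard choice, and it keeps the observed labelling
inside the permutation orbit. The default p-value is two-tailed (distance
from the permutation mean), with a one-tailed homophily alternative by
flag; the direction of published deviations is often unstated, so the
two-tailed default is the conservative one. All permutation p-values in
the package use the add-one convention `(1 + #extreme)/(1 + n_perm)`,
which includes the identity permutation and cannot produce p = 0. A
degenerate partition (single class) yields sd 0 and p = 1. The rescaled
E-I variant is not implemented.

## Brokerage

Roles are counted on open ordered two-paths `i → j → k` with `i ≠ k` and
no direct `i → k` arc — brokering is between two otherwise unconnected
animals; a flag counts closed triples too. The five label rules
(coordinator, gatekeeper, representative, consultant, liaison) partition
all label triples exhaustively and exclusively. Expected counts use
Monte-Carlo label permutation (group sizes fixed, graph fixed) rather
than closed-form expectations: the null concept is identical, and the
Monte-Carlo route is directly testable against exhaustive permutation on
small graphs; analytic formulas remain a future option. Typology is the
argmax of raw/expected among roles actually performed; all-zero raw
counts give `none`, tied maxima give `unresolved` (ties are reported,
never broken), and a performed role with zero expectation sets an
`excluded` flag marking the profile uninterpretable — a stated,
documented rule for a situation published analyses handle by silently
dropping animals. The pipeline's default partition is the coreness value
on the mean network.

## Subgroup inference

With one degree value per animal, a per-animal random effect cannot be
identified, so the package substitutes (and says so in its output
metadata): (a) a permutation omnibus test whose statistic is the
size-weighted between-group variance of group means, and (b) a
fixed-effects negative-binomial regression (statsmodels ML fit, NB2) of
rounded counts on subgroup indicators with the smallest-mean group as
reference. Adjusted (presence-weighted) degrees are the default response,
raw counts a flag. Non-convergence of the NB fit is flagged and never
fatal; the permutation result is always reported.

## Synthetic herd generator

The generator emulates the study design the pipeline targets: 78 sows, 7
near-equal breeding groups, parities uniform on 1–6, 7 observation days ×
3 one-hour sessions (21 h), and 14 animals with truncated presence (half
entering late, half leaving early, at day granularity). Sociality `s` is
gamma(shape 1.4, mean 1) — right-skewed so a minority of animals does
much of the approaching; attractiveness is `0.6·s + 0.4·g` with
independent gamma `g`, making popularity correlate with sociality
(r ≈ 0.6–0.7) without collapsing the two. Approaches i → j per session
are Poisson with mean `base_rate · s_i · a_j`, multiplied by a homophily
factor when both animals share the planted sociality class (tertiles of
`s`; default multiplier 1 = no planted assortment). 80% of approaches are
tolerated; 10% of tolerated durations fall at ≤ 60 s so the qualifying
filter is exercised; qualifying events per ordered dyad are capped at 5.

`base_rate = 0.016` per ordered dyad per session-hour was chosen once so
the default herd reproduces the qualitative structure reported for real
dynamic sow herds — original-network density ≈ 0.15, mean-network density
≈ 0.02–0.04, isolates rising steeply across thresholds, mean-network
reciprocity < 0.3, and a multi-shell core structure whose top core is
both the most social and the most popular. The generator does **not**
model space (resting-site preference is a known confounder of proximity
networks), temporal dynamics within the cycle, individual recognition
errors, or dyad-level reciprocity mechanisms — so passing tests show the
pipeline recovers planted structure of this statistical shape, not that
the generator is a behavioural model of sows. The i → j and j → i
processes being independent is what keeps generated reciprocity low; a
herd with true mutual bonds would violate it.

## Numerical and design choices

- Permutation tests and the generator take explicit integer seeds; the
  pipeline derives stage seeds from one master seed by fixed offsets, and
  reports are byte-identical across reruns with the same configuration.
- Equality comparisons on permutation statistics use a 1e-12 slack so
  ties at the observed value count as extreme (conservative).
- Degenerate inputs are mapped to missing values, not errors, where the
  quantity is genuinely undefined: reciprocity with no arcs, clustering
  with no connected triples, percentages of an empty census. Quantities
  undefined below a minimum size (density n < 2, centralization n < 3)
  raise instead, since calling them there is a caller bug.
- The test problem sizes (12-node graphs for geodesic enumeration,
  6-node graphs for exhaustive label permutation, 500 replicates for
  type-I calibration, 2000 observations per group for coefficient
  recovery) were chosen as the smallest sizes at which the oracles are
  exact and the statistical bands are tight enough to be informative.

## Known limitations

- Betweenness and E-I ignore weights by default; valued analogues exist
  in the literature and are only partially exposed (weighted E-I flag).
- The Monte-Carlo brokerage expectation has sampling error ∝ n_perm^(−1/2);
  for borderline typology calls, raise `n_perm`.
- The NB fit can fail to converge on degenerate or zero-variance inputs;
  it is flagged, and inference then rests on the permutation test alone.
- Adjusted degrees extrapolate linearly in presence hours; with very
  short presence windows they are noisy and heavy-tailed.
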