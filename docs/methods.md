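# Methods

## The layout model

A drawing of a network with `n` nodes is a placement
`R = (r_1, …, r_n)` of the nodes on integer cells of a bounded square
grid, one node per cell (nodes are treated as points; edges are straight
lines). Layout quality is the total pairwise interaction energy

```
cost(R) = Σ_{i<j}  w_ij · d_ij ,      d_ij = |x_i − x_j| + |y_i − y_j|
```

summed over unordered pairs of distinct nodes, with `d_ij` the Manhattan
distance between cells. Positive weights act as springs pulling a pair
together; negative weights push pairs apart. Because coordinates and
weights are integers, all cost arithmetic is exact — comparisons need no
floating-point tolerance.

Weights derive from the topology alone: `w_ij = χ(L_ij)` where `L_ij` is
the unweighted graph distance and `χ` a non-increasing integer table.
Three built-in tables give the layout styles:

| style | χ(1) | χ(2) | χ(3) | χ(4) | χ(≥5) | unreachable |
|---|---|---|---|---|---|---|
| common | 9 | 4 | 1 | −1 | −1 | −1 |
| compact | 9 | 4 | 2 | 1 | 0 | 0 |
| stretched | 6 | 1 | −2 | −2 | −2 | −2 |

*common* roughly balances attraction and repulsion (even node density,
clearly separated modules); *compact* is attraction-dominated (tight
drawings, modules may touch); *stretched* has weak attraction and strong
long-range repulsion (modules drift far apart). The specific integers are
this package's calibration of those qualitative contracts; what the test
suite pins down is the resulting ordering of mean occupied bounding-box
areas (compact ≤ common ≤ stretched), not the table entries, and any
custom table can be supplied (`StyleTable`, or a YAML mapping
distance/"inf" → weight). Pairs in different connected components take the
style's repulsive floor so disconnected components drift apart rather
than overlapping.

When functional-module labels are available, selected weights can be
boosted: add a positive `delta` to `w_ij` for same-module pairs, optionally
restricted to chosen graph distances (e.g. {2, 3}, pulling in module
members that are near but not adjacent) or to chosen module labels (so
only the subsystems of interest aggregate). Both restrictions are exposed
because both usages are natural; defaults apply no boost.

## The optimizer

1. **Initialization** — `n` distinct cells drawn uniformly without
   replacement.
2. **Neighborhood test** (local search) — sweep nodes in index order; for
   each node evaluate the cost change of moving it to every *vacant* cell
   of its Moore 8-neighborhood (4-neighborhood available) and apply the
   best strictly improving move, ties broken by the fixed offset order
   N, NE, E, SE, S, SW, W, NW. Repeat sweeps until one completes with no
   move: the layout is then a certified single-move local minimum.
3. **Re-optimization after perturbation** (global search) — for `niter`
   iterations: move each node with probability `p` to a uniformly chosen
   vacant neighboring cell (sequentially, so the one-node-per-cell
   invariant always holds and vacancy is evaluated at move time), re-run
   the neighborhood test, and accept the candidate only if its cost is
   *strictly* lower. The accepted-cost trace is therefore non-increasing.

The cost change of a single-node move is computed incrementally in O(n)
(`Σ_k w_ik (d'_ik − d_ik)`), verified exactly against full recomputation.
One `numpy.random.Generator` stream seeded once drives initialization and
every perturbation, so a fixed seed gives bit-identical layouts.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `p` | 0.7 | per-node perturbation probability; 0 disables global search, 1 discards most of the incumbent. Performance is not very sensitive in 0.3–0.7. |
| `n_iter` | 60 | perturbation/re-optimization iterations after the initial local search; more iterations help with rapidly diminishing returns. |
| `occupancy` | 0.25 | target fraction of grid cells occupied; the grid is the smallest square with `n / occupancy` cells (`side = ceil(sqrt(n/occupancy))`). Smaller occupancy gives repulsion more room. |
| `neighborhood` | moore | adjacency for both local moves and perturbation. |

Design points that were genuinely open and decided here: the initial
random layout receives one neighborhood-test pass *before* the main loop,
so the recorded trace starts at a local minimum and is monotone from its
first entry; sweeps use best-improvement with a fixed tie-break and
strict-improvement only, which prevents move cycles; perturbation targets
must be vacant and are claimed sequentially; grid dimensions are a free
choice of this implementation (exposed through `occupancy`) since only
relative positions matter to the cost. No adaptive stopping rule is
offered — `n_iter` is fixed and explicit.

## Data model and formats

Networks are undirected, simple (self-loops dropped at parse time — the
cost is defined on pairs of distinct nodes), with optional per-node
class (`metabolite`/`reaction`) and module labels. A bipartite
metabolite–reaction graph is built from a reaction table by connecting
each reaction node to every substrate and product metabolite; reaction
direction is discarded because distances and the cost are symmetric.
Currency metabolites (H2O, CO2, ATP, …; the shipped stoplist is an
editable text file) can be removed to avoid spurious hub connectivity;
nodes left isolated are kept and still placed. Edge lists are two-column
whitespace/tab-separated text with `#` comments; module labels are a
`node<TAB>label` table (unlisted nodes become `unassigned`); layouts are
`node<TAB>x<TAB>y` TSV with a `#grid` header. Degree-0 nodes cannot be
represented in an edge list, so the synth CLI drops them on export with a
warning. Grid coordinates are stored y-up and flipped to the y-down SVG
frame only at render time.

## Synthetic networks

Tests and demonstrations use planted-partition graphs: modules of given
sizes, within-module pair probability `p_in`, cross-module probability
`p_out ≤ p_in`, optionally bipartite (classes alternate within modules and
edges only join classes). The shipped fixtures — 290 nodes in 3 modules
and 677 nodes in 7 subsystems plus unassigned nodes — use bipartite
modules with within-module mean degree ≈ 4 (`p_in = 0.08` on ~100-node
modules) and sparse cross-module links, resembling a currency-filtered
metabolic subnetwork in size and density. They do **not** reproduce real
metabolic topology: degree distributions are binomial rather than
heavy-tailed, modules are homogeneous, and there are no hub metabolites.
Passing tests therefore demonstrate the optimizer's contracts (optimality
on enumerable instances, monotone acceptance, module cohesion under
boosts, style ordering, sub-quadratic growth of move evaluations) on
networks of realistic size and modular structure, not biological fidelity
of any particular drawing.

For the scaling measurement, networks of 50–400 nodes keep module size
(~50) and expected degree roughly constant (`p_out ∝ 1/n`) so that size is
the only variable; the reported exponent is the log-log slope of
delta-cost evaluation counts (the algorithm's unit of work, hardware
independent) against `n` under default parameters.

## Problem sizes used in checks

Exhaustive-enumeration checks run on ≤4 nodes and ≤3×3 grids (≤3024
placements); local-minimum certificates on random instances up to n = 50;
style ordering, cohesion and trace monotonicity on the 290-node fixture
(10–20 seeds); end-to-end completion additionally on the 677-node
fixture; scaling on n ∈ {50, 100, 200, 400}. These sizes were chosen to
keep each check's runtime in seconds-to-minutes while matching the scale
the method is intended for (hundreds of nodes).

## Known limitations

- Edge–node and edge–edge crossings are not penalized; node glyphs are
  laid out as points, so large glyphs can overlap visually.
- The style ordering is asserted on means over seeds; individual runs can
  deviate (both *common* and *stretched* often saturate the full grid).
- No adaptive stopping criterion; very large `n_iter` wastes time once
  improvements become rare.
- The planted-partition generator does not emulate heavy-tailed degree
  distributions; behavior on extreme hubs is untested.
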