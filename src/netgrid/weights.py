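"""Graph distances and the interaction weight matrix.

Pairwise interaction weights drive the grid layout: ``w_ij = chi(L_ij)``
where ``L_ij`` is the unweighted graph distance (shortest path length)
between nodes ``i`` and ``j`` and ``chi`` is a non-increasing integer
function. Positive weights act as attraction (the optimizer shortens the
Manhattan distance between the pair), negative weights as repulsion. A
:class:`StyleTable` is one concrete ``chi``; three built-in tables give the
*common*, *compact* and *stretched* layout styles. Module-membership
information, when available, can additionally boost selected weights so
that nodes of a functional module aggregate in the drawing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .network import Network, _open_text

#: Sentinel marking node pairs in different connected components.
UNREACHABLE = -1


@dataclass(frozen=True)
class StyleTable:
    """An integer weight function chi over graph distances.

    ``chi`` maps each distance 1..D to a weight; distances beyond D take the
    terminal value ``chi[D]``. Pairs in different components take
    ``chi_unreachable``. The table must be non-increasing with attractive
    nearest neighbours (``chi[1] > 0``).
    """

    name: str
    chi: Mapping[int, int]
    chi_unreachable: int

    def __post_init__(self) -> None:
        keys = sorted(self.chi)
        if keys != list(range(1, len(keys) + 1)):
            raise ValueError("chi must be defined on consecutive distances 1..D")
        values = [self.chi[k] for k in keys]
        if any(a < b for a, b in zip(values, values[1:])):
            raise ValueError("chi must be non-increasing in distance")
        if self.chi[1] <= 0:
            raise ValueError("chi(1) must be positive (edges attract)")

    @property
    def max_distance(self) -> int:
        return max(self.chi)

    def weight(self, distance: int) -> int:
        """Weight for one graph distance (``UNREACHABLE`` for split pairs)."""
        if distance == UNREACHABLE:
            return self.chi_unreachable
        if distance == 0:
            return 0
        return self.chi[min(distance, self.max_distance)]

    def lookup(self, max_needed: int) -> np.ndarray:
        """Vectorization table: index d -> chi(d) for d in 0..max_needed."""
        d = np.arange(max_needed + 1)
        table = np.array([self.weight(int(k)) for k in d], dtype=np.int64)
        return table


#: Built-in layout styles. The integer tables realize the qualitative
#: contracts of the three styles: *common* roughly balances attraction and
#: repulsion, *compact* is attraction-dominated (no negative weights), and
#: *stretched* has weak attraction and strong long-range repulsion.
STYLES: dict[str, StyleTable] = {
    "common": StyleTable("common", {1: 9, 2: 4, 3: 1, 4: -1}, chi_unreachable=-1),
    "compact": StyleTable("compact", {1: 9, 2: 4, 3: 2, 4: 1, 5: 0}, chi_unreachable=0),
    "stretched": StyleTable("stretched", {1: 6, 2: 1, 3: -2}, chi_unreachable=-2),
}


def resolve_style(style: str | StyleTable) -> StyleTable:
    if isinstance(style, StyleTable):
        return style
    try:
        return STYLES[style]
    except KeyError:
        raise ValueError(
            f"unknown style {style!r}; built-ins are {sorted(STYLES)}"
        ) from None


def load_style(source: str | Path | IO[str], name: str = "custom") -> StyleTable:
    """Load a chi table from a YAML/JSON mapping of distance (or "inf") -> weight."""
    with _open_text(source) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, Mapping):
        raise ValueError("style file must be a mapping of distance -> weight")
    chi: dict[int, int] = {}
    chi_unreachable: int | None = None
    for key, value in raw.items():
        if str(key).lower() in {"inf", "unreachable"}:
            chi_unreachable = int(value)
        else:
            chi[int(key)] = int(value)
    if chi_unreachable is None:
        chi_unreachable = chi[max(chi)] if chi else 0
    return StyleTable(name, chi, chi_unreachable)


def all_pairs_distances(net: Network) -> np.ndarray:
    """All-pairs unweighted shortest-path distances.

    Returns a symmetric ``(n, n)`` integer matrix with zero diagonal and
    :data:`UNREACHABLE` for pairs in different connected components.
    """
    n = net.n_nodes
    index = net.index()
    rows, cols = [], []
    for a, b in net.edges:
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
    adj = csr_array((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    out = np.full((n, n), UNREACHABLE, dtype=np.int64)
    reachable = np.isfinite(dist)
    out[reachable] = dist[reachable].astype(np.int64)
    return out


def build_weights(dist: np.ndarray, style: str | StyleTable) -> np.ndarray:
    """Elementwise ``W_ij = chi(L_ij)`` with zero diagonal."""
    table = resolve_style(style)
    dist = np.asarray(dist)
    maxd = int(dist.max(initial=0))
    lut = table.lookup(max(maxd, 1))
    clipped = np.clip(dist, 0, maxd)
    W = lut[np.where(dist == UNREACHABLE, 0, clipped)]
    W = np.where(dist == UNREACHABLE, table.chi_unreachable, W).astype(np.int64)
    np.fill_diagonal(W, 0)
    return W


def apply_module_boost(
    W: np.ndarray,
    modules: Mapping[str, str] | Sequence[str],
    nodes: Sequence[str],
    delta: int,
    dist: np.ndarray | None = None,
    distance_filter: Iterable[int] | None = None,
    target_modules: Iterable[str] | None = None,
) -> np.ndarray:
    """Add ``delta`` to the weights of same-module node pairs.

    Two variants are supported: restricting the boost to pairs whose graph
    distance lies in ``distance_filter`` (pulling in module members that are
    topologically close but not adjacent), and restricting to
    ``target_modules`` so only chosen subsystems aggregate. Entries outside
    the predicate are untouched; the result stays symmetric.
    """
    if delta <= 0:
        raise ValueError("boost delta must be a positive integer")
    if isinstance(modules, Mapping):
        labels = [modules.get(v) for v in nodes]
    else:
        labels = list(modules)
        if len(labels) != len(nodes):
            raise ValueError("module label sequence must match node count")
    codes, uniques = _factorize(labels)
    same = (codes[:, None] == codes[None, :]) & (codes[:, None] >= 0)
    if target_modules is not None:
        wanted = {u for u in target_modules}
        keep = np.array([u in wanted for u in uniques], dtype=bool)
        in_target = np.where(codes >= 0, keep[np.clip(codes, 0, None)], False)
        same &= in_target[:, None] & in_target[None, :]
    if distance_filter is not None:
        if dist is None:
            raise ValueError("distance_filter requires the distance matrix")
        same &= np.isin(dist, list(distance_filter))
    boosted = W + delta * same.astype(W.dtype)
    np.fill_diagonal(boosted, np.diagonal(W))
    return boosted


def _factorize(labels: Sequence) -> tuple[np.ndarray, list]:
    uniques: list = []
    lookup: dict = {}
    codes = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab is None:
            codes[i] = -1
            continue
        if lab not in lookup:
            lookup[lab] = len(uniques)
            uniques.append(lab)
        codes[i] = lookup[lab]
    return codes, uniques
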