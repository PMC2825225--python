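"""Scikit-learn style estimator for grid layout of networks.

:class:`GridLayout` follows the manifold-learner idiom: construct with
hyperparameters, ``fit`` on a network (a :class:`~netgrid.network.Network`,
a ``networkx.Graph`` or a square adjacency matrix), then read the fitted
``embedding_`` of integer grid coordinates. It composes with sklearn
utilities (``clone``, ``get_params``/``set_params``, pipelines whose final
step is a transformer-like embedder).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .network import Network, _edge
from .optimize import (
    NEIGHBORHOODS,
    CostTrace,
    Placement,
    make_grid,
    optimize_layout,
)
from .weights import (
    StyleTable,
    all_pairs_distances,
    apply_module_boost,
    build_weights,
    resolve_style,
)


def _as_network(X) -> Network:
    if isinstance(X, Network):
        return X
    if isinstance(X, nx.Graph):
        return Network.from_networkx(X)
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError(
            "X must be a Network, a networkx.Graph, or a square adjacency matrix"
        )
    if not np.allclose(X, X.T):
        raise ValueError("adjacency matrix must be symmetric (undirected network)")
    nodes = [str(i) for i in range(X.shape[0])]
    edges = {
        _edge(nodes[i], nodes[j])
        for i, j in zip(*np.nonzero(X))
        if i < j
    }
    return Network(nodes, edges)


class GridLayout(BaseEstimator):
    """Grid layout of a network by Manhattan-cost local search.

    Nodes are embedded on distinct integer cells of a square grid so that
    the total pairwise interaction energy ``sum w_ij * d_ij`` is low, where
    weights derive from graph distances via a layout-style table and
    ``d_ij`` is the Manhattan distance on the grid. Optimization is a
    neighborhood-test local search restarted by random perturbations.

    Parameters
    ----------
    style : str or StyleTable, default="common"
        Weight table: ``"common"`` balances attraction and repulsion,
        ``"compact"`` is attraction-dominated, ``"stretched"`` spreads
        modules far apart; or any custom :class:`StyleTable`.
    p : float, default=0.7
        Perturbation probability per node and iteration. ``0`` disables the
        global search; ``1`` discards most of the incumbent each iteration.
    n_iter : int, default=60
        Perturbation/re-optimization iterations after the initial local
        search.
    occupancy : float, default=0.25
        Target fraction of grid cells occupied; the grid is the smallest
        square with ``n / occupancy`` cells.
    neighborhood : {"moore", "von_neumann"}, default="moore"
        Adjacency used for both local moves and perturbation.
    boost_delta : int, optional
        If set, add this amount to the weight of same-module node pairs
        (module labels from ``y`` or the network's own annotations).
    boost_distances : iterable of int, optional
        Restrict the boost to pairs at these graph distances.
    boost_modules : iterable of str, optional
        Restrict the boost to these module labels.
    random_state : int or numpy Generator, optional
        Seed for the single RNG stream driving initialization and
        perturbations; fixed seeds give bit-identical layouts.

    Attributes
    ----------
    embedding_ : ndarray of shape (n_nodes, 2)
        Integer (x, y) grid coordinates, one row per node in network order.
    cost_ : int
        Final (accepted) cost.
    trace_ : CostTrace
        Accepted-cost history and delta-evaluation count.
    grid_shape_ : tuple of int
        (width, height) of the layout grid.
    node_ids_ : list of str
        Node identifiers in embedding row order.
    weight_matrix_ : ndarray
        The interaction weight matrix actually optimized (boosts included).

    Examples
    --------
    >>> import networkx as nx
    >>> est = GridLayout(n_iter=10, random_state=0)
    >>> coords = est.fit_transform(nx.path_graph(4))
    >>> coords.shape
    (4, 2)
    """

    def __init__(
        self,
        *,
        style: str | StyleTable = "common",
        p: float = 0.7,
        n_iter: int = 60,
        occupancy: float = 0.25,
        neighborhood: str = "moore",
        boost_delta: int | None = None,
        boost_distances: Iterable[int] | None = None,
        boost_modules: Iterable[str] | None = None,
        random_state=None,
    ):
        self.style = style
        self.p = p
        self.n_iter = n_iter
        self.occupancy = occupancy
        self.neighborhood = neighborhood
        self.boost_delta = boost_delta
        self.boost_distances = boost_distances
        self.boost_modules = boost_modules
        self.random_state = random_state

    def fit(self, X, y: Mapping[str, str] | Sequence[str] | None = None):
        """Compute the layout.

        Parameters
        ----------
        X : Network, networkx.Graph or square array
            The network to lay out.
        y : mapping or sequence, optional
            Module labels (node -> label, or one label per node in network
            order) used for the module boost; defaults to the network's own
            module annotations.
        """
        net = _as_network(X)
        style = resolve_style(self.style)
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")
        if self.n_iter < 0:
            raise ValueError("n_iter must be non-negative")
        try:
            offsets = NEIGHBORHOODS[self.neighborhood]
        except KeyError:
            raise ValueError(
                f"neighborhood must be one of {sorted(NEIGHBORHOODS)}"
            ) from None

        dist = all_pairs_distances(net)
        W = build_weights(dist, style)
        modules = y if y is not None else net.node_module
        if self.boost_delta is not None:
            if modules is None:
                raise ValueError("boost requested but no module labels available")
            W = apply_module_boost(
                W,
                modules,
                net.nodes,
                int(self.boost_delta),
                dist=dist,
                distance_filter=self.boost_distances,
                target_modules=self.boost_modules,
            )
        width, height = make_grid(net.n_nodes, self.occupancy)
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        coords, trace = optimize_layout(
            W, width, height, p=self.p, n_iter=self.n_iter, rng=rng, offsets=offsets
        )
        self.node_ids_ = list(net.nodes)
        self.embedding_ = coords
        self.cost_ = trace.accepted_costs[-1]
        self.trace_ = trace
        self.grid_shape_ = (width, height)
        self.distances_ = dist
        self.weight_matrix_ = W
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit and return the ``(n_nodes, 2)`` integer coordinate array."""
        return self.fit(X, y).embedding_

    @property
    def placement_(self) -> Placement:
        """The fitted layout as a :class:`Placement` (nodes + grid + coords)."""
        return Placement(
            self.node_ids_, self.embedding_, self.grid_shape_[0], self.grid_shape_[1]
        )


def layout_network(
    net: Network | nx.Graph,
    *,
    style: str | StyleTable = "common",
    p: float = 0.7,
    n_iter: int = 60,
    occupancy: float = 0.25,
    neighborhood: str = "moore",
    boost_delta: int | None = None,
    boost_distances: Iterable[int] | None = None,
    boost_modules: Iterable[str] | None = None,
    seed=None,
) -> tuple[Placement, CostTrace]:
    """Functional wrapper over :class:`GridLayout`: network in, layout out."""
    est = GridLayout(
        style=style,
        p=p,
        n_iter=n_iter,
        occupancy=occupancy,
        neighborhood=neighborhood,
        boost_delta=boost_delta,
        boost_distances=boost_distances,
        boost_modules=boost_modules,
        random_state=seed,
    )
    est.fit(net)
    return est.placement_, est.trace_
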