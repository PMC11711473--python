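"""Model/Results interface to the generative growth model.

`GenerativeNetworkModel` wraps one observed binary network (with its
spatial geometry and a seed network) the way a statistical model wraps an
endog/exog pair; ``fit`` runs the grid search and returns a `GNMResults`
carrying the parameter estimates, the energy landscape, fit diagnostics
(KS components, fingerprint dissimilarity, spatial embedding) and a
``summary()`` table.  Simulation at arbitrary parameters hangs off the
model; everything derived from the best fit hangs off the results.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import fitting
from .construction import threshold_to_density
from .fitting import FitResult, ParameterGrid, make_grid
from .geometry import NodeGeometry
from .gnm import DEFAULT_EPSILON, GNMSpec, GrowthTrace, grow_network
from .networks import BinaryNetwork, WeightedConnectome

__all__ = ["GenerativeNetworkModel", "GNMResults"]


class GenerativeNetworkModel:
    """Generative growth model of one observed binary network.

    Parameters
    ----------
    observed : BinaryNetwork
        The network whose topology the model should reproduce.
    geometry : NodeGeometry, optional
        Spatial embedding; defaults to the geometry attached to ``observed``.
    rule : str
        Value rule (default ``"matching"``, the homophily rule that fits
        neonatal networks best).
    seed_network : BinaryNetwork or array, optional
        Edges fixed before growth begins; defaults to the empty network.
    epsilon : float
        Offset added to the value term before exponentiation.
    edge_length_mode : {"nodal", "edge"}
        Convention for the KS edge-length distribution.
    """

    def __init__(
        self,
        observed: BinaryNetwork,
        geometry: Optional[NodeGeometry] = None,
        rule: str = "matching",
        seed_network=None,
        epsilon: float = DEFAULT_EPSILON,
        edge_length_mode: str = "nodal",
    ):
        if not isinstance(observed, BinaryNetwork):
            observed = BinaryNetwork(np.asarray(observed), geometry=geometry)
        geometry = geometry or observed.geometry
        if geometry is None:
            raise ValueError("a NodeGeometry is required (observed has none attached)")
        self.observed = observed
        self.geometry = geometry
        self.distances = geometry.distance_matrix
        self.rule = rule
        n = geometry.n_nodes
        if seed_network is None:
            seed_network = BinaryNetwork(np.zeros((n, n), dtype=np.uint8), geometry=geometry)
        elif not isinstance(seed_network, BinaryNetwork):
            seed_network = BinaryNetwork(np.asarray(seed_network), geometry=geometry)
        if not np.all(seed_network.adjacency <= observed.adjacency):
            # seed edges absent from the observed network are legal for
            # simulation but make the edge-count contract ambiguous
            if seed_network.n_edges > observed.n_edges:
                raise ValueError("seed network has more edges than the observed network")
        self.seed_network = seed_network
        self.epsilon = epsilon
        self.edge_length_mode = edge_length_mode

    @classmethod
    def from_weighted(
        cls,
        connectome: WeightedConnectome,
        geometry: NodeGeometry,
        target_density: float = 0.10,
        **kwargs,
    ) -> "GenerativeNetworkModel":
        """Build from a streamline-count matrix via density thresholding."""
        observed = threshold_to_density(connectome, target_density, geometry=geometry)
        return cls(observed, geometry=geometry, **kwargs)

    def simulate(
        self,
        eta: float,
        gamma: float,
        seed: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
        m_target: Optional[int] = None,
    ) -> GrowthTrace:
        """One growth run at (eta, gamma) to the observed edge count."""
        rng = np.random.default_rng(seed) if rng is None else rng
        spec = GNMSpec(self.rule, eta, gamma, self.epsilon)
        m = self.observed.n_edges if m_target is None else m_target
        return grow_network(self.seed_network.adjacency, self.distances, spec, m, rng)

    def fit(
        self,
        grid: Optional[ParameterGrid] = None,
        seed: int = 0,
        n_replicates: int = 1,
    ) -> "GNMResults":
        """Grid-search fit; default grid is 20x20 over the narrow bounds."""
        grid = grid or make_grid(n_eta=20, n_gamma=20)
        fr = fitting.fit_network(
            self.observed,
            self.seed_network,
            self.distances,
            rule=self.rule,
            grid=grid,
            seed=seed,
            epsilon=self.epsilon,
            edge_length_mode=self.edge_length_mode,
            n_replicates=n_replicates,
        )
        return GNMResults(self, fr)


class GNMResults:
    """Results of a grid-search fit of a `GenerativeNetworkModel`."""

    def __init__(self, model: GenerativeNetworkModel, fit_result: FitResult):
        self.model = model
        self._fr = fit_result

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {"eta": self._fr.best_eta, "gamma": self._fr.best_gamma}, name="params"
        )

    @property
    def energy(self) -> float:
        return self._fr.best_energy

    @property
    def ks_components(self) -> pd.Series:
        row = self._fr.landscape.loc[self._fr.best_index]
        return row[["ks_degree", "ks_clustering", "ks_betweenness", "ks_edge_length"]]

    @property
    def landscape(self) -> pd.DataFrame:
        return self._fr.landscape

    @property
    def network(self) -> BinaryNetwork:
        """Best-fit simulated network."""
        return self._fr.best_network

    @property
    def trace(self) -> GrowthTrace:
        return self._fr.best_trace

    def tf_dissimilarity(self) -> float:
        return self._fr.tf_dissimilarity()

    def spatial_embedding(self) -> pd.Series:
        return pd.Series(self._fr.spatial_embedding(), name="pearson_r")

    def grid_uncertainty(self) -> pd.Series:
        """Half a grid step per axis: the resolution limit of the search."""
        return pd.Series(
            {
                "eta": self._fr.grid.eta_step / 2.0,
                "gamma": self._fr.grid.gamma_step / 2.0,
            },
            name="half_grid_step",
        )

    def summary(self) -> str:
        obs = self.model.observed
        lines = [
            "Generative Network Model Results",
            "=" * 46,
            f"{'Value rule:':<28}{self.model.rule}",
            f"{'Nodes:':<28}{obs.n_nodes}",
            f"{'Observed edges:':<28}{obs.n_edges}",
            f"{'Seed edges:':<28}{self.model.seed_network.n_edges}",
            f"{'Grid:':<28}{len(self._fr.grid.eta_values)} x "
            f"{len(self._fr.grid.gamma_values)} points",
            "-" * 46,
            f"{'eta (cost exponent):':<28}{self.params['eta']: .4f}",
            f"{'gamma (value exponent):':<28}{self.params['gamma']: .4f}",
            f"{'energy (max KS):':<28}{self.energy: .4f}",
            f"{'  KS degree:':<28}{self.ks_components['ks_degree']: .4f}",
            f"{'  KS clustering:':<28}{self.ks_components['ks_clustering']: .4f}",
            f"{'  KS betweenness:':<28}{self.ks_components['ks_betweenness']: .4f}",
            f"{'  KS edge length:':<28}{self.ks_components['ks_edge_length']: .4f}",
            f"{'TF dissimilarity:':<28}{self.tf_dissimilarity(): .4f}",
            "=" * 46,
        ]
        return "\n".join(lines)
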