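"""Model/Results facade over the ensemble network machinery.

``PanomicNetworkModel`` is constructed from a validated dataset plus
penalty and constraint settings; ``fit`` runs the ensemble structure
search and returns an ``EnsembleResults`` carrying the consensus graph,
per-edge frequencies, reporting helpers, counterfactual simulation, and a
printable summary table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .counterfactual import InterventionResult, population_dose_response, simulate_intervention
from .datasets import PanomicDataset, class_map
from .scoring import PenaltyConfig
from .search import (
    ConsensusGraph,
    ConstraintSet,
    Ensemble,
    edge_frequencies,
    fit_ensemble,
    phenotype_parent_report,
    subnetwork,
)

__all__ = ["PanomicNetworkModel", "EnsembleResults"]


class PanomicNetworkModel:
    """Ensemble Bayesian-network model over a multi-modal patient dataset.

    Parameters
    ----------
    dataset : PanomicDataset
        Complete patients x variables matrix with class/kind metadata.
    penalty : PenaltyConfig, optional
        Class-penalty settings; defaults to the per-term incremental rule at
        gamma = 1/2 with the dataset's own class map.
    constraints : ConstraintSet, optional
        Structural constraints; defaults to genotype classes as roots and a
        parent cap of 3.

    Examples
    --------
    >>> from panomicnet import synthetic
    >>> ds = synthetic.sample_dataset(synthetic.default_ground_truth(), 600, seed=7)
    >>> results = PanomicNetworkModel(ds).fit(n_networks=50, seed=7)
    >>> results.consensus.to_frame().head()
    """

    def __init__(
        self,
        dataset: PanomicDataset,
        penalty: PenaltyConfig | None = None,
        constraints: ConstraintSet | None = None,
    ):
        self.dataset = dataset
        self.penalty = penalty or PenaltyConfig(class_map=class_map(dataset))
        self.constraints = constraints or ConstraintSet()

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        meta,
        penalty: PenaltyConfig | None = None,
        constraints: ConstraintSet | None = None,
    ) -> "PanomicNetworkModel":
        """Build from a raw DataFrame plus a VariableMeta sequence."""
        return cls(PanomicDataset(values, list(meta)), penalty, constraints)

    def fit(
        self,
        n_networks: int = 50,
        seed: int = 0,
        resample: str = "bootstrap",
        restarts: int = 2,
        threshold: float = 0.05,
    ) -> "EnsembleResults":
        """Learn the ensemble and return consensus results."""
        ensemble = fit_ensemble(
            self.dataset,
            self.penalty,
            self.constraints,
            n_networks=n_networks,
            resample=resample,
            base_seed=seed,
            restarts=restarts,
        )
        consensus = edge_frequencies(ensemble, threshold=threshold)
        return EnsembleResults(self, ensemble, consensus)


class EnsembleResults:
    """Fitted ensemble: consensus edge frequencies plus simulation helpers."""

    def __init__(
        self, model: PanomicNetworkModel, ensemble: Ensemble, consensus: ConsensusGraph
    ):
        self.model = model
        self.ensemble = ensemble
        self.consensus = consensus

    @property
    def dataset(self) -> PanomicDataset:
        return self.model.dataset

    def summary(self) -> str:
        """Printable overview: ensemble composition and reported edges."""
        df = self.consensus.to_frame()
        scores = [m.score for m in self.ensemble]
        lines = [
            "Ensemble Bayesian network results",
            "=" * 48,
            f"patients:          {self.dataset.n}",
            f"variables:         {self.dataset.p}",
            f"ensemble members:  {len(self.ensemble)}",
            f"penalty style:     {self.model.penalty.style} (gamma={self.model.penalty.gamma})",
            f"reporting cutoff:  frequency > {self.consensus.threshold}",
            f"member score:      mean {np.mean(scores):.1f}, min {np.min(scores):.1f}",
            f"reported edges:    {len(df)}",
            "",
            df.to_string(index=False),
        ]
        return "\n".join(lines)

    def edge_frame(self, reported_only: bool = True) -> pd.DataFrame:
        return self.consensus.to_frame(reported_only=reported_only)

    def subnetwork(self, focus_node: str, degree: int = 1, min_freq=None) -> ConsensusGraph:
        return subnetwork(self.consensus, focus_node, degree=degree, min_freq=min_freq)

    def phenotype_parents(self, phenotype_node: str) -> pd.DataFrame:
        return phenotype_parent_report(self.consensus, phenotype_node)

    def simulate_intervention(
        self, patient_id: str, node: str, set_value: float, targets
    ) -> InterventionResult:
        return simulate_intervention(
            self.ensemble, self.dataset, patient_id, node, set_value, list(targets)
        )

    def dose_response(self, node: str, grid, target: str) -> pd.DataFrame:
        return population_dose_response(self.ensemble, self.dataset, node, grid, target)
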