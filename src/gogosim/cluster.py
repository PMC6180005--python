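"""Affinity-propagation clustering of genes by functional similarity.

Exemplar-based clustering via responsibility/availability message passing
over the gene similarity matrix (scikit-learn's implementation, driven with
a precomputed affinity).  The shared "preference" — which controls how many
exemplars emerge — is set to the median functional similarity over pairs of
distinct genes.  A seeded, vanishingly small jitter breaks exact ties so
runs are bit-for-bit reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .genesim import SimilarityMatrix


@dataclass(frozen=True)
class APConfig:
    """Affinity-propagation settings (defaults follow the classic tool:
    500 iterations maximum, convergence after 50 stable iterations,
    damping factor 0.95, median preference)."""

    max_iterations: int = 500
    convits: int = 50
    damping: float = 0.95
    preference: float | str = "median"
    jitter_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.damping < 1.0:
            raise ValueError(f"damping must be in [0.5, 1), got {self.damping}")
        if self.convits >= self.max_iterations:
            raise ValueError("convits must be smaller than max_iterations")
        if isinstance(self.preference, str) and self.preference != "median":
            raise ValueError(f"preference must be a number or 'median', got {self.preference!r}")


@dataclass
class ClusterAssignment:
    """Partition of the input genes with one exemplar per cluster."""

    labels: dict[str, int]
    exemplars: dict[int, str]
    converged: bool
    iterations_run: int

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)

    def members(self, cluster: int) -> list[str]:
        return sorted(g for g, c in self.labels.items() if c == cluster)

    def partition(self) -> list[frozenset[str]]:
        """Clusters as label-free frozensets, sorted for stable comparison."""
        out = [frozenset(self.members(c)) for c in self.exemplars]
        return sorted(out, key=lambda s: sorted(s))


def affinity_propagation(sim: SimilarityMatrix, config: APConfig | None = None,
                         ) -> ClusterAssignment:
    """Cluster the genes of a similarity matrix by affinity propagation.

    The matrix must be symmetric; ``preference='median'`` resolves to the
    median of the off-diagonal similarities (self-similarities of 1 would
    bias it).  Given the same matrix and config (including seed) the
    assignment is reproducible.  If message passing does not converge the
    genes are left as singleton clusters with ``converged=False``.
    """
    config = config or APConfig()
    genes = list(sim.labels)
    n = len(genes)
    S = np.array(sim.values, dtype=float)
    if n == 0:
        raise ValueError("empty similarity matrix")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("similarity matrix is not symmetric")
    if n == 1:
        return ClusterAssignment(labels={genes[0]: 0}, exemplars={0: genes[0]},
                                 converged=True, iterations_run=0)

    off = S[~np.eye(n, dtype=bool)]
    if config.preference == "median":
        preference = float(np.median(off))
    else:
        preference = float(config.preference)

    # Seeded symmetric jitter far below similarity resolution: breaks exact
    # degeneracies without being able to move any non-tied decision.
    rng = np.random.default_rng(config.seed)
    span = float(S.max() - S.min()) or 1.0
    noise = rng.standard_normal((n, n))
    S = S + config.jitter_scale * span * 1e-12 * (noise + noise.T) / 2.0

    model = AffinityPropagation(
        damping=config.damping,
        max_iter=config.max_iterations,
        convergence_iter=config.convits,
        preference=preference,
        affinity="precomputed",
        random_state=int(config.seed) % (2**31),
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(S)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(S)

    iters = int(getattr(model, "n_iter_", config.max_iterations))
    raw = model.labels_
    if not converged or (raw < 0).any():
        warnings.warn("affinity propagation did not converge; "
                      "returning singleton clusters", stacklevel=2)
        labels = {g: i for i, g in enumerate(genes)}
        exemplars = {i: g for i, g in enumerate(genes)}
        return ClusterAssignment(labels=labels, exemplars=exemplars,
                                 converged=False, iterations_run=iters)

    labels = {g: int(c) for g, c in zip(genes, raw)}
    exemplars = {int(c): genes[int(idx)]
                 for c, idx in enumerate(model.cluster_centers_indices_)}
    return ClusterAssignment(labels=labels, exemplars=exemplars,
                             converged=True, iterations_run=iters)
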