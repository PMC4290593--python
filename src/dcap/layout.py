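"""Track layout: the (condition, factor, replicate) structure of a multi-track design.

A *condition* is a cell line, tissue or experimental state; a *factor* is one
assayed signal (a TF, a histone mark, DNase accessibility); each (condition,
factor) pair carries ``R`` replicate tracks.  Within a condition the ``P = K*R``
tracks are ordered factor-major, replicate-minor, and the full signal matrix
concatenates condition blocks left to right, so column ``j*P + k*R + r`` is
condition ``j``, factor ``k``, replicate ``r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TrackLayout:
    """Design of a C-condition, K-factor, R-replicate track collection.

    Parameters
    ----------
    conditions : list of str
        Condition names (C >= 2 for differential testing; C >= 1 accepted).
    factors : list of str
        Factor names (K >= 1).
    n_replicates : int
        Replicates per (condition, factor), R >= 1.
    """

    conditions: tuple[str, ...]
    factors: tuple[str, ...]
    n_replicates: int

    def __init__(self, conditions, factors, n_replicates: int):
        object.__setattr__(self, "conditions", tuple(conditions))
        object.__setattr__(self, "factors", tuple(factors))
        object.__setattr__(self, "n_replicates", int(n_replicates))
        if len(self.conditions) < 1 or len(self.factors) < 1:
            raise ValueError("need at least one condition and one factor")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition names must be unique")
        if len(set(self.factors)) != len(self.factors):
            raise ValueError("factor names must be unique")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def tracks_per_condition(self) -> int:
        """P = K * R, the dimension of one condition's signal vector."""
        return self.n_factors * self.n_replicates

    @property
    def n_tracks(self) -> int:
        return self.n_conditions * self.tracks_per_condition

    @property
    def design_matrix(self) -> np.ndarray:
        """P x K 0/1 matrix A mapping factor means to track means.

        Column k has ones exactly in the R rows of factor k's replicates, so a
        factor-level mean vector ``u_A`` (length K) expands to the track-level
        mean ``A @ u_A`` (length P) with replicate entries equal.
        """
        K, R = self.n_factors, self.n_replicates
        A = np.zeros((K * R, K))
        for k in range(K):
            A[k * R:(k + 1) * R, k] = 1.0
        return A

    def condition_slice(self, j: int) -> slice:
        """Column slice of condition j's block in the full N x (C*P) matrix."""
        P = self.tracks_per_condition
        return slice(j * P, (j + 1) * P)

    def replicate_columns(self, j: int, k: int) -> np.ndarray:
        """Global column indices of factor k's replicates in condition j."""
        P, R = self.tracks_per_condition, self.n_replicates
        return j * P + k * R + np.arange(R)

    def factor_columns(self, k: int) -> np.ndarray:
        """Global column indices of factor k across all conditions/replicates."""
        return np.concatenate(
            [self.replicate_columns(j, k) for j in range(self.n_conditions)]
        )

    @property
    def track_names(self) -> list[str]:
        """Names 'condition.factor.repN' in canonical column order."""
        names = []
        for c in self.conditions:
            for f in self.factors:
                for r in range(1, self.n_replicates + 1):
                    names.append(f"{c}.{f}.rep{r}")
        return names

    def factor_means(self, values: np.ndarray) -> np.ndarray:
        """Per-window mean of each factor over all conditions and replicates.

        Returns an N x (C*P) matrix with the factor-k mean broadcast into every
        (condition, factor-k, replicate) column — the matrix written
        ``X-bar`` in the covariance decomposition and the regression target of
        the LOESS normalization.
        """
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[1] != self.n_tracks:
            raise ValueError(
                f"expected {self.n_tracks} columns, got {values.shape}"
            )
        out = np.empty_like(values)
        for k in range(self.n_factors):
            cols = self.factor_columns(k)
            out[:, cols] = values[:, cols].mean(axis=1, keepdims=True)
        return out

    def to_dict(self) -> dict:
        return {
            "conditions": list(self.conditions),
            "factors": list(self.factors),
            "n_replicates": self.n_replicates,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrackLayout":
        return cls(d["conditions"], d["factors"], d["n_replicates"])
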