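"""Population-weighted social-connectedness weights.

Raw connectedness scores (the long ``ego, alter, sci`` format used by the
Social Connectedness Index) are rescaled by alter population, restricted to
out-of-state alters, and row-normalized.  The resulting row-stochastic matrix
is what turns alter states' policy indicators into a spillover exposure: the
exposure of ego county *i* on day *t* is the weighted average of its alters'
indicators, so it always lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError

SCI_COLUMNS = ("ego", "alter", "sci")


@dataclass
class ConnectivityMatrix:
    """Ego-by-alter nonnegative weight matrix.

    Parameters
    ----------
    egos, alters : pd.Index
        County identifiers labelling rows and columns of ``weights``.
    weights : np.ndarray
        Nonnegative (n_ego, n_alter) array.
    normalized : bool
        True once each admissible ego row sums to one.
    flagged_egos : list
        Egos with no admissible alters (zero row mass).  Their rows are kept
        at zero and excluded from exposure construction downstream.
    """

    egos: pd.Index
    alters: pd.Index
    weights: np.ndarray
    normalized: bool = False
    flagged_egos: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.egos = pd.Index(self.egos)
        self.alters = pd.Index(self.alters)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.egos), len(self.alters)):
            raise ConsistencyError(
                f"weight matrix shape {self.weights.shape} does not match "
                f"({len(self.egos)}, {len(self.alters)}) labels"
            )
        if (self.weights < 0).any():
            raise ConsistencyError("connectivity weights must be nonnegative")

    def row_sums(self) -> pd.Series:
        return pd.Series(self.weights.sum(axis=1), index=self.egos)

    def to_long(self) -> pd.DataFrame:
        """Long ``ego, alter, weight`` table of the nonzero entries."""
        i, j = np.nonzero(self.weights)
        return pd.DataFrame(
            {
                "ego": self.egos[i],
                "alter": self.alters[j],
                "weight": self.weights[i, j],
            }
        )


def population_weight_sci(raw_sci: pd.DataFrame, populations: pd.Series) -> ConnectivityMatrix:
    """Scale raw connectedness scores by alter population.

    weight(i, j) = sci(i, j) * pop(j); pairs absent from ``raw_sci`` get
    score 0.  The result is unnormalized; egos whose entire row is zero are
    flagged.

    Raises
    ------
    ConsistencyError
        If a county appearing in ``raw_sci`` has no population entry, naming
        the county.
    """
    missing = [c for c in SCI_COLUMNS if c not in raw_sci.columns]
    if missing:
        raise ConsistencyError(f"raw SCI table missing columns {missing}")
    if (raw_sci["sci"] < 0).any():
        raise ConsistencyError("raw SCI scores must be nonnegative")

    populations = pd.Series(populations)
    counties = pd.Index(
        pd.unique(pd.concat([raw_sci["ego"], raw_sci["alter"]], ignore_index=True))
    ).sort_values()
    unknown = counties.difference(populations.index)
    if len(unknown) > 0:
        raise ConsistencyError(f"no population for counties: {list(unknown)}")
    if len(counties) < 2:
        raise ConsistencyError("connectivity needs at least two counties")

    n = len(counties)
    pos = pd.Series(np.arange(n), index=counties)
    W = np.zeros((n, n))
    W[pos[raw_sci["ego"]].to_numpy(), pos[raw_sci["alter"]].to_numpy()] = (
        raw_sci["sci"].to_numpy()
    )
    np.fill_diagonal(W, 0.0)  # self-weight never admissible
    W *= populations.reindex(counties).to_numpy()[np.newaxis, :]
    flagged = list(counties[W.sum(axis=1) == 0])
    return ConnectivityMatrix(counties, counties, W, normalized=False, flagged_egos=flagged)


def restrict_to_alter_states(matrix: ConnectivityMatrix, state_of: pd.Series) -> ConnectivityMatrix:
    """Zero out same-state alters and row-normalize.

    Spillovers are defined against alter *states*' policies, so every county
    sharing the ego's state (not only the ego itself) is removed before
    normalization.  Egos left with zero out-of-state mass are flagged and
    their rows stay at zero rather than being silently renormalized.
    """
    state_of = pd.Series(state_of)
    for counties in (matrix.egos, matrix.alters):
        unknown = counties.difference(state_of.index)
        if len(unknown) > 0:
            raise ConsistencyError(f"no state label for counties: {list(unknown)}")

    ego_states = state_of.reindex(matrix.egos).to_numpy()
    alter_states = state_of.reindex(matrix.alters).to_numpy()
    W = matrix.weights.copy()
    W[ego_states[:, None] == alter_states[None, :]] = 0.0

    sums = W.sum(axis=1)
    flagged = list(matrix.egos[sums == 0])
    keep = sums > 0
    W[keep] /= sums[keep, None]
    return ConnectivityMatrix(
        matrix.egos, matrix.alters, W, normalized=True, flagged_egos=flagged
    )
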