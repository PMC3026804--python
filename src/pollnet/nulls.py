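"""Null-model randomizations and empirical significance tests.

Two randomization schemes are implemented:

* a cell-probability ("CE") null for nestedness, where each cell's presence
  probability is the average of its row and column fill proportions; and
* a visitation-frequency resampling null for the projection metrics, where a
  large master matrix of hypothetical plants is filled by independent
  Bernoulli draws per pollinator species at its empirical interaction
  frequency, and plant sets of the empirical size are repeatedly subsampled.

Empirical p-values use the plus-one rule ``(1 + b) / (reps + 1)`` and are
therefore never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .construction import IncidenceMatrix
from .metrics import clustering, connectance, nodf, relative_nestedness

__all__ = [
    "NullEnsemble",
    "ce_probabilities",
    "sample_ce",
    "nodf_null_test",
    "random_visitation_ensemble",
]


@dataclass
class NullEnsemble:
    """Observed metric vs its null distribution with an empirical p-value."""

    metric: str
    observed: float
    null_values: np.ndarray
    reps: int
    seed: int | None
    tail: str = "greater"
    p_value: float = field(init=False)

    def __post_init__(self) -> None:
        nulls = np.asarray(self.null_values, dtype=float)
        if self.tail == "greater":
            b = int((nulls >= self.observed).sum())
        elif self.tail == "less":
            b = int((nulls <= self.observed).sum())
        elif self.tail == "two_sided":
            center = nulls.mean()
            b = int(
                (np.abs(nulls - center) >= abs(self.observed - center)).sum()
            )
        else:
            raise ValueError(f"unknown tail {self.tail!r}")
        self.null_values = nulls
        self.p_value = (1 + b) / (len(nulls) + 1)

    def to_dict(self, include_nulls: bool = False) -> dict:
        out = {
            "metric": self.metric,
            "observed": self.observed,
            "null_mean": float(self.null_values.mean()),
            "null_sd": float(self.null_values.std(ddof=1)),
            "p_value": self.p_value,
            "reps": self.reps,
            "seed": self.seed,
            "tail": self.tail,
        }
        if include_nulls:
            out["null_values"] = self.null_values.tolist()
        return out


def ce_probabilities(presence: np.ndarray) -> np.ndarray:
    """Cell presence probabilities: mean of row and column fill proportions.

    ``p[i, k] = (P_i/C + P_k/R) / 2`` where ``P_i`` is the number of presences
    in row ``i``, ``P_k`` in column ``k``, and ``R x C`` is the matrix shape.
    """
    mat = np.asarray(presence)
    if mat.ndim != 2 or 0 in mat.shape:
        raise ValueError("presence must be a non-empty 2-D matrix")
    if not np.isin(mat, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    r, c = mat.shape
    row_fill = mat.sum(axis=1) / c
    col_fill = mat.sum(axis=0) / r
    return (row_fill[:, None] + col_fill[None, :]) / 2.0


def sample_ce(
    probs: np.ndarray,
    seed: int | np.random.Generator | None = None,
    max_redraws: int = 1000,
) -> np.ndarray:
    """Draw one binary matrix with independent Bernoulli cells.

    Draws with an all-zero row or column are rejected and redrawn, up to
    ``max_redraws`` attempts.
    """
    p = np.asarray(probs, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    for _ in range(max_redraws):
        draw = (rng.random(p.shape) < p).astype(int)
        if draw.sum(axis=1).all() and draw.sum(axis=0).all():
            return draw
    raise RuntimeError(
        f"no draw without empty rows/columns in {max_redraws} attempts; "
        "matrix fill is too low for the rejection sampler"
    )


def nodf_null_test(
    presence: np.ndarray,
    reps: int = 1000,
    seed: int | None = None,
) -> tuple[NullEnsemble, float]:
    """Observed NODF against the CE null; returns the ensemble and relative nestedness."""
    if reps < 100:
        raise ValueError("at least 100 null replicates are required")
    observed = nodf(presence)
    probs = ce_probabilities(presence)
    rng = np.random.default_rng(seed)
    nulls = np.empty(reps)
    for r in range(reps):
        nulls[r] = nodf(sample_ce(probs, rng))
    ens = NullEnsemble(
        metric="nodf", observed=observed, null_values=nulls, reps=reps,
        seed=seed, tail="greater",
    )
    return ens, relative_nestedness(observed, nulls)


def interaction_frequencies(
    inc: IncidenceMatrix, weighted: bool = False
) -> np.ndarray:
    """Per-species interaction frequency estimated from the empirical matrix.

    Default: presence frequency, the fraction of plants each species visits.
    With ``weighted=True``: each species' share of total visits, rescaled so
    the busiest species matches its presence frequency (kept in (0, 1]).
    """
    presence = np.asarray(inc.presence)
    p = presence.shape[0]
    f = presence.sum(axis=0) / p
    if weighted:
        counts = np.asarray(inc.counts, dtype=float)
        share = counts.sum(axis=0) / counts.sum()
        f = share * (f.max() / share.max())
    if (f == 0).all():
        raise ValueError("all interaction frequencies are zero")
    return f


def _projection_metrics(sub: np.ndarray) -> tuple[float, float, float]:
    """(mean degree, connectance, mean clustering) of the plant projection of ``sub``."""
    shared = sub @ sub.T
    np.fill_diagonal(shared, 0)
    adj = (shared > 0).astype(float)
    n = adj.shape[0]
    k = adj.sum(axis=1)
    kbar = float(k.mean())
    conn = float(k.sum() / (n * (n - 1)))
    tri2 = np.einsum("ij,jk,ki->i", adj, adj, adj)
    denom = k * (k - 1)
    ci = np.where(denom > 0, tri2 / np.where(denom > 0, denom, 1), 0.0)
    return kbar, conn, float(ci.mean())


def random_visitation_ensemble(
    inc: IncidenceMatrix,
    reps: int = 1000,
    master_rows: int = 100_000,
    seed: int | None = None,
    weighted: bool = False,
    freqs: np.ndarray | None = None,
) -> dict[str, NullEnsemble]:
    """Null distributions of mean degree, connectance and clustering.

    A master matrix of ``master_rows`` hypothetical plants x the empirical
    number of pollinator species is filled with independent Bernoulli draws
    per column at each species' interaction frequency (estimated from the
    data, or supplied via ``freqs``).  ``reps`` subsamples of the empirical
    number of plants are drawn without replacement; each is projected to a
    plant-plant network and its metrics recorded.  One-sided (greater)
    empirical p-values are reported per metric.
    """
    presence = np.asarray(inc.presence)
    p, pol = presence.shape
    if master_rows < p:
        raise ValueError("master_rows must be at least the number of plants")
    f = (
        np.asarray(freqs, dtype=float)
        if freqs is not None
        else interaction_frequencies(inc, weighted=weighted)
    )
    if f.shape != (pol,):
        raise ValueError("freqs must have one entry per pollinator species")
    rng = np.random.default_rng(seed)
    master = rng.random((master_rows, pol)) < f
    obs_kbar, obs_conn, obs_clus = _projection_metrics(presence.astype(np.int64))
    nulls = np.empty((reps, 3))
    for r in range(reps):
        rows = rng.choice(master_rows, size=p, replace=False)
        nulls[r] = _projection_metrics(master[rows].astype(np.int64))
    observed = {"mean_degree": obs_kbar, "connectance": obs_conn, "clustering": obs_clus}
    return {
        name: NullEnsemble(
            metric=name,
            observed=observed[name],
            null_values=nulls[:, i],
            reps=reps,
            seed=seed,
            tail="greater",
        )
        for i, name in enumerate(("mean_degree", "connectance", "clustering"))
    }
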