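"""MEMBAS: membership-margin based attribute selection.

Each probe is scored by its membership margin — the membership of a sample
to its own class minus its membership to the competing class — summed over
all training samples.  The feature-weight vector maximises ``w . m`` subject
to ``||w||_2 = 1`` and ``w >= 0``, whose analytical solution is
``w ∝ max(m, 0)`` normalised; probes are ranked by descending weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fuzzify import MembershipParams, memberships

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureWeightVector:
    """Non-negative fuzzy weights, unit L2 norm, with a descending ranking.

    ``margin_sum`` keeps the raw (possibly negative) per-probe margin sums;
    ``ranking`` is a permutation of probe indices sorting weights descending
    with ties broken by ascending probe identifier.
    """

    probe_ids: np.ndarray
    weights: np.ndarray
    margin_sum: np.ndarray
    ranking: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "probe_ids", np.asarray(self.probe_ids))
        object.__setattr__(self, "margin_sum", np.asarray(self.margin_sum, dtype=float))
        object.__setattr__(self, "ranking", np.asarray(self.ranking, dtype=int))

    def ranked_probe_ids(self) -> np.ndarray:
        return self.probe_ids[self.ranking]

    def to_frame(self):
        import pandas as pd

        order = self.ranking
        return pd.DataFrame(
            {"probe_id": self.probe_ids[order], "weight": self.weights[order]}
        )


def feature_margin(mu_own: np.ndarray, mu_other: np.ndarray) -> np.ndarray:
    """Per-feature margin mu_own - mu_other for one sample; range [-1, 1]."""
    mu_own = np.asarray(mu_own, dtype=float)
    mu_other = np.asarray(mu_other, dtype=float)
    if mu_own.shape != mu_other.shape:
        raise ValueError("membership vectors must share the same feature set")
    return mu_own - mu_other


def _tie_break_order(keys_desc: np.ndarray, probe_ids: np.ndarray) -> np.ndarray:
    """Stable descending sort of ``keys_desc``, ties by ascending probe id."""
    id_order = np.argsort(np.asarray(probe_ids).astype(str), kind="stable")
    desc = np.argsort(-keys_desc[id_order], kind="stable")
    return id_order[desc]


def membas_weights(
    standardized: np.ndarray,
    labels: np.ndarray,
    params: MembershipParams,
) -> FeatureWeightVector:
    """Weight probes by their summed two-class membership margin.

    Parameters
    ----------
    standardized
        (n_probes, n_samples) standardized training matrix.
    labels
        per-sample class labels; must be the two classes of ``params``.
    params
        membership parameters fitted on the same training samples.
    """
    if len(params.class_labels) != 2:
        raise ValueError("MEMBAS margins are defined for exactly two classes")
    labels = np.asarray(labels)
    mu = memberships(standardized, params)  # (2, n_probes, n_samples)
    own = (labels == params.class_labels[1]).astype(int)  # 0 or 1 per sample
    cols = np.arange(labels.shape[0])
    margins = mu[own, :, cols] - mu[1 - own, :, cols]  # (n_samples, n_probes)
    margin_sum = np.nansum(margins, axis=0)
    clipped = np.maximum(margin_sum, 0.0)
    norm = np.linalg.norm(clipped)
    if norm == 0.0:
        logger.warning(
            "all membership-margin sums are non-positive; returning zero "
            "weights and ranking by raw margin"
        )
        weights = clipped
        ranking = _tie_break_order(margin_sum, params.probe_ids)
    else:
        weights = clipped / norm
        ranking = _tie_break_order(weights, params.probe_ids)
    return FeatureWeightVector(
        probe_ids=params.probe_ids,
        weights=weights,
        margin_sum=margin_sum,
        ranking=ranking,
    )


def rank_features(weights: FeatureWeightVector, k: int) -> np.ndarray:
    """Return the top-``k`` probe identifiers of the descending ranking."""
    n = weights.probe_ids.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    return weights.ranked_probe_ids()[:k]
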