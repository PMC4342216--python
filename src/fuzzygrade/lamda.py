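"""LAMDA fuzzy classification: marginal and global adequacy degrees.

A sample's per-probe memberships to a class are its marginal adequacy
degrees (MADs).  They are aggregated into a single global adequacy degree
(GAD) with a mixed connective — a convex combination of a t-norm T and its
dual t-conorm S controlled by the exigency alpha::

    GAD = alpha * T(mads) + (1 - alpha) * S(mads)

The molecular grade score is the normalised adequacy to the grade-3-like
class, s = GAD3 / (GAD1 + GAD3); s >= 0.5 calls fMG3 (boundary inclusive)
and scores in [0.48, 0.52] are flagged equivocal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import fuzzify
from .fuzzify import MembershipParams, StandardizationBounds

logger = logging.getLogger(__name__)

#: supported (t-norm, t-conorm) pairs
CONNECTIVES = ("minmax", "prodsum")

#: inclusive equivocal zone around 0.5
EQUIVOCAL_LOW = 0.48
EQUIVOCAL_HIGH = 0.52

#: class labels used throughout: index 0 = grade-1-like, index 1 = grade-3-like
FMG1, FMG3 = "fMG1", "fMG3"


@dataclass(frozen=True)
class LamdaModel:
    """Frozen fuzzy classifier for the two molecular-grade classes.

    Classification never mutates the model.  ``nic`` enables the
    non-informative class (MAD 0.5 everywhere); calls whose class GADs both
    fall below the NIC's GAD are marked low-confidence.
    """

    params: MembershipParams  # class_labels must be (FMG1, FMG3)
    bounds: StandardizationBounds
    probe_ids: np.ndarray
    alpha: float
    connective: str = "minmax"
    nic: bool = False
    max_missing_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.connective not in CONNECTIVES:
            raise ValueError(f"unknown connective {self.connective!r}")
        probe_ids = np.asarray(self.probe_ids)
        if probe_ids.size == 0:
            raise ValueError("probe list must be non-empty")
        if self.params.class_labels != (FMG1, FMG3):
            raise ValueError(f"model classes must be ({FMG1!r}, {FMG3!r})")
        object.__setattr__(self, "probe_ids", probe_ids)

    def to_dict(self) -> dict:
        d = {
            "probe_ids": self.probe_ids.astype(str).tolist(),
            "family": self.params.family,
            "class_labels": list(self.params.class_labels),
            "center": self.params.center.tolist(),
            "spread": None if self.params.spread is None else self.params.spread.tolist(),
            "x_min": self.bounds.x_min.tolist(),
            "x_max": self.bounds.x_max.tolist(),
            "alpha": self.alpha,
            "connective": self.connective,
            "nic": self.nic,
            "max_missing_fraction": self.max_missing_fraction,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LamdaModel":
        probe_ids = np.asarray(d["probe_ids"])
        params = MembershipParams(
            family=d["family"],
            class_labels=tuple(d["class_labels"]),
            center=np.asarray(d["center"], dtype=float),
            spread=None if d["spread"] is None else np.asarray(d["spread"], dtype=float),
            probe_ids=probe_ids,
        )
        bounds = StandardizationBounds(
            x_min=np.asarray(d["x_min"], dtype=float),
            x_max=np.asarray(d["x_max"], dtype=float),
            probe_ids=probe_ids,
        )
        return cls(
            params=params,
            bounds=bounds,
            probe_ids=probe_ids,
            alpha=float(d["alpha"]),
            connective=d["connective"],
            nic=bool(d.get("nic", False)),
            max_missing_fraction=float(d.get("max_missing_fraction", 0.2)),
        )


@dataclass(frozen=True)
class GradeCall:
    """One sample's classification: MADs, GADs, score, label, flags."""

    sample_id: str
    mads: np.ndarray  # (2, n_probes) rows = (fMG1, fMG3); NaN where missing
    gad1: float
    gad3: float
    score: float
    label: str
    equivocal: bool
    low_confidence: bool = False
    n_probes_used: int = field(default=0)


def compute_mads(standardized_sample: np.ndarray, model: LamdaModel, cls: str) -> np.ndarray:
    """Per-probe marginal adequacy degrees of one sample to one class.

    ``standardized_sample`` is aligned with the model's probe list; NaN
    entries yield NaN MADs (excluded from aggregation downstream).
    """
    x = np.asarray(standardized_sample, dtype=float)
    if x.shape[0] != model.probe_ids.shape[0]:
        raise ValueError("sample must be restricted to the model's probe list")
    ci = model.params.class_index(cls)
    if model.params.family == "binomial":
        return fuzzify.membership_binomial(x, model.params.center[ci])
    return fuzzify.membership_gaussian(x, model.params.center[ci], model.params.spread[ci])


def aggregate_gad(mads: np.ndarray, alpha: float, connective: str = "minmax") -> float:
    """Mixed-connective aggregation alpha*T + (1-alpha)*S of a MAD vector.

    NaN MADs (missing probes) are excluded; aggregation runs over the
    present probes only.
    """
    mads = np.asarray(mads, dtype=float)
    mads = mads[np.isfinite(mads)]
    if mads.size == 0:
        raise ValueError("cannot aggregate an empty MAD vector")
    if connective == "minmax":
        t, s = mads.min(), mads.max()
    elif connective == "prodsum":
        t = float(np.prod(mads))
        s = 1.0 - float(np.prod(1.0 - mads))
    else:
        raise ValueError(f"unknown connective {connective!r}")
    return float(alpha * t + (1.0 - alpha) * s)


def score_from_gads(gad1: float, gad3: float) -> float:
    """Normalised grade-3 adequacy GAD3/(GAD1+GAD3); 0.5 when both vanish."""
    total = gad1 + gad3
    if total == 0.0:
        logger.warning("both GADs are zero; returning the indeterminate score 0.5")
        return 0.5
    return gad3 / total


def classify(
    sample: np.ndarray,
    model: LamdaModel,
    sample_id: str = "",
    standardized: bool = False,
) -> GradeCall:
    """Classify one sample into fMG1/fMG3 with the molecular grade score.

    ``sample`` holds the raw (or, with ``standardized=True``, already
    rescaled) values for the model's probes, in model probe order.  Missing
    probes are tolerated up to the model's ``max_missing_fraction``.
    """
    x = np.asarray(sample, dtype=float)
    if not standardized:
        x = fuzzify.standardize(x, model.bounds)
    present = np.isfinite(x)
    missing_frac = 1.0 - present.mean()
    if missing_frac > model.max_missing_fraction:
        raise ValueError(
            f"sample {sample_id!r}: {missing_frac:.0%} of signature probes are "
            f"missing (limit {model.max_missing_fraction:.0%}); refusing to classify"
        )
    if missing_frac > 0:
        logger.info(
            "sample %s: aggregating over %d/%d present probes",
            sample_id, int(present.sum()), present.size,
        )
    mads = np.vstack([compute_mads(x, model, FMG1), compute_mads(x, model, FMG3)])
    gad1 = aggregate_gad(mads[0], model.alpha, model.connective)
    gad3 = aggregate_gad(mads[1], model.alpha, model.connective)
    s = score_from_gads(gad1, gad3)
    low_conf = False
    if model.nic:
        gad_nic = aggregate_gad(np.full(int(present.sum()), 0.5), model.alpha, model.connective)
        low_conf = gad1 < gad_nic and gad3 < gad_nic
    return GradeCall(
        sample_id=sample_id,
        mads=mads,
        gad1=gad1,
        gad3=gad3,
        score=s,
        label=FMG3 if s >= 0.5 else FMG1,
        equivocal=EQUIVOCAL_LOW <= s <= EQUIVOCAL_HIGH,
        low_confidence=low_conf,
        n_probes_used=int(present.sum()),
    )


def save_model(model: LamdaModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def load_model(path) -> LamdaModel:
    with open(path) as fh:
        return LamdaModel.from_dict(json.load(fh))
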