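"""Fuzzification of expression values: min-max standardization and class memberships.

Raw (log-scale) expression values are first linearly rescaled per probe into
[0, 1] using bounds fitted on the training samples only::

    x = (x_hat - x_min) / (x_max - x_min)

and then mapped to a membership degree in each class through one of two
membership functions, both parametrised per (class, probe) pair from the
training data:

* fuzzy binomial:  mu = rho**x * (1 - rho)**(1 - x), with prototype ``rho``
  the class mean of the standardized values.  Well suited when standardized
  values concentrate near 0 or 1; unstable around 0.5, hence ``rho`` and
  ``x`` are clamped away from the open-interval endpoints.
* Gaussian:  mu = exp(-(x - mu_c)**2 / (2 * sigma_c**2)), with the class
  mean as center and the class standard deviation (floored) as spread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: families accepted throughout the package
FAMILIES = ("binomial", "gaussian")

#: clamp for the binomial prototype/exponent (avoids 0**0 and log overflow)
BINOMIAL_EPS = 1e-6

#: floor for the Gaussian spread on the unit-interval scale
SIGMA_FLOOR = 0.01


@dataclass(frozen=True)
class StandardizationBounds:
    """Per-probe min/max fitted on training samples.

    ``degenerate`` marks probes whose training min equals their max; their
    standardized value is fixed at 0.5 (non-informative).
    """

    x_min: np.ndarray
    x_max: np.ndarray
    probe_ids: np.ndarray
    degenerate: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        x_min = np.asarray(self.x_min, dtype=float)
        x_max = np.asarray(self.x_max, dtype=float)
        if x_min.shape != x_max.shape:
            raise ValueError("x_min and x_max must have the same shape")
        if np.any(x_max < x_min):
            bad = np.asarray(self.probe_ids)[x_max < x_min]
            raise ValueError(f"x_max < x_min for probes {bad[:5].tolist()}")
        object.__setattr__(self, "x_min", x_min)
        object.__setattr__(self, "x_max", x_max)
        object.__setattr__(self, "probe_ids", np.asarray(self.probe_ids))
        if self.degenerate is None:
            object.__setattr__(self, "degenerate", x_max == x_min)

    @property
    def range(self) -> np.ndarray:
        return self.x_max - self.x_min


@dataclass(frozen=True)
class MembershipParams:
    """Per-class, per-probe membership-function parameters.

    For the binomial family only ``center`` (= prototype rho) is used; for
    the Gaussian family ``center`` is mu_c and ``spread`` is sigma_c.
    Rows are classes in the order of ``class_labels``; columns are probes.
    """

    family: str
    class_labels: tuple
    center: np.ndarray  # (n_classes, n_probes)
    spread: np.ndarray | None  # (n_classes, n_probes) for gaussian, else None
    probe_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown membership family {self.family!r}")
        center = np.asarray(self.center, dtype=float)
        if center.ndim != 2 or center.shape[0] != len(self.class_labels):
            raise ValueError("center must be (n_classes, n_probes)")
        if np.any((center < 0) | (center > 1)):
            raise ValueError("centers must lie in [0, 1]")
        object.__setattr__(self, "center", center)
        if self.family == "gaussian":
            spread = np.asarray(self.spread, dtype=float)
            if spread.shape != center.shape:
                raise ValueError("spread must match center shape")
            if np.any(spread <= 0):
                raise ValueError("gaussian spread must be positive")
            object.__setattr__(self, "spread", spread)
        object.__setattr__(self, "probe_ids", np.asarray(self.probe_ids))

    def class_index(self, label) -> int:
        return self.class_labels.index(label)


def fit_bounds(values: np.ndarray, probe_ids) -> StandardizationBounds:
    """Fit per-probe min/max over training samples.

    Parameters
    ----------
    values
        (n_probes, n_samples) training expression matrix; NaN marks missing.
    probe_ids
        probe identifiers, length n_probes.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a (n_probes, n_samples) matrix")
    if values.shape[1] < 2:
        raise ValueError("need at least 2 training samples to fit bounds")
    finite = np.isfinite(values)
    n_finite = finite.sum(axis=1)
    if np.any(n_finite == 0):
        bad = np.asarray(probe_ids)[n_finite == 0]
        raise ValueError(f"all values missing for probes {bad[:5].tolist()}")
    with np.errstate(all="ignore"):
        x_min = np.nanmin(values, axis=1)
        x_max = np.nanmax(values, axis=1)
    bounds = StandardizationBounds(x_min=x_min, x_max=x_max, probe_ids=probe_ids)
    n_deg = int(bounds.degenerate.sum())
    if n_deg:
        logger.warning(
            "%d probe(s) are constant on the training samples and will be "
            "standardized to 0.5: %s",
            n_deg,
            np.asarray(probe_ids)[bounds.degenerate][:5].tolist(),
        )
    return bounds


def standardize(values: np.ndarray, bounds: StandardizationBounds) -> np.ndarray:
    """Min-max rescale into [0, 1], clipping out-of-range values.

    ``values`` is (n_probes, ...) aligned with the bounds' probes.  Training
    values map exactly into [0, 1]; validation values outside the training
    bounds are clipped.  Degenerate probes map to 0.5.  NaN passes through.
    """
    values = np.asarray(values, dtype=float)
    rng = bounds.range.astype(float).copy()
    rng[bounds.degenerate] = 1.0  # avoid 0/0; result overwritten below
    shape = (-1,) + (1,) * (values.ndim - 1)
    x = (values - bounds.x_min.reshape(shape)) / rng.reshape(shape)
    x = np.clip(x, 0.0, 1.0)
    if bounds.degenerate.any():
        deg = bounds.degenerate.reshape(shape) & np.isfinite(values)
        x = np.where(deg, 0.5, x)
    return x


def membership_binomial(x, rho):
    """Fuzzy-binomial membership rho**x * (1-rho)**(1-x), broadcasting.

    Both ``x`` and ``rho`` are clamped to [eps, 1-eps] first; the result is
    in (0, 1].
    """
    x = np.clip(np.asarray(x, dtype=float), BINOMIAL_EPS, 1.0 - BINOMIAL_EPS)
    rho = np.clip(np.asarray(rho, dtype=float), BINOMIAL_EPS, 1.0 - BINOMIAL_EPS)
    return np.exp(x * np.log(rho) + (1.0 - x) * np.log1p(-rho))


def membership_gaussian(x, mu_c, sigma_c):
    """Gaussian membership exp(-(x-mu_c)^2 / (2 sigma_c^2)); 1 at the center."""
    sigma_c = np.asarray(sigma_c, dtype=float)
    if np.any(sigma_c <= 0):
        raise ValueError("sigma_c must be positive")
    x = np.asarray(x, dtype=float)
    mu_c = np.asarray(mu_c, dtype=float)
    z = (x - mu_c) / sigma_c
    return np.exp(-0.5 * z * z)


def fit_membership_params(
    standardized: np.ndarray,
    labels: np.ndarray,
    family: str,
    probe_ids,
    class_labels: tuple | None = None,
) -> MembershipParams:
    """Estimate per-class membership parameters from standardized training data.

    Binomial: prototype rho = class mean.  Gaussian: center = class mean,
    spread = class standard deviation (ddof=1), floored at ``SIGMA_FLOOR``.
    Missing entries (NaN) are excluded from the estimates.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown membership family {family!r}")
    standardized = np.asarray(standardized, dtype=float)
    labels = np.asarray(labels)
    if standardized.shape[1] != labels.shape[0]:
        raise ValueError("label count must match sample count")
    if class_labels is None:
        class_labels = tuple(np.unique(labels).tolist())
    if len(class_labels) < 2:
        raise ValueError("need at least two classes")
    centers, spreads = [], []
    for cls in class_labels:
        cols = standardized[:, labels == cls]
        if cols.shape[1] < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        with np.errstate(all="ignore"):
            mu = np.nanmean(cols, axis=1)
            sd = np.nanstd(cols, axis=1, ddof=1)
        # probes with a single finite value in this class get the floor spread
        sd = np.where(np.isfinite(sd), sd, 0.0)
        mu = np.where(np.isfinite(mu), mu, 0.5)
        centers.append(mu)
        spreads.append(np.maximum(sd, SIGMA_FLOOR))
    return MembershipParams(
        family=family,
        class_labels=tuple(class_labels),
        center=np.vstack(centers),
        spread=np.vstack(spreads) if family == "gaussian" else None,
        probe_ids=probe_ids,
    )


def memberships(standardized: np.ndarray, params: MembershipParams) -> np.ndarray:
    """Membership of every (probe, sample) entry to every class.

    Parameters
    ----------
    standardized
        (n_probes, n_samples) standardized values; NaN propagates.
    params
        fitted membership parameters on the same probes.

    Returns
    -------
    (n_classes, n_probes, n_samples) array of membership degrees.
    """
    standardized = np.asarray(standardized, dtype=float)
    x = standardized[None, :, :]
    if params.family == "binomial":
        return membership_binomial(x, params.center[:, :, None])
    return membership_gaussian(x, params.center[:, :, None], params.spread[:, :, None])
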