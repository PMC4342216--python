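"""End-to-end molecular-grade signature construction.

Order of operations, mirroring how the grading method is run on a cohort:

1. split the cohort into a training set (histologic grade 1 and 3, optionally
   ER-positive only) and a deployment set (grade 2 and unknown grade);
2. fit standardization bounds and membership parameters on the training set
   and rank all probes with MEMBAS;
3. walk the ranking with an incremental probe count k, estimating
   sensitivity / specificity / global error at each k by leave-one-out
   cross-validation (bounds, prototypes and the exigency alpha re-estimated
   without the held-out sample);
4. pick the minimal k achieving the best sensitivity under a specificity
   floor, refit the model on the full training set → the gene signature;
5. classify the deployment samples into fMG1-like / fMG3-like with the
   molecular grade score and its equivocal zone.

The LOOCV loop is exact but vectorised: per-fold min/max bounds come from
precomputed first/second order statistics, and the mixed-connective GAD at
every candidate k is obtained in one pass with prefix aggregation along the
ranked probes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fuzzify, membas
from .fuzzify import SIGMA_FLOOR, fit_bounds, fit_membership_params, standardize
from .lamda import FMG1, FMG3, LamdaModel, classify
from .membas import membas_weights

logger = logging.getLogger(__name__)

#: exigency grid searched during LOOCV
ALPHA_GRID = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)

GRADE_VALUES = ("1", "2", "3", "unknown")


def round_half_up_percent(fraction: float) -> int:
    """Display rounding of a rate: half-up to integer percent."""
    return int(math.floor(fraction * 100.0 + 0.5))


def _normalize_grades(labels: pd.DataFrame) -> pd.Series:
    g = labels["grade"].astype(str).str.strip().str.lower()
    g = g.replace({"nan": "unknown", "": "unknown", "na": "unknown"})
    bad = set(g.unique()) - set(GRADE_VALUES)
    if bad:
        raise ValueError(f"unrecognised grade values {sorted(bad)}")
    return g


# ---------------------------------------------------------------------------
# cohort splitting


def split_cohort(
    expr: pd.DataFrame,
    labels: pd.DataFrame,
    er_mode: str = "all",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition a cohort into training (HG1 ∪ HG3) and deployment sets.

    The deployment set holds grade-2 and unknown-grade samples and is never
    ER-filtered; with ``er_mode='er_positive_only'`` the training set keeps
    ER-positive tumors only.
    """
    if er_mode not in ("all", "er_positive_only"):
        raise ValueError(f"unknown er_mode {er_mode!r}")
    labels = labels.loc[expr.columns]
    grades = _normalize_grades(labels)
    train_mask = grades.isin(["1", "3"])
    if er_mode == "er_positive_only":
        if "er" not in labels.columns:
            raise ValueError("er_mode='er_positive_only' requires an 'er' column")
        train_mask &= labels["er"].astype(str).str.lower().eq("pos")
    train_ids = expr.columns[train_mask.to_numpy()]
    deploy_ids = expr.columns[grades.isin(["2", "unknown"]).to_numpy()]
    n1 = int((grades.loc[train_ids] == "1").sum())
    n3 = int((grades.loc[train_ids] == "3").sum())
    if n1 < 5 or n3 < 5:
        raise ValueError(
            f"training set needs >=5 samples per histologic grade class "
            f"(got HG1={n1}, HG3={n3}, er_mode={er_mode})"
        )
    return (
        expr[train_ids],
        labels.loc[train_ids],
        expr[deploy_ids],
        labels.loc[deploy_ids],
    )


# ---------------------------------------------------------------------------
# model fitting


def fit_model(
    train_expr: pd.DataFrame,
    train_labels: pd.DataFrame,
    family: str,
    alpha: float,
    connective: str = "minmax",
    nic: bool = False,
) -> LamdaModel:
    """Fit a frozen LAMDA model (bounds + class prototypes) on HG1/HG3 data."""
    grades = _normalize_grades(train_labels)
    values = train_expr.to_numpy(dtype=float)
    probe_ids = train_expr.index.to_numpy()
    bounds = fit_bounds(values, probe_ids)
    std = standardize(values, bounds)
    fmg = np.where(grades.to_numpy() == "3", FMG3, FMG1)
    params = fit_membership_params(std, fmg, family, probe_ids, class_labels=(FMG1, FMG3))
    return LamdaModel(
        params=params, bounds=bounds, probe_ids=probe_ids, alpha=alpha,
        connective=connective, nic=nic,
    )


def rank_probes(
    train_expr: pd.DataFrame,
    train_labels: pd.DataFrame,
    family: str,
) -> membas.FeatureWeightVector:
    """Global MEMBAS ranking of all probes on the full training set."""
    grades = _normalize_grades(train_labels)
    values = train_expr.to_numpy(dtype=float)
    probe_ids = train_expr.index.to_numpy()
    bounds = fit_bounds(values, probe_ids)
    std = standardize(values, bounds)
    fmg = np.where(grades.to_numpy() == "3", FMG3, FMG1)
    params = fit_membership_params(std, fmg, family, probe_ids, class_labels=(FMG1, FMG3))
    return membas_weights(std, fmg, params)


# ---------------------------------------------------------------------------
# LOOCV trace


@dataclass(frozen=True)
class SelectionTrace:
    """LOOCV performance along the ranked-probe count grid.

    ``alpha`` records the exigency selected (by LOOCV error, ties to the
    stricter value) independently at each k.
    """

    k: np.ndarray
    error: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    alpha: np.ndarray
    ranked_probe_ids: np.ndarray
    family: str
    connective: str = "minmax"

    def __post_init__(self) -> None:
        k = np.asarray(self.k, dtype=int)
        if k.size == 0:
            raise ValueError("trace must be non-empty")
        if np.any(np.diff(k) <= 0):
            raise ValueError("k must be strictly increasing")
        object.__setattr__(self, "k", k)
        for name in ("error", "sensitivity", "specificity", "alpha"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != k.shape:
                raise ValueError(f"{name} must match k in length")
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "ranked_probe_ids", np.asarray(self.ranked_probe_ids))

    def probes_at(self, k: int) -> np.ndarray:
        return self.ranked_probe_ids[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "error": self.error,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "alpha": self.alpha,
            }
        )

    def to_dict(self) -> dict:
        return {
            "k": self.k.tolist(),
            "error": self.error.tolist(),
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
            "alpha": self.alpha.tolist(),
            "ranked_probe_ids": self.ranked_probe_ids.astype(str).tolist(),
            "family": self.family,
            "connective": self.connective,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionTrace":
        return cls(
            k=np.asarray(d["k"], dtype=int),
            error=np.asarray(d["error"], dtype=float),
            sensitivity=np.asarray(d["sensitivity"], dtype=float),
            specificity=np.asarray(d["specificity"], dtype=float),
            alpha=np.asarray(d["alpha"], dtype=float),
            ranked_probe_ids=np.asarray(d["ranked_probe_ids"]),
            family=d["family"],
            connective=d.get("connective", "minmax"),
        )


def default_k_grid(n_features: int, dense_to: int = 200, n_log: int = 20) -> np.ndarray:
    """All k up to ``dense_to``, then log-spaced to the full feature count."""
    dense = np.arange(1, min(dense_to, n_features) + 1)
    if n_features <= dense_to:
        return dense
    tail = np.unique(
        np.round(np.logspace(np.log10(dense_to), np.log10(n_features), n_log)).astype(int)
    )
    return np.unique(np.concatenate([dense, tail]))


def _fold_prototypes(Xr, F, Xz, y, S, Q, N, min1, min2, cnt_min, max1, max2, cnt_max, j):
    """Bounds and class prototypes with sample ``j`` left out; O(p)."""
    mn = np.where((Xz[j] == min1) & F[j] & (cnt_min == 1), min2, min1)
    mx = np.where((Xz[j] == max1) & F[j] & (cnt_max == 1), max2, max1)
    rng = mx - mn
    deg = ~(rng > 0)
    rngs = np.where(deg, 1.0, rng)
    c = y[j]
    mu_std = np.empty((2, Xr.shape[1]))
    sd_std = np.empty((2, Xr.shape[1]))
    for ci in (0, 1):
        if ci == c:
            Nc = N[ci] - F[j]
            Sc = S[ci] - Xz[j]
            Qc = Q[ci] - Xz[j] ** 2
        else:
            Nc, Sc, Qc = N[ci], S[ci], Q[ci]
        Nc_safe = np.maximum(Nc, 1)
        mu_raw = Sc / Nc_safe
        m = np.clip((mu_raw - mn) / rngs, 0.0, 1.0)
        m[deg | (Nc == 0)] = 0.5
        mu_std[ci] = m
        var = (Qc - Nc * mu_raw**2) / np.maximum(Nc - 1, 1)
        sd = np.sqrt(np.maximum(var, 0.0)) / rngs
        sd[Nc < 2] = 0.0
        sd_std[ci] = np.maximum(sd, SIGMA_FLOOR)
    x = np.clip((Xr[j] - mn) / rngs, 0.0, 1.0)
    x = np.where(deg & F[j], 0.5, x)
    x = np.where(F[j], x, np.nan)
    return mn, mx, rngs, deg, mu_std, sd_std, x


def _mads(x, mu_std, sd_std, family):
    if family == "binomial":
        return fuzzify.membership_binomial(x[None, :], mu_std)
    return fuzzify.membership_gaussian(x[None, :], mu_std, sd_std)


def _prefix_scores(mads, finite, alphas, connective):
    """Molecular grade score at every prefix length, for every alpha.

    Returns (n_alpha, p) scores; NaN MADs are skipped by the prefix
    aggregation (missing probes do not contribute).
    """
    if connective == "minmax":
        T = np.minimum.accumulate(np.where(finite, mads, np.inf), axis=1)
        Sagg = np.maximum.accumulate(np.where(finite, mads, -np.inf), axis=1)
    else:
        T = np.cumprod(np.where(finite, mads, 1.0), axis=1)
        Sagg = 1.0 - np.cumprod(np.where(finite, 1.0 - mads, 1.0), axis=1)
    none_seen = np.cumsum(finite, axis=1) == 0
    T = np.where(none_seen, 0.5, T)
    Sagg = np.where(none_seen, 0.5, Sagg)
    a = np.asarray(alphas)[:, None, None]
    gad = a * T[None] + (1.0 - a) * Sagg[None]  # (n_alpha, 2, p)
    total = gad[:, 0] + gad[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(total > 0, gad[:, 1] / np.where(total > 0, total, 1.0), 0.5)
    return s


def loocv_curve(
    train_expr: pd.DataFrame,
    train_labels: pd.DataFrame,
    ranking: np.ndarray,
    k_grid: np.ndarray | None = None,
    family: str = "binomial",
    alphas=ALPHA_GRID,
    connective: str = "minmax",
    rerank_per_fold: bool = False,
) -> SelectionTrace:
    """Leave-one-out performance at every candidate signature size.

    For each held-out sample, standardization bounds and class prototypes
    are re-fitted on the remaining samples; the exigency alpha is selected
    per k as the grid value minimising the LOOCV global error (ties to the
    larger, i.e. stricter, alpha).

    ``ranking`` is the descending probe-id ordering from MEMBAS; with
    ``rerank_per_fold=True`` the ranking itself is also recomputed without
    the held-out sample (slower; guards against selection bias).
    """
    grades = _normalize_grades(train_labels)
    ranking = np.asarray(ranking)
    expr_r = train_expr.loc[ranking]
    Xr = expr_r.to_numpy(dtype=float).T  # (n_samples, p) in ranked order
    y = (grades.to_numpy() == "3").astype(int)
    n, p = Xr.shape
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("LOOCV requires >=2 samples per class")
    if k_grid is None:
        k_grid = default_k_grid(p)
    k_grid = np.asarray(k_grid, dtype=int)
    if k_grid.size == 0 or k_grid.min() < 1 or k_grid.max() > p:
        raise ValueError(f"k_grid must lie within [1, {p}]")
    alphas = np.asarray(alphas, dtype=float)

    F = np.isfinite(Xr)
    if np.any(F.sum(axis=0) == 0):
        raise ValueError("every probe needs at least one finite training value")
    Xz = np.where(F, Xr, 0.0)
    S = np.stack([Xz[y == c].sum(axis=0) for c in (0, 1)])
    Q = np.stack([(Xz[y == c] ** 2).sum(axis=0) for c in (0, 1)])
    N = np.stack([F[y == c].sum(axis=0) for c in (0, 1)])
    Xmin = np.where(F, Xr, np.inf)
    pm = np.partition(Xmin, 1, axis=0)
    min1, min2 = pm[0], pm[1]
    cnt_min = (Xmin == min1).sum(axis=0)
    Xmax = np.where(F, Xr, -np.inf)
    px = np.partition(Xmax, n - 2, axis=0)
    max1, max2 = px[n - 1], px[n - 2]
    cnt_max = (Xmax == max1).sum(axis=0)

    preds = np.empty((n, alphas.size, k_grid.size), dtype=bool)
    for j in range(n):
        mn, mx, rngs, deg, mu_std, sd_std, x = _fold_prototypes(
            Xr, F, Xz, y, S, Q, N, min1, min2, cnt_min, max1, max2, cnt_max, j
        )
        order = slice(None)
        if rerank_per_fold:
            keep = np.arange(n) != j
            Xs = np.clip((Xr[keep] - mn) / rngs, 0.0, 1.0)
            Xs = np.where(deg & F[keep], 0.5, Xs)
            Xs = np.where(F[keep], Xs, np.nan)
            mu_all = _mads_matrix(Xs, mu_std, sd_std, family)  # (2, n-1, p)
            own = y[keep]
            rows = np.arange(keep.sum())
            margins = mu_all[own, rows] - mu_all[1 - own, rows]
            msum = np.nansum(margins, axis=0)
            w = np.maximum(msum, 0.0)
            order = np.argsort(-w, kind="stable")
        mads = _mads(x, mu_std, sd_std, family)
        if rerank_per_fold:
            mads = mads[:, order]
            finite = np.isfinite(x)[order]
        else:
            finite = np.isfinite(x)
        s = _prefix_scores(mads, finite[None, :].repeat(2, 0), alphas, connective)
        preds[j] = s[:, k_grid - 1] >= 0.5

    correct = preds == y[:, None, None].astype(bool)
    acc = correct.mean(axis=0)  # (n_alpha, n_k)
    best_a = alphas.size - 1 - np.argmax(acc[::-1], axis=0)  # ties -> larger alpha
    cols = np.arange(k_grid.size)
    err = 1.0 - acc[best_a, cols]
    pred_best = preds[:, best_a, cols]  # (n, n_k)
    sens = pred_best[y == 1].mean(axis=0)
    spec = 1.0 - pred_best[y == 0].mean(axis=0)
    return SelectionTrace(
        k=k_grid,
        error=err,
        sensitivity=sens,
        specificity=spec,
        alpha=alphas[best_a],
        ranked_probe_ids=ranking,
        family=family,
        connective=connective,
    )


def _mads_matrix(Xs, mu_std, sd_std, family):
    """(2, n, p) memberships of standardized rows Xs (n, p) to both classes."""
    if family == "binomial":
        return fuzzify.membership_binomial(Xs[None], mu_std[:, None, :])
    return fuzzify.membership_gaussian(Xs[None], mu_std[:, None, :], sd_std[:, None, :])


# ---------------------------------------------------------------------------
# signature selection


@dataclass(frozen=True)
class GeneSignature:
    """Ordered probe subset plus the frozen model defining the fMG profiles."""

    probe_ids: np.ndarray
    model: LamdaModel
    trace: SelectionTrace | None
    er_mode: str = "all"
    family: str = "binomial"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        probe_ids = np.asarray(self.probe_ids)
        if not np.array_equal(probe_ids, self.model.probe_ids):
            raise ValueError("signature probe list must equal the model's probe list")
        object.__setattr__(self, "probe_ids", probe_ids)

    @property
    def k(self) -> int:
        return int(self.probe_ids.size)

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "trace": None if self.trace is None else self.trace.to_dict(),
            "er_mode": self.er_mode,
            "family": self.family,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneSignature":
        model = LamdaModel.from_dict(d["model"])
        trace = None if d.get("trace") is None else SelectionTrace.from_dict(d["trace"])
        return cls(
            probe_ids=model.probe_ids,
            model=model,
            trace=trace,
            er_mode=d.get("er_mode", "all"),
            family=d.get("family", model.params.family),
            meta=d.get("meta", {}),
        )

    def save(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "GeneSignature":
        import json

        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def choose_signature(
    trace: SelectionTrace,
    train_expr: pd.DataFrame,
    train_labels: pd.DataFrame,
    min_specificity: float = 0.67,
    er_mode: str = "all",
) -> GeneSignature:
    """Pick the minimal k with the best sensitivity above a specificity floor.

    Among trace entries with specificity >= ``min_specificity``, keep those
    of maximal sensitivity, then the smallest k; the final model is refitted
    on the full training set restricted to the top-k probes, with that
    entry's exigency alpha.  If no entry reaches the floor the rule is
    applied to the whole trace with a warning.
    """
    eligible = trace.specificity >= min_specificity
    if not eligible.any():
        warnings.warn(
            f"no signature size reaches specificity {min_specificity:.2f}; "
            "falling back to the best-sensitivity size",
            stacklevel=2,
        )
        eligible = np.ones_like(eligible)
    idx = np.flatnonzero(eligible)
    best_sens = trace.sensitivity[idx].max()
    idx = idx[trace.sensitivity[idx] == best_sens]
    i = idx[np.argmin(trace.k[idx])]
    k = int(trace.k[i])
    probes = trace.probes_at(k)
    model = fit_model(
        train_expr.loc[probes], train_labels, trace.family,
        alpha=float(trace.alpha[i]), connective=trace.connective,
    )
    return GeneSignature(
        probe_ids=np.asarray(probes),
        model=model,
        trace=trace,
        er_mode=er_mode,
        family=trace.family,
        meta={
            "k": k,
            "loocv_error": float(trace.error[i]),
            "loocv_sensitivity": float(trace.sensitivity[i]),
            "loocv_specificity": float(trace.specificity[i]),
            "alpha": float(trace.alpha[i]),
            "min_specificity": min_specificity,
        },
    )


def select_signature(
    expr: pd.DataFrame,
    labels: pd.DataFrame,
    er_mode: str = "auto",
    family: str = "auto",
    min_specificity: float = 0.67,
    k_grid: np.ndarray | None = None,
    alphas=ALPHA_GRID,
    connective: str = "minmax",
    rerank_per_fold: bool = False,
) -> GeneSignature:
    """Full signature search over ER stratification and membership family.

    Runs the split → rank → LOOCV → choose pipeline for every requested
    combination and keeps the signature with the lowest LOOCV global error
    at its chosen size (ties → higher sensitivity).
    """
    er_candidates = {
        "auto": ["all", "er_positive_only"],
        "all": ["all"],
        "pos": ["er_positive_only"],
        "er_positive_only": ["er_positive_only"],
    }.get(er_mode)
    if er_candidates is None:
        raise ValueError(f"unknown er_mode {er_mode!r}")
    fam_candidates = {
        "auto": ["binomial", "gaussian"],
        "binomial": ["binomial"],
        "gaussian": ["gaussian"],
    }.get(family)
    if fam_candidates is None:
        raise ValueError(f"unknown family {family!r}")

    best: GeneSignature | None = None
    for em in er_candidates:
        try:
            tr_expr, tr_labels, _, _ = split_cohort(expr, labels, er_mode=em)
        except ValueError as exc:
            if er_mode == "auto" and em == "er_positive_only":
                logger.info("skipping ER-positive stratification: %s", exc)
                continue
            raise
        for fam in fam_candidates:
            weights = rank_probes(tr_expr, tr_labels, fam)
            trace = loocv_curve(
                tr_expr, tr_labels, weights.ranked_probe_ids(),
                k_grid=k_grid, family=fam, alphas=alphas,
                connective=connective, rerank_per_fold=rerank_per_fold,
            )
            sig = choose_signature(
                trace, tr_expr, tr_labels,
                min_specificity=min_specificity, er_mode=em,
            )
            logger.info(
                "candidate signature: er=%s family=%s k=%d err=%.3f sens=%.3f spec=%.3f",
                em, fam, sig.k, sig.meta["loocv_error"],
                sig.meta["loocv_sensitivity"], sig.meta["loocv_specificity"],
            )
            if best is None or (
                sig.meta["loocv_error"],
                -sig.meta["loocv_sensitivity"],
            ) < (best.meta["loocv_error"], -best.meta["loocv_sensitivity"]):
                best = sig
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# deployment


def classify_deployment(signature: GeneSignature, expr: pd.DataFrame) -> pd.DataFrame:
    """Classify samples with a frozen signature.

    ``expr`` is probes × samples; probes absent from it are treated as
    missing (classification refuses samples exceeding the model's missing
    fraction).  Returns one row per sample with columns sample_id, gad1,
    gad3, score, label, equivocal.
    """
    model = signature.model
    sub = expr.reindex(model.probe_ids)
    rows = []
    for sid in sub.columns:
        call = classify(sub[sid].to_numpy(dtype=float), model, sample_id=str(sid))
        rows.append(
            {
                "sample_id": call.sample_id,
                "gad1": call.gad1,
                "gad3": call.gad3,
                "score": call.score,
                "label": call.label,
                "equivocal": call.equivocal,
            }
        )
    cols = ["sample_id", "gad1", "gad3", "score", "label", "equivocal"]
    return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class ConfusionCounts:
    """HG truth × fMG call counts for the two training grades."""

    hg1_fmg1: int
    hg1_fmg3: int
    hg3_fmg1: int
    hg3_fmg3: int

    def __post_init__(self) -> None:
        for f in ("hg1_fmg1", "hg1_fmg3", "hg3_fmg1", "hg3_fmg3"):
            if getattr(self, f) < 0:
                raise ValueError("counts must be non-negative")

    @property
    def n_hg1(self) -> int:
        return self.hg1_fmg1 + self.hg1_fmg3

    @property
    def n_hg3(self) -> int:
        return self.hg3_fmg1 + self.hg3_fmg3

    @property
    def sensitivity(self) -> float:
        return self.hg3_fmg3 / self.n_hg3 if self.n_hg3 else float("nan")

    @property
    def specificity(self) -> float:
        return self.hg1_fmg1 / self.n_hg1 if self.n_hg1 else float("nan")

    @property
    def global_error(self) -> float:
        n = self.n_hg1 + self.n_hg3
        return (self.hg1_fmg3 + self.hg3_fmg1) / n if n else float("nan")

    def percent_display(self) -> dict:
        return {
            "sensitivity_pct": round_half_up_percent(self.sensitivity),
            "specificity_pct": round_half_up_percent(self.specificity),
            "global_error_pct": round_half_up_percent(self.global_error),
        }


def evaluate_agreement(calls: pd.DataFrame, labels: pd.DataFrame) -> ConfusionCounts:
    """Agreement between molecular calls and histologic grades 1/3."""
    labels = labels.copy()
    grades = _normalize_grades(labels)
    calls = calls.set_index("sample_id") if "sample_id" in calls.columns else calls
    missing = [s for s in calls.index if s not in grades.index]
    if missing:
        raise ValueError(f"no histologic label for samples {missing[:5]}")
    g = grades.loc[calls.index]
    if not g.isin(["1", "3"]).all():
        raise ValueError("agreement is defined for histologic grade 1/3 samples only")
    is3 = g == "3"
    called3 = calls["label"] == FMG3
    return ConfusionCounts(
        hg1_fmg1=int((~is3 & ~called3).sum()),
        hg1_fmg3=int((~is3 & called3).sum()),
        hg3_fmg1=int((is3 & ~called3).sum()),
        hg3_fmg3=int((is3 & called3).sum()),
    )


# ---------------------------------------------------------------------------
# cross-platform transfer


def apply_cross_platform(
    signature: GeneSignature,
    new_expr: pd.DataFrame,
    new_labels: pd.DataFrame,
    probe_to_gene: dict,
    min_gene_coverage: float = 0.8,
) -> GeneSignature:
    """Port a signature to a platform with several probes per gene.

    Candidate probes for each signature gene are ranked with MEMBAS on the
    new cohort's HG1/HG3 samples and the best probe per gene is retained;
    prototypes are then re-fitted on the new cohort with the adapted probe
    list, keeping the signature's family, connective and exigency.
    """
    sig_genes = []
    for pid in signature.probe_ids:
        gene = probe_to_gene.get(str(pid), probe_to_gene.get(pid))
        if gene is None:
            raise ValueError(f"signature probe {pid!r} has no gene mapping")
        if gene not in sig_genes:
            sig_genes.append(gene)

    candidates: dict[str, list] = {g: [] for g in sig_genes}
    for pid in new_expr.index:
        gene = probe_to_gene.get(str(pid), probe_to_gene.get(pid))
        if gene in candidates:
            candidates[gene].append(pid)
    covered = [g for g in sig_genes if candidates[g]]
    coverage = len(covered) / len(sig_genes)
    if coverage < min_gene_coverage:
        raise ValueError(
            f"only {coverage:.0%} of signature genes have probes on the new "
            f"platform (need >={min_gene_coverage:.0%})"
        )
    for g in sig_genes:
        if not candidates[g]:
            warnings.warn(f"gene {g!r} has no probe on the new platform; dropped",
                          stacklevel=2)

    tr_expr, tr_labels, _, _ = split_cohort(new_expr, new_labels, er_mode="all")
    all_cand = [pid for g in covered for pid in candidates[g]]
    weights = rank_probes(tr_expr.loc[all_cand], tr_labels, signature.family)
    rank_pos = {pid: i for i, pid in enumerate(weights.ranked_probe_ids())}
    adapted = [min(candidates[g], key=lambda pid: rank_pos[pid]) for g in covered]

    model = fit_model(
        tr_expr.loc[adapted], tr_labels, signature.family,
        alpha=signature.model.alpha, connective=signature.model.connective,
    )
    return GeneSignature(
        probe_ids=np.asarray(adapted),
        model=model,
        trace=None,
        er_mode="all",
        family=signature.family,
        meta={
            "adapted_from_k": signature.k,
            "gene_coverage": coverage,
            "genes": [str(g) for g in covered],
        },
    )
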