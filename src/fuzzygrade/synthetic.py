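"""Synthetic expression cohorts with known ground truth.

Emulates the statistical structure the grading method assumes: two
well-separated tumor archetypes (histologic grade 1 and 3) differing on a
small set of informative probes, a large background of noise probes, and an
intermediate grade-2 population drawn as a latent mixture of the two
archetypes, with a configurable fraction of truly intermediate (midpoint)
profiles that should land in the equivocal zone.  Values are on a
log2-intensity-like scale, normally distributed within class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GRADE1, GRADE2, GRADE3 = "1", "2", "3"


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; identical config + seed → identical cohort.

    ``effect`` is the between-class mean shift on informative probes in
    units of the within-class SD (``noise_sd``).  ``grade2_mix`` is the
    fraction of grade-2 samples drawn from the grade-3 archetype;
    ``equivocal_fraction`` of grade-2 samples are instead placed midway
    between the archetype means.  ``platform_scale``/``platform_offset``
    give the global affine distortion of the second platform in
    two-platform simulations.
    """

    n_grade1: int = 60
    n_grade3: int = 60
    n_grade2: int = 60
    n_informative: int = 20
    n_noise: int = 980
    effect: float = 2.0
    noise_sd: float = 1.0
    grade2_mix: float = 0.5
    equivocal_fraction: float = 0.10
    er_positive_fraction: float = 0.7
    platform_scale: float = 1.0
    platform_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_grade1", "n_grade3", "n_informative", "n_noise"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_grade2 < 0:
            raise ValueError("n_grade2 must be non-negative")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.grade2_mix <= 1.0:
            raise ValueError("grade2_mix must lie in [0, 1]")
        if not 0.0 <= self.equivocal_fraction <= 1.0:
            raise ValueError("equivocal_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for verification against recovered results."""

    informative_probes: np.ndarray
    grade2_archetype: pd.Series  # per grade-2 sample: "1" or "3"
    grade2_midpoint: pd.Series  # per grade-2 sample: True if midpoint profile
    er_status: pd.Series  # per sample: "pos"/"neg"

    def to_dict(self) -> dict:
        return {
            "informative_probes": self.informative_probes.astype(str).tolist(),
            "grade2_archetype": self.grade2_archetype.to_dict(),
            "grade2_midpoint": {k: bool(v) for k, v in self.grade2_midpoint.items()},
            "er_status": self.er_status.to_dict(),
        }


def _probe_ids(n: int, prefix: str = "probe") -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"{prefix}_{i:0{width}d}" for i in range(n)])


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one cohort.

    Returns
    -------
    expr
        probes × samples DataFrame of log-scale intensities.
    labels
        per-sample DataFrame with columns ``grade`` and ``er``.
    truth
        planted probes and latent grade-2 assignments.
    """
    rng = np.random.default_rng(config.seed)
    n1, n2, n3 = config.n_grade1, config.n_grade2, config.n_grade3
    n_samples = n1 + n2 + n3
    p_inf, p_noise = config.n_informative, config.n_noise
    p = p_inf + p_noise
    sd = config.noise_sd
    shift = config.effect * sd

    probe_ids = _probe_ids(p)
    # plant the informative probes at random positions
    inf_idx = rng.choice(p, size=p_inf, replace=False)
    inf_mask = np.zeros(p, dtype=bool)
    inf_mask[inf_idx] = True

    baselines = rng.uniform(6.0, 12.0, size=p)
    grades = np.array([GRADE1] * n1 + [GRADE3] * n3 + [GRADE2] * n2)
    sample_ids = np.array([f"S{i:04d}" for i in range(n_samples)])

    # class mean matrix (p, n): baseline everywhere, + shift on informative
    # probes for grade-3-archetype samples, + shift/2 for midpoints
    arch3 = np.zeros(n_samples, dtype=bool)
    arch3[n1 : n1 + n3] = True
    g2_slice = slice(n1 + n3, n_samples)
    g2_arch = rng.random(n2) < config.grade2_mix  # True = grade-3 archetype
    g2_mid = rng.random(n2) < config.equivocal_fraction
    arch3[g2_slice] = g2_arch

    means = np.tile(baselines[:, None], (1, n_samples))
    means[np.ix_(inf_mask, arch3)] += shift
    # midpoint grade-2 samples sit halfway regardless of latent archetype
    mid_cols = np.zeros(n_samples, dtype=bool)
    mid_cols[g2_slice] = g2_mid
    means[np.ix_(inf_mask, mid_cols)] = baselines[inf_mask, None] + shift / 2.0

    values = rng.normal(means, sd)
    expr = pd.DataFrame(values, index=probe_ids, columns=sample_ids)

    er = np.where(rng.random(n_samples) < config.er_positive_fraction, "pos", "neg")
    labels = pd.DataFrame({"grade": grades, "er": er}, index=pd.Index(sample_ids, name="sample_id"))

    g2_ids = sample_ids[g2_slice]
    truth = GroundTruth(
        informative_probes=probe_ids[inf_mask],
        grade2_archetype=pd.Series(np.where(g2_arch, GRADE3, GRADE1), index=g2_ids),
        grade2_midpoint=pd.Series(g2_mid, index=g2_ids),
        er_status=pd.Series(er, index=sample_ids),
    )
    return expr, labels, truth


@dataclass(frozen=True)
class TwoPlatformPair:
    """One cohort measured on two platforms sharing genes.

    Platform 1 has one probe per gene (probe id ``P1_<gene>``); platform 2
    has ``probes_per_gene`` affine-distorted, jitter-perturbed replicates
    per gene (``P2_<gene>_p<j>``).  ``probe_to_gene`` maps every probe on
    both platforms to its gene; ``probe_jitter`` records each platform-2
    probe's noise SD.
    """

    expr1: pd.DataFrame
    expr2: pd.DataFrame
    labels: pd.DataFrame
    truth: GroundTruth
    probe_to_gene: dict
    probe_jitter: pd.Series


def make_two_platform_pair(
    config: SimulationConfig,
    probes_per_gene: int = 9,
    jitter_max: float = 0.5,
) -> TwoPlatformPair:
    """Simulate one cohort and re-measure it on a second platform.

    Each platform-2 probe value is ``platform_scale * signal +
    platform_offset + N(0, jitter^2)`` with a per-probe jitter SD drawn
    uniformly from [0, jitter_max * noise_sd].  With one probe per gene and
    zero distortion/jitter the platforms coincide up to the probe namespace.
    """
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    expr, labels, truth = simulate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    genes = np.array([pid.replace("probe", "gene") for pid in expr.index])
    p, n = expr.shape

    expr1 = expr.copy()
    expr1.index = pd.Index([f"P1_{g}" for g in genes])
    p2_ids, p2_rows, jitters, p2g = [], [], [], {}
    for gi, g in enumerate(genes):
        p2g[f"P1_{g}"] = g
    signal = expr.to_numpy()
    jitter_sd = rng.uniform(0.0, jitter_max * config.noise_sd, size=(p, probes_per_gene))
    if jitter_max == 0.0:
        jitter_sd[:] = 0.0
    for j in range(probes_per_gene):
        noise = rng.normal(0.0, 1.0, size=(p, n)) * jitter_sd[:, [j]]
        vals = config.platform_scale * signal + config.platform_offset + noise
        ids = np.array([f"P2_{g}_p{j}" for g in genes])
        p2_ids.append(ids)
        p2_rows.append(vals)
        jitters.append(jitter_sd[:, j])
        for g, pid in zip(genes, ids):
            p2g[pid] = g
    expr2 = pd.DataFrame(
        np.vstack(p2_rows), index=np.concatenate(p2_ids), columns=expr.columns
    )
    truth2 = replace(
        truth,
        informative_probes=np.array(
            [f"P1_{pid.replace('probe', 'gene')}" for pid in truth.informative_probes]
        ),
    )
    return TwoPlatformPair(
        expr1=expr1,
        expr2=expr2,
        labels=labels,
        truth=truth2,
        probe_to_gene=p2g,
        probe_jitter=pd.Series(np.concatenate(jitters), index=np.concatenate(p2_ids)),
    )
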