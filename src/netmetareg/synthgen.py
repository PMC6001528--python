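"""Synthetic network meta-regression datasets with known truth.

The generator works directly on the contrast (analysis) scale: each study
gets a treatment pair (or triple, for three-arm trials), a covariate drawn
from a per-edge mixture of uniforms — supporting deliberate covariate "gaps"
that force interpolation, the situation the diagnostics in this package are
built to expose — and an observed effect

    y = d + beta * c + study effect (SD sigma) + sampling noise,

with the multi-arm covariance structure of the model: random study effects
have covariance sigma^2/2 between contrasts of one trial, and the sampling
covariance of contrasts sharing the baseline arm is the baseline-arm variance
component.  True effects are defined on the raw (uncentred) covariate scale.

A small arm-level binary simulator (binomial arms from a logistic model) is
included for end-to-end tests of the arm-level input path, and
:func:`triangle_fixture` supplies the deterministic 6-study, 3-treatment
dataset used as the oracle workbench throughout the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .data_io import ArmRecord, ContrastDataset, StudyContrasts, summarize_network
from .exceptions import ValidationError

__all__ = ["SimConfig", "simulate_dataset", "simulate_binary_arms", "triangle_fixture"]

# default per-edge covariate generator: a gappy mixture emulating a dataset
# whose trials cluster at low and high covariate values
DEFAULT_COVARIATE_MIXTURE = ((0.5, (2.0, 7.0)), (0.5, (25.0, 35.0)))


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters of a synthetic contrast-level network.

    ``d`` and ``beta`` give the true basic effects/coefficients versus
    treatment "1" for treatments "2".."T" (``beta`` may be a single float for
    a common coefficient).  ``covariate_mixture`` is a tuple of
    (probability, (lo, hi)) uniform components, optionally overridden per
    edge via ``edge_covariate_mixtures``.  ``arm_variance_range`` bounds the
    uniform draw of per-arm variance components (the baseline arm's component
    is the shared covariance of a multi-arm trial's contrasts).
    """

    T: int = 3
    N: int = 150
    prop_three_arm: float = 0.2
    d: tuple[float, ...] = (0.3, -0.2)
    beta: tuple[float, ...] | float = (0.02, -0.01)
    sigma2: float = 0.03
    covariate_mixture: tuple = DEFAULT_COVARIATE_MIXTURE
    edge_covariate_mixtures: dict = field(default_factory=dict)
    arm_variance_range: tuple[float, float] = (0.02, 0.15)
    seed: int | None = None
    max_connectivity_retries: int = 100

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError("need at least 2 treatments")
        if len(self.d) != self.T - 1:
            raise ValueError(f"d must have {self.T - 1} entries")
        if not isinstance(self.beta, (int, float)) and len(self.beta) != self.T - 1:
            raise ValueError(f"beta must be a float or have {self.T - 1} entries")
        if not 0 <= self.prop_three_arm <= 1:
            raise ValueError("prop_three_arm must be in [0, 1]")
        for prob, (lo, hi) in self.covariate_mixture:
            if hi <= lo:
                raise ValueError("mixture component bounds must satisfy lo < hi")
        total = sum(p for p, _ in self.covariate_mixture)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("mixture probabilities must sum to 1")

    @property
    def treatments(self) -> list[str]:
        return [str(t + 1) for t in range(self.T)]

    def true_d(self, t: str) -> float:
        """True basic effect of treatment t versus treatment '1'."""
        return 0.0 if t == "1" else self.d[int(t) - 2]

    def true_beta(self, t: str) -> float:
        if t == "1":
            return 0.0
        if isinstance(self.beta, (int, float)):
            return float(self.beta)
        return self.beta[int(t) - 2]


def _draw_covariate(cfg: SimConfig, edge: tuple[str, str], rng: np.random.Generator) -> float:
    mixture = cfg.edge_covariate_mixtures.get(edge, cfg.covariate_mixture)
    probs = np.array([p for p, _ in mixture])
    idx = rng.choice(len(mixture), p=probs / probs.sum())
    lo, hi = mixture[idx][1]
    return float(rng.uniform(lo, hi))


def simulate_dataset(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Draw one dataset; returns (ContrastDataset, truth dict).

    Study treatment sets are sampled uniformly over pairs (or triples), and
    the draw is repeated — bounded by ``max_connectivity_retries`` — until
    the network is connected.  The truth record carries every generating
    parameter so recovery can be checked.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    treatments = cfg.treatments
    pairs = list(itertools.combinations(treatments, 2))
    triples = list(itertools.combinations(treatments, 3))

    for _ in range(cfg.max_connectivity_retries):
        studies: list[StudyContrasts] = []
        for i in range(cfg.N):
            three_arm = cfg.T >= 3 and rng.uniform() < cfg.prop_three_arm
            if three_arm:
                arms = list(triples[rng.integers(len(triples))])
            else:
                arms = list(pairs[rng.integers(len(pairs))])
            baseline, others = arms[0], arms[1:]
            edge = (arms[0], arms[1])
            c = _draw_covariate(cfg, edge, rng)
            m = len(others)
            mean = np.array(
                [
                    (cfg.true_d(t) - cfg.true_d(baseline))
                    + (cfg.true_beta(t) - cfg.true_beta(baseline)) * c
                    for t in others
                ]
            )
            re_cov = 0.5 * cfg.sigma2 * (np.eye(m) + np.ones((m, m)))
            u = rng.uniform(*cfg.arm_variance_range, size=m + 1)
            samp_cov = u[0] * np.ones((m, m)) + np.diag(u[1:])
            y = rng.multivariate_normal(mean, re_cov + samp_cov) if cfg.sigma2 > 0 else (
                rng.multivariate_normal(mean, samp_cov)
            )
            studies.append(
                StudyContrasts(
                    study_id=f"S{i+1:03d}",
                    baseline=baseline,
                    treatments=others,
                    y=y,
                    cov=samp_cov,
                    covariate=c,
                )
            )
        ds = ContrastDataset(studies=studies)
        if set(ds.treatments) == set(treatments) and summarize_network(ds).connected:
            truth = {
                "d": {t: cfg.true_d(t) for t in treatments},
                "beta": {t: cfg.true_beta(t) for t in treatments},
                "sigma2": cfg.sigma2,
                "covariate_center": 0.0,
            }
            return ds, truth
    raise ValidationError(
        f"could not draw a connected network in {cfg.max_connectivity_retries} tries"
    )


def simulate_binary_arms(
    cfg: SimConfig,
    baseline_logodds: float = -1.0,
    arm_size: int = 200,
    rng: np.random.Generator | None = None,
) -> list[ArmRecord]:
    """Arm-level binomial counts from a logistic model with the same truth.

    Event probabilities follow ``logit(p) = baseline_logodds + d_t + beta_t*c``
    (plus a study intercept shift), so pushing the records through the binary
    contrast constructor yields approximately the contrast-level model.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ds, _ = simulate_dataset(cfg, rng=rng)
    records: list[ArmRecord] = []
    for s in ds.studies:
        mu = baseline_logodds + rng.normal(scale=0.3)
        all_arms = [s.baseline] + s.treatments
        for k, t in enumerate(all_arms, start=1):
            logit = mu + cfg.true_d(t) + cfg.true_beta(t) * s.covariate
            p = 1.0 / (1.0 + math.exp(-logit))
            events = int(rng.binomial(arm_size, p))
            records.append(
                ArmRecord(
                    study_id=s.study_id,
                    arm_index=k,
                    treatment=t,
                    covariate=s.covariate,
                    events=events,
                    total=arm_size,
                )
            )
    return records


def triangle_fixture() -> ContrastDataset:
    """Deterministic 6-study, 3-treatment network with a covariate gap.

    Five two-arm studies plus one three-arm study (with a correlated
    covariance block) spanning treatments A, B, C; covariates cluster at 2–5
    and 25–33 with nothing in between, so interpolation diagnostics have
    something to show.  Used as the oracle workbench across the test suite.
    """
    studies = [
        StudyContrasts("t01", "A", ["B"], np.array([0.50]), np.array([[0.04]]), 2.0),
        StudyContrasts("t02", "A", ["B"], np.array([0.80]), np.array([[0.09]]), 30.0),
        StudyContrasts("t03", "A", ["C"], np.array([-0.20]), np.array([[0.06]]), 3.0),
        StudyContrasts("t04", "A", ["C"], np.array([0.10]), np.array([[0.05]]), 25.0),
        StudyContrasts("t05", "B", ["C"], np.array([-0.60]), np.array([[0.08]]), 33.0),
        StudyContrasts(
            "t06",
            "A",
            ["B", "C"],
            np.array([0.40, -0.10]),
            np.array([[0.10, 0.04], [0.04, 0.12]]),
            5.0,
        ),
    ]
    ds = ContrastDataset(studies=studies)
    ds.validate()
    return ds
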