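"""Network meta-regression on the contrast scale.

The model for the observed effect of arm k versus arm 1 in trial i is

    y_ik ~ N(theta_ik, v_ik),
    theta_ik = delta_ik + beta_{t_i1, t_ik} * c_i,

where the trial-specific effects delta_ik equal the consistency combination
d_{1,t_ik} - d_{1,t_i1} (fixed effect) or are drawn around it with common
between-trial variance sigma^2 (random effects; contrasts of one multi-arm
trial share covariance sigma^2/2).  Interaction coefficients versus the
reference treatment (the "basic" coefficients beta_{1t}) can be independent,
exchangeable around a common mean B with SD upsilon, or common to all
comparisons; functional coefficients follow by consistency, and are zero by
construction under the common assumption.

Everything here is linear given the variance components, so estimation is
generalised least squares: fixed-effect fits plug sigma^2 = 0, random-effects
fits plug a REML estimate or a posterior median, and the Bayesian path runs a
Gibbs sampler on the marginal likelihood (trial effects integrated out) with
a Metropolis step for sigma.  Prior distributions enter as pseudo-rows of the
design system, which is exactly the representation the contribution matrices
in :mod:`netmetareg.contributions` need.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .data_io import ContrastDataset, summarize_network
from .exceptions import (
    ConvergenceError,
    EstimabilityError,
    NumericalError,
    UnsupportedConfigurationError,
    ValidationError,
)

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "DesignBlock",
    "DesignSystem",
    "FitResult",
    "PosteriorSummary",
    "build_design",
    "fit_gls",
    "estimate_heterogeneity",
    "augment_with_priors",
    "fit_mcmc",
    "fit_frequentist",
    "predict_effect",
]

INTERACTION_KINDS = ("independent", "exchangeable", "common")


@dataclass(frozen=True)
class ModelSpec:
    """What model to fit.

    ``heterogeneity`` selects how sigma^2 is obtained for random-effects
    fits: ``"reml"``, ``"mcmc_median"``, or a fixed non-negative number.
    For exchangeable interactions ``exchange_sd`` (upsilon) must be given;
    ``exchange_mean`` (B) is either a fixed value or ``None`` to estimate it
    as an extra free parameter.
    """

    effects: str = "fixed"
    interactions: str = "independent"
    reference: str | None = None
    heterogeneity: str | float = "reml"
    exchange_mean: float | None = None
    exchange_sd: float | None = None

    def __post_init__(self) -> None:
        if self.effects not in ("fixed", "random"):
            raise ValueError(f"effects must be 'fixed' or 'random', got {self.effects!r}")
        if self.interactions not in INTERACTION_KINDS:
            raise ValueError(f"interactions must be one of {INTERACTION_KINDS}")
        if isinstance(self.heterogeneity, (int, float)) and self.heterogeneity < 0:
            raise ValueError("fixed heterogeneity value must be >= 0")


@dataclass(frozen=True)
class PriorSpec:
    """Normal priors per basic parameter plus a uniform prior on sigma.

    Defaults are the conventional vague choices N(0, 100000) for location
    parameters and Uniform(0, 10) for the between-trial SD.
    """

    mean: float = 0.0
    variance: float = 1.0e5
    overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    sd_upper: float = 10.0

    def __post_init__(self) -> None:
        if self.variance <= 0 or self.sd_upper <= 0:
            raise ValueError("prior variance and sd_upper must be > 0")
        for name, (_, var) in self.overrides.items():
            if var <= 0:
                raise ValueError(f"prior variance for {name} must be > 0")

    def for_param(self, name: str) -> tuple[float, float]:
        return self.overrides.get(name, (self.mean, self.variance))


@dataclass
class DesignBlock:
    """A block of rows of the design system sharing one covariance block.

    ``kind`` is ``"data"`` (a study; covariance gets the sigma^2 heterogeneity
    augmentation), ``"shrinkage"`` (exchangeable-interaction pseudo-row) or
    ``"prior"`` (prior pseudo-row); pseudo-row variances are fixed.
    """

    kind: str
    label: str
    rows: slice
    within_cov: np.ndarray
    covariate: float | None = None
    contrasts: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return self.within_cov.shape[0]


def _effect_name(t: str) -> str:
    return f"d({t})"


def _beta_name(t: str) -> str:
    return f"beta({t})"


@dataclass
class DesignSystem:
    """Stacked response, design matrix and block covariance of the NMR model."""

    y: np.ndarray
    X: np.ndarray
    blocks: list[DesignBlock]
    param_names: list[str]
    reference: str
    spec: ModelSpec
    data: ContrastDataset
    sigma2: float = 0.0

    # -- basic introspection -------------------------------------------------

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def has_priors(self) -> bool:
        return any(b.kind == "prior" for b in self.blocks)

    @property
    def data_blocks(self) -> list[DesignBlock]:
        return [b for b in self.blocks if b.kind == "data"]

    @property
    def row_labels(self) -> list[tuple[str, str, str]]:
        """Per row: (kind, block label, contrast or parameter label)."""
        labels: list[tuple[str, str, str]] = [None] * len(self.y)  # type: ignore[list-item]
        for b in self.blocks:
            names = b.contrasts if b.contrasts else [b.label] * b.size
            for j, i in enumerate(range(b.rows.start, b.rows.stop)):
                labels[i] = (b.kind, b.label, names[j])
        return labels

    def with_sigma2(self, sigma2: float) -> "DesignSystem":
        if sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        return dataclasses.replace(self, sigma2=float(sigma2))

    def block_cov(self, block: DesignBlock, sigma2: float | None = None) -> np.ndarray:
        """Covariance of one block at the given heterogeneity."""
        s2 = self.sigma2 if sigma2 is None else sigma2
        if block.kind != "data" or s2 == 0:
            return block.within_cov
        m = block.size
        return block.within_cov + 0.5 * s2 * (np.eye(m) + np.ones((m, m)))

    def V(self, sigma2: float | None = None) -> np.ndarray:
        """Full (block-diagonal) covariance matrix; mainly for oracles/tests."""
        n = len(self.y)
        V = np.zeros((n, n))
        for b in self.blocks:
            V[b.rows, b.rows] = self.block_cov(b, sigma2)
        return V

    # -- GLS building blocks -------------------------------------------------

    def _row_groups(self):
        """Cache arrays for single-row blocks so GLS parts vectorise.

        Returns (idx1, v1, het1, multis) where idx1 indexes all size-1 block
        rows, v1 their within variances, het1 marks data rows (which receive
        the sigma^2 augmentation) and multis lists the multi-contrast blocks.
        """
        cache = getattr(self, "_row_groups_cache", None)
        if cache is not None:
            return cache
        idx1, v1, het1 = [], [], []
        multis = []
        for blk in self.blocks:
            if blk.size == 1:
                idx1.append(blk.rows.start)
                v1.append(blk.within_cov[0, 0])
                het1.append(blk.kind == "data")
            else:
                multis.append(blk)
        cache = (
            np.asarray(idx1, dtype=int),
            np.asarray(v1, dtype=float),
            np.asarray(het1, dtype=bool),
            multis,
        )
        object.__setattr__(self, "_row_groups_cache", cache)
        return cache

    def gls_parts(
        self, sigma2: float | None = None
    ) -> tuple[np.ndarray, np.ndarray, float, float]:
        """Return (X'V^-1 X, X'V^-1 y, y'V^-1 y, log|V|) at the given sigma^2."""
        s2 = self.sigma2 if sigma2 is None else sigma2
        idx1, v1, het1, multis = self._row_groups()
        A = np.zeros((self.n_params, self.n_params))
        b = np.zeros(self.n_params)
        quad = 0.0
        logdet = 0.0
        if idx1.size:
            v = v1 + s2 * het1
            X1 = self.X[idx1]
            y1 = self.y[idx1]
            w = 1.0 / v
            A += (X1 * w[:, None]).T @ X1
            b += X1.T @ (y1 * w)
            quad += float(y1 @ (y1 * w))
            logdet += float(np.log(v).sum())
        for blk in multis:
            Xb = self.X[blk.rows]
            yb = self.y[blk.rows]
            Vb = self.block_cov(blk, s2)
            try:
                cf = linalg.cho_factor(Vb, lower=True)
            except linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
                raise NumericalError(
                    f"covariance block of {blk.label} not positive definite"
                ) from exc
            Wi = linalg.cho_solve(cf, Xb)
            wy = linalg.cho_solve(cf, yb)
            A += Xb.T @ Wi
            b += Xb.T @ wy
            quad += float(yb @ wy)
            logdet += 2.0 * float(np.log(np.diag(cf[0])).sum())
        return A, b, quad, logdet

    def loglik(self, theta: np.ndarray, sigma2: float, data_only: bool = True) -> float:
        """Marginal Gaussian log-likelihood of the (data) rows at (theta, sigma^2)."""
        idx1, v1, het1, multis = self._row_groups()
        ll = 0.0
        if idx1.size:
            keep = het1 if data_only else np.ones_like(het1)
            if keep.any():
                idx = idx1[keep]
                v = v1[keep] + sigma2 * het1[keep]
                r = self.y[idx] - self.X[idx] @ theta
                ll += -0.5 * float(np.log(2 * math.pi * v).sum() + (r**2 / v).sum())
        for blk in multis:
            if data_only and blk.kind != "data":
                continue
            r = self.y[blk.rows] - self.X[blk.rows] @ theta
            Vb = self.block_cov(blk, sigma2)
            cf = linalg.cho_factor(Vb, lower=True)
            logdet = 2.0 * float(np.log(np.diag(cf[0])).sum())
            ll += -0.5 * (
                blk.size * math.log(2 * math.pi) + logdet + float(r @ linalg.cho_solve(cf, r))
            )
        return ll


# ---------------------------------------------------------------------------
# design construction


def build_design(
    data: ContrastDataset, spec: ModelSpec, sigma2: float | None = None
) -> DesignSystem:
    """Assemble the design system for a dataset under a model specification.

    Columns are the basic treatment effects d_{1t} (one per non-reference
    treatment) followed by the interaction block: one column per non-reference
    treatment for independent/exchangeable coefficients, a single column for a
    common coefficient, plus a hypermean column ``B`` when exchangeable
    coefficients shrink toward an estimated mean.
    """
    if not data.studies:
        raise ValidationError("empty dataset")
    net = summarize_network(data)
    if not net.connected:
        raise ValidationError("treatment network is not connected")
    treatments = data.treatments
    reference = spec.reference if spec.reference is not None else treatments[0]
    if reference not in treatments:
        raise ValidationError(f"reference treatment {reference!r} not in network")
    others = [t for t in treatments if t != reference]

    effect_cols = [_effect_name(t) for t in others]
    if spec.interactions == "common":
        beta_cols = ["beta"]
    else:
        beta_cols = [_beta_name(t) for t in others]
    param_names = effect_cols + list(beta_cols)

    estimate_B = False
    if spec.interactions == "exchangeable":
        if len(others) < 2:
            raise ValidationError("exchangeable interactions require >= 2 basic coefficients")
        if spec.exchange_sd is None or spec.exchange_sd <= 0:
            raise ValidationError(
                "exchangeable interactions require a positive exchange_sd (upsilon)"
            )
        if spec.exchange_mean is None:
            estimate_B = True
            param_names = param_names + ["B"]

    col = {name: j for j, name in enumerate(param_names)}
    p = len(param_names)

    rows_y: list[float] = []
    rows_X: list[np.ndarray] = []
    blocks: list[DesignBlock] = []
    cursor = 0
    for s in data.studies:
        for j, t in enumerate(s.treatments):
            x = np.zeros(p)
            if t != reference:
                x[col[_effect_name(t)]] += 1.0
            if s.baseline != reference:
                x[col[_effect_name(s.baseline)]] -= 1.0
            c = s.covariate
            if spec.interactions == "common":
                if s.baseline == reference:
                    x[col["beta"]] = c
            else:
                if t != reference:
                    x[col[_beta_name(t)]] += c
                if s.baseline != reference:
                    x[col[_beta_name(s.baseline)]] -= c
            rows_X.append(x)
            rows_y.append(float(s.y[j]))
        m = s.n_contrasts
        blocks.append(
            DesignBlock(
                kind="data",
                label=s.study_id,
                rows=slice(cursor, cursor + m),
                within_cov=np.asarray(s.cov, dtype=float),
                covariate=s.covariate,
                contrasts=[f"{t} vs {s.baseline}" for t in s.treatments],
            )
        )
        cursor += m

    if spec.interactions == "exchangeable":
        ups2 = float(spec.exchange_sd) ** 2
        for t in others:
            x = np.zeros(p)
            x[col[_beta_name(t)]] = 1.0
            if estimate_B:
                x[col["B"]] = -1.0
                rows_y.append(0.0)
            else:
                rows_y.append(float(spec.exchange_mean))
            rows_X.append(x)
            blocks.append(
                DesignBlock(
                    kind="shrinkage",
                    label=_beta_name(t),
                    rows=slice(cursor, cursor + 1),
                    within_cov=np.array([[ups2]]),
                )
            )
            cursor += 1

    ds = DesignSystem(
        y=np.asarray(rows_y, dtype=float),
        X=np.vstack(rows_X),
        blocks=blocks,
        param_names=param_names,
        reference=reference,
        spec=spec,
        data=data,
        sigma2=0.0,
    )
    if sigma2 is None and spec.effects == "random" and isinstance(spec.heterogeneity, (int, float)):
        sigma2 = float(spec.heterogeneity)
    if sigma2 is not None:
        ds = ds.with_sigma2(sigma2)
    _check_estimability(ds)
    return ds


def _check_estimability(ds: DesignSystem) -> None:
    X = ds.X
    rank = np.linalg.matrix_rank(X)
    if rank == ds.n_params:
        return
    # name an offending interaction column: all contributing rows share one
    # covariate value (or none contribute at all)
    for j, name in enumerate(ds.param_names):
        if not name.startswith("beta"):
            continue
        contributing = np.nonzero(X[:, j])[0]
        if contributing.size == 0:
            raise EstimabilityError(
                f"coefficient {name} not estimable: no study contributes to it"
            )
        sub = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(sub) == rank:
            raise EstimabilityError(
                f"coefficient {name} not estimable: the contributing trials do not "
                f"span distinct covariate values"
            )
    raise EstimabilityError(
        f"design matrix rank {rank} < {ds.n_params} parameters; model not estimable"
    )


# ---------------------------------------------------------------------------
# estimation


@dataclass
class PosteriorSummary:
    """Posterior draws and summaries from the Gibbs sampler."""

    samples: pd.DataFrame  # columns: parameters + "sigma"
    summary: pd.DataFrame  # index: parameters (+sigma); columns: median, lower, upper
    dic: dict[str, float]  # Dbar, Dhat, pD, DIC
    rhat: pd.Series


@dataclass
class FitResult:
    """Point estimates, covariance and diagnostics of one NMR fit."""

    params: pd.Series
    cov: pd.DataFrame
    sigma2: float
    resid_deviance: float
    reference: str
    spec: ModelSpec
    covariate_center: float
    posterior: PosteriorSummary | None = None

    @property
    def param_names(self) -> list[str]:
        return list(self.params.index)


def fit_gls(ds: DesignSystem) -> FitResult:
    """Generalised least squares at the design system's plugged-in sigma^2.

    estimates = (X'V^-1 X)^-1 X'V^-1 y with covariance S = (X'V^-1 X)^-1;
    the residual deviance is the weighted residual sum of squares.
    """
    A, b, quad, _ = ds.gls_parts()
    try:
        cf = linalg.cho_factor(A)
    except linalg.LinAlgError as exc:
        raise EstimabilityError("singular normal equations; model not estimable") from exc
    theta = linalg.cho_solve(cf, b)
    S = linalg.cho_solve(cf, np.eye(ds.n_params))
    S = 0.5 * (S + S.T)
    resid_dev = float(quad - b @ theta)
    return FitResult(
        params=pd.Series(theta, index=ds.param_names),
        cov=pd.DataFrame(S, index=ds.param_names, columns=ds.param_names),
        sigma2=ds.sigma2,
        resid_deviance=resid_dev,
        reference=ds.reference,
        spec=ds.spec,
        covariate_center=ds.data.covariate_center,
    )


def estimate_heterogeneity(ds: DesignSystem, sd_upper: float = 10.0) -> float:
    """REML estimate of the common between-trial variance sigma^2.

    Multi-arm blocks receive sigma^2 on the diagonal and sigma^2/2 off the
    diagonal.  The profile is searched on the SD scale over [0, sd_upper].
    """
    n_data = sum(b.size for b in ds.data_blocks)
    if n_data <= ds.n_params:
        raise ValidationError("REML needs more data rows than parameters")

    def neg2_restricted_ll(sigma: float) -> float:
        A, b, quad, logdet = ds.gls_parts(sigma2=sigma**2)
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        theta = np.linalg.solve(A, b)
        return logdet + logdetA + (quad - float(b @ theta))

    res = optimize.minimize_scalar(
        neg2_restricted_ll, bounds=(0.0, sd_upper), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        trace = [(s, neg2_restricted_ll(s)) for s in np.linspace(0, sd_upper, 11)]
        raise ConvergenceError(f"REML profile search failed; profile trace: {trace}")
    sigma = float(res.x)
    # the bounded minimiser cannot land exactly on 0; snap when the boundary
    # is at least as good
    if neg2_restricted_ll(0.0) <= res.fun + 1e-10:
        sigma = 0.0
    return sigma**2


def augment_with_priors(ds: DesignSystem, priors: PriorSpec) -> DesignSystem:
    """Append one pseudo-row per basic parameter encoding its normal prior."""
    p = ds.n_params
    extra_y = []
    extra_X = []
    blocks = list(ds.blocks)
    cursor = len(ds.y)
    for j, name in enumerate(ds.param_names):
        mean, var = priors.for_param(name)
        x = np.zeros(p)
        x[j] = 1.0
        extra_X.append(x)
        extra_y.append(mean)
        blocks.append(
            DesignBlock(
                kind="prior",
                label=name,
                rows=slice(cursor, cursor + 1),
                within_cov=np.array([[var]]),
            )
        )
        cursor += 1
    return dataclasses.replace(
        ds,
        y=np.concatenate([ds.y, np.asarray(extra_y, dtype=float)]),
        X=np.vstack([ds.X, np.vstack(extra_X)]),
        blocks=blocks,
    )


def fit_frequentist(data: ContrastDataset, spec: ModelSpec) -> FitResult:
    """Convenience pipeline: build the design, plug sigma^2, run GLS."""
    ds = build_design(data, spec)
    if spec.effects == "random":
        if spec.heterogeneity == "reml":
            ds = ds.with_sigma2(estimate_heterogeneity(ds))
        elif isinstance(spec.heterogeneity, (int, float)):
            ds = ds.with_sigma2(float(spec.heterogeneity))
        else:
            raise UnsupportedConfigurationError(
                "frequentist random-effects fits need heterogeneity='reml' or a fixed value"
            )
    return fit_gls(ds)


# ---------------------------------------------------------------------------
# Gibbs sampler


def _gelman_rubin(chains: list[np.ndarray]) -> float:
    """Split-chain potential scale reduction factor for one scalar parameter."""
    seqs = []
    for c in chains:
        half = len(c) // 2
        if half < 2:
            return np.nan
        seqs.append(c[:half])
        seqs.append(c[half : 2 * half])
    arr = np.asarray(seqs)
    m, n = arr.shape
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return math.sqrt(var_plus / W)


def fit_mcmc(
    ds: DesignSystem,
    priors: PriorSpec | None = None,
    chains: int = 3,
    iterations: int = 300_000,
    burn_in: int = 100_000,
    thin: int = 5,
    seed: int | None = None,
) -> FitResult:
    """Gibbs sampler for the marginalised NMR model.

    Basic parameters are drawn jointly from their multivariate-normal full
    conditional given sigma; sigma takes a random-walk Metropolis step under
    its Uniform(0, upper) prior, with the step size adapted during burn-in.
    Trial-specific effects are integrated out analytically, so the deviance
    (and hence DIC = Dbar + pD, pD = Dbar - Dhat, Dhat at the posterior means)
    refers to the marginal normal likelihood.  Fully reproducible given
    ``seed``.
    """
    if priors is None:
        priors = PriorSpec()
    if ds.has_priors:
        raise UnsupportedConfigurationError(
            "pass priors via the `priors` argument, not a prior-augmented design"
        )
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    spec = ds.spec
    sample_sigma = spec.effects == "random" and not isinstance(
        spec.heterogeneity, (int, float)
    )
    if spec.effects == "random" and isinstance(spec.heterogeneity, (int, float)):
        sigma_fixed = math.sqrt(float(spec.heterogeneity))
    else:
        sigma_fixed = 0.0

    p = ds.n_params
    prior_mean = np.array([priors.for_param(nm)[0] for nm in ds.param_names])
    prior_prec = np.diag([1.0 / priors.for_param(nm)[1] for nm in ds.param_names])
    prior_b = prior_prec @ prior_mean

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(chains)

    kept_theta: list[np.ndarray] = []
    kept_sigma: list[np.ndarray] = []
    kept_dev: list[np.ndarray] = []

    for ci in range(chains):
        rng = np.random.default_rng(chain_seeds[ci])
        # dispersed initial values: GLS solution jittered per chain
        A0, b0, _, _ = ds.gls_parts(sigma2=0.0)
        theta = np.linalg.solve(A0 + prior_prec, b0 + prior_b)
        theta = theta + rng.normal(scale=0.5 * (ci + 1) / chains, size=p) * (
            1.0 + np.abs(theta)
        )
        sigma = sigma_fixed
        if sample_sigma:
            sigma = priors.sd_upper * (0.02 + 0.2 * ci / max(chains - 1, 1))
        step = 0.1 * max(sigma, 0.1)
        accepted = proposed = 0
        cur_ll: float | None = None

        t_keep, s_keep, d_keep = [], [], []
        for it in range(iterations):
            A, b, _, _ = ds.gls_parts(sigma2=sigma**2)
            Ap = A + prior_prec
            bp = b + prior_b
            try:
                cf = linalg.cho_factor(Ap)
            except linalg.LinAlgError as exc:
                raise NumericalError("non-positive-definite conditional covariance") from exc
            mean = linalg.cho_solve(cf, bp)
            # draw theta ~ N(mean, Ap^-1): solve L' z with z standard normal
            z = rng.standard_normal(p)
            L = np.linalg.cholesky(Ap)
            theta = mean + linalg.solve_triangular(L.T, z, lower=False)
            cur_ll = None  # theta changed

            if sample_sigma:
                if cur_ll is None:
                    cur_ll = ds.loglik(theta, sigma**2)
                prop = sigma + rng.normal(scale=step)
                proposed += 1
                if 0.0 <= prop <= priors.sd_upper:
                    prop_ll = ds.loglik(theta, prop**2)
                    if math.log(rng.uniform()) < prop_ll - cur_ll:
                        sigma = prop
                        cur_ll = prop_ll
                        accepted += 1
                if it < burn_in and (it + 1) % 200 == 0:
                    rate = accepted / max(proposed, 1)
                    step *= math.exp(0.5 * (rate - 0.35))
                    accepted = proposed = 0

            if it >= burn_in and (it - burn_in) % thin == 0:
                if cur_ll is None:
                    cur_ll = ds.loglik(theta, sigma**2)
                t_keep.append(theta.copy())
                s_keep.append(sigma)
                d_keep.append(-2.0 * cur_ll)
        kept_theta.append(np.asarray(t_keep))
        kept_sigma.append(np.asarray(s_keep))
        kept_dev.append(np.asarray(d_keep))

    theta_all = np.concatenate(kept_theta)
    sigma_all = np.concatenate(kept_sigma)
    dev_all = np.concatenate(kept_dev)

    rhat_vals = {}
    for j, name in enumerate(ds.param_names):
        rhat_vals[name] = _gelman_rubin([c[:, j] for c in kept_theta])
    if sample_sigma:
        rhat_vals["sigma"] = _gelman_rubin(kept_sigma)
    rhat = pd.Series(rhat_vals)
    bad = rhat[rhat > 1.05]
    if len(bad):
        warnings.warn(
            f"MCMC convergence warning: R-hat > 1.05 for {list(bad.index)}",
            RuntimeWarning,
            stacklevel=2,
        )

    dbar = float(dev_all.mean())
    theta_mean = theta_all.mean(axis=0)
    sigma_mean = float(sigma_all.mean())
    dhat = -2.0 * ds.loglik(theta_mean, sigma_mean**2)
    pd_eff = dbar - dhat
    dic = dbar + pd_eff

    cols = {name: theta_all[:, j] for j, name in enumerate(ds.param_names)}
    cols["sigma"] = sigma_all
    samples = pd.DataFrame(cols)
    qs = samples.quantile([0.5, 0.025, 0.975]).T
    qs.columns = ["median", "lower", "upper"]
    post = PosteriorSummary(
        samples=samples,
        summary=qs,
        dic={"Dbar": dbar, "Dhat": dhat, "pD": pd_eff, "DIC": dic},
        rhat=rhat,
    )
    medians = samples[ds.param_names].median()
    cov = samples[ds.param_names].cov()
    return FitResult(
        params=pd.Series(medians, index=ds.param_names),
        cov=pd.DataFrame(cov, index=ds.param_names, columns=ds.param_names),
        sigma2=float(np.median(sigma_all) ** 2),
        resid_deviance=dbar,
        reference=ds.reference,
        spec=spec,
        covariate_center=ds.data.covariate_center,
        posterior=post,
    )


# ---------------------------------------------------------------------------
# prediction


def predict_effect(
    fit: FitResult,
    comparison: tuple[str, str],
    covariate_value: float,
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Treatment effect of ``comparison[0]`` vs ``comparison[1]`` at a covariate value.

    ``covariate_value`` is on the original (uncentred) scale; the model's
    centring is honoured internally.  Frequentist fits return a Wald interval;
    fits with a posterior return quantiles of the linear combination.
    """
    from .contributions import ResultSpec, result_contrast_vector

    rspec = ResultSpec(comparison=comparison, kind="effect_at_value", value=covariate_value)
    c = result_contrast_vector(
        rspec,
        param_names=fit.param_names,
        reference=fit.reference,
        interactions=fit.spec.interactions,
        center=fit.covariate_center,
    )
    if fit.posterior is not None:
        draws = fit.posterior.samples[fit.param_names].to_numpy() @ c
        lo, med, hi = np.quantile(draws, [(1 - level) / 2, 0.5, (1 + level) / 2])
        return float(med), (float(lo), float(hi))
    est = float(c @ fit.params.to_numpy())
    se = math.sqrt(float(c @ fit.cov.to_numpy() @ c))
    from scipy import stats

    z = stats.norm.ppf(0.5 + level / 2)
    return est, (est - z * se, est + z * se)
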