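"""Percentage contributions of trials (and priors) to NMR results.

Each NMR result — a treatment effect at the covariate centre (or at any
covariate value) or an interaction coefficient, for any comparison in the
network — is a linear combination ``c'theta`` of the basic parameters.  Under
generalised least squares the estimate is a linear function of the stacked
responses,

    c'theta_hat = w'y  with  w' = c' (X'V^-1 X)^-1 X'V^-1,

so row j of the system (one observed contrast of one trial, or one prior
pseudo-row) contributes ``100*|w_j| / sum_k |w_k|`` percent to the result.
Contributions can be aggregated to study level and summed within covariate
ranges (bins) to expose interpolation and extrapolation.

The module also implements the variance-decomposition study weights of Riley
et al. — ``100*[S(X_i'V_i^-1 X_i)S]_pp / S_pp`` with ``S=(X'V^-1 X)^-1`` —
which are per *study* rather than per data point, require a frequentist
system without prior rows, and handle functional comparisons by rebuilding
the design with a different reference treatment (hence independent
interactions only).  ``compare_methods`` quantifies how the two approaches
differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .data_io import ContrastDataset
from .exceptions import (
    EstimabilityError,
    UnsupportedConfigurationError,
    ValidationError,
)
from .model import DesignSystem, ModelSpec, build_design

__all__ = [
    "ResultSpec",
    "BinSpec",
    "ContributionTable",
    "result_contrast_vector",
    "contribution_new",
    "contribution_table",
    "aggregate_contributions",
    "riley_weights",
    "riley_functional",
    "riley_table",
    "compare_methods",
    "default_results",
]

RESULT_KINDS = ("effect_at_center", "effect_at_value", "coefficient")


@dataclass(frozen=True)
class ResultSpec:
    """One NMR result: a comparison and what is asked about it.

    ``comparison=(a, b)`` reads "a versus b".  ``kind`` is the treatment
    effect at the covariate centre, the effect at an explicit covariate value
    (on the original scale), or the interaction coefficient.
    """

    comparison: tuple[str, str]
    kind: str = "effect_at_center"
    value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in RESULT_KINDS:
            raise ValueError(f"kind must be one of {RESULT_KINDS}")
        if self.kind == "effect_at_value" and self.value is None:
            raise ValueError("effect_at_value needs a covariate value")
        a, b = self.comparison
        if a == b:
            raise ValueError("comparison must involve two distinct treatments")

    @property
    def label(self) -> str:
        a, b = self.comparison
        if self.kind == "coefficient":
            return f"beta:{a}_vs_{b}"
        if self.kind == "effect_at_center":
            return f"d:{a}_vs_{b}@center"
        return f"d:{a}_vs_{b}@{self.value:g}"


@dataclass(frozen=True)
class BinSpec:
    """Covariate bins on the original scale: [lo, hi) except the last, closed."""

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing with >= 2 values")

    @property
    def labels(self) -> list[str]:
        e = self.edges
        return [f"{e[i]:g}–{e[i+1]:g}" for i in range(len(e) - 1)]

    def assign(self, value: float) -> int | None:
        e = self.edges
        if value < e[0] or value > e[-1]:
            return None
        for i in range(len(e) - 1):
            if e[i] <= value < e[i + 1]:
                return i
        return len(e) - 2  # value == last edge: closed final bin


@dataclass
class ContributionTable:
    """Results x data-rows matrix of percentage contributions.

    Each row sums to 100 across all columns (data plus any prior columns).
    ``column_meta`` records, per column, its kind (data/shrinkage/prior), its
    study and the study covariate on the original scale, which is what study-
    and bin-level aggregation needs.
    """

    values: pd.DataFrame
    level: str  # datapoint | study | bin
    column_meta: pd.DataFrame  # index: columns of `values`; cols: kind, study, covariate

    @property
    def data_columns(self) -> list[str]:
        return list(self.column_meta.index[self.column_meta["kind"] == "data"])

    @property
    def prior_columns(self) -> list[str]:
        return list(self.column_meta.index[self.column_meta["kind"] != "data"])

    def row_sums(self) -> pd.Series:
        return self.values.sum(axis=1)

    def to_csv(self, path, sep: str = ",") -> None:
        out = self.values.copy()
        out.index.name = "result"
        out.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# contrast vectors


def result_contrast_vector(
    rspec: ResultSpec,
    param_names: Sequence[str],
    reference: str,
    interactions: str = "independent",
    center: float = 0.0,
) -> np.ndarray:
    """Vector c with result = c'theta over the basic parameters.

    Functional comparisons are built from basic ones through the consistency
    relations; an effect at covariate value x multiplies the interaction
    entries by (x - center).  Under common interactions a functional
    coefficient is identically zero — the zero vector is returned with a
    warning.
    """
    a, b = rspec.comparison
    cols = {name: j for j, name in enumerate(param_names)}
    c = np.zeros(len(param_names))

    def add_effect(t: str, sign: float) -> None:
        if t != reference:
            key = f"d({t})"
            if key not in cols:
                raise ValidationError(f"unknown treatment {t!r}")
            c[cols[key]] += sign

    def add_beta(t: str, sign: float, mult: float) -> None:
        if t == reference:
            return
        if interactions == "common":
            c[cols["beta"]] += sign * mult
        else:
            key = f"beta({t})"
            if key not in cols:
                raise ValidationError(f"unknown treatment {t!r}")
            c[cols[key]] += sign * mult

    for t in (a, b):
        if t != reference and f"d({t})" not in cols:
            raise ValidationError(f"unknown treatment {t!r}")

    if rspec.kind == "coefficient":
        if interactions == "common" and a != reference and b != reference:
            warnings.warn(
                f"functional coefficient {a} vs {b} is fixed to zero under common "
                f"interactions",
                UserWarning,
                stacklevel=2,
            )
            return c
        add_beta(a, +1.0, 1.0)
        add_beta(b, -1.0, 1.0)
        return c

    add_effect(a, +1.0)
    add_effect(b, -1.0)
    if rspec.kind == "effect_at_value":
        mult = float(rspec.value) - center
        add_beta(a, +1.0, mult)
        add_beta(b, -1.0, mult)
    return c


def default_results(
    treatments: Sequence[str], interactions: str = "independent", reference: str | None = None
) -> list[ResultSpec]:
    """All pairwise effects at the centre plus all coefficients.

    Comparisons are oriented "later vs earlier" in sorted treatment order.
    Under common interactions only the single shared coefficient (versus the
    reference) is meaningful, so functional coefficients are omitted.
    """
    ts = sorted(treatments)
    ref = reference if reference is not None else ts[0]
    out: list[ResultSpec] = []
    for i, t1 in enumerate(ts):
        for t2 in ts[i + 1 :]:
            out.append(ResultSpec(comparison=(t2, t1), kind="effect_at_center"))
    for i, t1 in enumerate(ts):
        for t2 in ts[i + 1 :]:
            if interactions == "common" and t1 != ref and t2 != ref:
                continue
            out.append(ResultSpec(comparison=(t2, t1), kind="coefficient"))
    return out


# ---------------------------------------------------------------------------
# the new (per-data-point) contribution method


def _weight_row(ds: DesignSystem, c: np.ndarray) -> np.ndarray:
    """w' = c' (X'V^-1 X)^-1 X'V^-1 over all rows of the system."""
    A, _, _, _ = ds.gls_parts()
    try:
        u = linalg.solve(A, c, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise EstimabilityError("singular normal equations") from exc
    w = np.empty(len(ds.y))
    for blk in ds.blocks:
        Xu = ds.X[blk.rows] @ u
        Vb = ds.block_cov(blk)
        if blk.size == 1:
            w[blk.rows] = Xu / Vb[0, 0]
        else:
            w[blk.rows] = linalg.solve(Vb, Xu, assume_a="pos")
    return w


def _column_labels(ds: DesignSystem) -> tuple[list[str], pd.DataFrame]:
    labels = []
    meta = []
    for kind, block_label, contrast in ds.row_labels:
        if kind == "data":
            lab = f"{block_label}|{contrast}"
            cov = ds.data.study(block_label).covariate + ds.data.covariate_center
            meta.append({"kind": "data", "study": block_label, "covariate": cov})
        else:
            lab = f"{kind}:{block_label}"
            meta.append({"kind": kind, "study": None, "covariate": np.nan})
        labels.append(lab)
    return labels, pd.DataFrame(meta, index=labels)


def contribution_new(
    ds: DesignSystem, rspec: ResultSpec, signed: bool = False
) -> pd.Series:
    """Percentage contribution of every row (data point or prior) to one result.

    Percentages are the normalised absolute linear weights,
    ``100*|w_j|/sum|w|``; set ``signed=True`` to get the signed weights on the
    percentage scale instead (diagnostic use; signed values need not be
    positive but still sum to a meaningful total only in absolute terms).
    """
    c = result_contrast_vector(
        rspec, ds.param_names, ds.reference, ds.spec.interactions, ds.data.covariate_center
    )
    w = _weight_row(ds, c)
    labels, _ = _column_labels(ds)
    absw = np.abs(w)
    total = absw.sum()
    if total == 0:
        return pd.Series(np.zeros_like(w), index=labels, name=rspec.label)
    vals = 100.0 * (w / total if signed else absw / total)
    return pd.Series(vals, index=labels, name=rspec.label)


def contribution_table(
    ds: DesignSystem, results: Sequence[ResultSpec] | None = None, signed: bool = False
) -> ContributionTable:
    """Stack :func:`contribution_new` rows for many results into one table."""
    if results is None:
        results = default_results(
            ds.data.treatments, ds.spec.interactions, ds.reference
        )
    labels, meta = _column_labels(ds)
    rows = [contribution_new(ds, r, signed=signed) for r in results]
    df = pd.DataFrame(rows, index=[r.label for r in results], columns=labels)
    return ContributionTable(values=df, level="datapoint", column_meta=meta)


def aggregate_contributions(
    table: ContributionTable, level: str, bins: BinSpec | None = None
) -> ContributionTable:
    """Sum contributions within studies or within covariate bins.

    Row sums are preserved (summation is over disjoint column groups); prior
    and shrinkage columns pass through unchanged as their own labelled block.
    """
    if level not in ("study", "bin"):
        raise ValueError("level must be 'study' or 'bin'")
    if level == "bin" and bins is None:
        raise ValueError("bin aggregation requires a BinSpec")

    meta = table.column_meta
    data_cols = table.data_columns
    prior_cols = table.prior_columns

    if level == "study":
        groups = meta.loc[data_cols, "study"]
        agg = table.values[data_cols].T.groupby(groups).sum().T
        new_meta_rows = []
        for study in agg.columns:
            cov = meta.loc[meta["study"] == study, "covariate"].iloc[0]
            new_meta_rows.append({"kind": "data", "study": study, "covariate": cov})
        new_meta = pd.DataFrame(new_meta_rows, index=list(agg.columns))
    else:
        assert bins is not None
        assignments = {}
        missing = []
        for colname in data_cols:
            cov = float(meta.loc[colname, "covariate"])
            idx = bins.assign(cov)
            if idx is None:
                missing.append(meta.loc[colname, "study"])
            else:
                assignments[colname] = idx
        if missing:
            raise ValidationError(
                f"covariate outside all bins for studies: {sorted(set(missing))}"
            )
        bin_labels = bins.labels
        agg = pd.DataFrame(
            0.0, index=table.values.index, columns=bin_labels
        )
        for colname, idx in assignments.items():
            agg[bin_labels[idx]] += table.values[colname]
        new_meta = pd.DataFrame(
            {"kind": "data", "study": None, "covariate": np.nan}, index=bin_labels
        )

    if prior_cols:
        agg = pd.concat([agg, table.values[prior_cols]], axis=1)
        new_meta = pd.concat([new_meta, meta.loc[prior_cols]])
    return ContributionTable(values=agg, level=level, column_meta=new_meta)


# ---------------------------------------------------------------------------
# Riley-style variance-decomposition study weights


def _require_frequentist(ds: DesignSystem) -> None:
    if ds.has_priors or any(b.kind == "shrinkage" for b in ds.blocks):
        raise UnsupportedConfigurationError(
            "variance-decomposition study weights are defined for frequentist "
            "systems without prior or shrinkage pseudo-rows"
        )


def riley_weights(ds: DesignSystem, parameter: int | str) -> pd.Series:
    """Per-study percentage weights for one basic parameter.

    With S = (X'V^-1 X)^-1 and F_i = X_i'V_i^-1 X_i the Fisher information of
    study i, the weight of study i for parameter p is
    ``100*[S F_i S]_pp / S_pp``; the weights sum to 100 over studies.
    """
    _require_frequentist(ds)
    if isinstance(parameter, str):
        try:
            pidx = ds.param_names.index(parameter)
        except ValueError as exc:
            raise ValidationError(f"unknown parameter {parameter!r}") from exc
    else:
        pidx = parameter
    A, _, _, _ = ds.gls_parts()
    try:
        S = linalg.inv(A)
    except linalg.LinAlgError as exc:
        raise EstimabilityError("singular normal equations") from exc
    out = {}
    for blk in ds.data_blocks:
        Xb = ds.X[blk.rows]
        Vb = ds.block_cov(blk)
        Fi = Xb.T @ linalg.solve(Vb, Xb, assume_a="pos")
        out[blk.label] = 100.0 * float((S @ Fi @ S)[pidx, pidx] / S[pidx, pidx])
    return pd.Series(out)


def riley_functional(ds: DesignSystem, rspec: ResultSpec) -> pd.Series:
    """Study weights for a (possibly functional) effect or coefficient.

    For a comparison a vs b the design is rebuilt with b as the reference so
    the requested parameter becomes basic; valid only under independent
    interactions, whose estimates do not depend on the reference choice.
    """
    _require_frequentist(ds)
    if ds.spec.interactions != "independent":
        raise UnsupportedConfigurationError(
            "study weights for functional comparisons require independent interactions"
        )
    if rspec.kind == "effect_at_value":
        raise UnsupportedConfigurationError(
            "study weights are defined for effects at the centre and coefficients"
        )
    a, b = rspec.comparison
    if b == ds.reference:
        ds2 = ds
    else:
        spec2 = ModelSpec(
            effects=ds.spec.effects,
            interactions="independent",
            reference=b,
            heterogeneity=ds.spec.heterogeneity,
        )
        ds2 = build_design(ds.data, spec2, sigma2=ds.sigma2)
    name = f"d({a})" if rspec.kind == "effect_at_center" else f"beta({a})"
    return riley_weights(ds2, name)


def riley_table(
    ds: DesignSystem, results: Sequence[ResultSpec] | None = None
) -> ContributionTable:
    """Study-level table of Riley weights for many results."""
    if results is None:
        results = default_results(
            ds.data.treatments, ds.spec.interactions, ds.reference
        )
    rows = {r.label: riley_functional(ds, r) for r in results}
    df = pd.DataFrame(rows).T
    meta_rows = []
    for study in df.columns:
        cov = ds.data.study(study).covariate + ds.data.covariate_center
        meta_rows.append({"kind": "data", "study": study, "covariate": cov})
    meta = pd.DataFrame(meta_rows, index=list(df.columns))
    return ContributionTable(values=df, level="study", column_meta=meta)


def compare_methods(
    new: ContributionTable, riley: ContributionTable
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Elementwise differences between the two study-level tables.

    Returns the difference table (new minus Riley) and a summary with the
    min/max absolute difference and the per-result maxima.
    """
    if new.level != "study" or riley.level != "study":
        raise ValueError("compare_methods expects study-level tables")
    new_data = new.values[new.data_columns]
    if set(new_data.columns) != set(riley.values.columns) or set(
        new_data.index
    ) != set(riley.values.index):
        raise ValidationError("study or result labels do not match between tables")
    riley_aligned = riley.values.loc[new_data.index, new_data.columns]
    diff = new_data - riley_aligned
    absdiff = diff.abs()
    summary = {
        "min_abs_diff": float(absdiff.min().min()),
        "max_abs_diff": float(absdiff.max().max()),
    }
    for label in absdiff.index:
        summary[f"max_abs_diff[{label}]"] = float(absdiff.loc[label].max())
    return diff, summary
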