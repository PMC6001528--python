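"""Reading trial-level tables and constructing treatment contrasts.

Trial evidence enters network meta-regression either at arm level (events/total
per arm for binary outcomes; mean/SD/n per arm for continuous outcomes) or
directly at contrast level (an effect versus the study's baseline arm with a
standard error, plus within-study covariances for multi-arm trials).  This
module parses both layouts, converts arm-level data to contrasts (log odds
ratios or standardised mean differences with the correct shared-baseline-arm
covariances), validates the treatment network, and centres the study-level
covariate.

All tables are delimiter-separated text (comma by default); writers emit full
double precision so a written dataset round-trips exactly.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateCellError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

BINARY_COLUMNS = ("study", "arm", "treatment", "covariate", "events", "total")
CONTINUOUS_COLUMNS = ("study", "arm", "treatment", "covariate", "mean", "sd", "n")
CONTRAST_COLUMNS = ("study", "covariate", "base_treatment", "treatment", "effect", "se")
COVARIANCE_COLUMNS = ("study", "treat_j", "treat_k", "cov")


@dataclass(frozen=True)
class ArmRecord:
    """One randomised arm of one trial.

    Binary outcomes carry ``events``/``total``; continuous outcomes carry
    ``mean``/``sd``/``n``.  The covariate is a study-level value repeated on
    every arm of the study.
    """

    study_id: str
    arm_index: int
    treatment: str
    covariate: float
    events: int | None = None
    total: int | None = None
    mean: float | None = None
    sd: float | None = None
    n: int | None = None


@dataclass
class StudyContrasts:
    """Contrasts of one study versus its baseline (arm-1) treatment.

    ``y[j]`` is the observed effect of ``treatments[j]`` versus ``baseline``
    on the analysis scale, and ``cov`` is the within-study covariance block
    (diagonal = the contrast variances; off-diagonals arise from the shared
    baseline arm in multi-arm trials).
    """

    study_id: str
    baseline: str
    treatments: list[str]
    y: np.ndarray
    cov: np.ndarray
    covariate: float

    @property
    def n_contrasts(self) -> int:
        return len(self.treatments)

    def validate(self) -> None:
        m = self.n_contrasts
        if self.cov.shape != (m, m):
            raise ValidationError(
                f"study {self.study_id}: covariance block is {self.cov.shape}, "
                f"expected ({m}, {m})"
            )
        if not np.allclose(self.cov, self.cov.T):
            raise ValidationError(f"study {self.study_id}: covariance block not symmetric")
        eigvals = np.linalg.eigvalsh(self.cov)
        if eigvals.min() <= 0:
            raise ValidationError(
                f"study {self.study_id}: covariance block not positive definite "
                f"(min eigenvalue {eigvals.min():.3g})"
            )


@dataclass
class ContrastDataset:
    """A network of studies on the contrast (normal-approximation) scale."""

    studies: list[StudyContrasts]
    covariate_center: float = 0.0

    @property
    def treatments(self) -> list[str]:
        seen: set[str] = set()
        for s in self.studies:
            seen.add(s.baseline)
            seen.update(s.treatments)
        return sorted(seen)

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    def study(self, study_id: str) -> StudyContrasts:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)

    def covariates(self, original_scale: bool = False) -> dict[str, float]:
        """Covariate per study; optionally decentred back to the raw scale."""
        shift = self.covariate_center if original_scale else 0.0
        return {s.study_id: s.covariate + shift for s in self.studies}

    def validate(self) -> None:
        for s in self.studies:
            s.validate()


@dataclass
class NetworkSummary:
    """Treatments, direct-comparison edges and per-edge covariate ranges."""

    treatments: list[str]
    edges: list[tuple[tuple[str, str], int]]
    connected: bool
    covariate_range: dict[tuple[str, str], tuple[float, float]]


# ---------------------------------------------------------------------------
# arm-level input


def read_arm_table(
    path, outcome_kind: str, sep: str = ","
) -> list[ArmRecord]:
    """Read an arm-level table and validate it into :class:`ArmRecord` rows.

    Studies with a missing covariate are dropped with a logged warning.
    Records are returned grouped by study and ordered by arm index.
    """
    if outcome_kind == "binary":
        required = BINARY_COLUMNS
    elif outcome_kind == "continuous":
        required = CONTINUOUS_COLUMNS
    else:
        raise ValueError(f"outcome_kind must be 'binary' or 'continuous', got {outcome_kind!r}")

    df = pd.read_csv(path, sep=sep, comment="#")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} for {outcome_kind} outcome")

    df["study"] = df["study"].astype(str)
    dupes = df.duplicated(subset=["study", "arm"], keep=False)
    if dupes.any():
        bad = df.loc[dupes, ["study", "arm"]].drop_duplicates().values.tolist()
        raise ValidationError(f"duplicate (study, arm) rows: {bad}")

    records: list[ArmRecord] = []
    for study_id, grp in df.groupby("study", sort=True):
        grp = grp.sort_values("arm")
        cov_vals = grp["covariate"]
        if cov_vals.isna().any():
            logger.warning("study %s dropped: missing covariate value", study_id)
            continue
        if cov_vals.nunique() > 1:
            raise ValidationError(
                f"study {study_id}: covariate varies within the study "
                f"({sorted(cov_vals.unique())})"
            )
        if 1 not in set(grp["arm"].astype(int)):
            raise ValidationError(f"study {study_id}: arm 1 missing")
        treatments = grp["treatment"].astype(str)
        if treatments.nunique() < len(grp):
            raise ValidationError(f"study {study_id}: repeated treatment within the study")
        for _, row in grp.iterrows():
            if outcome_kind == "binary":
                events, total = int(row["events"]), int(row["total"])
                if events < 0 or total <= 0:
                    raise ValidationError(
                        f"study {study_id} arm {int(row['arm'])}: "
                        f"events must be >=0 and total >0"
                    )
                if events > total:
                    raise ValidationError(
                        f"study {study_id} arm {int(row['arm'])}: events ({events}) "
                        f"> total ({total})"
                    )
                rec = ArmRecord(
                    study_id=str(study_id),
                    arm_index=int(row["arm"]),
                    treatment=str(row["treatment"]),
                    covariate=float(row["covariate"]),
                    events=events,
                    total=total,
                )
            else:
                sd, n = float(row["sd"]), int(row["n"])
                if sd <= 0:
                    raise ValidationError(f"study {study_id} arm {int(row['arm'])}: sd <= 0")
                if n < 2:
                    raise ValidationError(f"study {study_id} arm {int(row['arm'])}: n < 2")
                rec = ArmRecord(
                    study_id=str(study_id),
                    arm_index=int(row["arm"]),
                    treatment=str(row["treatment"]),
                    covariate=float(row["covariate"]),
                    mean=float(row["mean"]),
                    sd=sd,
                    n=n,
                )
            records.append(rec)
    return records


def _group_by_study(arms: Iterable[ArmRecord]) -> dict[str, list[ArmRecord]]:
    grouped: dict[str, list[ArmRecord]] = {}
    for rec in arms:
        grouped.setdefault(rec.study_id, []).append(rec)
    for study_id, recs in grouped.items():
        recs.sort(key=lambda r: r.arm_index)
        if recs[0].arm_index != 1:
            raise ValidationError(f"study {study_id}: arm 1 missing")
    return grouped


# ---------------------------------------------------------------------------
# contrast construction


def contrasts_from_binary(
    arms: Iterable[ArmRecord], correction: float = 0.5
) -> ContrastDataset:
    """Log odds ratios versus the baseline arm, with shared-arm covariances.

    For arm k with events a_k out of n_k, the contrast versus arm 1 is
    ``log odds(k) - log odds(1)`` with variance the sum of the four reciprocal
    cell counts; two contrasts of the same study share the baseline-arm
    component ``1/a_1 + 1/(n_1 - a_1)`` as their covariance.  If any cell of a
    study is zero, ``correction`` is added to every cell of that study
    (Haldane–Anscombe, default 0.5) before computing.
    """
    if correction < 0:
        raise ValueError("correction must be >= 0")
    studies: list[StudyContrasts] = []
    for study_id, recs in _group_by_study(arms).items():
        for r in recs:
            if r.events is None or r.total is None:
                raise ValidationError(f"study {study_id}: missing binary outcome fields")
        a = np.array([r.events for r in recs], dtype=float)
        n = np.array([r.total for r in recs], dtype=float)
        cells = np.concatenate([a, n - a])
        if np.any(cells == 0):
            if correction == 0:
                raise DegenerateCellError(
                    f"study {study_id}: zero cell with correction=0 "
                    f"(log odds undefined)"
                )
            a = a + correction
            n = n + 2 * correction
        logodds = np.log(a / (n - a))
        recip = 1.0 / a + 1.0 / (n - a)
        m = len(recs) - 1
        y = logodds[1:] - logodds[0]
        cov = np.full((m, m), recip[0])
        cov[np.diag_indices(m)] = recip[0] + recip[1:]
        studies.append(
            StudyContrasts(
                study_id=study_id,
                baseline=recs[0].treatment,
                treatments=[r.treatment for r in recs[1:]],
                y=y,
                cov=cov,
                covariate=recs[0].covariate,
            )
        )
    ds = ContrastDataset(studies=studies)
    ds.validate()
    return ds


def contrasts_from_continuous(
    arms: Iterable[ArmRecord], hedges_correction: bool = True
) -> ContrastDataset:
    """Standardised mean differences versus the baseline arm.

    Standardisation uses the SD pooled across all arms of the study.  With
    ``hedges_correction`` the small-sample factor J = 1 - 3/(4*df - 1) is
    applied (df = N_study - #arms); variances and covariances are scaled by
    J^2 accordingly.  The variance of contrast k is ``1/n_1 + 1/n_k +
    y_k^2/(2N)`` and the covariance of two contrasts sharing the baseline arm
    is ``1/n_1 + y_j*y_k/(2N)`` with N the total study sample size.
    """
    studies: list[StudyContrasts] = []
    for study_id, recs in _group_by_study(arms).items():
        for r in recs:
            if r.mean is None or r.sd is None or r.n is None:
                raise ValidationError(f"study {study_id}: missing continuous outcome fields")
            if r.sd <= 0:
                raise ValidationError(f"study {study_id}: sd <= 0")
        means = np.array([r.mean for r in recs], dtype=float)
        sds = np.array([r.sd for r in recs], dtype=float)
        ns = np.array([r.n for r in recs], dtype=float)
        N = ns.sum()
        df_pool = N - len(recs)
        s_pooled = math.sqrt(float(((ns - 1) * sds**2).sum() / df_pool))
        d = (means[1:] - means[0]) / s_pooled
        m = len(recs) - 1
        cov = np.empty((m, m))
        for j in range(m):
            for k in range(m):
                if j == k:
                    cov[j, k] = 1.0 / ns[0] + 1.0 / ns[j + 1] + d[j] ** 2 / (2 * N)
                else:
                    cov[j, k] = 1.0 / ns[0] + d[j] * d[k] / (2 * N)
        if hedges_correction:
            J = 1.0 - 3.0 / (4.0 * df_pool - 1.0)
            d = J * d
            cov = J**2 * cov
        studies.append(
            StudyContrasts(
                study_id=study_id,
                baseline=recs[0].treatment,
                treatments=[r.treatment for r in recs[1:]],
                y=d,
                cov=cov,
                covariate=recs[0].covariate,
            )
        )
    ds = ContrastDataset(studies=studies)
    ds.validate()
    return ds


def center_covariate(data: ContrastDataset, center: str | float = "mean") -> ContrastDataset:
    """Subtract ``center`` (or the mean covariate) from every study covariate.

    The accumulated shift is recorded in ``covariate_center`` so results can
    be mapped back to the original covariate scale; effects are unchanged.
    """
    if center == "mean":
        shift = float(np.mean([s.covariate for s in data.studies]))
    else:
        shift = float(center)
    studies = [replace(s, covariate=s.covariate - shift) for s in data.studies]
    return ContrastDataset(studies=studies, covariate_center=data.covariate_center + shift)


def summarize_network(data: ContrastDataset) -> NetworkSummary:
    """Edges (with direct-study counts), connectivity and covariate ranges.

    A study provides direct evidence on every pair of treatments it
    randomises, so a 3-arm trial contributes to three edges.
    """
    if not data.studies:
        raise ValidationError("empty dataset")
    graph = nx.Graph()
    graph.add_nodes_from(data.treatments)
    counts: dict[tuple[str, str], int] = {}
    cov_range: dict[tuple[str, str], tuple[float, float]] = {}
    for s in data.studies:
        all_arms = [s.baseline] + list(s.treatments)
        c = s.covariate + data.covariate_center
        for t1, t2 in itertools.combinations(sorted(all_arms), 2):
            edge = (t1, t2)
            counts[edge] = counts.get(edge, 0) + 1
            lo, hi = cov_range.get(edge, (math.inf, -math.inf))
            cov_range[edge] = (min(lo, c), max(hi, c))
            graph.add_edge(t1, t2)
    return NetworkSummary(
        treatments=data.treatments,
        edges=sorted(counts.items()),
        connected=nx.is_connected(graph),
        covariate_range=cov_range,
    )


# ---------------------------------------------------------------------------
# contrast-level I/O (long format, one row per contrast)


def write_contrast_table(data: ContrastDataset, path, cov_path=None, sep: str = ",") -> None:
    """Write a dataset in the long contrast dialect at full double precision.

    Multi-arm off-diagonal covariances go to ``cov_path``; omitting it for a
    dataset that has them would silently lose information, so that is an error.
    """
    rows = []
    cov_rows = []
    for s in data.studies:
        for j, t in enumerate(s.treatments):
            rows.append(
                {
                    "study": s.study_id,
                    "covariate": repr(s.covariate),
                    "base_treatment": s.baseline,
                    "treatment": t,
                    "effect": repr(float(s.y[j])),
                    "se": repr(math.sqrt(float(s.cov[j, j]))),
                }
            )
        if cov_path is not None or s.n_contrasts > 1:
            # diagonal rows carry the exact variances (se alone loses one ulp
            # in the sqrt/square round trip)
            for j in range(s.n_contrasts):
                for k in range(j, s.n_contrasts):
                    cov_rows.append(
                        {
                            "study": s.study_id,
                            "treat_j": s.treatments[j],
                            "treat_k": s.treatments[k],
                            "cov": repr(float(s.cov[j, k])),
                        }
                    )
    if cov_rows and cov_path is None:
        raise ValidationError(
            "dataset has multi-arm covariances; a cov_path is required to write them"
        )
    with open(path, "w") as fh:
        fh.write(f"# covariate_center={data.covariate_center!r}\n")
        pd.DataFrame(rows, columns=list(CONTRAST_COLUMNS)).to_csv(fh, sep=sep, index=False)
    if cov_path is not None:
        pd.DataFrame(cov_rows, columns=list(COVARIANCE_COLUMNS)).to_csv(
            cov_path, sep=sep, index=False
        )


def read_contrast_table(path, cov_path=None, sep: str = ",") -> ContrastDataset:
    """Read the long contrast dialect written by :func:`write_contrast_table`."""
    center = 0.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# covariate_center="):
            center = float(first.split("=", 1)[1])
    df = pd.read_csv(path, sep=sep, comment="#")
    for col in CONTRAST_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in contrast table")
    df["study"] = df["study"].astype(str)

    cov_df = None
    if cov_path is not None:
        cov_df = pd.read_csv(cov_path, sep=sep, comment="#")
        for col in COVARIANCE_COLUMNS:
            if col not in cov_df.columns:
                raise SchemaError(f"missing required column {col!r} in covariance table")
        cov_df["study"] = cov_df["study"].astype(str)

    studies = []
    for study_id, grp in df.groupby("study", sort=True):
        bases = grp["base_treatment"].astype(str).unique()
        if len(bases) > 1:
            raise ValidationError(f"study {study_id}: multiple baseline treatments {list(bases)}")
        covs = grp["covariate"].astype(float).unique()
        if len(covs) > 1:
            raise ValidationError(f"study {study_id}: covariate varies within the study")
        treatments = [str(t) for t in grp["treatment"]]
        y = grp["effect"].astype(float).to_numpy()
        se = grp["se"].astype(float).to_numpy()
        cov = np.diag(se**2)
        if cov_df is not None:
            idx = {t: i for i, t in enumerate(treatments)}
            for _, row in cov_df[cov_df["study"] == study_id].iterrows():
                j, k = idx[str(row["treat_j"])], idx[str(row["treat_k"])]
                cov[j, k] = cov[k, j] = float(row["cov"])
        studies.append(
            StudyContrasts(
                study_id=str(study_id),
                baseline=str(bases[0]),
                treatments=treatments,
                y=y,
                cov=cov,
                covariate=float(covs[0]),
            )
        )
    ds = ContrastDataset(studies=studies, covariate_center=center)
    ds.validate()
    return ds
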