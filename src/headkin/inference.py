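"""Group x task inference on per-participant task modes.

The response for participant *i* (group *g*) on task *t* is the histogram
mode of the angular-velocity-norm (deg/s) or angular-acceleration-norm
(deg/s^2) distribution.  It is modelled with a linear mixed-effects model

    y_ij = alpha + alpha_i + beta1 * group_g + beta2 * task_t
           + beta3 * (group_g x task_t) + eps_ij

with a random intercept ``alpha_i`` per participant, treatment coding with
healthy subjects (HS) and the Walk task as reference levels, and REML
estimation of the two variance components (random-intercept variance
``sigma_a^2`` and residual variance ``sigma_e^2``).

Because tasks repeat within participants, standard errors use the
Huber-White cluster-robust sandwich with clustering by participant.  Two
small-sample flavours are provided:

* ``cr0`` — the plain sandwich;
* ``cr2`` (default) — the bias-reduced adjustment that rescales each
  cluster's residuals so the sandwich is exactly unbiased under the fitted
  working covariance (the generalization of the Bell-McCaffrey HC2
  adjustment to weighted/correlated data).

Degrees of freedom per coefficient use Satterthwaite's approximation: the
robust variance estimator is a quadratic form in the data, and its first
two moments under the working model yield ``df = (tr G)^2 / tr(G^2)``.
A model-based covariance (the REML GLS covariance, with Satterthwaite df
from the variance-component delta method, as in lmerTest) is available via
``vcov="model"``.

Effect sizes are summarized as Delta-percent, the coefficient's relative
change against the reference-cell intercept: ``100 * (beta - alpha)/alpha``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

from .errors import (
    ConvergenceError,
    DegenerateInputError,
    InferenceError,
    IntegrityError,
    ParameterError,
    RankError,
    UndefinedCorrelationError,
)
from .imu_io import DifficultyRating, Group, Rating, Task
from .vestibulogram import TaskModeRecord

__all__ = [
    "ObservationTable",
    "Design",
    "MixedModelFit",
    "assemble_observations",
    "build_design",
    "fit_mixed_model",
    "cluster_robust_vcov",
    "satterthwaite_inference",
    "inference_table",
    "delta_percent",
    "mode_correlation",
    "difficulty_correlation",
    "RATING_SCORES",
]

MEASURES = ("angular_velocity", "angular_acceleration")

#: Numeric coding of difficulty ratings; "unable" is excluded from analysis.
RATING_SCORES = {Rating.EASY: 1, Rating.MEDIUM: 2, Rating.DIFFICULT: 3}


# ---------------------------------------------------------------------------
# Observation assembly and design construction
# ---------------------------------------------------------------------------

@dataclass
class ObservationTable:
    """Long-format response table: one row per (participant, task)."""

    measure: str
    frame: pd.DataFrame  # columns: participant_id, group, task, response

    def __len__(self) -> int:
        return len(self.frame)


def assemble_observations(
    records: Iterable[TaskModeRecord], measure: str
) -> ObservationTable:
    """Build the long-format table from per-participant task-mode records.

    Participants with missing tasks are simply absent from those rows; the
    design stays unbalanced, as in the real cohort.
    """
    if measure not in MEASURES:
        raise ParameterError(f"measure must be one of {MEASURES}, got {measure!r}")
    records = list(records)
    if not records:
        raise DegenerateInputError("no task-mode records to assemble")
    seen: dict[tuple[str, Task], float] = {}
    rows = []
    for r in records:
        resp = r.mode_velocity if measure == "angular_velocity" else r.mode_acceleration
        key = (r.participant_id, r.task)
        if key in seen:
            if seen[key] != resp:
                raise IntegrityError(
                    f"conflicting duplicate observation for {key[0]!r}/{key[1].value!r}"
                )
            continue
        seen[key] = resp
        rows.append(
            {
                "participant_id": r.participant_id,
                "group": r.group.value,
                "task": r.task.value,
                "response": float(resp),
            }
        )
    return ObservationTable(measure=measure, frame=pd.DataFrame(rows))


@dataclass
class Design:
    """Fixed-effects design, response and cluster ids for one measure."""

    X: pd.DataFrame  # n x p, documented stable column order
    y: np.ndarray
    clusters: np.ndarray  # participant id per row
    ref_group: Group
    ref_task: Task
    measure: str = ""

    @property
    def terms(self) -> list[str]:
        return list(self.X.columns)


def build_design(
    table: ObservationTable,
    ref_group: Group = Group.HS,
    ref_task: Task = Task.WALK,
) -> Design:
    """Treatment-coded design with interactions; HS / Walk as references.

    Column order (stable): intercept; group main effects in enum order
    (BV, UV) minus the reference; task main effects in enum order minus the
    reference; then one interaction block per non-reference task, each with
    the non-reference groups in enum order (mirroring how the result table
    is laid out).
    """
    frame = table.frame
    groups_present = set(frame["group"])
    tasks_present = set(frame["task"])
    if ref_group.value not in groups_present:
        raise ParameterError(f"reference group {ref_group.value} absent from data")
    if ref_task.value not in tasks_present:
        raise ParameterError(f"reference task {ref_task.value} absent from data")
    if len(groups_present) < 2 or len(tasks_present) < 2:
        raise ParameterError("need at least 2 groups and 2 tasks to build the design")

    group_levels = [g for g in Group if g is not ref_group and g.value in groups_present]
    task_levels = [t for t in Task if t is not ref_task and t.value in tasks_present]

    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(frame))}
    for g in group_levels:
        cols[f"group[{g.value}]"] = (frame["group"] == g.value).to_numpy(float)
    for t in task_levels:
        cols[f"task[{t.value}]"] = (frame["task"] == t.value).to_numpy(float)
    for t in task_levels:
        for g in group_levels:
            cols[f"group[{g.value}]:task[{t.value}]"] = (
                cols[f"group[{g.value}]"] * cols[f"task[{t.value}]"]
            )
    X = pd.DataFrame(cols, index=frame.index)
    return Design(
        X=X,
        y=frame["response"].to_numpy(float),
        clusters=frame["participant_id"].to_numpy(),
        ref_group=ref_group,
        ref_task=ref_task,
        measure=table.measure,
    )


# ---------------------------------------------------------------------------
# REML mixed-model fit
# ---------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    """REML estimates and everything the sandwich/inference stages need."""

    design: Design
    params: pd.Series  # fixed effects, indexed by term
    random_intercept_variance: float
    residual_variance: float
    loglike: float  # restricted log-likelihood
    converged: bool
    residuals: np.ndarray = field(repr=False)  # marginal residuals y - X beta
    model_vcov: np.ndarray = field(repr=False)  # GLS covariance (X' V^-1 X)^-1

    @property
    def measure(self) -> str:
        return self.design.measure

    def cluster_index(self) -> list[np.ndarray]:
        """Row indices per cluster, in order of first appearance."""
        ids = pd.Series(self.design.clusters)
        order = ids.drop_duplicates().tolist()
        return [np.flatnonzero((ids == c).to_numpy()) for c in order]


def _phi_blocks(fit_or_vars, cluster_sizes: Sequence[int]):
    """Working covariance blocks sigma_a^2 J + sigma_e^2 I per cluster."""
    sa2, se2 = fit_or_vars
    return [sa2 * np.ones((n, n)) + se2 * np.eye(n) for n in cluster_sizes]


def _gls_pieces(X: np.ndarray, idx: list[np.ndarray], sa2: float, se2: float):
    """Per-cluster W_c = Phi_c^-1 and the GLS information M = (X'WX)^-1."""
    W_blocks = []
    info = np.zeros((X.shape[1], X.shape[1]))
    for rows in idx:
        n = len(rows)
        # closed-form inverse of sigma_a^2 J + sigma_e^2 I
        shrink = sa2 / (se2 + n * sa2) if (se2 + n * sa2) > 0 else 0.0
        W = (np.eye(n) - shrink * np.ones((n, n))) / se2
        W_blocks.append(W)
        Xc = X[rows]
        info += Xc.T @ W @ Xc
    M = np.linalg.inv(info)
    return W_blocks, M


def fit_mixed_model(design: Design) -> MixedModelFit:
    """Fit the random-intercept model by REML.

    Fixed-effect and variance-component estimation delegates to
    ``statsmodels`` MixedLM; the contract is on the returned estimates.  If
    no participant has two observations the random intercept is not
    identifiable and the fit falls back to a residual-only (OLS) model with
    a warning.
    """
    X = design.X.to_numpy(float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise RankError("fixed-effects design is rank deficient")

    counts = pd.Series(design.clusters).value_counts()
    if (counts < 2).all():
        warnings.warn(
            "no participant has repeated observations; falling back to a "
            "residual-only (OLS) fit with zero random-intercept variance",
            stacklevel=2,
        )
        ols = sm.OLS(design.y, X).fit()
        resid = design.y - X @ ols.params
        sa2, se2 = 0.0, float(ols.scale)
        _, M = _gls_pieces(X, [np.array([i]) for i in range(n)], sa2, se2)
        return MixedModelFit(
            design=design,
            params=pd.Series(ols.params, index=design.terms),
            random_intercept_variance=sa2,
            residual_variance=se2,
            loglike=float(ols.llf),
            converged=True,
            residuals=resid,
            model_vcov=M,
        )

    result = None
    last_exc: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(design.y, X, groups=design.clusters)
        for method in (None, "powell", "nm"):
            try:
                candidate = (
                    model.fit(reml=True)
                    if method is None
                    else model.fit(reml=True, method=method)
                )
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if candidate.converged:
                result = candidate
                break
    if result is None:
        raise ConvergenceError(f"REML estimation did not converge ({last_exc})")
    beta = pd.Series(np.asarray(result.fe_params, float), index=design.terms)
    sa2 = float(np.asarray(result.cov_re)[0, 0])
    se2 = float(result.scale)
    resid = design.y - X @ beta.to_numpy()

    fit = MixedModelFit(
        design=design,
        params=beta,
        random_intercept_variance=sa2,
        residual_variance=se2,
        loglike=float(result.llf),
        converged=True,
        residuals=resid,
        model_vcov=np.zeros((p, p)),
    )
    if se2 > 0:  # degenerate zero-noise interpolation keeps a zero covariance
        _, M = _gls_pieces(X, fit.cluster_index(), sa2, se2)
        fit.model_vcov = M
    return fit


# ---------------------------------------------------------------------------
# Cluster-robust covariance and Satterthwaite inference
# ---------------------------------------------------------------------------

def _sym_inv_sqrt(A: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Symmetric pseudo-inverse square root (eigenvalues below rtol dropped)."""
    vals, vecs = np.linalg.eigh((A + A.T) / 2.0)
    cut = rtol * max(vals.max(), 1.0)
    inv_sqrt = np.where(vals > cut, 1.0 / np.sqrt(np.clip(vals, cut, None)), 0.0)
    return (vecs * inv_sqrt) @ vecs.T


def _sym_sqrt(A: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((A + A.T) / 2.0)
    return (vecs * np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T


def _sandwich_pieces(fit: MixedModelFit, kind: str):
    """Per-cluster matrices shared by the sandwich and the df computation.

    Returns (idx, X, M, and per-cluster adjusted weight matrices
    U_c = A_c' W_c for cr2 or W_c for cr0, plus Phi blocks).
    """
    if kind not in ("cr0", "cr2"):
        raise ParameterError(f"robust kind must be 'cr0' or 'cr2', got {kind!r}")
    idx = fit.cluster_index()
    if len(idx) < 2:
        raise DegenerateInputError("cluster-robust variance needs >= 2 clusters")
    X = fit.design.X.to_numpy(float)
    sa2, se2 = fit.random_intercept_variance, fit.residual_variance
    if se2 <= 0:
        raise InferenceError("non-positive residual variance estimate")
    W_blocks, M = _gls_pieces(X, idx, sa2, se2)
    phi_blocks = _phi_blocks((sa2, se2), [len(r) for r in idx])
    U_blocks = []
    for rows, W, Phi in zip(idx, W_blocks, phi_blocks):
        if kind == "cr0":
            U_blocks.append(W)
            continue
        Xc = X[rows]
        phi_sqrt = _sym_sqrt(Phi)
        phi_inv_sqrt = _sym_inv_sqrt(Phi)
        B = phi_inv_sqrt @ (Phi - Xc @ M @ Xc.T) @ phi_inv_sqrt
        A = phi_sqrt @ _sym_inv_sqrt(B) @ phi_inv_sqrt
        U_blocks.append(A.T @ W)
    return idx, X, M, U_blocks, phi_blocks


def cluster_robust_vcov(fit: MixedModelFit, kind: str = "cr2") -> np.ndarray:
    """Huber-White sandwich for the fixed effects, clustered by participant.

    ``cr2`` rescales each cluster's residuals by the symmetric adjustment
    A_c satisfying A_c (Phi_c - X_c M X_c') A_c' = Phi_c, which makes the
    estimator unbiased when the working covariance is correct; ``cr0`` is
    the unadjusted sandwich.
    """
    idx, X, M, U_blocks, _ = _sandwich_pieces(fit, kind)
    p = X.shape[1]
    meat = np.zeros((p, p))
    for rows, U in zip(idx, U_blocks):
        v = X[rows].T @ (U.T @ fit.residuals[rows])
        meat += np.outer(v, v)
    V = M @ meat @ M
    return (V + V.T) / 2.0


def _satterthwaite_df_robust(fit: MixedModelFit, kind: str) -> np.ndarray:
    """Satterthwaite df per coefficient for the cr0/cr2 sandwich.

    The estimator for coefficient l is sum_c (p_c' e_c)^2 with
    p_c = U_c' X_c M e_l.  Writing it as a quadratic form in the data under
    the working covariance Phi gives first/second moments tr(G), 2 tr(G^2)
    with G_{cd} = delta_cd p_c' Phi_c p_c - r_c' M r_d, r_c = X_c' p_c;
    hence df = tr(G)^2 / tr(G^2).
    """
    idx, X, M, U_blocks, phi_blocks = _sandwich_pieces(fit, kind)
    p = X.shape[1]
    C = len(idx)
    dfs = np.empty(p)
    for ell in range(p):
        Ml = M[:, ell]
        d = np.empty(C)
        R = np.empty((C, p))
        for c, (rows, U, Phi) in enumerate(zip(idx, U_blocks, phi_blocks)):
            Xc = X[rows]
            pc = U @ (Xc @ Ml)
            d[c] = pc @ Phi @ pc
            R[c] = Xc.T @ pc
        G = np.diag(d) - R @ M @ R.T
        tr = np.trace(G)
        tr2 = np.sum(G * G.T)
        if tr2 <= 0:
            raise InferenceError("degenerate Satterthwaite quadratic form")
        dfs[ell] = tr**2 / tr2
    return dfs


def _reml_loglik(fit: MixedModelFit, sa2: float, se2: float) -> float:
    """Restricted log-likelihood of the random-intercept model at (sa2, se2)."""
    sa2 = max(sa2, 0.0)
    X = fit.design.X.to_numpy(float)
    y = fit.design.y
    idx = fit.cluster_index()
    p = X.shape[1]
    W_blocks, M = _gls_pieces(X, idx, sa2, se2)
    Xty = np.zeros(p)
    for rows, W in zip(idx, W_blocks):
        Xty += X[rows].T @ W @ y[rows]
    beta = M @ Xty
    ll = 0.0
    for rows, W in zip(idx, W_blocks):
        r = y[rows] - X[rows] @ beta
        n = len(rows)
        logdet = (n - 1) * np.log(se2) + np.log(se2 + n * sa2)
        ll += -0.5 * (logdet + r @ W @ r)
    sign, logdet_info = np.linalg.slogdet(np.linalg.inv(M))
    ll += -0.5 * logdet_info - 0.5 * (len(y) - p) * np.log(2 * np.pi)
    return ll


def _satterthwaite_df_model(fit: MixedModelFit) -> np.ndarray:
    """Model-based Satterthwaite df via the variance-component delta method.

    df_l = 2 f^2 / (g' Sigma_theta g) with f = [M(theta)]_ll, g its gradient
    in theta = (sa2, se2), and Sigma_theta the inverse negative REML Hessian.
    """
    X = fit.design.X.to_numpy(float)
    idx = fit.cluster_index()
    sa2, se2 = fit.random_intercept_variance, fit.residual_variance
    h = np.array([max(sa2, se2) * 1e-4, se2 * 1e-4])

    def vdiag(theta):
        _, M = _gls_pieces(X, idx, max(theta[0], 0.0), theta[1])
        return np.diag(M)

    theta0 = np.array([sa2, se2])
    grads = []
    for j in range(2):
        e = np.zeros(2)
        e[j] = h[j]
        grads.append((vdiag(theta0 + e) - vdiag(theta0 - e)) / (2 * h[j]))
    Gmat = np.column_stack(grads)  # p x 2

    H = np.zeros((2, 2))
    for j in range(2):
        for k in range(j, 2):
            ej, ek = np.zeros(2), np.zeros(2)
            ej[j], ek[k] = h[j], h[k]
            fpp = _reml_loglik(fit, *(theta0 + ej + ek))
            fpm = _reml_loglik(fit, *(theta0 + ej - ek))
            fmp = _reml_loglik(fit, *(theta0 - ej + ek))
            fmm = _reml_loglik(fit, *(theta0 - ej - ek))
            H[j, k] = H[k, j] = (fpp - fpm - fmp + fmm) / (4 * h[j] * h[k])
    try:
        sigma_theta = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        sigma_theta = np.linalg.pinv(-H)
    f = vdiag(theta0)
    denom = np.einsum("pj,jk,pk->p", Gmat, sigma_theta, Gmat)
    denom = np.where(denom > 0, denom, np.inf)
    dfs = 2 * f**2 / denom
    # guard against numerical blow-ups; df cannot be below 1
    return np.clip(dfs, 1.0, None)


def satterthwaite_inference(
    fit: MixedModelFit, vcov: str | np.ndarray = "cr2", alpha: float = 0.05
) -> pd.DataFrame:
    """Per-coefficient estimate, SE, Satterthwaite df, t, p and CI.

    ``vcov`` selects the covariance: "cr2" (default) or "cr0" for the
    cluster-robust sandwich with matched quadratic-form df, or "model" for
    the REML GLS covariance with variance-component delta-method df.  A
    precomputed covariance matrix may be passed with "cr2"-style df.
    """
    if isinstance(vcov, str):
        if vcov in ("cr0", "cr2"):
            V = cluster_robust_vcov(fit, vcov)
            dfs = _satterthwaite_df_robust(fit, vcov)
        elif vcov == "model":
            V = fit.model_vcov
            dfs = _satterthwaite_df_model(fit)
        else:
            raise ParameterError(f"unknown vcov kind {vcov!r}")
    else:
        V = np.asarray(vcov, float)
        dfs = _satterthwaite_df_robust(fit, "cr2")
    se = np.sqrt(np.diag(V))
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise InferenceError("non-positive coefficient variance estimate")
    est = fit.params.to_numpy()
    t = est / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dfs)
    tcrit = stats.t.ppf(1 - alpha / 2.0, dfs)
    return pd.DataFrame(
        {
            "term": fit.design.terms,
            "estimate": est,
            "se": se,
            "df": dfs,
            "t": t,
            "p": pvals,
            "ci_low": est - tcrit * se,
            "ci_high": est + tcrit * se,
        }
    ).set_index("term")


def delta_percent(intercept: float, estimate: float) -> float:
    """Relative change of a coefficient against the reference-cell intercept.

    ``100 * (estimate - intercept) / intercept``, reported to one decimal.
    """
    if intercept == 0:
        raise ParameterError("delta-percent is undefined for a zero intercept")
    return round(100.0 * (estimate - intercept) / intercept, 1)


def inference_table(
    fit: MixedModelFit, vcov: str = "cr2", alpha: float = 0.05
) -> pd.DataFrame:
    """Result table: term, estimate, robust SE, CI, df, p, Delta-percent.

    The intercept row carries no Delta (it is the reference itself).
    """
    table = satterthwaite_inference(fit, vcov, alpha)
    icept = float(fit.params.iloc[0])
    deltas = [
        np.nan if term == "Intercept" else delta_percent(icept, est)
        for term, est in zip(table.index, table["estimate"])
    ]
    table = table.copy()
    table["delta_percent"] = deltas
    return table


# ---------------------------------------------------------------------------
# Correlation analyses
# ---------------------------------------------------------------------------

def mode_correlation(records: Iterable[TaskModeRecord], group: Group) -> float:
    """Pearson r between velocity and acceleration modes within a group."""
    recs = [r for r in records if r.group is group]
    if len(recs) < 3:
        raise DegenerateInputError("need at least 3 records for a correlation")
    v = np.array([r.mode_velocity for r in recs])
    a = np.array([r.mode_acceleration for r in recs])
    if np.ptp(v) == 0 or np.ptp(a) == 0:
        raise UndefinedCorrelationError("zero variance in one of the variables")
    return float(stats.pearsonr(v, a).statistic)


def difficulty_correlation(
    records: Iterable[TaskModeRecord], ratings: Iterable[DifficultyRating]
) -> pd.DataFrame:
    """Spearman rho between perceived difficulty and modes, per group.

    Ratings are scored easy=1, medium=2, difficult=3; "unable" is excluded.
    Returns one row per (group, measure) with rho, p and the pair count.
    Ties are handled by mid-ranks (the standard Spearman convention).
    """
    recs = list(records)
    score = {
        (r.participant_id, r.task): RATING_SCORES[r.rating]
        for r in ratings
        if r.rating is not Rating.UNABLE
    }
    rows = []
    for group in Group:
        pairs = [
            (score[(r.participant_id, r.task)], r.mode_velocity, r.mode_acceleration)
            for r in recs
            if r.group is group and (r.participant_id, r.task) in score
        ]
        if len(pairs) < 3:
            raise DegenerateInputError(
                f"fewer than 3 rated observations in group {group.value}"
            )
        s = np.array([p[0] for p in pairs], float)
        if np.ptp(s) == 0:
            raise UndefinedCorrelationError(
                f"all ratings identical in group {group.value}"
            )
        for measure, col in (("angular_velocity", 1), ("angular_acceleration", 2)):
            x = np.array([p[col] for p in pairs])
            if np.ptp(x) == 0:
                raise UndefinedCorrelationError(
                    f"zero variance in {measure} modes in group {group.value}"
                )
            res = stats.spearmanr(s, x)
            rows.append(
                {
                    "group": group.value,
                    "measure": measure,
                    "rho": float(res.statistic),
                    "p": float(res.pvalue),
                    "n": len(pairs),
                }
            )
    return pd.DataFrame(rows)
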