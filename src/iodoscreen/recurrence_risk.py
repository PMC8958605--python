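"""Expression-based recurrence risk modelling.

Implements the clinical arm of the pipeline: the log2(FPKM+1) expression
transform, nonparametric differential expression with Benjamini-Hochberg
FDR control, ROC analysis with Youden-optimal cutpoints, univariate and
multivariate Cox proportional-hazards fits, the multi-gene risk score
(sum of multivariate Cox coefficients times transformed expression), and
Kaplan-Meier stratification of high- versus low-risk patients with log-rank
testing and covariate-adjusted Cox models.

Cox partial likelihoods are maximized by statsmodels' PHReg (Breslow tie
handling by default, Efron optional); Kaplan-Meier curves and log-rank
statistics come from lifelines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("iodoscreen")

COVARIATE_COLUMNS = ["age", "gender", "disease_stage", "tumor_stage", "node_status"]


def log2p1(fpkm: Union[np.ndarray, pd.DataFrame, pd.Series, float]):
    """Elementwise log2(x + 1) expression transform; rejects negatives."""
    arr = np.asarray(fpkm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("FPKM values must be >= 0")
    out = np.log2(arr + 1.0)
    if isinstance(fpkm, pd.DataFrame):
        return pd.DataFrame(out, index=fpkm.index, columns=fpkm.columns)
    if isinstance(fpkm, pd.Series):
        return pd.Series(out, index=fpkm.index, name=fpkm.name)
    if np.isscalar(fpkm):
        return float(out)
    return out


@dataclass
class DEResult:
    gene: str
    log2fc: float
    p: float
    q: float = float("nan")


def differential_expression(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    genes: Optional[Sequence[str]] = None,
    test: str = "ks",
    already_transformed: bool = False,
) -> pd.DataFrame:
    """Per-gene two-group differential expression on the log2(FPKM+1) scale.

    log2fc is mean(A) - mean(B) of transformed values; p comes from the
    two-sample Kolmogorov-Smirnov test by default (Kruskal-Wallis optional,
    for symmetry with multi-group use); q is Benjamini-Hochberg adjusted
    over all tested genes.  A gene constant across both groups gets p = 1
    by convention (logged).
    """
    genes = list(genes) if genes is not None else list(group_a.columns)
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("need >= 3 samples per group")
    a = group_a[genes] if already_transformed else log2p1(group_a[genes])
    b = group_b[genes] if already_transformed else log2p1(group_b[genes])
    rows = []
    for g in genes:
        xa, xb = a[g].to_numpy(), b[g].to_numpy()
        lfc = float(xa.mean() - xb.mean())
        pooled = np.concatenate([xa, xb])
        if np.all(pooled == pooled[0]):
            p = 1.0
            logger.info("differential_expression: gene %s constant in both "
                        "groups, p=1 by convention", g)
        elif test == "ks":
            p = float(stats.ks_2samp(xa, xb).pvalue)
        elif test == "kruskal":
            p = float(stats.kruskal(xa, xb).pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({"gene": g, "log2fc": lfc, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted q-values over one testing family."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns (odds_ratio, p) with the conditional maximum-likelihood odds
    ratio; a zero margin gives p = 1 by convention (no association testable).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return float("nan"), 1.0
    res = stats.contingency.odds_ratio(t, kind="conditional")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(res.statistic), float(p)


def roc_curve_auc(
    score: Sequence[float], event_label: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC points and AUC for a continuous score against a binary outcome.

    The AUC equals the Mann-Whitney concordance probability with tied
    scores counted one half.
    """
    y = np.asarray(event_label, dtype=bool)
    s = np.asarray(score, dtype=float)
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    return fpr, tpr, thresholds, auc


def optimal_cutpoint(score: Sequence[float], event_label: Sequence[bool]) -> float:
    """Threshold maximizing Youden's J (sensitivity + specificity - 1).

    Candidate thresholds are midpoints between consecutive distinct score
    values (plus one below the minimum); a sample is called positive when
    its score exceeds the threshold.  Ties in J break toward the lower
    threshold.
    """
    y = np.asarray(event_label, dtype=bool)
    s = np.asarray(score, dtype=float)
    if y.all() or not y.any():
        raise ValueError("optimal_cutpoint needs both classes present")
    u = np.unique(s)
    candidates = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        pred = s > t
        sens = (pred & y).sum() / n_pos
        spec = (~pred & ~y).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j:  # strict >: ties keep the lower threshold
            best_j, best_t = j, t
    return float(best_t)


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model summary."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    converged: bool
    log_likelihood: float = float("nan")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms, "beta": self.beta, "se": self.se,
            "hr": self.hr, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.p,
        })

    def __getitem__(self, term: str) -> dict:
        i = self.terms.index(term)
        return {k: getattr(self, k)[i]
                for k in ("beta", "se", "hr", "ci_low", "ci_high", "p")}


def _fit_cox(
    X: pd.DataFrame,
    time: Sequence[float],
    event: Sequence[bool],
    ties: str = "breslow",
) -> CoxFit:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if np.any(time < 0):
        raise ValueError("negative follow-up time")
    if not event.any():
        raise ValueError("Cox fit needs >= 1 event")
    model = PHReg(time, X.to_numpy(dtype=float), status=event.astype(int), ties=ties)
    converged = True
    try:
        res = model.fit(disp=False)
        beta = np.asarray(res.params, dtype=float)
        se = np.asarray(res.bse, dtype=float)
        llf = float(res.llf)
    except (np.linalg.LinAlgError, ValueError):
        logger.warning("_fit_cox: likelihood maximization failed "
                       "(possible complete separation)")
        k = X.shape[1]
        return CoxFit(list(X.columns), np.full(k, np.nan), np.full(k, np.nan),
                      np.full(k, np.nan), np.full(k, np.nan), np.full(k, np.nan),
                      np.full(k, np.nan), converged=False)
    # monotone likelihood (separation) shows up as runaway coefficients
    if np.any(~np.isfinite(beta)) or np.any(~np.isfinite(se)) or np.any(np.abs(beta) > 50):
        logger.warning("_fit_cox: monotone likelihood diagnostic — "
                       "coefficients diverged (complete separation?)")
        converged = False
    z = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):  # diverged fits overflow exp harmlessly
        hr = np.exp(beta)
        return CoxFit(
            terms=list(X.columns), beta=beta, se=se, hr=hr,
            ci_low=np.exp(beta - z * se), ci_high=np.exp(beta + z * se),
            p=2.0 * stats.norm.sf(np.abs(beta / se)),
            converged=converged, log_likelihood=llf,
        )


def cox_univariate(
    covariate: Sequence[float],
    time: Sequence[float],
    event: Sequence[bool],
    name: str = "x",
    ties: str = "breslow",
) -> CoxFit:
    """Single-covariate Cox fit (group indicator or continuous variable).

    Reports beta, SE, HR with 95% Wald CI and p.  Complete separation is
    flagged via converged=False rather than raising.
    """
    X = pd.DataFrame({name: np.asarray(covariate, dtype=float)})
    if X[name].nunique() < 2:
        raise ValueError("covariate is constant; nothing to estimate")
    return _fit_cox(X, time, event, ties=ties)


@dataclass
class RiskScoreModel:
    """Multi-gene recurrence risk score.

    score_i = sum_g beta_g * log2(FPKM_{i,g} + 1), with beta the
    multivariate Cox coefficients of the gene panel.
    """

    genes: list[str]
    beta: np.ndarray
    group_cutoff: float
    auc: float
    cox: Optional[CoxFit] = None

    @property
    def converged(self) -> bool:
        return self.cox is None or self.cox.converged

    def scores(self, cohort: pd.DataFrame, already_transformed: bool = False) -> pd.Series:
        x = cohort[self.genes]
        if not already_transformed:
            x = log2p1(x)
        return pd.Series(x.to_numpy() @ self.beta, index=cohort.index, name="risk_score")

    def to_dict(self) -> dict:
        return {"genes": self.genes, "beta": [float(b) for b in self.beta],
                "group_cutoff": float(self.group_cutoff), "auc": float(self.auc)}


def build_risk_model(
    cohort: pd.DataFrame,
    genes: Sequence[str],
    ties: str = "breslow",
    forced_beta: Optional[Mapping[str, float]] = None,
) -> RiskScoreModel:
    """Fit the multi-gene risk model on a cohort.

    Runs a multivariate Cox fit on the transformed expression of all listed
    genes jointly, scores every patient, sets the default group cutoff at
    the median score, and records the score's ROC AUC against the event
    indicator.  ``forced_beta`` bypasses fitting (fixed coefficients), which
    is useful for scoring with an externally fitted model.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in cohort.columns]
    if missing:
        raise ValueError(f"genes absent from cohort: {missing}")
    n_events = int(cohort["event"].sum())
    if n_events < len(genes):
        logger.warning("build_risk_model: only %d events for %d genes; "
                       "coefficients will be unstable", n_events, len(genes))
    x = log2p1(cohort[genes])
    if forced_beta is not None:
        beta = np.array([forced_beta.get(g, 0.0) for g in genes], dtype=float)
        cox = None
    else:
        cox = _fit_cox(x, cohort["time"], cohort["event"], ties=ties)
        if not cox.converged:
            logger.warning("build_risk_model: Cox fit did not converge; "
                           "no score emitted")
            return RiskScoreModel(genes, np.full(len(genes), np.nan),
                                  float("nan"), float("nan"), cox)
        beta = cox.beta
    score = pd.Series(x.to_numpy() @ beta, index=cohort.index)
    _, _, _, auc = roc_curve_auc(score, cohort["event"])
    return RiskScoreModel(genes=genes, beta=beta,
                          group_cutoff=float(score.median()), auc=auc, cox=cox)


@dataclass
class StratificationResult:
    groups: pd.Series                 # "high" / "low" per retained patient
    km_curves: dict                   # group -> survival-function DataFrame
    logrank_stat: float
    logrank_p: float
    hr_fit: CoxFit                    # high vs low via univariate Cox

    @property
    def hazard_ratio(self) -> float:
        return float(self.hr_fit.hr[0])


def stratify_by_risk(
    model: RiskScoreModel,
    cohort: pd.DataFrame,
    mode: str = "cutoff",
    low_pct: float = 33.0,
    high_pct: float = 66.0,
) -> StratificationResult:
    """Split a cohort into high/low risk and compare their survival.

    mode="cutoff" splits at model.group_cutoff (default: the median score);
    mode="percentile" keeps only patients above the ``high_pct`` and below
    the ``low_pct`` score percentiles, mirroring single-gene tertile
    stratification.  Returns Kaplan-Meier curves per group, the log-rank
    statistic/p, and the high-vs-low hazard ratio from a univariate Cox fit.
    """
    if not model.converged:
        raise ValueError("risk model did not converge; cannot stratify")
    score = model.scores(cohort)
    if mode == "cutoff":
        high = score > model.group_cutoff
        keep = pd.Series(True, index=cohort.index)
    elif mode == "percentile":
        lo_t = np.percentile(score, low_pct)
        hi_t = np.percentile(score, high_pct)
        high = score > hi_t
        keep = (score > hi_t) | (score < lo_t)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sub = cohort[keep]
    high = high[keep]
    if high.all() or not high.any():
        raise ValueError("a risk group is empty; adjust the cutoff")
    groups = pd.Series(np.where(high, "high", "low"), index=sub.index, name="risk_group")

    km_curves = {}
    for label in ("low", "high"):
        mask = groups == label
        kmf = KaplanMeierFitter(label=label)
        kmf.fit(sub.loc[mask, "time"], sub.loc[mask, "event"])
        km_curves[label] = kmf.survival_function_

    lr = logrank_test(sub.loc[high, "time"], sub.loc[~high, "time"],
                      sub.loc[high, "event"], sub.loc[~high, "event"])
    hr_fit = cox_univariate(high.astype(float), sub["time"], sub["event"],
                            name="risk_high")
    logger.info("stratify_by_risk: %d high / %d low, log-rank p=%.3g, HR=%.3g",
                int(high.sum()), int((~high).sum()), lr.p_value, hr_fit.hr[0])
    return StratificationResult(groups=groups, km_curves=km_curves,
                                logrank_stat=float(lr.test_statistic),
                                logrank_p=float(lr.p_value), hr_fit=hr_fit)


def _encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode categorical covariates (first level = reference)."""
    num = covariates.select_dtypes(include=[np.number, bool]).astype(float)
    cat = covariates.select_dtypes(exclude=[np.number, bool])
    parts = [num]
    if not cat.empty:
        parts.append(pd.get_dummies(cat, drop_first=True, dtype=float))
    return pd.concat(parts, axis=1)


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Keep a maximal linearly independent, non-constant column subset."""
    kept: list[str] = []
    dropped: list[str] = []
    mat = np.empty((len(X), 0))
    for col in X.columns:
        v = X[col].to_numpy(dtype=float).reshape(-1, 1)
        if np.all(v == v[0]):
            dropped.append(col)
            continue
        trial = np.hstack([mat, v])
        if np.linalg.matrix_rank(trial) > mat.shape[1]:
            mat = trial
            kept.append(col)
        else:
            dropped.append(col)
    if dropped:
        logger.warning("multivariate Cox: dropped collinear/constant "
                       "covariates %s", dropped)
    return X[kept]


def multivariate_adjusted(
    risk_group: Sequence[Union[bool, float]],
    covariates: pd.DataFrame,
    time: Sequence[float],
    event: Sequence[bool],
    ties: str = "breslow",
) -> CoxFit:
    """Joint Cox fit of the risk-group indicator plus clinical covariates.

    Categorical covariates are one-hot encoded against their first level;
    collinear or constant columns are dropped with a warning.  The per-term
    HR/CI/p table lets one read off whether the risk score remains an
    independent predictor after adjustment.
    """
    X = pd.concat([
        pd.Series(np.asarray(risk_group, dtype=float), name="risk_high",
                  index=covariates.index),
        _encode_covariates(covariates),
    ], axis=1)
    X = _drop_collinear(X)
    return _fit_cox(X, time, event, ties=ties)
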