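"""Prognostic evaluation of candidate modules.

A module is summarised per patient by its eigengene (EM): the first
principal component of the standardised module-genes x patients
submatrix, with loadings oriented so the EM correlates positively with
the module's mean expression profile.  Patients are split at the median
EM into two groups; the group with the shorter Kaplan-Meier median
survival is labelled high-risk.  Group separation is tested by the
log-rank test and by univariate and covariate-adjusted Cox
proportional-hazards models (age, stage, grade, residual tumour size).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from survmod.cohort import SurvivalCohort

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# eigengene
# ---------------------------------------------------------------------------

@dataclass
class EigengeneModel:
    """Frozen training-time eigengene: genes, unit-norm first-PC loadings,
    per-gene standardisation, and the training median EM used for
    external-cohort splits."""

    genes: list[str]
    loadings: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    train_median_em: float


def fit_eigengene(expr_sub: pd.DataFrame) -> tuple[EigengeneModel, pd.Series]:
    """First principal component of the module submatrix (genes x patients).

    Each gene row is standardised with its training mean/SD; constant
    genes are excluded with a warning.  Loadings are the first left
    singular vector (unit Euclidean norm); the sign is fixed so the EM
    correlates positively with the mean standardised module profile,
    making EM comparable across cohorts.  Returns the model and the
    training EM series.
    """
    if expr_sub.shape[0] < 2 or expr_sub.shape[1] < 3:
        raise ValueError("need >= 2 genes and >= 3 patients for an eigengene")
    sds = expr_sub.std(axis=1, ddof=1)
    constant = sds <= 1e-12
    if constant.any():
        log.warning("excluding constant genes from eigengene: %s", list(sds.index[constant]))
        expr_sub = expr_sub.loc[~constant]
        sds = sds[~constant]
        if expr_sub.shape[0] < 2:
            raise ValueError("fewer than 2 non-constant genes remain")
    means = expr_sub.mean(axis=1)
    z = expr_sub.sub(means, axis=0).div(sds, axis=0).to_numpy(float)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = u[:, 0]
    em = loadings @ z
    mean_profile = z.mean(axis=0)
    orient = float(np.dot(em, mean_profile))
    if orient == 0.0:
        orient = float(np.sign(loadings[np.nonzero(loadings)[0][0]]))
    if orient < 0:
        loadings = -loadings
        em = -em
    em_series = pd.Series(em, index=expr_sub.columns, name="EM")
    model = EigengeneModel(
        genes=list(expr_sub.index),
        loadings=loadings,
        means=means.to_numpy(float),
        sds=sds.to_numpy(float),
        train_median_em=float(np.median(em)),
    )
    return model, em_series


def apply_eigengene(model: EigengeneModel, expr_sub: pd.DataFrame) -> pd.Series:
    """Project new patients onto the frozen eigengene (no refitting)."""
    missing = [g for g in model.genes if g not in expr_sub.index]
    if missing:
        raise KeyError(f"expression matrix lacks model genes: {missing}")
    z = (
        expr_sub.loc[model.genes].to_numpy(float) - model.means[:, None]
    ) / model.sds[:, None]
    return pd.Series(model.loadings @ z, index=expr_sub.columns, name="EM")


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMEstimate:
    times: np.ndarray
    survival: np.ndarray
    median: float  # inf when never reaching S(t) <= 0.5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})


def kaplan_meier(os_time, event) -> KMEstimate:
    """Product-limit survival estimate with its median survival time."""
    t = np.asarray(os_time, float)
    e = np.asarray(event, int)
    if len(t) == 0:
        raise ValueError("need at least one patient")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    return KMEstimate(
        times=sf.index.to_numpy(float),
        survival=sf.iloc[:, 0].to_numpy(float),
        median=float(kmf.median_survival_time_),
    )


def log_rank_test(labels, os_time, event) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p).

    Groups without events yield a warning but the statistic is still
    computed.
    """
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    t = np.asarray(os_time, float)
    e = np.asarray(event, int)
    for g in groups:
        if e[labels == g].sum() == 0:
            log.warning("group %r has no events; log-rank may be uninformative", g)
    mask = labels == groups[0]
    res = logrank_test(t[mask], t[~mask], e[mask], e[~mask])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox models
# ---------------------------------------------------------------------------

def cox_model(design: pd.DataFrame, os_time, event) -> pd.DataFrame:
    """Cox proportional-hazards fit (Breslow ties) for a numeric design.

    Returns a frame indexed by covariate with ``hr``, ``ci_low``,
    ``ci_high`` (Wald 95% on the log scale) and ``p``.  Constant or
    collinear covariates are detected up front and rejected by name.
    """
    design = design.astype(float)
    constant = design.columns[design.std(axis=0) <= 1e-12].tolist()
    if constant:
        raise ValueError(f"constant covariates: {constant}")
    centred = design - design.mean(axis=0)
    if np.linalg.matrix_rank(centred.to_numpy()) < design.shape[1]:
        raise ValueError(f"collinear covariates among: {list(design.columns)}")
    frame = design.copy()
    frame["_time"] = np.asarray(os_time, float)
    frame["_event"] = np.asarray(event, int)
    cph = CoxPHFitter()
    cph.fit(frame, duration_col="_time", event_col="_event")
    summary = cph.summary
    out = pd.DataFrame(
        {
            "hr": np.exp(summary["coef"]),
            "ci_low": np.exp(summary["coef"] - 1.96 * summary["se(coef)"]),
            "ci_high": np.exp(summary["coef"] + 1.96 * summary["se(coef)"]),
            "p": summary["p"],
        }
    )
    out.index.name = "covariate"
    return out


def clinical_design(clinical: pd.DataFrame, age_dichotomized: bool = True) -> pd.DataFrame:
    """Covariate coding for the adjusted model: age above cohort median
    (or continuous), stage IV vs III, grade G4 vs G3, residual >10mm vs
    0-10mm."""
    design = pd.DataFrame(index=clinical.index)
    if age_dichotomized:
        design["age_high"] = (clinical["age"] > clinical["age"].median()).astype(float)
    else:
        design["age"] = clinical["age"].astype(float)
    design["stage_iv"] = (clinical["stage"].astype(str) == "IV").astype(float)
    design["grade_g4"] = (clinical["grade"].astype(str) == "G4").astype(float)
    design["residual_gt10"] = (clinical["residual"].astype(str) == ">10mm").astype(float)
    return design


# ---------------------------------------------------------------------------
# risk groups and full evaluation
# ---------------------------------------------------------------------------

def assign_risk_groups(em: pd.Series, split_value: float, os_time=None, event=None) -> pd.Series:
    """Label patients high-/low-risk by their EM relative to ``split_value``.

    EM > split goes to one group, EM <= split to the other; when survival
    data is supplied the group with the shorter Kaplan-Meier median
    survival is named ``high``, otherwise the low-EM group is (the
    convention observed when high module expression is protective).
    """
    em = pd.Series(em)
    if em.nunique() <= 1:
        raise ValueError("all EM values identical; cannot split")
    upper = em > split_value
    if upper.all() or (~upper).all():
        raise ValueError("split value leaves one group empty")
    high_is_lower_em = True
    if os_time is not None and event is not None:
        t = pd.Series(np.asarray(os_time, float), index=em.index)
        e = pd.Series(np.asarray(event, int), index=em.index)
        med_upper = kaplan_meier(t[upper], e[upper]).median
        med_lower = kaplan_meier(t[~upper], e[~upper]).median
        high_is_lower_em = med_lower <= med_upper
    labels = np.where(upper ^ high_is_lower_em, "high", "low")
    return pd.Series(labels, index=em.index, name="risk")


@dataclass
class CohortReport:
    """Prognostic statistics for one cohort."""

    split_label: str
    em: pd.Series
    risk: pd.Series
    split_value: float
    km_median: dict[str, float]
    km_curves: dict[str, KMEstimate]
    logrank_chi2: float
    logrank_p: float
    cox_univariate: dict
    cox_multivariate: pd.DataFrame | None

    def to_dict(self) -> dict:
        return {
            "split_label": self.split_label,
            "n_patients": int(len(self.em)),
            "split_value": self.split_value,
            "km_median_months": {
                k: (None if np.isinf(v) else float(v)) for k, v in self.km_median.items()
            },
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "cox_univariate": self.cox_univariate,
            "cox_multivariate": (
                None
                if self.cox_multivariate is None
                else self.cox_multivariate.round(6).to_dict(orient="index")
            ),
        }


@dataclass
class PrognosticReport:
    """Module-level prognostic evaluation across cohorts."""

    module_genes: list[str]
    model: EigengeneModel
    screen_alpha: float
    screen_passed: bool
    cohorts: dict[str, CohortReport]

    def to_dict(self) -> dict:
        return {
            "module_genes": self.module_genes,
            "loadings": {g: round(float(l), 6) for g, l in zip(self.model.genes, self.model.loadings)},
            "train_median_em": self.model.train_median_em,
            "screen_alpha": self.screen_alpha,
            "screen_passed": self.screen_passed,
            "cohorts": {k: v.to_dict() for k, v in self.cohorts.items()},
        }


def _report_cohort(
    cohort: SurvivalCohort,
    em: pd.Series,
    split_value: float,
    adjust_covariates: bool,
) -> CohortReport:
    risk = assign_risk_groups(em, split_value, cohort.os_months, cohort.event)
    t = cohort.os_months
    e = cohort.event
    curves = {
        grp: kaplan_meier(t[risk == grp], e[risk == grp]) for grp in ("high", "low")
    }
    chi2, p = log_rank_test(risk.to_numpy(), t.to_numpy(), e.to_numpy())
    # the reported group indicator is high EM (module expression up)
    em_high = (em > split_value).astype(float).rename("em_high")
    uni = cox_model(em_high.to_frame(), t, e).loc["em_high"].to_dict()
    multi = None
    if adjust_covariates:
        design = clinical_design(cohort.clinical)
        design.insert(0, "em_high", em_high)
        try:
            multi = cox_model(design, t, e)
        except ValueError as err:
            log.warning("multivariate Cox skipped for %s: %s", cohort.split_label, err)
    return CohortReport(
        split_label=cohort.split_label,
        em=em,
        risk=risk,
        split_value=float(split_value),
        km_median={g: c.median for g, c in curves.items()},
        km_curves=curves,
        logrank_chi2=chi2,
        logrank_p=p,
        cox_univariate={k: float(v) for k, v in uni.items()},
        cox_multivariate=multi,
    )


def evaluate_module(
    module_genes,
    train: SurvivalCohort,
    test: SurvivalCohort | None = None,
    external: SurvivalCohort | None = None,
    alpha_screen: float = 0.1,
    internal_split: str = "own_median",
    adjust_covariates: bool = True,
) -> PrognosticReport:
    """Full prognostic evaluation of one module.

    The eigengene is fitted on the training cohort and applied without
    refitting elsewhere.  The training log-rank p against ``alpha_screen``
    is the survival-association screen.  The internal test cohort is
    split at its own median EM (``internal_split="train_median"``
    switches to the training median); the external cohort is always split
    at the training median.
    """
    genes = [g for g in module_genes if g in train.expression.index]
    missing = sorted(set(module_genes) - set(genes))
    if missing:
        log.warning("module genes absent from training expression: %s", missing)
    if len(genes) < 2:
        raise ValueError("fewer than 2 module genes present in training cohort")

    model, em_train = fit_eigengene(train.expression.loc[genes])
    reports = {
        "training": _report_cohort(
            train, em_train, model.train_median_em, adjust_covariates
        )
    }
    if test is not None:
        em_test = apply_eigengene(model, test.expression)
        split = (
            float(em_test.median()) if internal_split == "own_median" else model.train_median_em
        )
        reports["test"] = _report_cohort(test, em_test, split, adjust_covariates)
    if external is not None:
        em_ext = apply_eigengene(model, external.expression)
        reports["external"] = _report_cohort(
            external, em_ext, model.train_median_em, adjust_covariates
        )
    return PrognosticReport(
        module_genes=list(genes),
        model=model,
        screen_alpha=alpha_screen,
        screen_passed=bool(reports["training"].logrank_p < alpha_screen),
        cohorts=reports,
    )
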