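"""Dysbiosis index and the case-control evaluation layer.

The dysbiosis index (DI) of a sample is

    DI = (sum of relative abundances of case-enriched genera + eps)
       / (sum of relative abundances of control-enriched genera + eps)

with a symmetric pseudocount ``eps`` (default 1e-6) keeping the ratio finite
and preserving the side-swap inversion DI -> 1/DI. Around it sit the study's
standard statistics: rank-sum / ANOVA / chi-square / Kruskal-Wallis group
tests, ROC/AUC discrimination (scalar index and a leave-one-out logistic
model on the signature composition), per-marker logistic odds ratios, and
Spearman marker-taxon correlation grids with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

from .biomarkers import SignatureSet, _group_series

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float


# ---------------------------------------------------------------------------
# dysbiosis index
# ---------------------------------------------------------------------------

def dysbiosis_index(
    rel: pd.DataFrame, sig: SignatureSet, pseudocount: float = 1e-6
) -> pd.Series:
    """Per-sample ratio of case-enriched to control-enriched abundance mass."""
    if not sig.enriched_in_case or not sig.enriched_in_control:
        raise ValueError("both signature sides must be non-empty")
    missing = sorted(sig.members - set(rel.index))
    if missing:
        logger.warning("signature genera absent from table (contribute 0): %s", missing)
    num_taxa = sorted(sig.enriched_in_case & set(rel.index))
    den_taxa = sorted(sig.enriched_in_control & set(rel.index))
    num = rel.loc[num_taxa].sum(axis=0) if num_taxa else pd.Series(0.0, index=rel.columns)
    den = rel.loc[den_taxa].sum(axis=0) if den_taxa else pd.Series(0.0, index=rel.columns)
    di = (num + pseudocount) / (den + pseudocount)
    di.name = "dysbiosis_index"
    return di


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided rank-sum p: exact enumeration when both n <= 10, else the
    tie-corrected normal approximation. Returns (U statistic, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and not _has_ties(x, y)) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _has_ties(x, y) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def chi_square(table) -> tuple[float, float, int]:
    """Pearson chi-square on a contingency table, no continuity correction."""
    chi2, p, dof, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p), int(dof)


def anova(*samples) -> tuple[float, float]:
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def kruskal(*samples) -> tuple[float, float]:
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def compare_groups(values, groups, test: str) -> dict:
    """Dispatch a named test over per-sample values split by group label."""
    values = pd.Series(values)
    g = _group_series(groups, values.index)
    parts = [values[g == lvl].to_numpy() for lvl in pd.unique(g)]
    if any(len(p) == 0 for p in parts):
        raise ValueError("empty group")
    if test == "wilcoxon":
        if len(parts) != 2:
            raise ValueError("wilcoxon compares exactly two groups")
        stat, p = wilcoxon_rank_sum(parts[0], parts[1])
    elif test == "anova":
        stat, p = anova(*parts)
    elif test == "kruskal":
        stat, p = kruskal(*parts)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {"test": test, "statistic": stat, "p": p}


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels, positive) -> RocResult:
    """ROC by threshold sweep; AUC equals the Mann-Whitney concordance
    probability (ties counted one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = (labels == positive).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    pos, neg = scores[y == 1], scores[y == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * ties) / (len(pos) * len(neg))
    return RocResult(
        thresholds=thr, sensitivities=tpr, specificities=1 - fpr, auc=float(auc)
    )


def multivariate_auc(
    rel_sig: pd.DataFrame,
    labels,
    positive,
    seed: int = 0,
    pseudocount: float = 1e-6,
    cv: str = "lpo",
) -> RocResult:
    """Logistic discrimination on the log signature composition.

    Features are log10(relative abundance + pseudocount), standardized.
    The default validation scheme is leave-pair-out ("lpo"): every
    (case, control) pair is held out in turn and the AUC is the fraction of
    pairs the refitted model ranks correctly — the estimator of choice for
    small-sample AUC because, unlike leave-one-out, it is not pessimistically
    biased by the class-balance shift of the held-out fold. "loo" and
    "resubstitution" are available for comparison. Deterministic given
    ``seed``.

    For "lpo" the returned ROC curve is descriptive (built from each
    sample's mean held-out score); the ``auc`` field is the pairwise
    estimate and may differ slightly from the area of that curve.
    """
    labels = _group_series(labels, rel_sig.columns)
    y = (labels == positive).astype(int).to_numpy()
    if y.sum() < 5 or (len(y) - y.sum()) < 5:
        raise ValueError("need at least 5 samples per class")
    X = np.log10(rel_sig.to_numpy().T + pseudocount)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)

    def fit(Xtr, ytr):
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                return LogisticRegression(
                    C=1e6, max_iter=500, random_state=seed
                ).fit(Xtr, ytr)
            except ConvergenceWarning:
                logger.info("multivariate_auc: separation suspected, ridge fallback")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    return LogisticRegression(
                        C=1.0, max_iter=500, random_state=seed
                    ).fit(Xtr, ytr)

    n = len(y)
    if cv == "lpo":
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        held: list[list[float]] = [[] for _ in range(n)]
        correct = 0.0
        for i in pos_idx:
            for j in neg_idx:
                mask = np.ones(n, dtype=bool)
                mask[[i, j]] = False
                model = fit(X[mask], y[mask])
                si, sj = model.decision_function(X[[i, j]])
                held[i].append(si)
                held[j].append(sj)
                correct += 1.0 if si > sj else (0.5 if si == sj else 0.0)
        auc = correct / (len(pos_idx) * len(neg_idx))
        scores = np.array([np.mean(h) for h in held])
        curve = roc_auc(scores, y, positive=1)
        return RocResult(curve.thresholds, curve.sensitivities,
                         curve.specificities, float(auc))
    if cv == "loo":
        scores = np.empty(n)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            scores[i] = fit(X[mask], y[mask]).predict_proba(X[[i]])[0, 1]
        return roc_auc(scores, y, positive=1)
    if cv == "resubstitution":
        scores = fit(X, y).predict_proba(X)[:, 1]
        return roc_auc(scores, y, positive=1)
    raise ValueError(f"unknown cv scheme {cv!r}")


# ---------------------------------------------------------------------------
# odds ratios and correlations
# ---------------------------------------------------------------------------

def odds_ratios(
    metadata: pd.DataFrame,
    markers,
    case_group: str = "FRI",
    control_group: str = "FH",
    standardize: bool = True,
) -> pd.DataFrame:
    """Univariate logistic odds ratio per serum marker (case vs control)
    with Wald 95% CI; perfect separation falls back to a ridge-penalized
    fit, flagged with CI withheld."""
    meta = metadata.loc[metadata["group"].isin([case_group, control_group])]
    y = (meta["group"] == case_group).astype(float).to_numpy()
    rows = []
    for marker in markers:
        x = meta[marker].astype(float).to_numpy()
        if np.all(x == x[0]):
            raise ValueError(f"marker {marker!r} is constant")
        if standardize:
            x = (x - x.mean()) / x.std()
        X = sm.add_constant(pd.DataFrame({marker: x}))
        flagged = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
                if not np.isfinite(res.bse[marker]) or abs(res.params[marker]) > 20:
                    raise np.linalg.LinAlgError("separation")
                beta, se = float(res.params[marker]), float(res.bse[marker])
            except Exception:
                flagged = True
                logger.warning("odds_ratios: %s separated; ridge fallback", marker)
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
                    alpha=1.0, L1_wt=0.0
                )
                beta, se = float(res.params[marker]), np.nan
        or_ = float(np.exp(beta))
        ci = (np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)) if not flagged else (np.nan, np.nan)
        p = float(2 * stats.norm.sf(abs(beta / se))) if not flagged else np.nan
        rows.append((marker, or_, ci[0], ci[1], p, flagged))
    return pd.DataFrame(
        rows, columns=["marker", "OR", "ci_low", "ci_high", "p", "penalized"]
    ).set_index("marker")


def marker_taxon_correlations(
    rel: pd.DataFrame,
    metadata: pd.DataFrame,
    markers,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Tie-corrected Spearman rho and p for every (marker, taxon) pair, with
    Benjamini-Hochberg adjustment across the whole grid. Constant vectors
    yield missing rho."""
    common = rel.columns.intersection(metadata.index)
    if len(common) < 4:
        raise ValueError("need at least 4 paired observations")
    rows = []
    for marker in markers:
        m = metadata.loc[common, marker].astype(float).to_numpy()
        for taxon in rel.index:
            x = rel.loc[taxon, common].to_numpy()
            if np.all(x == x[0]) or np.all(m == m[0]):
                rows.append((marker, taxon, np.nan, np.nan))
                continue
            rho, p = stats.spearmanr(m, x)
            rows.append((marker, taxon, float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["marker", "taxon_id", "rho", "p"])
    out["p_adj"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method=adjust)[1]
    return out
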