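"""Signature discovery: Kruskal-Wallis + LDA effect size, and GLM filtering.

Two routes identify the genera that make up the dysbiosis signature:

* an LEfSe-style score — a Kruskal-Wallis screen across the three groups
  followed by a bootstrapped linear-discriminant effect size on features
  rescaled to parts-per-million, reported on a log10 scale and thresholded
  at 2.0 by convention;
* covariate-adjusted GLMs — per-genus negative-binomial regressions on raw
  counts with a log-total offset and ``group + age + sex`` design, run for
  the three-group and both pairwise case comparisons, with the union of
  significant genera forming the signature.

Only ranking and sign behaviour of the LDA score is contractual; the exact
per-bootstrap effect formula is pinned in comments below.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

logger = logging.getLogger(__name__)

CASE_GROUP = "FRI"
COMPARISONS = ("FRI-vs-FH-vs-HC", "FRI-vs-HC", "FRI-vs-FH")

#: LEfSe rescaling: relative abundances are analyzed in parts per million
LEFSE_SCALE = 1e6


@dataclass(frozen=True)
class SignatureSet:
    """The two disjoint genus sets defining the dysbiosis index."""

    enriched_in_case: frozenset
    enriched_in_control: frozenset
    provenance: str = "manual"

    def __post_init__(self):
        overlap = self.enriched_in_case & self.enriched_in_control
        if overlap:
            raise ValueError(f"signature sides overlap: {sorted(overlap)}")

    @property
    def members(self) -> frozenset:
        return self.enriched_in_case | self.enriched_in_control


def _group_series(groups, columns) -> pd.Series:
    if isinstance(groups, pd.Series):
        return groups.reindex(columns)
    return pd.Series(np.asarray(groups), index=columns)


# ---------------------------------------------------------------------------
# Kruskal-Wallis screen
# ---------------------------------------------------------------------------

def kruskal_wallis_screen(
    rel: pd.DataFrame, groups, alpha: float = 0.05
) -> pd.DataFrame:
    """Tie-corrected Kruskal-Wallis H and chi-square p per taxon.

    Constant taxa get H = 0, p = 1 rather than an error.
    """
    g = _group_series(groups, rel.columns)
    levels = g.unique()
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    masks = [(g == lvl).to_numpy() for lvl in levels]
    H = np.empty(len(rel.index))
    p = np.empty(len(rel.index))
    X = rel.to_numpy()
    for i in range(X.shape[0]):
        row = X[i]
        if np.all(row == row[0]):
            H[i], p[i] = 0.0, 1.0
            continue
        H[i], p[i] = stats.kruskal(*(row[m] for m in masks))
    return pd.DataFrame(
        {"H": H, "p": p, "passed": p < alpha},
        index=pd.Index(rel.index, name="taxon_id"),
    )


# ---------------------------------------------------------------------------
# LDA effect size
# ---------------------------------------------------------------------------

def _fit_lda(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    try:
        lda = LinearDiscriminantAnalysis(solver="svd").fit(X, y)
    except np.linalg.LinAlgError:
        # singular within-class scatter: shrinkage-regularized fallback
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-3).fit(X, y)
    return lda.coef_.ravel()


def lda_effect_size(
    rel: pd.DataFrame,
    groups,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    subsample_frac: float = 2 / 3,
    seed: int = 0,
    case_group: str = CASE_GROUP,
) -> pd.DataFrame:
    """LEfSe-style biomarker scores.

    Features passing the Kruskal-Wallis screen are rescaled to parts per
    million and scored one-vs-rest against the group where their mean is
    largest. Per bootstrap (stratified ``subsample_frac`` subsample, no
    replacement) an LDA is fitted on all passing features; the per-feature
    effect is the average of
      (a) the absolute between-class difference of the feature's mean, and
      (b) the feature's contribution along the unit discriminant axis,
          |w_j| * |w . dm| with w the unit coefficient vector and dm the
          vector of class-mean differences.
    The reported score is log10(1 + mean bootstrap effect), signed positive
    when the feature is enriched in ``case_group`` and negative otherwise.
    """
    g = _group_series(groups, rel.columns)
    sizes = g.value_counts()
    if len(sizes) < 2 or (sizes < 3).any():
        raise ValueError("need >=2 groups with >=3 samples each")
    screen = kruskal_wallis_screen(rel, g, alpha=alpha)
    passing = screen.index[screen["passed"]]
    out = pd.DataFrame(
        {
            "kw_p": screen["p"],
            "lda_score": 0.0,
            "enriched_group": "",
            "passed": False,
        }
    )
    if len(passing) == 0:
        return out

    X = (rel.loc[passing] * LEFSE_SCALE).to_numpy().T  # samples x features
    y_all = g.to_numpy()
    group_means = {
        lvl: X[y_all == lvl].mean(axis=0) for lvl in np.unique(y_all)
    }
    mean_mat = pd.DataFrame(group_means, index=passing)
    enriched = mean_mat.idxmax(axis=1)

    rng = np.random.default_rng(seed)
    effects = np.zeros((n_boot, len(passing)))
    classes = list(np.unique(y_all))
    for b in range(n_boot):
        idx = []
        for lvl in classes:
            members = np.flatnonzero(y_all == lvl)
            take = max(2, int(np.ceil(subsample_frac * len(members))))
            idx.append(rng.choice(members, size=min(take, len(members)), replace=False))
        idx = np.concatenate(idx)
        Xb, yb = X[idx], y_all[idx]
        for lvl in classes:
            which = np.flatnonzero(enriched.to_numpy() == lvl)
            if which.size == 0:
                continue
            yb_bin = (yb == lvl).astype(int)
            if yb_bin.sum() < 2 or yb_bin.sum() > len(yb_bin) - 2:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w = _fit_lda(Xb, yb_bin)
            norm = np.linalg.norm(w)
            w_unit = w / norm if norm > 0 else w
            dm = Xb[yb_bin == 1].mean(axis=0) - Xb[yb_bin == 0].mean(axis=0)
            proj = abs(float(w_unit @ dm))
            contrib = np.abs(w_unit) * proj
            effects[b, which] = 0.5 * (np.abs(dm[which]) + contrib[which])

    effect = effects.mean(axis=0)
    score = np.log10(1.0 + effect)
    sign = np.where(enriched.to_numpy() == case_group, 1.0, -1.0)
    out.loc[passing, "lda_score"] = sign * score
    out.loc[passing, "enriched_group"] = enriched
    out.loc[passing, "passed"] = score >= lda_threshold
    return out


# ---------------------------------------------------------------------------
# GLM differential abundance
# ---------------------------------------------------------------------------

def _design_matrix(meta: pd.DataFrame, levels: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=meta.index)
    X["const"] = 1.0
    # treatment coding, last level (HC when present) as reference
    for lvl in levels[:-1]:
        X[f"group_{lvl}"] = (meta["group"] == lvl).astype(float)
    X["age"] = meta["age"].astype(float)
    X["sex_M"] = (meta["sex"] == "M").astype(float)
    return X


def _fit_nb(y, X, offset):
    """NB regression: joint-MLE dispersion, falling back to a
    method-of-moments alpha plugged into a NB GLM on non-convergence."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.NegativeBinomial(y, X, offset=offset).fit(disp=0, maxiter=200)
            if res.converged and np.isfinite(res.bse[: X.shape[1]]).all():
                return res, True
        except Exception:
            pass
        pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        mu = np.asarray(pois.fittedvalues, dtype=float)
        # Cameron-Trivedi moment estimator of the NB2 dispersion
        alpha = float(((y - mu) ** 2 - mu).sum() / (mu**2).sum())
        alpha = min(max(alpha, 1e-8), 10.0)
        try:
            res = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
            ).fit(start_params=np.asarray(pois.params, dtype=float))
            if np.isfinite(np.asarray(res.bse, dtype=float)).all():
                return res, False
        except Exception:
            pass
        # last resort for pathologically sparse genera: the Poisson fit
        return pois, False


def glm_differential(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    comparison: str,
    family: str = "negative-binomial",
    totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-genus covariate-adjusted GLM; Wald z and two-sided p for the
    case-group coefficient.

    ``comparison`` is one of FRI-vs-FH-vs-HC, FRI-vs-HC, FRI-vs-FH; rows
    all-zero within the compared samples are skipped with a logged notice.
    The log-offset uses per-sample library totals: pass ``totals`` when
    ``table`` is a row subset of the full count table.
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    levels = comparison.split("-vs-")
    meta = metadata.loc[metadata["group"].isin(levels)]
    missing = sorted(set(levels) - set(meta["group"]))
    if missing:
        raise ValueError(f"groups absent from metadata: {missing}")
    for col in ("age", "sex"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks required covariate {col!r}")
    sub = table[meta.index]
    tot = (sub.sum(axis=0) if totals is None else totals.loc[meta.index]).astype(float)
    if (tot <= 0).any():
        raise ValueError(f"non-positive library totals: {tot.index[tot <= 0].tolist()}")
    offset = np.log(tot.to_numpy())
    X = _design_matrix(meta, levels)
    coef_name = f"group_{CASE_GROUP}"

    rows = []
    for taxon in sub.index:
        y = sub.loc[taxon].to_numpy().astype(float)
        if y.sum() == 0:
            logger.info("glm_differential: %s all-zero in %s, skipped", taxon, comparison)
            continue
        if family == "negative-binomial":
            res, converged = _fit_nb(y, X, offset)
        elif family == "poisson":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
            converged = True
        elif family == "binomial-presence":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM((y > 0).astype(float), X, family=sm.families.Binomial()).fit()
            converged = True
        else:
            raise ValueError(f"unknown family {family!r}")
        coef = float(res.params[coef_name])
        z = float(res.params[coef_name] / res.bse[coef_name])
        p = float(2 * stats.norm.sf(abs(z)))
        rows.append((taxon, comparison, coef, z, p, converged))
    return pd.DataFrame(
        rows, columns=["taxon_id", "comparison", "coef", "z", "p", "converged"]
    ).set_index("taxon_id")


# ---------------------------------------------------------------------------
# signature construction
# ---------------------------------------------------------------------------

def build_signature(
    mode: str,
    rel: pd.DataFrame | None = None,
    groups=None,
    lefse: pd.DataFrame | None = None,
    glm: pd.DataFrame | None = None,
    manual_case=None,
    manual_control=None,
    alpha: float = 0.05,
    case_group: str = CASE_GROUP,
) -> SignatureSet:
    """Assemble the enriched/depleted genus sets.

    glm-union: union of genera with p < alpha over the three comparisons,
    each assigned to the case side iff its mean relative abundance is higher
    in the case group than in the pooled controls (ties go to the control
    side with a warning). lefse: passing genera partitioned by their
    enriched group. manual: user-provided sets validated against the table.
    """
    if mode == "manual":
        case = frozenset(manual_case or ())
        control = frozenset(manual_control or ())
        if rel is not None:
            unknown = sorted((case | control) - set(rel.index))
            if unknown:
                raise ValueError(f"manual signature genera absent from table: {unknown}")
    elif mode == "lefse":
        if lefse is None:
            raise ValueError("lefse mode needs LDA scores")
        hits = lefse.loc[lefse["passed"]]
        case = frozenset(hits.index[hits["enriched_group"] == case_group])
        control = frozenset(hits.index[hits["enriched_group"] != case_group])
    elif mode == "glm-union":
        if glm is None or rel is None or groups is None:
            raise ValueError("glm-union mode needs GLM results, rel table and groups")
        union = sorted(set(glm.index[glm["p"] < alpha]))
        g = _group_series(groups, rel.columns)
        case_mask = (g == case_group).to_numpy()
        case_set, control_set = set(), set()
        for taxon in union:
            m_case = rel.loc[taxon].to_numpy()[case_mask].mean()
            m_ctrl = rel.loc[taxon].to_numpy()[~case_mask].mean()
            if m_case > m_ctrl:
                case_set.add(taxon)
            else:
                if m_case == m_ctrl:
                    warnings.warn(
                        f"{taxon}: equal case/control means; assigned to control side",
                        stacklevel=2,
                    )
                control_set.add(taxon)
        case, control = frozenset(case_set), frozenset(control_set)
    else:
        raise ValueError(f"unknown signature mode {mode!r}")
    if not case or not control:
        raise ValueError(
            "a signature side is empty; relax alpha or the LDA threshold"
        )
    return SignatureSet(case, control, provenance=mode)
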