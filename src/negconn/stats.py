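"""Longitudinal inference on the averaged negative-connectivity metric.

The repeated-scans design is modelled with a linear mixed-effects model:
a subject-level random intercept absorbs the dependence between a child's
scans, and fixed effects estimate group, sex, age and head-motion terms.
Three nested fixed-effect structures are compared by AIC on maximum-
likelihood fits:

* Model 1 — main effects only: group + age + sex + mean FD;
* Model 2 — Model 1 plus the group x age interaction;
* Model 3 — Model 1 plus all two-way interactions among group, age and sex
  and their three-way interaction.

Edge-level analyses refit Model 1 per mask edge with Benjamini-Hochberg
FDR across edges; region-level summaries sum significant t scores over the
edges incident to each ROI. A gender-balanced permutation refits the model
on repeated random subsets of the over-represented group's scans and
averages the p-value distribution. Brain-behavior coupling regresses CPT
d' on the connectivity metric in the same random-intercept framework.

t-tests use the between-within (containment) denominator-df convention:
terms constant within subject are tested against subject-level df, terms
varying within subject against observation-level df.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .mask import EdgeMask
from .types import validate_records

logger = logging.getLogger(__name__)

MODEL1_TERMS = ("adhd", "age_c", "female", "mean_fd")
_INTERACTIONS_2 = ("adhd:age_c",)
_INTERACTIONS_3 = ("adhd:age_c", "adhd:female", "age_c:female", "adhd:age_c:female")


@dataclass(frozen=True)
class ModelSpec:
    """A fixed-effect structure over the standard covariate set.

    All models share a subject random intercept and, by default, include
    mean FD as a nuisance covariate. ``extra_terms`` are appended
    interaction terms in ``a:b`` notation over the encoded columns
    (``adhd``, ``female``, ``age_c``, ``mean_fd``).
    """

    name: str
    extra_terms: tuple[str, ...] = ()
    include_fd: bool = True
    base_terms: tuple[str, ...] | None = None  # overrides the standard set

    @classmethod
    def model1(cls) -> "ModelSpec":
        return cls("Model1")

    @classmethod
    def model2(cls) -> "ModelSpec":
        return cls("Model2", extra_terms=_INTERACTIONS_2)

    @classmethod
    def model3(cls) -> "ModelSpec":
        return cls("Model3", extra_terms=_INTERACTIONS_3)

    def fixed_terms(self) -> list[str]:
        base = list(
            self.base_terms
            if self.base_terms is not None
            else (t for t in MODEL1_TERMS if self.include_fd or t != "mean_fd")
        )
        return base + [t for t in self.extra_terms if t not in base]

    def formula(self, outcome: str) -> str:
        return f"{outcome} ~ " + " + ".join(self.fixed_terms())


@dataclass
class ModelResult:
    """One mixed-model fit: per-term table, AIC and df accounting."""

    spec: ModelSpec
    outcome: str
    terms: pd.DataFrame  # index term; columns estimate, se, tvalue, df, pvalue
    aic: float
    loglik: float
    n_obs: int
    n_subjects: int
    df_model: int  # fixed effects + 2 variance components
    re_variance: float
    resid_variance: float
    singular: bool
    converged: bool

    def term(self, name: str) -> pd.Series:
        if name not in self.terms.index:
            raise KeyError(f"unknown term {name!r}; have {list(self.terms.index)}")
        return self.terms.loc[name]


def encode_records(records: pd.DataFrame, center_age: bool = True) -> pd.DataFrame:
    """Add the numeric design columns the model formulas use.

    ``adhd`` and ``female`` are 0/1 indicators; ``age_c`` is age centered
    at the sample mean (interaction models stay interpretable; tests of
    the highest-order terms are unaffected).
    """
    data = records.copy()
    data["adhd"] = (data["group"] == "adhd").astype(float)
    data["female"] = (data["sex"] == "F").astype(float)
    data["age_c"] = data["age"] - (data["age"].mean() if center_age else 0.0)
    return data


def _between_within_df(data: pd.DataFrame, terms: list[str]) -> dict[str, float]:
    """Containment denominator df per term.

    A term whose design column is constant within every subject is tested
    at subject level (``n_subjects - n_between - 1``); any other term at
    observation level (``n_obs - n_subjects - n_within``).
    """
    cols = {}
    for t in terms:
        parts = t.split(":")
        col = data[parts[0]].astype(float).copy()
        for p in parts[1:]:
            col = col * data[p]
        cols[t] = col
    grp = data["subject_id"]
    is_between = {
        t: bool((c.groupby(grp).nunique() <= 1).all()) for t, c in cols.items()
    }
    n_between = sum(is_between.values())
    n_within = len(terms) - n_between
    n_subj = grp.nunique()
    n_obs = len(data)
    df_b = max(n_subj - n_between - 1, 1)
    df_w = max(n_obs - n_subj - n_within, 1)
    out = {t: (df_b if b else df_w) for t, b in is_between.items()}
    out["Intercept"] = df_b
    return out


def _robust_ml_fit(model):
    """ML fit with an optimizer fallback chain.

    Boundary (zero random-variance) solutions can leave one optimizer's
    Hessian singular; trying the default BFGS first and falling back to
    lbfgs/powell/cg makes the fit succeed on such data.
    """
    last_exc: Exception | None = None
    for method in (None, "lbfgs", "powell", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if method is None:
                    return model.fit(reml=False)
                return model.fit(reml=False, method=method)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
    raise RuntimeError(f"mixed-model fit failed with every optimizer: {last_exc}")


def fit_lmm(
    records: pd.DataFrame,
    outcome: str,
    spec: ModelSpec | None = None,
    center_age: bool = True,
) -> ModelResult:
    """Maximum-likelihood mixed-model fit with a subject random intercept.

    Returns per-term estimates, between-within t-tests, and AIC computed
    from the ML log-likelihood with ``k = n_fixed + 2`` parameters (random-
    intercept and residual variances). A random variance estimated at the
    zero boundary is flagged ``singular`` but the fit is returned.
    """
    spec = spec or ModelSpec.model1()
    data = encode_records(records, center_age=center_age)
    needed = [outcome] + [p for t in spec.fixed_terms() for p in t.split(":")]
    for col in dict.fromkeys(needed):
        if col not in data:
            raise KeyError(f"records lack column {col!r}")
        if data[col].isna().any():
            raise ValueError(f"missing values in {col!r}")
    validate_records(records)

    terms = spec.fixed_terms()
    # rank check on the fixed-effect design
    X = np.column_stack(
        [np.ones(len(data))]
        + [np.prod([data[p].to_numpy(dtype=float) for p in t.split(":")], axis=0) for t in terms]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_columns(X, ["Intercept"] + terms)
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")

    model = smf.mixedlm(spec.formula(outcome), data, groups=data["subject_id"])
    result = _robust_ml_fit(model)

    re_var = float(np.asarray(result.cov_re).ravel()[0]) * result.scale
    singular = bool(re_var < 1e-8 * result.scale)
    if singular:
        logger.warning("singular fit: subject random variance at the zero boundary")

    k = X.shape[1] + 2
    aic = float(-2.0 * result.llf + 2.0 * k)
    dfs = _between_within_df(data, terms)
    rows = []
    for name in ["Intercept"] + terms:
        est = float(result.fe_params[name])
        se = float(result.bse_fe[name])
        df_t = dfs[name]
        tval = est / se
        pval = 2.0 * sps.t.sf(abs(tval), df_t)
        rows.append((name, est, se, tval, df_t, pval))
    table = pd.DataFrame(
        rows, columns=["term", "estimate", "se", "tvalue", "df", "pvalue"]
    ).set_index("term")

    return ModelResult(
        spec=spec,
        outcome=outcome,
        terms=table,
        aic=aic,
        loglik=float(result.llf),
        n_obs=len(data),
        n_subjects=data["subject_id"].nunique(),
        df_model=k,
        re_variance=re_var,
        resid_variance=float(result.scale),
        singular=singular,
        converged=bool(result.converged),
    )


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    aliased = []
    base_rank = 0
    cols: list[np.ndarray] = []
    for j, name in enumerate(names):
        trial = np.column_stack(cols + [X[:, j]]) if cols else X[:, [j]]
        r = np.linalg.matrix_rank(trial)
        if r > base_rank:
            base_rank = r
            cols.append(X[:, j])
        else:
            aliased.append(name)
    return aliased


def select_model(results: list[ModelResult]) -> tuple[ModelResult, pd.DataFrame]:
    """Pick the minimum-AIC fit among candidates on identical data.

    Returns the winner (first of any exact ties, which are reported) and a
    comparison table with delta-AIC for every candidate.
    """
    if not results:
        raise ValueError("no candidate fits")
    n_obs = {r.n_obs for r in results}
    outcomes = {r.outcome for r in results}
    if len(n_obs) > 1 or len(outcomes) > 1:
        raise ValueError("candidates differ in data or outcome; AIC not comparable")
    aics = np.array([r.aic for r in results])
    best_i = int(np.argmin(aics))
    ties = np.flatnonzero(aics == aics[best_i])
    if len(ties) > 1:
        logger.warning("AIC tie among candidates %s; returning the first",
                       [results[i].spec.name for i in ties])
    table = pd.DataFrame(
        {
            "model": [r.spec.name for r in results],
            "df": [r.df_model for r in results],
            "aic": aics,
            "delta_aic": aics - aics[best_i],
        }
    )
    return results[best_i], table


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics; q >= p elementwise and q is monotone in p.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class EdgeStats:
    """Per-edge Model-1 statistics with BH-FDR across edges, per term."""

    mask: EdgeMask
    table: pd.DataFrame  # columns edge, roi_i, roi_j, term, estimate, tvalue, pvalue, qvalue
    failed_edges: list[int] = field(default_factory=list)

    def for_term(self, term: str) -> pd.DataFrame:
        sub = self.table[self.table["term"] == term]
        if sub.empty:
            raise KeyError(f"unknown term {term!r}")
        return sub


def edgewise_fit(
    edge_z: np.ndarray,
    records: pd.DataFrame,
    mask: EdgeMask,
    spec: ModelSpec | None = None,
) -> EdgeStats:
    """Fit the mixed model separately to every mask edge.

    ``edge_z`` is (n_scans, n_edges), rows aligned with ``records``.
    q-values are computed per term across edges (never pooled across
    terms). An edge whose fit fails is recorded and skipped.
    """
    spec = spec or ModelSpec.model1()
    edge_z = np.asarray(edge_z, dtype=float)
    if edge_z.shape != (len(records), mask.n_edges):
        raise ValueError("edge_z must be (n_scans, n_mask_edges)")
    rows = []
    failed: list[int] = []
    work = records.copy()
    for e in range(mask.n_edges):
        work["_edge_z"] = edge_z[:, e]
        try:
            res = fit_lmm(work, "_edge_z", spec)
        except Exception as exc:  # single-edge failure must not sink the batch
            logger.warning("edge %d fit failed: %s", e, exc)
            failed.append(e)
            continue
        for term, row in res.terms.iterrows():
            rows.append(
                {
                    "edge": e,
                    "roi_i": int(mask.edges[e, 0] + 1),
                    "roi_j": int(mask.edges[e, 1] + 1),
                    "term": term,
                    "estimate": row["estimate"],
                    "tvalue": row["tvalue"],
                    "pvalue": row["pvalue"],
                }
            )
    table = pd.DataFrame(rows)
    table["qvalue"] = np.nan
    for term in table["term"].unique():
        sel = table["term"] == term
        table.loc[sel, "qvalue"] = bh_fdr(table.loc[sel, "pvalue"].to_numpy())
    return EdgeStats(mask=mask, table=table, failed_edges=failed)


def summed_t_map(
    stats: EdgeStats,
    term: str,
    direction: str,
    n_rois: int,
    p_cut: float = 0.05,
) -> np.ndarray:
    """Per-ROI sum of significant edge t scores in one direction.

    ``direction`` is ``"negative"`` or ``"positive"``: only edges with an
    uncorrected p below ``p_cut`` whose t has the requested sign
    contribute; each qualifying edge adds its t to both endpoints. ROIs
    with no qualifying incident edge score zero.
    """
    if direction not in ("negative", "positive"):
        raise ValueError("direction must be 'negative' or 'positive'")
    sub = stats.for_term(term)
    sig = sub["pvalue"] < p_cut
    sign_ok = sub["tvalue"] < 0 if direction == "negative" else sub["tvalue"] > 0
    hits = sub[sig & sign_ok]
    out = np.zeros(n_rois)
    for _, row in hits.iterrows():
        out[int(row["roi_i"]) - 1] += row["tvalue"]
        out[int(row["roi_j"]) - 1] += row["tvalue"]
    return out


def gender_balanced_permutation(
    records: pd.DataFrame,
    spec: ModelSpec | None = None,
    outcome: str = "avg_neg_conn",
    n_perm: int = 10_000,
    select: dict[str, int] | None = None,
    balance_group: str = "adhd",
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Average model p-values over sex-balanced random scan subsets.

    Each iteration keeps every scan of the reference group and draws,
    uniformly without replacement, ``select["M"]`` male and ``select["F"]``
    female scans from ``balance_group``, refits ``spec`` and records the
    per-term p-values. ``select`` defaults to the reference group's own
    sex counts, the balancing the procedure exists for. Returns the mean
    p per term and the full (n_perm x terms) distribution; deterministic
    under a seeded generator.
    """
    spec = spec or ModelSpec.model1()
    rng = np.random.default_rng(seed)
    keep = records[records["group"] != balance_group]
    pool = records[records["group"] == balance_group]
    pool_by_sex = {s: pool.index[pool["sex"] == s].to_numpy() for s in ("M", "F")}
    if select is None:
        # match the reference group's sex counts as closely as the pool allows
        target = keep["sex"].value_counts().to_dict()
        select = {
            s: min(int(n), len(pool_by_sex.get(s, ())))
            for s, n in target.items()
        }
    for s, n_wanted in select.items():
        avail = len(pool_by_sex.get(s, ()))
        if n_wanted > avail:
            raise ValueError(
                f"cannot draw {n_wanted} {s} scans from {balance_group}: only {avail} available"
            )

    all_p = []
    for _ in range(n_perm):
        chosen = np.concatenate(
            [
                rng.choice(pool_by_sex[s], size=n, replace=False)
                for s, n in sorted(select.items())
            ]
        )
        subset = pd.concat([keep, pool.loc[chosen]]).sort_index()
        res = fit_lmm(subset, outcome, spec)
        all_p.append(res.terms["pvalue"])
    dist = pd.DataFrame(all_p).reset_index(drop=True)
    return dist.mean(axis=0), dist


def brain_behavior_fit(
    records: pd.DataFrame,
    which_dprime: str = "both",
    include_group: bool = False,
    group_interaction: bool = False,
    difficulty_interaction: bool = True,
) -> ModelResult:
    """Relate CPT sensitivity to the averaged connectivity metric.

    With ``which_dprime="both"`` the two difficulty conditions are stacked
    into a repeated-measures outcome with a difficulty factor (and, by
    default, a connectivity x difficulty interaction); ``"easy"`` or
    ``"difficult"`` fit a single condition. Predictors are the averaged
    metric, mean FD, centered age and sex, plus optional group terms; the
    subject random intercept carries the longitudinal dependence. A
    negative connectivity coefficient means more negative connectivity
    goes with better performance.
    """
    if which_dprime in ("easy", "difficult"):
        data = records.copy()
        data["dprime"] = data[f"dprime_{which_dprime}"]
        extra: list[str] = []
    elif which_dprime == "both":
        long = []
        for cond, flag in (("easy", 0.0), ("difficult", 1.0)):
            part = records.copy()
            part["dprime"] = part[f"dprime_{cond}"]
            part["difficult"] = flag
            # stacked rows are repeated measures of the same scan
            part["wave"] = part["wave"].astype(str) + f"_{cond}"
            long.append(part)
        data = pd.concat(long, ignore_index=True)
        extra = ["difficult"]
        if difficulty_interaction:
            extra.append("avg_neg_conn:difficult")
    else:
        raise ValueError("which_dprime must be 'easy', 'difficult' or 'both'")

    terms: tuple[str, ...] = ("avg_neg_conn", *extra)
    if include_group:
        terms = terms + ("adhd",)
    if group_interaction:
        terms = terms + ("avg_neg_conn:adhd",)
    spec = ModelSpec(name=f"brain_behavior_{which_dprime}", extra_terms=terms)
    return _fit_behavior(data, spec)


def _fit_behavior(data: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    base = ["age_c", "female", "mean_fd"]
    terms = base + [t for t in spec.extra_terms if t not in base]
    custom = ModelSpec(name=spec.name, extra_terms=tuple(t for t in terms))
    # bypass the default group/age/sex set: build the formula directly
    enc = encode_records(data)
    formula = "dprime ~ " + " + ".join(terms)
    model = smf.mixedlm(formula, enc, groups=enc["subject_id"])
    result = _robust_ml_fit(model)
    k = len(result.fe_params) + 2
    dfs = _between_within_df(enc, terms)
    rows = []
    for name in result.fe_params.index:
        est = float(result.fe_params[name])
        se = float(result.bse_fe[name])
        df_t = dfs.get(name, len(enc) - enc["subject_id"].nunique() - len(terms))
        tval = est / se
        rows.append((name, est, se, tval, df_t, 2.0 * sps.t.sf(abs(tval), df_t)))
    table = pd.DataFrame(
        rows, columns=["term", "estimate", "se", "tvalue", "df", "pvalue"]
    ).set_index("term")
    re_var = float(np.asarray(result.cov_re).ravel()[0]) * result.scale
    return ModelResult(
        spec=custom,
        outcome="dprime",
        terms=table,
        aic=float(-2.0 * result.llf + 2.0 * k),
        loglik=float(result.llf),
        n_obs=len(enc),
        n_subjects=enc["subject_id"].nunique(),
        df_model=k,
        re_variance=re_var,
        resid_variance=float(result.scale),
        singular=bool(re_var < 1e-8 * result.scale),
        converged=bool(result.converged),
    )
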