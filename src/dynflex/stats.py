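"""Covariate-adjusted two-group comparison with permutation p-values and FDR.

Each feature (one metric at one unit of one level — e.g. global
flexibility, or cohesion in the DMN) is compared between groups by the t
statistic of the group coefficient in the linear model

    value ~ group + age + gender + mean_fd

which reduces to the pooled two-sample t when no covariates are supplied.
The group dummy codes group 1, so a negative t means group 1 sits below
group 2 (the convention under which the low-switch/trained group shows
negative t for flexibility).  Significance comes from an empirical null
built by randomly redistributing subjects between the two groups
(covariates stay attached to their subjects) and refitting; p-values are
two-sided with +1 smoothing, or exact when all distinct reassignments can
be enumerated.  Benjamini–Hochberg FDR is applied within each
metric × level family.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ContractError
from .metrics import METRICS

_T_EPS = 1e-12


@dataclass(frozen=True)
class ComparisonSpec:
    """Settings of the statistical pass."""

    n_permutations: int = 5000
    alpha: float = 0.05
    covariates: tuple[str, ...] = ("age", "gender", "mean_fd")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ContractError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ContractError("alpha must lie in (0, 1)")


def _design(dummy: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(dummy, dtype=float), dummy.astype(float)]
    names = ["intercept", "group"]
    if covariates is not None and covariates.size:
        for j in range(covariates.shape[1]):
            cols.append(covariates[:, j].astype(float))
            names.append(f"cov{j}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify the first column that is linearly dependent on the others
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == \
                    np.linalg.matrix_rank(X):
                raise ContractError(f"design matrix is rank deficient: "
                                    f"column {names[j]!r} is collinear")
        raise ContractError("design matrix is rank deficient")
    return X


def _t_group(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """t statistic of the group column (index 1) for every column of Y."""
    n, p = X.shape
    if n <= p:
        raise ContractError("need more subjects than design columns")
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / (n - p)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    # a numerically perfect fit leaves only rounding noise in the residuals;
    # the t ratio is then 0/0 junk, so resolve it by the coefficient itself
    tiny = np.finfo(float).eps * np.maximum((Y ** 2).mean(axis=0), 1.0) * 100
    degenerate = sigma2 < tiny
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    if np.any(degenerate):
        t = np.where(degenerate,
                     np.where(np.abs(beta[1]) < np.sqrt(tiny), 0.0,
                              np.sign(beta[1]) * np.inf), t)
    return t


def adjusted_t(values: np.ndarray, group: np.ndarray,
               covariates: np.ndarray | None = None) -> float:
    """Group-coefficient t for one feature.

    ``group`` holds 0/1 group indices; the dummy codes membership of group
    0 so the sign follows mean(group 0) − mean(group 1), adjusted for the
    covariates.  Without covariates this equals the classic pooled
    two-sample t statistic.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    if np.unique(group).size != 2:
        raise ContractError("need exactly two groups")
    counts = [np.sum(group == g) for g in np.unique(group)]
    if min(counts) < 2:
        raise ContractError("need at least 2 subjects per group")
    dummy = (group == np.unique(group)[0]).astype(float)
    X = _design(dummy, np.asarray(covariates, dtype=float)
                if covariates is not None else None)
    return float(_t_group(X, values[:, None])[0])


def _permutation_dummies(n: int, n_group1: int, n_permutations: int,
                         rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Matrix of permuted group dummies, exact if the null is enumerable."""
    total = comb(n, n_group1)
    if total <= n_permutations:
        warnings.warn(
            f"only {total} distinct group reassignments exist; using exact "
            "enumeration instead of sampling", stacklevel=2,
        )
        dummies = np.zeros((total, n))
        for r, idx in enumerate(combinations(range(n), n_group1)):
            dummies[r, list(idx)] = 1.0
        return dummies, True
    dummies = np.empty((n_permutations, n))
    base = np.zeros(n)
    base[:n_group1] = 1.0
    for r in range(n_permutations):
        dummies[r] = rng.permutation(base)
    return dummies, False


def permutation_test(Y: np.ndarray, group: np.ndarray,
                     covariates: np.ndarray | None,
                     spec: ComparisonSpec,
                     dummies: np.ndarray | None = None,
                     exact: bool | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Observed t and permutation p per feature (columns of Y).

    The same permutation sequence is applied to every feature so that
    features of one family share a null.  ``dummies`` may be passed in to
    reuse one sequence across several calls.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != len(group):
        Y = Y.T
    group = np.asarray(group)
    cov = np.asarray(covariates, dtype=float) if covariates is not None else None
    dummy_obs = (group == np.unique(group)[0]).astype(float)
    t_obs = _t_group(_design(dummy_obs, cov), Y)
    if dummies is None:
        rng = np.random.default_rng(spec.seed)
        dummies, exact = _permutation_dummies(
            len(group), int(dummy_obs.sum()), spec.n_permutations, rng)
    assert exact is not None
    exceed = np.zeros(Y.shape[1])
    valid = 0
    for r in range(dummies.shape[0]):
        try:
            X = _design(dummies[r], cov)
        except ContractError:
            # a permuted dummy can align exactly with a binary covariate;
            # that reassignment has no defined t and is dropped
            continue
        t_perm = _t_group(X, Y)
        valid += 1
        exceed += np.abs(t_perm) >= np.abs(t_obs) - _T_EPS
    if valid == 0:
        raise ContractError("no valid permutation had a full-rank design")
    if exact:
        p = exceed / valid
    else:
        p = (1.0 + exceed) / (1.0 + valid)
    return t_obs, p


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        raise ContractError("empty p-value family")
    return multipletests(p_values, method="fdr_bh")[1]


def compare_groups(values: pd.DataFrame, covariates: pd.DataFrame | None,
                   spec: ComparisonSpec = ComparisonSpec()) -> pd.DataFrame:
    """Full statistical pass over a tidy per-subject feature table.

    ``values`` columns: subject, group, level, unit, metric, value.
    ``covariates`` is indexed by subject with the columns named in
    ``spec.covariates`` (pass None for an unadjusted comparison).  Returns
    one row per feature: level, unit, metric, t, p_perm, p_fdr,
    significant.  The FDR family is all units of one metric at one level.
    """
    required = {"subject", "group", "level", "unit", "metric", "value"}
    if not required <= set(values.columns):
        raise ContractError(f"values table needs columns {sorted(required)}")
    subjects = values["subject"].unique()
    group = values.drop_duplicates("subject").set_index("subject")["group"] \
        .loc[subjects].to_numpy()
    cov = None
    if covariates is not None and spec.covariates:
        missing = set(spec.covariates) - set(covariates.columns)
        if missing:
            raise ContractError(f"covariates table lacks {sorted(missing)}")
        cov = covariates.loc[subjects, list(spec.covariates)].to_numpy(dtype=float)
    rng = np.random.default_rng(spec.seed)
    dummy_obs = (group == np.unique(group)[0])
    dummies, exact = _permutation_dummies(
        len(subjects), int(dummy_obs.sum()), spec.n_permutations, rng)
    out_rows = []
    for level, level_df in values.groupby("level", sort=False):
        wide = level_df.pivot_table(index="subject", columns=["metric", "unit"],
                                    values="value", sort=False).loc[subjects]
        Y = wide.to_numpy(dtype=float)
        t_obs, p_perm = permutation_test(Y, group, cov, spec,
                                         dummies=dummies, exact=exact)
        feat = pd.DataFrame({
            "level": level,
            "metric": [m for m, _ in wide.columns],
            "unit": [u for _, u in wide.columns],
            "t": t_obs,
            "p_perm": p_perm,
        })
        # BH within each metric's family at this level
        feat["p_fdr"] = np.nan
        for metric in feat["metric"].unique():
            sel = feat["metric"] == metric
            feat.loc[sel, "p_fdr"] = fdr_adjust(feat.loc[sel, "p_perm"].to_numpy())
        out_rows.append(feat)
    result = pd.concat(out_rows, ignore_index=True)
    result["significant"] = result["p_fdr"] < spec.alpha
    return result[["level", "unit", "metric", "t", "p_perm", "p_fdr",
                   "significant"]]


def metrics_long_table(per_subject: dict[str, pd.DataFrame],
                       groups: dict[str, int],
                       network_labels: list[str],
                       include_nodal: bool = True) -> pd.DataFrame:
    """Assemble the tidy feature table from per-subject nodal metric tables.

    ``per_subject`` maps subject id to its repetition-averaged nodal table;
    global and network aggregates are recomputed here so that all levels
    come from the same source.
    """
    from .metrics import aggregate  # local import to avoid cycle

    rows = []
    for subject, table in per_subject.items():
        agg = aggregate(table, network_labels)
        agg.insert(0, "group", groups[subject])
        agg.insert(0, "subject", subject)
        rows.append(agg)
        if include_nodal:
            nodal = table[list(METRICS)].stack().reset_index()
            nodal.columns = ["unit", "metric", "value"]
            nodal.insert(0, "level", "nodal")
            nodal.insert(0, "group", groups[subject])
            nodal.insert(0, "subject", subject)
            rows.append(nodal)
    return pd.concat(rows, ignore_index=True)[
        ["subject", "group", "level", "unit", "metric", "value"]
    ]
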