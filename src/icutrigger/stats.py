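"""Inferential layer: unit / ADR-strata comparisons and risk-factor modelling.

Group comparisons use chi-square for categorical variables (Fisher's exact
test when any expected cell count is below 5) and the two-sided Mann-Whitney
U test for quantitative variables. Risk factors for having at least one ADR
are identified by multiple logistic regression with forward stepwise
selection (entry/stay p = 0.05), reporting odds ratios with Wald 95%
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = ["GroupComparison", "VariableEffect", "LogisticModel",
           "compare_groups", "stepwise_logistic"]


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test_used: str  # chi_square | fisher_exact | mann_whitney
    statistic: float
    p_value: float


@dataclass(frozen=True)
class VariableEffect:
    variable: str
    coefficient: float
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    p_value: float


@dataclass
class LogisticModel:
    outcome: str
    selected: list[VariableEffect] = field(default_factory=list)

    @property
    def selected_variables(self) -> list[str]:
        return [e.variable for e in self.selected]


def _is_categorical(series: pd.Series) -> bool:
    if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype) or series.dtype == bool:
        return True
    return series.nunique() <= 2


def compare_groups(table: pd.DataFrame, variable: str, grouping: str,
                   categorical: bool | None = None) -> GroupComparison:
    """Compare a variable between the groups defined by ``grouping``.

    Categorical variables: chi-square on the contingency table, switching to
    Fisher's exact test (2x2) whenever any expected or observed cell count
    is below 5 (the conservative small-sample convention).
    Quantitative variables: two-sided Mann-Whitney U (exact for small
    tie-free samples, normal approximation with tie correction otherwise).
    """
    df = table[[variable, grouping]].dropna()
    groups = df[grouping].unique()
    if len(groups) < 2:
        raise ValueError(f"grouping {grouping!r} has fewer than 2 groups")
    var = df[variable]
    if var.nunique() < 2:
        raise ValueError(f"variable {variable!r} is constant; test is degenerate")
    if categorical is None:
        categorical = _is_categorical(var)

    if categorical:
        contingency = pd.crosstab(df[variable], df[grouping]).to_numpy()
        expected = sps.contingency.expected_freq(contingency)
        small = (expected < 5).any() or (contingency < 5).any()
        if small and contingency.shape == (2, 2):
            odds, p = sps.fisher_exact(contingency, alternative="two-sided")
            return GroupComparison(variable, "fisher_exact", float(odds), float(p))
        stat, p, _, _ = sps.chi2_contingency(contingency, correction=False)
        return GroupComparison(variable, "chi_square", float(stat), float(p))

    if len(groups) != 2:
        raise ValueError("Mann-Whitney comparison requires exactly 2 groups")
    x = df.loc[df[grouping] == groups[0], variable].to_numpy(dtype=float)
    y = df.loc[df[grouping] == groups[1], variable].to_numpy(dtype=float)
    method = "exact" if (len(x) <= 20 and len(y) <= 20) else "asymptotic"
    try:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:  # ties with exact method
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return GroupComparison(variable, "mann_whitney", float(res.statistic), float(res.pvalue))


def _fit(y: np.ndarray, X: pd.DataFrame):
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    try:
        return model.fit(disp=0, maxiter=200)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular design matrix (collinear covariates?): {exc}") from exc


def stepwise_logistic(table: pd.DataFrame, outcome: str, candidates: list[str],
                      p_enter: float = 0.05, p_stay: float = 0.05) -> LogisticModel:
    """Forward stepwise logistic regression with backward pruning.

    At each step the candidate with the smallest Wald p-value below
    ``p_enter`` joins the model; included variables whose p-value rises above
    ``p_stay`` are dropped. Reports OR = exp(coefficient) with Wald 95% CIs
    for the selected variables. Perfect separation or collinear candidates
    raise with a diagnostic.
    """
    df = table[[outcome] + list(candidates)].dropna()
    y = df[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    X_all = df[list(candidates)].astype(float)
    corr = X_all.corr().to_numpy()
    iu = np.triu_indices_from(corr, k=1)
    if np.any(np.abs(corr[iu]) > 1 - 1e-10):
        raise ValueError("perfectly collinear candidate covariates")

    selected: list[str] = []
    while True:
        changed = False
        remaining = [c for c in candidates if c not in selected]
        best_var, best_p = None, p_enter
        for cand in remaining:
            res = _fit(y, X_all[selected + [cand]])
            p = float(res.pvalues[cand])
            if np.isnan(p):
                raise ValueError(f"non-finite p-value for {cand!r}: possible separation")
            if p < best_p:
                best_var, best_p = cand, p
        if best_var is not None:
            selected.append(best_var)
            changed = True
        if selected:
            res = _fit(y, X_all[selected])
            worst = max(selected, key=lambda v: float(res.pvalues[v]))
            if float(res.pvalues[worst]) > p_stay and worst != best_var:
                selected.remove(worst)
                changed = True
        if not changed:
            break

    model = LogisticModel(outcome=outcome)
    if not selected:
        return model
    res = _fit(y, X_all[selected])
    if not res.mle_retvals.get("converged", True):
        raise ValueError("logistic fit failed to converge (possible separation)")
    conf = res.conf_int(alpha=0.05)
    for v in selected:
        beta = float(res.params[v])
        model.selected.append(VariableEffect(
            variable=v, coefficient=beta, odds_ratio=float(np.exp(beta)),
            ci95_low=float(np.exp(conf.loc[v, 0])), ci95_high=float(np.exp(conf.loc[v, 1])),
            p_value=float(res.pvalues[v]),
        ))
    return model
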