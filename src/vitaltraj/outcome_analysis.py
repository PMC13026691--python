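"""Mortality-association statistics for the labelled subphenotypes.

Contingency table, Pearson / likelihood-ratio chi-square with the
expected-count rule (plus a seeded Monte-Carlo conditional test for sparse
tables), Woolf odds ratios with Wald intervals, unconditional logistic
regression by Newton-Raphson, tie-corrected Mann-Whitney ROC AUC with the
Hanley-McNeil standard error, and one-way ANOVA with Bonferroni-adjusted
pairwise comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

# Normal multiplier for all 95% Wald intervals. The exact 0.975 quantile
# (1.959964...) — not the rounded 1.96 — is what reproduces the published
# interval bounds to their third printed decimal.
Z_95 = float(stats.norm.ppf(0.975))


class DegenerateTableError(ValueError):
    """A margin of the contingency table is zero."""


# ---------------------------------------------------------------------------
# Contingency table
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    """Deaths and survivors per group label."""

    labels: list[str]
    deaths: np.ndarray  # (G,), int
    survivors: np.ndarray  # (G,), int
    empty_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.deaths = np.asarray(self.deaths, int)
        self.survivors = np.asarray(self.survivors, int)
        if np.any(self.deaths < 0) or np.any(self.survivors < 0):
            raise ValueError("counts must be non-negative")

    @property
    def totals(self) -> np.ndarray:
        return self.deaths + self.survivors

    @property
    def n(self) -> int:
        return int(self.totals.sum())

    @property
    def n_deaths(self) -> int:
        return int(self.deaths.sum())

    @property
    def mortality_rate(self) -> float:
        return self.n_deaths / self.n

    def group_rates(self) -> dict[str, float]:
        with np.errstate(invalid="ignore"):
            rates = np.where(self.totals > 0, self.deaths / self.totals, np.nan)
        return dict(zip(self.labels, rates))

    @classmethod
    def from_counts(cls, counts: Mapping[str, tuple[int, int]]) -> "ContingencyTable":
        """Build from {label: (deaths, total)} pairs."""
        labels = list(counts)
        deaths = np.array([counts[lab][0] for lab in labels])
        totals = np.array([counts[lab][1] for lab in labels])
        if np.any(deaths > totals):
            raise ValueError("deaths exceed group totals")
        return cls(labels=labels, deaths=deaths, survivors=totals - deaths)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": self.labels,
            "deaths": self.deaths,
            "survivors": self.survivors,
            "total": self.totals,
            "mortality": [self.group_rates()[lab] for lab in self.labels],
        })


def contingency(
    group_labels: Sequence[str],
    died: Sequence[bool | int],
    all_labels: Sequence[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate per-patient group labels against the death flag.

    Labels listed in ``all_labels`` but absent from the data are retained
    with zero counts and flagged.
    """
    group_labels = list(group_labels)
    died = np.asarray(died, int)
    if len(group_labels) != len(died):
        raise ValueError("group_labels and died must have equal length")
    labels = sorted(set(group_labels) | set(all_labels or []))
    deaths = np.zeros(len(labels), int)
    survivors = np.zeros(len(labels), int)
    index = {lab: i for i, lab in enumerate(labels)}
    for lab, d in zip(group_labels, died):
        if d:
            deaths[index[lab]] += 1
        else:
            survivors[index[lab]] += 1
    table = ContingencyTable(labels=labels, deaths=deaths, survivors=survivors)
    table.empty_labels = [lab for i, lab in enumerate(labels) if table.totals[i] == 0]
    if table.empty_labels:
        logger.warning("labels with zero patients: %s", table.empty_labels)
    return table


# ---------------------------------------------------------------------------
# Chi-square tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chi2Result:
    pearson_stat: float
    pearson_p: float
    lr_stat: float
    lr_p: float
    df: int
    expected: np.ndarray  # (G, 2) expected deaths / survivors
    min_expected: float
    use_likelihood_ratio: bool  # raised when any expected count < 5


def chi2_tests(table: ContingencyTable) -> Chi2Result:
    """Pearson X^2 and likelihood-ratio G^2 for the G x 2 mortality table.

    Flags ``use_likelihood_ratio`` when any expected count falls below 5.
    Zero observed cells contribute 0 to G^2. A zero margin is fatal.
    """
    obs = np.column_stack([table.deaths, table.survivors]).astype(float)
    if obs.shape[0] < 2:
        raise ValueError("need at least 2 groups")
    row_tot = obs.sum(axis=1)
    col_tot = obs.sum(axis=0)
    if np.any(row_tot == 0) or np.any(col_tot == 0):
        raise DegenerateTableError("degenerate table: zero row or column margin")
    n = obs.sum()
    expected = np.outer(row_tot, col_tot) / n
    df = obs.shape[0] - 1  # (G-1)*(2-1)

    pearson = float(np.sum((obs - expected) ** 2 / expected))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g2 = float(2.0 * terms.sum())
    return Chi2Result(
        pearson_stat=pearson,
        pearson_p=float(stats.chi2.sf(pearson, df)),
        lr_stat=g2,
        lr_p=float(stats.chi2.sf(g2, df)),
        df=df,
        expected=expected,
        min_expected=float(expected.min()),
        use_likelihood_ratio=bool(expected.min() < 5.0),
    )


def mc_exact_test(
    table: ContingencyTable, n_draws: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo conditional p-value for G^2 with both margins fixed.

    Tables are sampled by distributing the death total across groups with
    a multivariate hypergeometric draw (group sizes fixed); the p-value is
    the fraction of sampled tables whose G^2 meets or exceeds the
    observed one (with the +1 correction for a valid test).
    """
    observed = chi2_tests(table).lr_stat
    rng = np.random.default_rng(seed)
    totals = table.totals
    n_dead = table.n_deaths

    draws = rng.multivariate_hypergeometric(totals, n_dead, size=n_draws)
    obs = np.stack([draws, totals[None, :] - draws], axis=2).astype(float)
    expected = np.outer(totals, [n_dead, table.n - n_dead]) / table.n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected[None, :, :]), 0.0)
    g2 = 2.0 * terms.sum(axis=(1, 2))
    exceed = int(np.sum(g2 >= observed - 1e-12))
    return (exceed + 1) / (n_draws + 1)


# ---------------------------------------------------------------------------
# Odds ratios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OddsRatioResult:
    group: str
    log_or: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    wald_p: float
    zero_cell: bool = False


def odds_ratios(
    table: ContingencyTable, reference: str
) -> list[OddsRatioResult]:
    """Woolf log-odds-ratio of each group against the reference.

    b = ln[(d_g/s_g)/(d_r/s_r)], se = sqrt(1/d_g + 1/s_g + 1/d_r + 1/s_r),
    CI = exp(b -+ 1.96 se), two-sided Wald p from z = b/se. Groups with a
    zero cell are flagged; no continuity correction is applied.
    """
    idx = {lab: i for i, lab in enumerate(table.labels)}
    if reference not in idx:
        raise ValueError(f"reference {reference!r} not among labels {table.labels}")
    r = idx[reference]
    d_r, s_r = table.deaths[r], table.survivors[r]
    if d_r < 1 or s_r < 1:
        raise ValueError("reference group needs at least 1 death and 1 survivor")

    results = []
    for lab in table.labels:
        if lab == reference:
            continue
        g = idx[lab]
        d_g, s_g = table.deaths[g], table.survivors[g]
        if d_g == 0 or s_g == 0:
            results.append(OddsRatioResult(
                group=lab, log_or=float("nan"), se=float("nan"),
                or_value=float("nan"), ci_low=float("nan"),
                ci_high=float("nan"), wald_p=float("nan"), zero_cell=True,
            ))
            continue
        b = math.log((d_g / s_g) / (d_r / s_r))
        se = math.sqrt(1 / d_g + 1 / s_g + 1 / d_r + 1 / s_r)
        z = b / se
        results.append(OddsRatioResult(
            group=lab, log_or=b, se=se, or_value=math.exp(b),
            ci_low=math.exp(b - Z_95 * se), ci_high=math.exp(b + Z_95 * se),
            wald_p=2.0 * float(stats.norm.sf(abs(z))),
        ))
    return results


def odds_ratio_frame(results: Sequence[OddsRatioResult],
                     reference: str,
                     intercept: tuple[float, float] | None = None) -> pd.DataFrame:
    """OR table mirroring the published layout (B, SE, Sig., OR, CI)."""
    rows = [
        {"group": r.group, "B": r.log_or, "SE": r.se, "sig": r.wald_p,
         "OR": r.or_value, "ci_low": r.ci_low, "ci_high": r.ci_high}
        for r in results
    ]
    rows.append({"group": f"{reference} (reference)", "B": 0.0, "SE": np.nan,
                 "sig": np.nan, "OR": 1.0, "ci_low": np.nan, "ci_high": np.nan})
    if intercept is not None:
        b0, se0 = intercept
        rows.append({"group": "(constant)", "B": b0, "SE": se0,
                     "sig": 2.0 * float(stats.norm.sf(abs(b0 / se0))),
                     "OR": math.exp(b0), "ci_low": np.nan, "ci_high": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Unconditional logistic regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticTerm:
    name: str
    coef: float
    se: float
    wald_p: float


@dataclass
class LogisticFit:
    reference: str
    terms: list[LogisticTerm]  # non-reference group dummies, in label order
    intercept: LogisticTerm
    loglik: float
    converged: bool
    n_iter: int
    diagnostics: str | None = None

    def term(self, name: str) -> LogisticTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def predicted_probability(self, group: str) -> float:
        eta = self.intercept.coef
        if group != self.reference:
            eta += self.term(group).coef
        return 1.0 / (1.0 + math.exp(-eta))


def _newton_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                     score_tol: float = 1e-8):
    """Newton-Raphson MLE; returns (beta, cov, loglik, converged, n_iter)."""
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        W = mu * (1.0 - mu)
        info = X.T @ (X * W[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # Dampen huge steps (separation drives |beta| to infinity).
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step *= 10.0 / norm
        beta = beta + step
    eta = X @ beta
    loglik = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    mu = 1.0 / (1.0 + np.exp(-eta))
    info = X.T @ (X * (mu * (1.0 - mu))[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, loglik, converged, it


def fit_logistic(
    group_labels: Sequence[str],
    died: Sequence[bool | int],
    reference: str,
) -> LogisticFit:
    """Unconditional logistic regression of death on group dummies.

    For this saturated dummy-only model the coefficients equal the
    contingency log-odds-ratios and the intercept equals ln(d_ref/s_ref).
    Separation (a non-reference group with all deaths or all survivors)
    is flagged as non-converged with a diagnostic.
    """
    group_labels = list(group_labels)
    y = np.asarray(died, float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one death and one survivor")
    labels = sorted(set(group_labels))
    if reference not in labels:
        raise ValueError(f"reference {reference!r} not present")
    others = [lab for lab in labels if lab != reference]
    X = np.column_stack(
        [np.ones(len(y))]
        + [np.asarray([1.0 if g == lab else 0.0 for g in group_labels])
           for lab in others]
    )

    diagnostics = None
    separated = []
    for lab in labels:
        mask = np.asarray([g == lab for g in group_labels])
        rate = y[mask].mean() if mask.any() else np.nan
        if rate in (0.0, 1.0):
            separated.append(lab)
    if separated:
        diagnostics = f"separation: group(s) {separated} have all-0 or all-1 outcomes"

    beta, cov, loglik, converged, n_iter = _newton_logistic(X, y)
    if separated:
        converged = False
    ses = np.sqrt(np.diag(cov))

    def term(name, i):
        z = beta[i] / ses[i] if ses[i] > 0 else float("nan")
        return LogisticTerm(name=name, coef=float(beta[i]), se=float(ses[i]),
                            wald_p=2.0 * float(stats.norm.sf(abs(z))))

    return LogisticFit(
        reference=reference,
        terms=[term(lab, i + 1) for i, lab in enumerate(others)],
        intercept=term("(constant)", 0),
        loglik=loglik,
        converged=converged,
        n_iter=n_iter,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    p_vs_half: float
    n_positive: int
    n_negative: int


def roc_auc(scores: Sequence[float], died: Sequence[bool | int]) -> RocResult:
    """Mann-Whitney AUC with ties counted one half; Hanley-McNeil SE.

    AUC = [#(case > control pairs) + 0.5 * #ties] / (n_case * n_control),
    computed via midranks. CI = auc -+ 1.96 se truncated to [0, 1];
    p_vs_half from z = (auc - 0.5)/se.
    """
    scores = np.asarray(scores, float)
    y = np.asarray(died, int)
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = rankdata(scores)  # midranks handle ties
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2)
           + (n0 - 1) * (q2 - auc ** 2)) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))
    z = (auc - 0.5) / se if se > 0 else float("inf")
    return RocResult(
        auc=float(auc),
        se=se,
        ci_low=max(0.0, auc - Z_95 * se),
        ci_high=min(1.0, auc + Z_95 * se),
        p_vs_half=2.0 * float(stats.norm.sf(abs(z))),
        n_positive=n1,
        n_negative=n0,
    )


def roc_curve_points(scores: Sequence[float],
                     died: Sequence[bool | int]) -> pd.DataFrame:
    """Empirical ROC coordinates (threshold, FPR, TPR), one row per cut."""
    scores = np.asarray(scores, float)
    y = np.asarray(died, int)
    n1, n0 = int(y.sum()), int(len(y) - y.sum())
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    rows = []
    for thr in thresholds:
        pred = scores >= thr
        tpr = float(np.sum(pred & (y == 1))) / n1
        fpr = float(np.sum(pred & (y == 0))) / n0
        rows.append({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA with Bonferroni-adjusted pairwise comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    t_stat: float
    raw_p: float
    adjusted_p: float


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    pairwise: list[PairwiseComparison]
    excluded: list[str] = field(default_factory=list)


def anova_bonferroni(
    values_by_group: Mapping[str, Sequence[float]],
    family_size: int | None = None,
) -> AnovaResult:
    """One-way ANOVA plus all pairwise t tests, Bonferroni-adjusted.

    Groups with fewer than 2 values are excluded with a warning. Adjusted
    p = min(1, raw_p * family_size); family_size defaults to the number
    of pairwise comparisons.
    """
    kept: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for lab, vals in values_by_group.items():
        arr = np.asarray(list(vals), float)
        if len(arr) < 2:
            excluded.append(lab)
            logger.warning("group %s has <2 values; excluded from ANOVA", lab)
        else:
            kept[lab] = arr
    if len(kept) < 2:
        raise ValueError("need at least 2 groups with >= 2 values each")
    labs = sorted(kept)
    samples = [kept[lab] for lab in labs]
    f_stat, p_value = stats.f_oneway(*samples)
    df_between = len(labs) - 1
    df_within = sum(len(s) for s in samples) - len(labs)

    pairs = [(a, b) for i, a in enumerate(labs) for b in labs[i + 1:]]
    m = family_size if family_size is not None else len(pairs)
    pairwise = []
    for a, b in pairs:
        t, p = stats.ttest_ind(kept[a], kept[b], equal_var=True)
        pairwise.append(PairwiseComparison(
            group_a=a, group_b=b,
            mean_diff=float(np.mean(kept[a]) - np.mean(kept[b])),
            t_stat=float(t), raw_p=float(p),
            adjusted_p=min(1.0, float(p) * m),
        ))
    return AnovaResult(
        f_stat=float(f_stat), df_between=df_between, df_within=df_within,
        p_value=float(p_value), pairwise=pairwise, excluded=excluded,
    )
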