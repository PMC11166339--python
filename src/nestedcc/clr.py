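"""Conditional logistic regression for 1:M matched sets, plus crude ORs.

The conditional likelihood eliminates per-set nuisance parameters by
conditioning on one case per stratum: with covariate rows x_j in stratum
s and case row x_i,

    L(beta) = prod_s exp(x_i beta) / sum_{j in s} exp(x_j beta).

The log-likelihood, score and observed information are computed
analytically and maximised by Newton-Raphson with step halving from
beta = 0. Strata whose covariate rows are all identical (no within-set
discordance) carry no information and are dropped (counted). In the 1:1
binary-exposure special case the estimate reduces to the classical
discordant-pair ratio.

Crude (unmatched) odds ratios against a fixed reference category use the
standard 2x2 cross-product with Woolf confidence intervals,
exp(ln OR +/- 1.96 * sqrt(sum of reciprocal cells)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import CATEGORIES

REFERENCE_CATEGORY = "non_user"
#: Model terms: indicator columns relative to the non-user reference.
TERMS = ("continuous_user", "irregular_user")


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the last iterate."""

    def __init__(self, message: str, beta: np.ndarray | None = None):
        super().__init__(message)
        self.beta = beta


@dataclass
class StratifiedData:
    """Design matrix + case indicator grouped into matched-set strata.

    Rows must be sorted by stratum; ``strata`` holds each row's set id.
    Exactly one case (y == 1) per stratum.
    """

    X: np.ndarray  # (n_rows, k)
    y: np.ndarray  # (n_rows,) 0/1
    strata: np.ndarray  # (n_rows,) set ids, sorted
    term_names: tuple[str, ...] = TERMS

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.strata = np.asarray(self.strata)
        order = np.argsort(self.strata, kind="stable")
        self.X, self.y, self.strata = self.X[order], self.y[order], self.strata[order]
        _, self.starts = np.unique(self.strata, return_index=True)
        counts = np.add.reduceat(self.y, self.starts)
        if not np.allclose(counts, 1.0):
            raise ValueError("each stratum must contain exactly one case")

    @property
    def n_strata(self) -> int:
        return len(self.starts)

    def informative_subset(self) -> tuple["StratifiedData", int]:
        """Drop strata whose rows are all identical (concordant sets)."""
        keep_rows = np.zeros(len(self.y), dtype=bool)
        n_dropped = 0
        bounds = np.append(self.starts, len(self.y))
        for a, b in zip(bounds[:-1], bounds[1:]):
            if np.any(self.X[a:b] != self.X[a]):
                keep_rows[a:b] = True
            else:
                n_dropped += 1
        sub = StratifiedData(
            self.X[keep_rows], self.y[keep_rows], self.strata[keep_rows], self.term_names
        )
        return sub, n_dropped

    @classmethod
    def from_matched_sets(
        cls, sets: pd.DataFrame, terms: tuple[str, ...] = TERMS
    ) -> "StratifiedData":
        """Build from a classified matched-set long frame.

        ``terms`` name the non-reference exposure categories; each
        becomes a 0/1 indicator column of the design matrix.
        """
        X = np.column_stack([(sets["category"] == t).to_numpy(float) for t in terms])
        y = (sets["role"] == "case").to_numpy(float)
        return cls(X, y, sets["set_id"].to_numpy(), tuple(terms))


def conditional_loglik(
    beta: np.ndarray, data: StratifiedData
) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact conditional log-likelihood with analytic score and information.

    Returns (loglik, score vector, observed information matrix); the
    information is the negative Hessian. At beta = 0 each stratum of size
    m contributes -log(m).
    """
    beta = np.asarray(beta, dtype=float)
    X, y, starts = data.X, data.y, data.starts
    eta = X @ beta
    # stable logsumexp per stratum
    mx = np.maximum.reduceat(eta, starts)
    reps = np.diff(np.append(starts, len(eta)))
    eta_c = eta - np.repeat(mx, reps)
    w = np.exp(eta_c)
    denom = np.add.reduceat(w, starts)
    logdenom = np.log(denom) + mx
    ll = float(np.sum(y * eta) - np.sum(logdenom))
    p = w / np.repeat(denom, reps)
    score = X.T @ (y - p)
    # information: sum_s [ sum_j p_j x_j x_j' - (sum_j p_j x_j)(...)']
    mean_x = np.empty((len(starts), X.shape[1]))
    for k in range(X.shape[1]):
        mean_x[:, k] = np.add.reduceat(p * X[:, k], starts)
    info = (X * p[:, None]).T @ X - mean_x.T @ mean_x
    return ll, score, info


@dataclass
class ClrFit:
    """Fitted conditional logistic regression."""

    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    n_strata_used: int
    n_strata_dropped: int
    converged: bool
    iterations: int
    term_names: tuple[str, ...] = TERMS
    inestimable: tuple[str, ...] = ()

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    @property
    def or_estimates(self) -> np.ndarray:
        return np.exp(self.beta)

    def wald_ci_95(self) -> np.ndarray:
        """(k, 2) array of 95% Wald limits on the OR scale."""
        z = stats.norm.ppf(0.975)
        lo = np.exp(self.beta - z * self.se)
        hi = np.exp(self.beta + z * self.se)
        return np.column_stack([lo, hi])

    @property
    def z_values(self) -> np.ndarray:
        return self.beta / self.se

    def summary_frame(self) -> pd.DataFrame:
        ci = self.wald_ci_95()
        return pd.DataFrame(
            {
                "term": list(self.term_names),
                "log_or": self.beta,
                "se": self.se,
                "or": self.or_estimates,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "z": self.z_values,
            }
        )


def fit_clr(
    data: StratifiedData,
    tol: float = 1e-8,
    max_iter: int = 50,
    _beta_bound: float = 15.0,
) -> ClrFit:
    """Maximise the conditional likelihood by Newton-Raphson.

    Starts at beta = 0, halves steps that fail to improve the
    log-likelihood, declares convergence when the maximal absolute score
    falls below ``tol``, and raises :class:`ConvergenceError` on
    non-convergence or when diverging coefficients indicate complete
    separation. Columns with no variation in the informative strata are
    reported as inestimable (NaN) rather than fitted.
    """
    sub, n_dropped = data.informative_subset()
    if sub.n_strata == 0:
        raise ValueError("no discordant stratum: model inestimable")

    active = np.flatnonzero(np.ptp(sub.X, axis=0) > 0)
    inactive = [sub.term_names[j] for j in range(sub.X.shape[1]) if j not in active]
    Xa = sub.X[:, active]
    work = StratifiedData(Xa, sub.y, sub.strata, tuple(sub.term_names[j] for j in active))

    k = Xa.shape[1]
    beta = np.zeros(k)
    ll, score, info = conditional_loglik(beta, work)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}", beta) from exc
        factor = 1.0
        for _ in range(40):
            cand = beta + factor * step
            ll_new, score_new, info_new = conditional_loglik(cand, work)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        else:
            raise ConvergenceError("step halving failed to improve likelihood", beta)
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if np.max(np.abs(beta)) > _beta_bound:
            raise ConvergenceError(
                "coefficients diverging: data likely completely separated", beta
            )
    else:
        if np.max(np.abs(score)) < tol:
            converged = True
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations", beta)

    cov_a = np.linalg.inv(info)
    p = data.X.shape[1]
    full_beta = np.full(p, np.nan)
    full_cov = np.full((p, p), np.nan)
    full_beta[active] = beta
    full_cov[np.ix_(active, active)] = cov_a
    return ClrFit(
        beta=full_beta,
        covariance=full_cov,
        loglik=ll,
        n_strata_used=sub.n_strata,
        n_strata_dropped=n_dropped,
        converged=converged,
        iterations=it,
        term_names=data.term_names,
        inestimable=tuple(inactive),
    )


def profile_ci(
    data: StratifiedData, fit: ClrFit, term: int, level: float = 0.95
) -> tuple[float, float]:
    """Profile-likelihood CI for one coefficient (OR scale).

    Inverts the likelihood-ratio test by bisection on each side of the
    maximum; the other coefficients are re-maximised at each probe via a
    short inner Newton loop.
    """
    sub, _ = data.informative_subset()
    target = stats.chi2.ppf(level, df=1) / 2.0
    k = data.X.shape[1]
    free = [j for j in range(k) if j != term and not np.isnan(fit.beta[j])]

    def profile_ll(val: float) -> float:
        beta = np.array([fit.beta[j] if not np.isnan(fit.beta[j]) else 0.0 for j in range(k)])
        beta[term] = val
        for _ in range(50):
            ll, score, info = conditional_loglik(beta, sub)
            if not free:
                return ll
            s = score[free]
            if np.max(np.abs(s)) < 1e-9:
                return ll
            h = info[np.ix_(free, free)]
            beta[free] += np.linalg.solve(h, s)
        return ll

    mle = fit.beta[term]
    ll_max = profile_ll(mle)

    def bound(direction: float) -> float:
        step = fit.se[term]
        hi = mle + direction * step
        while ll_max - profile_ll(hi) < target:
            step *= 2.0
            hi = mle + direction * step
            if abs(hi - mle) > 50 * fit.se[term]:
                return direction * np.inf
        lo = mle
        for _ in range(60):
            mid = (lo + hi) / 2.0
            if ll_max - profile_ll(mid) < target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2.0

    return float(np.exp(bound(-1.0))), float(np.exp(bound(+1.0)))


# ---------------------------------------------------------------------------
# crude (unmatched) analysis


@dataclass
class CrudeTable:
    """Category x (case, control) counts with a fixed reference row."""

    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    reference: str = REFERENCE_CATEGORY

    def __post_init__(self) -> None:
        for cat, (a, b) in self.counts.items():
            if a < 0 or b < 0:
                raise ValueError(f"negative count for {cat}")
        if self.reference not in self.counts:
            raise ValueError(f"reference category {self.reference!r} missing")

    @property
    def n_cases(self) -> int:
        return sum(a for a, _ in self.counts.values())

    @property
    def n_controls(self) -> int:
        return sum(b for _, b in self.counts.values())

    def column_percentages(self) -> dict[str, tuple[float, float]]:
        """Within-column percentages, as printed in study tables."""
        nc, nk = self.n_cases, self.n_controls
        return {
            cat: (100.0 * a / nc if nc else np.nan, 100.0 * b / nk if nk else np.nan)
            for cat, (a, b) in self.counts.items()
        }

    @classmethod
    def from_matched_sets(cls, sets: pd.DataFrame, reference: str = REFERENCE_CATEGORY):
        counts = {}
        for cat in CATEGORIES:
            sub = sets[sets["category"] == cat]
            counts[cat] = (
                int((sub["role"] == "case").sum()),
                int((sub["role"] == "control").sum()),
            )
        return cls(counts=counts, reference=reference)


def crude_or(table: CrudeTable) -> dict[str, tuple[float, tuple[float, float]]]:
    """Crude OR with Woolf 95% CI for each non-reference category.

    OR = (case_cat * control_ref) / (control_cat * case_ref). A zero cell
    raises (consider a continuity correction explicitly; none is applied
    silently).
    """
    ref_case, ref_ctrl = table.counts[table.reference]
    out = {}
    for cat, (a, b) in table.counts.items():
        if cat == table.reference:
            continue
        cells = (a, b, ref_case, ref_ctrl)
        if any(c == 0 for c in cells):
            raise ValueError(
                f"zero cell in 2x2 comparison for {cat!r}; "
                "apply a continuity correction explicitly if intended"
            )
        orr = (a * ref_ctrl) / (b * ref_case)
        se = np.sqrt(sum(1.0 / c for c in cells))
        lo, hi = np.exp(np.log(orr) - 1.96 * se), np.exp(np.log(orr) + 1.96 * se)
        out[cat] = (float(orr), (float(lo), float(hi)))
    return out


@dataclass
class ExposureSummary:
    """Exposure-category analysis in the study's reporting shape."""

    table: CrudeTable
    crude: dict[str, tuple[float, tuple[float, float]]]
    fit: ClrFit | None
    frame: pd.DataFrame

    def report(self) -> str:
        lines = ["Prescription status  Case  (%)    Control  (%)   Crude OR (95% CI)   Adjusted OR (95% CI)"]
        for _, r in self.frame.iterrows():
            lines.append(
                f"{r['category']:<20} {r['cases']:>4} ({r['case_pct']:.1f}) "
                f"{r['controls']:>6} ({r['control_pct']:.1f})  "
                f"{_fmt_or(r['crude_or'], r['crude_lo'], r['crude_hi'])}   "
                f"{_fmt_or(r['adj_or'], r['adj_lo'], r['adj_hi'])}"
            )
        return "\n".join(lines)


def _fmt_or(orr: float, lo: float, hi: float) -> str:
    if np.isnan(orr):
        return "inestimable"
    if orr == 1.0 and np.isnan(lo):
        return "1 (reference)"
    return f"{orr:.2f} ({lo:.2f}-{hi:.2f})"


def summarize_exposure_table(sets: pd.DataFrame) -> ExposureSummary:
    """Counts, column percentages, crude ORs and the matched CLR fit.

    ``sets`` is a classified matched-set long frame. Categories with no
    members (or no discordance) yield NaN ("inestimable") ORs instead of
    failing the whole summary.
    """
    table = CrudeTable.from_matched_sets(sets)
    try:
        crude = crude_or(table)
    except ValueError:
        crude = {}
    fit = None
    try:
        data = StratifiedData.from_matched_sets(sets)
        fit = fit_clr(data)
    except (ValueError, ConvergenceError):
        fit = None

    pct = table.column_percentages()
    rows = []
    for cat in CATEGORIES:
        a, b = table.counts.get(cat, (0, 0))
        row = {
            "category": cat,
            "cases": a,
            "controls": b,
            "case_pct": pct.get(cat, (np.nan, np.nan))[0],
            "control_pct": pct.get(cat, (np.nan, np.nan))[1],
        }
        if cat == table.reference:
            row.update(crude_or=1.0, crude_lo=np.nan, crude_hi=np.nan,
                       adj_or=1.0, adj_lo=np.nan, adj_hi=np.nan)
        else:
            if cat in crude:
                orr, (lo, hi) = crude[cat]
                row.update(crude_or=orr, crude_lo=lo, crude_hi=hi)
            else:
                row.update(crude_or=np.nan, crude_lo=np.nan, crude_hi=np.nan)
            if fit is not None and cat in fit.term_names:
                j = fit.term_names.index(cat)
                ci = fit.wald_ci_95()
                row.update(adj_or=fit.or_estimates[j], adj_lo=ci[j, 0], adj_hi=ci[j, 1])
            else:
                row.update(adj_or=np.nan, adj_lo=np.nan, adj_hi=np.nan)
        rows.append(row)
    return ExposureSummary(table=table, crude=crude, fit=fit, frame=pd.DataFrame(rows))


def run_subgroup(sets: pd.DataFrame, stratifier: str) -> dict[str, ExposureSummary]:
    """Refit within subgroups defined on the *case's* attributes.

    ``stratifier`` is ``"age"`` (splits at 65 years: under_65 / 65_plus)
    or ``"index_nsaid"`` (loxoprofen / celecoxib / diclofenac). Whole
    sets follow their case.
    """
    cases = sets[sets["role"] == "case"].set_index("set_id")
    if stratifier == "age":
        groups = {
            "under_65": cases.index[cases["age_at_t0"] < 65],
            "65_plus": cases.index[cases["age_at_t0"] >= 65],
        }
    elif stratifier == "index_nsaid":
        groups = {
            t: cases.index[cases["index_nsaid_type"] == t]
            for t in ("loxoprofen", "celecoxib", "diclofenac")
        }
    else:
        raise ValueError(f"unknown stratifier {stratifier!r}")
    out = {}
    for name, ids in groups.items():
        sub = sets[sets["set_id"].isin(ids)]
        if len(sub):
            out[name] = summarize_exposure_table(sub)
    return out
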