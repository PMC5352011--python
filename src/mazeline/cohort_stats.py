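"""Cohort-level statistics for disfluency-event tables.

The inferential workhorse is a mixed-effects logistic regression with a
per-subject random intercept: each disfluency event is a Bernoulli token
(e.g. content maze vs filler) and the fixed effects are diagnostic group
(sum-coded), standardized verbal IQ, and ADOS activity (sum-coded).
Maximum likelihood is computed by Gauss-Hermite quadrature over the
random intercept; per-factor significance comes from likelihood-ratio
tests, and group contrasts from all-pairs single-step (Tukey-HSD style)
familywise-adjusted z tests.

Also here: Kendall's tau-b exploratory correlations with
Benjamini-Hochberg FDR adjustment, Welch's unequal-variance t test, the
two-sample Anderson-Darling test, and the greedy group-matching search
that trims a cohort until every matching constraint passes both tests at
p >= 0.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .disfluency_core import DisfluencyEvent, DType
from .transcript_io import Activity

__all__ = [
    "SubjectRecord",
    "TokenRow",
    "Contrast",
    "RegressionResult",
    "CorrelationResult",
    "MatchConstraint",
    "MatchResult",
    "MissingCovariate",
    "ZeroVariance",
    "DegenerateSample",
    "AllTied",
    "Unsatisfiable",
    "NonConvergence",
    "build_token_table",
    "z_transform",
    "fit_mixed_logit",
    "kendall_tau_b",
    "bh_adjust",
    "welch_t",
    "anderson_darling_2s",
    "match_groups",
]

GROUP_ORDER = ("ASD", "SLI", "TD", "ALI", "ALN")
ACTIVITY_ORDER = tuple(a.name for a in Activity)


class MissingCovariate(KeyError):
    pass


class ZeroVariance(ValueError):
    pass


class DegenerateSample(ValueError):
    pass


class AllTied(ValueError):
    pass


class Unsatisfiable(ValueError):
    pass


class NonConvergence(RuntimeError):
    pass


@dataclass
class SubjectRecord:
    child_id: str
    group: str
    viq: float | None = None
    ados_module: int = 3
    covariates: dict[str, float] = field(default_factory=dict)

    def value(self, name: str) -> float:
        if name.lower() == "viq" and self.viq is not None:
            return self.viq
        if name in self.covariates:
            return self.covariates[name]
        raise MissingCovariate(f"{self.child_id}: no covariate {name!r}")


@dataclass(frozen=True)
class TokenRow:
    child_id: str
    outcome: int
    group: str
    viq_z: float
    activity: str


class Contrast(str, Enum):
    CONTENT_VS_FILLER = "content_vs_filler"
    REP_VS_REV = "rep_vs_rev"
    FS_VS_REPAIRBASED = "fs_vs_repairbased"
    CUED_VS_UNCUED = "cued_vs_uncued"


_CONTENT = {DType.REP, DType.REV, DType.FS}


def z_transform(values: Sequence[float]) -> np.ndarray:
    """Standardize to mean 0, unit (unbiased) standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ZeroVariance("need at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ZeroVariance("constant input")
    return (x - x.mean()) / sd


def build_token_table(
    events: Sequence[DisfluencyEvent],
    subjects: Mapping[str, SubjectRecord] | Sequence[SubjectRecord],
    contrast: Contrast | str,
    exclude_module: int | None = None,
) -> list[TokenRow]:
    """One binary token per included event, for the requested contrast.

    CONTENT_VS_FILLER keeps all events (1 = content maze);
    REP_VS_REV keeps repetitions and revisions (1 = repetition);
    FS_VS_REPAIRBASED keeps content events (1 = false start);
    CUED_VS_UNCUED keeps content events (1 = cued).
    Verbal IQ is z-scored over the distinct included subjects.
    """
    contrast = Contrast(contrast)
    if not isinstance(subjects, Mapping):
        subjects = {s.child_id: s for s in subjects}

    def keep_outcome(ev: DisfluencyEvent) -> tuple[bool, int]:
        if contrast is Contrast.CONTENT_VS_FILLER:
            return True, int(ev.dtype in _CONTENT)
        if contrast is Contrast.REP_VS_REV:
            return ev.dtype in (DType.REP, DType.REV), int(ev.dtype is DType.REP)
        if contrast is Contrast.FS_VS_REPAIRBASED:
            return ev.dtype in _CONTENT, int(ev.dtype is DType.FS)
        return ev.dtype in _CONTENT, int(ev.cued)

    kept: list[tuple[DisfluencyEvent, int]] = []
    for ev in events:
        if ev.child_id not in subjects:
            raise MissingCovariate(f"no subject record for {ev.child_id!r}")
        subj = subjects[ev.child_id]
        if exclude_module is not None and subj.ados_module == exclude_module:
            continue
        if subj.viq is None:
            raise MissingCovariate(f"{ev.child_id}: verbal IQ missing")
        inc, y = keep_outcome(ev)
        if inc:
            kept.append((ev, y))

    ids = sorted({ev.child_id for ev, _ in kept})
    try:
        viq_z = dict(zip(ids, z_transform([subjects[c].viq for c in ids])))
    except ZeroVariance:
        # one included subject, or all identical scores: centred at zero
        viq_z = {c: 0.0 for c in ids}
    return [
        TokenRow(
            child_id=ev.child_id,
            outcome=y,
            group=subjects[ev.child_id].group,
            viq_z=float(viq_z[ev.child_id]),
            activity=ev.activity.name if ev.activity is not None else "CONVERSATION",
        )
        for ev, y in kept
    ]


# ---------------------------------------------------------------------------
# mixed-effects logistic regression (random intercept, Gauss-Hermite ML)


def _level_order(levels: set[str], canonical: tuple[str, ...]) -> list[str]:
    ordered = [l for l in canonical if l in levels]
    return ordered + sorted(levels - set(ordered))


def _sum_code(values: Sequence[str], levels: list[str]) -> np.ndarray:
    """Sum (deviation) coding: len(levels)-1 columns; last level = -1 row."""
    idx = {l: i for i, l in enumerate(levels)}
    k = len(levels)
    out = np.zeros((len(values), k - 1))
    for r, v in enumerate(values):
        i = idx[v]
        if i < k - 1:
            out[r, i] = 1.0
        else:
            out[r, :] = -1.0
    return out


@dataclass
class LRT:
    chi2: float
    dof: int
    p: float


@dataclass
class PosthocContrast:
    pair: tuple[str, str]
    estimate: float
    se: float
    z: float
    p_adj: float


@dataclass
class RegressionResult:
    intercept: tuple[float, float]
    group: dict[str, tuple[float, float]]
    viq: tuple[float, float]
    activity: dict[str, tuple[float, float]]
    sigma: float
    loglik: float
    lrt: dict[str, LRT]
    posthoc: list[PosthocContrast]
    converged: bool
    n_obs: int
    n_subjects: int
    diagnostics: str = ""


class _GHLogit:
    """Random-intercept logit marginal likelihood, adaptive Gauss-Hermite.

    Quadrature nodes are recentred per subject on the posterior mode of
    the random intercept with the Laplace width, so accuracy does not
    degrade when subjects contribute many observations (where the
    integrand is far narrower than the prior).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, subj: np.ndarray, n_quad: int = 20):
        self.X, self.y, self.subj = X, y.astype(float), subj
        self.n_subj = int(subj.max()) + 1
        nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
        self.z = nodes
        self.logw_adj = np.log(weights) + nodes**2  # GH weights with e^{z^2} factor
        self.sign = 2.0 * self.y - 1.0

    def _modes(self, eta: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mode and Laplace sd of each subject's intercept."""
        b = np.zeros(self.n_subj)
        inv_v = 1.0 / sigma**2
        for _ in range(50):
            p = 1.0 / (1.0 + np.exp(-(eta + b[self.subj])))
            g1 = np.bincount(self.subj, weights=self.y - p, minlength=self.n_subj) - b * inv_v
            h = -np.bincount(self.subj, weights=p * (1 - p), minlength=self.n_subj) - inv_v
            step = g1 / h
            b -= step
            if np.abs(g1).max() < 1e-10:
                break
        p = 1.0 / (1.0 + np.exp(-(eta + b[self.subj])))
        h = -np.bincount(self.subj, weights=p * (1 - p), minlength=self.n_subj) - inv_v
        return b, 1.0 / np.sqrt(-h)

    def loglik_grad(self, params: np.ndarray) -> tuple[float, np.ndarray]:
        beta, sigma = params[:-1], float(params[-1])
        eta = self.X @ beta
        if sigma < 1e-6:
            # degenerate prior: plain logistic likelihood
            ll = float(-np.logaddexp(0.0, -self.sign * eta).sum())
            resid = self.y - 1.0 / (1.0 + np.exp(-eta))
            return ll, np.concatenate([self.X.T @ resid, [0.0]])
        mode, tau = self._modes(eta, sigma)
        B = mode[:, None] + np.sqrt(2.0) * tau[:, None] * self.z[None, :]  # (S, K)
        E = eta[:, None] + B[self.subj]
        ll_rows = -np.logaddexp(0.0, -self.sign[:, None] * E)
        H = np.zeros((self.n_subj, len(self.z)))
        np.add.at(H, self.subj, ll_rows)
        H += -(B**2) / (2 * sigma**2) - np.log(sigma) - 0.5 * np.log(2 * np.pi)
        logc = (
            H
            + self.logw_adj[None, :]
            + 0.5 * np.log(2.0)
            + np.log(tau)[:, None]
        )
        mx = logc.max(axis=1, keepdims=True)
        expc = np.exp(logc - mx)
        denom = expc.sum(axis=1)
        ll = float((mx[:, 0] + np.log(denom)).sum())
        alpha = expc / denom[:, None]  # posterior quadrature weights per subject
        w_rows = alpha[self.subj]
        resid = self.y[:, None] - 1.0 / (1.0 + np.exp(-E))
        g_beta = self.X.T @ (w_rows * resid).sum(axis=1)
        g_sigma = float((alpha * (B**2 / sigma**3 - 1.0 / sigma)).sum())
        return ll, np.concatenate([g_beta, [g_sigma]])

    def neg(self, params: np.ndarray) -> tuple[float, np.ndarray]:
        ll, g = self.loglik_grad(params)
        return -ll, -g


def _fit_gh(
    X: np.ndarray,
    y: np.ndarray,
    subj: np.ndarray,
    n_quad: int,
    start: np.ndarray | None,
    fix_sigma: float | None = None,
) -> tuple[np.ndarray, float, _GHLogit, bool, str]:
    model = _GHLogit(X, y, subj, n_quad)
    p = X.shape[1]
    if start is None:
        start = np.concatenate([np.zeros(p), [0.5 if fix_sigma is None else fix_sigma]])
    bounds = [(None, None)] * p + [
        (0.0, None) if fix_sigma is None else (fix_sigma, fix_sigma)
    ]
    if fix_sigma is not None:
        start = start.copy()
        start[-1] = fix_sigma
    res = optimize.minimize(
        model.neg, start, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 2000, "maxfun": 5000, "ftol": 1e-15, "gtol": 1e-7},
    )
    _, g = model.loglik_grad(res.x)
    if fix_sigma is not None or res.x[-1] <= 1e-8:
        g = g[:-1]  # sigma fixed or on the boundary: its gradient is unconstrained
    # convergence declared when the gradient is numerically flat at the
    # scale of the data (inf-norm below 1e-4 per 1000 observations)
    tol = 1e-4 * max(1.0, len(y) / 1000.0)
    converged = bool(np.linalg.norm(g, ord=np.inf) < tol)
    return res.x, -res.fun, model, converged, res.message


def _numeric_hessian(model: _GHLogit, params: np.ndarray, h: float = 1e-5) -> np.ndarray:
    k = params.size
    H = np.zeros((k, k))
    for j in range(k):
        step = h * max(1.0, abs(params[j]))
        lo, hi = params.copy(), params.copy()
        hi[j] += step
        lo[j] -= step
        if lo[j] < 0 and j == k - 1:
            lo[j] = 0.0
        _, g_hi = model.loglik_grad(hi)
        _, g_lo = model.loglik_grad(lo)
        H[j] = (g_hi - g_lo) / (hi[j] - lo[j])
    return -(H + H.T) / 2.0  # observed information


def _single_step_maxz_p(
    z_obs: np.ndarray, cov: np.ndarray, seed: int = 20170315, n_draws: int = 200_000
) -> np.ndarray:
    """Familywise p for each contrast: P(max_j |Z_j| >= |z_obs_j|).

    The joint normal of the contrasts is typically singular (all pairs of
    a factor), so the max-|Z| distribution is evaluated by quasi-random
    sampling of the underlying normal, as multcomp-style single-step
    adjustment does.
    """
    d = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    R = cov / np.outer(d, d)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R + 1e-10 * np.eye(len(R)))
    Z = rng.standard_normal((n_draws, len(R))) @ L.T
    maxabs = np.abs(Z).max(axis=1)
    return np.array([float((maxabs >= abs(z)).mean()) for z in z_obs])


def fit_mixed_logit(
    rows: Sequence[TokenRow],
    n_quad: int = 25,
    posthoc: bool = True,
    lrt_factors: Sequence[str] = ("group", "viq", "activity"),
    fix_sigma: float | None = None,
) -> RegressionResult:
    """Fit the random-intercept logit and run LRTs and group post hocs.

    Fixed effects: sum-coded group, z-scored verbal IQ, sum-coded
    activity (omitted when only one activity is present).  Each factor's
    likelihood-ratio test refits the model without the whole factor.
    Post hoc group contrasts use single-step max-|Z| adjustment.
    """
    if not rows:
        raise ValueError("empty token table")
    groups = _level_order({r.group for r in rows}, GROUP_ORDER)
    activities = _level_order({r.activity for r in rows}, ACTIVITY_ORDER)
    if len(groups) < 2:
        raise ValueError("need at least two groups")

    children = sorted({r.child_id for r in rows})
    subj_idx = {c: i for i, c in enumerate(children)}
    subj = np.array([subj_idx[r.child_id] for r in rows])
    y = np.array([r.outcome for r in rows], dtype=float)
    if y.min() == y.max():
        raise DegenerateSample("outcome is constant: complete separation")

    Xg = _sum_code([r.group for r in rows], groups)
    Xv = np.array([[r.viq_z] for r in rows])
    blocks: dict[str, np.ndarray] = {"group": Xg, "viq": Xv}
    if len(activities) > 1:
        blocks["activity"] = _sum_code([r.activity for r in rows], activities)
    ones = np.ones((len(rows), 1))
    X = np.hstack([ones] + list(blocks.values()))

    # column slices per factor (after the intercept)
    slices: dict[str, slice] = {}
    at = 1
    for name, B in blocks.items():
        slices[name] = slice(at, at + B.shape[1])
        at += B.shape[1]

    params, ll_full, model, converged, msg = _fit_gh(X, y, subj, n_quad, None, fix_sigma)
    beta, sigma = params[:-1], float(params[-1])

    H = _numeric_hessian(model, params)
    try:
        cov_all = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(H)
    cov_beta = cov_all[: len(beta), : len(beta)]
    se = np.sqrt(np.clip(np.diag(cov_beta), 0, None))

    def level_table(factor: str, levels: list[str]) -> dict[str, tuple[float, float]]:
        sl = slices[factor]
        b = beta[sl]
        V = cov_beta[sl, sl]
        out: dict[str, tuple[float, float]] = {}
        for i, lev in enumerate(levels[:-1]):
            out[lev] = (float(b[i]), float(np.sqrt(V[i, i])))
        last = -b.sum()
        last_se = float(np.sqrt(np.ones(len(b)) @ V @ np.ones(len(b))))
        out[levels[-1]] = (float(last), last_se)
        return out

    lrt: dict[str, LRT] = {}
    for factor in lrt_factors:
        if factor not in slices:
            continue
        sl = slices[factor]
        keep = [j for j in range(X.shape[1]) if not (sl.start <= j < sl.stop)]
        Xr = X[:, keep]
        start = np.concatenate([params[keep], [sigma]])
        _, ll_red, _, _, _ = _fit_gh(Xr, y, subj, n_quad, start, fix_sigma)
        chi2 = max(0.0, 2.0 * (ll_full - ll_red))
        dof = sl.stop - sl.start
        lrt[factor] = LRT(chi2=chi2, dof=dof, p=float(stats.chi2.sf(chi2, dof)))

    contrasts: list[PosthocContrast] = []
    if posthoc and len(groups) >= 2:
        sl = slices["group"]
        bg = beta[sl]
        Vg = cov_beta[sl, sl]
        k = len(groups)

        def coef_vec(i: int) -> np.ndarray:
            v = np.zeros(k - 1)
            if i < k - 1:
                v[i] = 1.0
            else:
                v[:] = -1.0
            return v

        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
        C = np.array([coef_vec(i) - coef_vec(j) for i, j in pairs])
        est = C @ bg
        Vc = C @ Vg @ C.T
        se_c = np.sqrt(np.clip(np.diag(Vc), 1e-300, None))
        zed = est / se_c
        if len(pairs) == 1:
            p_adj = 2.0 * stats.norm.sf(np.abs(zed))
        else:
            p_adj = _single_step_maxz_p(zed, Vc)
        for (i, j), e, s_, z_, p_ in zip(pairs, est, se_c, zed, p_adj):
            contrasts.append(
                PosthocContrast(
                    pair=(groups[i], groups[j]),
                    estimate=float(e),
                    se=float(s_),
                    z=float(z_),
                    p_adj=float(min(1.0, p_)),
                )
            )

    if not converged:
        warnings.warn(f"mixed logit did not converge: {msg}", stacklevel=2)

    return RegressionResult(
        intercept=(float(beta[0]), float(se[0])),
        group=level_table("group", groups),
        viq=(float(beta[slices["viq"].start]), float(se[slices["viq"].start])),
        activity=level_table("activity", activities) if "activity" in slices else {},
        sigma=sigma,
        loglik=ll_full,
        lrt=lrt,
        posthoc=contrasts,
        converged=converged,
        n_obs=len(rows),
        n_subjects=len(children),
        diagnostics=msg,
    )


# ---------------------------------------------------------------------------
# exploratory and matching statistics


@dataclass
class CorrelationResult:
    tau_b: float
    p: float
    p_adjusted: float
    n: int


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Kendall's tau-b (tie-corrected) with a two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise AllTied("a fully tied variable has no rank correlation")
    res = stats.kendalltau(x, y, variant="b", method="auto")
    return CorrelationResult(
        tau_b=float(res.statistic), p=float(res.pvalue), p_adjusted=float(res.pvalue), n=x.size
    )


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t test: (t, Satterthwaite dof, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DegenerateSample("each sample needs >= 2 observations")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        raise DegenerateSample("both samples are constant")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def anderson_darling_2s(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "asymptotic",
    n_resamples: int = 999,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Two-sample Anderson-Darling test (midrank k-sample version).

    ``method="asymptotic"`` uses the standard interpolated p (clipped to
    [0.001, 0.25]); ``method="permutation"`` draws ``n_resamples``
    permutations instead, which is preferable at very small n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DegenerateSample("each sample needs >= 2 observations")
    kwargs = {}
    if method == "permutation":
        kwargs["method"] = stats.PermutationMethod(
            n_resamples=n_resamples, rng=np.random.default_rng(seed)
        )
    elif method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns when p is clipped
        try:
            res = stats.anderson_ksamp([x, y], **kwargs)
        except ValueError as exc:
            raise DegenerateSample(str(exc)) from exc
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class MatchConstraint:
    variable: str
    groups: tuple[str, ...]


@dataclass
class ConstraintResult:
    variable: str
    groups: tuple[str, ...]
    welch_p: float  # minimum over group pairs
    ad_p: float


@dataclass
class MatchResult:
    retained: list[str]
    tests: list[ConstraintResult]
    satisfied: bool


def _constraint_tests(
    subjects: Sequence[SubjectRecord], c: MatchConstraint, ad_method: str
) -> ConstraintResult:
    by_group = {
        g: np.array([s.value(c.variable) for s in subjects if s.group == g]) for g in c.groups
    }
    for g, vals in by_group.items():
        if vals.size < 2:
            raise Unsatisfiable(f"group {g} too small for constraint on {c.variable}")
    welch_ps = []
    for i in range(len(c.groups)):
        for j in range(i + 1, len(c.groups)):
            welch_ps.append(welch_t(by_group[c.groups[i]], by_group[c.groups[j]])[2])
    ad_ps = []
    for i in range(len(c.groups)):
        for j in range(i + 1, len(c.groups)):
            ad_ps.append(
                anderson_darling_2s(
                    by_group[c.groups[i]], by_group[c.groups[j]], method=ad_method
                )[1]
            )
    return ConstraintResult(
        variable=c.variable, groups=c.groups, welch_p=min(welch_ps), ad_p=min(ad_ps)
    )


def match_groups(
    subjects: Sequence[SubjectRecord],
    constraints: Sequence[MatchConstraint],
    threshold: float = 0.2,
    min_group_size: int = 3,
    ad_method: str = "asymptotic",
) -> MatchResult:
    """Greedy cohort trimming until all matching constraints pass.

    Repeatedly removes the single subject whose exclusion most increases
    the worst constraint p value, stopping when every Welch and
    Anderson-Darling p is >= ``threshold``.  Raises :class:`Unsatisfiable`
    when no removal makes progress or a group would shrink below
    ``min_group_size``.
    """
    pool = list(subjects)

    def score(pool_: Sequence[SubjectRecord]) -> tuple[float, list[ConstraintResult]]:
        results = [_constraint_tests(pool_, c, ad_method) for c in constraints]
        return min(min(r.welch_p, r.ad_p) for r in results), results

    current, results = score(pool)
    while current < threshold:
        failing_groups = {
            g
            for r in results
            if min(r.welch_p, r.ad_p) < threshold
            for g in r.groups
        }
        best_score, best_idx = current, None
        for idx, s in enumerate(pool):
            if s.group not in failing_groups:
                continue
            if sum(1 for t in pool if t.group == s.group) <= min_group_size:
                continue
            trial = pool[:idx] + pool[idx + 1 :]
            try:
                sc, _ = score(trial)
            except Unsatisfiable:
                continue
            if sc > best_score:
                best_score, best_idx = sc, idx
        if best_idx is None:
            raise Unsatisfiable(
                f"no single removal raises the worst matching p above {current:.3f}"
            )
        pool.pop(best_idx)
        current, results = score(pool)

    return MatchResult(
        retained=[s.child_id for s in pool], tests=results, satisfied=True
    )
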