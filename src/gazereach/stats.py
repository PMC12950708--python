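"""Inferential layer: mixed ANOVA, paired/independent tests, mixed models.

Three families, mirroring the analyses the pipeline's metrics feed:

* :class:`MixedAnova` — split-plot (one between-subjects factor, one
  repeated factor) sums-of-squares ANOVA with partial η², Greenhouse–Geisser
  ε and Mauchly's sphericity test (correction applied conditionally for 3+
  within levels).
* :func:`compare_blocks` / :func:`compare_groups` — paired and independent
  comparisons; the paired test falls back to the Wilcoxon signed-rank test
  when Shapiro–Wilk rejects normality of the differences.
* :class:`RandomInterceptModel` — linear mixed model with a participant
  random intercept, REML-estimated by profiling the variance ratio (fast,
  closed-form GLS per candidate ratio), plus a robust variant using
  iteratively reweighted REML with Huber ψ (c = 1.345) applied to both
  residuals and random effects.  Significance is judged by whether 0 lies
  outside the Wald 95% CI, as robust mixed models do not provide p-values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .exceptions import ConfigurationError, ConvergenceError

__all__ = [
    "AnovaEffect",
    "MixedAnova",
    "MixedAnovaResults",
    "mixed_anova",
    "TestResult",
    "compare_blocks",
    "compare_groups",
    "wilcoxon_signed_rank",
    "RandomInterceptModel",
    "MixedModelResults",
    "fit_random_intercept_model",
]

HUBER_C = 1.345


# ---------------------------------------------------------------------------
# mixed (split-plot) ANOVA

@dataclass(frozen=True)
class AnovaEffect:
    name: str
    ss: float
    ss_error: float
    df1: float
    df2: float
    F: float
    p: float
    partial_eta_sq: float
    gg_epsilon: float | None = None
    corrected: bool = False


@dataclass
class MixedAnovaResults:
    effects: dict[str, AnovaEffect]
    ss_total: float
    ss_components: dict[str, float]
    epsilon: float | None
    mauchly: tuple[float, float, float, float] | None  # (W, chi2, df, p)
    k_within: int
    n_subjects: int

    def anova_table(self) -> pd.DataFrame:
        rows = []
        for e in self.effects.values():
            rows.append(
                {
                    "effect": e.name,
                    "SS": e.ss,
                    "df1": e.df1,
                    "df2": e.df2,
                    "F": e.F,
                    "p": e.p,
                    "partial_eta_sq": e.partial_eta_sq,
                    "gg_epsilon": e.gg_epsilon,
                    "sphericity_corrected": e.corrected,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Mixed ANOVA ({self.n_subjects} subjects, {self.k_within} within levels)"]
        for e in self.effects.values():
            lines.append(
                f"  {e.name:<12} F({e.df1:.2f}, {e.df2:.2f}) = {e.F:.2f}, "
                f"p = {e.p:.3f}, partial eta^2 = {e.partial_eta_sq:.2f}"
                + (" [GG corrected]" if e.corrected else "")
            )
        if self.mauchly is not None:
            w, chi2, df, p = self.mauchly
            lines.append(f"  Mauchly W = {w:.3f}, chi2({df:.0f}) = {chi2:.2f}, p = {p:.3f}")
        return "\n".join(lines)


class MixedAnova:
    """Split-plot ANOVA model: one within factor, optional between factor.

    ``data`` is long format with one row per subject × within-level cell.
    Between-subject effects are tested against subjects-within-groups;
    within and interaction effects against the block × subject error.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        dv: str,
        within: str,
        subject: str,
        between: str | None = None,
    ) -> None:
        self.dv, self.within, self.subject, self.between = dv, within, subject, between
        wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
        if wide.isna().any().any():
            missing = wide[wide.isna().any(axis=1)].index.tolist()
            raise ConfigurationError(
                f"missing within-level cells for subject(s) {missing}"
            )
        self._wide = wide
        if between is not None:
            g = data.groupby(subject)[between].first().reindex(wide.index)
            if g.isna().any():
                raise ConfigurationError("missing between-group label for some subjects")
            self._groups = g
        else:
            self._groups = pd.Series("all", index=wide.index)

    def fit(self, sphericity: str = "auto", alpha: float = 0.05) -> MixedAnovaResults:
        if sphericity not in ("auto", "always", "never"):
            raise ConfigurationError(f"unknown sphericity mode {sphericity!r}")
        Y = self._wide.to_numpy(dtype=float)
        n, k = Y.shape
        groups = self._groups.to_numpy()
        labels = pd.unique(groups)
        G = len(labels)
        if n < G + 1:
            raise ConfigurationError("need more subjects than groups")

        grand = Y.mean()
        subj_means = Y.mean(axis=1)
        block_means = Y.mean(axis=0)
        group_masks = [groups == lab for lab in labels]
        n_g = np.array([m.sum() for m in group_masks])
        group_means = np.array([subj_means[m].mean() for m in group_masks])
        cell_means = np.array([Y[m].mean(axis=0) for m in group_masks])  # G x k

        ss_total = float(((Y - grand) ** 2).sum())
        ss_between_subj = float(k * ((subj_means - grand) ** 2).sum())
        ss_A = float(k * (n_g * (group_means - grand) ** 2).sum())
        ss_subj_within = ss_between_subj - ss_A
        ss_B = float(n * ((block_means - grand) ** 2).sum())
        ss_AB = float(
            sum(
                n_g[i] * ((cell_means[i] - group_means[i] - block_means + grand) ** 2).sum()
                for i in range(G)
            )
        )
        ss_err = ss_total - ss_between_subj - ss_B - ss_AB

        df_A, df_SA = G - 1, n - G
        df_B = k - 1
        df_AB = (G - 1) * (k - 1)
        df_err = (n - G) * (k - 1)

        # Greenhouse–Geisser epsilon and Mauchly, from the pooled
        # within-group covariance of the repeated measures
        epsilon = None
        mauchly = None
        if k >= 2:
            dev = np.vstack([Y[m] - cell_means[i] for i, m in enumerate(group_masks)])
            S = dev.T @ dev / df_SA
            Sc = S - S.mean(axis=0) - S.mean(axis=1)[:, None] + S.mean()
            denom = (k - 1) * (Sc * Sc).sum()
            epsilon = float(np.trace(Sc) ** 2 / denom) if denom > 0 else 1.0
            epsilon = min(max(epsilon, 1.0 / (k - 1)), 1.0)
            if k >= 3:
                mauchly = _mauchly(S, k, df_SA)

        correct = sphericity == "always" or (
            sphericity == "auto" and mauchly is not None and mauchly[3] < alpha
        )

        effects: dict[str, AnovaEffect] = {}
        ms_SA = ss_subj_within / df_SA
        ms_err = ss_err / df_err if df_err > 0 else np.nan

        if G > 1:
            F_A = (ss_A / df_A) / ms_SA if ms_SA > 0 else math.inf
            effects["between"] = AnovaEffect(
                "between",
                ss_A,
                ss_subj_within,
                df_A,
                df_SA,
                F_A,
                float(sps.f.sf(F_A, df_A, df_SA)),
                ss_A / (ss_A + ss_subj_within),
            )

        for name, ss_eff, df_eff in (("within", ss_B, df_B), ("interaction", ss_AB, df_AB)):
            if df_eff == 0:
                continue
            F = (ss_eff / df_eff) / ms_err if ms_err > 0 else math.inf
            d1, d2 = df_eff, df_err
            corrected = False
            if correct and epsilon is not None:
                d1, d2 = df_eff * epsilon, df_err * epsilon
                corrected = True
            effects[name] = AnovaEffect(
                name,
                ss_eff,
                ss_err,
                d1,
                d2,
                F,
                float(sps.f.sf(F, d1, d2)),
                ss_eff / (ss_eff + ss_err),
                gg_epsilon=epsilon if k >= 3 else None,
                corrected=corrected,
            )

        return MixedAnovaResults(
            effects=effects,
            ss_total=ss_total,
            ss_components={
                "between": ss_A,
                "subjects_within_groups": ss_subj_within,
                "within": ss_B,
                "interaction": ss_AB,
                "error_within": ss_err,
            },
            epsilon=epsilon if k >= 3 else None,
            mauchly=mauchly,
            k_within=k,
            n_subjects=n,
        )


def _mauchly(S: np.ndarray, k: int, d: int) -> tuple[float, float, float, float]:
    """Mauchly's sphericity test on the orthonormal-contrast covariance."""
    C = _helmert(k)
    M = C @ S @ C.T
    eig = np.linalg.eigvalsh(M)
    eig = np.clip(eig, 1e-300, None)
    W = float(np.exp(np.sum(np.log(eig)) - (k - 1) * np.log(eig.mean())))
    f = 1.0 - (2.0 * (k - 1) ** 2 + (k - 1) + 2.0) / (6.0 * (k - 1) * d)
    chi2 = -f * d * math.log(max(W, 1e-300))
    df = k * (k - 1) / 2.0 - 1.0
    p = float(sps.chi2.sf(chi2, df))
    return W, chi2, df, p


def _helmert(k: int) -> np.ndarray:
    H = np.zeros((k - 1, k))
    for i in range(1, k):
        H[i - 1, :i] = 1.0 / i
        H[i - 1, i] = -1.0
        H[i - 1] /= np.linalg.norm(H[i - 1])
    return H


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: str | None = None,
    sphericity: str = "auto",
) -> MixedAnovaResults:
    """Convenience wrapper: build and fit a :class:`MixedAnova`."""
    return MixedAnova(data, dv, within, subject, between).fit(sphericity)


# ---------------------------------------------------------------------------
# paired / independent comparisons

@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    test_used: str  # t_independent | t_paired | wilcoxon_signed_rank
    df: float | None = None
    z: float | None = None
    note: str | None = None


def compare_blocks(a, b, alpha: float = 0.05) -> TestResult:
    """Paired block comparison with automatic test selection.

    Shapiro–Wilk on the paired differences picks the paired t test (normal)
    or the Wilcoxon signed-rank test.  The Wilcoxon drops zero differences
    and uses the continuity-corrected normal approximation for n > 25, the
    exact null distribution otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("paired samples must have equal length")
    d = a - b
    n = d.size
    if n < 3:
        raise ConfigurationError("paired comparison needs at least 3 pairs")
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; reporting no difference")
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank", note="degenerate: all zeros")
    if np.ptp(d) == 0:
        normal = False  # constant nonzero differences: not normal, Wilcoxon path
    else:
        normal = sps.shapiro(d).pvalue > alpha
    if normal:
        res = sps.ttest_rel(a, b)
        return TestResult(float(res.statistic), float(res.pvalue), "t_paired", df=float(n - 1))
    return wilcoxon_signed_rank(d)


def wilcoxon_signed_rank(d) -> TestResult:
    """Wilcoxon signed-rank test on a difference vector.

    Zero differences are dropped; the exact null distribution is used for
    n ≤ 25 and the continuity-corrected normal approximation (with a z
    statistic) above that.  The statistic is the smaller signed-rank sum.
    """
    d = np.asarray(d, dtype=float)
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all differences are zero; reporting no difference")
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank", note="degenerate: all zeros")
    method = "approx" if nz.size > 25 else "exact"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True, method=method)
    z = float(res.zstatistic) if method == "approx" else None
    return TestResult(
        float(res.statistic), float(res.pvalue), "wilcoxon_signed_rank", z=z
    )


def compare_groups(a, b) -> TestResult:
    """Independent two-group comparison: pooled-variance t, df = n1 + n2 − 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each group needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        raise ConfigurationError("t statistic undefined: zero variance, equal means")
    res = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(
        float(res.statistic),
        float(res.pvalue),
        "t_independent",
        df=float(a.size + b.size - 2),
    )


# ---------------------------------------------------------------------------
# random-intercept mixed model

@dataclass
class MixedModelResults:
    params: pd.Series
    bse: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    significant: pd.Series
    random_intercept_sd: float
    scale: float  # residual SD
    robust: bool
    nobs: int
    n_groups: int
    converged: bool = True
    reml_loglik: float | None = None
    random_effects: pd.Series | None = field(default=None, repr=False)

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame({"lower": self.ci_low, "upper": self.ci_high})

    def summary(self) -> str:
        kind = "Robust linear mixed model" if self.robust else "Linear mixed model"
        head = (
            f"{kind} ({self.nobs} obs, {self.n_groups} participants)\n"
            f"Random intercept SD = {self.random_intercept_sd:.3f}, "
            f"residual SD = {self.scale:.3f}\n"
        )
        rows = [f"{'Fixed effect':<22}{'Estimate':>10}{'Std. error':>12}"
                f"{'Lower 95% CI':>14}{'Higher 95% CI':>15}"]
        for name in self.params.index:
            star = " *" if self.significant[name] else ""
            rows.append(
                f"{name:<22}{self.params[name]:>10.2f}{self.bse[name]:>12.2f}"
                f"{self.ci_low[name]:>14.2f}{self.ci_high[name]:>15.2f}{star}"
            )
        return head + "\n".join(rows)


class RandomInterceptModel:
    """Linear model with a per-participant Gaussian random intercept.

    ``exog`` must already include a constant column.  ``fit(robust=False)``
    maximises the restricted likelihood profiled over the variance ratio
    λ = σ_b²/σ²; ``fit(robust=True)`` runs iteratively reweighted REML with
    Huber weights on scaled residuals and scaled random effects, a
    design-weight approximation to fully robust estimators.
    """

    def __init__(self, endog, exog, groups, exog_names: list[str] | None = None):
        self.y = np.asarray(endog, dtype=float)
        self.X = np.asarray(exog, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ConfigurationError("exog must be 2-D with one row per observation")
        codes, uniques = pd.factorize(np.asarray(groups))
        self.group_codes = codes
        self.group_labels = uniques
        self.m = len(uniques)
        self.n, self.p = self.X.shape
        if self.m < 2:
            raise ConfigurationError("need at least 2 participants")
        counts = np.bincount(codes, minlength=self.m)
        if counts.min() < 1:
            raise ConfigurationError("empty participant group")
        if np.any(np.bincount(codes) < 2):
            warnings.warn("some participants contribute a single observation")
        self.counts = counts
        self.exog_names = list(exog_names) if exog_names else [
            f"x{i}" for i in range(self.p)
        ]

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        predictors: list[str],
        groups: str = "participant",
    ) -> "RandomInterceptModel":
        cols = [response, *predictors, groups]
        sub = data[cols].dropna()
        X = np.column_stack(
            [np.ones(len(sub))] + [sub[p].to_numpy(dtype=float) for p in predictors]
        )
        return cls(
            sub[response].to_numpy(dtype=float),
            X,
            sub[groups].to_numpy(),
            exog_names=["intercept", *predictors],
        )

    # -- non-robust REML ----------------------------------------------------

    def _gls_pieces(self, lam: float, w_obs: np.ndarray | None = None):
        """Aggregates for (X'V⁻¹X, X'V⁻¹y, y'V⁻¹y) with V = I + λ ZZ'."""
        X, y, codes = self.X, self.y, self.group_codes
        if w_obs is None:
            XtX = X.T @ X
            Xty = X.T @ y
            yty = float(y @ y)
            Sx = np.zeros((self.m, self.p))
            Sy = np.zeros(self.m)
            np.add.at(Sx, codes, X)
            np.add.at(Sy, codes, y)
            n_i = self.counts.astype(float)
        else:
            Xw = X * w_obs[:, None]
            XtX = X.T @ Xw
            Xty = Xw.T @ y
            yty = float((y * w_obs) @ y)
            Sx = np.zeros((self.m, self.p))
            Sy = np.zeros(self.m)
            np.add.at(Sx, codes, Xw)
            np.add.at(Sy, codes, y * w_obs)
            n_i = np.bincount(codes, weights=w_obs, minlength=self.m)
        w_i = lam / (1.0 + lam * n_i)
        XtVX = XtX - (Sx * w_i[:, None]).T @ Sx
        XtVy = Xty - Sx.T @ (w_i * Sy)
        ytVy = yty - float(w_i @ (Sy * Sy))
        return XtVX, XtVy, ytVy, Sx, Sy, w_i, n_i

    def _reml_neg_loglik(self, lam: float) -> float:
        XtVX, XtVy, ytVy, _, _, _, n_i = self._gls_pieces(lam)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - float(beta @ XtVy)
        dof = self.n - self.p
        sigma2 = max(rss / dof, 1e-300)
        logdet_v = float(np.sum(np.log1p(lam * n_i)))
        sign, logdet_x = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        return 0.5 * (dof * math.log(sigma2) + logdet_v + logdet_x + dof)

    def fit(
        self,
        robust: bool = False,
        max_iter: int = 100,
        tol: float = 1e-8,
        variance_ratio: float | None = None,
    ) -> MixedModelResults:
        """REML fit; ``variance_ratio`` pins λ = σ_b²/σ² instead of
        profiling it (λ = 0 collapses the model to ordinary least squares)."""
        if variance_ratio is not None:
            if variance_ratio < 0:
                raise ConfigurationError("variance_ratio must be non-negative")
            lam = float(variance_ratio)
            neg_ll = self._reml_neg_loglik(lam)
        else:
            # profile REML over log-lambda; include the boundary lam = 0
            obj = lambda u: self._reml_neg_loglik(math.exp(u))
            res = optimize.minimize_scalar(obj, bounds=(-12.0, 8.0), method="bounded")
            lam, neg_ll = math.exp(res.x), float(res.fun)
            at_zero = self._reml_neg_loglik(0.0)
            if at_zero <= neg_ll:
                lam, neg_ll = 0.0, at_zero
        XtVX, XtVy, ytVy, Sx, Sy, w_i, _ = self._gls_pieces(lam)
        beta = np.linalg.solve(XtVX, XtVy)
        dof = self.n - self.p
        sigma2 = max((ytVy - float(beta @ XtVy)) / dof, 1e-300)
        resid_group = Sy - Sx @ beta  # per-group summed residuals
        b = w_i * resid_group  # BLUPs: lam/(1+lam n_i) * sum(resid_i)
        sigma_b = math.sqrt(lam * sigma2)
        cov = sigma2 * np.linalg.inv(XtVX)

        if not robust:
            return self._results(
                beta, cov, sigma_b, math.sqrt(sigma2), b, robust=False,
                reml_loglik=-neg_ll,
            )
        return self._fit_robust(beta, b, math.sqrt(sigma2), max(sigma_b, 1e-3),
                                max_iter=max_iter, tol=tol)

    def _fit_robust(self, beta, b, sigma, sigma_b, max_iter: int, tol: float):
        c = HUBER_C
        phi_c = sps.norm.pdf(c)
        Phi_c = sps.norm.cdf(c)
        kappa = (2 * Phi_c - 1) - 2 * c * phi_c + 2 * c * c * (1 - Phi_c)
        epsi = 2 * Phi_c - 1  # E[psi'(Z)]
        X, y, codes = self.X, self.y, self.group_codes
        M = None
        for _ in range(max_iter):
            e = y - X @ beta - b[codes]
            u = e / sigma
            w_e = np.where(np.abs(u) <= c, 1.0, c / np.maximum(np.abs(u), 1e-12))
            v = b / max(sigma_b, 1e-10)
            w_b = np.where(np.abs(v) <= c, 1.0, c / np.maximum(np.abs(v), 1e-12))
            gamma = (sigma / max(sigma_b, 1e-6)) ** 2

            Xw = X * w_e[:, None]
            XtWX = X.T @ Xw
            XtWy = Xw.T @ y
            Sxw = np.zeros((self.m, self.p))
            Syw = np.zeros(self.m)
            np.add.at(Sxw, codes, Xw)
            np.add.at(Syw, codes, y * w_e)
            s_i = np.bincount(codes, weights=w_e, minlength=self.m)
            d_i = s_i + gamma * w_b
            M = XtWX - (Sxw / d_i[:, None]).T @ Sxw
            rhs = XtWy - Sxw.T @ (Syw / d_i)
            beta_new = np.linalg.solve(M, rhs)
            b_new = (Syw - Sxw @ beta_new) / d_i

            e_new = y - X @ beta_new - b_new[codes]
            psi_e = np.clip(e_new / sigma, -c, c)
            sigma2_new = sigma**2 * float(psi_e @ psi_e) / ((self.n - self.p) * kappa)
            sigma_new = math.sqrt(max(sigma2_new, 1e-300))
            psi_b = np.clip(b_new / max(sigma_b, 1e-10), -c, c)
            sigma_b2_new = sigma_b**2 * float(psi_b @ psi_b) / (self.m * kappa)
            sigma_b_new = math.sqrt(max(sigma_b2_new, 1e-300))

            shift = float(np.max(np.abs(beta_new - beta)))
            beta, b, sigma, sigma_b = beta_new, b_new, sigma_new, sigma_b_new
            if shift < tol * (1.0 + float(np.max(np.abs(beta)))):
                tau = kappa / epsi**2
                cov = tau * sigma**2 * np.linalg.inv(M)
                return self._results(beta, cov, sigma_b, sigma, b, robust=True)
        raise ConvergenceError(
            f"robust mixed model did not converge in {max_iter} iterations "
            f"(last step {shift:.2e}, sigma={sigma:.3g}, sigma_b={sigma_b:.3g})"
        )

    def _results(self, beta, cov, sigma_b, sigma, b, robust, reml_loglik=None):
        names = self.exog_names
        bse = np.sqrt(np.diag(cov))
        lo = beta - 1.96 * bse
        hi = beta + 1.96 * bse
        sig = (lo > 0) | (hi < 0)
        return MixedModelResults(
            params=pd.Series(beta, index=names),
            bse=pd.Series(bse, index=names),
            ci_low=pd.Series(lo, index=names),
            ci_high=pd.Series(hi, index=names),
            significant=pd.Series(sig, index=names),
            random_intercept_sd=float(sigma_b),
            scale=float(sigma),
            robust=robust,
            nobs=self.n,
            n_groups=self.m,
            reml_loglik=reml_loglik,
            random_effects=pd.Series(b, index=self.group_labels),
        )


def fit_random_intercept_model(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    groups: str = "participant",
    robust: bool = False,
) -> MixedModelResults:
    """Convenience wrapper: build and fit a :class:`RandomInterceptModel`."""
    return RandomInterceptModel.from_dataframe(data, response, predictors, groups).fit(
        robust=robust
    )
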