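"""Trial-level linear mixed models with a per-mouse random intercept.

The model is

    y_ij = x_ijᵀ β + b_i + ε_ij,   b_i ~ N(0, σ²_b),  ε_ij ~ N(0, σ²_e),

fitted by maximum likelihood (not REML) so that nested models can be
compared with a likelihood-ratio test: the significance of a fixed effect
is 2·(ℓ_full − ℓ_reduced) against χ²(1), where the reduced model drops
exactly that predictor. For a single random intercept the likelihood is
profiled down to a one-dimensional search over the variance ratio
ψ = σ²_b/σ²_e: given ψ, the GLS estimate of β and the residual variance
are closed-form (Woodbury identity per group), which makes the fit exact,
fast and monotone in the profiled likelihood.

``analysis_bundles`` assembles the per-compartment coefficient tables of
the behavioural analysis: pre-cue ΔF/F against lick initiation and lick
latency, early ΔF/F against lick/cue and latency and bout rate, secondary
ΔF/F against bout rate, and late (lick-aligned) ΔF/F against reward, with
non-task lick epochs pooled as unrewarded controls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

_LOG2PI = math.log(2.0 * math.pi)


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class RandomInterceptResults:
    """ML fit of a random-intercept linear mixed model.

    ``params`` includes the intercept first; standard errors come from the
    GLS information matrix at the ML variance estimates.
    """

    params: np.ndarray
    bse: np.ndarray
    sigma2_b: float
    sigma2_e: float
    llf: float
    n_obs: int
    n_groups: int
    converged: bool
    exog_names: list[str] = field(default_factory=list)
    random_effects: dict = field(default_factory=dict)

    @property
    def beta(self) -> np.ndarray:
        return self.params

    def summary(self) -> str:
        lines = [
            "Random-intercept linear mixed model (ML)",
            f"  observations: {self.n_obs}   groups: {self.n_groups}",
            f"  log-likelihood: {self.llf:.4f}   converged: {self.converged}",
            f"  sigma2_b (group): {self.sigma2_b:.6g}   sigma2_e (residual): {self.sigma2_e:.6g}",
            f"  {'term':<16}{'coef':>12}{'se':>12}{'z':>9}",
        ]
        for name, b, se in zip(self.exog_names, self.params, self.bse):
            z = b / se if se > 0 else math.nan
            lines.append(f"  {name:<16}{b:>12.5f}{se:>12.5f}{z:>9.2f}")
        return "\n".join(lines)


class RandomInterceptModel:
    """Gaussian linear model with one random intercept per group.

    Parameters
    ----------
    endog : response vector.
    exog : fixed-effect design, one column per predictor. An intercept
        column is prepended automatically.
    groups : group label per observation (the mouse identity).
    exog_names : optional predictor names (without the intercept).
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != y.size:
            raise ValueError("endog and exog lengths differ")
        groups = np.asarray(groups)
        if groups.size != y.size:
            raise ValueError("groups length mismatch")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
            raise ValueError("endog/exog must be finite")
        self.endog = y
        self.exog = np.column_stack([np.ones(y.size), X])
        if exog_names is None:
            exog_names = [f"x{j + 1}" for j in range(X.shape[1])]
        self.exog_names = ["intercept"] + list(exog_names)
        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.exog.shape[1]:
            raise ValueError("fixed-effect design is collinear")
        self.group_labels, self.group_index = np.unique(groups, return_inverse=True)
        self.n_groups = self.group_labels.size
        # per-group sufficient statistics
        p = self.exog.shape[1]
        self._n_g = np.bincount(self.group_index)
        self._sx = np.zeros((self.n_groups, p))
        np.add.at(self._sx, self.group_index, self.exog)
        self._sy = np.bincount(self.group_index, weights=y)
        self._xtx = self.exog.T @ self.exog
        self._xty = self.exog.T @ y
        self._yty = float(y @ y)

    def _profile(self, psi: float):
        """GLS solution and profile log-likelihood at variance ratio ψ."""
        c = psi / (1.0 + psi * self._n_g)
        A = self._xtx - (self._sx * c[:, None]).T @ self._sx
        b = self._xty - self._sx.T @ (c * self._sy)
        q = self._yty - float(c @ self._sy**2)
        beta = np.linalg.solve(A, b)
        rss = q - float(beta @ b)
        n = self.endog.size
        sigma2_e = max(rss / n, 1e-300)
        llf = (
            -0.5 * n * (_LOG2PI + math.log(sigma2_e) + 1.0)
            - 0.5 * float(np.sum(np.log1p(psi * self._n_g)))
        )
        return llf, beta, sigma2_e, A, c

    def fit(self, tol: float = 1e-8) -> RandomInterceptResults:
        """Maximise the profiled ML likelihood over ψ = σ²_b/σ²_e ≥ 0."""
        if self.n_groups < 2:
            # the random intercept is unidentifiable: collapse to OLS
            psi_hat, converged = 0.0, True
        else:
            neg = lambda theta: -self._profile(math.exp(theta))[0]
            res = optimize.minimize_scalar(
                neg, bounds=(-18.0, 12.0), method="bounded",
                options={"xatol": 1e-10},
            )
            psi_hat = math.exp(res.x)
            llf_interior = -res.fun
            llf_zero = self._profile(0.0)[0]
            if llf_zero >= llf_interior - tol:
                psi_hat = 0.0
            converged = bool(res.success)
            if not converged:
                warnings.warn("variance-ratio search did not converge", ConvergenceWarning)
        llf, beta, sigma2_e, A, c = self._profile(psi_hat)
        cov = np.linalg.inv(A) * sigma2_e
        bse = np.sqrt(np.diag(cov))
        # BLUP of the group intercept: psi/(1 + psi n_g) * sum of residuals
        resid_sums = self._sy - self._sx @ beta
        random_effects = {
            label: float(c_g * r_g)
            for label, c_g, r_g in zip(self.group_labels, c, resid_sums)
        }
        return RandomInterceptResults(
            params=beta,
            bse=bse,
            sigma2_b=psi_hat * sigma2_e,
            sigma2_e=sigma2_e,
            llf=llf,
            n_obs=self.endog.size,
            n_groups=self.n_groups,
            converged=converged,
            exog_names=self.exog_names,
            random_effects=random_effects,
        )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, predictors, groups: str):
        sub = data[[response, *predictors, groups]].dropna()
        return cls(
            sub[response].to_numpy(),
            sub[list(predictors)].to_numpy(dtype=float),
            sub[groups].to_numpy(),
            exog_names=list(predictors),
        )


def fit_lmm(y, X, groups, exog_names=None, tol: float = 1e-8) -> RandomInterceptResults:
    """Functional wrapper around :class:`RandomInterceptModel`."""
    return RandomInterceptModel(y, X, groups, exog_names).fit(tol=tol)


def test_fixed_effect(
    full: RandomInterceptResults, reduced: RandomInterceptResults, tol: float = 1e-6
) -> float:
    """Likelihood-ratio p-value for the fixed effect dropped in ``reduced``.

    Both fits must be ML fits on identical observations; the statistic is
    2·(ℓ_full − ℓ_reduced) against χ²(1).
    """
    if full.n_obs != reduced.n_obs:
        raise ValueError("full and reduced fits use different data")
    if len(full.params) != len(reduced.params) + 1:
        raise ValueError("reduced model must drop exactly one fixed effect")
    lr = 2.0 * (full.llf - reduced.llf)
    if lr < -tol:
        raise ValueError("full-model likelihood below reduced model: fit failure")
    return float(stats.chi2.sf(max(lr, 0.0), df=1))


def ks_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test (asymptotic p-value)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# coefficient bundles

#: (window, response column, predictors, row filter) of each fitted model.
MODEL_SPECS = (
    ("pre_cue", "m_pre_cue", ("lick",),
     lambda d: (d["kind"] == "trial") & d["precue_eligible"]),
    ("pre_cue", "m_pre_cue", ("latency_s",),
     lambda d: (d["kind"] == "trial") & d["precue_eligible"] & (d["lick"] == 1)),
    ("early", "m_early", ("lick", "cue_go"),
     lambda d: d["kind"] == "trial"),
    ("early", "m_early", ("latency_s",),
     lambda d: (d["kind"] == "trial") & (d["lick"] == 1)),
    ("early", "m_early", ("bout_rate_hz",),
     lambda d: (d["kind"] == "trial") & (d["lick"] == 1)),
    ("secondary", "m_secondary", ("bout_rate_hz",),
     lambda d: (d["kind"] == "trial") & (d["lick"] == 1)),
    ("late", "m_late", ("reward",),
     lambda d: d["lick"] == 1),  # licking trials plus non-task epochs
)


def analysis_bundles(
    trial_table: pd.DataFrame,
    by: str = "compartment",
    min_obs: int = 10,
) -> pd.DataFrame:
    """Per-compartment mixed-model coefficient tables.

    ``trial_table`` is the tidy output of
    :func:`cfmap.responses.compartment_trial_table`, possibly concatenated
    across sessions and mice. Returns one row per compartment × model ×
    predictor with the ML coefficient, its standard error and the
    likelihood-ratio p-value.
    """
    rows = []
    for comp, comp_df in trial_table.groupby(by, sort=True):
        for window, response, predictors, row_filter in MODEL_SPECS:
            sub = comp_df[row_filter(comp_df)]
            cols = [response, *predictors, "mouse"]
            sub = sub.dropna(subset=cols)
            if len(sub) < min_obs:
                continue
            n_mice = sub["mouse"].nunique()
            if n_mice < 2:
                warnings.warn(
                    f"{comp}/{window}: fewer than 2 mice; "
                    "random-intercept variance reported as 0",
                    ConvergenceWarning,
                )
            y = sub[response].to_numpy()
            X = sub[list(predictors)].to_numpy(dtype=float)
            groups = sub["mouse"].to_numpy()
            full = fit_lmm(y, X, groups, exog_names=list(predictors))
            for j, predictor in enumerate(predictors):
                reduced_X = np.delete(X, j, axis=1)
                reduced = fit_lmm(y, reduced_X, groups)
                p = test_fixed_effect(full, reduced)
                rows.append(
                    {
                        by: comp,
                        "window": window,
                        "model": "+".join(predictors),
                        "predictor": predictor,
                        "beta": float(full.params[j + 1]),
                        "se": float(full.bse[j + 1]),
                        "p": p,
                        "sigma2_b": full.sigma2_b,
                        "sigma2_e": full.sigma2_e,
                        "n_obs": full.n_obs,
                        "n_mice": int(n_mice),
                    }
                )
    return pd.DataFrame.from_records(rows)
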