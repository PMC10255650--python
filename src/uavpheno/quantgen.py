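"""Quantitative genetics of replicated variety trials.

The observation model for a single trial is the one-way mixed model

    y_ij = mu + alpha_i + tau_j + eps_ij,   i = 1..g,  j = 1..r

with genotype effects ``alpha_i ~ N(0, sigma2_g)`` random, replicate
effects ``tau_j`` fixed (sum-to-zero) and residuals ``eps_ij ~ N(0,
sigma2_e)``.  For a balanced design the restricted likelihood factorizes
into two independent strata: the g-1 genotype contrasts with variance
``sigma2_e + r*sigma2_g`` and the (g-1)(r-1) residual contrasts with
variance ``sigma2_e``.  REML estimates maximize that stratum likelihood
exactly, with ``sigma2_g`` bounded at zero (the boundary case pools the
strata); ``anova_components`` provides the independent method-of-moments
route through a statsmodels ANOVA table.

Pooled analyses across trials treat trial and replicate-within-trial as
fixed, so strata simply accumulate across trials under shared variance
components.

On top of the components sit broad-sense heritability (entry-mean
``sigma2_g/(sigma2_g + sigma2_e/r)`` and plot basis), the genotypic
covariance/correlation between two traits, and direct (R = h * sigma_g)
and correlated (CR = h_x * r_g * sigma_gy) responses to selection with
their ratio CR/R, the relative selection efficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class TraitObservations:
    """Balanced complete-block observations of one trait in one trial."""

    trait: str
    genotype: np.ndarray
    replicate: np.ndarray
    value: np.ndarray
    trial: str = ""

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype)
        self.replicate = np.asarray(self.replicate)
        self.value = np.asarray(self.value, dtype=float)
        if not (len(self.genotype) == len(self.replicate) == len(self.value)):
            raise ValueError("genotype/replicate/value lengths differ")
        self._matrix, self._genotypes, self._replicates = self._pivot()

    @classmethod
    def from_frame(cls, df: pd.DataFrame, trait: str,
                   value_col: str | None = None,
                   trial: str = "") -> "TraitObservations":
        value_col = value_col or trait
        return cls(trait=trait, genotype=df["genotype_id"].to_numpy(),
                   replicate=df["replicate"].to_numpy(),
                   value=df[value_col].to_numpy(), trial=trial)

    def _pivot(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        genos = np.unique(self.genotype)
        reps = np.unique(self.replicate)
        g, r = len(genos), len(reps)
        if g < 2:
            raise ValueError("need at least 2 genotypes")
        if r < 2:
            raise ValueError("need at least 2 replicates")
        if len(self.value) != g * r:
            raise ValueError(
                f"unbalanced design: {len(self.value)} records for "
                f"{g} genotypes x {r} replicates"
            )
        gi = {v: i for i, v in enumerate(genos)}
        ri = {v: j for j, v in enumerate(reps)}
        mat = np.full((g, r), np.nan)
        for gen, rep, val in zip(self.genotype, self.replicate, self.value):
            i, j = gi[gen], ri[rep]
            if not np.isnan(mat[i, j]):
                raise ValueError(
                    f"duplicate record for genotype {gen!r} replicate {rep!r}"
                )
            mat[i, j] = val
        if np.isnan(mat).any():
            raise ValueError("unbalanced design: missing genotype x "
                             "replicate cells")
        return mat, genos, reps

    @property
    def matrix(self) -> np.ndarray:
        """Values as a (g, r) array, genotypes in sorted-label order."""
        return self._matrix

    @property
    def g(self) -> int:
        return self._matrix.shape[0]

    @property
    def r(self) -> int:
        return self._matrix.shape[1]


@dataclass
class VarianceComponents:
    """REML (or ANOVA) estimates for the one-way mixed model."""

    trait: str
    mu: float
    sigma2_g: float
    sigma2_e: float
    rep_effects: dict[str, np.ndarray]    # trial -> tau-hat (sum to zero)
    loglik: float                         # maximized restricted log-likelihood
    g: int                                # total genotypes (all trials)
    r: int
    df_g: int
    df_e: int
    method: str = "reml"
    truncated: bool = False               # sigma2_g hit the zero bound

    @property
    def sigma_g(self) -> float:
        return float(np.sqrt(self.sigma2_g))


@dataclass
class HeritabilityResult:
    trait: str
    entry_mean: float      # sigma2_g / (sigma2_g + sigma2_e / r)
    plot_basis: float      # sigma2_g / (sigma2_g + sigma2_e)
    basis: str = "entry_mean"

    @property
    def value(self) -> float:
        return self.entry_mean if self.basis == "entry_mean" else self.plot_basis


@dataclass
class GeneticCorrelationResult:
    trait_x: str
    trait_y: str
    cov_g: float
    r_g: float
    p_value: float
    g: int
    out_of_range: bool = False    # |r_g| > 1 from sampling; reported raw

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


# ---------------------------------------------------------------------------
# Strata (balanced-design sums of squares)

@dataclass
class _Strata:
    ss_g: float
    df_g: int
    ss_e: float
    df_e: int
    r: int
    g: int
    mu: float
    rep_effects: dict[str, np.ndarray] = field(default_factory=dict)


def _strata_one(obs: TraitObservations) -> _Strata:
    y = obs.matrix
    g, r = y.shape
    grand = y.mean()
    row = y.mean(axis=1)
    col = y.mean(axis=0)
    ss_g = r * float(np.sum((row - grand) ** 2))
    resid = y - row[:, None] - col[None, :] + grand
    ss_e = float(np.sum(resid ** 2))
    return _Strata(ss_g=ss_g, df_g=g - 1, ss_e=ss_e, df_e=(g - 1) * (r - 1),
                   r=r, g=g, mu=float(grand),
                   rep_effects={obs.trial or "": col - grand})


def _strata_pooled(obs_list: Sequence[TraitObservations]) -> _Strata:
    parts = [_strata_one(o) for o in obs_list]
    rs = {p.r for p in parts}
    if len(rs) != 1:
        raise ValueError("pooled trials must share the replicate count")
    n_tot = sum(p.g * p.r for p in parts)
    mu = sum(p.mu * p.g * p.r for p in parts) / n_tot
    reps = {}
    for p in parts:
        reps.update(p.rep_effects)
    return _Strata(
        ss_g=sum(p.ss_g for p in parts),
        df_g=sum(p.df_g for p in parts),
        ss_e=sum(p.ss_e for p in parts),
        df_e=sum(p.df_e for p in parts),
        r=rs.pop(), g=sum(p.g for p in parts), mu=mu, rep_effects=reps,
    )


def _as_list(obs) -> list[TraitObservations]:
    return list(obs) if isinstance(obs, (list, tuple)) else [obs]


def _restricted_ll(s2g: float, s2e: float, st: _Strata) -> float:
    lam = s2e + st.r * s2g
    return -0.5 * (
        (st.df_g + st.df_e) * _LOG2PI
        + st.df_g * np.log(lam) + st.ss_g / lam
        + st.df_e * np.log(s2e) + st.ss_e / s2e
    )


def fit_one_way_mixed(obs) -> VarianceComponents:
    """REML variance components for one trial (or pooled trials).

    Accepts a single ``TraitObservations`` or a sequence (pooled analysis
    with trial and replicate-within-trial fixed).  ``sigma2_g`` is bounded
    at zero; the maximized restricted log-likelihood is returned for
    likelihood-ratio testing.
    """
    obs_list = _as_list(obs)
    st = _strata_pooled(obs_list)
    total = (st.ss_g + st.ss_e) / (st.df_g + st.df_e)
    if total <= 0:
        # constant data: both components zero, likelihood degenerate
        return VarianceComponents(
            trait=obs_list[0].trait, mu=st.mu, sigma2_g=0.0, sigma2_e=0.0,
            rep_effects=st.rep_effects, loglik=np.inf, g=st.g, r=st.r,
            df_g=st.df_g, df_e=st.df_e, truncated=True,
        )

    # In (lambda, sigma2_e) coordinates the restricted likelihood separates
    # into two independent variance strata, each maximized at its mean
    # square, subject to the boundary constraint lambda >= sigma2_e
    # (i.e. sigma2_g >= 0).  If the unconstrained maximizer violates the
    # constraint, the constrained maximum pools both strata.
    lam_hat = st.ss_g / st.df_g
    s2e_hat = st.ss_e / st.df_e
    if lam_hat >= s2e_hat:
        s2g = (lam_hat - s2e_hat) / st.r
        s2e = s2e_hat
    else:
        s2g = 0.0
        s2e = total
    return VarianceComponents(
        trait=obs_list[0].trait, mu=st.mu, sigma2_g=s2g, sigma2_e=s2e,
        rep_effects=st.rep_effects,
        loglik=float(_restricted_ll(s2g, s2e, st)), g=st.g, r=st.r,
        df_g=st.df_g, df_e=st.df_e, truncated=bool(s2g == 0.0),
    )


def anova_components(obs: TraitObservations) -> VarianceComponents:
    """Method-of-moments components from a two-way fixed-effects ANOVA.

    Independent oracle for the REML fit: goes through statsmodels OLS and
    ``anova_lm``; sigma2_e = MS_error, sigma2_g = max(0, (MS_G - MS_E)/r).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": obs.value,
                       "genotype": obs.genotype.astype(str),
                       "rep": obs.replicate.astype(str)})
    fit = smf.ols("y ~ C(genotype) + C(rep)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    ms_g = table.loc["C(genotype)", "sum_sq"] / table.loc["C(genotype)", "df"]
    ms_e = table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"]
    r = obs.r
    raw = (ms_g - ms_e) / r
    s2g = max(0.0, float(raw))
    if raw < 0:
        warnings.warn(
            f"negative ANOVA genotypic component for {obs.trait!r} "
            f"({raw:.4g}) truncated at 0", stacklevel=2,
        )
    st = _strata_one(obs)
    return VarianceComponents(
        trait=obs.trait, mu=st.mu, sigma2_g=s2g, sigma2_e=float(ms_e),
        rep_effects=st.rep_effects,
        loglik=_restricted_ll(s2g, float(ms_e), st),
        g=obs.g, r=r, df_g=st.df_g, df_e=st.df_e,
        method="anova", truncated=raw < 0,
    )


def lrt_genotype(obs) -> tuple[float, float]:
    """Likelihood-ratio test for the genotype random effect.

    Compares the full REML fit against the model with sigma2_g = 0 (same
    fixed effects), statistic 2*(l_full - l_reduced); the p-value uses the
    boundary mixture 0.5*chi2_0 + 0.5*chi2_1.
    """
    obs_list = _as_list(obs)
    full = fit_one_way_mixed(obs_list)
    st = _strata_pooled(obs_list)
    s2_null = (st.ss_g + st.ss_e) / (st.df_g + st.df_e)
    ll_null = _restricted_ll(0.0, s2_null, st)
    stat = 2.0 * (full.loglik - ll_null)
    if stat < -1e-6:
        raise RuntimeError(f"negative LRT statistic {stat:.3g}: REML "
                           "optimization did not converge")
    stat = max(0.0, float(stat))
    p = 1.0 if stat == 0.0 else 0.5 * float(stats.chi2.sf(stat, df=1))
    return stat, p


def heritability(vc: VarianceComponents,
                 basis: str = "entry_mean") -> HeritabilityResult:
    """Broad-sense heritability on the entry-mean and plot bases."""
    tot = vc.sigma2_g + vc.sigma2_e
    if tot <= 0:
        raise ValueError("zero total variance; heritability undefined")
    if basis not in ("entry_mean", "plot"):
        raise ValueError(f"unknown basis {basis!r}")
    return HeritabilityResult(
        trait=vc.trait,
        entry_mean=vc.sigma2_g / (vc.sigma2_g + vc.sigma2_e / vc.r),
        plot_basis=vc.sigma2_g / tot,
        basis=basis,
    )


def _check_same_design(ox: TraitObservations, oy: TraitObservations) -> None:
    if not np.array_equal(ox._genotypes, oy._genotypes):
        raise ValueError("genotype sets differ between the two traits")
    if not np.array_equal(ox._replicates, oy._replicates):
        raise ValueError("replicate sets differ between the two traits")


def _raw_s2g(st: _Strata) -> float:
    """Untruncated method-of-moments genotypic variance from strata."""
    return (st.ss_g / st.df_g - st.ss_e / st.df_e) / st.r


def genotypic_covariance(obs_x, obs_y) -> float:
    """Genotypic covariance of two traits on the same design.

    Computed from genotype and error mean cross-products,
    COV_G = (MCP_G - MCP_E) / r, and cross-checked against the
    variance-of-sum identity 0.5*[s2g(x+y) - s2g(x) - s2g(y)] (both
    untruncated); the two routes must agree to within 1e-10 relative.
    """
    xs, ys = _as_list(obs_x), _as_list(obs_y)
    if len(xs) != len(ys):
        raise ValueError("trait observations cover different trials")
    scp_g = scp_e = 0.0
    df_g = df_e = 0
    sum_parts = []
    for ox, oy in zip(xs, ys):
        _check_same_design(ox, oy)
        X, Y = ox.matrix, oy.matrix
        r = X.shape[1]
        dx = X - X.mean()
        dy = Y - Y.mean()
        rowx, rowy = dx.mean(axis=1), dy.mean(axis=1)
        colx, coly = dx.mean(axis=0), dy.mean(axis=0)
        scp_g += r * float(np.sum(rowx * rowy))
        ex = dx - rowx[:, None] - colx[None, :]
        ey = dy - rowy[:, None] - coly[None, :]
        scp_e += float(np.sum(ex * ey))
        df_g += X.shape[0] - 1
        df_e += (X.shape[0] - 1) * (r - 1)
        sum_parts.append(TraitObservations(
            trait="x+y", genotype=ox.genotype, replicate=ox.replicate,
            value=ox.value + oy.value, trial=ox.trial))
    r = xs[0].r
    cov_mcp = (scp_g / df_g - scp_e / df_e) / r

    s2_sum = _raw_s2g(_strata_pooled(sum_parts))
    s2_x = _raw_s2g(_strata_pooled(xs))
    s2_y = _raw_s2g(_strata_pooled(ys))
    cov_ident = 0.5 * (s2_sum - s2_x - s2_y)
    scale = max(abs(cov_mcp), abs(s2_x), abs(s2_y), 1e-30)
    if abs(cov_mcp - cov_ident) > 1e-10 * scale:
        raise AssertionError(
            f"genotypic covariance routes disagree: {cov_mcp} vs {cov_ident}"
        )
    return float(cov_mcp)


def genetic_correlation(obs_x, obs_y) -> GeneticCorrelationResult:
    """Genotypic correlation r_G = COV_Gxy / sqrt(s2Gx * s2Gy).

    Significance uses a t-approximation with g - 2 degrees of freedom (g =
    total genotypes), a documented convention.  |r_G| can exceed 1 from
    sampling; it is reported raw with a flag, never clamped.
    """
    xs, ys = _as_list(obs_x), _as_list(obs_y)
    vx = fit_one_way_mixed(xs)
    vy = fit_one_way_mixed(ys)
    if vx.sigma2_g <= 0 or vy.sigma2_g <= 0:
        raise ValueError(
            "genotypic variance is zero for "
            f"{vx.trait if vx.sigma2_g <= 0 else vy.trait!r}; "
            "genetic correlation undefined"
        )
    cov = genotypic_covariance(xs, ys)
    r_g = cov / np.sqrt(vx.sigma2_g * vy.sigma2_g)
    g = vx.g
    out_of_range = abs(r_g) > 1.0
    if out_of_range:
        warnings.warn(
            f"|r_G| = {abs(r_g):.3f} > 1 between {vx.trait!r} and "
            f"{vy.trait!r} (sampling artefact); reported raw", stacklevel=2,
        )
        p = 0.0
    else:
        tval = abs(r_g) * np.sqrt(max(g - 2, 1) / max(1.0 - r_g ** 2, 1e-300))
        p = 2.0 * float(stats.t.sf(tval, df=max(g - 2, 1)))
    return GeneticCorrelationResult(
        trait_x=vx.trait, trait_y=vy.trait, cov_g=float(cov),
        r_g=float(r_g), p_value=p, g=g, out_of_range=out_of_range,
    )


def selection_response(h2: float, sigma_g: float) -> float:
    """Direct response to selection, R = sqrt(H2) * sigma_g (intensity 1)."""
    if h2 < 0 or sigma_g < 0:
        raise ValueError("inputs must be >= 0")
    return float(np.sqrt(h2) * sigma_g)


def correlated_response(h2_x: float, r_g: float, sigma_gy: float) -> float:
    """Correlated response in trait y from selecting on trait x:
    CR = sqrt(H2_x) * r_g * sigma_gy."""
    if h2_x < 0 or sigma_gy < 0:
        raise ValueError("heritability and genotypic SD must be >= 0")
    return float(np.sqrt(h2_x) * r_g * sigma_gy)


def relative_efficiency(cr: float, r_direct: float) -> float:
    """Relative selection efficiency CR / R."""
    if r_direct <= 0:
        raise ValueError("direct response must be > 0 for the CR/R ratio")
    return float(cr / r_direct)
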