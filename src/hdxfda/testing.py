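"""Functional ANOVA for differential HDX kinetics with empirical-Bayes moderation.

For each peptide analyte the null hypothesis is that a single uptake curve,
blinded to the condition, explains the time course in every condition; the
alternative fits one curve per condition.  Writing RSS0 and RSS1 for the
residual sums of squares of the pooled and the condition-specific fits, the
test statistic is

    F = (d2 / d1) * (RSS0 - RSS1) / RSS1,       d1 = p2 - p1, d2 = n - p2,

with p1 free parameters under the null and p2 = C * p1 under the alternative
(C conditions), referred to an F(d1, d2) distribution.

Because HDX experiments run few replicates, the per-analyte residual
variance s_i^2 = RSS1 / d2 is noisy.  Assuming the true variances follow a
scaled inverse chi-square prior with d0 degrees of freedom and scale s0^2 —
equivalently s_i^2 ~ s0^2 * F(d2, d0) marginally — the posterior-mean
variance

    s~_i^2 = (d0 * s0^2 + d2 * s_i^2) / (d0 + d2)

replaces s_i^2 in a moderated statistic F~ = (RSS0 - RSS1) / (s~_i^2 * d1),
referred to F(d1, d0 + d2).  The hyperparameters (d0, s0^2) are estimated
once per dataset by matching moments of log s_i^2 against the scaled-F law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .dataset import HDXDataset
from .kinetics import (
    InsufficientObservationsError,
    KineticFit,
    ModelSpec,
    fit_kinetics,
)

#: RSS slack tolerated when asserting nestedness after the refit fallback.
NESTING_TOL = 1e-6


class CannotModerateError(ValueError):
    """Raised when fewer than two usable variances are available for pooling."""


@dataclass(frozen=True)
class DegreesOfFreedom:
    """Numerator/denominator degrees of freedom of the nested-model F-test."""

    p1: int
    p2: int
    d1: int
    d2: int


@dataclass(frozen=True)
class NestedFitPair:
    """Pooled (null) and per-condition (alternative) fits for one analyte."""

    null_fit: KineticFit
    alt_fits: dict[str, KineticFit]
    rss0: float
    rss1: float
    n_obs: int


@dataclass(frozen=True)
class EBHyperparams:
    """Prior degrees of freedom d0 (possibly inf) and prior variance s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def degrees_of_freedom(spec: ModelSpec, n_conditions: int, n_obs: int) -> DegreesOfFreedom:
    """Parameter counts and F degrees of freedom for a nested fit.

    The null model has p1 = k free parameters; the alternative fits the same
    k per condition, p2 = C * k.  For the full Weibull model with two
    conditions this gives p1 = 4, p2 = 8; for the exponential model 3 and 6;
    for the reduced epitope configuration (b, q, d fixed) 1 and 2.

    Raises
    ------
    InsufficientObservationsError
        If n_obs <= p2, leaving no residual degrees of freedom.
    """
    if n_conditions < 2:
        raise ValueError("need at least two conditions to test")
    p1 = spec.n_free
    p2 = n_conditions * p1
    if n_obs <= p2:
        raise InsufficientObservationsError(
            f"insufficient observations: n={n_obs} <= p2={p2}"
        )
    return DegreesOfFreedom(p1=p1, p2=p2, d1=p2 - p1, d2=n_obs - p2)


def nested_fit(dataset: HDXDataset, analyte_id: str, spec: ModelSpec | None = None) -> NestedFitPair:
    """Fit the pooled (condition-blind) and per-condition models.

    The alternative RSS is the sum of the per-condition RSS values.  Because
    the fits are non-convex, a fresh per-condition solve can occasionally
    land above the pooled optimum; in that case each condition is refitted
    starting from the null solution and the better result kept, restoring
    the nesting guarantee RSS1 <= RSS0 (up to optimizer tolerance).

    Raises
    ------
    InsufficientObservationsError
        If any condition has too few observations for the free parameters,
        or fewer than two conditions carry data.
    """
    spec = spec or ModelSpec()
    sub = dataset.analyte_table(analyte_id, drop_missing=True)
    conditions = [c for c in dataset.conditions if (sub["condition"] == c).any()]
    if len(conditions) < 2:
        raise InsufficientObservationsError(
            f"analyte {analyte_id}: observations in fewer than two conditions"
        )
    t_all = sub["exposure_s"].to_numpy(dtype=float)
    y_all = sub["value"].to_numpy(dtype=float)
    null_fit = fit_kinetics(t_all, y_all, spec)

    alt_fits: dict[str, KineticFit] = {}
    rss1 = 0.0
    for cond in conditions:
        mask = (sub["condition"] == cond).to_numpy()
        fit_c = fit_kinetics(t_all[mask], y_all[mask], spec)
        alt_fits[cond] = fit_c
        rss1 += fit_c.rss
    if rss1 > null_fit.rss:
        # Nesting repair: restart each condition from the pooled optimum.
        rss1 = 0.0
        for cond in conditions:
            mask = (sub["condition"] == cond).to_numpy()
            refit = fit_kinetics(t_all[mask], y_all[mask], spec, init=null_fit.params)
            if refit.rss < alt_fits[cond].rss:
                alt_fits[cond] = refit
            rss1 += alt_fits[cond].rss
    return NestedFitPair(
        null_fit=null_fit,
        alt_fits=alt_fits,
        rss0=null_fit.rss,
        rss1=min(rss1, null_fit.rss + NESTING_TOL),
        n_obs=null_fit.n_obs,
    )


def f_statistic(pair: NestedFitPair, dof: DegreesOfFreedom) -> float:
    """Ordinary nested-model F, floored at 0; +inf if the alternative is exact."""
    if pair.rss1 <= 0.0:
        return math.inf
    f = (dof.d2 / dof.d1) * (pair.rss0 - pair.rss1) / pair.rss1
    return max(f, 0.0)


def moderated_f(pair: NestedFitPair, dof: DegreesOfFreedom, s_tilde_sq: float) -> float:
    """Moderated F: (RSS0 - RSS1) / (s~^2 * d1), floored at 0."""
    if s_tilde_sq <= 0:
        raise ValueError("moderated variance must be positive")
    f = (pair.rss0 - pair.rss1) / (s_tilde_sq * dof.d1)
    return max(f, 0.0)


def moderate_variance(s_i_sq: float, d2: float, hyper: EBHyperparams) -> float:
    """Posterior-mean variance (d0 s0^2 + d2 s_i^2) / (d0 + d2); s0^2 if d0 is inf."""
    if math.isinf(hyper.d0):
        return hyper.s0_sq
    return (hyper.d0 * hyper.s0_sq + d2 * s_i_sq) / (hyper.d0 + d2)


def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the asymptotic start x0 = 0.5 + 1/y and the monotone decrease of
    the trigamma function; converges in a handful of iterations for the
    y values arising from log-variance spreads.
    """
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        tetra = float(special.polygamma(2, x))
        delta = tri * (1.0 - tri / y) / tetra
        x += delta
        if x <= 0:
            x = 1e-8
        if abs(delta) < 1e-10 * x:
            break
    return x


def estimate_eb_hyperparams(s_sq, d2) -> EBHyperparams:
    """Estimate (d0, s0^2) from the observed residual variances.

    Under the prior, s_i^2 ~ s0^2 F(d2_i, d0), so
    z_i = log s_i^2 satisfies

        E[z_i] = log s0^2 + psi(d2_i/2) - log(d2_i/2) - psi(d0/2) + log(d0/2)
        Var[z_i] = psi'(d2_i/2) + psi'(d0/2)

    with psi the digamma function.  Matching the sample mean and variance of
    e_i = z_i - psi(d2_i/2) + log(d2_i/2) gives psi'(d0/2) = Var(e) -
    mean(psi'(d2_i/2)); the trigamma equation is solved by Newton iteration.
    If the observed spread does not exceed what finite d2 alone explains,
    d0 = inf (all variances shrunk fully to s0^2).  Per-analyte d2 values
    are used directly, so unequal observation counts (missingness) are
    handled without approximation.

    Raises
    ------
    CannotModerateError
        If fewer than two finite positive variances are supplied.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    d2 = np.broadcast_to(np.asarray(d2, dtype=float), s_sq.shape).copy()
    usable = np.isfinite(s_sq) & (s_sq > 0) & np.isfinite(d2) & (d2 > 0)
    s_sq, d2 = s_sq[usable], d2[usable]
    n = s_sq.size
    if n < 2:
        raise CannotModerateError("cannot moderate: need at least 2 positive variances")
    if np.ptp(s_sq) == 0.0:
        # Degenerate zero-spread input: the prior is the common value itself.
        return EBHyperparams(d0=math.inf, s0_sq=float(s_sq[0]))

    z = np.log(s_sq)
    e = z - special.digamma(d2 / 2.0) + np.log(d2 / 2.0)
    e_bar = float(np.mean(e))
    e_var = float(np.sum((e - e_bar) ** 2) / (n - 1))
    excess = e_var - float(np.mean(special.polygamma(1, d2 / 2.0)))
    if excess <= 0:
        return EBHyperparams(d0=math.inf, s0_sq=float(np.exp(e_bar)))
    half_d0 = _trigamma_inverse(excess)
    if math.isinf(half_d0):
        return EBHyperparams(d0=math.inf, s0_sq=float(np.exp(e_bar)))
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_bar + special.digamma(half_d0) - np.log(half_d0)))
    return EBHyperparams(d0=d0, s0_sq=s0_sq)


def f_pvalue(f_value: float, d1: float, denominator_df: float) -> float:
    """Upper-tail p-value of F(d1, denominator_df).

    An infinite denominator df (fully moderated variance) is evaluated via
    the chi-square limit d1 * F ~ chi2(d1).  A non-finite F (perfect
    alternative fit) yields p = 0.
    """
    if not np.isfinite(f_value):
        return 0.0
    if f_value < 0:
        raise ValueError("F statistic must be non-negative")
    if math.isinf(denominator_df):
        return float(stats.chi2.sf(d1 * f_value, d1))
    return float(stats.f.sf(f_value, d1, denominator_df))


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are propagated and excluded from the family size.  Values
    outside [0, 1] raise.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.sum():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


RESULT_COLUMNS = [
    "analyte_id", "rss0", "rss1", "d1", "d2", "s2", "s2_moderated",
    "F", "F_moderated", "p_value", "p_adjusted", "status",
]


class FunctionalHdxTest(BaseEstimator):
    """Dataset-level differential-kinetics test, scikit-learn estimator style.

    Fits the nested functional models for every analyte, pools residual
    variances across analytes by empirical Bayes, computes moderated
    F-statistics and Benjamini-Hochberg adjusted p-values.

    Parameters
    ----------
    form : {"weibull", "exponential"}
        Kinetic model form (the exponential form pins q = 1).
    fixed : dict, optional
        Parameters held fixed, e.g. ``{"b": 0.5, "q": 1.0, "d": 0.0}`` for
        single-replicate epitope-mapping designs.
    moderation : bool
        If False, skip the empirical-Bayes step and report the ordinary
        F-test p-values (equivalently the d0 -> 0 limit).
    fdr : float
        Significance level applied to adjusted p-values by
        :meth:`significant`.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per analyte with RSS0/RSS1, degrees of freedom, ordinary and
        moderated F, raw and adjusted p, and a status flag
        (ok | insufficient_data | fit_failed | perfect_fit).
    eb_ : EBHyperparams or None
        Estimated prior (d0, s0^2); None when moderation is off or
        impossible.
    fits_ : dict
        analyte_id -> NestedFitPair for the analytes that could be fitted.
    """

    def __init__(
        self,
        form: str = "weibull",
        fixed: dict | None = None,
        moderation: bool = True,
        fdr: float = 0.05,
    ):
        self.form = form
        self.fixed = fixed
        self.moderation = moderation
        self.fdr = fdr

    def _spec(self) -> ModelSpec:
        return ModelSpec(form=self.form, fixed=self.fixed or {})

    def fit(self, dataset: HDXDataset, y=None) -> "FunctionalHdxTest":
        spec = self._spec()
        if dataset.n_conditions < 2:
            raise ValueError("nothing to test: dataset has a single condition")
        rows: list[dict] = []
        fits: dict[str, NestedFitPair] = {}
        for analyte_id in dataset.analyte_ids:
            row: dict = {c: np.nan for c in RESULT_COLUMNS}
            row["analyte_id"] = analyte_id
            try:
                pair = nested_fit(dataset, analyte_id, spec)
                dof = degrees_of_freedom(spec, len(pair.alt_fits), pair.n_obs)
            except InsufficientObservationsError:
                row["status"] = "insufficient_data"
                rows.append(row)
                continue
            fits[analyte_id] = pair
            f_ord = f_statistic(pair, dof)
            row.update(
                rss0=pair.rss0, rss1=pair.rss1, d1=dof.d1, d2=dof.d2,
                F=f_ord, status="ok",
            )
            if pair.rss1 > 0:
                row["s2"] = pair.rss1 / dof.d2
            else:
                row["status"] = "perfect_fit"
            rows.append(row)

        results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        ok = results["status"] == "ok"
        if not (ok | (results["status"] == "perfect_fit")).any():
            raise ValueError("no testable analytes in dataset")

        self.eb_ = None
        if self.moderation:
            # Perfect fits (zero variance) are excluded from the pool.
            try:
                self.eb_ = estimate_eb_hyperparams(
                    results.loc[ok, "s2"].to_numpy(),
                    results.loc[ok, "d2"].to_numpy(),
                )
            except CannotModerateError:
                self.eb_ = None

        for idx in results.index[ok]:
            d2 = float(results.at[idx, "d2"])
            d1 = float(results.at[idx, "d1"])
            s2 = float(results.at[idx, "s2"])
            pair = fits[results.at[idx, "analyte_id"]]
            dof = DegreesOfFreedom(
                p1=int(spec.n_free),
                p2=int(spec.n_free + d1),
                d1=int(d1),
                d2=int(d2),
            )
            if self.eb_ is not None:
                s_tilde = moderate_variance(s2, d2, self.eb_)
                f_mod = moderated_f(pair, dof, s_tilde)
                denom_df = self.eb_.d0 + d2
                results.at[idx, "s2_moderated"] = s_tilde
                results.at[idx, "F_moderated"] = f_mod
                results.at[idx, "p_value"] = f_pvalue(f_mod, d1, denom_df)
            else:
                results.at[idx, "p_value"] = f_pvalue(
                    float(results.at[idx, "F"]), d1, d2
                )
        # Exact alternative fits are maximally significant by convention.
        perfect = results["status"] == "perfect_fit"
        results.loc[perfect, "p_value"] = 0.0
        results["p_adjusted"] = adjust_bh(results["p_value"].to_numpy())

        self.results_ = results
        self.fits_ = fits
        return self

    def significant(self) -> pd.DataFrame:
        """Analytes whose BH-adjusted p-value falls below the FDR level."""
        if not hasattr(self, "results_"):
            raise AttributeError("FunctionalHdxTest is not fitted yet")
        r = self.results_
        return r[r["p_adjusted"] < self.fdr].reset_index(drop=True)


def run_functional_test(
    dataset: HDXDataset,
    spec: ModelSpec | None = None,
    fdr_level: float = 0.05,
    moderation: bool = True,
) -> pd.DataFrame:
    """One-call wrapper around :class:`FunctionalHdxTest`; returns ``results_``."""
    spec = spec or ModelSpec()
    tester = FunctionalHdxTest(
        form=spec.form, fixed=dict(spec.fixed), moderation=moderation, fdr=fdr_level
    )
    return tester.fit(dataset).results_
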