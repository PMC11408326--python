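"""Shrinkage disproportionality detectors: BCPNN and the longitudinal GPS.

BCPNN scores a drug-event pair by the information component

    IC = log2( (n11 + 1/2) / (E11 + 1/2) ),   E11 = n1. * n.1 / n,

with a lower credible bound IC025 = log2 of the 2.5% quantile of a
Gamma(n11 + 1/2, rate = E11 + 1/2) posterior for the observed/expected ratio.
This is the simplified information component with +1/2 shrinkage terms and a
gamma-quantile credible interval, the variant in routine modern use, rather
than the original Dirichlet network formulation.

The longitudinal GPS replaces the contingency expectation with an indirectly
standardized expected count from stratified person-time,

    E_j = sum_s PT_exp,s * O_unexp,s / PT_unexp,s ,

and shrinks O/E with DuMouchel's two-component gamma-Poisson empirical-Bayes
model: the relative rate lambda has prior
w * Gamma(a1, b1) + (1-w) * Gamma(a2, b2), estimated by maximizing the
negative-binomial mixture marginal likelihood. Scores are the posterior
geometric mean EBGM = exp E[ln lambda] and the 5th posterior percentile EB05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# BCPNN
# ---------------------------------------------------------------------------

def bcpnn_scores(counts: pd.DataFrame) -> pd.DataFrame:
    """Information component and IC025 per code from 2x2 counts.

    ``counts`` is indexed by icd with columns n11, n10, n01, n00, n
    (as produced by :func:`pvborda.cohort.build_pair_counts`).
    Finite for every input including n11 = 0, thanks to the +1/2 terms.
    """
    if (counts["n"] <= 0).any():
        raise ValueError("all pairs must have n > 0")
    n11 = counts["n11"].to_numpy(dtype=float)
    n1_ = (counts["n11"] + counts["n10"]).to_numpy(dtype=float)
    n_1 = (counts["n11"] + counts["n01"]).to_numpy(dtype=float)
    n = counts["n"].to_numpy(dtype=float)
    e11 = n1_ * n_1 / n
    ic = np.log2((n11 + 0.5) / (e11 + 0.5))
    q = stats.gamma.ppf(0.025, a=n11 + 0.5, scale=1.0 / (e11 + 0.5))
    ic025 = np.log2(q)
    return pd.DataFrame({"ic": ic, "ic025": ic025}, index=counts.index)


# ---------------------------------------------------------------------------
# LGPS expected counts
# ---------------------------------------------------------------------------

def lgps_expected(person_time: pd.DataFrame) -> pd.DataFrame:
    """Observed and indirectly standardized expected exposed events per code.

    ``person_time`` has one row per (icd, stratum) with columns O_exp, PT_exp,
    O_unexp, PT_unexp. Strata with no unexposed person-time are dropped with a
    warning; codes with no usable stratum raise.
    """
    pt = person_time.copy()
    bad = pt["PT_unexp"] <= 0
    if bad.any():
        logger.warning(
            "lgps_expected: dropping %d strata with zero unexposed person-time", int(bad.sum())
        )
        pt = pt[~bad]
    dead = person_time.loc[~person_time["icd"].isin(pt["icd"]), "icd"].unique()
    if len(dead):
        raise ValueError(
            f"no stratum with unexposed person-time for code(s): {sorted(dead)}"
        )
    pt = pt.assign(E_s=pt["PT_exp"] * pt["O_unexp"] / pt["PT_unexp"])
    out = pt.groupby("icd").agg(O=("O_exp", "sum"), E=("E_s", "sum"))
    return out


# ---------------------------------------------------------------------------
# Two-gamma empirical-Bayes shrinkage
# ---------------------------------------------------------------------------

@dataclass
class GpsPrior:
    """Two-component gamma mixture prior for the relative rate lambda."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    loglik: float = np.nan

    def as_array(self):
        return np.array([self.alpha1, self.beta1, self.alpha2, self.beta2, self.w])


#: DuMouchel's classic starting values for the prior search.
DUMOUCHEL_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)

#: Fixed vague prior used when there is too little data to fit one.
VAGUE_PRIOR = GpsPrior(*DUMOUCHEL_START)


def _mixture_logmarglik(theta: np.ndarray, O: np.ndarray, E: np.ndarray) -> float:
    """Marginal log-likelihood; theta on (log a1, log b1, log a2, log b2, logit w)."""
    a1, b1, a2, b2 = np.exp(theta[:4])
    w = float(np.clip(special.expit(theta[4]), 1e-12, 1 - 1e-12))
    # marginal of each component is negative binomial with size a, p = b/(b+E)
    l1 = stats.nbinom.logpmf(O, a1, b1 / (b1 + E))
    l2 = stats.nbinom.logpmf(O, a2, b2 / (b2 + E))
    m = np.logaddexp(np.log(w) + l1, np.log1p(-w) + l2)
    return float(m.sum())


def mixture_loglik(prior: GpsPrior, O, E) -> float:
    """Marginal log-likelihood of the data under a given prior."""
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    theta = np.concatenate(
        [np.log([prior.alpha1, prior.beta1, prior.alpha2, prior.beta2]), [special.logit(prior.w)]]
    )
    return _mixture_logmarglik(theta, O, E)


def fit_gps_prior(O, E, n_starts: int = 10, seed: int = 0) -> GpsPrior:
    """Maximize the negative-binomial mixture marginal likelihood.

    The likelihood is multimodal, so the optimizer is restarted from
    DuMouchel's classic values plus ``n_starts - 1`` seeded perturbations;
    the best converged iterate wins. With a single pair the fit is hopeless
    and the fixed vague prior is returned with a warning.
    """
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    if O.shape != E.shape or O.ndim != 1:
        raise ValueError("O and E must be equal-length vectors")
    if (E <= 0).any():
        raise ValueError("all expected counts must be positive")
    if O.size < 2:
        warnings.warn(
            "too few pairs to fit an empirical-Bayes prior; using the fixed vague prior",
            stacklevel=2,
        )
        prior = GpsPrior(*DUMOUCHEL_START)
        prior.loglik = mixture_loglik(prior, O, E)
        return prior
    if O.size < 10:
        warnings.warn("fewer than 10 pairs; prior estimates will be unstable", stacklevel=2)

    theta0 = np.concatenate(
        [np.log(DUMOUCHEL_START[:4]), [special.logit(DUMOUCHEL_START[4])]]
    )
    rng = np.random.default_rng(seed)
    starts = [theta0] + [theta0 + rng.normal(0, 1.0, 5) for _ in range(n_starts - 1)]
    # box on the log/logit scale keeps the search out of the numerically
    # degenerate corners (huge shapes make the NB pmf overflow-prone)
    bounds = [(-12.0, 12.0)] * 4 + [(-8.0, 8.0)]

    best = None
    for s in starts:
        with np.errstate(over="ignore", invalid="ignore"):
            res = optimize.minimize(
                lambda t: -_mixture_logmarglik(t, O, E),
                np.clip(s, -8.0, 8.0),
                method="Nelder-Mead",
                bounds=bounds,
                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
            )
        # a discrete-likelihood value above 0 can only be numerical garbage
        if not np.isfinite(res.fun) or res.fun < 0.0:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("gamma-Poisson prior fit failed to converge from any start")
    a1, b1, a2, b2 = np.exp(best.x[:4])
    w = float(special.expit(best.x[4]))
    return GpsPrior(a1, b1, a2, b2, w, loglik=-float(best.fun))


def gps_scores(O, E, prior: GpsPrior, codes=None) -> pd.DataFrame:
    """EBGM, EB05 and the posterior mixture weight per pair.

    The posterior of lambda given (O, E) is again a two-gamma mixture with
    components (a_k + O, b_k + E) and weight q proportional to the component
    marginal likelihoods. EBGM uses the digamma closed form for E[ln lambda];
    EB05 solves mixture-CDF(lambda) = 0.05 by bracketed root-finding.
    """
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    l1 = stats.nbinom.logpmf(O, prior.alpha1, prior.beta1 / (prior.beta1 + E))
    l2 = stats.nbinom.logpmf(O, prior.alpha2, prior.beta2 / (prior.beta2 + E))
    with np.errstate(over="ignore"):
        q = special.expit(np.log(prior.w) - np.log1p(-prior.w) + l1 - l2)

    a1, b1 = prior.alpha1 + O, prior.beta1 + E
    a2, b2 = prior.alpha2 + O, prior.beta2 + E
    mean_log = q * (special.digamma(a1) - np.log(b1)) + (1 - q) * (
        special.digamma(a2) - np.log(b2)
    )
    ebgm = np.exp(mean_log)

    eb05 = np.empty_like(ebgm)
    for i in range(O.size):
        eb05[i] = _mixture_quantile(0.05, q[i], a1[i], b1[i], a2[i], b2[i])

    out = pd.DataFrame({"O": O, "E": E, "ebgm": ebgm, "eb05": eb05, "q_post": q})
    if codes is not None:
        out.index = pd.Index(codes, name="icd")
    return out


def _mixture_quantile(p, q, a1, b1, a2, b2):
    def cdf(lam):
        return q * stats.gamma.cdf(lam, a1, scale=1 / b1) + (1 - q) * stats.gamma.cdf(
            lam, a2, scale=1 / b2
        )

    lo, hi = 1e-12, 1.0
    for _ in range(200):
        if cdf(hi) >= p:
            break
        hi *= 2.0
    else:
        raise RuntimeError(
            f"quantile bracket failure: cdf({hi}) < {p} for mixture "
            f"(q={q}, a1={a1}, b1={b1}, a2={a2}, b2={b2})"
        )
    return optimize.brentq(lambda lam: cdf(lam) - p, lo, hi, xtol=1e-12, rtol=1e-12)
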