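"""Rank-abundance-distribution models and AIC model selection.

Four niche-theory models (brokenstick, niche preemption, lognormal, Zipf)
are fitted by maximising a Poisson log-likelihood of the observed
abundances around the model's expected rank abundances, so that their AIC
values are commensurable with the zero-sum multinomial neutral model's
exact likelihood.  AIC = -2 log-likelihood + 2 npar throughout; the model
with the smallest AIC wins, with ties broken toward fewer parameters.

Expected abundance of rank r (J individuals, S species):

    brokenstick  a_r = (J / S) sum_{k=r}^{S} 1/k                (npar 0)
    preemption   a_r = J alpha (1-alpha)^(r-1) / (1-(1-alpha)^S) (npar 1)
    lognormal    a_r = exp(mu + sigma z_r), z_r Blom normal score (npar 2)
    zipf         a_r = J p1 r^gamma                              (npar 2)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln
from scipy.stats import norm

from .neutral import NeutralCommunityModel

__all__ = [
    "RADFitResult",
    "RankAbundanceModel",
    "rank_abundance",
    "fit_rad",
    "model_select",
    "rescale_to_counts",
    "NICHE_MODELS",
]

NICHE_MODELS = ("brokenstick", "preemption", "lognormal", "zipf")
_NPAR = {"brokenstick": 0, "preemption": 1, "lognormal": 2, "zipf": 2, "zsm": 2}
_MIN_S = {"brokenstick": 2, "preemption": 2, "lognormal": 3, "zipf": 3, "zsm": 2}


@dataclass
class RADFitResult:
    model: str
    params: dict
    loglik: float
    npar: int
    converged: bool = True
    expected: Optional[np.ndarray] = None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.npar

    def summary(self) -> str:
        pstr = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items()) or "(none)"
        return (
            f"{self.model} RAD fit: params {pstr}; loglik {self.loglik:.4f}; "
            f"npar {self.npar}; AIC {self.aic:.4f}"
        )


def rank_abundance(counts) -> np.ndarray:
    """Sort positive abundances descending (zeros dropped, stable ties)."""
    a = np.asarray(counts, dtype=float)
    if a.ndim != 1:
        raise ValueError("need a 1-D vector")
    if (a < 0).any():
        raise ValueError("negative abundance")
    pos = a[a > 0]
    if pos.size == 0:
        raise ValueError("all-zero vector")
    return pos[np.argsort(-pos, kind="stable")]


# ---------------------------------------------------------------------------
# Expected rank abundances


def expected_brokenstick(J: float, S: int) -> np.ndarray:
    tail = np.cumsum(1.0 / np.arange(S, 0, -1))[::-1]  # sum_{k=r}^S 1/k
    return (J / S) * tail


def expected_preemption(J: float, S: int, alpha: float) -> np.ndarray:
    if not 0 < alpha < 1:
        raise ValueError("preemption alpha must be in (0, 1)")
    r = np.arange(1, S + 1)
    return J * alpha * (1 - alpha) ** (r - 1) / (1 - (1 - alpha) ** S)


def blom_scores(S: int) -> np.ndarray:
    """Expected normal order statistics (Blom approximation), descending."""
    r = np.arange(1, S + 1)
    return norm.ppf(1 - (r - 0.375) / (S + 0.25))


def expected_lognormal(S: int, mu: float, sigma: float) -> np.ndarray:
    return np.exp(mu + sigma * blom_scores(S))


def expected_zipf(J: float, S: int, p1: float, gamma: float) -> np.ndarray:
    r = np.arange(1, S + 1)
    return J * p1 * r ** gamma


def _poisson_loglik(observed: np.ndarray, expected: np.ndarray) -> float:
    if (expected <= 0).any() or not np.isfinite(expected).all():
        return -np.inf
    return float(
        (observed * np.log(expected) - expected - gammaln(observed + 1)).sum()
    )


# ---------------------------------------------------------------------------
# Fitting


class RankAbundanceModel:
    """One rank-abundance model for one community.

    >>> res = RankAbundanceModel([50, 25, 12, 6, 3], "preemption").fit()
    >>> res.aic  # doctest: +SKIP
    """

    def __init__(self, counts, model: str):
        if model not in NICHE_MODELS + ("zsm",):
            raise ValueError(f"unknown model {model!r}")
        self.model = model
        self.ranked = rank_abundance(counts)
        self.J = float(self.ranked.sum())
        self.S = int(len(self.ranked))
        if self.S < _MIN_S[model]:
            raise ValueError(
                f"{model} needs at least {_MIN_S[model]} species, got {self.S}"
            )

    def fit(self, seed: int = 0):
        if self.model == "zsm":
            return NeutralCommunityModel(self.ranked.astype(np.int64)).fit(seed=seed)
        method = getattr(self, f"_fit_{self.model}")
        return method()

    # -- per-model fits --------------------------------------------------
    def _fit_brokenstick(self) -> RADFitResult:
        exp = expected_brokenstick(self.J, self.S)
        return RADFitResult(
            "brokenstick", {}, _poisson_loglik(self.ranked, exp), 0, True, exp
        )

    def _fit_preemption(self) -> RADFitResult:
        def neg(logit_a):
            a = 1.0 / (1.0 + np.exp(-logit_a))
            return -_poisson_loglik(self.ranked, expected_preemption(self.J, self.S, a))

        opt = minimize_scalar(neg, bounds=(-20, 20), method="bounded",
                              options={"xatol": 1e-10})
        alpha = float(1.0 / (1.0 + np.exp(-opt.x)))
        exp = expected_preemption(self.J, self.S, alpha)
        return RADFitResult(
            "preemption", {"alpha": alpha}, -float(opt.fun), 1, bool(opt.success), exp
        )

    def _fit_lognormal(self) -> RADFitResult:
        logs = np.log(self.ranked)
        x0 = np.array([logs.mean(), np.log(max(logs.std(), 1e-3))])

        def neg(x):
            mu, sigma = x[0], np.exp(np.clip(x[1], -10, 10))
            return -_poisson_loglik(
                self.ranked, expected_lognormal(self.S, mu, sigma)
            )

        opt = minimize(neg, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        mu, sigma = float(opt.x[0]), float(np.exp(np.clip(opt.x[1], -10, 10)))
        exp = expected_lognormal(self.S, mu, sigma)
        return RADFitResult(
            "lognormal", {"mu": mu, "sigma": sigma}, -float(opt.fun), 2,
            bool(opt.success), exp,
        )

    def _fit_zipf(self) -> RADFitResult:
        r = np.arange(1, self.S + 1)
        slope, intercept = np.polyfit(np.log(r), np.log(self.ranked), 1)
        p1_0 = min(max(np.exp(intercept) / self.J, 1e-6), 1 - 1e-6)
        x0 = np.array([np.log(p1_0 / (1 - p1_0)), min(slope, -1e-3)])

        def neg(x):
            p1 = 1.0 / (1.0 + np.exp(-np.clip(x[0], -30, 30)))
            return -_poisson_loglik(self.ranked, expected_zipf(self.J, self.S, p1, x[1]))

        opt = minimize(neg, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        p1 = float(1.0 / (1.0 + np.exp(-np.clip(opt.x[0], -30, 30))))
        gamma = float(opt.x[1])
        exp = expected_zipf(self.J, self.S, p1, gamma)
        return RADFitResult(
            "zipf", {"p1": p1, "gamma": gamma}, -float(opt.fun), 2,
            bool(opt.success), exp,
        )


def fit_rad(model: str, ranked, seed: int = 0):
    """Fit one named RAD model; returns RADFitResult (or NeutralFitResult)."""
    return RankAbundanceModel(ranked, model).fit(seed=seed)


def model_select(ranked, seed: int = 0, models=NICHE_MODELS + ("zsm",)):
    """Fit all five RAD models and rank them by AIC.

    Returns (fits, best_label) where ``fits`` is sorted by AIC with ties
    (delta < 1e-9) broken toward fewer parameters.  A failing model is
    excluded with a warning; selection never aborts.
    """
    ranked = rank_abundance(ranked)
    if len(ranked) < 3:
        raise ValueError("model selection needs at least 3 species")
    fits = []
    for model in models:
        try:
            fits.append(fit_rad(model, ranked, seed=seed))
        except Exception as exc:  # noqa: BLE001 - a model failure must not abort
            warnings.warn(f"model {model!r} failed to fit: {exc}")
    if not fits:
        raise RuntimeError("every model failed to fit")
    fits.sort(key=lambda f: (round(f.aic / 1e-9) * 1e-9, f.npar))
    return fits, fits[0].model


def rescale_to_counts(relative, J_target: int) -> np.ndarray:
    """Largest-remainder integerisation of a relative-abundance vector.

    The result sums exactly to ``J_target`` and every positive input entry
    receives at least one count (gene tables are integerised this way before
    neutral-model fitting).
    """
    rel = np.asarray(relative, dtype=float)
    if (rel < 0).any():
        raise ValueError("negative relative abundance")
    if not np.isclose(rel.sum(), 1.0, atol=1e-6):
        raise ValueError("relative abundances must sum to 1")
    pos = rel > 0
    k = int(pos.sum())
    if J_target < k:
        raise ValueError(f"J_target={J_target} cannot give {k} positive features >= 1 count")
    x = rel * J_target
    base = np.floor(x).astype(np.int64)
    remainder = x - base
    deficit = J_target - int(base.sum())
    if deficit > 0:
        order = np.argsort(-remainder, kind="stable")[:deficit]
        base[order] += 1
    # repair: every positive entry gets >= 1, funded by the largest counts
    need = np.flatnonzero(pos & (base == 0))
    for i in need:
        donor = int(np.argmax(base))
        if base[donor] <= 1:
            raise ValueError("J_target too small to give all positive features >= 1")
        base[donor] -= 1
        base[i] = 1
    return base
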