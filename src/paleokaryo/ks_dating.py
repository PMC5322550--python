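"""Log-normal mixture modelling of Ks distributions and molecular dating.

Synonymous substitutions accumulate approximately clock-like, so the Ks
values of gene pairs born at one event (a WGD or a speciation) cluster
around 2*r*T, where r is the synonymous substitution rate per site per year
and T the event age. A whole-genome Ks distribution is therefore modelled as
a mixture of log-normal components, one per event; the number of components
is selected by BIC, and each component's central Ks converts to an age via

    T = Ks / (2 r),       r = 6.5e-9 /site/year by default.

The mixture is fitted by expectation-maximisation on log-transformed Ks with
multiple seeded restarts; an optional exponential component can absorb the
small-Ks excess of recent tandem duplicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger("paleokaryo")

DEFAULT_RATE = 6.5e-9  # substitutions / synonymous site / year
KS_SATURATION = 3.0    # Ks above this is saturated and excluded by default


@dataclass
class KsMixture:
    """A fitted mixture of log-normal Ks components."""

    weights: np.ndarray        # (k,)
    means: np.ndarray          # (k,) means of log-Ks
    sds: np.ndarray            # (k,) sds of log-Ks
    bic: float = np.inf
    log_likelihood: float = -np.inf
    ll_trace: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.weights)

    def component_modes(self, log_median: bool = True) -> np.ndarray:
        """Central Ks of each component: exp(mu) (the log-normal median) by
        default, or the true mode exp(mu - sigma^2)."""
        if log_median:
            return np.exp(self.means)
        return np.exp(self.means - self.sds ** 2)

    def posterior(self, ks: np.ndarray) -> np.ndarray:
        """Posterior component responsibilities for Ks values (n, k)."""
        x = np.log(np.asarray(ks, dtype=float))
        dens = np.stack([
            w * stats.norm.pdf(x, m, s)
            for w, m, s in zip(self.weights, self.means, self.sds)
        ], axis=1)
        tot = dens.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        return dens / tot


@dataclass
class EventDate:
    event: str
    ks_mode: float
    T: float
    rate: float


def _em_fit(x: np.ndarray, k: int, rng: np.random.Generator,
            max_iter: int = 500, tol: float = 1e-8):
    n = len(x)
    # initialise from random quantile split
    order = np.sort(x)
    cuts = np.sort(rng.choice(np.arange(1, n), size=k - 1, replace=False)) if k > 1 else []
    groups = np.split(order, cuts)
    means = np.array([g.mean() for g in groups])
    sds = np.array([max(g.std(), 1e-3) for g in groups])
    weights = np.array([len(g) / n for g in groups])
    ll_prev, trace = -np.inf, []
    for _ in range(max_iter):
        logdens = np.stack([
            np.log(w + 1e-300) + stats.norm.logpdf(x, m, s)
            for w, m, s in zip(weights, means, sds)
        ], axis=1)
        m_ = logdens.max(axis=1, keepdims=True)
        lse = m_[:, 0] + np.log(np.exp(logdens - m_).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        resp = np.exp(logdens - lse[:, None])
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-12)
        var = (resp * (x[:, None] - means) ** 2).sum(axis=0) / np.maximum(nk, 1e-12)
        sds = np.sqrt(np.maximum(var, 1e-8))
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            break
        ll_prev = ll
    n_params = 3 * k - 1
    bic = n_params * np.log(n) - 2 * ll
    return KsMixture(weights=weights, means=means, sds=sds, bic=float(bic),
                     log_likelihood=ll, ll_trace=trace)


def fit_lognormal_mixture(ks, k_range=(1, 2, 3, 4, 5), seed: int = 0,
                          n_restarts: int = 10, ks_max: float = KS_SATURATION,
                          tol: float = 1e-8) -> KsMixture:
    """Fit log-normal mixtures over ``k_range`` and return the BIC-minimal one.

    Needs >= 30 finite positive Ks values after excluding saturated ones
    (Ks > ``ks_max``). Deterministic given ``seed``. The EM log-likelihood is
    asserted non-decreasing on every fit.
    """
    ks = np.asarray(ks, dtype=float)
    ks = ks[np.isfinite(ks) & (ks > 0)]
    if ks_max is not None:
        ks = ks[ks <= ks_max]
    if len(ks) < 30:
        raise ValueError(f"need >= 30 usable Ks values, got {len(ks)}")
    if np.allclose(ks, ks[0]):
        raise ValueError("all Ks values identical; no mixture is identifiable")
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or k_range[0] < 1:
        raise ValueError("k_range must contain integers >= 1")
    x = np.log(ks)
    rng = np.random.default_rng(seed)
    best = None
    for k in k_range:
        for _ in range(n_restarts if k > 1 else 1):
            fit = _em_fit(x, k, rng, tol=tol)
            diffs = np.diff(fit.ll_trace)
            if np.any(diffs < -1e-6):
                raise AssertionError("EM log-likelihood decreased")
            if best is None or fit.bic < best.bic - 1e-9:
                best = fit
    order = np.argsort(best.means)
    return KsMixture(weights=best.weights[order], means=best.means[order],
                     sds=best.sds[order], bic=best.bic,
                     log_likelihood=best.log_likelihood, ll_trace=best.ll_trace)


def date_from_ks(ks_mode: float, r: float = DEFAULT_RATE) -> float:
    """Age in years of an event with central Ks ``ks_mode``: T = Ks / (2 r)."""
    if r <= 0:
        raise ValueError("substitution rate r must be positive")
    if ks_mode < 0:
        raise ValueError("Ks must be nonnegative")
    return ks_mode / (2.0 * r)


def date_components(mixture: KsMixture, labels=None, r: float = DEFAULT_RATE,
                    log_median: bool = True) -> list[EventDate]:
    """Convert every mixture component to an :class:`EventDate`."""
    modes = mixture.component_modes(log_median=log_median)
    if labels is None:
        labels = [f"k{i}" for i in range(mixture.k)]
    return [
        EventDate(event=lab, ks_mode=float(m), T=date_from_ks(float(m), r), rate=r)
        for lab, m in zip(labels, modes)
    ]
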