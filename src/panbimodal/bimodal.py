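"""Two-component Gaussian mixture fits, bimodality calls, and switch classing.

Each analyte is fit by EM with restarts (one k-means(2) initialization plus
random partitions); the two-component fit is compared against the closed-form
single Gaussian by BIC = k*ln(n) - 2*loglik (k = 5 vs 2).  An analyte is
called bimodal when bic1 - bic2 > 2 (strict).  Posterior probabilities of the
high component feed tissue-entropy diversity scoring and the downstream
coupling analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: BIC-difference threshold above which an analyte is called bimodal
BIC_THRESHOLD = 2.0
#: minor mixing-weight boundary separating common from rare switches
COMMON_WEIGHT = 0.25
#: relative variance floor applied to component variances
VARIANCE_FLOOR_FRAC = 1e-3

_MAX_ITER = 1000
_TOL = 1e-8


@dataclass
class MixtureFit:
    """Result of fitting one analyte (components ordered so mu_low <= mu_high)."""

    analyte_id: str
    mu_low: float
    mu_high: float
    sigma_low: float
    sigma_high: float
    pi_high: float
    loglik2: float
    loglik1: float
    bic2: float
    bic1: float
    n_used: int
    converged: bool
    n_restarts_used: int
    posteriors: pd.Series | None = None  # per-cell P(high); NaN where missing

    @property
    def delta_bic(self) -> float:
        return self.bic1 - self.bic2

    @property
    def is_bimodal(self) -> bool:
        return is_bimodal(self)

    @property
    def minor_weight(self) -> float:
        return min(self.pi_high, 1.0 - self.pi_high)


@dataclass
class SwitchClassification:
    analyte_id: str
    is_bimodal: bool
    entropy_low: float = float("nan")
    entropy_high: float = float("nan")
    min_entropy: float = float("nan")
    diversity_tertile: str | None = None  # low | medium | high (bimodal only)
    switch_class: str = "none"  # common | rare | none


_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


def _em_once(x: np.ndarray, resp_init: np.ndarray, var_floor: float
             ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, bool]:
    """Run EM from an initial responsibility vector for component 1."""
    n = x.size
    r1 = np.clip(resp_init, 1e-6, 1 - 1e-6)
    prev = -np.inf
    converged = False
    mu = np.zeros(2)
    sd = np.ones(2)
    pi = np.array([0.5, 0.5])
    for _ in range(_MAX_ITER):
        # M-step
        n1 = r1.sum()
        n0 = n - n1
        n1 = max(n1, 1e-10)
        n0 = max(n0, 1e-10)
        r0 = 1.0 - r1
        mu = np.array([(r0 * x).sum() / n0, (r1 * x).sum() / n1])
        var = np.array([
            (r0 * (x - mu[0]) ** 2).sum() / n0,
            (r1 * (x - mu[1]) ** 2).sum() / n1,
        ])
        var = np.maximum(var, var_floor)
        sd = np.sqrt(var)
        pi = np.array([n0 / n, n1 / n])
        # E-step (weighted Gaussian densities, plain numpy for speed)
        w0 = (pi[0] / sd[0]) * np.exp(-0.5 * ((x - mu[0]) / sd[0]) ** 2)
        w1 = (pi[1] / sd[1]) * np.exp(-0.5 * ((x - mu[1]) / sd[1]) ** 2)
        tot = np.maximum(w0 + w1, 1e-300)
        r1 = w1 / tot
        ll = float(np.sum(np.log(tot))) - n * _LOG_SQRT_2PI
        if ll - prev < _TOL and ll >= prev:
            converged = True
            prev = ll
            break
        prev = ll
    return prev, mu, sd, pi, converged


def _kmeans2_resp(x: np.ndarray) -> np.ndarray:
    """Deterministic 1-D 2-means: Lloyd iterations from the extreme values."""
    c = np.array([x.min(), x.max()])
    for _ in range(100):
        assign = np.abs(x[:, None] - c).argmin(axis=1)
        newc = np.array([
            x[assign == k].mean() if np.any(assign == k) else c[k] for k in (0, 1)])
        if np.allclose(newc, c):
            break
        c = newc
    return (assign == int(np.argmax(c))).astype(float)


def fit_gmm2(
    x: Sequence[float] | pd.Series,
    n_restarts: int = 10,
    seed: int = 0,
    analyte_id: str = "",
    min_n: int = 10,
) -> MixtureFit:
    """Fit a two-component Gaussian mixture to one analyte's values.

    ``x`` may contain missing values; they are excluded from fitting and get
    NaN posteriors.  The best log-likelihood over ``n_restarts`` EM starts
    wins; components are relabeled so mu_low <= mu_high.
    """
    if isinstance(x, pd.Series):
        index = x.index
        arr = x.to_numpy(dtype=float)
    else:
        arr = np.asarray(x, dtype=float)
        index = pd.RangeIndex(arr.size)
    finite = np.isfinite(arr)
    xs = arr[finite]
    n = xs.size
    if n < min_n:
        raise ValueError(f"analyte {analyte_id or '?'}: need >= {min_n} finite values, got {n}")
    sample_var = float(np.var(xs))
    if sample_var == 0.0:
        raise ValueError(f"degenerate analyte {analyte_id or '?'}: constant input")
    var_floor = VARIANCE_FLOOR_FRAC * sample_var

    rng = np.random.default_rng(seed)
    best = (-np.inf, None)
    used = 0
    for r in range(max(1, n_restarts)):
        if r == 0:
            resp = _kmeans2_resp(xs)
        else:
            resp = (rng.random(n) < 0.5).astype(float)
        ll, mu, sd, pi, conv = _em_once(xs, resp, var_floor)
        used += 1
        if ll > best[0]:
            best = (ll, (mu, sd, pi, conv))
    ll2, (mu, sd, pi, conv) = best

    # relabel: component with larger mean is "high"
    hi = int(np.argmax(mu))
    lo = 1 - hi
    mu_low, mu_high = float(mu[lo]), float(mu[hi])
    sigma_low, sigma_high = float(sd[lo]), float(sd[hi])
    pi_high = float(pi[hi])

    # closed-form single Gaussian fit (MLE)
    mu1 = float(np.mean(xs))
    sd1 = float(np.sqrt(np.var(xs)))
    ll1 = float(np.sum(norm.logpdf(xs, mu1, max(sd1, 1e-12))))

    bic2 = 5 * np.log(n) - 2 * ll2
    bic1 = 2 * np.log(n) - 2 * ll1

    fit = MixtureFit(
        analyte_id=analyte_id, mu_low=mu_low, mu_high=mu_high,
        sigma_low=sigma_low, sigma_high=sigma_high, pi_high=pi_high,
        loglik2=float(ll2), loglik1=ll1, bic2=float(bic2), bic1=float(bic1),
        n_used=n, converged=bool(conv), n_restarts_used=used,
    )
    post = np.full(arr.size, np.nan)
    post[finite] = posterior_high(fit, xs)
    fit.posteriors = pd.Series(post, index=index, name=analyte_id or None)
    return fit


def is_bimodal(fit: MixtureFit) -> bool:
    """Bimodal iff bic1 - bic2 > 2, strictly."""
    return fit.delta_bic > BIC_THRESHOLD


def posterior_high(fit: MixtureFit, x: float | np.ndarray) -> float | np.ndarray:
    """Bayes posterior P(high component | x)."""
    x = np.asarray(x, dtype=float)
    whi = fit.pi_high * norm.pdf(x, fit.mu_high, fit.sigma_high)
    wlo = (1 - fit.pi_high) * norm.pdf(x, fit.mu_low, fit.sigma_low)
    tot = np.maximum(whi + wlo, 1e-300)
    p = whi / tot
    return float(p) if p.ndim == 0 else p


def shannon_entropy(labels: Iterable[str]) -> float:
    """-sum q ln q over label frequencies (nats)."""
    counts = pd.Series(list(labels)).value_counts().to_numpy(dtype=float)
    if counts.size == 0:
        return 0.0
    q = counts / counts.sum()
    return float(-(q * np.log(q)).sum())


def tissue_entropy(
    posteriors: pd.Series, tissues: pd.Series
) -> tuple[float, float]:
    """Shannon entropies of tissue composition of the low and high groups.

    Cells with posterior < 0.5 form the low group, >= 0.5 the high group;
    missing posteriors are excluded.  An empty group has entropy 0 (warned).
    """
    tissues = tissues.reindex(posteriors.index)
    ok = posteriors.notna() & tissues.notna()
    if not ok.any():
        raise ValueError("all posteriors missing")
    p = posteriors[ok]
    t = tissues[ok]
    low_t = t[p < 0.5]
    high_t = t[p >= 0.5]
    if low_t.empty or high_t.empty:
        warnings.warn("empty low/high group; entropy defined as 0", stacklevel=2)
    h_low = shannon_entropy(low_t) if not low_t.empty else 0.0
    h_high = shannon_entropy(high_t) if not high_t.empty else 0.0
    return h_low, h_high


def classify_switches(
    fits: Sequence[MixtureFit], tissues: pd.Series
) -> list[SwitchClassification]:
    """Entropy, diversity tertile, and common/rare class for every fit.

    Tertile breakpoints are computed over the minimum tissue entropy of the
    bimodal analytes only.  Common iff the minor mixing weight exceeds 1/4.
    """
    out: list[SwitchClassification] = []
    bimodal_fits = [f for f in fits if f.is_bimodal]
    if len(bimodal_fits) < 3:
        raise ValueError("need >= 3 bimodal analytes to form tertiles")

    ent: dict[str, tuple[float, float]] = {}
    for f in bimodal_fits:
        ent[f.analyte_id] = tissue_entropy(f.posteriors, tissues)
    min_ent = np.array([min(ent[f.analyte_id]) for f in bimodal_fits])
    q1, q2 = np.quantile(min_ent, [1 / 3, 2 / 3])

    for f in fits:
        if not f.is_bimodal:
            out.append(SwitchClassification(f.analyte_id, False))
            continue
        h_low, h_high = ent[f.analyte_id]
        me = min(h_low, h_high)
        if me <= q1:
            tert = "low"
        elif me <= q2:
            tert = "medium"
        else:
            tert = "high"
        cls = "common" if f.minor_weight > COMMON_WEIGHT else "rare"
        out.append(SwitchClassification(
            f.analyte_id, True, entropy_low=h_low, entropy_high=h_high,
            min_entropy=me, diversity_tertile=tert, switch_class=cls))
    return out


def fit_matrix(
    values: pd.DataFrame,
    n_restarts: int = 10,
    seed: int = 0,
    min_cells: int = 40,
) -> dict[str, MixtureFit]:
    """Fit every analyte (row) with >= min_cells non-missing values.

    Degenerate analytes are skipped with a warning.  Seeds are derived per
    analyte from ``seed`` so results do not depend on iteration order.
    """
    fits: dict[str, MixtureFit] = {}
    root = np.random.default_rng(seed)
    # one spawned seed per row, stable under row subsets of identical order
    seeds = root.integers(0, 2**31 - 1, size=values.shape[0])
    for (analyte, row), s in zip(values.iterrows(), seeds):
        if row.notna().sum() < min_cells:
            continue
        try:
            fits[analyte] = fit_gmm2(row, n_restarts=n_restarts, seed=int(s),
                                     analyte_id=str(analyte))
        except ValueError as e:
            logger.warning("skipping %s: %s", analyte, e)
    return fits


def fits_table(fits: Sequence[MixtureFit],
               classes: Sequence[SwitchClassification] | None = None) -> pd.DataFrame:
    rows = []
    cls_by_id = {c.analyte_id: c for c in classes} if classes else {}
    for f in fits:
        c = cls_by_id.get(f.analyte_id)
        rows.append({
            "analyte": f.analyte_id, "mu_low": f.mu_low, "mu_high": f.mu_high,
            "sigma_low": f.sigma_low, "sigma_high": f.sigma_high,
            "pi_high": f.pi_high, "delta_bic": f.delta_bic,
            "is_bimodal": f.is_bimodal, "n_used": f.n_used,
            "converged": f.converged,
            "entropy_low": c.entropy_low if c else float("nan"),
            "entropy_high": c.entropy_high if c else float("nan"),
            "tertile": (c.diversity_tertile or "") if c else "",
            "switch_class": c.switch_class if c else "",
        })
    return pd.DataFrame(rows)


def posteriors_matrix(fits: Sequence[MixtureFit]) -> pd.DataFrame:
    """Stack per-fit posteriors into an analytes x cells matrix."""
    return pd.DataFrame({f.analyte_id: f.posteriors for f in fits}).T
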