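"""Convergence diagnostics for MCMC traces: Geweke z-scores, split-R-hat,
effective sample size, and max-ESS burn-in selection."""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "geweke_z",
    "effective_sample_size",
    "split_rhat",
    "max_ess_burn_in",
    "diagnostics",
]

SCALARS = ("delta", "mu", "tau", "m", "cv", "log_joint")


def _spectral_density_zero(x: np.ndarray) -> float:
    """Spectral density at frequency zero via Bartlett-windowed
    autocovariances; the long-run variance of the mean is S(0)/n."""
    x = np.asarray(x, float)
    n = len(x)
    x = x - x.mean()
    L = max(1, min(n - 1, int(round(n ** 0.5))))
    acov = np.correlate(x, x, mode="full")[n - 1:] / n
    w = 1.0 - np.arange(1, L + 1) / (L + 1.0)
    return float(acov[0] + 2.0 * np.sum(w * acov[1 : L + 1]))


def geweke_z(x, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing the first 10 % of a trace with
    the last 50 %, with spectral-density variance estimates."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 20:
        raise ValueError("trace too short for a Geweke score")
    a = x[: max(2, int(first * n))]
    b = x[n - max(2, int(last * n)):]
    va = _spectral_density_zero(a) / len(a)
    vb = _spectral_density_zero(b) / len(b)
    denom = np.sqrt(max(va + vb, 1e-300))
    return float((a.mean() - b.mean()) / denom)


def effective_sample_size(x) -> float:
    import arviz as az

    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[None, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(x))


def split_rhat(chains) -> float:
    """Split-chain potential scale reduction; the zero-variance degenerate
    case (identical constant chains) is defined as exactly 1."""
    import arviz as az

    chains = np.atleast_2d(np.asarray(chains, float))
    if chains.shape[0] < 2:
        raise ValueError("need at least 2 chains for R-hat")
    if np.ptp(chains) == 0.0:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = float(az.rhat(chains))
    return 1.0 if not np.isfinite(r) else r


def max_ess_burn_in(x, fractions=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5)) -> int:
    """Burn-in index maximising the ESS of the remaining trace."""
    x = np.asarray(x, float)
    best, best_ess = 0, -np.inf
    for f in fractions:
        cut = int(f * len(x))
        if len(x) - cut < 20:
            continue
        tail = x[cut:]
        ess = effective_sample_size(tail) if np.ptp(tail) > 0 else 0.0
        if ess > best_ess:
            best, best_ess = cut, ess
    return best


def diagnostics(trace, others=None, min_samples: int = 100) -> dict:
    """Per-scalar Geweke z and ESS, max-ESS burn-in, and split-R-hat when
    parallel traces are supplied.

    ``trace`` is a Trace or a DataFrame with the theta columns and the two
    log densities; ``others`` an optional list of further traces for the
    Gelman-Rubin statistic.
    """
    tab = trace.table if hasattr(trace, "table") else trace
    series = {
        name: tab[name].to_numpy(float)
        for name in ("delta", "mu", "tau", "m", "cv")
        if name in tab
    }
    series["log_joint"] = (tab["log_seq"] + tab["log_tree"]).to_numpy(float)

    burn = max_ess_burn_in(series["log_joint"])
    n_post = len(series["log_joint"]) - burn
    if n_post < min_samples:
        raise ValueError(
            f"only {n_post} post-burn-in samples; need >= {min_samples}"
        )
    report = {"burn_in": burn, "n_post": n_post, "scalars": {}}
    for name, x in series.items():
        tail = x[burn:]
        if np.ptp(tail) == 0.0:
            report["scalars"][name] = {"geweke_z": 0.0, "ess": 0.0, "constant": True}
            continue
        report["scalars"][name] = {
            "geweke_z": geweke_z(tail),
            "ess": effective_sample_size(tail),
            "constant": False,
        }
    if others:
        tabs = [tab] + [t.table if hasattr(t, "table") else t for t in others]
        rhats = {}
        for name in series:
            if name == "log_joint":
                arrs = [
                    (t["log_seq"] + t["log_tree"]).to_numpy(float) for t in tabs
                ]
            else:
                arrs = [t[name].to_numpy(float) for t in tabs]
            ln = min(len(a) for a in arrs)
            rhats[name] = split_rhat(np.vstack([a[burn:ln] for a in arrs]))
        report["rhat"] = rhats
    if hasattr(trace, "burn_in"):
        trace.burn_in = burn
    return report
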