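"""Chemical-reactivity (fluorescein-maleimide labeling) kinetics.

A cysteine engineered into the H3 tail reacts with fluorescein-5-maleimide
(FM) only while the tail is off the nucleosome surface.  Labeling progress
follows the single-phase exponential

    A(t) = A0 * (1 - exp(-k * t))

and the ratio of the observed NCP rate to the free-tetramer rate reports
the conformational equilibrium

    bound tail  <-- K_conf -->  unbound (reactive) tail.

Under a fast pre-equilibrium with the bound state unreactive,

    k_ncp / k_free = K_conf / (1 + K_conf)

so K_conf can be taken either directly as the rate ratio r (the small-K
approximation, ``method='ratio'``) or as the exact inversion r/(1-r)
(``method='two_state'``).  Both are exposed; they differ by ~1% at
K_conf = 0.01 and ~10% at K_conf = 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .binding_models import DegenerateInputError, DomainError

#: FM gel lane sampling times (s) for benchtop NCP reactions
NCP_TIME_GRID = np.array([10.0, 20.0, 30.0, 60.0, 120.0, 300.0])
#: default quenched-flow grid (s) for the much faster free-tetramer reaction
FREE_TIME_GRID = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 15.0, 30.0, 60.0])

MIN_TIME_POINTS = 4


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class KineticTrace:
    """One labeling time course (one replicate, one condition)."""

    time_s: np.ndarray
    labeled_signal: np.ndarray
    condition: str = "ncp"          # {'free_tetramer', 'ncp'}
    site_label: str = ""            # e.g. 'H3S10C'
    salt_mM: float = 50.0
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.labeled_signal = np.asarray(self.labeled_signal, dtype=float)
        if self.time_s.shape != self.labeled_signal.shape:
            raise ValueError("time and signal must have equal length")
        if np.any(self.time_s < 0):
            raise DomainError("time points must be non-negative")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(self.labeled_signal < 0):
            raise DomainError("labeled signal must be non-negative")
        if self.time_s.size < MIN_TIME_POINTS:
            raise ValueError(f"need at least {MIN_TIME_POINTS} time points")


@dataclass
class RateFit:
    """Fitted single-exponential rate for one condition."""

    k: float                      # s^-1
    a0: float                     # plateau amplitude
    k_sd: float = 0.0             # SD across replicates
    per_replicate_k: tuple = ()
    global_fit: bool = False
    converged: bool = True


@dataclass
class ConfEquilibrium:
    """Conformational equilibrium constant derived from a rate pair."""

    k_conf: float
    method: str                   # {'ratio', 'two_state'}
    k_free: float
    k_ncp: float
    sd: float = 0.0
    site_label: str = ""
    salt_mM: float = 50.0
    flagged: bool = False         # k_ncp > k_free is physically inconsistent


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def exponential_progress(t, a0: float, k: float):
    """Single-phase exponential labeling progress A0*(1-exp(-k t))."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be non-negative")
    if a0 <= 0:
        raise DomainError("amplitude A0 must be positive")
    if k < 0:
        raise DomainError("rate constant must be non-negative")
    return a0 * -np.expm1(-k * t)


def _profiled_a0(k: float, t: np.ndarray, y: np.ndarray) -> float:
    """Least-squares-optimal A0 at fixed k (linear in A0)."""
    f = -np.expm1(-k * t)
    denom = float(f @ f)
    if denom == 0.0:
        return 0.0
    return float(f @ y) / denom


def _fit_one_trace(t: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    if np.all(y == 0):
        raise DegenerateInputError("all-zero labeling signal")
    # initial k from the earliest point at >=half plateau: t_half = ln2/k
    a0_guess = float(np.max(y))
    above = t[(y >= 0.5 * a0_guess) & (t > 0)]
    k0 = np.log(2.0) / float(above[0]) if above.size else 1.0 / float(np.max(t))

    def resid(theta):
        return exponential_progress(t, np.exp(theta[1]), np.exp(theta[0])) - y

    best = None
    for fac in (1.0, 0.1, 10.0):
        sol = least_squares(resid, x0=[np.log(k0 * fac), np.log(a0_guess)],
                            method="lm", max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    return float(np.exp(best.x[0])), float(np.exp(best.x[1])), bool(best.success)


def fit_rate(traces, share_a0: bool = False) -> RateFit:
    """Fit the single-exponential model to one or more replicate traces.

    With ``share_a0=False`` each trace is fit independently and the mean
    rate (+/- SD) reported.  With ``share_a0=True`` a single (k, A0) pair
    is fit globally to all traces simultaneously.
    """
    if isinstance(traces, KineticTrace):
        traces = [traces]
    traces = list(traces)
    if not traces:
        raise ValueError("no traces supplied")

    if share_a0 and len(traces) > 1:
        t = np.concatenate([tr.time_s for tr in traces])
        y = np.concatenate([tr.labeled_signal for tr in traces])
        k, a0, ok = _fit_global(t, y)
        return RateFit(k=k, a0=a0, k_sd=0.0, per_replicate_k=(k,),
                       global_fit=True, converged=ok)

    ks, a0s, ok_all = [], [], True
    for tr in traces:
        k, a0, ok = _fit_one_trace(tr.time_s, tr.labeled_signal)
        ks.append(k)
        a0s.append(a0)
        ok_all = ok_all and ok
    ks = np.asarray(ks)
    return RateFit(
        k=float(np.mean(ks)),
        a0=float(np.mean(a0s)),
        k_sd=float(np.std(ks, ddof=1)) if ks.size > 1 else 0.0,
        per_replicate_k=tuple(float(k) for k in ks),
        global_fit=False,
        converged=ok_all,
    )


def _fit_global(t: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Global (k, A0) fit on pooled, unordered time/signal arrays."""
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    # collapse duplicate times is unnecessary for least squares
    if np.all(y == 0):
        raise DegenerateInputError("all-zero labeling signal")
    a0_guess = float(np.max(y))
    above = t[(y >= 0.5 * a0_guess) & (t > 0)]
    k0 = np.log(2.0) / float(above[0]) if above.size else 1.0 / float(np.max(t))

    def resid(theta):
        return np.expm1(-np.exp(theta[0]) * t) * -np.exp(theta[1]) - y

    best = None
    for fac in (1.0, 0.1, 10.0):
        sol = least_squares(resid, x0=[np.log(k0 * fac), np.log(a0_guess)],
                            method="lm", max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    return float(np.exp(best.x[0])), float(np.exp(best.x[1])), bool(best.success)


def kconf_from_rates(k_ncp: float, k_free: float, method: str = "ratio",
                     site_label: str = "", salt_mM: float = 50.0,
                     sd: float = 0.0) -> ConfEquilibrium:
    """Convert an (NCP, free) rate pair into a conformational equilibrium.

    ``method='ratio'`` takes K_conf = k_ncp/k_free directly;
    ``method='two_state'`` inverts k_ncp/k_free = K/(1+K), giving
    K = r/(1-r).  The two agree for small K.
    """
    if k_free <= 0 or k_ncp <= 0:
        raise DomainError("rates must be positive")
    if method not in ("ratio", "two_state"):
        raise ValueError(f"unknown method {method!r}")
    r = k_ncp / k_free
    flagged = r > 1.0
    if method == "ratio":
        k_conf = r
    else:
        if r >= 1.0:
            raise DomainError(
                "k_ncp >= k_free is inconsistent with the two-state model "
                "(the NCP-bound tail would have to be reactive)"
            )
        k_conf = r / (1.0 - r)
    return ConfEquilibrium(k_conf=float(k_conf), method=method,
                           k_free=float(k_free), k_ncp=float(k_ncp),
                           sd=float(sd), site_label=site_label,
                           salt_mM=salt_mM, flagged=flagged)


def fraction_unbound(k_conf: float) -> float:
    """Fraction of tails in the NCP-unbound (reader-accessible) state.

    K/(1+K) for the two-state equilibrium; K=0.01 gives 0.99%, i.e. under
    1% of tails accessible.
    """
    if k_conf < 0:
        raise DomainError("K_conf must be non-negative")
    return k_conf / (1.0 + k_conf)


def fold_change_summary(k_conf_a, k_conf_b) -> tuple[float, float]:
    """Fold change mean(b)/mean(a) with first-order SD propagation.

    Returns ``(fold, sd)`` where sd combines the per-set SDs as
    fold * sqrt((sd_a/mean_a)^2 + (sd_b/mean_b)^2).
    """
    a = np.asarray(list(k_conf_a), dtype=float)
    b = np.asarray(list(k_conf_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both K_conf sets must be non-empty")
    ma, mb = float(np.mean(a)), float(np.mean(b))
    if ma == 0:
        raise DomainError("zero mean in denominator set")
    sa = float(np.std(a, ddof=1)) if a.size > 1 else 0.0
    sb = float(np.std(b, ddof=1)) if b.size > 1 else 0.0
    fold = mb / ma
    sd = abs(fold) * np.sqrt((sa / ma) ** 2 + (sb / mb) ** 2) if mb != 0 else 0.0
    return fold, float(sd)
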