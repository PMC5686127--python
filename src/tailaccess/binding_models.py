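"""Closed-form equilibrium binding models and their least-squares fitting.

Three signal models are supported, named by ``model_tag``:

``quadratic``
    Ligand-depletion (tight-binding) model for a receptor at concentration
    [P] comparable to Kd, titrated with ligand [L]::

        dI = dImax * ((L + P + Kd) - sqrt((L + P + Kd)^2 - 4*P*L)) / (2*P)

``hyperbolic``
    Langmuir isotherm for a receptor dilute relative to Kd::

        dI = dImax * L / (Kd + L)

``isotherm``
    The same saturation form applied to a trace labeled receptor
    (e.g. 5 nM fluorescent nucleosome) titrated with protein, with the
    anisotropy change as the signal.  Kept as a distinct tag because the
    experiment and the meaning of the axes differ.

Fits are per replicate, parameterized in log(Kd) to enforce positivity,
with mean +/- SD aggregation across replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

MODEL_TAGS = ("quadratic", "hyperbolic", "isotherm")

#: multiplicative restart factors applied to the Kd initial guess before
#: a fit is declared non-converged
_RESTART_FACTORS = (1.0, 0.1, 10.0, 0.01, 100.0)

MIN_POINTS_PER_REPLICATE = 4


class DomainError(ValueError):
    """Input outside the physical domain of a model."""


class DegenerateInputError(ValueError):
    """Input that makes the model or fit mathematically degenerate."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TitrationSeries:
    """One replicate of a binding titration.

    Concentrations are in uM; the signal is in arbitrary units (a
    fluorescence-intensity change or an anisotropy value).
    """

    ligand_conc: np.ndarray
    signal: np.ndarray
    protein_conc: float | None = None
    replicate_id: str = "r1"
    condition: str = ""
    signal_sd: np.ndarray | None = None  # optional per-point sigma for weighting

    def __post_init__(self) -> None:
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal_sd is not None:
            self.signal_sd = np.asarray(self.signal_sd, dtype=float)
            if self.signal_sd.shape != self.signal.shape:
                raise ValueError("signal_sd must match signal length")
            if np.any(self.signal_sd <= 0):
                raise DomainError("signal_sd values must be positive")
        if self.ligand_conc.shape != self.signal.shape:
            raise ValueError("ligand_conc and signal must have equal length")
        if np.any(self.ligand_conc < 0):
            raise DomainError("ligand concentrations must be non-negative")
        if np.any(np.diff(self.ligand_conc) <= 0):
            raise ValueError(
                "ligand concentrations must be strictly increasing within a replicate"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal values must be finite")
        if self.protein_conc is not None and self.protein_conc <= 0:
            raise DomainError("protein_conc must be positive when present")


@dataclass
class BindingFit:
    """Result of fitting one model to one or more titration replicates."""

    kd: float
    delta_i_max: float
    per_replicate_kd: list[float]
    per_replicate_dimax: list[float]
    kd_sd: float
    model_tag: str
    converged: bool
    residual_norm: float
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# signal models
# ---------------------------------------------------------------------------

def quadratic_bound_signal(L, P: float, kd: float, dImax: float):
    """Ligand-depletion binding signal (exact two-component equilibrium).

    Parameters
    ----------
    L : array_like
        Total ligand concentration, uM.
    P : float
        Total receptor concentration, uM.
    kd : float
        Dissociation constant, uM.
    dImax : float
        Signal change at full receptor saturation.

    Returns
    -------
    Signal change dI; ``dImax`` times the bound receptor fraction.
    """
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise DomainError("ligand concentration must be non-negative")
    if P < 0 or kd < 0:
        raise DomainError("protein concentration and Kd must be non-negative")
    if P == 0 and kd == 0:
        raise DegenerateInputError("P and Kd cannot both be zero")
    if P == 0:
        # dilute-receptor limit of the quadratic form
        return hyperbolic_bound_signal(L, kd, dImax)
    s = L + P + kd
    disc = np.maximum(s * s - 4.0 * P * L, 0.0)  # >=0 algebraically; clip rounding
    # conjugate form of (s - sqrt(disc))/(2P): avoids cancellation when the
    # bound fraction is small (dilute receptor)
    bound = 2.0 * L / (s + np.sqrt(disc))
    return dImax * bound


def hyperbolic_bound_signal(L, kd: float, dImax: float):
    """Hyperbolic (Langmuir) binding signal dImax*L/(Kd+L)."""
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise DomainError("ligand concentration must be non-negative")
    if kd <= 0:
        raise DomainError("Kd must be positive for the hyperbolic model")
    return dImax * L / (kd + L)


def isotherm_bound_signal(L, kd: float, dImax: float):
    """Saturation isotherm on the titrant axis (trace receptor).

    Identical functional form to :func:`hyperbolic_bound_signal`; the tag
    exists so anisotropy titrations of a trace labeled receptor carry their
    own model identity.
    """
    return hyperbolic_bound_signal(L, kd, dImax)


_MODEL_FUNCS = {
    "quadratic": None,  # needs P, handled explicitly
    "hyperbolic": hyperbolic_bound_signal,
    "isotherm": isotherm_bound_signal,
}


def model_signal(model_tag: str, L, kd: float, dImax: float,
                 protein_conc: float | None = None):
    """Evaluate any of the named binding models on a concentration grid."""
    if model_tag not in MODEL_TAGS:
        raise ValueError(f"unknown model_tag {model_tag!r}")
    if model_tag == "quadratic":
        if protein_conc is None:
            raise ValueError("quadratic model requires protein_conc")
        return quadratic_bound_signal(L, protein_conc, kd, dImax)
    return _MODEL_FUNCS[model_tag](L, kd, dImax)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _initial_guess(L: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Kd0 = concentration at half-maximal observed signal; dImax0 = max signal."""
    ymax = float(np.max(np.abs(y)))
    if ymax == 0:
        raise DegenerateInputError("all-zero signal cannot be fit")
    half = 0.5 * np.max(y)
    above = L[y >= half]
    kd0 = float(above[0]) if above.size and above[0] > 0 else float(
        L[L > 0][0] if np.any(L > 0) else 1.0
    )
    return max(kd0, 1e-9), float(np.max(y))


def _fit_single(L: np.ndarray, y: np.ndarray, model_tag: str,
                protein_conc: float | None,
                sigma: np.ndarray | None = None
                ) -> tuple[float, float, float, bool]:
    """Fit (kd, dImax) to one replicate; returns (kd, dImax, resid_norm, ok)."""
    kd0, di0 = _initial_guess(L, y)
    w = 1.0 if sigma is None else 1.0 / sigma

    def resid(theta):
        kd = np.exp(theta[0])
        return w * (model_signal(model_tag, L, kd, theta[1], protein_conc) - y)

    best = None
    for fac in _RESTART_FACTORS:
        try:
            sol = least_squares(resid, x0=[np.log(kd0 * fac), di0],
                                method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and sol.cost <= (best.cost + 1e-30):
            best = sol if sol.cost <= best.cost else best
    if best is None:
        return np.nan, np.nan, np.inf, False
    kd = float(np.exp(best.x[0]))
    dimax = float(best.x[1])
    rnorm = float(np.sqrt(2.0 * best.cost))
    return kd, dimax, rnorm, bool(best.success)


def fit_binding_titration(data, model_tag: str,
                          fix_protein_conc: float | None = None) -> BindingFit:
    """Fit a binding model to a set of titration replicates.

    Each replicate is fit independently (mirroring per-experiment fitting
    with SD across runs); the reported ``kd`` / ``delta_i_max`` are means
    across replicates and ``kd_sd`` the SD (0 for a single replicate).

    Parameters
    ----------
    data : TitrationSeries or sequence of TitrationSeries
    model_tag : {'quadratic', 'hyperbolic', 'isotherm'}
    fix_protein_conc : float, optional
        Receptor concentration (uM) used for every replicate of the
        quadratic model; overrides each series' own ``protein_conc``.
    """
    if isinstance(data, TitrationSeries):
        data = [data]
    data = list(data)
    if not data:
        raise ValueError("no titration data supplied")
    if model_tag not in MODEL_TAGS:
        raise ValueError(f"unknown model_tag {model_tag!r}")

    fit_warnings: list[str] = []
    kds, dimaxs, rnorms = [], [], []
    ok_all = True
    for series in data:
        if series.ligand_conc.size < MIN_POINTS_PER_REPLICATE:
            raise ValueError(
                f"replicate {series.replicate_id!r} has fewer than "
                f"{MIN_POINTS_PER_REPLICATE} points"
            )
        P = fix_protein_conc if fix_protein_conc is not None else series.protein_conc
        if model_tag == "quadratic" and P is None:
            raise ValueError("quadratic model requires a protein concentration")
        # monotone-correlation sanity check
        if series.ligand_conc.size >= 3:
            r = np.corrcoef(series.ligand_conc, series.signal)[0, 1]
            if not np.isnan(r) and r < 0.0:
                fit_warnings.append(
                    f"replicate {series.replicate_id!r}: signal negatively "
                    "correlated with concentration"
                )
        kd, dimax, rn, ok = _fit_single(series.ligand_conc, series.signal,
                                        model_tag, P, series.signal_sd)
        kds.append(kd)
        dimaxs.append(dimax)
        rnorms.append(rn)
        ok_all = ok_all and ok

    for w in fit_warnings:
        warnings.warn(w, stacklevel=2)

    kd_arr = np.asarray(kds)
    return BindingFit(
        kd=float(np.mean(kd_arr)),
        delta_i_max=float(np.mean(dimaxs)),
        per_replicate_kd=[float(k) for k in kds],
        per_replicate_dimax=[float(d) for d in dimaxs],
        kd_sd=float(np.std(kd_arr, ddof=1)) if kd_arr.size > 1 else 0.0,
        model_tag=model_tag,
        converged=ok_all,
        residual_norm=float(np.sum(rnorms)),
        warnings=fit_warnings,
    )
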