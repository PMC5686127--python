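"""FRET efficiency by the (ratio)A method and site-exposure isotherm fits.

The (ratio)A method compares acceptor emission under donor excitation
(after removing the donor's own emission tail) with acceptor emission
under direct acceptor excitation.  With extinction-coefficient ratios

    eps_ratio_direct = epsA(l_Dex) / epsA(l_Aex)   (direct-excitation crosstalk)
    eps_ratio_cross  = epsA(l_Aex) / epsD(l_Dex)

and donor labeling fraction d+, the efficiency is

    E = ((ratio)A - eps_ratio_direct) * eps_ratio_cross / d+

Site exposure: a DNA-binding protein (LexA) traps transiently unwrapped
nucleosome states; titrating it lowers FRET along the isotherm

    E(C) = E0 + (Ef - E0) / (1 + S_half / C)

whose inflection point S_half is the apparent site-exposure constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .binding_models import DomainError


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EmissionSpectrum:
    """One emission scan: intensity vs wavelength at a fixed excitation."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    excitation_nm: float          # donor 510 or acceptor 610
    sample: str = "donor_acceptor"  # {'donor_acceptor','donor_only','acceptor_only'}

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength_nm.shape != self.intensity.shape:
            raise ValueError("wavelength and intensity must have equal length")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


@dataclass
class RatioAParams:
    """Constants of the (ratio)A calculation.

    The extinction-coefficient ratios are instrument/fluorophore specific
    configuration inputs, not physical constants of this package; defaults
    are placeholders representative of a Cy3/Cy5 pair.
    """

    eps_ratio_direct: float = 0.05    # epsA(510)/epsA(610)
    eps_ratio_cross: float = 2.0      # epsA(610)/epsD(510)
    d_plus: float = 1.0               # donor labeling fraction, (0, 1]
    integration_band_nm: tuple[float, float] = (650.0, 720.0)
    donor_window_nm: tuple[float, float] = (530.0, 545.0)

    def __post_init__(self) -> None:
        if self.eps_ratio_direct <= 0 or self.eps_ratio_cross <= 0:
            raise DomainError("extinction ratios must be positive")
        if not (0.0 < self.d_plus <= 1.0):
            raise DomainError("d_plus must lie in (0, 1]")


@dataclass
class FretTitration:
    """FRET efficiency vs titrant concentration for one replicate."""

    titrant_conc: np.ndarray      # uM
    efficiency: np.ndarray
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        self.titrant_conc = np.asarray(self.titrant_conc, dtype=float)
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        if self.titrant_conc.shape != self.efficiency.shape:
            raise ValueError("concentration and efficiency must have equal length")
        if np.any(self.titrant_conc < 0):
            raise DomainError("titrant concentrations must be non-negative")


@dataclass
class SiteExposureFit:
    """Fitted site-exposure isotherm parameters with replicate SDs."""

    e0: float
    ef: float
    s_half: float
    e0_sd: float = 0.0
    ef_sd: float = 0.0
    s_half_sd: float = 0.0
    per_replicate_s_half: tuple = ()
    converged: bool = True
    degenerate: bool = False
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# (ratio)A efficiency
# ---------------------------------------------------------------------------

def _band_integral(spec: EmissionSpectrum, band: tuple[float, float]) -> float:
    lo, hi = band
    mask = (spec.wavelength_nm >= lo) & (spec.wavelength_nm <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"spectrum (excitation {spec.excitation_nm} nm) does not cover "
            f"the {lo}-{hi} nm integration band"
        )
    return float(np.trapezoid(spec.intensity[mask], spec.wavelength_nm[mask]))


def ratioA_efficiency(da_donor_ex: EmissionSpectrum,
                      da_acceptor_ex: EmissionSpectrum,
                      donor_only: EmissionSpectrum,
                      params: RatioAParams) -> tuple[float, list[str]]:
    """FRET efficiency of a donor/acceptor sample by the (ratio)A method.

    Steps: (1) scale the donor-only spectrum to the donor/acceptor spectrum
    over the donor-dominated window and subtract it, leaving acceptor
    emission under donor excitation; (2) ratio its integral over the
    acceptor band to the directly excited acceptor integral; (3) convert
    (ratio)A to E with the extinction ratios and donor labeling fraction.

    Returns ``(E, flags)``; E is clamped to [0, 1] with a flag when the
    raw value falls outside.
    """
    if donor_only.excitation_nm != da_donor_ex.excitation_nm:
        raise ValueError("donor_only must be measured under donor excitation")

    # resample donor_only onto the donor/acceptor grid if needed
    if (donor_only.wavelength_nm.shape != da_donor_ex.wavelength_nm.shape or
            not np.allclose(donor_only.wavelength_nm, da_donor_ex.wavelength_nm)):
        lo = max(donor_only.wavelength_nm[0], da_donor_ex.wavelength_nm[0])
        hi = min(donor_only.wavelength_nm[-1], da_donor_ex.wavelength_nm[-1])
        if lo >= hi:
            raise ValueError("donor_only and donor/acceptor wavelength grids do not overlap")
        d_int = np.interp(da_donor_ex.wavelength_nm, donor_only.wavelength_nm,
                          donor_only.intensity)
    else:
        d_int = donor_only.intensity

    wl = da_donor_ex.wavelength_nm
    wlo, whi = params.donor_window_nm
    win = (wl >= wlo) & (wl <= whi)
    if win.sum() < 2:
        raise ValueError("donor window not covered by the donor-excitation spectra")
    denom = float(np.sum(d_int[win]))
    if denom <= 0:
        raise DomainError("donor-only spectrum has no intensity in the donor window")
    scale = float(np.sum(da_donor_ex.intensity[win])) / denom

    sensitized = EmissionSpectrum(
        wavelength_nm=wl,
        intensity=da_donor_ex.intensity - scale * d_int,
        excitation_nm=da_donor_ex.excitation_nm,
        sample="donor_acceptor",
    )

    flags: list[str] = []
    sens_int = _band_integral(sensitized, params.integration_band_nm)
    dir_int = _band_integral(da_acceptor_ex, params.integration_band_nm)
    if dir_int <= 0:
        raise DomainError("direct acceptor-excitation integral is non-positive")
    if sens_int < 0:
        flags.append("negative sensitized emission; efficiency floored at 0")
        return 0.0, flags

    ratio_a = sens_int / dir_int
    e = (ratio_a - params.eps_ratio_direct) * params.eps_ratio_cross / params.d_plus
    if e < 0.0:
        flags.append(f"raw efficiency {e:.4f} below 0; clamped")
        e = 0.0
    elif e > 1.0:
        flags.append(f"raw efficiency {e:.4f} above 1; clamped")
        e = 1.0
    return float(e), flags


# ---------------------------------------------------------------------------
# site-exposure isotherm
# ---------------------------------------------------------------------------

def site_exposure_efficiency(C, e0: float, ef: float, s_half: float):
    """Site-exposure isotherm E(C) = E0 + (Ef-E0)/(1 + S_half/C); E(0) = E0."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise DomainError("titrant concentration must be non-negative")
    if s_half <= 0:
        raise DomainError("S_half must be positive")
    with np.errstate(divide="ignore"):
        frac = np.where(C > 0, 1.0 / (1.0 + s_half / np.where(C > 0, C, 1.0)), 0.0)
    return e0 + (ef - e0) * frac


def _fit_one_titration(C: np.ndarray, E: np.ndarray) -> tuple[float, float, float, bool]:
    e0_guess = float(E[np.argmin(C)])
    ef_guess = float(E[np.argmax(C)])
    mid = 0.5 * (e0_guess + ef_guess)
    # concentration closest to the half-transition as the S_half guess
    pos = C[C > 0]
    s0 = float(pos[np.argmin(np.abs(E[C > 0] - mid))]) if pos.size else 1.0

    def resid(theta):
        return site_exposure_efficiency(C, theta[0], theta[1], np.exp(theta[2])) - E

    best = None
    for fac in (1.0, 0.1, 10.0):
        sol = least_squares(resid, x0=[e0_guess, ef_guess, np.log(max(s0 * fac, 1e-9))],
                            method="lm", max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    return (float(best.x[0]), float(best.x[1]), float(np.exp(best.x[2])),
            bool(best.success))


def fit_site_exposure(titrations, flat_tol: float = 0.01) -> SiteExposureFit:
    """Fit the site-exposure isotherm to one or more FRET titrations.

    Each replicate is fit independently; parameters are reported as mean
    +/- SD across replicates.  A series whose efficiency span is below
    ``flat_tol`` (no response, as for single PHD fingers) is flagged
    degenerate and not fit.
    """
    if isinstance(titrations, FretTitration):
        titrations = [titrations]
    titrations = list(titrations)
    if not titrations:
        raise ValueError("no titration data supplied")

    flags: list[str] = []
    spans = [float(np.ptp(t.efficiency)) for t in titrations]
    if max(spans) < flat_tol:
        e_mean = float(np.mean([np.mean(t.efficiency) for t in titrations]))
        return SiteExposureFit(e0=e_mean, ef=e_mean, s_half=float("nan"),
                               converged=False, degenerate=True,
                               flags=["flat efficiency series; no transition to fit"])

    e0s, efs, shs = [], [], []
    ok_all = True
    for t in titrations:
        if t.titrant_conc.size < 5:
            raise ValueError("need at least 5 concentration points per replicate")
        if np.any(t.efficiency < 0) or np.any(t.efficiency > 1):
            flags.append(
                f"replicate {t.replicate_id!r}: efficiencies outside [0,1]")
        e0, ef, sh, ok = _fit_one_titration(t.titrant_conc, t.efficiency)
        e0s.append(e0)
        efs.append(ef)
        shs.append(sh)
        ok_all = ok_all and ok

    shs_arr = np.asarray(shs)
    n = shs_arr.size
    sd = (lambda x: float(np.std(x, ddof=1)) if n > 1 else 0.0)
    return SiteExposureFit(
        e0=float(np.mean(e0s)), ef=float(np.mean(efs)),
        s_half=float(np.mean(shs_arr)),
        e0_sd=sd(np.asarray(e0s)), ef_sd=sd(np.asarray(efs)),
        s_half_sd=sd(shs_arr),
        per_replicate_s_half=tuple(float(s) for s in shs),
        converged=ok_all, degenerate=False, flags=flags,
    )
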