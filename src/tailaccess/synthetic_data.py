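"""Seeded generators for every input type the analysis stages consume.

Each generator emulates one experiment class at its study conditions:

* FM-labeling kinetics: free tetramer on a fast quenched-flow grid and NCP
  on the gel-lane grid (10...300 s), NCP rate suppressed to
  k_free * K/(1+K); gel-band noise is multiplicative log-normal (bands are
  positive and scale-dependent), parameterized mean-one so it is unbiased.
* Binding titrations: quadratic ligand-depletion curves at 0.5-1 uM
  receptor (tryptophan fluorescence) or saturation isotherms at trace
  (5 nM) labeled nucleosome (anisotropy); additive Gaussian signal noise.
* FRET: donor/acceptor emission spectra built from Gaussian bands that
  invert exactly under the shipped (ratio)A constants, and site-exposure
  titrations on a 0-10 uM grid following the unwrapping isotherm.
* NMR titrations: fast-exchange peak movement (shifts scale with bound
  fraction) with per-residue exchange attenuation; gamma ~ 0 emulates
  complete disappearance of one domain's amides on nucleosome binding.

One seed governs a generator call; replicate streams derive from
(seed, replicate_index) so any replicate can be regenerated alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding_models import TitrationSeries, model_signal, quadratic_bound_signal
from .fret_analysis import (EmissionSpectrum, FretTitration, RatioAParams,
                            site_exposure_efficiency)
from .reactivity_kinetics import (FREE_TIME_GRID, NCP_TIME_GRID, KineticTrace,
                                  exponential_progress)

#: default LexA titration grid, uM
FRET_CONC_GRID = np.array([0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0,
                           6.0, 8.0, 10.0])


@dataclass
class GeneratorConfig:
    """Shared knobs for all generators; identical config => identical output."""

    seed: int = 0
    n_replicates: int = 3
    kinetics_cv: float = 0.05          # lognormal CV on gel band intensities
    titration_sigma_frac: float = 0.02  # Gaussian sigma as fraction of dImax
    fret_sigma_e: float = 0.01         # Gaussian sigma on efficiency points
    nmr_sigma_ppm: float = 0.0         # Gaussian sigma on 1H ppm (15N scaled x5)
    nmr_sigma_intensity: float = 0.0   # fractional Gaussian sigma on intensities

    def __post_init__(self) -> None:
        for name in ("kinetics_cv", "titration_sigma_frac", "fret_sigma_e",
                     "nmr_sigma_ppm", "nmr_sigma_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def rng(self, replicate_index: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(replicate_index)])


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def gen_kinetics(k_free: float, k_conf: float, cfg: GeneratorConfig,
                 time_grid_free: np.ndarray = FREE_TIME_GRID,
                 time_grid_ncp: np.ndarray = NCP_TIME_GRID,
                 a0: float = 1.0, site_label: str = "H3S10C",
                 salt_mM: float = 50.0) -> list[KineticTrace]:
    """Paired free-tetramer / NCP labeling time courses.

    The NCP observed rate follows the two-state pre-equilibrium,
    k_ncp = k_free * K_conf/(1+K_conf).
    """
    if k_free <= 0 or k_conf <= 0:
        raise ValueError("k_free and k_conf must be positive")
    time_grid_free = np.asarray(time_grid_free, dtype=float)
    time_grid_ncp = np.asarray(time_grid_ncp, dtype=float)
    if time_grid_free.size == 0 or time_grid_ncp.size == 0:
        raise ValueError("time grids must be non-empty")
    k_ncp = k_free * k_conf / (1.0 + k_conf)

    traces: list[KineticTrace] = []
    for rep in range(cfg.n_replicates):
        rng = cfg.rng(rep)
        for cond, grid, k in (("free_tetramer", time_grid_free, k_free),
                              ("ncp", time_grid_ncp, k_ncp)):
            clean = exponential_progress(grid, a0, k)
            noisy = clean * _lognormal_factor(rng, cfg.kinetics_cv, grid.size)
            traces.append(KineticTrace(
                time_s=grid.copy(), labeled_signal=noisy, condition=cond,
                site_label=site_label, salt_mM=salt_mM,
                replicate_id=f"r{rep + 1}"))
    return traces


# ---------------------------------------------------------------------------
# binding titrations
# ---------------------------------------------------------------------------

def gen_titration(model_tag: str, kd: float, dImax: float,
                  protein_conc: float | None, conc_grid: np.ndarray,
                  cfg: GeneratorConfig, sigma: float | None = None,
                  condition: str = "") -> list[TitrationSeries]:
    """Binding titration replicates with additive Gaussian signal noise.

    ``sigma`` is the absolute noise SD in signal units; when omitted it is
    ``cfg.titration_sigma_frac * dImax``.
    """
    conc_grid = np.asarray(conc_grid, dtype=float)
    if conc_grid.size == 0:
        raise ValueError("concentration grid must be non-empty")
    if sigma is None:
        sigma = cfg.titration_sigma_frac * abs(dImax)
    clean = model_signal(model_tag, conc_grid, kd, dImax, protein_conc)

    out: list[TitrationSeries] = []
    for rep in range(cfg.n_replicates):
        rng = cfg.rng(rep)
        noise = rng.normal(0.0, sigma, size=conc_grid.size) if sigma > 0 else 0.0
        out.append(TitrationSeries(
            ligand_conc=conc_grid.copy(), signal=clean + noise,
            protein_conc=protein_conc, replicate_id=f"r{rep + 1}",
            condition=condition))
    return out


# ---------------------------------------------------------------------------
# FRET
# ---------------------------------------------------------------------------

#: Gaussian emission band shapes (center nm, width nm) for the dye pair
DONOR_BAND = (565.0, 18.0)
ACCEPTOR_BAND = (668.0, 22.0)


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def gen_fret_spectra(e_true: float, params: RatioAParams | None = None,
                     intensity_scale: float = 1000.0
                     ) -> tuple[EmissionSpectrum, EmissionSpectrum, EmissionSpectrum]:
    """Forward-simulate the spectrum triple the (ratio)A analysis consumes.

    Returns (donor/acceptor under donor excitation, donor/acceptor under
    acceptor excitation, donor-only under donor excitation), built from
    Gaussian donor and acceptor bands with amplitudes consistent with the
    supplied extinction-ratio constants, so analyzing them recovers
    ``e_true`` up to band-overlap error (<1e-3).
    """
    if not (0.0 <= e_true <= 1.0):
        raise ValueError("FRET efficiency must lie in [0, 1]")
    params = params or RatioAParams()
    wl_d = np.arange(530.0, 750.0 + 1, 2.0)   # donor-excitation scan
    wl_a = np.arange(630.0, 750.0 + 1, 2.0)   # acceptor-excitation scan

    eps_a_dex = params.eps_ratio_direct        # epsA(510), with epsA(610)=1
    eps_d_dex = 1.0 / params.eps_ratio_cross   # epsD(510)
    dp = params.d_plus

    donor_d = _gauss(wl_d, *DONOR_BAND)
    acc_d = _gauss(wl_d, *ACCEPTOR_BAND)
    acc_a = _gauss(wl_a, *ACCEPTOR_BAND)

    da_donor_ex = EmissionSpectrum(
        wavelength_nm=wl_d,
        intensity=intensity_scale * (
            eps_d_dex * (1.0 - e_true * dp) * donor_d
            + (eps_a_dex + e_true * dp * eps_d_dex) * acc_d),
        excitation_nm=510.0, sample="donor_acceptor")
    da_acceptor_ex = EmissionSpectrum(
        wavelength_nm=wl_a, intensity=intensity_scale * acc_a,
        excitation_nm=610.0, sample="donor_acceptor")
    donor_only = EmissionSpectrum(
        wavelength_nm=wl_d, intensity=intensity_scale * eps_d_dex * donor_d,
        excitation_nm=510.0, sample="donor_only")
    return da_donor_ex, da_acceptor_ex, donor_only


def gen_fret_titration(e0: float, ef: float, s_half: float,
                       cfg: GeneratorConfig,
                       conc_grid: np.ndarray = FRET_CONC_GRID
                       ) -> list[FretTitration]:
    """Site-exposure titration replicates with Gaussian efficiency noise."""
    conc_grid = np.asarray(conc_grid, dtype=float)
    clean = site_exposure_efficiency(conc_grid, e0, ef, s_half)
    out: list[FretTitration] = []
    for rep in range(cfg.n_replicates):
        rng = cfg.rng(rep)
        noise = rng.normal(0.0, cfg.fret_sigma_e, size=conc_grid.size) \
            if cfg.fret_sigma_e > 0 else 0.0
        out.append(FretTitration(titrant_conc=conc_grid.copy(),
                                 efficiency=clean + noise,
                                 replicate_id=f"r{rep + 1}"))
    return out


# ---------------------------------------------------------------------------
# NMR titrations
# ---------------------------------------------------------------------------

def default_residue_map(n_hot: int = 12) -> dict[int, dict]:
    """A small synthetic tandem-reader residue map for examples and tests.

    PHD1-region residues (361-417) get modest shift responses; PHD2-region
    residues (443-503) get larger responses and strong exchange attenuation
    (gamma ~ 0), mimicking interface asymmetry.  Deterministic.
    """
    rng = np.random.default_rng(20_2410)
    residues: dict[int, dict] = {}
    aa_pool = list("ACDEFGHIKLMNQRSTVWY")
    for i in range(361, 504):
        region_phd2 = i >= 443
        hot = (i % max(1, (503 - 361) // n_hot)) == 0
        dmax_h = (0.12 if region_phd2 else 0.05) if hot else 0.01
        residues[i] = {
            "aa": "P" if i in (380, 460) else aa_pool[i % len(aa_pool)],
            "h0": 7.5 + rng.uniform(-1.0, 1.5),
            "n0": 115.0 + rng.uniform(-10.0, 10.0),
            "dH_max": dmax_h,
            "dN_max": dmax_h * 4.0,
            "gamma": 0.05 if region_phd2 else 0.8,
        }
    return residues


def gen_nmr_titration(residue_map: dict[int, dict], kd: float,
                      protein_conc: float, ratio_grid: np.ndarray,
                      cfg: GeneratorConfig, i0: float = 1.0e6,
                      disappear_below: float = 0.01) -> pd.DataFrame:
    """Fast-exchange titration peak table across ligand:protein ratios.

    Observed shifts move with the bound fraction, delta_obs = delta_free +
    f_bound * delta_max per dimension; intensities follow
    I = I0 * ((1 - f) + f * gamma) with per-residue attenuation gamma.
    Rows whose intensity falls below ``disappear_below * I0`` are dropped
    (the peak has disappeared); prolines never appear.

    Returns a long-format table with columns residue, aa, h_ppm, n_ppm,
    intensity, point_id, molar_ratio.
    """
    ratio_grid = np.asarray(ratio_grid, dtype=float)
    if ratio_grid.size == 0:
        raise ValueError("ratio grid must be non-empty")
    rng = cfg.rng(0)
    rows = []
    for j, ratio in enumerate(ratio_grid):
        point_id = "ref" if ratio == 0 else f"p{j}"
        L = ratio * protein_conc
        f = float(quadratic_bound_signal(L, protein_conc, kd, 1.0))
        for res, info in sorted(residue_map.items()):
            if info["aa"].upper() == "P":
                continue
            h = info["h0"] + f * info["dH_max"]
            n = info["n0"] + f * info["dN_max"]
            inten = i0 * ((1.0 - f) + f * info["gamma"])
            if cfg.nmr_sigma_ppm > 0:
                h += rng.normal(0.0, cfg.nmr_sigma_ppm)
                n += rng.normal(0.0, 5.0 * cfg.nmr_sigma_ppm)
            if cfg.nmr_sigma_intensity > 0:
                inten *= 1.0 + rng.normal(0.0, cfg.nmr_sigma_intensity)
            if inten < disappear_below * i0:
                continue
            rows.append((res, info["aa"], h, n, inten, point_id, ratio))
    return pd.DataFrame(rows, columns=["residue", "aa", "h_ppm", "n_ppm",
                                       "intensity", "point_id", "molar_ratio"])
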