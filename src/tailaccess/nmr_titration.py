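"""Per-residue NMR titration profiling: CSPs, intensity fractions, calls.

Chemical shift perturbations combine the amide 1H and 15N shift changes as

    CSP = sqrt(dH^2 + (alpha * dN)^2),   alpha = 0.14 by default

(the community-standard nitrogen scaling).  Intensity fractions I/I0
capture exchange broadening; residues whose peaks vanish (e.g. all PHD2
backbone amides at a 1:4 protein:NCP ratio) contribute I/I0 = 0 to the
intensity metric but a *missing* CSP, never an infinite one.

Interface calling is threshold-based per region (PHD1 / linker / PHD2):
a residue is called perturbed when its metric exceeds the regional
mean + multiplier * SD, with region-specific multipliers.

Fast-exchange titrations are fit per residue with the ligand-depletion
bound fraction, yielding a per-residue Kd and a pooled (median) Kd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .binding_models import DomainError, quadratic_bound_signal

DEFAULT_ALPHA = 0.14

#: construct-numbering region boundaries for the tandem reader
DEFAULT_REGIONS = {"PHD1": (361, 417), "linker": (418, 442), "PHD2": (443, 503)}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PeakRecord:
    """One assigned amide crosspeak at one titration point."""

    residue_index: int
    amino_acid: str
    h_ppm: float | None
    n_ppm: float | None
    intensity: float | None
    point_id: str = "ref"
    molar_ratio: float = 0.0

    @property
    def missing(self) -> bool:
        return self.h_ppm is None or self.n_ppm is None

    def __post_init__(self) -> None:
        if self.amino_acid.upper() == "P" and not self.missing:
            raise ValueError(
                f"residue {self.residue_index}: prolines carry no amide peak"
            )
        for v in (self.h_ppm, self.n_ppm):
            if v is not None and not np.isfinite(v):
                raise ValueError("ppm values must be finite")


@dataclass
class PerturbationProfile:
    """Per-residue CSP and intensity-fraction profile for one titration point."""

    residue_index: np.ndarray
    csp: np.ndarray               # NaN where missing
    intensity_fraction: np.ndarray
    region: list[str]
    missing_reason: list[str]     # {'proline','disappeared','overlapped','none'}

    def __post_init__(self) -> None:
        n = len(self.residue_index)
        if not (len(self.csp) == len(self.intensity_fraction) ==
                len(self.region) == len(self.missing_reason) == n):
            raise ValueError("profile fields must have equal length")


# ---------------------------------------------------------------------------
# per-peak operations
# ---------------------------------------------------------------------------

def csp(ref: PeakRecord, titr: PeakRecord, alpha: float = DEFAULT_ALPHA) -> float:
    """Combined 1H/15N chemical shift perturbation between two points."""
    if ref.residue_index != titr.residue_index:
        raise ValueError("CSP requires matching residue indices")
    if ref.missing or titr.missing:
        raise ValueError("CSP undefined when either peak is missing")
    dh = titr.h_ppm - ref.h_ppm
    dn = titr.n_ppm - ref.n_ppm
    return float(np.hypot(dh, alpha * dn))


def intensity_fraction(ref: PeakRecord, titr: PeakRecord) -> float:
    """Intensity fraction I/I0; a disappeared peak gives 0."""
    if ref.residue_index != titr.residue_index:
        raise ValueError("intensity fraction requires matching residue indices")
    if ref.intensity is None or ref.intensity <= 0:
        raise DomainError("reference intensity must be positive")
    if titr.intensity is None:
        return 0.0
    return float(titr.intensity / ref.intensity)


def assign_region(residue_index: int,
                  regions: dict[str, tuple[int, int]] | None = None) -> str:
    regions = regions or DEFAULT_REGIONS
    for name, (lo, hi) in regions.items():
        if lo <= residue_index <= hi:
            return name
    return "other"


def build_profile(ref_peaks, titr_peaks, alpha: float = DEFAULT_ALPHA,
                  regions: dict[str, tuple[int, int]] | None = None
                  ) -> PerturbationProfile:
    """Assemble a per-residue profile from reference and titration peak lists.

    Peaks are matched by residue index (assignments assumed transferred).
    A residue present in the reference but absent from the titration point
    is treated as disappeared (I/I0 = 0, CSP missing).
    """
    ref_by_res = {p.residue_index: p for p in ref_peaks}
    titr_by_res = {p.residue_index: p for p in titr_peaks}
    idx = sorted(ref_by_res)

    csps, ifracs, regs, reasons = [], [], [], []
    for i in idx:
        r = ref_by_res[i]
        t = titr_by_res.get(i)
        regs.append(assign_region(i, regions))
        if r.amino_acid.upper() == "P" or r.missing:
            csps.append(np.nan)
            ifracs.append(np.nan)
            reasons.append("proline" if r.amino_acid.upper() == "P" else "overlapped")
            continue
        if t is None:
            csps.append(np.nan)
            ifracs.append(0.0)
            reasons.append("disappeared")
            continue
        ifracs.append(intensity_fraction(r, t))
        if t.missing:
            csps.append(np.nan)
            reasons.append("disappeared")
        else:
            csps.append(csp(r, t, alpha))
            reasons.append("none")

    return PerturbationProfile(
        residue_index=np.asarray(idx, dtype=int),
        csp=np.asarray(csps, dtype=float),
        intensity_fraction=np.asarray(ifracs, dtype=float),
        region=regs,
        missing_reason=reasons,
    )


# ---------------------------------------------------------------------------
# threshold-based interface calling
# ---------------------------------------------------------------------------

def perturbation_calls(profile: PerturbationProfile,
                       sd_multiplier_by_region: dict[str, float],
                       metric: str = "csp") -> set[int]:
    """Residues whose metric exceeds the regional mean + multiplier*SD.

    ``metric='csp'`` thresholds the CSP profile; ``metric='intensity_loss'``
    thresholds 1 - I/I0.  Statistics exclude missing residues and are
    computed per region over the same metric being thresholded.
    """
    if metric == "csp":
        values = profile.csp
    elif metric == "intensity_loss":
        values = 1.0 - profile.intensity_fraction
    else:
        raise ValueError(f"unknown metric {metric!r}")

    called: set[int] = set()
    for region, mult in sd_multiplier_by_region.items():
        mask = np.array([r == region for r in profile.region]) & np.isfinite(values)
        if mask.sum() == 0:
            raise ValueError(f"region {region!r} has no residues with defined values")
        if mask.sum() < 5:
            raise ValueError(f"region {region!r} has fewer than 5 defined residues")
        v = values[mask]
        threshold = float(np.mean(v)) + mult * float(np.std(v, ddof=0))
        over = mask & (values > threshold)
        called.update(int(i) for i in profile.residue_index[over])
    return called


# ---------------------------------------------------------------------------
# fast-exchange titration fitting
# ---------------------------------------------------------------------------

def _bound_fraction(L, P: float, kd: float):
    """Fraction of receptor bound at total ligand L (ligand depletion)."""
    return quadratic_bound_signal(L, P, kd, 1.0)


def fit_csp_titration(csp_by_residue: dict[int, np.ndarray],
                      ligand_conc: np.ndarray,
                      protein_conc: float,
                      csp_floor: float = 0.02) -> dict:
    """Per-residue fast-exchange Kd fits, pooled as the median.

    Parameters
    ----------
    csp_by_residue : mapping residue index -> CSP (ppm) at each titration point
    ligand_conc : total ligand concentration (uM) at each point
    protein_conc : receptor concentration (uM), assumed constant
    csp_floor : residues whose fitted CSP amplitude falls below this (ppm)
        are excluded from the pooled estimate

    Returns a dict with ``per_residue`` {residue: (kd, csp_max)},
    ``pooled_kd`` (median over included residues) and ``excluded`` list.
    """
    L = np.asarray(ligand_conc, dtype=float)
    if L.size < 4:
        raise ValueError("need at least 4 titration points for a Kd fit")
    if protein_conc <= 0:
        raise DomainError("protein concentration must be positive")

    per_residue: dict[int, tuple[float, float]] = {}
    excluded: list[int] = []
    for res, vals in csp_by_residue.items():
        y = np.asarray(vals, dtype=float)
        if y.shape != L.shape:
            raise ValueError(f"residue {res}: CSP series does not match titration points")
        if np.nanmax(y) <= 0:
            excluded.append(res)
            continue

        def resid(theta):
            return theta[1] * _bound_fraction(L, protein_conc, np.exp(theta[0])) - y

        kd0 = max(float(L[np.argmin(np.abs(y - 0.5 * np.max(y)))]), 1e-6)
        best = None
        for fac in (1.0, 0.1, 10.0):
            sol = least_squares(resid, x0=[np.log(kd0 * fac), float(np.max(y))],
                                method="lm", max_nfev=2000)
            if best is None or sol.cost < best.cost:
                best = sol
        kd = float(np.exp(best.x[0]))
        dmax = float(best.x[1])
        if dmax < csp_floor:
            excluded.append(res)
            continue
        per_residue[res] = (kd, dmax)

    pooled = float(np.median([kd for kd, _ in per_residue.values()])) \
        if per_residue else float("nan")
    return {"per_residue": per_residue, "pooled_kd": pooled, "excluded": excluded}
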