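"""Thermodynamic linkage between tail accessibility and reader affinity.

If a reader can engage the H3 tail only in its NCP-unbound state, and
bound/unbound interconversion (K_conf) is a fast pre-equilibrium, the
apparent dissociation constant measured against the nucleosome is

    Kd_app = Kd_peptide * (1 + K_conf) / K_conf

The factor (1+K)/K is the exact suppression of reader binding; its
small-K limit 1/K is the back-of-envelope version (K_conf ~ 0.1 at
near-physiological salt gives a ~10-fold reduction).  No ternary
reader-tail-DNA species is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

from .binding_models import DomainError


@dataclass
class SuppressionResult:
    """Suppression factors (and optional predicted apparent Kd) at one K_conf."""

    k_conf: float
    factor_exact: float           # (1+K)/K
    factor_approx: float          # 1/K
    kd_peptide: float | None = None
    kd_apparent_predicted: float | None = None


def suppression_factor(k_conf: float, approximate: bool = False) -> float:
    """Fold-reduction in reader affinity caused by intra-NCP tail binding.

    Exact mode returns (1+K)/K; approximate mode the small-K limit 1/K.
    The two differ by exactly 1.
    """
    if k_conf <= 0:
        raise DomainError("K_conf must be positive")
    if approximate:
        return 1.0 / k_conf
    return (1.0 + k_conf) / k_conf


def apparent_kd(kd_peptide: float, k_conf: float) -> float:
    """Predicted nucleosome-context Kd from the free-peptide Kd and K_conf."""
    if kd_peptide <= 0:
        raise DomainError("peptide Kd must be positive")
    return kd_peptide * suppression_factor(k_conf)


def observed_suppression(kd_ncp: float, kd_peptide: float) -> float:
    """Measured fold-weakening: Kd against NCP over Kd against free peptide."""
    if kd_ncp <= 0 or kd_peptide <= 0:
        raise DomainError("both Kd values must be positive")
    return kd_ncp / kd_peptide


def suppression_summary(k_conf: float,
                        kd_peptide: float | None = None) -> SuppressionResult:
    """Bundle exact and approximate factors, plus Kd_app when a peptide Kd is given."""
    exact = suppression_factor(k_conf)
    approx = suppression_factor(k_conf, approximate=True)
    kd_app = apparent_kd(kd_peptide, k_conf) if kd_peptide is not None else None
    return SuppressionResult(k_conf=k_conf, factor_exact=exact,
                             factor_approx=approx, kd_peptide=kd_peptide,
                             kd_apparent_predicted=kd_app)
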