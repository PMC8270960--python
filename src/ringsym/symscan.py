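"""Angular autocorrelation, rotational power spectrum, and symmetry calls.

The angular signal of an n-fold ring is periodic with fundamental harmonic
k = n; the order is read out as the argmax of the rotational power spectrum
within a user-declared candidate range.  Two spectrum routes are provided —
direct |DFT|^2 of the angular signal, and the DFT of the circular
autocorrelation — which agree by the Wiener–Khinchin relation and are kept
as mutual cross-checks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ringsym.polarize import PolarImage, RadialBand, angular_profile

logger = logging.getLogger(__name__)

_NEG_FLOOR = -1e-12  # ACF-route coefficients below this are genuine errors


@dataclass
class AngularACF:
    """Circular autocorrelation of a zero-mean angular signal.

    ``values[j]`` is the correlation at circular lag 2*pi*j/n_theta.  A real
    signal gives an even ACF: values[j] == values[n_theta - j].
    """

    values: np.ndarray
    normalization: str = "raw"  # raw | unit-at-zero


@dataclass
class RotationalSpectrum:
    """Power per integer angular harmonic k = 0 .. n_theta/2.

    ``power[k]`` is the squared modulus of the k-th Fourier coefficient of
    the angular signal (coefficient normalization 1/N), so the mean square
    of the signal equals ``total_power()`` — power summed with multiplicity
    two for the two-sided harmonics.
    """

    power: np.ndarray
    n_theta: int
    source: str = "per-radius-averaged"  # per-radius-averaged | collapsed-profile | acf

    def total_power(self) -> float:
        """Sum of power with two-sided multiplicity (Parseval's total)."""
        mult = np.full(len(self.power), 2.0)
        mult[0] = 1.0
        if self.n_theta % 2 == 0:
            mult[-1] = 1.0
        return float((mult * self.power).sum())


@dataclass
class SymmetryCall:
    """Assigned symmetry order with a confidence statistic.

    confidence = peak power / median power over the candidate range; status
    is 'assigned' when confidence clears the threshold and the peak is
    unrivalled, 'ambiguous' when a second candidate comes within 10% of the
    peak power (both are reported in ``candidates``), otherwise 'unassigned'
    with ``order`` None.
    """

    order: int | None
    peak_power: float
    confidence: float
    status: str
    candidate_range: tuple[int, int]
    candidates: list[tuple[int, float]] = field(default_factory=list)
    particle_id: str = ""


def angular_acf(profile: np.ndarray, normalization: str = "raw") -> AngularACF:
    """Circular autocorrelation acf[j] = (1/N) sum_t x[t] x[(t+j) mod N].

    The input must be a zero-mean signal of length >= 4.  With
    ``normalization='unit-at-zero'`` the ACF is divided by acf[0]; a
    zero-variance signal then raises.
    """
    x = np.asarray(profile, dtype=np.float64)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("profile must be 1D with length >= 4")
    if not np.all(np.isfinite(x)):
        raise ValueError("profile contains non-finite values")
    scale = max(1.0, float(np.sqrt(np.mean(x**2))))
    if abs(x.mean()) > 1e-9 * scale:
        raise ValueError(f"profile is not zero-mean (mean={x.mean():g})")
    n = len(x)
    f = np.fft.rfft(x)
    acf = np.fft.irfft(np.abs(f) ** 2, n=n) / n
    if normalization == "unit-at-zero":
        if acf[0] <= 0:
            raise ValueError("zero-variance signal: cannot normalize unit-at-zero")
        acf = acf / acf[0]
    elif normalization != "raw":
        raise ValueError(f"unknown normalization {normalization!r}")
    return AngularACF(values=acf, normalization=normalization)


def _profile_spectrum(x: np.ndarray, source: str) -> RotationalSpectrum:
    n = len(x)
    coeff = np.fft.rfft(x) / n
    return RotationalSpectrum(power=np.abs(coeff) ** 2, n_theta=n, source=source)


def rotational_power_spectrum(
    obj: np.ndarray | AngularACF | PolarImage,
    radial_weights: np.ndarray | None = None,
    source: str = "per-radius-averaged",
) -> RotationalSpectrum:
    """Rotational power spectrum from a profile, an ACF, or a PolarImage.

    - 1D array: power[k] = |k-th DFT coefficient|^2 (1/N normalization).
    - AngularACF (raw): power[k] = k-th Fourier coefficient of the ACF / N,
      equal to the direct route by Wiener–Khinchin; tiny negative values
      from numerical noise are clipped to zero.
    - PolarImage: each radius row is mean-subtracted independently;
      ``source='per-radius-averaged'`` (default) averages per-row power
      spectra with the radial weights (incoherent, robust to radial phase
      shifts between shells); ``source='collapsed-profile'`` collapses to a
      single profile first (coherent).
    """
    if isinstance(obj, AngularACF):
        if obj.normalization != "raw":
            raise ValueError("spectrum from ACF requires raw normalization")
        acf = np.asarray(obj.values, dtype=np.float64)
        if not np.all(np.isfinite(acf)):
            raise ValueError("ACF contains non-finite values")
        n = len(acf)
        coeff = np.fft.rfft(acf).real / n
        if coeff.min() < _NEG_FLOOR * max(1.0, float(np.abs(coeff).max())) - 1e-300:
            logger.debug("clipping negative ACF-route power %g", coeff.min())
        return RotationalSpectrum(power=np.clip(coeff, 0.0, None), n_theta=n, source="acf")
    if isinstance(obj, PolarImage):
        rows = obj.values - obj.values.mean(axis=1, keepdims=True)
        if not np.all(np.isfinite(rows)):
            raise ValueError("polar image contains non-finite values")
        if source == "collapsed-profile":
            prof = rows.mean(axis=0) if radial_weights is None else angular_profile(obj, radial_weights)
            prof = prof - prof.mean()
            return _profile_spectrum(prof, "collapsed-profile")
        if source != "per-radius-averaged":
            raise ValueError(f"unknown spectrum source {source!r}")
        n = obj.n_theta
        pw = np.abs(np.fft.rfft(rows, axis=1) / n) ** 2
        if radial_weights is None:
            power = pw.mean(axis=0)
        else:
            w = np.asarray(radial_weights, dtype=np.float64)
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError("radial weights must be nonnegative and not all zero")
            power = (w[:, None] * pw).sum(axis=0) / w.sum()
        return RotationalSpectrum(power=power, n_theta=n, source="per-radius-averaged")
    x = np.asarray(obj, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("profile contains non-finite values")
    return _profile_spectrum(x - x.mean(), "collapsed-profile")


def call_symmetry(
    spectrum: RotationalSpectrum,
    candidate_range: tuple[int, int],
    confidence_threshold: float = 3.0,
    method: str = "argmax",
) -> SymmetryCall:
    """Assign the symmetry order from a spectrum over a candidate range.

    The order is the argmax of power over [k_lo, k_hi] (exact ties resolve
    to the lower order — the more conservative stoichiometry — and the call
    is marked ambiguous).  ``method='harmonic-sum'`` instead scores each
    candidate by summed power over its harmonics within the spectrum.
    """
    k_lo, k_hi = int(candidate_range[0]), int(candidate_range[1])
    if k_hi < k_lo:
        raise ValueError("empty candidate range")
    if k_lo < 2:
        raise ValueError("k_lo must be >= 2")
    if k_hi > spectrum.n_theta / 4:
        raise ValueError(
            f"k_hi={k_hi} exceeds the anti-aliasing limit n_theta/4={spectrum.n_theta / 4}"
        )
    ks = np.arange(k_lo, k_hi + 1)
    power = spectrum.power[k_lo : k_hi + 1]
    if method == "harmonic-sum":
        kmax_avail = len(spectrum.power) - 1
        score = np.array(
            [spectrum.power[np.arange(k, kmax_avail + 1, k)].sum() for k in ks]
        )
    elif method == "argmax":
        score = power
    else:
        raise ValueError(f"unknown method {method!r}")
    i_best = int(np.argmax(score))  # argmax takes the first (lowest) on ties
    order = int(ks[i_best])
    peak = float(power[i_best])
    med = float(np.median(power))
    if med > 0:
        confidence = peak / med
    else:
        confidence = np.inf if peak > 0 else 1.0
    within = [(int(k), float(p)) for k, p in zip(ks, power) if p >= 0.9 * peak and peak > 0]
    rivals = [c for c in within if c[0] != order]
    if peak <= 0 or confidence < confidence_threshold:
        return SymmetryCall(
            order=None, peak_power=peak, confidence=float(confidence),
            status="unassigned", candidate_range=(k_lo, k_hi),
        )
    if rivals:
        return SymmetryCall(
            order=order, peak_power=peak, confidence=float(confidence),
            status="ambiguous", candidate_range=(k_lo, k_hi), candidates=within,
        )
    return SymmetryCall(
        order=order, peak_power=peak, confidence=float(confidence),
        status="assigned", candidate_range=(k_lo, k_hi), candidates=within,
    )


def radial_symmetry_scan(
    polar: PolarImage,
    annuli: list[RadialBand],
    candidate_range: tuple[int, int],
    confidence_threshold: float = 3.0,
) -> list[tuple[RadialBand, RotationalSpectrum, SymmetryCall]]:
    """Per-annulus spectra and symmetry calls, localizing subsymmetries by radius.

    Each annulus uses only its own polar rows.  Overlapping annuli are
    allowed but draw a warning; an annulus containing no radius rows raises.
    """
    if not annuli:
        raise ValueError("no annuli given")
    for i, a in enumerate(annuli):
        for b in annuli[i + 1 :]:
            if a.r_min_px < b.r_max_px and b.r_min_px < a.r_max_px:
                warnings.warn(f"annuli overlap: {a} and {b}", stacklevel=2)
    out = []
    for a in annuli:
        sel = (polar.r_grid >= a.r_min_px) & (polar.r_grid <= a.r_max_px)
        if not np.any(sel):
            raise ValueError(f"annulus {a} contains zero radius rows")
        sub = PolarImage(
            values=polar.values[sel],
            r_grid=polar.r_grid[sel],
            theta_grid=polar.theta_grid,
            center_used_xy_px=polar.center_used_xy_px,
        )
        spec = rotational_power_spectrum(sub)
        call = call_symmetry(spec, candidate_range, confidence_threshold)
        out.append((a, spec, call))
    return out
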