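"""Population-level symmetry analysis: per-particle classification, symmetry
distributions, distribution comparison, and symmetry-sorted class averages."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ringsym.config import AnalysisConfig
from ringsym.polarize import RingImage, estimate_center, to_polar, angular_profile
from ringsym.symscan import SymmetryCall, call_symmetry, rotational_power_spectrum

logger = logging.getLogger(__name__)


@dataclass
class SymmetryDistribution:
    """Counts and percentages of assigned symmetry orders over a population.

    Percentages are computed over assigned calls only; unassigned and
    ambiguous particles are excluded but remain visible through
    ``total_input`` vs ``total_assigned``.  Orders with zero count are kept
    when inside the candidate range.
    """

    counts: dict[int, int]
    total_assigned: int
    total_input: int
    percentages: dict[int, float]


def classify_particle(img: RingImage, config: AnalysisConfig) -> SymmetryCall:
    """Full single-particle pipeline: center -> polar -> spectrum -> call."""
    center = estimate_center(img, refine=config.refine_center)
    polar = to_polar(
        img, center, config.band, n_r=config.n_r, n_theta=config.n_theta,
        k_max=config.candidate_range[1],
    )
    if config.spectrum_source == "collapsed":
        spec = rotational_power_spectrum(polar, source="collapsed-profile")
    else:
        spec = rotational_power_spectrum(polar, source="per-radius-averaged")
    call = call_symmetry(spec, config.candidate_range, config.confidence_threshold)
    call.particle_id = img.id
    return call


def classify_stack(images: list[RingImage], config: AnalysisConfig) -> list[SymmetryCall]:
    """Classify every particle in a stack independently; results match stack order."""
    if not images:
        raise ValueError("empty stack")
    shape0 = images[0].pixels.shape
    for im in images:
        if im.pixels.shape != shape0:
            raise ValueError(
                f"mixed image shapes in stack: {shape0} vs {im.pixels.shape}"
            )
    calls = []
    for i, im in enumerate(images):
        if not im.id:
            im.id = f"p{i:05d}"
        call = classify_particle(im, config)
        logger.debug(
            "particle %s: order=%s status=%s confidence=%.2f",
            im.id, call.order, call.status, call.confidence,
        )
        calls.append(call)
    n_un = sum(1 for c in calls if c.status == "unassigned")
    n_amb = sum(1 for c in calls if c.status == "ambiguous")
    logger.info(
        "classified %d particles: %d assigned, %d ambiguous, %d unassigned",
        len(calls), len(calls) - n_un - n_amb, n_amb, n_un,
    )
    return calls


def symmetry_distribution(
    calls: list[SymmetryCall], candidate_range: tuple[int, int] | None = None
) -> SymmetryDistribution:
    """Tabulate assigned orders into counts and one-decimal percentages."""
    if not calls:
        raise ValueError("no calls given")
    assigned = [c for c in calls if c.status == "assigned"]
    if not assigned:
        raise ValueError("nothing to tabulate: no assigned calls")
    if candidate_range is None:
        candidate_range = assigned[0].candidate_range
    k_lo, k_hi = candidate_range
    counts = {k: 0 for k in range(int(k_lo), int(k_hi) + 1)}
    for c in assigned:
        counts[c.order] = counts.get(c.order, 0) + 1
    total = len(assigned)
    percentages = {k: round(100.0 * v / total, 1) for k, v in counts.items()}
    return SymmetryDistribution(
        counts=counts,
        total_assigned=total,
        total_input=len(calls),
        percentages=percentages,
    )


def compare_distributions(a: SymmetryDistribution, b: SymmetryDistribution) -> dict:
    """Per-order deltas and a Pearson chi-square statistic on pooled counts.

    Orders whose expected count falls below 1 are pooled into the adjacent
    order before the statistic is computed.  Only the statistic and its
    degrees of freedom are reported; no significance verdict is attached.
    """
    if a.total_assigned == 0 or b.total_assigned == 0:
        raise ValueError("empty distribution")
    orders_a, orders_b = set(a.counts), set(b.counts)
    if not (orders_a & orders_b):
        raise ValueError("disjoint candidate ranges: distributions share no orders")
    orders = sorted(orders_a | orders_b)
    ca = np.array([a.counts.get(k, 0) for k in orders], dtype=float)
    cb = np.array([b.counts.get(k, 0) for k in orders], dtype=float)
    deltas = {
        k: {
            "count_delta": int(a.counts.get(k, 0) - b.counts.get(k, 0)),
            "pct_delta": round(a.percentages.get(k, 0.0) - b.percentages.get(k, 0.0), 1),
        }
        for k in orders
    }
    # pool adjacent orders until every expected cell count is >= 1
    groups = [[k] for k in orders]
    while len(groups) > 1:
        na, nb = ca.sum(), cb.sum()
        col = ca + cb
        exp_a = col * na / (na + nb)
        exp_b = col * nb / (na + nb)
        min_exp = np.minimum(exp_a, exp_b)
        i = int(np.argmin(min_exp))
        if min_exp[i] >= 1.0:
            break
        j = i + 1 if i + 1 < len(groups) else i - 1
        lo, hi = min(i, j), max(i, j)
        groups[lo] = groups[lo] + groups[hi]
        ca[lo] += ca[hi]
        cb[lo] += cb[hi]
        groups.pop(hi)
        ca = np.delete(ca, hi)
        cb = np.delete(cb, hi)
    na, nb = ca.sum(), cb.sum()
    col = ca + cb
    exp_a = col * na / (na + nb)
    exp_b = col * nb / (na + nb)
    ok = col > 0
    chi2 = float(
        (((ca - exp_a) ** 2 / np.where(ok, exp_a, 1))[ok]).sum()
        + (((cb - exp_b) ** 2 / np.where(ok, exp_b, 1))[ok]).sum()
    )
    df = int(ok.sum()) - 1
    return {
        "per_order": deltas,
        "chi_square": chi2,
        "df": df,
        "pooled_groups": [g for g, keep in zip(groups, ok) if keep],
    }


def rotate_image(pixels: np.ndarray, angle_rad: float, center: tuple[float, float],
                 order: int = 3) -> np.ndarray:
    """Rotate image content counterclockwise (math convention, +x toward +y)
    by ``angle_rad`` about an arbitrary sub-pixel center.

    Cubic-spline resampling by default: averaging demands lower interpolation
    blur than the polar readout, where bilinear suffices.
    """
    size = pixels.shape[0]
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dx, dy = xx - center[0], yy - center[1]
    ca, sa = np.cos(-angle_rad), np.sin(-angle_rad)
    xs = center[0] + ca * dx - sa * dy
    ys = center[1] + sa * dx + ca * dy
    return ndimage.map_coordinates(pixels, [ys, xs], order=order, mode="constant", cval=0.0)


def align_and_average(
    images: list[RingImage],
    calls: list[SymmetryCall],
    target_order: int,
    config: AnalysisConfig,
) -> RingImage:
    """Rotationally align all assigned members of one order and average them.

    The first assigned member is the reference.  Each other member's angular
    profile is circularly cross-correlated against the reference's; the best
    lag (parabolically refined to sub-bin precision) is reduced modulo the
    symmetry period 2*pi/order, and the member is rotated back by that angle
    about its own center before pixel-wise averaging.
    """
    if len(images) != len(calls):
        raise ValueError("images and calls must align 1:1")
    members = [
        im for im, c in zip(images, calls)
        if c.status == "assigned" and c.order == target_order
    ]
    if not members:
        raise ValueError(f"no assigned members of order {target_order}")
    shape0 = members[0].pixels.shape
    for im in members:
        if im.pixels.shape != shape0:
            raise ValueError("mixed image shapes among members")
    if len(members) == 1:
        m = members[0]
        return RingImage(pixels=m.pixels.copy(), pixel_size_A=m.pixel_size_A,
                         id=f"avg_order{target_order}")

    def _profile(im: RingImage) -> tuple[np.ndarray, tuple[float, float]]:
        center = estimate_center(im, refine=config.refine_center)
        polar = to_polar(im, center, config.band, n_r=config.n_r,
                         n_theta=config.n_theta, k_max=config.candidate_range[1])
        return angular_profile(polar), center

    ref_prof, ref_center = _profile(members[0])
    n_theta = len(ref_prof)
    period = 2.0 * np.pi / target_order
    acc = members[0].pixels.astype(np.float64).copy()
    fr = np.fft.rfft(ref_prof)
    for im in members[1:]:
        prof, center = _profile(im)
        # c[s] = sum_t ref[t] * prof[t + s]; peak at the member's extra rotation
        xc = np.fft.irfft(np.conj(fr) * np.fft.rfft(prof), n=n_theta)
        s = int(np.argmax(xc))
        a, b, c = xc[(s - 1) % n_theta], xc[s], xc[(s + 1) % n_theta]
        denom = a - 2 * b + c
        frac = 0.5 * (a - c) / denom if abs(denom) > 1e-300 else 0.0
        lag = s + float(np.clip(frac, -0.5, 0.5))
        delta = (2.0 * np.pi * lag / n_theta) % period  # rotation in the symmetry-reduced range
        acc += rotate_image(im.pixels, -delta, center)
    return RingImage(
        pixels=acc / len(members),
        pixel_size_A=members[0].pixel_size_A,
        id=f"avg_order{target_order}",
    )
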