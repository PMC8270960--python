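"""Synthetic ring phantoms with known ground truth.

A phantom is a sum of coaxial shells; each shell is a train of n identical
Gaussian subunit blobs equally spaced around a circle, which is the angular
structure the symmetry pipeline is designed to read out.  Populations add
per-particle center jitter, random in-plane rotation and white Gaussian
noise at a controlled SNR, emulating classified end-on-view particle sets.

SNR here is defined as (peak subunit blob amplitude) / (per-pixel noise
standard deviation); the generator and all tests use this definition
consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ringsym.polarize import RingImage

_WINDOW_SIGMAS = 5.0  # blob evaluation window half-width, in blob sigmas


@dataclass(frozen=True)
class ShellSpec:
    """One shell: n-fold train of Gaussian blobs on a circle of given radius."""

    radius_px: float
    order_n: int
    blob_sigma_px: float = 2.0
    amplitude: float = 1.0
    phase_offset_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.order_n < 1:
            raise ValueError("order_n must be >= 1")
        if self.radius_px <= 2.0 * self.blob_sigma_px:
            raise ValueError("radius_px must exceed 2 * blob_sigma_px")
        if self.blob_sigma_px <= 0:
            raise ValueError("blob_sigma_px must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Complete recipe for one phantom image; same spec + seed is bit-identical."""

    image_size_px: int
    pixel_size_A: float = 1.0
    shells: tuple[ShellSpec, ...] = ()
    center_xy_px: tuple[float, float] | None = None
    rotation_rad: float = 0.0
    noise_sigma: float = 0.0
    lowpass_sigma_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shells", tuple(self.shells))
        if self.image_size_px < 32:
            raise ValueError("image_size_px must be >= 32")
        if self.pixel_size_A <= 0:
            raise ValueError("pixel_size_A must be positive")
        if self.noise_sigma < 0 or self.lowpass_sigma_px < 0:
            raise ValueError("noise_sigma and lowpass_sigma_px must be >= 0")
        if self.center_xy_px is None:
            c = self.image_size_px / 2.0
            object.__setattr__(self, "center_xy_px", (c, c))

    def to_dict(self) -> dict:
        d = {
            "image_size_px": self.image_size_px,
            "pixel_size_A": self.pixel_size_A,
            "shells": [vars(s) | {} for s in self.shells],
            "center_xy_px": list(self.center_xy_px),
            "rotation_rad": self.rotation_rad,
            "noise_sigma": self.noise_sigma,
            "lowpass_sigma_px": self.lowpass_sigma_px,
            "seed": self.seed,
        }
        d["shells"] = [
            {
                "radius_px": s.radius_px,
                "order_n": s.order_n,
                "blob_sigma_px": s.blob_sigma_px,
                "amplitude": s.amplitude,
                "phase_offset_rad": s.phase_offset_rad,
            }
            for s in self.shells
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        shells = tuple(ShellSpec(**s) for s in d.get("shells", []))
        return cls(
            image_size_px=d["image_size_px"],
            pixel_size_A=d.get("pixel_size_A", 1.0),
            shells=shells,
            center_xy_px=tuple(d["center_xy_px"]) if d.get("center_xy_px") else None,
            rotation_rad=d.get("rotation_rad", 0.0),
            noise_sigma=d.get("noise_sigma", 0.0),
            lowpass_sigma_px=d.get("lowpass_sigma_px", 0.0),
            seed=d.get("seed", 0),
        )


@dataclass(frozen=True)
class GroundTruthRecord:
    """Per-particle truth for a generated population, aligned 1:1 with the stack."""

    particle_id: str
    true_order: int
    rotation_rad: float
    center_xy_px: tuple[float, float]
    snr: float
    seed: int


def _render_clean(spec: PhantomSpec) -> np.ndarray:
    size = spec.image_size_px
    cx, cy = spec.center_xy_px
    img = np.zeros((size, size), dtype=np.float64)
    for i, sh in enumerate(spec.shells):
        if sh.radius_px + 3.0 * sh.blob_sigma_px >= size / 2.0:
            raise ValueError(
                f"shell {i} (order {sh.order_n}, radius {sh.radius_px} px) extends "
                f"outside the frame: radius + 3*sigma must stay below {size / 2.0} px"
            )
        if sh.amplitude == 0:
            continue
        half = _WINDOW_SIGMAS * sh.blob_sigma_px
        two_s2 = 2.0 * sh.blob_sigma_px**2
        phis = (
            sh.phase_offset_rad
            + spec.rotation_rad
            + 2.0 * np.pi * np.arange(sh.order_n) / sh.order_n
        )
        for phi in phis:
            bx = cx + sh.radius_px * np.cos(phi)
            by = cy + sh.radius_px * np.sin(phi)
            x0 = max(int(np.floor(bx - half)), 0)
            x1 = min(int(np.ceil(bx + half)) + 1, size)
            y0 = max(int(np.floor(by - half)), 0)
            y1 = min(int(np.ceil(by + half)) + 1, size)
            if x0 >= x1 or y0 >= y1:
                continue
            xs = np.arange(x0, x1, dtype=np.float64) - bx
            ys = np.arange(y0, y1, dtype=np.float64) - by
            img[y0:y1, x0:x1] += sh.amplitude * np.exp(
                -(xs[None, :] ** 2 + ys[:, None] ** 2) / two_s2
            )
    return img


def make_phantom(spec: PhantomSpec, id: str = "") -> RingImage:
    """Render one phantom: shells + per-pixel Gaussian noise + optional low-pass.

    Deterministic given (spec, seed): the noise stream is drawn from a fresh
    generator seeded with ``spec.seed``.
    """
    img = _render_clean(spec)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    if spec.lowpass_sigma_px > 0:
        img = ndimage.gaussian_filter(img, spec.lowpass_sigma_px)
    return RingImage(pixels=img, pixel_size_A=spec.pixel_size_A, id=id)


# --- fixture registry -------------------------------------------------------
#
# "sring34": one 34-blob shell at r=120 px (1 A/px -> 24 nm diameter, the
# S-ring scale).  "msring_shells": three coaxial shells emulating the inner
# M ring (23-fold), middle M ring (11-fold) and S ring (34-fold) at radii
# ratios 0.4 : 0.6 : 1.0 of the S-ring radius.  The ratios are emulation
# choices fixed here, not measurements.

FIXTURES: dict[str, PhantomSpec] = {
    "sring34": PhantomSpec(
        image_size_px=512,
        pixel_size_A=1.0,
        shells=(ShellSpec(radius_px=120.0, order_n=34, blob_sigma_px=2.0, amplitude=1.0),),
        seed=1,
    ),
    "msring_shells": PhantomSpec(
        image_size_px=512,
        pixel_size_A=1.0,
        shells=(
            ShellSpec(radius_px=48.0, order_n=23, blob_sigma_px=2.0, amplitude=1.0),
            ShellSpec(radius_px=72.0, order_n=11, blob_sigma_px=2.0, amplitude=1.0),
            ShellSpec(radius_px=120.0, order_n=34, blob_sigma_px=2.0, amplitude=1.0),
        ),
        seed=1,
    ),
}


def make_multishell_fixture(name: str) -> tuple[RingImage, PhantomSpec]:
    """Render a registered fixture and return it with the exact spec used."""
    if name not in FIXTURES:
        raise ValueError(
            f"unknown fixture {name!r}; registered fixtures: {sorted(FIXTURES)}"
        )
    spec = FIXTURES[name]
    return make_phantom(spec, id=name), spec


def draw_orders(
    proportions: dict[int, float], m: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw m symmetry orders i.i.d. from the given proportions."""
    if not proportions:
        raise ValueError("empty proportions")
    orders = np.array(sorted(proportions), dtype=int)
    p = np.array([proportions[k] for k in orders], dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("negative fraction in proportions")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1 (got {p.sum()!r})")
    return rng.choice(orders, size=m, p=p / p.sum())


def make_population(
    proportions: dict[int, float],
    m: int,
    snr: float,
    jitter: tuple[float, str] = (1.0, "uniform"),
    seed: int = 0,
    image_size_px: int = 128,
    radius_px: float = 44.0,
    blob_sigma_px: float = 1.5,
    amplitude: float = 1.0,
    pixel_size_A: float = 1.0,
) -> tuple[list[RingImage], list[GroundTruthRecord]]:
    """Generate a mixed-order particle population with a 1:1 truth table.

    Each particle's true order is drawn from ``proportions``; its center is
    jittered by a Gaussian of the given sigma around the image center, its
    in-plane rotation is uniform on [0, 2*pi), and white noise of sigma
    ``amplitude / snr`` is added (``snr = inf`` or 0 means noiseless).

    One generator seeded with ``seed`` drives everything, consumed in a fixed
    order — all labels first, then per particle (center jitter, rotation,
    noise) — so truth tables are reproducible.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if snr < 0:
        raise ValueError("snr must be >= 0")
    center_sigma, rot_mode = jitter
    if rot_mode != "uniform":
        raise ValueError("only uniform rotation jitter is supported")
    rng = np.random.default_rng(seed)
    labels = draw_orders(proportions, m, rng)
    noise_sigma = amplitude / snr if snr not in (0, np.inf) and np.isfinite(snr) and snr > 0 else 0.0
    c0 = image_size_px / 2.0
    images: list[RingImage] = []
    records: list[GroundTruthRecord] = []
    for i in range(m):
        dxy = rng.normal(0.0, center_sigma, 2) if center_sigma > 0 else np.zeros(2)
        rot = float(rng.uniform(0.0, 2.0 * np.pi))
        center = (c0 + float(dxy[0]), c0 + float(dxy[1]))
        spec = PhantomSpec(
            image_size_px=image_size_px,
            pixel_size_A=pixel_size_A,
            shells=(
                ShellSpec(
                    radius_px=radius_px,
                    order_n=int(labels[i]),
                    blob_sigma_px=blob_sigma_px,
                    amplitude=amplitude,
                ),
            ),
            center_xy_px=center,
            rotation_rad=rot,
            noise_sigma=0.0,
            seed=seed,
        )
        img = _render_clean(spec)
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, img.shape)
        pid = f"p{i:05d}"
        images.append(RingImage(pixels=img, pixel_size_A=pixel_size_A, id=pid))
        records.append(
            GroundTruthRecord(
                particle_id=pid,
                true_order=int(labels[i]),
                rotation_rad=rot,
                center_xy_px=center,
                snr=float(snr),
                seed=seed,
            )
        )
    return images, records
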