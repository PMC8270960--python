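"""Analysis configuration: the knobs shared by every pipeline stage."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from ringsym.polarize import RadialBand


@dataclass
class AnalysisConfig:
    """Validated parameters for the per-particle symmetry pipeline.

    band          radial band (px) selecting the shell to analyze
    n_theta       angular samples; must be >= 4 * k_hi (anti-aliasing margin)
    n_r           radial samples across the band
    candidate_range  inclusive [k_lo, k_hi] of candidate symmetry orders
    confidence_threshold  minimum peak/median power ratio to assign
    spectrum_source  'per-radius' (incoherent average, default) | 'collapsed'
    refine_center    sub-pixel center refinement on/off
    seed          seed recorded into run metadata
    """

    band: RadialBand
    n_theta: int = 720
    n_r: int = 32
    candidate_range: tuple[int, int] = (2, 40)
    confidence_threshold: float = 3.0
    spectrum_source: str = "per-radius"
    refine_center: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.band, (tuple, list)):
            self.band = RadialBand(*self.band)
        k_lo, k_hi = self.candidate_range
        self.candidate_range = (int(k_lo), int(k_hi))
        if k_lo < 2 or k_hi < k_lo:
            raise ValueError(f"invalid candidate_range {self.candidate_range}")
        if self.n_theta < 4 * k_hi:
            raise ValueError(
                f"n_theta={self.n_theta} below anti-aliasing minimum 4*k_hi={4 * k_hi}"
            )
        if self.n_r < 1:
            raise ValueError("n_r must be >= 1")
        if self.confidence_threshold <= 0:
            raise ValueError("confidence_threshold must be positive")
        if self.spectrum_source not in ("per-radius", "collapsed"):
            raise ValueError(f"unknown spectrum_source {self.spectrum_source!r}")

    def to_dict(self) -> dict:
        return {
            "band": [self.band.r_min_px, self.band.r_max_px],
            "n_theta": self.n_theta,
            "n_r": self.n_r,
            "candidate_range": list(self.candidate_range),
            "confidence_threshold": self.confidence_threshold,
            "spectrum_source": self.spectrum_source,
            "refine_center": self.refine_center,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(
            band=RadialBand(*d["band"]),
            n_theta=d.get("n_theta", 720),
            n_r=d.get("n_r", 32),
            candidate_range=tuple(d.get("candidate_range", (2, 40))),
            confidence_threshold=d.get("confidence_threshold", 3.0),
            spectrum_source=d.get("spectrum_source", "per-radius"),
            refine_center=d.get("refine_center", True),
            seed=d.get("seed", 0),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
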