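"""Run configuration with the study's defaults.

The defaults encode the published operating conditions: scans at 0.23 µm/pixel,
detector operating point 0.64, a 2 mm² hotspot with a 4:3 window, 4 mm² square
patches overlapping by 0.5 mm for the convex-hull selector, and an exact-solver
cutoff of 25 points per patch.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .geometry import ResolutionSpec


@dataclass
class RunConfig:
    #: scan resolution, micrometres per pixel
    mpp: float = 0.23
    #: detector probability operating point; candidates with probability >= this
    #: are treated as mitotic figures
    prob_threshold: float = 0.64
    #: optional lower threshold for "negative"-labelled review objects
    secondary_threshold: float | None = None
    #: area of the hotspot region, mm²
    hotspot_area_mm2: float = 2.0
    #: width-over-height aspect ratio of the search window
    window_aspect_w_over_h: float = 4.0 / 3.0
    #: stride of the window grid as a fraction of the window dimension
    #: (0.25 means the grid advances a quarter window per step, i.e. 75% overlap)
    window_overlap_fraction: float = 0.25
    #: if True, read the overlap fraction literally as the *overlap*, so the
    #: stride is (1 - fraction) of the dimension
    window_literal_overlap: bool = False
    #: area of the square patches the slide is subdivided into, mm²
    patch_area_mm2: float = 4.0
    #: overlap between neighbouring patches, mm
    patch_overlap_mm: float = 0.5
    #: patches with at most this many points are solved exactly
    exact_solver_max_points: int = 25
    #: seed for the (deterministic) heuristic solver
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        if not 0.0 <= self.prob_threshold <= 1.0:
            raise ValueError("prob_threshold must be in [0, 1]")
        if self.secondary_threshold is not None and not (
            0.0 <= self.secondary_threshold <= 1.0
        ):
            raise ValueError("secondary_threshold must be in [0, 1]")
        if self.hotspot_area_mm2 <= 0 or self.patch_area_mm2 <= 0:
            raise ValueError("areas must be positive")
        if self.window_aspect_w_over_h <= 0:
            raise ValueError("aspect ratio must be positive")
        if not 0.0 < self.window_overlap_fraction < 1.0:
            raise ValueError("window_overlap_fraction must be in (0, 1)")
        if self.patch_overlap_mm < 0:
            raise ValueError("patch_overlap_mm must be non-negative")
        if self.exact_solver_max_points < 3:
            raise ValueError("exact_solver_max_points must be at least 3")

    @property
    def resolution(self) -> ResolutionSpec:
        return ResolutionSpec(self.mpp)

    def to_dict(self) -> dict:
        return asdict(self)
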