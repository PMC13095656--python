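"""Run configuration shared by the pipeline stages and the CLI.

Every default is either a published acquisition/processing value (pixel
size 2.116 Å/px, +/-60 degree tilt fan in 2 degree steps, 37-48 Å peak
window around the ~40 Å protomer repeat, the 7 degree out-of-plane rule)
or a documented convention of this package (box 256 px with step = box
for literal non-overlap, 4x spectral oversampling, SNR 0.5 for the
synthetic experiment).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    pixel_size: float = 2.116  # Å/px of the analysis volumes
    box_px: int = 256          # extraction box (axial length of each segment)
    step_px: int | None = None  # center step along the filament; None = box_px
    pad_factor: int = 4        # spectral oversampling for peak localization
    window_A: tuple[float, float] = (37.0, 48.0)  # layer-line search window
    background_factor: float = 1.5
    peak_sides: str = "both"
    mask_half_width_px: float | None = None  # None = lattice radius + 3 sigma
    tilt_threshold_deg: float = 7.0
    score_threshold: float = 0.1
    # synthetic experiment
    tilt_min: float = -60.0
    tilt_max: float = 60.0
    tilt_increment: float = 2.0
    snr: float = 0.5
    blob_sigma_A: float = 6.0
    n_microtubules: int = 10       # per condition
    filaments_per_field: int = 2
    field_shape: tuple[int, int, int] = (128, 384, 896)  # (nz, ny, nx) px
    filament_spacing_px: float = 120.0  # lateral center-to-center in a field
    condition_spacings: dict = field(
        default_factory=lambda: {"gdp_like": 41.6, "gmpcpp_like": 43.1}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_px is None:
            self.step_px = self.box_px
        for name in ("pixel_size", "box_px", "step_px", "pad_factor", "snr", "blob_sigma_A"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.box_px % 2:
            raise ValueError("box_px must be even")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["window_A"] = list(d["window_A"])
        d["field_shape"] = list(d["field_shape"])
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        d["window_A"] = tuple(d["window_A"])
        d["field_shape"] = tuple(d["field_shape"])
        return cls(**d)
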