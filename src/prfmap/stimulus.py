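"""Bar-sweep stimulus protocols and binary effective-stimulus movies.

A retinotopic mapping run shows a contrast-reversing bar that traverses a
circular aperture in several motion directions, interleaved with uniform-gray
blank epochs.  For pRF model fitting only the *position* of the bar matters,
so the movie is rendered as a binary "effective stimulus": a T x H x W mask
sequence in visual-degree coordinates, 1 where the bar is visible through the
aperture and 0 elsewhere.

Two presets are provided:

``fmri``
    16 dva aperture, 2 dva bar, 20 steps of 2.5 s (one TR) per sweep, eight
    directions in the order 270, 315, 180, 225, 90, 135, 0, 45 degrees,
    37.5 s pre/post blanks and a 25 s blank after every horizontal or
    vertical sweep, rendered at 10 px/dva.

``ephys``
    28 dva aperture, 2 dva bar, 30 steps of 0.5 s, same direction order,
    2.5 s blanks.

Coordinates: x positive rightward, y positive upward, fixation at (0, 0).
Pixel centers sit at half-integer offsets so the grid is symmetric about
fixation and opposite sweep directions are exact frame-reversals of each
other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "StimulusProtocol",
    "EffectiveStimulus",
    "make_protocol",
    "render_effective_stimulus",
]

#: direction order used in the experiments (degrees; direction of bar motion)
DEFAULT_DIRECTION_ORDER = (270.0, 315.0, 180.0, 225.0, 90.0, 135.0, 0.0, 45.0)

#: cardinal directions after which the fMRI runs insert an extra blank
CARDINAL_DIRECTIONS = frozenset({0.0, 90.0, 180.0, 270.0})


@dataclass(frozen=True)
class StimulusProtocol:
    """Parameters of one bar-sweep mapping run.

    All spatial quantities are in degrees of visual angle (dva), durations in
    seconds.  ``inter_blank_after`` lists the sweep indices (0-based) that are
    followed by an inter-sweep blank of ``inter_blank`` seconds.
    """

    aperture_diameter: float
    bar_width: float
    n_steps_per_sweep: int
    step_duration: float
    sweep_directions: tuple[float, ...]
    pre_blank: float = 0.0
    inter_blank: float = 0.0
    post_blank: float = 0.0
    pixels_per_dva: int = 10
    inter_blank_after: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.aperture_diameter <= 0:
            raise ValueError("aperture_diameter must be positive")
        if self.bar_width <= 0:
            raise ValueError("bar_width must be positive")
        if self.n_steps_per_sweep < 1:
            raise ValueError("n_steps_per_sweep must be >= 1")
        if self.step_duration <= 0:
            raise ValueError("step_duration must be positive")
        if self.pixels_per_dva < 1:
            raise ValueError("pixels_per_dva must be >= 1")
        if len(self.sweep_directions) == 0:
            raise ValueError("at least one sweep direction required")
        for d in self.sweep_directions:
            if not (0.0 <= d < 360.0):
                raise ValueError(f"direction {d} outside [0, 360)")
        for dur in (self.pre_blank, self.inter_blank, self.post_blank):
            if dur < 0:
                raise ValueError("blank durations must be non-negative")
        for idx in self.inter_blank_after:
            if not (0 <= idx < len(self.sweep_directions)):
                raise ValueError(f"inter_blank_after index {idx} out of range")

    @property
    def aperture_radius(self) -> float:
        return self.aperture_diameter / 2.0

    @property
    def sweep_duration(self) -> float:
        """Duration of one full bar sweep, seconds."""
        return self.n_steps_per_sweep * self.step_duration

    @property
    def total_duration(self) -> float:
        """Total movie duration: blanks plus all sweeps."""
        return (
            self.pre_blank
            + len(self.sweep_directions) * self.sweep_duration
            + len(self.inter_blank_after) * self.inter_blank
            + self.post_blank
        )

    @property
    def grid_size(self) -> int:
        """Frame height/width in pixels."""
        return int(round(self.aperture_diameter * self.pixels_per_dva))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StimulusProtocol":
        d = json.loads(text)
        d["sweep_directions"] = tuple(d["sweep_directions"])
        d["inter_blank_after"] = tuple(d["inter_blank_after"])
        return cls(**d)


@dataclass
class EffectiveStimulus:
    """Binary aperture movie with its pixel <-> dva mapping.

    Attributes
    ----------
    frames : (T, H, W) uint8 array of {0, 1}
    frame_onsets : (T,) float array, onset of each frame in seconds
    xgrid, ygrid : (H, W) float arrays, pixel-center coordinates in dva
    bar_frame_index : (T,) int array; for bar frames the flat index
        sweep * n_steps + step, -1 for blank frames
    protocol : the generating :class:`StimulusProtocol`
    """

    frames: np.ndarray
    frame_onsets: np.ndarray
    xgrid: np.ndarray
    ygrid: np.ndarray
    bar_frame_index: np.ndarray
    protocol: StimulusProtocol

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_duration(self) -> float:
        return self.protocol.step_duration

    @property
    def is_bar_frame(self) -> np.ndarray:
        return self.bar_frame_index >= 0

    def bar_frames(self) -> np.ndarray:
        """The (n_sweeps * n_steps, H, W) bar frames, blank epochs dropped."""
        return self.frames[self.is_bar_frame]

    def flat_frames(self, bar_only: bool = False) -> np.ndarray:
        """Frames reshaped to (T, H*W) float64, for matrix-product drives."""
        fr = self.bar_frames() if bar_only else self.frames
        return fr.reshape(fr.shape[0], -1).astype(np.float64)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=self.frames, compression="gzip")
            f.create_dataset("frame_onsets", data=self.frame_onsets)
            f.create_dataset("bar_frame_index", data=self.bar_frame_index)
            f.attrs["protocol_json"] = self.protocol.to_json()

    @classmethod
    def from_hdf5(cls, path) -> "EffectiveStimulus":
        import h5py

        with h5py.File(path, "r") as f:
            protocol = StimulusProtocol.from_json(f.attrs["protocol_json"])
            frames = f["frames"][...]
            onsets = f["frame_onsets"][...]
            bar_idx = f["bar_frame_index"][...]
        xg, yg = pixel_grid(protocol)
        return cls(frames, onsets, xg, yg, bar_idx, protocol)

    def write_pgm_stack(self, directory) -> None:
        """Dump every frame as an ASCII PGM image for visual inspection."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        h, w = self.frames.shape[1:]
        for t, fr in enumerate(self.frames):
            lines = [f"P2\n{w} {h}\n1\n"]
            # image row 0 at the top = largest y, so flip vertically
            lines.extend(" ".join(str(v) for v in row) + "\n" for row in fr[::-1])
            (directory / f"frame_{t:04d}.pgm").write_text("".join(lines))


def pixel_grid(protocol: StimulusProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinate grids (x, y) in dva, symmetric about fixation.

    Row index increases with y so that ``frames[t, i, j]`` maps to
    ``(xgrid[i, j], ygrid[i, j])``.
    """
    n = protocol.grid_size
    ppd = protocol.pixels_per_dva
    coords = (np.arange(n) + 0.5 - n / 2.0) / ppd
    xg, yg = np.meshgrid(coords, coords)
    return xg, yg


def make_protocol(preset: str | None = None, **fields) -> StimulusProtocol:
    """Build a :class:`StimulusProtocol` from a named preset or explicit fields.

    ``preset="fmri"`` and ``preset="ephys"`` reproduce the two mapping
    protocols; any field can be overridden by keyword.
    """
    if preset is None:
        return StimulusProtocol(**fields)
    if preset == "fmri":
        directions = fields.pop("sweep_directions", DEFAULT_DIRECTION_ORDER)
        defaults = dict(
            aperture_diameter=16.0,
            bar_width=2.0,
            n_steps_per_sweep=20,
            step_duration=2.5,
            sweep_directions=tuple(directions),
            pre_blank=37.5,
            inter_blank=25.0,
            post_blank=37.5,
            pixels_per_dva=10,
            inter_blank_after=tuple(
                i for i, d in enumerate(directions) if d in CARDINAL_DIRECTIONS
            ),
        )
    elif preset == "ephys":
        directions = fields.pop("sweep_directions", DEFAULT_DIRECTION_ORDER)
        defaults = dict(
            aperture_diameter=28.0,
            bar_width=2.0,
            n_steps_per_sweep=30,
            step_duration=0.5,
            sweep_directions=tuple(directions),
            pre_blank=2.5,
            inter_blank=2.5,
            post_blank=2.5,
            pixels_per_dva=10,
            inter_blank_after=tuple(range(len(directions))),
        )
    else:
        raise ValueError(f"unknown preset {preset!r}; expected 'fmri' or 'ephys'")
    defaults.update(fields)
    return StimulusProtocol(**defaults)


def bar_mask(
    protocol: StimulusProtocol,
    direction_deg: float,
    center_offset: float,
    xgrid: np.ndarray,
    ygrid: np.ndarray,
) -> np.ndarray:
    """Binary mask of a bar at signed offset ``center_offset`` (dva) along the
    motion axis ``direction_deg``, clipped by the circular aperture.

    The bar is the infinite strip perpendicular to the motion direction with
    total width ``protocol.bar_width``.
    """
    theta = np.deg2rad(direction_deg)
    ux, uy = np.cos(theta), np.sin(theta)
    # signed distance of each pixel from the bar's center line, along motion axis
    proj = xgrid * ux + ygrid * uy
    in_bar = np.abs(proj - center_offset) <= protocol.bar_width / 2.0
    in_aperture = xgrid**2 + ygrid**2 <= protocol.aperture_radius**2
    return (in_bar & in_aperture).astype(np.uint8)


def bar_center_offsets(protocol: StimulusProtocol) -> np.ndarray:
    """Bar-center positions along the motion axis for one sweep.

    First and last centers flush with the aperture rim at +/- radius; a
    single-step sweep puts the bar at fixation.
    """
    n = protocol.n_steps_per_sweep
    r = protocol.aperture_radius
    if n == 1:
        return np.array([0.0])
    return np.linspace(-r, r, n)


def render_effective_stimulus(protocol: StimulusProtocol) -> EffectiveStimulus:
    """Render the full movie (blanks + sweeps) as a binary mask sequence.

    Blank epochs are rounded to whole frames of ``step_duration`` so the
    movie is a uniform frame raster; presets use blank durations that are
    exact multiples of the step.
    """
    xg, yg = pixel_grid(protocol)
    n = protocol.grid_size
    dt = protocol.step_duration

    def n_blank_frames(duration: float) -> int:
        return int(round(duration / dt))

    frames: list[np.ndarray] = []
    bar_index: list[int] = []
    zero = np.zeros((n, n), dtype=np.uint8)

    for _ in range(n_blank_frames(protocol.pre_blank)):
        frames.append(zero)
        bar_index.append(-1)
    offsets = bar_center_offsets(protocol)
    for s, direction in enumerate(protocol.sweep_directions):
        for k, off in enumerate(offsets):
            frames.append(bar_mask(protocol, direction, off, xg, yg))
            bar_index.append(s * protocol.n_steps_per_sweep + k)
        if s in protocol.inter_blank_after:
            for _ in range(n_blank_frames(protocol.inter_blank)):
                frames.append(zero)
                bar_index.append(-1)
    for _ in range(n_blank_frames(protocol.post_blank)):
        frames.append(zero)
        bar_index.append(-1)

    stack = np.stack(frames)
    onsets = np.arange(stack.shape[0]) * dt
    return EffectiveStimulus(
        frames=stack,
        frame_onsets=onsets,
        xgrid=xg,
        ygrid=yg,
        bar_frame_index=np.asarray(bar_index, dtype=np.int64),
        protocol=protocol,
    )
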