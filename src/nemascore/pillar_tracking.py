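"""Pillar detection and deflection tracking for micropillar force arenas.

A crawling nematode deflects soft PDMS pillars arranged on a square
lattice; the deflection of each pillar encodes the force the animal
exerts on it.  This module locates pillars in grayscale frames (dark
disks on a bright background), references detections to the rest
lattice, and extracts per-pillar deflection vectors together with the
per-frame maximal deflection that downstream strength analysis uses.

Coordinate conventions: image x increases rightward (columns), y
increases downward (rows), origin at the top-left pixel center.
Lattice indices are 0-based (row, col).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops


class EmptyFrameError(ValueError):
    """No pillar-like objects were detected in a frame."""


class TrackingAmbiguityError(ValueError):
    """A deflection reached half the lattice pitch; assignment to a rest
    position is no longer well defined."""


#: Default noise floor in pixel-equivalents: centroid jitter below half a
#: pixel is treated as "not in contact" rather than a real deflection.
DEFAULT_NOISE_FLOOR_PX = 0.5


@dataclass(frozen=True)
class PillarArena:
    """Geometry, material and imaging constants of a micropillar arena.

    Lengths are micrometres; the defaults are the standard NemaFlex
    device (44 um pillar diameter, 87 um height, 71 um edge-to-edge gap)
    imaged at 1.63 um/px and 5 frames per second.  ``elastic_modulus``
    and ``poisson_ratio`` are PDMS (10:1 base:curing agent) defaults used
    by the cantilever force model.
    """

    pillar_diameter: float = 44.0
    pillar_height: float = 87.0
    gap: float = 71.0
    elastic_modulus: float = 2.6e6  # Pa
    poisson_ratio: float = 0.5
    pixel_size: float = 1.63  # um / px
    frame_rate: float = 5.0  # 1 / s
    lattice_rows: int = 10
    lattice_cols: int = 10

    def __post_init__(self) -> None:
        for name in ("pillar_diameter", "pillar_height", "gap", "pixel_size",
                     "frame_rate", "elastic_modulus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lattice_rows < 1 or self.lattice_cols < 1:
            raise ValueError("lattice must have at least one row and column")

    @property
    def pitch(self) -> float:
        """Center-to-center pillar spacing (um)."""
        return self.pillar_diameter + self.gap

    @property
    def pitch_px(self) -> float:
        return self.pitch / self.pixel_size

    @property
    def pillar_radius_px(self) -> float:
        return 0.5 * self.pillar_diameter / self.pixel_size

    @property
    def margin_px(self) -> float:
        """Border between the image edge and the first lattice position."""
        return self.pitch_px

    @property
    def image_shape(self) -> tuple[int, int]:
        """(height, width) in pixels of a rendered frame."""
        h = int(np.ceil(2 * self.margin_px + (self.lattice_rows - 1) * self.pitch_px)) + 1
        w = int(np.ceil(2 * self.margin_px + (self.lattice_cols - 1) * self.pitch_px)) + 1
        return h, w

    def rest_lattice_px(self) -> np.ndarray:
        """Rest positions as an (rows, cols, 2) array of (x, y) pixels."""
        jj, ii = np.meshgrid(np.arange(self.lattice_cols),
                             np.arange(self.lattice_rows))
        x = self.margin_px + jj * self.pitch_px
        y = self.margin_px + ii * self.pitch_px
        return np.stack([x, y], axis=-1)

    def rest_lattice_um(self) -> np.ndarray:
        return self.rest_lattice_px() * self.pixel_size

    @property
    def noise_floor_um(self) -> float:
        return DEFAULT_NOISE_FLOOR_PX * self.pixel_size


@dataclass
class DeflectionFrame:
    """Per-pillar deflection vectors for one video frame.

    ``deflections`` is (rows, cols, 2) in um, ordered (dx, dy);
    ``contact_mask`` marks pillars whose deflection magnitude exceeds the
    noise floor; ``ambiguous`` lists (row, col) lattice sites whose
    centroid-to-lattice assignment was not unique.
    """

    frame_index: int
    deflections: np.ndarray
    contact_mask: np.ndarray
    ambiguous: list[tuple[int, int]] = field(default_factory=list)

    def magnitude(self) -> np.ndarray:
        """Deflection magnitudes |delta| (um), shape (rows, cols)."""
        return np.hypot(self.deflections[..., 0], self.deflections[..., 1])


def detect_pillars(image: np.ndarray, arena: PillarArena) -> np.ndarray:
    """Locate pillar centroids in a grayscale frame.

    Pillars appear as dark filled disks on a bright background.  The
    frame is thresholded (Otsu); connected components are kept only if
    their area lies between a quarter and four times the nominal disk
    area and they are nearly convex (solidity >= 0.8, which rejects the
    ragged speckle clusters an Otsu split of a pure-noise frame
    produces).  Each surviving component is reduced to its
    intensity-weighted (sub-pixel) centroid using the inverted image as
    weight.

    Returns an (N, 2) array of (x, y) centroids in pixels.

    Raises
    ------
    EmptyFrameError
        If no component survives filtering (e.g. a pure-noise frame).
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("image is empty")
    if arena.pillar_radius_px < 2:
        raise ValueError("pillar radius below 2 px cannot be resolved")
    if np.ptp(image) == 0:
        raise EmptyFrameError("flat image contains no pillars")

    thr = threshold_otsu(image)
    mask = image < thr
    labels = label(mask)
    inverted = image.max() - image

    disk_area = np.pi * arena.pillar_radius_px ** 2
    centroids = []
    for region in regionprops(labels, intensity_image=inverted):
        if not 0.25 * disk_area <= region.area <= 4.0 * disk_area:
            continue
        if region.solidity < 0.8:
            continue
        cy, cx = region.centroid_weighted
        centroids.append((cx, cy))
    if not centroids:
        raise EmptyFrameError("no pillar-like objects detected")
    return np.asarray(centroids, dtype=float)


def assign_to_lattice(
    centroids: np.ndarray,
    arena: PillarArena,
    frame_index: int = 0,
    noise_floor_um: float | None = None,
) -> DeflectionFrame:
    """Map detected centroids to rest-lattice sites and compute deflections.

    Each centroid is assigned to its nearest rest position; the
    deflection is ``(centroid - rest) * pixel_size`` in um.  Rest sites
    with no centroid get zero deflection and ``contact_mask`` False.
    A centroid that lies within half a pitch of two rest sites
    (including the exact-midpoint tie), or two centroids contending for
    one site, are flagged in ``ambiguous``.

    Raises
    ------
    TrackingAmbiguityError
        If any assigned deflection magnitude exceeds pitch/2, the point
        at which nearest-site assignment stops being meaningful.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if centroids.shape[1] != 2:
        raise ValueError("centroids must be an (N, 2) array of (x, y) px")
    if noise_floor_um is None:
        noise_floor_um = arena.noise_floor_um

    rest = arena.rest_lattice_px().reshape(-1, 2)
    rows, cols = arena.lattice_rows, arena.lattice_cols
    half_pitch_um = 0.5 * arena.pitch

    deflections = np.zeros((rows, cols, 2), dtype=float)
    contact = np.zeros((rows, cols), dtype=bool)
    occupied: dict[int, int] = {}
    ambiguous: set[tuple[int, int]] = set()

    # distances in um from every centroid to every rest site
    diff_px = centroids[:, None, :] - rest[None, :, :]
    dist_um = np.hypot(diff_px[..., 0], diff_px[..., 1]) * arena.pixel_size

    for c_idx in range(len(centroids)):
        order = np.argsort(dist_um[c_idx], kind="stable")
        nearest = int(order[0])
        d1 = dist_um[c_idx, order[0]]
        if d1 > half_pitch_um and not np.isclose(d1, half_pitch_um):
            raise TrackingAmbiguityError(
                f"centroid {c_idx} deflected {d1:.2f} um > half pitch "
                f"({half_pitch_um:.2f} um)")
        r, c = divmod(nearest, cols)
        if len(order) > 1:
            d2 = dist_um[c_idx, order[1]]
            if d2 <= half_pitch_um or np.isclose(d1, d2):
                ambiguous.add((r, c))
                r2, c2 = divmod(int(order[1]), cols)
                ambiguous.add((r2, c2))
        if nearest in occupied:
            ambiguous.add((r, c))
            # keep the closer centroid
            if d1 >= dist_um[occupied[nearest], nearest]:
                continue
        occupied[nearest] = c_idx
        deflections[r, c] = diff_px[c_idx, nearest] * arena.pixel_size
        contact[r, c] = np.hypot(*deflections[r, c]) >= noise_floor_um

    return DeflectionFrame(
        frame_index=frame_index,
        deflections=deflections,
        contact_mask=contact,
        ambiguous=sorted(ambiguous),
    )


def max_deflection_per_frame(
    frame: DeflectionFrame,
) -> tuple[tuple[int, int] | None, float]:
    """Return the in-contact pillar with the largest deflection magnitude.

    Returns ``((row, col), |delta| um)``; ties break to the lowest
    (row, col) in lexicographic order.  If no pillar is in contact the
    result is ``(None, 0.0)``.
    """
    if frame.deflections.size == 0:
        raise ValueError("frame has no pillars")
    mag = frame.magnitude()
    masked = np.where(frame.contact_mask, mag, -np.inf)
    if not frame.contact_mask.any():
        return None, 0.0
    best = np.max(masked)
    # argwhere scans row-major, so the first hit is the lexicographic min
    r, c = np.argwhere(masked == best)[0]
    return (int(r), int(c)), float(best)


# ---------------------------------------------------------------------------
# File interfaces


def write_deflection_csv(frames: list[DeflectionFrame], path) -> None:
    """Write per-frame deflection tables.

    Columns: frame, row, col, dx_um, dy_um, mag_um, contact.
    """
    records = []
    for fr in frames:
        mag = fr.magnitude()
        for r in range(fr.deflections.shape[0]):
            for c in range(fr.deflections.shape[1]):
                records.append({
                    "frame": fr.frame_index, "row": r, "col": c,
                    "dx_um": fr.deflections[r, c, 0],
                    "dy_um": fr.deflections[r, c, 1],
                    "mag_um": mag[r, c],
                    "contact": bool(fr.contact_mask[r, c]),
                })
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def read_centroid_csv(path) -> dict[int, np.ndarray]:
    """Read a centroid table (frame, pillar_row, pillar_col, x_px, y_px).

    Returns a mapping frame index -> (N, 2) array of (x, y) centroids.
    The pillar_row/pillar_col columns are optional bookkeeping from the
    generator and are not required for lattice assignment.
    """
    df = pd.read_csv(path)
    required = {"frame", "x_px", "y_px"}
    if not required.issubset(df.columns):
        raise ValueError(f"centroid CSV must contain columns {sorted(required)}")
    return {
        int(frame): grp[["x_px", "y_px"]].to_numpy(dtype=float)
        for frame, grp in df.groupby("frame")
    }


def track_stack(
    stack: np.ndarray, arena: PillarArena, noise_floor_um: float | None = None
) -> list[DeflectionFrame]:
    """Detect and assign pillars for every frame of an image stack."""
    frames = []
    for i, image in enumerate(stack):
        cents = detect_pillars(image, arena)
        frames.append(
            assign_to_lattice(cents, arena, frame_index=i,
                              noise_floor_um=noise_floor_um))
    return frames


def frames_from_centroid_table(
    table: dict[int, np.ndarray],
    arena: PillarArena,
    noise_floor_um: float | None = None,
) -> list[DeflectionFrame]:
    """Assign pre-computed centroid tables (e.g. from CSV) to the lattice."""
    if len(table) == 0:
        warnings.warn("empty centroid table", stacklevel=2)
    return [
        assign_to_lattice(cents, arena, frame_index=idx,
                          noise_floor_um=noise_floor_um)
        for idx, cents in sorted(table.items())
    ]
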