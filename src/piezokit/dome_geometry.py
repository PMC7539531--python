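"""Dome-depth statistic, rigid-body trajectory fitting and height maps.

The dome depth quantifies how far a membrane leaflet is pulled inward around
a mechanosensitive channel: the surface level is the mean z of the leaflet's
phosphate particles at or above the 90th centile of z (averaging suppresses
random membrane fluctuation), the dome bottom is the single lowest phosphate
z (well-determined because it is anchored to the protein), and the depth is
their difference.

Height maps bin phosphate x/y positions on a common grid (default 75 bins per
axis), store the per-frame mean z per bin, and average those matrices over
frames; bins empty in every frame are flagged missing rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .coords_io import ParticleFrame, Trajectory
from .leaflet_assign import LeafletPartition

__all__ = [
    "DomeDepthResult",
    "DepthSeriesSummary",
    "HeightMap",
    "FittingError",
    "fit_to_reference",
    "dome_depth",
    "dome_depth_series",
    "height_map",
]

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILE = 90.0
DEFAULT_N_BINS = 75


class FittingError(ValueError):
    """Rigid-body fitting is underdetermined (too few / collinear particles)."""


@dataclass
class DomeDepthResult:
    """Per-frame, per-leaflet dome depth decomposition (nm)."""

    frame_index: int
    leaflet: str  # "upper" | "lower"
    surface_level: float
    bottom_z: float
    depth: float


@dataclass
class DepthSeriesSummary:
    """Mean +/- sample sd of per-frame depths for one leaflet."""

    leaflet: str
    mean: float
    sd: float
    n_frames: int


@dataclass
class HeightMap:
    """Frame-averaged 2D map of mean phosphate z per x/y bin (nm)."""

    bin_edges_x: np.ndarray
    bin_edges_y: np.ndarray
    mean_z: np.ndarray  # NaN where missing
    frames_counted: np.ndarray
    missing: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges_x) - 1

    def relief(self) -> float:
        """max bin - min bin over non-missing bins (nm)."""
        vals = self.mean_z[~self.missing]
        if vals.size == 0:
            raise ValueError("height map has no occupied bins")
        return float(vals.max() - vals.min())

    def argmin_bin(self) -> tuple[int, int]:
        """(i, j) index of the lowest non-missing bin."""
        z = np.where(self.missing, np.inf, self.mean_z)
        return tuple(int(v) for v in np.unravel_index(np.argmin(z), z.shape))


# ---------------------------------------------------------------------------
# Rigid-body fitting (Kabsch superposition on a reference selection)
# ---------------------------------------------------------------------------

def _selection_mask(frame: ParticleFrame, predicate) -> np.ndarray:
    if callable(predicate):
        return np.array([bool(predicate(str(n))) for n in frame.names])
    import re

    rx = re.compile(predicate)
    return np.array([rx.fullmatch(str(n)) is not None for n in frame.names])


def fit_to_reference(
    traj: Trajectory,
    reference_selection,
    reference: ParticleFrame | None = None,
) -> Trajectory:
    """Least-squares superpose every frame onto the reference structure.

    For each frame, the rigid rotation + translation minimizing the RMSD of
    the selected particles (e.g. the protein beads) to the reference is found
    by Kabsch superposition and applied to *all* particles of the frame, so
    the membrane is expressed in the protein's frame of reference.

    Raises
    ------
    FittingError
        If the selection holds fewer than 3 particles or they are collinear.
    """
    ref = reference if reference is not None else traj.reference
    if ref is None:
        raise FittingError("no reference frame available for fitting")
    ref_mask = _selection_mask(ref, reference_selection)
    if ref_mask.sum() < 3:
        raise FittingError("reference selection must hold >= 3 particles")
    ref_sel = ref.positions[ref_mask]
    ref_centroid = ref_sel.mean(axis=0)
    ref_centered = ref_sel - ref_centroid
    s = np.linalg.svd(ref_centered, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise FittingError("reference selection particles are collinear")

    fitted = []
    for fr in traj.frames:
        mask = _selection_mask(fr, reference_selection)
        if mask.sum() != ref_mask.sum():
            raise FittingError(
                f"frame {fr.frame_index} selection size {mask.sum()} differs "
                f"from reference {ref_mask.sum()}"
            )
        sel = fr.positions[mask]
        centroid = sel.mean(axis=0)
        rot, _rssd = Rotation.align_vectors(ref_centered, sel - centroid)
        new_pos = rot.apply(fr.positions - centroid) + ref_centroid
        fitted.append(
            ParticleFrame(
                frame_index=fr.frame_index,
                particle_ids=fr.particle_ids,
                names=fr.names,
                positions=new_pos,
                box=fr.box,
                resnames=fr.resnames,
            )
        )
    return Trajectory(frames=fitted, reference=ref, provenance=traj.provenance)


# ---------------------------------------------------------------------------
# Dome depth
# ---------------------------------------------------------------------------

def dome_depth(
    zs: Sequence[float] | np.ndarray,
    percentile: float = DEFAULT_PERCENTILE,
    frame_index: int = 0,
    leaflet: str = "",
) -> DomeDepthResult:
    """Dome depth of one leaflet from its phosphate z-coordinates.

    surface_level = mean of {z : z >= P(percentile)} with the percentile by
    linear interpolation (inclusive >=, so the surface set is never empty
    even when the top values tie); bottom_z = min(z); depth = difference.
    """
    zs = np.asarray(zs, dtype=float)
    if zs.size < 2:
        raise ValueError("dome depth needs at least 2 z values")
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    threshold = np.percentile(zs, percentile)
    surface = float(zs[zs >= threshold].mean())
    bottom = float(zs.min())
    return DomeDepthResult(
        frame_index=frame_index,
        leaflet=leaflet,
        surface_level=surface,
        bottom_z=bottom,
        depth=surface - bottom,
    )


def dome_depth_series(
    traj: Trajectory,
    partitions: Sequence[LeafletPartition],
    percentile: float = DEFAULT_PERCENTILE,
) -> tuple[list[DomeDepthResult], dict[str, DepthSeriesSummary], int]:
    """Per-frame dome depths for both leaflets, with mean +/- sd summaries.

    Frames whose partition is degenerate or unvalidated are skipped; the
    number skipped is logged and returned.  Raises ``ValueError`` when no
    frame is analyzable.
    """
    if len(partitions) != traj.n_frames:
        raise ValueError("need one partition per frame")
    results: list[DomeDepthResult] = []
    per_leaflet: dict[str, list[float]] = {"upper": [], "lower": []}
    skipped = 0
    for fr, part in zip(traj.frames, partitions):
        if part.is_degenerate or not part.validated:
            skipped += 1
            continue
        id_to_index = {int(p): i for i, p in enumerate(fr.particle_ids)}
        for leaflet_name, members in (("upper", part.upper), ("lower", part.lower)):
            idx = [id_to_index[p] for p in members]
            res = dome_depth(
                fr.positions[idx, 2],
                percentile=percentile,
                frame_index=fr.frame_index,
                leaflet=leaflet_name,
            )
            results.append(res)
            per_leaflet[leaflet_name].append(res.depth)
    if skipped:
        logger.info("dome_depth_series: skipped %d degenerate frame(s)", skipped)
    if not results:
        raise ValueError("no analyzable frames (all partitions degenerate)")
    summaries = {
        name: DepthSeriesSummary(
            leaflet=name,
            mean=float(np.mean(vals)),
            sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            n_frames=len(vals),
        )
        for name, vals in per_leaflet.items()
        if vals
    }
    return results, summaries, skipped


# ---------------------------------------------------------------------------
# Height map
# ---------------------------------------------------------------------------

def height_map(
    traj: Trajectory,
    leaflet_ids: Iterable[int],
    n_bins: int = DEFAULT_N_BINS,
) -> HeightMap:
    """Frame-averaged 2D height map of one leaflet's phosphate particles.

    The bin range is fixed from the first frame (box extent when present,
    otherwise the x/y extent of the leaflet particles) and reused for every
    frame so the per-frame matrices share a common grid.  Per frame and bin,
    the mean z of contained particles is stored; the final map averages each
    bin over the frames in which it was nonempty.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    leaflet_ids = frozenset(int(i) for i in leaflet_ids)
    first = traj.frames[0]
    mask0 = np.isin(first.particle_ids, list(leaflet_ids))
    if not mask0.any():
        raise ValueError("leaflet_ids match no particles")
    if first.box is not None:
        edges_x = np.linspace(0.0, first.box[0], n_bins + 1)
        edges_y = np.linspace(0.0, first.box[1], n_bins + 1)
    else:
        xy = first.positions[mask0, :2]
        edges_x = np.linspace(xy[:, 0].min(), xy[:, 0].max(), n_bins + 1)
        edges_y = np.linspace(xy[:, 1].min(), xy[:, 1].max(), n_bins + 1)

    sum_of_means = np.zeros((n_bins, n_bins))
    frames_counted = np.zeros((n_bins, n_bins), dtype=int)
    for fr in traj.frames:
        mask = np.isin(fr.particle_ids, list(leaflet_ids))
        pos = fr.positions[mask]
        counts, _, _ = np.histogram2d(pos[:, 0], pos[:, 1], bins=[edges_x, edges_y])
        zsum, _, _ = np.histogram2d(
            pos[:, 0], pos[:, 1], bins=[edges_x, edges_y], weights=pos[:, 2]
        )
        occupied = counts > 0
        sum_of_means[occupied] += zsum[occupied] / counts[occupied]
        frames_counted += occupied.astype(int)

    missing = frames_counted == 0
    mean_z = np.full((n_bins, n_bins), np.nan)
    mean_z[~missing] = sum_of_means[~missing] / frames_counted[~missing]
    return HeightMap(
        bin_edges_x=edges_x,
        bin_edges_y=edges_y,
        mean_z=mean_z,
        frames_counted=frames_counted,
        missing=missing,
    )
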