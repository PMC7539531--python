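"""Synthetic bilayer generator with known leaflet membership and dome depth.

Builds two-leaflet configurations of phosphate-marker particles: each leaflet
sits on an analytic surface

    z(x, y) = +/- separation/2 - A * exp(-((x-cx)^2 + (y-cy)^2) / (2 sigma^2))

i.e. a flat plane carrying an inward (negative-z) Gaussian depression of
amplitude ``A`` — the shape a mechanosensitive channel imposes on the
surrounding membrane — plus optional Gaussian positional noise in z.
Particles are laid out on a jittered square lattice in-plane so the in-leaflet
nearest-neighbour spacing is uniform and well below the 2 nm leaflet-growth
cutoff used downstream.  Lipid-species labels are apportioned to the stated
composition fractions by deterministic largest-remainder allocation, so
species counts are exact and testable rather than sampled.

Everything is driven by a single integer seed; identical specs regenerate
bit-identical configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coords_io import ParticleFrame, Trajectory

__all__ = [
    "MembraneSpec",
    "MembraneGroundTruth",
    "InfeasibleSpecError",
    "generate_dome_bilayer",
    "generate_flat_bilayer",
    "largest_remainder_counts",
    "UPPER_COMPOSITION",
    "LOWER_COMPOSITION",
]

#: Upper-leaflet lipid composition (mole fractions) of the asymmetric
#: endothelial-like bilayer the generator emulates.
UPPER_COMPOSITION = {"POPC": 0.55, "SM": 0.05, "POPE": 0.20, "CHOL": 0.20}

#: Lower-leaflet composition.  The source recipe (50% POPC, 20% POPE, 5% SM,
#: 20% CHOL, 5% POPS, 5% PIP2) over-counts to 105%; fractions here are the
#: same proportions renormalized to sum to one.
LOWER_COMPOSITION = {
    "POPC": 0.50 / 1.05,
    "POPE": 0.20 / 1.05,
    "SM": 0.05 / 1.05,
    "CHOL": 0.20 / 1.05,
    "POPS": 0.05 / 1.05,
    "PIP2": 0.05 / 1.05,
}

#: Downstream leaflet assignment connects particles within this distance (nm);
#: the generator refuses lattices too sparse to stay connected under it.
CONNECTIVITY_CUTOFF_NM = 2.0


class InfeasibleSpecError(ValueError):
    """Spec implies an in-leaflet spacing too large for leaflet connectivity."""


@dataclass
class MembraneSpec:
    """Parameters of a synthetic two-leaflet dome configuration.

    All lengths in nm.  ``dome_amplitude`` is the depth of the inward Gaussian
    depression (0 gives a flat bilayer); ``dome_sigma`` its width;
    ``leaflet_separation`` the gap between the two flat surfaces;
    ``noise_sd`` the standard deviation of z-positional noise per particle.
    """

    particles_per_leaflet: int = 2000
    box_xy: tuple[float, float] = (40.0, 40.0)
    leaflet_separation: float = 4.0
    dome_amplitude: float = 6.0
    dome_sigma: float = 5.0
    noise_sd: float = 0.1
    upper_composition: dict[str, float] = field(
        default_factory=lambda: dict(UPPER_COMPOSITION)
    )
    lower_composition: dict[str, float] = field(
        default_factory=lambda: dict(LOWER_COMPOSITION)
    )
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.particles_per_leaflet < 1:
            raise ValueError("particles_per_leaflet must be positive")
        if self.leaflet_separation <= 0:
            raise ValueError("leaflet_separation must be > 0")
        if self.dome_sigma <= 0:
            raise ValueError("dome_sigma must be > 0")
        if self.dome_amplitude < 0:
            raise ValueError("dome_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for label, comp in (
            ("upper_composition", self.upper_composition),
            ("lower_composition", self.lower_composition),
        ):
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError(f"{label} fractions must sum to 1 within 1e-9")
            if any(f < 0 for f in comp.values()):
                raise ValueError(f"{label} fractions must be non-negative")

    @property
    def lattice_spacing(self) -> float:
        """Mean in-plane nearest-neighbour spacing implied by the spec (nm)."""
        area = self.box_xy[0] * self.box_xy[1]
        return math.sqrt(area / self.particles_per_leaflet)


@dataclass
class MembraneGroundTruth:
    """Exact generation record: membership, species and analytic depth."""

    upper_ids: np.ndarray
    lower_ids: np.ndarray
    species: np.ndarray  # per-particle species label, generator order
    true_depth: float  # analytic dome depth A of the noise-free surface
    dome_center: tuple[float, float]


def largest_remainder_counts(fractions: dict[str, float], total: int) -> dict[str, int]:
    """Apportion ``total`` items to fractions by the largest-remainder rule.

    Counts are exact: each species deviates from ``fraction * total`` by less
    than one particle, and the counts sum to ``total``.  Ties in remainder are
    broken by species-key order for determinism.
    """
    keys = list(fractions)
    ideal = np.array([fractions[k] * total for k in keys])
    counts = np.floor(ideal).astype(int)
    short = total - counts.sum()
    remainders = ideal - counts
    order = sorted(range(len(keys)), key=lambda i: (-remainders[i], keys[i]))
    for i in order[:short]:
        counts[i] += 1
    return dict(zip(keys, counts.tolist()))


def _species_labels(comp: dict[str, float], n: int, rng: np.random.Generator) -> np.ndarray:
    counts = largest_remainder_counts(comp, n)
    labels = np.concatenate(
        [np.full(c, k, dtype=object) for k, c in counts.items()]
    ) if counts else np.empty(0, dtype=object)
    rng.shuffle(labels)
    return labels


def _leaflet_xy(spec: MembraneSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered square lattice covering the box with exactly n points."""
    n = spec.particles_per_leaflet
    lx, ly = spec.box_xy
    ncols = max(1, int(math.ceil(math.sqrt(n * lx / ly))))
    nrows = int(math.ceil(n / ncols))
    dx, dy = lx / ncols, ly / nrows
    jx = min(dx, dy) * 0.25
    ix, iy = np.meshgrid(np.arange(ncols), np.arange(nrows), indexing="ij")
    xy = np.column_stack(
        [(ix.ravel() + 0.5) * dx, (iy.ravel() + 0.5) * dy]
    )[:n]
    xy += rng.uniform(-jx, jx, size=xy.shape)
    return np.mod(xy, [lx, ly])


def generate_dome_bilayer(spec: MembraneSpec) -> tuple[Trajectory, MembraneGroundTruth]:
    """Generate a two-leaflet dome configuration with exact ground truth.

    Returns a trajectory of ``spec.n_frames`` frames (fresh noise per frame,
    common lattice and labels) plus the generation record.  The dome is
    centred in the box and depresses both leaflets equally, so the analytic
    dome depth of either leaflet's noise-free surface is ``dome_amplitude``.

    Raises
    ------
    InfeasibleSpecError
        If the implied lattice spacing reaches the 2 nm connectivity cutoff,
        under which downstream leaflet growth could not traverse the leaflet.
    """
    if spec.lattice_spacing >= CONNECTIVITY_CUTOFF_NM:
        raise InfeasibleSpecError(
            f"in-leaflet spacing {spec.lattice_spacing:.2f} nm >= "
            f"{CONNECTIVITY_CUTOFF_NM} nm connectivity cutoff; increase "
            "particles_per_leaflet or shrink box_xy"
        )
    rng = np.random.default_rng(spec.seed)
    n = spec.particles_per_leaflet
    lx, ly = spec.box_xy
    cx, cy = lx / 2.0, ly / 2.0
    half = spec.leaflet_separation / 2.0
    box_z = 2.0 * (half + spec.dome_amplitude) + 10.0

    xy_upper = _leaflet_xy(spec, rng)
    xy_lower = _leaflet_xy(spec, rng)
    species = np.concatenate(
        [
            _species_labels(spec.upper_composition, n, rng),
            _species_labels(spec.lower_composition, n, rng),
        ]
    )

    def surface(xy: np.ndarray, sign: float) -> np.ndarray:
        r2 = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2
        return sign * half - spec.dome_amplitude * np.exp(
            -r2 / (2.0 * spec.dome_sigma**2)
        )

    names = np.full(2 * n, "PO4", dtype=object)
    ids = np.arange(2 * n)
    frames = []
    for fi in range(spec.n_frames):
        zu = surface(xy_upper, +1.0)
        zl = surface(xy_lower, -1.0)
        pos = np.empty((2 * n, 3))
        pos[:n, :2] = xy_upper
        pos[n:, :2] = xy_lower
        pos[:n, 2] = zu
        pos[n:, 2] = zl
        if spec.noise_sd > 0:
            pos[:, 2] += rng.normal(0.0, spec.noise_sd, size=2 * n)
        pos[:, 2] += box_z / 2.0  # keep coordinates positive for file output
        frames.append(
            ParticleFrame(
                frame_index=fi,
                particle_ids=ids,
                names=names,
                positions=pos,
                box=np.array([lx, ly, box_z]),
                resnames=species,
            )
        )
    truth = MembraneGroundTruth(
        upper_ids=ids[:n].copy(),
        lower_ids=ids[n:].copy(),
        species=species.copy(),
        true_depth=float(spec.dome_amplitude),
        dome_center=(cx, cy),
    )
    return Trajectory(frames=frames, provenance=f"synthetic dome A={spec.dome_amplitude}"), truth


def generate_flat_bilayer(spec: MembraneSpec) -> tuple[Trajectory, MembraneGroundTruth]:
    """Dome-free bilayer: :func:`generate_dome_bilayer` with amplitude 0."""
    flat = MembraneSpec(
        particles_per_leaflet=spec.particles_per_leaflet,
        box_xy=spec.box_xy,
        leaflet_separation=spec.leaflet_separation,
        dome_amplitude=0.0,
        dome_sigma=spec.dome_sigma,
        noise_sd=spec.noise_sd,
        upper_composition=dict(spec.upper_composition),
        lower_composition=dict(spec.lower_composition),
        n_frames=spec.n_frames,
        seed=spec.seed,
    )
    return generate_dome_bilayer(flat)
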