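"""Forward model for FROS (fluorescent repressor operator system) microscopy.

Renders synthetic 9-slice fluorescence z-stacks of budding-yeast-like cells in
which a GFP-tagged repressor binds a chromosomal operator array.  Each cell
carries

* a single diffraction-limited "chromosome dot" whose integrated intensity is
  ``photons_per_molecule x n_bound``, with ``n_bound`` set by Hill occupancy of
  the array (two repressor molecules per operator repeat),
* a diffuse free-protein background proportional to the cell's free
  concentration (widefield slab model: every slice collects light from an
  effective depth-of-field-thick slab), and
* a flat autofluorescence floor, also rendered into a matched unlabeled
  control stack.

A configurable minority of cells carries a replicated, co-localized pair of
arrays rendered as two dots of full brightness at small separation; these are
what the downstream 1.8x bright-dot filter is meant to remove.

Everything downstream of the simulator is testable against the returned
ground truth without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.special import erf

from .constants import MOLECULES_PER_UM3_PER_NM

__all__ = [
    "SimulationConfig",
    "GroundTruthCell",
    "SimulatedField",
    "SimulatedPopulation",
    "occupancy",
    "simulate_population",
    "background_rate_per_pixel",
]

_CONC_LAWS = ("log-uniform", "log-normal", "fixed")


def occupancy(conc, kd: float, n: float):
    """Hill occupancy theta = C^n / (Kd^n + C^n).

    Parameters
    ----------
    conc : float or array-like
        Free-protein concentration in nM; must be non-negative.
    kd : float
        Apparent dissociation constant in nM (> 0); the concentration at
        which half the sites are occupied.
    n : float
        Hill coefficient (> 0).

    Returns
    -------
    float or ndarray in [0, 1].
    """
    if kd <= 0:
        raise ValueError(f"kd must be positive, got {kd}")
    if n <= 0:
        raise ValueError(f"Hill coefficient must be positive, got {n}")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    # 1 / (1 + (kd/c)^n) is stable for large c; c == 0 maps to theta = 0.
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(c > 0, (kd / np.where(c > 0, c, 1.0)) ** n, np.inf)
        theta = 1.0 / (1.0 + ratio)
    if np.isscalar(conc) or getattr(conc, "ndim", 0) == 0:
        return float(theta)
    return theta


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a simulated FROS imaging experiment.

    Lengths are in micrometres, concentrations in nM, intensities in
    arbitrary camera units (a.u.).  ``photons_per_molecule`` sets the overall
    intensity scale; every downstream estimate is a ratio so its value
    cancels.
    """

    n_cells: int = 268
    lacO_repeats: int = 256
    true_kd: float = 592.0          # nM, apparent Kd used as generating truth
    true_hill_n: float = 2.93
    # Free-concentration law across cells (cell-to-cell expression variability)
    conc_law: str = "log-uniform"   # "log-uniform" | "log-normal" | "fixed"
    conc_low: float = 10.0          # nM (law value for "fixed")
    conc_high: float = 1500.0       # nM
    conc_mean: float = 300.0        # nM, log-normal only
    conc_cv: float = 0.5            # coefficient of variation, log-normal only
    photons_per_molecule: float = 100.0   # a.u. per molecule, integrated
    autofluorescence_rate: float = 50.0   # a.u. per pixel per slice
    psf_sigma_xy: float = 0.12      # um
    psf_sigma_z: float = 0.35       # um
    pixel_size: float = 0.1         # um / px
    z_spacing: float = 0.4          # um between slices
    n_z: int = 9
    dof: float = 1.6                # um, effective collection depth per slice
    replicated_dot_fraction: float = 0.1
    replicated_separation_px: float = 2.0
    dot_jitter_px: float = 2.0      # max |offset| of dot from nucleus center
    cell_semi_axis_y: Tuple[float, float] = (1.3, 1.6)   # um, sampled range
    cell_semi_axis_x: Tuple[float, float] = (1.4, 1.9)   # um
    noise: bool = True              # per-voxel Poisson shot noise
    seed: int = 0
    cells_per_field: int = 25
    tile_px: int = 40               # square region reserved per cell

    def __post_init__(self):
        if self.conc_law not in _CONC_LAWS:
            raise ValueError(f"conc_law must be one of {_CONC_LAWS}")
        positives = {
            "n_cells": self.n_cells,
            "lacO_repeats": self.lacO_repeats,
            "true_kd": self.true_kd,
            "true_hill_n": self.true_hill_n,
            "photons_per_molecule": self.photons_per_molecule,
            "psf_sigma_xy": self.psf_sigma_xy,
            "psf_sigma_z": self.psf_sigma_z,
            "pixel_size": self.pixel_size,
            "z_spacing": self.z_spacing,
            "dof": self.dof,
            "cells_per_field": self.cells_per_field,
            "tile_px": self.tile_px,
        }
        for name, value in positives.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.autofluorescence_rate < 0:
            raise ValueError("autofluorescence_rate must be non-negative")
        if self.n_z < 3:
            raise ValueError("n_z must be >= 3 so an in/out-of-focus profile exists")
        if not 0.0 <= self.replicated_dot_fraction <= 1.0:
            raise ValueError("replicated_dot_fraction must lie in [0, 1]")
        if self.conc_law == "log-uniform":
            if not 0 < self.conc_low <= self.conc_high:
                raise ValueError("log-uniform law needs 0 < conc_low <= conc_high")
        elif self.conc_law == "fixed":
            if self.conc_low < 0:
                raise ValueError("fixed concentration must be non-negative")
        else:
            if self.conc_mean <= 0 or self.conc_cv <= 0:
                raise ValueError("log-normal law needs positive conc_mean and conc_cv")
        min_semi_px = min(self.cell_semi_axis_y[0], self.cell_semi_axis_x[0]) / self.pixel_size
        max_offset = self.dot_jitter_px + self.replicated_separation_px
        if max_offset >= min_semi_px:
            raise ValueError(
                "dot_jitter_px + replicated_separation_px places dots outside the "
                f"cell mask (max offset {max_offset:.1f} px vs min semi-axis {min_semi_px:.1f} px)"
            )
        grid = math.ceil(math.sqrt(self.cells_per_field))
        if 2 * max(self.cell_semi_axis_y[1], self.cell_semi_axis_x[1]) / self.pixel_size >= self.tile_px:
            raise ValueError("tile_px too small for the configured cell semi-axes")
        del grid


@dataclass
class GroundTruthCell:
    """Per-cell generating truth emitted alongside the rendered stacks."""

    cell_id: int
    field_index: int
    label: int                      # value in the field's label mask
    true_free_conc: float           # nM
    true_bound_count: int           # molecules actually rendered (both dots if replicated)
    dot_position: Tuple[float, float, float]   # (z, y, x); z in slice units, y/x in px
    is_replicated: bool
    nucleus_center: Tuple[float, float]        # (y, x) px


@dataclass
class SimulatedField:
    """One field of view: labeled stack, matched unlabeled control, label mask."""

    labeled: np.ndarray             # (n_z, H, W) float64, a.u.
    control: np.ndarray             # (n_z, H, W) float64, autofluorescence only
    mask: np.ndarray                # (H, W) uint16 label image, 0 = background


@dataclass
class SimulatedPopulation:
    fields: List[SimulatedField]
    cells: List[GroundTruthCell]
    config: SimulationConfig

    def cell_mask(self, cell: GroundTruthCell) -> np.ndarray:
        return self.fields[cell.field_index].mask == cell.label


def background_rate_per_pixel(conc_nm: float, config: SimulationConfig) -> float:
    """Diffuse-background intensity per pixel per slice for a free concentration.

    Widefield slab model: a slice integrates fluorophores over an effective
    depth ``dof``, so the per-pixel rate is
    ``photons_per_molecule x density(conc) x pixel_size^2 x dof``.
    """
    density = conc_nm * MOLECULES_PER_UM3_PER_NM      # molecules / um^3
    return config.photons_per_molecule * density * config.pixel_size**2 * config.dof


def _pixel_integrated_gaussian(n: int, mu: float, sigma: float) -> np.ndarray:
    """Integral of a unit Gaussian over unit pixel bins centred on 0..n-1."""
    edges = np.arange(n + 1, dtype=float) - 0.5
    cdf = 0.5 * (1.0 + erf((edges - mu) / (sigma * math.sqrt(2.0))))
    return np.diff(cdf)


def _sample_concentrations(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_cells
    if config.conc_law == "fixed":
        return np.full(n, float(config.conc_low))
    if config.conc_law == "log-uniform":
        return np.exp(rng.uniform(math.log(config.conc_low), math.log(config.conc_high), n))
    sigma2 = math.log(1.0 + config.conc_cv**2)
    mu = math.log(config.conc_mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), n)


def _render_dot(
    stack: np.ndarray,
    total_intensity: float,
    pos: Tuple[float, float, float],
    config: SimulationConfig,
) -> None:
    """Add a separable 3D-Gaussian dot of exactly ``total_intensity`` a.u.

    The per-axis profiles are pixel-integrated and renormalized over the
    stack extent, so the discrete voxel sum equals ``total_intensity`` to
    float precision regardless of truncation.
    """
    n_z, h, w = stack.shape
    z, y, x = pos
    sig_xy = config.psf_sigma_xy / config.pixel_size
    sig_z = config.psf_sigma_z / config.z_spacing
    gz = _pixel_integrated_gaussian(n_z, z, sig_z)
    gy = _pixel_integrated_gaussian(h, y, sig_xy)
    gx = _pixel_integrated_gaussian(w, x, sig_xy)
    kernel = gz[:, None, None] * (gy[:, None] * gx[None, :])[None, :, :]
    total = kernel.sum()
    if total <= 0:
        raise ValueError("dot position lies outside the rendered stack")
    stack += (total_intensity / total) * kernel


def simulate_population(config: SimulationConfig) -> SimulatedPopulation:
    """Render a full synthetic population with ground truth.

    Returns one :class:`SimulatedField` per group of ``cells_per_field``
    cells (cells occupy disjoint square tiles arranged on a grid), plus one
    :class:`GroundTruthCell` per cell.  Identical ``config.seed`` gives
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    concs = _sample_concentrations(config, rng)
    replicated = rng.random(config.n_cells) < config.replicated_dot_fraction

    fields: List[SimulatedField] = []
    cells: List[GroundTruthCell] = []
    tile = config.tile_px
    cell_idx = 0
    for field_index, start in enumerate(range(0, config.n_cells, config.cells_per_field)):
        chunk = range(start, min(start + config.cells_per_field, config.n_cells))
        grid = math.ceil(math.sqrt(len(chunk)))
        h = w = grid * tile
        labeled = np.zeros((config.n_z, h, w), dtype=float)
        control = np.zeros_like(labeled)
        mask = np.zeros((h, w), dtype=np.uint16)

        for k, i in enumerate(chunk):
            r, c = divmod(k, grid)
            cy = r * tile + tile / 2.0
            cx = c * tile + tile / 2.0
            ry = rng.uniform(*config.cell_semi_axis_y) / config.pixel_size
            rx = rng.uniform(*config.cell_semi_axis_x) / config.pixel_size
            yy, xx = np.mgrid[r * tile : (r + 1) * tile, c * tile : (c + 1) * tile]
            inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
            label = k + 1
            mask[r * tile : (r + 1) * tile, c * tile : (c + 1) * tile][inside] = label

            dy, dx = rng.uniform(-config.dot_jitter_px, config.dot_jitter_px, 2)
            dz = rng.uniform(1.5, config.n_z - 2.5)
            if ((dy / ry) ** 2 + (dx / rx) ** 2) >= 1.0:
                raise ValueError("dot placed outside the cell mask")
            pos = (dz, cy + dy, cx + dx)

            theta = occupancy(concs[i], config.true_kd, config.true_hill_n)
            n_bound = int(round(2 * config.lacO_repeats * theta))
            total_bound = n_bound
            if n_bound > 0:
                _render_dot(labeled, config.photons_per_molecule * n_bound, pos, config)
            if replicated[i] and n_bound > 0:
                angle = rng.uniform(0, 2 * math.pi)
                sy = pos[1] + config.replicated_separation_px * math.sin(angle)
                sx = pos[2] + config.replicated_separation_px * math.cos(angle)
                if (((sy - cy) / ry) ** 2 + ((sx - cx) / rx) ** 2) >= 1.0:
                    raise ValueError("replicated dot placed outside the cell mask")
                _render_dot(labeled, config.photons_per_molecule * n_bound, (pos[0], sy, sx), config)
                total_bound = 2 * n_bound

            bg = background_rate_per_pixel(concs[i], config)
            sub_l = labeled[:, r * tile : (r + 1) * tile, c * tile : (c + 1) * tile]
            sub_c = control[:, r * tile : (r + 1) * tile, c * tile : (c + 1) * tile]
            sub_l[:, inside] += bg + config.autofluorescence_rate
            sub_c[:, inside] += config.autofluorescence_rate

            cells.append(
                GroundTruthCell(
                    cell_id=cell_idx,
                    field_index=field_index,
                    label=label,
                    true_free_conc=float(concs[i]),
                    true_bound_count=total_bound,
                    dot_position=pos,
                    is_replicated=bool(replicated[i] and n_bound > 0),
                    nucleus_center=(cy, cx),
                )
            )
            cell_idx += 1

        if config.noise:
            labeled = rng.poisson(labeled).astype(float)
            control = rng.poisson(control).astype(float)
        fields.append(SimulatedField(labeled=labeled, control=control, mask=mask))

    return SimulatedPopulation(fields=fields, cells=cells, config=config)
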