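"""Chromosome-dot quantification from z-stacks.

Implements the single-cell measurement: build a max-intensity composite to
locate the dot, integrate the dot in a small disc at every z (local annulus
background subtracted), measure the free-protein background in a ring
enclosing the dot at the best-focus slice, discard extra-bright (replicated)
dots, and convert intensities to molecule counts and free concentration via
a saturated-array calibration:

    dot_total / background_total = N_bound / (Concentration x area x DOF)

where the depth of field (DOF) converts the in-focus ring area into an
effective collection volume for the diffuse pool.  The resulting
concentration is the free-plus-transiently-nonspecifically-bound pool in the
nucleus near the array, which is what the Hill fit's x-axis means.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.feature import peak_local_max

from .constants import MOLECULES_PER_UM3_PER_NM
from .simulate import SimulatedPopulation

__all__ = [
    "QuantConfig",
    "CellRecord",
    "SaturationWarning",
    "estimate_autofluorescence",
    "max_composite",
    "detect_dot",
    "dot_profile",
    "ring_background",
    "quantify_cell",
    "quantify_population",
    "discard_bright",
    "discard_bright_by_bin",
    "calibrate_saturation",
    "estimate_concentration",
]


class SaturationWarning(UserWarning):
    """Raised when a supposedly saturated population fails the correlation check."""


@dataclass
class QuantConfig:
    """Geometry and calibration constants of the quantification.

    All radii are in pixels; ``ring_outer > ring_inner > dot_radius`` so the
    background annulus never overlaps the integration disc.
    """

    dof: float = 1.6                    # um, effective depth of field
    pixel_size: float = 0.1             # um / px
    dot_radius: float = 3.7             # px, dot integration disc
    ring_inner: float = 4.0             # px
    ring_outer: float = 8.0             # px
    bright_discard_factor: float = 1.8
    autofluorescence_level: float = 0.0  # a.u./px, from unlabeled control
    prominence_sigma: float = 5.0       # dot detection threshold in noise sigmas
    peak_min_distance: int = 3          # px, multiplicity detection
    ring_outlier_factor: float = 2.0    # contamination check on raw ring pixels
    min_ring_pixels: int = 8

    def __post_init__(self):
        if not (self.ring_outer > self.ring_inner > self.dot_radius > 0):
            raise ValueError("need ring_outer > ring_inner > dot_radius > 0")
        for name in ("dof", "pixel_size", "prominence_sigma", "ring_outlier_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.autofluorescence_level < 0:
            raise ValueError("autofluorescence_level must be non-negative")


@dataclass
class CellRecord:
    """One cell's measurement; ``nan`` fields are filled by later stages."""

    cell_id: int
    field_index: int = -1
    label: int = -1
    dot_total: float = float("nan")     # a.u., background- and autofluor-corrected
    best_z: int = -1
    ring_total: float = float("nan")    # a.u., autofluor-corrected annulus sum at best z
    ring_area: float = float("nan")     # um^2
    ring_outer_used: float = float("nan")
    n_peaks: int = 0
    dot_detected: bool = False
    clipped: bool = False               # negative corrected dot clipped to zero
    usable: bool = True
    note: str = ""
    discarded: bool = False
    n_bound_est: float = float("nan")   # molecules
    free_conc_est: float = float("nan")  # nM ([TF]' = diffusive + transiently bound)
    occupancy_est: float = float("nan")
    occupancy_outlier: bool = False


def estimate_autofluorescence(
    control_stacks: Sequence[np.ndarray], masks: Sequence[np.ndarray]
) -> float:
    """Mean per-pixel intensity inside cell masks of the unlabeled control."""
    total = 0.0
    count = 0
    for stack, mask in zip(control_stacks, masks):
        inside = np.asarray(mask) > 0
        if not inside.any():
            continue
        vals = np.asarray(stack)[:, inside]
        total += float(vals.sum())
        count += vals.size
    if count == 0:
        raise ValueError("no in-mask pixels in control stacks")
    return total / count


def max_composite(stack: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """2D composite: per-pixel maximum across z inside the mask, 0 outside."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be (n_z, H, W) with at least one slice")
    inside = np.asarray(mask) > 0
    if not inside.any():
        raise ValueError("empty cell mask")
    comp = stack.max(axis=0)
    comp[~inside] = 0.0
    return comp


def detect_dot(
    composite: np.ndarray, mask: np.ndarray, config: Optional[QuantConfig] = None
) -> Tuple[Optional[Tuple[int, int]], int]:
    """Locate the chromosome dot on a max composite.

    Returns ``(pos, n_peaks)`` where ``pos`` is the (y, x) of the brightest
    qualifying local maximum or ``None`` when no pixel rises above the local
    background by more than ``prominence_sigma`` robust noise sigmas (the
    dim-dot regime), and ``n_peaks`` counts comparably prominent maxima
    (> 1 signals a possible replicated pair).
    """
    config = config or QuantConfig()
    inside = np.asarray(mask) > 0
    if not inside.any():
        raise ValueError("empty cell mask")
    vals = composite[inside]
    med = float(np.median(vals))
    noise = 1.4826 * float(np.median(np.abs(vals - med)))
    masked = np.where(inside, composite, -np.inf)
    peak_pos = np.unravel_index(int(np.argmax(masked)), composite.shape)
    peak_val = composite[peak_pos]
    prominence = peak_val - med
    if prominence <= config.prominence_sigma * noise or prominence <= 0:
        return None, 0
    threshold = med + max(config.prominence_sigma * noise, 0.3 * prominence)
    peaks = peak_local_max(
        composite,
        min_distance=config.peak_min_distance,
        threshold_abs=threshold,
        labels=inside.astype(int),
        exclude_border=False,
    )
    return (int(peak_pos[0]), int(peak_pos[1])), max(len(peaks), 1)


def _distance_grid(shape: Tuple[int, int], pos: Tuple[int, int]) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return np.sqrt((yy - pos[0]) ** 2 + (xx - pos[1]) ** 2)


def _shrunk_ring(
    dist: np.ndarray, mask: np.ndarray, config: QuantConfig
) -> Tuple[Optional[np.ndarray], float]:
    """Largest annulus (inner fixed, outer shrinkable) fully inside the mask."""
    inside = np.asarray(mask) > 0
    for outer in np.arange(config.ring_outer, config.ring_inner + 0.49, -0.5):
        ring = (dist >= config.ring_inner) & (dist <= outer)
        if ring.sum() < config.min_ring_pixels:
            break
        if inside[ring].all():
            return ring, float(outer)
    return None, float("nan")


@dataclass
class DotProfile:
    dot_intensity: np.ndarray   # per z, a.u., local background subtracted
    local_background: np.ndarray  # per z, a.u. per pixel (autofluor-corrected)
    best_z: int

    @property
    def dot_total(self) -> float:
        """Peak volume: per-z dot intensity summed over the whole stack."""
        return float(self.dot_intensity.sum())


def dot_profile(
    stack: np.ndarray,
    pos: Tuple[int, int],
    config: QuantConfig,
    mask: Optional[np.ndarray] = None,
) -> DotProfile:
    """Per-z intensity scan of the dot at ``pos``.

    At each slice the dot is the sum over a disc of radius ``dot_radius``
    minus the local background (annulus mean) times the disc area, after
    subtracting the autofluorescence floor everywhere.  The z with the
    largest dot intensity is the best-focus slice.
    """
    stack = np.asarray(stack, dtype=float)
    n_z, h, w = stack.shape
    dist = _distance_grid((h, w), pos)
    disc = dist <= config.dot_radius
    r = config.dot_radius
    y, x = pos
    if y - r < -0.5 or x - r < -0.5 or y + r > h - 0.5 or x + r > w - 0.5:
        raise ValueError("dot integration disc clipped by the image edge")
    if mask is not None:
        ring, _ = _shrunk_ring(dist, mask, config)
    else:
        ring = (dist >= config.ring_inner) & (dist <= config.ring_outer)
    if ring is None or not ring.any():
        raise ValueError("no valid background annulus around the dot")
    corrected = stack - config.autofluorescence_level
    disc_sums = corrected[:, disc].sum(axis=1)
    bg_means = corrected[:, ring].mean(axis=1)
    dot = disc_sums - bg_means * disc.sum()
    return DotProfile(
        dot_intensity=dot,
        local_background=bg_means,
        best_z=int(np.argmax(dot)),
    )


@dataclass
class RingMeasurement:
    ring_total: float       # a.u., autofluorescence-subtracted
    ring_area: float        # um^2
    outer_used: float       # px
    contaminated: bool


def ring_background(
    stack: np.ndarray,
    pos: Tuple[int, int],
    best_z: int,
    mask: np.ndarray,
    config: QuantConfig,
) -> RingMeasurement:
    """Integrated free-protein background in an annulus enclosing the dot.

    The annulus is taken at the best-focus slice; if the configured outer
    radius leaves the cell mask the ring is shrunk, and if no valid ring
    remains a ``ValueError`` marks the cell unusable.  A raw-intensity
    outlier inside the ring (for instance a second, separated dot) flags the
    measurement as contaminated.
    """
    stack = np.asarray(stack, dtype=float)
    dist = _distance_grid(stack.shape[1:], pos)
    ring, outer_used = _shrunk_ring(dist, mask, config)
    if ring is None:
        raise ValueError("background ring cannot be fit inside the cell mask")
    raw = stack[best_z][ring]
    med = float(np.median(raw))
    contaminated = bool(
        raw.max() > config.ring_outlier_factor * med + 10.0 * math.sqrt(max(med, 0.0) + 1.0)
    )
    total = float((raw - config.autofluorescence_level).sum())
    area = ring.sum() * config.pixel_size**2
    return RingMeasurement(ring_total=total, ring_area=area, outer_used=outer_used, contaminated=contaminated)


def quantify_cell(
    stack: np.ndarray,
    mask: np.ndarray,
    config: QuantConfig,
    cell_id: int = 0,
    field_index: int = -1,
    label: int = -1,
) -> CellRecord:
    """Run the full single-cell measurement; failures mark the cell unusable.

    When no dot passes the prominence test (dim-dot regime) the measurement
    falls back to the brightest in-mask pixel so the cell still contributes a
    near-zero dot intensity and a background concentration to the binding
    curve.
    """
    rec = CellRecord(cell_id=cell_id, field_index=field_index, label=label)
    try:
        comp = max_composite(stack, mask)
        pos, n_peaks = detect_dot(comp, mask, config)
        rec.dot_detected = pos is not None
        rec.n_peaks = n_peaks
        if pos is None:
            # dim-dot regime: fall back to the brightest pixel that still has
            # clearance for the background ring inside the mask
            inside = np.asarray(mask) > 0
            clearance = ndimage.distance_transform_edt(inside)
            candidates = clearance >= config.ring_inner + 1.0
            if not candidates.any():
                candidates = clearance == clearance.max()
            masked = np.where(candidates, comp, -np.inf)
            pos = tuple(int(v) for v in np.unravel_index(int(np.argmax(masked)), comp.shape))
        profile = dot_profile(stack, pos, config, mask=mask)
        ring = ring_background(stack, pos, profile.best_z, mask, config)
        rec.best_z = profile.best_z
        dot_total = profile.dot_total
        if dot_total < 0:
            rec.clipped = True
            dot_total = 0.0
        rec.dot_total = dot_total
        rec.ring_total = max(ring.ring_total, 0.0)
        rec.ring_area = ring.ring_area
        rec.ring_outer_used = ring.outer_used
        if ring.contaminated:
            rec.usable = False
            rec.note = "ring contaminated"
    except ValueError as exc:
        rec.usable = False
        rec.note = str(exc)
    return rec


def quantify_population(
    population_or_fields: Union[SimulatedPopulation, Sequence],
    config: QuantConfig,
) -> pd.DataFrame:
    """Quantify every labeled cell in every field; one row per cell.

    Accepts a :class:`~froskd.simulate.SimulatedPopulation` or a sequence of
    ``(stack, mask)`` pairs.
    """
    if isinstance(population_or_fields, SimulatedPopulation):
        pairs = [(f.labeled, f.mask) for f in population_or_fields.fields]
    else:
        pairs = [
            (f[0], f[1]) if isinstance(f, (tuple, list)) else (f.labeled, f.mask)
            for f in population_or_fields
        ]
    records: List[CellRecord] = []
    cell_id = 0
    for field_index, (stack, mask) in enumerate(pairs):
        for label in np.unique(np.asarray(mask)):
            if label == 0:
                continue
            rec = quantify_cell(
                np.asarray(stack),
                np.asarray(mask) == label,
                config,
                cell_id=cell_id,
                field_index=field_index,
                label=int(label),
            )
            records.append(rec)
            cell_id += 1
    return pd.DataFrame([rec.__dict__ for rec in records])


def _as_frame(records: Union[pd.DataFrame, Sequence[CellRecord]]) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame([r.__dict__ for r in records])


def discard_bright(
    records: Union[pd.DataFrame, Sequence[CellRecord]], factor: float = 1.8
) -> pd.DataFrame:
    """Flag dots brighter than ``factor`` times the population's robust average.

    The robust average is the median ``dot_total`` of usable, not-yet-
    discarded records, which a bright minority (replicated, co-localized
    arrays at ~2x brightness) barely moves — so a second application changes
    nothing.  Intended for populations of comparable expected brightness;
    see :func:`discard_bright_by_bin` for a mixed-concentration curve.
    """
    df = _as_frame(records)
    if len(df) < 3:
        raise ValueError("need at least 3 records to define an average level")
    kept = df[df["usable"] & ~df["discarded"]]
    if len(kept) == 0:
        raise ValueError("no usable, undiscarded records left")
    med = float(kept["dot_total"].median())
    if med > 0:
        flag = df["usable"] & ~df["discarded"] & (df["dot_total"] > factor * med)
        df.loc[flag, "discarded"] = True
    if not (df["usable"] & ~df["discarded"]).any():
        raise ValueError("bright-dot filter discarded the entire population")
    return df


def discard_bright_by_bin(
    records: Union[pd.DataFrame, Sequence[CellRecord]],
    bin_width: float = 100.0,
    factor: float = 1.8,
    conc_column: str = "free_conc_est",
    min_median_occupancy: float = 0.5,
) -> pd.DataFrame:
    """Apply the bright-dot filter within concentration bins.

    On a binding curve the "average level" is only meaningful among cells at
    comparable free concentration, so the 1.8x cut is taken against the
    median of each ``bin_width``-nM bin.  It is applied only in bins whose
    median occupancy is at least ``min_median_occupancy``: above half
    saturation a replicated (doubled) dot provably exceeds the physical
    single-array ceiling, whereas lower down the cut cannot distinguish a
    replicated pair from the bin's own legitimate spread (a steep Hill curve
    covers more than ``factor``-fold intensity inside one bin) or from shot
    noise around a near-zero median.  Bins with fewer than 3 usable cells
    are left untouched.
    """
    df = _as_frame(records)
    if conc_column not in df or df[conc_column].isna().all():
        raise ValueError("records need concentration estimates before binwise discard")
    bins = np.floor(df[conc_column] / bin_width)
    for _, idx in df.groupby(bins).groups.items():
        sub = df.loc[idx]
        kept = sub[sub["usable"] & ~sub["discarded"]]
        if len(kept) < 3:
            continue
        if "occupancy_est" in kept and float(kept["occupancy_est"].median()) < min_median_occupancy:
            continue
        med = float(kept["dot_total"].median())
        if med > 0:
            flag = sub["usable"] & ~sub["discarded"] & (sub["dot_total"] > factor * med)
            df.loc[sub.index[flag.to_numpy()], "discarded"] = True
    return df


def calibrate_saturation(
    records: Union[pd.DataFrame, Sequence[CellRecord]],
    lacO_repeats: int,
    factor: float = 1.8,
    corr_threshold: float = 0.5,
    min_records: int = 10,
) -> float:
    """Intensity per molecule from a population with saturated binding.

    Under saturation every array carries ``2 x lacO_repeats`` molecules, so
    the mean (filtered) dot intensity divided by that count calibrates the
    scale.  Saturation itself is checked by requiring dot and background
    intensities to be uncorrelated; a large Pearson ``|R|`` raises a
    :class:`SaturationWarning`.
    """
    df = discard_bright(records, factor=factor)
    kept = df[df["usable"] & ~df["discarded"]]
    if len(kept) < min_records:
        raise ValueError(f"need at least {min_records} usable records, got {len(kept)}")
    dot = kept["dot_total"].to_numpy()
    ring = kept["ring_total"].to_numpy()
    # an essentially constant dot intensity is saturated by definition; only
    # a meaningful relative spread can evidence concentration dependence
    dot_cv = np.std(dot) / abs(np.mean(dot)) if np.mean(dot) != 0 else 0.0
    if dot_cv > 0.02 and np.std(ring) > 0:
        r, _ = stats.pearsonr(dot, ring)
        if abs(r) > corr_threshold:
            warnings.warn(
                f"dot and background intensities correlate (R = {r:.2f}); "
                "the population may not be saturated",
                SaturationWarning,
            )
    return float(dot.mean()) / (2 * lacO_repeats)


def estimate_concentration(
    records: Union[pd.DataFrame, Sequence[CellRecord]],
    saturated_reference: float,
    config: QuantConfig,
    lacO_repeats: int,
) -> pd.DataFrame:
    """Convert intensities to molecule counts, occupancy and free concentration.

    ``saturated_reference`` is the intensity per molecule from
    :func:`calibrate_saturation`.  The ring intensity divided by it counts
    free molecules in the ring's collection volume (``ring_area x DOF``);
    dividing by that volume and by 0.6022 molecules/um^3/nM gives nM.
    """
    if saturated_reference <= 0:
        raise ValueError("saturated_reference must be positive")
    df = _as_frame(records)
    if (df["usable"] & (df["ring_area"] <= 0)).any():
        raise ValueError("zero ring area in usable record")
    df["n_bound_est"] = df["dot_total"] / saturated_reference
    n_free = df["ring_total"] / saturated_reference
    density = n_free / (df["ring_area"] * config.dof)          # molecules / um^3
    df["free_conc_est"] = (density / MOLECULES_PER_UM3_PER_NM).clip(lower=0.0)
    df["occupancy_est"] = df["n_bound_est"] / (2 * lacO_repeats)
    df["occupancy_outlier"] = df["occupancy_est"] > 1.05
    return df
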