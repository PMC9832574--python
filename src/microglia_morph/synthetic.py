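"""Synthetic two-channel microglia fields with full ground truth.

Real acquisitions show tdTomato-expressing microglia in the red channel and
SYTOX-stained nucleic-acid debris as bright green puncta.  This module
renders parameterized stand-ins for both so that segmentation, morphometry,
classification and phagocytosis analysis can all be exercised against known
truth: every rendered field comes with its ground-truth label mask, a class
table and a particle table, and time-lapses carry per-frame truth.

Seven morphology archetypes are modelled after the classes observed in
neuron–glia cultures: ``round``, ``inflamed_ameboid``, ``fried_egg``,
``inflamed_fried_egg``, ``hypertrophic``, ``inflamed_hypertrophic`` and
``bipolar``.  The verbal class descriptions are qualitative, so the archetype
geometry here is this package's own construction: soma outlines are radial
functions sampled at pixel centres, processes are capsules (constant-width
segments) whose centrelines pass through the soma centre, and side branches
attach part-way along a process.  Inflamed variants double the soma area of
their cognate base shape; the inflamed hypertrophic additionally doubles
process length and carries two extra branch points.

Rendering is deterministic: identical specs (including seeds) give
bit-identical pixel arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from .types import DEFAULT_PIXEL_SIZE_UM, Field

MORPHOLOGY_CLASSES = (
    "round",
    "inflamed_ameboid",
    "fried_egg",
    "inflamed_fried_egg",
    "hypertrophic",
    "inflamed_hypertrophic",
    "bipolar",
)

_SQRT2 = float(np.sqrt(2.0))

# Internal archetype geometry (micrometres where dimensional).  aspect is the
# soma long/short axis ratio; wave_amp/wave_lobes shape the irregular
# ("ameboid") soma outline.  branch_points is the TOTAL number of skeleton
# junctions of the rendered cell, including the central junction formed where
# three or more process centrelines meet inside the soma.
_ARCHETYPES: dict[str, dict] = {
    "round": dict(
        soma_radius_um=9.0, aspect=1.0, wave_amp=0.0, wave_lobes=0,
        n_processes=0, process_length_um=0.0, process_width_um=0.0,
        branch_points=0,
    ),
    "inflamed_ameboid": dict(
        soma_radius_um=9.0 * _SQRT2, aspect=1.0, wave_amp=0.16, wave_lobes=3,
        n_processes=0, process_length_um=0.0, process_width_um=0.0,
        branch_points=0,
    ),
    "fried_egg": dict(
        soma_radius_um=16.0, aspect=1.4, wave_amp=0.05, wave_lobes=4,
        n_processes=0, process_length_um=0.0, process_width_um=0.0,
        branch_points=0,
    ),
    "inflamed_fried_egg": dict(
        soma_radius_um=16.0 * _SQRT2, aspect=1.15, wave_amp=0.12, wave_lobes=5,
        n_processes=0, process_length_um=0.0, process_width_um=0.0,
        branch_points=0,
    ),
    "hypertrophic": dict(
        soma_radius_um=7.0, aspect=1.0, wave_amp=0.0, wave_lobes=0,
        n_processes=3, process_length_um=25.0, process_width_um=2.2,
        branch_points=3,
    ),
    "inflamed_hypertrophic": dict(
        soma_radius_um=7.0 * _SQRT2, aspect=1.0, wave_amp=0.0, wave_lobes=0,
        n_processes=3, process_length_um=50.0, process_width_um=2.8,
        branch_points=5,
    ),
    "bipolar": dict(
        soma_radius_um=6.5, aspect=1.6, wave_amp=0.0, wave_lobes=0,
        n_processes=2, process_length_um=30.0, process_width_um=2.0,
        branch_points=0,
    ),
}

#: Peak intensity of rendered cells / particles (arbitrary units).
CELL_AMPLITUDE = 100.0
PARTICLE_AMPLITUDE = 150.0


@dataclass(frozen=True)
class ShapeSpec:
    """Parameterized description of one rendered microglia."""

    class_name: str
    soma_radius_um: float
    n_processes: int = 0
    process_length_um: float = 0.0
    process_width_um: float = 0.0
    branch_points: int = 0
    intensity_profile: str = "bright_center"
    seed: int = 0
    # generator-internal shape controls (per-class defaults when None)
    aspect: float | None = None
    wave_amp: float | None = None
    wave_lobes: int | None = None

    def __post_init__(self) -> None:
        if self.class_name not in MORPHOLOGY_CLASSES:
            raise ValueError(
                f"unknown morphology class {self.class_name!r}; "
                f"expected one of {MORPHOLOGY_CLASSES}"
            )
        if self.soma_radius_um <= 0:
            raise ValueError("soma_radius_um must be > 0")
        if min(self.n_processes, self.process_length_um,
               self.process_width_um, self.branch_points) < 0:
            raise ValueError("process parameters and branch_points must be >= 0")
        if self.intensity_profile not in ("uniform", "bright_center"):
            raise ValueError("intensity_profile must be 'uniform' or 'bright_center'")
        if self.class_name == "bipolar":
            if self.n_processes != 2:
                raise ValueError("bipolar cells have exactly 2 processes")
            if self.branch_points != 0:
                raise ValueError("bipolar processes are unbranched (branch_points=0)")
        if self.class_name in ("round", "fried_egg", "inflamed_ameboid",
                               "inflamed_fried_egg"):
            if self.n_processes != 0:
                raise ValueError(f"{self.class_name} cells have no processes")
            if self.branch_points != 0:
                raise ValueError(f"{self.class_name} cells have no branch points")
        if self.n_processes >= 3 and self.branch_points < 1:
            raise ValueError(
                "three or more processes meet in a central junction; "
                "branch_points must be >= 1"
            )
        if self.n_processes > 0 and (self.process_length_um <= 0
                                     or self.process_width_um <= 0):
            raise ValueError("processes require positive length and width")

    def _geometry(self) -> dict:
        base = _ARCHETYPES[self.class_name]
        return dict(
            aspect=self.aspect if self.aspect is not None else base["aspect"],
            wave_amp=self.wave_amp if self.wave_amp is not None else base["wave_amp"],
            wave_lobes=(self.wave_lobes if self.wave_lobes is not None
                        else base["wave_lobes"]),
        )


def archetype(class_name: str, seed: int = 0, **overrides) -> ShapeSpec:
    """Default :class:`ShapeSpec` for one of the seven morphology classes."""
    base = _ARCHETYPES[class_name]
    kwargs = dict(
        class_name=class_name,
        soma_radius_um=base["soma_radius_um"],
        n_processes=base["n_processes"],
        process_length_um=base["process_length_um"],
        process_width_um=base["process_width_um"],
        branch_points=base["branch_points"],
        seed=seed,
    )
    kwargs.update(overrides)
    return ShapeSpec(**kwargs)


@dataclass(frozen=True)
class ParticleSpec:
    """A SYTOX-like punctum: position (row, col) in px, radius in µm.

    ``engulfed_by`` names the host cell (1-based label in the field's cell
    list) for engulfed particles; ``None`` marks free debris.  An engulfed
    particle with ``position=None`` is placed at its host's soma centre.
    """

    radius_um: float
    position: tuple[float, float] | None = None
    engulfed_by: int | None = None

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("particle radius must be > 0")
        if self.engulfed_by is None and self.position is None:
            raise ValueError("free particles need an explicit position")


@dataclass(frozen=True)
class FieldSpec:
    """Full description of one synthetic acquisition."""

    image_size_px: tuple[int, int]
    cells: tuple[tuple[ShapeSpec, tuple[float, float]], ...] = ()
    particles: tuple[ParticleSpec, ...] = ()
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    background_level: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(
            (spec, (float(pos[0]), float(pos[1]))) for spec, pos in self.cells))
        object.__setattr__(self, "particles", tuple(self.particles))
        nr, nc = self.image_size_px
        if nr <= 0 or nc <= 0:
            raise ValueError("image_size_px must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for spec, (r, c) in self.cells:
            if not (0 <= r < nr and 0 <= c < nc):
                raise ValueError(
                    f"cell centre {(r, c)} lies outside the {nr}x{nc} image"
                )
        for p in self.particles:
            if p.engulfed_by is not None and not (
                    1 <= p.engulfed_by <= len(self.cells)):
                raise ValueError(
                    f"engulfed_by={p.engulfed_by} does not name a cell "
                    f"(field has {len(self.cells)})"
                )


@dataclass
class SyntheticField:
    """Rendered field plus its complete ground truth."""

    field: Field
    truth_mask: np.ndarray           # cell label mask
    particle_mask: np.ndarray        # particle label mask (green channel)
    cells: pd.DataFrame              # cell_id, class_name, area_px, centroid
    particles: pd.DataFrame          # particle_id, engulfed_by, area_px, centroid


# ---------------------------------------------------------------------------
# cell rendering

def _soma_radius_at(theta: np.ndarray, r0: float, aspect: float,
                    wave_amp: float, wave_lobes: int, phase: float) -> np.ndarray:
    """Radial soma outline r(theta); area-preserving elliptic stretch + waves."""
    a = r0 * np.sqrt(aspect)
    b = r0 / np.sqrt(aspect)
    ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    if wave_amp > 0 and wave_lobes > 0:
        ell = ell * (1.0 + wave_amp * np.sin(wave_lobes * theta + phase))
    return ell


def render_cell(spec: ShapeSpec, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM):
    """Render one cell onto a tight patch.

    Returns
    -------
    mask : 2-D bool array
        Connected binary shape of the cell.
    intensity : 2-D float array
        Non-negative intensity patch (0 outside the mask).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    geom = spec._geometry()
    rng = np.random.default_rng(spec.seed)
    phase = float(rng.uniform(0, 2 * np.pi))
    # orientation of the first process / soma major axis
    theta0 = float(rng.uniform(0, 2 * np.pi)) if spec.class_name != "round" else 0.0

    reach = spec.soma_radius_um * np.sqrt(geom["aspect"]) * (1 + geom["wave_amp"])
    if spec.n_processes:
        reach = max(reach, spec.soma_radius_um + spec.process_length_um
                    + spec.process_width_um)
    half = int(np.ceil(reach / pixel_size_um)) + 2
    n = 2 * half + 1
    # physical coordinates of pixel centres, origin at the patch centre
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    x = (xx - half) * pixel_size_um
    y = (yy - half) * pixel_size_um
    # rotate into the cell frame so the soma major axis lies along +x
    xr = x * np.cos(-theta0) - y * np.sin(-theta0)
    yr = x * np.sin(-theta0) + y * np.cos(-theta0)
    theta = np.arctan2(yr, xr)
    rr = np.hypot(xr, yr)

    mask = rr <= _soma_radius_at(theta, spec.soma_radius_um, geom["aspect"],
                                 geom["wave_amp"], geom["wave_lobes"], phase)

    for seg_a, seg_b, width in _process_segments(spec, theta0):
        mask |= _capsule(x, y, seg_a, seg_b, width / 2.0)

    if spec.intensity_profile == "uniform":
        intensity = np.where(mask, CELL_AMPLITUDE, 0.0)
    else:
        sigma = spec.soma_radius_um / 2.0
        bump = np.exp(-(x ** 2 + y ** 2) / (2 * sigma ** 2))
        intensity = np.where(mask, CELL_AMPLITUDE * (0.6 + 0.8 * bump), 0.0)

    # crop to the bounding box (1-px margin)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sl = (slice(max(rows[0] - 1, 0), rows[-1] + 2),
          slice(max(cols[0] - 1, 0), cols[-1] + 2))
    return mask[sl], intensity[sl]


def _process_segments(spec: ShapeSpec, theta0: float):
    """Yield (start_xy, end_xy, width) for process trunks and side branches.

    Trunk centrelines start at the patch origin so that, for three or more
    processes, thinning merges them into a single central junction.  Side
    branches attach at staggered fractions of the trunk's free length; the
    total junction count (central + side) equals ``spec.branch_points``.
    """
    if spec.n_processes == 0:
        return
    r0, L, w = spec.soma_radius_um, spec.process_length_um, spec.process_width_um
    if spec.class_name == "bipolar":
        angles = [theta0, theta0 + np.pi]
    else:
        angles = [theta0 + 2 * np.pi * k / spec.n_processes
                  for k in range(spec.n_processes)]
    trunks = []
    for ang in angles:
        u = np.array([np.cos(ang), np.sin(ang)])
        a = np.zeros(2)
        b = u * (r0 + L)
        trunks.append((a, b, u, ang))
        yield a, b, w

    n_side = spec.branch_points - (1 if spec.n_processes >= 3 else 0)
    fractions = (0.55, 0.75, 0.40, 0.65, 0.85, 0.50)
    for j in range(n_side):
        a0, b0, u, ang = trunks[j % len(trunks)]
        f = fractions[j % len(fractions)]
        attach = u * (r0 + f * L)
        side_ang = ang + (0.8 if (j // len(trunks)) % 2 == 0 else -0.8)
        v = np.array([np.cos(side_ang), np.sin(side_ang)])
        yield attach, attach + v * max(0.35 * L, 4.0), w


def _capsule(x, y, a, b, radius):
    """Pixels within ``radius`` of segment a-b (coordinates in µm)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.hypot(x - a[0], y - a[1]) <= radius
    t = ((x - a[0]) * ab[0] + (y - a[1]) * ab[1]) / denom
    t = np.clip(t, 0.0, 1.0)
    px = a[0] + t * ab[0]
    py = a[1] + t * ab[1]
    return np.hypot(x - px, y - py) <= radius


# ---------------------------------------------------------------------------
# field rendering

def _patch_window(shape_px: tuple[int, int], patch_shape: tuple[int, int],
                  centre: tuple[float, float]):
    """Slices placing a patch with its centre at ``centre`` on an image.

    Returns (image row slice, image col slice, patch row slice, patch col
    slice); raises if the patch falls fully outside the image.
    """
    pr, pc = patch_shape
    r0 = int(round(centre[0])) - pr // 2
    c0 = int(round(centre[1])) - pc // 2
    nr, nc = shape_px
    rs = slice(max(r0, 0), min(r0 + pr, nr))
    cs = slice(max(c0, 0), min(c0 + pc, nc))
    if rs.start >= rs.stop or cs.start >= cs.stop:
        raise ValueError(f"patch centred at {centre} falls fully outside the image")
    return (rs, cs,
            slice(rs.start - r0, rs.stop - r0),
            slice(cs.start - c0, cs.stop - c0))


def render_field(spec: FieldSpec) -> SyntheticField:
    """Render a two-channel field with ground-truth masks and tables.

    Red channel: cells; green channel: particles.  Engulfed particles must lie
    strictly inside their host cell's mask, otherwise rendering fails.
    """
    nr, nc = spec.image_size_px
    red = np.zeros((nr, nc))
    green = np.zeros((nr, nc))
    truth = np.zeros((nr, nc), dtype=np.int32)

    cell_rows = []
    for cell_id, (shape, pos) in enumerate(spec.cells, start=1):
        mask, inten = render_cell(shape, spec.pixel_size_um)
        rs, cs, prs, pcs = _patch_window((nr, nc), mask.shape, pos)
        m = mask[prs, pcs]
        if not spec.allow_overlap and np.any(truth[rs, cs][m] != 0):
            raise ValueError(
                f"cell {cell_id} overlaps a previously placed cell; "
                "set allow_overlap=True to permit this"
            )
        truth[rs, cs][m] = cell_id
        region = red[rs, cs]
        region[m] = np.maximum(region[m], inten[prs, pcs][m])
        com = np.argwhere(truth == cell_id).mean(axis=0)
        cell_rows.append(dict(
            cell_id=cell_id, class_name=shape.class_name,
            area_px=int((truth == cell_id).sum()),
            centroid_row=float(com[0]), centroid_col=float(com[1]),
        ))

    particle_mask = np.zeros((nr, nc), dtype=np.int32)
    particle_rows = []
    for pid, part in enumerate(spec.particles, start=1):
        if part.position is not None:
            pos = part.position
        else:
            host = cell_rows[part.engulfed_by - 1]
            pos = (host["centroid_row"], host["centroid_col"])
        rad_px = part.radius_um / spec.pixel_size_um
        half = int(np.ceil(rad_px)) + 1
        yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
        disk = np.hypot(yy, xx) <= rad_px
        rs, cs, prs, pcs = _patch_window((nr, nc), disk.shape, pos)
        m = disk[prs, pcs]
        if part.engulfed_by is not None:
            host_px = truth[rs, cs][m]
            if not np.all(host_px == part.engulfed_by):
                raise ValueError(
                    f"particle {pid} is not strictly inside cell "
                    f"{part.engulfed_by}"
                )
        particle_mask[rs, cs][m] = pid
        region = green[rs, cs]
        region[m] = np.maximum(region[m], PARTICLE_AMPLITUDE)
        com = np.argwhere(particle_mask == pid).mean(axis=0)
        particle_rows.append(dict(
            particle_id=pid,
            engulfed_by=part.engulfed_by if part.engulfed_by is not None else 0,
            radius_um=part.radius_um,
            area_px=int((particle_mask == pid).sum()),
            centroid_row=float(com[0]), centroid_col=float(com[1]),
        ))

    rng = np.random.default_rng(spec.seed)
    red = red + spec.background_level
    green = green + spec.background_level
    if spec.noise_sd > 0:
        red = red + rng.normal(0, spec.noise_sd, red.shape)
        green = green + rng.normal(0, spec.noise_sd, green.shape)
        np.clip(red, 0, None, out=red)
        np.clip(green, 0, None, out=green)

    return SyntheticField(
        field=Field(red=red, green=green, pixel_size_um=spec.pixel_size_um),
        truth_mask=truth,
        particle_mask=particle_mask,
        cells=pd.DataFrame(cell_rows, columns=[
            "cell_id", "class_name", "area_px", "centroid_row", "centroid_col"]),
        particles=pd.DataFrame(particle_rows, columns=[
            "particle_id", "engulfed_by", "radius_um", "area_px",
            "centroid_row", "centroid_col"]),
    )


def render_timelapse(spec: FieldSpec, n_frames: int,
                     motion: dict[int, tuple[float, float]] | None = None,
                     shrink_rate: float = 0.0) -> list[SyntheticField]:
    """Render an ordered time-lapse with per-frame ground truth.

    ``motion`` maps cell id -> constant (d_row, d_col) displacement in pixels
    per frame.  Engulfed particles translate with their host and their area
    decays geometrically by ``shrink_rate`` per frame (radius scales by
    ``sqrt(1 - shrink_rate)``); free particles are static.
    """
    if n_frames < 2:
        raise ValueError("a time-lapse needs n_frames >= 2")
    if not 0 <= shrink_rate < 1:
        raise ValueError("shrink_rate must lie in [0, 1)")
    motion = motion or {}
    for cid in motion:
        if not 1 <= cid <= len(spec.cells):
            raise ValueError(f"motion given for unknown cell {cid}")

    # freeze initial particle positions (engulfed ones at host centre)
    base = render_field(replace(spec, noise_sd=0.0))
    init_pos = {
        int(row.particle_id): (row.centroid_row, row.centroid_col)
        for row in base.particles.itertuples()
    }

    frames = []
    nr, nc = spec.image_size_px
    for t in range(n_frames):
        cells_t = []
        for cid, (shape, (r, c)) in enumerate(spec.cells, start=1):
            dr, dc = motion.get(cid, (0.0, 0.0))
            pos = (r + t * dr, c + t * dc)
            if not (0 <= pos[0] < nr and 0 <= pos[1] < nc):
                raise ValueError(
                    f"cell {cid} moves off-image at frame {t} (centre {pos})"
                )
            cells_t.append((shape, pos))
        parts_t = []
        for pid, part in enumerate(spec.particles, start=1):
            pr, pc = init_pos[pid]
            rad = part.radius_um
            if part.engulfed_by is not None:
                dr, dc = motion.get(part.engulfed_by, (0.0, 0.0))
                pr, pc = pr + t * dr, pc + t * dc
                rad = part.radius_um * (1.0 - shrink_rate) ** (t / 2.0)
            parts_t.append(replace(part, position=(pr, pc), radius_um=rad))
        frame_spec = replace(spec, cells=tuple(cells_t), particles=tuple(parts_t),
                             seed=int(np.random.SeedSequence(
                                 [spec.seed, t]).generate_state(1)[0] % (2 ** 31)))
        rendered = render_field(frame_spec)
        rendered.field.time_index = t
        frames.append(rendered)
    return frames


# ---------------------------------------------------------------------------
# sampled morphology populations (feature-space benchmarks)

def sample_shape_spec(class_name: str, rng: np.random.Generator,
                      separation: float = 1.0) -> ShapeSpec:
    """Draw one jittered ShapeSpec for ``class_name``.

    ``separation`` in [0, 1] interpolates every class's geometry toward the
    across-class mean: at 1 the archetypes keep their default geometry, at 0
    the continuous parameters of all classes coincide and only topology
    (process counts) distinguishes them.  Multiplicative jitter of ±12% on
    continuous parameters models within-class variability.
    """
    if not 0 <= separation <= 1:
        raise ValueError("separation must lie in [0, 1]")
    base = _ARCHETYPES[class_name]
    cont = ("soma_radius_um", "process_length_um", "process_width_um",
            "aspect", "wave_amp")
    means = {k: float(np.mean([_ARCHETYPES[c][k] for c in MORPHOLOGY_CLASSES]))
             for k in cont}
    p = {}
    for k in cont:
        v = means[k] + separation * (base[k] - means[k])
        p[k] = v * rng.uniform(0.88, 1.12)
    n_proc = base["n_processes"]
    bp = base["branch_points"]
    if class_name in ("hypertrophic", "inflamed_hypertrophic"):
        # blend branch count toward the hypertrophic-family mean, then jitter
        fam_mean = (_ARCHETYPES["hypertrophic"]["branch_points"]
                    + _ARCHETYPES["inflamed_hypertrophic"]["branch_points"]) / 2
        bp = int(round(fam_mean + separation * (bp - fam_mean)))
        bp = max(1, bp + int(rng.choice([-1, 0, 1], p=[0.25, 0.5, 0.25])))
        n_proc = int(np.clip(n_proc + rng.choice([0, 1], p=[0.7, 0.3]), 3, 5))
    has_proc = n_proc > 0
    return ShapeSpec(
        class_name=class_name,
        soma_radius_um=max(p["soma_radius_um"], 2.0),
        n_processes=n_proc,
        process_length_um=max(p["process_length_um"], 5.0) if has_proc else 0.0,
        process_width_um=float(np.clip(p["process_width_um"], 1.1, 6.0))
        if has_proc else 0.0,
        branch_points=bp,
        seed=int(rng.integers(0, 2 ** 31)),
        aspect=max(p["aspect"], 1.0),
        wave_amp=float(np.clip(p["wave_amp"], 0.0, 0.3)),
        wave_lobes=base["wave_lobes"] if base["wave_lobes"] else 3,
    )


def morphology_feature_table(n_per_class: int = 50, separation: float = 1.0,
                             seed: int = 0,
                             pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                             ) -> pd.DataFrame:
    """Render and measure a labelled 7-class morphology benchmark.

    Each row is one rendered cell measured by the morphometry module (base +
    derived features) with its ground-truth ``class_name``.  This is the
    feature-space test bed for the classifier: classes are well separated at
    ``separation=1`` and collapse together as it shrinks.
    """
    from . import morphometry  # local import: morphometry does not need us

    rng = np.random.default_rng(seed)
    rows = []
    for class_name in MORPHOLOGY_CLASSES:
        for _ in range(n_per_class):
            spec = sample_shape_spec(class_name, rng, separation)
            mask, inten = render_cell(spec, pixel_size_um)
            recs = morphometry.measure_base(mask.astype(np.int32), inten,
                                            pixel_size_um)
            rec = morphometry.derive(recs.iloc[0])
            rec["class_name"] = class_name
            rows.append(rec)
    df = pd.DataFrame(rows).reset_index(drop=True)
    df["cell_id"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# (de)serialization

def field_spec_to_json(spec: FieldSpec) -> str:
    d = asdict(spec)
    d["cells"] = [dict(shape=asdict(s), position=list(p)) for s, p in spec.cells]
    d["particles"] = [asdict(p) for p in spec.particles]
    return json.dumps(d, indent=2)


def field_spec_from_json(text: str) -> FieldSpec:
    d = json.loads(text)
    cells = tuple(
        (ShapeSpec(**c["shape"]), tuple(c["position"])) for c in d.pop("cells", [])
    )
    particles = tuple(
        ParticleSpec(
            radius_um=p["radius_um"],
            position=tuple(p["position"]) if p.get("position") else None,
            engulfed_by=p.get("engulfed_by"),
        )
        for p in d.pop("particles", [])
    )
    d["image_size_px"] = tuple(d["image_size_px"])
    return FieldSpec(cells=cells, particles=particles, **d)


def write_field(result: SyntheticField, outdir) -> None:
    """Write a rendered field as TIFFs + CSV truth tables under ``outdir``."""
    import tifffile
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stack = np.stack([result.field.red, result.field.green]).astype(np.float32)
    tifffile.imwrite(out / "field.tif", stack,
                     metadata={"axes": "CYX",
                               "pixel_size_um": result.field.pixel_size_um})
    tifffile.imwrite(out / "truth_mask.tif",
                     result.truth_mask.astype(np.uint16))
    tifffile.imwrite(out / "truth_particles.tif",
                     result.particle_mask.astype(np.uint16))
    result.cells.to_csv(out / "truth_cells.csv", index=False)
    result.particles.to_csv(out / "truth_particles.csv", index=False)
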