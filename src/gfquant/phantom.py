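"""Synthetic confocal phantoms with ground truth.

The generator emulates the structures the analysis is built to measure, at
the acquisition scale of the real data (0.22 μm in-plane pixels, 1 μm
slices, 8-bit):

* a tubular giant-fiber (GF) dendrite running anteroposteriorly, with
  straight medial branch offshoots;
* a cluster of JO-A axons around the dendrite and a medially displaced
  JO-B axon cluster, with the Neurobiotin (NB) label filling the dendrite
  plus a subset of JO-A axons (dye coupling);
* sub-micron Brp puncta (putative active zones), a subset of which sit on
  the dendrite surface;
* ShakB gap-junction plaques of ~1 μm diameter, concentrated in the JO-A
  territory, a fraction centered on existing puncta (colocalized);
* large (>= 3 μm) non-specific agglomeration blobs present in the
  fusion-protein (Brp) channel but absent from the native-antibody (nc82)
  channel.

Rendering order: paint geometry at nominal intensity -> Gaussian PSF ->
Poisson photon noise + Gaussian read noise -> clip and quantize to 8 bits.
Ground-truth masks are taken before blur and noise, so truth volumes equal
the rendered pre-noise foreground exactly.

Randomness is centralized: every structure class and every channel's noise
draws from its own fixed substream of the single phantom seed, so changing
one class's count leaves every other class (and channel) bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .stack_io import (
    BinaryMask,
    ChannelSet,
    SpecimenRecord,
    VoxelGeometry,
    VoxelStack,
    write_manifest,
    write_mask,
    write_stack,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "StudySpecimen",
    "StudyData",
    "generate_phantom",
    "generate_group_study",
    "STUDY_EFFECT_KEYS",
    "ALL_CHANNELS",
]

ALL_CHANNELS = ("GF", "NB", "Brp", "nc82", "ShB", "GFP")

#: Multiplier keys accepted by :func:`generate_group_study`.
STUDY_EFFECT_KEYS = ("shb_jo_b", "nb_axons", "medial_branch", "az_count")

# Fixed substream key per purpose (see module docstring).
_STREAM_KEYS = {
    "axons_a": 0,
    "axons_b": 1,
    "puncta_a": 2,
    "puncta_b": 3,
    "az": 4,
    "agglomerations": 5,
    "plaques_a": 6,
    "plaques_b": 7,
    "noise_GF": 10,
    "noise_NB": 11,
    "noise_Brp": 12,
    "noise_nc82": 13,
    "noise_ShB": 14,
    "noise_GFP": 15,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic specimen.

    Distances in μm, intensities in 8-bit counts.  The defaults reproduce
    the study conditions: ~1 μm plaques and sub-micron puncta at 0.22 μm
    pixels and 1 μm slices, a 4-fold JO-A/JO-B plaque asymmetry in controls,
    more puncta in JO-B than JO-A, and plaque SNR around 10.
    """

    shape: tuple = (60, 128, 128)
    geometry: VoxelGeometry = field(
        default_factory=lambda: VoxelGeometry(dx=0.22, dy=0.22, dz=1.0)
    )
    # dendrite
    dendrite_radius_um: float = 1.0
    dendrite_center_yx: tuple | None = None  # default: (ny//2, 0.4*nx)
    dendrite_z_range: tuple | None = None  # default: (0.1*nz, 0.9*nz)
    dendrite_intensity: int = 180
    # medial branches (lengths measured from the dendrite axis, medially)
    branch_lengths_um: tuple = (6.0, 7.0)
    branch_radius_um: float = 0.5
    branch_z_fracs: tuple = (0.45, 0.65)
    # axon cylinders
    axon_count_jo_a: int = 8
    axon_count_jo_b: int = 6
    axon_radius_um: float = 0.5
    axon_intensity: int = 150
    nb_coupled_count: int = 4
    nb_intensity: int = 160
    # territories
    jo_b_offset_um: float = 10.0  # JO-B cluster center, medial of the dendrite axis
    region_radius_um: float = 5.5
    cluster_radius_um: float = 3.8  # placement radius of puncta/plaques/axons in a territory
    # ShakB plaques
    plaque_count_jo_a: int = 24
    plaque_count_jo_b: int = 6
    plaque_diameter_um: float = 1.0
    plaque_intensity: int = 200
    plaque_coloc_fraction: float = 0.6
    # Brp puncta and active zones on the dendrite
    punctum_count_jo_a: int = 25
    punctum_count_jo_b: int = 35
    punctum_diameter_um: float = 0.5
    punctum_intensity: int = 180
    az_count: int = 40
    # agglomeration artifacts (Brp channel only)
    agglomeration_count: int = 4
    agglomeration_diameter_um: float = 3.0
    agglomeration_intensity: int = 230
    # optics and noise
    psf_sigma_um: tuple = (0.4, 0.08, 0.08)
    photon_scale: float = 1.0
    read_noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "dendrite_radius_um",
            "branch_radius_um",
            "axon_radius_um",
            "plaque_diameter_um",
            "punctum_diameter_um",
            "agglomeration_diameter_um",
            "jo_b_offset_um",
            "region_radius_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.shape) != 3 or min(self.shape) < 4:
            raise ValueError(f"shape too small: {self.shape}")
        if any(s < 0 for s in self.psf_sigma_um):
            raise ValueError("psf_sigma_um must be nonnegative")
        if self.photon_scale < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be nonnegative")

    # resolved placement defaults -------------------------------------
    @property
    def center_yx(self) -> tuple:
        if self.dendrite_center_yx is not None:
            return self.dendrite_center_yx
        return (self.shape[1] // 2, int(round(self.shape[2] * 0.4)))

    @property
    def z_range(self) -> tuple:
        if self.dendrite_z_range is not None:
            return self.dendrite_z_range
        return (max(1, int(round(self.shape[0] * 0.1))), int(round(self.shape[0] * 0.9)))


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside the rendered channels."""

    masks: dict[str, BinaryMask]
    volumes: dict[str, float]
    region_masks: dict[str, BinaryMask]
    effects: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# low-level painting
# ---------------------------------------------------------------------------

class _Renderer:
    def __init__(self, spec: PhantomSpec, channels: Sequence[str]):
        self.spec = spec
        self.geometry = spec.geometry
        self.shape = tuple(spec.shape)
        self.canvas = {c: np.zeros(self.shape, dtype=np.float32) for c in channels}
        self.truth = {}

    def rng(self, purpose: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.spec.seed, spawn_key=(_STREAM_KEYS[purpose],))
        )

    def _truth(self, name: str) -> np.ndarray:
        if name not in self.truth:
            self.truth[name] = np.zeros(self.shape, dtype=bool)
        return self.truth[name]

    def _radii_vox(self, radius_um: float) -> tuple:
        g = self.geometry
        return (radius_um / g.dz, radius_um / g.dy, radius_um / g.dx)

    def _check_bounds(self, name: str, los, his) -> None:
        for lo, hi, n in zip(los, his, self.shape):
            if lo < 0 or hi > n:
                raise ValueError(
                    f"object {name!r} out of bounds: extent [{los}, {his}) in stack {self.shape}"
                )

    def paint_ball(self, name, center, radius_um, channels, truth_classes, intensity):
        """Ellipsoidal ball (sphere in physical units) at a sub-voxel center.

        A voxel belongs to the ball iff its center lies inside; keeping the
        fractional object center avoids the systematic volume overestimate
        of lattice-aligned voxelization.
        """
        rz, ry, rx = self._radii_vox(radius_um)
        sz, sy, sx = (int(np.floor(r)) + 1 for r in (rz, ry, rx))
        cz, cy, cx = (int(np.floor(c)) for c in center)
        fz, fy, fx = (c - np.floor(c) for c in center)
        los = (cz - sz, cy - sy, cx - sx)
        his = (cz + sz + 1, cy + sy + 1, cx + sx + 1)
        self._check_bounds(name, los, his)
        zz, yy, xx = np.ogrid[-sz : sz + 1, -sy : sy + 1, -sx : sx + 1]
        block = (
            ((zz - fz) / rz) ** 2 + ((yy - fy) / ry) ** 2 + ((xx - fx) / rx) ** 2
            <= 1.0 + 1e-9
        )
        # a sub-voxel object is still a point source: always light the voxel
        # containing the center
        block[sz, sy, sx] = True
        sl = tuple(slice(lo, hi) for lo, hi in zip(los, his))
        for c in channels:
            if c in self.canvas:
                np.maximum(self.canvas[c][sl], block * float(intensity), out=self.canvas[c][sl])
        for t in truth_classes:
            self._truth(t)[sl] |= block

    def paint_tube_z(self, name, center_yx, radius_um, z0, z1, channels, truth_classes, intensity):
        """Cylinder along the slice axis (axon or main dendrite)."""
        _, ry, rx = self._radii_vox(radius_um)
        cy, cx = center_yx
        sy, sx = int(np.floor(ry)), int(np.floor(rx))
        los = (z0, int(round(cy)) - sy, int(round(cx)) - sx)
        his = (z1, int(round(cy)) + sy + 1, int(round(cx)) + sx + 1)
        if z1 <= z0:
            raise ValueError(f"object {name!r} has empty slice range [{z0}, {z1})")
        self._check_bounds(name, los, his)
        yy, xx = np.ogrid[-sy : sy + 1, -sx : sx + 1]
        disc = (yy / ry) ** 2 + (xx / rx) ** 2 <= 1.0 + 1e-9
        sl = (slice(z0, z1), slice(los[1], his[1]), slice(los[2], his[2]))
        for c in channels:
            if c in self.canvas:
                np.maximum(self.canvas[c][sl], disc * float(intensity), out=self.canvas[c][sl])
        for t in truth_classes:
            self._truth(t)[sl] |= disc

    def paint_tube_x(self, name, center_zy, radius_um, x0, x1, channels, truth_classes, intensity):
        """Cylinder along the mediolateral axis (medial branch)."""
        rz, ry, _ = self._radii_vox(radius_um)
        cz, cy = center_zy
        sz, sy = int(np.floor(rz)), int(np.floor(ry))
        sz = max(sz, 0)
        los = (int(round(cz)) - sz, int(round(cy)) - sy, x0)
        his = (int(round(cz)) + sz + 1, int(round(cy)) + sy + 1, x1)
        if x1 <= x0:
            raise ValueError(f"object {name!r} has empty column range [{x0}, {x1})")
        self._check_bounds(name, los, his)
        zz, yy = np.ogrid[-sz : sz + 1, -sy : sy + 1]
        ellipse = (zz / max(rz, 1e-6)) ** 2 + (yy / ry) ** 2 <= 1.0 + 1e-9
        sl = (slice(los[0], his[0]), slice(los[1], his[1]), slice(x0, x1))
        for c in channels:
            if c in self.canvas:
                np.maximum(
                    self.canvas[c][sl], ellipse[:, :, None] * float(intensity), out=self.canvas[c][sl]
                )
        for t in truth_classes:
            self._truth(t)[sl] |= ellipse[:, :, None]

    def disc_region(self, center_yx, radius_um) -> np.ndarray:
        """Full-depth cylindrical territory mask (clipped at stack edges)."""
        ny, nx = self.shape[1], self.shape[2]
        yy, xx = np.ogrid[:ny, :nx]
        _, ry, rx = self._radii_vox(radius_um)
        cy, cx = center_yx
        disc = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        return np.broadcast_to(disc[None, :, :], self.shape).copy()

    def finish(self) -> dict[str, np.ndarray]:
        """PSF blur, Poisson + Gaussian noise, 8-bit quantization."""
        spec = self.spec
        g = self.geometry
        sigma_vox = tuple(s / p for s, p in zip(spec.psf_sigma_um, (g.dz, g.dy, g.dx)))
        out = {}
        for name, canvas in self.canvas.items():
            img = canvas
            if any(s > 0 for s in sigma_vox):
                img = ndimage.gaussian_filter(img, sigma=sigma_vox, truncate=3.0)
            img = img.astype(np.float64)
            rng = self.rng(f"noise_{name}")
            if spec.photon_scale > 0:
                hot = img > 1e-3  # Poisson(0) voxels stay 0; skip them
                lam = img[hot] * spec.photon_scale
                img[hot] = rng.poisson(lam) / spec.photon_scale
            if spec.read_noise_sd > 0:
                img = img + rng.normal(0.0, spec.read_noise_sd, size=img.shape)
            out[name] = np.clip(np.round(img), 0, 255).astype(np.uint8)
        return out


def _sample_in_disc(rng, center_yx, radius_vox_yx, n):
    """Uniform points in an axis-aligned ellipse (voxel units)."""
    u = rng.random(n)
    theta = rng.random(n) * 2 * np.pi
    r = np.sqrt(u)
    ys = center_yx[0] + r * np.sin(theta) * radius_vox_yx[0]
    xs = center_yx[1] + r * np.cos(theta) * radius_vox_yx[1]
    return ys, xs


# ---------------------------------------------------------------------------
# phantom assembly
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec, channels: Sequence[str] | None = None):
    """Render one phantom specimen.

    Returns ``(ChannelSet, PhantomTruth)``.  ``channels`` selects a subset
    of :data:`ALL_CHANNELS` (all by default); truth and regions are always
    complete.  The same spec and seed yield bit-identical stacks.
    """
    if channels is None:
        channels = ALL_CHANNELS
    unknown = set(channels) - set(ALL_CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels {sorted(unknown)}; available: {ALL_CHANNELS}")
    r = _Renderer(spec, channels)
    g = spec.geometry
    cy, cx = spec.center_yx
    z0, z1 = spec.z_range
    nz = spec.shape[0]

    # --- giant-fiber dendrite: tube along z plus medial branches
    r.paint_tube_z(
        "dendrite", (cy, cx), spec.dendrite_radius_um, z0, z1,
        ("GF", "NB"), ("dendrite",), spec.dendrite_intensity,
    )
    branch_axis_info = []  # (z, y, x_start, x_end) in voxels, for AZ placement
    max_x = spec.shape[2] - 2
    for i, (length_um, zfrac) in enumerate(zip(spec.branch_lengths_um, spec.branch_z_fracs)):
        bz = int(round(z0 + zfrac * (z1 - 1 - z0)))
        x_end = int(round(cx + length_um / g.dx))
        if x_end > max_x:
            logger.warning(
                "branch %d clipped at the stack border (%.1f um requested)", i, length_um
            )
            x_end = max_x
        r.paint_tube_x(
            f"branch_{i}", (bz, cy), spec.branch_radius_um, int(cx), x_end,
            ("GF", "NB"), ("dendrite", "medial_branches"), spec.dendrite_intensity,
        )
        branch_axis_info.append((bz, cy, int(cx), x_end))

    # --- territories
    jo_b_center = (cy, cx + spec.jo_b_offset_um / g.dx)
    regions = {
        "JO-A": r.disc_region((cy, cx), spec.region_radius_um),
        "JO-B": r.disc_region(jo_b_center, spec.region_radius_um),
    }

    # --- axons: JO-A cluster around the dendrite, JO-B cluster medially
    _, r_ry, r_rx = r._radii_vox(1.0)  # voxels per μm in y/x
    az0, az1 = max(1, z0 - 3), min(nz, z1 + 3)
    rng_a = r.rng("axons_a")
    axon_margin = spec.axon_radius_um
    n_ax_a = max(spec.axon_count_jo_a, spec.nb_coupled_count)
    for i in range(n_ax_a):
        dist = rng_a.uniform(spec.dendrite_radius_um + axon_margin, 4.0)
        theta = rng_a.uniform(0, 2 * np.pi)
        ay = cy + dist * np.sin(theta) / g.dy
        ax = cx + dist * np.cos(theta) / g.dx
        coupled = i < spec.nb_coupled_count
        chans = ("GFP", "NB") if coupled else ("GFP",)
        classes = ("axons_jo_a", "nb_axons") if coupled else ("axons_jo_a",)
        r.paint_tube_z(
            f"axon_jo_a_{i}", (ay, ax), spec.axon_radius_um, az0, az1,
            chans, classes, spec.nb_intensity if coupled else spec.axon_intensity,
        )
    rng_b = r.rng("axons_b")
    ys, xs = _sample_in_disc(
        rng_b, jo_b_center,
        (spec.cluster_radius_um / g.dy, spec.cluster_radius_um / g.dx),
        spec.axon_count_jo_b,
    )
    for i, (ay, ax) in enumerate(zip(ys, xs)):
        r.paint_tube_z(
            f"axon_jo_b_{i}", (ay, ax), spec.axon_radius_um, az0, az1,
            ("GFP",), ("axons_jo_b",), spec.axon_intensity,
        )

    # --- Brp puncta in both territories (fusion channel and native nc82)
    punctum_r = spec.punctum_diameter_um / 2
    punctum_centers = {"JO-A": [], "JO-B": []}

    def _place_puncta(purpose, center_yx, count, region_name):
        rng = r.rng(purpose)
        ys, xs = _sample_in_disc(
            rng, center_yx, (spec.cluster_radius_um / g.dy, spec.cluster_radius_um / g.dx), count
        )
        zs = rng.uniform(z0 + 2, z1 - 2, size=count)
        for i in range(count):
            c = (zs[i], ys[i], xs[i])
            r.paint_ball(
                f"punctum_{region_name}_{i}", c, punctum_r,
                ("Brp", "nc82"), ("puncta",), spec.punctum_intensity,
            )
            punctum_centers[region_name].append(c)

    _place_puncta("puncta_a", (cy, cx), spec.punctum_count_jo_a, "JO-A")
    _place_puncta("puncta_b", jo_b_center, spec.punctum_count_jo_b, "JO-B")

    # --- active zones on the dendrite surface (main trunk + branches)
    rng_az = r.rng("az")
    trunk_len = (z1 - z0) * g.dz
    branch_lens = [max(bx1 - bx0, 1) * g.dx for (_, _, bx0, bx1) in branch_axis_info]
    weights = np.array([trunk_len] + branch_lens)
    weights = weights / weights.sum()
    for i in range(spec.az_count):
        which = rng_az.choice(len(weights), p=weights)
        theta = rng_az.uniform(0, 2 * np.pi)
        if which == 0:
            azz = rng_az.uniform(z0 + 1, z1 - 2)
            azy = cy + spec.dendrite_radius_um * np.sin(theta) / g.dy
            azx = cx + spec.dendrite_radius_um * np.cos(theta) / g.dx
        else:
            bz, by, bx0, bx1 = branch_axis_info[which - 1]
            azx = rng_az.uniform(bx0 + 1, bx1 - 1)
            azz = bz + spec.branch_radius_um * np.sin(theta) / g.dz
            azy = by + spec.branch_radius_um * np.cos(theta) / g.dy
        r.paint_ball(
            f"az_{i}", (azz, azy, azx), punctum_r,
            ("Brp", "nc82"), ("puncta", "az_puncta"), spec.punctum_intensity,
        )

    # --- ShakB plaques; a fraction colocalize with existing puncta
    plaque_r = spec.plaque_diameter_um / 2

    def _place_plaques(purpose, center_yx, count, region_name, truth_class):
        rng = r.rng(purpose)
        ys, xs = _sample_in_disc(
            rng, center_yx, (spec.cluster_radius_um / g.dy, spec.cluster_radius_um / g.dx), count
        )
        zs = rng.uniform(z0 + 2, z1 - 2, size=count)
        pool = punctum_centers[region_name]
        order = iter(rng.permutation(len(pool)) if pool else ())
        for i in range(count):
            host = next(order, None) if rng.random() < spec.plaque_coloc_fraction else None
            # colocalized plaques sit on distinct puncta until the pool runs out
            c = pool[host] if host is not None else (zs[i], ys[i], xs[i])
            r.paint_ball(
                f"plaque_{region_name}_{i}", c, plaque_r,
                ("ShB",), (truth_class,), spec.plaque_intensity,
            )

    _place_plaques("plaques_a", (cy, cx), spec.plaque_count_jo_a, "JO-A", "plaques_jo_a")
    _place_plaques("plaques_b", jo_b_center, spec.plaque_count_jo_b, "JO-B", "plaques_jo_b")

    # --- agglomeration artifacts: Brp channel only, never nc82
    rng_ag = r.rng("agglomerations")
    ag_r = spec.agglomeration_diameter_um / 2
    ag_centers_yx = [(cy, cx), jo_b_center]
    ag_margin_z = ag_r / g.dz + 1
    for i in range(spec.agglomeration_count):
        cyx = ag_centers_yx[i % 2]
        ys, xs = _sample_in_disc(rng_ag, cyx, (2.5 / g.dy, 2.5 / g.dx), 1)
        azz = rng_ag.uniform(ag_margin_z + 1, nz - ag_margin_z - 1)
        r.paint_ball(
            f"agglomeration_{i}", (azz, ys[0], xs[0]), ag_r,
            ("Brp",), ("agglomerations",), spec.agglomeration_intensity,
        )

    rendered = r.finish()
    channel_set = ChannelSet(
        {name: VoxelStack(arr, g, name) for name, arr in rendered.items()}
    )
    truth_masks = {name: BinaryMask(m, g) for name, m in r.truth.items()}
    truth = PhantomTruth(
        masks=truth_masks,
        volumes={name: m.volume() for name, m in truth_masks.items()},
        region_masks={name: BinaryMask(m, g) for name, m in regions.items()},
    )
    return channel_set, truth


# ---------------------------------------------------------------------------
# group studies
# ---------------------------------------------------------------------------

@dataclass
class StudySpecimen:
    specimen_id: str
    group: str
    spec: PhantomSpec


@dataclass
class StudyData:
    """A realizable synthetic study: per-specimen phantom recipes.

    Specimens are rendered lazily via :meth:`realize` so a whole study never
    has to sit in memory at once.
    """

    specimens: list[StudySpecimen]
    group_effects: dict[str, dict[str, float]]
    channels: tuple
    manifest_path: Path | None = None

    def groups(self) -> list[str]:
        seen = []
        for s in self.specimens:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def realize(self, specimen: StudySpecimen):
        return generate_phantom(specimen.spec, self.channels)


def _scaled_count(base: int, factor: float) -> int:
    return max(0, int(round(base * factor)))


def generate_group_study(
    base: PhantomSpec,
    group_effects: Mapping[str, Mapping[str, float]],
    n_per_group: int,
    seed: int,
    specimen_sd: float = 0.2,
    channels: Sequence[str] = ("GF", "NB", "Brp", "ShB"),
    out_dir=None,
) -> StudyData:
    """Build a multi-group synthetic study.

    ``group_effects`` maps each group label to multipliers on the four
    effect dimensions (:data:`STUDY_EFFECT_KEYS`): JO-B plaque load,
    NB-coupled axon count, medial branch length and active-zone count; a
    missing key means 1.  Each specimen additionally draws independent
    lognormal variability (log-sd ``specimen_sd``) on each dimension around
    its group mean.  One seed fixes every specimen via per-specimen
    substreams.  With ``out_dir`` set, stacks, territory masks and a
    manifest CSV are written there.
    """
    if n_per_group < 2:
        raise ValueError(f"n_per_group must be >= 2, got {n_per_group}")
    if len(group_effects) < 1:
        raise ValueError("at least one group required")
    for group, effects in group_effects.items():
        for key, mult in effects.items():
            if key not in STUDY_EFFECT_KEYS:
                raise ValueError(
                    f"group {group!r}: unknown effect {key!r}; allowed: {STUDY_EFFECT_KEYS}"
                )
            if not mult > 0:
                raise ValueError(f"group {group!r}: multiplier {key}={mult} must be > 0")

    specimens = []
    for gi, (group, effects) in enumerate(group_effects.items()):
        for i in range(n_per_group):
            ss = np.random.SeedSequence(seed, spawn_key=(gi, i))
            var_rng = np.random.default_rng(ss.spawn(1)[0])
            phantom_seed = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
            f = {
                key: effects.get(key, 1.0) * var_rng.lognormal(0.0, specimen_sd)
                for key in STUDY_EFFECT_KEYS
            }
            nb_count = _scaled_count(base.nb_coupled_count, f["nb_axons"])
            spec_i = replace(
                base,
                plaque_count_jo_b=_scaled_count(base.plaque_count_jo_b, f["shb_jo_b"]),
                nb_coupled_count=nb_count,
                axon_count_jo_a=max(base.axon_count_jo_a, nb_count),
                branch_lengths_um=tuple(
                    length * f["medial_branch"] for length in base.branch_lengths_um
                ),
                az_count=_scaled_count(base.az_count, f["az_count"]),
                seed=phantom_seed,
            )
            specimens.append(StudySpecimen(f"{group}_{i:02d}", group, spec_i))

    study = StudyData(specimens, {g: dict(e) for g, e in group_effects.items()}, tuple(channels))
    if out_dir is not None:
        study.manifest_path = _write_study(study, Path(out_dir))
    return study


def _write_study(study: StudyData, out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for sp in study.specimens:
        channel_set, truth = study.realize(sp)
        spec_dir = out_dir / sp.specimen_id
        channel_paths = {
            name: write_stack(stack, spec_dir / f"{name}.tif")
            for name, stack in channel_set.channels.items()
        }
        mask_paths = {
            name: write_mask(mask, spec_dir / f"region_{name}.tif")
            for name, mask in truth.region_masks.items()
        }
        records.append(
            SpecimenRecord(sp.specimen_id, sp.group, sp.spec.geometry, channel_paths, mask_paths)
        )
    return write_manifest(records, out_dir / "manifest.csv")
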