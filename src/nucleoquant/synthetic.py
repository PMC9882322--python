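"""Seeded generators for synthetic AFM scenes, condensate images, decay
traces, and binding tables, with ground-truth manifests.

Every generator is deterministic given its seed: sub-streams are derived per
object from one ``numpy.random.SeedSequence`` so that scenes are bit-identical
across runs and individual objects can be regenerated in isolation.

The defaults emulate the study conditions the analysis stages were built for:
1000-bp linear DNA deposited on mica and imaged at ~1 nm/pixel (modeled as
surface-equilibrated 2D worm-like chains with persistence length 50 nm),
protein particles of ~20.7 nm^3 per complex averaging 2.2 per molecule,
condensates with a dense core (median radius ~0.94 um) surrounded by a
lower-intensity halo (~0.66 um thick) at 100 nm/pixel, and single-exponential
intensity decay at ~0.034 s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .afm import HeightMap
from .errors import ParameterError, PlacementError, RenderError

#: default rise per base pair (nm/bp). The study's expected contour length of
#: 0.383 um for 1000 bp implies 0.383 nm/bp; the canonical B-form value is
#: 0.34 nm/bp. The rise is a parameter everywhere it matters.
DEFAULT_RISE_PER_BP = 0.383

#: reference volume of one protein complex (nm^3) used for default particle
#: volumes: mean particle = V_d / N_p = 303 / 2.2.
DEFAULT_PARTICLE_VOLUME = 137.7

DEFAULT_DECAY_RATE = 0.034  # 1/s

__all__ = [
    "WLCParams",
    "RenderParams",
    "GroundTruthManifest",
    "ParticleSpec",
    "expected_contour_length",
    "mean_squared_end_to_end",
    "sample_wlc_chain",
    "sample_wlc_ensemble",
    "place_particles",
    "draw_particle_count",
    "render_afm_scene",
    "simulate_afm_scene",
    "simulate_condensate",
    "simulate_condensate_field",
    "simulate_decay_traces",
    "simulate_binding_table",
]


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-object random stream derived from one scene seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# worm-like chains


@dataclass(frozen=True)
class WLCParams:
    """Worm-like-chain sampling parameters (all lengths in nm)."""

    contour_length: float
    persistence_length: float = 50.0
    step_length: float = 1.0
    n_chains: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.contour_length <= 0:
            raise ParameterError("contour_length must be positive")
        if self.persistence_length <= 0:
            raise ParameterError("persistence_length must be positive")
        if not (0 < self.step_length <= self.contour_length):
            raise ParameterError("step_length must satisfy 0 < ds <= L")
        if self.n_chains < 1:
            raise ParameterError("n_chains must be >= 1")


def expected_contour_length(n_bp: int, rise_per_bp: float = DEFAULT_RISE_PER_BP) -> float:
    """Expected contour length (nm) of an ``n_bp`` duplex."""
    if n_bp <= 0 or rise_per_bp <= 0:
        raise ParameterError("n_bp and rise_per_bp must be positive")
    return n_bp * rise_per_bp


def mean_squared_end_to_end(contour_length: float, persistence_length: float) -> float:
    """Closed-form <R^2> of a 2D worm-like chain.

    With turning-angle variance ds/l_p per step the tangent correlation is
    exp(-s / (2 l_p)); writing xi = 2 l_p for the decorrelation length,

        <R^2> = 2 xi L - 2 xi^2 (1 - exp(-L / xi)).
    """
    xi = 2.0 * persistence_length
    L = contour_length
    return 2 * xi * L - 2 * xi**2 * (1.0 - math.exp(-L / xi))


def sample_wlc_chain(params: WLCParams, seed: int | None = None) -> np.ndarray:
    """Sample one 2D worm-like chain; returns (n_steps + 1, 2) vertices in nm.

    The chain starts at the origin with a uniformly random initial direction;
    each step turns by a Gaussian angle of variance ds/l_p. The number of
    steps is ceil(L/ds), so the summed step length equals L to within one ds.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n_steps = math.ceil(params.contour_length / params.step_length)
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    dtheta = rng.normal(
        0.0, math.sqrt(params.step_length / params.persistence_length), n_steps - 1
    )
    theta = theta0 + np.concatenate([[0.0], np.cumsum(dtheta)])
    steps = params.step_length * np.column_stack([np.cos(theta), np.sin(theta)])
    verts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return verts


def sample_wlc_ensemble(params: WLCParams) -> np.ndarray:
    """Vectorized ensemble of ``n_chains`` chains; shape (n_chains, n+1, 2)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = math.ceil(params.contour_length / params.step_length)
    theta0 = rng.uniform(0.0, 2.0 * math.pi, size=(params.n_chains, 1))
    dtheta = rng.normal(
        0.0,
        math.sqrt(params.step_length / params.persistence_length),
        size=(params.n_chains, n - 1),
    )
    theta = theta0 + np.concatenate(
        [np.zeros((params.n_chains, 1)), np.cumsum(dtheta, axis=1)], axis=1
    )
    steps = params.step_length * np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    verts = np.concatenate(
        [np.zeros((params.n_chains, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    return verts


# ---------------------------------------------------------------------------
# particles on chains


@dataclass
class ParticleSpec:
    """A protein particle bound to a chain, with ground truth."""

    arc_position: float  # nm along the chain
    volume_nm3: float
    placement_class: str  # "end" | "interstitial"
    position: tuple[float, float]  # (x, y) nm
    chain_index: int = 0


def _arc_coords(chain: np.ndarray) -> tuple[np.ndarray, float]:
    seg = np.linalg.norm(np.diff(chain, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return cum, float(cum[-1])


def _point_at_arc(chain: np.ndarray, cum: np.ndarray, s: float) -> tuple[float, float]:
    x = float(np.interp(s, cum, chain[:, 0]))
    y = float(np.interp(s, cum, chain[:, 1]))
    return (x, y)


def place_particles(
    chain: np.ndarray,
    n: int,
    end_bias: float = 0.5,
    particle_volume: float = DEFAULT_PARTICLE_VOLUME,
    seed: int = 0,
    min_separation: float = 20.0,
    end_cap: float = 15.0,
    chain_index: int = 0,
) -> list[ParticleSpec]:
    """Place ``n`` non-overlapping particles on a chain.

    Each particle lands on a chain end (within ``end_cap`` nm of a terminus)
    with probability ``end_bias`` and otherwise uniformly along the interior
    arc. Particles are kept at least ``min_separation`` nm apart along the
    arc; an unsatisfiable request raises :class:`PlacementError`.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    if not 0.0 <= end_bias <= 1.0:
        raise ParameterError("end_bias must be in [0, 1]")
    if n == 0:
        return []
    cum, total = _arc_coords(chain)
    if n > max(1, int(total // min_separation)):
        raise PlacementError(
            f"cannot place {n} particles >= {min_separation} nm apart on a "
            f"{total:.0f} nm chain"
        )
    rng = np.random.default_rng(seed)
    placed: list[float] = []
    specs: list[ParticleSpec] = []
    for _ in range(n):
        ok = False
        for _attempt in range(500):
            if rng.random() < end_bias:
                arc = 0.0 if rng.random() < 0.5 else total
            else:
                arc = rng.uniform(end_cap, total - end_cap)
            if all(abs(arc - p) >= min_separation for p in placed):
                ok = True
                break
        if not ok:
            raise PlacementError("could not satisfy min_separation; too crowded")
        placed.append(arc)
        cls = "end" if (arc <= end_cap or arc >= total - end_cap) else "interstitial"
        specs.append(
            ParticleSpec(
                arc_position=arc,
                volume_nm3=particle_volume,
                placement_class=cls,
                position=_point_at_arc(chain, cum, arc),
                chain_index=chain_index,
            )
        )
    return specs


def draw_particle_count(
    rng: np.random.Generator, mean: float = 2.2, max_count: int = 12
) -> int:
    """Per-chain particle count: Poisson with the given mean, truncated above.

    ``max_count`` defaults high enough that the truncation bias on the mean
    is negligible (< 1e-3 at mean 2.2).
    """
    while True:
        k = int(rng.poisson(mean))
        if k <= max_count:
            return k


# ---------------------------------------------------------------------------
# AFM rendering


@dataclass(frozen=True)
class RenderParams:
    """Forward-model parameters for AFM scene rendering (lengths in nm)."""

    rx: float = 1.0
    ry: float = 1.0
    # pre-convolution ridge amplitude (nm x nm cross-section density); with
    # tip_sigma = 2 this yields an apparent ridge height of ~0.5 nm, the
    # typical tapping-mode value for surface-dried dsDNA
    dna_height: float = 2.5
    tip_sigma: float = 2.0  # isotropic Gaussian stand-in for tip broadening
    noise_sigma: float = 0.05
    extent: tuple[int, int] = (512, 512)  # (rows, cols) pixels
    background: float = 0.0

    def validate(self) -> None:
        if self.rx <= 0 or self.ry <= 0:
            raise ParameterError("rx, ry must be positive")
        if self.tip_sigma < 0 or self.noise_sigma < 0:
            raise ParameterError("tip_sigma and noise_sigma must be >= 0")
        if min(self.extent) < 8:
            raise ParameterError("image extent too small")


@dataclass
class GroundTruthManifest:
    """Ground truth for every rendered object in a synthetic dataset."""

    seed: int = 0
    chains: list[dict] = field(default_factory=list)
    particles: list[dict] = field(default_factory=list)
    condensates: list[dict] = field(default_factory=list)
    traces: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthManifest":
        return cls(
            seed=int(d.get("seed", 0)),
            chains=list(d.get("chains", [])),
            particles=list(d.get("particles", [])),
            condensates=list(d.get("condensates", [])),
            traces=list(d.get("traces", [])),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _chain_truth(chain: np.ndarray, chain_id: int) -> dict:
    _, total = _arc_coords(chain)
    return {
        "chain_id": int(chain_id),
        "contour_length_nm": float(total),
        "vertices_nm": [[float(x), float(y)] for x, y in chain],
    }


def _particle_truth(spec: ParticleSpec, particle_id: int) -> dict:
    return {
        "particle_id": int(particle_id),
        "chain_id": int(spec.chain_index),
        "arc_position_nm": float(spec.arc_position),
        "volume_nm3": float(spec.volume_nm3),
        "placement_class": spec.placement_class,
        "position_nm": [float(spec.position[0]), float(spec.position[1])],
    }


def _deposit_ridge(field_: np.ndarray, chain: np.ndarray, rp: RenderParams) -> None:
    """Lay a DNA ridge along the chain with constant mass per unit arc length.

    The chain is resampled at quarter-pixel arc steps and each sample
    deposits ``dna_height * 1 nm * ds`` of volume onto the four nearest
    pixels with bilinear weights. This keeps the post-convolution apparent
    ridge height independent of the local chain direction, which naive
    per-pixel rasterization does not (diagonal stretches come out fainter).
    """
    ny, nx = field_.shape
    cum, total = _arc_coords(chain)
    ds = 0.25 * min(rp.rx, rp.ry)
    s = np.arange(0.0, total + ds / 2, ds)
    xs = np.interp(s, cum, chain[:, 0]) / rp.rx
    ys = np.interp(s, cum, chain[:, 1]) / rp.ry
    dep = rp.dna_height * 1.0 * ds / (rp.rx * rp.ry)
    c0 = np.floor(xs).astype(int)
    r0 = np.floor(ys).astype(int)
    fc = xs - c0
    fr = ys - r0
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        np.add.at(
            field_,
            (np.clip(r0 + dr, 0, ny - 1), np.clip(c0 + dc, 0, nx - 1)),
            dep * w,
        )


def render_afm_scene(
    chains: list[np.ndarray],
    particles: list[ParticleSpec],
    rp: RenderParams,
    seed: int = 0,
) -> tuple[HeightMap, GroundTruthManifest]:
    """Render chains and particles into a height map.

    DNA is laid down as a one-pixel ridge of height ``dna_height``; each
    particle deposits its full volume onto the four nearest pixels with
    bilinear weights. The field is then convolved with a Gaussian of width
    ``tip_sigma`` (which conserves the integrated volume of isolated
    objects) and Gaussian height noise is added. Coordinates are (x, y) nm;
    x maps to columns, y to rows.
    """
    rp.validate()
    ny, nx = rp.extent
    margin = 3.0 * rp.tip_sigma
    xmax, ymax = nx * rp.rx, ny * rp.ry
    field_ = np.zeros((ny, nx), dtype=float)

    for chain in chains:
        if (
            chain[:, 0].min() < margin
            or chain[:, 1].min() < margin
            or chain[:, 0].max() > xmax - margin
            or chain[:, 1].max() > ymax - margin
        ):
            raise RenderError("chain outside image extent (margin 3*tip_sigma)")
        _deposit_ridge(field_, chain, rp)

    for spec in particles:
        x, y = spec.position
        if not (margin <= x <= xmax - margin and margin <= y <= ymax - margin):
            raise RenderError("particle outside image extent")
        c, r = x / rp.rx, y / rp.ry
        c0, r0 = int(math.floor(c)), int(math.floor(r))
        fc, fr = c - c0, r - r0
        h = spec.volume_nm3 / (rp.rx * rp.ry)
        for dr, dc, w in (
            (0, 0, (1 - fr) * (1 - fc)),
            (0, 1, (1 - fr) * fc),
            (1, 0, fr * (1 - fc)),
            (1, 1, fr * fc),
        ):
            field_[r0 + dr, c0 + dc] += h * w

    if rp.tip_sigma > 0:
        field_ = gaussian_filter(
            field_, sigma=(rp.tip_sigma / rp.ry, rp.tip_sigma / rp.rx), mode="constant"
        )
    field_ += rp.background
    if rp.noise_sigma > 0:
        rng = _substream(seed, 999)
        field_ += rng.normal(0.0, rp.noise_sigma, size=field_.shape)

    hm = HeightMap(grid=field_, rx=rp.rx, ry=rp.ry, background=rp.background)
    manifest = GroundTruthManifest(
        seed=seed,
        chains=[_chain_truth(ch, i) for i, ch in enumerate(chains)],
        particles=[_particle_truth(p, i) for i, p in enumerate(particles)],
    )
    return hm, manifest


def simulate_afm_scene(
    n_chains: int = 9,
    wlc: WLCParams | None = None,
    rp: RenderParams | None = None,
    particle_mean: float = 2.2,
    end_bias: float = 0.5,
    particle_volume: float = DEFAULT_PARTICLE_VOLUME,
    seed: int = 0,
) -> tuple[HeightMap, GroundTruthManifest]:
    """Sample, arrange, decorate, and render a full AFM scene.

    Chains are laid out on a square grid of cells (one chain per cell) so
    that molecules never touch; a chain is resampled from its own sub-stream
    until its bounding box fits the cell. Per-chain particle counts follow a
    truncated Poisson with mean ``particle_mean``.
    """
    if wlc is None:
        wlc = WLCParams(contour_length=383.0, persistence_length=50.0, seed=seed)
    wlc.validate()
    n_cells = math.ceil(math.sqrt(n_chains))
    # cell sized to hold a typical chain footprint with room to spare
    rms = math.sqrt(
        mean_squared_end_to_end(wlc.contour_length, wlc.persistence_length)
    )
    cell_nm = max(2.2 * rms, 0.45 * wlc.contour_length)
    if rp is None:
        ext = int(math.ceil(n_cells * cell_nm))
        rp = RenderParams(extent=(ext, ext))
    rp.validate()
    margin = 3.0 * rp.tip_sigma + 4.0
    ny, nx = rp.extent
    cell_x = nx * rp.rx / n_cells
    cell_y = ny * rp.ry / n_cells

    chains: list[np.ndarray] = []
    particles: list[ParticleSpec] = []
    for i in range(n_chains):
        cell_r, cell_c = divmod(i, n_cells)
        placed = None
        for attempt in range(200):
            rng = _substream(seed, i, attempt)
            verts = sample_wlc_chain(wlc, seed=int(rng.integers(2**31 - 1)))
            span_x = verts[:, 0].max() - verts[:, 0].min()
            span_y = verts[:, 1].max() - verts[:, 1].min()
            if span_x <= cell_x - 2 * margin and span_y <= cell_y - 2 * margin:
                off_x = (
                    cell_c * cell_x
                    + margin
                    - verts[:, 0].min()
                    + rng.uniform(0, cell_x - 2 * margin - span_x)
                )
                off_y = (
                    cell_r * cell_y
                    + margin
                    - verts[:, 1].min()
                    + rng.uniform(0, cell_y - 2 * margin - span_y)
                )
                placed = verts + np.array([off_x, off_y])
                n_part = draw_particle_count(rng, particle_mean)
                break
        if placed is None:
            raise RenderError(
                "could not fit chain in its cell; increase extent or reduce L"
            )
        chains.append(placed)
        try:
            specs = place_particles(
                placed,
                n_part,
                end_bias=end_bias,
                particle_volume=particle_volume,
                seed=int(_substream(seed, i, 9000).integers(2**31 - 1)),
                chain_index=i,
            )
        except PlacementError:
            specs = []
        particles.extend(specs)
    return render_afm_scene(chains, particles, rp, seed=seed)


# ---------------------------------------------------------------------------
# condensates


def _render_condensate_into(
    img: np.ndarray,
    center_px: tuple[float, float],
    core_radius: float,
    halo_thickness: float,
    core_intensity: float,
    halo_intensity: float,
    pixel_size: float,
) -> None:
    ny, nx = img.shape[-2:]
    rr, cc = np.mgrid[0:ny, 0:nx]
    dist = np.hypot(rr - center_px[0], cc - center_px[1]) * pixel_size
    halo = (dist > core_radius) & (dist <= core_radius + halo_thickness)
    core = dist <= core_radius
    for ch in range(img.shape[0]):
        img[ch][halo] = halo_intensity
        img[ch][core] = core_intensity


def simulate_condensate(
    core_radius: float,
    halo_thickness: float,
    core_intensity: float = 10.0,
    halo_intensity: float = 2.0,
    background: float = 0.1,
    noise: float = 0.05,
    pixel_size: float = 100.0,
    extent: tuple[int, int] = (64, 64),
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Render one two-channel condensate (dense core + halo annulus).

    Lengths are in nm; the returned image has shape (2, H, W) with channel 0
    conventionally the protein channel and channel 1 the DNA channel. Truth
    records the center (pixels), core radius, and halo thickness.
    """
    if core_radius <= 0:
        raise ParameterError("core_radius must be positive")
    if halo_thickness < 0:
        raise ParameterError("halo_thickness must be >= 0")
    if not core_intensity > halo_intensity > background:
        raise ParameterError("need core_intensity > halo_intensity > background")
    ny, nx = extent
    outer = core_radius + halo_thickness
    if outer + 2 * pixel_size > min(ny, nx) / 2 * pixel_size:
        raise RenderError("condensate exceeds image extent")
    img = np.full((2, ny, nx), background, dtype=float)
    center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    _render_condensate_into(
        img, center, core_radius, halo_thickness, core_intensity, halo_intensity,
        pixel_size,
    )
    if noise > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, noise, size=img.shape)
    truth = {
        "center_px": [center[0], center[1]],
        "core_radius_nm": float(core_radius),
        "halo_thickness_nm": float(halo_thickness),
        "pixel_size_nm": float(pixel_size),
    }
    return img, truth


def simulate_condensate_field(
    n_condensates: int,
    core_radius: float | np.ndarray = 940.0,
    halo_thickness: float | np.ndarray = 657.0,
    core_intensity: float = 10.0,
    halo_intensity: float = 2.0,
    background: float = 0.1,
    noise: float = 0.05,
    pixel_size: float = 100.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruthManifest]:
    """Render ``n_condensates`` on a grid in one two-channel image.

    ``core_radius`` and ``halo_thickness`` may be scalars or per-condensate
    arrays (nm). Defaults follow the study's median geometry.
    """
    if n_condensates < 1:
        raise ParameterError("n_condensates must be >= 1")
    radii = np.broadcast_to(np.asarray(core_radius, dtype=float), (n_condensates,))
    halos = np.broadcast_to(np.asarray(halo_thickness, dtype=float), (n_condensates,))
    n_cells = math.ceil(math.sqrt(n_condensates))
    cell_px = int(math.ceil(2 * (radii.max() + halos.max()) / pixel_size)) + 8
    ny = nx = n_cells * cell_px
    img = np.full((2, ny, nx), background, dtype=float)
    manifest = GroundTruthManifest(seed=seed)
    for i in range(n_condensates):
        cr, cc_ = divmod(i, n_cells)
        center = (cr * cell_px + (cell_px - 1) / 2.0, cc_ * cell_px + (cell_px - 1) / 2.0)
        _render_condensate_into(
            img, center, radii[i], halos[i], core_intensity, halo_intensity, pixel_size
        )
        manifest.condensates.append(
            {
                "condensate_id": i,
                "center_px": [float(center[0]), float(center[1])],
                "core_radius_nm": float(radii[i]),
                "halo_thickness_nm": float(halos[i]),
                "pixel_size_nm": float(pixel_size),
            }
        )
    if noise > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, noise, size=img.shape)
    return img, manifest


# ---------------------------------------------------------------------------
# decay traces and binding tables


def simulate_decay_traces(
    k: float = DEFAULT_DECAY_RATE,
    dt: float = 2.0,
    n_frames: int = 60,
    n_traces: int = 1,
    noise_model: str = "multiplicative",
    noise_level: float = 0.05,
    i0: float = 100.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruthManifest]:
    """Simulate photon-count decay traces I(t) = I0 exp(-k t).

    ``noise_model`` is one of "none", "multiplicative" (Gaussian fractional
    noise of size ``noise_level``), or "poisson" (photon counting noise).
    Returns ``(times, counts, manifest)`` with counts of shape
    (n_traces, n_frames).
    """
    if k < 0:
        raise ParameterError("k must be >= 0")
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if n_frames < 3:
        raise ParameterError("need at least 3 frames")
    if noise_model not in ("none", "multiplicative", "poisson"):
        raise ParameterError(f"unknown noise model {noise_model!r}")
    times = np.arange(n_frames) * dt
    clean = i0 * np.exp(-k * times)
    counts = np.tile(clean, (n_traces, 1))
    if noise_model == "multiplicative" and noise_level > 0:
        rng = np.random.default_rng(seed)
        counts = counts * (1.0 + rng.normal(0.0, noise_level, size=counts.shape))
    elif noise_model == "poisson":
        rng = np.random.default_rng(seed)
        counts = rng.poisson(counts).astype(float)
    manifest = GroundTruthManifest(
        seed=seed,
        traces=[
            {"trace_id": i, "true_rate_per_s": float(k), "dt_s": float(dt), "i0": float(i0)}
            for i in range(n_traces)
        ],
    )
    return times, counts, manifest


def simulate_binding_table(
    c50: float,
    concentrations: np.ndarray,
    steepness: float = 2.0,
    noise: float = 0.0,
    n_replicates: int = 1,
    substrate: str = "synthetic",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate an EMSA-style binding table.

    The noiseless expectation is a Hill-shaped sigmoid
    f(c) = c^h / (c^h + c50^h), which is monotone and crosses 0.5 exactly at
    ``c50``. Gaussian noise of SD ``noise`` is added and fractions clipped
    to [0, 1]. Returns a tidy DataFrame with columns
    concentration_nM, fraction_bound, replicate, substrate.
    """
    if c50 <= 0:
        raise ParameterError("c50 must be positive")
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ParameterError("concentration list must not be empty")
    if np.any(np.diff(conc) <= 0):
        raise ParameterError("concentrations must be strictly increasing")
    rng = np.random.default_rng(seed)
    rows = []
    clean = conc**steepness / (conc**steepness + c50**steepness)
    for rep in range(n_replicates):
        f = clean.copy()
        if noise > 0:
            f = np.clip(f + rng.normal(0.0, noise, size=f.shape), 0.0, 1.0)
        for c, fb in zip(conc, f):
            rows.append(
                {
                    "concentration_nM": float(c),
                    "fraction_bound": float(fb),
                    "replicate": rep,
                    "substrate": substrate,
                }
            )
    table = pd.DataFrame(rows)
    truth = {"c50_nM": float(c50), "steepness": float(steepness)}
    return table, truth
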