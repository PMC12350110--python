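"""Synthetic multi-channel fluorescence fields with full ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a monolayer of macrophages imaged in four channels (Hoechst 33342,
SYTOX Orange, MPO, CitH3), a minority of pyroptotic (SYTOX-positive nuclei)
and apoptotic (small, densely stained nuclei) cells, extracellular MET blobs
anchored at cell edges, cytoplasmic DNA puncta with staged marker
combinations, optionally polarized toward the MET release site, and a
time-lapse in which doomed cells turn SYTOX-positive at logistic-distributed
death times and plateau.

Geometry is deliberately simple — disk nucleus, annular cytoplasm, ellipse
MET blob tangent to the cell boundary — the simplest shapes that exercise
every measurement.  The forward model is: draw ideal intensities → Gaussian
PSF blur → Poisson shot noise → Gaussian read noise (clipped at zero).

DNA-bearing structures (nuclei and all puncta) carry Hoechst; puncta acquire
SYTOX, then MPO, then CitH3 in strictly nested stages 1–4, so a punctum
positive in a later-stage channel is positive in all earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from metquant.imgio import ChannelStack

CHANNELS = ("hoechst", "sytox", "mpo", "cith3")

#: staining-combination classes in staging order (Fig-style nesting)
STAGE_CLASSES = ("H", "H+S", "H+S+M", "H+S+M+C")


class SimConfig(BaseModel):
    """Parameters of the synthetic field.

    Fractions are per-cell probabilities; intensity units are arbitrary
    fluorescence counts (the analyses are scale-free where it matters).
    """

    model_config = ConfigDict(extra="forbid")

    field_size_px: tuple[int, int] = (1024, 1024)
    n_cells: int = Field(200, ge=0)
    n_z: int = Field(1, ge=1)

    frac_pyroptotic: float = Field(0.20, ge=0, le=1)
    frac_apoptotic: float = Field(0.02, ge=0, le=1)
    frac_met_positive: float = Field(0.16, ge=0, le=1)

    puncta_mean: float = Field(0.0, ge=0)
    puncta_dispersion: float = Field(2.0, gt=0)
    polarity_kappa: float = Field(4.0, ge=0)
    staining_stage_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    nucleus_radius_px: float = Field(6.0, gt=0)
    nucleus_radius_jitter_px: float = Field(1.0, ge=0)
    cytoplasm_ratio: float = Field(2.0, gt=1)
    condensed_area_factor: float = Field(0.4, gt=0, lt=1)
    condensed_intensity_factor: float = Field(2.0, gt=1)
    punctum_radius_px: float = Field(1.6, gt=0)
    met_semiaxes_px: tuple[float, float] = (4.0, 2.5)

    nucleus_intensity: float = Field(120.0, gt=0)
    sytox_nucleus_intensity: float = Field(150.0, gt=0)
    cytoplasm_intensity: float = Field(25.0, ge=0)
    punctum_intensity: float = Field(160.0, gt=0)
    met_intensity: float = Field(180.0, gt=0)
    background_level: float = Field(5.0, ge=0)

    psf_sigma_px: float = Field(1.0, ge=0)
    poisson_noise: bool = True
    gaussian_noise_sd: float = Field(2.0, ge=0)

    cell_min_spacing_px: float | None = None  # auto when None

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.frac_pyroptotic + self.frac_apoptotic > 1:
            raise ValueError("frac_pyroptotic + frac_apoptotic must be <= 1")
        s = sum(self.staining_stage_probs)
        if abs(s - 1.0) > 1e-9:
            raise ValueError("staining_stage_probs must sum to 1")
        if any(p < 0 for p in self.staining_stage_probs):
            raise ValueError("staining_stage_probs must be nonnegative")
        return self

    def noiseless(self) -> "SimConfig":
        """A copy with PSF blur and both noise sources switched off."""
        return self.model_copy(
            update={"psf_sigma_px": 0.0, "poisson_noise": False, "gaussian_noise_sd": 0.0}
        )

    @classmethod
    def high_res(cls, **overrides) -> "SimConfig":
        """Preset emulating high-resolution (63×) per-cell imaging.

        Cells are large enough that cytoplasmic puncta are resolved; the
        default low-magnification field (the class defaults) emulates the
        stitched overview used for counting, where individual puncta are
        below the resolution limit and therefore not rendered.
        """
        base = dict(
            field_size_px=(1024, 1024), n_cells=60,
            nucleus_radius_px=12.0, nucleus_radius_jitter_px=1.0,
            cytoplasm_ratio=2.4, puncta_mean=5.0, polarity_kappa=4.0,
            frac_met_positive=1.0, frac_pyroptotic=0.0, frac_apoptotic=0.0,
        )
        base.update(overrides)
        return cls(**base)

    @property
    def max_cell_radius(self) -> float:
        return self.cytoplasm_ratio * (self.nucleus_radius_px + self.nucleus_radius_jitter_px)

    @property
    def min_spacing(self) -> float:
        if self.cell_min_spacing_px is not None:
            return self.cell_min_spacing_px
        # leave room for MET blobs of adjacent cells plus dilation merging
        met_clearance = 2 * 2 * self.met_semiaxes_px[0] + 8 if self.frac_met_positive > 0 else 4
        return 2 * self.max_cell_radius + met_clearance


@dataclass
class PunctumTruth:
    x: float
    y: float
    z: int
    angle_deg: float          # from nucleus center, 0 = toward MET anchor axis if any
    stage: int                # 1..4, index into STAGE_CLASSES
    radius_px: float

    @property
    def combo_class(self) -> str:
        return STAGE_CLASSES[self.stage - 1]


@dataclass
class MetTruth:
    anchor_x: float
    anchor_y: float
    center_x: float
    center_y: float
    semiaxes: tuple[float, float]
    angle_rad: float           # orientation of the major (outward) axis


@dataclass
class CellTruth:
    cell_id: int
    center_x: float
    center_y: float
    nucleus_radius_px: float   # as rendered (already shrunk if condensed)
    cell_radius_px: float
    condensed: bool
    fate: str                  # "live" | "pyroptotic" | "apoptotic"
    met: MetTruth | None = None
    puncta: list[PunctumTruth] = field(default_factory=list)


@dataclass
class FieldTruth:
    cells: list[CellTruth]
    field_size_px: tuple[int, int]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_condensed(self) -> int:
        return sum(c.condensed for c in self.cells)

    @property
    def n_met_positive(self) -> int:
        return sum(c.met is not None for c in self.cells)

    def all_puncta(self) -> list[tuple[CellTruth, PunctumTruth]]:
        return [(c, p) for c in self.cells for p in c.puncta]

    def stage_fractions(self) -> dict[str, float]:
        puncta = self.all_puncta()
        if not puncta:
            return {k: 0.0 for k in STAGE_CLASSES}
        counts = {k: 0 for k in STAGE_CLASSES}
        for _, p in puncta:
            counts[p.combo_class] += 1
        return {k: v / len(puncta) for k, v in counts.items()}


@dataclass
class TimelapseTruth:
    death_time_h: list[float | None]   # per cell; None = survives
    frame_times_h: list[float]

    def dead_fraction_at(self, t: float) -> float:
        n = len(self.death_time_h)
        if n == 0:
            return 0.0
        return sum(1 for d in self.death_time_h if d is not None and d <= t) / n


class PlacementError(RuntimeError):
    """Cell count infeasible for the field size at the required spacing."""


def _place_cells(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Random sequential adsorption of cell centers with a minimum spacing."""
    h, w = config.field_size_px
    margin = config.max_cell_radius + 2 * config.met_semiaxes_px[0] + 2
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        if config.n_cells == 0:
            return np.empty((0, 2))
        raise PlacementError(f"field {config.field_size_px} too small for cell radius")
    d2 = config.min_spacing ** 2
    centers: list[tuple[float, float]] = []
    arr = np.empty((0, 2))
    max_tries = max(20000, 400 * config.n_cells)
    tries = 0
    while len(centers) < config.n_cells:
        if tries >= max_tries:
            raise PlacementError(
                f"placed only {len(centers)}/{config.n_cells} cells after {max_tries} tries; "
                "enlarge the field or reduce n_cells/spacing"
            )
        tries += 1
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if arr.size:
            dx = arr[:, 0] - x
            dy = arr[:, 1] - y
            if np.min(dx * dx + dy * dy) < d2:
                continue
        centers.append((x, y))
        arr = np.asarray(centers)
    return arr


def _add_disk(img: np.ndarray, cx: float, cy: float, r: float, value: float) -> None:
    rr, cc = draw_disk((cy, cx), r, shape=img.shape)
    img[rr, cc] += value


def _build_truth(config: SimConfig, rng: np.random.Generator) -> FieldTruth:
    centers = _place_cells(config, rng)
    n = len(centers)
    fate_draw = rng.random(n)
    met_draw = rng.random(n)
    radii = config.nucleus_radius_px + rng.uniform(
        -config.nucleus_radius_jitter_px, config.nucleus_radius_jitter_px, size=n
    )
    cells: list[CellTruth] = []
    for i in range(n):
        x, y = centers[i]
        if fate_draw[i] < config.frac_pyroptotic:
            fate = "pyroptotic"
        elif fate_draw[i] < config.frac_pyroptotic + config.frac_apoptotic:
            fate = "apoptotic"
        else:
            fate = "live"
        condensed = fate == "apoptotic"
        r_nuc = radii[i] * (math.sqrt(config.condensed_area_factor) if condensed else 1.0)
        r_cell = config.cytoplasm_ratio * radii[i]
        cell = CellTruth(i + 1, float(x), float(y), float(r_nuc), float(r_cell),
                         condensed, fate)
        if met_draw[i] < config.frac_met_positive:
            phi = rng.uniform(0, 2 * math.pi)
            a, b = config.met_semiaxes_px
            ax, ay = x + r_cell * math.cos(phi), y + r_cell * math.sin(phi)
            mx, my = x + (r_cell + a) * math.cos(phi), y + (r_cell + a) * math.sin(phi)
            cell.met = MetTruth(float(ax), float(ay), float(mx), float(my), (a, b), phi)
            # puncta belong to MET-releasing cells; count ~ negative binomial
            k = config.puncta_dispersion
            p_nb = k / (k + config.puncta_mean) if config.puncta_mean > 0 else 1.0
            n_puncta = int(rng.negative_binomial(k, p_nb)) if config.puncta_mean > 0 else 0
            cell.puncta = _draw_puncta(cell, n_puncta, phi, config, rng)
        cells.append(cell)
    return FieldTruth(cells, config.field_size_px)


def _draw_puncta(
    cell: CellTruth,
    n_puncta: int,
    anchor_angle: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[PunctumTruth]:
    """Place puncta in the cytoplasm annulus, von-Mises polarized toward the
    MET anchor (uniform when kappa=0), with no punctum-punctum overlap."""
    p_r = config.punctum_radius_px
    r_lo = cell.nucleus_radius_px + p_r + 3.0
    r_hi = cell.cell_radius_px - p_r - 1.0
    if r_hi <= r_lo:
        return []
    out: list[PunctumTruth] = []
    min_d2 = (2 * p_r + 3.0) ** 2
    for _ in range(n_puncta):
        for _try in range(50):
            if config.polarity_kappa > 0:
                theta = float(rng.vonmises(anchor_angle, config.polarity_kappa))
            else:
                theta = float(rng.uniform(-math.pi, math.pi))
            rad = float(np.sqrt(rng.uniform(r_lo ** 2, r_hi ** 2)))
            px = cell.center_x + rad * math.cos(theta)
            py = cell.center_y + rad * math.sin(theta)
            if all((px - q.x) ** 2 + (py - q.y) ** 2 >= min_d2 for q in out):
                stage = int(rng.choice(4, p=config.staining_stage_probs)) + 1
                z = int(rng.integers(config.n_z))
                rel = math.degrees(theta - anchor_angle)
                rel = (rel + 180.0) % 360.0 - 180.0
                out.append(PunctumTruth(px, py, z, rel, stage, p_r))
                break
        # a punctum that cannot be placed without overlap is dropped: the
        # truth always matches what is rendered
    return out


def _render_field(config: SimConfig, truth: FieldTruth) -> np.ndarray:
    h, w = config.field_size_px
    img = np.zeros((4, config.n_z, h, w), dtype=np.float64)
    hoechst, sytox, mpo, cith3 = img
    for z in range(config.n_z):
        for cell in truth.cells:
            # cytoplasm body (MPO) on every slice
            _add_disk(mpo[z], cell.center_x, cell.center_y, cell.cell_radius_px,
                      config.cytoplasm_intensity)
            # nucleus on every slice
            inten = config.nucleus_intensity * (
                config.condensed_intensity_factor if cell.condensed else 1.0
            )
            _add_disk(hoechst[z], cell.center_x, cell.center_y,
                      cell.nucleus_radius_px, inten)
            if cell.fate == "pyroptotic":
                _add_disk(sytox[z], cell.center_x, cell.center_y,
                          cell.nucleus_radius_px, config.sytox_nucleus_intensity)
            if cell.met is not None:
                m = cell.met
                for ch in (sytox[z], mpo[z], cith3[z]):
                    rr, cc = draw_ellipse(m.center_y, m.center_x,
                                          m.semiaxes[1], m.semiaxes[0],
                                          shape=ch.shape, rotation=-m.angle_rad)
                    ch[rr, cc] += config.met_intensity
            for p in cell.puncta:
                if p.z != z:
                    continue
                _add_disk(hoechst[z], p.x, p.y, p.radius_px, config.punctum_intensity)
                if p.stage >= 2:
                    _add_disk(sytox[z], p.x, p.y, p.radius_px, config.punctum_intensity)
                if p.stage >= 3:
                    _add_disk(mpo[z], p.x, p.y, p.radius_px, config.punctum_intensity)
                if p.stage >= 4:
                    _add_disk(cith3[z], p.x, p.y, p.radius_px, config.punctum_intensity)
    img += config.background_level
    return img


def _apply_noise(img: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.psf_sigma_px > 0:
        img = gaussian_filter(img, sigma=(0, 0, config.psf_sigma_px, config.psf_sigma_px))
    if config.poisson_noise:
        img = rng.poisson(img).astype(np.float64)
    if config.gaussian_noise_sd > 0:
        img = img + rng.normal(0, config.gaussian_noise_sd, size=img.shape)
    return np.clip(img, 0, None)


def simulate_field(config: SimConfig, seed: int) -> tuple[ChannelStack, FieldTruth]:
    """Render one synthetic 4-channel field; identical (config, seed) pairs
    produce bit-identical output."""
    rng = np.random.default_rng(seed)
    truth = _build_truth(config, rng)
    img = _render_field(config, truth)
    img = _apply_noise(img, config, rng)
    stack = ChannelStack(img, CHANNELS)
    return stack, truth


def simulate_timelapse(
    config: SimConfig,
    seed: int,
    plateau_frac: float = 0.20,
    onset_midpoint_h: float = 5.0,
    onset_scale_h: float = 1.0,
    interval_h: float = 0.25,
    duration_h: float = 16.0,
) -> tuple[list[ChannelStack], TimelapseTruth]:
    """Render a SYTOX/Hoechst time-lapse with logistic-distributed death onset.

    A fraction ``plateau_frac`` of cells is doomed; each doomed cell's SYTOX
    signal (its whole nucleus) switches on at a death time drawn from a
    logistic distribution truncated to the recording window, so the dead
    fraction plateaus at ``plateau_frac``.  Hoechst is rendered only at frame
    0 — a single UV exposure at the start — which provides the normalizing
    initial nucleus count.
    """
    if not 0 <= plateau_frac <= 1:
        raise ValueError("plateau_frac must be in [0, 1]")
    if interval_h <= 0 or duration_h <= 0:
        raise ValueError("interval and duration must be positive")
    rng = np.random.default_rng(seed)
    truth_field = _build_truth(
        config.model_copy(update={"frac_met_positive": 0.0, "frac_pyroptotic": 0.0,
                                  "frac_apoptotic": 0.0}),
        rng,
    )
    n = truth_field.n_cells
    doomed = rng.random(n) < plateau_frac
    death: list[float | None] = [None] * n
    # truncated logistic via inverse CDF, robust for any midpoint/scale
    cdf = lambda t: 1.0 / (1.0 + math.exp(-(t - onset_midpoint_h) / onset_scale_h))
    f0, f1 = cdf(0.0), cdf(duration_h)
    for i in np.flatnonzero(doomed):
        u = min(max(float(rng.uniform(f0, f1)), 1e-12), 1 - 1e-12)
        t = onset_midpoint_h + onset_scale_h * math.log(u / (1.0 - u))
        death[i] = min(max(t, 0.0), duration_h)
    n_frames = int(round(duration_h / interval_h)) + 1
    times = [i * interval_h for i in range(n_frames)]

    h, w = config.field_size_px
    frames: list[ChannelStack] = []
    for t in times:
        img = np.zeros((2, 1, h, w), dtype=np.float64)
        if t == times[0]:
            for cell in truth_field.cells:
                _add_disk(img[0, 0], cell.center_x, cell.center_y,
                          cell.nucleus_radius_px, config.nucleus_intensity)
        for i, cell in enumerate(truth_field.cells):
            if death[i] is not None and death[i] <= t:
                _add_disk(img[1, 0], cell.center_x, cell.center_y,
                          cell.nucleus_radius_px, config.sytox_nucleus_intensity)
        img += config.background_level
        img = _apply_noise(img, config, rng)
        frames.append(ChannelStack(img, ("hoechst", "sytox"), time_h=t))
    return frames, TimelapseTruth(death, times)


def truth_to_tables(truth: FieldTruth):
    """Flatten a FieldTruth into (cells, puncta) DataFrames for CSV export."""
    import pandas as pd

    cell_rows = []
    punctum_rows = []
    for c in truth.cells:
        cell_rows.append({
            "cell_id": c.cell_id, "center_x": c.center_x, "center_y": c.center_y,
            "nucleus_radius_px": c.nucleus_radius_px, "cell_radius_px": c.cell_radius_px,
            "condensed": c.condensed, "fate": c.fate,
            "met_anchor_x": c.met.anchor_x if c.met else np.nan,
            "met_anchor_y": c.met.anchor_y if c.met else np.nan,
            "n_puncta": len(c.puncta),
        })
        for p in c.puncta:
            punctum_rows.append({
                "cell_id": c.cell_id, "x": p.x, "y": p.y, "z": p.z,
                "angle_deg": p.angle_deg, "stage": p.stage,
                "combo_class": p.combo_class,
            })
    return pd.DataFrame(cell_rows), pd.DataFrame(punctum_rows)
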