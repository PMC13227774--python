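"""Ground-truthed synthetic data for the whole screening pipeline.

Three generators stand in for the laboratory artefacts:

1. :func:`render_plant_image` draws a fan of grass-like tillers on a
   near-white studio background with a calibration ruler, and returns
   the exact vector-geometry ground truth (hull area, Feret widths,
   bounding box, outline perimeter).  Ground truth is computed from the
   generating vectors, never from pixels, so any disagreement with the
   measurement code is attributable to pixelation or to the code under
   test — not to the fixture.
2. :func:`simulate_trial` draws a balanced two-environment nested
   randomized-block trial (replicates nested within salinity
   environment) with explicit stress / genotype / interaction / block
   effects.
3. :func:`simulate_physiology` draws pigment, proline and ion tables
   whose structure follows the canonical tolerance-class pattern:
   tolerant genotypes keep chlorophyll and a high K+/Na+ ratio under
   salt, sensitive ones do not.

All three are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString
from shapely.ops import unary_union
from PIL import Image

from .imaging import hsb_to_rgb
from .morphometrics import max_feret, min_feret

__all__ = [
    "PlantRenderSpec",
    "GroundTruth",
    "TrialSimSpec",
    "TraitEffect",
    "PhysioSimSpec",
    "ClassParams",
    "RULER_MARGIN_PX",
    "render_plant_image",
    "simulate_trial",
    "simulate_physiology",
    "write_image_with_sidecar",
    "DEFAULT_GENOTYPES",
    "DEFAULT_TOLERANCE_CLASSES",
]

#: bottom strip of the canvas reserved for the calibration ruler
RULER_MARGIN_PX = 40

#: six-genotype panel mirroring a typical salinity screen: three
#: doubled-haploid lines plus the usual tolerant (Pokkali) and
#: sensitive (IR29) checks and a mega-variety (Ciherang)
DEFAULT_GENOTYPES = ("DH1", "DH2", "DH3", "Ciherang", "Pokkali", "IR29")

DEFAULT_TOLERANCE_CLASSES = {
    "DH1": "tolerant",
    "DH2": "tolerant",
    "DH3": "moderate",
    "Ciherang": "sensitive",
    "Pokkali": "tolerant",
    "IR29": "sensitive",
}


# ---------------------------------------------------------------------------
# plant image rendering


@dataclass
class PlantRenderSpec:
    """Parameters of the vector fan plant and its studio scene."""

    n_tillers: int = 7
    tiller_length_px: float = 380.0
    fan_half_angle: float = 35.0  # degrees
    leaf_thickness_px: float = 9.0
    base_point: tuple[int, int] | None = None  # (row, col); default bottom-center
    leaf_hue: float = 110.0  # degrees, green band
    hue_jitter: float = 10.0
    background_level: int = 245
    ruler_length_px: int = 200
    ruler_length_cm: float = 20.0
    canvas_height: int = 480
    canvas_width: int = 640
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tillers < 1:
            raise ValueError("n_tillers must be >= 1")
        if not (0.0 < self.fan_half_angle < 90.0):
            raise ValueError("fan_half_angle must lie in (0, 90) degrees")
        if self.tiller_length_px <= 0 or self.leaf_thickness_px <= 0:
            raise ValueError("tiller length and thickness must be positive")
        if not (0 <= self.background_level <= 255):
            raise ValueError("background_level must be 0..255")
        if self.ruler_length_px <= 0 or self.ruler_length_cm <= 0:
            raise ValueError("ruler length must be positive in both units")

    @property
    def cm_per_pixel(self) -> float:
        return self.ruler_length_cm / self.ruler_length_px


@dataclass
class GroundTruth:
    """Vector-geometry truth for one rendered plant (cm units)."""

    true_convex_area: float
    true_width: float
    true_height: float
    true_feret: float
    true_minferet: float
    true_perimeter: float
    foreground_pixel_count: int

    def to_dict(self) -> dict:
        return asdict(self)


def _tiller_segments(spec: PlantRenderSpec) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Deterministic fan geometry in (x, y) = (col, row) coordinates."""
    if spec.base_point is None:
        # leave room for the capsule half-thickness below the base
        base = (spec.canvas_height - RULER_MARGIN_PX - 1 - int(np.ceil(spec.leaf_thickness_px)),
                spec.canvas_width // 2)
    else:
        base = spec.base_point
    by, bx = float(base[0]), float(base[1])
    n = spec.n_tillers
    if n == 1:
        angles = np.array([0.0])
    else:
        angles = np.linspace(-spec.fan_half_angle, spec.fan_half_angle, n)
    # central tillers tallest: a shallow parabolic taper gives a fan shape
    rel = angles / spec.fan_half_angle if spec.fan_half_angle > 0 else angles
    lengths = spec.tiller_length_px * (1.0 - 0.25 * rel**2)
    segs = []
    for ang, length in zip(np.deg2rad(angles), lengths):
        tip = (bx + length * np.sin(ang), by - length * np.cos(ang))
        segs.append(((bx, by), tip))
    return segs


def plant_geometry(spec: PlantRenderSpec) -> shapely.Geometry:
    """Union of flat-capped tiller capsules (vector foreground)."""
    half = spec.leaf_thickness_px / 2.0
    caps = []
    for i, (a, b) in enumerate(_tiller_segments(spec)):
        cap = LineString([a, b]).buffer(half, cap_style="flat")
        minx, miny, maxx, maxy = cap.bounds
        if (minx < 0 or miny < 0 or maxx > spec.canvas_width
                or maxy > spec.canvas_height - RULER_MARGIN_PX):
            raise ValueError(
                f"tiller {i} exceeds the canvas (bounds {cap.bounds}); "
                "enlarge the canvas or shorten the fan"
            )
        caps.append(cap)
    return unary_union(caps)


def _outline_vertices(geom: shapely.Geometry) -> np.ndarray:
    polys = [geom] if geom.geom_type == "Polygon" else list(geom.geoms)
    return np.concatenate([np.asarray(p.exterior.coords) for p in polys])


def _exterior_length(geom: shapely.Geometry) -> float:
    polys = [geom] if geom.geom_type == "Polygon" else list(geom.geoms)
    return float(sum(p.exterior.length for p in polys))


def render_plant_image(spec: PlantRenderSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render the fan plant and return (RGB uint8 image, GroundTruth).

    Foreground pixels are those whose centers fall inside the vector
    geometry; their hue is drawn around ``leaf_hue`` with per-pixel
    jitter.  The ruler bar lives in the reserved bottom margin and is
    excluded from the ground truth.
    """
    geom = plant_geometry(spec)
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas_height, spec.canvas_width

    # rasterise: pixel (r, c) center is (c + .5, r + .5) in (x, y)
    minx, miny, maxx, maxy = geom.bounds
    c0, c1 = max(int(minx) - 1, 0), min(int(maxx) + 2, w)
    r0, r1 = max(int(miny) - 1, 0), min(int(maxy) + 2, h)
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    inside = shapely.contains_xy(geom, cols + 0.5, rows + 0.5)
    fg_rows = rows[inside] + 0
    fg_cols = cols[inside] + 0
    n_fg = int(inside.sum())

    img = np.full((h, w, 3), spec.background_level, dtype=np.uint8)
    hue = spec.leaf_hue + rng.uniform(-spec.hue_jitter, spec.hue_jitter, n_fg)
    sat = np.clip(rng.normal(65.0, 5.0, n_fg), 30.0, 100.0)
    bri = np.clip(rng.normal(55.0, 5.0, n_fg), 20.0, 80.0)
    hsb = np.stack([hue, sat, bri], axis=-1).reshape(-1, 1, 3)
    img[fg_rows, fg_cols] = hsb_to_rgb(hsb).reshape(-1, 3)

    # ruler: dark horizontal bar in the reserved margin
    bar_row = h - RULER_MARGIN_PX // 2
    img[bar_row - 3 : bar_row + 3, 10 : 10 + spec.ruler_length_px] = 60

    s = spec.cm_per_pixel
    hull = geom.convex_hull
    hull_pts = np.asarray(hull.exterior.coords)[:-1]
    gt = GroundTruth(
        true_convex_area=hull.area * s * s,
        true_width=(maxx - minx) * s,
        true_height=(maxy - miny) * s,
        true_feret=max_feret(hull_pts) * s,
        true_minferet=min_feret(hull_pts) * s,
        true_perimeter=_exterior_length(geom) * s,
        foreground_pixel_count=n_fg,
    )
    return img, gt


def write_image_with_sidecar(
    path: str | Path, img: np.ndarray, gt: GroundTruth, cm_per_pixel: float
) -> Path:
    """Write an 8-bit RGB PNG plus a JSON sidecar with the ground truth
    and the calibration; returns the sidecar path."""
    path = Path(path)
    Image.fromarray(img, mode="RGB").save(path)
    sidecar = path.with_suffix(".json")
    payload = {"cm_per_pixel": cm_per_pixel, "ruler_margin_px": RULER_MARGIN_PX,
               "ground_truth": gt.to_dict()}
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return sidecar


# ---------------------------------------------------------------------------
# trial simulation


@dataclass
class TraitEffect:
    """Effect structure of one trait in the simulated trial.

    ``stress_effect`` is the normal-minus-saline difference d; the
    environment effects are +d/2 (normal) and -d/2 (saline), so they
    sum to zero.  ``genotype_effects`` (length g) and ``gxs_effects``
    (g x e) must sum to zero within their factor.
    """

    grand_mean: float
    stress_effect: float = 0.0
    genotype_effects: tuple[float, ...] | None = None
    gxs_effects: tuple[tuple[float, ...], ...] | None = None


@dataclass
class TrialSimSpec:
    """Balanced nested-RBD trial: |G| genotypes x 2 environments x
    n_reps replicate blocks (nested in environment) x n_samples plants
    per plot."""

    genotype_labels: tuple[str, ...] = DEFAULT_GENOTYPES
    env_labels: tuple[str, str] = ("normal", "saline")
    n_reps: int = 3
    n_samples_per_plot: int = 3
    traits: dict[str, TraitEffect] = field(default_factory=dict)
    block_sd: float = 0.03
    residual_sd: float = 0.08
    #: 'relative': SDs are fractions of each trait's grand mean (sane for
    #: multi-trait tables spanning orders of magnitude); 'absolute': SDs
    #: are on the raw trait scale
    sd_mode: str = "relative"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1 or self.n_samples_per_plot < 1:
            raise ValueError("replicates and samples must be >= 1")
        if self.sd_mode not in ("relative", "absolute"):
            raise ValueError("sd_mode must be 'relative' or 'absolute'")
        if self.block_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not self.traits:
            self.traits = default_trial_traits()
        g, e = len(self.genotype_labels), len(self.env_labels)
        for name, eff in self.traits.items():
            if eff.genotype_effects is not None:
                v = np.asarray(eff.genotype_effects, dtype=float)
                if v.shape != (g,) or abs(v.sum()) > 1e-8:
                    raise ValueError(
                        f"trait {name!r}: genotype_effects must be length {g} and sum to zero"
                    )
            if eff.gxs_effects is not None:
                m = np.asarray(eff.gxs_effects, dtype=float)
                if m.shape != (g, e):
                    raise ValueError(f"trait {name!r}: gxs_effects must be shape ({g}, {e})")
                if np.abs(m.sum(axis=0)).max() > 1e-8 or np.abs(m.sum(axis=1)).max() > 1e-8:
                    raise ValueError(
                        f"trait {name!r}: gxs_effects margins must sum to zero"
                    )


def default_trial_traits() -> dict[str, TraitEffect]:
    """Default effect structure: salinity depresses most geometric
    traits strongly while genotype and GxS effects are nil — the
    pattern a dominated-by-stress pot screen shows.  Means are on
    plausible raw trait scales (cm, cm^2, unitless)."""
    strong = {
        "convex_area": (600.0, 250.0), "green_area": (220.0, 90.0),
        "saturation_area": (300.0, 130.0), "ratio_sat_conv": (0.50, 0.18),
        "perimeter": (400.0, 120.0), "width": (55.0, 16.0),
        "major": (75.0, 18.0), "minor": (35.0, 12.0), "feret": (85.0, 20.0),
        "integrated_density": (9e5, 3.5e5), "min_feret": (40.0, 14.0),
        "aspect_ratio": (2.4, 0.55), "roundness": (0.28, 0.08),
    }
    weak = {
        "ratio_green_conv": 0.35, "ratio_green_sat": 0.72, "height": 95.0,
        "red_index": 0.30, "green_index": 0.45, "blue_index": 0.25,
    }
    out = {k: TraitEffect(grand_mean=m, stress_effect=d) for k, (m, d) in strong.items()}
    out.update({k: TraitEffect(grand_mean=m, stress_effect=0.0) for k, m in weak.items()})
    return out


def simulate_trial(spec: TrialSimSpec) -> pd.DataFrame:
    """Draw the long-format trait table.

    y = mu + stress + genotype + GxS + block(env) + eps, with Gaussian
    block and residual noise.  Noise SDs are applied on the raw scale
    of each trait proportionally to its grand mean (relative SDs), so
    a single pair (block_sd, residual_sd) expressed as fractions works
    across traits of very different magnitude; absolute SDs are
    obtained by using a single trait or unit grand means.
    """
    rng = np.random.default_rng(spec.seed)
    G = list(spec.genotype_labels)
    E = list(spec.env_labels)
    g, e, r, s = len(G), len(E), spec.n_reps, spec.n_samples_per_plot
    rows = []
    for trait, eff in spec.traits.items():
        genv = np.zeros(g) if eff.genotype_effects is None else np.asarray(eff.genotype_effects, float)
        gxs = np.zeros((g, e)) if eff.gxs_effects is None else np.asarray(eff.gxs_effects, float)
        env_eff = np.array([+eff.stress_effect / 2.0, -eff.stress_effect / 2.0])
        if spec.sd_mode == "relative":
            scale = abs(eff.grand_mean) if eff.grand_mean != 0 else 1.0
        else:
            scale = 1.0
        blocks = rng.normal(0.0, spec.block_sd * scale, size=(e, r))
        eps = rng.normal(0.0, spec.residual_sd * scale, size=(g, e, r, s))
        for gi, geno in enumerate(G):
            for ei, env in enumerate(E):
                for ri in range(r):
                    base = (eff.grand_mean + env_eff[ei] + genv[gi]
                            + gxs[gi, ei] + blocks[ei, ri])
                    for si in range(s):
                        rows.append((geno, env, ri + 1, si + 1, trait,
                                     base + eps[gi, ei, ri, si]))
    return pd.DataFrame(rows, columns=["genotype", "environment", "replicate",
                                       "sample", "trait", "value"])


# ---------------------------------------------------------------------------
# physiology / ion simulation


@dataclass
class ClassParams:
    """Saline-response parameters of one tolerance class."""

    chlorophyll_decline_pct: float
    carotenoid_decline_pct: float
    proline_increase_pct: float
    k_normal: float
    na_normal: float
    k_saline: float
    na_saline: float

    def __post_init__(self) -> None:
        for v in (self.chlorophyll_decline_pct, self.carotenoid_decline_pct):
            if v >= 100.0:
                raise ValueError("declines must stay below 100%")
        for v in (self.k_normal, self.na_normal, self.k_saline, self.na_saline):
            if v <= 0:
                raise ValueError("ion contents must be positive")


#: canonical class pattern: tolerant keeps pigments and K+/Na+ > 2,
#: moderate sits near 1 with a huge proline surge, sensitive collapses
DEFAULT_CLASS_PARAMS = {
    "tolerant": ClassParams(12.0, 10.0, 350.0, 3.9, 1.1, 3.0, 1.3),
    "moderate": ClassParams(50.0, 30.0, 1500.0, 3.2, 1.2, 2.2, 2.0),
    "sensitive": ClassParams(42.0, 25.0, 800.0, 2.6, 1.4, 1.2, 3.1),
}

#: baseline normal-environment physiology (mg/g pigments, umol/g proline)
PHYSIO_BASELINES = {
    "chlorophyll_total": 3.0,
    "chlorophyll_a": 2.2,
    "chlorophyll_b": 0.8,
    "carotenoid": 0.9,
    "proline": 2.0,
}


@dataclass
class PhysioSimSpec:
    """Physiology/ion generator: one value per genotype x environment."""

    tolerance_class: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TOLERANCE_CLASSES)
    )
    class_params: dict[str, ClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )
    baselines: dict[str, float] = field(default_factory=lambda: dict(PHYSIO_BASELINES))
    noise_sd: float = 0.0  # relative (fraction of each value)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.tolerance_class.values()) - set(self.class_params)
        if unknown:
            raise ValueError(f"unknown tolerance class(es): {sorted(unknown)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_physiology(spec: PhysioSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (physio_table, ion_table).

    physio_table: genotype, environment, trait, value (long format).
    ion_table: genotype, environment, na, k.
    With ``noise_sd`` = 0 the class parameters are reproduced exactly,
    e.g. a 10% chlorophyll-decline parameter yields a relative decrease
    of exactly 10.0.
    """
    rng = np.random.default_rng(spec.seed)
    physio_rows, ion_rows = [], []
    # small deterministic per-genotype offsets keep genotypes within a
    # class distinguishable without breaking the class ordering
    genotypes = list(spec.tolerance_class)
    for idx, geno in enumerate(genotypes):
        cls = spec.class_params[spec.tolerance_class[geno]]
        wiggle = 1.0 + 0.03 * ((idx % 3) - 1)
        for trait, base in spec.baselines.items():
            normal = base * wiggle
            if trait == "proline":
                saline = normal * (1.0 + cls.proline_increase_pct / 100.0)
            elif trait == "carotenoid":
                saline = normal * (1.0 - cls.carotenoid_decline_pct / 100.0)
            else:
                saline = normal * (1.0 - cls.chlorophyll_decline_pct / 100.0)
            for env, val in (("normal", normal), ("saline", saline)):
                noisy = val * (1.0 + rng.normal(0.0, spec.noise_sd)) if spec.noise_sd else val
                physio_rows.append((geno, env, trait, noisy))
        for env, k, na in (("normal", cls.k_normal * wiggle, cls.na_normal),
                           ("saline", cls.k_saline * wiggle, cls.na_saline)):
            if spec.noise_sd:
                k = k * (1.0 + rng.normal(0.0, spec.noise_sd))
                na = na * (1.0 + rng.normal(0.0, spec.noise_sd))
            ion_rows.append((geno, env, na, k))
    physio = pd.DataFrame(physio_rows, columns=["genotype", "environment", "trait", "value"])
    ions = pd.DataFrame(ion_rows, columns=["genotype", "environment", "na", "k"])
    return physio, ions
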