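"""End-to-end orchestration: images (or a measured trait table) ->
screening statistics -> multivariate grouping -> report.

Every stage writes its artifact (CSV/JSON, floats at 6 significant
digits) into the run's output directory before the next stage reads
on, so a run is reproducible byte-for-byte under a fixed seed and any
reported number is traceable to a file.  A stage failure halts the
pipeline with the stage name attached; optional inputs (physiology,
ions) merely mark their stages as skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from importlib.metadata import version as _dist_version

from . import imaging, morphometrics, multivariate, screening, synthetic

try:
    _pkg_version = _dist_version("potpheno")
except Exception:  # pragma: no cover - uninstalled source tree
    _pkg_version = "unknown"

__all__ = ["PipelineConfig", "RunReport", "PipelineError",
           "run_full", "simulate_fixtures"]

logger = logging.getLogger("potpheno")

_FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and input path."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, loadable from one YAML file.

    Unknown keys in the file are rejected so silent typos cannot
    change an analysis.
    """

    # segmentation
    channel: str = "brightness"
    min_object_px: int = 64
    largest_only: bool = False
    # colorimetric cutoffs
    green_lo: float = 60.0
    green_hi: float = 180.0
    s_min: float = 15.0
    sat_min: float = 25.0
    density_channel: str = "brightness"
    # screening
    alpha: float = 0.05
    log_offset: float = 1.0
    use_plot_means: bool = True
    relchange_scale: str = "percent"     # physiology tables
    ion_scale: str = "proportion"        # ion relative increases
    increase_traits: tuple[str, ...] = ("proline",)
    # multivariate
    n_factors: int = 3
    fa_rotation: str = "none"
    # run
    output_dir: str = "potpheno_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "increase_traits" in raw:
            raw["increase_traits"] = tuple(raw["increase_traits"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["increase_traits"] = list(d["increase_traits"])
        return d

    def analysis_dict(self) -> dict:
        """Config without the output location: what defines the analysis."""
        d = self.to_dict()
        d.pop("output_dir")
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.analysis_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def segmentation(self, exclude_margin_px: int = 0) -> imaging.SegmentationConfig:
        return imaging.SegmentationConfig(
            channel=self.channel, min_object_px=self.min_object_px,
            largest_only=self.largest_only, exclude_margin_px=exclude_margin_px,
        )

    def color_traits(self) -> morphometrics.ColorTraitConfig:
        return morphometrics.ColorTraitConfig(
            green_lo=self.green_lo, green_hi=self.green_hi, s_min=self.s_min,
            sat_min=self.sat_min, density_channel=self.density_channel,
        )


@dataclass
class RunReport:
    """Condensed result of one full run, JSON-serialisable."""

    retained_traits: list[str]
    sti: dict
    sti_means: dict
    pca_percent_variance: list[float]
    pca_quadrants: dict
    fa_loadings: dict | None
    relative_changes: dict | None
    ion_summary: dict | None
    correlations: dict | None
    skipped_stages: list[str]
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(_round_floats(dataclasses.asdict(self)),
                          indent=2, sort_keys=True)


def _round_floats(obj):
    """Round every float to 6 significant digits for stable output."""
    if isinstance(obj, float):
        return float(f"{obj:.6g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    stream = logging.StreamHandler(sys.stderr)
    stream.setFormatter(logging.Formatter("potpheno %(message)s"))
    logger.addHandler(stream)
    # no timestamps in the run log so re-runs stay byte-identical
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(message)s"))
    logger.addHandler(fh)


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, float_format=_FLOAT_FMT, index=index)


def measure_image_dir(image_dir: str | Path, cfg: PipelineConfig) -> pd.DataFrame:
    """Segment and measure every image listed in ``manifest.csv``
    inside ``image_dir``; returns the long trait table.

    The manifest columns are file, genotype, environment, replicate,
    sample; each image's JSON sidecar supplies the cm-per-pixel
    calibration and the ruler margin.
    """
    image_dir = Path(image_dir)
    manifest_path = image_dir / "manifest.csv"
    if not manifest_path.exists():
        raise PipelineError("measure", f"no manifest.csv in {image_dir}")
    manifest = pd.read_csv(manifest_path)
    rows = []
    from PIL import Image
    for rec in manifest.itertuples(index=False):
        img_path = image_dir / rec.file
        sidecar = json.loads(img_path.with_suffix(".json").read_text())
        img = np.asarray(Image.open(img_path).convert("RGB"))
        seg_cfg = cfg.segmentation(exclude_margin_px=int(sidecar.get("ruler_margin_px", 0)))
        try:
            mask = imaging.segment_plant(img, seg_cfg)
            roi = imaging.extract_roi(img, mask)
            scale = morphometrics.ScaleCalibration(sidecar["cm_per_pixel"])
            record = morphometrics.measure_all(roi, scale, cfg.color_traits())
        except (ValueError, imaging.SegmentationError) as exc:
            raise PipelineError("measure", f"{img_path}: {exc}") from exc
        for trait, value in record.to_dict().items():
            rows.append((rec.genotype, rec.environment, rec.replicate,
                         rec.sample, trait, value))
    return pd.DataFrame(rows, columns=screening.TABLE_COLUMNS)


def run_full(
    trait_csv: str | Path | None = None,
    image_dir: str | Path | None = None,
    physio_csv: str | Path | None = None,
    ion_csv: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> RunReport:
    """Execute the full screening chain and write all stage artifacts.

    Exactly one of ``trait_csv`` (a measured long trait table) or
    ``image_dir`` (images + manifest + sidecars) must be given.
    """
    cfg = config or PipelineConfig()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    skipped: list[str] = []

    if (trait_csv is None) == (image_dir is None):
        raise PipelineError("input", "give exactly one of trait_csv or image_dir")

    # --- stage: traits ---------------------------------------------------
    if image_dir is not None:
        traits = measure_image_dir(image_dir, cfg)
        logger.info("measure: %d images -> %d trait rows",
                    traits.groupby(["genotype", "environment", "replicate", "sample"]).ngroups,
                    len(traits))
    else:
        try:
            traits = pd.read_csv(trait_csv)
        except Exception as exc:
            raise PipelineError("traits", f"{trait_csv}: {exc}") from exc
    _write_csv(traits, outdir / "traits.csv")
    logger.info("traits: %d rows, %d traits", len(traits), traits["trait"].nunique())

    # --- stage: anova on the log scale -----------------------------------
    try:
        logged = screening.log_transform(traits, offset=cfg.log_offset)
        anova = screening.nested_anova(logged, use_plot_means=cfg.use_plot_means)
    except Exception as exc:
        raise PipelineError("anova", str(exc)) from exc
    _write_csv(anova.reset_index(), outdir / "anova.csv")
    retained = screening.filter_traits(anova, alpha=cfg.alpha)
    (outdir / "retained_traits.json").write_text(json.dumps(retained, indent=2))
    logger.info("anova: %d traits, %d stress-significant at alpha=%g",
                len(anova), len(retained), cfg.alpha)
    if len(retained) < 2:
        raise PipelineError("filter", "fewer than 2 stress-significant traits; "
                                      "cannot continue to STI/PCA")

    # --- stage: BLUE + STI on the raw scale ------------------------------
    try:
        blue = screening.blue_estimate(traits[traits["trait"].isin(retained)])
        sti_res = screening.sti(blue)
    except Exception as exc:
        raise PipelineError("blue/sti", str(exc)) from exc
    _write_csv(blue, outdir / "blue.csv")
    _write_csv(sti_res.with_mean_row().rename_axis("genotype").reset_index(),
               outdir / "sti.csv")
    logger.info("blue/sti: %d genotypes x %d traits",
                *sti_res.values.shape)

    # --- stage: multivariate grouping ------------------------------------
    try:
        pca_res = multivariate.pca(sti_res.values)
        n_factors = min(cfg.n_factors, sti_res.values.shape[1] - 1)
        fa_res = multivariate.factor_analysis(sti_res.values, n_factors=n_factors,
                                              rotation=cfg.fa_rotation)
    except Exception as exc:
        raise PipelineError("pca/fa", str(exc)) from exc
    (outdir / "pca.json").write_text(json.dumps(_round_floats({
        "eigenvalues": pca_res.eigenvalues.tolist(),
        "percent_variance": pca_res.percent_variance.tolist(),
        "cumulative_percent": pca_res.cumulative_percent.tolist(),
        "scores": pca_res.scores.to_dict(),
        "loadings": pca_res.loadings.to_dict(),
        "quadrant": pca_res.quadrant.to_dict(),
    }), indent=2, sort_keys=True))
    (outdir / "fa.json").write_text(json.dumps(_round_floats({
        "loadings": fa_res.loadings.to_dict(),
        "communality": fa_res.communality.to_dict(),
        "percent_variance": fa_res.percent_variance.to_dict(),
        "total_percent": fa_res.total_percent,
        "rotation": fa_res.rotation,
    }), indent=2, sort_keys=True))
    logger.info("pca: PC1 %.1f%%, PC1+PC2 %.1f%%",
                pca_res.percent_variance[0], pca_res.cumulative_percent[1])

    # --- stage: physiology integration (optional) ------------------------
    rel_changes = ion_summary = correlations = None
    if physio_csv is not None:
        try:
            physio = pd.read_csv(physio_csv)
            rel_changes = _physio_relative_changes(physio, cfg)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("relchange", f"{physio_csv}: {exc}") from exc
        _write_csv(rel_changes.rename_axis("genotype").reset_index(),
                   outdir / "relchange.csv")
        combined = sti_res.values.join(rel_changes, how="inner")
        try:
            corr = multivariate.correlate(combined)
            correlations = corr.r
        except ValueError as exc:
            logger.info("correlate: skipped (%s)", exc)
            skipped.append("correlate")
        else:
            _write_csv(correlations.rename_axis("variable").reset_index(),
                       outdir / "correlations.csv")
        logger.info("relchange: %d genotypes x %d physiology traits",
                    *rel_changes.shape)
    else:
        skipped.extend(["relchange", "correlate"])
        logger.info("relchange/correlate: skipped (no physiology table)")

    if ion_csv is not None:
        try:
            ions = pd.read_csv(ion_csv)
            ion_summary = screening.k_na_summary(ions)
        except Exception as exc:
            raise PipelineError("ions", f"{ion_csv}: {exc}") from exc
        _write_csv(ion_summary.reset_index(), outdir / "ions.csv")
        logger.info("ions: %d genotypes", len(ion_summary))
    else:
        skipped.append("ions")
        logger.info("ions: skipped (no ion table)")

    report = RunReport(
        retained_traits=retained,
        sti=sti_res.values.to_dict(),
        sti_means=sti_res.trait_means.to_dict(),
        pca_percent_variance=pca_res.percent_variance.tolist(),
        pca_quadrants=pca_res.quadrant.to_dict(),
        fa_loadings=fa_res.loadings.to_dict(),
        relative_changes=None if rel_changes is None else rel_changes.to_dict(),
        ion_summary=None if ion_summary is None else ion_summary.to_dict(),
        correlations=None if correlations is None else correlations.to_dict(),
        skipped_stages=skipped,
        provenance={
            "package_version": _pkg_version,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "config_hash": cfg.config_hash(),
            "config": cfg.analysis_dict(),
            "seed": cfg.seed,
        },
    )
    (outdir / "report.json").write_text(report.to_json())
    logger.info("report: written to %s", outdir / "report.json")
    return report


def _physio_relative_changes(physio: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Relative decrease for pigment-like traits, relative increase for
    the configured accumulation traits (proline by default)."""
    traits = list(physio["trait"].unique())
    inc = [t for t in traits if t in cfg.increase_traits]
    dec = [t for t in traits if t not in cfg.increase_traits]
    parts = []
    if dec:
        d = screening.relative_change(physio[physio["trait"].isin(dec)],
                                      mode="decrease", scale=cfg.relchange_scale)
        parts.append(d.rename(columns=lambda c: f"rd_{c}"))
    if inc:
        i = screening.relative_change(physio[physio["trait"].isin(inc)],
                                      mode="increase", scale=cfg.relchange_scale)
        parts.append(i.rename(columns=lambda c: f"ri_{c}"))
    return pd.concat(parts, axis=1)


def simulate_fixtures(kind: str, spec=None, outdir: str | Path = ".",
                      n_images: int = 3) -> list[Path]:
    """Write generator outputs (plus ground-truth sidecars) to disk.

    kind='images': n_images PNGs + JSON sidecars + manifest.csv.
    kind='trial': trial.csv, the long-format balanced trait table.
    kind='physiology': physio.csv + ions.csv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "images":
        base = spec or synthetic.PlantRenderSpec()
        manifest = []
        genos = synthetic.DEFAULT_GENOTYPES
        for i in range(n_images):
            env = ("normal", "saline")[(i // len(genos)) % 2]
            # salinity stunts the shoot: shorter, sparser fan
            stress = 0.65 if env == "saline" else 1.0
            ispec = dataclasses.replace(
                base, seed=base.seed + i,
                n_tillers=max(1, base.n_tillers + (i % 3) - (2 if env == "saline" else 0)),
                tiller_length_px=base.tiller_length_px * stress,
            )
            img, gt = synthetic.render_plant_image(ispec)
            path = outdir / f"plant_{i:03d}.png"
            synthetic.write_image_with_sidecar(path, img, gt, ispec.cm_per_pixel)
            written += [path, path.with_suffix(".json")]
            manifest.append((path.name, genos[i % len(genos)], env,
                             1 + (i // (2 * len(genos))), 1))
        mdf = pd.DataFrame(manifest, columns=["file", "genotype", "environment",
                                              "replicate", "sample"])
        mpath = outdir / "manifest.csv"
        mdf.to_csv(mpath, index=False)
        written.append(mpath)
    elif kind == "trial":
        tspec = spec or synthetic.TrialSimSpec()
        table = synthetic.simulate_trial(tspec)
        path = outdir / "trial.csv"
        _write_csv(table, path)
        written.append(path)
    elif kind == "physiology":
        pspec = spec or synthetic.PhysioSimSpec()
        physio, ions = synthetic.simulate_physiology(pspec)
        for name, df in (("physio.csv", physio), ("ions.csv", ions)):
            path = outdir / name
            _write_csv(df, path)
            written.append(path)
    else:
        raise ValueError("kind must be 'images', 'trial' or 'physiology'")
    return written
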