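"""Run configuration and end-to-end orchestration.

A :class:`RunConfig` bundles every knob of a simulated experiment — scene
template, photophysics, quenching model, acquisition, metric parameters and
the mandatory seed — and :func:`run_experiment` executes the corresponding
pipeline into a deterministic output directory: localization CSVs, rendered
TIFFs, metric JSONs and a single machine-readable ``summary.json``.
Identical config + seed give identical CSV/JSON bytes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .photophysics import AcquisitionParams, QuenchModel

__all__ = ["RunConfig", "run_experiment", "load_config"]


class SceneConfig(BaseModel):
    template: Literal["go_sheet", "fibres_over_flake", "capsules_on_film", "fig4_sweep"]
    field_nm: float = 10_000.0
    params: dict = Field(default_factory=dict)


class QuenchConfig(BaseModel):
    a: float = 2.6e-8
    wavelength_nm: float = 570.0

    def model_obj(self) -> QuenchModel:
        return QuenchModel(a=self.a, wavelength_nm=self.wavelength_nm)


class AcquisitionConfig(BaseModel):
    n_frames: int = 1000
    frame_rate_hz: float = 100.0
    p_on: float = 0.005
    psf_sigma_nm: float = 150.0
    camera_pixel_nm: float = 100.0
    detection_threshold_photons: float = 50.0
    background_photons_per_pixel: float = 1.0

    def params_obj(self) -> AcquisitionParams:
        return AcquisitionParams(**self.model_dump())


class PhotophysicsConfig(BaseModel):
    spacer_thickness_nm: float = 2.0
    photon_budget_mean: float = 1000.0
    densities: dict[str, float] = Field(default_factory=lambda: {
        "nonspecific_background": 50.0,
    })
    aggregate_rate_um2: float = 0.0


class MetricConfig(BaseModel):
    sr_pixel_nm: float = 10.0
    frc_pixel_nm: float = 5.0
    foi_bin_nm: float = 4.0
    fibre_width_nm: float = 11.0
    fluorophore_nm: float = 1.0


class RunConfig(BaseModel):
    """Schema-validated experiment configuration (units: nm, photons, um^-2)."""

    scene: SceneConfig
    quench: QuenchConfig = QuenchConfig()
    acquisition: AcquisitionConfig = AcquisitionConfig()
    photophysics: PhotophysicsConfig = PhotophysicsConfig()
    metrics: MetricConfig = MetricConfig()
    seed: int
    output_dir: str = "qstorm_run"

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v):
        if not 0 <= v < 2**31:
            raise ValueError("seed must be in [0, 2^31)")
        return v


def load_config(path, overrides: list[str] | None = None) -> RunConfig:
    """Load a JSON or YAML config file with optional ``key.sub=value`` overrides."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml  # PyYAML is ubiquitous but optional here

        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    for item in overrides or []:
        key, _, value = item.partition("=")
        node = payload
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        try:
            node[parts[-1]] = json.loads(value)
        except json.JSONDecodeError:
            node[parts[-1]] = value
    return RunConfig.model_validate(payload)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n")


def run_experiment(config: RunConfig) -> dict:
    """Execute the configured pipeline and persist a report bundle.

    Stage failures abort with the stage name attached; partial outputs
    written before the failure are left in place.
    """
    from . import experiments, metrics as met
    from .inference import RegionMask
    from .io import write_image, write_localizations
    from .photophysics import simulate_acquisition
    from .render import render_sr
    from .scene import AggregateParams, make_scene, place_fluorophores

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "template": config.scene.template}
    stage = "setup"
    try:
        if config.scene.template == "fig4_sweep":
            stage = "spacer_sweep"
            points, fit = experiments.spacer_sweep(
                true_a=config.quench.a,
                lambda_nm=config.quench.wavelength_nm,
                seed=config.seed,
                **config.scene.params,
            )
            points.to_csv(out / "efficiency_vs_gap.csv", index=False, float_format="%.6g")
            _dump(
                {"a_hat": fit.a_hat, "a_se": fit.a_se, "lambda_nm": fit.lambda_nm},
                out / "quench_fit.json",
            )
            summary["a_hat"] = fit.a_hat
            summary["a_se"] = fit.a_se
        else:
            stage = "make_scene"
            scene = make_scene(
                config.scene.template,
                seed=config.seed,
                field_nm=config.scene.field_nm,
                **config.scene.params,
            )
            (out / "scene.json").write_text(scene.to_json())
            stage = "place_fluorophores"
            pp = config.photophysics
            agg = (
                AggregateParams(rate_per_um2=pp.aggregate_rate_um2)
                if pp.aggregate_rate_um2 > 0
                else None
            )
            placements = place_fluorophores(
                scene,
                densities=pp.densities,
                spacer_thickness_nm=pp.spacer_thickness_nm,
                aggregate_params=agg,
                seed=config.seed,
                wavelength_nm=config.quench.wavelength_nm,
                photon_budget_mean=pp.photon_budget_mean,
            )
            stage = "simulate_acquisition"
            table = simulate_acquisition(
                placements,
                config.quench.model_obj(),
                config.acquisition.params_obj(),
                scene.go_membership(),
                seed=config.seed,
            )
            write_localizations(table, out / "localizations.csv")
            summary["n_localizations"] = int(len(table))
            stage = "render"
            image = render_sr(
                table,
                config.metrics.sr_pixel_nm,
                "histogram",
                field_size=scene.field_size,
            )
            write_image(image, out / "sr_image.tif")
            if len(table) >= 2:
                stage = "frc"
                frc_res = met.frc(
                    table,
                    pixel_nm=config.metrics.frc_pixel_nm,
                    seed=config.seed,
                    field_size=scene.field_size,
                )
                summary["frc_resolution_nm"] = (
                    float(frc_res.resolution_nm) if frc_res.resolved else None
                )
            if scene.go_regions and config.scene.template == "go_sheet":
                stage = "energy_transfer"
                from .inference import energy_transfer

                flake = scene.go_regions[0]
                xs = [v[0] for v in flake.vertices]
                ys = [v[1] for v in flake.vertices]
                margin = 0.1 * (max(xs) - min(xs))
                go_mask = RegionMask.from_rect(
                    min(xs) + margin, min(ys) + margin, max(xs) - margin, max(ys) - margin
                )
                w, h = scene.field_size
                # off-flake reference strip
                ngo_rect = _off_flake_rect(w, h, min(xs), max(xs), min(ys), max(ys))
                ngo_mask = RegionMask.from_rect(*ngo_rect, label="non-GO")
                est = energy_transfer(table, go_mask, ngo_mask)
                _dump(
                    {
                        "i_go": est.i_go,
                        "i_ngo": est.i_ngo,
                        "epsilon": est.epsilon,
                        "n_images": est.n_images,
                    },
                    out / "efficiency.json",
                )
                summary["epsilon"] = est.epsilon
        stage = "summary"
        _dump(summary, out / "summary.json")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return summary


def _off_flake_rect(w, h, x0, x1, y0, y1):
    """Largest axis-aligned strip of the field clear of the flake's bbox."""
    candidates = [
        (0.0, 0.0, x0, h),  # left
        (x1, 0.0, w, h),  # right
        (0.0, 0.0, w, y0),  # top
        (0.0, y1, w, h),  # bottom
    ]
    areas = [(c[2] - c[0]) * (c[3] - c[1]) for c in candidates]
    best = candidates[int(np.argmax(areas))]
    if min(best[2] - best[0], best[3] - best[1]) <= 0:
        raise ValueError("flake leaves no off-flake reference region")
    # inset 10% to avoid edge bleed
    mx = 0.1 * (best[2] - best[0])
    my = 0.1 * (best[3] - best[1])
    return best[0] + mx, best[1] + my, best[2] - mx, best[3] - my
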