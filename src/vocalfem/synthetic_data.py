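"""Synthetic ground-truth observations standing in for high-speed-video data.

The generator runs the forward model at known "true" parameters and adds
unbiased Gaussian noise whose area-equivalent standard deviation defaults to
1 mm² (width std = sigma_area / depth).  Negative noisy widths are clipped at
zero - the segmentation of a video frame would also floor at zero - and the
clip count is recorded in the metadata together with the truth and seed, so a
suite is exactly regenerable from its manifest.
"""
from __future__ import annotations

import json
import pathlib
from dataclasses import asdict, replace

import numpy as np

from .coupled_sim import ObservationSeries, SimulationConfig, run_forward
from .errors import ConfigurationError
from .geometry import LayeredMesh, build_m5_mesh
from .inference import ParameterVector
from .solid_fem import MaterialParams

#: experimental subglottal pressures (kPa) of the default suite
SUITE_PRESSURES = (0.910, 1.001, 1.092, 1.183)


def add_observation_noise(clean: ObservationSeries, noise_sigma_area: float,
                          seed: int) -> ObservationSeries:
    """Add unbiased Gaussian width noise (area sigma / depth), clipping at zero.

    The clip count is recorded in the metadata; clipping slightly biases the
    noise during closed phases, where a video segmentation would also floor
    at zero.
    """
    if noise_sigma_area < 0:
        raise ConfigurationError("noise level must be non-negative")
    depth = clean.depth if clean.depth > 0 else 14.0
    sigma_w = noise_sigma_area / depth
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    noisy = clean.width + rng.normal(0.0, sigma_w, size=clean.width.size) \
        if sigma_w > 0 else clean.width.copy()
    clipped = int(np.sum(noisy < 0))
    noisy = np.clip(noisy, 0.0, None)
    meta = dict(clean.metadata)
    meta.update({"seed": int(seed), "noise_sigma_area_mm2": noise_sigma_area,
                 "clip_count": clipped})
    return ObservationSeries(t=clean.t, width=noisy, depth=clean.depth,
                             noise_sigma_width=sigma_w, metadata=meta)


def make_observation(truth: ParameterVector, flow_model: str = "bernoulli_fixed",
                     noise_sigma_area: float = 1.0, seed: int = 0,
                     config: SimulationConfig | None = None,
                     mesh: LayeredMesh | None = None,
                     fixed: MaterialParams | None = None) -> ObservationSeries:
    """Simulate at ``truth`` and add the observation noise model.

    ``truth.p_sub``/``truth.m``/``truth.r_sep`` override the configuration;
    moduli, density and viscosity override the fixed material template.
    """
    if noise_sigma_area < 0:
        raise ConfigurationError("noise level must be non-negative")
    config = config or SimulationConfig(flow_model=flow_model)
    if config.flow_model != flow_model:
        config = replace(config, flow_model=flow_model)
    fixed = fixed or MaterialParams()
    mesh = mesh if mesh is not None else build_m5_mesh(config.resolution)
    mat = MaterialParams(E_body=truth.E_body, E_slp=truth.E_slp,
                         E_lig=truth.E_lig, E_epi=fixed.E_epi, nu=fixed.nu,
                         rho_b=truth.rho_b, eta=truth.eta)
    cfg = replace(config, p_sub=truth.p_sub, m=truth.m,
                  r_sep=truth.r_sep if truth.r_sep is not None else config.r_sep)
    clean = run_forward(cfg, mesh, mat)
    noisy = add_observation_noise(clean, noise_sigma_area, seed)
    noisy.metadata.update({"truth": truth.to_dict(),
                           "flow_model": cfg.flow_model})
    return noisy


def _suite_filename(p_sub: float) -> str:
    return f"obs_psub{int(round(p_sub * 1000)):04d}.csv"


def make_suite(outdir, truth: ParameterVector | None = None,
               flow_model: str = "bernoulli_fixed",
               pressures=SUITE_PRESSURES, noise_sigma_area: float = 1.0,
               base_seed: int = 0, config: SimulationConfig | None = None,
               mesh: LayeredMesh | None = None) -> dict:
    """Write one observation per subglottal pressure plus a truth manifest.

    Per-observation seeds derive deterministically from ``base_seed``, so
    regenerating from the manifest reproduces the CSVs bit for bit.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = truth or ParameterVector()
    config = config or SimulationConfig(flow_model=flow_model)
    mesh = mesh if mesh is not None else build_m5_mesh(config.resolution)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(base_seed).spawn(len(pressures))]
    manifest = {
        "flow_model": flow_model,
        "noise_sigma_area_mm2": noise_sigma_area,
        "base_seed": int(base_seed),
        "config": {k: v for k, v in asdict(config).items() if k != "viscous"},
        "observations": [],
    }
    for p_sub, seed in zip(pressures, seeds):
        t = replace(truth, p_sub=p_sub)
        obs = make_observation(t, flow_model, noise_sigma_area, seed,
                               config=config, mesh=mesh)
        name = _suite_filename(p_sub)
        obs.to_csv(outdir / name)
        manifest["observations"].append({
            "file": name, "p_sub_kpa": p_sub, "seed": seed,
            "truth": t.to_dict(),
            "clip_count": obs.metadata["clip_count"],
        })
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def regenerate_from_manifest(manifest_path, outdir=None) -> dict:
    """Re-run the generator with the seeds and truths recorded in a manifest."""
    manifest_path = pathlib.Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    outdir = pathlib.Path(outdir) if outdir is not None else manifest_path.parent
    cfg = SimulationConfig(**manifest["config"])
    mesh = build_m5_mesh(cfg.resolution)
    for entry in manifest["observations"]:
        truth = ParameterVector.from_mapping(entry["truth"])
        obs = make_observation(truth, manifest["flow_model"],
                               manifest["noise_sigma_area_mm2"], entry["seed"],
                               config=cfg, mesh=mesh)
        obs.to_csv(outdir / entry["file"])
    return manifest
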