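"""Run configurations, scenario presets, fixtures and orchestration.

Every reference run specification is available as a named preset with its
full-scale parameters; a ``scale`` factor produces desk-scale replicas:
the grid side shrinks linearly, field equilibration steps shrink with the
grid area (diffusive scaling), Langevin steps shrink linearly and the
particle count shrinks with the area so the area occupancy of the tracers
is preserved.  The scale factor is stamped into every manifest so reduced
and full-scale results are never conflated.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import io, stats
from .coupled import CouplingParams, run_coupled
from .phasefield import (DEFAULT_L, ModelParams, NormalizedField, equilibrate,
                         model_params, normalize_field)
from .tracers import ParticleSystem, PreferenceSpec, TrajectorySet, run_simulation

__all__ = [
    "RunConfig",
    "PRESET_NAMES",
    "load_preset",
    "load_config",
    "make_fixture_field",
    "run_scenario",
]


@dataclass
class RunConfig:
    """A complete, seeded recipe for one simulation scenario."""

    scenario: str
    model_id: int | None = 5
    field_overrides: dict = dc_field(default_factory=dict)
    n_field_steps: int | None = None
    particle: dict = dc_field(default_factory=dict)
    coupling: dict | None = None
    n_steps: int = 10_000_000
    n_discard: int = 1_000_000
    sample_every: int = 100
    field_seed: int = 1
    particle_seed: int = 2
    scale: float = 1.0
    L: int = DEFAULT_L
    analyses: tuple = ("tamsd", "rsd", "alpha")
    init_mean: float = 0.0

    def scaled(self, scale: float) -> "RunConfig":
        """Desk-scale replica: L ~ scale, field steps ~ scale^2, Langevin
        steps ~ scale, particle count ~ scale^2 (occupancy preserved)."""
        if scale == 1.0:
            return self
        cfg = dataclasses.replace(self)
        cfg.scale = scale
        cfg.L = max(16, int(round(self.L * scale)))
        if self.n_field_steps is not None:
            cfg.n_field_steps = max(1, int(round(self.n_field_steps * scale**2)))
        cfg.n_steps = max(1, int(round(self.n_steps * scale)))
        cfg.n_discard = int(round(self.n_discard * scale))
        cfg.particle = dict(self.particle)
        if cfg.particle.get("Np", 1) > 1:
            cfg.particle["Np"] = max(1, int(round(self.particle["Np"] * scale**2)))
        return cfg


def _single(Np=100, **kw):
    p = dict(Np=Np, epsilon=0.0, cb=1.0, D0=1.0, dt=1e-3, preference="none")
    p.update(kw)
    return p


def _multi(Np=512, epsilon=2.0, **kw):
    p = dict(Np=Np, epsilon=epsilon, sigma=3.0, cb=0.1, D0=1.0, dt=1e-3,
             preference="none")
    p.update(kw)
    return p


def _presets() -> dict[str, RunConfig]:
    reg = {}
    for m in range(1, 6):
        reg[f"model{m}"] = RunConfig(scenario=f"model{m}", model_id=m,
                                     n_steps=0, n_discard=0, analyses=())
    reg["fig2_single"] = RunConfig(
        scenario="fig2_single", model_id=5, particle=_single(),
        n_steps=10_000_000, n_discard=1_000_000, sample_every=10,
        analyses=("tamsd", "rsd", "residence"))
    reg["fig3_crowding"] = RunConfig(
        scenario="fig3_crowding", model_id=5, particle=_multi(Np=2048),
        n_steps=10_000_000, n_discard=1_000_000, sample_every=100,
        analyses=("tamsd", "alpha", "rsd"))
    reg["fig4_preference"] = RunConfig(
        scenario="fig4_preference", model_id=5,
        particle=_multi(Np=512, preference="Lo40"),
        n_steps=10_000_000, n_discard=1_000_000, sample_every=100,
        analyses=("tamsd", "alpha", "rsd"))
    reg["fig5_confinement"] = RunConfig(
        scenario="fig5_confinement", model_id=5, particle=_multi(Np=512),
        n_steps=2_000_000, n_discard=0, sample_every=1000,
        analyses=("confinement",))
    reg["fig6_coupled_weak"] = RunConfig(
        scenario="fig6_coupled_weak", model_id=None,
        field_overrides=dict(tau_r=np.inf, Lambda=-0.01, W=1.0, H=0.85,
                             l_rec=1280.0, alpha=0.0, N_imp=0),
        particle=_multi(Np=512), coupling=dict(alpha_g=0.5, r_g=2.0,
                                               update_stride=10),
        n_steps=40_000_000, n_discard=10_000_000, sample_every=1000,
        init_mean=0.0, analyses=("tamsd", "rsd"))
    reg["fig6_coupled_strong"] = dataclasses.replace(
        reg["fig6_coupled_weak"], scenario="fig6_coupled_strong",
        field_overrides=dict(tau_r=np.inf, Lambda=-1.0, W=1.0, H=0.85,
                             l_rec=1280.0, alpha=0.0, N_imp=0))
    return reg


_REGISTRY = _presets()
PRESET_NAMES = tuple(sorted(_REGISTRY))


def load_preset(name: str, scale: float = 1.0) -> RunConfig:
    """A fully populated :class:`RunConfig` for a named scenario.

    Names: model1..model5 (field equilibration only) and fig2_single,
    fig3_crowding, fig4_preference, fig5_confinement, fig6_coupled_weak,
    fig6_coupled_strong.  ``scale`` < 1 yields a desk-scale replica.
    """
    if name not in _REGISTRY:
        raise KeyError(f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}")
    return dataclasses.replace(_REGISTRY[name]).scaled(scale)


def load_config(path) -> RunConfig:
    """Read a run configuration from a flat YAML file.

    Sections: ``model`` (``model_id`` picks a reference preset, or any
    field parameter by name), ``grid`` (``L``, ``scale``), ``run``
    (``scenario``/``preset``, step counts, seeds, analyses), ``particles``
    and ``coupling``.  Any key overrides the preset value, e.g.::

        model: {model_id: 5, H: 2.12}
        grid: {L: 128}
        run: {preset: fig3_crowding, n_steps: 1000000, particle_seed: 7}
        particles: {Np: 512, epsilon: 2.0}
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    run = dict(raw.get("run", {}))
    name = run.pop("preset", run.pop("scenario", None))
    grid = dict(raw.get("grid", {}))
    cfg = load_preset(name, scale=grid.pop("scale", 1.0)) if name else \
        RunConfig(scenario=str(path))
    model = dict(raw.get("model", {}))
    if "model_id" in model:
        cfg.model_id = int(model.pop("model_id"))
    cfg.field_overrides = {**cfg.field_overrides, **model}
    if "L" in grid:
        cfg.L = int(grid.pop("L"))
    for key, val in run.items():
        if not hasattr(cfg, key):
            raise KeyError(f"unknown run key {key!r}")
        setattr(cfg, key, val)
    cfg.particle = {**cfg.particle, **raw.get("particles", {})}
    if raw.get("coupling"):
        cfg.coupling = {**(cfg.coupling or {}), **raw["coupling"]}
    return cfg


# ----------------------------------------------------------------------
# Test fixtures
# ----------------------------------------------------------------------

def make_fixture_field(kind: str, L: int = 64, seed: int = 0) -> NormalizedField:
    """Small synthetic normalized fields with known Lo geometry.

    * "stripe"  — left half cbar = 0 (Lo), right half 1 (Ld): Lo area
      fraction exactly one half.
    * "uniform" — constant cbar = 0.75 (all Ld).
    * "bimodal" — smoothed random two-level pattern (seeded), mimicking an
      equilibrated phase-separated field without running the PDE.
    """
    if L < 16:
        raise ValueError("fixture fields need L >= 16")
    if kind == "stripe":
        cbar = np.zeros((L, L))
        cbar[L // 2:, :] = 1.0
    elif kind == "uniform":
        cbar = np.full((L, L), 0.75)
    elif kind == "bimodal":
        from scipy.ndimage import gaussian_filter
        rng = np.random.default_rng(seed)
        raw = gaussian_filter(rng.standard_normal((L, L)), sigma=L / 16,
                              mode="wrap")
        levels = np.where(raw < np.median(raw), 0.2, 0.8)
        cbar = np.clip(gaussian_filter(levels, sigma=1.5, mode="wrap"), 0.0, 1.0)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return NormalizedField(cbar=cbar, c_min=0.0, c_max=1.0, dx=1.0)


# ----------------------------------------------------------------------
# Orchestration
# ----------------------------------------------------------------------

def _particle_system(cfg: RunConfig) -> ParticleSystem:
    p = dict(cfg.particle)
    pref = PreferenceSpec.from_string(p.pop("preference", "none"))
    return ParticleSystem(preference=pref, **p)


def run_scenario(config: RunConfig, out_dir) -> dict:
    """Execute a scenario end to end and write an output bundle.

    Stages: field equilibration (skipped for coupled scenarios, which
    grow their own field) -> particle run -> requested analyses.  Writes
    field/trajectory containers, tidy CSV analysis tables, a PNG of the
    final cbar and a ``manifest.json`` with the config, seeds, per-stage
    timings and output checksums.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": dataclasses.asdict(config), "stages": {},
                "outputs": {}, "scale": config.scale}
    t0 = time.perf_counter()
    files: dict[str, Path] = {}
    try:
        traj: TrajectorySet | None = None
        if config.coupling is not None:
            params = ModelParams(L=config.L, **config.field_overrides)
            sys_ = _particle_system(config)
            coup = CouplingParams(**config.coupling)
            traj, snaps = run_coupled(params, coup, sys_, config.n_steps,
                                      seed=config.particle_seed,
                                      n_discard=config.n_discard,
                                      sample_every=config.sample_every,
                                      init_mean=config.init_mean)
            nf = NormalizedField.from_raw(snaps[-1][1], dx=params.dx)
            manifest["stages"]["coupled"] = time.perf_counter() - t0
        else:
            params = model_params(config.model_id, L=config.L,
                                  n_steps=config.n_field_steps,
                                  **config.field_overrides)
            state = equilibrate(params, seed=config.field_seed)
            nf = normalize_field(state)
            files["field"] = out / "field.h5"
            io.save_field(files["field"], state, params, seed=config.field_seed)
            manifest["stages"]["field"] = time.perf_counter() - t0
            if config.n_steps > 0:
                sys_ = _particle_system(config)
                traj = run_simulation(nf, sys_, config.n_steps,
                                      n_discard=config.n_discard,
                                      sample_every=config.sample_every,
                                      seed=config.particle_seed)
                manifest["stages"]["particles"] = time.perf_counter() - t0
        files["cbar_png"] = out / "cbar.png"
        io.export_field_png(files["cbar_png"], nf)
        if traj is not None:
            files["traj"] = out / "traj.h5"
            io.save_trajectories(files["traj"], traj)
            _run_analyses(config, traj, nf, out, files)
        manifest["stages"]["total"] = time.perf_counter() - t0
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest["outputs"] = {k: str(v) for k, v in files.items()}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    manifest["outputs"] = {k: {"path": str(v), "sha256": io.file_sha256(v)}
                           for k, v in files.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_analyses(cfg: RunConfig, traj: TrajectorySet, nf: NormalizedField,
                  out: Path, files: dict) -> None:
    import pandas as pd
    if "tamsd" in cfg.analyses or "alpha" in cfg.analyses:
        curve = stats.ensemble_tamsd(traj)
        df = pd.DataFrame({"lag": curve.lags, "tamsd": curve.values})
        if "alpha" in cfg.analyses:
            df["alpha"] = stats.local_alpha(curve.lags, curve.values)
        files["tamsd"] = out / "tamsd.csv"
        df.to_csv(files["tamsd"], index=False)
    if "rsd" in cfg.analyses:
        curve = stats.rsd(traj, lag=traj.sampling_interval)
        sub = np.unique(np.geomspace(1, len(curve.times), 200).astype(int) - 1)
        files["rsd"] = out / "rsd.csv"
        pd.DataFrame({"t": curve.times[sub], "rsd": curve.values[sub]}
                     ).to_csv(files["rsd"], index=False)
    if "residence" in cfg.analyses:
        res = stats.residence_times(traj, nf)
        files["residence"] = out / "residence.csv"
        pd.DataFrame({"domain": np.where(res.lo, "Lo", "Ld"),
                      "duration": res.duration,
                      "censored": res.censored}).to_csv(files["residence"], index=False)
        try:
            fit = stats.fit_truncated_powerlaw(
                res.durations(), sampling_interval=traj.sampling_interval)
            files["residence_fit"] = out / "residence_fit.json"
            files["residence_fit"].write_text(json.dumps(dataclasses.asdict(fit)))
        except ValueError:
            pass
    if "confinement" in cfg.analyses:
        times, ratio = stats.confinement_ratio(traj, nf)
        files["confinement"] = out / "confinement.csv"
        pd.DataFrame({"t": times, "lo_ratio": ratio}
                     ).to_csv(files["confinement"], index=False)
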