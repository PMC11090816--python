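"""End-to-end pipeline: synthetic world -> soil moisture -> species fits
-> projections -> phytoclimates -> zones -> risk surfaces.

Stages are pure functions over a :class:`RunConfig`; :func:`run_pipeline`
chains them with per-stage caching (a stage is skipped when its outputs
exist and its config hash is unchanged in ``manifest.json``). Every
stochastic stage derives its own seed from the master seed, so two runs
with the same config are identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fitting, phyto, risk, synthetic
from .grids import Climatology, read_climatology, write_climatology
from .soil import simulate_soil_moisture
from .ttr import DEFAULT_CONSTANTS, uptake_ceiling

log = logging.getLogger("phytoclim")

STAGES = (
    "simulate-data", "soil-moisture", "fit-species", "project",
    "phytoclimate", "zones", "risk",
)


@dataclass
class ScenarioConfig:
    rcp_label: str = "rcp85"
    delta_t: float = 4.0
    precip_scale: float = 0.9
    co2: float = synthetic.RCP85_CO2
    n_gcms: int = 5
    temp_noise_sd: float = 0.5
    precip_noise_sd: float = 0.05


@dataclass
class RunConfig:
    """All knobs of a pipeline run, with field-protocol defaults.

    Defaults mirror the analysis protocol: ambient CO2 338 ppm, future
    CO2 438/677 ppm for the reduced/high emission pathways, presence cap
    400, 20 environmental zones, 18 phytoclimatic zones, TSS cutoff 0.7
    and 1000 DE generations (reduce ``generations`` for small runs; the
    deviation is logged).
    """

    n_rows: int = 30
    n_cols: int = 30
    cell_size: float = 25.0
    sea_fraction: float = 0.1
    seed: int = 0
    n_species: int = 42
    occurrences_min: int = 30
    occurrences_max: int = 200
    sampling_bias: bool = False
    scenarios: list[ScenarioConfig] = field(
        default_factory=lambda: [ScenarioConfig()]
    )
    co2_ambient: float = synthetic.AMBIENT_CO2
    generations: int = 1000
    popsize: int = 10
    presence_cap: int = 400
    k_env: int = 20
    k_zones: int = 18
    tss_cutoff: float = 0.7
    min_species_per_form: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scen = [ScenarioConfig(**s) for s in raw.pop("scenarios", [])]
        cfg = cls(**raw)
        if scen:
            cfg.scenarios = scen
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    def digest(self, *fields_used: str) -> str:
        d = asdict(self)
        if fields_used:
            d = {k: d[k] for k in fields_used}
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") & 0x7FFFFFFF


def _scenario_runs(cfg: RunConfig):
    for sc in cfg.scenarios:
        for g in range(sc.n_gcms):
            yield sc, g


class Manifest:
    def __init__(self, run_dir: Path):
        self.path = run_dir / "manifest.json"
        self.data = json.loads(self.path.read_text()) if self.path.exists() else {"stages": {}}

    def fresh(self, stage: str, digest: str, outputs: list[Path]) -> bool:
        entry = self.data["stages"].get(stage)
        return (
            entry is not None
            and entry["digest"] == digest
            and all(Path(p).exists() for p in entry["outputs"])
            and {str(p) for p in outputs} <= set(entry["outputs"])
        )

    def record(self, stage: str, digest: str, outputs: list[Path], seed: int,
               elapsed: float) -> None:
        self.data["stages"][stage] = {
            "digest": digest, "outputs": [str(p) for p in outputs],
            "seed": seed, "elapsed_s": round(elapsed, 3),
        }
        self.path.write_text(json.dumps(self.data, indent=1))


def run_pipeline(cfg: RunConfig, run_dir: str | Path, force: bool = False) -> Path:
    """Execute all stages into ``run_dir``; returns the run directory."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "config.yaml")
    manifest = Manifest(run_dir)
    if cfg.generations < 1000:
        log.info("protocol deviation: DE generations reduced to %d", cfg.generations)
    for stage in STAGES:
        _run_stage(stage, cfg, run_dir, manifest, force)
    return run_dir


def _run_stage(stage: str, cfg: RunConfig, run_dir: Path, manifest: Manifest,
               force: bool) -> None:
    fn = _STAGE_FNS[stage]
    digest = cfg.digest()
    t0 = time.time()
    outputs = fn(cfg, run_dir, manifest, force, dry=True)
    if not force and manifest.fresh(stage, digest, outputs):
        log.info("stage %s: cached, skipping", stage)
        return
    outputs = fn(cfg, run_dir, manifest, force, dry=False)
    seed = cfg.stage_seed(stage)
    manifest.record(stage, digest, outputs, seed, time.time() - t0)
    log.info("stage %s: done in %.1fs (seed %d)", stage, time.time() - t0, seed)


def _scen_tag(sc: ScenarioConfig, g: int) -> str:
    return f"{sc.rcp_label}_gcm{g}"


# --------------------------------------------------------------------- stages

def stage_simulate(cfg: RunConfig, run_dir: Path, manifest, force, dry=False):
    outputs = [run_dir / "ambient.nc", run_dir / "occurrences.csv",
               run_dir / "growth_forms.csv", run_dir / "species_truth.json"]
    outputs += [run_dir / f"future_{_scen_tag(sc, g)}.nc" for sc, g in _scenario_runs(cfg)]
    if dry:
        return outputs
    seed = cfg.stage_seed("simulate-data")
    clim = synthetic.generate_climatology(
        cfg.n_rows, cfg.n_cols, seed=seed, cell_size=cfg.cell_size,
        sea_fraction=cfg.sea_fraction, co2=cfg.co2_ambient,
    )
    write_climatology(clim, run_dir / "ambient.nc")
    for sc, g in _scenario_runs(cfg):
        spec = synthetic.ScenarioSpec(
            rcp_label=sc.rcp_label, delta_t=sc.delta_t, precip_scale=sc.precip_scale,
            co2=sc.co2, gcm_seed=seed + 1000 + g,
            temp_noise_sd=sc.temp_noise_sd, precip_noise_sd=sc.precip_noise_sd,
        )
        write_climatology(synthetic.generate_future(clim, spec),
                          run_dir / f"future_{_scen_tag(sc, g)}.nc")
    moisture = simulate_soil_moisture(clim).moisture
    species = synthetic.generate_species(
        cfg.n_species, clim, seed=seed + 1, moisture=moisture,
        occurrences_per_species=(cfg.occurrences_min, cfg.occurrences_max),
        sampling_bias=cfg.sampling_bias,
    )
    synthetic.occurrences_frame(species, clim.grid).to_csv(
        run_dir / "occurrences.csv", index=False)
    synthetic.growth_form_frame(species).to_csv(
        run_dir / "growth_forms.csv", index=False)
    truth = {
        s.species_id: {
            "growth_form": s.growth_form, "pathway": s.pathway,
            "params": s.true_params.to_vector().tolist(),
            "prevalence": s.prevalence,
            "suitable_cells": np.flatnonzero(s.true_suitable).tolist(),
        }
        for s in species
    }
    (run_dir / "species_truth.json").write_text(json.dumps(truth))
    return outputs


def stage_soil(cfg, run_dir, manifest, force, dry=False):
    tags = ["ambient"] + [_scen_tag(sc, g) for sc, g in _scenario_runs(cfg)]
    outputs = [run_dir / f"soil_{t}.npz" for t in tags]
    if dry:
        return outputs
    for t in tags:
        src = run_dir / (f"{t}.nc" if t == "ambient" else f"future_{t}.nc")
        if not src.exists():
            raise FileNotFoundError(
                f"missing climatology {src}; run the simulate-data stage first")
        clim = read_climatology(src)
        sm = simulate_soil_moisture(clim)
        np.savez_compressed(run_dir / f"soil_{t}.npz", moisture=sm.moisture, pet=sm.pet)
    return outputs


def _load_forcing(run_dir: Path, tag: str):
    src = run_dir / ("ambient.nc" if tag == "ambient" else f"future_{tag}.nc")
    clim = read_climatology(src)
    soil = np.load(run_dir / f"soil_{tag}.npz")
    mask = clim.grid.land_mask
    t = np.stack([clim.tmean[m][mask] for m in range(12)], axis=1)
    w = np.stack([soil["moisture"][m][mask] for m in range(12)], axis=1)
    r = np.stack([clim.rad[m][mask] for m in range(12)], axis=1)
    return clim, t, w, r


def stage_fit(cfg, run_dir, manifest, force, dry=False):
    outputs = [run_dir / "models.csv", run_dir / "env_zones.npz"]
    if dry:
        return outputs
    seed = cfg.stage_seed("fit-species")
    clim, t, w, r = _load_forcing(run_dir, "ambient")
    zones = fitting.classify_env_zones(
        clim, np.load(run_dir / "soil_ambient.npz")["moisture"],
        k=min(cfg.k_env, clim.grid.n_land // 4), seed=seed)
    np.savez_compressed(run_dir / "env_zones.npz",
                        zone_of_cell=zones.zone_of_cell, medoids=zones.medoids)
    occ = fitting.thin_occurrences(
        pd.read_csv(run_dir / "occurrences.csv"), clim.grid)
    forms = pd.read_csv(run_dir / "growth_forms.csv").set_index("species_id")["growth_form"]
    a_max = {p: uptake_ceiling(t, r, clim.co2, p) for p in ("C3", "C4")}
    models = []
    for i, (sid, group) in enumerate(occ.groupby("species_id", sort=True)):
        pathway = "C4" if forms.get(sid) == "c4_grass" else "C3"
        cells = group["land_cell"].to_numpy()
        try:
            pres = fitting.sample_presences(cells, zones, cap=cfg.presence_cap,
                                            seed=seed + 7 * i)
            # on small worlds a widespread species can leave fewer candidate
            # cells than the matched absence count; cap at availability
            wanted = pres.size if pres.size >= zones.k else 20
            n_abs = min(wanted, clim.grid.n_land - pres.size)
            if n_abs < wanted:
                log.warning("species %s: only %d candidate cells for %d "
                            "pseudo-absences", sid, n_abs, wanted)
            absc = fitting.sample_pseudo_absences(pres, zones, seed=seed + 7 * i + 1,
                                                  n_absences=n_abs)
            sample = fitting.FitSample(pres, absc)
        except fitting.DegenerateSampleError as exc:
            log.warning("species %s skipped: %s", sid, exc)
            continue
        idx = sample.cells
        model = fitting.fit_species(
            sample, t[idx], w[idx], a_max[pathway][idx],
            seed=seed + 7 * i + 2, species_id=sid, pathway=pathway,
            generations=cfg.generations, popsize=cfg.popsize,
        )
        model.accepted = model.tss > cfg.tss_cutoff
        models.append(model)
    fitting.models_frame(models).to_csv(run_dir / "models.csv", index=False)
    return outputs


def _select_models(models_df: pd.DataFrame, forms: pd.Series,
                   min_per_form: int) -> pd.DataFrame:
    """Accepted models, backfilling empty growth forms with their best fits."""
    df = models_df.copy()
    df["growth_form"] = df["species_id"].map(forms)
    keep = df[df["accepted"]]
    for form in synthetic.GROWTH_FORMS:
        have = (keep["growth_form"] == form).sum()
        if have < min_per_form:
            pool = df[(df["growth_form"] == form) & ~df.index.isin(keep.index)]
            extra = pool.nlargest(min_per_form - have, "tss")
            if not extra.empty:
                log.warning(
                    "growth form %s: only %d accepted models, backfilling %d best-TSS fits",
                    form, have, len(extra))
                keep = pd.concat([keep, extra])
    return keep


def stage_project(cfg, run_dir, manifest, force, dry=False):
    tags = ["ambient"] + [_scen_tag(sc, g) for sc, g in _scenario_runs(cfg)]
    outputs = [run_dir / f"binary_{t}.npz" for t in tags]
    if dry:
        return outputs
    models_df = pd.read_csv(run_dir / "models.csv")
    if models_df.empty:
        raise RuntimeError("no fitted models; run fit-species first")
    forms = pd.read_csv(run_dir / "growth_forms.csv").set_index("species_id")["growth_form"]
    selected = _select_models(models_df, forms, cfg.min_species_per_form)
    models = [fitting.FittedSpeciesModel.from_record(rec)
              for rec in selected.to_dict("records")]
    for tag in tags:
        clim, t, w, r = _load_forcing(run_dir, tag)
        a_max = {p: uptake_ceiling(t, r, clim.co2, p) for p in ("C3", "C4")}
        binary = np.stack([
            fitting.project_species(m, t, w, a_max[m.pathway])[1] for m in models
        ])
        np.savez_compressed(
            run_dir / f"binary_{tag}.npz", binary=binary,
            species=np.array([m.species_id for m in models]),
            growth_form=np.array([forms[m.species_id] for m in models]),
        )
    return outputs


def stage_phyto(cfg, run_dir, manifest, force, dry=False):
    tags = ["ambient"] + [_scen_tag(sc, g) for sc, g in _scenario_runs(cfg)]
    outputs = [run_dir / "surfaces.npz"]
    if dry:
        return outputs
    surfaces = {}
    for tag in tags:
        d = np.load(run_dir / f"binary_{tag}.npz", allow_pickle=False)
        surfaces[tag] = phyto.growth_form_suitability(
            d["binary"], [str(s) for s in d["growth_form"]])
    for sc in cfg.scenarios:
        members = [surfaces[_scen_tag(sc, g)] for g in range(sc.n_gcms)]
        surfaces[f"{sc.rcp_label}_median"] = risk.ensemble_median(members)
    np.savez_compressed(run_dir / "surfaces.npz", **surfaces)
    return outputs


def stage_zones(cfg, run_dir, manifest, force, dry=False):
    outputs = [run_dir / "zones.json"]
    if dry:
        return outputs
    seed = cfg.stage_seed("zones")
    surf = np.load(run_dir / "surfaces.npz")["ambient"]
    X = surf.T  # (n_land, 14)
    k = min(cfg.k_zones, max(2, X.shape[0] // 10))
    zm = phyto.fit_zones(X, k=k, seed=seed)
    Path(run_dir / "zones.json").write_text(json.dumps({
        "k": zm.k, "weights": zm.weights.tolist(), "means": zm.means.tolist(),
        "labels": zm.labels.tolist(), "bic": zm.bic,
        "log_likelihood": zm.log_likelihood, "threshold": zm.threshold,
    }))
    return outputs


def stage_risk(cfg, run_dir, manifest, force, dry=False):
    outputs = [run_dir / "risk.npz", run_dir / "summary.csv"]
    if dry:
        return outputs
    surf = np.load(run_dir / "surfaces.npz")
    zones = json.loads((run_dir / "zones.json").read_text())
    ambient = surf["ambient"].T
    threshold = zones["threshold"]
    labels = np.asarray(zones["labels"])
    rows = []
    arrays = {}
    for sc in cfg.scenarios:
        per_gcm = {"change": [], "novelty": [], "disappearance": []}
        for g in range(sc.n_gcms):
            fut = surf[_scen_tag(sc, g)].T
            per_gcm["change"].append(risk.local_change(ambient, fut))
            per_gcm["novelty"].append(risk.novelty(fut, ambient))
            per_gcm["disappearance"].append(risk.disappearance(ambient, fut))
        med = {k_: risk.ensemble_median(v) for k_, v in per_gcm.items()}
        fut_median = surf[f"{sc.rcp_label}_median"].T
        future_zones = risk.assign_future_zones(fut_median, ambient, labels, threshold)
        arrays.update({f"{sc.rcp_label}_{k_}": v for k_, v in med.items()})
        arrays[f"{sc.rcp_label}_future_zones"] = future_zones
        rows.append({
            "scenario": sc.rcp_label,
            "threshold": threshold,
            "pct_significant_change": 100 * risk.area_fraction_significant(
                med["change"], threshold),
            "pct_novel": 100 * risk.area_fraction_significant(
                med["novelty"], threshold),
            "pct_disappearing": 100 * risk.area_fraction_significant(
                med["disappearance"], threshold),
            "n_novel_cells": int((future_zones == risk.NOVEL).sum()),
        })
    np.savez_compressed(run_dir / "risk.npz", **arrays)
    pd.DataFrame(rows).to_csv(run_dir / "summary.csv", index=False)
    return outputs


_STAGE_FNS = {
    "simulate-data": stage_simulate,
    "soil-moisture": stage_soil,
    "fit-species": stage_fit,
    "project": stage_project,
    "phytoclimate": stage_phyto,
    "zones": stage_zones,
    "risk": stage_risk,
}
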