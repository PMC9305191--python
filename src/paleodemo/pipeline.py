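"""End-to-end orchestration: simulate -> diversity -> skyline -> pool ->
calibrate -> trend, with provenance and deterministic seed fan-out.

A run is described by a YAML manifest (species entries with alignment,
deme map, marker and generation time; optional nuclear SFS entries; a
temperature series; MCMC settings). One master seed fans out to per-stage,
per-item child seeds through a counter scheme so every stage is
independently reproducible; re-running an identical manifest reproduces
byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignment as aio
from . import diversity as dv
from . import registry
from .calibrate import calibrate_trajectory, pool_replicates, restrict_window
from .scenario import DemographicScenario
from .sfs import FoldedSFS, fit_stairway
from .simulate import simulate_dataset, simulate_folded_sfs, simulate_temperature
from .skyline import McmcConfig, run_mcmc
from .trend import (build_trend_table, delta_theta, group_summary,
                    interpolate_to_grid, mann_whitney_u, pairwise_correlations,
                    trajectory_support)

logger = logging.getLogger(__name__)

_STAGES = ("diversity", "skyline", "pool", "calibrate", "sfs_fit", "trend")


def child_seed(master: int, stage: str, item: int = 0) -> int:
    """Deterministic per-stage, per-item child seed below 2^31."""
    h = hashlib.sha256(f"{master}:{stage}:{item}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class SpeciesEntry:
    name: str
    fasta: str
    deme_map: str
    marker: str = "CR"
    generation_time_years: float = 25.0
    deme_names: dict[int, str] = field(default_factory=dict)


@dataclass
class NuclearEntry:
    name: str
    sfs: str
    n_epochs: int = 2
    generation_time_years: float = 25.0


@dataclass
class RunManifest:
    species: list[SpeciesEntry]
    temperature: str | None = None
    nuclear: list[NuclearEntry] = field(default_factory=list)
    seed: int = 1
    outdir: str = "paleodemo_run"
    n_replicates: int = 2
    max_sample_size: int = 250
    equalize: bool = False
    grid_step_years: float = 1000.0
    window_kya: tuple[float, float] = (1.0, 30.0)
    delta_theta_times: tuple[float, float] = (21_000.0, 1_000.0)
    mcmc: dict = field(default_factory=dict)
    synchrony_groups: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunManifest":
        raw = yaml.safe_load(Path(path).read_text())
        species = [SpeciesEntry(**s) for s in raw.pop("species")]
        nuclear = [NuclearEntry(**s) for s in raw.pop("nuclear", [])]
        base = Path(path).parent
        for s in species:
            s.fasta = str((base / s.fasta).resolve())
            s.deme_map = str((base / s.deme_map).resolve())
            s.deme_names = {int(k): v for k, v in (s.deme_names or {}).items()}
        for nuc in nuclear:
            nuc.sfs = str((base / nuc.sfs).resolve())
        if raw.get("temperature"):
            raw["temperature"] = str((base / raw["temperature"]).resolve())
        for key in ("window_kya", "delta_theta_times"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(species=species, nuclear=nuclear, **raw)

    def validate(self) -> None:
        names = [s.name for s in self.species] + [n.name for n in self.nuclear]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        missing = []
        for s in self.species:
            missing += [p for p in (s.fasta, s.deme_map) if not Path(p).exists()]
        missing += [n.sfs for n in self.nuclear if not Path(n.sfs).exists()]
        if self.temperature and not Path(self.temperature).exists():
            missing.append(self.temperature)
        if missing:
            raise FileNotFoundError(f"manifest references missing files: {missing}")


def _write_provenance(stage_dir: Path, stage: str, inputs: list[Path],
                      seed: int, params: dict) -> None:
    block = {
        "stage": stage,
        "inputs": {str(p): _sha256(p) for p in sorted(map(Path, inputs), key=str)},
        "seed": seed,
        "params": params,
    }
    (stage_dir / "provenance.json").write_text(
        json.dumps(block, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(manifest: RunManifest) -> dict[str, Path]:
    """Execute all stages in dependency order; returns key output paths."""
    manifest.validate()
    out = Path(manifest.outdir)
    outputs: dict[str, Path] = {}
    current_stage = "setup"
    try:
        # ---- diversity -------------------------------------------------
        current_stage = "diversity"
        ddir = out / "diversity"
        ddir.mkdir(parents=True, exist_ok=True)
        rows = []
        filtered: dict[str, aio.SequenceAlignment] = {}
        for s in manifest.species:
            aln = aio.read_alignment(s.fasta, s.deme_map, marker_class=_marker_class(s))
            aln, report = aio.filter_sites(aln)
            filtered[s.name] = aln
            summ = dv.summarize(aln).to_dict()
            summ["species"] = s.name
            summ.update(report.to_dict())
            del summ["removed_columns_1based"]
            rows.append(summ)
        dtable = pd.DataFrame(rows).set_index("species")
        dtable.to_csv(ddir / "diversity.tsv", sep="\t")
        (ddir / "diversity.json").write_text(
            json.dumps(dtable.reset_index().to_dict(orient="records"),
                       indent=2, sort_keys=True, default=_json_default) + "\n")
        _write_provenance(ddir, "diversity",
                          [Path(s.fasta) for s in manifest.species],
                          child_seed(manifest.seed, "diversity"), {})
        outputs["diversity"] = ddir / "diversity.tsv"

        # ---- skyline + pooling + calibration --------------------------
        current_stage = "skyline"
        sdir = out / "skyline"
        sdir.mkdir(parents=True, exist_ok=True)
        calibrated: dict[str, pd.DataFrame] = {}
        for si, s in enumerate(manifest.species):
            aln = filtered[s.name]
            aln = aio.subsample(aln, manifest.max_sample_size, manifest.equalize,
                                seed=child_seed(manifest.seed, "subsample", si))
            reps = []
            for r in range(manifest.n_replicates):
                cfg = McmcConfig(seed=child_seed(manifest.seed, f"skyline:{s.name}", r),
                                 **manifest.mcmc)
                result = run_mcmc(aln, cfg)
                result.skyline.to_tsv(sdir / f"{s.name}_rep{r}.tsv")
                reps.append(result.skyline.table)
            current_stage = "pool"
            calib = registry.calibration_for(s.marker, s.generation_time_years)
            demes = sorted(np.unique(aln.demes))
            for d_idx, d in enumerate(demes):
                label = s.deme_names.get(int(d), f"deme{d}")
                par = f"theta_{d_idx + 1}"
                rep_tables = [t[t["parameter"] == par]
                              .rename(columns={"median": "median", "sd": "sd"})
                              [["bin_start", "bin_stop", "median", "sd", "n"]]
                              .reset_index(drop=True) for t in reps]
                pooled = pool_replicates(rep_tables)
                current_stage = "calibrate"
                traj = calibrate_trajectory(pooled, calib)
                traj.to_csv(sdir / f"{s.name}@{label}_pooled.tsv", sep="\t", index=False)
                calibrated[f"{s.name}@{label}"] = traj
                current_stage = "skyline"
        _write_provenance(sdir, "skyline", [Path(s.fasta) for s in manifest.species],
                          child_seed(manifest.seed, "skyline"),
                          {"mcmc": manifest.mcmc,
                           "n_replicates": manifest.n_replicates})
        outputs["skyline"] = sdir

        # ---- nuclear SFS fits ------------------------------------------
        if manifest.nuclear:
            current_stage = "sfs_fit"
            ndir = out / "sfs_fit"
            ndir.mkdir(parents=True, exist_ok=True)
            for ni, nuc in enumerate(manifest.nuclear):
                sfs = FoldedSFS.from_tsv(nuc.sfs)
                fit = fit_stairway(
                    sfs, n_epochs=nuc.n_epochs,
                    generation_years=nuc.generation_time_years,
                    seed=child_seed(manifest.seed, "sfs_fit", ni))
                fit.trajectory.to_csv(ndir / f"{nuc.name}_stairway.tsv",
                                      sep="\t", index=False)
            _write_provenance(ndir, "sfs_fit", [Path(n.sfs) for n in manifest.nuclear],
                              child_seed(manifest.seed, "sfs_fit"),
                              {"n_epochs": [n.n_epochs for n in manifest.nuclear]})
            outputs["sfs_fit"] = ndir

        # ---- trend ------------------------------------------------------
        current_stage = "trend"
        tdir = out / "trend"
        tdir.mkdir(parents=True, exist_ok=True)
        series: dict[str, pd.Series] = {}
        lo_kya, hi_kya = manifest.window_kya
        for label, traj in calibrated.items():
            windowed = restrict_window(traj, lo_kya, hi_kya)
            t, v = trajectory_support(windowed)
            if t.size >= 2:
                series[label] = interpolate_to_grid(t, v, manifest.grid_step_years)
        if manifest.temperature:
            temp = aio.read_series(manifest.temperature)
            series["temperature"] = interpolate_to_grid(
                temp["age_years"].to_numpy(), temp["value"].to_numpy(),
                manifest.grid_step_years,
                t_min=lo_kya * 1000.0, t_max=hi_kya * 1000.0)
        table = build_trend_table(series)
        table.index.name = "age_years"
        table.to_csv(tdir / "trend_table.tsv", sep="\t")
        corr = pairwise_correlations(table)
        corr.r.to_csv(tdir / "correlations_r.tsv", sep="\t")
        corr.p.to_csv(tdir / "correlations_p.tsv", sep="\t")
        corr.n.to_csv(tdir / "correlations_n.tsv", sep="\t")

        t_ref, t_recent = manifest.delta_theta_times
        dts = {}
        for label, traj in calibrated.items():
            t, v = trajectory_support(traj)
            if t.size >= 2:
                full = pd.Series(v, index=t)
                dts[label] = delta_theta(full, t_ref=t_ref, t_recent=t_recent)
        pd.DataFrame(sorted(dts.items()), columns=["series", "delta_theta"]).to_csv(
            tdir / "delta_theta.tsv", sep="\t", index=False)

        mw_report = {}
        if manifest.synchrony_groups:
            grouping = {lab: g for g, labs in manifest.synchrony_groups.items()
                        for lab in labs if lab in dts}
            gs = group_summary(dts, grouping)
            gs.to_csv(tdir / "group_summary.tsv", sep="\t", index=False)
            gnames = sorted(manifest.synchrony_groups)
            if len(gnames) == 2:
                ga = [dts[x] for x in manifest.synchrony_groups[gnames[0]] if x in dts]
                gb = [dts[x] for x in manifest.synchrony_groups[gnames[1]] if x in dts]
                if len(ga) >= 2 and len(gb) >= 2:
                    U, p = mann_whitney_u(ga, gb)
                    mw_report = {"groups": gnames, "U": U, "p": p,
                                 "n": [len(ga), len(gb)]}
        (tdir / "mann_whitney.json").write_text(
            json.dumps(mw_report, indent=2, sort_keys=True) + "\n")
        _write_provenance(
            tdir, "trend",
            [Path(manifest.temperature)] if manifest.temperature else [],
            child_seed(manifest.seed, "trend"),
            {"grid_step_years": manifest.grid_step_years,
             "window_kya": list(manifest.window_kya)})
        outputs["trend"] = tdir
        return outputs
    except Exception:
        (out / "FAILED").write_text(f"stage: {current_stage}\n")
        logger.exception("pipeline failed at stage %s (outputs under %s)",
                         current_stage, out)
        raise


def _marker_class(s: SpeciesEntry) -> str:
    return registry.marker_class_for(s.marker)


def _json_default(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and np.isnan(x):
        return None
    return str(x)


# ---------------------------------------------------------------------------
# demo fixtures: a miniature analogue of the study design
# ---------------------------------------------------------------------------

def make_demo_fixtures(outdir: str | Path, seed: int = 1,
                       n_per_deme: int = 16, L: int = 350,
                       mcmc_overrides: dict | None = None) -> Path:
    """Generate a small two-ocean study: 3 whale-like and 2 prey-like taxa
    with a shared warming-driven expansion in the southern deme, plus a
    temperature series and a nuclear SFS, and a ready-to-run manifest.

    Returns the manifest path.
    """
    out = Path(outdir)
    data = out / "data"
    data.mkdir(parents=True, exist_ok=True)
    taxa = ["whale_A", "whale_B", "whale_C", "prey_A", "prey_B"]
    # control-region clock: ~5.3e-8 /site/year at G = 21.2
    mu_year = registry.DEFAULT_MUTATION_RATES["control_region"] / 21.2
    t30k = 30_000 * mu_year
    species_cfg = []
    for i, name in enumerate(taxa):
        s = child_seed(seed, "demo", i)
        # southern deme (1) expands 8x toward the present; northern (2) mild
        scen = DemographicScenario.piecewise(
            grid=[0.0, 0.6 * t30k],
            theta=[[0.024, 0.003], [0.012, 0.006]],
            mig=_sym_mig(2, 5.0),
        )
        sim = simulate_dataset(scen, [n_per_deme, n_per_deme], L, s)
        aio.write_alignment(sim.alignment, data / f"{name}.fasta")
        pd.DataFrame({"id": sim.alignment.ids,
                      "deme": sim.alignment.demes}).to_csv(
            data / f"{name}.demes.tsv", sep="\t", index=False)
        species_cfg.append({
            "name": name, "fasta": f"data/{name}.fasta",
            "deme_map": f"data/{name}.demes.tsv",
            "marker": "CR", "generation_time_years": 21.2,
            "deme_names": {1: "south", 2: "north"},
        })
    ages = np.arange(0.0, 40_001.0, 500.0)
    temp = simulate_temperature(ages, amplitude=15.0, noise_sd=0.4,
                                cold_spike_age=8200.0,
                                seed=child_seed(seed, "demo_temp"))
    temp.to_csv(data / "temperature.tsv", sep="\t", index=False)
    nuc_scen = DemographicScenario.piecewise(
        grid=[0.0, 2e-4], theta=[[0.004, 0.001]])
    nuc = simulate_folded_sfs(nuc_scen, n_chrom=40, L_sites=200_000,
                              seed=child_seed(seed, "demo_sfs"))
    nuc.to_tsv(data / "nuclear_sfs.tsv")

    mcmc = {"steps": 12000, "burn_in": 4000, "thin": 8, "n_time_bins": 24,
            "theta_bounds": [5e-4, 0.25], "m_bounds": [0.0, 100.0],
            "time_horizon": round(1.2 * t30k, 8), "epoch_boundaries": [0.0, 0.6 * t30k]}
    mcmc.update(mcmc_overrides or {})
    manifest = {
        "seed": seed,
        "outdir": str(out / "results"),
        "temperature": "data/temperature.tsv",
        "n_replicates": 2,
        "max_sample_size": 250,
        "grid_step_years": 1000.0,
        "window_kya": [1, 30],
        "mcmc": mcmc,
        "species": species_cfg,
        "nuclear": [{"name": "whale_A_nuclear", "sfs": "data/nuclear_sfs.tsv",
                     "n_epochs": 2, "generation_time_years": 21.2}],
        "synchrony_groups": {
            "south": [f"{t}@south" for t in taxa],
            "north": [f"{t}@north" for t in taxa],
        },
    }
    path = out / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


def _sym_mig(D: int, m: float, E: int = 2) -> np.ndarray:
    M = np.zeros((D, D, E))
    for e in range(E):
        M[:, :, e] = m * (1 - np.eye(D))
    return M
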