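"""End-to-end pipeline: transects -> ages -> proxies -> models -> report.

One config drives a full run, either on synthetic data (generated in-run
from a seed) or on user-supplied transect/metadata/hydro CSV files.  Every
stage writes its table under the run directory; a manifest records the
config hash, seed, stage completion and any per-fish exclusions, so a run
is reproducible and auditable.  Stage order follows the analysis logic:
otolith processing, chemical ageing, proxies and growth, hydrographic
alignment, statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemical_ageing as ca
from . import hydrography as hyd
from . import inference as inf
from . import proxies_growth as pg
from . import synthetic_data as syn
from . import transect_processing as tp

logger = logging.getLogger(__name__)

STAGES = ("inputs", "transects", "ageing", "proxies", "hydro", "models", "comparisons")


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # or "user-data"
    outdir: str = "run"
    seed: int = 0
    # user-data inputs
    transects_dir: str | None = None
    fish_csv: str | None = None
    hydro_csv: str | None = None
    # module configs
    scenario: syn.SyntheticScenario = field(default_factory=syn.SyntheticScenario)
    correction: tp.CorrectionConfig = field(default_factory=tp.CorrectionConfig)
    ageing: ca.AgeingConfig = field(default_factory=ca.AgeingConfig)
    salinity_cal: pg.SalinityCalibration = field(default_factory=pg.SalinityCalibration)
    growth_cal: pg.GrowthCalibration = field(default_factory=pg.GrowthCalibration)
    fit_window: tuple = (1960, 2019)
    comparison_min_n: int = 5
    log_level: str = "INFO"

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (frozenset, set, tuple)):
                return sorted(map(str, o)) if isinstance(o, (set, frozenset)) else list(o)
            if isinstance(o, np.generic):
                return o.item()
            raise TypeError(type(o))

        blob = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = dict(raw)
        for key, klass in (
            ("scenario", syn.SyntheticScenario),
            ("correction", tp.CorrectionConfig),
            ("ageing", ca.AgeingConfig),
            ("salinity_cal", pg.SalinityCalibration),
            ("growth_cal", pg.GrowthCalibration),
        ):
            if key in kw and isinstance(kw[key], dict):
                sub = dict(kw[key])
                if key == "scenario":
                    for nkey, nklass in (
                        ("env_params", syn.EnvParams),
                        ("growth_params", syn.GrowthParams),
                        ("proxy_link", syn.ProxyLink),
                        ("noise", syn.NoiseParams),
                    ):
                        if nkey in sub and isinstance(sub[nkey], dict):
                            sub[nkey] = nklass(**sub[nkey])
                    if "years_span" in sub:
                        sub["years_span"] = tuple(sub["years_span"])
                kw[key] = klass(**sub)
        if "fit_window" in kw:
            kw["fit_window"] = tuple(kw["fit_window"])
        return cls(**kw)


def _process_one_fish(transect, meta, cfg: PipelineConfig):
    """Raw transect -> proxy rows for one fish (may raise)."""
    t = tp.apply_mg_interference_correction(transect, cfg.correction)
    r = tp.compute_ratios(t, cfg.correction)
    r = tp.censor_diagenetic_spikes(r, "mn_ca", cfg.correction)
    annuli = ca.detect_annuli(r, cfg.ageing)
    annuli = ca.assign_calendar_years(
        annuli, int(meta["catch_year"]), int(meta.get("catch_quarter", 4))
    )
    zones = ca.annual_means(
        r, annuli, element_transect=t, mn_mg_mode=cfg.correction.mn_mg_mode
    )
    proxy = pg.build_proxy_table(zones, meta, cfg.salinity_cal, cfg.growth_cal)
    return annuli, proxy


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages; return the run directory.

    A per-fish failure is recorded in the exclusions report and the run
    continues; a stage-level failure stops the run but preserves partial
    outputs, with the failing stage named in the manifest.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    logging.getLogger().addHandler(fh)
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "mode": cfg.mode,
        "stages_complete": [],
        "failed_stage": None,
        "versions": _versions(),
    }
    exclusions = []
    try:
        # ---- inputs ---------------------------------------------------
        if cfg.mode == "synthetic":
            scenario = dataclasses.replace(cfg.scenario, seed=cfg.seed)
            env = syn.generate_environment(scenario)
            fish, truth = syn.generate_cohort(scenario, env)
            transects = {
                f.fish_id: syn.generate_transect(f, truth, env, scenario)
                for f in fish
            }
            syn.write_dataset(outdir / "inputs", scenario, env, fish, truth, transects)
            meta_table = pd.DataFrame([dataclasses.asdict(f) for f in fish])
        elif cfg.mode == "user-data":
            env = hyd.HydroSeries.from_csv(cfg.hydro_csv)
            meta_table = pd.read_csv(cfg.fish_csv)
            transects = {}
            for _, m in meta_table.iterrows():
                fid = str(m["fish_id"])
                path = Path(cfg.transects_dir) / f"{fid}.csv"
                try:
                    transects[fid] = tp.read_transect(
                        path, fish_id=fid, lab_tag=str(m.get("lab_tag", ""))
                    )
                except Exception as e:  # malformed file -> excluded, run continues
                    exclusions.append({"fish_id": fid, "stage": "inputs", "reason": str(e)})
        else:
            raise ValueError(f"unknown mode {cfg.mode!r}")
        manifest["stages_complete"].append("inputs")

        # ---- transects / ageing / proxies -----------------------------
        annuli_frames, proxy_frames = [], []
        for _, m in meta_table.iterrows():
            fid = str(m["fish_id"])
            if fid not in transects:
                continue
            try:
                annuli, proxy = _process_one_fish(transects[fid], m, cfg)
            except Exception as e:
                exclusions.append({"fish_id": fid, "stage": "ageing", "reason": str(e)})
                continue
            annuli_frames.append(annuli.to_frame())
            proxy_frames.append(proxy)
        if not proxy_frames:
            raise RuntimeError("no fish survived processing")
        annuli_table = pd.concat(annuli_frames, ignore_index=True)
        proxy_table = pd.concat(proxy_frames, ignore_index=True)
        annuli_table.to_csv(outdir / "annuli.csv", index=False)
        manifest["stages_complete"] += ["transects", "ageing"]

        proxy_table.to_csv(outdir / "proxy_table.csv", index=False)
        manifest["stages_complete"].append("proxies")

        # ---- hydrography ----------------------------------------------
        joined = hyd.align_covariates(proxy_table, env, cfg.fit_window)
        joined.to_csv(outdir / "analysis_table.csv", index=False)
        env.to_csv(outdir / "hydro.csv")
        manifest["stages_complete"].append("hydro")

        # ---- models ----------------------------------------------------
        results = {}
        for name, fitter in (
            ("hypoxia", inf.fit_hypoxia_model),
            ("metabolic", inf.fit_metabolic_model),
        ):
            try:
                res = fitter(joined)
                results[name] = res
                (outdir / f"model_{name}.json").write_text(
                    json.dumps(res.to_dict(), indent=2)
                )
                res.fixed_effects_frame().to_csv(
                    outdir / f"model_{name}_fixed_effects.csv", index=False
                )
            except Exception as e:
                exclusions.append({"fish_id": "(model)", "stage": name, "reason": str(e)})
        growth = inf.fit_length_at_age(joined)
        growth_tab = pd.concat(
            [g.predictions.assign(group=g.group) for g in growth.values()],
            ignore_index=True,
        )
        growth_tab.to_csv(outdir / "length_at_age.csv", index=False)
        manifest["stages_complete"].append("models")

        # ---- comparisons ----------------------------------------------
        cmp_res = inf.decade_group_comparisons(
            joined[joined["age"] >= 1], min_n=cfg.comparison_min_n
        )
        cmp_res.kw_table.to_csv(outdir / "comparisons_kw.csv", index=False)
        cmp_res.pairwise.to_csv(outdir / "comparisons_pairwise.csv", index=False)
        cmp_res.excluded.to_csv(outdir / "comparisons_excluded.csv", index=False)
        manifest["stages_complete"].append("comparisons")

        _make_figures(outdir, joined, env, growth_tab)
    except Exception as e:
        done = set(manifest["stages_complete"])
        manifest["failed_stage"] = next(
            (s for s in STAGES if s not in done), "unknown"
        )
        manifest["error"] = str(e)
        logger.exception("pipeline failed at stage %s", manifest["failed_stage"])
    finally:
        pd.DataFrame(
            exclusions, columns=["fish_id", "stage", "reason"]
        ).to_csv(outdir / "exclusions.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logging.getLogger().removeHandler(fh)
        fh.close()
    if manifest["failed_stage"]:
        raise RuntimeError(
            f"pipeline failed at stage {manifest['failed_stage']}; "
            f"partial outputs in {outdir}"
        )
    return outdir


def _versions() -> dict:
    import matplotlib
    import scipy
    import statsmodels

    from . import __version__

    return {
        "otolithchem": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.version.full_version
        if hasattr(statsmodels, "version")
        else statsmodels.__version__,
        "matplotlib": matplotlib.__version__,
    }


def _make_figures(outdir: Path, joined: pd.DataFrame, env, growth_tab) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    adults = joined[joined["age"] >= 1]

    # proxy time series vs environment (hypoxia)
    fig, ax = plt.subplots(figsize=(8, 4))
    ann = adults.groupby("calendar_year")["mn_mg"].mean()
    if len(ann) >= 2:
        ax.plot(ann.index, hyd.moving_average_3yr(ann), color="tab:blue",
                label="Mn:Mg (3-yr MA)")
    ax2 = ax.twinx()
    vol = env.table.set_index("year")["anoxic_km3"]
    ax2.plot(vol.index, hyd.moving_average_3yr(vol), color="k",
             label="anoxic volume (3-yr MA)")
    ax.set_xlabel("year"); ax.set_ylabel("annual mean Mn:Mg")
    ax2.set_ylabel("anoxic volume (km$^3$)")
    fig.tight_layout(); fig.savefig(outdir / "fig_hypoxia_timeseries.png", dpi=120)
    plt.close(fig)

    # decade x salinity-group boxplots
    fig, axes = plt.subplots(2, 2, figsize=(10, 6), sharex=False)
    for g, axg in zip([1, 2, 3, 4], axes.ravel()):
        sub = adults[adults["salinity_group"] == g]
        groups = [(d, v["mn_mg"].dropna().to_numpy()) for d, v in sub.groupby("decade")]
        groups = [(d, v) for d, v in groups if v.size > 0]
        if groups:
            axg.boxplot([v for _, v in groups], tick_labels=[d for d, _ in groups])
        axg.set_title(f"salinity group {g}")
        axg.tick_params(axis="x", rotation=45)
    fig.suptitle("Mn:Mg by decade per salinity group")
    fig.tight_layout(); fig.savefig(outdir / "fig_decade_boxplots.png", dpi=120)
    plt.close(fig)

    # metabolic time series vs DO saturation
    fig, ax = plt.subplots(figsize=(8, 4))
    ann = adults.groupby("calendar_year")["mg_ca"].mean()
    if len(ann) >= 2:
        ax.plot(ann.index, hyd.moving_average_3yr(ann), color="tab:green",
                label="Mg:Ca (3-yr MA)")
    ax2 = ax.twinx()
    do = env.table.set_index("year")["do_pct_sat"]
    ax2.plot(do.index, hyd.moving_average_3yr(do), color="tab:blue")
    ax.set_xlabel("year"); ax.set_ylabel("annual mean Mg:Ca (mmol/mol)")
    ax2.set_ylabel("DO saturation (%)")
    fig.tight_layout(); fig.savefig(outdir / "fig_metabolic_timeseries.png", dpi=120)
    plt.close(fig)

    # predicted length at age per decade
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for grp, sub in growth_tab.groupby("group"):
        ax.plot(sub["age"], sub["mean_length_mm"], marker="o", label=str(grp))
    ax.set_xlabel("age (years)"); ax.set_ylabel("predicted mean length (mm)")
    ax.legend(fontsize=7)
    fig.tight_layout(); fig.savefig(outdir / "fig_length_at_age.png", dpi=120)
    plt.close(fig)


def make_report(run_dir) -> Path:
    """Write a human-readable markdown summary of a completed run."""
    run_dir = Path(run_dir)
    lines = ["# Otolith chemistry pipeline report", ""]
    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines += [
            f"- config hash: `{manifest['config_hash']}`",
            f"- seed: {manifest['seed']}",
            f"- stages complete: {', '.join(manifest['stages_complete'])}",
            "",
        ]
    sections = [
        ("Hypoxia proxy vs anoxic volume", "fig_hypoxia_timeseries.png"),
        ("Mn:Mg by decade per salinity group", "fig_decade_boxplots.png"),
        ("Metabolic proxy vs DO saturation", "fig_metabolic_timeseries.png"),
        ("Predicted length at age", "fig_length_at_age.png"),
    ]
    for title, png in sections:
        lines.append(f"## {title}")
        if (run_dir / png).exists():
            lines.append(f"![{title}]({png})")
        else:
            lines.append("*(unavailable — stage did not complete)*")
        lines.append("")
    for name in ("hypoxia", "metabolic"):
        path = run_dir / f"model_{name}_fixed_effects.csv"
        lines.append(f"## Fixed effects: {name} model")
        if path.exists():
            lines.append(pd.read_csv(path).to_markdown(index=False))
        else:
            lines.append("*(unavailable)*")
        lines.append("")
    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out
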