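"""End-to-end orchestration: data -> g extraction -> group stats -> connectome.

A single YAML-serialisable configuration drives every stage; all randomness
derives from one integer seed, so a run is reproducible byte for byte.
Stages mirror the analysis structure: (1) factor extraction of g with
adequacy diagnostics, (2) effect sizes / LDA / g-adjustment, (3) covariate
associations, (4) connectome density sweep, group tests and participation-g
correlations. The connectome stage is optional.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectome as cn
from . import groupstats as gs
from . import io as gio
from ._seeds import child_seed, substream
from .psychometrics import ScoreTable, extract_g

__all__ = ["RunConfig", "run", "validate_inputs"]

log = logging.getLogger("gconnect.pipeline")

DEFAULTS: dict = {
    "seed": 0,
    "battery": {
        "synth": {
            "n_per_group": 100,
            "loadings": [0.7] * 11,
            "group_shift": -0.85,
        },
        "csv": None,
    },
    "covariates": {
        "synth": {
            "coeffs": {
                "education": 0.5,
                "onset_age": 0.3,
                "duration": -0.3,
                "n_asms": -0.3,
            },
            "adi_slope": -0.5,
        },
        "continuous": ["education", "onset_age", "duration", "n_asms"],
        "spearman": ["n_asms"],
    },
    "independent": {
        "processing_speed": {"slope": 0.5, "group_effect": -0.5},
        "picture_vocab": {"slope": 0.7, "group_effect": 0.0},
    },
    "g": {"n_factors": None},
    "groupstats": {"n_perm": 10000},
    "connectome": {
        "enabled": True,
        "synth": {
            "n_nodes": 90,
            "module_sizes": [15] * 6,
            "within_corr": 0.5,
            "between_corr": 0.1,
            "subject_noise_sd": 0.06,
            "group_delta": 0.12,
            "n_subjects_per_group": 30,
        },
        "manifest": None,
        "parcellation": None,
        "densities": [0.2, 0.3, 0.4],
        "k_nulls": 20,
        "n_swaps_per_edge": 10,
        "n_restarts": 100,
        "mode": "weighted",
        "negative_policy": "zero",
        "alpha": 0.05,
        "pc_g_link": {"module": "M0", "strength": 0.5},
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


@dataclass
class RunConfig:
    """Nested run configuration; unspecified values fall back to defaults."""

    data: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = _deep_merge(DEFAULTS, self.data)

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.data, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# input assembly
# ---------------------------------------------------------------------------

def _load_battery(cfg: RunConfig) -> ScoreTable:
    from .synth import BatterySpec, simulate_battery, simulate_covariates

    bc = cfg["battery"]
    if bc.get("csv"):
        table = ScoreTable.from_csv(bc["csv"])
    else:
        spec = BatterySpec(
            n_per_group=bc["synth"]["n_per_group"],
            loadings=np.asarray(bc["synth"]["loadings"], dtype=float),
            group_shift=bc["synth"]["group_shift"],
            seed=child_seed(cfg.seed, "battery"),
        )
        table = simulate_battery(spec)
        cov_cfg = cfg["covariates"].get("synth")
        if cov_cfg and table.latent_g is not None:
            table.covariates = simulate_covariates(
                table.latent_g,
                cov_cfg["coeffs"],
                seed=child_seed(cfg.seed, "covariates"),
                adi_slope=cov_cfg.get("adi_slope"),
            )
    return table


def _load_connectomes(cfg: RunConfig):
    from .synth import NetworkSpec, simulate_connectomes

    cc = cfg["connectome"]
    if cc.get("manifest"):
        subjects = gio.load_cohort(cc["manifest"])
        if not cc.get("parcellation"):
            raise ValueError("a parcellation TSV is required with a manifest")
        parcellation = gio.load_parcellation(cc["parcellation"])
    else:
        spec = NetworkSpec(
            n_nodes=cc["synth"]["n_nodes"],
            module_sizes=np.asarray(cc["synth"]["module_sizes"], dtype=int),
            within_corr=cc["synth"]["within_corr"],
            between_corr=cc["synth"]["between_corr"],
            subject_noise_sd=cc["synth"]["subject_noise_sd"],
            group_delta=cc["synth"]["group_delta"],
            seed=child_seed(cfg.seed, "connectomes"),
        )
        subjects = simulate_connectomes(spec, cc["synth"]["n_subjects_per_group"])
        parcellation = spec.parcellation()
    return subjects, parcellation


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_inputs(config: RunConfig) -> list[dict]:
    """Machine-readable issue list for the configured inputs (no exceptions)."""
    issues: list[dict] = []
    try:
        table = _load_battery(config)
    except Exception as exc:  # diagnostics, not exceptions
        issues.append({"stage": "battery", "issue": str(exc)})
        table = None
    if table is not None:
        if not set(np.unique(table.group)).issubset({0, 1}):
            issues.append(
                {"stage": "battery", "issue": "group labels must be coded 0/1"}
            )
        if table.scores.isna().any().any():
            issues.append({"stage": "battery", "issue": "missing scores"})
    if config["connectome"]["enabled"]:
        try:
            subjects, parcellation = _load_connectomes(config)
        except Exception as exc:
            issues.append({"stage": "connectome", "issue": str(exc)})
            subjects, parcellation = [], None
        for s in subjects:
            asym = np.abs(s.z - s.z.T)
            if asym.max() > 1e-10:
                i, j = np.unravel_index(np.argmax(asym), asym.shape)
                issues.append(
                    {
                        "stage": "connectome",
                        "issue": f"asymmetry at ({i},{j})",
                        "subject": s.subject_id,
                    }
                )
        if subjects and parcellation is not None:
            if parcellation.n_nodes != subjects[0].n_nodes:
                missing = set(range(subjects[0].n_nodes)) - set(
                    range(parcellation.n_nodes)
                )
                issues.append(
                    {
                        "stage": "connectome",
                        "issue": f"nodes missing from parcellation: {sorted(missing)}",
                    }
                )
    return issues


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def _stage(name: str):
    log.info("stage %s", name)
    return time.perf_counter()


def run(config: RunConfig, outdir) -> dict:
    """Execute every configured stage and write the report bundle.

    Returns the in-memory report; on disk the bundle holds CSV/JSON tables
    per stage plus a manifest with the config hash and master seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    seed = config.seed

    # ---- stage 1: battery + g extraction ---------------------------------
    t0 = _stage("psychometrics")
    table = _load_battery(config)
    gres = extract_g(table, n_factors=config["g"]["n_factors"])
    model = gres["model"]
    gscores = gres["gscores"]
    rep = gres["adequacy"]
    report["psychometrics"] = {
        "kmo_overall": rep.kmo_overall,
        "msa_per_item": rep.msa_per_item.to_dict(),
        "bartlett_chi2": rep.bartlett_chi2,
        "bartlett_df": rep.bartlett_df,
        "bartlett_p": rep.bartlett_p,
        "map_1976": gres["map_1976"],
        "map_2000": gres["map_2000"],
        "n_factors": model.n_factors,
        "loadings": model.loadings.iloc[:, 0].to_dict(),
        "uniquenesses": model.uniquenesses.to_dict(),
        "rmsr": model.rmsr,
        "tli": model.tli,
        "score_validity": float(model.score_validity[0]),
        "score_r2": float(model.score_r2[0]),
    }
    _write_json(outdir / "psychometrics.json", report["psychometrics"])
    gdf = pd.DataFrame({"group": table.group, "g": gscores.g})
    gdf.to_csv(outdir / "gscores.csv", index_label="subject_id", float_format="%.8g")
    log.info("psychometrics done in %.1fs", time.perf_counter() - t0)

    # ---- stage 2: group statistics ---------------------------------------
    t0 = _stage("groupstats")
    n_perm = config["groupstats"]["n_perm"]
    lda = gs.lda_fit(table)
    extra = {"g": gscores.g, "lda": lda.scores}
    eff = gs.effect_size_table(
        table, extra=extra, n_perm=n_perm, seed=child_seed(seed, "effects")
    )
    eff.to_csv(outdir / "effect_sizes.csv", float_format="%.8g")
    comparison = gs.lda_vs_g(lda.scores, gscores.g, table)
    report["groupstats"] = {
        "effect_sizes": eff,
        "lda_weights": lda.direction.to_dict(),
        **{k: v for k, v in comparison.items()},
    }
    _write_json(
        outdir / "lda.json",
        {
            "weights": lda.direction.to_dict(),
            "threshold": lda.threshold,
            "r_g_lda": comparison["r_g_lda"],
            "g_outranks_all_tests": comparison.get("g_outranks_all_tests"),
        },
    )

    # independent measures: group difference before/after adjusting for g
    adj_rows = []
    if config["independent"] and table.latent_g is not None:
        for name, pars in config["independent"].items():
            rng = substream(seed, "independent", name)
            vals = (
                pars["slope"] * table.latent_g.to_numpy()
                + pars["group_effect"] * table.group.to_numpy()
                + rng.standard_normal(table.n_subjects)
            )
            res = gs.adjust_for_g(
                vals, gscores.g.to_numpy(), table.group.to_numpy(),
                n_perm=n_perm, seed=child_seed(seed, "adjust", name),
            )
            adj_rows.append(
                {
                    "measure": name,
                    "p_before": res["p_before"],
                    "p_after": res["p_after"],
                    "slope_on_g": res["slope"],
                }
            )
    if adj_rows:
        pd.DataFrame(adj_rows).to_csv(
            outdir / "adjusted_measures.csv", index=False, float_format="%.8g"
        )
        report["adjusted_measures"] = adj_rows

    # covariate associations (within patients, as in the clinical analysis)
    assoc_rows = []
    if table.covariates is not None:
        pat = (table.group == 1).to_numpy()
        gpat = gscores.g.to_numpy()[pat]
        spearman_set = set(config["covariates"].get("spearman", []))
        for name in config["covariates"].get("continuous", []):
            if name not in table.covariates.columns:
                continue
            kind = "spearman" if name in spearman_set else "pearson"
            row = gs.associate(
                gpat, table.covariates[name].to_numpy()[pat], kind
            )
            assoc_rows.append(
                {"covariate": name, "method": row.method,
                 "statistic": row.statistic, "p": row.p, "n": row.n}
            )
        if "adi" in table.covariates.columns:
            row = gs.associate(
                gscores.g.to_numpy(), table.covariates["adi"], "t"
            )
            assoc_rows.append(
                {"covariate": "adi", "method": row.method,
                 "statistic": row.statistic, "p": row.p, "n": row.n}
            )
    if assoc_rows:
        pd.DataFrame(assoc_rows).to_csv(
            outdir / "associations.csv", index=False, float_format="%.8g"
        )
        report["associations"] = assoc_rows
    log.info("groupstats done in %.1fs", time.perf_counter() - t0)

    # ---- stage 3: connectome ---------------------------------------------
    if config["connectome"]["enabled"]:
        t0 = _stage("connectome")
        cc = config["connectome"]
        subjects, parcellation = _load_connectomes(config)
        profiles = cn.density_sweep(
            subjects,
            densities=cc["densities"],
            parcellation=parcellation,
            k_nulls=cc["k_nulls"],
            seed=child_seed(seed, "sweep"),
            mode=cc["mode"],
            n_restarts=cc["n_restarts"],
            n_swaps_per_edge=cc["n_swaps_per_edge"],
            negative_policy=cc["negative_policy"],
        )
        glob = cn.global_table(profiles)
        glob.to_csv(outdir / "global_metrics.csv", index=False, float_format="%.8g")
        tests = cn.group_metric_tests(
            profiles,
            n_perm=n_perm,
            seed=child_seed(seed, "group_tests"),
            alpha=cc["alpha"],
        )
        tests["global"].to_csv(
            outdir / "group_tests_global.csv", index=False, float_format="%.8g"
        )
        tests["parcel_pc"].to_csv(
            outdir / "group_tests_pc.csv", index=False, float_format="%.8g"
        )
        pc_density = tests["pc_density"]
        pc_wide = cn.parcel_table(profiles, pc_density)
        pc_wide.to_csv(outdir / "parcel_pc.csv", index_label="subject_id",
                       float_format="%.8g")

        # participation-g correlations: the synthetic connectome cohort gets
        # its own g, optionally with a planted monotone link to one module's
        # participation (config connectome.pc_g_link), so the FDR-flagging
        # pathway is exercised end to end
        pc_only = pc_wide.drop(columns="group")
        groups_conn = pc_wide["group"].to_numpy()
        link = cc.get("pc_g_link") or {}
        rng = substream(seed, "pc_g")
        noise = rng.standard_normal(len(pc_only))
        if link:
            anchor = pc_only[link["module"]].to_numpy()
            anchor = (anchor - anchor.mean()) / anchor.std(ddof=1)
            rho = float(link["strength"])
            g_conn = rho * anchor + np.sqrt(1 - rho**2) * noise
        else:
            g_conn = noise
        pcg = cn.pc_g_correlation(
            pc_only, pd.Series(g_conn, index=pc_only.index), groups_conn,
            alpha=cc["alpha"],
        )
        pcg.to_csv(outdir / "pc_g_correlations.csv", index=False, float_format="%.8g")
        report["connectome"] = {
            "profiles": profiles,
            "global_tests": tests["global"],
            "pc_tests": tests["parcel_pc"],
            "pc_density": pc_density,
            "pc_g": pcg,
        }
        log.info("connectome done in %.1fs", time.perf_counter() - t0)

    _write_json(
        outdir / "manifest.json",
        {"config_hash": config.config_hash(), "seed": seed,
         "stages": sorted(report.keys())},
    )
    report["outdir"] = str(outdir)
    return report
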