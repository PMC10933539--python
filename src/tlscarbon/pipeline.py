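"""End-to-end orchestration: clouds → metrics → volumes → rates → allometry.

The pipeline runs either on point-cloud files on disk (a directory of
PLY/XYZ clouds plus a tree metadata CSV) or on a fully synthetic
three-site study whose cohort templates — avenue-planted old trees at two
sites plus a mixed-age botanical-garden site — mirror the structure of a
UK giant-sequoia survey: known planting dates, ~100 trees, two age
cohorts at the mixed site.  Every stage is seeded, per-tree failures are
recorded and skipped (never imputed), and a manifest captures enough to
reproduce any number in any output table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import allometry
from .errors import ConfigError
from .growth import (
    GrowthParams,
    age_cohort_rule,
    compare_rates,
    growth_rates,
    rates_long_table,
    site_summary,
)
from .metrics import (
    MetricsConfig,
    StructuralMetrics,
    compute_all_metrics,
    write_metrics_table,
)
from .pointcloud_io import PointCloud, TreeRecord, read_cloud, read_tree_table
from .synthetic import SiteTemplate, SyntheticTreeSpec, generate_site
from .volume import VolumeConfig

log = logging.getLogger("tlscarbon")


@dataclass
class PipelineConfig:
    """Flat, typed pipeline configuration; defaults are the study constants."""

    seed: int = 0
    out_dir: str = "tlscarbon_out"
    cloud_dir: str = ""              # if set, read clouds from here ...
    tree_table: str = ""             # ... with this metadata CSV
    cloud_format: str = "ply"
    breast_low: float = 1.2
    breast_high: float = 1.4
    buttress_low: float = 4.0
    buttress_high: float = 4.5
    wood_density: float = 0.34       # Mg m^-3
    carbon_fraction: float = 0.54
    n_repeats: int = 10              # volume repeat fits
    n_boot: int = 100                # bootstrap samples per UK form
    slice_height: float = 0.5        # m, volume slabs
    branch_multiplier: float = 0.15
    site_scale: float = 1.0          # fraction of full per-site tree counts
    point_spacing: float = 0.08      # m, synthetic sampling
    noise_sd: float = 0.005          # m, synthetic range noise
    jitter_frac: float = 0.10        # synthetic within-site size spread
    cohort_age_threshold: int = 50   # yr, young/old split

    def validate(self) -> None:
        if not (0.2 < self.wood_density < 0.6):
            raise ConfigError(f"wood_density {self.wood_density} outside (0.2, 0.6)")
        if not (0.4 < self.carbon_fraction < 0.6):
            raise ConfigError(f"carbon_fraction {self.carbon_fraction} outside (0.4, 0.6)")
        if self.breast_high <= self.breast_low or self.buttress_high <= self.buttress_low:
            raise ConfigError("slice intervals must have high > low")
        if self.n_repeats < 1 or self.n_boot < 1:
            raise ConfigError("n_repeats and n_boot must be >= 1")
        if self.slice_height <= 0 or self.point_spacing <= 0:
            raise ConfigError("slice_height and point_spacing must be positive")
        if not (0 < self.site_scale <= 1):
            raise ConfigError("site_scale must lie in (0, 1]")
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")

    # flat key = value text serialisation (lossless for these field types)
    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        import ast

        types = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"config line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in types:
                raise ConfigError(f"config line {lineno}: unknown key {key!r}")
            try:
                kwargs[key] = ast.literal_eval(value.strip())
            except (ValueError, SyntaxError):
                raise ConfigError(f"config line {lineno}: cannot parse value for {key!r}")
        config = cls(**kwargs)
        config.validate()
        return config


# ---------------------------------------------------------------------------
# synthetic study
# ---------------------------------------------------------------------------

def study_templates(config: PipelineConfig) -> list[SiteTemplate]:
    """The synthetic three-site study: cohort sizes, ages and tree forms.

    Cohort means follow the surveyed UK sites: a wet-climate avenue of 40
    old trees ("benmore": planted 1863, mean H ≈ 44 m), a dry-climate
    avenue of 34 ("havering": 1870, H ≈ 24.5 m), and a mixed-age garden
    ("wakehurst") with 10 old (≈1900) and 13 young (1989) trees.
    """
    ps, noise = config.point_spacing, config.noise_sd

    def spec(h, dbh, crown_r, crown_base, flare_h, flare_b, spacing):
        return SyntheticTreeSpec(
            total_height=h, dbh_true=dbh, crown_max_radius=crown_r,
            crown_base_height=crown_base, flare_height=flare_h,
            buttress_extra_radius=flare_b, taper_exponent=1.0,
            point_spacing=spacing, noise_sd=noise,
        )

    return [
        SiteTemplate("benmore", 40, 1863, 2022,
                     spec(44.3, 1.80, 5.5, 8.0, 3.0, 0.30, ps),
                     config.jitter_frac, tree_prefix="B_T"),
        # crown bases sit clear of the 4.0-4.5 m buttress-diameter slice even
        # at the lower end of the size jitter, so DTB stays a stem measure
        SiteTemplate("havering", 34, 1870, 2022,
                     spec(24.5, 1.12, 3.5, 6.0, 2.2, 0.15, ps),
                     config.jitter_frac, tree_prefix="H_T"),
        SiteTemplate("wakehurst", 10, 1900, 2023,
                     spec(35.0, 1.79, 5.0, 7.0, 3.0, 0.25, ps),
                     config.jitter_frac, tree_prefix="W_O_T"),
        SiteTemplate("wakehurst", 13, 1989, 2023,
                     spec(22.8, 0.47, 2.5, 6.0, 1.6, 0.05,
                          min(ps, 0.06)),
                     config.jitter_frac, tree_prefix="W_Y_T"),
    ]


def simulate_study(config: PipelineConfig):
    """Generate the synthetic study: (clouds, records, truths)."""
    rng = np.random.default_rng(config.seed)
    clouds, records, truths = [], [], []
    for tpl in study_templates(config):
        n = max(2, int(round(tpl.n_trees * config.site_scale)))
        c, r, t = generate_site(
            n, tpl.planting_year, tpl.scan_year, tpl.spec_template,
            jitter_frac=tpl.jitter_frac, seed=int(rng.integers(0, 2**31 - 1)),
            site=tpl.site, tree_prefix=tpl.tree_prefix,
        )
        clouds += c
        records += r
        truths += t
    return clouds, records, truths


def _load_clouds(config: PipelineConfig):
    """Read per-tree clouds; unreadable files become ledger entries, not halts."""
    records = read_tree_table(config.tree_table)
    clouds: list[Optional[PointCloud]] = []
    load_errors: dict[str, str] = {}
    suffix = {"ply": ".ply", "xyz": ".xyz", "las": ".las"}[config.cloud_format]
    for rec in records:
        path = Path(config.cloud_dir) / f"{rec.tree_id}{suffix}"
        try:
            clouds.append(read_cloud(path, config.cloud_format))
        except Exception as exc:
            log.warning("cloud for %s unreadable: %s", rec.tree_id, exc)
            load_errors[rec.tree_id] = f"{type(exc).__name__}: {exc}"
            clouds.append(None)
    return clouds, records, load_errors


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the output tables; returns the manifest.

    Stages: load or simulate clouds → structural metrics (incl. slice-stack
    volume with repeat-fit SD) → per-tree growth/carbon rates and
    site/cohort summaries with Welch t-tests → published-model evaluation
    and UK-model refits with parametric-bootstrap envelopes.  A tree whose
    metrics fail is excluded from downstream tables and listed in the
    manifest's error ledger; the pipeline continues.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    load_errors: dict[str, str] = {}
    if config.cloud_dir:
        clouds, records, load_errors = _load_clouds(config)
    else:
        clouds, records, _truths = simulate_study(config)

    params = GrowthParams(config.wood_density, config.carbon_fraction)
    volume_config = VolumeConfig(
        slice_height=config.slice_height,
        n_repeats=config.n_repeats,
        branch_multiplier=config.branch_multiplier,
    )
    metrics_config = MetricsConfig(
        breast_slice=(config.breast_low, config.breast_high),
        buttress_slice=(config.buttress_low, config.buttress_high),
        volume_config=volume_config,
    )

    ledger: dict[str, dict] = {
        tree_id: {"fatal": reason} for tree_id, reason in load_errors.items()
    }
    all_metrics: list[StructuralMetrics] = []
    seed_rng = np.random.default_rng(config.seed + 1)
    for cloud, rec in zip(clouds, records):
        mc = replace(metrics_config, volume_seed=int(seed_rng.integers(0, 2**31 - 1)))
        if cloud is None:
            all_metrics.append(StructuralMetrics(tree_id=rec.tree_id))
            continue
        try:
            m = compute_all_metrics(cloud, mc, tree_id=rec.tree_id)
        except Exception as exc:  # corrupt cloud: record and move on
            log.warning("tree %s failed: %s", rec.tree_id, exc)
            ledger[rec.tree_id] = {"fatal": f"{type(exc).__name__}: {exc}"}
            all_metrics.append(StructuralMetrics(tree_id=rec.tree_id))
            continue
        if m.errors:
            ledger[rec.tree_id] = dict(m.errors)
        all_metrics.append(m)
    write_metrics_table(all_metrics, out / "metrics.csv")

    # growth and carbon
    pairs = [(m, r) for m, r in zip(all_metrics, records)
             if m.height is not None]
    rates = [growth_rates(m, r, params) for m, r in pairs]
    cohort_rule = age_cohort_rule(config.cohort_age_threshold)
    cohorts = {r.tree_id: cohort_rule(r) for _, r in pairs}
    rates_long_table(rates, cohorts).to_csv(out / "rates.csv", index=False)
    summaries = site_summary(pairs, cohort_rule=cohort_rule, params=params)
    pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
        out / "site_summary.csv", index=False
    )

    # Welch t-tests between site AGB accumulation-rate distributions
    by_site: dict[str, list[float]] = {}
    for t in rates:
        if t.agb_rate is not None:
            by_site.setdefault(t.site, []).append(t.agb_rate)
    ttest_rows = []
    sites = sorted(by_site)
    for i, a in enumerate(sites):
        for b in sites[i + 1:]:
            if len(by_site[a]) >= 2 and len(by_site[b]) >= 2:
                cmp = compare_rates(by_site[a], by_site[b])
                ttest_rows.append((a, b, cmp.statistic, cmp.p_value, cmp.df))
    pd.DataFrame(ttest_rows, columns=["site_a", "site_b", "t", "p", "df"]).to_csv(
        out / "rate_ttests.csv", index=False
    )

    # allometry: published-model evaluation against TLS-derived AGB
    complete = [m for m in all_metrics
                if None not in (m.height, m.dbh, m.dtb, m.fdbh,
                                m.crown_volume, m.woody_volume)]
    eval_rows, pred_rows = [], []
    fit_rows, boot_frames = [], []
    if len(complete) >= 5:
        observed = np.array([m.woody_volume * config.wood_density for m in complete])
        for model_id, model in allometry.MODEL_REGISTRY.items():
            if model_id.startswith("uk_"):
                continue
            predicted = np.array([allometry.predict_agb(model, m) for m in complete])
            for m, p in zip(complete, predicted):
                pred_rows.append((m.tree_id, model_id, p))
            ev = allometry.evaluate_model(predicted, observed)
            eval_rows.append((model_id, ev.gradient, ev.intercept, ev.rmse,
                              ev.r2, ev.std_error, ev.n))

        # UK refits with bootstrap envelopes
        data = [(m, float(o)) for m, o in zip(complete, observed)]
        boot_rng = np.random.default_rng(config.seed + 2)
        for form in ("dbh_h", "dtb_h", "dbh_only", "h_only"):
            fit = allometry.fit_uk_model(form, data)
            ev = allometry.evaluate_model(fit.predict(fit.x), fit.y)
            fit_rows.append((form, fit.a, fit.b, ev.gradient, ev.intercept,
                             fit.rmse, fit.r2, fit.bias_pct, fit.n))
            env = allometry.parametric_bootstrap(
                fit, n_boot=config.n_boot,
                seed=int(boot_rng.integers(0, 2**31 - 1)),
            )
            boot_frames.append(pd.DataFrame({
                "form": form, "x": env.x_grid, "lo": env.lo, "hi": env.hi,
                "p2_5": env.p2_5, "p97_5": env.p97_5,
            }))
    pd.DataFrame(pred_rows, columns=["tree_id", "model_id", "agb_mg"]).to_csv(
        out / "model_predictions.csv", index=False
    )
    pd.DataFrame(eval_rows, columns=["model_id", "gradient", "intercept",
                                     "rmse_mg", "r2", "std_error", "n"]).to_csv(
        out / "model_eval.csv", index=False
    )
    pd.DataFrame(fit_rows, columns=["form", "a", "b", "gradient", "intercept",
                                    "rmse_mg", "r2", "bias_pct", "n"]).to_csv(
        out / "uk_models.csv", index=False
    )
    if boot_frames:
        pd.concat(boot_frames, ignore_index=True).to_csv(
            out / "uk_bootstrap.csv", index=False
        )
    allometry.save_registry(out / "model_registry.json")

    config_text = config.to_text()
    manifest = {
        "config": {f.name: getattr(config, f.name)
                   for f in dataclasses.fields(config)},
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": config.seed,
        "n_trees": len(records),
        "n_complete": len(complete),
        "error_ledger": ledger,
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out / "config.txt", "w", encoding="utf-8") as fh:
        fh.write(config_text)
    return manifest
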