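"""Two-step pipeline orchestration: networks first, regression second.

``run_pipeline`` drives the whole procedure — read (or simulate) the
panel, derive per-HRR ownership networks and concentration, aggregate the
HRR-level covariates, then fit the Bayesian Poisson models — and writes
every artifact (coefficient tables, HRR summaries, ICCs, random-effect
prevalence ratios, GraphML exports, a hashed run manifest and a Markdown
report) under one output directory.  A stage failure keeps the artifacts
already written and records the failed stage in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import glmm
from . import hrr_aggregation as agg
from . import ownership_network as net
from . import synthetic_data as synth
from .nhc_io import MODEL1_COVARIATES, Panel

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """The run configuration is unusable."""


@dataclass
class RunConfig:
    seed: int
    out_dir: str
    variant: str = "model1"  # model1 | model2 | both
    fixture_dir: str | None = None
    simulate: synth.GeneratorConfig | None = None
    mcmc: glmm.MCMCSettings | None = None
    write_fixture: bool = False
    export_graphml: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if self.variant not in ("model1", "model2", "both"):
            raise PipelineConfigError(f"unknown variant {self.variant!r}")
        if (self.fixture_dir is None) == (self.simulate is None):
            raise PipelineConfigError(
                "exactly one of fixture_dir or simulate must be given"
            )


def run_config_from_yaml(path, seed: int | None = None) -> RunConfig:
    """Load a run configuration; a --seed argument overrides the file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if seed is not None:
        raw["seed"] = seed
    if "seed" not in raw:
        raise PipelineConfigError("a seed is mandatory (config key or --seed)")
    sim = raw.get("simulate")
    mcmc = raw.get("mcmc")
    try:
        return RunConfig(
            seed=int(raw["seed"]),
            out_dir=str(raw.get("out_dir", "nhnet_out")),
            variant=raw.get("variant", "model1"),
            fixture_dir=raw.get("fixture_dir"),
            simulate=synth.GeneratorConfig(**sim) if sim is not None else None,
            mcmc=glmm.MCMCSettings(**mcmc) if mcmc is not None else None,
            write_fixture=bool(raw.get("write_fixture", False)),
            export_graphml=bool(raw.get("export_graphml", False)),
            log_level=raw.get("log_level", "INFO"),
        )
    except (TypeError, synth.ConfigError, glmm.SettingsError) as exc:
        raise PipelineConfigError(str(exc)) from exc


@dataclass
class ReportBundle:
    config: RunConfig
    out_dir: Path
    n_dates: int = 0
    n_complete: int = 0
    n_hrrs: int = 0
    metrics: pd.DataFrame | None = None
    summaries: list[agg.NationalSummary] = field(default_factory=list)
    fits: dict[str, glmm.PosteriorSummary] = field(default_factory=dict)
    files: list[Path] = field(default_factory=list)
    failed_stage: str | None = None
    converged: bool = True


def _setup_run_logging(out_dir: Path, level: str) -> logging.Handler:
    """JSON-lines log file alongside whatever console handlers exist."""

    class _JsonFormatter(logging.Formatter):
        def format(self, record):
            return json.dumps(
                {
                    "t": round(record.created, 3),
                    "level": record.levelname,
                    "logger": record.name,
                    "msg": record.getMessage(),
                }
            )

    handler = logging.FileHandler(out_dir / "run_log.jsonl")
    handler.setFormatter(_JsonFormatter())
    root = logging.getLogger("nhnet")
    root.setLevel(getattr(logging, level.upper(), logging.INFO))
    root.addHandler(handler)
    return handler


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every stage and write the artifact set.

    Stages: panel (read or simulate) -> ownership networks -> HRR metrics
    and national summaries -> model frame(s) -> MCMC fit(s) -> report and
    manifest.  On a stage exception the bundle's ``failed_stage`` names
    it; artifacts from completed stages remain on disk.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(out_dir, config.log_level)
    bundle = ReportBundle(config=config, out_dir=out_dir)
    timings: dict[str, float] = {}
    stage = "panel"
    try:
        t0 = time.time()
        if config.simulate is not None:
            data = synth.generate(config.simulate, config.seed)
            if config.write_fixture:
                synth.emit_fixture(config.simulate, config.seed, out_dir / "fixture")
            panel = data.assemble()
        else:
            panel = synth.load_fixture(config.fixture_dir)
        bundle.n_dates = len(panel.dates)
        bundle.n_complete = len(panel.complete_providers)
        timings[stage] = time.time() - t0

        variants = ["model1", "model2"] if config.variant == "both" else [config.variant]
        settings = config.mcmc or glmm.MCMCSettings(seed=config.seed)
        if config.mcmc is not None and config.mcmc.seed != config.seed:
            settings = glmm.MCMCSettings(
                **{**config.mcmc.__dict__, "seed": config.seed}
            )

        for variant in variants:
            stage = f"network[{variant}]"
            t0 = time.time()
            vpanel = panel
            if variant == "model2":
                # the MDS completeness requirement shrinks the cohort, so
                # networks and metrics are re-derived on that cohort
                vpanel = _reassemble_for_model2(config, panel)
            networks = agg.derive_hrr_networks(vpanel, seed=config.seed)
            metrics = agg.compute_hrr_metrics(networks)
            bundle.n_hrrs = len({m.hrr for m in metrics})
            timings[stage] = time.time() - t0

            stage = f"metrics[{variant}]"
            if not metrics:
                logger.warning("no analyzable HRRs for %s; skipping fit", variant)
                continue
            mframe = agg.metrics_frame(metrics)
            mpath = out_dir / f"hrr_metrics_{variant}.csv"
            mframe.to_csv(mpath, index=False)
            bundle.files.append(mpath)
            summaries = [
                agg.national_summary(metrics, d) for d in sorted(vpanel.dates)
            ]
            spath = out_dir / f"national_summary_{variant}.csv"
            agg.summary_frame(summaries).to_csv(spath, index=False)
            bundle.files.append(spath)
            if variant == variants[0]:
                bundle.metrics = mframe
                bundle.summaries = summaries

            if config.export_graphml:
                gdir = out_dir / "graphs"
                for nw in networks.values():
                    bundle.files.extend(net.export_graphml(nw.bipartite, nw.projection, gdir))

            stage = f"fit[{variant}]"
            t0 = time.time()
            frame = glmm.assemble_model_frame(vpanel, networks, metrics)
            spec = glmm.ModelSpec(variant=variant)
            design = glmm.build_design(frame, spec)
            samples = glmm.fit_poisson_glmm(design, settings)
            summary = glmm.summarize(samples)
            bundle.fits[variant] = summary
            bundle.converged = bundle.converged and summary.diagnostics.get(
                "converged", True
            )
            timings[stage] = time.time() - t0

            logger.info(
                "fit[%s] diagnostics: min ESS %.0f, max split-Rhat %.3f, "
                "beta acceptance %.2f",
                variant,
                summary.diagnostics.get("min_ess", float("nan")),
                summary.diagnostics.get("max_rhat", float("nan")),
                summary.diagnostics.get("beta_acceptance", float("nan")),
            )
            draws = pd.DataFrame(samples.beta, columns=samples.colnames)
            for comp, sdraws in samples.sigma2.items():
                draws[f"sigma2_{comp}"] = sdraws
            dpath = out_dir / f"posterior_draws_{variant}.csv"
            draws.to_csv(dpath, index=False)
            bundle.files.append(dpath)

            cpath = out_dir / f"coefficients_{variant}.csv"
            summary.fixed.to_csv(cpath, index=False)
            bundle.files.append(cpath)
            ipath = out_dir / f"icc_{variant}.csv"
            summary.icc.to_csv(ipath, index=False)
            bundle.files.append(ipath)
            for factor, table in summary.random_pr.items():
                rpath = out_dir / f"random_pr_{factor}_{variant}.csv"
                table.to_csv(rpath, index=False)
                bundle.files.append(rpath)
        stage = "report"
        report = render_report(bundle)
        rpath = out_dir / "report.md"
        rpath.write_text(report)
        bundle.files.append(rpath)
    except Exception:
        bundle.failed_stage = stage
        logger.exception("pipeline stage %r failed", stage)
        raise
    finally:
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "variant": config.variant,
            "config_hash": hashlib.sha256(
                json.dumps(_config_dict(config), sort_keys=True, default=str).encode()
            ).hexdigest(),
            "failed_stage": bundle.failed_stage,
            "converged": bundle.converged,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "files": {
                str(p.relative_to(out_dir)): _sha256(p)
                for p in bundle.files
                if p.exists()
            },
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        logging.getLogger("nhnet").removeHandler(handler)
        handler.close()
    return bundle


def _config_dict(config: RunConfig) -> dict:
    d = dict(config.__dict__)
    if config.simulate is not None:
        d["simulate"] = dict(config.simulate.__dict__)
    if config.mcmc is not None:
        d["mcmc"] = dict(config.mcmc.__dict__)
    return d


def _reassemble_for_model2(config: RunConfig, panel: Panel) -> Panel:
    from .nhc_io import assemble_panel

    codes = (
        config.simulate.mds_codes if config.simulate is not None else synth.MDS_CODES
    )
    required = tuple(c for c in MODEL1_COVARIATES if c != "five_star")
    mds_by_date = {
        d: {s.provider_id: s.mds for s in panel.snapshots(d)} for d in panel.dates
    }
    return assemble_panel(
        panel.snapshots_by_date,
        panel.owners_by_date,
        panel.crosswalk,
        required_covariates=required,
        mds_by_date=mds_by_date,
        required_mds_codes=codes,
    )


def render_report(bundle: ReportBundle) -> str:
    """Human-readable Markdown report of the run's summary tables."""
    lines = [
        "# Nursing-home ownership network analysis",
        "",
        f"- processing dates: {bundle.n_dates}",
        f"- complete-case facilities: {bundle.n_complete}",
        f"- hospital referral regions represented: {bundle.n_hrrs}",
        "",
    ]
    if bundle.n_hrrs == 0:
        lines.append("No HRRs contained analyzable facilities; nothing to report.")
        return "\n".join(lines) + "\n"
    if bundle.summaries:
        lines.append("## HRR-level covariates by processing date")
        lines.append("")
        lines.append("```")
        lines.append(agg.summary_frame(bundle.summaries).to_string(index=False))
        lines.append("```")
        lines.append("")
    for variant, summary in bundle.fits.items():
        lines.append(f"## Prevalence ratios ({variant})")
        lines.append("")
        lines.append("```")
        cols = ["term", "pr", "l95_hpdi", "u95_hpdi", "pmcmc_label"]
        lines.append(summary.fixed[cols].to_string(index=False))
        lines.append("```")
        lines.append("")
        lines.append(f"## Intraclass correlation coefficients ({variant})")
        lines.append("")
        lines.append("```")
        lines.append(summary.icc.to_string(index=False))
        lines.append("```")
        lines.append("")
        if not summary.diagnostics.get("converged", True):
            lines.append(
                "**Warning:** chain diagnostics indicate poor mixing; "
                "interpret the tables with caution."
            )
            lines.append("")
    return "\n".join(lines)
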