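"""File formats, run configuration, seeding, and pipeline orchestration.

All stage outputs are plain CSV or structured text. One global seed expands
into independent per-stage substreams keyed by stage name, so inserting a
stage never perturbs the randomness of the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .competency import (
    DEFAULT_THRESHOLD,
    PriorSpec,
    binarize_competency,
    convergence_diagnostics,
    cue_tc50_contrasts,
    fit_competency_model,
    tc50_draws,
    tc50_from_draws,
    threshold_sweep,
)
from .datatypes import ASSAY_COLUMNS, SamplerConfig
from .gam import GamPriorSpec, auc_per_draw, curve_from_draws, fit_settlement_gam, rank_cues
from .summaries import (
    DEFAULT_CLASS_BOUNDARIES,
    classify_precompetency,
    summarize_species_table,
)

__all__ = [
    "read_assay_csv",
    "write_assay_csv",
    "write_profile_sidecar",
    "stage_seed",
    "RunConfig",
    "RunManifest",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def read_assay_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate an assay observation table.

    Requires the canonical header; rows violating the count or age
    invariants are rejected with a warning naming their row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    df = df[list(ASSAY_COLUMNS)]
    bad = (
        (df["n_settled"] < 0)
        | (df["n_larvae"] < 0)
        | (df["n_settled"] > df["n_larvae"])
        | (df["age_days"] < 0)
    )
    if bad.any():
        logger.warning(
            "rejecting %d invalid assay rows (file rows %s)",
            int(bad.sum()),
            [int(i) + 2 for i in df.index[bad]],  # 1-based incl. header
        )
        df = df[~bad]
    return df.reset_index(drop=True)


def write_assay_csv(observations: pd.DataFrame, path: str | Path) -> None:
    """Write an assay table in the canonical column order, byte-stable."""
    observations[list(ASSAY_COLUMNS)].to_csv(path, index=False)


def write_profile_sidecar(profile, design, seed: int, path: str | Path) -> None:
    """Record the generating ground truth next to a simulated table."""
    payload = {
        "seed": seed,
        "profile": {
            "species_id": profile.species_id,
            "onset_age_tc50_true": profile.onset_age_tc50_true,
            "onset_slope_true": profile.onset_slope_true,
            "cue_effects": dict(profile.cue_effects),
            "asymptote": profile.asymptote,
            "temporal_modes": [
                {"center": m.center, "width": m.width, "amplitude": m.amplitude}
                for m in profile.temporal_modes
            ],
            "plate_sd": profile.plate_sd,
            "plate_slope_sd": profile.plate_slope_sd,
        },
        "design": {
            "timepoints": list(map(float, design.timepoints)),
            "cues": list(design.cues),
            "wells_per_treatment": design.wells_per_treatment,
            "larvae_per_well": design.larvae_per_well,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return int(
        np.random.SeedSequence((int(seed), zlib.crc32(stage.encode()))).generate_state(1)[0]
    )


@dataclass
class RunConfig:
    """Everything a full pipeline run needs; defaults follow the published settings."""

    input_csv: str = ""
    out_dir: str = "out"
    threshold: float = DEFAULT_THRESHOLD
    sweep_thresholds: tuple = ()  # empty = skip the sweep stage
    n_chains: int = 3
    n_iterations: int = 6000
    warmup: int = 2000
    thin: int = 10
    n_knots: int = 5
    resolution: int = 100
    exceedance_cutoff: float = 0.95
    class_boundaries: tuple = DEFAULT_CLASS_BOUNDARIES
    decay_rate: float = 0.05
    seed: int = 0
    log_level: str = "INFO"
    control_cue: str = "control"
    prior: PriorSpec = field(default_factory=PriorSpec)
    gam_prior: GamPriorSpec = field(default_factory=GamPriorSpec)

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        for t in self.sweep_thresholds:
            if not (0.0 < t < 1.0):
                raise ValueError(f"sweep threshold {t} outside (0, 1)")
        if self.resolution < 2:
            raise ValueError("resolution must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        prior = PriorSpec(**raw.pop("prior", {}))
        gam_prior = GamPriorSpec(**raw.pop("gam_prior", {}))
        for key in ("sweep_thresholds", "class_boundaries"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(prior=prior, gam_prior=gam_prior, **raw)

    def sampler_config(self, stage: str) -> SamplerConfig:
        return SamplerConfig(
            n_chains=self.n_chains,
            n_iterations=self.n_iterations,
            warmup=self.warmup,
            thin=self.thin,
            seed=stage_seed(self.seed, stage),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sweep_thresholds"] = list(self.sweep_thresholds)
        d["class_boundaries"] = list(self.class_boundaries)
        return d


@dataclass
class RunManifest:
    """Reproducibility record emitted with every pipeline run."""

    config: dict
    package_version: str
    seed: int
    input_checksums: dict
    started: str
    finished: str = ""
    outputs: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run every analysis stage on an assay table and write all outputs.

    Stages per species: binarize at the primary threshold, fit the logistic
    competency model, extract per-cue TC50 and contrasts, optionally sweep
    thresholds, fit the settlement GAM, integrate AUCs and rank cues, then
    assemble the cross-species summary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        package_version=__version__,
        seed=config.seed,
        input_checksums={config.input_csv: _sha256(config.input_csv)},
        started=datetime.now(timezone.utc).isoformat(),
    )
    obs = read_assay_csv(config.input_csv)
    species_list = sorted(obs["species_id"].unique())

    tc50_rows = []
    sweep_rows = []
    ranking_lines = []
    diag_lines = []
    summary_rows = []
    for species in species_list:
        sobs = obs[obs["species_id"] == species].reset_index(drop=True)
        max_age = float(sobs["age_days"].max())

        records = binarize_competency(sobs, config.threshold)
        draws = fit_competency_model(
            records, config.sampler_config(f"tc50:{species}"), config.prior
        )
        draws.meta["species_id"] = species
        report = convergence_diagnostics(draws)
        diag_lines.append(
            f"{species} competency-logistic: pass={report.passed} "
            f"max_rhat={np.nanmax(report.rhat):.4f} min_ess={np.nanmin(report.ess):.0f}"
        )
        per_cue = {}
        for cue in draws.meta["cues"]:
            est = tc50_from_draws(draws, cue, max_age, threshold=config.threshold)
            per_cue[cue] = est
            tc50_rows.append(dataclasses.asdict(est))
        contrasts = cue_tc50_contrasts(
            {c: tc50_draws(draws, c) for c in draws.meta["cues"]}
        )
        contrasts.to_csv(out / f"tc50_exceedance_{species}.csv")

        if config.sweep_thresholds:
            sweep = threshold_sweep(
                sobs,
                config.sweep_thresholds,
                config.sampler_config(f"sweep:{species}"),
                config.prior,
                control_cue=config.control_cue,
            )
            sweep_rows.extend(dataclasses.asdict(e) for e in sweep)

        gam_draws = fit_settlement_gam(
            sobs,
            n_knots=config.n_knots,
            config=config.sampler_config(f"gam:{species}"),
            prior_spec=config.gam_prior,
        )
        grid = np.linspace(
            float(sobs["age_days"].min()), max_age, config.resolution
        )
        curves = []
        aucs = {}
        for cue in gam_draws.meta["cues"]:
            c = curve_from_draws(gam_draws, cue, grid)
            curves.append(
                pd.DataFrame(
                    {
                        "species_id": species,
                        "cue": cue,
                        "age_days": c.age_grid,
                        "median": c.median,
                        "ci_lower": c.ci_lower,
                        "ci_upper": c.ci_upper,
                    }
                )
            )
            aucs[cue] = auc_per_draw(gam_draws, cue, resolution=config.resolution)
        pd.concat(curves, ignore_index=True).to_csv(
            out / f"curves_{species}.csv", index=False
        )
        pd.DataFrame({c: a.areas for c, a in aucs.items()}).to_csv(
            out / f"auc_{species}.csv", index=False
        )
        ranking = rank_cues(aucs, cutoff=config.exceedance_cutoff)
        ranking_lines.append(
            f"{species}: {ranking.display}  (exceedance cutoff "
            f"{ranking.exceedance_cutoff})"
        )

        inducers = {
            c: e for c, e in per_cue.items() if c != config.control_cue and not e.truncated
        }
        pool = inducers or per_cue
        best_cue = min(pool, key=lambda c: pool[c].tc50_median)
        best = per_cue[best_cue]
        summary_rows.append(
            {
                "species_id": species,
                "family": "",
                "species": species,
                "tc50": best.tc50_median,
                "ci_lower": best.ci_lower,
                "ci_upper": best.ci_upper,
                "best_cue": best_cue,
                "precompetency_class": classify_precompetency(
                    best.tc50_median, config.class_boundaries
                )
                if np.isfinite(best.tc50_median) and best.tc50_median > 0
                else "unresolved",
                "oocyte_diameter_um": np.nan,
            }
        )

    tc50_df = pd.DataFrame(tc50_rows)
    tc50_df.to_csv(out / "tc50_table.csv", index=False)
    if sweep_rows:
        pd.DataFrame(sweep_rows).to_csv(out / "tc50_sweep.csv", index=False)
    (out / "rankings.txt").write_text("\n".join(ranking_lines) + "\n")
    (out / "diagnostics.txt").write_text("\n".join(diag_lines) + "\n")
    summary_df = pd.DataFrame(summary_rows)
    summary_df.to_csv(out / "species_summary.csv", index=False)
    summary = summarize_species_table(summary_df, config.class_boundaries)
    (out / "summary.txt").write_text(
        f"n_species: {summary.n_species}\n"
        f"mean_tc50: {summary.mean_tc50}\n"
        f"min_tc50: {summary.min_tc50} ({summary.min_species})\n"
        f"max_tc50: {summary.max_tc50} ({summary.max_species})\n"
        f"class_counts: {summary.class_counts}\n"
        f"class_percentages: {summary.class_percentages}\n"
    )
    manifest.outputs = {
        p.name: _sha256(p) for p in sorted(out.glob("*.csv"))
    }
    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.write(out / "manifest.json")
    return manifest
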