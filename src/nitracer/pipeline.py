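"""Seeded, logged end-to-end pipeline over synthetic or user data.

Stages run in dependency order::

    simulate -> mix -> apportion -> diversity -> ordinate -> couple -> report

Each run writes one CSV per result table plus a manifest (seed, config,
versions), so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .apportion import SourceGrouping, contribution_table
from .community import alpha_diversity, anosim, bray_curtis, mantel, pcoa
from .coupling import correlate, fit_path_model, indirect_effect
from .errors import NitracerError, SchemaError
from .io import (
    read_community_table,
    read_isotope_csv,
    read_sources_csv,
    read_watershed_csv,
    write_community_table,
    write_results,
)
from .mixing import MixingConfig, fit_mixing_model, posterior_summary

__all__ = ["RunConfig", "run_pipeline", "report"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "mix", "apportion", "diversity", "ordinate", "couple")

# stage -> stages that must run before it (when inputs are synthetic)
_DEPS = {
    "simulate": (),
    "mix": ("simulate",),
    "apportion": ("mix",),
    "diversity": ("simulate",),
    "ordinate": ("simulate",),
    "couple": ("simulate",),
}


@dataclass
class RunConfig:
    """Pipeline configuration; every randomized stage derives from ``seed``."""

    seed: int = 1
    out_dir: str = "results"
    stages: tuple[str, ...] = ALL_STAGES
    # synthetic sizes (kept modest so a demo run completes in seconds)
    n_isotope_samples: int = 100
    n_watershed: int = 2_000
    n_sem: int = 5_000
    n_sites: int = 60
    n_taxa: int = 200
    community_depth: int = 20_000
    n_perm: int = 999
    mcmc: dict = field(
        default_factory=lambda: {
            "n_chains": 4,
            "n_iter": 4_000,
            "n_burnin": 2_000,
            "thin": 2,
        }
    )
    # optional user-supplied inputs; when set they replace synthetic data
    isotope_csv: str | None = None
    sources_csv: str | None = None
    community_tsv: str | None = None
    watershed_csv: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise SchemaError(f"unknown stage(s): {sorted(unknown)}")
        for stage in self.stages:
            missing = [d for d in _DEPS[stage] if d not in self.stages]
            if missing and not self._inputs_cover(stage):
                raise NitracerError(
                    f"stage {stage!r} requires {missing} to run first"
                )
        for attr in ("isotope_csv", "sources_csv", "community_tsv", "watershed_csv"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise NitracerError(f"input file for {attr} not found: {path}")

    def _inputs_cover(self, stage: str) -> bool:
        if stage == "mix":
            return self.isotope_csv is not None and self.sources_csv is not None
        if stage in ("diversity", "ordinate"):
            return self.community_tsv is not None
        if stage == "couple":
            return self.watershed_csv is not None
        return False


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages and return the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    logger.info("pipeline start: stages=%s seed=%d", config.stages, config.seed)
    rng_base = int(config.seed)
    tables: dict[str, pd.DataFrame] = {}
    state: dict = {}

    if "simulate" in config.stages:
        _stage_simulate(config, rng_base, tables, state, out)
    _load_user_inputs(config, state)

    if "mix" in config.stages:
        _stage_mix(config, rng_base, tables, state)
    if "apportion" in config.stages:
        _stage_apportion(tables, state)
    if "diversity" in config.stages:
        tables["diversity"] = alpha_diversity(state["community"])
    if "ordinate" in config.stages:
        _stage_ordinate(config, rng_base, tables, state)
    if "couple" in config.stages:
        _stage_couple(config, rng_base, tables, state)

    write_results(tables, out, seed=config.seed, config=asdict(config))
    logger.info("pipeline complete: %d result tables in %s", len(tables), out)
    return out


def _setup_logging(out: Path) -> None:
    root = logging.getLogger("nitracer")
    if not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == (out / "run.log").resolve()
        for h in root.handlers
    ):
        fh = logging.FileHandler(out / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        root.addHandler(fh)
    if root.level == logging.NOTSET:
        root.setLevel(logging.INFO)


def _stage_simulate(config, seed, tables, state, out: Path) -> None:
    dry = synthetic.SCENARIO_DRY
    wet = synthetic.SCENARIO_WET
    samples = {
        "dry": synthetic.generate_isotope_dataset(dry, seed=seed),
        "wet": synthetic.generate_isotope_dataset(wet, seed=seed + 1),
    }
    state["isotopes"] = samples
    state["signatures"] = dry.signatures
    tables["isotopes"] = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "region": s.region,
                "season": s.season,
                "d15n": s.d15n,
                "d18o": s.d18o,
            }
            for season in samples.values()
            for s in season
        ]
    )
    watershed = synthetic.generate_watershed_dataset(
        synthetic.SCENARIO_COUPLING, seed=seed + 2, n=config.n_watershed
    )
    state["watershed"] = watershed
    tables["watershed"] = watershed.data
    sem = synthetic.generate_sem_dataset(
        synthetic.SCENARIO_SEM, seed=seed + 3, n=config.n_sem
    )
    state["sem_data"] = sem
    tables["watershed_sem"] = sem.data
    conn = np.random.default_rng(seed + 4).uniform(0.1, 0.3, config.n_sites)
    community = synthetic.generate_community_tables(
        config.n_sites,
        config.n_taxa,
        conn,
        diversity_loading=-0.74,
        seed=seed + 5,
        depth=config.community_depth,
    )
    state["community"] = community
    write_community_table(community, out / "community.tsv")
    d1, d2 = synthetic.generate_correlated_distances(
        config.n_sites, target_r=0.45, seed=seed + 6
    )
    state["distances"] = (d1, d2)


def _load_user_inputs(config, state) -> None:
    if config.isotope_csv:
        samples = read_isotope_csv(config.isotope_csv)
        by_season: dict[str, list] = {}
        for s in samples:
            by_season.setdefault(s.season, []).append(s)
        state["isotopes"] = by_season
    if config.sources_csv:
        state["signatures"] = read_sources_csv(config.sources_csv)
    if config.community_tsv:
        state["community"] = read_community_table(config.community_tsv)
    if config.watershed_csv:
        state["watershed"] = read_watershed_csv(config.watershed_csv)
        state["sem_data"] = state["watershed"]


def _stage_mix(config, seed, tables, state) -> None:
    posteriors = {}
    summary_rows, diag_rows = [], []
    for i, (season, samples) in enumerate(sorted(state["isotopes"].items())):
        mc = MixingConfig(seed=seed + 10 + i, **config.mcmc)
        post = fit_mixing_model(samples, state["signatures"], mc)
        posteriors[season] = post
        logger.info("mix[%s]: converged=%s", season, post.converged)
        summ = posterior_summary(post)
        summ.insert(0, "stratum", season)
        summary_rows.append(summ)
        diag = post.diagnostics.copy()
        diag.insert(0, "stratum", season)
        diag_rows.append(diag)
    state["posteriors"] = posteriors
    tables["mixing_summary"] = pd.concat(summary_rows, ignore_index=True)
    tables["mixing_diagnostics"] = pd.concat(diag_rows, ignore_index=True)


def _stage_apportion(tables, state) -> None:
    strata = sorted(state["posteriors"].items())
    tables["contributions"] = contribution_table(strata, SourceGrouping())


def _stage_ordinate(config, seed, tables, state) -> None:
    community = state["community"]
    d = bray_curtis(community)
    ord_res = pcoa(d, n_axes=2)
    coords = ord_res.to_frame().reset_index()
    tables["ordination"] = coords
    tables["ordination_axes"] = pd.DataFrame(
        {
            "axis": [f"PCoA{i + 1}" for i in range(len(ord_res.proportion_explained))],
            "proportion_explained": ord_res.proportion_explained,
        }
    )
    if community.metadata is not None and "connectivity" in community.metadata:
        conn = community.metadata["connectivity"].to_numpy()
        groups = np.where(conn >= np.median(conn), "high", "low")
    else:
        half = community.n_sites // 2
        groups = np.array(["A"] * half + ["B"] * (community.n_sites - half))
    R, p = anosim(d, groups, n_perm=config.n_perm, seed=seed + 20)
    tables["group_tests"] = pd.DataFrame(
        [{"test": "anosim", "statistic": R, "p_value": p, "n_perm": config.n_perm}]
    )


def _stage_couple(config, seed, tables, state) -> None:
    ws = state["watershed"]
    conn = ws.column("connectivity")
    rows = []
    for var in ("tn", "no3", "nh4", "chao1", "shannon"):
        r, p = correlate(conn, ws.column(var))
        rows.append({"x": "connectivity", "y": var, "r": r, "p_value": p})
    tables["correlations"] = pd.DataFrame(rows)

    if "distances" in state:
        d1, d2 = state["distances"]
        r, p = mantel(d1, d2, n_perm=config.n_perm, seed=seed + 30)
        mantel_row = pd.DataFrame(
            [{"test": "mantel", "statistic": r, "p_value": p, "n_perm": config.n_perm}]
        )
        tables["group_tests"] = (
            pd.concat([tables["group_tests"], mantel_row], ignore_index=True)
            if "group_tests" in tables
            else mantel_row
        )

    edges = [
        (synthetic.SEM_COLUMN_MAP[a], synthetic.SEM_COLUMN_MAP[b])
        for a, b, _ in synthetic.SCENARIO_SEM.edges
    ]
    model = fit_path_model(state["sem_data"], edges)
    tables["sem_edges"] = model.to_frame()
    tables["sem_r2"] = pd.DataFrame(
        [{"variable": v, "r_squared": r2} for v, r2 in model.r_squared.items()]
    )
    tables["sem_indirect"] = pd.DataFrame(
        [
            {
                "path": "connectivity->tn->shannon",
                "effect": indirect_effect(model, ["connectivity", "tn", "shannon"]),
            }
        ]
    )


def report(results_dir: str | Path) -> str:
    """Human-readable markdown summary of a completed run."""
    out = Path(results_dir)
    lines = ["# nitracer run report", ""]

    def _table(name: str) -> pd.DataFrame | None:
        path = out / f"{name}.csv"
        return pd.read_csv(path) if path.exists() else None

    contrib = _table("contributions")
    if contrib is not None:
        lines.append("## Source contributions (% of nitrate)")
        for stratum, grp in contrib.groupby("stratum"):
            lines.append(f"### stratum: {stratum}")
            for _, row in grp.iterrows():
                lines.append(
                    f"- {row['name']} ({row['kind']}): "
                    f"{row['mean_pct']:.1f}% [{row['lo_pct']:.1f}, {row['hi_pct']:.1f}]"
                )
        lines.append("")
    else:
        lines.append("## Source contributions: not run\n")

    div = _table("diversity")
    if div is not None:
        lines.append("## Alpha diversity")
        for col in ("chao1", "shannon", "simpson"):
            lines.append(
                f"- {col}: {div[col].min():.4g} - {div[col].max():.4g} "
                f"(median {div[col].median():.4g})"
            )
        lines.append("")
    else:
        lines.append("## Alpha diversity: not run\n")

    tests = _table("group_tests")
    if tests is not None:
        lines.append("## Permutation tests")
        for _, row in tests.iterrows():
            lines.append(
                f"- {row['test']}: statistic = {row['statistic']:.4f}, "
                f"p = {row['p_value']:.4f} ({int(row['n_perm'])} permutations)"
            )
        lines.append("")

    corr = _table("correlations")
    if corr is not None:
        lines.append("## Connectivity correlations")
        for _, row in corr.iterrows():
            lines.append(
                f"- r(connectivity, {row['y']}) = {row['r']:.3f} (p = {row['p_value']:.3g})"
            )
        lines.append("")

    sem = _table("sem_edges")
    if sem is not None:
        lines.append("## Path model")
        for _, row in sem.iterrows():
            lines.append(
                f"- {row['source']} -> {row['target']}: "
                f"{row['coefficient']:.3f} (p = {row['p_value']:.3g})"
            )
        r2 = _table("sem_r2")
        if r2 is not None:
            for _, row in r2.iterrows():
                lines.append(f"- R²({row['variable']}) = {row['r_squared']:.3f}")
        lines.append("")
    else:
        lines.append("## Path model: not run\n")

    text = "\n".join(lines)
    (out / "report.md").write_text(text)
    return text
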