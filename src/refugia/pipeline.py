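"""End-to-end orchestration: simulate -> clean -> sdm -> diversity ->
prioritize -> gaps/refugia, driven by one structured config.

Every stochastic stage draws its own child seed from the master seed, so a
rerun with the same config is reproducible bit for bit.  Warnings raised by
any stage are collected into the provenance log rather than swallowed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import gap_refugia as gr
from . import io as rio
from . import prioritization as pz
from . import qc, sdm, synthetic
from .grids import EnvStack, GridSpec, PAMask

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_outputs"]

DIMENSIONS = ("TD", "PD", "FD")


@dataclass
class PipelineConfig:
    """All knobs of the synthetic study in one place.

    Defaults describe the demo study: a 100x100 landscape, 30 species split
    across the three record tiers roughly like a half/third/fifth mix, the
    current climate plus three ordered severity presets at one horizon, and
    the standard thresholds (TSS 0.7, AUC 0.7, 5% presence quantile, 5-km
    buffer, |r| < 0.8, top 30%).
    """

    seed: int = 0
    # landscape
    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 1.0
    n_layers: int = 5
    correlation_length: float = 8.0
    latitudinal_trend: float = 0.5
    # scenarios
    scenarios: tuple[str, ...] = ("mild", "moderate", "severe")
    horizon: str = "2050s"
    scenario_noise_sd: float = 0.05
    # species and occurrences
    n_tier1: int = 15
    n_tier2: int = 9
    n_tier3: int = 6
    tier1_records: tuple[int, int] = (20, 80)
    presence_cutoff: float = 0.5
    breadth_range: tuple[float, float] = (1.0, 2.0)
    coordinate_noise: float = 0.0
    birth_rate: float = 1.0
    # traits
    n_continuous: int = 4
    n_categorical: int = 2
    trait_signal: float = 1.0
    missing_fraction: float = 0.15
    impute_k: int = 5
    # protected areas / condition
    pa_coverage: float = 0.1
    pa_patches: int = 6
    influence_correlation_length: float = 6.0
    use_condition: bool = True
    # qc
    collinearity_threshold: float = 0.8
    # sdm
    sdm: sdm.SDMConfig = field(default_factory=sdm.SDMConfig)
    # prioritization / reporting
    top_fraction: float = 0.30
    connectivity_radius: int = 5
    hotspot_percents: tuple[float, ...] = (0.01, 0.05)
    refugia_min_area: int = 5
    refugia_connectivity: int = 8

    @property
    def n_species(self) -> int:
        return self.n_tier1 + self.n_tier2 + self.n_tier3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sdm_raw = raw.pop("sdm", {})
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if sdm_raw:
            cfg = dataclasses.replace(cfg, sdm=sdm.SDMConfig(**sdm_raw))
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


def _child_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


@dataclass
class PipelineResult:
    config: PipelineConfig
    grid: GridSpec
    env_stacks: dict[str, EnvStack]
    tree: Any
    traits: synthetic.TraitMatrix
    dendrogram: Any
    true_species: list[synthetic.TrueSpecies]
    occurrences: pd.DataFrame
    cleaned: pd.DataFrame
    qc_report: qc.QCReport
    retained_layers: list[str]
    pa: PAMask
    condition: np.ndarray
    atlas: sdm.RangeAtlas
    diversity_maps: dict[tuple[str, str], dv.DiversityMap]  # (metric, scenario)
    priorities: dict[tuple[str, str], pz.PriorityMap]
    top_masks: dict[tuple[str, str], np.ndarray]
    optimal_masks: dict[str, np.ndarray]
    refugia: gr.RefugiaResult
    report: dict[str, Any]
    provenance: dict[str, Any]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage in dependency order and assemble the final report."""
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        result = _run(config)
    caught.extend(f"{w.category.__name__}: {w.message}" for w in wlist)
    result.provenance["warnings"] = caught
    return result


def _run(config: PipelineConfig) -> PipelineResult:
    seeds = _child_seeds(config.seed, 10)
    (
        s_env,
        s_scen,
        s_tree,
        s_traits,
        s_species,
        s_occ,
        s_pa,
        s_influence,
        s_tiers,
        s_sdm,
    ) = seeds

    # --- simulate -------------------------------------------------------
    grid = GridSpec(config.n_rows, config.n_cols, cell_size=config.cell_size)
    env = synthetic.generate_environment(
        grid,
        n_layers=config.n_layers,
        correlation_length=config.correlation_length,
        seed=s_env,
        latitudinal_trend=config.latitudinal_trend,
    )
    scen_seeds = _child_seeds(s_scen, len(config.scenarios))
    env_stacks: dict[str, EnvStack] = {"current": env}
    for name, sseed in zip(config.scenarios, scen_seeds):
        stack = synthetic.scenario_preset(
            env, name, horizon=config.horizon, seed=sseed, noise_sd=config.scenario_noise_sd
        )
        env_stacks[stack.scenario_tag] = stack
    scenario_tags = list(env_stacks)

    tree = synthetic.generate_phylogeny(config.n_species, config.birth_rate, seed=s_tree)
    species_ids = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    traits = synthetic.generate_traits(
        tree,
        n_continuous=config.n_continuous,
        n_categorical=config.n_categorical,
        signal=config.trait_signal,
        missing_fraction=config.missing_fraction,
        seed=s_traits,
    )
    true_species = synthetic.generate_virtual_species(
        env,
        species_ids,
        presence_cutoff=config.presence_cutoff,
        breadth_range=config.breadth_range,
        seed=s_species,
    )

    tier_rng = np.random.default_rng(s_tiers)
    order = tier_rng.permutation(len(true_species))
    plan: dict[str, int] = {}
    for rank, idx in enumerate(order):
        sp = true_species[idx]
        if rank < config.n_tier1:
            sp.tier = "tier1"
            plan[sp.species_id] = int(tier_rng.integers(*config.tier1_records))
        elif rank < config.n_tier1 + config.n_tier2:
            sp.tier = "tier2"
            plan[sp.species_id] = int(tier_rng.integers(2, 6))
        else:
            sp.tier = "tier3"
            plan[sp.species_id] = 1
    occurrences = synthetic.sample_occurrences(
        true_species, plan, coordinate_noise=config.coordinate_noise, seed=s_occ, grid=grid
    )
    pa = synthetic.generate_protected_areas(
        grid, target_coverage=config.pa_coverage, n_patches=config.pa_patches, seed=s_pa
    )
    influence = synthetic.generate_human_influence(
        grid, correlation_length=config.influence_correlation_length, seed=s_influence
    )
    condition = 1.0 - influence  # heavily impacted cells lose value

    # --- clean ----------------------------------------------------------
    cleaned, qc_report = qc.clean_occurrences(occurrences, grid)
    retained_layers = qc.select_variables(env, threshold=config.collinearity_threshold)
    stacks_sel = {tag: stack.subset(retained_layers) for tag, stack in env_stacks.items()}
    env_sel = stacks_sel["current"]

    # --- sdm ------------------------------------------------------------
    sdm_seeds = _child_seeds(s_sdm, len(species_ids))
    ranges: dict[tuple[str, str], sdm.SpeciesRange] = {}
    modeled_species: list[str] = []
    models: dict[str, Any] = {}
    for sid, sp_seed in zip(species_ids, sdm_seeds):
        recs = cleaned[cleaned["species"] == sid]
        n_rec = len(recs)
        if n_rec == 0:
            warnings.warn(f"{sid}: no records survived QC; species dropped")
            continue
        modeled_species.append(sid)
        rc = recs[["row", "col"]].to_numpy(int)
        rng = np.random.default_rng(sp_seed)
        presence_cells = {(int(r), int(c)) for r, c in rc}
        if n_rec >= config.sdm.min_records_tier1:
            b_rows, b_cols = sdm.sample_background(grid, presence_cells, config.sdm.background_n, rng)
            model = sdm.fit_tier1_ensemble(
                rc, env_sel, np.column_stack([b_rows, b_cols]), config.sdm,
                seed=int(rng.integers(2**31)), species_id=sid,
            )
            models[sid] = model
            for tag, stack in stacks_sel.items():
                ranges[(sid, tag)] = model.predict_range(stack)
        elif n_rec >= 2:
            b_rows, b_cols = sdm.sample_background(grid, presence_cells, config.sdm.background_n, rng)
            model = sdm.fit_tier2_small(
                rc, env_sel, np.column_stack([b_rows, b_cols]), config.sdm, species_id=sid
            )
            models[sid] = model
            for tag, stack in stacks_sel.items():
                ranges[(sid, tag)] = model.predict_range(stack)
        else:
            rec = recs.iloc[0]
            base = sdm.buffer_single(
                float(rec["x"]), float(rec["y"]), config.sdm.buffer_km, grid, species_id=sid
            )
            # single-record ranges are static across every scenario
            for tag in scenario_tags:
                ranges[(sid, tag)] = sdm.SpeciesRange(
                    sid, tag, base.presence.copy(), tier="tier3", threshold=base.threshold
                )
    atlas = sdm.build_range_atlas(ranges, modeled_species, scenario_tags, grid)

    # --- diversity ------------------------------------------------------
    imputed = dv.impute_traits(traits, tree, k=config.impute_k)
    gower = dv.gower_matrix(imputed)
    dendrogram = dv.upgma_dendrogram(gower)
    diversity_maps: dict[tuple[str, str], dv.DiversityMap] = {}
    for tag in scenario_tags:
        diversity_maps[("TD", tag)] = dv.richness_map(atlas, tag)
        diversity_maps[("PD", tag)] = dv.faith_pd_map(atlas, tree, tag)
        diversity_maps[("FD", tag)] = dv.fdend_map(atlas, dendrogram, tag)

    # --- prioritize -----------------------------------------------------
    priorities: dict[tuple[str, str], pz.PriorityMap] = {}
    top_masks: dict[tuple[str, str], np.ndarray] = {}
    for dim in DIMENSIONS:
        dim_tree = {"TD": None, "PD": tree, "FD": dendrogram}[dim]
        current_features = {
            f.feature_id: f for f in pz.build_features(dim, atlas, "current", tree=dim_tree).features
        }
        for tag in scenario_tags:
            fs = pz.build_features(dim, atlas, tag, tree=dim_tree)
            if tag != "current" and config.connectivity_radius >= 0:
                adjusted = []
                for f in fs.features:
                    cur = current_features.get(f.feature_id)
                    if cur is None:
                        adjusted.append(f)
                        continue
                    vals = pz.link_future_connectivity(
                        cur.values > 0, f.values > 0, radius=config.connectivity_radius
                    )
                    if vals.sum() > 0:
                        adjusted.append(pz.Feature(f.feature_id, f.weight, vals))
                if adjusted:
                    fs = pz.FeatureSet(grid, dim, adjusted, condition_tag=fs.condition_tag)
            if config.use_condition:
                fs = pz.apply_condition(fs, condition, tag="1-influence")
            pm = pz.caz_rank(fs, scenario_tag=tag)
            priorities[(dim, tag)] = pm
            top_masks[(dim, tag)] = pz.top_fraction_mask(pm, config.top_fraction)

    # --- gaps / refugia -------------------------------------------------
    mask = grid.analysis_mask
    report: dict[str, Any] = {"qc": qc_report.as_dict(), "retained_layers": retained_layers}
    report["tau_div"] = {
        f"{a}-{b}": gr.kendall_tau(
            diversity_maps[(a, "current")].values, diversity_maps[(b, "current")].values, mask
        )
        for a, b in (("TD", "PD"), ("TD", "FD"), ("PD", "FD"))
    }
    report["tau_prio"] = {
        f"{a}-{b}": gr.kendall_tau(priorities[(a, "current")].rank, priorities[(b, "current")].rank, mask)
        for a, b in (("TD", "PD"), ("TD", "FD"), ("PD", "FD"))
    }
    overlaps = {}
    optimal_masks: dict[str, np.ndarray] = {}
    for tag in scenario_tags:
        named = {dim: top_masks[(dim, tag)] for dim in DIMENSIONS}
        rep = gr.overlap_table(named, mask, pa=pa)
        overlaps[tag] = rep.as_dict()
        optimal_masks[tag] = np.logical_and.reduce([named[d] for d in DIMENSIONS])
    report["priority_overlap"] = overlaps
    report["hotspots"] = _hotspot_report(config, diversity_maps, mask, pa, scenario_tags)
    refugia = gr.refugia_mask(
        optimal_masks, pa=pa, connectivity=config.refugia_connectivity, min_area=config.refugia_min_area
    )
    report["refugia"] = {
        "n_cells": int(refugia.mask.sum()),
        "n_regions": int(len(refugia.regions)),
        "pa_coverage": refugia.pa_coverage,
        "scenarios": refugia.scenarios,
    }
    report["range_summary"] = atlas.summary().to_dict(orient="records")

    provenance = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_modeled_species": len(modeled_species),
    }
    return PipelineResult(
        config=config,
        grid=grid,
        env_stacks=env_stacks,
        tree=tree,
        traits=imputed,
        dendrogram=dendrogram,
        true_species=true_species,
        occurrences=occurrences,
        cleaned=cleaned,
        qc_report=qc_report,
        retained_layers=retained_layers,
        pa=pa,
        condition=condition,
        atlas=atlas,
        diversity_maps=diversity_maps,
        priorities=priorities,
        top_masks=top_masks,
        optimal_masks=optimal_masks,
        refugia=refugia,
        report=report,
        provenance=provenance,
    )


def _hotspot_report(config, diversity_maps, mask, pa, scenario_tags) -> dict:
    out: dict[str, Any] = {}
    for dim in DIMENSIONS:
        for pct in config.hotspot_percents:
            key = f"{dim}_top{pct:g}"
            entry = {}
            for tag in scenario_tags:
                hmask, vstar = gr.hotspot_mask(diversity_maps[(dim, tag)].values, mask, pct)
                entry[tag] = {
                    "threshold": vstar,
                    "n_cells": int(hmask.sum()),
                    "pa_coverage": gr.coverage(hmask, pa) if hmask.any() else float("nan"),
                }
            out[key] = entry
    return out


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write the artifact set: rasters (.asc), tables (CSV), trees (Newick),
    reports (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = result.grid
    rio.write_occurrences(outdir / "occurrences.csv", result.occurrences)
    rio.write_occurrences(outdir / "occurrences_cleaned.csv", result.cleaned)
    rio.write_newick(outdir / "phylogeny.nwk", result.tree)
    rio.write_newick(outdir / "dendrogram.nwk", result.dendrogram)
    result.traits.data.to_csv(outdir / "traits_imputed.csv")
    rio.write_ascii_grid(outdir / "protected_areas.asc", result.pa.mask.astype(int), grid)
    rio.write_ascii_grid(outdir / "condition.asc", result.condition, grid)
    for (metric, tag), dmap in result.diversity_maps.items():
        rio.write_ascii_grid(outdir / f"diversity_{metric}_{tag}.asc", dmap.values, grid)
    for (dim, tag), pm in result.priorities.items():
        rio.write_ascii_grid(outdir / f"priority_{dim}_{tag}.asc", pm.rank, grid)
        np.savetxt(outdir / f"removal_order_{dim}_{tag}.csv", pm.removal_order, fmt="%d")
    for (dim, tag), m in result.top_masks.items():
        rio.write_ascii_grid(outdir / f"top{result.config.top_fraction:g}_{dim}_{tag}.asc", m.astype(int), grid)
    rio.write_ascii_grid(outdir / "refugia.asc", result.refugia.mask.astype(int), grid)
    result.refugia.regions.to_csv(outdir / "refugia_regions.csv", index=False)
    (outdir / "report.json").write_text(json.dumps(result.report, indent=2, default=_json_default))
    (outdir / "provenance.json").write_text(
        json.dumps(result.provenance, indent=2, default=_json_default)
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
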