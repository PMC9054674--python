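"""End-to-end pipeline: site effects -> meta-analysis -> similarity reports.

Ties the stages into the two analyses the package exists for: the multi-site
meta-analysis of trait-morphometry partial correlations (with moderator
tests and FDR) and the cross-map pattern-similarity stage against provided
disorder effect-size maps. All outputs are diff-friendly delimited text with
a commented configuration header, and every run is fully determined by the
configuration and its seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .meta_analysis import MetaResult, ModeratorResult, apply_fdr, bh_fdr, meta_region, moderator_test
from .parcellation import ParcelAtlas, load_atlas, load_map
from .pattern_similarity import build_spin_null, label_shuffle_test, spin_test, steiger_test
from .site_effects import (
    SiteEffect,
    SubjectTable,
    effect_to_meta_input,
    effects_to_frame,
    get_model,
    read_subject_table,
    site_effects,
)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError", "ConfigError"]

log = logging.getLogger("parcelmeta")


class PipelineError(RuntimeError):
    """A stage failed at run time."""


class ConfigError(ValueError):
    """The configuration failed validation."""


@dataclass
class PipelineConfig:
    atlas_path: str
    site_table_dir: str
    output_dir: str
    covariate_model: str = "model1"
    modality: str = "thickness"
    meta_scale: str = "fisher_z"
    meta_method: str = "REML"
    fdr_alpha: float = 0.05
    n_perm: int = 10_000
    seed: int = 0
    similarity_tail: str = "two_sided"
    disorder_maps: list[str] = field(default_factory=list)
    moderators: list[str] = field(default_factory=list)
    site_metadata_path: str | None = None
    include_ventricles: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ConfigError("fdr_alpha must lie in (0, 1)")
        if not Path(self.atlas_path).exists():
            raise ConfigError(f"atlas file not found: {self.atlas_path}")
        if not Path(self.site_table_dir).is_dir():
            raise ConfigError(f"site table directory not found: {self.site_table_dir}")
        for m in self.disorder_maps:
            if not Path(m).exists():
                raise ConfigError(f"disorder map not found: {m}")
        if self.site_metadata_path and not Path(self.site_metadata_path).exists():
            raise ConfigError(f"site metadata not found: {self.site_metadata_path}")
        if self.moderators and not self.site_metadata_path:
            raise ConfigError("moderator analysis needs site_metadata_path")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _write_report(path: Path, df: pd.DataFrame, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, na_rep="NA")


def _header(config: PipelineConfig) -> list[str]:
    lines = [f"parcelmeta {__version__}", f"config_hash {config.digest()}"]
    for key, value in sorted(asdict(config).items()):
        lines.append(f"config {key} = {value}")
    return lines


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured analyses; returns a summary dict.

    Writes ``region_table.csv`` (pooled effects with FDR), an optional
    ``moderator_table.csv`` and ``similarity_table.csv``, a per-site
    ``site_effects.csv`` dump, and ``run_log.txt`` capturing the config
    echo, seeds and per-site exclusions. Partial outputs are removed on
    stage failure.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    t0 = time.time()
    try:
        return _run_stages(config, out, written, t0)
    except Exception:
        for p in written:
            if p.exists():
                p.unlink()
        raise


def _run_stages(config: PipelineConfig, out: Path, written: list[Path], t0: float) -> dict:
    header = _header(config)
    atlas = load_atlas(config.atlas_path)
    model = get_model(config.covariate_model)
    site_files = sorted(Path(config.site_table_dir).glob("*.csv"))
    if not site_files:
        raise PipelineError("site-effects stage: no site tables found")
    tables = [read_subject_table(f) for f in site_files]
    log.info("loaded %d site tables", len(tables))

    # --- stage: per-site effects ---------------------------------------
    all_effects: list[SiteEffect] = []
    exclusions: list[str] = []
    for table in tables:
        try:
            eff = site_effects(table, model, atlas, config.modality)
        except Exception as err:
            raise PipelineError(f"site-effects stage failed at {table.site_id}: {err}") from err
        for e in eff:
            if not e.valid:
                exclusions.append(f"{e.site_id}/{e.region}: {e.reason}")
        all_effects.extend(eff)
    eff_path = out / "site_effects.csv"
    _write_report(eff_path, effects_to_frame(all_effects), header)
    written.append(eff_path)
    log.info("site effects done (%.1fs), %d exclusions", time.time() - t0, len(exclusions))

    # --- stage: meta-analysis ------------------------------------------
    cls = "subcortical" if config.modality == "subcortical_volume" else "cortical"
    regions = atlas.region_names(cls)
    by_region: dict[str, list[SiteEffect]] = {r: [] for r in regions}
    for e in all_effects:
        if e.valid:
            by_region[e.region].append(e)
    results: list[MetaResult] = []
    for region in regions:
        eff = by_region[region]
        if not eff:
            raise PipelineError(f"meta stage: no valid site effects for region {region}")
        results.append(meta_region(eff, config.meta_scale, config.meta_method))
    results = apply_fdr(results)
    region_df = pd.DataFrame(
        [
            {
                "region": r.region, "pooled_r": r.pooled_r, "ci_low": r.ci_low,
                "ci_high": r.ci_high, "tau2": r.tau2, "Q": r.Q, "I2": r.I2,
                "k": r.k_sites, "p_unc": r.p_unc, "p_fdr": r.p_fdr,
                "single_site": r.single_site,
            }
            for r in results
        ]
    )
    region_path = out / "region_table.csv"
    _write_report(region_path, region_df, header)
    written.append(region_path)
    log.info("meta-analysis done (%.1fs)", time.time() - t0)

    # --- stage: moderators ---------------------------------------------
    moderator_rows: list[ModeratorResult] = []
    if config.moderators:
        meta_df = pd.read_csv(config.site_metadata_path).set_index("site")
        for moderator in config.moderators:
            if moderator not in meta_df.columns:
                raise PipelineError(f"moderator stage: column {moderator!r} missing")
            # the moderator omnibus is run per region, then FDR'd across regions
            p_by_region = []
            for region in regions:
                eff = [e for e in by_region[region] if e.site_id in meta_df.index]
                yv = [effect_to_meta_input(e, config.meta_scale) for e in eff]
                levels = [meta_df.loc[e.site_id, moderator] for e in eff]
                res = moderator_test(yv, levels, config.meta_method, moderator)
                p_by_region.append(res)
            adj = bh_fdr([r.p_unc for r in p_by_region])
            for region, res, a in zip(regions, p_by_region, adj):
                moderator_rows.append(
                    ModeratorResult(f"{moderator}:{region}", res.QM, res.df, res.p_unc, float(a))
                )
        mod_df = pd.DataFrame(
            [
                {"moderator": m.moderator, "QM": m.QM, "df": m.df,
                 "p_unc": m.p_unc, "p_fdr": m.p_fdr}
                for m in moderator_rows
            ]
        )
        mod_path = out / "moderator_table.csv"
        _write_report(mod_path, mod_df, header)
        written.append(mod_path)
        log.info("moderator tests done (%.1fs)", time.time() - t0)

    # --- stage: pattern similarity -------------------------------------
    similarity_rows: list[dict] = []
    if config.disorder_maps:
        trait_map_values = np.array([r.pooled_r for r in results])
        from .parcellation import EffectSizeMap

        trait_map = EffectSizeMap(atlas, trait_map_values, measure="partial_r",
                                  modality=config.modality)  # type: ignore[arg-type]
        if cls == "cortical":
            null = build_spin_null(atlas, config.n_perm, config.seed)
        sims = []
        b_used: list[np.ndarray] = []
        for i, map_path in enumerate(config.disorder_maps):
            dmap = load_map(map_path, atlas, measure="cohens_d", modality=config.modality)
            if not config.include_ventricles and cls == "subcortical":
                keep = [j for j, n in enumerate(trait_map.region_names)
                        if "ventricle" not in n.lower()]
                sub_names = [trait_map.region_names[j] for j in keep]
                sub_atlas = _subset_atlas(atlas, sub_names)
                a = EffectSizeMap(sub_atlas, trait_map.values[keep],
                                  measure="partial_r", modality=config.modality)  # type: ignore[arg-type]
                b = EffectSizeMap(sub_atlas, dmap.values[keep],
                                  measure="cohens_d", modality=config.modality)  # type: ignore[arg-type]
            else:
                a, b = trait_map, dmap
            if cls == "cortical":
                res = spin_test(a, b, null, tail=config.similarity_tail)  # type: ignore[arg-type]
            else:
                res = label_shuffle_test(a, b, config.n_perm, config.seed,
                                         tail=config.similarity_tail)  # type: ignore[arg-type]
            sims.append(res)
            b_used.append(b.values)
            similarity_rows.append(
                {"comparison": Path(map_path).stem, "kind": res.method,
                 "coefficient": res.coefficient, "p_perm": res.p_perm,
                 "tail": res.tail, "n_perm": res.n_perm}
            )
        # Steiger comparisons of the first map's similarity vs each other map;
        # r_kh is computed on the same region set and coefficient family
        # (ranks for the Spearman-based subcortical analysis) as the
        # similarities it accompanies
        if len(sims) >= 2:
            n_regions_used = len(b_used[0])
            for i in range(1, len(sims)):
                bk, bh = b_used[0], b_used[i]
                if cls == "subcortical":
                    from scipy.stats import rankdata

                    bk, bh = rankdata(bk), rankdata(bh)
                r_kh = float(np.corrcoef(bk, bh)[0, 1])
                st = steiger_test(sims[0].coefficient, sims[i].coefficient, r_kh,
                                  n_regions_used, tail="greater")
                similarity_rows.append(
                    {"comparison": f"steiger:{Path(config.disorder_maps[0]).stem}"
                                   f"_vs_{Path(config.disorder_maps[i]).stem}",
                     "kind": "steiger", "coefficient": st.Z, "p_perm": st.p,
                     "tail": "greater", "n_perm": 0}
                )
        sim_df = pd.DataFrame(similarity_rows)
        sim_path = out / "similarity_table.csv"
        _write_report(sim_path, sim_df, header)
        written.append(sim_path)
        log.info("similarity done (%.1fs)", time.time() - t0)

    # --- run log ---------------------------------------------------------
    log_path = out / "run_log.txt"
    with open(log_path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        fh.write(f"n_sites {len(tables)}\n")
        fh.write(f"n_regions {len(regions)}\n")
        fh.write(f"seed {config.seed}\n")
        for line in exclusions:
            fh.write(f"excluded {line}\n")
    written.append(log_path)
    return {
        "n_sites": len(tables),
        "n_regions": len(regions),
        "n_excluded": len(exclusions),
        "results": results,
        "moderators": moderator_rows,
        "similarity": similarity_rows,
        "output_dir": str(out),
    }


def _subset_atlas(atlas: ParcelAtlas, names: list[str]) -> ParcelAtlas:
    keep = [atlas.index_of(n) for n in names]
    arr = np.array
    return ParcelAtlas(
        tuple(arr(atlas.names)[keep]),
        tuple(arr(atlas.hemisphere)[keep]),
        tuple(arr(atlas.structure_class)[keep]),
        atlas.centroids[keep],
    )
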