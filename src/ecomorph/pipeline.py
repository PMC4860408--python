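"""Full-analysis orchestration from a single configuration.

Stage order follows the scientific workflow: superimposition and relative
warps → taxonomy/sex group tests → allometry → PLS against climate → PLS
against competition → angular comparison of the two shape covariation
vectors → variation partitioning (global and per genus) → species-level
comparative tests.  Each stage writes plain CSV tables into the output
directory and can be skipped by flag; a run log records the seed and
stage timings.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    aggregate_means,
    competition_block,
    gpa,
    independent_contrasts,
    load_traits,
    manova,
    multivariate_regression,
    nested_varpart,
    pairwise_angle_table,
    pairwise_shape_tests,
    per_species_allometry,
    phylo_signal_test,
    pls,
    pls_size,
    pooled_within_group_regression,
    read_tps,
    read_tree,
    relative_warps,
    select_rws,
    size_tests,
    slope_heterogeneity_test,
    variable_correlations,
    variation_partitioning,
    vector_angle,
    weight_matrix,
)
from .pls import BIOCLIM_NAMES


class PipelineError(RuntimeError):
    """A stage failed; the message names it.  Partial outputs are kept."""


@dataclass
class PipelineConfig:
    tps: str = ""
    metadata: str = ""
    climate: str = ""
    traits: str = ""
    presence: str = ""
    tree: str = ""
    output_dir: str = "ecomorph_output"
    n_permutations: int = 9999
    seed: int = 0
    rw_variance_threshold: float = 95.0
    killing_window: tuple = (2.0, 5.4)
    angle_unit: str = "deg10"
    grouping_keys: tuple = ("locality_id", "species")
    skip_stages: tuple = ()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("tps", "climate", "traits", "presence"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.rw_variance_threshold <= 100:
            raise ValueError("rw_variance_threshold must be in (0, 100]")


def _genus(species: str) -> str:
    return species.split()[0]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every (non-skipped) stage; returns a report dict of results."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    timings: dict = {}
    skip = set(config.skip_stages)
    nperm = config.n_permutations
    rng = np.random.default_rng(config.seed)

    def stage(name):
        def wrap(fn):
            if name in skip:
                return None
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            timings[name] = round(time.perf_counter() - t0, 3)
            report[name] = result
            return result
        return wrap

    # --- load & superimpose -------------------------------------------------
    table = read_tps(config.tps, metadata=config.metadata or None)
    climate_tbl = pd.read_csv(config.climate, index_col="locality_id")
    traits = load_traits(config.traits)
    presence_df = pd.read_csv(config.presence, dtype=str)
    sample = gpa(table)
    wm = weight_matrix(sample)
    rw = relative_warps(wm)
    m_star = select_rws(rw, config.rw_variance_threshold)
    wm.frame().assign(specimen_id=sample.metadata["specimen_id"]).to_csv(
        out / "weight_matrix.csv", index=False
    )
    rw.frame().assign(specimen_id=sample.metadata["specimen_id"]).to_csv(
        out / "relative_warps.csv", index=False
    )
    report["gpa"] = {
        "n": sample.n,
        "k": sample.k,
        "converged": bool(sample.converged),
        "n_selected_rws": int(m_star),
    }

    avg = aggregate_means(sample, config.grouping_keys)
    avg_wm = weight_matrix(avg) if len(avg) >= 3 else None
    species = sample.metadata["species"].to_numpy()
    avg_species = avg.metadata["species"].to_numpy()

    @stage("group_tests")
    def _group_tests():
        sexed = sample.metadata["sex"].to_numpy() != "unknown"
        res = {}
        if sexed.sum() >= 10:
            use = min(m_star, max(1, int(sexed.sum()) - 3 * len(set(species)) - 2))
            try:
                terms = manova(
                    rw.scores[sexed][:, :use],
                    species[sexed],
                    sample.metadata["sex"].to_numpy()[sexed],
                    interaction=True,
                )
                res["manova"] = [vars(t) for t in terms]
            except ValueError as exc:
                res["manova_error"] = str(exc)
        pw = pairwise_shape_tests(rw.scores[:, :2], species)
        pw.to_csv(out / "pairwise_shape.csv")
        st = size_tests(
            sample.lnCS, species, sample.metadata["sex"].to_numpy()
        )
        st["anova"].to_csv(out / "size_anova.csv")
        st["pairwise_t"].to_csv(out / "pairwise_size_t.csv")
        res["size_n"] = st["n"]
        return res

    @stage("allometry")
    def _allometry():
        seed1 = int(rng.integers(2**31 - 1))
        table4 = per_species_allometry(
            wm.scores, sample.lnCS, species, n_perm=nperm, seed=seed1
        )
        table4.to_csv(out / "allometry_by_species.csv", index=False)
        pooled = pooled_within_group_regression(
            wm.scores, sample.lnCS, species, n_perm=nperm,
            seed=int(rng.integers(2**31 - 1)),
        )
        het = slope_heterogeneity_test(
            wm.scores, sample.lnCS, species, n_perm=nperm,
            seed=int(rng.integers(2**31 - 1)),
        )
        return {
            "global_percent": float(table4.iloc[0]["percent_variance"]),
            "global_p": float(table4.iloc[0]["p"]),
            "pooled_percent": pooled.percent_variance,
            "pooled_p": pooled.permutation_p,
            "slope_F": het.f_statistic,
            "slope_p": het.permutation_p,
        }

    # row-aligned environmental blocks for the averaged sample
    locs = avg.metadata["locality_id"].astype(str).to_numpy()
    bio = climate_tbl.loc[locs, BIOCLIM_NAMES].to_numpy(float)
    comp = competition_block(
        avg_species, locs, presence_df, traits=traits,
        window=tuple(config.killing_window), angle_unit=config.angle_unit,
    )

    @stage("pls_climate")
    def _pls_climate():
        target = avg_wm if avg_wm is not None else wm
        res = pls(
            target.scores, bio, n_perm=nperm,
            seed=int(rng.integers(2**31 - 1)), right_names=BIOCLIM_NAMES,
        )
        variable_correlations(res, bio).to_csv(out / "pls_climate_loadings.csv")
        res_size = pls_size(
            avg.lnCS, bio, n_perm=nperm,
            seed=int(rng.integers(2**31 - 1)), right_names=BIOCLIM_NAMES,
        )
        return {
            "shape": res,
            "size": res_size,
            "shape_r1": float(res.score_correlations[0]),
            "shape_p1": float(res.permutation_p[0]),
            "pct_cov1": float(res.percent_covariation[0]),
            "size_r": float(res_size.score_correlations[0]),
        }

    @stage("pls_competition")
    def _pls_competition():
        target = avg_wm if avg_wm is not None else wm
        res = pls(
            target.scores, comp.to_numpy(float), n_perm=nperm,
            seed=int(rng.integers(2**31 - 1)), right_names=list(comp.columns),
        )
        variable_correlations(res, comp.to_numpy(float)).to_csv(
            out / "pls_competition_loadings.csv"
        )
        res_size = pls_size(
            avg.lnCS, comp.to_numpy(float), n_perm=nperm,
            seed=int(rng.integers(2**31 - 1)), right_names=list(comp.columns),
        )
        return {
            "shape": res,
            "size": res_size,
            "shape_r1": float(res.score_correlations[0]),
            "shape_p1": float(res.permutation_p[0]),
        }

    @stage("angles")
    def _angles():
        if "pls_climate" not in report or "pls_competition" not in report:
            raise ValueError("angles stage needs both PLS stages")
        u = report["pls_climate"]["shape"].left_vectors[:, 0]
        v = report["pls_competition"]["shape"].left_vectors[:, 0]
        res = vector_angle(u, v)
        genera = sorted({_genus(s) for s in avg_species})
        genus_vectors_clim, genus_vectors_comp = {}, {}
        target = avg_wm if avg_wm is not None else wm
        for gen in genera:
            mask = np.array([_genus(s) == gen for s in avg_species])
            if mask.sum() < 4:
                continue
            try:
                genus_vectors_clim[gen] = pls(
                    target.scores[mask], bio[mask], n_perm=1,
                    seed=int(rng.integers(2**31 - 1)),
                ).left_vectors[:, 0]
                genus_vectors_comp[gen] = pls(
                    target.scores[mask], comp.to_numpy(float)[mask], n_perm=1,
                    seed=int(rng.integers(2**31 - 1)),
                ).left_vectors[:, 0]
            except ValueError:
                continue
        tables = {}
        if len(genus_vectors_clim) >= 2:
            t = pairwise_angle_table(genus_vectors_clim)
            t.to_csv(out / "angles_climate_genera.csv")
            tables["climate"] = t
        if len(genus_vectors_comp) >= 2:
            t = pairwise_angle_table(genus_vectors_comp)
            t.to_csv(out / "angles_competition_genera.csv")
            tables["competition"] = t
        return {
            "climate_vs_competition_angle": res.angle_degrees,
            "p": res.p,
            "genus_tables": tables,
        }

    @stage("varpart")
    def _varpart():
        target = avg_wm if avg_wm is not None else wm
        blocks = {
            "taxonomy": avg_species,
            "size": avg.lnCS,
            "climate": bio,
            "competition": comp.to_numpy(float),
        }
        shape_vp = variation_partitioning(target.scores, blocks)
        shape_vp.frame().to_csv(out / "varpart_shape.csv", index=False)
        size_blocks = {k: v for k, v in blocks.items() if k != "size"}
        size_vp = variation_partitioning(avg.lnCS[:, None], size_blocks)
        size_vp.frame().to_csv(out / "varpart_size.csv", index=False)
        nested = {}
        genus_of = {s: _genus(s) for s in set(avg_species)}
        for gen in sorted(set(genus_of.values())):
            try:
                nested[gen] = nested_varpart(
                    target.scores, avg_species, genus_of, gen, blocks
                )
                nested[gen].frame().to_csv(
                    out / f"varpart_shape_{gen}.csv", index=False
                )
            except ValueError:
                continue
        return {"shape": shape_vp, "size": size_vp, "nested": nested}

    @stage("comparative")
    def _comparative():
        if not config.tree:
            raise ValueError("comparative stage requested but no tree configured")
        tree = read_tree(config.tree)
        sp_means = aggregate_means(sample, ["species"])
        sp_wm = weight_matrix(sp_means)
        labels = sp_means.metadata["species"].tolist()
        tips_shape = {s: sp_wm.scores[i] for i, s in enumerate(labels)}
        tips_size = {s: np.array([sp_means.lnCS[i]]) for i, s in enumerate(labels)}
        sig_shape = phylo_signal_test(
            tree, tips_shape, n_perm=nperm, seed=int(rng.integers(2**31 - 1))
        )
        sig_size = phylo_signal_test(
            tree, tips_size, n_perm=nperm, seed=int(rng.integers(2**31 - 1))
        )
        pic_shape = independent_contrasts(tree, tips_shape)
        pic_size = independent_contrasts(tree, tips_size)
        # allometry on contrasts: regression through the origin
        x = pic_size[:, 0]
        beta = (x @ pic_shape) / (x @ x)
        ss_model = (beta**2).sum() * (x @ x)
        ss_tot = (pic_shape**2).sum()
        pd.DataFrame(
            {
                "statistic": ["tree_length_shape", "p_shape", "tree_length_size", "p_size"],
                "value": [
                    sig_shape.tree_length,
                    sig_shape.permutation_p,
                    sig_size.tree_length,
                    sig_size.permutation_p,
                ],
            }
        ).to_csv(out / "phylo_signal.csv", index=False)
        return {
            "signal_shape": vars(sig_shape),
            "signal_size": vars(sig_size),
            "contrast_allometry_percent": float(100 * ss_model / ss_tot),
        }

    from . import __version__

    log = {
        "seed": config.seed,
        "n_permutations": nperm,
        "versions": {"ecomorph": __version__, "numpy": np.__version__},
        "stages_run": sorted(timings),
        "timings_s": timings,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    report["log"] = log
    return report
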