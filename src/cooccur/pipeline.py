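"""End-to-end analysis: counts -> null models -> gradients -> spatial
vectors -> occupancy GLMMs -> RDA / variance partitioning -> residual
correlations, under one config and one global seed.

The global seed is expanded into per-stage streams with
``numpy.random.SeedSequence(seed).spawn``, so reordering or disabling a
stage never silently changes another stage's randomness.  Any stage may
fail numerically; the failure is recorded and the report still carries
every completed stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, glmm, gradients, nullmodels, ordination, spatial
from .community import CommunityMatrix, SiteTable
from .glmm import GlmmSpec

log = logging.getLogger("cooccur")

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis", "render_report"]

#: covariates treated as abiotic vs biotic when grouping gradient axes
ABIOTIC_VARS = ("elevation", "distance_to_coast", "moisture", "conductivity",
                "pH", "organic_C", "total_N")
BIOTIC_VARS = ("microbial_biomass", "bacterial_richness", "fungal_richness",
               "arthropods", "rotifers", "tardigrades")


@dataclass
class AnalysisConfig:
    """Settings for one full analysis run."""

    species_order: tuple[str, ...] = community.DEFAULT_SPECIES_ORDER
    presence_threshold: float = 0.0
    null_iters: int = 5000
    null_burn_in: int = nullmodels.DEFAULT_BURN_IN
    null_thin: int | None = None
    alpha: float = 0.05
    pca_target_fraction: float = 2 / 3
    glmm_max_iter: int = 50
    glmm_tolerance: float = 1e-6
    rda_permutations: int = 999
    seed: int = 0
    stages: tuple[str, ...] = ("counts", "nullmodel", "gradients", "spatial",
                               "glmm", "rda")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "species_order" in raw:
            raw["species_order"] = tuple(raw["species_order"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


@dataclass
class AnalysisReport:
    """Structured results of every stage, JSON-serializable."""

    config: dict
    stages_run: list[str] = field(default_factory=list)
    stage_failures: dict[str, str] = field(default_factory=dict)
    counts: dict | None = None
    null: dict | None = None
    pairs: list[dict] | None = None
    glmm_fits: dict[str, dict] | None = None
    correlograms: dict[str, dict] | None = None
    rda: dict | None = None
    variance_partition: dict | None = None
    residual_correlations: list[dict] | None = None
    provenance: dict = field(default_factory=dict)
    # non-serialized working objects for rendering
    _artifacts: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "stages_run": self.stages_run,
            "stage_failures": self.stage_failures,
            "counts": self.counts,
            "null": self.null,
            "pairs": self.pairs,
            "glmm": self.glmm_fits,
            "correlograms": self.correlograms,
            "rda": self.rda,
            "variance_partition": self.variance_partition,
            "residual_correlations": self.residual_correlations,
            "provenance": self.provenance,
        }

    def to_json(self, path=None, with_timestamps: bool = True) -> str:
        d = self.to_dict()
        if not with_timestamps:
            d["provenance"] = {k: v for k, v in d["provenance"].items()
                               if k != "timestamp"}
        s = json.dumps(d, indent=2, default=_json_default)
        if path is not None:
            Path(path).write_text(s)
        return s


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        v = float(o)
        return None if np.isnan(v) else v
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _stage_seed(ss_children, idx: int) -> int:
    return int(ss_children[idx].generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def _group_axes(gset: gradients.GradientSet) -> tuple[list[str], list[str]]:
    """Label each selected PCA axis abiotic or biotic by its top loadings.

    An axis is 'biotic' when biotic variables dominate its squared
    loadings, else 'abiotic'.  Labels are used only to group predictors
    for variance partitioning.
    """
    abiotic_axes, biotic_axes = [], []
    load = gset.loadings
    groups = gset.variable_groups
    for k, ax in enumerate(load.columns):
        if not gset.selected[k]:
            continue
        sq = load[ax] ** 2
        bio = sum(sq[v] for v in load.index if groups.get(v) == "biotic")
        abio = sum(sq[v] for v in load.index if groups.get(v) == "abiotic")
        (biotic_axes if bio > abio else abiotic_axes).append(ax)
    return abiotic_axes, biotic_axes


def run_full_analysis(
    sites: SiteTable,
    cm: CommunityMatrix,
    cfg: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run every configured stage on a site table + abundance matrix."""
    cfg = cfg or AnalysisConfig()
    ss = np.random.SeedSequence(cfg.seed).spawn(8)
    report = AnalysisReport(config={k: (list(v) if isinstance(v, tuple) else v)
                                    for k, v in vars(cfg).items()})
    report.provenance = {
        "seed": cfg.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_sites_input": len(sites),
    }

    # align and order species
    order = [s for s in cfg.species_order if s in cm.species] + \
            [s for s in cm.species if s not in cfg.species_order]
    cm = CommunityMatrix(cm.abundance[order])
    pm_all = community.to_presence(cm, cfg.presence_threshold)
    pm = community.filter_occupied_sites(pm_all)
    occupied = pm.sites
    site_df = sites.data.set_index(sites.data["site_id"].astype(str)).loc[occupied]
    coords = site_df[["x", "y"]].to_numpy(dtype=float)
    cm_occ = CommunityMatrix(cm.abundance.loc[occupied])

    def _run(stage, fn):
        if stage not in cfg.stages:
            return
        t0 = time.perf_counter()
        try:
            fn()
            report.stages_run.append(stage)
            log.info("stage %-10s ok (%.2f s)", stage, time.perf_counter() - t0)
        except Exception as exc:  # stage isolation: record and continue
            report.stage_failures[stage] = f"{type(exc).__name__}: {exc}"
            log.warning("stage %-10s FAILED: %s", stage, exc)

    # -- counts ---------------------------------------------------------
    def counts_stage():
        report.counts = community.cooccurrence_counts(pm).to_dict()
    _run("counts", counts_stage)

    # -- null model -----------------------------------------------------
    def null_stage():
        nd = nullmodels.null_distribution(
            pm, n_iter=cfg.null_iters, burn_in=cfg.null_burn_in,
            thin=cfg.null_thin, rng_seed=_stage_seed(ss, 1))
        pairs = nullmodels.pairwise_tests(
            pm, n_iter=cfg.null_iters, alpha=cfg.alpha,
            rng_seed=_stage_seed(ss, 2), burn_in=cfg.null_burn_in,
            thin=cfg.null_thin)
        report.null = nd.to_dict()
        report.pairs = [p.to_dict() for p in pairs]
    _run("nullmodel", null_stage)

    # -- gradients ------------------------------------------------------
    gsel = None

    def gradients_stage():
        nonlocal gsel
        table = SiteTable(site_df.reset_index(drop=True))
        num = table.numeric_columns()
        groups = {c: ("biotic" if c in BIOTIC_VARS else "abiotic") for c in num.columns}
        z = gradients.standardize(num)
        g = gradients.pca_gradients(z, variable_groups=groups)
        gsel = gradients.select_axes(g, cfg.pca_target_fraction)
        report._artifacts["gradients"] = gsel
    _run("gradients", gradients_stage)

    # -- spatial eigenvectors -------------------------------------------
    sev_sel = None

    def spatial_stage():
        nonlocal sev_sel
        sev = spatial.build_pcnm(coords)
        hel = ordination.hellinger(cm_occ)
        sev_sel = spatial.forward_select_aic(hel, sev)
        report._artifacts["pcnm"] = sev_sel
        report.correlograms = {}
    _run("spatial", spatial_stage)

    # -- occupancy GLMMs ------------------------------------------------
    def glmm_stage():
        if gsel is None:
            raise RuntimeError("gradients stage required before GLMMs")
        fits = {}
        correlos = {}
        scores = gsel.selected_scores()
        aspect = pd.get_dummies(site_df["aspect"], prefix="aspect", dtype=float) \
            if "aspect" in site_df.columns else pd.DataFrame(index=site_df.index)
        if not aspect.empty:
            ref = site_df["aspect"].value_counts().idxmax()
            aspect = aspect.drop(columns=f"aspect_{ref}")
        for target in pm.species:
            others = [s for s in pm.species if s != target]
            x = pd.DataFrame(index=pd.Index(occupied))
            x["(Intercept)"] = 1.0
            for ax in scores.columns:
                x[ax] = scores[ax].to_numpy()
            for c in aspect.columns:
                x[c] = aspect[c].to_numpy()
            for o in others:
                x[f"{o} (yes)"] = pm.occupancy[o].to_numpy(dtype=float)
            y = pm.occupancy[target].to_numpy()
            spec = GlmmSpec(response=target, predictors=list(x.columns)[1:],
                            max_iter=cfg.glmm_max_iter, tolerance=cfg.glmm_tolerance)
            fit = glmm.fit_binomial_pql(x, y, coords, spec=spec)
            fits[target] = fit.to_dict()
            report._artifacts.setdefault("glmm", {})[target] = fit
            cg = glmm.residual_correlogram(fit, coords, n_perm=99,
                                           rng_seed=_stage_seed(ss, 3))
            correlos[target] = cg.to_dict()
        report.glmm_fits = fits
        report.correlograms = correlos
    _run("glmm", glmm_stage)

    # -- RDA + variance partitioning ------------------------------------
    def rda_stage():
        if gsel is None or sev_sel is None:
            raise RuntimeError("gradients and spatial stages required before RDA")
        hel = ordination.hellinger(cm_occ)
        abio_axes, bio_axes = _group_axes(gsel)
        scores = gsel.scores
        x_abio = scores[abio_axes].to_numpy() if abio_axes else None
        x_bio = scores[bio_axes].to_numpy() if bio_axes else None
        x_spa = sev_sel.selected_vectors() if sev_sel.selected.size else None
        blocks = [b for b in (x_abio, x_bio, x_spa) if b is not None]
        x_all = np.hstack(blocks)
        res = ordination.rda(hel, x_all, n_perm=cfg.rda_permutations,
                             rng_seed=_stage_seed(ss, 4), species=pm.species)
        vp = ordination.variance_partition(hel, x_abio, x_bio, x_spa)
        rc = ordination.residual_correlations(res)
        report.rda = {
            "r2": res.r2, "adj_r2": res.adj_r2,
            "canonical_eigenvalues": res.canonical_eigenvalues.tolist(),
            "permutation_p": None if np.isnan(res.permutation_p) else res.permutation_p,
        }
        report.variance_partition = vp.to_dict()
        report.residual_correlations = rc.to_dict(orient="records")
        report._artifacts["rda"] = res
    _run("rda", rda_stage)

    report._artifacts["coords"] = coords
    report._artifacts["presence"] = pm
    return report


def render_report(report: AnalysisReport, outdir) -> list[Path]:
    """Write report.json plus residual-map, residual-scatter and
    correlogram figures; returns the list of files written."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    jpath = outdir / "report.json"
    report.to_json(jpath)
    written.append(jpath)

    coords = report._artifacts.get("coords")
    fits = report._artifacts.get("glmm", {})
    for sp, fit in fits.items():
        fig, ax = plt.subplots(figsize=(6, 4))
        res = fit.standardized_residuals
        ax.scatter(coords[:, 0], coords[:, 1], c=np.where(res < 0, "k", "0.6"),
                   s=12 + 18 * np.abs(res) / (np.abs(res).max() or 1))
        ax.set_title(f"standardized residuals: {sp}")
        ax.set_xlabel("x (m)"); ax.set_ylabel("y (m)")
        p = outdir / f"residual_map_{sp}.png"
        fig.savefig(p, dpi=120); plt.close(fig)
        written.append(p)

    rda_res = report._artifacts.get("rda")
    if rda_res is not None:
        frame = rda_res.residual_frame()
        cols = list(frame.columns)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                fig, ax = plt.subplots(figsize=(4, 4))
                ax.scatter(frame[cols[i]], frame[cols[j]], s=8, alpha=0.6)
                ax.set_xlabel(f"{cols[i]} residual")
                ax.set_ylabel(f"{cols[j]} residual")
                p = outdir / f"residual_scatter_{cols[i]}_{cols[j]}.png"
                fig.savefig(p, dpi=120); plt.close(fig)
                written.append(p)

    if report.correlograms:
        fig, ax = plt.subplots(figsize=(6, 4))
        for sp, cg in report.correlograms.items():
            edges = np.asarray(cg["class_edges"], dtype=float)
            mids = 0.5 * (edges[:-1] + edges[1:])
            vals = [np.nan if v is None else v for v in cg["morans_i"]]
            ax.plot(mids, vals, marker="o", label=sp)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("distance class midpoint (m)")
        ax.set_ylabel("Moran's I")
        ax.legend()
        p = outdir / "correlogram.png"
        fig.savefig(p, dpi=120); plt.close(fig)
        written.append(p)
    return written
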