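"""End-to-end pipeline driver: filtering -> diversity -> MF -> network ->
keystones -> associations, run per site (one network per site), with all
results written to an output directory and the RMT scan and seeds logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, diversity, io, multifunctionality, network
from .config import PipelineConfig
from .datatypes import OtuTable, ValidationError, align_tables
from .network import RmtSelectionError

__all__ = ["run_pipeline", "PipelineResult", "SiteResult", "PipelineStageError"]

logger = logging.getLogger("edaphonet.pipeline")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, site: str | None, cause: Exception):
        self.stage = stage
        self.site = site
        where = f"stage '{stage}'" + (f" (site {site})" if site else "")
        super().__init__(f"{where} failed: {cause}")


def _derive_seed(seed: int, *context: int) -> int:
    return int(np.random.SeedSequence([seed, *context]).generate_state(1)[0] % (2**31))


@dataclass
class SiteResult:
    site: str
    filtered_table: OtuTable
    alpha: pd.DataFrame
    anosim: diversity.AnosimResult
    cpcoa: diversity.OrdinationResult
    mf: multifunctionality.MfResult
    correlation: network.CorrelationResult
    rmt_scan: network.RmtScan | None
    threshold_used: float
    graph: "object"
    topology: network.TopologySummary
    sample_topology: pd.DataFrame
    keystones: pd.DataFrame
    regressions: pd.DataFrame
    kruskal: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    sites: dict[str, SiteResult]
    anova: dict = field(default_factory=dict)


def _stage(stage: str, site: str | None = None):
    """Decorator-free stage wrapper: re-raise with stage context."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(stage, site, exc) from exc
            return False

    return _Ctx()


def _run_site(
    site: str,
    otu: OtuTable,
    metadata: pd.DataFrame,
    soil: pd.DataFrame,
    cfg: PipelineConfig,
    site_index: int,
) -> SiteResult:
    md = metadata.loc[[s for s in otu.sample_ids]]
    erosion = md["erosion"].astype(str).to_numpy()

    with _stage("filter", site):
        filtered = network.filter_otus(
            otu, cfg.min_rel_abundance, pooled=False
        )
    logger.info("site %s: %d/%d OTUs retained by the %.4g filter",
                site, filtered.n_otus, otu.n_otus, cfg.min_rel_abundance)

    with _stage("alpha_diversity", site):
        # alpha diversity on the unfiltered table; the abundance filter only
        # applies to network construction
        alpha = diversity.alpha_diversity_table(otu)

    with _stage("beta_diversity", site):
        dm = diversity.bray_curtis_matrix(otu)
        anosim_res = diversity.anosim(
            dm, erosion, n_permutations=cfg.anosim_permutations,
            seed=_derive_seed(cfg.seed, site_index, 1), pairwise=True,
        )
        cpcoa_res = diversity.cpcoa(
            dm, erosion, n_permutations=cfg.cpcoa_permutations,
            seed=_derive_seed(cfg.seed, site_index, 2),
        )

    with _stage("multifunctionality", site):
        mf_res = multifunctionality.multifunctionality(
            soil, excluded=list(cfg.mf_excluded_variables)
        )

    with _stage("correlation", site):
        corr = network.spearman_matrix(filtered)

    scan = None
    with _stage("rmt_threshold", site):
        grid = np.round(
            np.arange(cfg.rmt_lo, cfg.rmt_hi + 1e-9, cfg.rmt_step), 6
        )
        try:
            if cfg.threshold is not None:
                threshold = cfg.threshold
            else:
                scan = network.rmt_select_threshold(corr, grid=grid)
                threshold = scan.selected
                logger.info("site %s: RMT selected threshold %.2f", site, threshold)
        except (RmtSelectionError, ValidationError) as exc:
            if cfg.rmt_fallback_threshold is None:
                raise
            threshold = cfg.rmt_fallback_threshold
            logger.warning(
                "site %s: RMT selection failed (%s); using fallback %.2f",
                site, exc, threshold,
            )

    with _stage("network", site):
        graph = network.build_network(
            corr, threshold, fdr_alpha=cfg.fdr_alpha,
            positive_only=cfg.positive_only, site=site,
        )
        topo = network.global_topology(graph, modularity=True)
        sample_topo = network.sample_subgraph_topology(graph, filtered)

    with _stage("keystones", site):
        keystones = network.identify_keystones(graph, cfg.keystone_thresholds())

    with _stage("associations", site):
        mf_vec = mf_res.table["mf"]
        regs = []
        for name, series in [
            ("shannon", alpha["shannon"]),
            ("observed_species", alpha["observed_species"]),
            ("ace", alpha["ace"]),
            ("node_number", sample_topo["node_number"]),
            ("edge_number", sample_topo["edge_number"]),
            ("betweenness", sample_topo["betweenness"]),
            ("assortativity", sample_topo["assortativity"]),
        ]:
            x = series.reindex(mf_vec.index).to_numpy(dtype=float)
            y = mf_vec.to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.ptp(x[ok]) == 0:
                continue
            r = association.linear_regression(
                x[ok], y[ok], predictor=name, response="mf"
            )
            regs.append({
                "predictor": r.predictor, "response": r.response,
                "slope": r.slope, "intercept": r.intercept,
                "r_squared": r.r_squared, "p_value": r.p_value, "n": r.n,
            })
        regressions = pd.DataFrame(regs)

        kruskal = {}
        for name, series in [("shannon", alpha["shannon"]), ("mf", mf_vec)]:
            res = association.kruskal_wallis(
                series.reindex(md.index).to_numpy(dtype=float), erosion
            )
            kruskal[name] = {
                "H": res.statistic, "p_value": res.p_value, "letters": res.letters,
            }

    return SiteResult(
        site=site, filtered_table=filtered, alpha=alpha, anosim=anosim_res,
        cpcoa=cpcoa_res, mf=mf_res, correlation=corr, rmt_scan=scan,
        threshold_used=threshold, graph=graph, topology=topo,
        sample_topology=sample_topo, keystones=keystones,
        regressions=regressions, kruskal=kruskal,
    )


def run_pipeline(
    config: PipelineConfig,
    otu: OtuTable,
    metadata: pd.DataFrame,
    soil: pd.DataFrame,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis, per site, and write results to ``out_dir``."""
    with _stage("align"):
        align_tables(otu, metadata, soil)

    sites = list(pd.unique(metadata["site"]))
    if config.pooled_sites:
        metadata = metadata.copy()
        metadata["site_original"] = metadata["site"]
        metadata["site"] = "pooled"
        sites = ["pooled"]

    results: dict[str, SiteResult] = {}
    for i, site in enumerate(sites):
        samples = metadata.index[metadata["site"] == site].tolist()
        site_otu = otu.subset_samples(samples)
        site_soil = soil.loc[samples]
        if config.global_scaling:
            site_soil = soil  # MF scaled over the full dataset
        res = _run_site(site, site_otu, metadata, site_soil, config, i)
        if config.global_scaling:
            res.mf = multifunctionality.MfResult(
                table=res.mf.table.loc[samples], transforms=res.mf.transforms
            )
        results[site] = res

    anova = {}
    if len(sites) > 1:
        with _stage("two_way_anova"):
            alpha_all = pd.concat([r.alpha for r in results.values()])
            mf_all = pd.concat([r.mf.table["mf"] for r in results.values()])
            md = metadata.loc[alpha_all.index]
            for name, series in [
                ("shannon", alpha_all["shannon"]),
                ("mf", mf_all.reindex(alpha_all.index)),
            ]:
                res = association.two_way_anova(
                    series.to_numpy(dtype=float),
                    md["site"], md["erosion"].astype(str), md["transect"],
                )
                anova[name] = {
                    "F_erosion": res.statistic, "p_erosion": res.p_value,
                    "letters": res.letters,
                    "terms": {
                        str(ix): {"F": float(row["F"]), "p": float(row["PR(>F)"])}
                        for ix, row in res.table.iterrows()
                        if np.isfinite(row.get("F", np.nan))
                    },
                }

    if out_dir is not None:
        _write_outputs(Path(out_dir), config, results, anova)
    return PipelineResult(sites=results, anova=anova)


def _write_outputs(
    out: Path,
    config: PipelineConfig,
    results: dict[str, SiteResult],
    anova: dict,
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "pipeline_config.yaml")
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        for site, r in results.items():
            d = out / site
            d.mkdir(exist_ok=True)
            r.alpha.to_csv(d / "diversity.tsv", sep="\t", index=False)
            r.mf.table.to_csv(d / "multifunctionality.tsv", sep="\t")
            r.sample_topology.to_csv(d / "sample_topology.tsv", sep="\t",
                                     index=False)
            r.keystones.to_csv(d / "keystones.tsv", sep="\t", index=False)
            r.regressions.to_csv(d / "regressions.tsv", sep="\t", index=False)
            if r.rmt_scan is not None:
                r.rmt_scan.as_frame().to_csv(d / "rmt_scan.tsv", sep="\t",
                                             index=False)
            io.write_network(r.graph, d / "network_edges.tsv", "edgelist")
            io.write_network(r.graph, d / "network.graphml", "graphml")
            r.cpcoa.coordinates.to_csv(d / "cpcoa_coordinates.tsv", sep="\t")
            summary = {
                "site": site,
                "threshold_used": r.threshold_used,
                "rmt_selected": (r.rmt_scan.selected if r.rmt_scan else None),
                "anosim": {"R": r.anosim.R, "p_value": r.anosim.p_value,
                           "n_permutations": r.anosim.n_permutations},
                "anosim_pairwise": (r.anosim.pairwise.to_dict("records")
                                    if r.anosim.pairwise is not None else None),
                "cpcoa": {"proportion_explained": r.cpcoa.proportion_explained,
                          "p_value": r.cpcoa.p_value},
                "topology": r.topology.as_dict(),
                "n_keystones": int(r.keystones["keystone"].sum())
                if len(r.keystones) else 0,
                "kruskal": r.kruskal,
                "seed": config.seed,
            }
            with open(d / "summary.json", "w") as fh:
                json.dump(summary, fh, indent=1, sort_keys=True, default=float)
            logger.info("site %s: threshold %.2f, %d nodes, %d edges",
                        site, r.threshold_used, r.topology.node_number,
                        r.topology.edge_number)
        with open(out / "anova.json", "w") as fh:
            json.dump(anova, fh, indent=1, sort_keys=True, default=float)
    finally:
        logger.removeHandler(handler)
        handler.close()
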