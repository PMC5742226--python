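"""End-to-end orchestration: filters → dated tree → beta diversity → SES →
habitat statistics → clade representation, with per-stage seeding, CSV
one table per analytical product, and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beta_diversity import bray_curtis, drop_singletons, group_ellipses, nmds, ward_cluster
from .clade_representation import nodesig_matrix, summary_frame, tabulate_habitat
from .data_core import (
    IncidenceMatrix,
    SiteRecord,
    TaxonName,
    apply_site_filters,
    drop_taxa,
    read_incidence,
    read_metadata,
    summarize,
)
from .habitat_stats import anova_frame, check_assumptions, one_tailed_t, tukey_contrast, two_way_anova
from .megatree import bladj_date, graft_species, read_ages, read_backbone
from .phylo_structure import cophenetic, ses, ses_frame
from .synthetic_data import SyntheticConfig, simulate_communities, simulate_tree

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "derive_seed"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed so any stage can be re-run independently."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    # exactly one of these two input modes
    inputs: dict[str, str] | None = None  # matrix, metadata, backbone, ages[, families, drop]
    synthetic: SyntheticConfig | None = None

    seed: int = 0
    n_null: int = 999
    nodesig_mode: str = "analytic"
    nodesig_runs: int = 1000
    alpha: float = 0.05
    nmds_starts: int = 20
    outdir: str = "rupestre_out"

    def __post_init__(self):
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of real inputs or a synthetic config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        syn = raw.pop("synthetic", None)
        if syn is not None:
            syn = SyntheticConfig(**syn)
        return cls(synthetic=syn, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and write CSV/newick outputs plus a manifest.

    Returns a bundle with the in-memory results.  On a stage failure the
    partial outputs are kept alongside a FAILED marker naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def save_df(df: pd.DataFrame, name: str, index: bool = False) -> None:
        p = out / name
        df.to_csv(p, index=index)
        written.append(p)

    def save_text(text: str, name: str) -> None:
        p = out / name
        p.write_text(text + "\n")
        written.append(p)

    bundle: dict[str, Any] = {}
    try:
        stage = "inputs"
        if config.synthetic is not None:
            syn = config.synthetic
            tree = simulate_tree(syn.n_species, syn.root_age,
                                 seed=derive_seed(syn.seed, "tree"))
            matrix, meta, truth = simulate_communities(tree, syn)
            bundle["truth"] = truth
            logger.info("synthetic data: %d sites, %d species", matrix.n_sites, matrix.n_species)
        else:
            paths = config.inputs
            matrix = read_incidence(paths["matrix"])
            meta = read_metadata(paths["metadata"])
            n0 = matrix.n_sites
            matrix, meta = apply_site_filters(matrix, meta)
            logger.info("site filters: %d -> %d sites", n0, matrix.n_sites)
            if paths.get("drop"):
                matrix = drop_taxa(matrix, Path(paths["drop"]).read_text().split())
            fam = {}
            if paths.get("families"):
                fdf = pd.read_csv(paths["families"])
                fam = dict(zip(fdf.iloc[:, 0].str.lower(), fdf.iloc[:, 1].str.lower()))
            taxa = [TaxonName(label=s, genus=s.split("_")[0],
                              family=fam.get(s.split("_")[0], ""))
                    for s in matrix.species]
            backbone = read_backbone(paths["backbone"])
            grafted, report = graft_species(backbone, taxa)
            logger.info("grafted %d species (%d unplaced)", report.n_placed, len(report.unplaced))
            tree = bladj_date(grafted, read_ages(paths["ages"]))
        bundle["matrix"], bundle["meta"], bundle["tree"] = matrix, meta, tree
        habitats = {r.site_id: r.habitat.value for r in meta if r.habitat is not None}

        stage = "summary"
        summ = summarize(matrix)
        save_df(pd.DataFrame([summ.__dict__]), "dataset_summary.csv")
        bundle["summary"] = summ

        stage = "beta_diversity"
        reduced = drop_singletons(matrix)
        dist = bray_curtis(reduced)
        save_df(dist.to_frame(), "bray_curtis.csv", index=True)
        dendro = ward_cluster(dist)
        save_text(dendro.to_newick(), "ward_dendrogram.nwk")
        ordi = nmds(dist, n_starts=config.nmds_starts, seed=derive_seed(config.seed, "nmds"))
        save_df(ordi.to_frame(), "nmds.csv", index=True)
        save_df(group_ellipses(ordi, habitats), "nmds_group_ellipses.csv")
        bundle.update(distance=dist, dendrogram=dendro, ordination=ordi)
        logger.info("NMDS stress %.4f (%d starts)", ordi.stress, ordi.n_starts)

        stage = "phylo_structure"
        pat = cophenetic(tree)
        res = ses(matrix, pat, "MPD", n_null=config.n_null,
                  seed=derive_seed(config.seed, "ses_mpd"))
        res += ses(matrix, pat, "MNTD", n_null=config.n_null,
                   seed=derive_seed(config.seed, "ses_mntd"))
        sesdf = ses_frame(res)
        save_df(sesdf, "ses_per_site.csv")
        bundle["ses"] = res

        stage = "habitat_stats"
        sesdf["habitat"] = sesdf["site_id"].map(habitats)
        t_rows, assum = [], []
        for (hab, iname), grp in sesdf.dropna(subset=["habitat"]).groupby(
            ["habitat", "index_name"]
        ):
            vals = grp["index"].dropna().to_numpy()
            if len(vals) >= 2 and vals.std(ddof=1) > 0:
                t_rows.append(one_tailed_t(vals, habitat=hab, metric=iname).__dict__)
        for iname, grp in sesdf.dropna(subset=["habitat"]).groupby("index_name"):
            rep = check_assumptions(
                {h: g["index"].dropna().to_numpy() for h, g in grp.groupby("habitat")}
            )
            rep.insert(0, "metric", iname)
            assum.append(rep)
        save_df(pd.DataFrame(t_rows), "habitat_t_tests.csv")
        save_df(pd.concat(assum, ignore_index=True), "assumption_checks.csv")

        meta_by_id = {r.site_id: r for r in meta}
        anova_rows, tukey_frames = [], []
        for iname, grp in sesdf.dropna(subset=["habitat"]).groupby("index_name"):
            g = grp.dropna(subset=["index"])
            subs = [meta_by_id[s].substrate.value for s in g["site_id"]]
            phys = [meta_by_id[s].physiognomy.value for s in g["site_id"]]
            rows = two_way_anova(g["index"], subs, phys, response_name=iname)
            anova_rows += rows
            err = next(r for r in rows if r.term == "error")
            for fac_name, fac in (("substrate", subs), ("physiognomy", phys)):
                tk = tukey_contrast(g["index"], fac, err.mean_square, err.df)
                tk.insert(0, "factor", fac_name)
                tk.insert(0, "response", iname)
                tukey_frames.append(tk)
        save_df(anova_frame(anova_rows), "habitat_anova.csv")
        save_df(pd.concat(tukey_frames, ignore_index=True), "tukey_contrasts.csv")
        bundle["anova"] = anova_rows

        stage = "clade_representation"
        reps = nodesig_matrix(
            tree, matrix, mode=config.nodesig_mode, runs=config.nodesig_runs,
            seed=derive_seed(config.seed, "nodesig"), alpha=config.alpha,
        )
        summaries = tabulate_habitat(reps, meta, tree)
        save_df(summary_frame(summaries), "clade_representation.csv")
        flagged = [s for s in summaries if s.flagged_over or s.flagged_under]
        save_df(summary_frame(flagged), "clade_representation_flagged.csv")
        bundle["clade_summaries"] = summaries

        stage = "manifest"
        manifest = {
            "version": __version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "n_null": config.n_null,
            "nodesig_mode": config.nodesig_mode,
            "alpha": config.alpha,
            "nmds": {"starts": config.nmds_starts, "stress": ordi.stress,
                     "converged": ordi.converged},
            "stage_seeds": {s: derive_seed(config.seed, s)
                            for s in ("nmds", "ses_mpd", "ses_mntd", "nodesig")},
            "outputs": {p.name: _sha256(p) for p in written},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        bundle["manifest"] = manifest
        return bundle
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
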