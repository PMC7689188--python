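"""End-to-end orchestration: filter -> dysregulation -> network -> labels
-> features -> classify -> overlap/enrichment -> survival -> associations.

Each stage reads declared inputs, writes its outputs under the run
directory, and is recorded in a manifest with parameter echo, wall-clock
and a sha256 checksum per produced file.  With ``resume=True`` a stage
whose outputs already exist is loaded from disk instead of recomputed, so
deleting one intermediate re-executes only the downstream stages.  One
global seed is set in the config; per-stage substreams are derived from a
hash of (seed, stage name) so reordering stages never reshuffles
randomness silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import associations as assoc
from . import classifier as clf
from . import dysregulation as dys
from . import io as eio
from . import setstats
from . import survival as surv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineConfig:
    """Paths and stage parameters for a full run (YAML-serializable)."""

    outdir: str
    mirna_expression: str
    gene_expression: str
    groups: str
    pairs: str
    disease_lists: list[str] = field(default_factory=list)
    clinical: str | None = None
    abundance: str | None = None
    drug_ic50: str | None = None
    cellline_expression: str | None = None
    annotation_gmt: str | None = None
    max_zero_frac: float = 0.10
    corr_method: str = "spearman"
    n_perm: int = 1000
    alpha: float = 0.05
    k_negatives: int = 95
    folds: int = 5
    ga_population: int = 20
    ga_generations: int = 15
    r_min: float = 0.2
    min_n: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


class _Run:
    def __init__(self, cfg: PipelineConfig, resume: bool):
        self.cfg = cfg
        self.resume = resume
        self.manifest: dict = {"seed": cfg.seed, "stages": []}
        os.makedirs(cfg.outdir, exist_ok=True)

    def path(self, name: str) -> str:
        return os.path.join(self.cfg.outdir, name)

    def stage(self, name: str, outputs: list[str], compute, load, params: dict):
        paths = [self.path(o) for o in outputs]
        t0 = time.monotonic()
        if self.resume and paths and all(os.path.exists(p) for p in paths):
            logger.info("stage %-10s resumed from existing outputs", name)
            result = load()
            status = "resumed"
        else:
            logger.info("stage %-10s running", name)
            try:
                result = compute()
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            status = "completed"
        self.manifest["stages"].append(
            {
                "name": name,
                "status": status,
                "params": params,
                "outputs": {o: _sha256(p) for o, p in zip(outputs, paths)
                            if os.path.exists(p)},
                "seconds": round(time.monotonic() - t0, 3),
            }
        )
        return result


def _write_hist(hist: dict, path: str, key: str) -> None:
    pd.DataFrame(sorted(hist.items()), columns=[key, "count"]).to_csv(
        path, sep="\t", index=False
    )


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    run = _Run(cfg, resume)
    groups = eio.read_groups(cfg.groups)

    # ------------------------------------------------------------- filter
    def _filter():
        em_m = eio.filter_zero_fraction(
            eio.read_expression(cfg.mirna_expression, "miRNA"), groups, cfg.max_zero_frac
        )
        em_g = eio.filter_zero_fraction(
            eio.read_expression(cfg.gene_expression, "mRNA"), groups, cfg.max_zero_frac
        )
        eio.write_expression(em_m, run.path("filtered_mirna.tsv"))
        eio.write_expression(em_g, run.path("filtered_gene.tsv"))
        return em_m, em_g

    em_mirna, em_gene = run.stage(
        "filter",
        ["filtered_mirna.tsv", "filtered_gene.tsv"],
        _filter,
        lambda: (
            eio.read_expression(run.path("filtered_mirna.tsv"), "miRNA"),
            eio.read_expression(run.path("filtered_gene.tsv"), "mRNA"),
        ),
        {"max_zero_frac": cfg.max_zero_frac},
    )

    # ------------------------------------------------------------- dysreg
    def _dysreg():
        pairs = eio.read_pairs(cfg.pairs)
        rec = dys.dysregulation_scores(em_mirna, em_gene, pairs, groups,
                                       method=cfg.corr_method)
        rec = dys.permutation_pvalues(
            rec, em_mirna, em_gene, groups, n_perm=cfg.n_perm,
            seed=stage_seed(cfg.seed, "dysreg"), method=cfg.corr_method,
        )
        rec.to_csv(run.path("dysregulation.tsv"), sep="\t", index=False,
                   float_format="%.10g")
        return rec

    records = run.stage(
        "dysreg",
        ["dysregulation.tsv"],
        _dysreg,
        lambda: pd.read_csv(run.path("dysregulation.tsv"), sep="\t"),
        {"n_perm": cfg.n_perm, "method": cfg.corr_method},
    )

    # ------------------------------------------------------------ network
    def _network():
        net = dys.build_dmtn(records, alpha=cfg.alpha)
        net.to_frame().to_csv(run.path("dmtn_edges.tsv"), sep="\t", index=False)
        deg_hist, slope = dys.out_degree_distribution(net)
        _write_hist(deg_hist, run.path("out_degree_hist.tsv"), "degree")
        path_hist, unreachable = dys.mirna_shortest_paths(net)
        _write_hist(path_hist, run.path("shortest_path_hist.tsv"), "length")
        with open(run.path("network_summary.json"), "w") as fh:
            json.dump(
                {
                    "n_mirnas": len(net.mirnas),
                    "n_genes": len(net.genes),
                    "n_edges": len(net.edges),
                    "out_degree_loglog_slope": slope,
                    "unreachable_mirna_pairs": unreachable,
                },
                fh, indent=2,
            )
        return net

    def _load_network():
        edges = pd.read_csv(run.path("dmtn_edges.tsv"), sep="\t")
        return dys.BipartiteNetwork.from_edges(zip(edges["miRNA"], edges["gene"]))

    net = run.stage(
        "network",
        ["dmtn_edges.tsv", "out_degree_hist.tsv", "shortest_path_hist.tsv",
         "network_summary.json"],
        _network,
        _load_network,
        {"alpha": cfg.alpha},
    )

    disease_lists = []
    for p in cfg.disease_lists:
        with open(p) as fh:
            disease_lists.append([l.strip() for l in fh if l.strip()])
    disease_set = set().union(*disease_lists) if disease_lists else set()

    # ------------------------------------------------------------- labels
    def _labels():
        tp = clf.select_true_positives(disease_lists, net)
        k = min(cfg.k_negatives, em_mirna.n_features)
        cand = clf.rank_sum_negatives(em_mirna, groups, k=k)
        tn = clf.finalize_negatives(cand, tp, net)
        tbl = pd.DataFrame(
            {"miRNA": sorted(tp) + list(tn),
             "class": ["TP"] * len(tp) + ["TN"] * len(tn)}
        )
        tbl.to_csv(run.path("labels.tsv"), sep="\t", index=False)
        return clf.LabelSets(tp=tp, tn=set(tn))

    def _load_labels():
        tbl = pd.read_csv(run.path("labels.tsv"), sep="\t")
        return clf.LabelSets(
            tp=set(tbl.loc[tbl["class"] == "TP", "miRNA"]),
            tn=set(tbl.loc[tbl["class"] == "TN", "miRNA"]),
        )

    labels = run.stage(
        "labels", ["labels.tsv"], _labels, _load_labels,
        {"k_negatives": cfg.k_negatives},
    )

    # ----------------------------------------------------------- features
    def _features():
        feats = clf.compute_features(net, em_mirna, groups, disease_set)
        feats.to_csv(run.path("features.tsv"), sep="\t", float_format="%.10g")
        return feats

    features = run.stage(
        "features", ["features.tsv"], _features,
        lambda: pd.read_csv(run.path("features.tsv"), sep="\t", index_col=0),
        {},
    )

    # ----------------------------------------------------------- classify
    def _classify():
        ga = clf.GAConfig(population=cfg.ga_population, generations=cfg.ga_generations)
        model = clf.train_classifier(
            features, labels, folds=cfg.folds, ga=ga,
            seed=stage_seed(cfg.seed, "classify"),
        )
        thr = clf.recognition_threshold(model, features.loc[sorted(labels.tn)])
        preds = clf.predict_risk(model, features, thr)
        preds.rename_axis("miRNA").to_csv(run.path("predictions.tsv"), sep="\t",
                                          float_format="%.10g")
        with open(run.path("model_summary.json"), "w") as fh:
            json.dump(model.summary(), fh, indent=2)
        return preds

    preds = run.stage(
        "classify",
        ["predictions.tsv", "model_summary.json"],
        _classify,
        lambda: pd.read_csv(run.path("predictions.tsv"), sep="\t", index_col=0),
        {"folds": cfg.folds, "ga_population": cfg.ga_population,
         "ga_generations": cfg.ga_generations},
    )
    risk_mirnas = set(preds.index[preds["risk"]])
    neighbor_genes = net.neighbor_genes(risk_mirnas)

    # ------------------------------------------------------------ overlap
    def _overlap():
        universe = set(em_mirna.feature_ids)
        res = setstats.overlap_test(risk_mirnas, disease_set & universe, universe)
        pd.DataFrame([vars(res)]).to_csv(run.path("overlap.tsv"), sep="\t",
                                         index=False, float_format="%.10g")
        if cfg.annotation_gmt:
            ann = setstats.read_gmt(cfg.annotation_gmt)
            table = setstats.enrich(neighbor_genes, ann, set(em_gene.feature_ids),
                                    alpha=cfg.alpha)
            table.to_csv(run.path("enrichment.tsv"), sep="\t", index=False,
                         float_format="%.10g")
        return res

    overlap_outputs = ["overlap.tsv"] + (["enrichment.tsv"] if cfg.annotation_gmt else [])
    run.stage(
        "overlap", overlap_outputs, _overlap,
        lambda: None, {"alpha": cfg.alpha},
    )

    # ------------------------------------------------------------ survive
    if cfg.clinical:
        def _survive():
            clinical = surv.read_clinical(cfg.clinical)
            screened = em_mirna.subset_features(
                [m for m in em_mirna.feature_ids if m in risk_mirnas]
            )
            table = surv.survival_screen(screened, clinical)
            table.to_csv(run.path("survival_screen.tsv"), sep="\t", index=False,
                         float_format="%.10g")
            return table

        run.stage(
            "survive", ["survival_screen.tsv"], _survive,
            lambda: pd.read_csv(run.path("survival_screen.tsv"), sep="\t"), {},
        )

    # ---------------------------------------------------------- associate
    if cfg.abundance or (cfg.drug_ic50 and cfg.cellline_expression):
        def _associate():
            outs = []
            screened = em_mirna.subset_features(
                [m for m in em_mirna.feature_ids if m in risk_mirnas]
            )
            if cfg.abundance:
                ab = assoc.read_abundance(cfg.abundance)
                res = assoc.immune_associations(screened, ab, alpha=cfg.alpha)
                res.to_csv(run.path("immune_associations.tsv"), sep="\t",
                           index=False, float_format="%.10g")
                outs.append(res)
            if cfg.drug_ic50 and cfg.cellline_expression:
                drugs = assoc.read_drug_response(cfg.drug_ic50)
                em_lines = eio.read_expression(cfg.cellline_expression, "miRNA")
                keep = [m for m in em_lines.feature_ids if m in risk_mirnas]
                res = assoc.drug_associations(
                    em_lines.subset_features(keep), drugs,
                    r_min=cfg.r_min, alpha=cfg.alpha, min_n=cfg.min_n,
                )
                res.to_csv(run.path("drug_associations.tsv"), sep="\t",
                           index=False, float_format="%.10g")
                outs.append(res)
            return outs

        assoc_outputs = []
        if cfg.abundance:
            assoc_outputs.append("immune_associations.tsv")
        if cfg.drug_ic50 and cfg.cellline_expression:
            assoc_outputs.append("drug_associations.tsv")
        run.stage(
            "associate", assoc_outputs, _associate, lambda: None,
            {"r_min": cfg.r_min, "min_n": cfg.min_n, "alpha": cfg.alpha},
        )

    with open(run.path("run_manifest.json"), "w") as fh:
        json.dump(run.manifest, fh, indent=2)
    return run.manifest
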