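"""Configuration, orchestration and plain-text I/O for a full run.

A run directory contains one sub-folder per stage, each holding fixed
column-order TSVs, plus a ``manifest.json`` recording the configuration,
seeds, input checksums, and output checksums. All randomness derives from
the single configured seed, and no timestamps enter the outputs, so
identical config + inputs give byte-identical run directories.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import (
    CohortSpec,
    LatentModule,
    PlantedDEG,
    PlantedLRPair,
    generate_cohort,
    read_cohort,
    write_cohort,
)

log = logging.getLogger("condcomm")

STAGES = (
    "simulate",
    "preprocess",
    "de",
    "prioritize",
    "connectome",
    "trajectory",
    "enrich",
    "crosstalk",
)

_FLOAT_FMT = "%.6g"


def default_config() -> dict:
    """Demo configuration: a small cohort with one planted effect of each
    kind, analysed end to end."""
    return {
        "seed": 0,
        "qc": {"min_genes": 301, "max_mito_fraction": 0.30},
        "normalize": {"scale": 1e4},
        "simulate": {
            "n_genes": 1000,
            "n_mito": 10,
            "cell_types": [
                "macrophage",
                "monocyte",
                "AT2",
                "endothelial_cell",
                "club_cell",
                "T_cell",
            ],
            "cells_per_type_per_individual": [50, 70],
            "qc_failure_fraction": 0.02,
            # balanced up/down effects keep per-cell totals comparable
            "planted_degs": (
                [["G%05d" % (50 + i), "monocyte", "disease", 2.0 if i % 2 else -2.0]
                 for i in range(20)]
                + [["G%05d" % (70 + i), "club_cell", "aging", 2.0 if i % 2 else -2.0]
                   for i in range(6)]
                + [["G%05d" % (80 + i), "macrophage", "smoking", 2.0 if i % 2 else -2.0]
                   for i in range(6)]
            ),
            "planted_lr_pairs": [["G00060", "G00061", "monocyte", "AT2", "disease", 2.5]],
            "latent_modules": [
                {
                    "sender_ct": "macrophage",
                    "focal_genes": ["G00090", "G00091"],
                    "receiver_ct": "endothelial_cell",
                    "target_genes": ["G%05d" % (100 + i) for i in range(12)],
                    "gamma": 3.0,
                }
            ],
        },
        "de": {"method": "pseudobulk_lm", "fdr_threshold": 0.05, "min_abs_log2fc": 0.25},
        "prioritize": {"n_reps": 5, "min_cells_floor": 30},
        "connectome": {"n_perm": 200, "alpha": 0.05, "expr_gate": 0.10, "condition": "disease"},
        "trajectory": {
            "start_cluster": "monocyte",
            "end_cluster": "AT2",
            "top_n": 100,
            "condition": "disease",
        },
        "enrich": {
            "risk_genes": ["G00050", "G00051", "G00052", "G00200", "G00201", "G00202"],
            "cell_type": "monocyte",
        },
        "crosstalk": {
            "sender_ct": "macrophage",
            "focal_genes": ["G00090", "G00091"],
            "threshold": 0.8,
            "min_individuals": 5,
        },
        "stages": list(STAGES),
    }


def validate_config(config: dict) -> None:
    qc = config.get("qc", {})
    if qc.get("min_genes", 301) < 1:
        raise ValueError("config error: qc.min_genes must be >= 1")
    if not 0 < qc.get("max_mito_fraction", 0.3) <= 1:
        raise ValueError("config error: qc.max_mito_fraction must be in (0, 1]")
    if "seed" not in config:
        raise ValueError("config error: seed is mandatory")
    for s in config.get("stages", []):
        if s not in STAGES:
            raise ValueError(f"config error: unknown stage {s!r}")
    thr = config.get("crosstalk", {}).get("threshold", 0.8)
    if not 0 <= thr <= 1:
        raise ValueError("config error: crosstalk.threshold must be in [0, 1]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index=False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _spec_from_config(config: dict) -> CohortSpec:
    sim = config.get("simulate", {})
    kwargs = {}
    if "cell_types" in sim:
        kwargs["cell_types"] = tuple(sim["cell_types"])
    if "cells_per_type_per_individual" in sim:
        kwargs["cells_per_type_per_individual"] = tuple(sim["cells_per_type_per_individual"])
    for key in ("n_genes", "n_mito", "qc_failure_fraction", "dispersion"):
        if key in sim:
            kwargs[key] = sim[key]
    degs = [PlantedDEG(*row) for row in sim.get("planted_degs", [])]
    lrs = [PlantedLRPair(*row) for row in sim.get("planted_lr_pairs", [])]
    mods = [
        LatentModule(
            sender_ct=m["sender_ct"],
            focal_genes=tuple(m["focal_genes"]),
            receiver_ct=m["receiver_ct"],
            target_genes=tuple(m["target_genes"]),
            gamma=m["gamma"],
        )
        for m in sim.get("latent_modules", [])
    ]
    return CohortSpec(
        planted_degs=degs,
        planted_lr_pairs=lrs,
        latent_modules=mods,
        seed=config["seed"],
        **kwargs,
    )


def _demo_lr_db(spec: CohortSpec, config: dict) -> pd.DataFrame:
    genes = spec.gene_names()
    rows = [(p.ligand, p.receptor) for p in spec.planted_lr_pairs]
    rng = np.random.default_rng(config["seed"] + 17)
    non_mito = [g for g in genes if not g.startswith(spec.mito_prefix)]
    extra = rng.choice(non_mito, size=(12, 2), replace=False)
    rows += [tuple(r) for r in extra]
    db = pd.DataFrame(rows, columns=["ligand", "receptor"]).drop_duplicates()
    db["pair_id"] = db["ligand"] + "_" + db["receptor"]
    return db


def run_pipeline(config: dict, outdir, stages=None) -> Path:
    """Execute the enabled stages in dependency order into ``outdir``."""
    from . import connectome as cn
    from . import crosstalk as xt
    from . import de as de_mod
    from . import enrich as en
    from . import prioritize as pr
    from . import preprocess as pp
    from . import trajectory as tj

    validate_config(config)
    stages = list(stages or config.get("stages", STAGES))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "stages": stages,
        "inputs": {},
        "outputs": {},
    }

    timings = {}
    adata = truth = None
    spec = _spec_from_config(config)

    def _stage(name):
        enabled = name in stages
        if enabled:
            log.info("stage %s: start", name)
        return enabled

    t0 = time.perf_counter()
    if _stage("simulate"):
        adata, truth = generate_cohort(spec)
        write_cohort(adata, truth, outdir / "simulate")
        db = _demo_lr_db(spec, config)
        _write_tsv(db, outdir / "simulate" / "lr_db.tsv")
        timings["simulate"] = time.perf_counter() - t0
    else:
        src = config.get("paths", {}).get("cohort")
        if src is None:
            raise ValueError("stage dependency: no simulated cohort and no paths.cohort")
        adata = read_cohort(src)
        for f in Path(src).iterdir():
            manifest["inputs"][f.name] = _sha256(f)

    qc_conf = config.get("qc", {})
    thresholds = pp.QCThresholds(
        min_genes=qc_conf.get("min_genes", 301),
        max_mito_fraction=qc_conf.get("max_mito_fraction", 0.30),
    )
    norm = None
    if _stage("preprocess"):
        t = time.perf_counter()
        filtered, report = pp.qc_filter(adata, thresholds)
        norm = pp.normalize(filtered, scale=config.get("normalize", {}).get("scale", 1e4))
        _write_tsv(report, outdir / "preprocess" / "qc_report.tsv", index=True)
        write_cohort(
            filtered,
            truth if truth is not None else _empty_truth(),
            outdir / "preprocess" / "filtered",
        )
        timings["preprocess"] = time.perf_counter() - t
    if norm is None and any(
        s in stages for s in ("de", "prioritize", "connectome", "trajectory", "enrich", "crosstalk")
    ):
        filtered, _ = pp.qc_filter(adata, thresholds)
        norm = pp.normalize(filtered, scale=config.get("normalize", {}).get("scale", 1e4))

    degs = None
    if _stage("de"):
        t = time.perf_counter()
        de_conf = config.get("de", {})
        tables = []
        for ct in sorted(pd.unique(norm.obs["cell_type"])):
            tables.append(
                de_mod.fit_condition_de(norm, ct, method=de_conf.get("method", "pseudobulk_lm"))
            )
        degs = de_mod.call_degs(
            pd.concat(tables, ignore_index=True),
            fdr_threshold=de_conf.get("fdr_threshold", 0.05),
            min_abs_log2fc=de_conf.get("min_abs_log2fc", 0.25),
        )
        _write_tsv(degs, outdir / "de" / "degs.tsv")
        timings["de"] = time.perf_counter() - t

    if _stage("prioritize"):
        t = time.perf_counter()
        pconf = config.get("prioritize", {})
        res = pr.downsample_prioritize(
            norm,
            n_reps=pconf.get("n_reps", 5),
            seed=seed + 1,
            min_cells_floor=pconf.get("min_cells_floor", 30),
        )
        _write_tsv(res.replicates, outdir / "prioritize" / "prioritization.tsv")
        _write_tsv(res.ranks, outdir / "prioritize" / "ranks.tsv")
        timings["prioritize"] = time.perf_counter() - t

    if _stage("connectome"):
        t = time.perf_counter()
        cconf = config.get("connectome", {})
        db = cn.load_lr_database(outdir / "simulate" / "lr_db.tsv") if (
            outdir / "simulate" / "lr_db.tsv"
        ).exists() else cn.load_lr_database(config["paths"]["lr_db"])
        cond = cconf.get("condition", "disease")
        case_mask = pr.condition_labels(norm.obs, cond)
        kwargs = dict(
            n_perm=cconf.get("n_perm", 200),
            alpha=cconf.get("alpha", 0.05),
            expr_gate=cconf.get("expr_gate", 0.10),
        )
        case = cn.lr_score_test(norm[case_mask], db, seed=seed + 2, **kwargs)
        control = cn.lr_score_test(norm[~case_mask], db, seed=seed + 3, **kwargs)
        delta = cn.condition_delta(case, control)
        edges, _ = cn.delta_network(delta)
        _write_tsv(case, outdir / "connectome" / "interactions_case.tsv")
        _write_tsv(control, outdir / "connectome" / "interactions_control.tsv")
        _write_tsv(delta.pairs, outdir / "connectome" / "delta_matrix.tsv")
        _write_tsv(edges, outdir / "connectome" / "network_edges.tsv")
        timings["connectome"] = time.perf_counter() - t

    if _stage("trajectory"):
        t = time.perf_counter()
        tconf = config.get("trajectory", {})
        pt = tj.compute_pseudotime(norm, tconf["start_cluster"], tconf["end_cluster"])
        sub = norm[pt.index]
        from .preprocess import expressed_gene_set

        genes = sorted(
            expressed_gene_set(norm, tconf["start_cluster"])
            | expressed_gene_set(norm, tconf["end_cluster"])
        )
        X = sub[:, genes].X
        from scipy import sparse as sp

        X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
        assoc = tj.association_statistic(pd.DataFrame(X, columns=genes), pt.to_numpy())
        ranking = tj.rank_drivers(assoc, top_n=tconf.get("top_n", 250))
        _write_tsv(pt.to_frame(), outdir / "trajectory" / "pseudotime.tsv", index=True)
        _write_tsv(ranking.table, outdir / "trajectory" / "driver_ranking.tsv")
        if degs is not None:
            cond = tconf.get("condition", "disease")
            deg_set = set(
                degs[
                    degs["is_deg"]
                    & (degs["condition"] == cond)
                    & (degs["cell_type"] == tconf["start_cluster"])
                ]["gene"]
            )
            if deg_set & set(ranking.table["gene"]):
                res = tj.driver_enrichment_ks(ranking, deg_set)
                _write_tsv(
                    pd.DataFrame([res]), outdir / "trajectory" / "enrichment.tsv"
                )
        timings["trajectory"] = time.perf_counter() - t

    if _stage("enrich"):
        t = time.perf_counter()
        econf = config.get("enrich", {})
        ct = econf.get("cell_type", "monocyte")
        background = pp.expressed_gene_set(norm, ct)
        risk = set(econf.get("risk_genes", [])) & background
        rows = []
        if degs is not None and risk:
            for cond in ("disease", "aging", "smoking"):
                hit = set(
                    degs[
                        degs["is_deg"]
                        & (degs["condition"] == cond)
                        & (degs["cell_type"] == ct)
                    ]["gene"]
                ) & background
                r = en.fisher_enrichment(hit, risk, background)
                rows.append(
                    {
                        "cell_type": ct,
                        "condition": cond,
                        "a": r.a,
                        "b": r.b,
                        "c": r.c,
                        "d": r.d,
                        "odds_ratio": r.odds_ratio,
                        "p_value": r.p_value,
                    }
                )
        _write_tsv(pd.DataFrame(rows), outdir / "enrich" / "enrichment.tsv")
        timings["enrich"] = time.perf_counter() - t

    if _stage("crosstalk"):
        t = time.perf_counter()
        xconf = config.get("crosstalk", {})
        cube = pp.individual_pseudobulk(norm)
        sets = {
            ct: pp.expressed_gene_set(norm, ct) for ct in pd.unique(norm.obs["cell_type"])
        }
        cmap = xt.sender_receiver_correlation(
            cube,
            xconf["focal_genes"],
            xconf["sender_ct"],
            sorted(sets),
            expressed_sets=sets,
            min_individuals=xconf.get("min_individuals", 5),
            threshold=xconf.get("threshold", 0.8),
        )
        heat, order = xt.correlated_proportion(cmap)
        _write_tsv(heat, outdir / "crosstalk" / "proportions.tsv", index=True)
        lists = xt.correlated_gene_lists(cmap)
        gdir = outdir / "crosstalk" / "gene_lists"
        gdir.mkdir(parents=True, exist_ok=True)
        for rct, per_focal in sorted(lists.items()):
            for g, gl in sorted(per_focal.items()):
                (gdir / f"{rct}__{g}.txt").write_text("\n".join(gl) + "\n")
        rho_long = []
        for rct, rho in cmap.rho.items():
            m = rho.reset_index(names="focal_gene").melt(
                id_vars="focal_gene", var_name="target_gene", value_name="rho"
            )
            m.insert(0, "recipient_ct", rct)
            rho_long.append(m)
        _write_tsv(pd.concat(rho_long, ignore_index=True), outdir / "crosstalk" / "rho_matrix.tsv")
        timings["crosstalk"] = time.perf_counter() - t

    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][str(f.relative_to(outdir))] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    for name, dt in timings.items():
        log.info("stage %s: %.2fs", name, dt)
    return outdir


def _empty_truth():
    from .simulate import SyntheticTruth

    return SyntheticTruth()
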