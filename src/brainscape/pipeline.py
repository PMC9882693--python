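"""File-based pipeline stages tying the library together.

Each ``run_*`` function maps to one stage of the analysis: it reads its
inputs from a run directory, computes with the library modules, writes TSV
/JSON outputs plus a JSON manifest (parameters, seed, input/output
digests), and returns the paths it wrote.  Reruns with the same config and
seed produce byte-identical outputs, which the manifests make checkable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import harmonize as hz
from . import io as bio
from . import landscape as ls
from . import pathways as pw
from . import survival as sv
from .matrix import GeneUniverse
from .simulate import OverlaySpec, SimulationConfig, SubtypeSpec, simulate_cohorts


def default_config() -> dict:
    """The default synthetic scenario and stage parameters."""
    return {
        "seed": 0,
        "simulate": {
            "n_cohorts": 2,
            "samples_per_cohort_per_subtype": 100,
            "n_genes": 2000,
            "subtypes": [
                {"name": "idh_wildtype", "n_signature_genes": 50,
                 "signature_effect": 2.0, "survival_median": 1.0, "survival_shape": 1.0},
                {"name": "astrocytoma", "n_signature_genes": 50,
                 "signature_effect": 2.0, "survival_median": 3.0, "survival_shape": 1.0},
                {"name": "oligodendroglioma", "n_signature_genes": 50,
                 "signature_effect": 2.0, "survival_median": 8.0, "survival_shape": 1.0},
            ],
            "batch_location_sd": 1.8,
            "batch_scale_shape": 20.0,
            "batch_scale_scale": 19.0,
            "noise_sd": 1.0,
            "censoring_rate": 0.2,
            "n_random_sets": 40,
            "genes_per_random_set": 30,
        },
        "harmonize": {"mode": "parametric_eb", "pseudocount": 1.0},
        "embed": {"method": "umap", "d": 2},
        "annotate": {"radius": 2.0, "neighbor_fraction": 0.25, "min_neighbors": 10,
                     "stratify_by": ["subtype", "dataset"]},
        "pathways": {"min_size": 5, "max_size": 500, "adj_p_threshold": 0.05,
                     "contrasts": [["idh_wildtype", "astrocytoma"],
                                   ["idh_wildtype", "oligodendroglioma"]]},
        "classify": {"k": 15, "fraction_unlabeled": 0.1},
        "overlay": {"genes": ["G00001", "G00051", "G00101"]},
    }


def simulation_config_from(cfg: dict, seed: int) -> SimulationConfig:
    sc = cfg["simulate"]
    subtypes = tuple(
        SubtypeSpec(
            s["name"], s["n_signature_genes"], s["signature_effect"],
            s["survival_median"], s.get("survival_shape", 1.0),
        )
        for s in sc["subtypes"]
    )
    overlay = None
    if "overlays" in sc:
        overlay = {name: OverlaySpec(**spec) for name, spec in sc["overlays"].items()}
    return SimulationConfig(
        n_cohorts=sc["n_cohorts"],
        samples_per_cohort_per_subtype=sc["samples_per_cohort_per_subtype"],
        n_genes=sc["n_genes"],
        subtype_specs=subtypes,
        batch_location_sd=sc["batch_location_sd"],
        batch_scale_shape=sc["batch_scale_shape"],
        batch_scale_scale=sc["batch_scale_scale"],
        noise_sd=sc["noise_sd"],
        censoring_rate=sc["censoring_rate"],
        overlay_specs=overlay,
        seed=seed,
    )


def _manifest(outdir: Path, stage: str, inputs: dict, outputs: dict, params: dict, seed):
    bio.write_manifest(outdir / f"manifest_{stage}.json", stage, inputs, outputs, params, seed)


def run_simulate(cfg: dict, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    sim_cfg = simulation_config_from(cfg, seed)
    matrices, meta, overlays, truth = simulate_cohorts(sim_cfg)

    outputs = {}
    for m, cohort in zip(matrices, sim_cfg.cohort_names):
        p = outdir / f"expression_{cohort}.tsv"
        bio.write_expression(m, p)
        outputs[f"expression_{cohort}"] = p
    bio.write_metadata(meta, outdir / "metadata.tsv")
    bio.write_table(overlays.mutations, outdir / "mutations.tsv")
    bio.write_table(overlays.fusions, outdir / "fusions.tsv")
    cn = overlays.copy_number.copy()
    cn.index.name = "gene_id"
    cn.to_csv(outdir / "copy_number.tsv", sep="\t")
    (outdir / "truth.json").write_text(truth.to_json())

    # gene sets: one per subtype signature plus seeded random decoys
    sets: dict[str, tuple[str, ...]] = {
        f"SIG_{name.upper()}": tuple(genes)
        for name, genes in truth.signature_genes.items()
    }
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    genes = sim_cfg.gene_names
    for i in range(cfg["simulate"].get("n_random_sets", 40)):
        size = cfg["simulate"].get("genes_per_random_set", 30)
        members = tuple(sorted(rng.choice(genes, size=size, replace=False)))
        sets[f"RANDOM_{i + 1:03d}"] = members
    bio.write_gmt(sets, outdir / "gene_sets.gmt")

    outputs.update(
        metadata=outdir / "metadata.tsv", mutations=outdir / "mutations.tsv",
        fusions=outdir / "fusions.tsv", copy_number=outdir / "copy_number.tsv",
        truth=outdir / "truth.json", gene_sets=outdir / "gene_sets.gmt",
    )
    _manifest(outdir, "simulate", {}, outputs, cfg["simulate"], seed)
    return {k: str(v) for k, v in outputs.items()}


def run_harmonize(cfg: dict, outdir) -> dict:
    outdir = Path(outdir)
    hc = cfg["harmonize"]
    expr_paths = sorted(outdir.glob("expression_cohort*.tsv"))
    if not expr_paths:
        raise FileNotFoundError(f"no expression_cohort*.tsv under {outdir}")
    matrices = [bio.read_expression(p, "FPKM") for p in expr_paths]
    meta = bio.read_metadata(outdir / "metadata.tsv")

    universe = GeneUniverse.from_iterable(matrices[0].gene_ids)
    matrices, dropped = hz.intersect_to_universe(matrices, universe)
    tpm = [hz.fpkm_to_tpm(m) for m in matrices]
    logged = [hz.log_transform(m, hc.get("pseudocount", 1.0)) for m in tpm]
    combined = logged[0].copy_with(
        pd.concat([m.values for m in logged], axis=1), "log2TPM"
    )
    batches = meta.table.loc[combined.sample_ids, "dataset"]
    corrected, report = hz.correct_batch(combined, batches, mode=hc.get("mode", "parametric_eb"))

    p_out = outdir / "corrected.tsv"
    bio.write_expression(corrected, p_out)
    rep = report.to_dict()
    rep["dropped_genes_per_matrix"] = dropped
    (outdir / "correction_report.json").write_text(json.dumps(rep, sort_keys=True, indent=1))
    _manifest(
        outdir, "harmonize",
        {p.stem: p for p in expr_paths},
        {"corrected": p_out, "report": outdir / "correction_report.json"},
        hc, cfg["seed"],
    )
    return {"corrected": str(p_out)}


def run_embed(cfg: dict, outdir) -> dict:
    outdir = Path(outdir)
    ec = cfg["embed"]
    corrected = bio.read_expression(outdir / "corrected.tsv", "log2TPM_corrected")
    L = ls.embed(corrected, method=ec.get("method", "umap"), d=ec.get("d", 2),
                 seed=cfg["seed"], params=ec.get("params"))
    bio.write_landscape(L, outdir / "landscape.tsv", outdir / "landscape.json")
    _manifest(outdir, "embed", {"corrected": outdir / "corrected.tsv"},
              {"landscape": outdir / "landscape.tsv"}, ec, cfg["seed"])
    return {"landscape": str(outdir / "landscape.tsv")}


def run_annotate_survival(cfg: dict, outdir) -> dict:
    outdir = Path(outdir)
    ac = cfg["annotate"]
    L = bio.read_landscape(outdir / "landscape.tsv", outdir / "landscape.json")
    meta = bio.read_metadata(outdir / "metadata.tsv")
    kept, log = sv.filter_primary_unique(meta)
    keep_idx = [i for i, s in enumerate(L.sample_ids) if s in set(kept)]
    Lf = ls.Landscape(
        sample_ids=[L.sample_ids[i] for i in keep_idx],
        coordinates=L.coordinates[keep_idx],
        method=L.method, seed=L.seed, provenance=L.provenance,
    )
    meta_f = meta.subset(Lf.sample_ids)
    records = meta_f.table[["time", "event"]]
    config = sv.AnnotationConfig(
        radius=ac.get("radius", 2.0),
        neighbor_fraction=ac.get("neighbor_fraction", 0.25),
        min_neighbors=ac.get("min_neighbors", 10),
        stratify_by=tuple(ac.get("stratify_by", ("subtype", "dataset"))),
    )
    ann = sv.annotate_survival(Lf, records, meta_f, config)
    out = Lf.to_frame().join(meta_f.table[["subtype", "dataset"]]).join(ann)

    groups = sv.km_by_group(records, meta_f.table["subtype"])
    med_rows = [
        {"subtype": name, "km_median": (np.nan if med is None else med), "n": curve.n}
        for name, (curve, med) in groups.items()
    ]
    bio.write_table(pd.DataFrame(med_rows), outdir / "km_medians.tsv")
    out.to_csv(outdir / "survival_annotation.tsv", sep="\t", float_format="%.17g")
    bio.write_table(log, outdir / "exclusion_log.tsv")
    _manifest(outdir, "annotate_survival",
              {"landscape": outdir / "landscape.tsv", "metadata": outdir / "metadata.tsv"},
              {"annotation": outdir / "survival_annotation.tsv",
               "km_medians": outdir / "km_medians.tsv",
               "exclusions": outdir / "exclusion_log.tsv"},
              vars(config) | {"stratify_by": list(config.stratify_by)}, cfg["seed"])
    return {"annotation": str(outdir / "survival_annotation.tsv")}


def run_score_pathways(cfg: dict, outdir) -> dict:
    outdir = Path(outdir)
    pc = cfg["pathways"]
    corrected = bio.read_expression(outdir / "corrected.tsv", "log2TPM_corrected")
    sets = pw.read_gmt(outdir / "gene_sets.gmt")
    scored = pw.score_samples(corrected, sets,
                              min_size=pc.get("min_size", 5),
                              max_size=pc.get("max_size", 500))
    scored.scores.to_csv(outdir / "pathway_scores.tsv", sep="\t", float_format="%.17g")
    _manifest(outdir, "score_pathways",
              {"corrected": outdir / "corrected.tsv", "gene_sets": outdir / "gene_sets.gmt"},
              {"scores": outdir / "pathway_scores.tsv"},
              {"method": scored.method, "min_size": pc.get("min_size", 5),
               "max_size": pc.get("max_size", 500),
               "dropped": scored.dropped_sets}, cfg["seed"])
    return {"scores": str(outdir / "pathway_scores.tsv")}


def run_test_pathways(cfg: dict, outdir) -> dict:
    outdir = Path(outdir)
    pc = cfg["pathways"]
    scores = pd.read_csv(outdir / "pathway_scores.tsv", sep="\t", index_col=0)
    meta = bio.read_metadata(outdir / "metadata.tsv")
    psm = pw.PathwayScoreMatrix(scores, method="rank_ks")
    outputs = {}
    tables = []
    for ref, other in pc["contrasts"]:
        samples = meta.table.index[meta.table["subtype"].isin([ref, other])]
        groups = meta.table.loc[samples, "subtype"]
        res = pw.moderated_t_test(psm, groups)
        name = f"differential_{ref}_vs_{other}.tsv"
        res.to_csv(outdir / name, sep="\t", index_label="set", float_format="%.17g")
        outputs[name] = outdir / name
        tables.append(res)
    summary = {}
    if len(tables) >= 2:
        for direction in ("up", "down"):
            shared, counts = pw.shared_regulated(
                tables, adj_p_threshold=pc.get("adj_p_threshold", 0.05), direction=direction
            )
            summary[direction] = {"sets": sorted(shared), "counts": counts}
    (outdir / "shared_pathways.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
    outputs["shared"] = outdir / "shared_pathways.json"
    _manifest(outdir, "test_pathways", {"scores": outdir / "pathway_scores.tsv"},
              outputs, pc, cfg["seed"])
    return {k: str(v) for k, v in outputs.items()}


def run_classify(cfg: dict, outdir) -> dict:
    outdir = Path(outdir)
    cc = cfg["classify"]
    L = bio.read_landscape(outdir / "landscape.tsv", outdir / "landscape.json")
    meta = bio.read_metadata(outdir / "metadata.tsv")
    labels = meta.table.loc[L.sample_ids, "subtype"]
    targets = list(labels.index[labels.isna()])
    truth = None
    if not targets:
        # self-validation: withhold a deterministic fraction and recover it
        frac = cc.get("fraction_unlabeled", 0.1)
        rng = np.random.default_rng(np.random.SeedSequence([cfg["seed"], 211]))
        n_hold = max(1, int(round(frac * len(labels))))
        targets = sorted(rng.choice(labels.index.to_numpy(), size=n_hold, replace=False))
        truth = labels.loc[targets]
        labels = labels.drop(index=targets)
    pred = ls.classify_by_neighbors(L, labels, targets, k=cc.get("k", 15))
    if truth is not None:
        pred["true_subtype"] = truth
        pred["correct"] = pred["predicted"] == pred["true_subtype"]
    pred.to_csv(outdir / "classification.tsv", sep="\t", float_format="%.17g")
    _manifest(outdir, "classify",
              {"landscape": outdir / "landscape.tsv", "metadata": outdir / "metadata.tsv"},
              {"classification": outdir / "classification.tsv"}, cc, cfg["seed"])
    return {"classification": str(outdir / "classification.tsv")}


def run_overlay(cfg: dict, outdir) -> dict:
    outdir = Path(outdir)
    oc = cfg["overlay"]
    L = bio.read_landscape(outdir / "landscape.tsv", outdir / "landscape.json")
    corrected = bio.read_expression(outdir / "corrected.tsv", "log2TPM_corrected")
    mutations = bio.read_mutations(outdir / "mutations.tsv")
    fusions, n_removed = bio.read_fusions(outdir / "fusions.tsv", retain=("high",))
    cnv = bio.read_cnv(outdir / "copy_number.tsv")

    outputs = {}
    for gene in oc.get("genes", []):
        table = bio.overlay_gene(L, gene, corrected, mutations, fusions, cnv)
        name = f"overlay_{gene}.tsv"
        table.to_csv(outdir / name, sep="\t", float_format="%.17g")
        outputs[name] = outdir / name

    burden = pd.DataFrame(
        {
            "n_mutations": bio.burden_per_sample(mutations, L.sample_ids),
            "n_fusions": bio.burden_per_sample(
                fusions.rename(columns={"gene_5prime": "gene_id"}), L.sample_ids
            ),
        }
    ).join(cnv_reindexed(cnv, L.sample_ids))
    burden.index.name = "sample_id"
    burden.to_csv(outdir / "burdens.tsv", sep="\t")
    outputs["burdens"] = outdir / "burdens.tsv"
    _manifest(outdir, "overlay",
              {"mutations": outdir / "mutations.tsv", "fusions": outdir / "fusions.tsv",
               "copy_number": outdir / "copy_number.tsv"},
              outputs, {"genes": oc.get("genes", []), "fusions_removed": n_removed},
              cfg["seed"])
    return {k: str(v) for k, v in outputs.items()}


def cnv_reindexed(cnv: pd.DataFrame, sample_ids) -> pd.DataFrame:
    b = bio.cnv_burden_per_sample(cnv)
    return b.reindex(list(sample_ids)).fillna(0).astype(int)


def run_report(cfg: dict, outdir) -> dict:
    """Aggregate stage outputs into one summary JSON."""
    outdir = Path(outdir)
    report: dict = {"seed": cfg["seed"]}
    ann = pd.read_csv(outdir / "survival_annotation.tsv", sep="\t", index_col=0)
    report["n_samples"] = int(len(ann))
    report["fraction_annotated"] = float((ann["status"] == "annotated").mean())
    meds = pd.read_csv(outdir / "km_medians.tsv", sep="\t")
    report["km_medians"] = {r["subtype"]: r["km_median"] for _, r in meds.iterrows()}
    cls = pd.read_csv(outdir / "classification.tsv", sep="\t", index_col=0)
    if "correct" in cls.columns:
        report["classification_accuracy"] = float(cls["correct"].mean())
    shared = json.loads((outdir / "shared_pathways.json").read_text())
    if shared:
        report["shared_pathways_up"] = shared.get("up", {}).get("counts", {})
    (outdir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    return {"report": str(outdir / "report.json")}


STAGES = {
    "simulate": run_simulate,
    "harmonize": run_harmonize,
    "embed": run_embed,
    "annotate-survival": run_annotate_survival,
    "score-pathways": run_score_pathways,
    "test-pathways": run_test_pathways,
    "classify": run_classify,
    "overlay": run_overlay,
    "report": run_report,
}

PIPELINE_ORDER = list(STAGES)


def run_pipeline(cfg: dict, outdir) -> dict:
    results = {}
    for stage in PIPELINE_ORDER:
        results[stage] = STAGES[stage](cfg, outdir)
    return results
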