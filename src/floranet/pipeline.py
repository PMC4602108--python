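"""End-to-end orchestration: simulate, co-express, predict, enrich, tree.

``run_all`` drives every stage on a synthetic study, checkpoints each
stage's TSV outputs under the output directory, and writes a ranked
candidate-gene report: candidates are module genes that survive the alpha
co-expression screen against the seed genes and gain at least one
predicted, co-localized interaction edge to a seed, ranked lexicographically
by (module significance, own-module kME, SVM decision score).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import coexpression as cx
from . import enrichment as en
from . import io as fio
from . import phylo as ph
from . import ppi
from . import simulate as sim
from .config import PipelineConfig, validate_config  # noqa: F401  (re-export)

logger = logging.getLogger("floranet")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunResult:
    """In-memory artifacts of one full pipeline run."""

    config: PipelineConfig
    expression: cx.ExpressionData
    truth: sim.GroundTruth
    partition: cx.ModulePartition
    beta: int
    adjacency: pd.DataFrame
    auroc: float
    alpha: float | None
    edges: pd.DataFrame
    enrichment: pd.DataFrame
    tree: str | None
    report: dict[str, Any] = field(default_factory=dict)


def _derive_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(tag,)).generate_state(1)[0] % (2**31))


def holdout_auroc(
    proteins: dict[str, ppi.ProteinRecord],
    truth: sim.GroundTruth,
    positives: list[tuple[str, str]],
    config: PipelineConfig,
    test_fraction: float = 0.35,
    n_test_pairs: int = 60,
) -> float:
    """Held-out classifier performance on a protein-disjoint split.

    Proteins are split into a training and a held-out set; the model is
    trained on the given positive pairs falling inside the training set
    (plus a balanced disjoint-localization negative sample) and evaluated
    on freshly sampled positive and negative pairs among held-out proteins.
    The protein-level split prevents the classifier from scoring test
    pairs by recognizing individual training proteins.
    """
    rng = np.random.default_rng(_derive_seed(config.seed, 41))
    ids = sorted(proteins)
    perm = rng.permutation(len(ids))
    n_test = int(test_fraction * len(ids))
    test_ids = {ids[i] for i in perm[:n_test]}
    train_ids = {ids[i] for i in perm[n_test:]}

    train_pos = [p for p in positives if p[0] in train_ids and p[1] in train_ids]
    train_proteins = {i: proteins[i] for i in train_ids}
    negatives = ppi.build_negative_set(
        train_proteins, positives, n=len(train_pos), seed=_derive_seed(config.seed, 42)
    )
    dataset = ppi.PPIDataset(
        pairs=[(a, b, ppi.POSITIVE) for a, b in train_pos] + negatives.pairs,
        provenance="holdout-train",
    )
    model = ppi.train_classifier(
        dataset, proteins, config.ppi, grid_search=config.grid_search,
        seed=_derive_seed(config.seed, 43),
    )

    test_same = [
        (a, b)
        for a, b in combinations(sorted(test_ids), 2)
        if truth.interacts(a, b)
    ]
    if not test_same:
        raise ValueError("no held-out positive pairs available")
    n_pos = min(n_test_pairs, len(test_same))
    pos_idx = rng.choice(len(test_same), size=n_pos, replace=False)
    test_pos = [test_same[i] for i in sorted(pos_idx)]
    test_proteins = {i: proteins[i] for i in test_ids}
    test_neg = ppi.build_negative_set(
        test_proteins, positives + test_pos, n=n_pos,
        seed=_derive_seed(config.seed, 44),
    ).pairs
    pairs = test_pos + [(a, b) for a, b, _ in test_neg]
    y = np.array([1] * len(test_pos) + [0] * len(test_neg))
    scores = model.decision_scores(pairs, proteins)
    return float(roc_auc_score(y, scores))


def _checkpoint_simulation(outdir: Path, expr, truth, proteins, positives, annotations):
    fio.write_expression(outdir / "expression.tsv", expr.values)
    fio.write_trait(outdir / "trait.tsv", expr.trait)
    fio.write_fasta(outdir / "proteins.fasta", {p.id: p.sequence for p in proteins.values()})
    fio.write_pairs(outdir / "positive_pairs.tsv", positives)
    fio.write_localizations(
        outdir / "localizations.tsv", {p.id: p.localizations for p in proteins.values()}
    )
    fio.write_annotations(outdir / "annotations.tsv", annotations)
    (outdir / "ground_truth.json").write_text(
        json.dumps(
            {
                "gene_modules": truth.gene_modules,
                "protein_families": {
                    k: v for k, v in truth.protein_families.items()
                },
                "module_terms": truth.module_terms,
            },
            indent=2,
            sort_keys=True,
        )
    )


def run_all(config: PipelineConfig, outdir: str | Path) -> RunResult:
    """Run every stage in order, checkpointing artifacts under ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.simulation.seed = config.seed

    # ------------------------------------------------------------------ simulate
    stage = "simulate"
    try:
        expr, truth = sim.generate_expression(config.simulation)
        proteins, positives, ppi_truth = sim.generate_ppi_corpus(config.simulation)
        truth.protein_families.update(ppi_truth.protein_families)
        truth.positive_pairs = positives
        annotations = sim.generate_annotations(config.simulation, truth)
        _checkpoint_simulation(outdir, expr, truth, proteins, positives, annotations)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---------------------------------------------------------------- coexpress
    stage = "coexpress"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            partition, beta, fit_table, adj = cx.analyze(expr, config.network)
        own_kme = pd.Series(
            {
                g: (
                    partition.kme.loc[g, partition.labels[g]]
                    if partition.labels[g] in partition.kme.columns
                    else float("nan")
                )
                for g in partition.labels.index
            }
        )
        pd.DataFrame(
            {
                "gene": partition.labels.index,
                "module": partition.labels.to_numpy(),
                "GS": partition.gs.reindex(partition.labels.index).to_numpy(),
                "kME_own": own_kme.reindex(partition.labels.index).to_numpy(),
            }
        ).to_csv(outdir / "partition.tsv", sep="\t", index=False)
        partition.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t")
        fit_table.to_csv(outdir / "soft_threshold.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---------------------------------------------------------------------- ppi
    stage = "ppi"
    try:
        if any(not p.localizations for p in proteins.values()):
            raise ValueError("localization table missing entries for corpus proteins")
        identity = 0.4 if config.redundancy_filter else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curated, curation_report = ppi.curate_positives(
                positives, proteins, identity_threshold=identity
            )
        negatives = ppi.build_negative_set(
            proteins,
            [(a, b) for a, b, _ in curated.pairs],
            n=len(curated.pairs),
            seed=_derive_seed(config.seed, 21),
        )
        dataset = ppi.PPIDataset(pairs=curated.pairs + negatives.pairs)
        pd.DataFrame(dataset.pairs, columns=["protein_a", "protein_b", "label"]).to_csv(
            outdir / "ppi_dataset.tsv", sep="\t", index=False
        )
        auroc = holdout_auroc(proteins, truth, [(a, b) for a, b, _ in curated.pairs], config)
        model = ppi.train_classifier(
            dataset, proteins, config.ppi, grid_search=config.grid_search,
            seed=_derive_seed(config.seed, 22),
        )

        # seed genes: top hubs of the top-significance module; each seed's
        # planted partners are its most co-expressed unassigned module
        # genes, mirroring the premise that interacting proteins are
        # strongly co-expressed
        top_module = partition.module_significance.index[0]
        members = partition.members(top_module)
        ranked = sorted(members, key=lambda g: (-partition.kme.loc[g, top_module], g))
        n_seed = config.n_seed_genes
        k = config.partners_per_seed
        seeds = ranked[:n_seed]
        assigned = set(seeds)
        groups = []
        for s in seeds:
            pool = [g for g in members if g not in assigned]
            pool.sort(key=lambda g: (-float(adj.loc[s, g]), g))
            partners = pool[:k]
            assigned.update(partners)
            groups.append([s] + partners)
        grouped = {g for grp in groups for g in grp}
        background_genes = [g for g in partition.labels.index if g not in grouped]
        gene_proteins, _, gene_truth = sim.generate_ppi_corpus(
            config.simulation, groups=groups, background_ids=background_genes, stream=1
        )
        truth.protein_families.update(gene_truth.protein_families)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            edges, thr = ppi.module_subnetwork(
                seeds,
                members,
                adj,
                model,
                gene_proteins,
                alpha_override=config.alpha_override,
                reference_genes=list(partition.labels.index),
            )
        alpha = (
            config.alpha_override
            if config.alpha_override is not None
            else (thr.alpha if thr is not None else None)
        )
        edges.to_csv(outdir / "predicted_edges.tsv", sep="\t", index=False)
        fio.write_fasta(
            outdir / "gene_proteins.fasta",
            {p.id: p.sequence for p in gene_proteins.values()},
        )
        fio.write_localizations(
            outdir / "gene_localizations.tsv",
            {p.id: p.localizations for p in gene_proteins.values()},
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ------------------------------------------------------------------- enrich
    stage = "enrich"
    try:
        universe = set(partition.labels.index)
        ann_set = en.AnnotationSet(universe=universe, terms=annotations)
        module_members = {m: set(partition.members(m)) for m in partition.modules()}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            enrichment_table = en.enrich_partition(module_members, ann_set, config.enrichment)
        enrichment_table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -------------------------------------------------------------------- phylo
    stage = "phylo"
    try:
        candidates = sorted(set(edges["candidate"])) if len(edges) else []
        phylo_taxa = seeds + [c for c in candidates if c not in seeds]
        tree = None
        nearest: dict[str, str] = {}
        if len(phylo_taxa) >= 3:
            profiles = [
                ph.composition_profile(g, [gene_proteins[g].sequence], k=config.phylo.k)
                for g in phylo_taxa
            ]
            dm = ph.build_distance_matrix(profiles)
            tree = ph.build_tree(dm, method=config.phylo.method)
            (outdir / "tree.nwk").write_text(tree + "\n")
            fio.write_phylip_distances(outdir / "cv_distances.phylip", dm.taxa, dm.matrix)
            idx = {t: i for i, t in enumerate(dm.taxa)}
            for c in candidates:
                dists = [(dm.matrix[idx[c], idx[s]], s) for s in seeds if s != c]
                nearest[c] = min(dists)[1] if dists else ""
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ------------------------------------------------------------------- report
    stage = "report"
    try:
        ms_rank = {m: r + 1 for r, m in enumerate(partition.module_significance.index)}
        rows = []
        for c in candidates:
            sub = edges[edges["candidate"] == c]
            module = partition.labels[c]
            rows.append(
                {
                    "gene": c,
                    "module": module,
                    "module_significance_rank": ms_rank.get(module),
                    "module_significance": float(
                        partition.module_significance.get(module, float("nan"))
                    ),
                    "GS": float(partition.gs[c]),
                    "kME": float(partition.kme.loc[c, module])
                    if module in partition.kme.columns
                    else None,
                    "predicted_partners": sorted(set(sub["seed"])),
                    "colocalized": bool(sub["colocalized"].all()),
                    "svm_score": float(sub["score"].max()),
                    "nearest_seed": nearest.get(c, ""),
                }
            )
        rows.sort(
            key=lambda r: (
                -r["module_significance"],
                -(r["kME"] if r["kME"] is not None else -1.0),
                -r["svm_score"],
                r["gene"],
            )
        )
        report = {
            "parameters": {
                "seed": config.seed,
                "beta": beta,
                "alpha": alpha,
                "svm_c": config.ppi.svm_c,
                "svm_gamma": config.ppi.svm_gamma,
                "kappa_threshold": config.enrichment.kappa_threshold,
                "k_tuple": config.phylo.k,
            },
            "coexpression": {
                "n_genes_retained": int(partition.labels.size),
                "modules": {
                    m: int((partition.labels == m).sum()) for m in partition.modules()
                },
                "n_grey": int((partition.labels == cx.GREY).sum()),
                "module_significance": {
                    m: float(v) for m, v in partition.module_significance.items()
                },
                "top_module": top_module,
            },
            "ppi": {
                "curation": curation_report,
                "n_training_pairs": len(dataset.pairs),
                "holdout_auroc": auroc,
                "seed_genes": seeds,
                "n_predicted_edges": int(len(edges)),
            },
            "enrichment": {
                "n_tests": int(len(enrichment_table)),
                "n_overrepresented": int(enrichment_table["overrepresented"].sum())
                if len(enrichment_table)
                else 0,
            },
            "phylo": {"tree": tree},
            "candidates": rows,
        }
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    return RunResult(
        config=config,
        expression=expr,
        truth=truth,
        partition=partition,
        beta=beta,
        adjacency=adj,
        auroc=auroc,
        alpha=alpha,
        edges=edges,
        enrichment=enrichment_table,
        tree=tree,
        report=report,
    )
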