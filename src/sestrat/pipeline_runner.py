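"""End-to-end orchestration of the stratification analysis.

Stage order: consensus clustering of seRNA -> cluster-specific SEs ->
windowed SE-gene linkage (SPGs) -> one-vs-rest differential expression ->
SPG/DEG overlap (SE-regulated genes) -> promoter motif enrichment ->
LASSO core-TF index -> survival validation -> signature scoring. A plain
in-process sequential runner: each stage is a pure function of (inputs,
config, seed); any failure aborts with the stage name and earlier results
are preserved in the partially filled report. SHA-256 hashes of every
written artifact are recorded so re-runs can be verified byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import (
    consensus_clustering as cc,
    diffexpr as dx,
    enrichment as en,
    se_linkage as lk,
    survival_scoring as sv,
    tf_index as ti,
)
from .io_formats import (
    ExprMatrix,
    Pwm,
    SERegion,
    SurvivalRecord,
    TssRecord,
    logger,
)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in ``stage``."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineInputs:
    """The full input bundle (real data or `simulate` output)."""

    se_rna: ExprMatrix
    mrna: ExprMatrix
    se_regions: list[SERegion]
    tss_table: list[TssRecord]
    promoters: dict[str, str]
    pwms: list[Pwm]
    survival: list[SurvivalRecord]
    signature_genes: list[str] = field(default_factory=list)

    @classmethod
    def from_dir(cls, indir: str | Path) -> "PipelineInputs":
        from . import io_formats as iof

        indir = Path(indir)

        def need(name: str) -> Path:
            p = indir / name
            if not p.exists():
                raise FileNotFoundError(f"missing input file {p}")
            return p

        sig_path = indir / "signature_genes.txt"
        signature = (
            [l.strip() for l in sig_path.read_text().splitlines() if l.strip()]
            if sig_path.exists()
            else []
        )
        return cls(
            se_rna=iof.read_expression(need("se_rna.tsv")),
            mrna=iof.read_expression(need("mrna.tsv")),
            se_regions=iof.read_bed(need("se_regions.bed")),
            tss_table=iof.read_tss(need("tss.tsv")),
            promoters=iof.read_fasta(need("promoters.fasta")),
            pwms=iof.read_pwm_library(need("motifs.pfm")),
            survival=iof.read_survival(need("survival.tsv")),
            signature_genes=signature,
        )

    @classmethod
    def from_cohort(cls, cohort) -> "PipelineInputs":
        return cls(
            se_rna=cohort.se_rna,
            mrna=cohort.mrna,
            se_regions=cohort.se_regions,
            tss_table=cohort.tss_table,
            promoters=cohort.promoters,
            pwms=cohort.pwms,
            survival=cohort.survival,
            signature_genes=list(cohort.truth.get("signature_genes", [])),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _worst_prognosis_cluster(
    records: Sequence[SurvivalRecord], labels: np.ndarray, sample_ids: Sequence[str]
) -> int:
    """Cluster with the lowest restricted mean survival time."""
    by_sample = dict(zip(sample_ids, labels))
    horizon = max(r.time for r in records)
    rmst: dict[int, float] = {}
    for c in sorted(set(int(x) for x in labels)):
        recs = [r for r in records if by_sample.get(r.sample_id) == c]
        curve = sv.km_estimate(recs)
        ts = np.concatenate([[0.0], curve.event_times, [horizon]])
        ss = np.concatenate([[1.0], curve.survival_probs, [curve.survival_probs[-1] if len(curve.survival_probs) else 1.0]])
        rmst[c] = float(np.sum(ss[:-1] * np.diff(ts)))
    return min(rmst, key=rmst.get)


def run_all(
    inputs: PipelineInputs,
    config: Mapping,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> dict:
    """Run the full pipeline; returns the structured run report (JSON-able)."""
    cfg = dict(config)
    report: dict = {"seed": seed, "config": cfg, "artifact_hashes": {}}
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def record(name: str, path: Path) -> None:
        report["artifact_hashes"][name] = _sha256(path)

    sample_ids = inputs.se_rna.sample_ids

    # --- stage: cluster ----------------------------------------------------
    stage = "cluster"
    try:
        X = cc.prepare_features(inputs.se_rna, top_n=cfg["top_features"])
        sweep = cc.run_consensus_sweep(
            X,
            range(cfg["k_min"], cfg["k_max"] + 1),
            n_resamples=cfg["n_resamples"],
            subsample_frac=cfg["subsample_frac"],
            seed=seed,
            n_init=cfg["kmeans_n_init"],
            pac_lower=cfg["pac_lower"],
            pac_upper=cfg["pac_upper"],
        )
        for res in sweep.values():
            res.validate()
        k = cc.select_k(sweep)
        labels = sweep[k].labels
        report["chosen_k"] = int(k)
        report["pac_by_k"] = {int(kk): sweep[kk].pac for kk in sweep}
        report["cluster_sizes"] = {
            int(c): int(n) for c, n in zip(*np.unique(labels, return_counts=True))
        }
        if out is not None:
            p = out / "labels.tsv"
            with open(p, "w") as fh:
                fh.write("sample_id\tcluster\n")
                for s, l in zip(sample_ids, labels):
                    fh.write(f"{s}\t{int(l)}\n")
            record("labels.tsv", p)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    clusters = sorted(int(c) for c in np.unique(labels))

    # --- stage: cluster-specific SEs ---------------------------------------
    stage = "specific_ses"
    try:
        specific_ses = {
            c: lk.cluster_specific_ses(
                inputs.se_rna, labels, c,
                q_max=cfg["de_q_max"], lfc_min=cfg["de_lfc_min"],
            )
            for c in clusters
        }
        report["specific_se_counts"] = {c: len(s) for c, s in specific_ses.items()}
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- stage: link (SPGs) -------------------------------------------------
    stage = "link"
    try:
        region_by_id = {r.se_id: r for r in inputs.se_regions}
        spgs: dict[int, set[str]] = {}
        all_links = []
        for c in clusters:
            regions = [region_by_id[s] for s in specific_ses[c] if s in region_by_id]
            pairs = lk.candidate_pairs(regions, inputs.tss_table, cfg["window_bp"])
            links = lk.correlate_links(
                pairs, inputs.se_rna, inputs.mrna, method=cfg["corr_method"]
            )
            spgs[c] = lk.define_spgs(
                links, rho_min=cfg["rho_min"], q_max=cfg["link_q_max"],
                sign=cfg["link_sign"],
            )
            all_links.extend((c, l) for l in links)
        report["spg_counts"] = {c: len(s) for c, s in spgs.items()}
        if out is not None:
            p = out / "links.tsv"
            with open(p, "w") as fh:
                fh.write("cluster\tse_id\tgene_id\tdistance_bp\trho\tp\tq\n")
                for c, l in all_links:
                    fh.write(
                        f"{c}\t{l.se_id}\t{l.gene_id}\t{l.distance_bp}\t"
                        f"{l.rho:.6g}\t{l.p:.6g}\t{l.q:.6g}\n"
                    )
            record("links.tsv", p)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- stage: de ----------------------------------------------------------
    stage = "de"
    try:
        deg_up: dict[int, set[str]] = {}
        deg_down: dict[int, set[str]] = {}
        for c in clusters:
            res = dx.de_test(inputs.mrna, labels, c)
            deg_up[c], deg_down[c] = dx.deg_sets(
                res, q_max=cfg["de_q_max"], lfc_min=cfg["de_lfc_min"]
            )
        report["deg_counts"] = {
            c: {"up": len(deg_up[c]), "down": len(deg_down[c])} for c in clusters
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- stage: overlap (SE-regulated genes) --------------------------------
    stage = "overlap"
    try:
        universe = set(inputs.mrna.feature_ids)
        se_regulated: dict[int, set[str]] = {}
        report["se_regulated"] = {}
        for c in clusters:
            direction = "up" if len(spgs[c] & deg_up[c]) >= len(spgs[c] & deg_down[c]) else "down"
            genes, ov = en.se_regulated_genes(
                spgs[c], deg_up[c], deg_down[c], direction, universe
            )
            se_regulated[c] = genes
            report["se_regulated"][c] = {
                "direction": direction,
                "n_genes": len(genes),
                "overlap_p": ov.p,
                "odds_ratio": ov.odds_ratio,
            }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- stage: enrich ------------------------------------------------------
    stage = "enrich"
    try:
        if not inputs.promoters:
            raise ValueError("no promoter sequences supplied")
        candidate_tfs: set[str] = set()
        report["motif_enrichment"] = {}
        for c in clusters:
            enr = en.motif_enrichment(
                se_regulated[c], inputs.promoters, inputs.pwms,
                threshold_frac=cfg["pwm_threshold_frac"],
            )
            enr.sort(key=lambda r: (r.q, r.p))
            sig = [r for r in enr if r.q <= cfg["motif_q_max"]]
            candidate_tfs.update(r.motif_id for r in sig)
            report["motif_enrichment"][c] = [
                {"motif_id": r.motif_id, "q": r.q, "odds_ratio": r.odds_ratio}
                for r in enr[:5]
            ]
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- stage: index -------------------------------------------------------
    stage = "index"
    try:
        # motif ids name TF genes: the candidate panel is their expression rows
        panel = sorted(t for t in candidate_tfs if t in set(inputs.mrna.feature_ids))
        if len(panel) < 2:
            raise ValueError(
                f"candidate TF panel too small ({len(panel)}); "
                "no index can be fit"
            )
        worst = _worst_prognosis_cluster(inputs.survival, labels, sample_ids)
        model = ti.fit_core_tfs(
            inputs.mrna.subset_features(panel), labels,
            n_folds=cfg["cv_folds"], seed=seed, index_cluster=worst,
        )
        index_vals = ti.build_tf_index(model, inputs.mrna)
        predicted = ti.predict_clusters(model, inputs.mrna)
        report["core_tfs"] = {c: model.core_tfs[c] for c in clusters}
        report["selected_tfs"] = model.selected_tfs
        report["index_cluster"] = int(worst)
        report["index_summary"] = {
            "mean": float(np.mean(index_vals)),
            "sd": float(np.std(index_vals)),
        }
        if out is not None:
            p = out / "index.tsv"
            with open(p, "w") as fh:
                fh.write("sample_id\tindex\tpredicted_cluster\n")
                for s, v, pc in zip(sample_ids, index_vals, predicted):
                    fh.write(f"{s}\t{v:.6g}\t{int(pc)}\n")
            record("index.tsv", p)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- stage: survival ----------------------------------------------------
    stage = "survival"
    try:
        label_groups = dict(zip(sample_ids, (int(l) for l in labels)))
        _, lr_clusters = sv.stratified_km_report(inputs.survival, groups=label_groups)
        index_map = dict(zip(sample_ids, index_vals))
        _, lr_index = sv.stratified_km_report(
            inputs.survival, index=index_map, cut_rule=cfg["index_cut"]
        )
        pred_groups = dict(zip(sample_ids, (int(l) for l in predicted)))
        if len(set(pred_groups.values())) >= 2:
            _, lr_pred = sv.stratified_km_report(inputs.survival, groups=pred_groups)
            pred_res = {"chi2": lr_pred.chi2, "df": lr_pred.df, "p": lr_pred.p}
        else:
            pred_res = None
            logger.warning("all samples predicted into one cluster; no log-rank")
        report["logrank"] = {
            "clusters": {"chi2": lr_clusters.chi2, "df": lr_clusters.df, "p": lr_clusters.p},
            "index_median_split": {"chi2": lr_index.chi2, "df": lr_index.df, "p": lr_index.p},
            "predicted_clusters": pred_res,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- stage: score -------------------------------------------------------
    stage = "score"
    try:
        if inputs.signature_genes:
            scores = sv.signature_score(inputs.mrna, inputs.signature_genes)
            by_sample = {s.sample_id: s.score for s in scores}
            per_cluster = {
                c: float(np.mean([by_sample[s] for s, l in zip(sample_ids, labels) if l == c]))
                for c in clusters
            }
            report["signature_scores"] = {
                "n_genes_used": scores[0].n_genes_used,
                "mean_by_cluster": per_cluster,
            }
        else:
            report["signature_scores"] = None
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    if out is not None:
        p = out / "report.json"
        with open(p, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")
    return report
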