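"""Synthetic cohort generator.

Emulates the statistical structure of a super-enhancer-RNA tumor cohort:
``k`` latent clusters with cluster-specific active SE sets, positively
correlated SE -> target-gene pairs within a genomic window, cluster-specific
differentially expressed genes, driver transcription factors whose binding
motifs are planted in the promoters of SE-regulated genes, a planted
glycolysis-like gene signature, and cluster-dependent survival hazards with
right censoring.

Raw-scale expression is log-normal; every planted effect is an additive mean
shift on the log2 scale, expressed in units of the within-cluster standard
deviation (which is 1 by construction). Each cluster's active SEs and their
target genes live on their own synthetic chromosome with deterministic
spacing; decoy genes sit just beyond the linkage window so window-boundary
behavior is unambiguous. A single global seed is expanded into per-component
substreams, so adding a component never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .io_formats import (
    ALPHABET,
    ExprMatrix,
    Pwm,
    SERegion,
    SurvivalRecord,
    TssRecord,
    logger,
)

import json
import pandas as pd


class ConfigError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults correspond to the study conditions the downstream recovery
    analyses assume: three clusters of 300 tumors, 500 SE loci of which 20
    per cluster are specifically active with a 2-SD activation effect,
    linked target genes within a 500 kb window, 20 candidate TFs with one
    planted driver per cluster, and a 22-gene signature elevated by 1 SD in
    the worst-prognosis cluster.
    """

    n_samples: int = 300
    n_clusters: int = 3
    cluster_proportions: Sequence[float] | None = None
    n_se: int = 500
    n_active_se_per_cluster: int = 20
    n_genes: int = 400
    n_linked_genes_per_cluster: int = 30
    n_candidate_tfs: int = 20
    n_driver_tfs_per_cluster: int = 1
    se_activation_effect: float = 2.0
    link_noise_sd: float = 0.5
    baseline_hazard: Sequence[float] = (0.02, 0.02, 0.08)
    censor_rate: float = 0.2
    window_bp: int = 500_000
    promoter_len: int = 600
    motif_plant_rate: float = 0.8
    motif_len: int = 8
    n_signature_genes: int = 22
    signature_effect: float = 1.0
    seed: int = 0

    # layout constants (bp)
    se_len: int = 10_000
    se_spacing: int = 1_200_000
    gene_offset0: int = 20_000
    gene_spacing: int = 40_000

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be >= 1")
        if self.cluster_proportions is None:
            self.cluster_proportions = [1.0 / self.n_clusters] * self.n_clusters
        props = np.asarray(self.cluster_proportions, dtype=float)
        if len(props) != self.n_clusters or not np.isclose(props.sum(), 1.0):
            raise ConfigError("cluster_proportions must have length k and sum to 1")
        if not 0 <= self.censor_rate < 1:
            raise ConfigError("censor_rate must be in [0, 1)")
        if len(self.baseline_hazard) != self.n_clusters:
            raise ConfigError("need one baseline hazard per cluster")
        if any(h <= 0 for h in self.baseline_hazard):
            raise ConfigError("baseline hazards must be > 0")
        for name in (
            "n_samples", "n_se", "n_active_se_per_cluster", "n_genes",
            "n_linked_genes_per_cluster", "n_candidate_tfs",
            "n_driver_tfs_per_cluster", "window_bp", "promoter_len",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_clusters * self.n_active_se_per_cluster > self.n_se:
            raise ConfigError("more active SEs requested than total SEs")
        needed = (
            self.n_clusters * self.n_linked_genes_per_cluster
            + self.n_candidate_tfs
            + self.n_signature_genes
        )
        if needed > self.n_genes:
            raise ConfigError(
                f"n_genes={self.n_genes} too small for {needed} planted genes"
            )
        genes_per_se = -(-self.n_linked_genes_per_cluster // self.n_active_se_per_cluster)
        max_offset = self.gene_offset0 + (genes_per_se - 1) * self.gene_spacing
        if max_offset > self.window_bp:
            raise ConfigError(
                "layout infeasible: linked-gene offsets exceed window_bp "
                f"({max_offset} > {self.window_bp})"
            )
        if self.motif_len > self.promoter_len:
            raise ConfigError("motif longer than promoter")
        if not 0 < self.motif_plant_rate <= 1:
            raise ConfigError("motif_plant_rate must be in (0, 1]")


@dataclass
class SyntheticCohort:
    """A generated cohort plus complete ground-truth bookkeeping."""

    se_rna: ExprMatrix
    mrna: ExprMatrix
    se_regions: list[SERegion]
    tss_table: list[TssRecord]
    promoters: dict[str, str]
    pwms: list[Pwm]
    survival: list[SurvivalRecord]
    truth: dict
    config: CohortConfig


def _cluster_sizes(n: int, props: Sequence[float]) -> list[int]:
    sizes = [int(np.floor(p * n)) for p in props]
    for i in range(n - sum(sizes)):
        sizes[i % len(sizes)] += 1
    return sizes


def plant_motif(sequence: str, pwm: Pwm, position: int) -> str:
    """Replace a substring with the PWM consensus (argmax base per position)."""
    cons = pwm.consensus
    if position < 0 or position + len(cons) > len(sequence):
        raise ValueError(
            f"plant position {position} out of range for sequence of length {len(sequence)}"
        )
    return sequence[:position] + cons + sequence[position + len(cons):]


def _solve_censor_horizon(hazards: np.ndarray, censor_rate: float) -> float:
    """Horizon T of Unif(0, T) censoring achieving ``censor_rate`` in expectation.

    For X ~ Exp(lam) and C ~ Unif(0, T), P(C < X) = (1 - exp(-lam*T)) / (lam*T).
    """

    def expected_censor(T: float) -> float:
        lt = hazards * T
        return float(np.mean((1.0 - np.exp(-lt)) / lt))

    lo, hi = 1e-9, 1e9
    return brentq(lambda T: expected_censor(T) - censor_rate, lo, hi, xtol=1e-10)


def generate_survival(
    labels: Sequence[int],
    hazards: Sequence[float],
    censor_rate: float,
    seed: int | np.random.SeedSequence,
    sample_ids: Sequence[str] | None = None,
) -> list[SurvivalRecord]:
    """Exponential event times with cluster-specific hazards and uniform censoring.

    ``labels`` are 1-based cluster assignments; ``hazards[c-1]`` is cluster
    c's rate. Censoring times are Unif(0, T) with T solved so the expected
    censoring fraction equals ``censor_rate``; censoring is independent of
    the event time.
    """
    labels = np.asarray(labels, dtype=int)
    hazards = np.asarray(hazards, dtype=float)
    if (hazards <= 0).any():
        raise ValueError("hazards must be > 0")
    rng = np.random.default_rng(seed)
    lam = hazards[labels - 1]
    event_t = rng.exponential(1.0 / lam)
    if censor_rate == 0:
        time, event = event_t, np.ones(len(labels), dtype=int)
    else:
        horizon = _solve_censor_horizon(lam, censor_rate)
        censor_t = rng.uniform(0.0, horizon, size=len(labels))
        event = (event_t <= censor_t).astype(int)
        time = np.minimum(event_t, censor_t)
    time = np.maximum(time, 1e-9)  # guard strict positivity
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(len(labels))]
    return [
        SurvivalRecord(s, float(t), int(e))
        for s, t, e in zip(sample_ids, time, event)
    ]


def _random_pwms(n: int, motif_len: int, rng: np.random.Generator) -> list[Pwm]:
    """Well-separated informative PWMs (consensus base prob 0.88)."""
    consensi: list[np.ndarray] = []
    while len(consensi) < n:
        cand = rng.integers(0, 4, size=motif_len)
        if all(np.sum(cand != c) >= 3 for c in consensi):
            consensi.append(cand)
    pwms = []
    for i, cons in enumerate(consensi):
        probs = np.full((motif_len, 4), 0.04)
        probs[np.arange(motif_len), cons] = 0.88
        pwms.append(Pwm(f"TF{i + 1:02d}", probs))
    return pwms


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full cohort with ground truth.

    Deterministic given ``config.seed``: the seed is expanded into a fixed
    sequence of per-component substreams (labels, seRNA, mRNA, motifs,
    promoters, planting, survival).
    """
    cfg = config
    k = cfg.n_clusters
    ss = np.random.SeedSequence(cfg.seed)
    (ss_se, ss_mrna, ss_pwm, ss_prom, ss_plant, ss_surv) = ss.spawn(6)

    sample_ids = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    sizes = _cluster_sizes(cfg.n_samples, cfg.cluster_proportions)
    labels = np.repeat(np.arange(1, k + 1), sizes)
    members = {c: np.flatnonzero(labels == c) for c in range(1, k + 1)}

    # --- SE identities, activity assignment and genomic layout -------------
    se_ids = [f"SE{i + 1:04d}" for i in range(cfg.n_se)]
    active: dict[int, list[str]] = {}
    idx = 0
    for c in range(1, k + 1):
        active[c] = se_ids[idx: idx + cfg.n_active_se_per_cluster]
        idx += cfg.n_active_se_per_cluster
    background_ses = se_ids[idx:]

    se_regions: list[SERegion] = []
    se_pos: dict[str, SERegion] = {}
    for c in range(1, k + 1):
        for j, sid in enumerate(active[c]):
            start = 1_000_000 + j * cfg.se_spacing
            reg = SERegion(sid, f"chrS{c}", start, start + cfg.se_len)
            se_regions.append(reg)
            se_pos[sid] = reg
    for j, sid in enumerate(background_ses):
        start = 1_000_000 + j * cfg.se_spacing * 2
        reg = SERegion(sid, "chrB", start, start + cfg.se_len)
        se_regions.append(reg)
        se_pos[sid] = reg

    # --- seRNA expression: log-normal baseline + cluster activation --------
    rng_se = np.random.default_rng(ss_se)
    se_mu = rng_se.normal(5.0, 1.0, size=cfg.n_se)
    se_log = se_mu[:, None] + rng_se.normal(0.0, 1.0, size=(cfg.n_se, cfg.n_samples))
    se_index = {sid: i for i, sid in enumerate(se_ids)}
    for c in range(1, k + 1):
        rows = [se_index[s] for s in active[c]]
        se_log[np.ix_(rows, members[c])] += cfg.se_activation_effect
    se_raw = np.exp2(se_log)
    se_rna = ExprMatrix(pd.DataFrame(se_raw, index=se_ids, columns=sample_ids))

    # --- gene identities ----------------------------------------------------
    linked: dict[int, list[str]] = {}
    links: list[dict] = []
    gid = 0

    def next_gene(prefix: str = "G") -> str:
        nonlocal gid
        gid += 1
        return f"{prefix}{gid:04d}"

    tss_table: list[TssRecord] = []
    genes_per_se = -(-cfg.n_linked_genes_per_cluster // cfg.n_active_se_per_cluster)
    for c in range(1, k + 1):
        linked[c] = []
        gi = 0
        for j, sid in enumerate(active[c]):
            for slot in range(genes_per_se):
                if gi >= cfg.n_linked_genes_per_cluster:
                    break
                g = next_gene()
                reg = se_pos[sid]
                tss = reg.start + cfg.gene_offset0 + slot * cfg.gene_spacing
                tss_table.append(TssRecord(g, reg.chrom, tss, "+"))
                linked[c].append(g)
                links.append({"se_id": sid, "gene_id": g, "cluster": c})
                gi += 1

    tf_ids = [f"TF{i + 1:02d}" for i in range(cfg.n_candidate_tfs)]
    for i, t in enumerate(tf_ids):
        tss_table.append(TssRecord(t, "chrTF", 1_000_000 + i * 100_000, "+"))
    drivers: dict[int, list[str]] = {}
    ti = 0
    for c in range(1, k + 1):
        drivers[c] = tf_ids[ti: ti + cfg.n_driver_tfs_per_cluster]
        ti += cfg.n_driver_tfs_per_cluster

    signature_cluster = int(np.argmax(cfg.baseline_hazard)) + 1
    signature_genes = [next_gene("SIG") for _ in range(cfg.n_signature_genes)]
    n_planted = gid
    n_decoys = cfg.n_genes - (k * cfg.n_linked_genes_per_cluster
                              + cfg.n_candidate_tfs + cfg.n_signature_genes)
    decoy_genes = [next_gene("D") for _ in range(n_decoys)]
    # decoys just beyond the window of background SEs; signature genes on chrB too
    bg_cursor = 0
    for i, g in enumerate(signature_genes + decoy_genes):
        if background_ses:
            ref = se_pos[background_ses[bg_cursor % len(background_ses)]]
            tss = ref.end + cfg.window_bp + 10_000 + (i // len(background_ses)) * 1_000
            bg_cursor += 1
            tss_table.append(TssRecord(g, ref.chrom, tss, "+"))
        else:
            tss_table.append(TssRecord(g, "chrB", 10_000_000 + i * 1_000, "+"))

    all_genes = [r.gene_id for r in tss_table]
    gene_index = {g: i for i, g in enumerate(all_genes)}

    # --- mRNA expression ----------------------------------------------------
    rng_m = np.random.default_rng(ss_mrna)
    mrna_log = (
        rng_m.normal(5.0, 1.0, size=len(all_genes))[:, None]
        + rng_m.normal(0.0, 1.0, size=(len(all_genes), cfg.n_samples))
    )
    # linked genes: mrna = a * seRNA + noise on log2 scale (a = 1), centered to
    # keep gene baselines on the same scale as the rest of the transcriptome
    for link in links:
        gi_, si_ = gene_index[link["gene_id"]], se_index[link["se_id"]]
        noise = rng_m.normal(0.0, cfg.link_noise_sd, size=cfg.n_samples)
        mrna_log[gi_] = 1.0 * se_log[si_] + noise
    for c in range(1, k + 1):
        for t in drivers[c]:
            mrna_log[gene_index[t], members[c]] += cfg.se_activation_effect
    for g in signature_genes:
        mrna_log[gene_index[g], members[signature_cluster]] += cfg.signature_effect
    mrna = ExprMatrix(pd.DataFrame(np.exp2(mrna_log), index=all_genes, columns=sample_ids))

    # --- motifs and promoters ----------------------------------------------
    rng_pwm = np.random.default_rng(ss_pwm)
    pwms = _random_pwms(cfg.n_candidate_tfs, cfg.motif_len, rng_pwm)
    pwm_by_id = {p.motif_id: p for p in pwms}

    rng_prom = np.random.default_rng(ss_prom)
    bases = np.array(list(ALPHABET))
    promoters = {
        g: "".join(bases[rng_prom.integers(0, 4, size=cfg.promoter_len)])
        for g in all_genes
    }

    rng_plant = np.random.default_rng(ss_plant)
    planted_positions: dict[str, list[dict]] = {}
    for c in range(1, k + 1):
        genes = linked[c]
        n_plant = int(np.ceil(cfg.motif_plant_rate * len(genes)))
        chosen = rng_plant.choice(len(genes), size=n_plant, replace=False)
        for t in drivers[c]:
            pwm = pwm_by_id[t]
            for gi_ in chosen:
                g = genes[gi_]
                pos = int(rng_plant.integers(0, cfg.promoter_len - len(pwm) + 1))
                promoters[g] = plant_motif(promoters[g], pwm, pos)
                planted_positions.setdefault(g, []).append(
                    {"motif_id": t, "position": pos}
                )

    # --- survival -----------------------------------------------------------
    survival = generate_survival(
        labels, cfg.baseline_hazard, cfg.censor_rate, ss_surv, sample_ids
    )

    de_genes = {c: sorted(linked[c]) + sorted(drivers[c]) for c in range(1, k + 1)}
    truth = {
        "labels": {s: int(c) for s, c in zip(sample_ids, labels)},
        "active_ses": {str(c): list(active[c]) for c in range(1, k + 1)},
        "links": links,
        "de_genes": {str(c): de_genes[c] for c in range(1, k + 1)},
        "driver_tfs": {str(c): list(drivers[c]) for c in range(1, k + 1)},
        "signature_genes": signature_genes,
        "signature_cluster": signature_cluster,
        "planted_motif_positions": planted_positions,
    }
    return SyntheticCohort(
        se_rna=se_rna,
        mrna=mrna,
        se_regions=se_regions,
        tss_table=tss_table,
        promoters=promoters,
        pwms=pwms,
        survival=survival,
        truth=truth,
        config=cfg,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write all cohort files (the `simulate` CLI output set)."""
    from . import io_formats as iof

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "se_rna": outdir / "se_rna.tsv",
        "mrna": outdir / "mrna.tsv",
        "se_regions": outdir / "se_regions.bed",
        "tss": outdir / "tss.tsv",
        "promoters": outdir / "promoters.fasta",
        "motifs": outdir / "motifs.pfm",
        "survival": outdir / "survival.tsv",
        "truth": outdir / "truth.json",
    }
    iof.write_expression(cohort.se_rna, paths["se_rna"])
    iof.write_expression(cohort.mrna, paths["mrna"])
    iof.write_bed(cohort.se_regions, paths["se_regions"])
    iof.write_tss(cohort.tss_table, paths["tss"])
    iof.write_fasta(cohort.promoters, paths["promoters"])
    iof.write_pwm_library(cohort.pwms, paths["motifs"])
    iof.write_survival(cohort.survival, paths["survival"])
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
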