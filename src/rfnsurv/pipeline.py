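"""End-to-end screen: preprocessing, repeated biclustering, survival gates.

The full protocol, on (expression Z-scores, mutation list, clinical
survival) for one cohort:

1. keep genes with at least one mutation record and samples with survival
   information; map Z-scores into [0, 1] (0 = no change or down-regulated,
   1 = strongly up-regulated);
2. split samples 90/10 into training and validation;
3. many times over: subsample ``samples_per_run`` training samples, fit the
   rectified factor network on the (per-gene mean-centered) submatrix,
   extract candidate biclusters, keep the density-significant ones, and
   keep those whose gene set separates training survival in the repeated
   log-rank screen;
4. merge recurring gene sets across iterations (Jaccard matching), and
   promote to biomarkers the sets that also separate survival on the
   held-out validation split.

Validation samples never reach the factor fit or the training survival
screen; they are touched only in step 4.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .bicluster import (
    ExtractionThresholds,
    SignificanceParams,
    biclusters_to_tsv,
    extract_biclusters,
    filter_significant,
    score_bicluster,
)
from .rfn import EMConfig, fit_rfn
from .survival import (
    SurvivalRecord,
    assign_groups,
    km_curve_to_tsv,
    km_estimate,
    logrank_test,
    multisample_survival_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "RunConfig",
    "BiomarkerSet",
    "IterationResult",
    "normalize_expression",
    "preprocess",
    "split_train_validation",
    "run_iteration",
    "aggregate_biomarkers",
    "run_screen",
]


@dataclass
class Dataset:
    """Normalized cohort: expression in [0,1] plus survival per sample."""

    V_norm: pd.DataFrame  # genes x samples, values in [0, 1]
    survival: dict[str, SurvivalRecord]

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.V_norm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.V_norm.columns)

    def records_for(self, sample_ids) -> tuple[np.ndarray, np.ndarray]:
        t = np.array([self.survival[s].time for s in sample_ids])
        e = np.array([self.survival[s].event for s in sample_ids])
        return t, e

    def subset(self, sample_ids) -> "Dataset":
        ids = list(sample_ids)
        return Dataset(
            V_norm=self.V_norm[ids],
            survival={s: self.survival[s] for s in ids},
        )


@dataclass
class RunConfig:
    """Every tunable of the screen, with the protocol defaults."""

    n_iterations: int = 100
    samples_per_run: int = 100
    train_frac: float = 0.9
    r: int = 10
    thresholds: ExtractionThresholds = field(default_factory=ExtractionThresholds)
    p_star: float = 0.05
    alpha: float = 0.05
    min_nonzero_ratio: float = 0.5
    tau_up: float = 0.5
    frac: float = 0.8
    reps: int = 100
    pass_frac: float = 0.8
    match_jaccard: float = 0.8
    z_cap: float = 2.0
    em: EMConfig = field(default_factory=EMConfig)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


@dataclass(frozen=True)
class BiomarkerSet:
    """A recurring, survival-validated bicluster gene set."""

    genes: frozenset[str]
    occurrences: int
    train_pass_rate: float
    validation_p: float
    rank: int = 0


@dataclass
class IterationResult:
    """Survival-passing gene sets of one sampling iteration (for aggregation)."""

    gene_sets: list[frozenset[str]]
    pass_rates: list[float]
    sampled_ids: list[str]
    n_candidates: int = 0
    n_significant: int = 0


def normalize_expression(Z: pd.DataFrame, z_cap: float = 2.0) -> pd.DataFrame:
    """Map Z-scores into [0,1]: clamp to [0, z_cap], divide by z_cap.

    Non-positive scores (no change or down-regulation) map to 0, scores at
    or above ``z_cap`` map to 1.  NaNs are imputed as 0 (no change) with a
    logged count.
    """
    n_nan = int(Z.isna().to_numpy().sum())
    if n_nan:
        logger.warning("imputing %d NaN expression values as 0 (no change)", n_nan)
        Z = Z.fillna(0.0)
    return Z.clip(lower=0.0, upper=z_cap) / z_cap


def preprocess(
    expression: pd.DataFrame,
    mutations: pd.DataFrame,
    clinical: list[SurvivalRecord],
    config: RunConfig | None = None,
) -> Dataset:
    """Intersect the three inputs and normalize.

    Keeps genes with >= 1 mutation record and samples present in both the
    expression matrix and the clinical table.  Duplicate gene symbols keep
    the highest-variance row.
    """
    config = config or RunConfig()
    if expression.index.duplicated().any():
        dups = expression.index[expression.index.duplicated()].unique()
        logger.warning("duplicate gene symbols %s: keeping highest-variance rows",
                       list(dups))
        variances = expression.var(axis=1)
        order = np.argsort(-variances.to_numpy(), kind="stable")
        expression = expression.iloc[order]
        expression = expression[~expression.index.duplicated(keep="first")]

    mutated = set(mutations["Hugo_Symbol"].astype(str))
    unknown = mutated - set(expression.index)
    if unknown:
        logger.warning("%d mutated genes absent from the expression matrix; ignored",
                       len(unknown))
    genes = [g for g in expression.index if g in mutated]
    surv = {rec.sample_id: rec for rec in clinical}
    samples = [s for s in expression.columns if s in surv]
    if not samples:
        raise ValueError("no samples shared between expression and clinical inputs")
    if not genes:
        raise ValueError("no expression genes carry a mutation record")
    logger.info("preprocess: kept %d/%d genes, %d/%d samples",
                len(genes), expression.shape[0], len(samples), expression.shape[1])
    V_norm = normalize_expression(expression.loc[genes, samples], config.z_cap)
    return Dataset(V_norm=V_norm, survival={s: surv[s] for s in samples})


def split_train_validation(
    dataset: Dataset, train_frac: float = 0.9, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Random disjoint, exhaustive sample partition, deterministic in seed."""
    ids = dataset.sample_ids
    if len(ids) < 10:
        raise ValueError(f"need at least 10 samples to split, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(len(ids) * train_frac)
    train_ids = sorted(ids[i] for i in perm[:n_train])
    valid_ids = sorted(ids[i] for i in perm[n_train:])
    return dataset.subset(train_ids), dataset.subset(valid_ids)


def run_iteration(
    train: Dataset, config: RunConfig, iter_seed: int
) -> IterationResult:
    """One sampling iteration: subsample, fit, extract, filter, screen.

    The factor network sees only ``samples_per_run`` subsampled training
    columns (per-gene mean-centered); G1/G2 assignment and the repeated
    log-rank screen then use the full training set.
    """
    rng = np.random.default_rng(iter_seed)
    ids = train.sample_ids
    if len(ids) >= config.samples_per_run:
        chosen = sorted(rng.choice(len(ids), size=config.samples_per_run, replace=False))
    else:
        logger.warning("training set smaller than samples_per_run; using all %d samples",
                       len(ids))
        chosen = list(range(len(ids)))
    sampled_ids = [ids[i] for i in chosen]
    V_sub = train.V_norm[sampled_ids].to_numpy(float)
    V_centered = V_sub - V_sub.mean(axis=1, keepdims=True)

    em = EMConfig(
        n_iters=config.em.n_iters,
        psi_floor=config.em.psi_floor,
        dropout_rate=config.em.dropout_rate,
        l1_weight=config.em.l1_weight,
        seed=iter_seed,
        rectify=True,
        tol=config.em.tol,
    )
    fit = fit_rfn(V_centered, config.r, em)

    candidates = extract_biclusters(fit.model.W, fit.means, config.thresholds)
    density = float(np.mean(V_sub > 0))
    if not 0 < density < 1:
        return IterationResult([], [], sampled_ids, n_candidates=len(candidates))
    params = SignificanceParams(
        q=density,
        p_star=config.p_star,
        alpha=config.alpha,
        min_nonzero_ratio=config.min_nonzero_ratio,
    )
    scored = [score_bicluster(c, V_sub, params) for c in candidates]
    significant = filter_significant(scored, params)

    gene_sets: list[frozenset[str]] = []
    pass_rates: list[float] = []
    symbols = train.gene_symbols
    seen: set[frozenset[str]] = set()
    for bc_idx, bc in enumerate(significant):
        genes = frozenset(symbols[g] for g in bc.genes)
        if genes in seen:
            continue
        seen.add(genes)
        split = assign_groups(genes, train.V_norm, config.tau_up, config.frac)
        if len(split.g1) < 2 or len(split.g2) < 2:
            continue
        try:
            passed, rate = multisample_survival_test(
                train.records_for(split.g1),
                train.records_for(split.g2),
                reps=config.reps,
                alpha=config.alpha,
                pass_frac=config.pass_frac,
                seed=(iter_seed, bc_idx),
            )
        except ValueError:
            continue
        if passed:
            gene_sets.append(genes)
            pass_rates.append(rate)
    return IterationResult(
        gene_sets=gene_sets,
        pass_rates=pass_rates,
        sampled_ids=sampled_ids,
        n_candidates=len(candidates),
        n_significant=len(significant),
    )


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def aggregate_biomarkers(
    per_iteration_results: list[IterationResult],
    validation: Dataset,
    config: RunConfig,
) -> list[BiomarkerSet]:
    """Merge recurring gene sets across iterations and validate survival.

    Gene sets are merged greedily: each incoming set joins the existing
    candidate with the highest Jaccard similarity >= ``match_jaccard``
    (merged set = union), otherwise opens a new candidate.  Candidates seen
    in >= 2 iterations are tested once on the validation split (G1/G2
    assignment + log-rank) and kept iff p < alpha; ranked by occurrences
    descending then validation p ascending.
    """
    if not per_iteration_results:
        raise ValueError("no iterations to aggregate")
    candidates: list[dict] = []
    for it_res in per_iteration_results:
        for genes, rate in zip(it_res.gene_sets, it_res.pass_rates):
            best, best_sim = None, 0.0
            for cand in candidates:
                sim = _jaccard(genes, cand["genes"])
                if sim > best_sim:
                    best, best_sim = cand, sim
            if best is not None and best_sim >= config.match_jaccard:
                best["genes"] = best["genes"] | genes
                best["occurrences"] += 1
                best["pass_rates"].append(rate)
            else:
                candidates.append(
                    {"genes": genes, "occurrences": 1, "pass_rates": [rate]}
                )

    kept: list[BiomarkerSet] = []
    for cand in candidates:
        if cand["occurrences"] < 2:
            continue
        genes = cand["genes"]
        try:
            split = assign_groups(genes, validation.V_norm, config.tau_up, config.frac)
            if len(split.g1) < 1 or len(split.g2) < 1:
                continue
            res = logrank_test(
                validation.records_for(split.g1), validation.records_for(split.g2)
            )
        except (ValueError, KeyError):
            logger.info("validation test degenerate for a candidate; dropped")
            continue
        if res.p_value < config.alpha:
            kept.append(
                BiomarkerSet(
                    genes=genes,
                    occurrences=cand["occurrences"],
                    train_pass_rate=float(np.mean(cand["pass_rates"])),
                    validation_p=res.p_value,
                )
            )
    kept.sort(key=lambda b: (-b.occurrences, b.validation_p, sorted(b.genes)))
    return [
        BiomarkerSet(
            genes=b.genes,
            occurrences=b.occurrences,
            train_pass_rate=b.train_pass_rate,
            validation_p=b.validation_p,
            rank=i + 1,
        )
        for i, b in enumerate(kept)
    ]


def _biomarkers_to_tsv(biomarkers: list[BiomarkerSet]) -> str:
    lines = ["rank\tgenes\tn_genes\toccurrences\ttrain_pass_rate\tvalidation_p"]
    for b in biomarkers:
        lines.append(
            f"{b.rank}\t{','.join(sorted(b.genes))}\t{len(b.genes)}"
            f"\t{b.occurrences}\t{b.train_pass_rate:.6g}\t{b.validation_p:.6g}"
        )
    return "\n".join(lines) + "\n"


def run_screen(
    expression: pd.DataFrame,
    mutations: pd.DataFrame,
    clinical: list[SurvivalRecord],
    config: RunConfig,
    out_dir=None,
) -> list[BiomarkerSet]:
    """The whole protocol; optionally writes a report directory.

    The report holds biomarkers.tsv, biclusters.tsv (per-iteration
    survival-passing sets), km_curves/ (per-biomarker G1/G2 curves on the
    full cohort), config.json and run.log.  Outputs are byte-identical
    across reruns with the same inputs and config.
    """
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    log(f"screen: seed={config.seed} iterations={config.n_iterations} "
        f"samples_per_run={config.samples_per_run} r={config.r}")
    dataset = preprocess(expression, mutations, clinical, config)
    log(f"dataset: {dataset.V_norm.shape[0]} genes x {dataset.V_norm.shape[1]} samples")
    train, validation = split_train_validation(dataset, config.train_frac, config.seed)
    log(f"split: {len(train.sample_ids)} train / {len(validation.sample_ids)} validation")

    root_rng = np.random.default_rng(config.seed)
    iter_seeds = root_rng.integers(0, 2**31 - 1, size=config.n_iterations)
    results = []
    for i, iseed in enumerate(iter_seeds):
        res = run_iteration(train, config, int(iseed))
        results.append(res)
        if res.gene_sets:
            log(f"iteration {i}: {res.n_candidates} candidates, "
                f"{res.n_significant} significant, {len(res.gene_sets)} survival-passing")
    biomarkers = aggregate_biomarkers(results, validation, config)
    log(f"biomarkers: {len(biomarkers)} validated gene sets")

    if out_dir is not None:
        out = rio.ensure_dir(out_dir)
        (out / "config.json").write_text(config.to_json() + "\n")
        (out / "biomarkers.tsv").write_text(_biomarkers_to_tsv(biomarkers))
        passing = ["iteration\tgenes\ttrain_pass_rate"]
        for i, res in enumerate(results):
            for genes, rate in zip(res.gene_sets, res.pass_rates):
                passing.append(f"{i}\t{','.join(sorted(genes))}\t{rate:.6g}")
        (out / "biclusters.tsv").write_text("\n".join(passing) + "\n")
        km_dir = rio.ensure_dir(out / "km_curves")
        for b in biomarkers:
            split = assign_groups(b.genes, dataset.V_norm, config.tau_up, config.frac)
            for label, group in (("g1", split.g1), ("g2", split.g2)):
                if not group:
                    continue
                curve = km_estimate(dataset.records_for(group))
                (km_dir / f"set{b.rank}_{label}.tsv").write_text(km_curve_to_tsv(curve))
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return biomarkers
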