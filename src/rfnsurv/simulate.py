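"""Synthetic cohorts with planted biclusters and survival structure.

The generator emulates the statistical shape of the screen's real inputs:
a gene x sample matrix of median Z-scores whose background is
Normal(0, background_noise_sd), with planted up-regulated gene x sample
blocks shifted by z_cap * mean_up (so the [0,1] normalization puts block
entries near mean_up); a mutation list guaranteeing every gene at least
one record; and exponential overall-survival times whose hazard is
multiplied by ``hazard_ratio`` for carriers -- samples belonging to any
survival-linked planted block.  Censoring is independent: each patient is
censored with probability ``censor_rate``, at a uniform fraction of their
event time.  Everything is deterministic given the seed.

Planted gene blocks are kept disjoint so that Jaccard-based recovery
scoring is unambiguous; sample blocks may overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import SurvivalRecord

__all__ = ["BlockSpec", "PlantSpec", "SyntheticDataset", "generate_dataset", "score_recovery"]


@dataclass(frozen=True)
class BlockSpec:
    """One planted bicluster: size, mean up-regulation (on the [0,1] scale
    after normalization), within-block noise, and survival linkage."""

    n_genes: int = 20
    n_samples: int = 30
    mean_up: float = 0.8
    noise_sd: float = 0.1
    survival_linked: bool = True


@dataclass(frozen=True)
class PlantSpec:
    """Study conditions for one synthetic cohort."""

    n_genes: int = 500
    n_samples: int = 200
    biclusters: tuple[BlockSpec, ...] = (BlockSpec(),)
    background_noise_sd: float = 0.5
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.03  # events per month; median ~23 months
    censor_rate: float = 0.1
    z_cap: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(b.n_genes for b in self.biclusters) > self.n_genes:
            raise ValueError("planted gene blocks exceed the matrix")
        if any(b.n_samples > self.n_samples for b in self.biclusters):
            raise ValueError("a planted sample block exceeds the matrix")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.hazard_ratio < 1 or self.baseline_hazard <= 0:
            raise ValueError("hazard_ratio must be >= 1 and baseline_hazard > 0")


@dataclass
class SyntheticDataset:
    """Generated inputs plus the ground truth needed for recovery scoring."""

    expression: pd.DataFrame  # Z-scores, genes x samples
    mutations: pd.DataFrame
    clinical: list[SurvivalRecord]
    truth: dict


def generate_dataset(spec: PlantSpec) -> SyntheticDataset:
    """Draw one cohort under the planted-block model."""
    rng = np.random.default_rng(spec.seed)
    G, S = spec.n_genes, spec.n_samples
    Z = rng.normal(0.0, spec.background_noise_sd, size=(G, S))

    gene_pool = rng.permutation(G)
    offset = 0
    blocks = []
    carriers: set[int] = set()
    for blk in spec.biclusters:
        genes = np.sort(gene_pool[offset : offset + blk.n_genes])
        offset += blk.n_genes
        samples = np.sort(rng.choice(S, size=blk.n_samples, replace=False))
        Z[np.ix_(genes, samples)] += spec.z_cap * blk.mean_up + rng.normal(
            0.0, blk.noise_sd, size=(blk.n_genes, blk.n_samples)
        )
        blocks.append({"genes": genes, "samples": samples, "linked": blk.survival_linked})
        if blk.survival_linked:
            carriers.update(int(s) for s in samples)

    gene_symbols = [f"G{i:04d}" for i in range(G)]
    sample_ids = [f"S{i:04d}" for i in range(S)]
    expression = pd.DataFrame(Z, index=gene_symbols, columns=sample_ids)
    expression.index.name = "gene"

    # every gene mutated in >= 1 random sample so preprocessing keeps it
    mut_samples = rng.integers(0, S, size=G)
    mutations = pd.DataFrame(
        {
            "Hugo_Symbol": gene_symbols,
            "Tumor_Sample_Barcode": [sample_ids[j] for j in mut_samples],
        }
    )

    clinical: list[SurvivalRecord] = []
    for s in range(S):
        hazard = spec.baseline_hazard * (spec.hazard_ratio if s in carriers else 1.0)
        t = rng.exponential(1.0 / hazard)
        censored = rng.random() < spec.censor_rate
        if censored:
            t *= rng.random()
        clinical.append(SurvivalRecord(sample_id=sample_ids[s], time=t, event=not censored))

    truth = {
        "blocks": [
            {
                "genes": [gene_symbols[g] for g in blk["genes"]],
                "samples": [sample_ids[s] for s in blk["samples"]],
                "survival_linked": bool(blk["linked"]),
            }
            for blk in blocks
        ],
        "carriers": sorted(sample_ids[s] for s in carriers),
    }
    return SyntheticDataset(
        expression=expression, mutations=mutations, clinical=clinical, truth=truth
    )


def score_recovery(
    reported, truth: dict, fp_jaccard: float = 0.2
) -> tuple[list[float], int]:
    """Recovery of planted survival-linked gene sets.

    Returns, for each planted linked set, the best Jaccard similarity
    against any reported set (0 when nothing is reported), plus the number
    of reported sets whose best similarity against every planted set is
    below ``fp_jaccard`` (false positives).  ``reported`` may hold
    BiomarkerSet objects or plain gene-symbol sets.
    """

    def genes_of(item) -> frozenset:
        return frozenset(getattr(item, "genes", item))

    reported_sets = [genes_of(r) for r in reported]
    planted = [
        frozenset(blk["genes"]) for blk in truth["blocks"] if blk["survival_linked"]
    ]

    def jac(a, b):
        return len(a & b) / len(a | b) if a | b else 0.0

    best = [max((jac(p, r) for r in reported_sets), default=0.0) for p in planted]
    all_planted = [frozenset(blk["genes"]) for blk in truth["blocks"]]
    fp = sum(
        1
        for r in reported_sets
        if max((jac(p, r) for p in all_planted), default=0.0) < fp_jaccard
    )
    return best, fp
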