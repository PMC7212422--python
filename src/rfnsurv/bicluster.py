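"""Bicluster extraction from a fitted factor model, with significance control.

Each hidden unit of the fitted model is a bicluster candidate: the genes
whose loadings are within a ratio bound of the unit's top loading, paired
with the samples whose codes are within a ratio bound of the unit's top
code.  A candidate is then judged against a Bernoulli null for the
normalized (uncentered, in [0,1]) expression matrix: under no association
every entry is nonzero independently with probability q = K/MN (the matrix
density), so the nonzero count k of an m_b x n_b candidate is Binomial(m_b
n_b, q).  The operational significance rule is the Chernoff-bound
criterion

    k  >=  m_b n_b q  +  sqrt(3 (-ln p*) m_b n_b q),

equivalently C(m,n,k) = k - threshold >= 0, applied at the
Bonferroni-corrected level p* = alpha / (number of candidates).  The exact
binomial upper tail is reported alongside for diagnostics; decisions use
the Chernoff criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

__all__ = [
    "ExtractionThresholds",
    "SignificanceParams",
    "Bicluster",
    "extract_biclusters",
    "significance_threshold",
    "score_bicluster",
    "filter_significant",
    "biclusters_to_tsv",
]


@dataclass(frozen=True)
class ExtractionThresholds:
    """Membership ratio bounds and minimum bicluster size.

    A positive element belongs to a unit's membership vector when
    max / element <= thr (so thr = 3 keeps everything within 3x of the
    peak).  Candidates need at least two genes and two samples.
    """

    thr_w: float = 3.0
    thr_h: float = 3.0
    min_genes: int = 2
    min_samples: int = 2

    def __post_init__(self) -> None:
        if self.thr_w <= 0 or self.thr_h <= 0:
            raise ValueError("ratio thresholds must be positive")
        if self.min_genes < 2 or self.min_samples < 2:
            raise ValueError("biclusters need at least 2 genes and 2 samples")


@dataclass(frozen=True)
class SignificanceParams:
    """Bernoulli-null parameters for the density significance test."""

    q: float  # matrix density K/MN
    p_star: float = 0.05  # per-bicluster level before correction
    alpha: float = 0.05  # family-wise level for Bonferroni
    min_nonzero_ratio: float = 0.5  # quality-control floor

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("density q must lie strictly between 0 and 1")
        if not 0 < self.p_star < 1:
            raise ValueError("p_star must lie strictly between 0 and 1")


@dataclass(frozen=True)
class Bicluster:
    """A scored candidate: index sets plus density statistics."""

    genes: tuple[int, ...]
    samples: tuple[int, ...]
    k: int
    nonzero_ratio: float
    score_C: float
    p_exact: float

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.genes), len(self.samples))


def _ratio_members(vec: np.ndarray, thr: float) -> np.ndarray:
    """Indices of positive entries within a factor-of-thr of the maximum."""
    top = vec.max(initial=0.0)
    if top <= 0:
        return np.empty(0, dtype=int)
    with np.errstate(divide="ignore"):
        ok = (vec > 0) & (top / np.where(vec > 0, vec, 1.0) <= thr)
    return np.flatnonzero(ok)


def extract_biclusters(
    W: np.ndarray,
    H: np.ndarray,
    thresholds: ExtractionThresholds = ExtractionThresholds(),
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Candidate (gene indices, sample indices) pairs, one per hidden unit.

    Gene i joins unit j iff W[i, j] > 0 and max(W[:, j]) / W[i, j] <=
    thr_w; sample s joins iff H[j, s] > 0 and max(H[j, :]) / H[j, s] <=
    thr_h.  Units yielding fewer than min_genes genes or min_samples
    samples emit nothing.  The rule is scale-free: rescaling a column of W
    or a row of H by any positive constant leaves memberships unchanged.
    """
    if W.shape[1] != H.shape[0]:
        raise ValueError("W columns and H rows must both index hidden units")
    out: list[tuple[np.ndarray, np.ndarray]] = []
    for j in range(W.shape[1]):
        genes = _ratio_members(W[:, j], thresholds.thr_w)
        if genes.size < thresholds.min_genes:
            continue
        samples = _ratio_members(H[j, :], thresholds.thr_h)
        if samples.size < thresholds.min_samples:
            continue
        out.append((genes, samples))
    return out


def significance_threshold(m_b: int, n_b: int, q: float, p_star: float) -> float:
    """Minimum nonzero count for Chernoff significance at level p_star.

    mnq(1 + delta) with delta = sqrt(3 (-ln p_star) / (mnq)); a candidate
    with k at or above this count has binomial tail probability at most
    p_star whenever delta <= 1 (the bound's validity regime).
    """
    mnq = m_b * n_b * q
    return mnq + np.sqrt(3.0 * (-np.log(p_star)) * mnq)


def score_bicluster(
    candidate: tuple[np.ndarray, np.ndarray],
    V_norm: np.ndarray,
    params: SignificanceParams,
) -> Bicluster:
    """Score a candidate against the uncentered [0,1] matrix.

    k counts entries strictly greater than zero in the candidate's
    submatrix (normalization maps "no change" and down-regulation to 0).
    """
    genes, samples = (np.asarray(candidate[0]), np.asarray(candidate[1]))
    if genes.size == 0 or samples.size == 0:
        raise ValueError("candidate bicluster has an empty index set")
    sub = V_norm[np.ix_(genes, samples)]
    k = int(np.count_nonzero(sub > 0))
    mn = genes.size * samples.size
    return Bicluster(
        genes=tuple(int(g) for g in genes),
        samples=tuple(int(s) for s in samples),
        k=k,
        nonzero_ratio=k / mn,
        score_C=k - significance_threshold(genes.size, samples.size, params.q, params.p_star),
        p_exact=float(sps.binom.sf(k - 1, mn, params.q)),
    )


def filter_significant(
    candidates: list[Bicluster], params: SignificanceParams
) -> list[Bicluster]:
    """Quality gate plus Chernoff criterion at the Bonferroni level.

    With b candidates entering, each is re-scored at p* = alpha / b and
    kept iff nonzero_ratio >= min_nonzero_ratio and C >= 0.  Output sorted
    by exact binomial tail (ascending), ties broken by gene indices for
    determinism.
    """
    b = len(candidates)
    if b == 0:
        return []
    level = params.alpha / b
    kept = []
    for cand in candidates:
        m_b, n_b = cand.shape
        score = cand.k - significance_threshold(m_b, n_b, params.q, level)
        if cand.nonzero_ratio >= params.min_nonzero_ratio and score >= 0:
            kept.append(replace(cand, score_C=score))
    kept.sort(key=lambda c: (c.p_exact, c.genes))
    return kept


def biclusters_to_tsv(
    biclusters: list[Bicluster],
    gene_symbols: list[str],
    sample_ids: list[str],
) -> str:
    """Serialize scored biclusters: one TSV row per bicluster."""
    lines = ["id\tgenes\tsamples\tm_b\tn_b\tk\tnonzero_ratio\tscore_C\tp_exact"]
    for idx, bc in enumerate(biclusters, start=1):
        lines.append(
            "\t".join(
                [
                    str(idx),
                    ",".join(gene_symbols[g] for g in bc.genes),
                    ",".join(sample_ids[s] for s in bc.samples),
                    str(bc.shape[0]),
                    str(bc.shape[1]),
                    str(bc.k),
                    f"{bc.nonzero_ratio:.6g}",
                    f"{bc.score_C:.6g}",
                    f"{bc.p_exact:.6g}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
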