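"""Transcriptomic decoding of connectivity hotspots.

Given a genes x regions matrix of expression energies (the regional mean of
"expression energy": sum of expressing pixel intensities divided by total
pixels), the decoding proceeds per region pair:

1. normalize each gene's energies by its total over regions (removing probe
   affinity differences);
2. select candidates either as the intersection of the top-q quantile in
   both regions (fixed-threshold hypergeometric test per gene set) or by
   ranking genes on the sum of their normalized values in the pair — the L1
   score — and applying flexible-threshold minimum-hypergeometric (mHG)
   enrichment per gene set;
3. control the false discovery rate across sets within each mode;
4. establish specificity by repeating the analysis on randomly chosen
   control region pairs.

The mHG statistic for a ranked list of N genes containing B targets is the
minimum over all prefix lengths n of the hypergeometric upper tail
P[X >= b(n)] with b(n) targets in the top n. Its exact p-value is computed
by dynamic programming over the lattice of (prefix length, targets seen)
states: the probability, under uniformly random orderings, that a path ever
enters the region where the tail probability is at most the observed
minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from fcdecode.connectivity import fdr_adjust
from fcdecode.types import Parcellation

logger = logging.getLogger(__name__)

#: relative slack when testing tail probabilities against the observed minimum,
#: guarding against float round-off in ties
_TIE_RTOL = 1e-9


@dataclass
class ExpressionMatrix:
    """Genes x regions expression energies with per-gene normalization state."""

    gene_ids: list[str]
    region_labels: list[str]
    energies: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.region_labels = [str(r) for r in self.region_labels]
        self.energies = np.asarray(self.energies, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if self.energies.shape != (len(self.gene_ids), len(self.region_labels)):
            raise ValueError(
                f"energies shape {self.energies.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.region_labels)} regions"
            )
        if np.any(self.energies < 0):
            raise ValueError("expression energies must be nonnegative")

    def region_index(self, label) -> int:
        label = str(label)
        try:
            return self.region_labels.index(label)
        except ValueError:
            raise KeyError(f"region label {label!r} not in matrix") from None

    def column(self, label) -> np.ndarray:
        return self.energies[:, self.region_index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.energies, index=self.gene_ids, columns=self.region_labels)


@dataclass
class RankedGeneList:
    """Genes ordered best-first with aligned nonincreasing scores."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != self.scores.shape[0]:
            raise ValueError("genes and scores must align")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be nonincreasing")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    """Outcome of one gene-set enrichment test."""

    set_name: str
    statistic: float
    optimal_rank: int
    exact_p: float
    fdr_q: float = np.nan
    mode: str = "mhg"


def expression_energy_by_region(
    expression_volumes: dict[str, np.ndarray], parcellation: Parcellation
) -> ExpressionMatrix:
    """Mean expression energy of each gene under each parcellation region."""
    regions = parcellation.region_labels
    if not regions:
        raise ValueError("parcellation has no regions")
    masks = []
    for lab in regions:
        m = parcellation.mask_of(lab)
        if not m.any():
            raise ValueError(f"region {lab} is empty")
        masks.append(m)
    genes = sorted(expression_volumes)
    energies = np.empty((len(genes), len(regions)))
    for i, g in enumerate(genes):
        vol = np.asarray(expression_volumes[g], dtype=float)
        if vol.shape != parcellation.labels.shape:
            raise ValueError(
                f"volume for gene {g!r} has shape {vol.shape}, "
                f"parcellation grid is {parcellation.labels.shape}"
            )
        for j, m in enumerate(masks):
            energies[i, j] = vol[m].mean()
    return ExpressionMatrix(
        gene_ids=genes,
        region_labels=[str(r) for r in regions],
        energies=energies,
        normalized=False,
    )


def normalize_by_total(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each gene's energies by its total over regions.

    Genes with zero total expression carry no ranking information; they are
    dropped and logged rather than imputed.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    totals = matrix.energies.sum(axis=1)
    keep = totals > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d genes with zero total expression", n_dropped)
    energies = matrix.energies[keep] / totals[keep, None]
    genes = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return ExpressionMatrix(
        gene_ids=genes,
        region_labels=list(matrix.region_labels),
        energies=energies,
        normalized=True,
    )


def _require_normalized(matrix: ExpressionMatrix) -> None:
    if not matrix.normalized:
        raise ValueError("operation requires a normalized matrix")


def top_quantile_intersection(
    matrix: ExpressionMatrix, pair: tuple, q: float = 0.20
) -> set[str]:
    """Genes in the top ceil(qN) of both regions' normalized values.

    Ranking within each region is by value descending with ties broken by
    gene id ascending, so the selection is deterministic.
    """
    _require_normalized(matrix)
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    n = len(matrix.gene_ids)
    k = int(np.ceil(q * n))
    gene_arr = np.array(matrix.gene_ids)
    tops = []
    for label in pair:
        col = matrix.column(label)
        order = np.lexsort((gene_arr, -col))  # value desc, gene id asc on ties
        tops.append(set(gene_arr[order[:k]]))
    return tops[0] & tops[1]


def l1_rank(matrix: ExpressionMatrix, pair: tuple) -> RankedGeneList:
    """Rank genes by the sum of normalized values in the two regions.

    The score is the L1 magnitude of each gene's (r1, r2) profile; it also
    favours genes expressed strongly in just one of the two regions.
    """
    _require_normalized(matrix)
    score = matrix.column(pair[0]) + matrix.column(pair[1])
    gene_arr = np.array(matrix.gene_ids)
    order = np.lexsort((gene_arr, -score))
    return RankedGeneList(genes=gene_arr[order].tolist(), scores=score[order])


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_tail(k: int, N: int, B: int, n: int) -> float:
    """Upper tail P[X >= k] for X ~ Hypergeometric(N, B, n), log-space sum."""
    if not (0 <= k <= n <= N and 0 <= B <= N):
        raise ValueError("require 0 <= k <= n <= N and 0 <= B <= N")
    if k == 0:
        return 1.0
    hi = min(B, n)
    if k > hi:
        return 0.0
    j = np.arange(k, hi + 1)
    log_terms = _log_comb(B, j) + _log_comb(N - B, n - j) - _log_comb(N, n)
    m = log_terms.max()
    return float(min(1.0, np.exp(m) * np.exp(log_terms - m).sum()))


def _tail_grid(N: int, B: int) -> np.ndarray:
    """tail[n, b] = P[X >= b] for X ~ Hypergeometric(N, B, n); shape (N+1, B+1).

    Infeasible states (b > min(n, B) or n - b > N - B) hold the value of the
    nearest feasible boundary; they are never visited by the DP.
    """
    n_grid = np.arange(N + 1)[:, None]
    b_grid = np.arange(B + 1)[None, :]
    with np.errstate(invalid="ignore"):
        logpmf = (
            _log_comb(B, b_grid)
            + _log_comb(N - B, n_grid - b_grid)
            - _log_comb(N, n_grid)
        )
    feasible = (b_grid <= np.minimum(n_grid, B)) & (n_grid - b_grid <= N - B)
    pmf = np.where(feasible, np.exp(logpmf), 0.0)
    tail = np.cumsum(pmf[:, ::-1], axis=1)[:, ::-1]
    return np.minimum(tail, 1.0)


def mhg_statistic(hit_indicator: np.ndarray) -> tuple[float, int]:
    """Minimum hypergeometric tail over all ranked-list prefixes.

    ``hit_indicator`` marks target genes along the ranked list (best first).
    Returns (statistic, optimal prefix length); the earliest minimizing
    prefix wins ties.
    """
    hits = np.asarray(hit_indicator, dtype=int)
    N = hits.size
    B = int(hits.sum())
    if B == 0:
        raise ValueError("target set is empty on the ranked list")
    tail = _tail_grid(N, B)
    b_of_n = np.cumsum(hits)
    prefix_tails = tail[np.arange(1, N + 1), b_of_n]
    best = int(np.argmin(prefix_tails))
    return float(prefix_tails[best]), best + 1


def mhg_exact_pvalue(N: int, B: int, stat: float) -> float:
    """Exact p-value of the mHG statistic by lattice-path dynamic programming.

    A uniformly random ordering of B targets among N genes is a monotone
    lattice path from (0, 0) to (N, B). The statistic is at most ``stat``
    iff the path enters the region R = {(n, b): P[X >= b | n] <= stat}. The
    DP propagates the probability mass of paths that have avoided R,
    zeroing states inside R; the p-value is one minus the surviving mass.
    """
    if not 0 < B <= N:
        raise ValueError("require 0 < B <= N")
    tail = _tail_grid(N, B)
    in_region = tail <= stat * (1.0 + _TIE_RTOL)

    # f[b] = P(path reaches (n, b) without having entered R); the p-value is
    # the mass absorbed into R, accumulated directly so that tiny p-values
    # are sums of positive terms rather than a 1 - (1 - p) cancellation
    f = np.zeros(B + 1)
    f[0] = 1.0
    if in_region[0, 0]:  # degenerate: everything significant
        return 1.0
    absorbed = 0.0
    b = np.arange(B + 1)
    for n in range(1, N + 1):
        prev_b = f
        # step with a non-target: stay at b; probability (N - B - (n-1-b)) / (N - n + 1)
        remaining = N - n + 1
        p_nontarget = np.clip((N - B) - (n - 1 - b), 0, None) / remaining
        # step with a target from b-1: probability (B - (b-1)) / (N - n + 1)
        p_target = np.clip(B - (b - 1), 0, None) / remaining
        f = prev_b * p_nontarget
        f[1:] += prev_b[:-1] * p_target[1:]
        hit = in_region[n]
        if hit.any():
            absorbed += float(f[hit].sum())
            f[hit] = 0.0
    return float(min(1.0, absorbed))


def mhg_enrichment(
    ranked: RankedGeneList, target_set: set[str], universe: set[str] | None = None
) -> EnrichmentResult:
    """Flexible-threshold enrichment of a gene set on a ranked list.

    The list is thresholded at every prefix and the best (minimum)
    hypergeometric tail is taken as the statistic; the exact p-value
    corrects for the data-driven choice of threshold.
    """
    if universe is not None:
        missing = set(ranked.genes) ^ set(universe)
        if missing:
            raise ValueError("ranked list must cover exactly the universe")
        target_set = target_set & universe
    else:
        target_set = target_set & set(ranked.genes)
    if not target_set:
        raise ValueError("target set is empty within the universe")
    hits = np.fromiter((g in target_set for g in ranked.genes), dtype=bool, count=len(ranked))
    stat, opt_rank = mhg_statistic(hits)
    p = mhg_exact_pvalue(len(ranked), int(hits.sum()), stat)
    return EnrichmentResult(
        set_name="", statistic=stat, optimal_rank=opt_rank, exact_p=p, mode="mhg"
    )


def permute_gene_labels(
    matrix: ExpressionMatrix, rng: np.random.Generator
) -> ExpressionMatrix:
    """Null control: randomly reassign gene ids to expression rows.

    Destroys any real gene-to-profile association while preserving the
    marginal distribution of regional profiles, so planted enrichment should
    vanish on the permuted matrix.
    """
    perm = rng.permutation(len(matrix.gene_ids))
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        region_labels=list(matrix.region_labels),
        energies=matrix.energies[perm],
        normalized=matrix.normalized,
    )


def decode_pair(
    matrix: ExpressionMatrix,
    pair: tuple,
    annotations: dict[str, list[str]],
    q: float = 0.20,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Run both candidate-selection modes and test every annotation set.

    Fixed mode: dual-region top-quantile intersection, one hypergeometric
    tail test per set. Ranked mode: L1 ranking with mHG enrichment per set.
    BH-FDR is applied across sets within each mode; rows are sorted by q
    within mode.
    """
    _require_normalized(matrix)
    if not annotations:
        raise ValueError("annotations must be nonempty")
    universe = set(matrix.gene_ids)
    N = len(universe)

    selected = top_quantile_intersection(matrix, pair, q)
    ranked = l1_rank(matrix, pair)

    rows = []
    for mode in ("fixed", "mhg"):
        results = []
        for name, members in annotations.items():
            target = set(members) & universe
            if not target:
                raise ValueError(f"annotation set {name!r} has no genes in the universe")
            if mode == "fixed":
                k = len(selected & target)
                p = hypergeometric_tail(k, N, len(target), len(selected))
                results.append(
                    EnrichmentResult(
                        set_name=name,
                        statistic=p,
                        optimal_rank=len(selected),
                        exact_p=p,
                        mode="fixed",
                    )
                )
            else:
                res = replace(mhg_enrichment(ranked, target), set_name=name)
                results.append(res)
        qvals = fdr_adjust([r.exact_p for r in results])
        for r, qv in zip(results, qvals):
            rows.append(
                {
                    "set": r.set_name,
                    "mode": mode,
                    "statistic": r.statistic,
                    "optimal_rank": r.optimal_rank,
                    "exact_p": r.exact_p,
                    "q": qv,
                }
            )
    out = pd.DataFrame(rows)
    return (
        out.sort_values(["mode", "q", "set"], kind="stable")
        .reset_index(drop=True)
    )


def random_pair_control(
    matrix: ExpressionMatrix,
    annotations: dict[str, list[str]],
    focal_pair: tuple,
    n_pairs: int = 10,
    q: float = 0.20,
    alpha_fdr: float = 0.05,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Specificity control: decode randomly chosen region pairs.

    Draws ``n_pairs`` distinct unordered region pairs (excluding the focal
    pair) uniformly without replacement, runs :func:`decode_pair` on each,
    and reports per pair the number of annotation sets significant
    (q <= alpha in either selection mode), with the focal pair first.
    """
    _require_normalized(matrix)
    focal = tuple(str(x) for x in focal_pair)
    focal_key = frozenset(focal)
    all_pairs = [
        p
        for p in combinations(matrix.region_labels, 2)
        if frozenset(p) != focal_key
    ]
    if n_pairs > len(all_pairs):
        raise ValueError(
            f"requested {n_pairs} control pairs but only {len(all_pairs)} exist"
        )
    rng = np.random.default_rng(rng_seed)
    chosen_idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)

    def n_significant(p) -> int:
        table = decode_pair(matrix, p, annotations, q=q, alpha_fdr=alpha_fdr)
        sig = table[table["q"] <= alpha_fdr]["set"].unique()
        return int(len(sig))

    rows = [
        {
            "region_1": focal[0],
            "region_2": focal[1],
            "is_focal": True,
            "n_significant_sets": n_significant(focal),
        }
    ]
    for i in chosen_idx:
        p = all_pairs[i]
        rows.append(
            {
                "region_1": p[0],
                "region_2": p[1],
                "is_focal": False,
                "n_significant_sets": n_significant(p),
            }
        )
    return pd.DataFrame(rows)
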