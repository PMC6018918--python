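"""Gene-set overlap statistics: 2x2 contingency, Fisher's exact test, odds ratio.

Quantifies the overlap between a differentially-expressed-gene set and a
risk-gene list within an explicit gene universe. The universe must be
supplied (e.g. all genes detected in the experiment); no default universe is
invented, because the p-value and odds ratio both depend on it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable2x2:
    """Counts for DEG/risk-list overlap: a = both, b = DEG only, c = list only,
    d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError("contingency cells must be nonnegative")

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def build_contingency(
    deg_genes: set[str], risk_genes: set[str], universe: set[str]
) -> ContingencyTable2x2:
    """Cross-classify the universe by DEG membership and risk-list membership.

    DEGs must be a subset of the universe; risk genes outside the universe
    (e.g. annotated on another platform) are dropped with a logged count.
    """
    deg_genes, risk_genes, universe = set(deg_genes), set(risk_genes), set(universe)
    if not universe:
        raise ValueError("universe is empty")
    if not deg_genes <= universe:
        raise ValueError("DEG genes must be a subset of the universe")
    n_outside = len(risk_genes - universe)
    if n_outside:
        logger.warning("dropping %d risk genes outside the universe", n_outside)
    risk = risk_genes & universe
    a = len(deg_genes & risk)
    b = len(deg_genes - risk)
    c = len(risk - deg_genes)
    d = len(universe) - a - b - c
    return ContingencyTable2x2(a=a, b=b, c=c, d=d)


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_or(
    table: ContingencyTable2x2, conditional_mle: bool = False
) -> tuple[float, float]:
    """Two-sided Fisher exact p-value and odds ratio for a 2x2 table.

    The two-sided p sums, over all tables with the observed margins, the
    hypergeometric point probabilities not exceeding the observed one
    (the standard ``fisher.test`` convention), in log space. The odds ratio
    is the sample cross-product ratio ``ad / bc`` by default (+inf when
    bc = 0 and ad > 0); ``conditional_mle=True`` returns the conditional
    maximum-likelihood estimate instead.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.universe_size
    r1 = a + b  # DEG margin
    c1 = a + c  # risk margin

    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        warnings.warn("degenerate table with an all-or-nothing margin", stacklevel=2)
        return 1.0, float("nan")

    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = (
        _log_comb(r1, support)
        + _log_comb(n - r1, c1 - support)
        - _log_comb(n, c1)
    )
    log_obs = logp[a - lo]
    # include tables whose point probability is <= observed, with round-off slack
    keep = logp <= log_obs + 1e-9
    m = logp[keep].max()
    p = float(min(1.0, np.exp(m) * np.exp(logp[keep] - m).sum()))

    if conditional_mle:
        from scipy.stats.contingency import odds_ratio as _cond_or

        oratio = float(_cond_or(table.as_array(), kind="conditional").statistic)
    else:
        ad, bc = a * d, b * c
        if bc == 0:
            oratio = float("inf") if ad > 0 else float("nan")
            if np.isnan(oratio):
                warnings.warn("odds ratio undefined (both cross-products zero)", stacklevel=2)
        else:
            oratio = ad / bc
    return p, oratio
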