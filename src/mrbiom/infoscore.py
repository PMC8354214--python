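"""Entropy-based total-information scoring and biomarker selection.

The core idea: a differentially expressed (DE) mRNA is a promising
biomarker when (a) it is significantly coexpressed with many DE miRNAs
and DE lncRNAs, and (b) its protein product is densely connected in the
protein-protein interaction (PPI) network of DE mRNAs.

For each DE mRNA x the pipeline computes

* Pearson correlation rows against all DE miRNAs (matrix M, N x J) and
  all DE lncRNAs (matrix L, N x K), with two-sided t-test p-values;
* information-rate vectors p_x and q_x: the significant (p < alpha)
  correlation magnitudes of row x, each normalized by the row's sum of
  significant magnitudes;
* the coexpression information S_RNA(x): the Shannon entropy, in bits,
  of p_x plus that of q_x;
* the PPI information S_PPI(x) = 1 + sum of connection scores of edges
  incident to x's protein within the DE-mRNA universe;
* the total information S(x) = S_RNA(x)/max S_RNA + S_PPI(x)/max S_PPI,
  bounded by 2.

Candidate biomarkers are the top-Q mRNAs by S(x), with Q set either at
the knee of the descending score curve or fixed by the caller.

Negative significant correlations enter the rate vectors via their
absolute value: a raw negative coefficient would produce a negative
"rate" and an undefined logarithm, while |r| preserves the strength of
the coupling regardless of sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AlignmentError, ExpressionMatrix, PPINetwork

__all__ = [
    "CorrelationBlock",
    "RateVector",
    "InfoScoreTable",
    "PmbSelection",
    "pearson_with_p",
    "correlation_blocks",
    "information_rates",
    "coexpression_entropy",
    "ppi_information",
    "total_information",
    "compute_scores",
    "select_pmbs",
]


@dataclass
class CorrelationBlock:
    """Pearson r and matched two-sided p-values for one mRNA-vs-class block."""

    r: pd.DataFrame  # mRNAs x (miRNAs or lncRNAs), values in [-1, 1]
    p: pd.DataFrame  # same shape, values in [0, 1]

    def __post_init__(self) -> None:
        if self.r.shape != self.p.shape:
            raise ValueError("r and p matrices must share a shape")


@dataclass
class RateVector:
    """Normalized magnitudes of one mRNA's significant correlations.

    ``rates`` sum to 1 whenever ``source_count > 0``; an mRNA without a
    single significant partner carries an empty vector.
    """

    rates: np.ndarray
    source_count: int

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.source_count != self.rates.size:
            raise ValueError("source_count must equal the number of rates")
        if self.source_count > 0 and not np.isclose(self.rates.sum(), 1.0, atol=1e-9):
            raise ValueError("nonempty rate vector must sum to 1")


@dataclass
class InfoScoreTable:
    """Per-mRNA S_RNA, S_PPI, total information and rank (1 = best)."""

    table: pd.DataFrame  # columns: feature_id, symbol, s_rna, s_ppi, s_total, rank

    def sorted(self) -> pd.DataFrame:
        return self.table.sort_values("rank").reset_index(drop=True)


@dataclass
class PmbSelection:
    """The top-Q mRNAs by total information."""

    selected_ids: list[str]
    method: str  # "knee" or "fixed"
    q: int = field(init=False)

    def __post_init__(self) -> None:
        self.q = len(self.selected_ids)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value.

    The p-value comes from the exact t-test with n - 2 degrees of
    freedom. A zero-variance vector yields (nan, 1.0): degenerate input,
    treated downstream as "no significant correlation".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), 1.0
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and p between rows of a (n_a x s) and b (n_b x s)."""
    n = a.shape[1]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((ac**2).sum(axis=1))
    bsd = np.sqrt((bc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac @ bc.T) / np.outer(asd, bsd)
    r = np.clip(r, -1.0, 1.0)
    # two-sided t-test with n - 2 df; |r| = 1 maps to p = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    degenerate = np.isnan(r)
    r[degenerate] = np.nan
    p[degenerate] = 1.0
    return r, p


def correlation_blocks(
    mrna: ExpressionMatrix, mirna: ExpressionMatrix, lncrna: ExpressionMatrix
) -> tuple[CorrelationBlock, CorrelationBlock]:
    """Correlation blocks M (mRNA x miRNA) and L (mRNA x lncRNA).

    All three matrices must carry the identical sample set in identical
    order — correlations are computed across samples.
    """
    for other, name in ((mirna, "miRNA"), (lncrna, "lncRNA")):
        if other.sample_ids != mrna.sample_ids:
            raise AlignmentError(f"{name} samples do not match mRNA samples")
    blocks = []
    for other in (mirna, lncrna):
        r, p = _pearson_rows(mrna.values, other.values)
        blocks.append(
            CorrelationBlock(
                r=pd.DataFrame(r, index=mrna.feature_ids, columns=other.feature_ids),
                p=pd.DataFrame(p, index=mrna.feature_ids, columns=other.feature_ids),
            )
        )
    return blocks[0], blocks[1]


def information_rates(
    r_row: np.ndarray, p_row: np.ndarray, alpha: float = 0.05
) -> RateVector:
    """Normalized |r| shares of one mRNA's significant correlations.

    Entries with p < alpha are kept; each kept |r| is divided by the sum
    of kept |r| values. No significant entry gives an empty vector.
    """
    r_row = np.asarray(r_row, dtype=float)
    p_row = np.asarray(p_row, dtype=float)
    if r_row.shape != p_row.shape:
        raise ValueError("r_row and p_row must match")
    keep = (p_row < alpha) & ~np.isnan(r_row)
    mags = np.abs(r_row[keep])
    total = mags.sum()
    if total == 0:
        return RateVector(np.empty(0), 0)
    return RateVector(mags / total, int(mags.size))


def coexpression_entropy(p_x: RateVector, q_x: RateVector) -> float:
    """Shannon entropy (bits) of the two rate vectors, summed.

    An empty vector contributes 0; so does a singleton (a single rate of
    1 carries no uncertainty).
    """
    total = 0.0
    for vec in (p_x, q_x):
        if vec.source_count > 0:
            total += float(stats.entropy(vec.rates, base=2))
    return total


def ppi_information(ppi: PPINetwork, symbol: str, universe: set[str]) -> float:
    """1 + sum of PPI connection scores to other symbols in the universe.

    The universe is the DE-mRNA symbol set; edges leaving it are
    ignored. A symbol absent from the network scores the additive
    constant 1.
    """
    scores = ppi.neighbor_scores(symbol)
    return 1.0 + sum(s for n, s in scores.items() if n in universe and n != symbol)


def total_information(s_rna: np.ndarray, s_ppi: np.ndarray) -> np.ndarray:
    """Sum of the two max-normalized components, each in [0, 1].

    A component whose maximum is 0 contributes 0 for every mRNA (only
    possible for S_RNA; S_PPI is bounded below by 1).
    """
    s_rna = np.asarray(s_rna, dtype=float)
    s_ppi = np.asarray(s_ppi, dtype=float)
    if s_rna.shape != s_ppi.shape:
        raise ValueError("component vectors must match in length")
    out = np.zeros_like(s_rna)
    for comp in (s_rna, s_ppi):
        m = comp.max(initial=0.0)
        if m > 0:
            out = out + comp / m
    return out


def compute_scores(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    lncrna: ExpressionMatrix,
    ppi: PPINetwork,
    symbol_map: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> InfoScoreTable:
    """Run the full scoring chain over DE expression matrices.

    ``symbol_map`` translates mRNA feature ids to gene symbols for the
    PPI lookup; without one, feature ids are used as symbols directly.
    Unmapped mRNAs get S_PPI = 1.
    """
    blocks_m, blocks_l = correlation_blocks(mrna, mirna, lncrna)
    n = len(mrna.feature_ids)
    s_rna = np.zeros(n)
    for i in range(n):
        p_x = information_rates(blocks_m.r.values[i], blocks_m.p.values[i], alpha)
        q_x = information_rates(blocks_l.r.values[i], blocks_l.p.values[i], alpha)
        s_rna[i] = coexpression_entropy(p_x, q_x)
    symbol_map = symbol_map or {}
    symbols = [symbol_map.get(f, f) for f in mrna.feature_ids]
    universe = set(symbols)
    s_ppi = np.array([ppi_information(ppi, sym, universe) for sym in symbols])
    s_total = total_information(s_rna, s_ppi)
    table = pd.DataFrame(
        {
            "feature_id": mrna.feature_ids,
            "symbol": symbols,
            "s_rna": s_rna,
            "s_ppi": s_ppi,
            "s_total": s_total,
        }
    )
    order = table.sort_values(
        ["s_total", "feature_id"], ascending=[False, True], kind="mergesort"
    ).index
    table.loc[order, "rank"] = np.arange(1, n + 1)
    table["rank"] = table["rank"].astype(int)
    return InfoScoreTable(table)


def select_pmbs(
    scores: InfoScoreTable,
    method: str = "knee",
    q_fixed: int | None = None,
    q_min: int = 10,
) -> PmbSelection:
    """Pick the candidate biomarkers from the ranked score table.

    ``knee`` sorts the total-information curve descending and sets Q to
    the 1-based index of the point immediately preceding the largest
    single-step drop, floored at ``q_min``; a flat curve (all steps
    equal) falls back to ``q_min`` with a warning. ``fixed`` takes
    ``q_fixed`` directly. Ties in s_total are broken lexicographically
    by feature id.
    """
    ranked = scores.sorted()
    n = len(ranked)
    if n < 2:
        raise ValueError("need at least 2 scored mRNAs")
    if method == "fixed":
        if q_fixed is None or not (1 <= q_fixed <= n):
            raise ValueError("fixed selection needs 1 <= q_fixed <= number of mRNAs")
        q = q_fixed
    elif method == "knee":
        curve = ranked["s_total"].to_numpy()
        drops = curve[:-1] - curve[1:]
        if np.allclose(drops, drops[0]):
            warnings.warn("flat score curve: falling back to q_min", stacklevel=2)
            q = min(q_min, n)
        else:
            q = int(np.argmax(drops)) + 1  # point before the largest drop, 1-based
            q = max(q, min(q_min, n))
    else:
        raise ValueError("method must be 'knee' or 'fixed'")
    return PmbSelection(list(ranked["feature_id"].iloc[:q]), method)
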