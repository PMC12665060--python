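"""Differential expression along a continuous per-cell covariate.

The same machinery serves the two covariates of the pipeline — pseudotime
and MTIS: per gene, counts are regressed on a natural cubic spline basis of
the covariate with a negative binomial log-link GLM and a log size-factor
offset, and tested against the intercept-only model with a likelihood-ratio
test (chi-squared, df = spline degrees of freedom). The per-gene dispersion
is a method-of-moments estimate from a Poisson fit of the full model,
shared between the null and full fits so the LRT is well defined.

Downstream selection: top-k ranking by q value, the intersection of the two
top-50 lists (CTPMs), a co-most-significant rule scoring genes by the
smaller of their two -log10 q values, and the network rule declaring a CTPM
a key gene when it has at least ``min_ct_neighbors`` high-confidence
interaction partners among the common targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

from .io import CellGeneMatrix, InteractionNetwork, TargetSet

__all__ = [
    "DEGene",
    "KeyGeneReport",
    "natural_spline_basis",
    "de_along_covariate",
    "benjamini_hochberg",
    "top_k",
    "ctpm_intersect",
    "co_most_significant",
    "select_key_genes",
]

_Q_FLOOR = 1e-300  # q values floored before -log10 to avoid infinities


@dataclass
class DEGene:
    gene: str
    lrt_stat: float
    p_value: float
    q_value: float
    direction: str  # {"increasing", "decreasing", "nonmonotone"}
    converged: bool = True


@dataclass
class KeyGeneReport:
    """Key-gene selection result.

    ``kgs`` is the union of the network-qualified CTPMs and the co-most
    significant genes. ``ct_member_ctpms`` flags CTPMs that are themselves
    common targets (membership alone does not make them key genes).
    """

    ctpms: list[str]
    key_ctpms: list[str]
    co_most: list[str]
    kgs: list[str] = field(init=False)
    ct_member_ctpms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.kgs = sorted(set(self.key_ctpms) | set(self.co_most))


def natural_spline_basis(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis (no intercept column), ``df`` columns.

    Knots sit at evenly spaced quantiles of ``x`` (boundary knots at the
    extremes, ``df - 1`` interior knots), making the fitted column space
    invariant to affine rescaling of the covariate.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if df == 1:
        return x[:, None]
    knots = np.quantile(x, np.linspace(0, 1, df + 1))
    if np.unique(knots).size != knots.size:
        raise ValueError("covariate has too few distinct values for the spline")
    kmax, ksecond = knots[-1], knots[-2]

    def d(k):
        return ((np.maximum(x - k, 0) ** 3) - (np.maximum(x - kmax, 0) ** 3)) / (
            kmax - k
        )

    cols = [x] + [d(knots[j]) - d(ksecond) for j in range(df - 1)]
    return np.column_stack(cols)


def _fit_nb_lrt(y, basis, offset):
    """LRT p of the spline NB GLM against intercept-only; returns
    (stat, p, endpoint_diff, converged)."""
    n = y.size
    x_full = sm.add_constant(basis)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            pois = sm.GLM(y, x_full, family=sm.families.Poisson(), offset=offset).fit()
            mu = pois.mu
            denom = float(np.sum(mu**2))
            alpha = float(np.sum((y - mu) ** 2 - mu) / denom) if denom > 0 else 1e-8
            alpha = float(np.clip(alpha, 1e-8, 100.0))
            fam = sm.families.NegativeBinomial(alpha=alpha)
            full = sm.GLM(y, x_full, family=fam, offset=offset).fit()
            null = sm.GLM(y, np.ones((n, 1)), family=fam, offset=offset).fit()
        except Exception:
            return 0.0, 1.0, 0.0, False
    stat = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(chi2.sf(stat, basis.shape[1]))
    # direction: sign of the fitted linear predictor at the covariate extremes
    lin = x_full @ full.params
    endpoint_diff = float(lin[-1] - lin[0])
    return float(stat), p, endpoint_diff, bool(full.converged)


def de_along_covariate(
    cg: CellGeneMatrix | np.ndarray,
    covariate: np.ndarray,
    spline_df: int = 3,
    size_factors: np.ndarray | None = None,
) -> list[DEGene]:
    """Test each gene for expression change along a continuous covariate.

    Parameters
    ----------
    cg
        Counts (cells x genes) as a :class:`CellGeneMatrix` or array.
    covariate
        Finite per-cell value (pseudotime or MTIS).
    spline_df
        Degrees of freedom of the natural cubic spline (default 3).
    size_factors
        Optional per-cell size factors for the log offset; computed as
        total/median(total) when omitted.

    Returns the genes in input order with LRT statistics, BH-adjusted
    q values, and the direction of the fitted trend (sign of the fitted
    curve's endpoint difference). Genes whose fit fails get p = 1 and are
    flagged unconverged.
    """
    counts = np.asarray(getattr(cg, "counts", cg), dtype=float)
    genes = (
        list(cg.gene_symbols)
        if isinstance(cg, CellGeneMatrix)
        else [f"G{j}" for j in range(counts.shape[1])]
    )
    t = np.asarray(covariate, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("covariate must be finite for all cells")
    if t.size != counts.shape[0]:
        raise ValueError("covariate length must equal the number of cells")
    if np.unique(t).size == 1:
        raise ValueError("covariate is constant")
    if size_factors is None:
        total = counts.sum(axis=1)
        med = np.median(total)
        size_factors = np.where(total > 0, total, 1.0) / (med if med > 0 else 1.0)
    offset = np.log(np.asarray(size_factors, dtype=float))

    # sort cells by covariate so endpoint rows are the covariate extremes
    order = np.argsort(t, kind="stable")
    basis = natural_spline_basis(t[order], df=spline_df)
    # center/scale basis columns for IRLS conditioning (does not change the LRT)
    basis = (basis - basis.mean(axis=0)) / np.where(
        basis.std(axis=0) > 0, basis.std(axis=0), 1.0
    )
    counts_o = counts[order]
    offset_o = offset[order]

    results = []
    for j, gene in enumerate(genes):
        y = counts_o[:, j]
        if np.unique(y).size == 1:  # constant gene: null fit by construction
            results.append(DEGene(gene, 0.0, 1.0, 1.0, "nonmonotone", True))
            continue
        stat, p, diff, ok = _fit_nb_lrt(y, basis, offset_o)
        if diff > 0:
            direction = "increasing"
        elif diff < 0:
            direction = "decreasing"
        else:
            direction = "nonmonotone"
        results.append(DEGene(gene, stat, p, 1.0, direction, ok))
    q = benjamini_hochberg([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return results


def benjamini_hochberg(p) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def top_k(de: list[DEGene], k: int = 50) -> list[DEGene]:
    """First ``k`` genes sorted by (q, p, gene name)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(de, key=lambda r: (r.q_value, r.p_value, r.gene))
    return ranked[:k]


def ctpm_intersect(top_pt, top_mtis) -> list[str]:
    """Genes common to the two top lists (covariate x covariate), sorted."""
    a = {r.gene if isinstance(r, DEGene) else r for r in top_pt}
    b = {r.gene if isinstance(r, DEGene) else r for r in top_mtis}
    return sorted(a & b)


def co_most_significant(
    de_pt: list[DEGene], de_mtis: list[DEGene], k: int = 2
) -> list[str]:
    """Genes simultaneously most significant under both covariates.

    Each gene in the shared universe scores min(-log10 q_pt, -log10 q_mtis);
    the top ``k`` are returned, ties broken by the sum of the two scores and
    then by name.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    q_pt = {r.gene: r.q_value for r in de_pt}
    q_mt = {r.gene: r.q_value for r in de_mtis}
    shared = sorted(set(q_pt) & set(q_mt))

    def neglog(q):
        return -np.log10(max(q, _Q_FLOOR))

    scored = [
        (min(neglog(q_pt[g]), neglog(q_mt[g])), neglog(q_pt[g]) + neglog(q_mt[g]), g)
        for g in shared
    ]
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return sorted(g for _, _, g in scored[:k])


def select_key_genes(
    ctpms,
    co_most,
    cts: TargetSet,
    net: InteractionNetwork,
    min_ct_neighbors: int = 2,
    min_score: float = 0.7,
) -> KeyGeneReport:
    """Network rule for key mediating genes.

    Edges below ``min_score`` are discarded; a CTPM qualifies when it has at
    least ``min_ct_neighbors`` distinct common-target interaction partners
    other than itself. The key genes are the qualifying CTPMs plus the
    co-most-significant genes. CTPMs that are themselves common targets are
    flagged in the report but must still meet the neighbour rule.
    """
    ctpms = sorted({str(g).strip().upper() for g in ctpms})
    co_most = sorted({str(g).strip().upper() for g in co_most})
    key = []
    for g in ctpms:
        ct_neighbors = net.neighbors(g, min_score=min_score) & cts.symbols
        ct_neighbors.discard(g)
        if len(ct_neighbors) >= min_ct_neighbors:
            key.append(g)
    report = KeyGeneReport(ctpms=ctpms, key_ctpms=key, co_most=co_most)
    report.ct_member_ctpms = sorted(set(ctpms) & cts.symbols)
    return report
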