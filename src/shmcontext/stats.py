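"""Statistical layer: correlation and regression of mutability against
context features, rank/means tests, Fisher's exact test, and the
synonymous-mutation contingency analysis of the FW1 CAGCTG motif.

The contingency analysis classifies each clonally independent sequence
by the hexamer at V-segment positions 7-12 (the in-frame FW1 CAGCTG).
Mutations at hexamer sites 3 and 6 (V positions 9 and 12) sit at third
codon positions and are synonymous (CAG/CAA glutamine, CTG/CTA/CTC/CTT
leucine), so their frequencies are untouched by protein-level selection;
a site-6 mutation additionally destroys the CANNTG E-box.  Clones are
cross-classified into G3/G6, A3/G6, G3/H6, A3/H6 (any other hexamer is
dropped) and the conditional site-3 mutation frequencies

    f(3 | 6 unmutated) = n_A3G6 / (n_G3G6 + n_A3G6)
    f(3 | 6 mutated)   = n_A3H6 / (n_G3H6 + n_A3H6)

are compared with a two-sided Fisher exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .features import ContextFeatures
from .kmers import KmerRecord
from .simulate import Repertoire

_CATEGORIES = ("G3G6", "A3G6", "G3H6", "A3H6")


# --------------------------------------------------------------------
# correlation and regression
# --------------------------------------------------------------------

def _check_pair(x: np.ndarray, y: np.ndarray, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    return x, y


def pearson_with_wald(x, y) -> tuple[float, float]:
    """Pearson r with the Wald p-value of the regression slope of y on x."""
    x, y = _check_pair(x, y)
    res = sps.linregress(x, y)
    return float(res.rvalue), float(res.pvalue)


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit summary: coefficients (intercept first), R^2, and the
    marginal Pearson r of each predictor with the response."""

    names: tuple[str, ...]
    coefficients: np.ndarray
    r_squared: float
    pearson_r: dict[str, float] = field(default_factory=dict)

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])


def ols_fit(X, y, names: tuple[str, ...] | None = None) -> RegressionResult:
    """Ordinary least squares on a design matrix that already includes an
    intercept column.  R^2 = 1 - SSE/SST (centred)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) with n matching y")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if names is None:
        names = ("intercept",) + tuple(f"x{i}" for i in range(1, X.shape[1]))
    fit = sm.OLS(y, X).fit()
    pearson = {}
    for i, name in enumerate(names):
        col = X[:, i]
        if np.ptp(col) > 0 and np.ptp(y) > 0:
            pearson[name] = float(sps.pearsonr(col, y).statistic)
    return RegressionResult(
        names=tuple(names),
        coefficients=np.asarray(fit.params, dtype=float),
        r_squared=float(fit.rsquared),
        pearson_r=pearson,
    )


def pypy_ebox_model(
    pairs: list[tuple[KmerRecord, ContextFeatures]],
) -> tuple[RegressionResult, RegressionResult, RegressionResult]:
    """Fit mutability on PyPy count alone, E-box indicator alone, and both.

    With a planted suppressive E-box and an enhancing PyPy effect the
    expected signature is a positive PyPy coefficient/correlation, a
    negative E-box one, and a combined R^2 at least as large as either
    single-variable R^2 (nesting).
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError("need at least 3 AGCT records with defined features")
    y = np.array([rec.mut_freq for rec, _ in pairs], dtype=float)
    if np.isnan(y).any():
        raise ValueError("all records must carry an observed mut_freq")
    pypy = np.array([f.pypy_count for _, f in pairs], dtype=float)
    ebox = np.array([float(f.ebox) for _, f in pairs])
    for name, col in (("pypy_count", pypy), ("ebox", ebox)):
        if np.ptp(col) == 0:
            raise ValueError(f"feature {name} is degenerate (all values identical)")
    ones = np.ones_like(y)
    fit_pypy = ols_fit(np.column_stack([ones, pypy]), y, names=("intercept", "pypy_count"))
    fit_ebox = ols_fit(np.column_stack([ones, ebox]), y, names=("intercept", "ebox"))
    fit_both = ols_fit(
        np.column_stack([ones, pypy, ebox]), y, names=("intercept", "pypy_count", "ebox")
    )
    return fit_pypy, fit_ebox, fit_both


# --------------------------------------------------------------------
# two-sample tests
# --------------------------------------------------------------------

def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both samples have at most 20 observations and
    there are no ties; otherwise the normal approximation with tie
    correction (and continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def welch_t(x, y) -> tuple[float, float]:
    """Two-sided Welch t-test (unequal variances, Welch-Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples must have at least 2 observations")
    if np.var(x, ddof=1) == 0 or np.var(y, ddof=1) == 0:
        raise ValueError("zero-variance sample")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------
# contingency analysis
# --------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Clone counts cross-classified by site-6 (rows) and site-3 (columns)
    status of the FW1 CAGCTG hexamer."""

    n_G3G6: int
    n_A3G6: int
    n_G3H6: int
    n_A3H6: int

    def __post_init__(self) -> None:
        for name in ("n_G3G6", "n_A3G6", "n_G3H6", "n_A3H6"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.n_G3G6 + self.n_A3G6 + self.n_G3H6 + self.n_A3H6

    def as_array(self) -> np.ndarray:
        return np.array([[self.n_G3G6, self.n_A3G6], [self.n_G3H6, self.n_A3H6]])


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test by the usual summation of
    hypergeometric probabilities no larger than the observed one.
    Returns (odds_ratio, p)."""
    odds, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    return float(odds), float(p)


def fisher_log10_p_bound(table: ContingencyTable2x2) -> float:
    """Certified log10 upper bound on the two-sided Fisher p, computed in
    log space: p_two_sided <= 2 * min(P(X <= x), P(X >= x)) under the
    hypergeometric null.  Robust to underflow on very large tables."""
    a = table.n_G3G6
    n1 = table.n_G3G6 + table.n_A3G6
    k = table.n_G3G6 + table.n_G3H6
    N = table.total
    hg = sps.hypergeom(N, n1, k)
    log_lower = hg.logcdf(a)
    log_upper = hg.logsf(a - 1)
    return float(min((math.log(2.0) + min(log_lower, log_upper)) / math.log(10.0), 0.0))


def classify_fw1_motif(v_segment: str) -> str:
    """Category of the hexamer at V-segment positions 7-12.

    G3G6 = intact CAGCTG; A3G6 = CAACTG; G3H6 = CAGCTH; A3H6 = CAACTH
    (H = A/C/T).  Any hexamer not matching CA[G/A]CT? — e.g. mutated at
    sites 1, 2, 4 or 5, or a non-G/A base at site 3 — is 'other'.
    """
    if len(v_segment) < 12:
        raise ValueError("V segment must be at least 12 nt")
    hexamer = v_segment[6:12]
    if set(hexamer) - set("ACGT"):
        raise ValueError(f"invalid bases in hexamer {hexamer!r}")
    if hexamer[0:2] != "CA" or hexamer[3:5] != "CT" or hexamer[2] not in "GA":
        return "other"
    site3 = "G" if hexamer[2] == "G" else "A"
    site6 = "G" if hexamer[5] == "G" else "H"
    return f"{site3}3{site6}6"


@dataclass(frozen=True)
class ContingencyResult:
    table: ContingencyTable2x2
    freq_g3_given_g6_unmut: float  # NaN when the denominator is zero
    freq_g3_given_g6_mut: float
    fisher_p: float
    fisher_log10_p_bound: float
    n_other: int


def contingency_from_table(table: ContingencyTable2x2) -> ContingencyResult:
    """Conditional site-3 mutation frequencies and Fisher p for a
    pre-tabulated 2x2 table of clone counts."""
    denom_unmut = table.n_G3G6 + table.n_A3G6
    denom_mut = table.n_G3H6 + table.n_A3H6
    _, p = fisher_exact(table)
    return ContingencyResult(
        table=table,
        freq_g3_given_g6_unmut=table.n_A3G6 / denom_unmut if denom_unmut else math.nan,
        freq_g3_given_g6_mut=table.n_A3H6 / denom_mut if denom_mut else math.nan,
        fisher_p=p,
        fisher_log10_p_bound=fisher_log10_p_bound(table),
        n_other=0,
    )


def contingency_pipeline(
    repertoire: Repertoire | list[list[str]],
    fw1_start: int = 1,
    seed: int = 0,
) -> ContingencyResult:
    """Classify clonally independent sequences and tabulate site-3/site-6
    mutation status of the FW1 CAGCTG.

    ``repertoire`` is either a Repertoire (already one representative per
    clonal group) or a list of clonal groups (lists of sequences), from
    which one sequence per group is chosen at random with ``seed``.
    ``fw1_start`` is the 1-based position where the V segment begins.
    """
    if isinstance(repertoire, Repertoire):
        selected = repertoire.clones
    else:
        rng = np.random.default_rng(seed)
        selected = [group[rng.integers(len(group))] for group in repertoire if group]
    counts = dict.fromkeys(_CATEGORIES, 0)
    n_other = 0
    for seq in selected:
        cat = classify_fw1_motif(seq[fw1_start - 1 :])
        if cat == "other":
            n_other += 1
        else:
            counts[cat] += 1
    table = ContingencyTable2x2(
        n_G3G6=counts["G3G6"],
        n_A3G6=counts["A3G6"],
        n_G3H6=counts["G3H6"],
        n_A3H6=counts["A3H6"],
    )
    if table.total == 0:
        raise ValueError("no classifiable clones (every hexamer fell in 'other')")
    result = contingency_from_table(table)
    return ContingencyResult(
        table=result.table,
        freq_g3_given_g6_unmut=result.freq_g3_given_g6_unmut,
        freq_g3_given_g6_mut=result.freq_g3_given_g6_mut,
        fisher_p=result.fisher_p,
        fisher_log10_p_bound=result.fisher_log10_p_bound,
        n_other=n_other,
    )
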