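"""Paired beta-power inference: channel-wise Wilcoxon screening,
Z-magnitude channel selection, intra-individual paired centering,
correlation-matrix PCA, PC-score testing, and a single IQR-outlier
re-run.

The entry point is the :class:`PairedComparison` model — construct it
from a :class:`BetaPowerTable` (or a tidy DataFrame) and two condition
labels, call :meth:`~PairedComparison.fit`, and read the
:class:`PairedComparisonResults`, statsmodels-style::

    model = PairedComparison.from_dataframe(df, "nutcrack.hold", "cut.hold")
    res = model.fit()
    print(res.summary())

Statistical conventions (documented because every downstream number
depends on them):

* Wilcoxon signed-rank: zero differences dropped, tied absolute
  differences get average ranks, ``W`` is the rank sum of positive
  ``a - b`` differences, ``Z = (W - n(n+1)/4) / sigma`` with the
  tie-corrected ``sigma`` and no continuity correction, two-sided
  ``p = 2 (1 - Phi(|Z|))``.  ``Z`` is negative when the first-listed
  condition tends to be smaller.  For ``n <= 12`` an exact
  enumeration p-value is attached alongside (the normal approximation is
  still what the pipeline reports, for comparability).
* Channel screening excludes the six noise-prone peripheral sites
  Fp1, Fp2, TP9, TP10, FT9, FT10, leaving 26 of 32 channels.
* Selection: if at least five channels reach p < 0.05, the five largest
  |Z| among the significant ones; otherwise the overall top five |Z|.
  Output ordered by |Z| descending, ties broken by montage order.
* PCA is on the correlation matrix of the five selected channels after
  intra-individual paired centering (each subject's two-condition mean
  subtracted), so condition scores come in exact mirror pairs.
* The scree rule plots the components before the largest eigenvalue
  drop, with a floor of two (PC1/PC2 are always inspected).
* If IQR outliers appear on a significant plotted axis, the whole chain
  is re-run exactly once without those subjects.

No correction across the 26 channel tests is applied (matching the
protocol this reimplements); Benjamini-Hochberg adjusted p-values are
emitted as a clearly supplementary column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .montage import CHANNELS_32, Montage, load_montage

__all__ = [
    "BetaPowerTable",
    "PairedTestResult",
    "ChannelSelection",
    "PCAReport",
    "OutlierRule",
    "wilcoxon_signed_rank",
    "p_from_z",
    "compare_channels",
    "select_channels",
    "paired_center",
    "pca_correlation",
    "scree_components",
    "test_pc_scores",
    "iqr_outliers",
    "run_paired_comparison",
    "PairedComparison",
    "PairedComparisonResults",
    "DEFAULT_EXCLUDED_CHANNELS",
]

DEFAULT_EXCLUDED_CHANNELS = ("Fp1", "Fp2", "TP10", "TP9", "FT10", "FT9")
EXACT_ENUMERATION_MAX_N = 12


class BetaPowerTable:
    """Subjects x conditions x channels mean beta amplitudes (uV).

    Thin wrapper over a tidy frame with columns ``subject``,
    ``condition``, ``channel``, ``beta_uv``.
    """

    def __init__(self, data: pd.DataFrame):
        required = {"subject", "condition", "channel", "beta_uv"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"beta table missing columns {sorted(missing)}")
        if (data["beta_uv"] < 0).any():
            raise ValueError("beta amplitudes must be >= 0")
        dup = data.duplicated(["subject", "condition", "channel"])
        if dup.any():
            raise ValueError("duplicate (subject, condition, channel) entries")
        self.data = data.reset_index(drop=True)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique())

    @property
    def channels(self) -> list[str]:
        present = set(self.data["channel"].unique())
        ordered = [c for c in CHANNELS_32 if c in present]
        return ordered + sorted(present - set(ordered))

    def pivot(self, condition: str) -> pd.DataFrame:
        """subjects x channels frame for one condition."""
        sub = self.data[self.data["condition"] == condition]
        if sub.empty:
            raise KeyError(f"condition {condition!r} not in table")
        return sub.pivot(index="subject", columns="channel", values="beta_uv")

    def drop_subjects(self, subjects) -> "BetaPowerTable":
        return BetaPowerTable(
            self.data[~self.data["subject"].isin(set(subjects))].copy()
        )

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BetaPowerTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class PairedTestResult:
    channel: str
    n: int                      # effective pairs after zero-dropping
    W: float                    # rank sum of positive (a - b) differences
    Z: float                    # signed standardized statistic
    p: float                    # two-sided normal approximation
    p_exact: float | None = None
    small_n: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.W <= self.n * (self.n + 1) / 2):
            raise ValueError("W outside [0, n(n+1)/2]")
        if not (0 < self.p <= 1):
            raise ValueError("p must lie in (0, 1]")


@dataclass(frozen=True)
class ChannelSelection:
    comparison: str
    channels: tuple[str, ...]
    rule_used: str              # {"significant-ranked", "top-absZ-fallback"}
    excluded_channels: tuple[str, ...] = DEFAULT_EXCLUDED_CHANNELS


@dataclass(frozen=True)
class OutlierRule:
    k: float = 1.5

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("IQR multiplier must be positive")


@dataclass
class PCAReport:
    channels: tuple[str, ...]
    loadings: pd.DataFrame          # channels x PCs
    scores: pd.DataFrame            # (subject, condition) rows x PCs
    var_explained: np.ndarray       # percent per PC, sums to 100
    n_pcs_plotted: int
    elbow: int
    pc_tests: list[PairedTestResult] = field(default_factory=list)
    outliers_removed: tuple[str, ...] = ()
    rerun: bool = False


def p_from_z(z: float) -> float:
    """Two-sided normal-tail p-value convention: ``2 (1 - Phi(|z|))``."""
    return min(1.0, 2.0 * (1.0 - stats.norm.cdf(abs(z))))


def _exact_two_sided_p(abs_ranks: np.ndarray, W_obs: float) -> float:
    """Exact two-sided p over all sign assignments of the given ranks."""
    n = abs_ranks.shape[0]
    mu = abs_ranks.sum() / 2.0
    dev = abs(W_obs - mu)
    count = 0
    for bits in product((0.0, 1.0), repeat=n):
        w = float(np.dot(bits, abs_ranks))
        if abs(w - mu) >= dev - 1e-12:
            count += 1
    return count / 2.0**n


def wilcoxon_signed_rank(a, b) -> PairedTestResult:
    """Paired Wilcoxon signed-rank test (normal approximation).

    See the module docstring for the exact conventions.  Raises if fewer
    than 5 non-zero differences remain.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0.0]
    n = d.shape[0]
    if n < 5:
        raise ValueError(
            f"too few non-zero paired differences (n={n} < 5) for the test"
        )
    ranks = stats.rankdata(np.abs(d))
    W = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 from the null variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        raise ValueError("degenerate variance (all differences tied at one value)")
    Z = (W - mu) / np.sqrt(var)
    p = max(p_from_z(Z), np.finfo(float).tiny)
    small = n <= EXACT_ENUMERATION_MAX_N
    p_exact = _exact_two_sided_p(ranks, W) if small else None
    return PairedTestResult("", n, W, float(Z), float(p), p_exact, small)


def compare_channels(
    table: BetaPowerTable,
    cond_a: str,
    cond_b: str,
    excluded_channels=DEFAULT_EXCLUDED_CHANNELS,
) -> list[PairedTestResult]:
    """One paired Wilcoxon per retained channel, on matched subjects."""
    A = table.pivot(cond_a)
    B = table.pivot(cond_b)
    shared = [s for s in A.index if s in set(B.index)]
    if len(shared) < 5:
        raise ValueError(f"only {len(shared)} shared subjects; need >= 5")
    excluded = set(excluded_channels)
    out = []
    for ch in table.channels:
        if ch in excluded or ch not in A.columns or ch not in B.columns:
            continue
        r = wilcoxon_signed_rank(A.loc[shared, ch].to_numpy(),
                                 B.loc[shared, ch].to_numpy())
        out.append(PairedTestResult(ch, r.n, r.W, r.Z, r.p, r.p_exact, r.small_n))
    return out


def _montage_rank(channel: str) -> int:
    try:
        return CHANNELS_32.index(channel)
    except ValueError:
        return len(CHANNELS_32)


def select_channels(
    results: list[PairedTestResult],
    comparison: str = "",
    n_select: int = 5,
    alpha: float = 0.05,
    excluded_channels=DEFAULT_EXCLUDED_CHANNELS,
) -> ChannelSelection:
    """Pick the channels entering the PCA, by |Z| magnitude.

    Significant channels (p < alpha) are preferred when at least
    ``n_select`` exist; otherwise the overall top ``n_select`` by |Z|.
    Output is |Z|-descending with montage-order tie-breaks.
    """
    if len(results) < n_select:
        raise ValueError(f"need at least {n_select} channel results")
    sig = [r for r in results if r.p < alpha]
    if len(sig) >= n_select:
        pool, rule = sig, "significant-ranked"
    else:
        pool, rule = list(results), "top-absZ-fallback"
    ordered = sorted(pool, key=lambda r: (-abs(r.Z), _montage_rank(r.channel)))
    return ChannelSelection(
        comparison,
        tuple(r.channel for r in ordered[:n_select]),
        rule,
        tuple(excluded_channels),
    )


def paired_center(
    table: BetaPowerTable, cond_a: str, cond_b: str,
    channels: list[str] | None = None,
) -> pd.DataFrame:
    """Subtract each subject's two-condition mean, channel by channel.

    Returns a frame indexed by (subject, condition) with channel columns;
    by construction ``x'(s, A, c) = -x'(s, B, c)`` exactly.
    """
    A = table.pivot(cond_a)
    B = table.pivot(cond_b)
    shared = [s for s in A.index if s in set(B.index)]
    if not shared:
        raise ValueError("no shared subjects between conditions")
    channels = channels or [c for c in table.channels
                            if c in A.columns and c in B.columns]
    A = A.loc[shared, channels]
    B = B.loc[shared, channels]
    if A.isna().any().any() or B.isna().any().any():
        raise ValueError("missing pair member in the beta table")
    mean = (A + B) / 2.0
    rows = []
    for cond, X in ((cond_a, A - mean), (cond_b, B - mean)):
        X = X.copy()
        X.insert(0, "subject", shared)
        X.insert(1, "condition", cond)
        rows.append(X)
    out = pd.concat(rows, ignore_index=True)
    return out.set_index(["subject", "condition"])


def pca_correlation(centered: pd.DataFrame) -> PCAReport:
    """Correlation-matrix PCA of the centered two-condition observations.

    Columns are standardized (mean 0, unit variance), the correlation
    matrix eigen-decomposed, loadings sign-fixed so each PC's largest
    |loading| is positive, scores are the standardized data projected on
    the loadings, and variance explained is reported in percent (summing
    to 100 over all PCs).
    """
    X = centered.to_numpy(dtype=float)
    n_obs, n_var = X.shape
    if n_obs < 6:
        raise ValueError("need at least 3 subjects (6 paired observations)")
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        bad = [centered.columns[i] for i in zero]
        raise ValueError(f"zero-variance channel column(s): {bad}")
    Zm = (X - X.mean(axis=0)) / sd
    corr = (Zm.T @ Zm) / (n_obs - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    for j in range(n_var):
        i_max = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i_max, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    var_explained = eigval / eigval.sum() * 100.0
    pcs = [f"PC{j + 1}" for j in range(n_var)]
    loadings = pd.DataFrame(eigvec, index=centered.columns, columns=pcs)
    scores = pd.DataFrame(Zm @ eigvec, index=centered.index, columns=pcs)
    n_plot = scree_components(var_explained)
    return PCAReport(
        channels=tuple(centered.columns),
        loadings=loadings,
        scores=scores,
        var_explained=var_explained,
        n_pcs_plotted=n_plot,
        elbow=_elbow(var_explained),
    )


def _elbow(var_explained: np.ndarray) -> int:
    drops = np.diff(np.asarray(var_explained, dtype=float))
    return int(np.argmax(-drops)) + 1


def scree_components(var_explained) -> int:
    """Components to plot: before the largest drop-off, floor of two."""
    var_explained = np.asarray(var_explained, dtype=float)
    if var_explained.shape[0] < 2:
        raise ValueError("need at least 2 components")
    return max(2, min(_elbow(var_explained), var_explained.shape[0]))


def test_pc_scores(report: PCAReport, cond_a: str, cond_b: str) -> PCAReport:
    """Paired Wilcoxon of condition-A vs condition-B scores per plotted axis."""
    tests = []
    sc = report.scores
    subjects = sc.index.get_level_values("subject").unique()
    for j in range(report.n_pcs_plotted):
        pc = f"PC{j + 1}"
        a = sc.xs(cond_a, level="condition").loc[subjects, pc].to_numpy()
        b = sc.xs(cond_b, level="condition").loc[subjects, pc].to_numpy()
        r = wilcoxon_signed_rank(a, b)
        tests.append(PairedTestResult(pc, r.n, r.W, r.Z, r.p, r.p_exact, r.small_n))
    report.pc_tests = tests
    return report


def iqr_outliers(scores: pd.Series, rule: OutlierRule = OutlierRule()) -> set[str]:
    """Subjects with any score outside ``[Q1 - k IQR, Q3 + k IQR]``.

    Quartiles by linear interpolation (the numpy default).
    """
    values = scores.to_numpy(dtype=float)
    if np.unique(scores.index.get_level_values("subject")).size < 5:
        raise ValueError("need at least 5 subjects for outlier screening")
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - rule.k * iqr, q3 + rule.k * iqr
    mask = (values < lo) | (values > hi)
    return set(scores.index.get_level_values("subject")[mask])


# ---------------------------------------------------------------------------
# model / results


class PairedComparison:
    """Paired two-condition comparison model over a beta-power table.

    Parameters
    ----------
    table : BetaPowerTable
    cond_a, cond_b : str
        Condition labels; the Z-sign convention makes Z negative when
        ``cond_a`` tends to be smaller.
    excluded_channels : sequence of str
        Channels never entering the statistics.
    alpha : float
        Significance level for screening, selection and PC tests.
    k_iqr : float
        IQR multiplier of the outlier rule.
    rerun_on_outliers : bool
        Repeat the whole chain once without outlier subjects (default).
    """

    def __init__(
        self,
        table: BetaPowerTable,
        cond_a: str,
        cond_b: str,
        excluded_channels=DEFAULT_EXCLUDED_CHANNELS,
        alpha: float = 0.05,
        k_iqr: float = 1.5,
        n_select: int = 5,
        rerun_on_outliers: bool = True,
    ):
        if cond_a == cond_b:
            raise ValueError("cannot compare a condition with itself")
        self.table = table
        self.cond_a = cond_a
        self.cond_b = cond_b
        self.excluded_channels = tuple(excluded_channels)
        self.alpha = alpha
        self.k_iqr = k_iqr
        self.n_select = n_select
        self.rerun_on_outliers = rerun_on_outliers

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, cond_a: str, cond_b: str, **kw
                       ) -> "PairedComparison":
        return cls(BetaPowerTable(df), cond_a, cond_b, **kw)

    def _single_pass(self, table: BetaPowerTable):
        results = compare_channels(table, self.cond_a, self.cond_b,
                                   self.excluded_channels)
        name = f"{self.cond_a} vs {self.cond_b}"
        selection = select_channels(results, name, self.n_select, self.alpha,
                                    self.excluded_channels)
        centered = paired_center(table, self.cond_a, self.cond_b,
                                 list(selection.channels))
        report = pca_correlation(centered)
        report = test_pc_scores(report, self.cond_a, self.cond_b)
        return results, selection, report

    def fit(self) -> "PairedComparisonResults":
        results, selection, report = self._single_pass(self.table)
        outliers: set[str] = set()
        rule = OutlierRule(self.k_iqr)
        for j, t in enumerate(report.pc_tests):
            if t.p < self.alpha:
                outliers |= iqr_outliers(report.scores[f"PC{j + 1}"], rule)
        first_pass = (results, selection, report)
        rerun = False
        if outliers and self.rerun_on_outliers:
            remaining = set(self.table.subjects) - outliers
            if len(remaining) >= 5:
                results, selection, report = self._single_pass(
                    self.table.drop_subjects(outliers)
                )
                report.outliers_removed = tuple(sorted(outliers))
                report.rerun = rerun = True
        return PairedComparisonResults(
            model=self,
            channel_tests=results,
            selection=selection,
            pca=report,
            outliers_removed=tuple(sorted(outliers)),
            rerun=rerun,
            first_pass=first_pass if rerun else None,
        )


@dataclass
class PairedComparisonResults:
    """Fitted artifacts of one paired comparison.

    ``channel_tests``, ``selection`` and ``pca`` reflect the final pass
    (after the single outlier re-run, if it happened); ``first_pass``
    keeps the pre-rerun artifacts when a re-run occurred.
    """

    model: PairedComparison
    channel_tests: list[PairedTestResult]
    selection: ChannelSelection
    pca: PCAReport
    outliers_removed: tuple[str, ...]
    rerun: bool
    first_pass: tuple | None = None

    @property
    def comparison(self) -> str:
        return f"{self.model.cond_a} vs {self.model.cond_b}"

    def channel_frame(self) -> pd.DataFrame:
        """Channel statistics with a supplementary BH-adjusted column."""
        df = pd.DataFrame(
            [{"channel": r.channel, "n": r.n, "W": r.W, "Z": r.Z, "p": r.p}
             for r in self.channel_tests]
        )
        df["p_bh_supplementary"] = _benjamini_hochberg(df["p"].to_numpy())
        return df

    def pc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"axis": r.channel, "n": r.n, "W": r.W, "Z": r.Z, "p": r.p,
              "var_explained_pct": self.pca.var_explained[i]}
             for i, r in enumerate(self.pca.pc_tests)]
        )

    def mean_abs_difference(self) -> pd.Series:
        """Grand-average |A - B| beta per channel (topomap input)."""
        A = self.model.table.pivot(self.model.cond_a)
        B = self.model.table.pivot(self.model.cond_b)
        shared = [s for s in A.index if s in set(B.index)]
        cols = [c for c in A.columns if c in B.columns]
        return (A.loc[shared, cols] - B.loc[shared, cols]).abs().mean(axis=0)

    def summary(self) -> str:
        lines = [
            f"Paired comparison: {self.comparison}",
            f"subjects: {len(self.model.table.subjects) - len(self.outliers_removed)}"
            + (f" (re-run without outliers: {', '.join(self.outliers_removed)})"
               if self.rerun else ""),
            f"channels tested: {len(self.channel_tests)} "
            f"(excluded: {', '.join(self.model.excluded_channels)})",
            "",
            f"selected channels ({self.selection.rule_used}):",
        ]
        by_name = {r.channel: r for r in self.channel_tests}
        for ch in self.selection.channels:
            r = by_name[ch]
            lines.append(f"  {ch:>4s}   Z = {r.Z:6.2f}   p = {r.p:.4g}")
        lines.append("")
        lines.append("principal components (correlation matrix, paired-centered):")
        for i, t in enumerate(self.pca.pc_tests):
            lines.append(
                f"  PC{i + 1}: var = {self.pca.var_explained[i]:5.2f}%   "
                f"Z = {t.Z:6.2f}   p = {t.p:.4g}"
            )
        return "\n".join(lines)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.shape[0]
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def run_paired_comparison(
    table: BetaPowerTable,
    cond_a: str,
    cond_b: str,
    **kwargs,
) -> PairedComparisonResults:
    """Functional facade over :class:`PairedComparison` (build + fit)."""
    return PairedComparison(table, cond_a, cond_b, **kwargs).fit()
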