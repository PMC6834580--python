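"""3'UTR-length-matched resampling tests for miRNA target repression.

Longer 3'UTRs accrue more chance seed matches, so naive target-vs-
non-target comparisons confound target status with UTR length.  The
procedure implemented here removes the confound by stratified
subsampling: 3'UTR lengths are binned (half-open bins of 200 nt starting
at 0; the final bin is closed at the global maximum length), and within
each bin the larger of the target / non-target groups is subsampled
without replacement to the size of the smaller, so the matched vectors
have identical per-bin length composition.

On the matched vectors two tests are run:

* a one-sided two-sample Kolmogorov-Smirnov test on log2 fold changes
  (alternative ``greater`` for up-regulated miRNAs -- targets expected
  repressed, i.e. stochastically smaller; ``less`` for down-regulated
  miRNAs -- targets expected de-repressed), and
* a one-sided (``greater``) Fisher exact test for enrichment of
  opposite-direction differentially expressed mRNAs among targets; here
  gene identifiers rather than fold-change values are matched.

Because the subsampling is stochastic, each test is repeated ``n_reps``
times (default 100) with independent sub-seeds and the arithmetic mean
p-value is reported; the mean of p-values is not itself a valid p-value
under the null, so the median p and the per-repetition rejection
fraction are reported alongside as diagnostics.  Mean p-values across
the test family are Benjamini-Hochberg adjusted at FDR 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_BIN_WIDTH = 200
DEFAULT_N_REPS = 100
DEFAULT_FDR_ALPHA = 0.05


@dataclass(frozen=True)
class TestConfig:
    __test__ = False  # not a pytest class, despite the name

    bin_width: int = DEFAULT_BIN_WIDTH
    n_reps: int = DEFAULT_N_REPS
    fdr_alpha: float = DEFAULT_FDR_ALPHA
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# Binning and stratified matching


def make_bins(
    target_lengths, nontarget_lengths, bin_width: int = DEFAULT_BIN_WIDTH
) -> list[tuple[float, float]]:
    """Histogram bins over both groups' 3'UTR lengths.

    Half-open bins ``[0, w), [w, 2w), ...``; the final bin is closed on
    the right at the maximum length over both groups.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    t = np.asarray(target_lengths)
    n = np.asarray(nontarget_lengths)
    if t.size == 0 or n.size == 0:
        raise ValueError("empty length vector")
    if (t <= 0).any() or (n <= 0).any():
        raise ValueError("lengths must be positive")
    max_len = max(t.max(), n.max())
    n_bins = max(1, math.ceil(max_len / bin_width))
    edges = [(float(i * bin_width), float(min((i + 1) * bin_width, max_len)))
             for i in range(n_bins)]
    return edges


def assign_bins(lengths, max_len: float, bin_width: int) -> np.ndarray:
    """Bin index per length under the :func:`make_bins` convention."""
    lengths = np.asarray(lengths)
    n_bins = max(1, math.ceil(max_len / bin_width))
    return np.minimum(lengths // bin_width, n_bins - 1).astype(np.intp)


@dataclass
class MatchedSample:
    """Per-repetition length-matched target/non-target draw."""

    target_idx: np.ndarray  # indices into the target item vector
    nontarget_idx: np.ndarray
    n_matched: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.target_idx) != len(self.nontarget_idx):
            raise AssertionError("matched vectors must have equal length")
        self.n_matched = len(self.target_idx)


def stratified_match(
    target_lengths,
    nontarget_lengths,
    bin_width: int,
    rng: np.random.Generator,
) -> MatchedSample:
    """One stratified draw equalising per-bin target/non-target counts.

    Within each length bin the larger group is subsampled without
    replacement to the smaller group's count; bins where either group is
    empty contribute nothing.  Equal-count bins pass through unsampled,
    order preserved.  A fully unmatched configuration (disjoint bins)
    yields an empty MatchedSample, which callers report as NA.
    """
    t = np.asarray(target_lengths)
    n = np.asarray(nontarget_lengths)
    bins = make_bins(t, n, bin_width)
    max_len = max(t.max(), n.max())
    tb = assign_bins(t, max_len, bin_width)
    nb = assign_bins(n, max_len, bin_width)
    t_keep, n_keep = [], []
    for b in range(len(bins)):
        ti = np.flatnonzero(tb == b)
        ni = np.flatnonzero(nb == b)
        if ti.size == 0 or ni.size == 0:
            continue
        k = min(ti.size, ni.size)
        if ti.size > k:
            ti = rng.choice(ti, size=k, replace=False)
        if ni.size > k:
            ni = rng.choice(ni, size=k, replace=False)
        t_keep.append(ti)
        n_keep.append(ni)
    empty = np.empty(0, dtype=np.intp)
    return MatchedSample(
        np.concatenate(t_keep) if t_keep else empty,
        np.concatenate(n_keep) if n_keep else empty,
    )


def _shared_bin_pools(
    t_len: np.ndarray, n_len: np.ndarray, bin_width: int
) -> list[tuple[np.ndarray, np.ndarray, int]]:
    """Per-bin (target indices, non-target indices, matched count) for the
    bins populated by both groups; the same min rule as stratified_match."""
    max_len = max(t_len.max(), n_len.max())
    n_bins = max(1, math.ceil(max_len / bin_width))
    tb = assign_bins(t_len, max_len, bin_width)
    nb = assign_bins(n_len, max_len, bin_width)
    pools = []
    for b in range(n_bins):
        ti = np.flatnonzero(tb == b)
        ni = np.flatnonzero(nb == b)
        if ti.size and ni.size:
            pools.append((ti, ni, min(ti.size, ni.size)))
    return pools


# ---------------------------------------------------------------------------
# Statistical tests


def _dplus(x: np.ndarray, y: np.ndarray) -> float:
    """sup_t (F_x(t) - F_y(t)) over the pooled sample points."""
    xs = np.sort(x)
    ys = np.sort(y)
    pooled = np.concatenate([xs, ys])
    fx = np.searchsorted(xs, pooled, side="right") / xs.size
    fy = np.searchsorted(ys, pooled, side="right") / ys.size
    return float(np.max(fx - fy))


def ks_one_sided(
    x, y, alternative: str, method: str = "asymp"
) -> tuple[float, float]:
    """One-sided two-sample Kolmogorov-Smirnov test.

    ``alternative="greater"`` uses D+ = sup(F_x - F_y): a small p means x
    is stochastically smaller than y (its ECDF lies above), e.g. target
    fold changes depressed relative to non-targets.  ``"less"`` uses
    D- = sup(F_y - F_x).

    ``method="asymp"`` (default) gives the one-sided asymptotic p-value
    ``exp(-2 D^2 nm/(n+m))`` capped at 1; ``method="exact"`` enumerates
    all pooled-rank assignments (permutation null, feasible for
    n + m <= ~14).

    Returns ``(D, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if alternative == "greater":
        d = _dplus(x, y)
    elif alternative == "less":
        d = _dplus(y, x)
    else:
        raise ValueError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    n, m = x.size, y.size
    if method == "asymp":
        p = min(1.0, math.exp(-2.0 * d * d * n * m / (n + m)))
    elif method == "exact":
        p = _ks_exact_pvalue(x, y, d, alternative)
    else:
        raise ValueError(f"unknown method: {method}")
    return d, p


def _ks_exact_pvalue(x, y, d_obs: float, alternative: str) -> float:
    """Exact permutation p-value: P(D >= d_obs) over all pooled splits."""
    pooled = np.concatenate([x, y])
    n = len(x)
    idx = range(len(pooled))
    tol = 1e-12
    hits = total = 0
    for combo in itertools.combinations(idx, n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(combo)] = True
        xs, ys = pooled[mask], pooled[~mask]
        d = _dplus(xs, ys) if alternative == "greater" else _dplus(ys, xs)
        hits += d >= d_obs - tol
        total += 1
    return hits / total


def fisher_one_sided(table) -> float:
    """One-sided ('greater') Fisher exact test on a 2x2 table.

    Rows are {target, non-target}, columns {opposite-direction DE, not};
    p is the hypergeometric upper-tail probability of the observed or a
    more extreme top-left cell.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("contingency table must be 2x2")
    if (table < 0).any():
        raise ValueError("negative counts")
    return float(stats.fisher_exact(table, alternative="greater")[1])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, original order.

    NaN entries (NA tests) are excluded from the family (m = number of
    non-NA p-values) and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        from statsmodels.stats.multitest import multipletests

        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Repeated matched tests


@dataclass
class MatchedTestResult:
    """Outcome of one repeated length-matched test."""

    test_id: str
    test_type: str  # "ks" | "fisher"
    comparison: str
    alternative: str
    rep_pvalues: np.ndarray
    n_matched: np.ndarray  # per-rep matched group size
    na_reason: str | None = None
    bh_q: float = np.nan

    @property
    def is_na(self) -> bool:
        return self.na_reason is not None

    @property
    def mean_p(self) -> float:
        return float(np.mean(self.rep_pvalues)) if not self.is_na else np.nan

    @property
    def median_p(self) -> float:
        return float(np.median(self.rep_pvalues)) if not self.is_na else np.nan

    def rejection_fraction(self, alpha: float = 0.05) -> float:
        if self.is_na:
            return np.nan
        return float(np.mean(self.rep_pvalues < alpha))


def _rep_rng(master_seed: int, rep: int) -> np.random.Generator:
    # counter-based sub-seeding: repetitions are independent streams and
    # the whole run is reproducible from the master seed
    return np.random.default_rng([master_seed, rep])


def run_matched_test(
    test_id: str,
    test_type: str,
    direction: str,
    target_mask: np.ndarray,
    lengths: np.ndarray,
    log2fc: np.ndarray | None = None,
    opposite_de_mask: np.ndarray | None = None,
    cfg: TestConfig | None = None,
    comparison: str = "",
) -> MatchedTestResult:
    """Repeat stratified matching + one test ``cfg.n_reps`` times.

    Parameters
    ----------
    test_type
        ``"ks"`` (fold-change distributions; needs ``log2fc``) or
        ``"fisher"`` (opposite-direction DE enrichment; needs
        ``opposite_de_mask``, a per-gene boolean of DE in the direction
        opposite to the miRNA's).
    direction
        The miRNA's DE direction: ``up`` -> KS alternative ``greater``
        (targets repressed), ``down`` -> ``less`` (targets de-repressed).
        Fisher is always one-sided ``greater``.
    target_mask, lengths, log2fc, opposite_de_mask
        Aligned per-gene arrays over the retained gene universe.
    """
    cfg = cfg or TestConfig()
    if test_type not in ("ks", "fisher"):
        raise ValueError(f"unknown test_type: {test_type}")
    if direction not in ("up", "down"):
        raise ValueError(f"miRNA direction must be 'up' or 'down', got {direction!r}")
    target_mask = np.asarray(target_mask, dtype=bool)
    lengths = np.asarray(lengths)
    alternative = "greater" if direction == "up" else "less"
    if test_type == "fisher":
        alternative = "greater"
        if opposite_de_mask is None:
            raise ValueError("fisher test needs opposite_de_mask")
        opposite_de_mask = np.asarray(opposite_de_mask, dtype=bool)
    else:
        if log2fc is None:
            raise ValueError("ks test needs log2fc values")
        log2fc = np.asarray(log2fc, dtype=float)

    t_len = lengths[target_mask]
    n_len = lengths[~target_mask]

    def na(reason: str) -> MatchedTestResult:
        return MatchedTestResult(
            test_id, test_type, comparison, alternative,
            np.full(cfg.n_reps, np.nan), np.zeros(cfg.n_reps, dtype=int), reason,
        )

    if t_len.size == 0:
        return na("no predicted targets in retained gene set")
    if n_len.size == 0:
        return na("no non-targets in retained gene set")

    t_pool = np.flatnonzero(target_mask)
    n_pool = np.flatnonzero(~target_mask)
    # bin membership is a function of the data only: compute once, then
    # draw the per-repetition subsamples from the cached per-bin pools
    shared_bins = _shared_bin_pools(t_len, n_len, cfg.bin_width)
    if not shared_bins:
        return na("no length bin contains both targets and non-targets")
    pvals = np.empty(cfg.n_reps)
    sizes = np.empty(cfg.n_reps, dtype=int)
    for rep in range(cfg.n_reps):
        rng = _rep_rng(cfg.rng_seed, rep)
        t_keep, n_keep = [], []
        for ti, ni, k in shared_bins:
            t_keep.append(rng.choice(ti, size=k, replace=False) if ti.size > k else ti)
            n_keep.append(rng.choice(ni, size=k, replace=False) if ni.size > k else ni)
        ms = MatchedSample(np.concatenate(t_keep), np.concatenate(n_keep))
        sizes[rep] = ms.n_matched
        ti = t_pool[ms.target_idx]
        ni = n_pool[ms.nontarget_idx]
        if test_type == "ks":
            _, pvals[rep] = ks_one_sided(log2fc[ti], log2fc[ni], alternative)
        else:
            a = int(opposite_de_mask[ti].sum())
            c = int(opposite_de_mask[ni].sum())
            table = [[a, ms.n_matched - a], [c, ms.n_matched - c]]
            pvals[rep] = fisher_one_sided(table)
    return MatchedTestResult(
        test_id, test_type, comparison, alternative, pvals, sizes
    )


def pairwise_combination_tests(
    de_mirnas: dict[str, str],
    targets_by_mirna: dict[str, set[str]],
    gene_ids: list[str],
    lengths: np.ndarray,
    log2fc: np.ndarray | None = None,
    opposite_de_masks: dict[str, np.ndarray] | None = None,
    test_type: str = "ks",
    cfg: TestConfig | None = None,
    comparison: str = "",
) -> list[MatchedTestResult]:
    """Combinatorial tests for pairs of same-direction DE miRNAs.

    For each unordered pair of miRNAs sharing a direction label, the
    target set is the intersection of the two predicted target sets and
    the non-targets are genes targeted by neither; the repeated matched
    test then runs as for a single miRNA.  Fewer than two same-direction
    miRNAs give an empty list.
    """
    cfg = cfg or TestConfig()
    results = []
    by_direction: dict[str, list[str]] = {}
    for m, d in de_mirnas.items():
        by_direction.setdefault(d, []).append(m)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for direction, members in sorted(by_direction.items()):
        for a, b in itertools.combinations(sorted(members), 2):
            shared = targets_by_mirna.get(a, set()) & targets_by_mirna.get(b, set())
            either = targets_by_mirna.get(a, set()) | targets_by_mirna.get(b, set())
            target_mask = np.zeros(len(gene_ids), dtype=bool)
            for g in shared:
                if g in gene_index:
                    target_mask[gene_index[g]] = True
            eligible = np.ones(len(gene_ids), dtype=bool)
            for g in either - shared:
                if g in gene_index:
                    eligible[gene_index[g]] = False
            opp = None
            if opposite_de_masks is not None:
                opp = np.asarray(opposite_de_masks[a], dtype=bool)[eligible]
            res = run_matched_test(
                f"{a}+{b}", test_type, direction,
                target_mask[eligible], np.asarray(lengths)[eligible],
                None if log2fc is None else np.asarray(log2fc)[eligible],
                opp, cfg, comparison,
            )
            results.append(res)
    return results


def results_frame(results: list[MatchedTestResult], fdr_alpha: float = DEFAULT_FDR_ALPHA) -> pd.DataFrame:
    """Summarise results and BH-adjust mean p-values across the family.

    NA tests are excluded from the BH family and keep a NaN q-value.
    """
    mean_ps = [r.mean_p for r in results]
    qs = bh_adjust(mean_ps)
    for r, q in zip(results, qs):
        r.bh_q = float(q)
    return pd.DataFrame(
        {
            "test_id": [r.test_id for r in results],
            "test_type": [r.test_type for r in results],
            "comparison": [r.comparison for r in results],
            "alternative": [r.alternative for r in results],
            "n_matched_median": [
                int(np.median(r.n_matched)) if not r.is_na else 0 for r in results
            ],
            "n_reps": [len(r.rep_pvalues) for r in results],
            "mean_p": mean_ps,
            "median_p": [r.median_p for r in results],
            "rejection_fraction": [r.rejection_fraction() for r in results],
            "bh_q": qs,
            "significant": [
                (not r.is_na) and q < fdr_alpha for r, q in zip(results, qs)
            ],
            "na_reason": [r.na_reason or "" for r in results],
        }
    )
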