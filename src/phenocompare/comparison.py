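"""Phenotype-level similarity between two gene sets.

Two gene sets are compared through the sets of terms significantly
enriched in each (the Phenotypic Overlap Ratio, POR) or through all
annotated terms (the Relaxed POR, RPOR).  The overlap coefficient is
either the Jaccard index

    POR = |A ∩ B| / |A ∪ B|

or the Forbes coefficient with Alroy's correction,

    N = a + b + c,   POR = a (N + √N) / [(a+b)(a+c) + a√N + bc/2]

with a = |A ∩ B|, b = |A \\ B|, c = |B \\ A|.  Significance is assessed by
randomization: random gene sets of matching size are drawn uniformly
from the shared universe and the empirical P value is the proportion of
null coefficients strictly greater than the observed one.  In the
*conditional* mode (G' derived from G) only the derived side is
randomized; in the *overlapping* mode each side is randomized in turn and
the 2m null values pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import hypergeom

from ._engine import DbIndex
from .annotation_db import AnnotationDatabase
from .enrichment import EnrichmentResult, GeneSet, adjust_pvalues, enrich
from .errors import DataError

MODES = ("overlapping", "conditional")
METHODS = ("jaccard", "forbes")


@dataclass(frozen=True)
class SignificantTermSet:
    """The (database, term_id) pairs significant for one gene set."""

    source_label: str
    terms: frozenset  # of (database, term_id)
    criterion: str = "raw"
    alpha: float = 0.05

    def __len__(self):
        return len(self.terms)


@dataclass(frozen=True)
class OverlapCounts:
    """a = shared, b = exclusive to A, c = exclusive to B."""

    a: int
    b: int
    c: int

    def __post_init__(self):
        if min(self.a, self.b, self.c) < 0:
            raise DataError("overlap counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c

    @classmethod
    def from_sets(cls, A, B) -> "OverlapCounts":
        A, B = set(A), set(B)
        return cls(a=len(A & B), b=len(A - B), c=len(B - A))


@dataclass(frozen=True)
class RandomizationPlan:
    """Replicate count, null mode and seed for the POR significance test."""

    m: int = 1000
    mode: str = "overlapping"
    seed: int = 0

    def __post_init__(self):
        if self.m < 1:
            raise DataError("randomization needs m >= 1 replicates")
        if self.mode not in MODES:
            raise DataError(f"unknown randomization mode {self.mode!r}")


@dataclass(frozen=True)
class RelevanceRegression:
    """OLS of per-term gene counts in B on counts in A over shared terms."""

    n_terms: int
    slope: float = float("nan")
    intercept: float = float("nan")
    r2: float = float("nan")
    r2_adj: float = float("nan")
    p_value: float = float("nan")
    defined: bool = False
    low_information: bool = False


def _as_term_set(x) -> set:
    return set(x.terms) if isinstance(x, SignificantTermSet) else set(x)


def significant_terms(result: EnrichmentResult, alpha: float | None = None,
                      criterion: str | None = None,
                      include_sentinels: bool = False) -> SignificantTermSet:
    """Extract the significant (database, term) pairs from an enrichment run."""
    alpha = result.alpha if alpha is None else alpha
    criterion = result.criterion if criterion is None else criterion
    rows = result.significant(alpha, criterion, include_sentinels)
    terms = frozenset(zip(rows["database"], rows["term_id"]))
    return SignificantTermSet(result.label, terms, criterion, alpha)


def annotated_terms(result: EnrichmentResult, include_sentinels: bool = False) -> SignificantTermSet:
    """All tested (g >= 1) terms regardless of significance (RPOR sets)."""
    rows = result.table
    if not include_sentinels:
        rows = rows[~rows["is_sentinel"]]
    terms = frozenset(zip(rows["database"], rows["term_id"]))
    return SignificantTermSet(result.label, terms, "annotated", 1.0)


# ----------------------------------------------------------------------
# Overlap coefficients
# ----------------------------------------------------------------------

def por_jaccard(A, B) -> float:
    """Jaccard overlap of two term sets; 0 when both are empty."""
    A, B = _as_term_set(A), _as_term_set(B)
    union = len(A | B)
    return len(A & B) / union if union else 0.0


def por_jaccard_from_counts(intersection: int, union: int) -> float:
    """Jaccard coefficient from pre-tabulated intersection/union counts."""
    if intersection < 0 or union < intersection:
        raise DataError("need 0 <= intersection <= union")
    return intersection / union if union else 0.0


def por_forbes(counts: OverlapCounts) -> float:
    """Forbes coefficient with Alroy's correction.

    Equals 0 when nothing is shared and 1 when either set is a subset of
    the other (b = 0 or c = 0 with a > 0).
    """
    a, b, c, n = counts.a, counts.b, counts.c, counts.n
    if n == 0 or a == 0:
        return 0.0
    if b == 0 or c == 0:
        return 1.0
    sqrt_n = math.sqrt(n)
    return a * (n + sqrt_n) / ((a + b) * (a + c) + a * sqrt_n + b * c / 2.0)


def por(A, B, method: str = "jaccard") -> float:
    if method == "jaccard":
        return por_jaccard(A, B)
    if method == "forbes":
        return por_forbes(OverlapCounts.from_sets(_as_term_set(A), _as_term_set(B)))
    raise DataError(f"unknown method {method!r}")


def empirical_pvalue(null_values, observed: float, pseudocount: bool = False) -> float:
    """Proportion of null values strictly greater than the observed one.

    Ties (null exactly equal to observed) do NOT count as exceeding.
    With ``pseudocount=True`` the add-one estimate (1 + #{null >= obs})
    / (m + 1) is returned instead, guaranteeing P > 0.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise DataError("empirical P needs at least one null value")
    if pseudocount:
        return float((1 + np.sum(null_values >= observed)) / (null_values.size + 1))
    return float(np.sum(null_values > observed) / null_values.size)


# ----------------------------------------------------------------------
# Differential terms & relevance
# ----------------------------------------------------------------------

@dataclass
class DifferentialTables:
    shared: pd.DataFrame
    exclusive_to_a: pd.DataFrame
    exclusive_to_b: pd.DataFrame


def _merged_table(resA: EnrichmentResult, resB: EnrichmentResult) -> pd.DataFrame:
    cols = ["database", "term_id", "term_name", "is_sentinel", "gdb", "g", "p_raw",
            "p_bonferroni", "q_fdr"]
    a = resA.table[cols].rename(columns={c: f"{c}_a" for c in cols[5:]})
    b = resB.table[cols].rename(columns={c: f"{c}_b" for c in cols[5:]})
    merged = a.merge(b, on=["database", "term_id", "term_name", "is_sentinel", "gdb"],
                     how="outer")
    # untested in one set: g = 0 and upper-tail P(X >= 0) = 1
    for side in ("a", "b"):
        merged[f"g_{side}"] = merged[f"g_{side}"].fillna(0).astype(int)
        merged[f"p_raw_{side}"] = merged[f"p_raw_{side}"].fillna(1.0)
    return merged.sort_values(["database", "term_id"]).reset_index(drop=True)


def differential_terms(resA: EnrichmentResult, resB: EnrichmentResult,
                       alpha: float | None = None, criterion: str | None = None,
                       include_sentinels: bool = False) -> DifferentialTables:
    """Partition the union of significant terms into shared / A-only / B-only.

    Exclusive rows carry the term's gene count and raw P value in the
    other set as well (P = 1 when the term is untested there).
    """
    if set(resA.databases) != set(resB.databases):
        raise DataError(
            f"database mismatch: {sorted(resA.databases)} vs {sorted(resB.databases)}")
    setA = significant_terms(resA, alpha, criterion, include_sentinels).terms
    setB = significant_terms(resB, alpha, criterion, include_sentinels).terms
    merged = _merged_table(resA, resB)
    key = list(zip(merged["database"], merged["term_id"]))
    in_a = np.array([k in setA for k in key])
    in_b = np.array([k in setB for k in key])
    return DifferentialTables(
        shared=merged[in_a & in_b].reset_index(drop=True),
        exclusive_to_a=merged[in_a & ~in_b].reset_index(drop=True),
        exclusive_to_b=merged[~in_a & in_b].reset_index(drop=True),
    )


def relevance_regression(pairs) -> RelevanceRegression:
    """OLS of gene counts y (set B) on x (set A) over shared terms.

    Measures whether shared terms have similar *relevance* (number of
    contributing genes) in both sets; adjusted R² is the headline value.
    Undefined for fewer than 3 terms or constant x.
    """
    pairs = list(pairs)
    n = len(pairs)
    if n < 3:
        return RelevanceRegression(n_terms=n)
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.allclose(x, x[0]):
        return RelevanceRegression(n_terms=n)
    if np.allclose(y, y[0]):
        # constant response: slope 0, no variance explained
        return RelevanceRegression(n_terms=n, slope=0.0, intercept=float(y[0]),
                                   r2=0.0, r2_adj=0.0, p_value=float("nan"),
                                   defined=True, low_information=True)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RelevanceRegression(
        n_terms=n,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        r2_adj=float(fit.rsquared_adj),
        p_value=float(fit.f_pvalue),
        defined=True,
    )


# ----------------------------------------------------------------------
# Randomization machinery
# ----------------------------------------------------------------------

class _NullSampler:
    """Draw random gene sets from the shared universe and read off their
    significant (or, relaxed, annotated) term sets across databases."""

    def __init__(self, dbs, alpha, criterion, relaxed, mode="upper_tail"):
        self.dbs = dbs
        self.indices = [DbIndex.for_db(db) for db in dbs]
        shared = set(dbs[0].universe)
        for db in dbs[1:]:
            shared &= set(db.universe)
        if not shared:
            raise DataError("selected databases have no universe genes in common")
        self.symbols = sorted(shared)
        # per db: universe row index of each shared symbol
        self.row_maps = [np.array([idx.gene_pos[s] for s in self.symbols], dtype=np.int64)
                         for idx in self.indices]
        self.alpha = alpha
        self.criterion = criterion
        self.relaxed = relaxed
        self.mode = mode

    @property
    def n_universe(self):
        return len(self.symbols)

    def term_set(self, picks: np.ndarray) -> set:
        """Significant-term set for the gene set given by shared-universe
        positions ``picks``."""
        out = set()
        if self.relaxed:
            for db, idx, rmap in zip(self.dbs, self.indices, self.row_maps):
                g = idx.counts(rmap[picks])
                for j in np.flatnonzero((g >= 1) & ~idx.is_sentinel):
                    out.add((db.name, idx.term_ids[int(j)]))
            return out
        if self.criterion == "raw" and self.mode == "upper_tail":
            for db, idx, rmap in zip(self.dbs, self.indices, self.row_maps):
                mask = idx.raw_significant(rmap[picks], self.alpha)
                for j in np.flatnonzero(mask):
                    out.add((db.name, idx.term_ids[int(j)]))
            return out
        # general path: pooled adjustment over tested terms of all dbs
        p_all, keys = [], []
        for db, idx, rmap in zip(self.dbs, self.indices, self.row_maps):
            rows = rmap[picks]
            g = idx.counts(rows)
            tested = np.flatnonzero(g >= 1)
            p = idx.pvalues(g, len(rows), self.mode)[tested] if self.mode != "upper_tail" \
                else hypergeom.sf(g[tested] - 1, idx.universe_size, idx.gdb[tested], len(rows))
            p_all.append(p)
            keys.extend((db.name, idx.term_ids[int(j)], bool(idx.is_sentinel[int(j)]))
                        for j in tested)
        p_all = np.concatenate(p_all) if p_all else np.array([])
        if self.criterion == "bonferroni":
            p_adj = adjust_pvalues(p_all, "bonferroni")
        elif self.criterion == "fdr":
            p_adj = adjust_pvalues(p_all, "bh_fdr")
        else:
            p_adj = p_all
        for (name, tid, sent), pa in zip(keys, p_adj):
            if pa < self.alpha and not sent:
                out.add((name, tid))
        return out


@dataclass
class ComparisonResult:
    """Full output of one two-set comparison."""

    label_a: str
    label_b: str
    por: float
    method: str
    relaxed: bool
    empirical_p: float
    null_values: np.ndarray
    counts: OverlapCounts
    shared: pd.DataFrame
    exclusive_to_a: pd.DataFrame
    exclusive_to_b: pd.DataFrame
    relevance: RelevanceRegression
    plan: RandomizationPlan
    alpha: float
    criterion: str
    gene_overlap: int = 0
    set_size_a: int = 0
    set_size_b: int = 0
    null_breakdown: dict = field(default_factory=dict)

    @property
    def gene_overlap_percent(self) -> float:
        """Shared genes as a percentage of gene set A."""
        return 100.0 * self.gene_overlap / self.set_size_a if self.set_size_a else 0.0

    @property
    def summary_message(self) -> str:
        return summarize(self)

    def to_dict(self) -> dict:
        rel = self.relevance
        return {
            "gene_set_a": self.label_a,
            "gene_set_b": self.label_b,
            "method": self.method,
            "relaxed": self.relaxed,
            "por": self.por,
            "empirical_p": self.empirical_p,
            "n_null": int(len(self.null_values)),
            "mode": self.plan.mode,
            "m": self.plan.m,
            "seed": self.plan.seed,
            "alpha": self.alpha,
            "criterion": self.criterion,
            "counts": {"shared": self.counts.a, "exclusive_a": self.counts.b,
                       "exclusive_b": self.counts.c, "union": self.counts.n},
            "gene_overlap": self.gene_overlap,
            "gene_overlap_percent": round(self.gene_overlap_percent, 1),
            "set_size_a": self.set_size_a,
            "set_size_b": self.set_size_b,
            "relevance": {
                "defined": rel.defined, "n_terms": rel.n_terms,
                "slope": rel.slope, "intercept": rel.intercept,
                "r2": rel.r2, "r2_adj": rel.r2_adj, "p_value": rel.p_value,
            } if rel.defined else {"defined": False, "n_terms": rel.n_terms},
            "null_breakdown": {k: float(v) for k, v in self.null_breakdown.items()},
            "summary_message": self.summary_message,
        }


def por_significance(G: GeneSet, G2: GeneSet, dbs, plan: RandomizationPlan,
                     method: str = "jaccard", relaxed: bool = False,
                     alpha: float = 0.05, criterion: str = "raw",
                     pseudocount: bool = False,
                     include_sentinels: bool = False) -> ComparisonResult:
    """POR/RPOR between two gene sets with a randomization significance test.

    ``overlapping`` mode randomizes each side in turn (2m null values);
    ``conditional`` mode keeps G fixed and randomizes only the derived
    set G2 (m null values).  The empirical P is the fraction of null
    coefficients strictly greater than the observed one.
    """
    if isinstance(dbs, AnnotationDatabase):
        dbs = [dbs]
    if method not in METHODS:
        raise DataError(f"unknown method {method!r}")
    resA = enrich(G, dbs, alpha=alpha, criterion=criterion)
    resB = enrich(G2, dbs, alpha=alpha, criterion=criterion)
    extract = annotated_terms if relaxed else significant_terms
    if relaxed:
        setA, setB = extract(resA, include_sentinels), extract(resB, include_sentinels)
    else:
        setA = extract(resA, alpha, criterion, include_sentinels)
        setB = extract(resB, alpha, criterion, include_sentinels)
    observed = por(setA, setB, method)

    sampler = _NullSampler(dbs, alpha, criterion, relaxed)
    nA = len(G.genes & set(sampler.symbols))
    nB = len(G2.genes & set(sampler.symbols))
    if sampler.n_universe < max(nA, nB) or min(nA, nB) == 0:
        raise DataError("shared universe too small for the requested gene-set sizes")
    rng = np.random.default_rng(plan.seed)
    termsA, termsB = _as_term_set(setA), _as_term_set(setB)

    null_vals = []
    breakdown = {}
    if plan.mode == "conditional":
        for _ in range(plan.m):
            picks = rng.choice(sampler.n_universe, size=nB, replace=False)
            null_vals.append(por(termsA, sampler.term_set(picks), method))
        breakdown["mean_null_por"] = float(np.mean(null_vals))
    else:
        vs_randB, vs_randA = [], []
        for _ in range(plan.m):
            picksB = rng.choice(sampler.n_universe, size=nB, replace=False)
            vs_randB.append(por(termsA, sampler.term_set(picksB), method))
            picksA = rng.choice(sampler.n_universe, size=nA, replace=False)
            vs_randA.append(por(sampler.term_set(picksA), termsB, method))
        null_vals = vs_randB + vs_randA
        breakdown["mean_null_por_random_b"] = float(np.mean(vs_randB))
        breakdown["mean_null_por_random_a"] = float(np.mean(vs_randA))
        breakdown["empirical_p_random_b"] = float(np.sum(np.array(vs_randB) > observed) / plan.m)
        breakdown["empirical_p_random_a"] = float(np.sum(np.array(vs_randA) > observed) / plan.m)
    null_vals = np.array(null_vals)
    emp_p = empirical_pvalue(null_vals, observed, pseudocount)

    diff = differential_terms(resA, resB, alpha, criterion, include_sentinels)
    relevance = relevance_regression(
        list(zip(diff.shared["g_a"], diff.shared["g_b"])))
    counts = OverlapCounts.from_sets(termsA, termsB)
    return ComparisonResult(
        label_a=G.label, label_b=G2.label, por=observed, method=method, relaxed=relaxed,
        empirical_p=emp_p, null_values=null_vals, counts=counts,
        shared=diff.shared, exclusive_to_a=diff.exclusive_to_a,
        exclusive_to_b=diff.exclusive_to_b, relevance=relevance, plan=plan,
        alpha=alpha, criterion=criterion,
        gene_overlap=len(G.genes & G2.genes), set_size_a=len(G.genes),
        set_size_b=len(G2.genes), null_breakdown=breakdown,
    )


def rpor(G: GeneSet, G2: GeneSet, dbs, method: str = "jaccard",
         include_sentinels: bool = False) -> float:
    """Relaxed POR: the overlap coefficient over all annotated (g >= 1)
    non-sentinel terms of each gene set, enriched or not."""
    if isinstance(dbs, AnnotationDatabase):
        dbs = [dbs]
    resA = enrich(G, dbs)
    resB = enrich(G2, dbs)
    return por(annotated_terms(resA, include_sentinels),
               annotated_terms(resB, include_sentinels), method)


def summarize(result: ComparisonResult) -> str:
    """One-paragraph, diffable summary of a comparison."""
    c = result.counts
    parts = []
    if result.gene_overlap and result.set_size_a:
        parts.append(
            f"Gene sets '{result.label_a}' ({result.set_size_a} genes) and "
            f"'{result.label_b}' ({result.set_size_b} genes) share "
            f"{result.gene_overlap} genes ({result.gene_overlap_percent:.1f}% of "
            f"'{result.label_a}')."
        )
    else:
        parts.append(
            f"Gene sets '{result.label_a}' ({result.set_size_a} genes) and "
            f"'{result.label_b}' ({result.set_size_b} genes) share no genes."
        )
    score = "RPOR" if result.relaxed else "POR"
    if c.n == 0:
        parts.append("No significant terms were found in either gene set.")
    elif c.a == 0:
        parts.append(
            f"They share no significant terms (out of {c.n} in the union); "
            f"{score} ({result.method}) = {result.por:.3f}."
        )
    else:
        parts.append(
            f"They share {c.a} significant terms out of {c.n} unique significant "
            f"terms in both; {score} ({result.method}) = {result.por:.3f}."
        )
    parts.append(
        f"Empirical P = {result.empirical_p:.3g} from {len(result.null_values)} "
        f"random gene sets ({result.plan.mode} mode, seed {result.plan.seed})."
    )
    if result.relevance.defined:
        parts.append(
            f"Phenotype relevance regression over {result.relevance.n_terms} shared "
            f"terms: adjusted R² = {result.relevance.r2_adj:.3f} "
            f"(P = {result.relevance.p_value:.3g})."
        )
    return " ".join(parts)
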