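"""Synthetic annotation databases and the two evaluation experiments.

The generator emulates a real gene-term annotation database at a chosen
scale: per-gene annotation counts follow a dispersed (gamma-Poisson)
distribution around a target mean — real databases range from ~4.4 to
~17.7 terms per gene — and term popularity is heavy-tailed (power-law
weights), so a few terms are huge and most are small.  An optional
*disease module* plants a block of genes and terms with elevated
co-association, giving overlap experiments a known signal.

Two experiments are built on top:

* ``type1_experiment`` — false-positive rate of the enrichment test on
  uniform random gene sets over a grid of set sizes (the classic
  validity check: with the exact upper-tail test the expected per-term
  FPR never exceeds alpha);
* ``por_sensitivity_experiment`` — POR between a fixed seed gene set and
  artificial sets mixing seed genes, connectivity-matched filler genes
  and a small fraction of "noise" genes that share the seed set's
  enriched terms, over a grid of seed-gene proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._engine import DbIndex
from .annotation_db import AnnotationDatabase, GeneUniverse, TermRecord, standardize
from .comparison import _NullSampler, por, significant_terms
from .enrichment import GeneSet, enrich
from .errors import DataError

METRICS = ("per_term_all", "per_term_tested", "any_hit_adjusted")


@dataclass(frozen=True)
class DiseaseModuleSpec:
    """A planted block of co-associated genes and terms."""

    n_module_genes: int = 300
    n_module_terms: int = 80
    p_within: float = 0.25


@dataclass(frozen=True)
class SyntheticDbSpec:
    """Parameters of one synthetic annotation database.

    Defaults mirror a dense real database: ~19,000 protein-coding genes,
    5,000 terms, mean 17.7 annotations per gene with gamma-Poisson
    dispersion, and Zipf-like (exponent 1) term popularity.
    """

    n_genes: int = 19000
    n_terms: int = 5000
    mean_terms_per_gene: float = 17.7
    density_dispersion: float = 0.3
    term_size_skew: float = 1.0
    disease_module: DiseaseModuleSpec | None = None
    kind: str = "phenotype"
    name: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_terms < 1:
            raise DataError("need n_genes >= 1 and n_terms >= 1")
        if self.mean_terms_per_gene <= 0:
            raise DataError("mean_terms_per_gene must be positive")
        if self.mean_terms_per_gene > self.n_terms:
            raise DataError(
                f"infeasible spec: mean_terms_per_gene {self.mean_terms_per_gene} "
                f"exceeds n_terms {self.n_terms}")


@dataclass(frozen=True)
class MixtureSpec:
    """Composition of one artificial gene set."""

    target_size: int = 261
    proportion_seed: float = 0.5
    noise_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.target_size < 1:
            raise DataError("target_size must be >= 1")
        if not (0.0 <= self.proportion_seed <= 1.0 and 0.0 <= self.noise_rate <= 1.0):
            raise DataError("proportion_seed and noise_rate must lie in [0, 1]")


def _per_gene_counts(spec: SyntheticDbSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.mean_terms_per_gene == spec.n_terms:
        return np.full(spec.n_genes, spec.n_terms, dtype=np.int64)
    mu = spec.mean_terms_per_gene
    if spec.density_dispersion <= 0:
        counts = rng.poisson(mu, size=spec.n_genes)
    else:
        lam = rng.gamma(shape=1.0 / spec.density_dispersion,
                        scale=mu * spec.density_dispersion, size=spec.n_genes)
        counts = rng.poisson(lam)
    return np.clip(counts, 0, spec.n_terms).astype(np.int64)


def generate_synthetic_db(spec: SyntheticDbSpec) -> AnnotationDatabase:
    """Generate a standardized synthetic database (fully seed-deterministic).

    Per gene, the number of annotations k is drawn from the dispersed
    count distribution, then k distinct terms are sampled without
    replacement with probability proportional to power-law term weights
    (Gumbel top-k).  The optional disease module adds Bernoulli
    co-associations within its gene/term block.
    """
    rng = np.random.default_rng(spec.seed)
    gene_names = np.array([f"G{i + 1:05d}" for i in range(spec.n_genes)])
    term_ids = [f"T{j + 1:04d}" for j in range(spec.n_terms)]

    counts = _per_gene_counts(spec, rng)
    if spec.term_size_skew > 0:
        logw = -spec.term_size_skew * np.log(np.arange(1, spec.n_terms + 1, dtype=float))
    else:
        logw = np.zeros(spec.n_terms)

    genes_assoc, terms_assoc = [], []
    chunk = max(1, min(spec.n_genes, 2_000_000 // max(spec.n_terms, 1)))
    for start in range(0, spec.n_genes, chunk):
        stop = min(start + chunk, spec.n_genes)
        k = counts[start:stop]
        kmax = int(k.max()) if k.size else 0
        if kmax == 0:
            continue
        gumbel = rng.gumbel(size=(stop - start, spec.n_terms))
        keys = logw[None, :] + gumbel
        top = np.argpartition(-keys, kth=min(kmax, spec.n_terms - 1), axis=1)[:, :kmax]
        for r in range(stop - start):
            ki = int(k[r])
            if ki:
                genes_assoc.extend([start + r] * ki)
                terms_assoc.extend(top[r, :ki].tolist())

    associations = {(gene_names[i], term_ids[j]) for i, j in zip(genes_assoc, terms_assoc)}

    module_genes, module_terms = [], []
    if spec.disease_module is not None:
        m = spec.disease_module
        if m.n_module_genes > spec.n_genes or m.n_module_terms > spec.n_terms:
            raise DataError("disease module larger than the database")
        mg = rng.choice(spec.n_genes, size=m.n_module_genes, replace=False)
        mt = rng.choice(spec.n_terms, size=m.n_module_terms, replace=False)
        hits = rng.random((m.n_module_genes, m.n_module_terms)) < m.p_within
        for a, b in zip(*np.nonzero(hits)):
            associations.add((gene_names[mg[a]], term_ids[mt[b]]))
        module_genes = sorted(gene_names[mg])
        module_terms = sorted(term_ids[j] for j in mt)

    db = AnnotationDatabase(
        name=spec.name, kind=spec.kind,
        terms={t: TermRecord(t, f"synthetic term {t}", spec.kind) for t in term_ids},
        associations=associations,
    )
    universe = GeneUniverse(frozenset(gene_names), "human")
    out = standardize(db, universe)
    out.extras.update({
        "spec": spec,
        "module_genes": module_genes,
        "module_terms": module_terms,
    })
    return out


# ----------------------------------------------------------------------
# Experiment 1: type-I error of the enrichment test
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Type1Cell:
    db_name: str
    set_size: int
    replicates: int
    fpr: float
    fpr_sd: float
    metric: str


@dataclass
class Type1Result:
    cells: list
    correlation: float
    correlation_p: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.cells])


def type1_experiment(dbs, sizes, replicates: int, alpha: float = 0.05,
                     metric: str = "per_term_all", mode: str = "upper_tail",
                     seed: int = 0) -> Type1Result:
    """False-positive rate of enrichment on uniform random gene sets.

    Metrics: ``per_term_all`` = significant non-sentinel terms over *all*
    non-sentinel terms (untested terms count as non-significant; the only
    reading guaranteed <= alpha in expectation for a valid test);
    ``per_term_tested`` = same numerator over tested (g >= 1) terms;
    ``any_hit_adjusted`` = fraction of replicates with at least one
    Bonferroni-significant term.  Also reports the Pearson correlation
    between set size and FPR across cells.
    """
    if metric not in METRICS:
        raise DataError(f"unknown metric {metric!r}")
    if isinstance(dbs, AnnotationDatabase):
        dbs = [dbs]
    if replicates < 1:
        raise DataError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    cells = []
    for db in dbs:
        idx = DbIndex.for_db(db)
        real = ~idx.is_sentinel
        n_real = int(real.sum())
        for size in sizes:
            if size > idx.universe_size:
                raise DataError(f"set size {size} exceeds universe of {db.name!r}")
            crit = idx.critical_g(size, alpha) if mode == "upper_tail" else None
            fprs = np.empty(replicates)
            for r in range(replicates):
                picks = rng.choice(idx.universe_size, size=size, replace=False)
                g = idx.counts(picks)
                if mode == "upper_tail":
                    sig = (g >= crit) & real
                else:
                    p = idx.pvalues(g, size, mode)
                    sig = (p < alpha) & (g >= 1) & real
                if metric == "per_term_all":
                    fprs[r] = sig.sum() / n_real
                elif metric == "per_term_tested":
                    n_tested = int(((g >= 1) & real).sum())
                    fprs[r] = sig.sum() / n_tested if n_tested else 0.0
                else:  # any_hit_adjusted
                    tested = np.flatnonzero((g >= 1) & real)
                    if tested.size == 0:
                        fprs[r] = 0.0
                    else:
                        p = stats.hypergeom.sf(
                            g[tested] - 1, idx.universe_size, idx.gdb[tested], size)
                        fprs[r] = float(p.min() * tested.size < alpha)
            cells.append(Type1Cell(db.name, int(size), replicates,
                                   float(fprs.mean()), float(fprs.std(ddof=1) if replicates > 1 else 0.0),
                                   metric))
    if len(cells) >= 3 and len({c.fpr for c in cells}) > 1 and len({c.set_size for c in cells}) > 1:
        r, p = stats.pearsonr([c.set_size for c in cells], [c.fpr for c in cells])
    else:
        r, p = float("nan"), float("nan")
    return Type1Result(cells=cells, correlation=float(r), correlation_p=float(p))


# ----------------------------------------------------------------------
# Experiment 2: POR sensitivity to gene-set composition
# ----------------------------------------------------------------------

def _annotation_counts(dbs, genes) -> dict:
    """Total non-sentinel association count per gene across databases."""
    out = {g: 0 for g in genes}
    for db in dbs:
        idx = DbIndex.for_db(db)
        per_gene = np.asarray(idx.mat[:, ~idx.is_sentinel].sum(axis=1)).ravel()
        for g in genes:
            pos = idx.gene_pos.get(g)
            if pos is not None:
                out[g] += int(per_gene[pos])
    return out


def _noise_pool(dbs, seed_sig_terms, exclude) -> set:
    """Genes outside the seed set annotated to >= 1 seed-enriched term."""
    pool = set()
    by_db = {}
    for db_name, term_id in seed_sig_terms:
        by_db.setdefault(db_name, set()).add(term_id)
    for db in dbs:
        wanted = by_db.get(db.name)
        if not wanted:
            continue
        for g, t in db.associations:
            if t in wanted:
                pool.add(g)
    return pool - set(exclude)


def build_artificial_set(seed_set: GeneSet, dbs, spec: MixtureSpec,
                         filler_pool: GeneSet, alpha: float = 0.05,
                         seed_sig_terms=None) -> GeneSet:
    """Mix seed genes, noise genes and connectivity-matched filler genes.

    The result has exactly ``target_size`` genes: round(p * target) seed
    genes; of the remainder, a ``noise_rate`` fraction drawn from genes
    outside the seed set that carry at least one term enriched in the
    seed set; the rest drawn from ``filler_pool`` matched to the seed
    genes' annotation-count deciles ("similar phenotypic connectivity").
    Fully determined by ``spec.seed``.
    """
    if isinstance(dbs, AnnotationDatabase):
        dbs = [dbs]
    rng = np.random.default_rng(spec.seed)
    n_seed = round(spec.proportion_seed * spec.target_size)
    remainder = spec.target_size - n_seed
    n_noise = round(spec.noise_rate * remainder)
    n_filler = remainder - n_noise

    seed_genes = sorted(seed_set.genes)
    if n_seed > len(seed_genes):
        raise DataError(f"seed_set too small: need {n_seed}, have {len(seed_genes)}")
    chosen = list(rng.choice(seed_genes, size=n_seed, replace=False)) if n_seed else []

    if n_noise:
        if seed_sig_terms is None:
            seed_sig_terms = significant_terms(enrich(seed_set, dbs, alpha=alpha)).terms
        pool = sorted(_noise_pool(dbs, seed_sig_terms, seed_set.genes))
        if len(pool) < n_noise:
            raise DataError(f"noise pool too small: need {n_noise}, have {len(pool)}")
        chosen.extend(rng.choice(pool, size=n_noise, replace=False))

    if n_filler:
        pool = sorted(filler_pool.genes - seed_set.genes - set(chosen))
        if len(pool) < n_filler:
            raise DataError(f"filler_pool too small: need {n_filler}, have {len(pool)}")
        counts = _annotation_counts(dbs, set(seed_genes) | set(pool))
        seed_counts = np.array([counts[g] for g in seed_genes], dtype=float)
        edges = np.quantile(seed_counts, np.linspace(0.1, 0.9, 9))
        pool_bins = np.searchsorted(edges, [counts[g] for g in pool])
        by_bin = {b: [pool[i] for i in np.flatnonzero(pool_bins == b)] for b in range(10)}
        target_bins = rng.choice(np.searchsorted(edges, seed_counts), size=n_filler)
        taken = {b: 0 for b in range(10)}
        picks = []
        order = sorted(range(10), key=lambda b: b)
        for tb in target_bins:
            # nearest non-exhausted decile bin
            best = min(order, key=lambda b: (abs(b - tb), b)
                       if taken[b] < len(by_bin.get(b, [])) else (99, b))
            if taken[best] >= len(by_bin.get(best, [])):
                raise DataError(f"filler_pool too small: exhausted all decile bins")
            bucket = by_bin[best]
            # draw without replacement within the bin
            j = int(rng.integers(taken[best], len(bucket)))
            bucket[taken[best]], bucket[j] = bucket[j], bucket[taken[best]]
            picks.append(bucket[taken[best]])
            taken[best] += 1
        chosen.extend(picks)

    assert len(chosen) == spec.target_size
    return GeneSet(label=f"artificial_p{spec.proportion_seed:g}",
                   genes=frozenset(chosen), organism=seed_set.organism)


@dataclass
class SensitivityResult:
    """POR-vs-composition experiment output."""

    points: pd.DataFrame    # columns: p, replicate, por
    table: pd.DataFrame     # columns: p, mean_por, sd_por
    slope: float
    intercept: float
    r2: float
    r2_adj: float
    p_value: float
    welch: pd.DataFrame     # adjacent-p Welch t-tests

    def por_values(self, p: float) -> np.ndarray:
        return self.points.loc[self.points["p"] == p, "por"].to_numpy()


def por_sensitivity_experiment(seed_set: GeneSet, dbs, p_grid, replicates: int,
                               noise_rate: float = 0.05,
                               target_size: int | None = None,
                               filler_pool: GeneSet | None = None,
                               method: str = "jaccard", alpha: float = 0.05,
                               seed: int = 0) -> SensitivityResult:
    """POR between a seed gene set and artificial mixtures over a p grid.

    Per grid point, ``replicates`` artificial sets are built and their
    POR against the seed set recorded; an OLS of POR on p over all
    points and Welch t-tests between adjacent grid levels summarize the
    dose-response.
    """
    if isinstance(dbs, AnnotationDatabase):
        dbs = [dbs]
    if replicates < 2:
        raise DataError("replicates must be >= 2")
    p_grid = sorted(float(p) for p in p_grid)
    if any(p < 0 or p > 1 for p in p_grid):
        raise DataError("p_grid values must lie in [0, 1]")
    target_size = target_size or len(seed_set.genes)
    if filler_pool is None:
        shared = set(dbs[0].universe)
        for db in dbs[1:]:
            shared &= set(db.universe)
        filler_pool = GeneSet("filler", frozenset(shared - seed_set.genes),
                              seed_set.organism)

    seed_sig = significant_terms(enrich(seed_set, dbs, alpha=alpha)).terms
    sampler = _NullSampler(dbs, alpha, "raw", relaxed=False)
    pos = {s: i for i, s in enumerate(sampler.symbols)}

    rng = np.random.default_rng(seed)
    rows = []
    for p in p_grid:
        for rep in range(replicates):
            mix = MixtureSpec(target_size=target_size, proportion_seed=p,
                              noise_rate=noise_rate,
                              seed=int(rng.integers(2 ** 31)))
            art = build_artificial_set(seed_set, dbs, mix, filler_pool,
                                       alpha=alpha, seed_sig_terms=seed_sig)
            picks = np.array(sorted(pos[g] for g in art.genes if g in pos))
            art_sig = sampler.term_set(picks)
            rows.append({"p": p, "replicate": rep,
                         "por": por(seed_sig, art_sig, method)})
    points = pd.DataFrame(rows)
    table = (points.groupby("p")["por"].agg(mean_por="mean", sd_por="std")
             .reset_index())
    fit = sm.OLS(points["por"].to_numpy(),
                 sm.add_constant(points["p"].to_numpy())).fit()
    welch_rows = []
    for lo, hi in zip(p_grid[:-1], p_grid[1:]):
        a = points.loc[points["p"] == lo, "por"]
        b = points.loc[points["p"] == hi, "por"]
        t, pv = stats.ttest_ind(a, b, equal_var=False)
        welch_rows.append({"p_lo": lo, "p_hi": hi, "t": float(t), "p_value": float(pv)})
    return SensitivityResult(
        points=points, table=table,
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        r2=float(fit.rsquared), r2_adj=float(fit.rsquared_adj),
        p_value=float(fit.f_pvalue), welch=pd.DataFrame(welch_rows),
    )
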