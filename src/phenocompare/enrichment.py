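"""Hypergeometric term enrichment of a gene set.

For a gene set G and a term with ``gdb`` annotated genes in a database of
``GDB`` genes, the number of G genes hitting the term under random
sampling is hypergeometric; the enrichment P value is the upper tail
P(X >= g).  The point probability P(X = g) is available as ``mode='pmf'``
but is not a valid enrichment P value for g near its expectation, so the
upper tail is the default.  Only terms with g >= 1 are tested; raw,
Bonferroni and Benjamini-Hochberg adjusted values are reported, adjusted
jointly over all tested terms of the analysis (all selected databases
pooled) by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._engine import DbIndex
from .annotation_db import AnnotationDatabase, normalize_symbol
from .errors import DataError

logger = logging.getLogger(__name__)

CRITERIA = ("raw", "bonferroni", "fdr")
_CRIT_COLUMN = {"raw": "p_raw", "bonferroni": "p_bonferroni", "fdr": "q_fdr"}

TABLE_COLUMNS = [
    "database", "term_id", "term_name", "kind", "is_sentinel",
    "g", "gdb", "set_size", "universe_size",
    "p_raw", "p_bonferroni", "q_fdr", "genes",
]


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of normalized gene symbols."""

    label: str
    genes: frozenset
    organism: str = "human"

    @classmethod
    def from_iterable(cls, label: str, genes: Iterable[str], organism: str = "human") -> "GeneSet":
        norm = frozenset(normalize_symbol(g) for g in genes if g.strip())
        if not norm:
            raise DataError(f"gene set {label!r} is empty after normalization")
        return cls(label, norm, organism)

    @classmethod
    def from_file(cls, path, label: str | None = None, organism: str = "human") -> "GeneSet":
        """Plain-text gene list, one symbol per line, '#' comments."""
        path = Path(path)
        symbols = [ln.strip() for ln in path.read_text().splitlines()
                   if ln.strip() and not ln.strip().startswith("#")]
        return cls.from_iterable(label or path.stem, symbols, organism)

    def __len__(self):
        return len(self.genes)


def term_pvalue(g: int, gdb: int, set_size: int, universe_size: int,
                mode: str = "upper_tail") -> float:
    """Exact hypergeometric enrichment probability for one term.

    ``upper_tail`` returns P(X >= g); ``pmf`` the point probability
    P(X = g).  Bounds are validated strictly.
    """
    if not (0 <= g <= min(gdb, set_size)):
        raise ValueError(f"g={g} outside [0, min(gdb={gdb}, set_size={set_size})]")
    if not (0 <= gdb <= universe_size):
        raise ValueError(f"gdb={gdb} outside [0, universe_size={universe_size}]")
    if not (0 <= set_size <= universe_size):
        raise ValueError(f"set_size={set_size} outside [0, universe_size={universe_size}]")
    if mode == "upper_tail":
        return float(hypergeom.sf(g - 1, universe_size, gdb, set_size))
    if mode == "pmf":
        return float(hypergeom.pmf(g, universe_size, gdb, set_size))
    raise ValueError(f"unknown mode {mode!r}")


def adjust_pvalues(p: Sequence[float], method: str) -> np.ndarray:
    """Bonferroni (min(1, n*p)) or Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh_fdr":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


@dataclass
class EnrichmentResult:
    """Per-term test table for one analysis (one or more databases pooled).

    ``table`` is sorted by ascending raw P with deterministic tie-breaks
    on (database, term_id); ``n_tested`` counts all tested rows.
    """

    table: pd.DataFrame
    alpha: float = 0.05
    criterion: str = "raw"
    mode: str = "upper_tail"
    label: str = ""
    set_sizes: dict = field(default_factory=dict)  # database -> |G| used

    @property
    def n_tested(self) -> int:
        return len(self.table)

    @property
    def databases(self) -> tuple:
        return tuple(dict.fromkeys(self.table["database"]))

    def significant_mask(self, alpha: float | None = None,
                         criterion: str | None = None) -> pd.Series:
        alpha = self.alpha if alpha is None else alpha
        criterion = self.criterion if criterion is None else criterion
        if criterion not in CRITERIA:
            raise DataError(f"unknown criterion {criterion!r}")
        return self.table[_CRIT_COLUMN[criterion]] < alpha

    def significant(self, alpha: float | None = None, criterion: str | None = None,
                    include_sentinels: bool = False) -> pd.DataFrame:
        mask = self.significant_mask(alpha, criterion)
        if not include_sentinels:
            mask &= ~self.table["is_sentinel"]
        return self.table[mask]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self, top: int = 25) -> dict:
        head = self.table.head(top)
        return {
            "label": self.label,
            "databases": list(self.databases),
            "n_tested": self.n_tested,
            "alpha": self.alpha,
            "criterion": self.criterion,
            "n_significant": int(self.significant().shape[0]),
            "top_terms": head[["database", "term_id", "term_name", "g", "gdb",
                               "p_raw", "p_bonferroni", "q_fdr"]].to_dict("records"),
        }


def _rows_for_db(db: AnnotationDatabase, genes: frozenset, mode: str):
    idx = DbIndex.for_db(db)
    in_universe = sorted(genes & set(db.universe))
    rows = idx.rows_for(in_universe)
    g = idx.counts(rows)
    tested = np.flatnonzero(g >= 1)
    set_size = len(in_universe)
    p = np.empty(tested.size)
    if mode == "upper_tail":
        p[:] = hypergeom.sf(g[tested] - 1, idx.universe_size, idx.gdb[tested], set_size)
    elif mode == "pmf":
        p[:] = hypergeom.pmf(g[tested], idx.universe_size, idx.gdb[tested], set_size)
    else:
        raise DataError(f"unknown mode {mode!r}")
    # contributing genes per tested term
    genes_per_term = {int(j): [] for j in tested}
    indptr, indices = idx.mat.indptr, idx.mat.indices
    for r, sym in zip(rows, in_universe):
        for j in indices[indptr[r]:indptr[r + 1]]:
            lst = genes_per_term.get(int(j))
            if lst is not None:
                lst.append(sym)
    recs = []
    for pos, j in enumerate(tested):
        j = int(j)
        recs.append({
            "database": db.name,
            "term_id": idx.term_ids[j],
            "term_name": idx.term_names[j],
            "kind": db.kind,
            "is_sentinel": bool(idx.is_sentinel[j]),
            "g": int(g[j]),
            "gdb": int(idx.gdb[j]),
            "set_size": set_size,
            "universe_size": idx.universe_size,
            "p_raw": float(p[pos]),
            "genes": ";".join(sorted(genes_per_term[j])),
        })
    return recs, set_size


def enrich(gene_set: GeneSet, dbs, alpha: float = 0.05, mode: str = "upper_tail",
           criterion: str = "raw", pooled_adjustment: bool = True) -> EnrichmentResult:
    """Test every term with at least one gene of ``gene_set`` in each database.

    Multiple-testing adjustment (Bonferroni and BH-FDR) is computed over
    the pooled tested rows of all selected databases by default, or per
    database with ``pooled_adjustment=False``.
    """
    if isinstance(dbs, AnnotationDatabase):
        dbs = [dbs]
    if not dbs:
        raise DataError("no databases selected")
    if criterion not in CRITERIA:
        raise DataError(f"unknown criterion {criterion!r}")
    records, set_sizes = [], {}
    any_overlap = False
    for db in dbs:
        if not db.is_standardized:
            raise DataError(f"database {db.name!r} must be standardized")
        overlap = gene_set.genes & set(db.universe)
        if not overlap:
            set_sizes[db.name] = 0
            continue
        any_overlap = True
        dropped = len(gene_set.genes) - len(overlap)
        if dropped:
            logger.warning("%s: %d gene(s) of %r outside the universe of %r",
                           db.name, dropped, gene_set.label, db.name)
        recs, n = _rows_for_db(db, gene_set.genes, mode)
        records.extend(recs)
        set_sizes[db.name] = n
    if not any_overlap:
        raise DataError(
            f"gene set {gene_set.label!r} is disjoint from every selected database universe")
    table = pd.DataFrame.from_records(records, columns=TABLE_COLUMNS[:10] + ["genes"])
    p = table["p_raw"].to_numpy()
    if pooled_adjustment or len(dbs) == 1:
        table["p_bonferroni"] = adjust_pvalues(p, "bonferroni")
        table["q_fdr"] = adjust_pvalues(p, "bh_fdr")
    else:
        table["p_bonferroni"] = np.nan
        table["q_fdr"] = np.nan
        for name, grp in table.groupby("database"):
            table.loc[grp.index, "p_bonferroni"] = adjust_pvalues(grp["p_raw"], "bonferroni")
            table.loc[grp.index, "q_fdr"] = adjust_pvalues(grp["p_raw"], "bh_fdr")
    table = table.sort_values(["p_raw", "database", "term_id"],
                              kind="mergesort").reset_index(drop=True)
    table = table[TABLE_COLUMNS]
    return EnrichmentResult(table=table, alpha=alpha, criterion=criterion, mode=mode,
                            label=gene_set.label, set_sizes=set_sizes)
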