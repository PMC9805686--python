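"""Vectorized incidence-matrix backend.

A :class:`DbIndex` caches, per standardized database, a CSR gene-by-term
incidence matrix plus per-term annotation counts (gdb).  It serves two
hot paths:

* per-set term counts ``g`` via sparse row sums, and
* raw-significance decisions via precomputed critical counts
  ``g*(gdb)`` — the smallest g with upper-tail P < alpha — so that the
  randomization and simulation loops never re-evaluate the
  hypergeometric survival function per replicate.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.stats import hypergeom

from .errors import DataError


class DbIndex:
    """Immutable numeric view of one standardized AnnotationDatabase."""

    def __init__(self, db):
        if not db.is_standardized:
            raise DataError(f"database {db.name!r} must be standardized")
        self.name = db.name
        self.genes = sorted(db.universe)
        self.gene_pos = {g: i for i, g in enumerate(self.genes)}
        self.term_ids = sorted(db.terms)
        term_pos = {t: j for j, t in enumerate(self.term_ids)}
        self.term_names = np.array(
            [db.terms[t].term_name for t in self.term_ids], dtype=object)
        self.is_sentinel = np.array(
            [db.terms[t].is_sentinel for t in self.term_ids], dtype=bool)
        rows, cols = [], []
        for g, t in db.associations:
            rows.append(self.gene_pos[g])
            cols.append(term_pos[t])
        data = np.ones(len(rows), dtype=np.int32)
        self.mat = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(self.genes), len(self.term_ids)))
        self.mat.sum_duplicates()
        self.mat.data[:] = 1
        self.gdb = np.asarray(self.mat.sum(axis=0)).ravel().astype(np.int64)
        self.universe_size = len(self.genes)
        self._crit_cache = {}

    # ------------------------------------------------------------------
    @classmethod
    def for_db(cls, db) -> "DbIndex":
        idx = db.__dict__.get("_index")
        if idx is None:
            idx = cls(db)
            db.__dict__["_index"] = idx
        return idx

    def rows_for(self, symbols) -> np.ndarray:
        try:
            return np.array(sorted(self.gene_pos[s] for s in symbols), dtype=np.int64)
        except KeyError as exc:
            raise DataError(f"gene {exc.args[0]!r} not in universe of {self.name!r}") from None

    def counts(self, rows: np.ndarray) -> np.ndarray:
        """g per term for the gene set given by universe row indices."""
        return np.asarray(self.mat[rows].sum(axis=0)).ravel().astype(np.int64)

    def pvalues(self, g: np.ndarray, set_size: int, mode: str = "upper_tail") -> np.ndarray:
        """Hypergeometric P per term (vectorized over terms)."""
        if mode == "upper_tail":
            return hypergeom.sf(g - 1, self.universe_size, self.gdb, set_size)
        if mode == "pmf":
            return hypergeom.pmf(g, self.universe_size, self.gdb, set_size)
        raise DataError(f"unknown mode {mode!r}")

    # ------------------------------------------------------------------
    def critical_g(self, set_size: int, alpha: float, mode: str = "upper_tail") -> np.ndarray:
        """Per-term smallest g with P < alpha (strict); inf if unreachable.

        Only defined for the upper-tail test, where P is non-increasing
        in g.  Computed once per distinct gdb and cached per
        (set_size, alpha).
        """
        if mode != "upper_tail":
            raise DataError("critical counts only defined for the upper-tail test")
        key = (set_size, float(alpha))
        crit = self._crit_cache.get(key)
        if crit is not None:
            return crit
        crit_by_gdb = {}
        N = self.universe_size
        for k in np.unique(self.gdb):
            k = int(k)
            hi = min(k, set_size)
            if hi < 1 or hypergeom.sf(hi - 1, N, k, set_size) >= alpha:
                crit_by_gdb[k] = np.inf
                continue
            lo, up = 1, hi  # sf(up-1) < alpha holds; find smallest such g
            while lo < up:
                mid = (lo + up) // 2
                if hypergeom.sf(mid - 1, N, k, set_size) < alpha:
                    up = mid
                else:
                    lo = mid + 1
            crit_by_gdb[k] = float(lo)
        crit = np.array([crit_by_gdb[int(k)] for k in self.gdb])
        self._crit_cache[key] = crit
        return crit

    def raw_significant(self, rows: np.ndarray, alpha: float) -> np.ndarray:
        """Boolean mask of non-sentinel terms with raw upper-tail P < alpha."""
        g = self.counts(rows)
        mask = g >= self.critical_g(len(rows), alpha)
        mask &= ~self.is_sentinel
        return mask
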