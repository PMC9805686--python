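"""Gene-term annotation databases.

An :class:`AnnotationDatabase` is a flat store of (gene symbol, term id)
associations plus term metadata, standardized against a protein-coding
gene universe.  Standardization uppercases symbols, drops genes outside
the universe, and links every unannotated universe gene to a per-database
*sentinel* term ("no annotation"), so that the universe is completely
covered and the hypergeometric population size GDB is well defined.

Terms are treated as flat labels: no ontology-graph propagation is
performed.  Symbol normalization is uppercase + exact match; alias
resolution is out of scope.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import DataError

logger = logging.getLogger(__name__)

ORGANISMS = ("human", "mouse")
KINDS = ("phenotype", "disease")
DIALECTS = ("two_col", "hpo_g2p", "mgi_rpt")


def normalize_symbol(symbol: str) -> str:
    """Uppercase, whitespace-stripped gene symbol (HGNC-style matching)."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneUniverse:
    """The population of protein-coding gene symbols a database covers."""

    symbols: frozenset
    organism: str = "human"

    def __post_init__(self):
        if not self.symbols:
            raise DataError("gene universe is empty")
        if self.organism not in ORGANISMS:
            raise DataError(f"unknown organism {self.organism!r}")

    @classmethod
    def from_iterable(cls, symbols: Iterable[str], organism: str = "human") -> "GeneUniverse":
        return cls(frozenset(normalize_symbol(s) for s in symbols if s.strip()), organism)

    @classmethod
    def from_file(cls, path, organism: str = "human") -> "GeneUniverse":
        """Read a plain-text gene list (one symbol per line, '#' comments)."""
        symbols = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.append(line.split("\t")[0])
        if not symbols:
            raise DataError(f"{path}: no gene symbols found")
        return cls.from_iterable(symbols, organism)

    def __len__(self):
        return len(self.symbols)

    def __contains__(self, symbol):
        return symbol in self.symbols


@dataclass(frozen=True)
class TermRecord:
    """One phenotype or disease term (flat label, no ontology structure)."""

    term_id: str
    term_name: str = ""
    kind: str = "phenotype"
    is_sentinel: bool = False


@dataclass(frozen=True)
class OrthologMap:
    """Many-to-many mouse-symbol to human-symbol mapping."""

    pairs: frozenset  # of (mouse symbol, human symbol)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "OrthologMap":
        return cls(frozenset((normalize_symbol(m), normalize_symbol(h)) for m, h in pairs))

    @classmethod
    def from_file(cls, path) -> "OrthologMap":
        """Two-column TSV: mouse symbol, human symbol."""
        pairs = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise DataError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            pairs.append((cols[0], cols[1]))
        return cls.from_pairs(pairs)

    def human_symbols(self, mouse_symbol: str) -> frozenset:
        return frozenset(h for m, h in self.pairs if m == mouse_symbol)


@dataclass(frozen=True)
class DbStats:
    """Database size: genes/terms/associations, sentinel reported separately."""

    n_genes: int
    n_terms: int
    n_associations: int
    n_sentinel_genes: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


def make_sentinel(name: str, kind: str) -> TermRecord:
    noun = "phenotype" if kind == "phenotype" else "diseases"
    return TermRecord(
        term_id=f"{name.upper()}:XXX",
        term_name=f"No {name} {noun} associated",
        kind=kind,
        is_sentinel=True,
    )


@dataclass
class AnnotationDatabase:
    """One named gene-term association store.

    ``universe`` is None until :func:`standardize` has been applied; after
    that every association gene is in the universe and every universe gene
    has at least one association (possibly only the sentinel).
    """

    name: str
    kind: str = "phenotype"
    terms: dict = field(default_factory=dict)  # term_id -> TermRecord
    associations: set = field(default_factory=set)  # of (gene, term_id)
    universe: frozenset | None = None
    organism: str = "human"
    dropped_genes: int = 0
    extras: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    @property
    def is_standardized(self) -> bool:
        return self.universe is not None

    @property
    def universe_size(self) -> int:
        if self.universe is None:
            raise DataError(f"database {self.name!r} is not standardized (no universe)")
        return len(self.universe)

    @property
    def sentinel_id(self) -> str | None:
        for t in self.terms.values():
            if t.is_sentinel:
                return t.term_id
        return None

    def genes(self) -> set:
        return {g for g, _ in self.associations}

    def term_to_genes(self) -> dict:
        out = defaultdict(set)
        for g, t in self.associations:
            out[t].add(g)
        return dict(out)

    def gene_to_terms(self) -> dict:
        out = defaultdict(set)
        for g, t in self.associations:
            out[g].add(t)
        return dict(out)

    def _invalidate_index(self):
        self.__dict__.pop("_index", None)


# ----------------------------------------------------------------------
# Readers / writers
# ----------------------------------------------------------------------

def _parse_row(cols, dialect):
    """Return (gene, term_id, term_name) for one data row, or raise ValueError."""
    if dialect == "two_col":
        if len(cols) < 2:
            raise ValueError(f"expected >=2 columns, got {len(cols)}")
        return cols[0], cols[1], (cols[2] if len(cols) > 2 else "")
    if dialect == "hpo_g2p":
        # term_id, term_name, [entrez id,] gene symbol (last column)
        if len(cols) < 3:
            raise ValueError(f"expected >=3 columns, got {len(cols)}")
        return cols[-1], cols[0], cols[1]
    if dialect == "mgi_rpt":
        # pre-joined: human gene, MP term id, MP term name
        if len(cols) < 2:
            raise ValueError(f"expected >=2 columns, got {len(cols)}")
        return cols[0], cols[1], (cols[2] if len(cols) > 2 else "")
    raise DataError(f"unknown dialect {dialect!r}")


def load_association_table(path, dialect: str, kind: str = "phenotype",
                           name: str | None = None) -> AnnotationDatabase:
    """Load a gene-term association TSV in one of the supported dialects.

    Lines starting with '#' are comments; headers must be commented.
    Associations are deduplicated (set semantics).  Gene symbols are kept
    verbatim here; normalization happens in :func:`standardize`.
    """
    if dialect not in DIALECTS:
        raise DataError(f"unknown dialect {dialect!r} (choose from {DIALECTS})")
    if kind not in KINDS:
        raise DataError(f"unknown kind {kind!r}")
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: file not found")
    name = name or path.stem
    db = AnnotationDatabase(name=name, kind=kind)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        raw = line.rstrip("\n")
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        cols = raw.split("\t")
        try:
            gene, term_id, term_name = _parse_row(cols, dialect)
        except ValueError as exc:
            raise DataError(f"{path}:{lineno}: malformed row: {exc}") from None
        gene, term_id, term_name = gene.strip(), term_id.strip(), term_name.strip()
        if not gene or not term_id:
            raise DataError(f"{path}:{lineno}: malformed row: empty gene or term id")
        db.associations.add((gene, term_id))
        prev = db.terms.get(term_id)
        if prev is None or (not prev.term_name and term_name):
            db.terms[term_id] = TermRecord(term_id, term_name, kind)
    if not db.associations:
        raise DataError(f"{path}: no associations")
    return db


def write_two_col(db: AnnotationDatabase, path) -> None:
    """Canonical two_col writer: gene<TAB>term_id[<TAB>term_name], sorted."""
    lines = [f"# database: {db.name}\tkind: {db.kind}"]
    for gene, term_id in sorted(db.associations):
        term = db.terms.get(term_id)
        name = term.term_name if term else ""
        lines.append(f"{gene}\t{term_id}\t{name}" if name else f"{gene}\t{term_id}")
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Standardization
# ----------------------------------------------------------------------

def standardize(db: AnnotationDatabase, universe: GeneUniverse) -> AnnotationDatabase:
    """Normalize a database against a gene universe.

    Symbols are uppercased and intersected with the universe (genes outside
    are dropped, counted, and logged); a sentinel term is added and every
    universe gene with no remaining annotation is linked to it.  Idempotent.
    """
    sentinel = None
    for t in db.terms.values():
        if t.is_sentinel:
            sentinel = t
            break
    if sentinel is None:
        sentinel = make_sentinel(db.name, db.kind)

    kept, dropped = set(), set()
    for gene, term_id in db.associations:
        g = normalize_symbol(gene)
        if g in universe.symbols:
            if term_id != sentinel.term_id:
                kept.add((g, term_id))
        else:
            dropped.add(g)
    if dropped:
        logger.warning("%s: dropped %d gene(s) outside the universe", db.name, len(dropped))

    terms = {tid: rec for tid, rec in db.terms.items() if not rec.is_sentinel}
    terms[sentinel.term_id] = sentinel
    annotated = {g for g, _ in kept}
    for g in universe.symbols - annotated:
        kept.add((g, sentinel.term_id))

    return AnnotationDatabase(
        name=db.name,
        kind=db.kind,
        terms=terms,
        associations=kept,
        universe=frozenset(universe.symbols),
        organism=universe.organism,
        dropped_genes=len(dropped),
        extras=dict(db.extras),
    )


def map_orthologs(db: AnnotationDatabase, ortholog_map: OrthologMap,
                  human_universe: GeneUniverse) -> AnnotationDatabase:
    """Re-key a mouse-gene database to human symbols via orthology.

    Each mouse association is expanded to the union of all mapped human
    symbols (many-to-many), then the result is standardized against the
    human universe.  Mouse genes without a mapping are dropped (logged).
    """
    if not ortholog_map.pairs:
        raise DataError("ortholog map is empty")
    mapping = defaultdict(set)
    for m, h in ortholog_map.pairs:
        mapping[m].add(h)
    human_assoc = set()
    unmapped = set()
    for gene, term_id in db.associations:
        m = normalize_symbol(gene)
        if m in mapping:
            for h in mapping[m]:
                human_assoc.add((h, term_id))
        else:
            unmapped.add(m)
    if unmapped:
        logger.warning("%s: %d mouse gene(s) without ortholog mapping dropped",
                       db.name, len(unmapped))
    human_db = AnnotationDatabase(
        name=db.name, kind=db.kind, terms=dict(db.terms),
        associations=human_assoc, organism="human", extras=dict(db.extras),
    )
    out = standardize(human_db, human_universe)
    out.dropped_genes += len(unmapped)
    return out


CRISPR_CLASSES = ("Positive-Hit", "Negative-Hit")


def encode_crispr_screens(rows: Iterable[tuple], universe: GeneUniverse,
                          name: str = "CRISPR") -> AnnotationDatabase:
    """Encode CRISPR screen hit tables as a three-class phenotype database.

    ``rows`` holds (screen name, gene symbol, hit class) triples with hit
    class in {'Positive-Hit', 'Negative-Hit'}.  Each screen yields up to
    three terms: *association* (either class), *positive*, *negative*;
    empty class terms are omitted since a term with no genes can never be
    tested.  The result is standardized (sentinel completion) against the
    universe.
    """
    per_screen = defaultdict(lambda: {"association": set(), "positive": set(), "negative": set()})
    for screen, gene, hit_class in rows:
        if hit_class not in CRISPR_CLASSES:
            raise DataError(
                f"unknown hit class {hit_class!r} for gene {gene!r} in screen {screen!r}"
            )
        g = normalize_symbol(gene)
        per_screen[screen]["association"].add(g)
        per_screen[screen]["positive" if hit_class == "Positive-Hit" else "negative"].add(g)

    db = AnnotationDatabase(name=name, kind="phenotype")
    for screen in sorted(per_screen):
        for cls in ("association", "positive", "negative"):
            genes = per_screen[screen][cls]
            if not genes:
                continue
            term_id = f"CRB:{screen}:{cls}"
            db.terms[term_id] = TermRecord(term_id, f"{cls} with {screen}", "phenotype")
            for g in genes:
                db.associations.add((g, term_id))
    return standardize(db, universe)


def db_stats(db: AnnotationDatabase) -> DbStats:
    """Genes/terms/associations counts, excluding the sentinel term."""
    if not db.is_standardized:
        raise DataError(f"database {db.name!r} must be standardized before db_stats")
    sid = db.sentinel_id
    real = {(g, t) for g, t in db.associations if t != sid}
    sentinel_genes = {g for g, t in db.associations if t == sid}
    return DbStats(
        n_genes=len({g for g, _ in real}),
        n_terms=sum(1 for t in db.terms.values() if not t.is_sentinel),
        n_associations=len(real),
        n_sentinel_genes=len(sentinel_genes),
    )
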