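"""Small deterministic fixture set for tests and tutorials.

A 40-gene universe, one toy phenotype database and one toy disease
database, plus two gene lists constructed so each list has at least one
clearly enriched term.  Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotation_db import (AnnotationDatabase, GeneUniverse, TermRecord,
                            standardize, write_two_col)
from .enrichment import GeneSet


@dataclass
class Fixtures:
    universe: GeneUniverse
    db_phenotype: AnnotationDatabase
    db_disease: AnnotationDatabase
    genes_a: GeneSet
    genes_b: GeneSet


def make_fixtures(seed: int = 7, out_dir=None) -> Fixtures:
    """Build the toy universe/databases/gene lists; optionally write them.

    When ``out_dir`` is given, writes universe.txt, toypheno.tsv and
    toydis.tsv (two_col dialect) and genes_a.txt / genes_b.txt.
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:02d}" for i in range(1, 41)]
    universe = GeneUniverse.from_iterable(genes)

    pheno = AnnotationDatabase(name="toypheno", kind="phenotype")
    structured = {
        "P01": genes[0:8],    # GENE01..GENE08
        "P02": genes[0:5],
        "P03": genes[8:14],
    }
    for tid, members in structured.items():
        pheno.terms[tid] = TermRecord(tid, f"toy phenotype {tid}", "phenotype")
        for g in members:
            pheno.associations.add((g, tid))
    for tid in [f"P{j:02d}" for j in range(4, 11)]:
        pheno.terms[tid] = TermRecord(tid, f"toy phenotype {tid}", "phenotype")
    # sparse background annotations
    for g in genes:
        for tid in rng.choice([f"P{j:02d}" for j in range(4, 11)], size=2, replace=False):
            pheno.associations.add((g, str(tid)))

    dis = AnnotationDatabase(name="toydis", kind="disease")
    dis_structured = {"D01": genes[2:10], "D02": genes[20:26]}
    for tid, members in dis_structured.items():
        dis.terms[tid] = TermRecord(tid, f"toy disease {tid}", "disease")
        for g in members:
            dis.associations.add((g, tid))
    for tid in [f"D{j:02d}" for j in range(3, 7)]:
        dis.terms[tid] = TermRecord(tid, f"toy disease {tid}", "disease")
    for g in genes[::2]:
        tid = rng.choice([f"D{j:02d}" for j in range(3, 7)])
        dis.associations.add((g, str(tid)))

    db_phenotype = standardize(pheno, universe)
    db_disease = standardize(dis, universe)
    genes_a = GeneSet.from_iterable("genes_a", genes[0:6])     # enriched in P01/P02
    genes_b = GeneSet.from_iterable("genes_b", genes[2:10])    # enriched in P01/D01

    fx = Fixtures(universe, db_phenotype, db_disease, genes_a, genes_b)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "universe.txt").write_text("\n".join(sorted(universe.symbols)) + "\n")
        # write the raw association tables (pre-sentinel); the loader
        # re-standardizes against universe.txt
        write_two_col(pheno, out / "toypheno.tsv")
        write_two_col(dis, out / "toydis.tsv")
        (out / "genes_a.txt").write_text("\n".join(sorted(genes_a.genes)) + "\n")
        (out / "genes_b.txt").write_text("\n".join(sorted(genes_b.genes)) + "\n")
    return fx
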