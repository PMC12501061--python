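"""Gene-set over-representation analysis of module member lists.

One-tailed Fisher exact (hypergeometric upper-tail) enrichment of a gene
list against GMT-formatted collections, with Benjamini-Hochberg FDR
applied across the sets tested for each module. The testing universe is
the set of genes surviving preprocessing, not the genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    """Named gene-symbol sets (e.g. one GMT file)."""

    sets: dict[str, set[str]]
    source: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)


def parse_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: name, description, genes...).

    Duplicate genes within a set are deduplicated; sets left empty are
    dropped with a warning; a line with fewer than three fields is an
    error naming the line."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    dropped = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *genes = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = {g for g in genes if g}
            if not members:
                dropped.append(name)
                continue
            sets[name] = members
            descriptions[name] = desc
    if dropped:
        warnings.warn(f"{path}: dropped {len(dropped)} empty set(s)", stacklevel=2)
    return GeneSetCollection(sets=sets, source=str(path), descriptions=descriptions)


def fisher_enrichment(
    module_genes: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    module: str = "",
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``module_genes`` in every
    set of the collection (sets are intersected with the universe first);
    BH adjustment across all sets tested. Returns one record per set."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module_set = set(module_genes)
    if not module_set <= universe:
        raise ValueError("module genes must be a subset of the universe")
    rows = []
    for name, genes in collection.sets.items():
        in_universe = genes & universe
        if not in_universe:
            continue
        overlap = len(module_set & in_universe)
        p = stats.hypergeom.sf(
            overlap - 1, len(universe), len(in_universe), len(module_set)
        )
        rows.append(
            {
                "module": module,
                "term": name,
                "overlap_count": overlap,
                "module_size": len(module_set),
                "set_size": len(in_universe),
                "universe_size": len(universe),
                "fet_p": float(p),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "module",
            "term",
            "overlap_count",
            "module_size",
            "set_size",
            "universe_size",
            "fet_p",
        ],
    )
    if len(out):
        out["fdr"] = multipletests(out["fet_p"], method="fdr_bh")[1]
        out = out.sort_values("fet_p", kind="stable").reset_index(drop=True)
    else:
        out["fdr"] = []
    return out


def enrich_modules(
    module_gene_lists: dict[str, list[str]],
    universe: Iterable[str],
    collection: GeneSetCollection,
    global_fdr: bool = False,
) -> pd.DataFrame:
    """Enrichment for several modules. BH is applied per module by
    default (matching per-module reporting); ``global_fdr`` re-adjusts
    across all modules jointly."""
    universe = set(universe)
    frames = [
        fisher_enrichment(genes, universe, collection, module=m)
        for m, genes in module_gene_lists.items()
    ]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if global_fdr and len(out):
        out["fdr"] = multipletests(out["fet_p"], method="fdr_bh")[1]
    return out
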