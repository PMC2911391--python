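"""Gene-set over-representation against a custom reference set.

Right-tailed Fisher's exact test of whether a category contains more
significant genes than expected given the background, where the
background ("reference set") is the universe of genes actually
detectable in the assayed tissue — not the whole genome.  Categories
are intersected with the reference before testing, and testing is at
the gene level: multiple significant transcripts mapping to one gene
count once, and transcripts without a gene symbol are excluded with a
logged count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues

log = logging.getLogger(__name__)


class EnrichmentInputError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets with upper-cased canonical symbols."""

    categories: dict[str, set[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for name, genes in self.categories.items():
            genes = {g.strip().upper() for g in genes if g.strip()}
            if not genes:
                raise EnrichmentInputError(f"category {name!r} is empty")
            clean[name] = genes
        self.categories = clean

    def __len__(self) -> int:
        return len(self.categories)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> gene...)."""
    categories: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise EnrichmentInputError(f"malformed GMT line: {line[:60]!r}")
        categories[fields[0]] = set(fields[2:])
    return GeneSetCollection(categories, provenance=str(path))


def fisher_right(k: int, K: int, n: int, N: int) -> float:
    """Right tail P(X >= k) of the hypergeometric(N, K, n) overlap.

    k: overlap, K: category size in the reference, n: significant-set
    size, N: reference size.  The tail sum is computed in log space by
    ``scipy.stats.hypergeom.sf``.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise EnrichmentInputError(
            f"inconsistent margins: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def collapse_to_genes(
    transcripts: list[str], gene_map: dict[str, str]
) -> tuple[set[str], int]:
    """Map transcript ids to unique gene symbols.

    Returns (gene set, number of unmappable transcripts dropped).
    """
    genes = set()
    dropped = 0
    for t in transcripts:
        g = gene_map.get(t)
        if g is None or not str(g).strip():
            dropped += 1
        else:
            genes.add(str(g).strip().upper())
    if dropped:
        log.info("dropped %d transcripts without a gene symbol", dropped)
    return genes, dropped


def enrich(
    significant_genes: set[str],
    sets: GeneSetCollection,
    reference: set[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-category right-tailed Fisher's exact test, sorted by p.

    Significant genes outside the reference are dropped with a warning;
    every category is intersected with the reference before counting.
    Columns: category, k (overlap), K (category size in reference),
    n (significant-set size), N (reference size), p, q, enriched.
    """
    reference = {g.strip().upper() for g in reference}
    if not reference:
        raise EnrichmentInputError("empty reference set")
    significant = {g.strip().upper() for g in significant_genes}
    outside = significant - reference
    if outside:
        warnings.warn(
            f"{len(outside)} significant gene(s) absent from the reference "
            "set were dropped", stacklevel=2
        )
        significant &= reference
    N = len(reference)
    n = len(significant)
    rows = []
    for name, genes in sets.categories.items():
        in_ref = genes & reference
        K = len(in_ref)
        k = len(in_ref & significant)
        p = fisher_right(k, K, n, N) if K > 0 else 1.0
        rows.append((name, k, K, n, N, p))
    table = pd.DataFrame(rows, columns=["category", "k", "K", "n", "N", "p"])
    table["q"] = bh_qvalues(table["p"].to_numpy()) if len(table) else []
    table["enriched"] = table["q"] <= fdr
    return table.sort_values("p", kind="mergesort").reset_index(drop=True)
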