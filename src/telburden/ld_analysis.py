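"""Counting independent telomere-length-associated variants from LD matrices.

Within each chromosome, pairs of SNPs with R² below the cutoff (default 0.5)
are treated as uncorrelated; the remaining pairs form an undirected graph and
clusters of mutually correlated SNPs are counted as single candidate causal
variants.  The pairwise rule does not disambiguate transitive cases (A~B, B~C,
A!~C), so two clustering rules are implemented and reported side by side:

* ``connected_components`` — clusters are graph components (order-invariant);
* ``greedy_sentinel`` — SNPs are visited in table order; each unclaimed SNP
  becomes a sentinel and claims all unclaimed SNPs with R² ≥ cutoff to it
  (order-dependent, akin to LD clumping).

MISSING R² cells (unmeasurable correlations) contribute no edge by default: an
unmeasurable correlation cannot justify merging two variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .tables_io import LDMatrix, SNPRecord, ValidationError

__all__ = [
    "LDThresholdConfig",
    "VariantCluster",
    "build_ld_graph",
    "cluster_variants",
    "summarize_snp_panel",
]

CONNECTED_COMPONENTS = "connected_components"
GREEDY_SENTINEL = "greedy_sentinel"


@dataclass(frozen=True)
class LDThresholdConfig:
    """Correlation threshold and clustering rule for variant counting."""

    r2_cutoff: float = 0.5
    method: str = CONNECTED_COMPONENTS
    missing_policy: str = "no_edge"  # or "error"

    def __post_init__(self):
        if not (0.0 <= self.r2_cutoff <= 1.0):
            raise ValidationError(f"r2_cutoff {self.r2_cutoff} outside [0, 1]")
        if self.method not in (CONNECTED_COMPONENTS, GREEDY_SENTINEL):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.missing_policy not in ("no_edge", "error"):
            raise ValidationError(f"unknown missing_policy {self.missing_policy!r}")


@dataclass(frozen=True)
class VariantCluster:
    """A labeled set of mutually correlated SNPs with a sentinel member."""

    cluster_id: int
    chromosome: str
    members: tuple[str, ...]
    sentinel: str


def build_ld_graph(matrix: LDMatrix, cfg: LDThresholdConfig) -> nx.Graph:
    """Threshold an R² matrix into an undirected graph over rsids.

    Edge (i, j) exists iff r2[i, j] ≥ cutoff; no self-edges; MISSING cells
    follow ``cfg.missing_policy``.
    """
    g = nx.Graph()
    g.add_nodes_from(matrix.rsids)
    n = matrix.n
    for i in range(n):
        for j in range(i + 1, n):
            v = matrix.r2[i, j]
            if np.isnan(v):
                if cfg.missing_policy == "error":
                    raise ValidationError(
                        f"chromosome {matrix.chromosome}: MISSING R^2 between "
                        f"{matrix.rsids[i]} and {matrix.rsids[j]}"
                    )
                continue
            if v >= cfg.r2_cutoff:
                g.add_edge(matrix.rsids[i], matrix.rsids[j], r2=float(v))
    return g


def _choose_sentinel(members: Sequence[str], positions: Mapping[str, int] | None) -> str:
    """Lowest chromosomal position wins; falls back to lexical order when no
    position annotation is supplied.  Deterministic and biologically neutral."""
    if positions:
        known = [m for m in members if m in positions]
        if known:
            return min(known, key=lambda m: (positions[m], m))
    return min(members)


def cluster_variants(
    matrices: Iterable[LDMatrix],
    cfg: LDThresholdConfig | None = None,
    positions: Mapping[str, int] | None = None,
) -> list[VariantCluster]:
    """Partition SNPs into clusters of correlated variants, per chromosome.

    SNPs on chromosomes with a single listed SNP enter as 1x1 matrices and
    yield singleton clusters.  The independent-variant count is the number of
    clusters summed over chromosomes.  rsids must be unique across matrices.
    """
    cfg = cfg or LDThresholdConfig()
    seen: set[str] = set()
    clusters: list[VariantCluster] = []
    next_id = 0
    for matrix in matrices:
        dup = seen & set(matrix.rsids)
        if dup:
            raise ValidationError(f"duplicate rsids across matrices: {sorted(dup)}")
        seen |= set(matrix.rsids)
        if cfg.method == CONNECTED_COMPONENTS:
            g = build_ld_graph(matrix, cfg)
            groups = [sorted(c, key=matrix.rsids.index) for c in nx.connected_components(g)]
            # deterministic output order: by first member's table position
            groups.sort(key=lambda grp: matrix.rsids.index(grp[0]))
        else:
            groups = _greedy_sentinel_groups(matrix, cfg)
        for members in groups:
            clusters.append(
                VariantCluster(
                    cluster_id=next_id,
                    chromosome=matrix.chromosome,
                    members=tuple(members),
                    sentinel=_choose_sentinel(members, positions),
                )
            )
            next_id += 1
    return clusters


def _greedy_sentinel_groups(matrix: LDMatrix, cfg: LDThresholdConfig) -> list[list[str]]:
    n = matrix.n
    claimed = [False] * n
    groups: list[list[str]] = []
    for i in range(n):
        if claimed[i]:
            continue
        claimed[i] = True
        members = [matrix.rsids[i]]
        for j in range(n):
            if claimed[j]:
                continue
            v = matrix.r2[i, j]
            if np.isnan(v):
                if cfg.missing_policy == "error":
                    raise ValidationError(
                        f"chromosome {matrix.chromosome}: MISSING R^2 between "
                        f"{matrix.rsids[i]} and {matrix.rsids[j]}"
                    )
                continue
            if v >= cfg.r2_cutoff:
                claimed[j] = True
                members.append(matrix.rsids[j])
        groups.append(members)
    return groups


def summarize_snp_panel(
    snps: Sequence[SNPRecord], clusters: Sequence[VariantCluster]
) -> dict:
    """Bookkeeping summary of a SNP panel and its clustering.

    Returns counts of SNPs, chromosomes, clusters, and SNPs flagged as lying
    in known telomere-maintenance genes, plus per-cluster sentinel annotation.
    Every cluster member must appear in the SNP table.
    """
    by_rsid = {s.rsid: s for s in snps}
    orphans = [m for c in clusters for m in c.members if m not in by_rsid]
    if orphans:
        raise ValidationError(f"cluster members absent from SNP table: {orphans}")
    return {
        "n_snps": len(snps),
        "n_chromosomes": len({s.chromosome for s in snps}),
        "n_clusters": len(clusters),
        "n_telomere_maintenance_snps": sum(
            1 for s in snps if s.gene_is_telomere_maintenance == "yes"
        ),
        "clusters": [
            {
                "cluster_id": c.cluster_id,
                "chromosome": c.chromosome,
                "size": len(c.members),
                "sentinel": c.sentinel,
                "members": list(c.members),
            }
            for c in clusters
        ],
    }
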