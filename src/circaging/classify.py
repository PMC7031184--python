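"""Age-class partitioning, candidate selection and gene-set enrichment.

circRNAs are partitioned by pool presence into ``young_only``,
``old_only`` and ``shared`` classes; shared circRNAs are ranked by
absolute log2 fold change between pools, exclusive ones by abundance.
Host genes of the top-decile most abundant circRNAs feed a two-sided
hypergeometric over-representation test with Holm (Bonferroni step-down)
correction against user-supplied GMT gene sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import BpmProfile

__all__ = [
    "CLASS_LABELS",
    "EnrichmentResult",
    "partition_classes",
    "rank_shared_differential",
    "select_candidates",
    "top_decile_hosts",
    "enrich_gene_sets",
    "read_gmt",
]

CLASS_LABELS = ("young_only", "old_only", "shared")


def partition_classes(
    presence_young: set[str],
    presence_old: set[str],
    profile_young: BpmProfile | None = None,
    profile_old: BpmProfile | None = None,
) -> pd.DataFrame:
    """Partition the union of the two presence sets into age classes.

    Returns a DataFrame with columns ``circ_id``, ``class_label``,
    ``bpm_young``, ``bpm_old`` (0.0 where a profile is absent or the
    circRNA is not in it).  ``df.attrs["eps"]`` holds the fold-change
    pseudocount: the bpm equivalent of one read in the smaller library
    (1e6 / min(D_young, D_old)), when both profiles are given.
    """
    union = sorted(presence_young | presence_old)
    if not union:
        warnings.warn("both presence sets empty; returning empty class table")
    rows = []
    for circ in union:
        in_y = circ in presence_young
        in_o = circ in presence_old
        label = "shared" if (in_y and in_o) else ("young_only" if in_y else "old_only")
        rows.append((circ, label))
    table = pd.DataFrame(rows, columns=["circ_id", "class_label"])

    def _bpm(profile: BpmProfile | None) -> pd.Series:
        if profile is None:
            return pd.Series(0.0, index=table["circ_id"])
        return profile.bpm.reindex(table["circ_id"]).fillna(0.0)

    table["bpm_young"] = _bpm(profile_young).values
    table["bpm_old"] = _bpm(profile_old).values
    if profile_young is not None and profile_old is not None:
        table.attrs["eps"] = 1e6 / min(
            profile_young.denominator, profile_old.denominator
        )
    return table


def class_counts(table: pd.DataFrame) -> dict[str, int]:
    """Per-class circRNA counts (zero for absent classes)."""
    counts = table["class_label"].value_counts().to_dict()
    return {label: int(counts.get(label, 0)) for label in CLASS_LABELS}


def rank_shared_differential(table: pd.DataFrame, eps: float | None = None) -> pd.DataFrame:
    """Rank shared circRNAs by |log2 fold change| between pools.

    log2_fc = log2((bpm_old + eps) / (bpm_young + eps)); ``eps`` defaults
    to ``table.attrs["eps"]`` (one read converted through the smaller
    library's bpm denominator).  Sorting: descending |log2_fc|, ties by
    larger max(bpm_young, bpm_old), then lexical circ_id.
    """
    if eps is None:
        eps = table.attrs.get("eps")
    if eps is None or eps <= 0:
        raise ValueError("a positive fold-change pseudocount eps is required")
    shared = table[table["class_label"] == "shared"].copy()
    shared["log2_fc"] = np.log2((shared["bpm_old"] + eps) / (shared["bpm_young"] + eps))
    shared["_abs_fc"] = shared["log2_fc"].abs()
    shared["_max_bpm"] = shared[["bpm_young", "bpm_old"]].max(axis=1)
    shared = shared.sort_values(
        ["_abs_fc", "_max_bpm", "circ_id"], ascending=[False, False, True]
    ).drop(columns=["_abs_fc", "_max_bpm"])
    return shared.reset_index(drop=True)


def select_candidates(
    table: pd.DataFrame, k_per_class: int = 5, eps: float | None = None
) -> pd.DataFrame:
    """Select follow-up candidates: top-k per class.

    Exclusive classes are ranked by abundance in their own pool (ties by
    circ_id); shared circRNAs by the differential ranking.  Output order:
    young_only, old_only, shared.  If a class has fewer than
    ``k_per_class`` members, all are taken with a warning.
    """
    if k_per_class <= 0:
        raise ValueError("k_per_class must be positive")
    picks = []
    for label, bpm_col in (("young_only", "bpm_young"), ("old_only", "bpm_old")):
        cls = table[table["class_label"] == label].copy()
        cls = cls.sort_values([bpm_col, "circ_id"], ascending=[False, True])
        if len(cls) < k_per_class:
            warnings.warn(
                f"class {label} has only {len(cls)} members (< {k_per_class}); taking all"
            )
        picks.append(cls.head(k_per_class))
    ranked_shared = rank_shared_differential(table, eps=eps)
    if len(ranked_shared) < k_per_class:
        warnings.warn(
            f"class shared has only {len(ranked_shared)} members (< {k_per_class}); taking all"
        )
    picks.append(ranked_shared.head(k_per_class))
    out = pd.concat(picks, ignore_index=True)
    return out


def top_decile_hosts(
    profile: BpmProfile,
    hosts: Mapping[str, str] | pd.Series | None = None,
    top_fraction: float = 0.10,
) -> list[str]:
    """Host genes of the top-fraction most abundant circRNAs in one pool.

    circRNAs are sorted by bpm descending (ties by circ_id); the top
    ceil(top_fraction * n) are taken and their host genes deduplicated
    preserving rank order.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if profile.n_circ == 0:
        raise ValueError("empty bpm profile")
    if hosts is None:
        hosts = profile.hosts
    if hosts is None:
        raise ValueError("host gene mapping required")
    hosts = pd.Series(hosts)
    n_top = math.ceil(top_fraction * profile.n_circ)
    order = (
        profile.bpm.rename_axis("circ_id")
        .to_frame("bpm")
        .reset_index()
        .sort_values(["bpm", "circ_id"], ascending=[False, True])
    )
    top_ids = order["circ_id"].head(n_top)
    genes: list[str] = []
    for circ in top_ids:
        gene = hosts.get(circ)
        if gene is None:
            raise KeyError(f"no host gene for {circ!r}")
        if gene not in genes:
            genes.append(gene)
    return genes


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's over/under-representation statistics."""

    set_id: str
    k: int  # overlap
    q: int  # query size
    m: int  # set size (within universe)
    N: int  # universe size
    p_enrich: float
    p_deplete: float
    p_two_sided: float
    p_adjusted: float
    leading_genes: tuple[str, ...]


def _holm(pvals: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    n = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adjusted = np.empty(n)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (n - rank) * pvals[idx])
        running_max = max(running_max, val)
        adjusted[idx] = running_max
    return adjusted.tolist()


def enrich_gene_sets(
    query: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Two-sided hypergeometric over-representation with Holm correction.

    For each set: k = |query ∩ set ∩ universe| with X ~
    Hypergeometric(N=|universe|, m=|set ∩ universe|, q=|query|);
    p_enrich = P(X >= k), p_deplete = P(X <= k),
    p_two_sided = min(1, 2 * min(p_enrich, p_deplete)).
    Results are sorted by (p_adjusted, set_id).
    """
    universe_set = set(universe)
    query_set = set(query)
    outside = sorted(query_set - universe_set)
    if outside:
        raise ValueError(f"query genes outside universe: {outside}")
    n_universe = len(universe_set)
    q = len(query_set)
    results = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & universe_set
        m = len(members)
        overlap = sorted(query_set & members)
        k = len(overlap)
        p_enrich = float(stats.hypergeom.sf(k - 1, n_universe, m, q))
        p_deplete = float(stats.hypergeom.cdf(k, n_universe, m, q))
        p_two = min(1.0, 2.0 * min(p_enrich, p_deplete))
        results.append((set_id, k, m, p_enrich, p_deplete, p_two, tuple(overlap)))
    adjusted = _holm([r[5] for r in results])
    out = [
        EnrichmentResult(
            set_id=set_id,
            k=k,
            q=q,
            m=m,
            N=n_universe,
            p_enrich=p_enrich,
            p_deplete=p_deplete,
            p_two_sided=p_two,
            p_adjusted=p_adj,
            leading_genes=overlap,
        )
        for (set_id, k, m, p_enrich, p_deplete, p_two, overlap), p_adj in zip(
            results, adjusted
        )
    ]
    out.sort(key=lambda r: (r.p_adjusted, r.set_id))
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (set_id, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets
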