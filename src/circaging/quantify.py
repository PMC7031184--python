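"""Abundance statistics for circular RNA junction count tables.

The central statistic is *bpm* (back-spliced reads per million mapped
reads): for circRNA ``i`` in one library,

    bpm_i = j_i / (sum_a j_a + sum_b c_b) * 1e6

where ``j`` are back-spliced-junction (BSJ) read counts, ``c`` are the
canonical read counts of the host gene of each circRNA, and both sums run
over the circRNAs detected in the library.  By default the canonical term
is summed once per circRNA (so a gene hosting two circRNAs contributes its
canonical count twice); ``canonical_per_gene_once=True`` switches to a
per-gene-once denominator.

Also provided: per-exon RPKM, presence calling on RNase-R-treated
libraries, and the 1..10 bar scaling used to depict junction read depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "JUNCTION_COLUMNS",
    "EXON_COLUMNS",
    "BpmProfile",
    "validate_junction_table",
    "compute_bpm",
    "compute_bpm_all",
    "compute_rpkm",
    "call_presence",
    "scale_junction_depth",
    "junction_table_to_bed",
]

#: Required columns of a junction count table (long format, one row per
#: circRNA per library).  ``canonical_reads`` is the canonical read count
#: of the circRNA's host gene in the same library.
JUNCTION_COLUMNS = [
    "circ_id",
    "host_gene",
    "chrom",
    "junction_start",
    "junction_end",
    "library_id",
    "bsj_reads",
    "canonical_reads",
]

#: Required columns of a per-exon count table.
EXON_COLUMNS = ["gene", "exon", "exon_length", "library_id", "reads", "total_mapped_reads"]


class EmptyLibraryError(ValueError):
    """Raised when a library has a zero bpm denominator."""


@dataclass(frozen=True)
class BpmProfile:
    """bpm values for one library.

    Attributes
    ----------
    library_id : str
        The library the profile was computed from.
    bpm : pandas.Series
        bpm per circ_id (index: circ_id, sorted lexically).
    bsj_reads : pandas.Series
        Raw BSJ read counts per circ_id, same index as ``bpm``.
    denominator : int
        The library denominator ``D = sum(j) + sum(c)``.
    """

    library_id: str
    bpm: pd.Series
    bsj_reads: pd.Series
    denominator: int
    hosts: pd.Series = field(default=None, repr=False)

    @property
    def n_circ(self) -> int:
        return len(self.bpm)


def validate_junction_table(table: pd.DataFrame) -> None:
    """Validate structural invariants of a junction count table.

    Raises ``ValueError`` on missing columns, negative counts, duplicated
    (circ_id, library_id) pairs, or junction_start >= junction_end.
    """
    missing = [c for c in JUNCTION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"junction table missing columns: {missing}")
    if (table["bsj_reads"] < 0).any():
        raise ValueError("negative bsj_reads")
    if (table["canonical_reads"] < 0).any():
        raise ValueError("negative canonical_reads")
    dup = table.duplicated(subset=["circ_id", "library_id"])
    if dup.any():
        offenders = table.loc[dup, "circ_id"].unique()[:5].tolist()
        raise ValueError(f"duplicated (circ_id, library_id) rows, e.g. {offenders}")
    if (table["junction_start"] >= table["junction_end"]).any():
        raise ValueError("junction_start must be < junction_end (0-based half-open)")


def _library_slice(table: pd.DataFrame, library_id: str) -> pd.DataFrame:
    sub = table[table["library_id"] == library_id]
    if sub.empty:
        raise KeyError(f"library {library_id!r} not present in table")
    return sub


def _denominator(sub: pd.DataFrame, canonical_per_gene_once: bool) -> int:
    j_sum = int(sub["bsj_reads"].sum())
    if canonical_per_gene_once:
        per_gene = sub.groupby("host_gene")["canonical_reads"].nunique()
        if (per_gene > 1).any():
            bad = per_gene[per_gene > 1].index.tolist()
            raise ValueError(
                f"inconsistent canonical_reads within host gene(s) {bad}; "
                "cannot collapse per gene"
            )
        c_sum = int(sub.groupby("host_gene")["canonical_reads"].first().sum())
    else:
        c_sum = int(sub["canonical_reads"].sum())
    return j_sum + c_sum


def compute_bpm(
    table: pd.DataFrame,
    library_id: str,
    canonical_per_gene_once: bool = False,
) -> BpmProfile:
    """Compute the bpm profile of one library.

    Parameters
    ----------
    table : pandas.DataFrame
        Junction count table with :data:`JUNCTION_COLUMNS`.
    library_id : str
        Library to profile.
    canonical_per_gene_once : bool
        If True, each host gene's canonical count enters the denominator
        once instead of once per circRNA.

    Raises
    ------
    EmptyLibraryError
        If the library denominator is zero.
    """
    validate_junction_table(table)
    sub = _library_slice(table, library_id).sort_values("circ_id")
    d = _denominator(sub, canonical_per_gene_once)
    if d == 0:
        raise EmptyLibraryError(f"library {library_id!r} has zero total reads")
    j = sub.set_index("circ_id")["bsj_reads"].astype(float)
    bpm = j / d * 1e6
    bpm.name = "bpm"
    hosts = sub.set_index("circ_id")["host_gene"]
    return BpmProfile(
        library_id=library_id,
        bpm=bpm,
        bsj_reads=j.astype(int),
        denominator=d,
        hosts=hosts,
    )


def compute_bpm_all(
    table: pd.DataFrame, canonical_per_gene_once: bool = False
) -> dict[str, BpmProfile]:
    """Compute bpm profiles for every library in a table."""
    validate_junction_table(table)
    return {
        lib: compute_bpm(table, lib, canonical_per_gene_once)
        for lib in sorted(table["library_id"].unique())
    }


def compute_rpkm(table: pd.DataFrame, library_id: str | None = None) -> pd.Series:
    """Per-exon RPKM: reads / ((exon_length/1e3) * (total_mapped_reads/1e6)).

    ``table`` needs :data:`EXON_COLUMNS`; ``total_mapped_reads`` must be
    constant within a library and at least the sum of exon reads.
    Returns a Series indexed by (gene, exon).
    """
    missing = [c for c in EXON_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"exon table missing columns: {missing}")
    sub = table if library_id is None else table[table["library_id"] == library_id]
    if sub.empty:
        raise KeyError(f"library {library_id!r} not present in exon table")
    if (sub["exon_length"] <= 0).any():
        raise ValueError("exon_length must be positive")
    if (sub["total_mapped_reads"] <= 0).any():
        raise ValueError("total_mapped_reads must be positive")
    if (sub["reads"] < 0).any():
        raise ValueError("negative read counts")
    for lib, grp in sub.groupby("library_id"):
        total = grp["total_mapped_reads"].iloc[0]
        if grp["total_mapped_reads"].nunique() > 1:
            raise ValueError(f"total_mapped_reads not constant in library {lib!r}")
        if grp["reads"].sum() > total:
            raise ValueError(f"library {lib!r}: exon reads exceed total_mapped_reads")
    rpkm = sub["reads"] / ((sub["exon_length"] / 1e3) * (sub["total_mapped_reads"] / 1e6))
    rpkm.index = pd.MultiIndex.from_frame(sub[["gene", "exon"]])
    rpkm.name = "rpkm"
    return rpkm


def call_presence(profile: BpmProfile, min_bsj_reads: int = 2) -> set[str]:
    """Presence set: circRNAs with at least ``min_bsj_reads`` BSJ reads.

    Intended to be run on the RNase-R-treated library of a pool; the mock
    library never contributes to presence.
    """
    if min_bsj_reads < 0:
        raise ValueError("min_bsj_reads must be non-negative")
    present = profile.bsj_reads[profile.bsj_reads >= min_bsj_reads]
    return set(present.index)


def scale_junction_depth(depths: Iterable[float]) -> np.ndarray:
    """Map junction read depths onto integer bar counts in 1..10.

    bars = round(1 + 9 * (d - d_min) / (d_max - d_min)), round-half-up.
    A constant depth vector maps every junction to 10 bars (each junction
    is simultaneously the minimum and the maximum; the maximum wins).
    """
    d = np.asarray(list(depths), dtype=float)
    if d.size == 0:
        raise ValueError("scale_junction_depth requires at least one depth")
    if (d <= 0).any() or not np.isfinite(d).all():
        raise ValueError("depths must be positive finite numbers")
    dmin, dmax = d.min(), d.max()
    if dmax == dmin:
        return np.full(d.shape, 10, dtype=int)
    # round-half-up, not banker's rounding
    bars = np.floor(1.0 + 9.0 * (d - dmin) / (dmax - dmin) + 0.5).astype(int)
    return np.clip(bars, 1, 10)


def junction_table_to_bed(table: pd.DataFrame, library_id: str) -> pd.DataFrame:
    """Export junctions of one library as 6-column BED.

    name = circ_id, score = BSJ read count, strand reported as '.'
    (junction coordinates are genome-oriented regardless of strand).
    """
    validate_junction_table(table)
    sub = _library_slice(table, library_id).sort_values(["chrom", "junction_start"])
    return pd.DataFrame(
        {
            "chrom": sub["chrom"].values,
            "chromStart": sub["junction_start"].astype(int).values,
            "chromEnd": sub["junction_end"].astype(int).values,
            "name": sub["circ_id"].values,
            "score": sub["bsj_reads"].astype(int).values,
            "strand": ".",
        }
    )
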