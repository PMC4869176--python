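"""Feature assignment and fold-enrichment of differential sites.

Each query (a site, or a region represented by its midpoint) receives exactly
one primary feature label, the highest-precedence feature it overlaps; CpG
island overlap is recorded as an independent flag. The enrichment statistic
for a feature is

    fold = observed_pct / expected_pct

where observed_pct is the percentage of differential sites whose primary
label is the feature and expected_pct is the percentage of genomic space the
feature occupies once overlaps between labels are flattened by the same
precedence, so that both percentages sum to 100 over the label partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnnotationError
from .io import GenomeAnnotation

#: default precedence, proximal regulatory context first
DEFAULT_PRECEDENCE = ("promoter", "exon", "intron", "downstream", "upstream",
                      "intergenic")


@dataclass
class FeatureAssignment:
    query: tuple  # (chrom, start, end) half-open
    feature: str  # primary label
    gene_ids: tuple[str, ...]  # all gene bodies overlapped by the full query
    intragenic: bool
    cpg_island: bool  # independent flag, never a primary label


def _as_region(query) -> tuple[str, int, int]:
    if len(query) == 2:  # (chrom, pos)
        chrom, pos = query
        return chrom, int(pos), int(pos) + 1
    chrom, start, end = query
    return chrom, int(start), int(end)


def assign_feature(query, annotation: GenomeAnnotation,
                   precedence: tuple[str, ...] = DEFAULT_PRECEDENCE
                   ) -> FeatureAssignment:
    """Assign a primary feature label to a (chrom, pos) site or a
    (chrom, start, end) region.

    The primary label is resolved at a single point (the site itself, or the
    region midpoint); gene-body and island overlap use the full region with a
    >= 1 bp rule.
    """
    chrom, start, end = _as_region(query)
    if chrom not in annotation.chrom_sizes:
        raise AnnotationError(f"query on unknown chromosome {chrom!r}")
    point = (start + end) // 2
    label = "intergenic"
    for feature in precedence:
        if feature == "intergenic":
            continue
        tree = annotation.feature_trees.get(feature, {}).get(chrom)
        if tree is not None and tree.overlaps(point, point + 1):
            label = feature
            break
    gene_tree = annotation.gene_trees.get(chrom)
    hits = sorted(h.data for h in gene_tree.overlap(start, end)) if gene_tree else []
    island_tree = annotation.island_trees.get(chrom)
    in_island = bool(island_tree.overlap(start, end)) if island_tree else False
    return FeatureAssignment(
        query=(chrom, start, end),
        feature=label,
        gene_ids=tuple(hits),
        intragenic=bool(hits),
        cpg_island=in_island,
    )


def enrichment_fold(dm_sites: pd.DataFrame, annotation: GenomeAnnotation,
                    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE
                    ) -> pd.DataFrame:
    """Observed vs expected feature occupancy of differential sites.

    Returns one row per label with observed_pct (share of sites assigned the
    label), expected_pct (share of flattened genomic space) and
    fold = observed_pct / expected_pct (NaN when expected_pct is 0).
    """
    if len(dm_sites) == 0:
        raise AnnotationError("no differential sites: skip enrichment")
    labels = list(precedence)
    counts = dict.fromkeys(labels, 0)
    for row in dm_sites.itertuples(index=False):
        counts[assign_feature((row.chrom, row.pos), annotation, precedence).feature] += 1
    lengths = annotation.flattened_lengths(tuple(precedence))
    genome = sum(annotation.chrom_sizes.values())
    n = len(dm_sites)
    rows = []
    for label in labels:
        observed = 100.0 * counts[label] / n
        expected = 100.0 * lengths[label] / genome
        fold = observed / expected if expected > 0 else np.nan
        rows.append((label, observed, expected, fold))
    return pd.DataFrame(rows, columns=["feature", "observed_pct", "expected_pct", "fold"])


def assign_genes(dmrs, annotation: GenomeAnnotation
                 ) -> tuple[pd.DataFrame, float | None]:
    """Map DMRs to genes by >= 1 bp gene-body overlap.

    ``dmrs`` is a list of :class:`methylseg.dmr.DMR` or a DataFrame with
    chrom/start/end. Returns (table, intragenic_fraction); the fraction is
    None for an empty input. DMRs overlapping several gene bodies list every
    gene.
    """
    if not isinstance(dmrs, pd.DataFrame):
        from .dmr import dmrs_to_frame

        dmrs = dmrs_to_frame(dmrs)
    rows = []
    for row in dmrs.itertuples(index=False):
        fa = assign_feature((row.chrom, row.start, row.end), annotation)
        rows.append({
            "chrom": row.chrom,
            "start": row.start,
            "end": row.end,
            "gene_ids": ";".join(fa.gene_ids),
            "n_genes": len(fa.gene_ids),
            "intragenic": fa.intragenic,
        })
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_ids",
                                        "n_genes", "intragenic"])
    fraction = float(table["intragenic"].mean()) if len(table) else None
    return table, fraction
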