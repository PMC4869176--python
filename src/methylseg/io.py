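"""Readers and writers with strict coordinate conventions.

Internally every coordinate is 0-based, half-open. File dialects are converted
only at this boundary:

* cytosine reports (bismark-style TSV) carry 1-based positions;
* BED is 0-based half-open, as is the 6-column gene-model TSV.

The cytosine report is one record per strand. :func:`read_cytosine_report` can
optionally merge symmetric CpG pairs onto the plus strand, but by default every
per-strand record is kept as its own site.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from . import _intervals as iv
from .errors import AnnotationError, ParseError

log = logging.getLogger("methylseg")

#: canonical column order of the in-memory cytosine table (pos is 0-based)
REPORT_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "unmeth"]

VALID_STRANDS = {"+", "-"}
VALID_CONTEXTS = {"CpG", "CpH"}

PROMOTER_HALF_WIDTH = 2_000  # promoter = TSS +/- 2 kb
FLANK_LENGTH = 50_000  # upstream/downstream flank length


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

def read_cytosine_report(path, merge_strands: bool = False) -> pd.DataFrame:
    """Read a 6-column cytosine report (chrom, 1-based pos, strand, context,
    methylated count, unmethylated count) into the internal 0-based table.

    A single header line is tolerated. Rows are validated one by one so parse
    errors can name the offending line. Output is sorted by (chrom, pos).
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines:
        first = lines[0].split("\t")
        if len(first) >= 5 and not first[1].lstrip("-").isdigit():
            start = 1  # header
    records = []
    for ln, raw in enumerate(lines[start:], start=start + 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) != 6:
            raise ParseError(f"expected 6 tab-separated fields, got {len(parts)}", ln)
        chrom, pos_s, strand, context, meth_s, unmeth_s = parts
        try:
            pos = int(pos_s)
            meth = int(meth_s)
            unmeth = int(unmeth_s)
        except ValueError:
            raise ParseError(f"non-integer position or count in {parts!r}", ln) from None
        if pos < 1:
            raise ParseError(f"position {pos} is not 1-based positive", ln)
        if strand not in VALID_STRANDS:
            raise ParseError(f"unknown strand {strand!r}", ln)
        if context not in VALID_CONTEXTS:
            raise ParseError(f"unknown context {context!r}", ln)
        if meth < 0 or unmeth < 0:
            raise ParseError(f"negative count in {parts!r}", ln)
        records.append((chrom, pos - 1, strand, context, meth, unmeth))
    table = pd.DataFrame(records, columns=REPORT_COLUMNS)
    dup = table.duplicated(subset=["chrom", "pos", "strand"])
    if dup.any():
        first_bad = dup.idxmax()
        raise ParseError(
            f"duplicate record for {table.loc[first_bad, 'chrom']}:"
            f"{table.loc[first_bad, 'pos'] + 1}"
        )
    if merge_strands:
        table = merge_symmetric_cpgs(table)
    return table.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def merge_symmetric_cpgs(table: pd.DataFrame) -> pd.DataFrame:
    """Merge minus-strand CpG records onto the plus-strand partner at pos-1,
    summing counts. CpH records and unpaired CpGs pass through unchanged."""
    cpg = table[table["context"] == "CpG"]
    rest = table[table["context"] != "CpG"]
    minus = cpg[cpg["strand"] == "-"].copy()
    minus["pos"] -= 1  # symmetric partner position on the plus strand
    minus["strand"] = "+"
    merged = (
        pd.concat([cpg[cpg["strand"] == "+"], minus])
        .groupby(["chrom", "pos", "strand", "context"], as_index=False)[["meth", "unmeth"]]
        .sum()
    )
    return pd.concat([merged, rest], ignore_index=True)[REPORT_COLUMNS]


def write_cytosine_report(table: pd.DataFrame, path) -> None:
    """Write the internal table back to the 1-based on-disk dialect."""
    out = table[REPORT_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED and gene models
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read BED3+ (0-based half-open). Comment/track lines are skipped."""
    rows = []
    with Path(path).open() as fh:
        for ln, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError("BED line has fewer than 3 fields", ln)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"non-integer BED coordinates {parts[1:3]}", ln) from None
            if start < 0 or end < start:
                raise ParseError(f"invalid BED interval [{start}, {end})", ln)
            name = parts[3] if len(parts) > 3 else "."
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(regions: pd.DataFrame, path, comment: str | None = None) -> None:
    """Write chrom/start/end (+ optional name/score/strand columns) as BED."""
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"]
            if c in regions.columns]
    with Path(path).open("w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for row in regions[cols].itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


def _parse_exon_blocks(text: str, ln: int) -> list[tuple[int, int]]:
    text = text.strip()
    if not text or text == ".":
        return []
    out = []
    for block in text.split(","):
        try:
            s, e = block.split("-")
            out.append((int(s), int(e)))
        except ValueError:
            raise ParseError(f"malformed exon block {block!r}", ln) from None
    return out


def read_gene_table(path) -> pd.DataFrame:
    """Read the 6-column gene-model TSV: chrom, tss, tes, strand, gene_id,
    exon blocks ("start-end,start-end", 0-based half-open, "." for none).

    tss/tes are the 0-based first/last transcribed base, so tss > tes on the
    minus strand.
    """
    rows = []
    with Path(path).open() as fh:
        for ln, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ParseError(f"expected 6 fields, got {len(parts)}", ln)
            chrom, tss_s, tes_s, strand, gene_id, blocks = parts
            if strand not in VALID_STRANDS:
                raise ParseError(f"unknown strand {strand!r}", ln)
            rows.append((chrom, int(tss_s), int(tes_s), strand, gene_id,
                         _parse_exon_blocks(blocks, ln)))
    return pd.DataFrame(rows, columns=["chrom", "tss", "tes", "strand", "gene_id", "exons"])


def write_gene_table(genes: pd.DataFrame, path) -> None:
    with Path(path).open("w") as fh:
        for g in genes.itertuples(index=False):
            blocks = ",".join(f"{s}-{e}" for s, e in g.exons) or "."
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tes}\t{g.strand}\t{g.gene_id}\t{blocks}\n")


# ---------------------------------------------------------------------------
# genome annotation
# ---------------------------------------------------------------------------

#: feature labels that can serve as a primary assignment
FEATURE_LABELS = ("promoter", "exon", "intron", "downstream", "upstream", "intergenic")


@dataclass
class GenomeAnnotation:
    """Derived feature intervals for a set of gene models and CpG islands.

    ``features[label][chrom]`` holds raw (possibly overlapping between genes)
    intervals; overlap between labels is resolved only at assignment time by
    precedence. CpG islands are kept separately: island overlap is an
    independent flag, never a primary label.
    """

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame
    features: dict[str, dict[str, list[tuple[int, int]]]]
    cpg_islands: dict[str, list[tuple[int, int]]]
    feature_trees: dict[str, dict[str, IntervalTree]] = field(repr=False, default_factory=dict)
    gene_trees: dict[str, IntervalTree] = field(repr=False, default_factory=dict)
    island_trees: dict[str, IntervalTree] = field(repr=False, default_factory=dict)
    _flat_cache: dict = field(repr=False, default_factory=dict)

    def flattened_lengths(self, precedence: tuple[str, ...]) -> dict[str, int]:
        """Genomic bp occupied by each label once overlaps are resolved by
        precedence; ``intergenic`` is the complement. Labels partition the
        genome, so the lengths sum to the genome size."""
        key = tuple(precedence)
        if key in self._flat_cache:
            return self._flat_cache[key]
        lengths = {label: 0 for label in precedence}
        genome = 0
        for chrom, size in self.chrom_sizes.items():
            genome += size
            claimed: list[tuple[int, int]] = []
            for label in precedence:
                if label == "intergenic":
                    continue
                raw = self.features.get(label, {}).get(chrom, [])
                avail = iv.subtract(raw, claimed)
                lengths[label] += iv.total_length(avail)
                claimed = iv.merge(claimed + avail)
            if "intergenic" in lengths:
                lengths["intergenic"] += size - iv.total_length(claimed)
        self._flat_cache[key] = lengths
        return lengths


def _gene_feature_intervals(tss: int, tes: int, strand: str, size: int):
    """Per-gene promoter/upstream/downstream intervals, clipped to the
    chromosome. The promoter is an absolute +/-2 kb window around the TSS
    (strand only selects which end is the TSS)."""
    promoter = (tss - PROMOTER_HALF_WIDTH, tss + PROMOTER_HALF_WIDTH)
    if strand == "+":
        upstream = (promoter[0] - FLANK_LENGTH, promoter[0])
        downstream = (tes + 1, tes + 1 + FLANK_LENGTH)
    else:
        upstream = (promoter[1], promoter[1] + FLANK_LENGTH)
        downstream = (tes - FLANK_LENGTH, tes)
    out = {}
    for label, span in [("promoter", promoter), ("upstream", upstream),
                        ("downstream", downstream)]:
        out[label] = iv.clip([span], size)
    return out


def build_annotation(genes: pd.DataFrame, cpg_islands: pd.DataFrame,
                     chrom_sizes: dict[str, int]) -> GenomeAnnotation:
    """Derive promoter/exon/intron/upstream/downstream intervals from gene
    models plus CpG islands.

    ``genes`` needs columns chrom, tss, tes, strand, gene_id, exons (list of
    0-based half-open intervals; empty list means the whole body is exonic).
    ``cpg_islands`` needs chrom, start, end.
    """
    features: dict[str, dict[str, list]] = {
        label: {} for label in ("promoter", "exon", "intron", "upstream", "downstream")
    }
    gene_trees: dict[str, IntervalTree] = {}
    for g in genes.itertuples(index=False):
        if g.chrom not in chrom_sizes:
            raise AnnotationError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        size = chrom_sizes[g.chrom]
        body = (min(g.tss, g.tes), max(g.tss, g.tes) + 1)
        if body[0] < 0 or body[1] > size:
            raise AnnotationError(
                f"gene {g.gene_id} body {body} outside chromosome {g.chrom} (size {size})")
        exons = list(g.exons) if len(g.exons) else [body]
        for s, e in exons:
            if s < body[0] or e > body[1]:
                raise AnnotationError(f"gene {g.gene_id} exon ({s}, {e}) outside body {body}")
        introns = iv.subtract([body], exons)
        per_gene = _gene_feature_intervals(g.tss, g.tes, g.strand, size)
        per_gene["exon"] = iv.merge(exons)
        per_gene["intron"] = introns
        for label, ivs in per_gene.items():
            features[label].setdefault(g.chrom, []).extend(ivs)
        gene_trees.setdefault(g.chrom, IntervalTree())[body[0]:body[1]] = g.gene_id

    islands: dict[str, list] = {}
    island_trees: dict[str, IntervalTree] = {}
    for isl in cpg_islands.itertuples(index=False):
        if isl.chrom not in chrom_sizes:
            raise AnnotationError(f"CpG island on unknown chromosome {isl.chrom}")
        if isl.start < 0 or isl.end > chrom_sizes[isl.chrom]:
            raise AnnotationError(
                f"CpG island ({isl.start}, {isl.end}) outside chromosome {isl.chrom}")
        islands.setdefault(isl.chrom, []).append((int(isl.start), int(isl.end)))
    for chrom, ivs in islands.items():
        islands[chrom] = iv.merge(ivs)
        tree = IntervalTree()
        for s, e in islands[chrom]:
            tree[s:e] = True
        island_trees[chrom] = tree

    feature_trees: dict[str, dict[str, IntervalTree]] = {}
    for label, per_chrom in features.items():
        feature_trees[label] = {}
        for chrom, ivs in per_chrom.items():
            tree = IntervalTree()
            for s, e in ivs:
                tree[s:e] = label
            feature_trees[label][chrom] = tree

    return GenomeAnnotation(
        chrom_sizes=dict(chrom_sizes),
        genes=genes.reset_index(drop=True),
        features=features,
        cpg_islands=islands,
        feature_trees=feature_trees,
        gene_trees=gene_trees,
        island_trees=island_trees,
    )


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------

def write_dmr_outputs(dmrs, enrichment, segregation, outdir) -> dict[str, Path]:
    """Write DMRs (BED + per-DMR TSV), the enrichment table (TSV) and the
    segregation report (JSON) under ``outdir``. Returns the paths written.

    ``dmrs`` is a list of :class:`methylseg.dmr.DMR`; ``enrichment`` a
    DataFrame or None; ``segregation`` a JSON-serializable mapping or None.
    """
    from .dmr import dmrs_to_frame  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    frame = dmrs_to_frame(dmrs)
    bed = frame[["chrom", "start", "end"]].copy()
    bed["name"] = [f"DMR_{i + 1}" for i in range(len(frame))]
    paths["dmr_bed"] = outdir / "dmrs.bed"
    write_bed(bed, paths["dmr_bed"], comment="methylseg DMRs (0-based half-open)")
    paths["dmr_tsv"] = outdir / "dmrs.tsv"
    frame.to_csv(paths["dmr_tsv"], sep="\t", index=False)
    log.info("wrote %d DMRs to %s", len(frame), paths["dmr_bed"])

    if enrichment is not None:
        paths["enrichment"] = outdir / "enrichment.tsv"
        enrichment.to_csv(paths["enrichment"], sep="\t", index=False)
        log.info("wrote enrichment table to %s", paths["enrichment"])
    if segregation is not None:
        paths["segregation"] = outdir / "segregation.json"
        with paths["segregation"].open("w") as fh:
            json.dump(segregation, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log.info("wrote segregation report to %s", paths["segregation"])
    return paths
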