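"""Cross-generational DMR set algebra and end-to-end orchestration.

Cohort DMR sets are compared by genomic overlap (>= 1 bp by default; a
gene-level matching mode is available since figure-level intersections are
often reported per gene). The trait-segregation rule returns the regions of
the first "present" cohort that are supported by every other "present"
cohort and absent from every "absent" cohort — the somatic profile
(present {F1, F2}, absent {F3}) and the gametic profile (present {F2, F2-G},
no exclusions, q < 0.05) are the two shipped configurations.

Overlap significance uses a Fisher exact test on a 2x2 membership table over
a region universe. The universe is built by clustering every TESTED site
(regardless of significance) with the same min_sites/max_gap rule, which
makes the test self-contained and reproducible.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Mapping, Sequence
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import fisher_exact as _scipy_fisher

from .annotation import assign_genes, enrichment_fold
from .dmr import DMR, chain_positions, cluster_sites, dmrs_to_frame, summarize_dmrs
from .errors import ConfigError, ConsistencyError
from .io import write_bed, write_dmr_outputs
from .sites import ThresholdConfig, call_dm_sites, pool_replicates
from .synthetic import (CoverageSpec, EffectSpec, GenomeConfig, build_genome_spec,
                        plant_dmrs, planted_to_bed, simulate_counts)

log = logging.getLogger("methylseg")

REGION_COLUMNS = ["chrom", "start", "end"]


# ---------------------------------------------------------------------------
# region set algebra
# ---------------------------------------------------------------------------

def overlap_regions(set_a: pd.DataFrame, set_b: pd.DataFrame,
                    min_overlap_bp: int = 1) -> pd.DataFrame:
    """All pairs (a_index, b_index) whose interval intersection is at least
    ``min_overlap_bp``. Each set must be internally non-overlapping (any row
    order is accepted; original indices are reported); intervals are
    half-open, so touching regions do not overlap."""
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    pairs = []
    for chrom in sorted(set(set_a["chrom"]) & set(set_b["chrom"])):
        a = set_a[set_a["chrom"] == chrom].sort_values("start", kind="mergesort")
        b = set_b[set_b["chrom"] == chrom].sort_values("start", kind="mergesort")
        ai, bi = a.index.to_numpy(), b.index.to_numpy()
        a_start, a_end = a["start"].to_numpy(), a["end"].to_numpy()
        b_start, b_end = b["start"].to_numpy(), b["end"].to_numpy()
        i = j = 0
        while i < len(a) and j < len(b):
            ov = min(a_end[i], b_end[j]) - max(a_start[i], b_start[j])
            if ov >= min_overlap_bp:
                pairs.append((ai[i], bi[j], chrom, int(ov)))
            if a_end[i] <= b_end[j]:
                i += 1
            else:
                j += 1
    return pd.DataFrame(pairs, columns=["a_index", "b_index", "chrom", "overlap_bp"])


def candidate_universe(tested_sites: pd.DataFrame, min_sites: int = 4,
                       max_gap: int = 1_000) -> pd.DataFrame:
    """Candidate regions from ALL tested sites (no significance filter),
    clustered with the same min_sites/max_gap rule as DMR calling."""
    regions = []
    for chrom, group in tested_sites.groupby("chrom", sort=True):
        pos = np.sort(group["pos"].to_numpy())
        for s, e in chain_positions(pos, min_sites, max_gap):
            regions.append((chrom, int(pos[s]), int(pos[e - 1]) + 1))
    return pd.DataFrame(regions, columns=REGION_COLUMNS)


@dataclass
class OverlapTestResult:
    both: int
    a_only: int
    b_only: int
    neither: int
    odds_ratio: float  # cross-product ratio; inf when a denominator cell is 0
    odds_ratio_infinite: bool
    p: float  # two-sided Fisher exact
    universe_size: int
    universe_definition: str

    def to_dict(self) -> dict:
        d = asdict(self)
        d["odds_ratio"] = None if self.odds_ratio_infinite else self.odds_ratio
        return d


def fisher_overlap_test(set_a: pd.DataFrame, set_b: pd.DataFrame,
                        universe: pd.DataFrame, min_overlap_bp: int = 1,
                        universe_definition: str = "candidate regions from all tested sites"
                        ) -> OverlapTestResult:
    """2x2 membership test: each universe region is classified by whether it
    overlaps set A and/or set B; the odds ratio is the unconditional
    cross-product ratio and p the two-sided Fisher exact probability."""
    in_a = np.zeros(len(universe), dtype=bool)
    in_b = np.zeros(len(universe), dtype=bool)
    pairs_a = overlap_regions(universe, set_a, min_overlap_bp)
    pairs_b = overlap_regions(universe, set_b, min_overlap_bp)
    pos = {ix: k for k, ix in enumerate(universe.index)}
    in_a[[pos[i] for i in pairs_a["a_index"]]] = True
    in_b[[pos[i] for i in pairs_b["a_index"]]] = True
    for label, member_set, matched in (("A", set_a, set(pairs_a["b_index"])),
                                       ("B", set_b, set(pairs_b["b_index"]))):
        missing = set(member_set.index) - matched
        if missing:
            raise ConsistencyError(
                f"universe does not cover {len(missing)} region(s) of set {label}")
    both = int(np.sum(in_a & in_b))
    a_only = int(np.sum(in_a & ~in_b))
    b_only = int(np.sum(~in_a & in_b))
    neither = int(np.sum(~in_a & ~in_b))
    if a_only * b_only > 0:
        odds = both * neither / (a_only * b_only)
        infinite = False
    else:  # zero denominator cell: cross-product ratio is unbounded/undefined
        odds = float("inf")
        infinite = True
    _, p = _scipy_fisher([[both, a_only], [b_only, neither]], alternative="two-sided")
    return OverlapTestResult(both=both, a_only=a_only, b_only=b_only,
                             neither=neither, odds_ratio=float(odds),
                             odds_ratio_infinite=infinite, p=float(p),
                             universe_size=len(universe),
                             universe_definition=universe_definition)


def trait_segregation(collection: Mapping[str, pd.DataFrame],
                      present_in: Sequence[str], absent_in: Sequence[str] = (),
                      min_overlap_bp: int = 1, mode: str = "region",
                      annotation=None) -> pd.DataFrame:
    """Regions of the first "present" cohort supported by every other
    "present" cohort and absent from every "absent" cohort.

    mode="region" matches by genomic overlap; mode="gene" matches by shared
    assigned gene (requires ``annotation``), for gene-level intersection
    reports. The result carries a supported_by column citing the cohorts.
    """
    unknown = [c for c in list(present_in) + list(absent_in) if c not in collection]
    if unknown:
        raise ConfigError(f"unknown cohort label(s): {unknown}")
    if not present_in:
        raise ConfigError("at least one 'present' cohort is required")
    first = collection[present_in[0]]
    keep = np.ones(len(first), dtype=bool)
    if mode == "region":
        for cohort in present_in[1:]:
            hit = set(overlap_regions(first, collection[cohort], min_overlap_bp)["a_index"])
            keep &= np.array([ix in hit for ix in first.index])
        for cohort in absent_in:
            hit = set(overlap_regions(first, collection[cohort], min_overlap_bp)["a_index"])
            keep &= np.array([ix not in hit for ix in first.index])
    elif mode == "gene":
        if annotation is None:
            raise ConfigError("gene-level matching requires an annotation")
        genes_of = {}
        for cohort in set(list(present_in) + list(absent_in)):
            table, _ = assign_genes(collection[cohort], annotation)
            genes_of[cohort] = [set(g.split(";")) - {""} for g in table["gene_ids"]]
        first_genes = genes_of[present_in[0]]
        for cohort in present_in[1:]:
            pool = set().union(*genes_of[cohort]) if genes_of[cohort] else set()
            keep &= np.array([bool(g & pool) for g in first_genes])
        for cohort in absent_in:
            pool = set().union(*genes_of[cohort]) if genes_of[cohort] else set()
            keep &= np.array([not (g & pool) for g in first_genes])
    else:
        raise ConfigError(f"unknown matching mode {mode!r}")
    out = first[keep].copy()
    out["supported_by"] = ";".join(present_in)
    return out


# ---------------------------------------------------------------------------
# propagation of germline DMRs into downstream tissues
# ---------------------------------------------------------------------------

def propagation_check(pgc_dmrs: pd.DataFrame,
                      downstream_tables: Mapping[str, Sequence[pd.DataFrame]],
                      thresholds: ThresholdConfig | None = None) -> pd.DataFrame:
    """Ask whether each germ-cell DMR reappears in a downstream cohort pair.

    ``downstream_tables`` maps exactly two cohort labels to their replicate
    cytosine tables. Sites falling inside each DMR are tested with the same
    machinery (pooled Fisher + BH over all tested DMR sites, then the
    min_sites/max_gap cluster rule inside the region); a region propagates
    iff it would be called a DMR downstream. Regions with no covered sites
    are reported as untestable, not as non-propagating.
    """
    thresholds = thresholds or ThresholdConfig()
    pooled = pool_replicates(downstream_tables, thresholds.min_coverage)
    masks = []
    any_mask = np.zeros(len(pooled), dtype=bool)
    for region in pgc_dmrs.itertuples(index=False):
        m = ((pooled["chrom"] == region.chrom)
             & (pooled["pos"] >= region.start)
             & (pooled["pos"] < region.end)).to_numpy()
        masks.append(m)
        any_mask |= m
    called = call_dm_sites(pooled[any_mask], thresholds) if any_mask.any() else None
    rows = []
    for region, m in zip(pgc_dmrs.itertuples(index=False), masks):
        n_sites = int(m.sum())
        if n_sites == 0:
            rows.append({"chrom": region.chrom, "start": region.start,
                         "end": region.end, "status": "untestable", "n_sites": 0,
                         "mean_diff": np.nan, "n_dm_sites": 0, "propagates": None})
            continue
        here = called[(called["chrom"] == region.chrom)
                      & (called["pos"] >= region.start)
                      & (called["pos"] < region.end)]
        dm = here[here["is_dm"]]
        runs = chain_positions(np.sort(dm["pos"].to_numpy()),
                               thresholds.min_sites, thresholds.max_gap)
        rows.append({"chrom": region.chrom, "start": region.start,
                     "end": region.end, "status": "tested", "n_sites": n_sites,
                     "mean_diff": float(here["diff"].mean()),
                     "n_dm_sites": int(len(dm)), "propagates": bool(runs)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "status", "n_sites",
                                       "mean_diff", "n_dm_sites", "propagates"])


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

REQUIRED_KEYS = ("seed", "thresholds", "contrasts")


def load_config(source) -> dict:
    """Load a pipeline config from a YAML path or pass a dict through."""
    if isinstance(source, (str, Path)):
        with Path(source).open() as fh:
            return yaml.safe_load(fh)
    return dict(source)


def demo_config() -> dict:
    """The shipped demonstration configuration (simulation mode)."""
    from importlib.resources import files

    with (files("methylseg") / "data" / "demo_config.yaml").open() as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> None:
    missing = [k for k in REQUIRED_KEYS if k not in config]
    if "simulation" not in config and "inputs" not in config:
        missing.append("simulation|inputs")
    if missing:
        raise ConfigError(f"missing config key(s): {', '.join(missing)}")
    contrasts = config["contrasts"]
    for key in ("control", "cohorts"):
        if key not in contrasts:
            raise ConfigError(f"contrasts block is missing '{key}'")


def _evaluate_recovery(called: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Sensitivity and FDR of called regions against planted truth
    (>= 1 bp overlap)."""
    if len(truth) == 0:
        return {"sensitivity": None, "fdr": 0.0 if len(called) == 0 else 1.0,
                "n_called": int(len(called)), "n_truth": 0}
    pairs = overlap_regions(called.reset_index(drop=True), truth.reset_index(drop=True))
    recovered = len(set(pairs["b_index"]))
    true_pos = len(set(pairs["a_index"]))
    fdr = 1.0 - true_pos / len(called) if len(called) else 0.0
    return {"sensitivity": recovered / len(truth), "fdr": fdr,
            "n_called": int(len(called)), "n_truth": int(len(truth))}


def _simulate_from_config(config: dict):
    sim = config["simulation"]
    gcfg = dict(sim.get("genome", {}))
    if "chromosomes" in gcfg:
        gcfg["chromosomes"] = tuple(tuple(c) for c in gcfg["chromosomes"])
    for key in ("gene_length", "exons_per_gene", "island_length"):
        if key in gcfg:
            gcfg[key] = tuple(gcfg[key])
    seed = int(config["seed"])
    genome = build_genome_spec(GenomeConfig(**gcfg), seed)
    design = {g: tuple(s) for g, s in sim["design"].items()}
    planted_by_class: dict[str, list] = {}
    avoid: list[tuple[str, int, int]] = []
    for k, cls in enumerate(sim.get("classes", [])):
        spec = EffectSpec(
            delta=cls.get("delta", 0.30),
            n_sites=tuple(cls["n_sites"]) if isinstance(cls.get("n_sites"), list)
            else cls.get("n_sites", 6),
            spacing=tuple(cls.get("spacing", (40, 60))),
            hypo_fraction=cls.get("hypo_fraction", 0.55),
            affected_groups=tuple(cls["affected_groups"]),
            cpg_fraction=cls.get("cpg_fraction", 0.97),
        )
        label = cls.get("label", f"class_{k + 1}")
        planted = plant_dmrs(genome, int(cls["n_dmrs"]), spec,
                             seed=seed + 1000 * (k + 1), avoid=avoid)
        planted_by_class[label] = planted
        avoid.extend((d.chrom, d.start, d.end) for d in planted)
    all_planted = [d for ds in planted_by_class.values() for d in ds]
    coverage = CoverageSpec(**sim.get("coverage", {}))
    samples, truth = simulate_counts(genome, all_planted, design, coverage, seed)
    return genome, design, samples, truth, planted_by_class


def _load_inputs(config: dict):
    from .io import read_bed, read_cytosine_report, read_gene_table

    inputs = config["inputs"]
    design = {g: tuple(s) for g, s in inputs["design"].items()}
    samples = {sid: read_cytosine_report(path)
               for sid, path in inputs["samples"].items()}
    genome = None
    annotation = None
    if all(k in inputs for k in ("genes", "cpg_islands", "chrom_sizes")):
        from .io import build_annotation

        islands = read_bed(inputs["cpg_islands"])[["chrom", "start", "end"]]
        annotation = build_annotation(read_gene_table(inputs["genes"]), islands,
                                      {c: int(s) for c, s in inputs["chrom_sizes"].items()})
    return genome, design, samples, annotation


def run_pipeline(config, outdir) -> dict:
    """Run simulation/loading, per-cohort differential calling, DMR
    clustering, enrichment, segregation profiles, overlap tests and the
    optional germline-propagation check; write all outputs under ``outdir``
    and return the report dict (also written as report.json)."""
    config = load_config(config)
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_pipeline(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_pipeline(config: dict, outdir: Path) -> dict:
    thresholds = ThresholdConfig(**config.get("thresholds", {}))
    truth = None
    planted_by_class: dict[str, list] = {}
    if "simulation" in config:
        genome, design, samples, truth, planted_by_class = _simulate_from_config(config)
        annotation = genome.annotation()
        truth.to_json(outdir / "truth.json")
        write_bed(planted_to_bed(truth.planted), outdir / "truth.bed",
                  comment="planted truth regions")
        if config.get("write_samples", False):
            from .io import write_cytosine_report

            sampledir = outdir / "samples"
            sampledir.mkdir(exist_ok=True)
            for sid, table in samples.items():
                write_cytosine_report(table, sampledir / f"{sid}.tsv")
    else:
        genome, design, samples, annotation = _load_inputs(config)

    control = config["contrasts"]["control"]
    cohorts = list(config["contrasts"]["cohorts"])

    def tables_of(group: str) -> list[pd.DataFrame]:
        return [samples[sid] for sid in design[group]]

    def call_cohort(cohort: str, th: ThresholdConfig):
        pooled = pool_replicates({control: tables_of(control),
                                  cohort: tables_of(cohort)}, th.min_coverage)
        called = call_dm_sites(pooled, th)
        dmrs = cluster_sites(called[called["is_dm"]], th.min_sites, th.max_gap)
        return pooled, called, dmrs

    report: dict = {"thresholds": asdict(thresholds), "control": control,
                    "cohorts": {}, "segregation": {}, "overlap_tests": {}}
    results: dict[str, dict] = {}
    for cohort in cohorts:
        pooled, called, dmrs = call_cohort(cohort, thresholds)
        results[cohort] = {"pooled": pooled, "called": called, "dmrs": dmrs}
        summary = summarize_dmrs(dmrs)
        entry = {
            "n_tested_sites": int(len(pooled)),
            "n_dm_sites": int(called["is_dm"].sum()),
            "n_dmrs": summary.n_dmrs,
            "summary": asdict(summary),
        }
        cohort_dir = outdir / f"cohort_{cohort}"
        enrichment = None
        dm_sites = called[called["is_dm"]]
        if annotation is not None and len(dm_sites) > 0:
            enrichment = enrichment_fold(dm_sites, annotation)
            _, intragenic = assign_genes(dmrs, annotation)
            entry["intragenic_fraction"] = intragenic
            entry["enrichment"] = {
                r.feature: {"observed_pct": r.observed_pct,
                            "expected_pct": r.expected_pct,
                            "fold": None if pd.isna(r.fold) else r.fold}
                for r in enrichment.itertuples(index=False)
            }
        write_dmr_outputs(dmrs, enrichment, None, cohort_dir)
        if annotation is not None:
            gene_table, _ = assign_genes(dmrs, annotation)
            gene_table.to_csv(cohort_dir / "genes.tsv", sep="\t", index=False)
        if truth is not None:
            truth_regions = planted_to_bed(
                [d for d in truth.planted if cohort in d.affected_groups])
            entry["recovery"] = _evaluate_recovery(dmrs_to_frame(dmrs), truth_regions)
        report["cohorts"][cohort] = entry

    collection = {c: dmrs_to_frame(r["dmrs"]) for c, r in results.items()}
    for name, profile in config.get("profiles", {}).items():
        th = thresholds
        if "q_max" in profile:
            th = ThresholdConfig(**{**asdict(thresholds), "q_max": profile["q_max"]})
        local = dict(collection)
        if th is not thresholds:
            for cohort in set(profile["present"]) | set(profile.get("absent", [])):
                _, _, dmrs = call_cohort(cohort, th)
                local[cohort] = dmrs_to_frame(dmrs)
        min_ov = int(profile.get("min_overlap_bp", 1))
        seg = trait_segregation(local, profile["present"], profile.get("absent", []),
                                min_overlap_bp=min_ov)
        seg_path = outdir / f"segregation_{name}.bed"
        write_bed(seg.assign(name=seg.get("direction_class", ".")), seg_path,
                  comment=f"profile {name}: present={profile['present']} "
                          f"absent={profile.get('absent', [])}")
        entry = {
            "present": list(profile["present"]),
            "absent": list(profile.get("absent", [])),
            "q_max": th.q_max,
            "n_regions": int(len(seg)),
            "regions": [
                {"chrom": r.chrom, "start": int(r.start), "end": int(r.end)}
                for r in seg[REGION_COLUMNS].itertuples(index=False)
            ],
        }
        if truth is not None and "expected_class" in profile:
            truth_regions = planted_to_bed(planted_by_class[profile["expected_class"]])
            entry["recovery"] = _evaluate_recovery(
                seg[REGION_COLUMNS].reset_index(drop=True), truth_regions)
        report["segregation"][name] = entry
        if profile.get("overlap_test") and len(profile["present"]) >= 2:
            a_label, b_label = profile["present"][:2]
            universe = candidate_universe(results[a_label]["pooled"],
                                          th.min_sites, th.max_gap)
            test = fisher_overlap_test(local[a_label], local[b_label], universe,
                                       min_overlap_bp=min_ov)
            report["overlap_tests"][name] = test.to_dict()

    if "propagation" in config:
        prop = config["propagation"]
        pgc = dmrs_to_frame(results[prop["pgc_cohort"]]["dmrs"])
        g1, g2 = prop["downstream"]
        table = propagation_check(pgc, {g1: tables_of(g1), g2: tables_of(g2)},
                                  thresholds)
        table.to_csv(outdir / "propagation.tsv", sep="\t", index=False)
        tested = table[table["status"] == "tested"]
        report["propagation"] = {
            "downstream": [g1, g2],
            "n_regions": int(len(table)),
            "n_untestable": int((table["status"] == "untestable").sum()),
            "n_propagating": int(tested["propagates"].fillna(False).sum()),
        }

    with (outdir / "report.json").open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline finished: %d cohorts, outputs in %s", len(cohorts), outdir)
    return report
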