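"""Synthetic multigroup bisulfite count data with planted DMRs.

The generator emulates the statistical structure that the downstream
inference assumes for reduced-representation bisulfite data:

* a genome of genes, CpG islands and cytosine sites arranged in covered
  fragments, as in reduced-representation sequencing (overall density
  ~1 site / 100 bp, mostly CpG context);
* a baseline methylation landscape that is low inside CpG islands (mean
  0.10), high at non-island CpG sites (mean 0.80) and near zero at CpH sites
  (mean 0.03), with mild per-site variation;
* planted differentially methylated regions: short runs of sites 40-60 bp
  apart whose methylation in the affected cohorts is shifted by a signed
  effect Δ. Planted sites receive an intermediate baseline (|Δ| for
  hypomethylation, 1-|Δ| for hypermethylation) so the affected cohort
  saturates at the fully unmethylated/methylated state and the planted
  contrast equals Δ exactly, the switch-like behaviour typical of regions
  that are variably methylated between cohorts;
* negative-binomial per-site coverage and beta-binomial methylated counts
  (small replicate overdispersion).

A single master seed fans out to named substreams (genome, placement,
baseline, per-sample counts) so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _intervals as iv
from .errors import ConfigError, DesignError, PlacementError
from .io import REPORT_COLUMNS, build_annotation

BASELINE_MEANS = {"island_cpg": 0.10, "cpg": 0.80, "cph": 0.03}
BASELINE_CONCENTRATION = 50.0  # per-site jitter of the baseline landscape
DEFAULT_DESIGN = {
    "WT": ("WT_1", "WT_2", "WT_3"),
    "F1": ("F1_1", "F1_2", "F1_3"),
}
_PLACEMENT_BUFFER = 2_000  # min bp between planted regions (> max_gap)


def substream(seed: int, *names) -> np.random.SeedSequence:
    """Derive a named, platform-stable child stream from a master seed."""
    tags = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.SeedSequence(entropy=[int(seed), *tags])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeConfig:
    """Synthetic genome layout.

    Cytosine sites are placed in covered fragments, mimicking the
    reduced-representation structure of the assay: each fragment holds
    ~``fragment_sites`` sites (Poisson) with geometric intra-fragment gaps of
    mean ``site_spacing`` bp, and consecutive fragments are separated by
    ``fragment_gap_min`` plus an exponential extra gap of mean
    ``fragment_gap`` bp. The defaults give an overall site density of
    1 per 100 bp (see :meth:`site_density`). cpg_fraction is the CpG share
    of sites (the remainder is CpH).
    """

    chromosomes: tuple = (("chr1", 2_000_000),)
    n_genes: int = 20
    gene_length: tuple[int, int] = (10_000, 60_000)
    exons_per_gene: tuple[int, int] = (3, 8)
    islands_per_mb: float = 5.0
    island_length: tuple[int, int] = (300, 1_500)
    fragment_sites: float = 20.0
    site_spacing: float = 50.0
    fragment_gap_min: int = 800
    fragment_gap: float = 250.0
    cpg_fraction: float = 0.97

    def __post_init__(self):
        problems = []
        if not self.chromosomes or any(int(ln) <= 0 for _, ln in self.chromosomes):
            problems.append("chromosome lengths must be positive")
        if self.n_genes < 0:
            problems.append("n_genes must be >= 0")
        if self.islands_per_mb < 0:
            problems.append("islands_per_mb must be >= 0")
        if self.fragment_sites < 1:
            problems.append("fragment_sites must be >= 1")
        if self.site_spacing <= 1:
            problems.append("site_spacing must exceed 1 bp")
        if self.fragment_gap_min < 1 or self.fragment_gap < 0:
            problems.append("fragment gaps must be positive")
        if not (0.0 <= self.cpg_fraction <= 1.0):
            problems.append("cpg_fraction must lie in [0, 1]")
        if problems:
            raise ConfigError("; ".join(problems))

    def site_density(self) -> float:
        """Expected sites per bp (renewal rate of the fragment process)."""
        period = ((self.fragment_sites - 1) * self.site_spacing
                  + self.fragment_gap_min + self.fragment_gap)
        return self.fragment_sites / period


@dataclass
class GenomeSpec:
    """Materialized genome: chromosome sizes, gene models, CpG islands and
    the cytosine site table (chrom, pos, strand, context), sorted with
    strictly increasing positions per chromosome."""

    chromosomes: list[tuple[str, int]]
    genes: pd.DataFrame
    cpg_islands: pd.DataFrame
    sites: pd.DataFrame
    config: GenomeConfig
    seed: int

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {name: int(size) for name, size in self.chromosomes}

    def annotation(self):
        return build_annotation(self.genes, self.cpg_islands, self.chrom_sizes)

    def island_mask(self) -> np.ndarray:
        """Boolean per-site mask: site lies inside a CpG island."""
        mask = np.zeros(len(self.sites), dtype=bool)
        for chrom, group in self.sites.groupby("chrom"):
            ivs = iv.merge(
                [(int(r.start), int(r.end))
                 for r in self.cpg_islands[self.cpg_islands["chrom"] == chrom]
                 .itertuples(index=False)])
            if not ivs:
                continue
            starts = np.array([s for s, _ in ivs])
            ends = np.array([e for _, e in ivs])
            pos = group["pos"].to_numpy()
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
            mask[group.index.to_numpy()] = ok
        return mask


def _place_genes(rng, chrom, size, count, cfg: GenomeConfig) -> list[dict]:
    if count == 0:
        return []
    slot = size // count
    genes = []
    for i in range(count):
        lo, hi = cfg.gene_length
        length = int(min(rng.integers(lo, hi + 1), max(4, slot - 2)))
        start = int(i * slot + rng.integers(0, max(1, slot - length)))
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        n_ex = max(1, min(n_ex, (length - 1) // 2))
        if n_ex > 1:
            inner = np.sort(rng.choice(np.arange(1, length), size=2 * n_ex - 2,
                                       replace=False))
            bounds = np.concatenate([[0], inner, [length]])
        else:
            bounds = np.array([0, length])
        exons = [(start + int(bounds[2 * j]), start + int(bounds[2 * j + 1]))
                 for j in range(n_ex)]
        tss, tes = (start, start + length - 1) if strand == "+" else (start + length - 1, start)
        genes.append({"chrom": chrom, "tss": tss, "tes": tes, "strand": strand,
                      "gene_id": f"{chrom}_g{i + 1}", "exons": exons})
    return genes


def build_genome_spec(config: GenomeConfig | None = None, seed: int = 0) -> GenomeSpec:
    """Deterministically generate a genome from (config, seed)."""
    config = config or GenomeConfig()
    rng = np.random.default_rng(substream(seed, "genome"))
    total = sum(int(ln) for _, ln in config.chromosomes)

    genes: list[dict] = []
    remaining = config.n_genes
    for i, (chrom, size) in enumerate(config.chromosomes):
        if i == len(config.chromosomes) - 1:
            count = remaining
        else:
            count = int(round(config.n_genes * size / total))
            count = min(count, remaining)
        remaining -= count
        genes.extend(_place_genes(rng, chrom, int(size), count, config))
    genes_df = pd.DataFrame(genes, columns=["chrom", "tss", "tes", "strand",
                                            "gene_id", "exons"])

    islands = []
    for chrom, size in config.chromosomes:
        size = int(size)
        count = int(round(config.islands_per_mb * size / 1e6))
        chrom_genes = [g for g in genes if g["chrom"] == chrom]
        for _ in range(count):
            length = int(rng.integers(config.island_length[0], config.island_length[1] + 1))
            if chrom_genes and rng.random() < 0.7:
                g = chrom_genes[int(rng.integers(len(chrom_genes)))]
                center = g["tss"]  # islands are often promoter-associated
            else:
                center = int(rng.integers(0, size))
            s = max(0, center - length // 2)
            e = min(size, s + length)
            if e > s:
                islands.append((chrom, s, e))
    merged_islands = []
    for chrom, _ in config.chromosomes:
        for s, e in iv.merge([(s, e) for c, s, e in islands if c == chrom]):
            merged_islands.append((chrom, s, e))
    islands_df = pd.DataFrame(merged_islands, columns=["chrom", "start", "end"])

    site_frames = []
    for chrom, size in config.chromosomes:
        size = int(size)
        pos: list[np.ndarray] = []
        cur = 0
        while cur < size:
            n = max(1, int(rng.poisson(config.fragment_sites)))
            gaps = rng.geometric(1.0 / config.site_spacing, size=n - 1)
            frag = cur + np.concatenate([[0], np.cumsum(gaps)])
            pos.append(frag)
            cur = int(frag[-1]) + config.fragment_gap_min \
                + int(rng.exponential(config.fragment_gap))
        p = np.concatenate(pos) if pos else np.empty(0, dtype=int)
        p = p[p < size]
        context = np.where(rng.random(len(p)) < config.cpg_fraction, "CpG", "CpH")
        strand = np.where(rng.random(len(p)) < 0.5, "+", "-")
        site_frames.append(pd.DataFrame({"chrom": chrom, "pos": p,
                                         "strand": strand, "context": context}))
    sites_df = (pd.concat(site_frames, ignore_index=True)
                if site_frames else
                pd.DataFrame(columns=["chrom", "pos", "strand", "context"]))

    return GenomeSpec(
        chromosomes=[(name, int(size)) for name, size in config.chromosomes],
        genes=genes_df,
        cpg_islands=islands_df,
        sites=sites_df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True),
        config=config,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# planted DMRs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """Distribution of planted effects.

    delta: |Δ| of the methylation shift, a float or a (lo, hi) uniform range.
    n_sites: sites per region, an int or inclusive (lo, hi) range.
    spacing: inclusive bp range between consecutive planted sites.
    hypo_fraction: share of regions planted as hypomethylation (the 55/45
        hypo/hyper mix observed for brain DMRs).
    affected_groups: cohort labels whose methylation is shifted.
    cpg_fraction: CpG share of planted sites.
    """

    delta: float | tuple[float, float] = 0.30
    n_sites: int | tuple[int, int] = 6
    spacing: tuple[int, int] = (40, 60)
    hypo_fraction: float = 0.55
    affected_groups: tuple[str, ...] = ("F1",)
    cpg_fraction: float = 0.97

    def __post_init__(self):
        deltas = self.delta if isinstance(self.delta, tuple) else (self.delta,)
        if any(not (0 < d <= 1) for d in deltas):
            raise ConfigError(f"delta magnitudes must lie in (0, 1]: {self.delta}")
        ns = self.n_sites if isinstance(self.n_sites, tuple) else (self.n_sites,)
        if any(n < 1 for n in ns):
            raise ConfigError("n_sites must be >= 1")
        if not (0.0 <= self.hypo_fraction <= 1.0):
            raise ConfigError("hypo_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedDMR:
    chrom: str
    positions: tuple[int, ...]
    contexts: tuple[str, ...]
    delta: float  # signed shift applied to affected cohorts
    affected_groups: tuple[str, ...]

    @property
    def direction(self) -> str:
        return "hypo" if self.delta < 0 else "hyper"

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        return self.positions[-1] + 1


def plant_dmrs(genome: GenomeSpec, n_dmrs: int,
               effect_spec: EffectSpec | None = None, seed: int = 0,
               avoid: list[tuple[str, int, int]] | None = None
               ) -> list[PlantedDMR]:
    """Place non-overlapping DMRs and insert their sites into the genome.

    The planted site positions (spacing drawn from ``effect_spec.spacing``)
    are added to ``genome.sites`` in place, so after this call every planted
    position is an existing genome site. ``avoid`` lists (chrom, start, end)
    regions (e.g. previously planted classes) that must stay clear; placed
    regions keep a 2 kb buffer so neighbouring regions cannot chain together
    downstream.
    """
    if n_dmrs < 0:
        raise ConfigError("n_dmrs must be >= 0")
    spec = effect_spec or EffectSpec()
    rng = np.random.default_rng(substream(seed, "placement"))
    sizes = genome.chrom_sizes
    chroms = list(sizes)
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for region in avoid or []:
        chrom, s, e = region
        placed[chrom].append((int(s) - _PLACEMENT_BUFFER, int(e) + _PLACEMENT_BUFFER))

    out: list[PlantedDMR] = []
    tries = 0
    max_tries = 200 * max(1, n_dmrs)
    while len(out) < n_dmrs:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n_dmrs} non-overlapping regions "
                f"(placed {len(out)} after {tries} attempts)")
        tries += 1
        if isinstance(spec.n_sites, tuple):
            n_sites = int(rng.integers(spec.n_sites[0], spec.n_sites[1] + 1))
        else:
            n_sites = int(spec.n_sites)
        gaps = rng.integers(spec.spacing[0], spec.spacing[1] + 1, size=n_sites - 1)
        length = int(gaps.sum()) + 1
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        if sizes[chrom] <= length + 2 * _PLACEMENT_BUFFER:
            continue
        start = int(rng.integers(_PLACEMENT_BUFFER, sizes[chrom] - length - _PLACEMENT_BUFFER))
        candidate = (start - _PLACEMENT_BUFFER, start + length + _PLACEMENT_BUFFER)
        if any(iv.overlap_length(candidate, p) > 0 for p in placed[chrom]):
            continue
        if isinstance(spec.delta, tuple):
            magnitude = float(rng.uniform(spec.delta[0], spec.delta[1]))
        else:
            magnitude = float(spec.delta)
        sign = -1.0 if rng.random() < spec.hypo_fraction else 1.0
        positions = tuple(int(p) for p in start + np.concatenate([[0], np.cumsum(gaps)]))
        contexts = tuple("CpG" if rng.random() < spec.cpg_fraction else "CpH"
                         for _ in positions)
        placed[chrom].append(candidate)
        out.append(PlantedDMR(chrom=chrom, positions=positions, contexts=contexts,
                              delta=sign * magnitude,
                              affected_groups=tuple(spec.affected_groups)))
    apply_planted(genome, out)
    return out


def apply_planted(genome: GenomeSpec, planted: list[PlantedDMR]) -> None:
    """Insert planted site positions into the genome site table (in place).
    A planted site replaces any background site at the same position."""
    if not planted:
        return
    rows = [{"chrom": d.chrom, "pos": p, "strand": "+", "context": ctx}
            for d in planted for p, ctx in zip(d.positions, d.contexts)]
    combined = pd.concat([pd.DataFrame(rows), genome.sites], ignore_index=True)
    combined = combined.drop_duplicates(subset=["chrom", "pos"], keep="first")
    genome.sites = (combined.sort_values(["chrom", "pos"], kind="mergesort")
                    .reset_index(drop=True))


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageSpec:
    """Sequencing depth and noise: negative-binomial coverage (mean, NB
    dispersion/size) and beta-binomial replicate overdispersion rho (the
    intraclass correlation of methylation between replicates)."""

    mean: float = 30.0
    dispersion: float = 5.0
    overdispersion: float = 0.005

    def __post_init__(self):
        if self.mean <= 0 or self.dispersion <= 0:
            raise ConfigError("coverage mean and dispersion must be positive")
        if not (0.0 <= self.overdispersion < 1.0):
            raise ConfigError("overdispersion must lie in [0, 1)")


@dataclass
class TruthSet:
    """Everything needed to regenerate the simulation: the genome recipe,
    the planted regions, the per-site baselines and the master seed."""

    genome_config: dict
    genome_seed: int
    planted: list[PlantedDMR]
    baseline: np.ndarray  # per-site baseline fraction, genome site order
    seed: int
    design: dict[str, tuple[str, ...]]
    coverage: CoverageSpec

    def to_json(self, path=None) -> str:
        payload = {
            "genome_config": self.genome_config,
            "genome_seed": self.genome_seed,
            "planted": [asdict(d) for d in self.planted],
            "baseline": [float(x) for x in self.baseline],
            "seed": self.seed,
            "design": {g: list(s) for g, s in self.design.items()},
            "coverage": asdict(self.coverage),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "TruthSet":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text_or_path).read_text()
        payload = json.loads(text)
        planted = [PlantedDMR(chrom=d["chrom"], positions=tuple(d["positions"]),
                              contexts=tuple(d["contexts"]), delta=d["delta"],
                              affected_groups=tuple(d["affected_groups"]))
                   for d in payload["planted"]]
        return cls(
            genome_config=payload["genome_config"],
            genome_seed=payload["genome_seed"],
            planted=planted,
            baseline=np.asarray(payload["baseline"], dtype=float),
            seed=payload["seed"],
            design={g: tuple(s) for g, s in payload["design"].items()},
            coverage=CoverageSpec(**payload["coverage"]),
        )

    def regenerate(self) -> tuple[GenomeSpec, dict[str, pd.DataFrame]]:
        """Rebuild the genome and the per-sample count tables from scratch."""
        cfg = dict(self.genome_config)
        cfg["chromosomes"] = tuple(tuple(c) for c in cfg["chromosomes"])
        for key in ("gene_length", "exons_per_gene", "island_length"):
            cfg[key] = tuple(cfg[key])
        genome = build_genome_spec(GenomeConfig(**cfg), self.genome_seed)
        apply_planted(genome, self.planted)
        samples, _ = simulate_counts(genome, self.planted, self.design,
                                     self.coverage, self.seed)
        return genome, samples


def baseline_fractions(genome: GenomeSpec, planted: list[PlantedDMR],
                       seed: int) -> np.ndarray:
    """Per-site baseline methylation: beta-jittered class means (island CpG
    0.10, non-island CpG 0.80, CpH 0.03); planted sites pinned to |Δ| (hypo)
    or 1-|Δ| (hyper) so the shifted cohort saturates at 0/1."""
    rng = np.random.default_rng(substream(seed, "baseline"))
    island = genome.island_mask()
    context = genome.sites["context"].to_numpy()
    mean = np.where(context == "CpH", BASELINE_MEANS["cph"],
                    np.where(island, BASELINE_MEANS["island_cpg"],
                             BASELINE_MEANS["cpg"]))
    conc = BASELINE_CONCENTRATION
    base = rng.beta(mean * conc, (1.0 - mean) * conc)
    index = _site_index(genome)
    for d in planted:
        level = abs(d.delta) if d.delta < 0 else 1.0 - abs(d.delta)
        for p in d.positions:
            base[index[(d.chrom, p)]] = level
    return base


def _site_index(genome: GenomeSpec) -> dict[tuple[str, int], int]:
    return {(c, int(p)): i
            for i, (c, p) in enumerate(zip(genome.sites["chrom"], genome.sites["pos"]))}


def simulate_counts(genome: GenomeSpec, planted: list[PlantedDMR],
                    design: dict[str, tuple[str, ...]] | None = None,
                    coverage_spec: CoverageSpec | None = None, seed: int = 0
                    ) -> tuple[dict[str, pd.DataFrame], TruthSet]:
    """Simulate per-sample cytosine count tables.

    Every cohort shares the per-site baseline; cohorts listed in a planted
    region's affected_groups have their methylation fraction shifted by that
    region's Δ (clipped to [0, 1]) at its sites. Counts are beta-binomial on
    negative-binomial coverage. Returns ({sample_id: table}, TruthSet).
    """
    design = {g: tuple(s) for g, s in (design or DEFAULT_DESIGN).items()}
    if len(design) < 2:
        raise DesignError("design must name at least two cohorts")
    all_ids = [s for ids in design.values() for s in ids]
    if len(set(all_ids)) != len(all_ids):
        raise DesignError("sample ids must be unique across cohorts")
    for d in planted:
        unknown = set(d.affected_groups) - set(design)
        if unknown:
            raise DesignError(f"planted region affects unknown cohorts {sorted(unknown)}")
    coverage = coverage_spec or CoverageSpec()

    base = baseline_fractions(genome, planted, seed)
    index = _site_index(genome)
    group_mean: dict[str, np.ndarray] = {}
    for group in design:
        m = base.copy()
        for d in planted:
            if group in d.affected_groups:
                for p in d.positions:
                    m[index[(d.chrom, p)]] += d.delta
        group_mean[group] = np.clip(m, 0.0, 1.0)

    rho = coverage.overdispersion
    conc = (1.0 - rho) / rho if rho > 0 else None
    nb_p = coverage.dispersion / (coverage.dispersion + coverage.mean)
    template = genome.sites.reset_index(drop=True)
    samples: dict[str, pd.DataFrame] = {}
    for group, ids in design.items():
        m = group_mean[group]
        for sample in ids:
            rng = np.random.default_rng(substream(seed, "counts", sample))
            cov = rng.negative_binomial(coverage.dispersion, nb_p, size=len(m))
            if conc is None:
                p = m
            else:
                interior = (m > 0.0) & (m < 1.0)
                p = m.copy()
                if interior.any():
                    p[interior] = rng.beta(m[interior] * conc,
                                           (1.0 - m[interior]) * conc)
            meth = rng.binomial(cov, p)
            table = template.copy()
            table["meth"] = meth
            table["unmeth"] = cov - meth
            samples[sample] = table[REPORT_COLUMNS]

    truth = TruthSet(
        genome_config=asdict(genome.config),
        genome_seed=genome.seed,
        planted=list(planted),
        baseline=base,
        seed=int(seed),
        design=design,
        coverage=coverage,
    )
    return samples, truth


def planted_to_bed(planted: list[PlantedDMR]) -> pd.DataFrame:
    """Truth regions as a BED-style frame (0-based half-open)."""
    return pd.DataFrame(
        [{"chrom": d.chrom, "start": d.start, "end": d.end,
          "name": f"{d.direction}:{','.join(d.affected_groups)}"}
         for d in planted],
        columns=["chrom", "start", "end", "name"],
    )
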