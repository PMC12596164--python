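"""Forward-time simulator of a clonal, seasonally bottlenecked population.

A single-species population descends from ``n_clades`` founder genotypes,
each a fixed number of substitutions away from a common reference.  The
census follows a log-linear interpolation of a seasonal Log10 schedule,
capped at a scaled effective size (drift layer) and floored so troughs act
as bottlenecks.  Purifying constraint is modeled as site immutability: each
gene has a fixed constrained-site set that never mutates, so a gene's
expected diversity decreases monotonically with its constrained fraction.
Abundance observations are generated as a separate layer on the same
schedule with replicate noise and left-censoring at the LOD.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .abundance import CensoredSeries, series_to_frame

__all__ = [
    "GeneModel",
    "SimulationConfig",
    "IsolateSample",
    "SimulationTruth",
    "default_gene_models",
    "default_schedule",
    "simulate_population",
    "generate_abundance",
    "write_sample",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}

#: AbundanceSeries and CensoredSeries share one implementation.
AbundanceSeries = CensoredSeries


@dataclass(frozen=True)
class GeneModel:
    """A named gene with coding length and a purifying-constraint fraction.

    ``constrained_fraction`` is the fraction of nucleotide sites that are
    immutable; the constrained-site set is drawn once per simulation.
    """

    name: str
    cds_length_nt: int
    constrained_fraction: float

    def __post_init__(self) -> None:
        if self.cds_length_nt <= 0 or self.cds_length_nt % 3 != 0:
            raise ValueError(
                f"{self.name}: cds_length_nt must be a positive multiple of 3, "
                f"got {self.cds_length_nt}"
            )
        if not 0.0 <= self.constrained_fraction <= 1.0:
            raise ValueError(
                f"{self.name}: constrained_fraction must be in [0, 1], "
                f"got {self.constrained_fraction}"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to run one reproducible simulation.

    ``seasonal_log10_peaks`` is the full ordered schedule of
    (time-point label, Log10 abundance) pairs, including trough points;
    consecutive schedule points are ``generations_per_interval``
    generations apart.  ``sample_sizes`` maps a subset of schedule labels
    to the number of isolates drawn there.
    """

    genes: tuple[GeneModel, ...]
    n_clades: int
    founder_divergence_nt: int
    mu: float
    generations_per_interval: int
    seasonal_log10_peaks: tuple[tuple[str, float], ...]
    trough_log10: float
    sample_sizes: Mapping[str, int]
    effective_size_cap: int = 2000
    lod: float = 1.0
    seed: int = 1
    founder_weights: tuple[float, ...] | None = None
    allow_extinction: bool = False

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("at least one gene is required")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names")
        if self.n_clades < 1:
            raise ValueError("n_clades must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.founder_divergence_nt < 0:
            raise ValueError("founder_divergence_nt must be non-negative")
        if self.generations_per_interval < 1:
            raise ValueError("generations_per_interval must be positive")
        if self.effective_size_cap < self.n_clades:
            raise ValueError("effective_size_cap must be at least n_clades")
        labels = [lbl for lbl, _ in self.seasonal_log10_peaks]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate schedule labels")
        if not labels:
            raise ValueError("empty seasonal schedule")
        unknown = set(self.sample_sizes) - set(labels)
        if unknown:
            raise ValueError(
                f"sampled time points missing from the schedule: {sorted(unknown)}"
            )
        peak = max(level for _, level in self.seasonal_log10_peaks)
        if peak - self.trough_log10 < 0:
            raise ValueError("trough_log10 exceeds the maximum scheduled level")
        if self.founder_weights is not None:
            if len(self.founder_weights) != self.n_clades:
                raise ValueError("founder_weights length must equal n_clades")
            if any(w < 0 for w in self.founder_weights) or sum(self.founder_weights) <= 0:
                raise ValueError("founder_weights must be non-negative and sum > 0")

    @property
    def total_length(self) -> int:
        return sum(g.cds_length_nt for g in self.genes)

    @property
    def schedule_labels(self) -> tuple[str, ...]:
        return tuple(lbl for lbl, _ in self.seasonal_log10_peaks)

    def census_floor(self) -> int:
        return 1 if self.allow_extinction else self.n_clades

    def census_at(self, log10_level: float) -> int:
        n = int(round(10.0 ** log10_level))
        return max(self.census_floor(), min(self.effective_size_cap, n))


@dataclass(frozen=True)
class IsolateSample:
    """One sampled isolate with its per-gene coding sequences."""

    isolate_id: str
    time_point: str
    source: str
    clade: int
    sequences: dict[str, str]

    def concatenated(self, gene_order: Sequence[str]) -> str:
        return "".join(self.sequences[g] for g in gene_order)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth retained from a simulation run for downstream checks."""

    reference: str
    founders: dict[int, str]
    constrained_sites: dict[str, tuple[int, ...]]
    gene_offsets: dict[str, tuple[int, int]]
    isolate_clades: dict[str, int]
    census_at_schedule: dict[str, int]
    seed: int


# ---------------------------------------------------------------------------
# defaults
# ---------------------------------------------------------------------------

def default_gene_models() -> tuple[GeneModel, ...]:
    """Gene roster: a biosynthetic cluster (tdaA-F), two accessory
    biosynthesis genes, three housekeeping genes and one free gene.

    Constraint fractions are distinct so score rank order is a usable
    truth signal; housekeeping genes are near-totally constrained and the
    free gene is unconstrained.
    """
    return (
        GeneModel("tdaA", 900, 0.83),
        GeneModel("tdaB", 660, 0.50),
        GeneModel("tdaC", 735, 0.95),
        GeneModel("tdaD", 603, 0.74),
        GeneModel("tdaE", 1140, 0.63),
        GeneModel("tdaF", 1002, 0.90),
        GeneModel("sulfurase", 1203, 0.35),
        GeneModel("gst", 903, 0.18),
        GeneModel("gyrA", 2640, 0.975),
        GeneModel("rpoB", 4062, 0.99),
        GeneModel("recA", 1041, 1.0),
        GeneModel("neutral", 900, 0.0),
    )


def default_schedule(
    n_years: int = 12,
    peak_log10: float = 5.2,
    autumn_log10: float = 4.6,
    trough_log10: float = 0.0,
) -> tuple[tuple[tuple[str, float], ...], dict[str, int]]:
    """Two sampled seasons per year (summer peak, autumn shoulder) with a
    winter trough between years; samples only at summer/autumn points.
    """
    schedule: list[tuple[str, float]] = []
    sample_sizes: dict[str, int] = {}
    sizes = [6, 7, 4, 11, 14, 4, 13, 9, 19, 8, 23, 11]
    for year in range(n_years):
        summer = f"Y{year + 1:02d}-summer"
        autumn = f"Y{year + 1:02d}-autumn"
        winter = f"Y{year + 1:02d}-winter"
        schedule.append((summer, peak_log10))
        schedule.append((autumn, autumn_log10))
        schedule.append((winter, trough_log10))
        sample_sizes[summer] = sizes[year % len(sizes)]
        sample_sizes[autumn] = max(4, sizes[(year + 5) % len(sizes)] // 2)
    return tuple(schedule), sample_sizes


def parameter_recovery_config(seed: int = 1) -> SimulationConfig:
    """Scaled benchmark population for conservation-rank recovery.

    Twelve years of two sampled seasons (24 seasonal intervals), a 2000-
    individual drift cap, moderate winter bottlenecks that keep several
    founder clades segregating, and founder divergence strong enough that
    each gene's diversity reflects its constrained fraction.
    """
    schedule: list[tuple[str, float]] = []
    sample_sizes: dict[str, int] = {}
    sizes = [6, 7, 4, 11, 14, 4, 13, 19, 9, 23, 11, 8]
    for year in range(12):
        summer = f"Y{year + 1:02d}-summer"
        winter = f"Y{year + 1:02d}-winter"
        schedule.append((summer, 5.2))
        schedule.append((winter, 2.5))
        sample_sizes[summer] = sizes[year]
    return SimulationConfig(
        genes=default_gene_models(),
        n_clades=8,
        founder_divergence_nt=600,
        mu=5e-5,
        generations_per_interval=6,
        seasonal_log10_peaks=tuple(schedule),
        trough_log10=2.5,
        sample_sizes=sample_sizes,
        effective_size_cap=2000,
        lod=1.0,
        seed=seed,
    )


def clade_recovery_config(seed: int = 1, n_years: int = 7) -> SimulationConfig:
    """Benchmark population for clade assignment and timeline checks.

    Founder divergence is calibrated so minimum pairwise identity sits
    near 0.986; founder weights are skewed so two dominant clades persist
    through every sampled season while minor clades drift.
    """
    schedule: list[tuple[str, float]] = []
    sample_sizes: dict[str, int] = {}
    for year in range(n_years):
        summer = f"Y{year + 1:02d}-summer"
        winter = f"Y{year + 1:02d}-winter"
        schedule.append((summer, 5.2))
        schedule.append((winter, 3.0))
        sample_sizes[summer] = 24
    return SimulationConfig(
        genes=default_gene_models(),
        n_clades=8,
        founder_divergence_nt=110,
        mu=1e-6,
        generations_per_interval=6,
        seasonal_log10_peaks=tuple(schedule),
        trough_log10=3.0,
        sample_sizes=sample_sizes,
        effective_size_cap=2000,
        lod=1.0,
        seed=seed,
        founder_weights=(0.04, 0.42, 0.36, 0.05, 0.04, 0.04, 0.03, 0.02),
    )


def default_config(seed: int = 1, n_years: int = 12) -> SimulationConfig:
    schedule, sample_sizes = default_schedule(n_years=n_years)
    return SimulationConfig(
        genes=default_gene_models(),
        n_clades=8,
        founder_divergence_nt=60,
        mu=2e-5,
        generations_per_interval=6,
        seasonal_log10_peaks=schedule,
        trough_log10=0.0,
        sample_sizes=sample_sizes,
        effective_size_cap=2000,
        lod=1.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# simulation internals
# ---------------------------------------------------------------------------

def _random_reference(rng: np.random.Generator, genes: Sequence[GeneModel]) -> np.ndarray:
    """Random coding genome: per gene an ATG start, no internal stop codons
    and a single terminal stop codon (TAA).  The terminal stop is kept
    immutable by the constraint mask so translated proteins stay equal
    length across isolates."""
    chunks = []
    for gene in genes:
        n_codons = gene.cds_length_nt // 3
        codons = rng.integers(0, 4, size=(n_codons, 3))
        for i in range(n_codons):
            while _codon_str(codons[i]) in _STOPS:
                codons[i] = rng.integers(0, 4, size=3)
        codons[0] = [0, 3, 2]  # ATG
        codons[-1] = [3, 0, 0]  # TAA
        chunks.append(codons.reshape(-1))
    return np.concatenate(chunks).astype(np.uint8)


def _codon_str(codon: np.ndarray) -> str:
    return "".join("ACGT"[b] for b in codon)


def decode(genome: np.ndarray) -> str:
    return _BASES[genome].tobytes().decode("ascii")


def _gene_offsets(genes: Sequence[GeneModel]) -> dict[str, tuple[int, int]]:
    offsets = {}
    pos = 0
    for g in genes:
        offsets[g.name] = (pos, pos + g.cds_length_nt)
        pos += g.cds_length_nt
    return offsets


def _constrained_mask(
    rng: np.random.Generator, genes: Sequence[GeneModel], offsets: Mapping[str, tuple[int, int]]
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    total = sum(g.cds_length_nt for g in genes)
    mask = np.zeros(total, dtype=bool)
    per_gene: dict[str, np.ndarray] = {}
    for g in genes:
        start, end = offsets[g.name]
        L = g.cds_length_nt
        # the terminal stop codon is always immutable so that translated
        # proteins keep one common length across isolates
        stop_sites = np.array([L - 3, L - 2, L - 1], dtype=int)
        k = min(int(round(g.constrained_fraction * L)), L - 3)
        body = (
            np.sort(rng.choice(L - 3, size=k, replace=False)) if k else np.array([], dtype=int)
        )
        sites = np.concatenate([body, stop_sites])
        mask[start + sites] = True
        per_gene[g.name] = sites
    return mask, per_gene


def _interpolated_levels(config: SimulationConfig) -> np.ndarray:
    """Log10 level at every generation: piecewise-linear between schedule
    points, ``generations_per_interval`` generations apart."""
    levels = np.array([lvl for _, lvl in config.seasonal_log10_peaks], dtype=float)
    k = config.generations_per_interval
    if len(levels) == 1:
        return levels
    grid = np.arange((len(levels) - 1) * k + 1, dtype=float)
    anchors = np.arange(len(levels), dtype=float) * k
    return np.interp(grid, anchors, levels)


def simulate_population(
    config: SimulationConfig,
) -> tuple[list[IsolateSample], SimulationTruth]:
    """Run the forward-time simulation and draw isolates at sampled points.

    Generations are discrete; each generation the next census is drawn from
    the interpolated schedule, offspring choose parents uniformly at random
    (multinomial drift) and receive Poisson(mu x unconstrained sites)
    mutations placed uniformly on unconstrained sites, each a uniform
    choice among the 3 alternative bases.  Constrained sites never mutate.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.genes
    offsets = _gene_offsets(genes)
    total = config.total_length

    reference = _random_reference(rng, genes)
    mask, constrained_per_gene = _constrained_mask(rng, genes, offsets)
    unconstrained = np.flatnonzero(~mask)
    n_free = len(unconstrained)

    # founders: d substitutions each, at unconstrained sites
    founders = np.tile(reference, (config.n_clades, 1))
    d = config.founder_divergence_nt
    if d > n_free:
        raise ValueError(
            f"founder_divergence_nt={d} exceeds the {n_free} unconstrained sites"
        )
    for c in range(config.n_clades):
        if d:
            sites = rng.choice(unconstrained, size=d, replace=False)
            founders[c, sites] = (founders[c, sites] + rng.integers(1, 4, size=d)) % 4

    levels = _interpolated_levels(config)
    k = config.generations_per_interval
    schedule_gens = {i * k: lbl for i, lbl in enumerate(config.schedule_labels)}

    # initial population at the first schedule point
    n0 = config.census_at(levels[0])
    if config.founder_weights is not None:
        w = np.asarray(config.founder_weights, dtype=float)
        clades = rng.choice(config.n_clades, size=n0, p=w / w.sum())
    else:
        clades = np.arange(n0) % config.n_clades
    pop = founders[clades].copy()
    clades = clades.copy()

    mu_total = config.mu * n_free
    isolates: list[IsolateSample] = []
    isolate_clades: dict[str, int] = {}
    census_at_schedule: dict[str, int] = {}

    def mutate(population: np.ndarray) -> None:
        if mu_total == 0 or population.shape[0] == 0:
            return
        counts = rng.poisson(mu_total, size=population.shape[0])
        total_mut = int(counts.sum())
        if total_mut == 0:
            return
        rows = np.repeat(np.arange(population.shape[0]), counts)
        sites = unconstrained[rng.integers(0, n_free, size=total_mut)]
        shifts = rng.integers(1, 4, size=total_mut).astype(np.uint8)
        population[rows, sites] = (population[rows, sites] + shifts) % 4

    def sample_at(label: str) -> None:
        n_req = config.sample_sizes.get(label)
        if n_req is None:
            return
        if n_req > pop.shape[0]:
            raise ValueError(
                f"sample size {n_req} at time point {label!r} exceeds the "
                f"census of {pop.shape[0]}"
            )
        idx = rng.choice(pop.shape[0], size=n_req, replace=False)
        for j, i in enumerate(sorted(int(x) for x in idx), start=1):
            iso_id = f"{label}_i{j:03d}"
            seq = decode(pop[i])
            sequences = {g.name: seq[offsets[g.name][0] : offsets[g.name][1]] for g in genes}
            iso = IsolateSample(
                isolate_id=iso_id,
                time_point=label,
                source="bryozoan",
                clade=int(clades[i]) + 1,
                sequences=sequences,
            )
            isolates.append(iso)
            isolate_clades[iso_id] = iso.clade

    census_at_schedule[config.schedule_labels[0]] = n0
    sample_at(config.schedule_labels[0])

    for g in range(1, len(levels)):
        n_next = config.census_at(levels[g])
        parents = rng.integers(0, pop.shape[0], size=n_next)
        pop = pop[parents]
        clades = clades[parents]
        mutate(pop)
        label = schedule_gens.get(g)
        if label is not None:
            census_at_schedule[label] = n_next
            sample_at(label)

    truth = SimulationTruth(
        reference=decode(reference),
        founders={c + 1: decode(founders[c]) for c in range(config.n_clades)},
        constrained_sites={
            g.name: tuple(int(s) for s in constrained_per_gene[g.name]) for g in genes
        },
        gene_offsets=offsets,
        isolate_clades=isolate_clades,
        census_at_schedule=census_at_schedule,
        seed=config.seed,
    )
    return isolates, truth


# ---------------------------------------------------------------------------
# abundance observation layer
# ---------------------------------------------------------------------------

def generate_abundance(
    config: SimulationConfig,
    replicate_sd: float,
    n_replicates: int,
    *,
    compartment: str = "bryozoan",
    schedule: Sequence[tuple[str, float]] | None = None,
    seed: int | None = None,
) -> CensoredSeries:
    """Observation layer: replicate Log10 CFU draws around the schedule.

    Per time point, ``n_replicates`` values are drawn from
    Normal(scheduled level, replicate_sd); draws below the LOD are flagged
    censored and carried at the LOD.  Deterministic under the seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if replicate_sd < 0:
        raise ValueError("replicate_sd must be non-negative")
    sched = tuple(schedule) if schedule is not None else config.seasonal_log10_peaks
    rng = np.random.default_rng(config.seed if seed is None else seed)
    raw: dict[str, list[float]] = {}
    for label, level in sched:
        raw[label] = list(rng.normal(level, replicate_sd, size=n_replicates))
    return CensoredSeries.from_observations(
        compartment, [lbl for lbl, _ in sched], raw, lod=config.lod
    )


# ---------------------------------------------------------------------------
# on-disk artifacts
# ---------------------------------------------------------------------------

def write_sample(
    isolates: Sequence[IsolateSample],
    abundance: Sequence[CensoredSeries] | CensoredSeries | None,
    directory: str | Path,
    truth: SimulationTruth | None = None,
) -> dict[str, Path]:
    """Write per-gene FASTAs, the metadata CSV, the abundance CSV and the
    truth JSON.  Round-trips losslessly through the io_cli readers."""
    from .io_cli.io import write_fasta  # local import avoids a cycle

    if not isolates:
        raise ValueError("empty isolate list")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    gene_names = list(isolates[0].sequences)
    for gene in gene_names:
        path = directory / f"{gene}.fasta"
        write_fasta([(iso.isolate_id, iso.sequences[gene]) for iso in isolates], path)
        written[f"fasta:{gene}"] = path

    meta_path = directory / "metadata.csv"
    with open(meta_path, "w") as fh:
        fh.write("isolate_id,time_point,source,clade\n")
        for iso in isolates:
            fh.write(f"{iso.isolate_id},{iso.time_point},{iso.source},{iso.clade}\n")
    written["metadata"] = meta_path

    if abundance is not None:
        series_list = [abundance] if isinstance(abundance, CensoredSeries) else list(abundance)
        import pandas as pd

        frame = pd.concat([series_to_frame(s) for s in series_list], ignore_index=True)
        ab_path = directory / "abundance.csv"
        # %.17g round-trips doubles exactly
        frame.to_csv(ab_path, index=False, float_format="%.17g")
        written["abundance"] = ab_path

    if truth is not None:
        truth_path = directory / "truth.json"
        payload = {
            "reference": truth.reference,
            "founders": {str(k): v for k, v in truth.founders.items()},
            "constrained_sites": {g: list(v) for g, v in truth.constrained_sites.items()},
            "gene_offsets": {g: list(v) for g, v in truth.gene_offsets.items()},
            "isolate_clades": truth.isolate_clades,
            "census_at_schedule": truth.census_at_schedule,
            "seed": truth.seed,
        }
        with open(truth_path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        written["truth"] = truth_path
    return written


def read_truth(path: str | Path) -> SimulationTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return SimulationTruth(
        reference=payload["reference"],
        founders={int(k): v for k, v in payload["founders"].items()},
        constrained_sites={g: tuple(v) for g, v in payload["constrained_sites"].items()},
        gene_offsets={g: (v[0], v[1]) for g, v in payload["gene_offsets"].items()},
        isolate_clades={k: int(v) for k, v in payload["isolate_clades"].items()},
        census_at_schedule={k: int(v) for k, v in payload["census_at_schedule"].items()},
        seed=int(payload["seed"]),
    )
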