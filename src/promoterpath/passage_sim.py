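"""Forward stochastic simulator of serial-passage phage evolution.

A phage genotype is the joint state of its promoter network: for each
annotated promoter locus, the current motif triplet and a copy number.
Each passage consists of a fixed number of replication rounds — fitness-
weighted multinomial resampling with per-base substitution and per-locus
duplication — followed by a multinomial bottleneck emulating the
transfer of a lysate aliquot to a fresh host culture. Fitness derives
from the activity landscape: each locus contributes its weight times a
saturating function of (copy number x expression level x activity).

The population is tracked in genotype-frequency space with a
configurable effective sampling size rather than as 10^7-10^8 individual
virions; drift at the bottleneck and during growth is represented by
multinomial sampling at that effective size. Allele-frequency records
can be re-sampled at finite sequencing depth to emulate population
sequencing.

All randomness flows from a single master seed via
``numpy.random.SeedSequence``; per-line streams are spawned
deterministically, so a run is a pure function of (config, inputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path as FilePath
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import ComputationError, InputError, MissingGenotypeError
from .landscape import Landscape
from .sequence_space import DNA, as_genotype

#: Length of the full promoter element in nt (positions -17..+6 around
#: the transcription start; the specificity-determining triplet sits at
#: positions -11..-9, offsets 6..8 from the promoter start).
PROMOTER_LENGTH = 23
MOTIF_OFFSET_START = 6  # 0-based offset of position -11 from promoter start
MOTIF_OFFSET_END = 8    # 0-based offset of position -9


@dataclass(frozen=True)
class PromoterLocus:
    """One promoter of the phage genome.

    ``genome_start`` is the 1-based coordinate of the first promoter
    base; ``weight`` is the locus's relative contribution to phage
    fitness (the experiments do not measure these, so fixtures default
    to equal weights).
    """

    name: str
    genome_start: int
    strand: str
    ancestral_triplet: str
    weight: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "ancestral_triplet", as_genotype(self.ancestral_triplet))
        if self.genome_start < 1:
            raise InputError(f"{self.name}: genome_start must be >= 1")
        if self.strand not in ("+", "-"):
            raise InputError(f"{self.name}: strand must be '+' or '-'")
        if self.weight < 0:
            raise InputError(f"{self.name}: weight must be non-negative")

    def motif_window(self) -> tuple[int, int]:
        """1-based closed interval of genome positions holding the triplet."""
        if self.strand == "+":
            lo = self.genome_start + MOTIF_OFFSET_START
            return (lo, lo + (MOTIF_OFFSET_END - MOTIF_OFFSET_START))
        end = self.genome_start + PROMOTER_LENGTH - 1
        hi = end - MOTIF_OFFSET_START
        return (hi - (MOTIF_OFFSET_END - MOTIF_OFFSET_START), hi)


@dataclass(frozen=True)
class PhageGenotype:
    """Per-locus (triplet, copy number) state of one phage genome.

    Stored as a sorted tuple of ``(locus, triplet, copy_number)`` so the
    object is hashable and usable as a population-composition key.
    """

    locus_states: tuple[tuple[str, str, int], ...]

    @classmethod
    def from_dict(cls, states: Mapping[str, tuple[str, int]]) -> "PhageGenotype":
        items = tuple(
            sorted((name, as_genotype(trip), int(copy)) for name, (trip, copy) in states.items())
        )
        for _, _, copy in items:
            if copy < 1:
                raise InputError("copy_number must be >= 1")
        return cls(items)

    @classmethod
    def ancestral(cls, loci: Sequence[PromoterLocus]) -> "PhageGenotype":
        return cls.from_dict({l.name: (l.ancestral_triplet, 1) for l in loci})

    def as_dict(self) -> dict[str, tuple[str, int]]:
        return {name: (trip, copy) for name, trip, copy in self.locus_states}

    def triplet(self, locus: str) -> str:
        return self.as_dict()[locus][0]

    def copy_number(self, locus: str) -> int:
        return self.as_dict()[locus][1]

    def with_state(self, locus: str, triplet: str | None = None,
                   copy_number: int | None = None) -> "PhageGenotype":
        d = self.as_dict()
        if locus not in d:
            raise InputError(f"unknown locus {locus!r}")
        trip, copy = d[locus]
        d[locus] = (triplet if triplet is not None else trip,
                    copy_number if copy_number is not None else copy)
        return PhageGenotype.from_dict(d)


@dataclass
class PopulationState:
    """Genotype-frequency composition of one phage line."""

    composition: dict[PhageGenotype, float]
    census_size: int

    def __post_init__(self):
        if self.census_size <= 0:
            raise InputError("census_size must be positive")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"frequencies must sum to 1, got {total}")


@dataclass
class PassageConfig:
    """All serial-passage simulator parameters.

    The bottleneck transfers ~``bottleneck_size`` phage between
    passages; drift is simulated at ``effective_sample_size`` draws
    (the smaller of the two governs sampling). ``expression_level``
    applies through ``expression_switch_passage`` and then drops to
    ``expression_level_late``, emulating induced vs uninduced supply of
    the complementing polymerase over the two halves of the experiment.
    """

    n_passages: int = 100
    n_lines: int = 4
    bottleneck_size: int = 10_000_000
    effective_sample_size: int = 100_000
    moi: float = 0.01
    generations_per_passage: int = 5
    mutation_rate: float = 1e-6       # per motif base per replication
    duplication_rate: float = 1e-7    # per locus per replication
    max_copy_number: int = 2
    expression_level: float = 1.0
    expression_level_late: float = 0.2
    expression_switch_passage: int = 50
    fitness_k: float = 50.0           # half-saturation activity, % units
    default_activity: float | None = None
    sample_passages: tuple[int, ...] = (50, 100)
    sequencing_depth: int = 360_000
    seed: int = 0

    def __post_init__(self):
        if self.n_passages < 1:
            raise InputError("n_passages must be >= 1")
        if self.n_lines < 1:
            raise InputError("n_lines must be >= 1")
        if self.bottleneck_size < 1 or self.effective_sample_size < 1:
            raise InputError("population sizes must be positive")
        if self.generations_per_passage < 1:
            raise InputError("generations_per_passage must be >= 1")
        for rate_name in ("mutation_rate", "duplication_rate"):
            r = getattr(self, rate_name)
            if not 0.0 <= r <= 1.0:
                raise InputError(f"{rate_name} must be in [0, 1], got {r}")
        if self.max_copy_number < 1:
            raise InputError("max_copy_number must be >= 1")
        if not self.sample_passages:
            raise InputError("sample_passages must be non-empty")
        self.sample_passages = tuple(int(p) for p in self.sample_passages)

    def expression_at(self, passage: int) -> float:
        if passage <= self.expression_switch_passage:
            return self.expression_level
        return self.expression_level_late

    def to_yaml(self, path: str | FilePath) -> None:
        d = asdict(self)
        d["sample_passages"] = list(d["sample_passages"])
        FilePath(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | FilePath) -> "PassageConfig":
        data = yaml.safe_load(FilePath(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**data)


@dataclass
class TrajectoryRecord:
    """Per-line, per-passage marginal allele and duplication frequencies."""

    line_id: str
    passage: int
    allele_frequencies: dict[str, dict[str, float]]  # locus -> triplet -> freq
    duplication_frequencies: dict[str, float]        # locus -> freq(copy >= 2)


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------

def phage_fitness(
    genotype: PhageGenotype,
    landscape: Landscape,
    loci: Sequence[PromoterLocus],
    k: float = 50.0,
    expression_level: float = 1.0,
    default_activity: float | None = None,
) -> float:
    """Relative fitness of a phage genotype under the activity landscape.

    ``w = sum_l weight_l * x_l / (k + x_l)`` with
    ``x_l = copy_number_l * expression_level * a(triplet_l)``. The
    saturating (Michaelis-Menten) map means each locus's contribution is
    strictly increasing but diminishing in transcription activity —
    doubling an already-strong promoter helps less than rescuing a dead
    one. ``k`` is the half-saturation activity in percent units.
    Unmeasured triplets use ``default_activity`` when given, otherwise
    raise :class:`MissingGenotypeError`.
    """
    if k <= 0:
        raise InputError(f"half-saturation k must be positive, got {k}")
    states = genotype.as_dict()
    w = 0.0
    missing: set[str] = set()
    for locus in loci:
        trip, copy = states[locus.name]
        if trip in landscape:
            a = landscape.mean(trip)
        elif default_activity is not None:
            a = default_activity
        else:
            missing.add(trip)
            continue
        x = copy * expression_level * a
        w += locus.weight * x / (k + x)
    if missing:
        raise MissingGenotypeError(missing)
    return w


# ---------------------------------------------------------------------------
# Simulation core
# ---------------------------------------------------------------------------

class _MutationKernel:
    """Cached single-event mutation/duplication targets per genotype.

    Probability mass ``mutation_rate/3`` flows to each specific
    single-base substitution at each motif position of each locus
    (uniform over the three alternatives, no transition/transversion
    bias); mass ``duplication_rate`` flows to the copy-number+1 state of
    each locus still below ``max_copy_number``. Rates are small, so the
    linearised single-event approximation is used. The target list of a
    genotype never changes, so it is computed once and reused across
    generations and lines.
    """

    def __init__(self, mutation_rate: float, duplication_rate: float,
                 max_copy_number: int):
        self.mutation_rate = mutation_rate
        self.duplication_rate = duplication_rate
        self.max_copy_number = max_copy_number
        self._per_alt = mutation_rate / 3.0
        self._cache: dict[
            PhageGenotype, tuple[tuple[tuple[PhageGenotype, float], ...], float]
        ] = {}

    @property
    def active(self) -> bool:
        return self.mutation_rate > 0.0 or self.duplication_rate > 0.0

    def targets(self, g: PhageGenotype):
        """(mutant genotypes, their conditional probs, total event prob)."""
        cached = self._cache.get(g)
        if cached is not None:
            return cached
        muts: list[PhageGenotype] = []
        masses: list[float] = []
        states = g.locus_states
        for idx, (name, trip, copy) in enumerate(states):
            head, tail = states[:idx], states[idx + 1:]
            if self.mutation_rate > 0.0:
                for i, base in enumerate(trip):
                    for alt in DNA:
                        if alt == base:
                            continue
                        nt = trip[:i] + alt + trip[i + 1:]
                        # single-field replacement keeps the tuple sorted
                        muts.append(PhageGenotype(head + ((name, nt, copy),) + tail))
                        masses.append(self._per_alt)
            if self.duplication_rate > 0.0 and copy < self.max_copy_number:
                muts.append(PhageGenotype(head + ((name, trip, copy + 1),) + tail))
                masses.append(self.duplication_rate)
        moved = float(sum(masses))
        if moved > 1.0:
            raise ComputationError(
                "mutation/duplication rates too large for the linearised "
                "single-event model; reduce the rates"
            )
        probs = np.asarray(masses, dtype=float) / moved if moved > 0 else np.empty(0)
        cached = (tuple(muts), probs, moved)
        self._cache[g] = cached
        return cached


def _mutate_counts(
    counts: dict[PhageGenotype, int],
    kernel: _MutationKernel,
    rng: np.random.Generator,
) -> dict[PhageGenotype, int]:
    """Apply one replication round of mutation/duplication to counts.

    Each individual independently experiences a single event with
    probability ``moved`` (linearised per-replication hazard); the
    number of mutated offspring per genotype is binomial and the chosen
    targets multinomial, so only the few realised mutants cost anything.
    """
    out: dict[PhageGenotype, int] = {}
    for g, c in counts.items():
        muts, probs, moved = kernel.targets(g)
        m = int(rng.binomial(c, moved)) if moved > 0 else 0
        if c - m:
            out[g] = out.get(g, 0) + (c - m)
        if m:
            alloc = rng.multinomial(m, probs)
            for tg, k in zip(muts, alloc):
                if k:
                    out[tg] = out.get(tg, 0) + int(k)
    return out


def _select(
    comp: dict[PhageGenotype, float],
    fitness_cache: dict[PhageGenotype, float],
    fitness_fn,
) -> dict[PhageGenotype, float]:
    weighted = {}
    for g, f in comp.items():
        if g not in fitness_cache:
            fitness_cache[g] = fitness_fn(g)
        weighted[g] = f * fitness_cache[g]
    total = sum(weighted.values())
    if total <= 0:
        raise ComputationError("total population fitness is zero; cannot select")
    return {g: w / total for g, w in weighted.items()}


def _sample_counts(
    comp: dict[PhageGenotype, float], n: int, rng: np.random.Generator
) -> dict[PhageGenotype, int]:
    keys = sorted(comp, key=lambda g: g.locus_states)
    p = np.array([comp[g] for g in keys], dtype=float)
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    counts = rng.multinomial(n, p)
    return {g: int(c) for g, c in zip(keys, counts) if c > 0}


def _resample(
    comp: dict[PhageGenotype, float], n: int, rng: np.random.Generator
) -> dict[PhageGenotype, float]:
    return {g: c / n for g, c in _sample_counts(comp, n, rng).items()}


def marginal_frequencies(
    comp: dict[PhageGenotype, float], loci: Sequence[PromoterLocus]
) -> tuple[dict[str, dict[str, float]], dict[str, float]]:
    """Per-locus allele and duplication (copy >= 2) frequencies."""
    alleles: dict[str, dict[str, float]] = {l.name: {} for l in loci}
    dups: dict[str, float] = {l.name: 0.0 for l in loci}
    for g, f in comp.items():
        for name, trip, copy in g.locus_states:
            alleles[name][trip] = alleles[name].get(trip, 0.0) + f
            if copy >= 2:
                dups[name] += f
    return alleles, dups


def simulate_passages(
    config: PassageConfig,
    loci: Sequence[PromoterLocus],
    landscape: Landscape,
    initial_composition: Mapping[PhageGenotype, float] | None = None,
) -> list[TrajectoryRecord]:
    """Run all replicate lines and return records at the sampled passages.

    Each line evolves independently from the ancestral genotype (or
    ``initial_composition``): per passage, ``generations_per_passage``
    rounds of selection + mutation + multinomial resampling, then a
    bottleneck. Records are emitted at ``config.sample_passages`` (the
    final passage is always included if sampled).
    """
    names = [l.name for l in loci]
    if len(set(names)) != len(names):
        raise InputError("locus names must be unique")
    if initial_composition is None:
        initial_composition = {PhageGenotype.ancestral(loci): 1.0}
    init = dict(initial_composition)
    total = sum(init.values())
    if not init or abs(total - 1.0) > 1e-9:
        raise InputError("initial composition must be non-empty and sum to 1")

    n_draw = min(config.bottleneck_size, config.effective_sample_size)
    kernel = _MutationKernel(
        config.mutation_rate, config.duplication_rate, config.max_copy_number
    )
    streams = np.random.SeedSequence(config.seed).spawn(config.n_lines)
    records: list[TrajectoryRecord] = []
    for line_idx, stream in enumerate(streams, start=1):
        rng = np.random.default_rng(stream)
        line_id = f"line{line_idx}"
        comp = dict(init)
        fitness_cache_by_expr: dict[float, dict[PhageGenotype, float]] = {}
        for passage in range(1, config.n_passages + 1):
            expr = config.expression_at(passage)
            cache = fitness_cache_by_expr.setdefault(expr, {})

            def w(g, _expr=expr):
                return phage_fitness(
                    g, landscape, loci, k=config.fitness_k,
                    expression_level=_expr,
                    default_activity=config.default_activity,
                )

            for _ in range(config.generations_per_passage):
                comp = _select(comp, cache, w)
                counts = _sample_counts(comp, config.effective_sample_size, rng)
                if kernel.active:
                    counts = _mutate_counts(counts, kernel, rng)
                total = sum(counts.values())
                comp = {g: c / total for g, c in counts.items()}
            comp = _resample(comp, n_draw, rng)
            if passage in config.sample_passages:
                alleles, dups = marginal_frequencies(comp, loci)
                records.append(TrajectoryRecord(line_id, passage, alleles, dups))
    return records


# ---------------------------------------------------------------------------
# Sequencing emulation and summaries
# ---------------------------------------------------------------------------

def sequencing_sample(
    record: TrajectoryRecord, depth: int = 360_000,
    seed: int | np.random.Generator = 0,
) -> TrajectoryRecord:
    """Re-draw a record's frequencies at finite sequencing depth.

    Allele counts per locus are multinomial at ``depth`` reads;
    duplication presence is binomial at the same depth. An allele at
    true frequency 0 stays at 0.
    """
    if depth < 1:
        raise InputError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    new_alleles: dict[str, dict[str, float]] = {}
    for locus, freqs in record.allele_frequencies.items():
        trips = sorted(freqs)
        p = np.array([freqs[t] for t in trips], dtype=float)
        if p.sum() <= 0:
            new_alleles[locus] = {t: 0.0 for t in trips}
            continue
        counts = rng.multinomial(depth, p / p.sum())
        new_alleles[locus] = {t: c / depth for t, c in zip(trips, counts)}
    new_dups = {
        locus: rng.binomial(depth, min(max(f, 0.0), 1.0)) / depth
        for locus, f in record.duplication_frequencies.items()
    }
    return TrajectoryRecord(record.line_id, record.passage, new_alleles, new_dups)


@dataclass
class LocusSummary:
    """Fate of one locus in one line at the end of sampling."""

    fixed_allele: str | None
    alleles: dict[str, float]           # alleles above the reporting floor
    fixation_passage: int | None


def summarize_trajectory(
    records: Sequence[TrajectoryRecord],
    fixation_threshold: float = 0.95,
    reporting_floor: float = 0.02,
) -> dict[str, dict[str, LocusSummary]]:
    """Per-line, per-locus fixation/heterogeneity summary.

    An allele is *fixed* when its frequency at the final sampled passage
    reaches ``fixation_threshold``; ``fixation_passage`` is the first
    sampled passage at which it already met the threshold. Loci without
    a fixed allele report their allele set above ``reporting_floor``.
    """
    by_line: dict[str, list[TrajectoryRecord]] = {}
    for rec in records:
        by_line.setdefault(rec.line_id, []).append(rec)
    out: dict[str, dict[str, LocusSummary]] = {}
    for line_id, recs in by_line.items():
        recs = sorted(recs, key=lambda r: r.passage)
        final = recs[-1]
        out[line_id] = {}
        for locus, freqs in final.allele_frequencies.items():
            reported = {t: f for t, f in freqs.items() if f >= reporting_floor}
            fixed = None
            fix_passage = None
            if freqs:
                top = max(freqs, key=freqs.get)
                if freqs[top] >= fixation_threshold:
                    fixed = top
                    for r in recs:
                        if r.allele_frequencies.get(locus, {}).get(top, 0.0) >= fixation_threshold:
                            fix_passage = r.passage
                            break
            out[line_id][locus] = LocusSummary(fixed, reported, fix_passage)
    return out
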