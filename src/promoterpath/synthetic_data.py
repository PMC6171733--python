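"""Generators for every input the pipeline consumes.

Nothing here is downloaded: activity tables with replicate noise,
promoter-annotation fixtures, the observed-variant fixture encoding the
text-reported outcome of the passaging experiment, OD600 lysis curves,
and full simulator runs exported in the observation-table dialect.

Two kinds of numbers coexist and are kept strictly apart:

* *reported* values — counts and frequencies stated in the experimental
  record the fixture encodes (e.g. the 46.6%/25.6% trajectory of one
  promoter allele, the promoter inventory of 17 vs 16 loci);
* *fixture* values — placeholders chosen here so the pipeline has
  something concrete to chew on (activity truth levels, placeholder
  genome coordinates, the 20% frequency assigned to variants reported
  only as "present"). These carry flags in file headers or row flags so
  no count-based result ever depends on them.

Every generator is a deterministic function of its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError
from .landscape import ActivityRecord, Landscape, normalize_activity, write_activity_table
from .observed_data import (
    UNQUANTIFIED,
    VariantObservation,
    write_promoter_annotation,
    write_variant_table,
)
from .passage_sim import (
    PassageConfig,
    PromoterLocus,
    TrajectoryRecord,
    sequencing_sample,
    simulate_passages,
)
from .phenotype import GrowthCurve
from .sequence_space import as_genotype, direct_intermediates

WT_TRIPLET = "GAC"
TARGET_TRIPLET = "CGG"
ALT_BACKGROUND_TRIPLET = "AAC"  # the two non-canonical promoters

#: Default true mean activities, percent of the wild-type polymerase on
#: its cognate GAC promoter. The *ordering* encodes the measured
#: qualitative structure (GAG is the best single mutant; CAG and GGG are
#: near-tied, well above CGC and every single mutant; CGG is maximal;
#: GAC minimal; the three off-path triplets observed during passaging are
#: at least as active as the predicted single mutants). The numeric
#: levels themselves are fixture values.
DEFAULT_ACTIVITY_TRUTH: dict[str, float] = {
    "GAC": 2.0,
    "CAC": 8.0,
    "GGC": 6.0,
    "CGC": 10.0,
    "GAG": 20.0,
    "CAG": 55.0,
    "GGG": 50.0,
    "CGG": 80.0,
    # off-path triplets assayed only after they appeared in the evolved lines
    "GCC": 25.0,
    "CCC": 30.0,
    "AAG": 22.0,
}

#: Raw endpoint fluorescence of the reference pair (wild-type polymerase
#: on GAC), arbitrary units.
REFERENCE_RAW_VALUE = 1000.0


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic measurement process.

    ``replicate_cv`` is the coefficient of variation of the
    multiplicative gaussian replicate noise; triplicates at 5% CV mimic
    tight in vitro transcription endpoints. ``depth`` is the sequencing
    depth used when sampling simulated allele frequencies.
    """

    seed: int = 0
    activity_truth: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_TRUTH)
    )
    replicate_cv: float = 0.05
    n_replicates: int = 3
    od_growth_rate: float = 0.3        # per minute, logistic rise
    od_carrying: float = 1.0           # carrying OD600
    od_initial: float = 0.05
    od_drop_width: float = 1.5         # minutes, lysis drop steepness
    od_residual: float = 0.05          # debris OD after full lysis
    od_duration_min: float = 120.0
    depth: int = 360_000

    def __post_init__(self):
        if self.replicate_cv < 0:
            raise InputError("replicate_cv must be >= 0")
        if self.n_replicates < 1:
            raise InputError("n_replicates must be >= 1")
        self.activity_truth = {
            as_genotype(g): float(v) for g, v in self.activity_truth.items()
        }


# ---------------------------------------------------------------------------
# Activity tables
# ---------------------------------------------------------------------------

def validate_activity_orderings(
    truth: Mapping[str, float],
    src: str = WT_TRIPLET,
    dst: str = TARGET_TRIPLET,
) -> None:
    """Check a truth table against the measured qualitative orderings.

    Raises :class:`InputError` naming the violated constraint. The
    constraints (for the GAC -> CGG cube): GAG strictly tops the single
    mutants; CAG and GGG both exceed every single mutant and CGC; CGG is
    maximal; GAC is minimal among measured motifs.
    """
    required = {src, dst} | direct_intermediates(src, dst)
    missing = required - set(truth)
    if missing:
        raise InputError(
            "activity truth must cover src, dst and all direct intermediates; "
            "missing: " + ", ".join(sorted(missing))
        )
    t = truth

    def check(cond: bool, description: str) -> None:
        if not cond:
            raise InputError(f"activity ordering violated: {description}")

    check(t["GAG"] > t["CAC"] and t["GAG"] > t["GGC"],
          "GAG must exceed the other single mutants (CAC, GGC)")
    singles = ("GAG", "CAC", "GGC")
    for g in ("CAG", "GGG"):
        check(all(t[g] > t[s] for s in singles),
              f"{g} must exceed every single mutant")
        check(t[g] > t["CGC"], f"{g} must exceed CGC")
    check(all(t[dst] > v for g, v in t.items() if g != dst),
          f"{dst} must have the highest activity")
    check(all(t[src] < v for g, v in t.items() if g != src),
          f"{src} must have the lowest activity")


def make_activity_table(
    spec: SyntheticSpec,
    rnap_id: str = "evolved-RNAP",
    src: str = WT_TRIPLET,
    dst: str = TARGET_TRIPLET,
) -> tuple[list[ActivityRecord], ActivityRecord]:
    """Noisy replicate activity records plus the reference record.

    Replicates are ``truth * (1 + N(0, cv))`` floored at zero; the
    reference (wild-type polymerase on its cognate promoter) gets the
    same noise around :data:`REFERENCE_RAW_VALUE`. Returns
    ``(records, reference)`` ready for
    :func:`~promoterpath.landscape.normalize_activity`.
    """
    validate_activity_orderings(spec.activity_truth, src, dst)
    rng = np.random.default_rng(spec.seed)

    def noisy(mean: float) -> tuple[float, ...]:
        vals = mean * (1.0 + rng.normal(0.0, spec.replicate_cv, size=spec.n_replicates))
        return tuple(float(max(v, 0.0)) for v in vals)

    reference = ActivityRecord(src, "WT", noisy(REFERENCE_RAW_VALUE))
    records = [
        ActivityRecord(g, rnap_id, noisy(truth / 100.0 * REFERENCE_RAW_VALUE))
        for g, truth in sorted(spec.activity_truth.items())
    ]
    return records, reference


def make_landscape(spec: SyntheticSpec, **kwargs) -> Landscape:
    """Convenience: noisy activity table normalised to the reference."""
    records, reference = make_activity_table(spec, **kwargs)
    return normalize_activity(records, reference)


# ---------------------------------------------------------------------------
# Annotation fixtures
# ---------------------------------------------------------------------------

# Promoter inventory of the wild-type phage: 17 promoters, 15 with the
# GAC triplet and 2 (the leftmost and one weak internal promoter) with
# AAC. Coordinates for phi1.5 (7761) and phi2.5 (9090) are the reported
# genome positions; all other coordinates are plausible placeholders
# (flagged in file headers), spaced along the ~40-kb genome so motif
# windows never overlap.
_WT_PROMOTERS: list[tuple[str, int, str]] = [
    ("phiOL",   405,   ALT_BACKGROUND_TRIPLET),
    ("phi1.1A", 7588,  WT_TRIPLET),
    ("phi1.1B", 7655,  WT_TRIPLET),
    ("phi1.5",  7761,  WT_TRIPLET),   # reported coordinate
    ("phi1.3",  8120,  WT_TRIPLET),
    ("phi1.6",  8650,  WT_TRIPLET),
    ("phi2.5",  9090,  WT_TRIPLET),   # reported coordinate
    ("phi3.8",  11200, WT_TRIPLET),
    ("phi4c",   12600, ALT_BACKGROUND_TRIPLET),
    ("phi4.3",  13350, WT_TRIPLET),
    ("phi4.7",  14100, WT_TRIPLET),
    ("phi6.5",  18500, WT_TRIPLET),
    ("phi9",    21800, WT_TRIPLET),
    ("phi10",   22900, WT_TRIPLET),
    ("phi13",   27250, WT_TRIPLET),
    ("phi17",   34600, WT_TRIPLET),
    ("phiOR",   39200, WT_TRIPLET),
]

ANNOTATION_VARIANTS = ("T7_wildtype", "T7_delta1")

ANNOTATION_HEADER = (
    "synthetic promoter annotation fixture\n"
    "coordinates for phi1.5 and phi2.5 are reported genome positions; all "
    "other coordinates are non-reported placeholders\n"
    "weights are uniform placeholders (no measured per-promoter weights exist)"
)


def make_annotation_fixture(variant: str = "T7_delta1") -> list[PromoterLocus]:
    """Promoter loci for the wild-type phage (17) or the RNAP-deletion
    phage (16; the deletion also removes the first promoter, phi1.1A)."""
    if variant not in ANNOTATION_VARIANTS:
        raise InputError(
            f"variant must be one of {ANNOTATION_VARIANTS}, got {variant!r}"
        )
    rows = _WT_PROMOTERS
    if variant == "T7_delta1":
        rows = [r for r in rows if r[0] != "phi1.1A"]
    return [
        PromoterLocus(name=n, genome_start=s, strand="+",
                      ancestral_triplet=t, weight=1.0)
        for n, s, t in rows
    ]


# ---------------------------------------------------------------------------
# Observed-variant fixture (the experiment's reported outcome)
# ---------------------------------------------------------------------------

#: Placeholder frequency (%) for variants reported only as present.
PRESENT_PCT = 20.0
#: Sentinel frequency (%) for alleles reported as fixed.
FIXED_PCT = 100.0

OBSERVED_FIXTURE_HEADER = (
    "observed promoter-variant fixture encoding the reported passaging outcome\n"
    "rows flagged 'unquantified' carry placeholder frequencies (the record "
    "states presence only); unflagged frequencies are reported values"
)

ALL_LINES = ("line1", "line2", "line3", "line4")


def make_observed_fixture() -> list[VariantObservation]:
    """Variant table encoding the reported outcome of the passaging.

    Substitutions occurred in five promoters. phi1.5 swept to GAG in all
    four lines by passage 50 and stayed fixed; phi2.5 evolved to GAG in
    line 3 only, at 46.6% (p50) falling to 25.6% (p100); the leftmost
    promoter (AAC background) evolved AGC in line 4 (39% -> 3.2%) and
    ACC in lines 1-3 by p100, duplicating in all lines; phiOR evolved
    GCC in all lines by p50 and a heterogeneous mixture
    {GCC, GGG, AAG, GAG, CCC} by p100; phi6.5 was heterogeneous at both
    passages and duplicated in lines 2-4. Quantified frequencies are
    reported values; everything else is flagged unquantified.
    """
    obs: list[VariantObservation] = []

    def add(line, passage, prom, trip, pct, dup=False, flag=UNQUANTIFIED):
        obs.append(VariantObservation(line, passage, prom, trip, pct, dup, flag))

    # phi1.5 -> GAG, fixed in all four lines at both sampled passages.
    for line in ALL_LINES:
        for passage in (50, 100):
            add(line, passage, "phi1.5", "GAG", FIXED_PCT, flag="fixed")

    # phi2.5 -> GAG in line 3 only; reported frequencies.
    add("line3", 50, "phi2.5", "GAG", 46.6, flag="")
    add("line3", 100, "phi2.5", "GAG", 25.6, flag="")

    # phiOL (AAC background): AGC in line 4 with reported frequencies;
    # ACC in lines 1-3 (and AGC additionally in line 3) by passage 100.
    add("line4", 50, "phiOL", "AGC", 39.0, flag="")
    add("line4", 100, "phiOL", "AGC", 3.2, flag="")
    for line in ("line1", "line2", "line3"):
        add(line, 100, "phiOL", "ACC", PRESENT_PCT)
    add("line3", 100, "phiOL", "AGC", PRESENT_PCT)
    # widespread duplication of phiOL in all lines by passage 100
    for line in ALL_LINES:
        add(line, 100, "phiOL", ALT_BACKGROUND_TRIPLET, PRESENT_PCT, dup=True)

    # phiOR: GCC in all four lines by p50, heterogeneous mixture at p100.
    for line in ALL_LINES:
        add(line, 50, "phiOR", "GCC", PRESENT_PCT)
        for trip in ("GCC", "GGG", "AAG", "GAG", "CCC"):
            add(line, 100, "phiOR", trip, PRESENT_PCT)

    # phi6.5: heterogeneous at both passages; duplicated in lines 2-4.
    for line in ALL_LINES:
        for trip in ("GAC", "GAG", "CCC", "GCC"):
            add(line, 50, "phi6.5", trip, PRESENT_PCT)
        for trip in ("GAG", "CCC", "GCC", "GGG", "AAG"):
            add(line, 100, "phi6.5", trip, PRESENT_PCT)
    for line in ("line2", "line3", "line4"):
        add(line, 100, "phi6.5", WT_TRIPLET, PRESENT_PCT, dup=True)

    return obs


# ---------------------------------------------------------------------------
# OD600 lysis curves
# ---------------------------------------------------------------------------

def make_od_curve(
    spec: SyntheticSpec,
    lysis_midpoint_min: float | None,
    label: str = "",
    moi: float = 0.01,
) -> GrowthCurve:
    """Logistic growth followed by a sharp lysis drop, sampled every minute.

    The curve rises logistically from ``od_initial`` to ``od_carrying``
    and, unless ``lysis_midpoint_min`` is None (no lysis), is multiplied
    by a logistic decline centred at the midpoint with width
    ``od_drop_width``; the drop midpoint is the ground-truth lysis time.
    """
    t = np.arange(0.0, spec.od_duration_min + 1.0, 1.0)
    k, n0, r = spec.od_carrying, spec.od_initial, spec.od_growth_rate
    rise = k / (1.0 + (k - n0) / n0 * np.exp(-r * t))
    if lysis_midpoint_min is None:
        od = rise
    else:
        if not t[0] <= lysis_midpoint_min <= t[-1]:
            raise InputError("lysis midpoint outside the recorded time range")
        drop = spec.od_residual + (1.0 - spec.od_residual) / (
            1.0 + np.exp((t - lysis_midpoint_min) / spec.od_drop_width)
        )
        od = rise * drop
    return GrowthCurve(t, od, moi=moi, label=label or (
        "no-lysis" if lysis_midpoint_min is None else f"lysis@{lysis_midpoint_min:g}min"
    ))


# ---------------------------------------------------------------------------
# End-to-end simulator export
# ---------------------------------------------------------------------------

def trajectory_to_observations(
    records: Sequence[TrajectoryRecord],
    loci: Sequence[PromoterLocus],
    min_frequency: float = 0.0,
) -> list[VariantObservation]:
    """Flatten trajectory records into the observation-table dialect."""
    ancestral = {l.name: l.ancestral_triplet for l in loci}
    obs: list[VariantObservation] = []
    for rec in records:
        for locus, freqs in sorted(rec.allele_frequencies.items()):
            for trip, f in sorted(freqs.items()):
                if f > min_frequency or (f > 0 and trip != ancestral[locus]):
                    obs.append(
                        VariantObservation(
                            rec.line_id, rec.passage, locus, trip,
                            min(100.0, 100.0 * f),
                        )
                    )
        for locus, f in sorted(rec.duplication_frequencies.items()):
            if f > 0:
                obs.append(
                    VariantObservation(
                        rec.line_id, rec.passage, locus, ancestral[locus],
                        min(100.0, 100.0 * f), is_duplication=True,
                    )
                )
    return obs


def simulate_and_export(
    config: PassageConfig,
    loci: Sequence[PromoterLocus],
    landscape: Landscape,
    outdir: str | FilePath,
) -> dict[str, FilePath]:
    """Run the simulator, sequencing-sample the records, and write TSVs.

    Writes ``trajectory.tsv`` (true frequencies), ``observations.tsv``
    (depth-sampled, loadable by the observed-data module) and
    ``manifest.json`` (seed, depth, config echo). Returns the paths.
    """
    outdir = FilePath(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = simulate_passages(config, loci, landscape)
    seq_rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    sampled = [
        sequencing_sample(rec, depth=config.sequencing_depth, seed=seq_rng)
        for rec in records
    ]

    true_obs = trajectory_to_observations(records, loci)
    sampled_obs = trajectory_to_observations(sampled, loci)
    paths = {
        "trajectory": outdir / "trajectory.tsv",
        "observations": outdir / "observations.tsv",
        "manifest": outdir / "manifest.json",
        "config": outdir / "config.yaml",
    }
    write_variant_table(true_obs, paths["trajectory"],
                        header_comment="true simulated allele frequencies")
    write_variant_table(
        sampled_obs, paths["observations"],
        header_comment=f"sequencing-sampled at depth {config.sequencing_depth}",
    )
    config.to_yaml(paths["config"])
    manifest = {
        "seed": config.seed,
        "sequencing_depth": config.sequencing_depth,
        "n_lines": config.n_lines,
        "n_passages": config.n_passages,
        "sample_passages": list(config.sample_passages),
        "files": {k: p.name for k, p in paths.items() if k != "manifest"},
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
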