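"""Serial-passage simulator: fitness model, conservation, drift, fixation."""

import numpy as np
import pytest

from promoterpath.errors import ComputationError, InputError, MissingGenotypeError
from promoterpath.landscape import Landscape
from promoterpath.passage_sim import (
    LocusSummary,
    PassageConfig,
    PhageGenotype,
    PromoterLocus,
    TrajectoryRecord,
    marginal_frequencies,
    phage_fitness,
    sequencing_sample,
    simulate_passages,
    summarize_trajectory,
)

SRC, DST = "GAC", "CGG"


def flat_landscape(mapping):
    return Landscape({g: (float(v), 0.0) for g, v in mapping.items()}, SRC)


@pytest.fixture
def single_locus():
    return [PromoterLocus("pA", 100, "+", SRC, weight=1.0)]


@pytest.fixture
def two_loci():
    return [
        PromoterLocus("pA", 100, "+", SRC, weight=1.0),
        PromoterLocus("pB", 500, "+", SRC, weight=1.0),
    ]


def seeded_mix(loci, mutant_triplet, mutant_freq):
    anc = PhageGenotype.ancestral(loci)
    mut = anc.with_state(loci[0].name, triplet=mutant_triplet)
    return {anc: 1.0 - mutant_freq, mut: mutant_freq}


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------

def test_fitness_closed_form_single_activity(two_loci):
    # all loci at activity a, weights summing to 1, copy 1 -> w = a/(K+a)
    loci = [
        PromoterLocus("pA", 100, "+", SRC, weight=0.5),
        PromoterLocus("pB", 500, "+", SRC, weight=0.5),
    ]
    ls = flat_landscape({SRC: 40.0})
    g = PhageGenotype.ancestral(loci)
    assert phage_fitness(g, ls, loci, k=50.0) == pytest.approx(40.0 / 90.0)


def test_fitness_strictly_increasing_in_activity(single_locus):
    g_lo = PhageGenotype.ancestral(single_locus)
    g_hi = g_lo.with_state("pA", triplet="GAG")
    ls = flat_landscape({SRC: 5.0, "GAG": 30.0})
    assert phage_fitness(g_hi, ls, single_locus) > phage_fitness(g_lo, ls, single_locus)


def test_fitness_zero_weight_locus_has_no_effect(two_loci):
    loci = [
        PromoterLocus("pA", 100, "+", SRC, weight=1.0),
        PromoterLocus("pB", 500, "+", SRC, weight=0.0),
    ]
    ls = flat_landscape({SRC: 10.0, "GAG": 90.0})
    base = PhageGenotype.ancestral(loci)
    changed = base.with_state("pB", triplet="GAG")
    assert phage_fitness(base, ls, loci) == pytest.approx(
        phage_fitness(changed, ls, loci)
    )


def test_fitness_duplication_increases_saturating_contribution(single_locus):
    ls = flat_landscape({SRC: 20.0})
    g1 = PhageGenotype.ancestral(single_locus)
    g2 = g1.with_state("pA", copy_number=2)
    w1 = phage_fitness(g1, ls, single_locus)
    w2 = phage_fitness(g2, ls, single_locus)
    assert w1 < w2 < 2 * w1  # diminishing returns


def test_fitness_unmeasured_triplet_errors_without_default(single_locus):
    ls = flat_landscape({"GAG": 10.0})
    g = PhageGenotype.ancestral(single_locus)
    with pytest.raises(MissingGenotypeError):
        phage_fitness(g, ls, single_locus)
    assert phage_fitness(g, ls, single_locus, default_activity=5.0) > 0


# ---------------------------------------------------------------------------
# Simulation invariants
# ---------------------------------------------------------------------------

def test_zero_rates_keep_composition_constant(single_locus):
    ls = flat_landscape({SRC: 10.0})
    cfg = PassageConfig(
        n_passages=100, n_lines=1, mutation_rate=0.0, duplication_rate=0.0,
        sample_passages=(50, 100), effective_sample_size=2000, seed=5,
    )
    records = simulate_passages(cfg, single_locus, ls)
    for rec in records:
        assert rec.allele_frequencies["pA"] == {SRC: 1.0}
        assert rec.duplication_frequencies["pA"] == 0.0


def test_frequencies_conserved_at_sampled_passages(two_loci):
    ls = flat_landscape(
        {SRC: 5.0, **{g: 10.0 for g in
                      ("AAC", "CAC", "TAC", "GCC", "GGC", "GTC", "GAA", "GAG", "GAT")}}
    )
    cfg = PassageConfig(
        n_passages=20, n_lines=2, mutation_rate=1e-3, duplication_rate=1e-4,
        sample_passages=(10, 20), effective_sample_size=5000, seed=7,
        default_activity=5.0,
    )
    records = simulate_passages(cfg, two_loci, ls)
    assert len(records) == 4  # 2 lines x 2 sampled passages
    for rec in records:
        for locus, freqs in rec.allele_frequencies.items():
            assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(f >= 0 for f in freqs.values())


def test_strongly_beneficial_mutant_fixes_in_most_replicates(single_locus):
    """A mutant seeded at 50% with a large selection coefficient exceeds
    99% frequency by passage 50 in at least 95% of 200 replicate lines."""
    ls = flat_landscape({SRC: 2.0, DST: 80.0})
    cfg = PassageConfig(
        n_passages=50, n_lines=200, mutation_rate=0.0, duplication_rate=0.0,
        sample_passages=(50,), effective_sample_size=10_000, seed=13,
    )
    records = simulate_passages(
        cfg, single_locus, ls, initial_composition=seeded_mix(single_locus, DST, 0.5)
    )
    assert len(records) == 200
    n_fixed = sum(r.allele_frequencies["pA"].get(DST, 0.0) > 0.99 for r in records)
    assert n_fixed >= 0.95 * 200


def test_flat_landscape_shows_no_systematic_frequency_change(single_locus):
    """Neutral drift: pooling 200 replicates from each of five master
    seeds, the mean frequency change of a 50% allele at passage 50 is
    statistically consistent with zero."""
    ls = flat_landscape({SRC: 20.0, DST: 20.0})
    deltas = []
    for seed in range(5):
        cfg = PassageConfig(
            n_passages=50, n_lines=200, mutation_rate=0.0, duplication_rate=0.0,
            sample_passages=(50,), effective_sample_size=5000, seed=seed,
        )
        records = simulate_passages(
            cfg, single_locus, ls,
            initial_composition=seeded_mix(single_locus, DST, 0.5),
        )
        deltas.extend(
            r.allele_frequencies["pA"].get(DST, 0.0) - 0.5 for r in records
        )
    deltas = np.array(deltas)
    se = deltas.std(ddof=1) / np.sqrt(len(deltas))
    assert abs(deltas.mean()) <= 3 * se


def test_fixation_probability_monotone_in_selection_coefficient(single_locus):
    """From a 10% seed, stronger selection fixes the mutant in more lines."""
    fractions = []
    for activity in (2.0, 10.0, 80.0):
        ls = flat_landscape({SRC: 2.0, DST: activity})
        cfg = PassageConfig(
            n_passages=30, n_lines=100, mutation_rate=0.0, duplication_rate=0.0,
            sample_passages=(30,), effective_sample_size=300, seed=23,
        )
        records = simulate_passages(
            cfg, single_locus, ls,
            initial_composition=seeded_mix(single_locus, DST, 0.1),
        )
        fractions.append(
            sum(r.allele_frequencies["pA"].get(DST, 0.0) > 0.99 for r in records)
        )
    assert fractions[0] <= fractions[1] <= fractions[2]
    assert fractions[2] > fractions[0]


def test_same_seed_reproduces_run_and_seed_changes_it(two_loci):
    ls = flat_landscape({SRC: 5.0, "GAG": 50.0, "CAC": 6.0, "GGC": 6.0,
                         "AAC": 5.0, "TAC": 5.0, "GCC": 5.0, "GTC": 5.0,
                         "GAA": 5.0, "GAT": 5.0})
    def run(seed):
        cfg = PassageConfig(
            n_passages=10, n_lines=2, mutation_rate=1e-3, duplication_rate=0.0,
            sample_passages=(10,), effective_sample_size=2000, seed=seed,
            default_activity=5.0,
        )
        return simulate_passages(cfg, two_loci, ls)

    a, b, c = run(1), run(1), run(2)
    assert [r.allele_frequencies for r in a] == [r.allele_frequencies for r in b]
    assert [r.allele_frequencies for r in a] != [r.allele_frequencies for r in c]


def test_invalid_configs_rejected():
    with pytest.raises(InputError):
        PassageConfig(n_passages=0)
    with pytest.raises(InputError):
        PassageConfig(mutation_rate=1.5)
    with pytest.raises(InputError):
        PassageConfig(sample_passages=())


def test_config_yaml_round_trip(tmp_path):
    cfg = PassageConfig(n_passages=12, seed=99, mutation_rate=3e-5)
    path = tmp_path / "config.yaml"
    cfg.to_yaml(path)
    assert PassageConfig.from_yaml(path) == cfg
    (tmp_path / "bad.yaml").write_text("not_a_field: 1\n")
    with pytest.raises(InputError):
        PassageConfig.from_yaml(tmp_path / "bad.yaml")


# ---------------------------------------------------------------------------
# Sequencing sampling and trajectory summaries
# ---------------------------------------------------------------------------

def _record(freqs, dups=None, line="line1", passage=100):
    return TrajectoryRecord(line, passage, freqs, dups or {l: 0.0 for l in freqs})


def test_sequencing_sample_zero_stays_zero_and_sums_to_one():
    rec = _record({"pA": {SRC: 0.7, "GAG": 0.3, DST: 0.0}})
    out = sequencing_sample(rec, depth=1000, seed=1)
    assert out.allele_frequencies["pA"][DST] == 0.0
    assert sum(out.allele_frequencies["pA"].values()) == pytest.approx(1.0)


def test_sequencing_sample_converges_with_depth():
    rec = _record({"pA": {SRC: 0.534, "GAG": 0.466}})
    out = sequencing_sample(rec, depth=10_000_000, seed=2)
    assert out.allele_frequencies["pA"]["GAG"] == pytest.approx(0.466, abs=1e-3)


def test_sequencing_sample_binomial_error_at_experiment_depth():
    """At 3.6e5 reads a 46.6% allele is recovered within 3 binomial
    standard errors in at least 99% of replicates."""
    depth = 360_000
    p = 0.466
    se3 = 3 * np.sqrt(p * (1 - p) / depth)
    rec = _record({"pA": {SRC: 1 - p, "GAG": p}})
    rng = np.random.default_rng(29)
    hits = sum(
        abs(sequencing_sample(rec, depth=depth, seed=rng).allele_frequencies["pA"]["GAG"] - p) <= se3
        for _ in range(200)
    )
    assert hits >= 0.99 * 200


def test_summarize_trajectory_fixed_and_heterogeneous():
    recs = [
        _record({"pA": {SRC: 0.6, "GAG": 0.4}}, passage=50),
        _record({"pA": {"GAG": 1.0}, "pB": {SRC: 0.744, "GAG": 0.256}}, passage=100),
    ]
    summary = summarize_trajectory(recs)
    assert summary["line1"]["pA"] == LocusSummary("GAG", {"GAG": 1.0}, 100)
    pb = summary["line1"]["pB"]
    assert pb.fixed_allele is None  # 25.6% does not fix
    assert set(pb.alleles) == {SRC, "GAG"}


def test_summarize_trajectory_empty_and_fixation_passage():
    assert summarize_trajectory([]) == {}
    recs = [
        _record({"pA": {"GAG": 0.99}}, passage=50),
        _record({"pA": {"GAG": 0.999}}, passage=100),
    ]
    assert summarize_trajectory(recs)["line1"]["pA"].fixation_passage == 50


def test_marginal_frequencies_tracks_duplications(two_loci):
    anc = PhageGenotype.ancestral(two_loci)
    dup = anc.with_state("pA", copy_number=2)
    alleles, dups = marginal_frequencies({anc: 0.75, dup: 0.25}, two_loci)
    assert alleles["pA"][SRC] == pytest.approx(1.0)
    assert dups["pA"] == pytest.approx(0.25)
    assert dups["pB"] == 0.0
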