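"""Activity landscapes over promoter motifs and trajectory prediction.

The central object is a :class:`Landscape`: a (possibly partial) map from
promoter motif to in vitro transcription activity, expressed as a
percentage of a reference polymerase/promoter pair, with replicate
standard errors. From a landscape the module derives the prediction
objects used to anticipate promoter evolution:

* a layered *prediction matrix* between an ancestral motif and a target
  motif, whose nodes are the endpoints plus all direct intermediates;
* a *greedy prediction DAG* — from each reachable node, edges to the
  highest-activity next-layer candidates (a relative tie tolerance keeps
  near-ties, matching how "substantially higher" activity is judged by
  eye on a bar chart);
* counts of *accessible* direct paths, i.e. shortest paths along which
  activity increases strictly at every step;
* strong-selection weak-mutation (SSWM) step probabilities, where the
  probability of fixing candidate ``h`` from genotype ``g`` is
  proportional to the selection coefficient ``s_h = max(0, a(h)/a(g) - 1)``;
* a five-way classification of any observed motif relative to the
  prediction (ancestral / target / predicted single / predicted double /
  unanticipated).

Unmeasured genotypes are never imputed: any operation touching a motif
absent from the landscape raises :class:`~promoterpath.errors.MissingGenotypeError`
listing the gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ComputationError, InputError, MissingGenotypeError
from .sequence_space import (
    Path,
    as_genotype,
    direct_intermediates,
    direct_paths,
    hamming_distance,
)

# Classification labels (classify_triplet).
ANCESTRAL = "ancestral"
TARGET = "target"
PREDICTED_SINGLE = "predicted_single"
PREDICTED_DOUBLE = "predicted_double"
PREDICTED_MULTI = "predicted_multi"  # only possible when hamming(src, dst) > 3
UNANTICIPATED = "unanticipated"

#: Default relative tolerance for treating two candidate activities as a tie.
DEFAULT_TIE_TOL = 0.15


@dataclass(frozen=True)
class ActivityRecord:
    """Replicate activity measurements for one polymerase/promoter pair.

    ``replicate_values`` are raw endpoint readouts (e.g. fluorescence
    after 1 h, arbitrary units); normalisation to a reference happens in
    :func:`normalize_activity`.
    """

    genotype: str
    rnap_id: str
    replicate_values: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "genotype", as_genotype(self.genotype))
        vals = tuple(float(v) for v in self.replicate_values)
        if len(vals) < 1:
            raise InputError("at least one replicate value is required")
        if any(v < 0 for v in vals):
            raise InputError("replicate values must be non-negative")
        object.__setattr__(self, "replicate_values", vals)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_values))

    @property
    def sem(self) -> float:
        if self.n_replicates < 2:
            return 0.0
        return float(np.std(self.replicate_values, ddof=1) / np.sqrt(self.n_replicates))


@dataclass
class Landscape:
    """Partial genotype -> (mean %, sem %) activity map with its reference."""

    activities: dict[str, tuple[float, float]]
    reference_genotype: str
    reference_label: str = "reference"

    def __contains__(self, genotype: str) -> bool:
        return as_genotype(genotype) in self.activities

    def mean(self, genotype: str) -> float:
        g = as_genotype(genotype)
        if g not in self.activities:
            raise MissingGenotypeError({g})
        return self.activities[g][0]

    def sem(self, genotype: str) -> float:
        g = as_genotype(genotype)
        if g not in self.activities:
            raise MissingGenotypeError({g})
        return self.activities[g][1]

    def missing(self, genotypes: Iterable[str]) -> set[str]:
        """The subset of ``genotypes`` with no measured activity."""
        return {as_genotype(g) for g in genotypes} - set(self.activities)

    def require(self, genotypes: Iterable[str]) -> None:
        gaps = self.missing(genotypes)
        if gaps:
            raise MissingGenotypeError(gaps)


def normalize_activity(
    records: Sequence[ActivityRecord],
    reference: ActivityRecord,
    reference_label: str | None = None,
) -> Landscape:
    """Normalise raw replicate activities to percent of a reference pair.

    ``mean_pct = 100 * mean(replicates) / mean(reference replicates)``;
    the standard error is propagated on the same scale
    (``100 * sem(replicates) / mean(reference)``). Duplicate genotypes in
    ``records`` are pooled across their replicates.
    """
    ref_mean = reference.mean
    if ref_mean <= 0:
        raise ComputationError(
            f"reference mean must be positive, got {ref_mean} "
            f"({reference.rnap_id} on {reference.genotype})"
        )
    pooled: dict[str, list[float]] = {}
    for rec in records:
        pooled.setdefault(rec.genotype, []).extend(rec.replicate_values)
    activities = {}
    for g, vals in pooled.items():
        rec = ActivityRecord(g, "pooled", tuple(vals))
        activities[g] = (100.0 * rec.mean / ref_mean, 100.0 * rec.sem / ref_mean)
    label = reference_label or f"{reference.rnap_id} on {reference.genotype}"
    return Landscape(activities, reference.genotype, label)


# ---------------------------------------------------------------------------
# Prediction matrix and greedy DAG
# ---------------------------------------------------------------------------

@dataclass
class PredictionMatrix:
    """Layered prediction graph between an ancestral and a target motif.

    ``layers[k]`` holds the genotypes at Hamming distance ``k`` from
    ``src`` that lie on direct paths (layer 0 is ``[src]``, the last layer
    ``[dst]``). ``greedy_dag`` holds the predicted most-likely steps.
    """

    src: str
    dst: str
    layers: list[list[str]]
    activities: dict[str, tuple[float, float]]
    greedy_dag: set[tuple[str, str]]
    tie_tol: float = DEFAULT_TIE_TOL

    @property
    def nodes(self) -> list[str]:
        return [g for layer in self.layers for g in layer]

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "from": a,
                "to": b,
                "from_activity_pct": self.activities[a][0],
                "to_activity_pct": self.activities[b][0],
            }
            for a, b in sorted(self.greedy_dag)
        ]
        return pd.DataFrame(rows, columns=["from", "to", "from_activity_pct", "to_activity_pct"])

    def to_edge_tsv(self, path: str | FilePath) -> None:
        self.to_edge_frame().to_csv(path, sep="\t", index=False)

    def to_dot(self) -> str:
        """GraphViz DOT text: ranks by layer, predicted steps as edges."""
        lines = ["digraph prediction_matrix {", "  rankdir=BT;"]
        for k, layer in enumerate(self.layers):
            names = " ".join(f'"{g}"' for g in layer)
            lines.append(f"  {{ rank=same; {names} }}  // layer {k}")
        for g in self.nodes:
            mean, sem_ = self.activities[g]
            lines.append(f'  "{g}" [label="{g}\\n{mean:.1f}%"];')
        for a, b in sorted(self.greedy_dag):
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        return "\n".join(lines) + "\n"


def _layered_nodes(src: str, dst: str) -> list[list[str]]:
    d = hamming_distance(src, dst)
    if d == 0:
        return [[src]]
    inter = direct_intermediates(src, dst)
    layers: list[list[str]] = [[src]]
    for k in range(1, d):
        layers.append(sorted(g for g in inter if hamming_distance(src, g) == k))
    layers.append([dst])
    return layers


def build_prediction_matrix(
    landscape: Landscape,
    src: str,
    dst: str,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> PredictionMatrix:
    """Assemble the layered matrix with activities and the greedy DAG.

    Raises :class:`MissingGenotypeError` listing every endpoint or direct
    intermediate absent from the landscape.
    """
    src, dst = as_genotype(src), as_genotype(dst)
    layers = _layered_nodes(src, dst)
    nodes = [g for layer in layers for g in layer]
    landscape.require(nodes)
    dag = greedy_prediction_dag(landscape, src, dst, tie_tol)
    acts = {g: landscape.activities[g] for g in nodes}
    return PredictionMatrix(src, dst, layers, acts, dag, tie_tol)


def greedy_prediction_dag(
    landscape: Landscape,
    src: str,
    dst: str,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> set[tuple[str, str]]:
    """Predicted most-likely steps through the direct-path hypercube.

    Starting from ``src``, each reachable node gets edges to every
    adjacent next-layer direct intermediate whose activity is within a
    relative tolerance of the best adjacent candidate
    (``a >= (1 - tie_tol) * max``). With ``tie_tol = 0`` only exact ties
    are kept. The target is always terminal.
    """
    src, dst = as_genotype(src), as_genotype(dst)
    if not 0 <= tie_tol < 1:
        raise InputError(f"tie_tol must be in [0, 1), got {tie_tol}")
    layers = _layered_nodes(src, dst)
    landscape.require(g for layer in layers for g in layer)
    edges: set[tuple[str, str]] = set()
    frontier = {src}
    for k in range(len(layers) - 1):
        nxt: set[str] = set()
        for node in sorted(frontier):
            cands = [h for h in layers[k + 1] if hamming_distance(node, h) == 1]
            if not cands:
                continue
            best = max(landscape.mean(h) for h in cands)
            keep = [h for h in cands if landscape.mean(h) >= (1.0 - tie_tol) * best]
            edges.update((node, h) for h in keep)
            nxt.update(keep)
        frontier = nxt
    return edges


def accessible_direct_paths(
    landscape: Landscape, src: str, dst: str
) -> tuple[int, list[Path]]:
    """Direct paths along which activity increases strictly at every step.

    Returns ``(count, paths)``; paths keep the lexicographic order of
    :func:`~promoterpath.sequence_space.direct_paths`. All genotypes on
    any direct path must be measured.
    """
    src, dst = as_genotype(src), as_genotype(dst)
    all_paths = direct_paths(src, dst)
    landscape.require(g for p in all_paths for g in p)
    ok = [
        p
        for p in all_paths
        if all(landscape.mean(b) > landscape.mean(a) for a, b in zip(p, p[1:]))
    ]
    return len(ok), ok


# ---------------------------------------------------------------------------
# SSWM step probabilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SSWMResult:
    """Step probabilities under strong-selection weak-mutation.

    ``uniform_fallback`` is True when no candidate was beneficial, in
    which case the probabilities are uniform over the candidates (the
    chain has no preferred direction).
    """

    probabilities: dict[str, float]
    uniform_fallback: bool


def next_layer_candidates(g: str, src: str, dst: str) -> set[str]:
    """Adjacent direct intermediates (or the target) one layer closer to ``dst``."""
    g, src, dst = as_genotype(g), as_genotype(src), as_genotype(dst)
    pool = direct_intermediates(src, dst) | {dst}
    k = hamming_distance(src, g)
    return {
        h
        for h in pool
        if hamming_distance(src, h) == k + 1 and hamming_distance(g, h) == 1
        and hamming_distance(src, h) + hamming_distance(h, dst) == hamming_distance(src, dst)
    }


def sswm_step_probabilities(
    landscape: Landscape, g: str, candidates: Iterable[str]
) -> SSWMResult:
    """Fixation-weighted step probabilities from ``g`` to each candidate.

    The selection coefficient of candidate ``h`` is
    ``s_h = max(0, a(h)/a(g) - 1)``; each probability is ``s_h / sum(s)``.
    If every candidate is neutral or deleterious the distribution falls
    back to uniform and the result is flagged.
    """
    g = as_genotype(g)
    cands = sorted({as_genotype(c) for c in candidates})
    if not cands:
        raise InputError("candidate set must be non-empty")
    landscape.require([g, *cands])
    a_g = landscape.mean(g)
    if a_g <= 0:
        raise ComputationError(f"activity of {g} must be positive, got {a_g}")
    s = {h: max(0.0, landscape.mean(h) / a_g - 1.0) for h in cands}
    total = sum(s.values())
    if total == 0.0:
        p = 1.0 / len(cands)
        return SSWMResult({h: p for h in cands}, uniform_fallback=True)
    return SSWMResult({h: s[h] / total for h in cands}, uniform_fallback=False)


# ---------------------------------------------------------------------------
# Classification of observed motifs against the prediction
# ---------------------------------------------------------------------------

def classify_triplet(observed: str, src: str, dst: str) -> str:
    """Label an observed motif relative to the src->dst prediction.

    Labels: ``ancestral`` (== src), ``target`` (== dst),
    ``predicted_single`` / ``predicted_double`` (direct intermediate one
    or two steps from src), ``unanticipated`` (off every direct path).
    For the default three-site motif these five labels partition the 64
    triplets 1/1/3/3/56. ``predicted_multi`` only arises for distances
    above three.
    """
    observed, src, dst = as_genotype(observed), as_genotype(src), as_genotype(dst)
    if len(observed) != len(src) or len(src) != len(dst):
        raise InputError("observed, src and dst must have equal length")
    if observed == src:
        return ANCESTRAL
    if observed == dst:
        return TARGET
    d = hamming_distance(src, dst)
    k = hamming_distance(src, observed)
    if k + hamming_distance(observed, dst) == d:
        if k == 1:
            return PREDICTED_SINGLE
        if k == 2:
            return PREDICTED_DOUBLE
        return PREDICTED_MULTI
    return UNANTICIPATED


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

ACTIVITY_COLUMNS = ["genotype", "rnap_id", "replicate", "value"]


def read_activity_table(path: str | FilePath) -> list[ActivityRecord]:
    """Read a long-format activity TSV (genotype, rnap_id, replicate, value)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise InputError(f"cannot read activity table {path}: {exc}") from exc
    missing = set(ACTIVITY_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(
            f"activity table {path} lacks columns: {', '.join(sorted(missing))}"
        )
    records = []
    for (g, rnap), grp in df.groupby(["genotype", "rnap_id"], sort=True):
        vals = tuple(grp.sort_values("replicate")["value"].astype(float))
        records.append(ActivityRecord(str(g), str(rnap), vals))
    return records


def write_activity_table(
    records: Sequence[ActivityRecord], path: str | FilePath, header_comment: str = ""
) -> None:
    rows = [
        {"genotype": r.genotype, "rnap_id": r.rnap_id, "replicate": i + 1, "value": v}
        for r in records
        for i, v in enumerate(r.replicate_values)
    ]
    with open(path, "w") as fh:
        for line in header_comment.splitlines():
            fh.write(f"# {line}\n")
        pd.DataFrame(rows, columns=ACTIVITY_COLUMNS).to_csv(fh, sep="\t", index=False)


def write_landscape_tsv(landscape: Landscape, path: str | FilePath) -> None:
    rows = [
        {"genotype": g, "mean_pct": m, "sem_pct": s}
        for g, (m, s) in sorted(landscape.activities.items())
    ]
    with open(path, "w") as fh:
        fh.write(f"# reference: {landscape.reference_label} "
                 f"(genotype {landscape.reference_genotype})\n")
        pd.DataFrame(rows, columns=["genotype", "mean_pct", "sem_pct"]).to_csv(
            fh, sep="\t", index=False
        )


def read_landscape_tsv(path: str | FilePath) -> Landscape:
    header = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            header = first.lstrip("# ").strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    acts = {
        as_genotype(r.genotype): (float(r.mean_pct), float(r.sem_pct))
        for r in df.itertuples()
    }
    ref_g = header.split("genotype")[-1].strip(" ()") if "genotype" in header else ""
    return Landscape(acts, ref_g or next(iter(acts)), header or "reference")
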