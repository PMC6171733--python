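"""Observed promoter variants: loading, assignment, and prediction scoring.

Consumes two kinds of tables derived from population sequencing of the
evolved phage lines:

* a promoter annotation (BED-like TSV or GFF3) naming each promoter
  locus, its 1-based genome start, strand, ancestral motif triplet, and
  fitness weight;
* a variant table of (line, passage, promoter-or-position, observed
  triplet, frequency %, duplication flag) records.

It assigns positional variants to promoter motif windows, summarises
which promoters evolved and what fixed where, and scores every observed
triplet against the prediction matrix (ancestral / target / predicted
single / predicted double / unanticipated). Loci whose ancestral triplet
differs from the main background are classified against their *own*
ancestral motif, and flagged when the landscape holds no measurements
for their intermediates — for those promoters there was no basis for a
prediction in the first place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AmbiguousWindowError, InputError
from .landscape import (
    ANCESTRAL,
    PREDICTED_DOUBLE,
    PREDICTED_SINGLE,
    TARGET,
    UNANTICIPATED,
    Landscape,
    classify_triplet,
)
from .sequence_space import as_genotype, direct_intermediates
from .passage_sim import PromoterLocus

NON_PROMOTER = "non-promoter"

#: Flag carried by fixture rows whose frequency is a placeholder, not a
#: measured number; count-based summaries never depend on the value.
UNQUANTIFIED = "unquantified"

OBS_COLUMNS = [
    "line_id", "passage", "promoter", "observed_triplet",
    "frequency_pct", "is_duplication", "flag",
]

ANNOTATION_COLUMNS = ["name", "genome_start", "strand", "ancestral_triplet", "weight"]


@dataclass(frozen=True)
class VariantObservation:
    """One population-sequencing variant record."""

    line_id: str
    passage: int
    promoter: str
    observed_triplet: str
    frequency_pct: float
    is_duplication: bool = False
    flag: str = ""

    def __post_init__(self):
        object.__setattr__(self, "observed_triplet", as_genotype(self.observed_triplet))
        if not 0.0 <= self.frequency_pct <= 100.0:
            raise InputError(
                f"frequency_pct must be in [0, 100], got {self.frequency_pct}"
            )


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def load_promoter_annotation(path: str | FilePath) -> list[PromoterLocus]:
    """Read a BED-like promoter annotation TSV.

    Columns: name, genome_start (1-based), strand, ancestral_triplet,
    weight. Comment lines start with '#'. Duplicate names or malformed
    rows raise :class:`InputError` with the offending line number; an
    empty table yields an empty list with a warning.
    """
    path = FilePath(path)
    loci: list[PromoterLocus] = []
    seen: set[str] = set()
    lines = path.read_text().splitlines()
    header: list[str] | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None and fields[0] == "name":
            header = fields
            missing = set(ANNOTATION_COLUMNS) - set(header)
            if missing:
                raise InputError(
                    f"{path}:{lineno}: annotation lacks columns "
                    + ", ".join(sorted(missing))
                )
            continue
        cols = dict(zip(header, fields)) if header else dict(
            zip(ANNOTATION_COLUMNS, fields)
        )
        try:
            locus = PromoterLocus(
                name=cols["name"],
                genome_start=int(cols["genome_start"]),
                strand=cols["strand"],
                ancestral_triplet=cols["ancestral_triplet"],
                weight=float(cols.get("weight", 1.0)),
            )
        except (KeyError, ValueError, InputError) as exc:
            raise InputError(f"{path}:{lineno}: malformed annotation row: {exc}") from exc
        if locus.name in seen:
            raise InputError(f"{path}:{lineno}: duplicate promoter name {locus.name!r}")
        seen.add(locus.name)
        loci.append(locus)
    if not loci:
        warnings.warn(f"annotation {path} contains no promoters", stacklevel=2)
    return loci


def write_promoter_annotation(
    loci: Sequence[PromoterLocus], path: str | FilePath, header_comment: str = ""
) -> None:
    with open(path, "w") as fh:
        for line in header_comment.splitlines():
            fh.write(f"# {line}\n")
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for l in loci:
            fh.write(
                f"{l.name}\t{l.genome_start}\t{l.strand}\t"
                f"{l.ancestral_triplet}\t{l.weight:g}\n"
            )


def load_promoter_annotation_gff3(path: str | FilePath) -> list[PromoterLocus]:
    """Read promoters from GFF3; ``triplet`` and ``weight`` attributes."""
    loci: list[PromoterLocus] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(FilePath(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise InputError(f"{path}:{lineno}: GFF3 rows need 9 columns")
        _, _, ftype, start, _, _, strand, _, attrs = fields
        if ftype != "promoter":
            continue
        attr = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        name = attr.get("Name") or attr.get("ID")
        if name is None or "triplet" not in attr:
            raise InputError(f"{path}:{lineno}: promoter needs Name and triplet attributes")
        if name in seen:
            raise InputError(f"{path}:{lineno}: duplicate promoter name {name!r}")
        seen.add(name)
        loci.append(
            PromoterLocus(
                name=name,
                genome_start=int(start),
                strand=strand,
                ancestral_triplet=attr["triplet"],
                weight=float(attr.get("weight", 1.0)),
            )
        )
    return loci


# ---------------------------------------------------------------------------
# Variant table I/O
# ---------------------------------------------------------------------------

def load_variant_table(
    path: str | FilePath, reporting_floor_pct: float = 0.0
) -> list[VariantObservation]:
    """Read an observation TSV; rows below ``reporting_floor_pct`` dropped
    (except unquantified placeholder rows, which carry no real frequency)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        return []
    missing = set(OBS_COLUMNS) - {"flag"} - set(df.columns)
    if missing:
        raise InputError(
            f"variant table {path} lacks columns: {', '.join(sorted(missing))}"
        )
    if "flag" not in df.columns:
        df["flag"] = ""
    out = []
    for i, row in enumerate(df.itertuples(), start=2):
        try:
            obs = VariantObservation(
                line_id=str(row.line_id),
                passage=int(row.passage),
                promoter=str(row.promoter),
                observed_triplet=str(row.observed_triplet),
                frequency_pct=float(row.frequency_pct),
                is_duplication=bool(row.is_duplication),
                flag="" if pd.isna(row.flag) else str(row.flag),
            )
        except (ValueError, InputError) as exc:
            raise InputError(f"{path}: row {i}: {exc}") from exc
        if obs.frequency_pct < reporting_floor_pct and obs.flag != UNQUANTIFIED:
            continue
        out.append(obs)
    return out


def observations_to_frame(observations: Sequence[VariantObservation]) -> pd.DataFrame:
    rows = [
        {
            "line_id": o.line_id, "passage": o.passage, "promoter": o.promoter,
            "observed_triplet": o.observed_triplet,
            "frequency_pct": o.frequency_pct,
            "is_duplication": o.is_duplication, "flag": o.flag,
        }
        for o in observations
    ]
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


def write_variant_table(
    observations: Sequence[VariantObservation],
    path: str | FilePath,
    header_comment: str = "",
) -> None:
    with open(path, "w") as fh:
        for line in header_comment.splitlines():
            fh.write(f"# {line}\n")
        observations_to_frame(observations).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant -> promoter assignment
# ---------------------------------------------------------------------------

def assign_variant_to_promoter(
    position: int, loci: Sequence[PromoterLocus]
) -> str:
    """Name of the promoter whose motif window contains ``position``.

    Windows are 1-based closed intervals over the specificity triplet
    (promoter start + offsets of positions -11..-9 under the 23-nt
    promoter convention); boundary positions are included. Positions in
    no window return ``"non-promoter"``; overlapping windows raise
    :class:`AmbiguousWindowError`.
    """
    if position < 1:
        raise InputError(f"position must be >= 1, got {position}")
    hits = [
        l.name
        for l in loci
        if l.motif_window()[0] <= position <= l.motif_window()[1]
    ]
    if len(hits) > 1:
        raise AmbiguousWindowError(
            f"position {position} falls in motif windows of: {', '.join(hits)}"
        )
    return hits[0] if hits else NON_PROMOTER


def resolve_promoters(
    observations: Sequence[VariantObservation], loci: Sequence[PromoterLocus]
) -> list[VariantObservation]:
    """Replace positional ``promoter`` fields with locus names.

    Numeric promoter fields are treated as 1-based genome positions and
    assigned via :func:`assign_variant_to_promoter`; unknown promoter
    names raise :class:`InputError`.
    """
    names = {l.name for l in loci}
    out = []
    for o in observations:
        prom = o.promoter
        if prom not in names:
            try:
                pos = int(prom)
            except ValueError:
                raise InputError(f"unknown promoter {prom!r}") from None
            prom = assign_variant_to_promoter(pos, loci)
        out.append(
            VariantObservation(
                o.line_id, o.passage, prom, o.observed_triplet,
                o.frequency_pct, o.is_duplication, o.flag,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Summaries and prediction comparison
# ---------------------------------------------------------------------------

@dataclass
class ObservationSummary:
    """Counts of promoter evolution across lines and passages."""

    n_promoters: int
    evolved_promoters: list[str]
    triplets_by_promoter: dict[str, list[str]]      # non-ancestral triplets
    fixed_lines_by_promoter: dict[str, dict[str, list[str]]]  # promoter -> allele -> lines
    duplicated_promoters: list[str]

    @property
    def n_evolved_promoters(self) -> int:
        return len(self.evolved_promoters)


def summarize_observations(
    observations: Sequence[VariantObservation],
    loci: Sequence[PromoterLocus],
    fixation_threshold_pct: float = 95.0,
) -> ObservationSummary:
    """Which promoters evolved, what they evolved to, and what fixed where.

    A promoter counts as *evolved* when any line at any passage carries a
    non-ancestral triplet in it. An allele counts as *fixed* in a line
    when its frequency at that line's final sampled passage reaches
    ``fixation_threshold_pct``. The summary is invariant to the row
    order of the input table.
    """
    observations = resolve_promoters(observations, loci)
    ancestral = {l.name: l.ancestral_triplet for l in loci}
    non_prom = [o for o in observations if o.promoter == NON_PROMOTER]
    observations = [o for o in observations if o.promoter != NON_PROMOTER]

    evolved: set[str] = set()
    triplets: dict[str, set[str]] = {}
    duplicated: set[str] = set()
    for o in observations:
        if o.observed_triplet != ancestral[o.promoter]:
            evolved.add(o.promoter)
            triplets.setdefault(o.promoter, set()).add(o.observed_triplet)
        if o.is_duplication:
            duplicated.add(o.promoter)

    fixed: dict[str, dict[str, list[str]]] = {}
    final_passage: dict[str, int] = {}
    for o in observations:
        final_passage[o.line_id] = max(final_passage.get(o.line_id, 0), o.passage)
    for o in observations:
        if (
            o.passage == final_passage[o.line_id]
            and not o.is_duplication
            and o.frequency_pct >= fixation_threshold_pct
        ):
            fixed.setdefault(o.promoter, {}).setdefault(
                o.observed_triplet, []
            ).append(o.line_id)
    for allele_map in fixed.values():
        for lines in allele_map.values():
            lines.sort()

    return ObservationSummary(
        n_promoters=len(loci),
        evolved_promoters=sorted(evolved),
        triplets_by_promoter={p: sorted(ts) for p, ts in sorted(triplets.items())},
        fixed_lines_by_promoter={p: dict(sorted(m.items())) for p, m in sorted(fixed.items())},
        duplicated_promoters=sorted(duplicated),
    )


#: Caveat attached to observations at loci whose own mutational
#: neighbourhood was never assayed in vitro.
NO_LANDSCAPE_CAVEAT = "no measured landscape for this background"


@dataclass
class ComparisonReport:
    """Per-observation prediction labels plus aggregate counts."""

    labels: pd.DataFrame          # observation fields + background, label, caveat
    summary: ObservationSummary
    counts: dict[str, int]
    unanticipated_triplets: list[str]   # distinct, main-background loci only
    predicted_triplets: list[str]
    src: str = ""
    dst: str = ""

    def to_tsv(self, path: str | FilePath) -> None:
        self.labels.to_csv(path, sep="\t", index=False)

    def text_summary(self) -> str:
        c = self.counts
        lines = [
            f"Prediction comparison ({self.src} -> {self.dst})",
            f"  promoters annotated: {self.summary.n_promoters}",
            f"  promoters with substitutions: {self.summary.n_evolved_promoters} "
            f"({', '.join(self.summary.evolved_promoters)})",
            f"  distinct observed triplets: {c['distinct_triplets']}",
            f"  predicted (single/double/target): {c['predicted']} "
            f"({', '.join(self.predicted_triplets) or 'none'})",
            f"  unanticipated: {c['unanticipated']} "
            f"({', '.join(self.unanticipated_triplets) or 'none'})",
            f"  promoters with duplications: "
            f"{', '.join(self.summary.duplicated_promoters) or 'none'}",
        ]
        for prom, allele_map in self.summary.fixed_lines_by_promoter.items():
            for allele, line_ids in allele_map.items():
                lines.append(
                    f"  fixed: {prom} -> {allele} in {len(line_ids)} line(s) "
                    f"({', '.join(line_ids)})"
                )
        return "\n".join(lines) + "\n"


def compare_to_prediction(
    observations: Sequence[VariantObservation],
    loci: Sequence[PromoterLocus],
    landscape: Landscape | None,
    src: str,
    dst: str,
    fixation_threshold_pct: float = 95.0,
) -> ComparisonReport:
    """Score every observed triplet against the src->dst prediction.

    Each observation is classified against its *locus's* ancestral
    triplet as the path source (so promoters on a different ancestral
    background are judged on their own sub-cube) with the common target
    ``dst``. When a landscape is supplied, observations at loci whose
    background neighbourhood (ancestral motif + its direct intermediates
    to ``dst``) is unmeasured carry a caveat: no prediction was possible
    there. Aggregate unanticipated/predicted triplet sets are reported
    for the main-background (``src``) loci, where the prediction was
    actually made.
    """
    src, dst = as_genotype(src), as_genotype(dst)
    observations = resolve_promoters(observations, loci)
    ancestral = {l.name: l.ancestral_triplet for l in loci}

    caveat_backgrounds: set[str] = set()
    for bg in {l.ancestral_triplet for l in loci}:
        if landscape is None:
            if bg != src:
                caveat_backgrounds.add(bg)
            continue
        needed = {bg, dst} | direct_intermediates(bg, dst)
        if landscape.missing(needed):
            caveat_backgrounds.add(bg)

    rows = []
    for o in observations:
        if o.promoter == NON_PROMOTER:
            rows.append((o, NON_PROMOTER, NON_PROMOTER, ""))
            continue
        bg = ancestral[o.promoter]
        label = classify_triplet(o.observed_triplet, bg, dst)
        caveat = NO_LANDSCAPE_CAVEAT if bg in caveat_backgrounds else ""
        rows.append((o, bg, label, caveat))

    labels = pd.DataFrame(
        [
            {
                "line_id": o.line_id, "passage": o.passage, "promoter": o.promoter,
                "observed_triplet": o.observed_triplet,
                "frequency_pct": o.frequency_pct,
                "is_duplication": o.is_duplication, "flag": o.flag,
                "background": bg, "label": label, "caveat": caveat,
            }
            for o, bg, label, caveat in rows
        ],
        columns=OBS_COLUMNS + ["background", "label", "caveat"],
    ).sort_values(
        ["promoter", "line_id", "passage", "observed_triplet"]
    ).reset_index(drop=True)

    main_rows = [
        (o, label) for o, bg, label, _ in rows
        if bg == src and o.promoter != NON_PROMOTER
    ]
    distinct = {o.observed_triplet for o, _ in main_rows}
    unanticipated = sorted(
        {o.observed_triplet for o, label in main_rows if label == UNANTICIPATED}
    )
    predicted = sorted(
        {
            o.observed_triplet
            for o, label in main_rows
            if label in (PREDICTED_SINGLE, PREDICTED_DOUBLE)
        }
    )
    counts = {
        "distinct_triplets": len(distinct),
        "predicted": len(predicted),
        "unanticipated": len(unanticipated),
        "ancestral": len({o.observed_triplet for o, l in main_rows if l == ANCESTRAL}),
        "target": len({o.observed_triplet for o, l in main_rows if l == TARGET}),
    }
    summary = summarize_observations(observations, loci, fixation_threshold_pct)
    return ComparisonReport(
        labels=labels, summary=summary, counts=counts,
        unanticipated_triplets=unanticipated, predicted_triplets=predicted,
        src=src, dst=dst,
    )
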