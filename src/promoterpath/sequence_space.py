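"""Combinatorics of short promoter-motif genotypes.

A genotype here is a fixed-length DNA string — by default the three
variable promoter positions (-11..-9) that govern single-subunit RNA
polymerase specificity. The module enumerates the genotype space
(4^L motifs), measures Hamming distances, and lists the intermediates
and shortest ("direct") mutational paths between two motifs on the
Hamming hypercube. Positions are indexed 1..L in motif coordinates;
mapping to genome or promoter coordinates lives in the annotation layer.

All genotypes are plain uppercase strings; :func:`as_genotype` is the
single normalisation/validation entry point. Paths are tuples of
genotypes and are returned in lexicographic order so downstream output
is reproducible.
"""

from __future__ import annotations

import itertools
from math import factorial
from pathlib import Path as FilePath
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

#: The DNA alphabet, in lexicographic order.
DNA = ("A", "C", "G", "T")

#: A mutational path: tuple of genotypes, consecutive entries adjacent.
Path = tuple[str, ...]


def as_genotype(seq: str, alphabet: Sequence[str] = DNA) -> str:
    """Normalise ``seq`` to an uppercase genotype, validating the alphabet.

    Characters outside the alphabet (including IUPAC ambiguity codes)
    are rejected: the analysis deals only in concrete motifs.
    """
    if not isinstance(seq, str):
        raise InputError(f"genotype must be a string, got {type(seq).__name__}")
    s = seq.strip().upper()
    if not s:
        raise InputError("genotype must be non-empty")
    bad = set(s) - set(alphabet)
    if bad:
        raise InputError(
            f"genotype {s!r} contains characters outside alphabet "
            f"{''.join(alphabet)}: {''.join(sorted(bad))}"
        )
    return s


def hamming_distance(a: str, b: str) -> int:
    """Number of positions at which two equal-length genotypes differ."""
    a, b = as_genotype(a), as_genotype(b)
    if len(a) != len(b):
        raise InputError(
            f"length mismatch: {a!r} (L={len(a)}) vs {b!r} (L={len(b)})"
        )
    return sum(x != y for x, y in zip(a, b))


def enumerate_genotypes(length: int, alphabet: Sequence[str] = DNA) -> list[str]:
    """All ``|alphabet|**length`` genotypes, each once, in lexicographic order.

    For the default DNA alphabet and length 3 this is the full 64-triplet
    genotype space of the promoter motif.
    """
    if length < 1:
        raise InputError(f"length must be >= 1, got {length}")
    if not alphabet:
        raise InputError("alphabet must be non-empty")
    return ["".join(p) for p in itertools.product(sorted(alphabet), repeat=length)]


def one_step_neighbors(g: str, alphabet: Sequence[str] = DNA) -> set[str]:
    """All genotypes at Hamming distance exactly 1 from ``g``.

    There are ``L * (|alphabet| - 1)`` of them (9 for a DNA triplet).
    """
    g = as_genotype(g, alphabet)
    out: set[str] = set()
    for i, base in enumerate(g):
        for alt in alphabet:
            if alt != base:
                out.add(g[:i] + alt + g[i + 1:])
    return out


def _differing_positions(src: str, dst: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(src, dst)) if x != y]


def direct_intermediates(src: str, dst: str) -> set[str]:
    """Genotypes strictly between ``src`` and ``dst`` on shortest paths.

    These are the genotypes ``g`` with
    ``hamming(src, g) + hamming(g, dst) == hamming(src, dst)``,
    excluding the endpoints: every position of ``g`` matches ``src`` or
    ``dst``. For ``d`` differing sites there are ``2**d - 2`` of them —
    six for the three-site promoter motif problem.
    """
    src, dst = as_genotype(src), as_genotype(dst)
    if len(src) != len(dst):
        raise InputError("src and dst must have equal length")
    diff = _differing_positions(src, dst)
    out: set[str] = set()
    for k in range(1, len(diff)):
        for subset in itertools.combinations(diff, k):
            chars = list(src)
            for i in subset:
                chars[i] = dst[i]
            out.add("".join(chars))
    return out


def direct_paths(src: str, dst: str) -> list[Path]:
    """All shortest mutational paths from ``src`` to ``dst``.

    Each path changes one not-yet-changed differing site per step, so
    there are ``d!`` paths for ``d`` differing sites (6 for d=3, 120 for
    d=5). Paths are returned sorted lexicographically by step sequence;
    ``src == dst`` yields the single zero-step path ``(src,)``.
    """
    src, dst = as_genotype(src), as_genotype(dst)
    if len(src) != len(dst):
        raise InputError("src and dst must have equal length")
    diff = _differing_positions(src, dst)
    paths: list[Path] = []
    for order in itertools.permutations(diff):
        steps = [src]
        chars = list(src)
        for i in order:
            chars[i] = dst[i]
            steps.append("".join(chars))
        paths.append(tuple(steps))
    paths.sort()
    return paths


def n_direct_paths(src: str, dst: str) -> int:
    """``d!`` for ``d = hamming(src, dst)``, without enumerating paths."""
    return factorial(hamming_distance(src, dst))


# ---------------------------------------------------------------------------
# Plain-text I/O for genotype sets
# ---------------------------------------------------------------------------

def read_motif_list(path: str | FilePath, alphabet: Sequence[str] = DNA) -> list[str]:
    """Read genotypes from a text file, one motif per line; '#' comments."""
    out = []
    for line in FilePath(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(as_genotype(line, alphabet))
    return out


def write_motif_list(genotypes: Iterable[str], path: str | FilePath) -> None:
    FilePath(path).write_text("".join(f"{as_genotype(g)}\n" for g in genotypes))


def read_motif_fasta(path: str | FilePath, alphabet: Sequence[str] = DNA) -> list[str]:
    """Read genotypes from FASTA, one motif per record."""
    return [as_genotype(str(rec.seq), alphabet) for rec in SeqIO.parse(str(path), "fasta")]


def write_motif_fasta(genotypes: Iterable[str], path: str | FilePath) -> None:
    records = [
        SeqRecord(Seq(as_genotype(g)), id=f"motif_{i + 1}", description="")
        for i, g in enumerate(genotypes)
    ]
    SeqIO.write(records, str(path), "fasta")
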