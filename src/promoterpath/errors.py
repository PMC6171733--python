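"""Exception hierarchy shared across the package.

Input problems (malformed tables, invalid characters, bad coordinates)
raise :class:`InputError`; gaps in a partial activity landscape raise
:class:`MissingGenotypeError` so callers can report exactly which motifs
were never assayed instead of silently imputing them.
"""

from __future__ import annotations


class PromoterPathError(Exception):
    """Base class for all package-specific errors."""


class InputError(PromoterPathError, ValueError):
    """Malformed or invalid user input (files, sequences, parameters)."""


class ComputationError(PromoterPathError, ArithmeticError):
    """A computation is undefined for the given data (e.g. zero reference)."""


class MissingGenotypeError(PromoterPathError, KeyError):
    """An operation needs activities for genotypes absent from the landscape.

    Attributes
    ----------
    missing : frozenset of str
        The genotypes that were required but not measured.
    """

    def __init__(self, missing):
        self.missing = frozenset(missing)
        super().__init__(
            "unmeasured genotype(s) in landscape: "
            + ", ".join(sorted(self.missing))
        )


class AmbiguousWindowError(InputError):
    """A genome position falls inside more than one promoter motif window."""
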