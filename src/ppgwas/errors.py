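"""Exception hierarchy.

All library errors derive from :class:`PpgwasError` so callers can catch one
base class; the CLI maps the subclasses onto distinct exit codes.
"""


class PpgwasError(Exception):
    """Base class for all errors raised by this package."""


class RingError(PpgwasError):
    """Shares from mismatched rings, malformed share tuples, missing hosts."""


class RangeError(PpgwasError, ValueError):
    """A secret or public constant falls outside the ring (or a contract bound)."""


class ProtocolError(PpgwasError):
    """A secure protocol was invoked with inconsistent inputs (e.g. a missing
    host store, or vectors of unequal length)."""


class ConfigurationError(PpgwasError):
    """A run-level configuration problem: triple exhaustion, a ring too narrow
    for the requested cohort size, an invalid significance level."""


class GenotypeImportError(PpgwasError):
    """Malformed genotype/phenotype input files; carries file coordinates."""


class CriterionError(PpgwasError):
    """A cohort inclusion criterion that cannot be parsed or does not match
    the phenotype schema."""


class StoreFormatError(PpgwasError):
    """A share-store file with a bad header, wrong version or truncated body."""
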