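"""Exception hierarchy.

Every error raised by this package derives from :class:`VcfSiftError`, so
callers (and the CLI) can distinguish domain errors from programming bugs.
"""


class VcfSiftError(Exception):
    """Base class for all errors raised by vcfsift."""


class InputError(VcfSiftError):
    """A required input file is missing or unreadable."""


class MalformedVcfError(VcfSiftError):
    """The file is structurally not a VCF (bad header section)."""


class MalformedRecordError(MalformedVcfError):
    """A data line violates the VCF column contract; message names the line."""


class GenotypeParseError(VcfSiftError):
    """A GT value does not follow genotype syntax."""


class CsqError(VcfSiftError):
    """A CSQ annotation block has more sub-values than the declared schema."""


class ConfigurationError(VcfSiftError):
    """An unknown field or sample name was requested."""


class StateError(VcfSiftError):
    """A workflow step was invoked before its prerequisite artifact exists."""


class ConsistencyError(VcfSiftError):
    """Filter history and engine state disagree (count chain broken)."""
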