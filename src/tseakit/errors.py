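"""Exception hierarchy for the toolkit.

Three broad failure classes: malformed input files, invalid configuration,
and violated call contracts (caller bugs). QC failures are never exceptions;
they are reported in :class:`~tseakit.qc.QCReport`.
"""


class TseaError(Exception):
    """Base class for all toolkit errors."""


class FormatError(TseaError):
    """An input file is malformed (empty, bad coordinates, duplicate keys...)."""


class ConfigurationError(TseaError):
    """A configuration value is missing or inconsistent with the data."""


class ContractError(TseaError):
    """A function precondition was violated by the caller."""
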