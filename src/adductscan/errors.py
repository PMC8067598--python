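"""Exception hierarchy: user-facing errors carry a stage/context message."""


class AdductScanError(Exception):
    """Base class for all package errors."""


class FormatError(AdductScanError):
    """The input file is not parseable under the named standard, or is
    profile-mode where centroided data are required."""


class StructureError(AdductScanError):
    """The file parses but is not a DIA run (no MS2 scans, missing isolation
    metadata, inconsistent cycle structure)."""


class ParameterError(AdductScanError):
    """A parameter value violates its contract."""
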