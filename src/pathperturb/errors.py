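"""Exception hierarchy shared across the pipeline."""


class PathPerturbError(Exception):
    """Base class for all errors raised by pathperturb."""


class FormatError(PathPerturbError):
    """A file violates its expected on-disk format (bad cell, duplicate id, malformed line)."""


class ConfigError(PathPerturbError):
    """Inconsistent or incomplete run configuration (e.g. unlabelled sample)."""


class ParameterError(PathPerturbError, ValueError):
    """An argument is outside the domain an operation is defined on."""
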