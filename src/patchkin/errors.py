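"""Exception types shared across the package."""


class PatchkinError(Exception):
    """Base class for all package errors."""


class SchemeError(PatchkinError, ValueError):
    """Invalid kinetic-scheme topology or rate set."""


class ConfigurationError(PatchkinError, ValueError):
    """Missing or inconsistent run-time configuration (ligands, filters...)."""


class FitError(PatchkinError, RuntimeError):
    """Numerical failure during likelihood evaluation or optimisation."""
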