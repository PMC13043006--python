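"""Exception hierarchy shared across the pipeline.

Exit codes distinguish configuration mistakes (bad parameter files,
unknown labels) from malformed input data and from runtime failures,
so shell callers can branch on the failure class.
"""


class PipelineError(Exception):
    """Base class for all package errors. CLI exit code 4."""

    exit_code = 4


class ConfigurationError(PipelineError):
    """Invalid configuration: bad CRF parameters, unknown scenario or SSP
    label, missing registry entry. CLI exit code 2."""

    exit_code = 2


class InputError(PipelineError):
    """Malformed or out-of-domain input data (negative concentration,
    nonpositive rate history, key mismatch). CLI exit code 3."""

    exit_code = 3
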