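"""Exception hierarchy shared by all pdsense modules.

``ParameterError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class PdsenseError(Exception):
    """Base class for all pdsense errors."""


class ParameterError(PdsenseError, ValueError):
    """A configuration value or function argument is invalid."""


class DataError(PdsenseError, RuntimeError):
    """Input data is malformed, inconsistent or insufficient."""
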