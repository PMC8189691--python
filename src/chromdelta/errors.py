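"""Exception hierarchy.

``ValidationError`` covers violated statistical or structural preconditions
(CLI exit code 2); ``InputError`` covers malformed or missing input files
(CLI exit code 3).
"""


class ChromdeltaError(Exception):
    """Base class for all package errors."""


class ValidationError(ChromdeltaError, ValueError):
    """A structural invariant or statistical assumption is violated."""


class AssumptionError(ValidationError):
    """The scoring system fails the local-score applicability assumptions."""


class InputError(ChromdeltaError, ValueError):
    """An input file is malformed or inconsistent with the dataset."""
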