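"""Exception hierarchy.

ValidationError signals malformed or inconsistent *input* (bad Newick,
duplicate labels, shape mismatches); DataError signals conditions that arise
from otherwise well-formed data (all samples filtered out, no OOB sample).
The CLI maps ValidationError to exit code 2 and DataError to 3.
"""


class PIRFError(Exception):
    """Base class for all package errors."""


class ValidationError(PIRFError, ValueError):
    """Invalid user input or violated precondition."""


class DataError(PIRFError, RuntimeError):
    """Well-formed input that cannot be processed (e.g. everything filtered)."""
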