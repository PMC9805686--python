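"""Exception hierarchy.

``DataError`` marks problems with user-supplied data (malformed tables,
infeasible requests); the CLI maps it to exit code 3, while usage errors
(bad flags) exit 2 via click.
"""


class PhenoCompareError(Exception):
    """Base class for package errors."""


class DataError(PhenoCompareError):
    """Invalid or infeasible input data."""
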