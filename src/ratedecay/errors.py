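"""Exception hierarchy.

Exit codes used by the command-line interface are attached here so that
library users and the CLI agree on the severity classes: schema problems
(wrong columns, unreadable table layout) are distinct from row-level
validation problems (bad values), which are distinct from runtime failures.
"""


class RateDecayError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(RateDecayError):
    """The input table does not have the expected columns/layout."""

    exit_code = 2


class ValidationError(RateDecayError):
    """A record or group of records violates a data invariant."""

    exit_code = 3


class DegenerateFitError(RateDecayError):
    """A regression was requested on data that cannot support one."""

    exit_code = 3
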