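"""Exception hierarchy shared across the pipeline.

Input-side problems (bad files, bad parameters, bad calibration) map to CLI
exit code 2; degenerate-data problems (no tissue, zero variance) map to 3.
"""


class CPCQuantError(Exception):
    """Base class for all package errors."""

    exit_code = 2


class ParameterError(CPCQuantError):
    """A parameter is outside its documented range."""


class FormatError(CPCQuantError):
    """An input file does not match the expected layout."""


class CalibrationError(CPCQuantError):
    """White-reference / background calibration failed."""


class StainBasisError(CPCQuantError):
    """The stain basis matrix is invalid or singular."""


class PlacementError(CPCQuantError):
    """Synthetic signals could not be placed within the retry budget."""


class NoTissueError(CPCQuantError):
    """An operation that needs tissue received an empty mask."""

    exit_code = 3


class DegenerateDataError(CPCQuantError):
    """Statistics cannot be computed (e.g. all values identical)."""

    exit_code = 3
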