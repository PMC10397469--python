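"""Exception hierarchy for midkit.

Every error raised on a statistical precondition derives from
:class:`MidkitError`, so pipeline code can trap estimation failures per cell
without masking programming errors.
"""


class MidkitError(Exception):
    """Base class for all midkit errors."""


class ConfigError(MidkitError):
    """Invalid metric/anchor definition or simulation configuration."""


class GroupTooSmallError(MidkitError):
    """A patient group is too small for the requested estimator."""


class DegenerateDataError(MidkitError):
    """Zero-variance or otherwise degenerate input series."""


class NotDefinedError(MidkitError):
    """The requested quantity does not exist for this anchor/direction.

    The canonical case is an improvement MID under the mortality anchor:
    there is no "improved" group among survivors vs non-survivors.
    """
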