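"""Exception hierarchy for fermkin.

All package errors derive from :class:`FermkinError` so callers can catch
everything with one clause; the subclasses additionally derive from the
matching builtin (``ValueError`` / ``RuntimeError``) so generic handling
keeps working.
"""


class FermkinError(Exception):
    """Base class for all fermkin errors."""


class InvalidInputError(FermkinError, ValueError):
    """An argument is malformed: non-finite, wrong shape, wrong protocol."""


class RangeError(FermkinError, ValueError):
    """A value left its physically valid range (temperature window,
    non-positive temperature-adjusted parameter, negative time)."""


class ConfigError(InvalidInputError):
    """A configuration file failed validation; the message names the key."""


class IntegrationError(FermkinError, RuntimeError):
    """The ODE solver failed or produced a physically impossible state."""


class OptimizationError(FermkinError, RuntimeError):
    """The particle swarm could not make progress (e.g. the objective is
    non-finite on most of the search box)."""


class MetricError(FermkinError, RuntimeError):
    """A response metric is ill-defined on the given trajectory."""
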