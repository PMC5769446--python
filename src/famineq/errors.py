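"""Exception hierarchy.

All famineq errors derive from :class:`FamineqError` so callers can catch
everything with one clause; the subclasses distinguish plain parameter-domain
violations from structural infeasibility (no model attains the inputs) and
degeneracy (the inputs pin a boundary model with unidentifiable parameters).
"""


class FamineqError(ValueError):
    """Base class for all famineq errors."""


class DomainError(FamineqError):
    """A parameter lies outside its mathematical domain (e.g. q outside (0,1))."""


class InfeasibleError(FamineqError):
    """No model in the family attains the requested inputs."""


class DegenerateError(FamineqError):
    """The inputs imply a degenerate (boundary) model with unidentifiable parameters."""


class UndefinedEstimateError(FamineqError):
    """An empirical estimate is undefined because the conditioning event never occurred."""
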