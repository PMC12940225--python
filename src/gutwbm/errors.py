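"""Exception hierarchy for gutwbm.

All package errors derive from :class:`GutWbmError` so callers can catch one
base class; the subclasses mirror the failure modes of the pipeline stages.
"""


class GutWbmError(Exception):
    """Base class for all gutwbm errors."""


class ConfigError(GutWbmError):
    """Invalid synthetic-cohort or pipeline configuration."""


class InputError(GutWbmError):
    """Malformed or inconsistent input data (tables, abundances)."""


class AssemblyError(GutWbmError):
    """Model construction failed (conflicting stoichiometry, missing biomass)."""


class StructuralError(GutWbmError):
    """A model lacks a structural prerequisite (compartment, reaction)."""


class SolverError(GutWbmError):
    """The LP backend reported a failure that is not a clean status."""
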