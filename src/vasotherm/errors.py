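"""Exception hierarchy."""


class VasothermError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VasothermError):
    """Invalid problem definition (domain, tree, or parameter files)."""


class CouplingError(VasothermError):
    """Terminal/voxel coupling cannot be built (e.g. empty sphere of influence)."""


class AssemblyError(VasothermError):
    """Linear-system assembly failed (singular structure, isolated unknowns)."""


class SolverError(VasothermError):
    """Iterative solver failed to converge."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history if residual_history is not None else []
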