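"""Exception hierarchy shared across the package."""


class IggAllosteryError(Exception):
    """Base class for all package-specific errors."""


class TopologyError(IggAllosteryError):
    """Atom/residue bookkeeping inconsistent with a trajectory or file."""


class ConfigurationError(IggAllosteryError):
    """A domain map, selection or analysis config could not be resolved."""


class DegenerateGeometryError(IggAllosteryError):
    """Coincident or collinear points make a descriptor undefined."""


class SpecError(IggAllosteryError):
    """A synthetic-data or sweep specification is infeasible or contradictory."""
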